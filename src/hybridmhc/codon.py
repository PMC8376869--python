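"""Codon-level substitution machinery for the GY94 family of models.

The 61 sense codons of the standard genetic code are indexed in fixed
lexicographic order (TCAG alphabet order is *not* used; plain ACGT order
keeps the table readable).  Rate matrices follow Goldman-Yang/Muse-Gaut
conventions: only single-nucleotide changes have nonzero rate, transitions
are scaled by kappa and nonsynonymous changes by omega, and the target
codon's equilibrium frequency multiplies every rate (GY94 style).
"""

from __future__ import annotations

import numpy as np
from Bio.Data import CodonTable

NUCS = "ACGT"
NUC_INDEX = {n: i for i, n in enumerate(NUCS)}

_standard = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = tuple(sorted(_standard.stop_codons))
CODONS = tuple(
    a + b + c
    for a in NUCS
    for b in NUCS
    for c in NUCS
    if a + b + c not in _standard.stop_codons
)
N_CODONS = len(CODONS)  # 61
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
CODON_AA = tuple(_standard.forward_table[c] for c in CODONS)

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def _single_change_pairs():
    """Precompute (i, j, is_transition, is_synonymous) for one-step codon pairs."""
    pairs = []
    for i, ci in enumerate(CODONS):
        for j, cj in enumerate(CODONS):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            ts = diffs[0] in _TRANSITIONS
            syn = CODON_AA[i] == CODON_AA[j]
            pairs.append((i, j, ts, syn))
    return pairs

_PAIRS = _single_change_pairs()
_PAIR_I = np.array([p[0] for p in _PAIRS])
_PAIR_J = np.array([p[1] for p in _PAIRS])
_PAIR_TS = np.array([p[2] for p in _PAIRS])
_PAIR_SYN = np.array([p[3] for p in _PAIRS])


def equal_frequencies() -> np.ndarray:
    return np.full(N_CODONS, 1.0 / N_CODONS)


def _codon_freqs_from_nuc(nuc_freqs: np.ndarray) -> np.ndarray:
    """Codon frequencies proportional to the product of per-position
    nucleotide frequencies, renormalized over sense codons.

    ``nuc_freqs`` is (3, 4) for F3x4 or (4,) broadcast for F1x4.
    """
    nf = np.asarray(nuc_freqs, dtype=float)
    if nf.ndim == 1:
        nf = np.tile(nf, (3, 1))
    freqs = np.array(
        [nf[0, NUC_INDEX[c[0]]] * nf[1, NUC_INDEX[c[1]]] * nf[2, NUC_INDEX[c[2]]]
         for c in CODONS]
    )
    total = freqs.sum()
    if total <= 0:
        raise ValueError("degenerate nucleotide frequencies")
    return freqs / total


def f3x4_frequencies(codon_rows) -> np.ndarray:
    """F3x4 equilibrium codon frequencies from observed codon columns.

    ``codon_rows``: iterable of codon strings (the alignment flattened).
    """
    counts = np.zeros((3, 4))
    for codon in codon_rows:
        for pos, nuc in enumerate(codon):
            if nuc in NUC_INDEX:
                counts[pos, NUC_INDEX[nuc]] += 1
    counts += 1e-9
    return _codon_freqs_from_nuc(counts / counts.sum(axis=1, keepdims=True))


def f1x4_frequencies(codon_rows) -> np.ndarray:
    counts = np.zeros(4)
    for codon in codon_rows:
        for nuc in codon:
            if nuc in NUC_INDEX:
                counts[NUC_INDEX[nuc]] += 1
    counts += 1e-9
    return _codon_freqs_from_nuc(counts / counts.sum())


def empirical_frequencies(codon_rows) -> np.ndarray:
    counts = np.zeros(N_CODONS)
    for codon in codon_rows:
        if codon in CODON_INDEX:
            counts[CODON_INDEX[codon]] += 1
    counts += 1e-6  # avoid structural zeros that disconnect the chain
    return counts / counts.sum()


def codon_rate_matrix(
    kappa: float,
    omega: float,
    codon_freqs: np.ndarray,
    normalize: bool = True,
) -> np.ndarray:
    """GY94 61x61 generator.

    Off-diagonal rate for a single-nucleotide change i->j is
    pi_j * (kappa if transition) * (omega if nonsynonymous); zero for
    multi-nucleotide changes.  Rows sum to zero.  With ``normalize`` the
    matrix is scaled so the expected rate at equilibrium is one
    substitution per codon per unit branch length.
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    if omega < 0:
        raise ValueError("omega must be nonnegative")
    pi = np.asarray(codon_freqs, dtype=float)
    if pi.shape != (N_CODONS,):
        raise ValueError(f"codon_freqs must have length {N_CODONS}")
    if abs(pi.sum() - 1.0) > 1e-8:
        raise ValueError("codon_freqs must sum to 1 over sense codons")
    Q = np.zeros((N_CODONS, N_CODONS))
    rates = pi[_PAIR_J] * np.where(_PAIR_TS, kappa, 1.0) * np.where(_PAIR_SYN, 1.0, omega)
    Q[_PAIR_I, _PAIR_J] = rates
    np.fill_diagonal(Q, -Q.sum(axis=1))
    if normalize:
        mean_rate = -np.dot(pi, np.diag(Q))
        if mean_rate > 0:
            Q /= mean_rate
    return Q


def mean_rate(kappa: float, omega: float, codon_freqs: np.ndarray) -> float:
    """Expected substitutions/codon/unit-time of the *unnormalized* generator."""
    Q = codon_rate_matrix(kappa, omega, codon_freqs, normalize=False)
    return float(-np.dot(codon_freqs, np.diag(Q)))


class CodonPropagator:
    """Eigendecomposition cache turning one generator into P(t) for many t.

    The GY94 chain is reversible, so D^{1/2} Q D^{-1/2} is symmetric and a
    single `eigh` yields numerically stable transition matrices for every
    branch length.
    """

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        self.pi = pi
        sqrt_pi = np.sqrt(np.clip(pi, 1e-300, None))
        S = (sqrt_pi[:, None] * Q) / sqrt_pi[None, :]
        S = 0.5 * (S + S.T)
        self.evals, self.evecs = np.linalg.eigh(S)
        self._left = self.evecs / sqrt_pi[:, None]
        self._right = (self.evecs * sqrt_pi[:, None]).T

    def transition_matrix(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError("branch length must be nonnegative")
        P = (self._left * np.exp(self.evals * t)) @ self._right
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P
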