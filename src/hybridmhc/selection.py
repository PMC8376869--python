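"""Random-site codon models of positive selection (M0-M8), LRTs and BEB.

The models are the GY94 random-site family: every codon site draws its
dN/dS ratio omega from a small mixture distribution shared across sites.

==========  =======================================================
model       omega distribution
==========  =======================================================
M0          single omega
M1a         p0 at omega0 < 1, p1 = 1 - p0 at omega1 = 1
M2a         M1a plus p2 at omega2 >= 1
M3          K = 3 free discrete classes
M7          Beta(p, q) on (0, 1), 10 equal-probability categories
M8          p0 Beta(p, q) + (1 - p0) at omega_s >= 1  (11 classes)
==========  =======================================================

Positive selection is tested by likelihood-ratio tests of nested pairs
(M1a/M2a, M0/M3, M7/M8) and localized with the Bayes empirical Bayes
(BEB) scheme: the mixture parameters are integrated over a uniform prior
grid instead of being fixed at their MLEs, which protects the per-site
posteriors against sampling error in small data sets.

Branch lengths are measured in expected substitutions per codon under the
fitted mixture; a single free scale factor adapts a user-supplied or NJ
tree to each model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

from .codon import (
    CODON_INDEX,
    CODONS,
    CODON_AA,
    N_CODONS,
    CodonPropagator,
    codon_rate_matrix,
    empirical_frequencies,
    equal_frequencies,
    f1x4_frequencies,
    f3x4_frequencies,
)
from .phylo import PhyloTree, PruningEngine, jc69_codon_distances, nj_tree

SITE_MODELS = ("M0", "M1a", "M2a", "M3", "M7", "M8")
NESTED_PAIRS = {("M1a", "M2a"): 2, ("M0", "M3"): 4, ("M7", "M8"): 2}
N_BETA_CATEGORIES = 10


# ---------------------------------------------------------------------------
# alignment container

@dataclass
class CodonAlignment:
    """Aligned in-frame codon sequences; -1 encodes a missing/ambiguous codon."""

    names: list[str]
    codons: np.ndarray

    def __post_init__(self):
        self.codons = np.asarray(self.codons, dtype=int)
        if self.codons.ndim != 2 or len(self.names) != self.codons.shape[0]:
            raise ValueError("codon matrix must be (n_taxa, n_codons)")

    @property
    def n_taxa(self) -> int:
        return self.codons.shape[0]

    @property
    def n_codons(self) -> int:
        return self.codons.shape[1]

    def codon_string(self, i: int, h: int) -> str:
        idx = self.codons[i, h]
        return CODONS[idx] if idx >= 0 else "NNN"

    def nucleotide_sequences(self) -> list[str]:
        return ["".join(self.codon_string(i, h) for h in range(self.n_codons))
                for i in range(self.n_taxa)]

    def amino_acid_sequences(self) -> list[str]:
        out = []
        for i in range(self.n_taxa):
            out.append("".join(CODON_AA[c] if c >= 0 else "X"
                               for c in self.codons[i]))
        return out

    def all_codon_strings(self):
        for i in range(self.n_taxa):
            for h in range(self.n_codons):
                idx = self.codons[i, h]
                if idx >= 0:
                    yield CODONS[idx]


def translate_and_check(records, frame: int = 0) -> CodonAlignment:
    """Build a checked CodonAlignment from aligned nucleotide sequences.

    ``records``: iterable of (name, sequence).  Sequences must share one
    length divisible by 3 after the frame offset; any internal stop codon
    is rejected naming the sequence and codon index.
    """
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    names, seqs = [], []
    for name, seq in records:
        names.append(str(name))
        seqs.append(str(seq).upper().replace("U", "T")[frame:])
    if not names:
        raise ValueError("no sequences supplied")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("sequences are not aligned to a single length")
    L = lengths.pop()
    if L % 3 != 0:
        raise ValueError(f"alignment length {L} not divisible by 3 after frame offset")
    n_codons = L // 3
    mat = np.full((len(seqs), n_codons), -1, dtype=int)
    for i, seq in enumerate(seqs):
        for h in range(n_codons):
            codon = seq[3 * h: 3 * h + 3]
            if codon in CODON_INDEX:
                mat[i, h] = CODON_INDEX[codon]
            elif set(codon) <= set("ACGT"):
                raise ValueError(
                    f"internal stop codon {codon} in '{names[i]}' at codon {h + 1}")
    return CodonAlignment(names=names, codons=mat)


def build_nj_tree(alignment: CodonAlignment) -> PhyloTree:
    """NJ tree on JC69-corrected nucleotide distances (per-codon units)."""
    if alignment.n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    D = jc69_codon_distances(alignment.nucleotide_sequences())
    return nj_tree(alignment.names, D / max(alignment.n_codons, 1))


def codon_frequencies(alignment: CodonAlignment, mode: str = "F3x4") -> np.ndarray:
    codons = alignment.all_codon_strings()
    if mode == "Fequal":
        return equal_frequencies()
    if mode == "F1x4":
        return f1x4_frequencies(codons)
    if mode == "F3x4":
        return f3x4_frequencies(codons)
    if mode == "empirical":
        return empirical_frequencies(codons)
    raise ValueError(f"unknown codon frequency mode: {mode}")


# ---------------------------------------------------------------------------
# model parameterization (unconstrained <-> natural)

def _sigmoid(x):
    return special.expit(x)


def _logit(p):
    p = np.clip(p, 1e-9, 1 - 1e-9)
    return np.log(p / (1 - p))


def _stick_to_probs(a):
    """Stick-breaking logits -> K+1 probabilities."""
    probs = []
    rest = 1.0
    for x in a:
        p = _sigmoid(x) * rest
        probs.append(p)
        rest -= p
    probs.append(rest)
    return np.clip(np.array(probs), 1e-12, 1.0)


def _probs_to_stick(p):
    a = []
    rest = 1.0
    for pk in p[:-1]:
        a.append(_logit(pk / max(rest, 1e-12)))
        rest -= pk
    return a


_CLIP_BETA = (0.005, 99.0)


def beta_category_omegas(p: float, q: float, k: int = N_BETA_CATEGORIES) -> np.ndarray:
    """Means of k equal-probability categories of Beta(p, q)."""
    p = float(np.clip(p, *_CLIP_BETA))
    q = float(np.clip(q, *_CLIP_BETA))
    edges = stats.beta.ppf(np.linspace(0.0, 1.0, k + 1), p, q)
    upper = special.betainc(p + 1.0, q, edges)
    means = (upper[1:] - upper[:-1]) * k * p / (p + q)
    return np.clip(means, 1e-8, 1.0 - 1e-8)


def _n_free(model: str) -> int:
    return {"M0": 1, "M1a": 2, "M2a": 4, "M3": 5, "M7": 2, "M8": 4}[model]


def _decode(model: str, theta: np.ndarray):
    """theta -> (kappa, scale, class_probs, class_omegas, params dict)."""
    kappa = float(np.exp(np.clip(theta[0], -5, 6)))
    scale = float(np.exp(np.clip(theta[1], -12, 8)))
    rest = theta[2:]
    if model == "M0":
        w = float(np.exp(np.clip(rest[0], -12, 5)))
        return kappa, scale, np.array([1.0]), np.array([w]), {"omega": w}
    if model == "M1a":
        p0 = float(_sigmoid(rest[0]))
        w0 = float(_sigmoid(rest[1]))
        return (kappa, scale, np.array([p0, 1 - p0]), np.array([w0, 1.0]),
                {"p0": p0, "omega0": w0})
    if model == "M2a":
        probs = _stick_to_probs(rest[:2])
        w0 = float(_sigmoid(rest[2]))
        w2 = 1.0 + float(np.exp(np.clip(rest[3], -12, 5)))
        return (kappa, scale, probs, np.array([w0, 1.0, w2]),
                {"p0": probs[0], "p1": probs[1], "p2": probs[2],
                 "omega0": w0, "omega2": w2})
    if model == "M3":
        probs = _stick_to_probs(rest[:2])
        ws = np.exp(np.clip(rest[2:5], -12, 5))
        order = np.argsort(ws)
        return (kappa, scale, probs[order], ws[order],
                {"proportions": probs[order].tolist(), "omegas": ws[order].tolist()})
    if model == "M7":
        p = float(np.clip(np.exp(rest[0]), *_CLIP_BETA))
        q = float(np.clip(np.exp(rest[1]), *_CLIP_BETA))
        omegas = beta_category_omegas(p, q)
        probs = np.full(N_BETA_CATEGORIES, 1.0 / N_BETA_CATEGORIES)
        return kappa, scale, probs, omegas, {"p": p, "q": q}
    if model == "M8":
        p0 = float(_sigmoid(rest[0]))
        p = float(np.clip(np.exp(rest[1]), *_CLIP_BETA))
        q = float(np.clip(np.exp(rest[2]), *_CLIP_BETA))
        ws = 1.0 + float(np.exp(np.clip(rest[3], -12, 5)))
        omegas = np.append(beta_category_omegas(p, q), ws)
        probs = np.append(np.full(N_BETA_CATEGORIES, p0 / N_BETA_CATEGORIES), 1 - p0)
        return (kappa, scale, probs, omegas,
                {"p0": p0, "p": p, "q": q, "omega_s": ws})
    raise ValueError(f"unknown model {model}")


_DEFAULT_STARTS = {
    "M0": [np.log(0.4)],
    "M1a": [_logit(0.8), _logit(0.1)],
    "M2a": [_logit(0.7), _logit(0.2 / 0.3), _logit(0.1), np.log(2.0)],
    "M3": [_logit(1 / 3), _logit(0.5), np.log(0.05), np.log(0.5), np.log(2.5)],
    "M7": [np.log(0.5), np.log(1.5)],
    "M8": [_logit(0.9), np.log(0.5), np.log(1.5), np.log(2.0)],
}


def _start_vector(model: str, kappa: float = 2.0, scale: float = 1.0):
    return np.array([np.log(kappa), np.log(scale)] + _DEFAULT_STARTS[model])


def _embed_start(null_fit: "CodonFit", model: str) -> np.ndarray | None:
    """Start the alternative model at (a neighborhood of) the null MLE."""
    base = [np.log(null_fit.kappa), np.log(null_fit.scale)]
    p = null_fit.params
    if null_fit.model == "M1a" and model == "M2a":
        p0, p1 = p["p0"] * 0.99, (1 - p["p0"]) * 0.99
        return np.array(base + [_logit(p0), _logit(p1 / max(1 - p0, 1e-9)),
                                _logit(p["omega0"]), np.log(0.05)])
    if null_fit.model == "M0" and model == "M3":
        w = max(p["omega"], 1e-4)
        return np.array(base + [_logit(1 / 3), _logit(0.5),
                                np.log(w * 0.8), np.log(w), np.log(w * 1.2)])
    if null_fit.model == "M7" and model == "M8":
        return np.array(base + [_logit(0.99), np.log(p["p"]), np.log(p["q"]),
                                np.log(0.05)])
    return None


# ---------------------------------------------------------------------------
# likelihood

def _compress_patterns(codons: np.ndarray):
    patterns, inverse, counts = np.unique(
        codons, axis=1, return_inverse=True, return_counts=True)
    return patterns, inverse.ravel(), counts.astype(float)


class _Likelihood:
    """Mixture log-likelihood on compressed site patterns."""

    def __init__(self, alignment: CodonAlignment, tree: PhyloTree,
                 pi: np.ndarray):
        self.pi = pi
        self.tree = tree
        self.patterns, self.inverse, self.weights = _compress_patterns(
            alignment.codons)
        self.engine = PruningEngine(tree, self.patterns, alignment.names)
        self.n_sites = alignment.n_codons

    def class_site_logliks(self, kappa: float, omegas: np.ndarray,
                           eff_lengths: np.ndarray) -> np.ndarray:
        """(K, n_patterns) per-class pattern log-likelihoods.

        ``eff_lengths``: per-node branch lengths already on the generator's
        (unnormalized) time scale.
        """
        out = np.empty((len(omegas), self.patterns.shape[1]))
        for k, w in enumerate(omegas):
            Q = codon_rate_matrix(kappa, float(w), self.pi, normalize=False)
            prop = CodonPropagator(Q, self.pi)
            P_by_node = {int(nd): prop.transition_matrix(float(t))
                         for nd, t in enumerate(eff_lengths)
                         if self.tree.parent[nd] >= 0}
            out[k] = self.engine.site_log_likelihoods(P_by_node, self.pi)
        return out

    def mixture_loglik(self, kappa, scale, probs, omegas):
        rates = np.array([
            -np.dot(self.pi, np.diag(codon_rate_matrix(kappa, float(w), self.pi,
                                                       normalize=False)))
            for w in omegas])
        mean = float(np.dot(probs, rates))
        eff = self.tree.edge_length * scale / max(mean, 1e-12)
        site_logs = self.class_site_logliks(kappa, omegas, eff)
        mixed = special.logsumexp(site_logs + np.log(probs)[:, None], axis=0)
        return float(np.dot(self.weights, mixed)), mixed, eff

    def neg_loglik(self, theta, model):
        kappa, scale, probs, omegas, _ = _decode(model, theta)
        ll, _, _ = self.mixture_loglik(kappa, scale, probs, omegas)
        if not np.isfinite(ll):
            return 1e12
        return -ll


def site_log_likelihood(alignment: CodonAlignment, tree: PhyloTree,
                        kappa: float, scale: float,
                        class_probs: np.ndarray, class_omegas: np.ndarray,
                        pi: np.ndarray | None = None,
                        freq_mode: str = "F3x4") -> np.ndarray:
    """Per-site mixture log-likelihood vector (pruning algorithm)."""
    if pi is None:
        pi = codon_frequencies(alignment, freq_mode)
    lk = _Likelihood(alignment, tree, pi)
    _, mixed, _ = lk.mixture_loglik(kappa, scale, np.asarray(class_probs),
                                    np.asarray(class_omegas))
    return mixed[lk.inverse]


# ---------------------------------------------------------------------------
# fitting

@dataclass
class CodonFit:
    model: str
    lnL: float
    kappa: float
    scale: float
    class_probs: np.ndarray
    class_omegas: np.ndarray
    params: dict
    converged: bool
    n_starts: int
    freq_mode: str
    pi: np.ndarray
    eff_lengths: np.ndarray
    theta: np.ndarray = field(repr=False, default=None)
    _likelihood: "_Likelihood" = field(repr=False, default=None)

    def summary(self) -> dict:
        return {
            "model": self.model,
            "lnL": self.lnL,
            "kappa": self.kappa,
            "tree_scale": self.scale,
            "converged": self.converged,
            **{k: (v if not isinstance(v, np.ndarray) else v.tolist())
               for k, v in self.params.items()},
        }


def fit_site_model(alignment: CodonAlignment, tree: PhyloTree, model: str,
                   freq_mode: str = "F3x4", n_starts: int = 3,
                   seed: int = 0, init_from: CodonFit | None = None,
                   pi: np.ndarray | None = None, theta0: np.ndarray | None = None,
                   gtol: float = 1e-6) -> CodonFit:
    """Maximum-likelihood fit of one random-site model.

    Multi-start bounded quasi-Newton on log/logit-transformed parameters.
    ``init_from`` additionally seeds the optimizer at the embedding of a
    nested null fit, which guarantees nested-model lnL dominance in
    practice.
    """
    if model not in SITE_MODELS:
        raise ValueError(f"unknown model {model}; choose from {SITE_MODELS}")
    if pi is None:
        pi = codon_frequencies(alignment, freq_mode)
    lk = (init_from._likelihood
          if init_from is not None and init_from._likelihood is not None
          and init_from.freq_mode == freq_mode
          and init_from._likelihood.tree is tree
          else _Likelihood(alignment, tree, pi))
    rng = np.random.default_rng(seed)
    starts = [_start_vector(model)]
    if init_from is not None:
        emb = _embed_start(init_from, model)
        if emb is not None:
            starts.insert(0, emb)
    if theta0 is not None:
        starts = [np.asarray(theta0, dtype=float)] + starts[:max(n_starts - 1, 0)]
    base = starts[-1]
    while len(starts) < n_starts + (init_from is not None):
        starts.append(base + rng.normal(0, 0.75, size=base.shape))

    best = None
    for x0 in starts:
        res = optimize.minimize(lk.neg_loglik, x0, args=(model,),
                                method="L-BFGS-B",
                                options={"gtol": gtol, "maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
    if not best.success and best.fun >= 1e11:
        warnings.warn(f"{model} fit did not converge", RuntimeWarning)
    kappa, scale, probs, omegas, params = _decode(model, best.x)
    ll, _, eff = lk.mixture_loglik(kappa, scale, probs, omegas)
    fit = CodonFit(model=model, lnL=ll, kappa=kappa, scale=scale,
                   class_probs=probs, class_omegas=omegas, params=params,
                   converged=bool(best.success), n_starts=len(starts),
                   freq_mode=freq_mode, pi=pi, eff_lengths=eff,
                   theta=best.x, _likelihood=lk)
    return fit


def fit_model_series(alignment: CodonAlignment, tree: PhyloTree,
                     models=SITE_MODELS, freq_mode: str = "F3x4",
                     n_starts: int = 3, seed: int = 0) -> dict[str, CodonFit]:
    """Fit several site models, chaining nested starts (M0->M3 etc.)."""
    fits: dict[str, CodonFit] = {}
    nested_null = {"M2a": "M1a", "M3": "M0", "M8": "M7"}
    for model in models:
        null = fits.get(nested_null.get(model))
        fits[model] = fit_site_model(alignment, tree, model,
                                     freq_mode=freq_mode, n_starts=n_starts,
                                     seed=seed, init_from=null)
    return fits


def lrt(null_fit: CodonFit, alt_fit: CodonFit, tolerance: float = 1e-4):
    """Likelihood-ratio test of a properly nested model pair.

    Returns (2*delta_lnL clamped at 0, df, chi-square p-value).
    """
    pair = (null_fit.model, alt_fit.model)
    if pair not in NESTED_PAIRS:
        raise ValueError(f"models {pair} are not a supported nested pair")
    stat = 2.0 * (alt_fit.lnL - null_fit.lnL)
    if stat < -tolerance:
        warnings.warn(
            f"alternative {alt_fit.model} lnL below null {null_fit.model} "
            f"by {-stat / 2:.6f}; check convergence", RuntimeWarning)
    stat = max(stat, 0.0)
    df = NESTED_PAIRS[pair]
    p = float(stats.chi2.sf(stat, df))
    return stat, df, p


# ---------------------------------------------------------------------------
# Bayes empirical Bayes

@dataclass
class BEBResult:
    p_positive: np.ndarray
    post_mean_omega: np.ndarray
    pss_95: list[int]
    pss_99: list[int]

    def pss(self, level: float = 0.95) -> list[int]:
        return [int(h) + 1 for h in np.flatnonzero(self.p_positive > level)]


def _grid_midpoints(lo: float, hi: float, k: int) -> np.ndarray:
    return lo + (hi - lo) * (np.arange(k) + 0.5) / k


def beb_site_posteriors(fit: CodonFit, grid_points: int = 10) -> BEBResult:
    """BEB per-site posteriors of the positive class under M2a or M8.

    Branch lengths and kappa stay at their MLEs; the mixture parameters
    are integrated over a uniform prior grid (``grid_points`` per free
    dimension): omega0 ~ U(0,1), omega2/omega_s ~ U(1,11), proportions
    uniform on the simplex (M2a) or p0 ~ U(0,1) with Beta p, q ~ U(0,2)
    (M8).
    """
    if fit.model not in ("M2a", "M8"):
        raise ValueError("BEB is defined for M2a and M8 fits")
    lk = fit._likelihood
    if lk is None:
        raise ValueError("fit lacks its likelihood context")
    G = grid_points
    kappa, eff = fit.kappa, fit.eff_lengths
    weights = lk.weights
    npat = lk.patterns.shape[1]

    def loglik_for(omegas: np.ndarray) -> np.ndarray:
        return lk.class_site_logliks(kappa, np.asarray(omegas), eff)

    if fit.model == "M2a":
        w0_grid = _grid_midpoints(0, 1, G)
        w2_grid = _grid_midpoints(1, 11, G)
        f_w0 = loglik_for(w0_grid)            # (G, npat)
        f_1 = loglik_for(np.array([1.0]))[0]  # (npat,)
        f_w2 = loglik_for(w2_grid)
        p_grid = _grid_midpoints(0, 1, G)
        thetas, log_m, post_pos, post_mean = [], [], [], []
        for i0, p0 in enumerate(p_grid):
            for i1, p1 in enumerate(p_grid):
                if p0 + p1 > 1.0:
                    continue
                p2 = 1.0 - p0 - p1
                for a, w0 in enumerate(w0_grid):
                    for b, w2 in enumerate(w2_grid):
                        comps = np.stack([np.log(max(p0, 1e-300)) + f_w0[a],
                                          np.log(max(p1, 1e-300)) + f_1,
                                          np.log(max(p2, 1e-300)) + f_w2[b]])
                        mix = special.logsumexp(comps, axis=0)
                        r = np.exp(comps - mix)
                        log_m.append(float(np.dot(weights, mix)))
                        post_pos.append(r[2])
                        post_mean.append(r[0] * w0 + r[1] * 1.0 + r[2] * w2)
        log_m = np.array(log_m)
        wts = np.exp(log_m - special.logsumexp(log_m))
        p_pos_pat = np.tensordot(wts, np.stack(post_pos), axes=1)
        mean_pat = np.tensordot(wts, np.stack(post_mean), axes=1)
    else:  # M8
        p_grid = _grid_midpoints(*_M8_PQ_RANGE, G)
        q_grid = _grid_midpoints(*_M8_PQ_RANGE, G)
        ws_grid = _grid_midpoints(1, 11, G)
        p0_grid = _grid_midpoints(0, 1, G)
        f_ws = loglik_for(ws_grid)  # (G, npat)
        p_pos_num = np.zeros(npat)
        mean_num = np.zeros(npat)
        log_m_all, pos_all, mean_all = [], [], []
        for p in p_grid:
            for q in q_grid:
                betas = beta_category_omegas(p, q)
                f_beta = loglik_for(betas)  # (10, npat)
                lb = special.logsumexp(f_beta, axis=0) - np.log(len(betas))
                mean_beta_num = special.logsumexp(
                    f_beta, axis=0, b=(betas / len(betas))[:, None])
                for p0 in p0_grid:
                    for s, ws in enumerate(ws_grid):
                        mix = np.logaddexp(np.log(p0) + lb,
                                           np.log(1 - p0) + f_ws[s])
                        r_pos = np.exp(np.log(1 - p0) + f_ws[s] - mix)
                        mean_h = (p0 * np.exp(mean_beta_num - mix)
                                  + r_pos * ws)
                        log_m_all.append(float(np.dot(weights, mix)))
                        pos_all.append(r_pos)
                        mean_all.append(mean_h)
        log_m = np.array(log_m_all)
        wts = np.exp(log_m - special.logsumexp(log_m))
        p_pos_pat = np.tensordot(wts, np.stack(pos_all), axes=1)
        mean_pat = np.tensordot(wts, np.stack(mean_all), axes=1)

    p_pos = p_pos_pat[lk.inverse]
    mean_w = mean_pat[lk.inverse]
    res = BEBResult(p_positive=p_pos, post_mean_omega=mean_w,
                    pss_95=[], pss_99=[])
    res.pss_95 = res.pss(0.95)
    res.pss_99 = res.pss(0.99)
    return res


_M8_PQ_RANGE = (0.0, 2.0)


def compare_pss_sets(pss_by_group: dict[str, list[int]],
                     alignment_length: int | None = None) -> dict:
    """Shared/unique positively selected site sets across host groups."""
    groups = list(pss_by_group)
    sets = {g: set(pss_by_group[g]) for g in groups}
    if alignment_length is not None:
        for g, s in sets.items():
            bad = [h for h in s if not (1 <= h <= alignment_length)]
            if bad:
                raise ValueError(f"PSS {bad} of group {g} outside alignment")
    all_shared = set.intersection(*sets.values()) if sets else set()
    out = {"all_shared": sorted(all_shared), "pairwise_exclusive": {},
           "unique": {}}
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1:]:
            excl = sets[g1] & sets[g2]
            for other in groups:
                if other not in (g1, g2):
                    excl -= sets[other]
            out["pairwise_exclusive"][f"{g1}&{g2}"] = sorted(excl)
    for g in groups:
        uniq = set(sets[g])
        for other in groups:
            if other != g:
                uniq -= sets[other]
        out["unique"][g] = sorted(uniq)
    return out
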