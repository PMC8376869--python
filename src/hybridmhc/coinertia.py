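"""Co-inertia analysis (COIA) between MHC and parasite matrices.

Follows the duality-diagram construction: the binary MHC table is
analyzed by correspondence analysis (CA), the parasite table by a PCA
weighted with the CA row masses, and the two ordinations are coupled by
a singular value decomposition of their weighted cross-covariance.  The
global co-structure is the RV coefficient, tested by Monte-Carlo row
permutation of the parasite table (the CA row weights stay attached to
the MHC rows, preserving that triplet under the null).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import GenotypeTable, ParasiteMatrix


@dataclass
class Triplet:
    """Statistical triplet (table, column weights, row weights)."""

    table: pd.DataFrame
    col_weights: np.ndarray
    row_weights: np.ndarray

    def crossprod(self) -> np.ndarray:
        """Q^{1/2} Z^T D Z Q^{1/2} — the weighted scatter."""
        Z = self.table.values
        qs = np.sqrt(self.col_weights)
        return (qs[:, None] * (Z.T * self.row_weights) @ Z) * qs[None, :]

    @property
    def total_inertia(self) -> float:
        Z = self.table.values
        return float(np.sum(self.row_weights[:, None] * Z ** 2
                            * self.col_weights[None, :]))


def correspondence_analysis(table: pd.DataFrame) -> Triplet:
    """CA triplet of a nonnegative (typically 0/1) table.

    All-zero rows/columns are dropped with a report in ``.attrs``.  The
    table is transformed to P/(r c^T) - 1 with row masses r as row
    weights and column masses c as column weights; its total inertia is
    chi-square / grand total.
    """
    N = table.astype(float)
    zero_rows = N.index[N.sum(axis=1) == 0]
    zero_cols = N.columns[N.sum(axis=0) == 0]
    N = N.drop(index=zero_rows, columns=zero_cols)
    total = float(N.values.sum())
    if total <= 0:
        raise ValueError("zero grand total in CA table")
    P = N.values / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    Z = P / np.outer(r, c) - 1.0
    trip = Triplet(pd.DataFrame(Z, index=N.index, columns=N.columns), c, r)
    trip.table.attrs["dropped_rows"] = list(zero_rows)
    trip.table.attrs["dropped_cols"] = list(zero_cols)
    return trip


def weighted_pca(table: pd.DataFrame, row_weights: np.ndarray,
                 scale: bool = False, log1p: bool = False) -> Triplet:
    """Column-centered (optionally scaled) PCA triplet with given row weights."""
    if table.shape[1] < 2:
        raise ValueError("weighted PCA needs at least 2 columns")
    w = np.asarray(row_weights, dtype=float)
    if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-8:
        raise ValueError("row weights must be nonnegative and sum to 1")
    Y = table.values.astype(float)
    if log1p:
        Y = np.log1p(Y)
    mean = w @ Y
    Yc = Y - mean
    if scale:
        sd = np.sqrt(w @ (Yc ** 2))
        sd[sd == 0] = 1.0
        Yc = Yc / sd
    return Triplet(pd.DataFrame(Yc, index=table.index, columns=table.columns),
                   np.ones(Y.shape[1]), w)


def triplet_eigen(trip: Triplet):
    """Eigenvalues and axes of one triplet (weighted SVD)."""
    Z = trip.table.values
    A = (np.sqrt(trip.row_weights)[:, None] * Z
         * np.sqrt(trip.col_weights)[None, :])
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    return s ** 2, U, Vt


@dataclass
class CoinertiaResult:
    eigenvalues: np.ndarray
    percent: np.ndarray
    total_coinertia: float
    rv: float
    row_scores_x: pd.DataFrame
    row_scores_y: pd.DataFrame
    col_loadings_x: pd.DataFrame
    col_loadings_y: pd.DataFrame
    p_value: float | None = None
    n_permutations: int | None = None


def _cross_matrix(tx: Triplet, ty: Triplet) -> np.ndarray:
    X, Y = tx.table.values, ty.table.values
    qx = np.sqrt(tx.col_weights)
    qy = np.sqrt(ty.col_weights)
    return (qx[:, None] * (X.T * tx.row_weights) @ Y) * qy[None, :]


def rv_coefficient(tx: Triplet, ty: Triplet) -> float:
    """RV = total co-inertia / (||S_X||_F ||S_Y||_F); 1 when Y = X."""
    K = _cross_matrix(tx, ty)
    nx = np.linalg.norm(tx.crossprod())
    ny = np.linalg.norm(ty.crossprod())
    if nx == 0 or ny == 0:
        raise ValueError("RV undefined for a constant matrix")
    return float(np.sum(K ** 2) / (nx * ny))


def coinertia(tx: Triplet, ty: Triplet) -> CoinertiaResult:
    """Couple two triplets sharing rows and row weights."""
    if not tx.table.index.equals(ty.table.index):
        raise ValueError("triplets must share the same row set")
    if not np.allclose(tx.row_weights, ty.row_weights):
        raise ValueError("triplets must share row weights")
    K = _cross_matrix(tx, ty)
    U, s, Vt = np.linalg.svd(K, full_matrices=False)
    eig = s ** 2
    total = float(eig.sum())
    percent = 100.0 * eig / total if total > 0 else np.zeros_like(eig)
    ax = np.sqrt(tx.col_weights)[:, None] * U      # co-inertia axes, X side
    ay = np.sqrt(ty.col_weights)[:, None] * Vt.T
    naxes = min(5, len(s))
    cols = [f"F{i + 1}" for i in range(naxes)]
    res = CoinertiaResult(
        eigenvalues=eig, percent=percent, total_coinertia=total,
        rv=rv_coefficient(tx, ty),
        row_scores_x=pd.DataFrame(tx.table.values @ (tx.col_weights[:, None]
                                                     * ax)[:, :naxes],
                                  index=tx.table.index, columns=cols),
        row_scores_y=pd.DataFrame(ty.table.values @ (ty.col_weights[:, None]
                                                     * ay)[:, :naxes],
                                  index=ty.table.index, columns=cols),
        col_loadings_x=pd.DataFrame(ax[:, :naxes], index=tx.table.columns,
                                    columns=cols),
        col_loadings_y=pd.DataFrame(ay[:, :naxes], index=ty.table.columns,
                                    columns=cols),
    )
    return res


def rv_test(tx: Triplet, ty: Triplet, n_perm: int = 999,
            seed: int = 0) -> tuple[float, float]:
    """Monte-Carlo RV permutation test; p = (1 + #{RV* >= RV}) / (n + 1).

    Rows of the Y (parasite) table are permuted; row weights stay fixed
    to the X-side CA masses.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rv_obs = rv_coefficient(tx, ty)
    rng = np.random.default_rng(seed)
    Y = ty.table.values
    count = 0
    nx = np.linalg.norm(tx.crossprod())
    X = tx.table.values
    qx = np.sqrt(tx.col_weights)
    qy = np.sqrt(ty.col_weights)
    XtD = qx[:, None] * (X.T * tx.row_weights)
    for _ in range(n_perm):
        perm = rng.permutation(Y.shape[0])
        Kp = (XtD @ Y[perm]) * qy[None, :]
        # permuting rows of Y changes its scatter under non-uniform weights
        Yp = Y[perm]
        nyp = np.linalg.norm((qy[:, None] * (Yp.T * tx.row_weights) @ Yp)
                             * qy[None, :])
        rv_p = np.sum(Kp ** 2) / (nx * nyp) if nyp > 0 else 0.0
        if rv_p >= rv_obs - 1e-12:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return rv_obs, p


# ---------------------------------------------------------------------------
# study presets

def filter_parasites_by_prevalence(parasites: ParasiteMatrix,
                                   groups: pd.Series,
                                   threshold: float = 0.02,
                                   parental=("bream", "roach")
                                   ) -> ParasiteMatrix:
    """Keep a species iff its prevalence exceeds ``threshold`` in at
    least one parental group."""
    keep = []
    for taxon in parasites.taxa:
        prevs = [
            float((parasites.abundance.loc[groups == g, taxon] > 0).mean())
            if (groups == g).any() else 0.0
            for g in parental]
        if max(prevs) > threshold:
            keep.append(taxon)
    tm = (parasites.taxon_meta.loc[keep]
          if parasites.taxon_meta is not None else None)
    return ParasiteMatrix(parasites.abundance[keep], tm)


def coinertia_analysis(genotypes: GenotypeTable, parasites: ParasiteMatrix,
                       mode: str = "alleles-x-species",
                       supertypes: pd.DataFrame | None = None,
                       min_carriers: int = 5, prevalence_threshold: float = 0.02,
                       group: str | None = None, scale_pca: bool = False,
                       log1p: bool = False, n_perm: int = 999,
                       seed: int = 0) -> CoinertiaResult:
    """One of the three study pairings, pooled or per host group.

    Modes: ``alleles-x-species``, ``alleles-x-groups``,
    ``supertypes-x-groups`` (requires a supertype assignment with a
    ``supertype`` column indexed by allele).
    """
    groups_all = genotypes.ind_meta["group"]
    parasites = filter_parasites_by_prevalence(
        parasites, groups_all, prevalence_threshold)
    individuals = [i for i in genotypes.individuals
                   if i in parasites.abundance.index
                   and (group is None or groups_all.loc[i] == group)]
    mhc = genotypes.presence.loc[individuals]
    if mode.startswith("alleles"):
        carriers = mhc.sum(axis=0)
        mhc = mhc[carriers.index[carriers >= min_carriers]]
    elif mode.startswith("supertypes"):
        if supertypes is None:
            raise ValueError("supertype assignment required")
        kept = supertypes[supertypes["kept"]]
        st_presence = {}
        for st in sorted(kept["supertype"].unique()):
            members = kept.index[kept["supertype"] == st]
            cols = [a for a in members if a in mhc.columns]
            st_presence[st] = (mhc[cols].sum(axis=1) > 0).astype(int)
        mhc = pd.DataFrame(st_presence)
    else:
        raise ValueError(f"unknown mode {mode}")
    if mode.endswith("species"):
        Y = parasites.abundance.loc[individuals]
    else:
        Y = parasites.group_abundance().loc[individuals]

    tx = correspondence_analysis(mhc)
    rows = tx.table.index
    ty = weighted_pca(Y.loc[rows], tx.row_weights, scale=scale_pca,
                      log1p=log1p)
    res = coinertia(tx, ty)
    res.rv, res.p_value = rv_test(tx, ty, n_perm=n_perm, seed=seed)
    res.n_permutations = n_perm
    return res
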