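"""Functional clustering of MHC alleles into supertypes.

Alleles are represented by the five z-scale physicochemical descriptors
(Sandberg et al. principal properties: z1 hydrophobicity, z2 steric
bulk/polarizability, z3 polarity, z4/z5 electronic effects) of the
residues at positively selected sites, clustered by K-means with the
number of clusters picked from a BIC elbow, assigned membership
probabilities by discriminant analysis of principal components (DAPC),
and screened for clustering consistency across repeated runs.

Supertype letters A, B, C... map to clusters by descending size (ties
broken by centroid lexicographic order), so downstream results are
invariant to K-means label permutations.
"""

from __future__ import annotations

import string
import warnings

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

#: Sandberg z-scales (z1-z5) for the 20 proteinogenic residues.
Z_SCALES = {
    "A": (0.24, -2.32, 0.60, -0.14, 1.30),
    "R": (3.52, 2.50, -3.50, 1.99, -0.17),
    "N": (3.05, 1.62, 1.04, -1.15, 1.61),
    "D": (3.98, 0.93, 1.93, -2.46, 0.75),
    "C": (0.84, -1.67, 3.71, 0.18, -2.65),
    "Q": (1.75, 0.50, -1.44, -1.34, 0.66),
    "E": (3.11, 0.26, -0.11, -3.04, -0.25),
    "G": (2.05, -4.06, 0.36, -0.82, -0.38),
    "H": (2.47, 1.95, 0.26, 3.90, 0.09),
    "I": (-3.89, -1.73, -1.71, -0.84, 0.26),
    "L": (-4.28, -1.30, -1.49, -0.72, 0.84),
    "K": (2.29, 0.89, -2.49, 1.49, 0.31),
    "M": (-2.85, -0.22, 0.47, 1.94, -0.98),
    "F": (-4.22, 1.94, 1.06, 0.54, -0.62),
    "P": (-1.66, 0.27, 1.84, 0.70, 2.00),
    "S": (2.39, -1.07, 1.15, -1.39, 0.67),
    "T": (0.75, -2.18, -1.12, -1.46, -0.40),
    "W": (-4.36, 3.94, 0.59, 3.44, -1.59),
    "Y": (-2.54, 2.44, 0.43, 0.04, -1.47),
    "V": (-2.59, -2.64, -1.54, -0.85, -0.02),
}


def encode_descriptors(protein_seqs: dict, pss_positions,
                       descriptor_table: dict | None = None,
                       standardize: bool = True):
    """Allele x (5 descriptors per PSS position) matrix.

    ``pss_positions`` are 1-based codon/residue positions.  Alleles with
    a residue outside the descriptor table (gap, X) at any PSS are
    dropped with a warning.  Columns are standardized to zero mean and
    unit variance by default.

    Returns (DataFrame, dropped allele list).
    """
    table = descriptor_table or Z_SCALES
    d = len(next(iter(table.values())))
    positions = sorted(int(p) for p in pss_positions)
    if not positions:
        raise ValueError("no PSS positions supplied")
    rows, dropped = {}, []
    for allele, seq in protein_seqs.items():
        if positions[-1] > len(seq):
            raise ValueError(f"PSS position {positions[-1]} beyond sequence "
                             f"length {len(seq)} for {allele}")
        feats = []
        ok = True
        for p in positions:
            aa = seq[p - 1]
            if aa not in table:
                dropped.append(allele)
                ok = False
                break
            feats.extend(table[aa])
        if ok:
            rows[allele] = feats
    if dropped:
        warnings.warn(f"dropped {len(dropped)} allele(s) with residues "
                      f"outside the descriptor table: {dropped}")
    cols = [f"p{p}_z{z + 1}" for p in positions for z in range(d)]
    X = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    if standardize and len(X):
        sd = X.std(axis=0, ddof=0).replace(0.0, 1.0)
        X = (X - X.mean(axis=0)) / sd
    return X, dropped


def kmeans_bic(X: np.ndarray, labels: np.ndarray, centers: np.ndarray) -> float:
    """BIC(k) = n ln(W/n) + k d ln(n), W = total within-cluster SSQ."""
    n, d = X.shape
    W = float(((X - centers[labels]) ** 2).sum())
    k = centers.shape[0]
    return n * np.log(max(W, 1e-12) / n) + k * d * np.log(n)


def kmeans_bic_scan(X, k_range, n_starts: int = 10, seed: int = 0,
                    elbow_fraction: float = 0.1) -> dict:
    """BIC curve over k with an elbow stopping rule.

    The chosen k is the smallest k at which the BIC decrease to k+1
    falls below ``elbow_fraction`` of the initial decrease.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    ks = sorted(int(k) for k in k_range)
    if ks[0] < 1 or ks[-1] > n - 1:
        raise ValueError("k_range must lie within [1, n_alleles - 1]")
    bic, labels_by_k = {}, {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_starts, random_state=seed).fit(X)
        bic[k] = kmeans_bic(X, km.labels_, km.cluster_centers_)
        labels_by_k[k] = km.labels_
    curve = pd.Series(bic).sort_index()
    chosen = ks[-1]
    if len(ks) > 1:
        decreases = -np.diff(curve.values)
        initial = max(decreases[0], 1e-12)
        for i in range(1, len(decreases)):
            if decreases[i] < elbow_fraction * initial:
                chosen = ks[i]
                break
    return {"bic": curve, "chosen_k": chosen, "labels": labels_by_k}


def _letters(n: int) -> list[str]:
    alphabet = string.ascii_uppercase
    return [alphabet[i % 26] * (i // 26 + 1) for i in range(n)]


def relabel_by_size(labels: np.ndarray, X: np.ndarray) -> dict:
    """Cluster id -> letter, by descending size then centroid lex order."""
    ids = np.unique(labels)
    sizes = {c: int((labels == c).sum()) for c in ids}
    centroids = {c: tuple(np.round(X[labels == c].mean(axis=0), 9))
                 for c in ids}
    order = sorted(ids, key=lambda c: (-sizes[c], centroids[c]))
    letters = _letters(len(order))
    return {c: letters[i] for i, c in enumerate(order)}


def dapc_assign(X, labels, n_pcs: int | None = None,
                variance_retained: float = 0.9):
    """PCA-reduced linear discriminant membership probabilities.

    Returns (membership DataFrame with cluster-id columns, modal labels).
    """
    Xv = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("DAPC needs at least 2 clusters")
    if n_pcs is None:
        pca = PCA(n_components=min(Xv.shape[0] - 1, Xv.shape[1]))
        scores = pca.fit_transform(Xv)
        cum = np.cumsum(pca.explained_variance_ratio_)
        n_pcs = int(np.searchsorted(cum, variance_retained) + 1)
        scores = scores[:, :n_pcs]
    else:
        if n_pcs > min(Xv.shape):
            raise ValueError("n_pcs exceeds matrix rank bound")
        scores = PCA(n_components=n_pcs).fit_transform(Xv)
    try:
        lda = LinearDiscriminantAnalysis(solver="svd").fit(scores, labels)
        probs = lda.predict_proba(scores)
    except np.linalg.LinAlgError:
        warnings.warn("singular within-class scatter; ridge applied")
        lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=0.1)
        probs = lda.fit(scores, labels).predict_proba(scores)
    index = X.index if isinstance(X, pd.DataFrame) else np.arange(len(Xv))
    membership = pd.DataFrame(probs, index=index, columns=lda.classes_)
    modal = membership.idxmax(axis=1)
    return membership, modal


def consistency_filter(X, k: int, n_repeats: int = 20, seed: int = 0,
                       threshold: float = 0.9) -> pd.DataFrame:
    """Repeated K-means with label alignment; flags unstable alleles.

    Labels of each repeat are matched to the reference run by maximizing
    the label-overlap contingency (Hungarian assignment); an allele's
    consistency is the fraction of repeats agreeing with its reference
    label.  Alleles below ``threshold`` are marked removed.
    """
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2")
    Xv = np.asarray(X, dtype=float)
    ref = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(Xv)
    ref_labels = ref.labels_
    agree = np.zeros(len(Xv))
    for r in range(n_repeats):
        km = KMeans(n_clusters=k, n_init=1,
                    random_state=seed + 1 + r).fit(Xv)
        cont = np.zeros((k, k))
        for a, b in zip(km.labels_, ref_labels):
            cont[a, b] += 1
        rows, cols = linear_sum_assignment(-cont)
        mapping = dict(zip(rows, cols))
        aligned = np.array([mapping[l] for l in km.labels_])
        agree += aligned == ref_labels
    consistency = agree / n_repeats
    letter_of = relabel_by_size(ref_labels, Xv)
    membership, modal = dapc_assign(X, ref_labels)
    membership.columns = [letter_of[c] for c in membership.columns]
    membership = membership[sorted(membership.columns)]
    index = X.index if isinstance(X, pd.DataFrame) else np.arange(len(Xv))
    out = pd.DataFrame({
        "supertype": [letter_of[l] for l in ref_labels],
        "modal_dapc": [letter_of[m] for m in modal],
        "membership_prob": [membership.loc[i, letter_of[l]]
                            for i, l in zip(index, ref_labels)],
        "consistency": consistency,
        "kept": consistency >= threshold,
    }, index=index)
    return pd.concat([out, membership.add_prefix("prob_")], axis=1)


def supertype_alleles(protein_seqs: dict, pss_positions, k_range=None,
                      n_repeats: int = 20, seed: int = 0,
                      consistency_threshold: float = 0.9) -> dict:
    """Full supertyping pass: encode, BIC scan, DAPC, consistency filter."""
    X, dropped = encode_descriptors(protein_seqs, pss_positions)
    if k_range is None:
        k_range = range(1, min(16, len(X)))
    scan = kmeans_bic_scan(X, k_range, seed=seed)
    assign = consistency_filter(X, scan["chosen_k"], n_repeats=n_repeats,
                                seed=seed, threshold=consistency_threshold)
    return {"descriptors": X, "dropped": dropped, "bic": scan["bic"],
            "chosen_k": scan["chosen_k"], "assignment": assign}
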