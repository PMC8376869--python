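"""Allele counts, sharing partitions and nonparametric group comparisons.

"Allele frequency" throughout is carrier frequency among expressing
individuals: expression genotyping cannot count gene copies, so the
fraction of individuals carrying an allele is the natural per-group
frequency (a flag switches the denominator to all specimens).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import GenotypeTable


@dataclass
class SharingPartition:
    """Exact partition of allele occurrence across host groups.

    For every group g: total(g) = private(g) + sum of pairwise-exclusive
    shared counts involving g + all-groups-shared count.
    """

    groups: tuple
    totals: dict
    private: dict
    pairwise_exclusive: dict = field(default_factory=dict)  # frozenset -> n
    all_shared: int = 0

    def check_identity(self) -> bool:
        for g in self.groups:
            rhs = self.private[g] + self.all_shared + sum(
                n for pair, n in self.pairwise_exclusive.items() if g in pair)
            if rhs != self.totals[g]:
                return False
        return True


def sharing_partition(occurrence: dict) -> SharingPartition:
    """Partition alleles by the exact set of groups carrying them.

    ``occurrence``: allele -> iterable of group labels (nonempty).
    """
    groups = tuple(sorted({g for gs in occurrence.values() for g in gs}))
    exact: dict[frozenset, int] = {}
    for gs in occurrence.values():
        key = frozenset(gs)
        if not key:
            raise ValueError("allele with empty group occurrence")
        exact[key] = exact.get(key, 0) + 1
    totals = {g: sum(n for k, n in exact.items() if g in k) for g in groups}
    private = {g: exact.get(frozenset([g]), 0) for g in groups}
    pairwise = {frozenset(p): exact.get(frozenset(p), 0)
                for p in combinations(groups, 2)}
    all_shared = exact.get(frozenset(groups), 0) if len(groups) > 2 else 0
    return SharingPartition(groups=groups, totals=totals, private=private,
                            pairwise_exclusive=pairwise, all_shared=all_shared)


def occurrence_from_table(table: GenotypeTable,
                          lineage: str | None = None) -> dict:
    occ = {}
    for allele in table.alleles:
        if lineage is not None and table.lineage(allele) != lineage:
            continue
        carried = table.presence[allele] == 1
        gs = set(table.ind_meta.loc[carried, "group"])
        if gs:
            occ[allele] = gs
    return occ


def allele_counts(table: GenotypeTable) -> dict:
    """Per-group allele totals, private counts and per-individual stats.

    Per-individual statistics are computed only over individuals that
    express at least one allele.
    """
    if table.presence.empty:
        raise ValueError("empty genotype table")
    partition = sharing_partition(occurrence_from_table(table))
    by_lineage = {lin: sharing_partition(occ)
                  for lin in ("DAB1", "DAB3")
                  if (occ := occurrence_from_table(table, lin))}
    per_ind = {}
    counts_all = table.counts_per_individual()
    expressing = counts_all > 0
    for group in sorted(set(table.ind_meta["group"])):
        sel = (table.ind_meta["group"] == group) & expressing
        c = counts_all[sel]
        row = {"n_expressing": int(sel.sum())}
        for lin in (None, "DAB1", "DAB3"):
            cl = table.counts_per_individual(lin)[sel]
            tag = "overall" if lin is None else lin
            row[tag] = {
                "mean": float(cl.mean()) if len(cl) else np.nan,
                "sd": float(cl.std(ddof=1)) if len(cl) > 1 else 0.0,
                "min": int(cl.min()) if len(cl) else 0,
                "max": int(cl.max()) if len(cl) else 0,
            }
        per_ind[group] = row
    return {"partition": partition, "by_lineage": by_lineage,
            "per_individual": per_ind}


def expression_success_from_counts(n_by_group: dict,
                                   no_allele_by_group: dict) -> dict:
    """Expression success from specimen counts (pooled and per group)."""
    out = {}
    for g, n in n_by_group.items():
        out[g] = (n - no_allele_by_group.get(g, 0)) / n if n else np.nan
    total = sum(n_by_group.values())
    failed = sum(no_allele_by_group.values())
    out["pooled"] = (total - failed) / total if total else np.nan
    return out


def expression_success(table: GenotypeTable) -> dict:
    """Proportion of specimens expressing >= 1 validated allele."""
    counts = table.counts_per_individual()
    expressing = counts > 0
    if "amplified" in table.ind_meta.columns:
        expressing &= table.ind_meta["amplified"].astype(bool)
    n_by_group, no_by_group = {}, {}
    for group, idx in table.ind_meta.groupby("group").groups.items():
        n_by_group[group] = len(idx)
        no_by_group[group] = int((~expressing.loc[idx]).sum())
    return expression_success_from_counts(n_by_group, no_by_group)


def expression_class_counts(table: GenotypeTable) -> pd.DataFrame:
    """Per-group specimen counts of {none, only DAB1, only DAB3, both}."""
    c1 = table.counts_per_individual("DAB1")
    c3 = table.counts_per_individual("DAB3")
    cls = pd.Series("none", index=table.presence.index)
    cls[(c1 > 0) & (c3 == 0)] = "only_DAB1"
    cls[(c1 == 0) & (c3 > 0)] = "only_DAB3"
    cls[(c1 > 0) & (c3 > 0)] = "both"
    out = pd.crosstab(table.ind_meta["group"], cls)
    for col in ("none", "only_DAB1", "only_DAB3", "both"):
        if col not in out:
            out[col] = 0
    return out[["none", "only_DAB1", "only_DAB3", "both"]]


def allele_frequencies(table: GenotypeTable,
                       denominator: str = "expressing") -> pd.DataFrame:
    """Per-group carrier frequencies per allele."""
    if denominator not in ("expressing", "all"):
        raise ValueError("denominator must be 'expressing' or 'all'")
    expressing = table.counts_per_individual() > 0
    rows = {}
    for group in sorted(set(table.ind_meta["group"])):
        sel = table.ind_meta["group"] == group
        if denominator == "expressing":
            sel &= expressing
        n = int(sel.sum())
        if n == 0:
            raise ValueError(f"group {group} has no individuals")
        rows[group] = table.presence[sel].sum(axis=0) / n
    return pd.DataFrame(rows)


def kruskal_wallis(counts_by_group: dict, adjust: str = "bonferroni") -> dict:
    """Tie-corrected Kruskal-Wallis H with Dunn's pairwise post hoc.

    ``counts_by_group``: group -> 1-d array of per-individual counts.
    ``adjust``: 'bonferroni' (default) or 'holm' family-wise adjustment
    of the Dunn z-test p-values.
    """
    groups = list(counts_by_group)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    samples = [np.asarray(counts_by_group[g], dtype=float) for g in groups]
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group needs at least one observation")
    H, p = stats.kruskal(*samples)

    pooled = np.concatenate(samples)
    ranks = stats.rankdata(pooled)
    N = len(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / (12.0 * (N - 1))
    mean_ranks, sizes, offset = {}, {}, 0
    for g, s in zip(groups, samples):
        mean_ranks[g] = float(ranks[offset:offset + len(s)].mean())
        sizes[g] = len(s)
        offset += len(s)
    pairs, zvals, pvals = [], [], []
    for g1, g2 in combinations(groups, 2):
        se = np.sqrt((N * (N + 1) / 12.0 - tie_term)
                     * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        z = (mean_ranks[g1] - mean_ranks[g2]) / se if se > 0 else 0.0
        pairs.append((g1, g2))
        zvals.append(z)
        pvals.append(2.0 * stats.norm.sf(abs(z)))
    adj = multipletests(pvals, method=adjust)[1] if pvals else []
    posthoc = pd.DataFrame({
        "group1": [a for a, _ in pairs], "group2": [b for _, b in pairs],
        "z": zvals, "p_raw": pvals, "p_adjusted": list(adj)})
    return {"H": float(H), "p": float(p), "posthoc": posthoc}
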