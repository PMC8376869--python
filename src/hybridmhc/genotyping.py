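"""Amplicon-based validation of expressed MHC alleles.

The filtering chain separates true expressed alleles from PCR/sequencing
artifacts using read-frequency evidence alone (no error-model learning):

1. variants with frameshift-causing length offsets or a single read
   across the whole data set are excluded outright;
2. the maximum per-amplicon frequency (MPAF) is computed per variant;
   variants at or above the MPAF threshold (default 5%) are accepted;
3. variants below the threshold are accepted only where they cannot be
   explained, inside the amplicons that contain them, as a 1-bp
   substitution from - or a single-breakpoint chimera of - strictly
   more abundant same-amplicon variants.

Coordinates are 0-based half-open internally; chimera breakpoints are
reported 1-based inclusive (the last position taken from the first
parent).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import GenotypeTable

_AMBIGUOUS = set("RYSWKMBDHVN")


def normalize_sequence(seq: str) -> str:
    return seq.upper().replace("U", "T")


@dataclass
class Amplicon:
    """One specimen x replicate read set, tallied by distinct sequence."""

    specimen_id: str
    replicate_id: str
    tallies: dict  # sequence -> read count
    lineage_hint: str | None = None

    def __post_init__(self):
        self.tallies = {normalize_sequence(s): int(c)
                        for s, c in self.tallies.items() if c > 0}
        if self.total <= 0:
            raise ValueError(
                f"empty amplicon {self.specimen_id}/{self.replicate_id}")

    @property
    def key(self):
        return (self.specimen_id, self.replicate_id)

    @property
    def total(self) -> int:
        return sum(self.tallies.values())

    def frequency(self, seq: str) -> float:
        return self.tallies.get(seq, 0) / self.total


@dataclass
class VariantRecord:
    variant_id: str
    sequence: str
    per_amplicon_counts: dict = field(default_factory=dict)
    mpaf: float = 0.0
    flags: set = field(default_factory=set)
    status: str = "unresolved"

    @property
    def total_reads(self) -> int:
        return sum(self.per_amplicon_counts.values())


def tally_and_mpaf(amplicons: list[Amplicon]) -> dict[str, VariantRecord]:
    """One VariantRecord per distinct sequence with its MPAF."""
    records: dict[str, VariantRecord] = {}
    for amp in amplicons:
        if amp.total <= 0:
            raise ValueError(f"empty amplicon {amp.key}")
        for seq, count in amp.tallies.items():
            rec = records.setdefault(
                seq, VariantRecord(variant_id=f"v{len(records) + 1:05d}",
                                   sequence=seq))
            rec.per_amplicon_counts[amp.key] = \
                rec.per_amplicon_counts.get(amp.key, 0) + count
    totals = {amp.key: amp.total for amp in amplicons}
    for rec in records.values():
        rec.mpaf = max(c / totals[k] for k, c in rec.per_amplicon_counts.items())
        if _AMBIGUOUS & set(rec.sequence):
            rec.flags.add("ambiguous_bases")
    return records


def prefilter_variants(records: dict[str, VariantRecord],
                       reference_length: int) -> dict[str, VariantRecord]:
    """Flag frameshift-length variants and data-set-wide singletons.

    A variant is a frameshift candidate when its length differs from the
    reference length by a non-multiple of 3 (a literal 1-2 bp indel);
    in-frame length differences are left alone.
    """
    for rec in records.values():
        if (len(rec.sequence) - reference_length) % 3 != 0:
            rec.flags.add("frameshift_indel")
        if rec.total_reads == 1:
            rec.flags.add("global_singleton")
    return records


def _hamming1(a: str, b: str) -> bool:
    if len(a) != len(b):
        return False
    diff = 0
    for x, y in zip(a, b):
        if x != y:
            diff += 1
            if diff > 1:
                return False
    return diff == 1


def classify_substitution_artifact(seq: str, amplicon: Amplicon) -> bool:
    """True iff a same-length variant at Hamming distance 1 is strictly
    more frequent in this amplicon (frequency ties do not explain)."""
    f = amplicon.frequency(seq)
    for other, count in amplicon.tallies.items():
        if other == seq or len(other) != len(seq):
            continue
        if count / amplicon.total > f and _hamming1(seq, other):
            return True
    return False


def _lcp(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def classify_chimera(seq: str, amplicon: Amplicon):
    """Single-breakpoint chimera check against strictly more frequent,
    equal-length same-amplicon parents.

    Returns (is_chimera, breakpoint) with the breakpoint 1-based
    inclusive (last position contributed by the 5' parent), or
    (False, None).
    """
    L = len(seq)
    f = amplicon.frequency(seq)
    parents = [other for other, count in amplicon.tallies.items()
               if other != seq and len(other) == L
               and count / amplicon.total > f]
    if len(parents) < 2 or L < 2:
        return False, None
    lcp = {p: _lcp(seq, p) for p in parents}
    lcs = {p: _lcp(seq[::-1], p[::-1]) for p in parents}
    best = None
    for p1 in parents:
        for p2 in parents:
            if p1 == p2:
                continue
            lo = max(1, L - lcs[p2])
            hi = min(lcp[p1], L - 1)
            if lo <= hi:
                if best is None or lo < best:
                    best = lo
    return (True, best) if best is not None else (False, None)


def validate_alleles(records: dict[str, VariantRecord],
                     amplicons: list[Amplicon],
                     mpaf_threshold: float = 0.05,
                     acceptance_rule: str = "amplicon_fraction",
                     acceptance_fraction: float = 0.5,
                     min_coverage: int = 1):
    """Assign true_allele/artifact status and build per-specimen genotypes.

    ``acceptance_rule``:
      * ``amplicon_fraction`` (default): a low-MPAF variant is accepted
        when the fraction of amplicons containing it in which it is NOT
        explainable as a substitution or chimera artifact reaches
        ``acceptance_fraction``;
      * ``read_share``: the literal per-read reading - accepted when the
        share of the variant's reads that sit in unexplained amplicons
        reaches ``acceptance_fraction``.

    Returns (true allele sequences, per-specimen genotype dict, records).
    Specimens whose amplicons all fall below ``min_coverage`` map to
    ``None`` ("no amplification").
    """
    if acceptance_rule not in ("amplicon_fraction", "read_share"):
        raise ValueError(f"unknown acceptance rule {acceptance_rule}")
    covered = [a for a in amplicons if a.total >= min_coverage]
    by_key = {a.key: a for a in covered}
    for rec in records.values():
        if rec.flags & {"frameshift_indel", "global_singleton",
                        "ambiguous_bases"}:
            rec.status = "artifact"
            continue
        keys = [k for k in rec.per_amplicon_counts if k in by_key]
        if not keys:
            rec.status = "artifact"
            continue
        if rec.mpaf >= mpaf_threshold:
            rec.status = "true_allele"
            continue
        unexplained, weights = [], []
        for k in keys:
            amp = by_key[k]
            sub = classify_substitution_artifact(rec.sequence, amp)
            chim, _ = classify_chimera(rec.sequence, amp)
            if sub:
                rec.flags.add("substitution_artifact")
            if chim:
                rec.flags.add("chimera_artifact")
            unexplained.append(not (sub or chim))
            weights.append(rec.per_amplicon_counts[k])
        if acceptance_rule == "amplicon_fraction":
            score = float(np.mean(unexplained))
        else:
            weights = np.asarray(weights, dtype=float)
            score = float(weights[np.asarray(unexplained)].sum() / weights.sum())
        rec.status = "true_allele" if score >= acceptance_fraction else "artifact"

    true_seqs = {seq for seq, rec in records.items()
                 if rec.status == "true_allele"}
    genotypes: dict[str, set | None] = {}
    specimens_with_cov = {a.specimen_id for a in covered}
    for amp in amplicons:
        genotypes.setdefault(
            amp.specimen_id,
            set() if amp.specimen_id in specimens_with_cov else None)
    for amp in covered:
        for seq in amp.tallies:
            if seq in true_seqs:
                genotypes[amp.specimen_id].add(seq)
    return true_seqs, genotypes, records


def replicate_concordance(amplicons: list[Amplicon], true_seqs: set,
                          threshold: float = 0.8) -> pd.DataFrame:
    """Jaccard concordance of replicate-level allele calls per specimen."""
    calls: dict[str, dict[str, set]] = {}
    for amp in amplicons:
        reps = calls.setdefault(amp.specimen_id, {})
        reps.setdefault(amp.replicate_id, set()).update(
            s for s in amp.tallies if s in true_seqs)
    rows = []
    for specimen, reps in sorted(calls.items()):
        if len(reps) < 2:
            rows.append((specimen, len(reps), None, "unreplicated"))
            continue
        sets = list(reps.values())
        union = set.union(*sets)
        inter = set.intersection(*sets)
        j = 1.0 if not union else len(inter) / len(union)
        rows.append((specimen, len(reps), j,
                     "low_concordance" if j < threshold else "ok"))
    return pd.DataFrame(rows, columns=["specimen", "n_replicates",
                                       "jaccard", "flag"])


def assign_lineage(allele_seqs: dict[str, str],
                   exemplars: dict[str, list[str]]) -> dict[str, str]:
    """Label each allele by its highest-identity lineage exemplar.

    ``exemplars`` maps lineage name -> list of exemplar sequences.  Exact
    identity fraction over the aligned length; ties across lineages are
    reported ``unresolved``.
    """
    if not exemplars or not any(exemplars.values()):
        raise ValueError("at least one exemplar per lineage is required")

    def identity(a: str, b: str) -> float:
        L = min(len(a), len(b))
        if L == 0:
            return 0.0
        same = sum(x == y for x, y in zip(a[:L], b[:L]))
        return same / max(len(a), len(b))

    labels = {}
    for allele, seq in allele_seqs.items():
        seq = normalize_sequence(seq)
        best = {lin: max(identity(seq, normalize_sequence(e)) for e in exs)
                for lin, exs in exemplars.items() if exs}
        top = max(best.values())
        winners = [lin for lin, v in best.items() if v == top]
        labels[allele] = winners[0] if len(winners) == 1 else "unresolved"
    return labels


def build_genotype_table(genotypes: dict, ind_meta: pd.DataFrame,
                         allele_names: dict[str, str],
                         allele_meta: pd.DataFrame | None = None
                         ) -> GenotypeTable:
    """Assemble a GenotypeTable from validate_alleles output.

    ``allele_names`` maps sequence -> allele name; specimens with a None
    genotype (no amplification) get an all-zero row and ``amplified``
    False in the metadata.
    """
    columns = sorted(set(allele_names.values()))
    idx = [i for i in ind_meta.index if i in genotypes]
    presence = pd.DataFrame(0, index=idx, columns=columns)
    amplified = []
    for ind in idx:
        geno = genotypes[ind]
        amplified.append(geno is not None)
        if geno:
            presence.loc[ind, sorted({allele_names[s] for s in geno})] = 1
    meta = ind_meta.loc[idx].copy()
    meta["amplified"] = amplified
    return GenotypeTable(presence, meta, allele_meta)
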