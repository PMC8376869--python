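"""Shared tabular containers: genotype and parasite matrices.

Both are thin wrappers around pandas DataFrames with the metadata the
downstream statistics need (host group, season, year, maternal line for
genotypes; taxonomic group and host specificity for parasites).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

GROUPS = ("bream", "roach", "hybrid")
META_COLUMNS = ("group", "season", "year", "maternal_line")


def lineage_of(allele: str) -> str:
    """DAB1/DAB3 lineage from the Klein-style allele name."""
    if "DAB1" in allele:
        return "DAB1"
    if "DAB3" in allele:
        return "DAB3"
    return "unknown"


@dataclass
class GenotypeTable:
    """Binary individual x allele presence with per-individual metadata.

    ``presence``: 0/1 DataFrame indexed by individual id.
    ``ind_meta``: DataFrame indexed identically, columns from META_COLUMNS
    (plus optional extras such as ``amplified``).
    ``allele_meta``: optional per-allele DataFrame (lineage, occurrence).
    """

    presence: pd.DataFrame
    ind_meta: pd.DataFrame
    allele_meta: pd.DataFrame | None = None

    def __post_init__(self):
        self.presence = self.presence.astype(int)
        if not self.presence.index.equals(self.ind_meta.index):
            raise ValueError("presence and ind_meta must share an index")
        bad = set(self.presence.values.ravel()) - {0, 1}
        if bad:
            raise ValueError(f"presence matrix is not binary: {sorted(bad)}")
        unknown = set(self.ind_meta["group"]) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown group labels: {sorted(unknown)}")

    @property
    def alleles(self) -> list[str]:
        return list(self.presence.columns)

    @property
    def individuals(self) -> list[str]:
        return list(self.presence.index)

    def lineage(self, allele: str) -> str:
        if self.allele_meta is not None and allele in self.allele_meta.index:
            return str(self.allele_meta.loc[allele, "lineage"])
        return lineage_of(allele)

    def counts_per_individual(self, lineage: str | None = None) -> pd.Series:
        cols = self.alleles if lineage is None else [
            a for a in self.alleles if self.lineage(a) == lineage]
        return self.presence[cols].sum(axis=1)

    def drop_empty_alleles(self) -> "GenotypeTable":
        keep = self.presence.columns[self.presence.sum(axis=0) > 0]
        am = (self.allele_meta.loc[self.allele_meta.index.intersection(keep)]
              if self.allele_meta is not None else None)
        return GenotypeTable(self.presence[keep], self.ind_meta, am)

    def to_tsv(self, path) -> None:
        meta_cols = [c for c in self.ind_meta.columns]
        df = pd.concat([self.ind_meta[meta_cols], self.presence], axis=1)
        df.to_csv(path, sep="\t", index_label="individual")

    @classmethod
    def from_tsv(cls, path, allele_meta: pd.DataFrame | None = None):
        df = pd.read_csv(path, sep="\t", index_col="individual")
        meta_cols = [c for c in df.columns
                     if c in META_COLUMNS or c == "amplified"]
        presence = df.drop(columns=meta_cols)
        return cls(presence, df[meta_cols], allele_meta)


@dataclass
class ParasiteMatrix:
    """Individual x parasite abundance counts with taxon annotations."""

    abundance: pd.DataFrame
    taxon_meta: pd.DataFrame = field(default=None)

    def __post_init__(self):
        if (self.abundance.values < 0).any():
            raise ValueError("parasite abundances must be nonnegative")

    @property
    def taxa(self) -> list[str]:
        return list(self.abundance.columns)

    def prevalence(self, subset=None) -> pd.Series:
        df = self.abundance if subset is None else self.abundance.loc[subset]
        return (df > 0).mean(axis=0)

    def group_abundance(self) -> pd.DataFrame:
        """Sum abundances within higher taxonomic groups (Monogenea, ...)."""
        if self.taxon_meta is None:
            raise ValueError("taxon_meta required for group aggregation")
        groups = self.taxon_meta.loc[self.taxa, "taxon_group"]
        return self.abundance.T.groupby(groups).sum().T

    def to_tsv(self, path) -> None:
        self.abundance.to_csv(path, sep="\t", index_label="individual")

    @classmethod
    def from_tsv(cls, path, taxon_meta: pd.DataFrame | None = None):
        df = pd.read_csv(path, sep="\t", index_col="individual")
        return cls(df, taxon_meta)
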