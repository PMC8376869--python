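"""Synthetic data with the statistical structure of a two-species MHC study.

The generator emulates a wild system of two hybridizing fish species
("bream"-like group A, "roach"-like group B) and their F1 hybrids:

* two species allele pools per gene lineage (DAB1, DAB3) with partial
  trans-species sharing and optional hybrid-only variants;
* per-individual expressed genotypes (1-5 alleles) with a maternal bias
  in hybrids;
* per-specimen amplicon read sets contaminated by 1-bp PCR substitution
  errors and single-breakpoint chimeras, with Dirichlet amplification
  skew between a specimen's alleles;
* seasonal, group-structured, negative-binomially dispersed parasite
  communities mixing host-specific and generalist taxa, with optional
  planted allele -> taxon effects on the log scale.

Every operation draws from a named substream of a single top-level seed,
so each stage is independently reproducible and full runs are
byte-identical for a fixed seed.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .codon import CODONS, N_CODONS, CodonPropagator, codon_rate_matrix
from .phylo import PhyloTree
from .selection import CodonAlignment
from .tables import GenotypeTable, ParasiteMatrix


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent generator derived from (seed, name)."""
    key = zlib.crc32(name.encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))


# ---------------------------------------------------------------------------
# configuration

@dataclass
class ParasiteTaxon:
    name: str
    taxon_group: str            # Monogenea, Crustacea, Digenea, ...
    host: str                   # "bream", "roach" or "generalist"
    base_mean: float            # autumn mean abundance in the primary host
    spring_multiplier: float = 3.0
    hybrid_factor: float = 0.3  # host-specific load carried over to hybrids
    dispersion: float = 0.5     # NB size parameter; smaller = more dispersed


def default_parasite_taxa() -> list[ParasiteTaxon]:
    return [
        ParasiteTaxon("Dactylogyrus_a1", "Monogenea", "bream", 15.0),
        ParasiteTaxon("Dactylogyrus_a2", "Monogenea", "bream", 8.0),
        ParasiteTaxon("Dactylogyrus_b1", "Monogenea", "roach", 20.0),
        ParasiteTaxon("Dactylogyrus_b2", "Monogenea", "roach", 5.0),
        ParasiteTaxon("Dactylogyrus_b3", "Monogenea", "roach", 2.0),
        ParasiteTaxon("Gyrodactylus_gen", "Monogenea", "generalist", 1.0),
        ParasiteTaxon("Argulus_gen", "Crustacea", "generalist", 1.5),
        ParasiteTaxon("Ergasilus_gen", "Crustacea", "generalist", 2.5),
        ParasiteTaxon("Diplostomum_gen", "Digenea", "generalist", 1.0,
                      spring_multiplier=1.5),
        ParasiteTaxon("Caryophyllaeidae_gen", "Cestoda", "generalist", 0.4,
                      spring_multiplier=1.0),
    ]


@dataclass
class SimulationConfig:
    """Study-scale defaults: sample sizes, pool sizes and per-individual
    allele-count ranges follow the field survey the generator emulates."""

    n_individuals: dict = field(default_factory=lambda: {
        "bream": 109, "roach": 97, "hybrid": 88})
    pool_sizes: dict = field(default_factory=lambda: {
        ("bream", "DAB1"): 6, ("bream", "DAB3"): 24,
        ("roach", "DAB1"): 16, ("roach", "DAB3"): 49})
    shared_fraction: float = 0.10     # of the smaller pool, shared A<->B
    n_hybrid_novel: int = 2           # hybrid-only alleles per lineage
    allele_count_range: dict = field(default_factory=lambda: {
        "bream": (1, 3), "roach": (1, 5), "hybrid": (1, 4)})
    maternal_bias: float = 0.55
    no_amplification_rate: float = 0.05
    n_replicates: int = 2
    read_depth: int = 300
    substitution_error_rate: float = 0.01
    chimera_rate: float = 0.02
    skew_concentration: float = 1.0
    n_codons: int = 90                # exon-2 scale amplicon
    allele_divergence: int = 8        # codon substitutions from lineage ancestor
    lineage_divergence: int = 30      # codon substitutions between lineages
    parasite_taxa: list = field(default_factory=default_parasite_taxa)
    allele_effects: dict = field(default_factory=dict)  # (allele, taxon) -> log effect
    seed: int = 0

    def __post_init__(self):
        for p in (self.shared_fraction, self.maternal_bias,
                  self.substitution_error_rate, self.chimera_rate,
                  self.no_amplification_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0,1]: {p}")
        if self.shared_fraction >= 1.0:
            raise ValueError("shared_fraction must be < 1")
        for g, (lo, hi) in self.allele_count_range.items():
            if not (1 <= lo <= hi <= 5):
                raise ValueError(f"allele count range for {g} must lie in [1,5]")
        for t in self.parasite_taxa:
            if t.dispersion <= 0:
                raise ValueError("NB dispersion must be > 0")


@dataclass
class SimulationTruth:
    alleles_per_individual: dict = field(default_factory=dict)
    variant_provenance: dict = field(default_factory=dict)
    site_classes: list = field(default_factory=list)
    parasite_coefficients: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# trees and codon evolution

def simulate_tree(n_taxa: int, seed: int = 0) -> PhyloTree:
    """Random ultrametric binary tree by sequential pairwise coalescence."""
    if n_taxa < 3:
        raise ValueError("n_taxa must be >= 3")
    rng = substream(seed, "tree")
    nodes = [(f"t{i + 1}", 0.0) for i in range(n_taxa)]
    height = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        height += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        (nwk_j, h_j) = nodes.pop(j)
        (nwk_i, h_i) = nodes.pop(i)
        merged = f"({nwk_i}:{height - h_i:.6f},{nwk_j}:{height - h_j:.6f})"
        nodes.append((merged, height))
    return PhyloTree.from_newick(nodes[0][0] + ";")


def evolve_codon_alignment(tree: PhyloTree, site_classes, kappa: float,
                           codon_freqs: np.ndarray, n_codons: int,
                           seed: int = 0):
    """Simulate a codon alignment under a discrete omega mixture on a tree.

    ``site_classes``: list of (proportion, omega).  Branch lengths are
    expected substitutions per codon under the mixture.  Returns
    (CodonAlignment, per-site class labels).
    """
    pi = np.asarray(codon_freqs, dtype=float)
    if pi.shape == (64,):
        raise ValueError(
            "stop-codon frequencies not allowed: supply the 61 sense codons")
    if pi.shape != (N_CODONS,):
        raise ValueError("codon_freqs must have length 61 (sense codons)")
    props = np.array([p for p, _ in site_classes], dtype=float)
    omegas = np.array([w for _, w in site_classes], dtype=float)
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("site-class proportions must sum to 1")
    rng = substream(seed, "codon-evolution")
    labels = rng.choice(len(props), size=n_codons, p=props)
    if n_codons == 0:
        return CodonAlignment(names=list(tree.taxa),
                              codons=np.zeros((len(tree.taxa), 0), int)), labels

    rates = np.array([
        -np.dot(pi, np.diag(codon_rate_matrix(kappa, w, pi, normalize=False)))
        for w in omegas])
    mean_rate = float(np.dot(props, rates))
    props_used = [CodonPropagator(
        codon_rate_matrix(kappa, w, pi, normalize=False), pi) for w in omegas]

    states = {tree.root: rng.choice(N_CODONS, size=n_codons, p=pi)}
    for node in tree.postorder[::-1]:
        if node == tree.root:
            continue
        parent_states = states[tree.parent[node]]
        t = tree.edge_length[node] / max(mean_rate, 1e-12)
        child = np.empty(n_codons, dtype=int)
        for k in range(len(omegas)):
            sel = labels == k
            if not sel.any():
                continue
            P = props_used[k].transition_matrix(t)
            cum = P.cumsum(axis=1)
            u = rng.random(sel.sum())
            child[sel] = (cum[parent_states[sel]] < u[:, None]).sum(axis=1)
        states[node] = np.clip(child, 0, N_CODONS - 1)
    mat = np.stack([states[tree.leaf_index[name]] for name in tree.taxa])
    return CodonAlignment(names=list(tree.taxa), codons=mat), labels


# ---------------------------------------------------------------------------
# allele pools

def _random_codon_seq(rng, n_codons: int) -> list[int]:
    return list(rng.choice(N_CODONS, size=n_codons))

def _mutate(rng, codons: list[int], n_changes: int) -> list[int]:
    out = list(codons)
    for pos in rng.choice(len(out), size=min(n_changes, len(out)), replace=False):
        out[pos] = int(rng.choice(N_CODONS))
    return out

def _to_nt(codons) -> str:
    return "".join(CODONS[c] for c in codons)


def simulate_allele_pools(config: SimulationConfig):
    """Generate species allele pools with trans-species sharing.

    Returns (pools DataFrame indexed by allele id with columns sequence,
    lineage, in_bream, in_roach, hybrid_only; truth dict of configured
    sharing counts).
    """
    for key, size in config.pool_sizes.items():
        if size <= 0:
            raise ValueError(f"pool size for {key} must be positive")
    rng = substream(config.seed, "allele-pools")
    ancestor = _random_codon_seq(rng, config.n_codons)
    lineage_anc = {
        "DAB1": _mutate(rng, ancestor, config.lineage_divergence),
        "DAB3": _mutate(rng, ancestor, config.lineage_divergence),
    }
    rows = []
    truth = {"shared": {}, "private": {}}
    for lineage in ("DAB1", "DAB3"):
        size_a = config.pool_sizes[("bream", lineage)]
        size_b = config.pool_sizes[("roach", lineage)]
        n_shared = int(round(config.shared_fraction * min(size_a, size_b)))
        n_priv_a, n_priv_b = size_a - n_shared, size_b - n_shared
        truth["shared"][lineage] = n_shared
        truth["private"][lineage] = {"bream": n_priv_a, "roach": n_priv_b}
        counter = 0
        seen = set()

        def new_seq():
            nonlocal counter
            while True:
                seq = _mutate(rng, lineage_anc[lineage],
                              config.allele_divergence)
                key = tuple(seq)
                if key not in seen:
                    seen.add(key)
                    return seq

        for _ in range(n_shared):
            counter += 1
            rows.append((f"Arbr-{lineage}*{counter:02d}", _to_nt(new_seq()),
                         lineage, True, True, False))
        for _ in range(n_priv_a):
            counter += 1
            rows.append((f"Abbr-{lineage}*{counter:02d}", _to_nt(new_seq()),
                         lineage, True, False, False))
        for _ in range(n_priv_b):
            counter += 1
            rows.append((f"Ruru-{lineage}*{counter:02d}", _to_nt(new_seq()),
                         lineage, False, True, False))
        for _ in range(config.n_hybrid_novel):
            counter += 1
            rows.append((f"Arbr-{lineage}*{counter:02d}h", _to_nt(new_seq()),
                         lineage, False, False, True))
    pools = pd.DataFrame(
        rows, columns=["allele", "sequence", "lineage",
                       "in_bream", "in_roach", "hybrid_only"]
    ).set_index("allele")
    return pools, truth


def write_pool_fasta(pools: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for allele, row in pools.iterrows():
            fh.write(f">{allele}\n{row.sequence}\n")


# ---------------------------------------------------------------------------
# genotypes

_COUNT_WEIGHTS = np.array([0.50, 0.30, 0.12, 0.06, 0.02])


def _draw_count(rng, lo: int, hi: int) -> int:
    w = _COUNT_WEIGHTS[lo - 1: hi]
    return int(rng.choice(np.arange(lo, hi + 1), p=w / w.sum()))


def simulate_genotypes(pools: pd.DataFrame, config: SimulationConfig):
    """Draw per-individual expressed allele sets; returns (GenotypeTable, truth)."""
    if pools.empty:
        raise ValueError("allele pools are empty")
    rng = substream(config.seed, "genotypes")
    pool_by_group = {
        "bream": pools.index[pools.in_bream].tolist(),
        "roach": pools.index[pools.in_roach].tolist(),
    }
    novel = pools.index[pools.hybrid_only].tolist()
    popularity = {g: rng.dirichlet(np.full(len(p), 1.0))
                  for g, p in pool_by_group.items()}

    records, meta, truth = [], [], SimulationTruth()
    for group, n in config.n_individuals.items():
        lo, hi = config.allele_count_range[group]
        for i in range(n):
            ind = f"{group[0].upper()}{i + 1:03d}"
            season = "spring" if i % 2 == 0 else "autumn"
            year = 1 + (i % 3)
            if group == "hybrid":
                maternal = "bream" if rng.random() < 0.5 else "roach"
                count = _draw_count(rng, lo, hi)
                alleles: set[str] = set()
                guard = 0
                while len(alleles) < count and guard < 200:
                    guard += 1
                    if novel and rng.random() < 0.03:
                        alleles.add(str(rng.choice(novel)))
                        continue
                    src = maternal if rng.random() < config.maternal_bias else (
                        "roach" if maternal == "bream" else "bream")
                    cand = rng.choice(pool_by_group[src], p=popularity[src])
                    alleles.add(str(cand))
            else:
                maternal = group
                pool = pool_by_group[group]
                count = _draw_count(rng, lo, hi)
                if count > len(pool):
                    raise ValueError(
                        f"requested {count} alleles from pool of {len(pool)}")
                alleles = set(rng.choice(pool, size=count, replace=False,
                                         p=popularity[group]))
            amplified = rng.random() >= config.no_amplification_rate
            records.append((ind, sorted(alleles)))
            meta.append((ind, group, season, year, maternal, amplified))
            truth.alleles_per_individual[ind] = sorted(alleles)

    ind_meta = pd.DataFrame(
        meta, columns=["individual", "group", "season", "year",
                       "maternal_line", "amplified"]).set_index("individual")
    presence = pd.DataFrame(0, index=ind_meta.index, columns=pools.index)
    for ind, alleles in records:
        presence.loc[ind, list(alleles)] = 1
    allele_meta = pd.DataFrame({"lineage": pools.lineage})
    table = GenotypeTable(presence, ind_meta, allele_meta).drop_empty_alleles()
    return table, truth


# ---------------------------------------------------------------------------
# amplicons

@dataclass
class SimulatedAmplicon:
    specimen_id: str
    replicate_id: str
    tallies: dict  # sequence -> read count


def _one_bp_error(rng, seq: str) -> str:
    pos = int(rng.integers(len(seq)))
    alt = "ACGT".replace(seq[pos], "")[int(rng.integers(3))]
    return seq[:pos] + alt + seq[pos + 1:]


def _chimera(rng, s1: str, s2: str) -> str:
    b = int(rng.integers(1, len(s1)))  # breakpoint uniform over internal cuts
    return s1[:b] + s2[b:]


def simulate_amplicons(genotypes: GenotypeTable, pools: pd.DataFrame,
                       config: SimulationConfig):
    """Per specimen x replicate read-variant tallies with PCR artifacts.

    Returns (list of SimulatedAmplicon, truth) where truth labels every
    emitted variant sequence as true / 1bp-error / chimera.
    """
    if config.read_depth < 1:
        raise ValueError("read depth must be >= 1")
    rng = substream(config.seed, "amplicons")
    seq_of = pools.sequence.to_dict()
    true_seqs = set(seq_of.values())
    amplicons: list[SimulatedAmplicon] = []
    truth = SimulationTruth(variant_provenance={})
    provenance = truth.variant_provenance

    for ind in genotypes.individuals:
        if not bool(genotypes.ind_meta.loc[ind].get("amplified", True)):
            continue
        alleles = [a for a in genotypes.alleles
                   if genotypes.presence.loc[ind, a] == 1]
        if not alleles:
            continue
        seqs = [seq_of[a] for a in alleles]
        for rep in range(1, config.n_replicates + 1):
            weights = rng.dirichlet(
                np.full(len(seqs), config.skew_concentration))
            tallies: dict[str, int] = {}
            assignment = rng.multinomial(config.read_depth, weights)
            for ai, n_reads in enumerate(assignment):
                if n_reads == 0:
                    continue
                n_chim = rng.binomial(n_reads, config.chimera_rate) \
                    if len(seqs) > 1 else 0
                n_err = rng.binomial(n_reads - n_chim,
                                     config.substitution_error_rate)
                n_clean = n_reads - n_chim - n_err
                base = seqs[ai]
                if n_clean:
                    tallies[base] = tallies.get(base, 0) + int(n_clean)
                for _ in range(n_err):
                    err = _one_bp_error(rng, base)
                    tallies[err] = tallies.get(err, 0) + 1
                    if err not in true_seqs:
                        provenance.setdefault(err, "1bp-error")
                for _ in range(n_chim):
                    other = int(rng.integers(len(seqs) - 1))
                    other += other >= ai
                    chim = _chimera(rng, base, seqs[other])
                    tallies[chim] = tallies.get(chim, 0) + 1
                    if chim not in true_seqs:
                        provenance[chim] = "chimera"
            amplicons.append(SimulatedAmplicon(ind, f"r{rep}", tallies))
    for s in true_seqs:
        provenance[s] = "true"
    return amplicons, truth


# ---------------------------------------------------------------------------
# parasites

def simulate_parasites(genotypes: GenotypeTable, config: SimulationConfig):
    """Negative-binomial parasite counts with season/group/allele effects."""
    rng = substream(config.seed, "parasites")
    taxa = config.parasite_taxa
    coef = {}
    counts = np.zeros((len(genotypes.individuals), len(taxa)), dtype=int)
    for j, taxon in enumerate(taxa):
        coef[taxon.name] = {
            "log_base": float(np.log(taxon.base_mean)) if taxon.base_mean > 0
            else -np.inf,
            "log_spring": float(np.log(taxon.spring_multiplier)),
            "host": taxon.host,
            "dispersion": taxon.dispersion,
        }
    for i, ind in enumerate(genotypes.individuals):
        row = genotypes.ind_meta.loc[ind]
        carried = set(genotypes.presence.columns[
            genotypes.presence.loc[ind].values == 1])
        for j, taxon in enumerate(taxa):
            if taxon.base_mean <= 0:
                continue
            if taxon.host == "generalist":
                host_factor = 1.0
            elif row.group == taxon.host:
                host_factor = 1.0
            elif row.group == "hybrid":
                host_factor = taxon.hybrid_factor
            else:
                host_factor = 0.0
            if host_factor == 0.0:
                continue
            log_mu = np.log(taxon.base_mean * host_factor)
            if row.season == "spring":
                log_mu += np.log(taxon.spring_multiplier)
            for (allele, tname), beta in config.allele_effects.items():
                if tname == taxon.name and allele in carried:
                    log_mu += beta
            mu = float(np.exp(log_mu))
            k = taxon.dispersion
            counts[i, j] = rng.negative_binomial(k, k / (k + mu))
    abundance = pd.DataFrame(counts, index=genotypes.individuals,
                             columns=[t.name for t in taxa])
    taxon_meta = pd.DataFrame(
        {"taxon_group": [t.taxon_group for t in taxa],
         "host": [t.host for t in taxa]},
        index=[t.name for t in taxa])
    truth = SimulationTruth(parasite_coefficients={
        "taxa": coef,
        "allele_effects": {f"{a}|{t}": b
                           for (a, t), b in config.allele_effects.items()},
    })
    return ParasiteMatrix(abundance, taxon_meta), truth


# ---------------------------------------------------------------------------
# end-to-end dataset

def simulate_dataset(config: SimulationConfig, outdir=None):
    """Run every stage; optionally write alleles.fasta, amplicons.tsv,
    genotypes.tsv, parasites.tsv and truth.json under ``outdir``."""
    pools, pool_truth = simulate_allele_pools(config)
    genotypes, geno_truth = simulate_genotypes(pools, config)
    amplicons, amp_truth = simulate_amplicons(genotypes, pools, config)
    parasites, para_truth = simulate_parasites(genotypes, config)
    truth = SimulationTruth(
        alleles_per_individual=geno_truth.alleles_per_individual,
        variant_provenance=amp_truth.variant_provenance,
        parasite_coefficients=para_truth.parasite_coefficients,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_pool_fasta(pools, outdir / "alleles.fasta")
        rows = []
        for amp in amplicons:
            for v, (seq, reads) in enumerate(sorted(amp.tallies.items())):
                rows.append((amp.specimen_id, amp.replicate_id,
                             f"{amp.specimen_id}.{amp.replicate_id}.v{v}",
                             seq, reads))
        pd.DataFrame(rows, columns=["specimen", "replicate", "variant_id",
                                    "sequence", "reads"]
                     ).to_csv(outdir / "amplicons.tsv", sep="\t", index=False)
        genotypes.to_tsv(outdir / "genotypes.tsv")
        parasites.to_tsv(outdir / "parasites.tsv")
        with open(outdir / "truth.json", "w") as fh:
            json.dump({
                "sharing": pool_truth,
                "alleles_per_individual": truth.alleles_per_individual,
                "variant_provenance": truth.variant_provenance,
                "parasite_coefficients": truth.parasite_coefficients,
            }, fh, indent=1, sort_keys=True)
    return {"pools": pools, "pool_truth": pool_truth, "genotypes": genotypes,
            "amplicons": amplicons, "parasites": parasites, "truth": truth}
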