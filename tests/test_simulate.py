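"""Unit tests for the synthetic-data generator."""

import numpy as np
import pytest

from hybridmhc.codon import CODON_AA, CODON_INDEX, equal_frequencies
from hybridmhc.diversity import sharing_partition
from hybridmhc.simulate import (
    SimulationConfig,
    evolve_codon_alignment,
    simulate_allele_pools,
    simulate_amplicons,
    simulate_genotypes,
    simulate_parasites,
    simulate_tree,
)


class TestSimulateTree:
    def test_three_taxa_forced_topology(self):
        tree = simulate_tree(3, seed=0)
        assert len(tree.taxa) == 3
        internal = sum(1 for n in range(tree.n_nodes)
                       if tree.children[n] and n != tree.root)
        assert internal == 1  # one internal node besides the root join

    def test_determinism(self):
        assert (simulate_tree(20, seed=1).to_newick()
                == simulate_tree(20, seed=1).to_newick())

    def test_positive_finite_length(self):
        tree = simulate_tree(20, seed=2)
        assert 0 < tree.total_length < np.inf
        assert (tree.edge_length[:-1] >= 0).all()

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            simulate_tree(2)


class TestEvolveCodonAlignment:
    def test_neutral_class_balances_substitution_types(self):
        """Under omega=1 the nonsynonymous fraction of observed one-step
        codon differences matches the mutation process expectation."""
        tree = simulate_tree(6, seed=3)
        pi = equal_frequencies()
        kappa = 2.0
        aln, _ = evolve_codon_alignment(tree, [(1.0, 1.0)], kappa, pi, 2000,
                                        seed=4)
        # expectation from the generator itself: enumerate one-step changes
        from hybridmhc.codon import _PAIR_SYN, _PAIR_TS  # noqa
        rates = np.where(_PAIR_TS, kappa, 1.0)
        expected_nonsyn = rates[~_PAIR_SYN].sum() / rates.sum()
        # observed: classify differences between the two most similar leaves
        nonsyn = syn = 0
        a, b = aln.codons[0], aln.codons[1]
        for x, y in zip(a, b):
            if x == y or x < 0 or y < 0:
                continue
            cx, cy = list(CODON_AA)[x], list(CODON_AA)[y]
            diffs = sum(p != q for p, q in
                        zip(_codon_str(x), _codon_str(y)))
            if diffs != 1:
                continue
            if cx == cy:
                syn += 1
            else:
                nonsyn += 1
        frac = nonsyn / max(nonsyn + syn, 1)
        assert abs(frac - expected_nonsyn) < 0.07

    def test_positive_sites_accumulate_amino_acid_changes(self):
        tree = simulate_tree(10, seed=5)
        pi = equal_frequencies()
        aln, labels = evolve_codon_alignment(
            tree, [(0.9, 0.1), (0.1, 4.0)], 2.0, pi, 400, seed=6)
        aa = np.array([[CODON_AA[c] for c in row] for row in aln.codons])
        n_states = np.array([len(set(aa[:, h])) for h in range(aln.n_codons)])
        assert n_states[labels == 1].mean() > n_states[labels == 0].mean()

    def test_empty_alignment(self):
        tree = simulate_tree(4, seed=0)
        aln, labels = evolve_codon_alignment(tree, [(1.0, 0.5)], 2.0,
                                             equal_frequencies(), 0, seed=0)
        assert aln.n_codons == 0 and len(labels) == 0

    def test_bad_proportions_rejected(self):
        tree = simulate_tree(4, seed=0)
        with pytest.raises(ValueError):
            evolve_codon_alignment(tree, [(0.5, 0.1), (0.4, 1.0)], 2.0,
                                   equal_frequencies(), 10, seed=0)

    def test_stop_codon_frequencies_rejected(self):
        tree = simulate_tree(4, seed=0)
        with pytest.raises(ValueError):
            evolve_codon_alignment(tree, [(1.0, 1.0)], 2.0,
                                   np.full(64, 1 / 64), 10, seed=0)


def _codon_str(idx):
    from hybridmhc.codon import CODONS
    return CODONS[idx]


class TestAllelePools:
    def test_zero_sharing_means_all_private(self):
        cfg = SimulationConfig(shared_fraction=0.0, n_hybrid_novel=0, seed=1)
        pools, truth = simulate_allele_pools(cfg)
        for lineage in ("DAB1", "DAB3"):
            sub = pools[pools.lineage == lineage]
            assert truth["shared"][lineage] == 0
            assert (sub.in_bream & sub.in_roach).sum() == 0
            assert sub.in_bream.sum() == cfg.pool_sizes[("bream", lineage)]

    def test_configured_sharing_recovered_by_partition(self):
        cfg = SimulationConfig(shared_fraction=0.2, n_hybrid_novel=0, seed=2,
                               pool_sizes={("bream", "DAB1"): 10,
                                           ("bream", "DAB3"): 20,
                                           ("roach", "DAB1"): 15,
                                           ("roach", "DAB3"): 45})
        pools, truth = simulate_allele_pools(cfg)
        occ = {a: {g for g, flag in
                   (("bream", r.in_bream), ("roach", r.in_roach)) if flag}
               for a, r in pools.iterrows()}
        part = sharing_partition(occ)
        expected_shared = sum(truth["shared"].values())
        assert part.pairwise_exclusive[frozenset(("bream", "roach"))] \
            == expected_shared
        for g in ("bream", "roach"):
            assert part.private[g] == sum(
                truth["private"][lin][g] for lin in ("DAB1", "DAB3"))

    def test_determinism(self):
        cfg = SimulationConfig(seed=3)
        p1, _ = simulate_allele_pools(cfg)
        p2, _ = simulate_allele_pools(cfg)
        assert p1.equals(p2)

    def test_zero_pool_rejected(self):
        cfg = SimulationConfig(seed=0)
        cfg.pool_sizes[("bream", "DAB1")] = 0
        with pytest.raises(ValueError):
            simulate_allele_pools(cfg)

    def test_sequences_have_no_stop_codons(self):
        pools, _ = simulate_allele_pools(SimulationConfig(seed=4))
        for seq in pools.sequence:
            for h in range(0, len(seq), 3):
                assert seq[h:h + 3] in CODON_INDEX


class TestGenotypes:
    def test_single_allele_range(self):
        cfg = SimulationConfig(
            seed=5, allele_count_range={"bream": (1, 1), "roach": (1, 1),
                                        "hybrid": (1, 1)},
            n_individuals={"bream": 20, "roach": 20, "hybrid": 20})
        pools, _ = simulate_allele_pools(cfg)
        table, _ = simulate_genotypes(pools, cfg)
        assert (table.counts_per_individual() == 1).all()

    def test_maternal_bias_half_is_balanced(self):
        cfg = SimulationConfig(
            seed=6, maternal_bias=0.5, n_hybrid_novel=0,
            n_individuals={"bream": 1, "roach": 1, "hybrid": 4000})
        pools, _ = simulate_allele_pools(cfg)
        table, _ = simulate_genotypes(pools, cfg)
        hyb = table.ind_meta[table.ind_meta.group == "hybrid"]
        # among hybrid-carried alleles private to one species, the share
        # from the maternal side should be ~0.5
        from_maternal = total = 0
        for ind, row in hyb.iterrows():
            for a in table.presence.columns[table.presence.loc[ind] == 1]:
                in_b = pools.loc[a, "in_bream"]
                in_r = pools.loc[a, "in_roach"]
                if in_b == in_r:
                    continue  # shared or novel: uninformative
                src = "bream" if in_b else "roach"
                total += 1
                from_maternal += src == row.maternal_line
        assert total > 2000
        assert abs(from_maternal / total - 0.5) < 0.03

    def test_hybrid_alleles_within_parental_union(self, small_dataset):
        pools = small_dataset["pools"]
        table = small_dataset["genotypes"]
        allowed = set(pools.index[pools.in_bream | pools.in_roach
                                  | pools.hybrid_only])
        hyb = table.ind_meta.index[table.ind_meta.group == "hybrid"]
        for ind in hyb:
            carried = set(table.presence.columns[table.presence.loc[ind] == 1])
            assert carried <= allowed

    def test_count_exceeding_pool_rejected(self):
        cfg = SimulationConfig(
            seed=7, allele_count_range={"bream": (5, 5), "roach": (1, 2),
                                        "hybrid": (1, 2)},
            pool_sizes={("bream", "DAB1"): 1, ("bream", "DAB3"): 1,
                        ("roach", "DAB1"): 4, ("roach", "DAB3"): 6},
            n_individuals={"bream": 5, "roach": 2, "hybrid": 2})
        pools, _ = simulate_allele_pools(cfg)
        with pytest.raises(ValueError):
            simulate_genotypes(pools, cfg)


class TestAmplicons:
    def test_error_free_amplicons_match_truth(self):
        cfg = SimulationConfig(
            seed=8, substitution_error_rate=0.0, chimera_rate=0.0,
            no_amplification_rate=0.0,
            n_individuals={"bream": 10, "roach": 10, "hybrid": 5})
        pools, _ = simulate_allele_pools(cfg)
        table, _ = simulate_genotypes(pools, cfg)
        amps, truth = simulate_amplicons(table, pools, cfg)
        seq_of = pools.sequence.to_dict()
        for amp in amps:
            true_alleles = {
                seq_of[a] for a in table.presence.columns
                if table.presence.loc[amp.specimen_id, a] == 1}
            assert set(amp.tallies) <= true_alleles

    def test_chimeras_reconstructable_from_parents(self, small_dataset):
        truth = small_dataset["truth"].variant_provenance
        pools = small_dataset["pools"]
        table = small_dataset["genotypes"]
        seq_of = pools.sequence.to_dict()
        chimeras = [(s, lbl) for s, lbl in truth.items() if lbl == "chimera"]
        assert chimeras, "chimera rate 0.02 at depth 200 must yield chimeras"
        checked = 0
        for amp in small_dataset["amplicons"]:
            present = {seq_of[a] for a in table.presence.columns
                       if table.presence.loc[amp.specimen_id, a] == 1}
            for seq in amp.tallies:
                if truth.get(seq) != "chimera":
                    continue
                ok = any(
                    seq == p1[:b] + p2[b:]
                    for p1 in present for p2 in present if p1 != p2
                    for b in range(1, len(seq)))
                assert ok, "chimera not explained by same-amplicon parents"
                checked += 1
                if checked > 20:
                    return
        assert checked > 0

    def test_provenance_partition(self, small_dataset):
        labels = set(small_dataset["truth"].variant_provenance.values())
        assert labels <= {"true", "1bp-error", "chimera"}

    def test_determinism(self, small_config):
        a1, _ = simulate_amplicons(*_geno(small_config), small_config)
        a2, _ = simulate_amplicons(*_geno(small_config), small_config)
        assert [(x.specimen_id, x.replicate_id, x.tallies) for x in a1] \
            == [(y.specimen_id, y.replicate_id, y.tallies) for y in a2]


def _geno(cfg):
    from hybridmhc.simulate import simulate_allele_pools, simulate_genotypes
    pools, _ = simulate_allele_pools(cfg)
    table, _ = simulate_genotypes(pools, cfg)
    return table, pools


class TestParasites:
    def test_zero_means_give_zero_matrix(self, small_config):
        import dataclasses
        from hybridmhc.simulate import ParasiteTaxon
        cfg = dataclasses.replace(
            small_config,
            parasite_taxa=[ParasiteTaxon("t0", "Monogenea", "generalist", 0.0)])
        table, pools = _geno(cfg)[0], None
        mat, _ = simulate_parasites(table, cfg)
        assert (mat.abundance.values == 0).all()

    def test_spring_multiplier_recovered_by_glm(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        from hybridmhc.simulate import ParasiteTaxon
        cfg = SimulationConfig(
            seed=9, n_individuals={"bream": 500, "roach": 2, "hybrid": 2},
            parasite_taxa=[ParasiteTaxon("tx", "Monogenea", "bream", 10.0,
                                         spring_multiplier=3.0,
                                         dispersion=2.0)])
        table, _ = _geno(cfg), None
        table = table[0]
        mat, _ = simulate_parasites(table, cfg)
        df = table.ind_meta.join(mat.abundance)
        df = df[df.group == "bream"]
        fit = smf.glm("tx ~ season", df,
                      family=sm.families.Poisson()).fit()
        ratio = np.exp(fit.params["season[T.spring]"])
        assert abs(ratio - 3.0) < 0.6

    def test_nb_dispersion_recovered_by_moments(self):
        from hybridmhc.simulate import ParasiteTaxon
        cfg = SimulationConfig(
            seed=10, n_individuals={"bream": 1000, "roach": 2, "hybrid": 2},
            parasite_taxa=[ParasiteTaxon("tx", "Monogenea", "bream", 8.0,
                                         spring_multiplier=1.0,
                                         dispersion=0.5)])
        table = _geno(cfg)[0]
        mat, _ = simulate_parasites(table, cfg)
        x = mat.abundance.loc[table.ind_meta.group == "bream", "tx"].values
        m, v = x.mean(), x.var(ddof=1)
        k_hat = m ** 2 / (v - m)
        assert abs(k_hat - 0.5) < 0.15

    def test_counts_nonnegative_integers(self, small_dataset):
        ab = small_dataset["parasites"].abundance.values
        assert (ab >= 0).all() and np.issubdtype(ab.dtype, np.integer)
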