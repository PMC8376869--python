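"""Unit tests for amplicon allele validation (MPAF/artifact rules)."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hybridmhc.genotyping import (
    Amplicon,
    assign_lineage,
    classify_chimera,
    classify_substitution_artifact,
    prefilter_variants,
    replicate_concordance,
    tally_and_mpaf,
    validate_alleles,
)

SEQ = "ATGGCTAAAGGT"  # 12 nt reference


def amp(spec, rep, tallies):
    return Amplicon(spec, rep, tallies)


class TestTallyAndMpaf:
    def test_mpaf_is_max_over_amplicons(self):
        a1 = amp("s1", "r1", {SEQ: 10, "A" * 12: 90})
        a2 = amp("s2", "r1", {SEQ: 2, "A" * 12: 98})
        records = tally_and_mpaf([a1, a2])
        assert records[SEQ].mpaf == pytest.approx(0.10)

    def test_within_amplicon_frequencies(self):
        a = amp("s", "r", {"A" * 12: 60, "C" * 12: 30, SEQ: 10})
        assert a.frequency("A" * 12) == pytest.approx(0.6)
        assert a.frequency("C" * 12) == pytest.approx(0.3)
        assert a.frequency(SEQ) == pytest.approx(0.1)

    def test_absent_variants_not_emitted(self):
        records = tally_and_mpaf([amp("s", "r", {SEQ: 5})])
        assert set(records) == {SEQ}

    def test_empty_amplicon_rejected(self):
        with pytest.raises(ValueError):
            Amplicon("s", "r", {})


class TestPrefilter:
    @pytest.mark.parametrize("delta,flagged", [(-1, True), (-3, False),
                                               (1, True), (0, False)])
    def test_frameshift_flag(self, delta, flagged):
        seq = "A" * (12 + delta)
        records = tally_and_mpaf([amp("s", "r", {seq: 10, SEQ: 10})])
        prefilter_variants(records, reference_length=12)
        assert ("frameshift_indel" in records[seq].flags) is flagged

    def test_global_singleton(self):
        records = tally_and_mpaf([amp("s", "r", {SEQ: 1, "A" * 12: 99})])
        prefilter_variants(records, 12)
        assert "global_singleton" in records[SEQ].flags
        assert "global_singleton" not in records["A" * 12].flags


class TestSubstitutionArtifact:
    def test_distance_one_from_dominant(self):
        v = "ATGGCTAAAGGA"  # 1 bp from SEQ
        a = amp("s", "r", {SEQ: 60, "C" * 12: 39, v: 1})
        assert classify_substitution_artifact(v, a) is True

    def test_distance_two_is_not_explained(self):
        v = "ATGGCTAAATTA"
        a = amp("s", "r", {SEQ: 60, v: 1})
        assert classify_substitution_artifact(v, a) is False

    def test_lower_frequency_neighbor_does_not_explain(self):
        v = "ATGGCTAAAGGA"
        a = amp("s", "r", {v: 10, SEQ: 5, "C" * 12: 85})
        assert classify_substitution_artifact(v, a) is False


class TestChimera:
    P1 = "AAAAAACCCCCC"
    P2 = "GGGGGGTTTTTT"

    def test_exact_recombinant_detected_with_breakpoint(self):
        v = self.P1[:6] + self.P2[6:]
        a = amp("s", "r", {self.P1: 50, self.P2: 45, v: 5})
        ok, bp = classify_chimera(v, a)
        assert ok and 1 <= bp <= 11
        assert v == self.P1[:bp] + self.P2[bp:]

    def test_variant_equal_to_parent_is_not_chimera(self):
        a = amp("s", "r", {self.P1: 50, self.P2: 45, "A" * 12: 5})
        # A*12 shares prefix with P1 but no breakpoint reproduces it
        ok, _ = classify_chimera("A" * 12, a)
        assert not ok

    def test_low_frequency_parent_excluded(self):
        v = self.P1[:6] + self.P2[6:]
        a = amp("s", "r", {self.P1: 80, self.P2: 3, v: 5, "C" * 12: 12})
        ok, _ = classify_chimera(v, a)
        assert not ok

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.data())
    def test_matches_exhaustive_breakpoint_oracle(self, data):
        rng_seqs = data.draw(st.lists(
            st.text(alphabet="ACGT", min_size=8, max_size=8),
            min_size=3, max_size=6, unique=True))
        counts = data.draw(st.lists(
            st.integers(min_value=1, max_value=100),
            min_size=len(rng_seqs), max_size=len(rng_seqs)))
        a = amp("s", "r", dict(zip(rng_seqs, counts)))
        for v in rng_seqs:
            got, _ = classify_chimera(v, a)
            f = a.frequency(v)
            parents = [p for p in rng_seqs
                       if p != v and a.frequency(p) > f]
            expect = any(
                v == p1[:b] + p2[b:] and v != p1 and v != p2
                for p1 in parents for p2 in parents if p1 != p2
                for b in range(1, 8))
            assert got == expect


class TestValidateAlleles:
    def test_clean_data_recovers_truth_exactly(self):
        alleles = ["AAAAAACCCCCC", "GGGGGGTTTTTT", "ACGTACGTACGT"]
        amps = [amp("s1", "r1", {alleles[0]: 100, alleles[1]: 100}),
                amp("s2", "r1", {alleles[2]: 150})]
        records = prefilter_variants(tally_and_mpaf(amps), 12)
        true_seqs, genos, _ = validate_alleles(records, amps)
        assert true_seqs == set(alleles)
        assert genos["s1"] == set(alleles[:2])
        assert genos["s2"] == {alleles[2]}

    def test_prefilter_dominates_high_mpaf(self):
        short = "A" * 11  # frameshift vs 12-nt reference
        amps = [amp("s", "r", {SEQ: 90, short: 6, "C" * 12: 4})]
        records = prefilter_variants(tally_and_mpaf(amps), 12)
        assert records[short].mpaf > 0.05
        _, _, records = validate_alleles(records, amps)
        assert records[short].status == "artifact"

    def test_every_variant_gets_exactly_one_status(self, small_dataset):
        amps = [Amplicon(a.specimen_id, a.replicate_id, a.tallies)
                for a in small_dataset["amplicons"]]
        records = prefilter_variants(tally_and_mpaf(amps), 270)
        _, _, records = validate_alleles(records, amps, min_coverage=100)
        assert all(r.status in ("true_allele", "artifact")
                   for r in records.values())

    def test_no_amplification_reported_as_none(self):
        amps = [amp("s1", "r1", {SEQ: 10})]
        records = prefilter_variants(tally_and_mpaf(amps), 12)
        _, genos, _ = validate_alleles(records, amps, min_coverage=100)
        assert genos["s1"] is None

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=20))
    def test_mpaf_threshold_monotonicity(self, small_dataset, pct):
        """Raising the MPAF threshold never converts artifact -> true."""
        amps = [Amplicon(a.specimen_id, a.replicate_id, a.tallies)
                for a in small_dataset["amplicons"][:40]]
        lo, hi = pct / 100.0, pct / 100.0 + 0.05
        rec_lo = prefilter_variants(tally_and_mpaf(amps), 270)
        t_lo, _, _ = validate_alleles(rec_lo, amps, mpaf_threshold=lo)
        rec_hi = prefilter_variants(tally_and_mpaf(amps), 270)
        t_hi, _, _ = validate_alleles(rec_hi, amps, mpaf_threshold=hi)
        assert t_hi <= t_lo

    def test_idempotence_of_statuses(self):
        alleles = ["AAAAAACCCCCC", "GGGGGGTTTTTT"]
        amps = [amp("s1", "r1", {alleles[0]: 100, alleles[1]: 80,
                                 alleles[0][:6] + alleles[1][6:]: 3})]
        records = prefilter_variants(tally_and_mpaf(amps), 12)
        _, _, rec1 = validate_alleles(records, amps)
        statuses1 = {s: r.status for s, r in rec1.items()}
        _, _, rec2 = validate_alleles(rec1, amps)
        assert statuses1 == {s: r.status for s, r in rec2.items()}


class TestReplicateConcordance:
    def test_identical_replicates(self):
        amps = [amp("s", "r1", {SEQ: 100}), amp("s", "r2", {SEQ: 90})]
        rep = replicate_concordance(amps, {SEQ})
        assert rep.loc[0, "jaccard"] == 1.0

    def test_disjoint_replicates(self):
        amps = [amp("s", "r1", {SEQ: 100}),
                amp("s", "r2", {"A" * 12: 90})]
        rep = replicate_concordance(amps, {SEQ, "A" * 12})
        assert rep.loc[0, "jaccard"] == 0.0

    def test_single_replicate_flagged_unreplicated(self):
        rep = replicate_concordance([amp("s", "r1", {SEQ: 10})], {SEQ})
        assert rep.loc[0, "flag"] == "unreplicated"
        assert rep.loc[0, "jaccard"] is None or np.isnan(rep.loc[0, "jaccard"])


class TestAssignLineage:
    def test_exact_match(self):
        labels = assign_lineage({"a": SEQ}, {"DAB1": [SEQ],
                                             "DAB3": ["C" * 12]})
        assert labels["a"] == "DAB1"

    def test_equidistant_is_unresolved(self):
        labels = assign_lineage({"a": "AACC"},
                                {"DAB1": ["AAGG"], "DAB3": ["TTCC"]})
        assert labels["a"] == "unresolved"

    def test_no_exemplars_rejected(self):
        with pytest.raises(ValueError):
            assign_lineage({"a": SEQ}, {})

    def test_full_recovery_on_synthetic_pools(self, small_dataset):
        pools = small_dataset["pools"]
        exemplars = {
            lin: pools.sequence[pools.lineage == lin].iloc[:1].tolist()
            for lin in ("DAB1", "DAB3")}
        labels = assign_lineage(pools.sequence.to_dict(), exemplars)
        assert all(labels[a] == pools.loc[a, "lineage"] for a in pools.index)
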