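"""Read counting, outcome classification, efficiency computation and
normalization."""

import numpy as np
import pandas as pd
import pytest

from peginsert.core import InsertSequence
from peginsert.screen import (
    CountTable,
    average_replicates,
    classify_outcomes,
    combine_replicates,
    compute_efficiencies,
    length_normalize,
    match_pegrna_reads,
    match_target_reads,
    merge_sets,
    osa_distance,
    outcome_counts,
    pegrna_plasmid_flanks,
    snv_profile,
    trim_window,
    zscore_normalize,
)

LIB = [
    InsertSequence("short", "CAC"),
    InsertSequence("mid", "GATTACAGGATCC"),
    InsertSequence("long", "GCGTACGCAGGCTAGAAATAGCC"),
]


def _target_read(site, insert=""):
    return site.flank_up[-10:] + insert + site.flank_down[:10]


class TestMatchTargetReads:
    def test_exact_counting_and_unedited(self, site):
        reads = (
            [_target_read(site, "CAC")] * 40
            + [_target_read(site)] * 60
            + ["GGGG" + _target_read(site, "CAC") + "TTTT"] * 2  # embedded ok
        )
        table = match_target_reads(reads, site, LIB)
        assert table.counts["short"] == 42
        assert table.unedited == 60
        assert table.unmatched == 0
        assert table.total_reads == 102

    def test_zero_mismatch_requirement(self, site):
        # one substitution in the insert: must be unmatched, not counted
        read = site.flank_up[-10:] + "CAG" + site.flank_down[:10]
        table = match_target_reads([read], site, LIB)
        assert table.counts["short"] == 0
        assert table.unmatched == 1

    def test_wrong_site_raises(self, site):
        with pytest.raises(ValueError, match="wrong target site"):
            match_target_reads(["T" * 40] * 10, site, LIB)

    def test_count_invariant(self, site):
        reads = [_target_read(site, "CAC")] * 5 + [_target_read(site)] * 3 + ["A" * 30]
        t = match_target_reads(reads, site, LIB)
        assert sum(t.counts.values()) + t.unedited + t.unmatched == t.total_reads


class TestMatchPegrnaReads:
    def test_fifteen_nt_anchor_roundtrip(self, site):
        up, down = pegrna_plasmid_flanks(site)
        reads = [up + "CAC" + down] * 7 + [up + "TTTTTTT" + down] * 2
        table = match_pegrna_reads(reads, LIB, up, down)
        assert table.counts["short"] == 7
        assert table.unmatched == 2  # insert absent from library

    def test_short_anchor_rejected(self, site):
        with pytest.raises(ValueError):
            match_pegrna_reads([], LIB, "ACGT", "ACGTACGTACGTACG")


class TestClassifyOutcomes:
    def _window(self, site, insert=""):
        return site.flank_up[-23:] + insert + site.flank_down[:60]

    def test_known_composition_fixture(self, site):
        """200 reads of known composition classify to exact category counts."""
        prefix = site.flank_up[-23:]
        suffix = site.flank_down[:60]
        ha = site.flank_down[:34]
        mutated = list(LIB[2].written_seq)
        mutated[3] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mutated[3]]
        snv = list(prefix + suffix)
        snv[5] = "A" if snv[5] != "A" else "G"
        reads = (
            [self._window(site, "CAC")] * 70                      # library_insertion
            + [self._window(site)] * 60                           # unedited
            + ["".join(snv)] * 10                                 # snv_only
            + [self._window(site, "CAC").replace("C", "N", 1)] * 5  # dropped
            + [prefix + LIB[2].written_seq + ha + "GCACCGA" + suffix] * 15
            + [prefix + "".join(mutated) + suffix] * 12           # mutated_insertion
            + [prefix + ha + suffix] * 8                          # duplication
            + [prefix[:-3] + suffix[3:]] * 11                     # nick_deletion
            + [prefix + suffix[:40] + suffix[46:]] * 9            # other_deletion
        )
        records = classify_outcomes(reads, site, LIB)
        counts = outcome_counts(records)
        assert counts["library_insertion"] == 70
        assert counts["unedited"] == 60
        assert counts["snv_only"] == 10
        assert counts["dropped"] == 5
        assert counts["scaffold_integration"] == 15
        assert counts["mutated_insertion"] == 12
        assert counts["duplication"] == 8
        assert counts["nick_deletion"] == 11
        assert counts["other_deletion"] == 9
        assert counts.sum() == 200

    def test_indel_free_length_is_not_an_indel(self, site):
        read = list(self._window(site))
        read[2] = "A" if read[2] != "A" else "C"
        rec = classify_outcomes(["".join(read)], site, LIB)[0]
        assert rec.category == "snv_only"

    def test_mutated_insertion_respects_osa_cutoff(self, site):
        base = LIB[2].written_seq
        four_subs = list(base)
        for i in range(4):
            four_subs[i * 3] = {"A": "C", "C": "A", "G": "T", "T": "G"}[four_subs[i * 3]]
        read = site.flank_up[-23:] + "".join(four_subs) + site.flank_down[:60]
        rec = classify_outcomes([read], site, LIB)[0]
        assert rec.category != "mutated_insertion"

    def test_short_inserts_excluded_from_fuzzy_match(self, site):
        # 3-nt insert with 1 mismatch: not fuzzy-matched (library insert <=10 nt)
        read = site.flank_up[-23:] + "CAG" + site.flank_down[:60]
        rec = classify_outcomes([read], site, LIB)[0]
        assert rec.category != "mutated_insertion"

    def test_trim_window_anchors(self, site):
        inner = site.flank_up[-23:] + "CAC" + site.flank_down[:60]
        trimmed = trim_window([("r1", "GGAA" + inner + "CCTT"), ("r2", "TTTT")], site)
        assert trimmed == [("r1", inner)]


class TestOsaDistance:
    @pytest.mark.parametrize(
        "a,b,d",
        [("ABC", "ABC", 0), ("ABC", "ACB", 1), ("ABC", "AXC", 1),
         ("ABC", "AB", 1), ("KITTEN", "SITTING", 3), ("CA", "ABC", 3)],
    )
    def test_known_distances(self, a, b, d):
        assert osa_distance(a, b) == d

    def test_cutoff_short_circuits(self):
        assert osa_distance("A" * 30, "C" * 30, cutoff=3) == 4


class TestSnvProfile:
    def test_all_reference_reads_have_zero_rates(self, site):
        read = site.flank_up[-23:] + site.flank_down[:60]
        rates, _ = snv_profile([read] * 20, site)
        assert (rates["mutation_rate"] == 0).all()
        assert list(rates["offset"])[:3] == [-23, -22, -21]
        assert list(rates["offset"])[-1] == 60

    def test_spiked_substitution_recovered(self, site):
        ref = site.flank_up[-23:] + site.flank_down[:60]
        mut = list(ref)
        pos = 30  # offset +8 downstream
        mut[pos] = "A" if ref[pos] != "A" else "G"
        reads = [ref] * 90 + ["".join(mut)] * 10
        rates, _ = snv_profile(reads, site)
        row = rates[rates["offset"] == pos - 23 + 1].iloc[0]
        assert row["mutation_rate"] == pytest.approx(0.10)

    def test_known_variant_excluded_from_mutations(self, site):
        from peginsert.core import KnownVariant, TargetSite

        ref = site.flank_up[-23:] + site.flank_down[:60]
        pos9 = 23 + 8  # offset +9
        alt = "A" if ref[pos9] != "A" else "T"
        kv_site = TargetSite(site.name, site.flank_up, site.flank_down,
                             known_variant=KnownVariant(9, ref[pos9], alt))
        mut = list(ref)
        mut[pos9] = alt
        reads = [ref] * 67 + ["".join(mut)] * 33
        rates, variant_freq = snv_profile(reads, kv_site)
        row = rates[rates["offset"] == 9].iloc[0]
        assert row["mutation_rate"] == 0.0
        assert variant_freq == pytest.approx(0.33)


def _tables(target_counts, pegrna_counts, screen_id="s", replicate="r1",
            t_extra=0, p_extra=0):
    t = CountTable(screen_id, replicate, "target", dict(target_counts),
                   unmatched=t_extra)
    p = CountTable(screen_id, replicate, "pegRNA", dict(pegrna_counts),
                   unmatched=p_extra)
    return t, p


class TestEfficiencies:
    def test_frequency_ratio(self):
        # target freq 0.02, pegRNA freq 0.04 -> 0.5
        t, p = _tables({"a": 20}, {"a": 40}, t_extra=980, p_extra=960)
        eff = compute_efficiencies(t, p)
        assert eff.set_index("insert_id").loc["a", "efficiency"] == pytest.approx(0.5)

    def test_scale_invariance(self):
        t, p = _tables({"a": 30, "b": 50}, {"a": 40, "b": 25}, t_extra=100)
        e1 = compute_efficiencies(t, p)
        t10, p10 = _tables({"a": 300, "b": 500}, {"a": 400, "b": 250}, t_extra=1000)
        e2 = compute_efficiencies(t10, p10)
        pd.testing.assert_frame_equal(e1, e2)

    def test_min_reads_filter_any_replicate(self):
        r1 = _tables({"a": 30, "b": 10}, {"a": 25, "b": 19}, replicate="r1")
        r2 = _tables({"a": 30, "b": 10}, {"a": 25, "b": 40}, replicate="r2")
        eff = combine_replicates([r1, r2])
        assert set(eff["insert_id"]) == {"a"}  # b dropped everywhere (19 < 20)
        assert len(eff) == 2  # a present in both replicates

    def test_average_replicates(self):
        eff = pd.DataFrame(
            {"insert_id": ["a", "a"], "screen_id": ["s", "s"],
             "replicate": ["r1", "r2"], "efficiency": [0.2, 0.4]}
        )
        avg = average_replicates(eff)
        assert avg.loc[0, "efficiency"] == pytest.approx(0.3)


class TestMergeSets:
    def test_identical_shared_means_leave_set2_unchanged(self):
        s1 = pd.DataFrame({"insert_id": ["a", "b"], "efficiency": [1.0, 3.0]})
        s2 = pd.DataFrame({"insert_id": ["a", "b", "c"], "efficiency": [1.0, 3.0, 5.0]})
        merged = merge_sets(s1, s2).set_index("insert_id")
        assert merged.loc["c", "efficiency"] == pytest.approx(5.0)

    def test_half_scale_recovered(self):
        s1 = pd.DataFrame({"insert_id": ["a", "b"], "efficiency": [2.0, 4.0]})
        s2 = pd.DataFrame({"insert_id": ["a", "b", "c"], "efficiency": [1.0, 2.0, 3.0]})
        merged = merge_sets(s1, s2).set_index("insert_id")
        assert merged.loc["c", "efficiency"] == pytest.approx(6.0)  # scale 2
        # shared inserts: mean of both sets after scaling
        assert merged.loc["a", "efficiency"] == pytest.approx(2.0)

    def test_random_perturbation_matches_hand_computation(self):
        rng = np.random.default_rng(0)
        e1 = rng.uniform(0.5, 2.0, 5)
        e2 = rng.uniform(0.5, 2.0, 5)
        ids = [f"i{k}" for k in range(5)]
        s1 = pd.DataFrame({"insert_id": ids, "efficiency": e1})
        s2 = pd.DataFrame({"insert_id": ids, "efficiency": e2})
        merged = merge_sets(s1, s2).set_index("insert_id")
        scale = e1.mean() / e2.mean()
        expected = (e1 + e2 * scale) / 2
        np.testing.assert_allclose(
            merged.loc[ids, "efficiency"].to_numpy(), expected
        )

    def test_no_shared_inserts_errors(self):
        s1 = pd.DataFrame({"insert_id": ["a"], "efficiency": [1.0]})
        s2 = pd.DataFrame({"insert_id": ["b"], "efficiency": [1.0]})
        with pytest.raises(ValueError):
            merge_sets(s1, s2)


class TestLengthNormalize:
    def test_bin_median_divisor(self):
        eff = pd.DataFrame(
            {"insert_id": ["a", "b", "c"], "screen_id": "s", "replicate": "r1",
             "efficiency": [2.0, 4.0, 8.0]}
        )
        lengths = {"a": 12, "b": 13, "c": 14}  # all in bin 10-14, median 4
        out = length_normalize(eff, lengths)
        assert list(out["length_relative"]) == [0.5, 1.0, 2.0]

    def test_single_insert_bin_is_one(self):
        eff = pd.DataFrame(
            {"insert_id": ["a"], "screen_id": "s", "replicate": "r1",
             "efficiency": [7.0]}
        )
        out = length_normalize(eff, {"a": 25})
        assert out.loc[0, "length_relative"] == 1.0

    def test_exact_length_below_ten(self):
        eff = pd.DataFrame(
            {"insert_id": list("abcd"), "screen_id": "s", "replicate": "r1",
             "efficiency": [1.0, 3.0, 10.0, 30.0]}
        )
        lengths = {"a": 5, "b": 5, "c": 6, "d": 6}
        out = length_normalize(eff, lengths).set_index("insert_id")
        assert out.loc["a", "length_relative"] == pytest.approx(0.5)
        assert out.loc["c", "length_relative"] == pytest.approx(0.5)


class TestZscoreNormalize:
    def test_population_zscore_values(self):
        eff = pd.DataFrame(
            {"insert_id": list("abc"), "screen_id": "s", "replicate": "r1",
             "efficiency": [1.0, 2.0, 3.0]}
        )
        out = zscore_normalize(eff)
        np.testing.assert_allclose(
            out["zscore"], [-1.224745, 0.0, 1.224745], atol=1e-6
        )

    def test_group_mean_zero_sd_one(self):
        rng = np.random.default_rng(1)
        eff = pd.DataFrame(
            {
                "insert_id": [f"i{k}" for k in range(40)],
                "screen_id": ["s1"] * 20 + ["s2"] * 20,
                "replicate": (["r1"] * 10 + ["r2"] * 10) * 2,
                "efficiency": rng.lognormal(0, 1, 40),
            }
        )
        out = zscore_normalize(eff)
        for _, grp in out.groupby(["screen_id", "replicate"]):
            assert grp["zscore"].mean() == pytest.approx(0.0, abs=1e-12)
            assert grp["zscore"].std(ddof=0) == pytest.approx(1.0, abs=1e-12)

    def test_constant_group_errors(self):
        eff = pd.DataFrame(
            {"insert_id": ["a", "b"], "screen_id": "s", "replicate": "r1",
             "efficiency": [1.0, 1.0]}
        )
        with pytest.raises(ValueError):
            zscore_normalize(eff)
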