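"""Tag mapping, copy-number bins, Venn partition, target calling/ranking."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from dgescreen.profile import (
    DEFAULT_COPY_BINS,
    copy_number_distribution,
    map_tags,
    rank_targets,
    stage_specific_calls,
    tags_per_million,
    venn_partition,
)
from dgescreen.tag_filter import CleanTagTable, filter_tags
from dgescreen.tag_reference import build_tag_index
from dgescreen.simulate import sample_tag_library

STAGES = ("egg", "larva", "pupa", "adult")

# Ten larval-stage tags with printed per-stage copy numbers, used as a
# worked mapping/screening example (a chymotrypsin-like protease tag
# reaches 3,281 copies in larva and none elsewhere, etc.)
LARVAL_TAGS = {
    "DS2": ("GACGCTGGTGAACACCT", (0, 6325, 1942, 1136)),
    "DS3": ("CTGACCGCCGCCGCGGA", (0, 5134, 2839, 550)),
    "DS5": ("GTTTAACAGCCATATGT", (0, 3281, 0, 0)),
    "DS6": ("GGGCTTCCCCTGCGCCC", (8, 2244, 0, 8)),
    "DS10": ("CACCCTCAGTGGACCCC", (0, 1239, 2, 0)),
    "DS12": ("GTGTTCGCGTGAACAAC", (15, 1229, 29, 64)),
    "DS28": ("AGAATAATGCAAGCTTG", (0, 566, 0, 0)),
    "DS30": ("ACGAGCTATCATCGCCT", (0, 537, 0, 0)),
    "DS34": ("CAGTACAAGCCGAACCA", (0, 421, 2, 0)),
    "DS35": ("ATGGTTCTTTATCCAAC", (4, 390, 0, 0)),
}


@pytest.fixture(scope="module")
def larval_profile():
    """Index + clean tables realising the ten-tag example."""
    unigenes = {name: "CATG" + tag17 for name, (tag17, _) in LARVAL_TAGS.items()}
    index = build_tag_index(unigenes)
    clean = {}
    for i, stage in enumerate(STAGES):
        counts = {t: c[i] for t, c in LARVAL_TAGS.values() if c[i] >= 2}
        clean[stage] = CleanTagTable(library=stage, counts=counts)
    return map_tags(clean, index)


class TestMapTags:
    def test_unique_hit_credits_unigene(self, larval_profile):
        row = larval_profile.unigene_counts.loc["DS5"]
        assert row.tolist() == [0, 3281, 0, 0]

    def test_unmapped_tag_counted_not_credited(self):
        index = build_tag_index({"u1": "CATG" + "A" * 17})
        clean = {"egg": CleanTagTable("egg", {"C" * 17: 5})}
        prof = map_tags(clean, index)
        assert prof.unmapped["egg"] == 5
        assert len(prof.unigene_counts) == 0

    def test_ambiguous_tags_sidelined(self):
        shared = "CATG" + "G" * 17
        index = build_tag_index({"u1": shared, "u2": "TT" + shared})
        clean = {"egg": CleanTagTable("egg", {"G" * 17: 7})}
        prof = map_tags(clean, index)
        assert prof.ambiguous_totals["egg"] == 7
        assert len(prof.unigene_counts) == 0
        prof.check_conservation()

    def test_conservation_identity(self, larval_profile):
        larval_profile.check_conservation()
        for s in STAGES:
            assert (
                int(larval_profile.tag_counts[s].sum())
                + larval_profile.ambiguous_totals[s]
                + larval_profile.unmapped[s]
                == larval_profile.clean_totals[s]
            )

    def test_stage_label_mismatch_rejected(self):
        index = build_tag_index({"u1": "CATG" + "A" * 17})
        with pytest.raises(ValueError, match="label"):
            map_tags({"egg": CleanTagTable("larva", {})}, index)

    def test_noise_free_pipeline_matches_sampled_counts(self, small_config, small_truth):
        """Without noise, unigene counts equal the multinomial library
        sample aggregated per unigene (exact conservation end to end)."""
        unigenes, truth = small_truth
        index = build_tag_index(unigenes)
        clean = {}
        for stage in STAGES:
            lib = sample_tag_library(truth, stage, small_config)
            clean[stage], _ = filter_tags(lib, library=stage)
        prof = map_tags(clean, index)
        # every sampled tag is a true canonical tag, so mapped + unmapped
        # (dropped singletons are the only loss) equals the library depth
        for stage in STAGES:
            assert prof.clean_totals[stage] <= small_config.library_depth
            assert prof.unmapped[stage] == 0 and prof.ambiguous_totals[stage] == 0


class TestCopyNumberDistribution:
    def test_single_tag_count_two(self):
        dist = copy_number_distribution({"egg": CleanTagTable("egg", {"A" * 17: 2})})
        assert dist.table.loc["2", "egg"] == 1
        assert dist.table["egg"].sum() == 1

    def test_matches_brute_force_binning(self):
        rng = np.random.default_rng(2)
        counts = {f"TAG{i:013d}AAAA"[:17]: int(c) for i, c in
                  enumerate(rng.integers(2, 20000, size=500))}
        table = CleanTagTable("egg", counts)
        dist = copy_number_distribution({"egg": table})
        edges = list(DEFAULT_COPY_BINS) + [math.inf]
        expected = [
            sum(1 for c in counts.values() if lo <= c < hi)
            for lo, hi in zip(edges, edges[1:])
        ]
        assert dist.table["egg"].tolist() == expected
        assert dist.table["egg"].sum() == len(counts)

    def test_column_total_equals_clean_unique(self, larval_profile):
        tables = {
            s: CleanTagTable(s, {t: c[i] for t, c in LARVAL_TAGS.values() if c[i] >= 2})
            for i, s in enumerate(STAGES)
        }
        dist = copy_number_distribution(tables)
        for s in STAGES:
            assert dist.column_totals[s] == tables[s].n_unique
        assert dist.grand_total == sum(t.n_unique for t in tables.values())

    def test_bad_bins_rejected(self):
        table = {"egg": CleanTagTable("egg", {})}
        with pytest.raises(ValueError):
            copy_number_distribution(table, boundaries=(3, 10))
        with pytest.raises(ValueError):
            copy_number_distribution(table, boundaries=(2, 10, 5))


class TestVennPartition:
    def test_larva_only_items(self):
        m = pd.DataFrame({"egg": [0, 0], "larva": [3, 9], "pupa": [0, 0], "adult": [0, 0]})
        counts = venn_partition(m)
        assert counts[frozenset({"larva"})] == 2
        assert sum(counts.values()) == 2

    def test_everywhere_item(self):
        m = pd.DataFrame({s: [1] for s in STAGES})
        counts = venn_partition(m)
        assert counts[frozenset(STAGES)] == 1

    def test_fifteen_categories_for_four_stages(self):
        m = pd.DataFrame({s: [1] for s in STAGES})
        assert len(venn_partition(m)) == 15

    def test_matches_subset_enumeration_oracle(self):
        rng = np.random.default_rng(9)
        m = pd.DataFrame(rng.integers(0, 3, size=(40, 4)), columns=STAGES)
        m = m[m.sum(axis=1) > 0]
        counts = venn_partition(m)
        for r in range(1, 5):
            for subset in itertools.combinations(STAGES, r):
                expected = sum(
                    1
                    for _, row in m.iterrows()
                    if {s for s in STAGES if row[s] > 0} == set(subset)
                )
                assert counts[frozenset(subset)] == expected
        assert sum(counts.values()) == len(m)


class TestStageSpecificCalls:
    def test_strict_call_on_single_stage_tag(self, larval_profile):
        calls = stage_specific_calls(larval_profile, mode="strict", min_count=100)
        by_id = {c.unigene_id: c for c in calls}
        assert "DS5" in by_id and by_id["DS5"].called_stage == "larva"
        assert by_id["DS5"].fold_dominance == math.inf

    def test_strict_rejects_multi_stage_dominance_accepts(self, larval_profile):
        strict = {c.unigene_id for c in
                  stage_specific_calls(larval_profile, mode="strict", min_count=100)}
        dom10 = {c.unigene_id: c for c in
                 stage_specific_calls(larval_profile, mode="dominance",
                                      min_count=100, fold_threshold=10)}
        assert "DS6" not in strict
        assert "DS6" in dom10
        assert dom10["DS6"].fold_dominance == pytest.approx(2244 / 8)  # 280.5

    def test_dominance_threshold_boundary(self, larval_profile):
        # fold 6325/1942 = 3.257: accepted at threshold 3, rejected at 5
        at3 = {c.unigene_id for c in
               stage_specific_calls(larval_profile, mode="dominance",
                                    min_count=100, fold_threshold=3)}
        at5 = {c.unigene_id for c in
               stage_specific_calls(larval_profile, mode="dominance",
                                    min_count=100, fold_threshold=5)}
        assert "DS2" in at3 and "DS2" not in at5

    def test_strict_subset_of_dominance(self, larval_profile):
        strict = {c.tag17 for c in
                  stage_specific_calls(larval_profile, mode="strict", min_count=100)}
        dom = {c.tag17 for c in
               stage_specific_calls(larval_profile, mode="dominance",
                                    min_count=100, fold_threshold=50)}
        assert strict <= dom

    def test_invalid_mode_rejected(self, larval_profile):
        with pytest.raises(ValueError):
            stage_specific_calls(larval_profile, mode="loose")


class TestRankTargets:
    def test_printed_copy_number_order(self, larval_profile):
        calls = stage_specific_calls(larval_profile, mode="dominance",
                                     min_count=100, fold_threshold=3)
        ranked = rank_targets(calls, "larva")
        assert ranked[0].unigene_id == "DS2" and ranked[0].counts["larva"] == 6325
        assert ranked[-1].unigene_id == "DS35" and ranked[-1].counts["larva"] == 390
        assert [c.rank for c in ranked] == list(range(1, len(ranked) + 1))

    def test_tie_broken_lexicographically(self):
        index = build_tag_index({"u1": "CATG" + "A" * 17, "u2": "CATG" + "C" * 17})
        clean = {"larva": CleanTagTable("larva", {"A" * 17: 500, "C" * 17: 500})}
        prof = map_tags(clean, index)
        ranked = rank_targets(
            stage_specific_calls(prof, mode="strict", min_count=2), "larva"
        )
        assert [c.tag17 for c in ranked] == ["A" * 17, "C" * 17]

    def test_top_k_truncation(self, larval_profile):
        calls = stage_specific_calls(larval_profile, mode="dominance",
                                     min_count=100, fold_threshold=3)
        assert len(rank_targets(calls, "larva", top_k=1)) == 1

    def test_unknown_stage_rejected(self, larval_profile):
        calls = stage_specific_calls(larval_profile, mode="strict", min_count=100)
        with pytest.raises(ValueError):
            rank_targets(calls, "imago")


class TestTagsPerMillion:
    def test_single_tag(self):
        tpm = tags_per_million(CleanTagTable("x", {"A" * 17: 50}))
        assert tpm["A" * 17] == 1e6

    def test_even_split(self):
        tpm = tags_per_million(CleanTagTable("x", {"A" * 17: 2, "C" * 17: 2}))
        assert set(tpm.index) == {"A" * 17, "C" * 17}
        assert all(v == 5e5 for v in tpm)

    def test_sums_to_one_million(self):
        rng = np.random.default_rng(4)
        counts = {f"{i:017d}": int(c) for i, c in enumerate(rng.integers(2, 999, 100))}
        tpm = tags_per_million(CleanTagTable("x", counts))
        assert tpm.sum() == pytest.approx(1e6, rel=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            tags_per_million(CleanTagTable("x", {}))
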