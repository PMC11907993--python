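"""Composite scanning, region screening and multi-dataset aggregation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import random_dna
from helpers import oracle_composites
from smadscan.errors import InputError
from smadscan.grammar import (
    CANONICAL_ELEMENTS,
    BindingMode,
    Responsiveness,
    reverse_complement,
)
from smadscan.io import Region
from smadscan.scanner import (
    CompositeClass,
    canonical_classes,
    scan_composites,
    screen_regions,
    summarize_screen,
)
from smadscan.simulate import generate_background, plant_composites


class TestScanComposites:
    def test_id_like_example(self):
        hits = scan_composites(
            "AAGGCGCCAACTTGTCTGAA",
            CANONICAL_ELEMENTS["pGC_SBE"],
            CANONICAL_ELEMENTS["SBE"],
            5,
        )
        assert len(hits) == 1
        h = hits[0]
        assert (h.upstream.start, h.upstream.end) == (2, 8)
        assert (h.downstream.start, h.downstream.end) == (13, 18)
        assert h.spacer_seq == "AACTT"
        assert h.modes == frozenset(
            {BindingMode.FACE_TO_BACK, BindingMode.BACK_TO_BACK}
        )
        assert h.label is Responsiveness.BMP

    def test_empty_sequence(self):
        assert scan_composites(
            "", CANONICAL_ELEMENTS["pGC_SBE"], CANONICAL_ELEMENTS["SBE"], 5
        ) == []

    def test_negative_spacer_rejected(self):
        with pytest.raises(InputError):
            scan_composites(
                "ACGT", CANONICAL_ELEMENTS["SBE"], CANONICAL_ELEMENTS["SBE"], -1
            )

    def test_unordered_detects_both_element_orders(self):
        seq = "CAGACAACTTGGCGCC"
        unordered = scan_composites(
            seq, CANONICAL_ELEMENTS["pGC_SBE"], CANONICAL_ELEMENTS["SBE"], 5
        )
        ordered = scan_composites(
            seq, CANONICAL_ELEMENTS["pGC_SBE"], CANONICAL_ELEMENTS["SBE"], 5,
            ordered=True,
        )
        assert len(unordered) == 1 and ordered == []

    def test_matches_brute_force_double_loop(self, rng):
        ids = list(CANONICAL_ELEMENTS)
        for _ in range(15):
            seq = random_dna(rng, 2000, gc=0.55)
            for a, b in itertools.combinations_with_replacement(ids, 2):
                ea, eb = CANONICAL_ELEMENTS[a], CANONICAL_ELEMENTS[b]
                for spacer in (0, 2, 5, 7):
                    got = {
                        (h.upstream.start, h.downstream.start)
                        for h in scan_composites(seq, ea, eb, spacer)
                    }
                    expected = {
                        (u, d)
                        for u, d, _ in oracle_composites(
                            seq, ea.variants, eb.variants, spacer
                        )
                    }
                    assert got == expected, (a, b, spacer)


class TestScreenRegions:
    def test_planted_truth_recovered_exactly(self):
        background = generate_background(100, 300, seed=3)
        cls = CompositeClass(
            CANONICAL_ELEMENTS["pGC_SBE"], CANONICAL_ELEMENTS["SBE"], 5
        )
        planted = plant_composites(background, cls, count=3, seed=9)
        summary = screen_regions(planted.peaks, planted.sequences)
        counts = summary.class_counts.set_index("class_id")
        assert counts.loc[cls.class_id, "n_positive_regions"] == 3
        # no other class gains a positive region
        assert summary.class_counts["n_positive_regions"].sum() == 3
        positives = {
            r for r, sub in summary.per_region.groupby("region_id")
            if sub["positive"].any()
        }
        assert positives == set(planted.truth["region_id"])

    def test_empty_region_set_reports_na_fractions(self):
        summary = screen_regions([], {})
        assert (summary.class_counts["n_positive_regions"] == 0).all()
        assert summary.class_counts["fraction_positive"].isna().all()

    def test_reverse_complementing_regions_preserves_positivity(self):
        background = generate_background(30, 200, seed=21)
        cls = CompositeClass(
            CANONICAL_ELEMENTS["pGC_SBE"], CANONICAL_ELEMENTS["pGC_SBE"], 5
        )
        planted = plant_composites(background, cls, count=4, seed=5)
        fwd = screen_regions(planted.peaks, planted.sequences)
        flipped = {
            name: reverse_complement(seq) for name, seq in planted.sequences.items()
        }
        rev = screen_regions(planted.peaks, flipped)
        fwd_pos = fwd.per_region.set_index(["region_id", "class_id"])["positive"]
        rev_pos = rev.per_region.set_index(["region_id", "class_id"])["positive"]
        pd.testing.assert_series_equal(fwd_pos, rev_pos)
        # back-to-back achievability is likewise strand-symmetric
        for rec_f, rec_r in zip(fwd.regions, rev.regions):
            b2b_f = any(
                BindingMode.BACK_TO_BACK in h.modes
                for hits in rec_f.hits.values() for h in hits
            )
            b2b_r = any(
                BindingMode.BACK_TO_BACK in h.modes
                for hits in rec_r.hits.values() for h in hits
            )
            assert b2b_f == b2b_r

    def test_out_of_bounds_region_excluded_with_report(self):
        regions = [Region("chrA", 0, 50, "ok"), Region("chrA", 40, 120, "oob")]
        summary = screen_regions(regions, {"chrA": "A" * 60})
        assert [name for name, _ in summary.excluded] == ["oob"]
        assert summary.n_total_regions == 1

    def test_mask_policy_exclude_skips_soft_masked_plants(self):
        seq = "aaggcgccaacttgtctgaa".upper()
        soft = "aaggcgccaacttgtctgaa"
        regions = [Region("r", 0, 20, "r")]
        upper = screen_regions(regions, {"r": soft}, mask_policy="upper")
        excl = screen_regions(regions, {"r": soft}, mask_policy="exclude")
        cid = "SBE+pGC_SBE/5"
        assert upper.per_region.set_index("class_id").loc[cid, "positive"]
        assert not excl.per_region.set_index("class_id").loc[cid, "positive"]
        del seq

    def test_adding_a_plant_never_removes_positive_classes(self):
        background = generate_background(20, 300, seed=8)
        cls1 = CompositeClass(
            CANONICAL_ELEMENTS["pGC_SBE"], CANONICAL_ELEMENTS["SBE"], 5
        )
        once = plant_composites(background, cls1, count=5, seed=2)
        before = screen_regions(once.peaks, once.sequences)
        # planting a second class into fresh regions only adds positives
        cls2 = CompositeClass(
            CANONICAL_ELEMENTS["npGC_SBE"], CANONICAL_ELEMENTS["SBE"], 5
        )
        twice = plant_composites(once, cls2, count=5, seed=4)
        after = screen_regions(twice.peaks, twice.sequences)
        for rec_b, rec_a in zip(before.regions, after.regions):
            planted_here = set(
                twice.truth.loc[twice.truth.region_id == rec_a.region_id, "class_id"]
            )
            assert rec_b.positive_classes - planted_here <= rec_a.positive_classes
            assert rec_b.positive_classes <= rec_a.positive_classes | planted_here


class TestSummarize:
    def _mini_summary(self, n_planted, n_regions, seed):
        background = generate_background(n_regions, 200, seed=seed)
        cls = CompositeClass(
            CANONICAL_ELEMENTS["pGC_SBE"], CANONICAL_ELEMENTS["SBE"], 5
        )
        planted = plant_composites(background, cls, count=n_planted, seed=seed + 1)
        return screen_regions(planted.peaks, planted.sequences)

    def test_single_dataset_round_trips(self):
        s = self._mini_summary(2, 20, 31)
        tidy = summarize_screen({"d1": s})
        sub = tidy[(tidy.dataset == "d1") & (tidy.class_id != "total")]
        assert sub["n_positive"].sum() == 2
        total = tidy[(tidy.dataset == "d1") & (tidy.class_id == "total")]
        assert int(total["n_positive"].iloc[0]) == 2

    def test_two_datasets_totals_are_sums(self):
        s1 = self._mini_summary(2, 20, 41)
        s2 = self._mini_summary(3, 25, 43)
        tidy = summarize_screen({"a": s1, "b": s2})
        totals = tidy[tidy.class_id == "total"].set_index("dataset")["n_positive"]
        assert totals["a"] == 2 and totals["b"] == 3

    def test_empty_input_rejected(self):
        with pytest.raises(InputError):
            summarize_screen({})

    def test_planting_rates_within_binomial_bounds(self):
        # fractions equal planted truth exactly on rejection-sampled background
        rates = {"r0": 0, "r1": 3, "r2": 6}
        cls_id = "SBE+pGC_SBE/5"
        tidy = summarize_screen(
            {
                name: self._mini_summary(k, 50, 100 + 7 * k)
                for name, (k) in rates.items()
            }
        )
        got = tidy[tidy.class_id == cls_id].set_index("dataset")["n_positive"]
        assert got.to_dict() == rates
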