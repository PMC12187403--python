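"""Orchard layouts, foraging walks, assay model, and study generation."""

import numpy as np
import pandas as pd
import pytest

import pollenflow as pf
from pollenflow.deconvolution import deconvolve_dataset
from pollenflow.simulate import (
    AssayParams,
    ForagingParams,
    PollenLoad,
    build_orchard,
    generate_study,
    simulate_assay,
    simulate_trip,
)


def study_config(panel, **over):
    cfg = {
        "panel": panel,
        "orchards": [
            {"preset": "wide", "offtype_rate": 0.05, "offtype_pool": ["741"]},
            {"preset": "narrow", "offtype_rate": 0.05, "offtype_pool": ["741"]},
        ],
        "bees_per_point": 6,
        "foraging": {"p_row_switch": 0.1, "n_visits": 30,
                     "carryover_retention": 0.7},
        "assay": {"theta_detect": 1e-9, "fn_rate": 0.0, "fp_rate": 0.0},
    }
    cfg.update(over)
    return cfg


class TestBuildOrchard:
    def test_wide_preset(self, panel):
        lay = build_orchard({"preset": "wide"}, universe=panel.cultivars)
        assert lay.blocks == [("816", 42), ("Daddow", 48)]
        assert (lay.row_spacing_m, lay.tree_spacing_m) == (8.0, 4.0)
        assert lay.n_rows == 90

    def test_narrow_preset(self, panel):
        lay = build_orchard({"preset": "narrow"}, universe=panel.cultivars)
        assert lay.blocks == [("A203", 5), ("842", 5), ("816", 5),
                              ("A4", 5), ("741", 5)]
        assert (lay.row_spacing_m, lay.tree_spacing_m) == (10.0, 2.0)

    def test_no_offtypes_means_pure_blocks(self, panel):
        lay = build_orchard({"preset": "wide", "offtype_rate": 0.0},
                            universe=panel.cultivars)
        for cultivar, lo_hi in [("816", (0, 41)), ("Daddow", (42, 89))]:
            lo, hi = lay.block_span(cultivar)
            assert (lo, hi) == lo_hi
            assert (lay.grid[lo:hi + 1] == cultivar).all()

    def test_offtypes_seeded(self, panel):
        kw = dict(universe=panel.cultivars)
        a = build_orchard({"preset": "wide", "offtype_rate": 0.1,
                           "offtype_pool": ["741"]}, rng=5, **kw)
        b = build_orchard({"preset": "wide", "offtype_rate": 0.1,
                           "offtype_pool": ["741"]}, rng=5, **kw)
        assert (a.grid == b.grid).all()
        assert (a.grid == "741").sum() > 0

    def test_unknown_cultivar(self, panel):
        with pytest.raises(ValueError, match="not in panel"):
            build_orchard({"blocks": [["ZZZ", 5]], "row_spacing_m": 8,
                           "tree_spacing_m": 4}, universe=panel.cultivars)

    def test_zero_rows(self, panel):
        with pytest.raises(ValueError, match="1 row"):
            build_orchard({"blocks": [["816", 0]], "row_spacing_m": 8,
                           "tree_spacing_m": 4}, universe=panel.cultivars)


class TestSimulateTrip:
    def make_layout(self, panel, **kw):
        return build_orchard({"preset": "wide", **kw},
                             universe=panel.cultivars)

    def test_no_row_switch_stays_in_cultivar(self, panel):
        lay = self.make_layout(panel, offtype_rate=0.0)
        fp = ForagingParams(p_row_switch=0.0, n_visits=40, capture_visit=40)
        load = simulate_trip(lay, fp, start=(5, 50), rng=1)
        assert set(load.grains) == {"816"}

    def test_zero_retention_keeps_last_tree_only(self, panel):
        lay = self.make_layout(panel, offtype_rate=0.0)
        fp = ForagingParams(p_row_switch=0.5, n_visits=50,
                            carryover_retention=0.0, capture_visit=50)
        load = simulate_trip(lay, fp, start=(41, 50), rng=2)
        assert len(load.grains) == 1
        assert load.total == fp.pickup_grains

    def test_seed_reproducibility(self, panel):
        lay = self.make_layout(panel)
        fp = ForagingParams(capture_visit="uniform")
        a = simulate_trip(lay, fp, start=(10, 10), rng=7)
        b = simulate_trip(lay, fp, start=(10, 10), rng=7)
        assert a.grains == b.grains

    def test_capture_beyond_trip_raises(self, panel):
        lay = self.make_layout(panel)
        fp = ForagingParams(n_visits=5, capture_visit=6)
        with pytest.raises(ValueError, match="capture_visit"):
            simulate_trip(lay, fp, start=(0, 0), rng=0)

    def test_grain_bookkeeping_geometric_total(self, panel):
        # after n visits: total = pickup * (1 - rho^n) / (1 - rho)
        lay = self.make_layout(panel, offtype_rate=0.0)
        rho, n = 0.7, 12
        fp = ForagingParams(carryover_retention=rho, n_visits=n,
                            capture_visit=n, pickup_grains=2.0)
        load = simulate_trip(lay, fp, start=(3, 3), rng=0)
        assert load.total == pytest.approx(2.0 * (1 - rho**n) / (1 - rho))


class TestSimulateAssay:
    def test_pure_load_fires_exactly_its_loci(self, panel):
        load = PollenLoad("b", {"741": 10.0})
        ap = AssayParams(theta_detect=0.01, fn_rate=0.0, fp_rate=0.0)
        calls = simulate_assay(load, panel, ap, rng=0)
        assert calls.alt_detected == {"27718", "52998"}

    def test_detection_threshold_arithmetic(self, panel):
        load = PollenLoad("b", {"816": 95.0, "741": 5.0})
        high = AssayParams(theta_detect=0.10, fn_rate=0.0, fp_rate=0.0)
        low = AssayParams(theta_detect=0.01, fn_rate=0.0, fp_rate=0.0)
        assert "27718" not in simulate_assay(load, panel, high, rng=0).alt_detected
        assert "27718" in simulate_assay(load, panel, low, rng=0).alt_detected

    def test_het_dosage_is_half(self, panel):
        # 814 pollen carries one ALT copy at 10725 -> dosage fraction 0.5
        load = PollenLoad("b", {"814": 1.0})
        ap = AssayParams(theta_detect=0.51, fn_rate=0.0, fp_rate=0.0)
        assert "10725" not in simulate_assay(load, panel, ap, rng=0).alt_detected
        ap2 = AssayParams(theta_detect=0.50, fn_rate=0.0, fp_rate=0.0)
        assert "10725" in simulate_assay(load, panel, ap2, rng=0).alt_detected

    def test_total_false_negatives(self, panel):
        load = PollenLoad("b", {"741": 1.0})
        ap = AssayParams(theta_detect=0.01, fn_rate=1.0, fp_rate=0.0)
        assert simulate_assay(load, panel, ap, rng=0).alt_detected == frozenset()

    def test_empty_load_all_false(self, panel):
        calls = simulate_assay(PollenLoad("b", {}), panel,
                               AssayParams(fn_rate=0.0, fp_rate=0.0), rng=0)
        assert calls.alt_detected == frozenset()


class TestGenerateStudy:
    def test_default_design_counts(self, panel):
        meta, calls, truth = generate_study(study_config(panel), 1)
        wide = meta[meta["orchard_type"] == "WIDE"]
        narrow = meta[meta["orchard_type"] == "NARROW"]
        assert len(wide) == 8 * 4 * 6 == 192
        assert len(narrow) == 7 * 4 * 6 == 168
        assert sorted(wide["row_index"].unique()) == [1, 2, 3, 11]
        assert sorted(narrow["row_index"].unique()) == [1, 2, 3, 4]
        assert set(wide["distance_m"]) == {8.0, 16.0, 24.0, 88.0}
        # two ALT/REF rows per bee and locus
        assert len(calls) == len(meta) * len(panel.loci) * 2
        assert len(truth) == len(meta)

    def test_zero_bees_rejected(self, panel):
        with pytest.raises(ValueError, match="bees_per_point"):
            generate_study(study_config(panel, bees_per_point=0), 1)

    def test_seed_determinism(self, panel, tmp_path):
        frames_a = generate_study(study_config(panel), 42)
        frames_b = generate_study(study_config(panel), 42)
        for a, b in zip(frames_a, frames_b):
            pd.testing.assert_frame_equal(a, b)
        a_csv = tmp_path / "a.csv"; b_csv = tmp_path / "b.csv"
        frames_a[1].to_csv(a_csv, index=False)
        frames_b[1].to_csv(b_csv, index=False)
        assert a_csv.read_bytes() == b_csv.read_bytes()


class TestEndToEnd:
    def test_perfect_detection_round_trip(self, panel):
        """With an effectively zero detection threshold and no assay noise,
        pipeline categories equal ground truth for every bee."""
        meta, calls, truth = generate_study(study_config(panel), 11)
        bees = deconvolve_dataset(calls, panel, meta)
        merged = bees.merge(truth, on="bee_id")
        assert (merged["category"] == merged["true_category"]).all()

    def test_zero_switch_zero_cross(self, panel):
        cfg = study_config(
            panel,
            orchards=[{"preset": "wide", "offtype_rate": 0.0}],
            foraging={"p_row_switch": 0.0, "n_visits": 30,
                      "carryover_retention": 0.7},
        )
        meta, calls, truth = generate_study(cfg, 3)
        bees = deconvolve_dataset(calls, panel, meta)
        assert (bees["score"].fillna(0) == 0).all()
        assert set(bees["category"]) <= {"SELF_ONLY", "UNDETERMINED"}

    def test_offtype_rate_monotone_in_cross_carriage(self, panel):
        """Common random numbers: more off-type trees -> weakly more bees
        carrying cross-pollen (ground truth categories)."""
        pcts = []
        for rate in (0.0, 0.05, 0.15):
            vals = []
            for seed in (1, 2, 3):
                cfg = study_config(panel, orchards=[
                    {"preset": "wide", "offtype_rate": rate,
                     "offtype_pool": ["741"]}])
                _, _, truth = generate_study(cfg, seed)
                vals.append(
                    truth["true_category"].isin(["CROSS_ONLY", "MIXED"]).mean())
            pcts.append(np.mean(vals))
        # baseline cross-carriage (boundary crossings only) rises as
        # off-type trees add a within-block cross source
        assert pcts[0] <= pcts[1] <= pcts[2]
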