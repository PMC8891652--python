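"""Efficiency statistic, detection limit, and multi-site incorporation model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from scrkit.screen_quant import (
    EfficiencyEstimate,
    FluorescenceTimeSeries,
    ReferenceSet,
    YieldModel,
    below_detection,
    fold_improvement,
    lysate_efficiency,
    multi_site_yield,
    reassignment_efficiency,
    screen_from_plate,
    species_distribution,
    window_signal,
)
from scrkit.synthetic_data import ScreenConfig, gen_screen_series, screen_dataset_to_frames


def series(t, od, fl, label="w"):
    return FluorescenceTimeSeries(label, np.asarray(t), np.asarray(od), np.asarray(fl))


class TestWindowSignal:
    def test_constant_ratio_is_returned_exactly(self):
        t = np.arange(0, 250, 10.0)
        od = 0.1 * np.exp(t / 100)
        assert window_signal(series(t, od, 5.0 * od)) == pytest.approx(5.0)

    def test_ratio_invariant_to_growth_profile(self):
        t = np.arange(0, 250, 10.0)
        slow = 0.05 * 2 ** (t / 60)
        fast = 0.05 * 2 ** (t / 35)
        k = 123.4
        assert window_signal(series(t, slow, k * slow)) == pytest.approx(
            window_signal(series(t, fast, k * fast))
        )

    def test_window_outside_data_rejected(self):
        t = np.arange(0, 100, 10.0)
        with pytest.raises(ValueError, match="outside"):
            window_signal(series(t, np.ones_like(t), np.ones_like(t)), 0, 240)

    def test_nonpositive_od_rejected(self):
        t = np.arange(0, 250, 10.0)
        od = np.ones_like(t)
        od[3] = 0.0
        with pytest.raises(ValueError, match="non-positive OD"):
            window_signal(series(t, od, od))

    def test_generator_asymptotic_ratio_recovered(self):
        ds = gen_screen_series(ScreenConfig(seed=11, true_efficiency=1.0,
                                            noise_cv=0.01, replicate_cv=0.0))
        sig = window_signal(ds.ref100[0])
        assert sig == pytest.approx(1000.0, rel=0.01)


class TestReassignmentEfficiency:
    def test_reference_signals_map_to_endpoints(self):
        refs = ReferenceSet(s100=900.0, s0=50.0)
        full = reassignment_efficiency([900.0, 900.0, 900.0], refs)
        assert full.mean_pct == pytest.approx(100.0)
        assert full.sd_pct == 0.0
        zero = reassignment_efficiency([50.0], refs)
        assert zero.mean_pct == pytest.approx(0.0)
        assert zero.n == 1

    @settings(derandomize=True, max_examples=50)
    @given(
        a=st.floats(0.01, 1e4),
        b=st.floats(-1e4, 1e4),
        s=st.floats(10.0, 800.0),
    )
    def test_affine_invariance(self, a, b, s):
        refs = ReferenceSet(s100=1000.0, s0=5.0)
        scaled = ReferenceSet(s100=a * 1000.0 + b, s0=a * 5.0 + b)
        e1 = reassignment_efficiency([s], refs)
        e2 = reassignment_efficiency([a * s + b], scaled)
        assert e2.mean_pct == pytest.approx(e1.mean_pct, rel=1e-9, abs=1e-9)

    def test_degenerate_references_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            ReferenceSet(s100=10.0, s0=10.0)

    def test_out_of_range_flagged_not_clipped(self):
        refs = ReferenceSet(s100=100.0, s0=0.0)
        est = reassignment_efficiency([110.0], refs)
        assert est.mean_pct == pytest.approx(110.0)
        assert est.out_of_range

    def test_twelve_replicate_recovery_at_parent_level(self):
        ds = gen_screen_series(ScreenConfig(seed=5, true_efficiency=0.569))
        refs = ReferenceSet(
            s100=float(np.mean([window_signal(w) for w in ds.ref100])),
            s0=float(np.mean([window_signal(w) for w in ds.ref0])),
        )
        est = reassignment_efficiency([window_signal(w) for w in ds.test], refs)
        assert est.n == 12
        assert est.mean_pct == pytest.approx(56.9, abs=2.0)


class TestLysateEfficiency:
    def test_pure_ncaa_control_reads_hundred_percent(self):
        refs = ReferenceSet(s100=40.0, s0=1.0)  # fluorescence per protein
        est = lysate_efficiency([400.0], [10.0], refs)
        assert est.mean_pct == pytest.approx(100.0)

    def test_linear_mixture_oracle(self):
        """A fraction f of fluorescent protein gives 100*f efficiency."""
        per_protein_100 = 50.0
        refs = ReferenceSet(s100=per_protein_100, s0=0.0)
        for f in (0.0, 0.25, 0.569, 1.0):
            protein = 8.0
            fluor = f * protein * per_protein_100
            est = lysate_efficiency([fluor], [protein], refs)
            assert est.mean_pct == pytest.approx(100.0 * f)

    def test_matches_in_vivo_statistic_when_uncorrected(self):
        refs = ReferenceSet(s100=50.0, s0=2.0)
        fl = [120.0, 150.0]
        pr = [4.0, 5.0]
        a = lysate_efficiency(fl, pr, refs, brightness_correction=1.0)
        b = reassignment_efficiency(np.array(fl) / np.array(pr), refs)
        assert a == b

    def test_brightness_correction_rescales_reference(self):
        refs = ReferenceSet(s100=100.0, s0=0.0)
        dim = lysate_efficiency([10.0], [1.0], refs, brightness_correction=0.1)
        assert dim.mean_pct == pytest.approx(100.0)

    def test_zero_protein_rejected(self):
        with pytest.raises(ValueError, match="protein"):
            lysate_efficiency([1.0], [0.0], ReferenceSet(10.0, 0.0))


class TestDetectionLimit:
    def test_below_and_boundary(self):
        assert below_detection(EfficiencyEstimate(0.1, 0.0, 1))
        assert not below_detection(EfficiencyEstimate(0.2, 0.0, 1))  # strict <
        assert not below_detection(EfficiencyEstimate(56.9, 2.4, 12))

    def test_limit_must_be_positive(self):
        with pytest.raises(ValueError):
            below_detection(EfficiencyEstimate(1.0, 0.0, 1), limit_pct=0.0)


class TestYieldModel:
    def test_half_efficiency_three_sites(self):
        assert multi_site_yield(YieldModel(0.5, 3)) == pytest.approx(0.125)

    @pytest.mark.parametrize("p", [0.0, 0.3, 0.9, 1.0])
    def test_single_site_returns_p_and_perfect_is_flat(self, p):
        assert multi_site_yield(YieldModel(p, 1)) == pytest.approx(p)
        assert multi_site_yield(YieldModel(1.0, 7)) == 1.0

    def test_yield_monotone_in_sites_and_efficiency(self):
        for p in (0.1, 0.5, 0.9):
            yields = [multi_site_yield(YieldModel(p, n)) for n in range(1, 7)]
            assert all(a > b for a, b in zip(yields, yields[1:]))
        for n in (1, 3, 6):
            by_p = [multi_site_yield(YieldModel(p, n)) for p in (0.2, 0.5, 0.8)]
            assert by_p[0] < by_p[1] < by_p[2]

    def test_species_distribution_matches_binomial_oracle(self):
        for p in np.linspace(0, 1, 11):
            for n in range(7):
                dist = species_distribution(YieldModel(float(p), n))
                oracle = stats.binom.pmf(np.arange(n + 1), n, p)
                assert dist == pytest.approx(oracle, abs=1e-12)
                assert dist.sum() == pytest.approx(1.0)
                assert dist[-1] == pytest.approx(multi_site_yield(YieldModel(float(p), n)))

    def test_degenerate_edges(self):
        assert species_distribution(YieldModel(0.0, 4))[0] == 1.0
        assert species_distribution(YieldModel(0.5, 3))[-1] == pytest.approx(0.125)

    def test_invalid_model_rejected(self):
        with pytest.raises(ValueError):
            YieldModel(1.5, 2)
        with pytest.raises(ValueError):
            YieldModel(0.5, -1)


def test_fold_improvement_at_printed_precision():
    assert round(fold_improvement(50.1, 29.5), 1) == 1.7
    assert round(fold_improvement(98.6, 56.9), 1) == 1.7


class TestPlateWorkflow:
    def test_end_to_end_recovers_ground_truth(self):
        ds = gen_screen_series(ScreenConfig(seed=21, true_efficiency=0.30))
        reads, smap = screen_dataset_to_frames(ds)
        result = screen_from_plate(reads, smap)
        row = result[result["sample"] == "test"].iloc[0]
        assert row["mean_pct"] == pytest.approx(30.0, abs=2.0)
        assert row["n"] == 12
        assert not row["below_detection"]

    def test_missing_reference_wells_rejected(self):
        ds = gen_screen_series(ScreenConfig(seed=1, n_replicates=2))
        reads, smap = screen_dataset_to_frames(ds)
        no_ref = smap[smap["role"] != "ref0"]
        with pytest.raises(ValueError, match="ref0"):
            screen_from_plate(reads, no_ref)
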