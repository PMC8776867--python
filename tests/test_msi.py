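"""ERP/IC arithmetic, response-window classification and IC matrices."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mauthner import msi
from mauthner.msi import (
    ResponseWindows,
    classify_response,
    classify_responses,
    expected_response_probability,
    fit_uv_boundaries,
    ic_matrix,
    integration_coefficient,
    inverse_effectiveness_fit,
    lp_interval_length,
    mean_ic,
    proportion_estimate,
    unisensory_probabilities,
)

probs = st.floats(0.0, 1.0)


class TestArithmetic:
    @pytest.mark.parametrize(
        "p_v,p_a,expected",
        [(0.10, 0.10, 0.19), (0.70, 0.80, 0.94), (0.0, 0.37, 0.37), (1.0, 0.5, 1.0)],
    )
    def test_erp_addition_rule(self, p_v, p_a, expected):
        assert expected_response_probability(p_v, p_a) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "orp,erp,expected",
        [(0.50, 0.19, 0.45), (1.0, 0.94, 0.03), (0.3, 0.3, 0.0)],
    )
    def test_ic_worked_values(self, orp, erp, expected):
        assert round(integration_coefficient(orp, erp), 2) == pytest.approx(expected)

    def test_ic_undefined_when_both_zero(self):
        with pytest.raises(ValueError):
            integration_coefficient(0.0, 0.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            expected_response_probability(-0.1, 0.5)
        with pytest.raises(ValueError):
            integration_coefficient(1.2, 0.5)

    @settings(max_examples=100, derandomize=True)
    @given(p_v=probs, p_a=probs)
    def test_erp_bounds(self, p_v, p_a):
        erp = expected_response_probability(p_v, p_a)
        assert max(p_v, p_a) - 1e-12 <= erp <= min(1.0, p_v + p_a) + 1e-12

    @settings(max_examples=100, derandomize=True)
    @given(orp=probs, erp=probs)
    def test_ic_sign_and_antisymmetry(self, orp, erp):
        if orp + erp == 0:
            return
        ic = integration_coefficient(orp, erp)
        assert -1.0 <= ic <= 1.0
        assert (ic > 0) == (orp > erp)
        assert ic == pytest.approx(-integration_coefficient(erp, orp))

    def test_proportion_estimate_se(self):
        est = proportion_estimate(30, 120)
        assert est.p == 0.25
        assert est.se == pytest.approx(np.sqrt(0.25 * 0.75 / 120))


class TestWindows:
    def test_classification_examples(self):
        w = ResponseWindows(auditory_onset=-160.0, uv_start=-80.0, uv_end=60.0)
        assert classify_response(-150.0, w) == "MSI"
        assert classify_response(-161.0, w) == "PRE"
        assert classify_response(-100.0, w) == "LP"
        assert classify_response(-10.0, w) == "UV"

    def test_single_late_cluster_classified_uv(self):
        # post-MSI responses concentrated +/-80 ms around the end of expansion
        rng = np.random.default_rng(1)
        times = rng.uniform(-80, 80, 200)
        w = ResponseWindows(auditory_onset=-160.0)
        labels, w = classify_responses(times, w)
        assert (labels == "UV").mean() >= 0.9
        assert -80 <= w.uv_start <= w.uv_end <= 80

    def test_classification_exhaustive_and_exclusive(self):
        rng = np.random.default_rng(2)
        times = rng.uniform(-900, 100, 500)
        w = ResponseWindows(auditory_onset=-160.0)
        labels, _ = classify_responses(times, w)
        assert set(labels) <= {"PRE", "MSI", "LP", "UV"}
        assert len(labels) == 500

    def test_lp_interval_from_quantile_boundary(self):
        # late responses start 200 ms after the MSI window ends
        times = np.concatenate([np.full(50, -150.0), np.linspace(80, 100, 50)])
        w = fit_uv_boundaries(times, ResponseWindows(auditory_onset=-160.0))
        assert lp_interval_length(w) == pytest.approx(80.0 - (-120.0), abs=2.0)

    def test_no_late_responses_gives_zero_lp(self):
        w = fit_uv_boundaries([-150.0, -130.0], ResponseWindows(auditory_onset=-160.0))
        assert lp_interval_length(w) == 0.0

    def test_invalid_windows_rejected(self):
        with pytest.raises(ValueError):
            ResponseWindows(auditory_onset=-160.0, msi_width=0.0)
        with pytest.raises(ValueError):
            ResponseWindows(auditory_onset=-160.0, lp_uv_quantiles=(0.9, 0.1))


def _uniform_unisensory(p_v_levels, p_a_levels, n=1000):
    rows = []
    for mod, probs_ in (("V", p_v_levels), ("A", p_a_levels)):
        for level, p in enumerate(probs_, start=1):
            rows.append(
                {"modality": mod, "level": level, "n": n, "p": p,
                 "p_msi": p, "p_uv": p}
            )
    return pd.DataFrame(rows)


def _make_trials(rng, p_grid, n=400, onset=-160.0):
    rows = []
    for (ci, ai), p in p_grid.items():
        responded = rng.random(n) < p
        times = np.where(responded, onset + rng.uniform(0, 30, n), np.nan)
        rows.append(
            pd.DataFrame(
                {
                    "contrast_level": ci,
                    "amplitude_level": ai,
                    "responded": responded,
                    "response_time": times,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


class TestIcMatrix:
    def test_independent_generator_gives_zero_mean_ic(self):
        rng = np.random.default_rng(3)
        p_v = [0.2, 0.4, 0.6]
        p_a = [0.1, 0.3, 0.5]
        grid = {
            (i + 1, j + 1): p_v[i] + p_a[j] - p_v[i] * p_a[j]
            for i in range(3)
            for j in range(3)
        }
        trials = _make_trials(rng, grid, n=600)
        uni = _uniform_unisensory(p_v, p_a)
        w = ResponseWindows(auditory_onset=-160.0, uv_start=-60.0, uv_end=60.0)
        table = ic_matrix(trials, uni, window="MSI", windows=w)
        m, se = mean_ic(table)
        assert abs(m) < 2 * se

    def test_superadditive_cell_recovers_worked_ic(self):
        # ORP 0.50 against unisensory 0.10/0.10 (ERP 0.19) gives IC ~ 0.45
        n = 200
        trials = pd.DataFrame(
            {
                "contrast_level": 1,
                "amplitude_level": 1,
                "responded": np.arange(n) < 100,
                "response_time": np.where(np.arange(n) < 100, -150.0, np.nan),
            }
        )
        uni = _uniform_unisensory([0.10], [0.10])
        w = ResponseWindows(auditory_onset=-160.0, uv_start=-60.0, uv_end=60.0)
        table = ic_matrix(trials, uni, window="MSI", windows=w)
        assert table.loc[0, "orp"] == 0.5
        assert table.loc[0, "erp"] == pytest.approx(0.19)
        assert table.loc[0, "ic"] == pytest.approx(0.45, abs=0.005)

    def test_all_zero_table_flags_undefined(self):
        trials = pd.DataFrame(
            {
                "contrast_level": [1] * 10,
                "amplitude_level": [1] * 10,
                "responded": False,
                "response_time": np.nan,
            }
        )
        uni = _uniform_unisensory([0.0], [0.0])
        w = ResponseWindows(auditory_onset=-160.0, uv_start=-60.0, uv_end=60.0)
        table = ic_matrix(trials, uni, window="MSI", windows=w)
        assert not table.loc[0, "defined"]
        assert np.isnan(table.loc[0, "ic"])

    def test_missing_unisensory_level_raises(self):
        trials = _make_trials(np.random.default_rng(4), {(1, 2): 0.5}, n=50)
        uni = _uniform_unisensory([0.1], [0.1])  # amplitude level 2 missing
        w = ResponseWindows(auditory_onset=-160.0)
        with pytest.raises(ValueError):
            ic_matrix(trials, uni, window="MSI", windows=w)

    def test_unisensory_probabilities_windowed(self):
        trials = pd.DataFrame(
            {
                "modality": ["V"] * 8 + ["A"] * 4,
                "level": [1] * 8 + [1] * 4,
                "responded": [True] * 6 + [False] * 2 + [True] * 2 + [False] * 2,
                # 2 V responses in MSI, 4 in UV; A times on the onset axis
                "response_time": [-150.0, -140.0, -20.0, -10.0, 0.0, 10.0,
                                  np.nan, np.nan, 8.0, 12.0, np.nan, np.nan],
            }
        )
        w = ResponseWindows(
            auditory_onset=-160.0, uv_start=-30.0, uv_end=30.0
        )
        out = unisensory_probabilities(trials, w, auditory_time_base="onset")
        v = out[out["modality"] == "V"].iloc[0]
        a = out[out["modality"] == "A"].iloc[0]
        assert v["p"] == 0.75 and v["p_msi"] == 0.25 and v["p_uv"] == 0.5
        assert a["p"] == 0.5 and a["p_msi"] == 0.5 and a["p_uv"] == 0.0


class TestInverseEffectiveness:
    def test_constant_ic_gives_zero_slopes(self):
        table = pd.DataFrame(
            {
                "contrast_level": [1, 2, 3, 1, 2, 3],
                "amplitude_level": [1, 1, 1, 2, 2, 2],
                "ic": 0.3,
            }
        )
        fits = inverse_effectiveness_fit(table)
        assert fits["amplitude"]["slope"] == pytest.approx(0.0, abs=1e-12)
        assert fits["contrast"]["slope"] == pytest.approx(0.0, abs=1e-12)

    def test_amplitude_only_trend_detected(self):
        rng = np.random.default_rng(5)
        rows = []
        for ai in range(1, 7):
            for ci in range(1, 7):
                rows.append(
                    {
                        "contrast_level": ci,
                        "amplitude_level": ai,
                        "ic": 0.6 - 0.1 * ai + rng.normal(0, 0.02),
                    }
                )
        fits = inverse_effectiveness_fit(pd.DataFrame(rows))
        assert fits["amplitude"]["slope"] < 0
        assert fits["amplitude"]["ci_high"] < 0
        assert fits["contrast"]["ci_low"] < 0 < fits["contrast"]["ci_high"]

    def test_rank_deficiency_rejected(self):
        table = pd.DataFrame(
            {"contrast_level": [1, 2, 3], "amplitude_level": 2, "ic": [0.1, 0.2, 0.3]}
        )
        with pytest.raises(ValueError):
            inverse_effectiveness_fit(table)
        with pytest.raises(ValueError):
            inverse_effectiveness_fit(table.iloc[:2])
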