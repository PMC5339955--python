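"""MTT cytotoxicity, IC50 estimation and antimicrobial screening logic."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from endodiv import bioactivity as bio
from endodiv.io import parse_pm_cell


def make_series(params, concs=(10, 25, 50, 100), noise=None):
    lower, upper, hill, ic50 = params
    pts = []
    for i, c in enumerate(concs):
        gi = lower + (upper - lower) / (1 + (ic50 / c) ** hill)
        if noise is not None:
            gi += noise[i]
        pts.append((float(c), float(gi)))
    return bio.DoseResponseSeries("E", "L", tuple(pts))


class TestPercentGrowthInhibition:
    def test_treated_equals_control_is_zero(self):
        assert bio.percent_growth_inhibition(1.2, 1.2, 0.2) == pytest.approx(0.0)

    def test_treated_equals_blank_is_full_kill(self):
        assert bio.percent_growth_inhibition(0.2, 1.2, 0.2) == pytest.approx(100.0)

    def test_midpoint(self):
        assert bio.percent_growth_inhibition(0.7, 1.2, 0.2) == pytest.approx(50.0)

    def test_dead_control_rejected(self):
        with pytest.raises(ValueError):
            bio.percent_growth_inhibition(0.1, 0.2, 0.2)

    @given(
        od_t=st.floats(0.0, 2.0),
        od_b=st.floats(0.01, 0.5),
        window=st.floats(0.1, 2.0),
        scale=st.floats(0.1, 10.0),
        offset=st.floats(-0.5, 5.0),
    )
    @settings(deadline=None)
    def test_affine_invariance(self, od_t, od_b, window, scale, offset):
        od_c = od_b + window
        base = bio.percent_growth_inhibition(od_t, od_c, od_b)
        shifted = bio.percent_growth_inhibition(
            od_t * scale + offset, od_c * scale + offset, od_b * scale + offset
        )
        assert shifted == pytest.approx(base, abs=1e-6)


class TestCytotoxicScreen:
    def test_survey_counts(self, gi_table):
        summary = bio.cytotoxic_screen_summary(gi_table, threshold=50)
        assert summary["all_line_active"] == 11
        assert summary["all_line_fraction"] == pytest.approx(11 / 28)
        assert summary["any_line_active"] == 19

    def test_strict_comparison(self):
        # a value exactly at the threshold does not count
        df = pd.DataFrame({"A": [50.0], "B": [50.0]}, index=["x"])
        summary = bio.cytotoxic_screen_summary(df, threshold=50)
        assert summary["any_line_active"] == 0

    def test_all_zero_matrix(self):
        df = pd.DataFrame(np.zeros((3, 2)), columns=["A", "B"])
        summary = bio.cytotoxic_screen_summary(df, threshold=50)
        assert summary["any_line_active"] == 0 and summary["all_line_active"] == 0

    @given(threshold=st.floats(0, 100))
    @settings(deadline=None, max_examples=25)
    def test_all_line_never_exceeds_any_line(self, gi_table, threshold):
        summary = bio.cytotoxic_screen_summary(gi_table, threshold=threshold)
        assert summary["all_line_active"] <= summary["any_line_active"]


class TestFitIC50:
    def test_exact_recovery_noise_free(self):
        est = bio.fit_ic50(make_series((0, 100, 1, 15)))
        assert est.censor == "exact"
        assert est.value == pytest.approx(15.0, abs=1e-6)
        assert est.fit_params[3] == pytest.approx(15.0, abs=1e-6)

    def test_bracketing_point_at_fifty(self):
        pts = ((10.0, 20.0), (25.0, 50.0), (50.0, 70.0), (100.0, 90.0))
        est = bio.fit_ic50(bio.DoseResponseSeries("E", "L", pts))
        assert est.value == pytest.approx(25.0, rel=0.02)

    def test_below_min_censoring(self):
        pts = ((10.0, 94.0), (25.0, 97.0), (50.0, 99.0), (100.0, 99.5))
        est = bio.fit_ic50(bio.DoseResponseSeries("E", "L", pts))
        assert est.censor == "below_min" and est.value == 10.0
        assert str(est) == "<10"

    def test_above_max_censoring_flat_curve(self):
        est = bio.fit_ic50(make_series((5, 5, 1, 15)))
        assert est.censor == "above_max" and est.value == 100.0

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            bio.fit_ic50(bio.DoseResponseSeries("E", "L", ((10.0, 40.0),)))

    def test_duplicate_concentrations_rejected(self):
        with pytest.raises(ValueError):
            bio.DoseResponseSeries("E", "L", ((10.0, 1.0), (10.0, 2.0)))

    def test_recovery_under_noise(self):
        """Median |relative error| < 5% over 200 noisy curves (sd = 2%)."""
        rng = np.random.default_rng(20170307)
        errors, censor_agree, n_curves = [], 0, 200
        for _ in range(n_curves):
            hill = rng.uniform(0.8, 2.0)
            ic50 = rng.uniform(12, 80)
            noise = rng.normal(0, 2.0, size=4)
            truth = bio.fit_ic50(make_series((0, 100, hill, ic50)))
            est = bio.fit_ic50(make_series((0, 100, hill, ic50), noise=noise))
            if est.censor == truth.censor:
                censor_agree += 1
            if est.censor == "exact" and truth.censor == "exact":
                errors.append(abs(est.value - ic50) / ic50)
        assert censor_agree / n_curves > 0.95
        assert float(np.median(errors)) < 0.05


class TestIC50Counts:
    def test_survey_counts(self, ic50_table):
        counts = bio.ic50_activity_counts(ic50_table, threshold=20)
        assert counts["any_line_active"] == 7
        assert counts["per_line_active"] == {
            "HCT-116": 5, "A-549": 6, "PC-3": 4, "T47D": 6,
        }

    def test_censored_below_min_counts_when_bound_below_threshold(self):
        t = pd.DataFrame(
            {
                "extract_id": ["a", "b"],
                "cell_line": ["L", "L"],
                "ic50": [10.0, 10.0],
                "censor": ["below_min", "exact"],
            }
        )
        assert bio.ic50_activity_counts(t, threshold=20)["any_line_active"] == 2
        # bound not below a tighter threshold -> censored entry excluded
        assert bio.ic50_activity_counts(t, threshold=5)["any_line_active"] == 0


class TestZoneInhibition:
    def test_survey_counts(self, zi_table):
        summary = bio.zi_screen_summary(zi_table)
        assert summary["overall_active"] == 21
        assert summary["overall_fraction"] == pytest.approx(0.75)
        assert summary["per_pathogen_active"]["S. aureus"] == 14
        assert summary["per_pathogen_fraction"]["S. aureus"] == pytest.approx(0.5)

    def test_no_zones_recorded(self):
        panel = pd.DataFrame(
            {"extract_id": ["a", "a"], "pathogen": ["p", "q"], "zi_mm": [math.nan] * 2}
        )
        assert bio.zi_screen_summary(panel)["overall_active"] == 0


class TestMicEndpoint:
    SERIES = [12.5, 25.0, 50.0, 100.0]

    def test_growth_only_at_lowest(self):
        assert bio.mic_from_dilution([True, False, False, False], self.SERIES) == (25.0, "exact")

    def test_growth_everywhere_right_censored(self):
        assert bio.mic_from_dilution([True] * 4, self.SERIES) == (100.0, "gt")

    def test_clear_everywhere_left_censored(self):
        assert bio.mic_from_dilution([False] * 4, self.SERIES) == (12.5, "le")

    def test_regrowth_is_invalid_well(self):
        with pytest.raises(ValueError, match="invalid well"):
            bio.mic_from_dilution([True, False, True, False], self.SERIES)

    def test_monotone_in_growth_flags(self):
        # flipping any one well from clear to grown never lowers the MIC
        base_flags = [True, False, False, False]
        base, _ = bio.mic_from_dilution(base_flags, self.SERIES)
        for i in range(1, 4):
            flags = base_flags.copy()
            for j in range(1, i + 1):
                flags[j] = True
            mic, censor = bio.mic_from_dilution(flags, self.SERIES)
            assert censor == "gt" or mic >= base


class TestMicScreen:
    def test_survey_counts(self, mic_table):
        summary = bio.mic_screen_summary(mic_table, cutoff=100)
        assert summary["overall_active"] == 8
        assert summary["per_pathogen_active"]["C. albicans"] == 3

    def test_cutoff_below_series(self, mic_table):
        assert bio.mic_screen_summary(mic_table, cutoff=1.0)["overall_active"] == 0


class TestCellParsing:
    @pytest.mark.parametrize(
        "cell, expected",
        [
            ("13 ± 0.8", (13.0, 0.8, "exact")),
            ("<10 ± 0.0", (10.0, 0.0, "lt")),
            (">100", (100.0, math.nan, "gt")),
            ("12.5 (MBC)", (12.5, math.nan, "exact+mbc")),
            ("-", None),
            ("30", (30.0, math.nan, "exact")),
        ],
    )
    def test_pm_cells(self, cell, expected):
        got = parse_pm_cell(cell)
        if expected is None:
            assert got is None
        else:
            assert got[0] == expected[0]
            assert got[2] == expected[2]
            assert (math.isnan(got[1]) and math.isnan(expected[1])) or got[1] == expected[1]
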