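"""Isotope-dilution correction, weighted calibration and interpolation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ccmquant.errors import (
    CalibrationError,
    MissingInternalStandardError,
    ValidationError,
)
from ccmquant.quantify import (
    CalibrationModel,
    PrepFactors,
    apply_prep_factors,
    corrected_response,
    fit_calibration,
    interpolate,
)
from ccmquant.synthetic import true_extract_concentrations


def make_series(x, ratios, metabolite_id="met", is_area=1000.0, blank=True):
    """Long-format calibration slice from (level, corrected response) pairs."""
    rows = []
    levels = list(zip(x, ratios))
    if blank:
        levels = [(0.0, 0.0)] + levels
    for j, (conc, ratio) in enumerate(levels):
        role = "blank" if conc == 0 else "calibrant"
        for channel, area in [("analyte", ratio * is_area), ("internal_standard", is_area)]:
            rows.append(
                {
                    "sample_id": f"L{j}",
                    "group_id": "calibration",
                    "metabolite_id": metabolite_id,
                    "channel": channel,
                    "area": area,
                    "role": role,
                    "level_conc": conc,
                }
            )
    return pd.DataFrame(rows)


def wls_normal_equations(x, y, w):
    """Independent closed-form weighted fit: solve the 2x2 normal equations."""
    A = np.array([[np.sum(w), np.sum(w * x)], [np.sum(w * x), np.sum(w * x * x)]])
    b = np.array([np.sum(w * y), np.sum(w * x * y)])
    intercept, slope = np.linalg.solve(A, b)
    return intercept, slope


class TestCorrectedResponse:
    def test_ratio(self):
        assert corrected_response(1000.0, 500.0) == pytest.approx(2.0)

    def test_zero_analyte(self):
        assert corrected_response(0.0, 500.0) == 0.0

    def test_zero_is_raises(self):
        with pytest.raises(MissingInternalStandardError):
            corrected_response(1000.0, 0.0)


class TestFitCalibration:
    def test_exact_line(self):
        x = np.array([1e-7, 1e-6, 1e-5, 1e-4])
        model = fit_calibration(make_series(x, 2.0 * x))
        assert model.slope == pytest.approx(2.0, rel=1e-9)
        assert model.intercept == pytest.approx(0.0, abs=1e-12)
        assert model.r_squared == pytest.approx(1.0, abs=1e-12)
        assert model.lloq == pytest.approx(1e-7)
        assert model.uloq == pytest.approx(1e-4)

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = rng.integers(4, 10)
            x = 10.0 ** rng.uniform(-1, 1, n)
            y = rng.uniform(0.5, 2.0) * x + rng.normal(0, 0.05 * x)
            model = fit_calibration(make_series(x, y), weighting="one_over_x")
            b0, b1 = wls_normal_equations(x, y, 1.0 / x)
            assert model.slope == pytest.approx(b1, rel=1e-10)
            assert model.intercept == pytest.approx(b0, rel=1e-10, abs=1e-14)

    def test_one_over_x_beats_unweighted_at_low_end(self):
        # proportional (multiplicative) noise: 1/x weighting should track the
        # low concentrations better than an unweighted fit
        rng = np.random.default_rng(42)
        x = np.array([1e-8, 3e-8, 1e-7, 3e-7, 1e-6, 3e-6, 1e-5, 3e-5, 1e-4])
        err = {"one_over_x": [], "none": []}
        for _ in range(200):
            y = 3.0 * x * rng.lognormal(0, 0.15, len(x))
            for weighting in err:
                m = fit_calibration(
                    make_series(x, y),
                    weighting=weighting,
                    backcalc_tol=np.inf,
                    backcalc_tol_lowest=np.inf,
                )
                back = (y[0] - m.intercept) / m.slope
                err[weighting].append(abs(back / x[0] - 1.0))
        assert np.mean(err["one_over_x"]) < np.mean(err["none"])

    def test_too_few_levels(self):
        x = np.array([1e-6, 1e-5])
        with pytest.raises(CalibrationError, match="fewer than 3"):
            fit_calibration(make_series(x, 2.0 * x))

    def test_degenerate_equal_responses(self):
        x = np.array([1e-6, 1e-5, 1e-4])
        with pytest.raises(CalibrationError, match="degenerate"):
            fit_calibration(make_series(x, np.full(3, 0.5)))


class TestInterpolate:
    model = CalibrationModel("met", 2.0, 0.0, "one_over_x", 1.0, 1e-6, 1e-4, 8)

    def test_in_range(self):
        conc, flag = interpolate(self.model, 2e-5)
        assert conc == pytest.approx(1e-5)
        assert flag == "ok"

    def test_negative_clamps_to_zero(self):
        conc, flag = interpolate(self.model, -0.5)
        assert conc == 0.0 and flag == "below_lloq"

    def test_range_flags(self):
        assert interpolate(self.model, 2e-7)[1] == "below_lloq"
        assert interpolate(self.model, 1.0)[1] == "above_uloq"

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(min_value=-1.0, max_value=1.0), st.floats(min_value=1e-6, max_value=0.5))
    def test_strictly_increasing_in_ratio(self, ratio, delta):
        lo = interpolate(self.model, ratio)[0]
        hi = interpolate(self.model, ratio + delta)[0]
        assert hi >= lo
        if lo > 0:  # both above the zero clamp
            assert hi > lo


class TestPrepFactors:
    def test_twenty_percent_spike(self):
        assert apply_prep_factors(1e-5, PrepFactors(0.20)) == pytest.approx(1.25e-5)

    def test_five_percent_spike(self):
        assert PrepFactors(0.05).net_factor == pytest.approx(1 / 0.95)

    def test_identity(self):
        assert apply_prep_factors(3.3e-6, PrepFactors(0.0)) == pytest.approx(3.3e-6)

    def test_invalid_spike(self):
        with pytest.raises(ValidationError):
            PrepFactors(1.0)


class TestQuantifyTable:
    def test_noiseless_extract_recovery(self, noiseless_bundle):
        """Quantified extract concentrations equal the generator's forward
        extract truth to float precision when all noise terms are off."""
        from ccmquant.quantify import default_prep_factors

        b = noiseless_bundle
        prep = default_prep_factors()
        truth_extract = true_extract_concentrations(
            b["truth"], b["biomass"], b["panel"], prep, b["config"].study
        )
        merged = b["extract"].merge(truth_extract, on=["sample_id", "metabolite_id"])
        # truth is the *measured* extract; quantify reports the original
        # extract, so compare after removing the preparation factor
        method_of = b["panel"].method_of()
        net = merged["metabolite_id"].map(lambda m: prep[method_of[m].value].net_factor)
        rel = (merged["conc_extract_M"] - merged["c_meas_M"] * net).abs() / (
            merged["c_meas_M"] * net
        )
        assert (merged["flag"] == "ok").all()
        assert rel.max() < 1e-9

    def test_flag_partition(self, default_bundle):
        extract = default_bundle["extract"]
        n_samples = default_bundle["biomass"].shape[0]
        assert len(extract) == n_samples * 68
        assert set(extract["flag"]).issubset({"ok", "below_lloq", "above_uloq", "missing_is", "missing"})

    def test_calibrants_never_emitted_as_samples(self, default_bundle):
        assert not default_bundle["extract"]["sample_id"].str.startswith("cal_").any()

    def test_missing_is_flagged(self, default_bundle, panel):
        from ccmquant.quantify import default_prep_factors, quantify_table

        raw = default_bundle["raw"]
        sub = raw[(raw["role"] == "sample") & (raw["sample_id"] == "bsubtilis_r1")].copy()
        sub = sub[~((sub["metabolite_id"] == "atp") & (sub["channel"] == "internal_standard"))]
        out = quantify_table(sub, default_bundle["models"], default_prep_factors(), panel)
        row = out[(out["sample_id"] == "bsubtilis_r1") & (out["metabolite_id"] == "atp")]
        assert row["flag"].iloc[0] == "missing_is"
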