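import numpy as np
import pytest
from numpy.polynomial import Polynomial

from triohap.correction import (
    CorrectionModel,
    apply_correction,
    assign_reference,
    build_correction_table,
    corrected_residual_records,
    fit_all_models,
    fit_correction_model,
)
from triohap.model import Genotype, PeakObservation, TrioGenotypes
from triohap.synthetic_data import (
    ShiftModelParams,
    default_shift_params,
    simulate_peak_table,
    simulate_trios,
)

from .conftest import make_population


def _peak(observed, dye="FAM", marker="STR", family="F1", member="child"):
    return PeakObservation(
        family_id=family,
        run_id=f"{family}_r1",
        member=member,
        dye=dye,
        marker=marker,
        observed_size=observed,
    )


def _truth(family="F1", member="child", marker="STR", alleles=(226.0, 226.0)):
    trio = TrioGenotypes(family_id=family)
    trio.genotypes[(member, marker)] = Genotype(alleles=alleles)
    return {family: trio}


class TestAssignReference:
    def test_truth_assignment_records_exact_shift(self, panel):
        recs = assign_reference([_peak(223.74)], panel.ladders, truth=_truth())
        assert recs[0].reference_size == 226.0
        assert recs[0].shift == pytest.approx(-2.26)

    def test_exact_rung_zero_prior_gives_zero_shift(self, panel):
        recs = assign_reference([_peak(230.0)], panel.ladders)
        assert recs[0].reference_size == 230.0
        assert recs[0].shift == 0.0

    def test_far_off_ladder_peak_left_unassigned(self, panel):
        recs = assign_reference([_peak(300.0)], panel.ladders)
        assert not recs[0].assigned
        assert "unassigned" in recs[0].flags
        assert recs[0].shift is None

    def test_rank_matching_disambiguates_adjacent_heterozygote(self, panel):
        # with a -2.26 shift the 230-allele peak (227.74) lies nearer the
        # 226 rung; rank matching against the true genotype must still
        # assign it to 230
        peaks = [_peak(223.74), _peak(227.74)]
        recs = assign_reference(
            peaks, panel.ladders, truth=_truth(alleles=(226.0, 230.0))
        )
        assert [r.reference_size for r in recs] == [226.0, 230.0]
        assert recs[1].shift == pytest.approx(-2.26)

    def test_prior_mean_shift_recenters_nearest_rung(self, panel):
        recs = assign_reference(
            [_peak(227.74)], panel.ladders, prior_mean_shift={"FAM": -2.26}
        )
        assert recs[0].reference_size == 230.0


class TestBuildCorrectionTable:
    def test_noise_free_simulation_recovers_published_coefficients(
        self, panel, noise_free_params
    ):
        pop = make_population(panel, n_families=100, seed=21)
        trios = simulate_trios(pop)
        peaks = simulate_peak_table(trios, noise_free_params)
        truth = {t.family_id: t for t in trios}
        table = build_correction_table(
            assign_reference(peaks, panel.ladders, truth=truth)
        )
        assert table.coefficient("FAM", 226.0) == pytest.approx(-2.26, abs=1e-9)
        assert table.coefficient("TAMRA", 514.0) == pytest.approx(-1.18, abs=1e-9)

    def test_single_observation_cell_is_that_shift(self, panel):
        recs = assign_reference([_peak(223.5)], panel.ladders, truth=_truth())
        table = build_correction_table(recs)
        assert table.coefficient("FAM", 226.0) == pytest.approx(-2.5)
        assert table.n("FAM", 226.0) == 1

    def test_unobserved_cell_is_missing(self, panel):
        recs = assign_reference([_peak(223.5)], panel.ladders, truth=_truth())
        table = build_correction_table(recs)
        assert table.coefficient("TAMRA", 254.0) is None
        assert table.n("TAMRA", 254.0) == 0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no assigned"):
            build_correction_table([])


class TestFitCorrectionModel:
    @pytest.mark.parametrize(
        "dye,expected_r2",
        [("FAM", 0.98), ("HEX", 0.97), ("TAMRA", 0.99)],
    )
    def test_degree6_fit_reproduces_published_r_squared(
        self, calibration_correction_table, dye, expected_r2
    ):
        model = fit_correction_model(calibration_correction_table, dye, degree=6)
        assert model.r_squared == pytest.approx(expected_r2, abs=0.02)
        assert model.n_points == 12

    def test_residuals_sum_to_zero(self, calibration_correction_table):
        for dye in ("FAM", "HEX", "TAMRA"):
            model = fit_correction_model(calibration_correction_table, dye)
            pts = calibration_correction_table.points(dye)
            x = np.array([r + c for r, c in pts])
            y = np.array([c for _, c in pts])
            assert abs(float(np.sum(y - model.poly(x)))) < 1e-6

    def test_r_squared_nondecreasing_in_degree(self, calibration_correction_table):
        r2 = [
            fit_correction_model(calibration_correction_table, "FAM", degree=d).r_squared
            for d in range(1, 8)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(r2, r2[1:]))

    def test_exact_interpolation_at_full_degree(self, calibration_correction_table):
        # 12 points, degree 11: zero residual df, R^2 = 1, SE undefined
        model = fit_correction_model(calibration_correction_table, "FAM", degree=11)
        assert model.r_squared == pytest.approx(1.0, abs=1e-7)
        assert model.se is None

    def test_too_few_points_suggests_lower_degree(self, calibration_correction_table):
        with pytest.raises(ValueError, match="lower degree"):
            fit_correction_model(calibration_correction_table, "FAM", degree=12)

    def test_fitted_model_self_consistent_at_published_row(
        self, calibration_correction_table
    ):
        model = fit_correction_model(calibration_correction_table, "FAM")
        coef, clamped = model.predict(223.74)
        assert not clamped
        assert coef == pytest.approx(-2.26, abs=0.1)

    def test_raw_coefficients_match_stable_form_at_full_precision(
        self, calibration_correction_table
    ):
        # the power-basis expansion is exact at full precision; it is the
        # *printed* truncation that is not evaluable
        model = fit_correction_model(calibration_correction_table, "FAM")
        raw = Polynomial(model.coefficients_raw)
        for x in np.linspace(*model.x_range, 20):
            assert raw(x) == pytest.approx(model.poly(x), abs=1e-6)


class TestApplyCorrection:
    def _constant_model(self, value, dye="FAM"):
        return CorrectionModel(
            dye=dye,
            degree=0,
            poly=Polynomial([value], domain=[200.0, 600.0], window=[-1.0, 1.0]),
            r_squared=1.0,
            se=None,
            n_points=1,
            x_range=(200.0, 600.0),
        )

    def test_zero_polynomial_is_identity(self):
        peaks = [_peak(223.74), _peak(331.2)]
        out = apply_correction(peaks, {"FAM": self._constant_model(0.0)})
        assert [c.corrected_size for c in out] == [223.74, 331.2]

    def test_constant_coefficient_subtracted(self):
        out = apply_correction([_peak(224.0)], {"FAM": self._constant_model(-2.0)})
        assert out[0].corrected_size == pytest.approx(226.0)

    def test_missing_dye_model_yields_per_peak_error(self):
        out = apply_correction(
            [_peak(224.0), _peak(224.0, dye="HEX")],
            {"FAM": self._constant_model(-2.0)},
        )
        assert out[0].error is None
        assert out[1].corrected_size is None
        assert "HEX" in out[1].error

    def test_out_of_range_evaluation_clamps_and_flags(
        self, calibration_correction_table
    ):
        model = fit_correction_model(calibration_correction_table, "FAM")
        lo = model.x_range[0]
        out = apply_correction([_peak(lo - 10.0)], {"FAM": model})
        assert "extrapolated" in out[0].flags
        assert out[0].corrected_size == pytest.approx(
            (lo - 10.0) - model.poly(lo)
        )

    def test_fitted_fam_model_round_trips_published_row(
        self, calibration_correction_table
    ):
        model = fit_correction_model(calibration_correction_table, "FAM")
        out = apply_correction([_peak(223.74)], {"FAM": model})
        assert out[0].corrected_size == pytest.approx(226.0, abs=0.1)


class TestRoundTrip:
    def test_published_shift_round_trip_within_tenth_bp(self, panel, noise_free_params):
        """Noise-free simulate -> assign -> build -> fit -> apply leaves
        every corrected size within 0.1 bp of its reference allele."""
        pop = make_population(panel, n_families=100, seed=33)
        trios = simulate_trios(pop)
        peaks = simulate_peak_table(trios, noise_free_params)
        truth = {t.family_id: t for t in trios}
        shifts = assign_reference(peaks, panel.ladders, truth=truth)
        models = fit_all_models(build_correction_table(shifts), degree=6)
        corrected = apply_correction(peaks, models)
        errors = [
            abs(c.corrected_size - s.reference_size)
            for s, c in zip(shifts, corrected)
        ]
        assert max(errors) < 0.1

    def test_smooth_shift_round_trip_within_five_hundredths(self, panel):
        """With a genuinely smooth (quadratic) shift function the degree-6
        fit is near-exact and the round trip is tighter than 0.05 bp."""

        def mu(x):
            return -2.0 - 1e-3 * (x - 220.0) + 2e-6 * (x - 220.0) ** 2

        grid = [float(g) for g in range(200, 601, 10)]
        params = ShiftModelParams(
            mean_shift={
                d: [(g, mu(g)) for g in grid] for d in ("FAM", "HEX", "TAMRA")
            },
            seed=0,
        )
        pop = make_population(panel, n_families=100, seed=34)
        trios = simulate_trios(pop)
        peaks = simulate_peak_table(trios, params)
        truth = {t.family_id: t for t in trios}
        shifts = assign_reference(peaks, panel.ladders, truth=truth)
        models = fit_all_models(build_correction_table(shifts), degree=6)
        corrected = apply_correction(peaks, models)
        errors = [
            abs(c.corrected_size - s.reference_size)
            for s, c in zip(shifts, corrected)
        ]
        assert max(errors) < 0.05

    def test_correction_shrinks_absolute_error_for_every_dye(self, panel):
        params = default_shift_params(seed=55)
        pop = make_population(panel, n_families=500, seed=55)
        trios = simulate_trios(pop)
        peaks = simulate_peak_table(trios, params)
        truth = {t.family_id: t for t in trios}
        shifts = assign_reference(peaks, panel.ladders, truth=truth)
        models = fit_all_models(build_correction_table(shifts), degree=6)
        corrected = apply_correction(peaks, models)
        raw_err: dict[str, list] = {}
        cor_err: dict[str, list] = {}
        for s, c in zip(shifts, corrected):
            raw_err.setdefault(s.peak.dye, []).append(abs(s.shift))
            cor_err.setdefault(s.peak.dye, []).append(
                abs(c.corrected_size - s.reference_size)
            )
        for dye in raw_err:
            assert np.mean(cor_err[dye]) < np.mean(raw_err[dye])


def test_residual_records_carry_corrected_sizes(panel, calibration_correction_table):
    peaks = [_peak(223.74)]
    shifts = assign_reference(peaks, panel.ladders, truth=_truth())
    model = fit_correction_model(calibration_correction_table, "FAM")
    corrected = apply_correction(peaks, {"FAM": model})
    residuals = corrected_residual_records(corrected, shifts)
    assert len(residuals) == 1
    assert residuals[0].shift == pytest.approx(
        corrected[0].corrected_size - 226.0
    )
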