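import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coastiso.errors import (
    ConfigurationError,
    InsufficientDataError,
    SingularFitError,
)
from coastiso.lipid import (
    CorrectionModel,
    apply_corrections,
    bonferroni_screen,
    fit_correction,
    load_genus_map,
    load_model_bank,
    paired_wilcoxon,
    screen_and_fit,
)
from coastiso.records import from_frame
from coastiso.simulate import gen_paired_lipid


def brute_force_signed_rank_p(d):
    """Independent oracle: enumerate all 2^n sign assignments."""
    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    sums = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([True, False], repeat=len(d))
    ]
    sums = np.asarray(sums)
    p_le = (sums <= w_obs + 1e-12).mean()
    p_ge = (sums >= w_obs - 1e-12).mean()
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestPairedWilcoxon:
    def test_six_uniform_shifts_give_exact_smallest_p(self):
        res = paired_wilcoxon([0] * 6, [1, 2, 3, 4, 5, 6])
        assert res.p_value == 0.03125
        assert res.method == "exact"

    def test_all_zero_differences_are_insufficient(self):
        with pytest.raises(InsufficientDataError):
            paired_wilcoxon([1.0] * 8, [1.0] * 8)

    def test_zero_differences_dropped_and_counted(self):
        x = np.arange(8.0)
        y = x + np.array([0, 0, 1, 2, 3, 4, 5, 6.0])
        res = paired_wilcoxon(x, y)
        assert res.n_zero == 2 and res.n_used == 6

    def test_balanced_antisymmetric_differences_give_p_one(self):
        x = np.zeros(6)
        y = np.array([1.0, -1.0, 2.0, -2.0, 3.0, -3.0])
        assert paired_wilcoxon(x, y).p_value == 1.0

    @pytest.mark.parametrize("n", range(5, 11))
    def test_exact_p_matches_sign_enumeration_oracle(self, n, rng):
        for _ in range(5):
            d = rng.normal(0.3, 1.0, size=n)
            d[np.abs(d) < 1e-6] = 0.5  # keep differences nonzero
            res = paired_wilcoxon(np.zeros(n), d)
            assert res.p_value == pytest.approx(
                brute_force_signed_rank_p(d), abs=1e-12)

    def test_tie_free_case_agrees_with_scipy_exact(self, rng):
        d = rng.normal(0.5, 1.0, size=12)
        ours = paired_wilcoxon(np.zeros(12), d)
        ref = stats.wilcoxon(d, method="exact")
        assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_large_n_uses_normal_approximation(self, rng):
        d = rng.normal(0.4, 1.0, size=60)
        res = paired_wilcoxon(np.zeros(60), d)
        ref = stats.wilcoxon(d, method="approx", correction=True)
        assert res.method == "normal"
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)


class TestBonferroni:
    def test_flags_use_alpha_over_m_strictly(self):
        assert bonferroni_screen([0.001, 0.04]) == [True, False]
        assert bonferroni_screen([0.05]) == [False]

    def test_explicit_family_size_overrides_list_length(self):
        threshold = 0.001 / 16
        flags = bonferroni_screen(
            [threshold * 0.9, threshold * 1.1],
            alpha=0.001, family_size=16)
        assert flags == [True, False]

    def test_empty_or_invalid_input_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_screen([])
        with pytest.raises(ValueError):
            bonferroni_screen([1.2])


class TestFitCorrection:
    @pytest.mark.parametrize("key,model", sorted(load_model_bank().items()))
    def test_noiseless_pairs_refit_each_published_equation(
        self, key, model
    ):
        xs = np.linspace(-30.0, -12.0, 25)
        pairs = gen_paired_lipid(model, xs, noise_sd=0.0)
        refit = fit_correction(
            pairs["x"], pairs["y"], *key, model.treatment)
        assert refit.slope == pytest.approx(model.slope, abs=1e-10)
        assert refit.intercept == pytest.approx(model.intercept, abs=1e-9)

    def test_two_points_rejected_despite_exact_interpolation(self):
        with pytest.raises(InsufficientDataError):
            fit_correction([0.0, 1.0], [1.0, 2.0], "A", "d13C", "t")

    def test_zero_variance_x_is_singular(self):
        with pytest.raises(SingularFitError):
            fit_correction([1.0, 1.0, 1.0], [1.0, 2.0, 3.0],
                           "A", "d13C", "t")

    @pytest.mark.parametrize("n", [10, 30, 100])
    def test_ols_recovery_error_shrinks_with_sample_size(self, n, rng):
        # parameter-recovery sweep: RMSE of the slope ~ sigma/sqrt(n)
        true = CorrectionModel("X", "d13C", "t", 0.8, -2.0)
        errors = []
        for _ in range(200):
            xs = rng.uniform(-30, -12, size=n)
            pairs = gen_paired_lipid(true, xs, noise_sd=0.5, seed=rng)
            fit = fit_correction(pairs["x"], pairs["y"], "X", "d13C", "t")
            errors.append(fit.slope - true.slope)
        errors = np.array(errors)
        assert abs(errors.mean()) < 0.02
        sigma_x = (30 - 12) / np.sqrt(12)
        predicted_rmse = 0.5 / (sigma_x * np.sqrt(n))
        assert np.sqrt((errors**2).mean()) == pytest.approx(
            predicted_rmse, rel=0.35)


def _tiny_dataset(rows):
    frame = pd.DataFrame(rows)
    frame["date"] = pd.to_datetime(frame["date"]).dt.date
    frame.index = pd.Index(
        [f"r{i}" for i in range(len(frame))], name="record_id")
    for col, default in (("group", "consumer"), ("treatment", "none"),
                         ("lipid_corrected", False)):
        if col not in frame.columns:
            frame[col] = default
    return from_frame(frame)


class TestApplyCorrections:
    def _rows(self, **over):
        row = {"date": "2010-01-01", "genus": "Gammarus",
               "d13C": -20.0, "d15N": 10.0}
        row.update(over)
        return row

    def test_published_equation_arithmetic(self):
        ds = _tiny_dataset([
            self._rows(),                      # Arthropoda: 0.76x - 3.9
            self._rows(genus="Calanus", d13C=-24.0),  # 1.2x + 7.6
        ])
        out, summary = apply_corrections(ds)
        assert out.frame.loc["r0", "d13C"] == pytest.approx(-19.1)
        assert out.frame.loc["r1", "d13C"] == pytest.approx(-21.2)
        assert out.frame["lipid_corrected"].all()
        assert summary.loc[summary.isotope == "d13C",
                           "n_corrected"].item() == 2

    def test_unmapped_genus_left_unchanged(self):
        ds = _tiny_dataset([self._rows(genus="Yoldia")])
        out, _ = apply_corrections(ds)
        assert out.frame.loc["r0", "d13C"] == -20.0
        assert not out.frame.loc["r0", "lipid_corrected"]

    def test_already_extracted_tissue_never_corrected(self):
        ds = _tiny_dataset(
            [self._rows(treatment="lipid_extraction")])
        out, _ = apply_corrections(ds)
        assert out.frame.loc["r0", "d13C"] == -20.0

    def test_correction_is_idempotent_guarded(self):
        ds = _tiny_dataset([self._rows()])
        once, _ = apply_corrections(ds)
        twice, summary = apply_corrections(once)
        assert twice.frame.loc["r0", "d13C"] == once.frame.loc["r0", "d13C"]
        assert summary["n_corrected"].sum() == 0

    def test_endmembers_never_corrected(self):
        ds = _tiny_dataset([self._rows(group="end-member")])
        out, _ = apply_corrections(ds)
        assert out.frame.loc["r0", "d13C"] == -20.0

    def test_genus_mapped_to_missing_model_is_configuration_error(self):
        ds = _tiny_dataset([self._rows()])
        with pytest.raises(ConfigurationError):
            apply_corrections(ds, genus_map={"Gammarus": "Nematoda"})

    def test_apply_then_invert_recovers_original(self, rng):
        for model in load_model_bank().values():
            x = rng.uniform(-30, -10, size=50)
            assert np.allclose(model.invert(model.apply(x)), x,
                               atol=1e-12)


class TestScreenAndFit:
    def test_shifted_cell_fitted_null_cell_not(self, rng):
        x = rng.uniform(-28, -16, size=30)
        shifted = pd.DataFrame({
            "taxon_key": "Mollusca", "isotope": "d13C",
            "treatment": "lipid_extraction",
            "x": x, "y": 0.9 * x - 1.5 + rng.normal(0, 0.1, 30)})
        null = pd.DataFrame({
            "taxon_key": "Porifera", "isotope": "d15N",
            "treatment": "lipid_extraction",
            "x": x, "y": x + rng.normal(0, 0.3, 30)})
        table = screen_and_fit(pd.concat([shifted, null]))
        m = table.set_index("taxon_key")
        assert m.loc["Mollusca", "significant_after_bonferroni"]
        assert not m.loc["Porifera", "significant_after_bonferroni"]
        assert m.loc["Mollusca", "slope"] == pytest.approx(0.9, abs=0.05)
        assert np.isnan(m.loc["Porifera", "slope"])


def test_packaged_genus_map_targets_only_banked_taxa():
    bank_taxa = {k for k, _ in load_model_bank()}
    assert set(load_genus_map().values()) <= bank_taxa
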