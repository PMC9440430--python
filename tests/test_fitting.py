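"""Fitting: identifiability, recovery, model selection, statistics."""

import math

import numpy as np
import pytest
from scipy import stats

import kappabind as kb
from kappabind.anisotropy import LabelConfig

from conftest import make_tandem_curves

TRUTH = kb.BindingParams(kd_site1=2.2, amplitude=0.08, baseline=0.17)


def noise_free_curve(kd, isotherm="quadratic", d_total=5.0):
    conc = kb.default_concentration_series()
    if isotherm == "quadratic":
        frac = np.array([kb.single_site_complex(x, d_total, kd) / d_total for x in conc])
    else:
        frac = conc / (conc + kd)
    return kb.TitrationCurve(
        construct="synthetic",
        label=LabelConfig(labeled_strand="hairpin"),
        replicate=1,
        concentrations=conc,
        anisotropy=0.17 + 0.08 * frac,
        d_total=d_total,
    )


class TestSingleSiteFit:
    def test_zero_noise_quadratic_recovery(self):
        fit = kb.fit_single_site(noise_free_curve(2.2, "quadratic"))
        assert fit.params.kd_site1 == pytest.approx(2.2, rel=1e-6)
        assert fit.params.amplitude == pytest.approx(0.08, rel=1e-6)
        assert fit.converged

    def test_zero_noise_hyperbolic_recovery(self):
        fit = kb.fit_single_site(noise_free_curve(130.0, "hyperbolic"), "hyperbolic")
        assert fit.params.kd_site1 == pytest.approx(130.0, rel=1e-6)

    def test_noisy_nonspecific_recovery_within_fifteen_percent(self):
        """Triplicate random-hairpin titrations at the weak nonspecific
        affinity recover the generating Kd on average."""
        hp = kb.fixtures()["hairpin_random"]
        lab = LabelConfig.for_construct(hp, "hairpin")
        conc = kb.default_concentration_series(1.0, 10000.0, 12)
        truth = kb.BindingParams(kd_site1=130.0, amplitude=0.08, baseline=0.17)
        curves = kb.generate_titration(
            truth, hp, lab, 5.0, conc, kb.NoiseModel(sigma=0.003, seed=1)
        )
        kds = [kb.fit_single_site(c, "hyperbolic").params.kd_site1 for c in curves]
        assert np.mean(kds) == pytest.approx(130.0, rel=0.15)

    def test_flat_curve_flagged_unidentifiable(self):
        conc = kb.default_concentration_series()
        flat = kb.TitrationCurve(
            construct="flat",
            label=LabelConfig(labeled_strand="hairpin"),
            replicate=1,
            concentrations=conc,
            anisotropy=np.full(conc.shape, 0.17),
        )
        fit = kb.fit_single_site(flat)
        assert not fit.converged
        assert fit.params.amplitude == pytest.approx(0.0, abs=1e-6)

    def test_unit_rescaling_invariance(self):
        """Fitting in μM instead of nM rescales Kd by exactly 1000."""
        c = noise_free_curve(2.2)
        c_um = kb.TitrationCurve(
            construct=c.construct,
            label=c.label,
            replicate=1,
            concentrations=c.concentrations / 1000.0,
            anisotropy=c.anisotropy,
            d_total=c.d_total / 1000.0,
        )
        kd_nm = kb.fit_single_site(c).params.kd_site1
        kd_um = kb.fit_single_site(c_um).params.kd_site1
        assert kd_um * 1000.0 == pytest.approx(kd_nm, rel=1e-4)

    def test_median_bias_small_over_seeds(self):
        """Parameter-recovery bias: median relative Kd error stays below 5%
        for in-range Kd at the experimental noise level."""
        hp = kb.fixtures()["hairpin_ifn_beta"]
        lab = LabelConfig.for_construct(hp, "hairpin")
        conc = kb.default_concentration_series()
        truth = kb.BindingParams(kd_site1=2.2, amplitude=0.08, baseline=0.17)
        errs = []
        for seed in range(100):
            curve = kb.generate_titration(
                truth, hp, lab, 5.0, conc,
                kb.NoiseModel(sigma=0.003, seed=seed, n_replicates=1),
            )[0]
            kd = kb.fit_single_site(curve).params.kd_site1
            errs.append((kd - 2.2) / 2.2)
        assert abs(np.median(errs)) < 0.05


class TestGlobalTwoSiteFit:
    def test_zero_noise_equal_kd_exact_recovery(self, hiv_labeled):
        truth = kb.BindingParams(kd_site1=1.3, kd_site2=1.3, amplitude=0.08, baseline=0.17)
        fw, rv = make_tandem_curves(hiv_labeled, truth, seed=0, sigma=0.0)
        fit = kb.fit_global_two_site([fw[0], rv[0]], hiv_labeled, model="equal_kd")
        assert fit.params.kd_site1 == pytest.approx(1.3, rel=1e-6)
        assert fit.converged

    def test_zero_noise_distinct_kd_exact_recovery(self, nfkbia_labeled):
        truth = kb.BindingParams(kd_site1=1.7, kd_site2=10.0, amplitude=0.08, baseline=0.17)
        fw, rv = make_tandem_curves(nfkbia_labeled, truth, seed=0, sigma=0.0)
        fit = kb.fit_global_two_site([fw[0], rv[0]], nfkbia_labeled, model="distinct_kd")
        assert fit.params.kd_site1 == pytest.approx(1.7, rel=1e-6)
        assert fit.params.kd_site2 == pytest.approx(10.0, rel=1e-6)

    def test_zero_noise_cooperative_exact_recovery(self, hiv_labeled):
        truth = kb.BindingParams(
            kd_site1=1.7, kd_site2=1.7, omega=5.0, amplitude=0.08, baseline=0.17
        )
        fw, rv = make_tandem_curves(hiv_labeled, truth, seed=0, sigma=0.0)
        fit = kb.fit_global_two_site([fw[0], rv[0]], hiv_labeled, model="cooperative")
        assert fit.params.kd_site1 == pytest.approx(1.7, rel=1e-5)
        assert fit.params.omega == pytest.approx(5.0, rel=1e-4)

    def test_noisy_site2_recovery_within_twenty_percent(self, nfkbia_labeled):
        truth = kb.BindingParams(kd_site1=1.7, kd_site2=10.0, amplitude=0.08, baseline=0.17)
        fw, rv = make_tandem_curves(nfkbia_labeled, truth, seed=1)
        kd2s = [
            kb.fit_global_two_site([fw[r], rv[r]], nfkbia_labeled, "distinct_kd").params.kd_site2
            for r in range(3)
        ]
        assert np.mean(kd2s) == pytest.approx(10.0, rel=0.20)

    def test_weak_site_occupancy_lags_below_site_concentration(self, nfkbia_labeled):
        """With Kd2 > Kd1, site 2 stays less occupied than site 1 while
        protein is below the 10 nM site concentration — the sigmoidal lag."""
        params = kb.BindingParams(kd_site1=1.7, kd_site2=10.0)
        conc = np.linspace(0.1, 10.0, 25)
        th1, th2 = kb.two_site_occupancies(conc, 5.0, params)
        assert np.all(th2 < th1)

    def test_equal_kd_never_beats_distinct_on_rss(self, nfkbia_labeled):
        truth = kb.BindingParams(kd_site1=1.7, kd_site2=10.0, amplitude=0.08, baseline=0.17)
        for seed in (1, 2, 3):
            fw, rv = make_tandem_curves(nfkbia_labeled, truth, seed=seed)
            eq = kb.fit_global_two_site([fw[0], rv[0]], nfkbia_labeled, "equal_kd")
            di = kb.fit_global_two_site([fw[0], rv[0]], nfkbia_labeled, "distinct_kd")
            assert di.rss <= eq.rss + 1e-12

    def test_requires_both_label_orientations(self, hiv_labeled):
        truth = kb.BindingParams(kd_site1=1.3, kd_site2=1.3, amplitude=0.08, baseline=0.17)
        fw, _ = make_tandem_curves(hiv_labeled, truth, seed=0)
        with pytest.raises(ValueError, match="forward.*reverse|reverse.*forward"):
            kb.fit_global_two_site([fw[0], fw[1]], hiv_labeled)


class TestModelSelection:
    def test_true_model_recovered_zero_noise(self, hiv_labeled, nfkbia_labeled):
        eq_truth = kb.BindingParams(kd_site1=1.7, kd_site2=1.7, amplitude=0.08, baseline=0.17)
        fw, rv = make_tandem_curves(hiv_labeled, eq_truth, seed=0, sigma=0.0)
        chosen, _ = kb.select_model([fw[0], rv[0]], hiv_labeled)
        assert chosen == "equal_kd"

    def test_distinct_kd_detected_at_noise(self, nfkbia_labeled):
        truth = kb.BindingParams(kd_site1=1.7, kd_site2=10.0, amplitude=0.08, baseline=0.17)
        fw, rv = make_tandem_curves(nfkbia_labeled, truth, seed=42)
        chosen, fits = kb.select_model(fw + rv, nfkbia_labeled)
        assert chosen == "distinct_kd"
        assert fits["distinct_kd"].aicc < fits["equal_kd"].aicc

    def test_cooperative_detected_at_noise(self, hiv_labeled):
        """ω = 5 is detectable when Kd (10 nM, the weak-site value) is above
        the 10 nM site concentration; in the stoichiometric regime
        (Kd ≪ [DNA]) curve shape carries almost no cooperativity signal."""
        truth = kb.BindingParams(
            kd_site1=10.0, kd_site2=10.0, omega=5.0, amplitude=0.08, baseline=0.17
        )
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            fw, rv = make_tandem_curves(hiv_labeled, truth, seed=seed)
            chosen, _ = kb.select_model(fw + rv, hiv_labeled)
            hits += chosen == "cooperative"
        assert hits >= 0.9 * n_seeds


class TestAggregation:
    def test_closed_form_example(self):
        mean, sem = kb.mean_sem([1.0, 1.3, 1.6])
        assert mean == pytest.approx(1.3)
        assert sem == pytest.approx(0.3 / math.sqrt(3), rel=1e-9)

    def test_identical_replicates_have_zero_sem(self):
        assert kb.mean_sem([2.0, 2.0, 2.0])[1] == 0.0

    def test_matches_direct_formula_on_random_draws(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            v = rng.lognormal(0, 1, size=rng.integers(2, 8))
            mean, sem = kb.mean_sem(v)
            assert mean == pytest.approx(v.sum() / len(v))
            sd = math.sqrt(((v - v.mean()) ** 2).sum() / (len(v) - 1))
            assert sem == pytest.approx(sd / math.sqrt(len(v)))

    def test_aggregate_requires_two_fits(self):
        fit = kb.fit_single_site(noise_free_curve(2.2))
        with pytest.raises(ValueError):
            kb.aggregate_replicates([fit])

    def test_aggregate_reports_parameter_means(self):
        fits = [kb.fit_single_site(noise_free_curve(kd)) for kd in (2.0, 2.2, 2.4)]
        agg = kb.aggregate_replicates(fits)
        assert agg["kd_site1"][0] == pytest.approx(2.2, rel=1e-5)


class TestGroupComparison:
    def test_identical_groups_p_one(self):
        assert kb.compare_groups([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]) == 1.0

    def test_separated_groups_significant(self):
        p = kb.compare_groups([1.0, 1.1, 0.9], [100.0, 110.0, 90.0])
        assert p < 0.01

    def test_matches_reference_welch_implementation(self):
        rng = np.random.default_rng(11)
        a = rng.normal(130, 40, 3)
        b = rng.normal(1500, 100, 3)
        assert kb.compare_groups(a, b) == pytest.approx(
            stats.ttest_ind(a, b, equal_var=False).pvalue
        )

    def test_permutation_agrees_with_parametric(self):
        rng = np.random.default_rng(5)
        a = rng.normal(10, 2, 6)
        b = rng.normal(13, 2, 6)
        p_w = kb.compare_groups(a, b, "welch")
        p_p = kb.compare_groups(a, b, "permutation", seed=0)
        assert p_p == pytest.approx(p_w, abs=0.05)
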