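"""Bayesian inference: likelihood/priors, fits, degeneracy, propagation."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

import allokit as ak
from allokit.inference import (
    ConvergenceWarning,
    GlobalFitModel,
    GlobalFitPriors,
    HillModel,
    HillThermoModel,
    SingleStrainModel,
    degeneracy_scan,
    log_likelihood,
    log_prior_global,
    log_prior_single,
    propagate_properties,
)
from allokit.synthetic import DesignSpec, simulate_induction_table

TRUTH_KT_A = -np.log10(139e-6)
TRUTH_KT_I = -np.log10(0.53e-6)


def o2_table(sigma=0.02, seed=42, **kwargs):
    design = DesignSpec(
        repressor_levels=(260.0,), operators=(("O2", -13.9),),
        sigma=sigma, seed=seed, **kwargs,
    )
    return simulate_induction_table(design)


def exact_table(n_rows=10):
    """Table whose fold-change equals the model prediction exactly."""
    tab = o2_table(sigma=1e-12, seed=0)
    tab = tab.iloc[:n_rows].copy()
    tab["fold_change"] = tab["fold_change_true"]
    return tab


class TestLikelihood:
    def test_zero_residual_closed_form(self):
        tab = exact_table(10)
        ll = log_likelihood((TRUTH_KT_A, TRUTH_KT_I, 0.1), tab)
        assert ll == pytest.approx(-5.0 * np.log(2 * np.pi * 0.01), rel=1e-12)

    def test_one_sigma_perturbation_costs_half(self):
        tab = exact_table(10)
        base = log_likelihood((TRUTH_KT_A, TRUTH_KT_I, 0.1), tab)
        tab2 = tab.copy()
        tab2.loc[0, "fold_change"] += 0.1
        assert log_likelihood((TRUTH_KT_A, TRUTH_KT_I, 0.1), tab2) == (
            pytest.approx(base - 0.5, abs=1e-10)
        )

    def test_matches_normal_density_product_oracle(self, rng):
        for _ in range(5):
            tab = o2_table(sigma=0.05, seed=int(rng.integers(1e6)))
            params = (
                float(rng.uniform(2, 5)),
                float(rng.uniform(4, 7)),
                float(rng.uniform(0.01, 0.2)),
            )
            pred = ak.fold_change(
                tab["iptg_M"].to_numpy(),
                ak.AllosterySpec(
                    ka=10.0 ** -params[0], ki=10.0 ** -params[1], d_eps_ai=4.5
                ),
                ak.StrainSpec(repressors=260, d_eps_ra=-13.9),
            )
            oracle = float(
                np.sum(norm.logpdf(tab["fold_change"], pred, params[2]))
            )
            assert log_likelihood(params, tab) == pytest.approx(oracle, rel=1e-10)


class TestPriors:
    def test_out_of_bounds_log_constant(self):
        assert log_prior_single((8.0, 5.0, 0.1)) == -np.inf
        assert log_prior_single((3.0, -7.5, 0.1)) == -np.inf

    def test_jeffreys_scaling(self):
        assert log_prior_single((3.0, 5.0, 0.2)) == pytest.approx(
            log_prior_single((3.0, 5.0, 0.1)) - np.log(2), abs=1e-12
        )

    def test_global_prior_peaks_at_prior_means(self):
        priors = GlobalFitPriors(
            r_means={22.0: 22.0}, r_sds={22.0: 4.0},
            eps_means={"O1": -15.3}, eps_sds={"O1": 0.2},
        )
        at_mean = log_prior_global((3.0, 5.0, 22.0, -15.3, 0.1), priors)
        assert at_mean > log_prior_global((3.0, 5.0, 30.0, -15.3, 0.1), priors)
        assert at_mean > log_prior_global((3.0, 5.0, 22.0, -15.0, 0.1), priors)


class TestSingleStrainFit:
    def test_requires_single_strain_and_enough_concentrations(self):
        design = DesignSpec(
            repressor_levels=(22.0, 260.0), operators=(("O2", -13.9),),
            sigma=0.02, seed=1,
        )
        with pytest.raises(ValueError, match="one"):
            SingleStrainModel(simulate_induction_table(design))
        few = o2_table().iloc[:4]
        with pytest.raises(ValueError, match="6 distinct"):
            SingleStrainModel(few)

    def test_recovers_truth_within_credible_interval(self):
        res = ak.fit_single_strain(o2_table(), seed=7)
        ci = res.conf_int()
        assert ci.loc["kt_a", "lower"] <= TRUTH_KT_A <= ci.loc["kt_a", "upper"]
        assert ci.loc["kt_i", "lower"] <= TRUTH_KT_I <= ci.loc["kt_i", "upper"]
        assert ci.loc["sigma", "lower"] <= 0.02 <= ci.loc["sigma", "upper"]
        assert res.posterior.converged()

    def test_same_seed_identical_summaries(self):
        tab = o2_table()
        r1 = ak.fit_single_strain(tab, seed=3)
        r2 = ak.fit_single_strain(tab, seed=3)
        assert np.array_equal(r1.posterior.draws, r2.posterior.draws)
        assert r1.summary().to_csv() == r2.summary().to_csv()

    def test_equal_constants_degenerate_posterior(self):
        """Flat data leaves the individual constants unidentified but keeps
        the flat-response ridge (K_A ~ K_I, or both outside the measured
        window) in the posterior; a responsive strain excludes ratio ~ 1."""
        a_eq = ak.AllosterySpec(ka=1e-5, ki=1e-5, d_eps_ai=4.5)
        design = DesignSpec(
            repressor_levels=(260.0,), operators=(("O2", -13.9),),
            sigma=0.01, seed=9,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            flat = ak.fit_single_strain(
                simulate_induction_table(design, truth=a_eq), seed=2
            )
        d = flat.posterior.to_frame()
        span = d["kt_a"].quantile(0.975) - d["kt_a"].quantile(0.025)
        assert span > 8.0  # essentially the whole prior
        frac_ratio_one = float(((d["kt_a"] - d["kt_i"]).abs() < 0.3).mean())
        assert frac_ratio_one > 0.02
        responsive = ak.fit_single_strain(o2_table(), seed=2)
        dr = responsive.posterior.to_frame()
        assert float(((dr["kt_a"] - dr["kt_i"]).abs() < 0.3).mean()) == 0.0

    def test_flat_data_warns(self):
        design = DesignSpec(
            repressor_levels=(22.0,), operators=(("O3", -9.7),),
            sigma=0.02, seed=5,
        )
        with pytest.warns(UserWarning, match="flat"):
            SingleStrainModel(simulate_induction_table(design))


class TestGlobalFit:
    @pytest.fixture(scope="class")
    def global_fit(self):
        design = DesignSpec(
            repressor_levels=(260.0, 1220.0),
            operators=(("O1", -15.3), ("O2", -13.9)),
            sigma=0.02, seed=7,
        )
        table = simulate_induction_table(design)
        priors = GlobalFitPriors(
            r_means={260.0: 260.0, 1220.0: 1220.0},
            r_sds={260.0: 40.0, 1220.0: 160.0},
            eps_means={"O1": -15.3, "O2": -13.9},
            eps_sds={"O1": 0.2, "O2": 0.2},
        )
        return ak.fit_global(table, priors, seed=4), priors

    def test_recovers_dissociation_constants(self, global_fit):
        res, _ = global_fit
        ci = res.conf_int()
        assert ci.loc["kt_a", "lower"] <= TRUTH_KT_A <= ci.loc["kt_a", "upper"]
        assert ci.loc["kt_i", "lower"] <= TRUTH_KT_I <= ci.loc["kt_i", "upper"]

    def test_nuisance_parameters_stay_near_priors(self, global_fit):
        res, priors = global_fit
        p = res.params
        for key, mu in priors.r_means.items():
            assert abs(p[f"R[{key}]"] - mu) < 3 * priors.r_sds[key]
        for key, mu in priors.eps_means.items():
            assert abs(p[f"eps[{key}]"] - mu) < 3 * priors.eps_sds[key]

    def test_tight_prior_pins_repressor_count(self):
        design = DesignSpec(
            repressor_levels=(260.0, 1220.0),
            operators=(("O1", -15.3), ("O2", -13.9)),
            sigma=0.02, seed=8,
        )
        table = simulate_induction_table(design)
        priors = GlobalFitPriors(
            r_means={260.0: 260.0, 1220.0: 1220.0},
            r_sds={260.0: 1e-4, 1220.0: 1e-4},
            eps_means={"O1": -15.3, "O2": -13.9},
            eps_sds={"O1": 0.2, "O2": 0.2},
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            res = ak.fit_global(table, priors, seed=5,
                                n_burn=500, n_steps=300)
        d = res.posterior.to_frame()
        assert d["R[260.0]"].std() < 0.01
        assert d["R[260.0]"].mean() == pytest.approx(260.0, abs=0.01)

    def test_single_strain_design_rejected(self):
        priors = GlobalFitPriors(
            r_means={260.0: 260.0}, r_sds={260.0: 40.0},
            eps_means={"O2": -13.9}, eps_sds={"O2": 0.2},
        )
        with pytest.raises(ValueError, match=">= 2"):
            GlobalFitModel(o2_table(), priors)

    def test_missing_prior_entry_rejected(self):
        design = DesignSpec(
            repressor_levels=(260.0, 1220.0),
            operators=(("O1", -15.3), ("O2", -13.9)),
            sigma=0.02, seed=7,
        )
        table = simulate_induction_table(design)
        priors = GlobalFitPriors(
            r_means={260.0: 260.0}, r_sds={260.0: 40.0},
            eps_means={"O1": -15.3, "O2": -13.9},
            eps_sds={"O1": 0.2, "O2": 0.2},
        )
        with pytest.raises(ValueError, match="1220"):
            GlobalFitModel(table, priors)


class TestDegeneracyScan:
    def test_degenerate_energies_fit_equally_well(self):
        tab = o2_table(sigma=0.01, seed=12)
        scan = degeneracy_scan(tab, [2.0, 4.5, 7.0])
        assert (scan["resid_sd"] < 2 * 0.01).all()

    def test_single_point_grid_is_conditional_fit(self):
        tab = o2_table(sigma=0.01, seed=12)
        scan = degeneracy_scan(tab, [4.5])
        assert len(scan) == 1
        assert scan.loc[0, "ka"] == pytest.approx(139e-6, rel=0.3)

    def test_compensating_ka_monotone_along_grid(self):
        tab = o2_table(sigma=0.005, seed=13)
        scan = degeneracy_scan(tab, np.linspace(2.0, 7.0, 6))
        assert (np.diff(scan["ka"]) < 0).all() or (np.diff(scan["ka"]) > 0).all()


class TestPropagateProperties:
    def test_degenerate_draws_give_zero_width(self, o2_strain):
        draws = np.tile([TRUTH_KT_A, TRUTH_KT_I, 0.02], (50, 1))
        samples = ak.PosteriorSamples(
            draws=draws, names=["kt_a", "kt_i", "sigma"],
            diagnostics=pd.DataFrame(
                {"rhat": [1.0] * 3, "ess": [np.inf] * 3},
                index=["kt_a", "kt_i", "sigma"],
            ),
            seed=0,
        )
        props = propagate_properties(samples, o2_strain)
        assert props.loc["ec50", "lower"] == props.loc["ec50", "upper"]
        assert props.loc["ec50", "mode"] == pytest.approx(4.94e-5, rel=1e-2)

    def test_interval_endpoints_are_percentiles(self, o2_strain):
        res = ak.fit_single_strain(o2_table(), seed=6)
        props = res.propagate_properties()
        d = res.posterior.to_frame()
        leak = 1.0 / (
            1.0
            + (1.0 / (1.0 + np.exp(-4.5)))
            * 260 / 4.6e6 * np.exp(13.9)
        ) * np.ones(len(d))  # leakiness is k-independent here
        assert props.loc["leakiness", "lower"] == pytest.approx(
            float(np.percentile(leak, 2.5)), rel=1e-9
        )
        ec50_draws = [
            ak.ec50(
                ak.AllosterySpec(ka=10.0**-ka, ki=10.0**-ki, d_eps_ai=4.5),
                o2_strain,
            )
            for ka, ki in zip(d["kt_a"], d["kt_i"])
        ]
        assert props.loc["ec50", "lower"] == pytest.approx(
            float(np.percentile(ec50_draws, 2.5)), rel=1e-9
        )

    def test_flat_strain_has_wide_asymmetric_ec50(self):
        design = DesignSpec(
            repressor_levels=(22.0,), operators=(("O3", -9.7),),
            sigma=0.02, seed=5,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            flat = ak.fit_single_strain(
                simulate_induction_table(design), seed=3
            ).propagate_properties()
        ref = ak.fit_single_strain(o2_table(), seed=3).propagate_properties()
        width = lambda p: p.loc["ec50", "upper"] / p.loc["ec50", "lower"]
        assert width(flat) > 5 * width(ref)
        upper_arm = flat.loc["ec50", "upper"] - flat.loc["ec50", "mode"]
        lower_arm = flat.loc["ec50", "mode"] - flat.loc["ec50", "lower"]
        assert upper_arm > 2 * lower_arm


class TestHillFits:
    def test_hill_self_recovery(self):
        truth = dict(leak=0.02, dr=0.9, k=5e-5, n=1.8)
        c = np.concatenate([[0.0], np.logspace(-7, np.log10(5e-3), 11)])
        rng = np.random.default_rng(3)
        tab = pd.DataFrame(
            {
                "operator": "O2", "d_eps_ra_kT": -13.9, "repressors": 260.0,
                "iptg_M": c, "replicate": 1,
                "fold_change": HillModel.curve(c, *truth.values())
                + rng.normal(0, 0.01, c.size),
            }
        )
        res = ak.fit_hill(tab, seed=4)
        ci = res.conf_int()
        assert ci.loc["leakiness", "lower"] <= truth["leak"] <= ci.loc["leakiness", "upper"]
        assert ci.loc["n_hill", "lower"] <= truth["n"] <= ci.loc["n_hill", "upper"]
        assert ci.loc["log10_k", "lower"] <= np.log10(truth["k"]) <= ci.loc["log10_k", "upper"]

    def test_fixed_unit_n_midpoint_equals_k(self):
        tab = o2_table(sigma=0.01, seed=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            res = HillModel(tab, fix_n=1.0).fit(seed=5, n_burn=800,
                                                n_steps=800)
        p = res.map_params
        k = 10.0 ** p["log10_k"]
        mid = p["leakiness"] + 0.5 * p["dynamic_range"]
        assert res.predict(k) == pytest.approx(mid, rel=1e-9)

    def test_zero_concentration_only_rejected(self):
        tab = o2_table().iloc[:1]
        with pytest.raises(ValueError):
            HillModel(tab)

    def test_hill_thermo_transfers_across_strains(self, fitted_allostery):
        res = ak.fit_hill_thermo(o2_table(), seed=3)
        c = np.concatenate([[0.0], np.logspace(-8, -2, 40)])
        for strain in [
            ak.StrainSpec(repressors=1220, d_eps_ra=-15.3),
            ak.StrainSpec(repressors=22, d_eps_ra=-9.7),
            ak.StrainSpec(repressors=1740, d_eps_ra=-13.9),
        ]:
            pred = res.predict(c, strain)
            true = ak.fold_change(c, fitted_allostery, strain)
            assert np.max(np.abs(pred - true)) < 0.05

    def test_hill_thermo_active_fraction_limits(self):
        pa = HillThermoModel.active_fraction(
            np.array([0.0, 1e-6, 1e-3]), 0.9, 0.0, 1e-5, 2.0
        )
        assert np.allclose(pa, 0.9)  # zero range: constant in c

    def test_hill_thermo_pa_max_near_true_active_fraction(
        self, fitted_allostery
    ):
        res = ak.fit_hill_thermo(o2_table(), seed=3)
        pa0 = ak.active_probability(0.0, fitted_allostery)
        assert res.params["pa_max"] == pytest.approx(pa0, abs=0.1)
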