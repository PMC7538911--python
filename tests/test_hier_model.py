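"""Hierarchical rating regression: recovery, WAIC, selection, contrasts."""

import math
import warnings

import arviz as az
import numpy as np
import pytest

from facetrait.errors import ContractError, SpecificationError
from facetrait.hier_model import (
    MCMCConfig,
    ModelSpec,
    TEST_SCALE_MCMC,
    candidate_specs,
    fit_hierarchical,
    generated_quantities,
    select_best,
    waic,
    waic_detail,
)
from facetrait.synthetic_data import make_ground_truth, simulate_level_trials

SMALL_MCMC = MCMCConfig(iterations=800, burn_in=200, chains=2, seed=9)


def _small_trials(b1=0.8, b2=-0.05, seed=0, n_participants=10, n_faces=10):
    truth = make_ground_truth(-0.4, seed=0, b1=b1, b2=b2)
    return simulate_level_trials(
        truth, n_participants=n_participants, n_base_faces=n_faces, seed=seed
    )


@pytest.fixture(scope="module")
def small_fit():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_hierarchical(_small_trials(), ModelSpec(), SMALL_MCMC)


class TestModelSpec:
    def test_default_mcmc_is_study_scale(self):
        cfg = MCMCConfig()
        assert (cfg.iterations, cfg.burn_in, cfg.chains) == (13_000, 3_000, 4)

    def test_quadratic_requires_linear(self):
        with pytest.raises(SpecificationError):
            ModelSpec(level=False, quadratic=True)

    def test_full_fixed_terms(self):
        terms = ModelSpec().fixed_terms
        assert terms == (
            "intercept",
            "level",
            "level2",
            "face_sex",
            "face_sex:level",
            "face_sex:level2",
            "rater_sex",
            "rater_sex:level",
            "rater_sex:level2",
        )

    def test_candidate_lattice(self):
        specs = candidate_specs()
        assert len(specs) == 8
        assert all(s.level for s in specs)
        assert len({s.name for s in specs}) == 8


class TestWaic:
    # fixed 4-draw x 3-observation log-likelihood table
    LL = np.array(
        [
            [-1.0, -2.0, -0.3],
            [-0.5, -1.5, -0.4],
            [-0.7, -1.8, -0.2],
            [-1.2, -2.2, -0.5],
        ]
    )

    def test_hand_computed_oracle(self):
        lppd = 0.0
        p_waic = 0.0
        s = self.LL.shape[0]
        for i in range(self.LL.shape[1]):
            col = [self.LL[d, i] for d in range(s)]
            lppd += math.log(sum(math.exp(v) for v in col) / s)
            mean = sum(col) / s
            p_waic += sum((v - mean) ** 2 for v in col) / (s - 1)
        oracle = -2.0 * (lppd - p_waic)
        assert waic(self.LL) == pytest.approx(oracle, abs=1e-10)

    def test_identical_draw_tables_identical_waic(self):
        assert waic(self.LL) == waic(self.LL.copy())

    def test_matches_arviz(self):
        ll = np.random.default_rng(0).normal(-1.0, 0.3, size=(2, 200, 12))
        idata = az.from_dict(log_likelihood={"y": ll})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = az.waic(idata, scale="deviance")
        s = 2 * 200
        ours, lppd, p = waic_detail(ll.reshape(-1, 12))
        # arviz computes the draw variance with ddof=0; we use the sample
        # variance (ddof=1), so rescale p_waic before comparing
        assert p * (s - 1) / s == pytest.approx(float(ref.p_waic), rel=1e-8)
        assert ours - 2 * p / s == pytest.approx(float(ref.elpd_waic), rel=1e-8)

    def test_missing_loglik_contract_error(self, small_fit):
        stripped = small_fit
        ll, stripped.log_lik = stripped.log_lik, None
        try:
            with pytest.raises(ContractError):
                waic(stripped)
        finally:
            stripped.log_lik = ll

    def test_generating_model_beats_intercept_only(self):
        trials = _small_trials(b1=1.0, b2=0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            good = fit_hierarchical(
                trials, ModelSpec(quadratic=False, face_sex=False, rater_sex=False),
                SMALL_MCMC,
            )
            bare = fit_hierarchical(
                trials,
                ModelSpec(level=False, quadratic=False, face_sex=False, rater_sex=False),
                SMALL_MCMC,
            )
        assert waic(good) < waic(bare)


class TestFitHierarchical:
    def test_recovers_generating_fixed_effects(self):
        """Validation-scale design (16 raters x 20 base faces x 7 levels) with
        known latent effects: both 95% CrIs cover the generating values."""
        truth = make_ground_truth(-0.4, seed=0, b1=0.8, b2=-0.05)
        trials = simulate_level_trials(
            truth, n_participants=16, n_base_faces=20, seed=0
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_hierarchical(trials, ModelSpec(), TEST_SCALE_MCMC)
        lo, hi = fit.cri("b_level")
        assert lo <= 0.8 <= hi
        lo, hi = fit.cri("b_level2")
        assert lo <= -0.05 <= hi

    def test_null_linear_effect_cri_contains_zero(self):
        trials = _small_trials(b1=0.0, b2=0.0, seed=4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_hierarchical(
                trials, ModelSpec(quadratic=False, face_sex=False, rater_sex=False),
                SMALL_MCMC,
            )
        lo, hi = fit.cri("b_level")
        assert lo <= 0.0 <= hi

    def test_summary_invariants(self, small_fit):
        t = small_fit.table
        assert (t["cri_low"] <= t["eap"]).all() and (t["eap"] <= t["cri_high"]).all()
        assert t["rhat"].notna().all()
        assert small_fit.random_structure["participant"][0] == "intercept"

    def test_random_slope_for_constant_term_rejected(self):
        # rater sex never varies within a participant
        with pytest.raises(SpecificationError, match="rater_sex"):
            fit_hierarchical(
                _small_trials(),
                ModelSpec(),
                SMALL_MCMC,
                random_terms={"participant": ("intercept", "rater_sex")},
            )

    def test_single_level_rejected(self):
        trials = _small_trials()
        trials = trials[trials["level_sd"] == 0.0]
        with pytest.raises(SpecificationError, match="levels"):
            fit_hierarchical(trials, ModelSpec(), SMALL_MCMC)

    def test_convergence_at_study_scale_settings(self):
        """At the study-scale sampler settings (13,000 iterations, 3,000
        burn-in, 4 chains) every parameter of the maximal model converges:
        split-Rhat < 1.01 throughout."""
        truth = make_ground_truth(-0.4, seed=0)
        trials = simulate_level_trials(
            truth, n_participants=10, n_base_faces=14, seed=1
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_hierarchical(trials, ModelSpec(), MCMCConfig(seed=2))
        assert fit.max_rhat() < 1.01

    def test_coverage_across_replicates(self):
        """Nominal CrI coverage: over 20 seeded replicates of the
        validation-scale simulation, each fixed effect's 95% CrI covers its
        generating value in at least 17."""
        truth = make_ground_truth(-0.4, seed=0, b1=0.8, b2=-0.05)
        cfg = MCMCConfig(iterations=1200, burn_in=400, chains=2, seed=7)
        spec = ModelSpec(face_sex=False, rater_sex=False)
        hits = {"b_level": 0, "b_level2": 0}
        for rep in range(20):
            trials = simulate_level_trials(
                truth, n_participants=16, n_base_faces=20, seed=rep
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_hierarchical(trials, spec, cfg)
            for term, value in (("b_level", 0.8), ("b_level2", -0.05)):
                lo, hi = fit.cri(term)
                hits[term] += lo <= value <= hi
        assert hits["b_level"] >= 17
        assert hits["b_level2"] >= 17

    def test_level_rescaling_equivariance(self):
        """Rescaling the level axis by c rescales the linear coefficient by
        1/c and leaves the model's fit quality (WAIC) essentially unchanged."""
        trials = _small_trials(seed=6)
        scaled = trials.copy()
        scaled["level_sd"] = scaled["level_sd"] * 2.0
        spec = ModelSpec(face_sex=False, rater_sex=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit_a = fit_hierarchical(trials, spec, SMALL_MCMC)
            fit_b = fit_hierarchical(scaled, spec, SMALL_MCMC)
        assert fit_b.eap("b_level") == pytest.approx(
            fit_a.eap("b_level") / 2.0, abs=0.02
        )
        assert waic(fit_b) == pytest.approx(waic(fit_a), rel=0.01)


class TestSelectBest:
    def test_ladder_sorted_and_best_is_head(self):
        trials = _small_trials(seed=2)
        candidates = [
            ModelSpec(quadratic=False, face_sex=False, rater_sex=False),
            ModelSpec(quadratic=True, face_sex=False, rater_sex=False),
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            comp = select_best(trials, candidates, SMALL_MCMC)
        assert np.all(np.isfinite(comp.ladder["waic"]))
        assert comp.ladder["waic"].is_monotonic_increasing
        assert comp.best == comp.ladder.iloc[0]["model"]
        assert set(comp.fits) == {c.name for c in candidates}

    def test_strong_quadratic_data_selects_quadratic(self):
        trials = _small_trials(b1=0.6, b2=-0.3, seed=3)
        candidates = [
            ModelSpec(quadratic=False, face_sex=False, rater_sex=False),
            ModelSpec(quadratic=True, face_sex=False, rater_sex=False),
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            comp = select_best(trials, candidates, SMALL_MCMC)
        assert "quad" in comp.best

    def test_needs_two_candidates(self):
        with pytest.raises(SpecificationError):
            select_best(_small_trials(), [ModelSpec()], SMALL_MCMC)


class TestGeneratedQuantities:
    def test_same_fit_difference_near_zero(self, small_fit):
        gq = generated_quantities(small_fit, small_fit, "b_level")
        assert gq.eap("delta_b_level") == pytest.approx(0.0, abs=1e-12)

    def test_antisymmetry(self, small_fit):
        trials = _small_trials(b1=0.2, seed=8)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            other = fit_hierarchical(
                trials, ModelSpec(face_sex=False, rater_sex=False), SMALL_MCMC
            )
        ab = generated_quantities(small_fit, other, "b_level")
        ba = generated_quantities(other, small_fit, "b_level")
        assert ab.eap("delta_b_level") == pytest.approx(
            -ba.eap("delta_b_level"), abs=1e-12
        )

    def test_recovers_known_difference(self):
        spec = ModelSpec(quadratic=False, face_sex=False, rater_sex=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit_a = fit_hierarchical(_small_trials(b1=0.6, b2=0.0, seed=11), spec, SMALL_MCMC)
            fit_b = fit_hierarchical(_small_trials(b1=0.0, b2=0.0, seed=12), spec, SMALL_MCMC)
        gq = generated_quantities(fit_a, fit_b, "b_level")
        lo, hi = gq.cri("delta_b_level")
        assert lo <= 0.6 <= hi
        assert not (lo <= 0.0 <= hi)

    def test_absent_term_rejected(self, small_fit):
        with pytest.raises(ContractError):
            generated_quantities(small_fit, small_fit, "b_nonexistent")
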