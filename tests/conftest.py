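import warnings

import pytest
from hypothesis import HealthCheck, settings

from facetrait.hier_model import MCMCConfig
from facetrait.pipeline import run_default_pipeline
from facetrait.synthetic_data import make_ground_truth, sample_faces, simulate_ratings
from facetrait.trait_model import (
    fit_trait_direction,
    orthogonalize,
    scale_to_sd_units,
    standardize_scores_by_face_sex,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")


@pytest.fixture(scope="session")
def truth():
    """Default-noise ground truth with the male-face-like direction angle."""
    return make_ground_truth(cos_angle=-0.4, seed=0)


@pytest.fixture(scope="session")
def faces400():
    return sample_faces(400, seed=1)


@pytest.fixture(scope="session")
def rating_pair(truth, faces400):
    """Model-building ratings of the same 400 faces on both tasks."""
    attr, attr_trials = simulate_ratings(faces400, truth, "attr", n_raters=20, seed=2)
    masc, masc_trials = simulate_ratings(faces400, truth, "masc", n_raters=20, seed=3)
    return {
        "attr": attr,
        "masc": masc,
        "attr_trials": attr_trials,
        "masc_trials": masc_trials,
    }


@pytest.fixture(scope="session")
def fitted_directions(faces400, rating_pair):
    """SD-scaled trait directions fitted from the session ratings."""
    out = {}
    for key in ("attr", "masc"):
        scores = standardize_scores_by_face_sex(rating_pair[key])
        out[key] = scale_to_sd_units(fit_trait_direction(faces400, scores))
    return out


@pytest.fixture(scope="session")
def orth_directions(fitted_directions):
    return {
        "attr_orth": orthogonalize(fitted_directions["attr"], fitted_directions["masc"]),
        "masc_orth": orthogonalize(fitted_directions["masc"], fitted_directions["attr"]),
    }


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One end-to-end pipeline run at desk-scale MCMC, shared across tests.

    Study-scale data (400 faces x 20 raters for model building; 20 base
    faces x 7 levels x 2 transformations x 16 raters per validation cell)
    with reduced sampler settings.
    """
    run_dir = tmp_path_factory.mktemp("pipeline_run")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = run_default_pipeline(
            run_dir,
            seed=0,
            mcmc=MCMCConfig(iterations=1500, burn_in=400, chains=2, seed=1),
        )
    return {"run_dir": run_dir, "report": report}
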