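"""Trait-direction fitting, SD scaling, orthogonalization, prediction."""

import numpy as np
import pytest

from facetrait.errors import (
    AlignmentError,
    ContractError,
    DegenerateDataError,
    DegenerateOrthogonalizationError,
    FormatError,
    UnderdeterminedFitError,
)
from facetrait.face_space import TransformSpec, transform_faces
from facetrait.synthetic_data import sample_faces
from facetrait.trait_model import (
    RatingMatrix,
    StandardizedScores,
    TraitDirection,
    fit_direction_from_arrays,
    fit_trait_direction,
    orthogonalize,
    predict_score,
    scale_to_sd_units,
    standardize_scores,
)


def _scores_for(faces, values, task="attractiveness"):
    v = np.asarray(values, float)
    z = (v - v.mean()) / v.std(ddof=1)
    return StandardizedScores(
        face_ids=faces.face_ids, scores=z, task=task, n_raters=20
    )


def _pad(*active):
    beta = np.zeros(100)
    beta[: len(active)] = active
    return beta


class TestStandardizeScores:
    def test_hand_example(self):
        ratings = RatingMatrix(
            values=np.array([[2, 2], [5, 5], [8, 8]]),
            face_ids=["a", "b", "c"],
            rater_ids=["r1", "r2"],
            face_sex=["male", "male", "male"],
            rater_sex=["male", "female"],
            task="attractiveness",
        )
        out = standardize_scores(ratings)
        np.testing.assert_allclose(out.scores, [-1.0, 0.0, 1.0], atol=1e-12)

    def test_degenerate_equal_means(self):
        ratings = RatingMatrix(
            values=np.array([[2, 4], [4, 2], [3, 3]]),
            face_ids=["a", "b", "c"],
            rater_ids=["r1", "r2"],
            face_sex=["male"] * 3,
            rater_sex=["male", "female"],
            task="attractiveness",
        )
        with pytest.raises(DegenerateDataError):
            standardize_scores(ratings)

    @pytest.mark.parametrize("seed", range(5))
    def test_output_invariant(self, seed):
        rng = np.random.default_rng(seed)
        ratings = RatingMatrix(
            values=rng.integers(1, 10, size=(12, 5)),
            face_ids=[f"f{i}" for i in range(12)],
            rater_ids=[f"r{i}" for i in range(5)],
            face_sex=["male"] * 12,
            rater_sex=["male"] * 5,
            task="sexual_dimorphism",
        )
        out = standardize_scores(ratings)
        assert abs(out.scores.mean()) < 1e-10
        assert abs(out.scores.std(ddof=1) - 1.0) < 1e-10

    def test_invariant_enforced_on_construction(self):
        with pytest.raises(FormatError):
            StandardizedScores(
                face_ids=["a", "b"],
                scores=np.array([1.0, 2.0]),
                task="attractiveness",
                n_raters=2,
            )


class TestFitTraitDirection:
    def test_toy_system_matches_hand_normal_equations(self):
        # X = [[1,0],[0,1],[1,1]], y = [1,2,4]: exactly determined with
        # intercept; solving by hand gives intercept -1, beta (2, 3).
        X = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        y = np.array([1.0, 2.0, 4.0])
        beta, intercept = fit_direction_from_arrays(X, y)
        np.testing.assert_allclose(beta, [2.0, 3.0], atol=1e-10)
        assert intercept == pytest.approx(-1.0, abs=1e-10)

    @pytest.mark.parametrize("n,p,seed", [(50, 5, 0), (30, 3, 1), (12, 5, 2)])
    def test_agrees_with_normal_equation_oracle(self, n, p, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, p))
        y = rng.standard_normal(n)
        beta, intercept = fit_direction_from_arrays(X, y)
        A = np.column_stack([np.ones(n), X])
        oracle = np.linalg.solve(A.T @ A, A.T @ y)
        np.testing.assert_allclose(
            np.concatenate([[intercept], beta]), oracle, atol=1e-8
        )

    def test_noise_free_recovery(self, faces400, truth):
        s = faces400.coord_matrix() @ truth.beta_attr
        scores = _scores_for(faces400, s)
        d = fit_trait_direction(faces400, scores)
        sd = s.std(ddof=1)
        np.testing.assert_allclose(d.beta, truth.beta_attr / sd, atol=1e-8)
        assert d.intercept == pytest.approx(-s.mean() / sd, abs=1e-8)

    def test_pure_noise_coefficients_small(self, faces400):
        rng = np.random.default_rng(77)
        scores = _scores_for(faces400, rng.standard_normal(400))
        d = fit_trait_direction(faces400, scores)
        assert np.max(np.abs(d.beta)) < 5.0 / np.sqrt(400)

    def test_r_squared_consistent_with_oracle(self, faces400, truth):
        rng = np.random.default_rng(5)
        s = faces400.coord_matrix() @ truth.beta_attr + 0.5 * rng.standard_normal(400)
        scores = _scores_for(faces400, s)
        d = fit_trait_direction(faces400, scores)
        pred = d.intercept + faces400.coord_matrix() @ d.beta
        y = scores.scores
        ss_res = np.sum((y - pred) ** 2)
        r2_fit = 1.0 - ss_res / np.sum((y - y.mean()) ** 2)
        r2_corr = np.corrcoef(pred, y)[0, 1] ** 2
        assert r2_fit == pytest.approx(r2_corr, abs=1e-10)

    def test_underdetermined_rejected(self):
        faces = sample_faces(50, seed=0)
        scores = _scores_for(faces, np.arange(50.0))
        with pytest.raises(UnderdeterminedFitError):
            fit_trait_direction(faces, scores)

    def test_id_mismatch_rejected(self, faces400):
        scores = _scores_for(faces400, np.arange(400.0))
        scores.face_ids[0] = "not_a_face"
        with pytest.raises(AlignmentError):
            fit_trait_direction(faces400, scores)


class TestScaleToSdUnits:
    def test_closed_form(self):
        d = scale_to_sd_units(TraitDirection(name="t", beta=_pad(2.0)))
        expected = np.zeros(100)
        expected[0] = 0.5
        np.testing.assert_allclose(d.unit_step, expected)

    def test_unit_step_gains_one_score_unit(self):
        rng = np.random.default_rng(3)
        d = scale_to_sd_units(
            TraitDirection(name="t", beta=rng.standard_normal(100), intercept=0.3)
        )
        x = rng.standard_normal(100)
        gain = predict_score(d, x + d.unit_step) - predict_score(d, x)
        assert gain == pytest.approx(1.0, abs=1e-10)

    def test_transform_three_levels_gains_three(self, fitted_directions):
        d = fitted_directions["attr"]
        faces = sample_faces(10, seed=8)
        moved = transform_faces(faces, d, TransformSpec("attr", (3.0,)))
        for before, after in zip(faces, moved):
            gain = predict_score(d, after) - predict_score(d, before)
            assert gain == pytest.approx(3.0, abs=1e-8)

    def test_zero_direction_rejected(self):
        with pytest.raises((DegenerateDataError, FormatError)):
            scale_to_sd_units(TraitDirection(name="t", beta=np.zeros(100)))


class TestOrthogonalize:
    def test_hand_gram_schmidt(self):
        target = TraitDirection(name="t", beta=_pad(1.0, 1.0))
        nuisance = TraitDirection(name="n", beta=_pad(0.0, 1.0))
        out = orthogonalize(target, nuisance)
        direction = out.beta / np.linalg.norm(out.beta)
        np.testing.assert_allclose(direction, _pad(1.0), atol=1e-12)

    def test_already_orthogonal_unchanged(self):
        target = TraitDirection(name="t", beta=_pad(2.0))
        nuisance = TraitDirection(name="n", beta=_pad(0.0, 3.0))
        out = orthogonalize(target, nuisance)
        np.testing.assert_allclose(out.beta, target.beta, atol=1e-12)

    def test_self_orthogonalization_degenerate(self):
        d = TraitDirection(name="t", beta=_pad(1.0, 2.0))
        with pytest.raises(DegenerateOrthogonalizationError):
            orthogonalize(d, d)

    def test_idempotent(self, fitted_directions):
        once = orthogonalize(fitted_directions["attr"], fitted_directions["masc"])
        twice = orthogonalize(once, fitted_directions["masc"])
        rel = np.linalg.norm(twice.beta - once.beta) / np.linalg.norm(once.beta)
        assert rel < 1e-10

    def test_records_nuisance_name(self, orth_directions):
        assert orth_directions["attr_orth"].orthogonalized_against == "sexual_dimorphism"

    def test_dissociation_identity(self, fitted_directions, orth_directions):
        """Moving along the orthogonalized target leaves the nuisance
        model's predicted score unchanged, while the target score moves by
        exactly the level."""
        rng = np.random.default_rng(42)
        X = rng.standard_normal((1000, 100))
        ao = orth_directions["attr_orth"]
        masc = fitted_directions["masc"]
        for k in (-3.0, -1.0, 2.0, 3.0):
            moved = X + k * ao.unit_step
            nuis_shift = (moved - X) @ masc.beta
            assert np.max(np.abs(nuis_shift)) < 1e-10
            target_shift = (moved - X) @ ao.beta
            np.testing.assert_allclose(target_shift, k, atol=1e-8)


class TestPredictScore:
    def test_origin_returns_intercept(self):
        d = TraitDirection(name="t", beta=_pad(1.0), intercept=0.7)
        assert predict_score(d, np.zeros(100)) == pytest.approx(0.7)

    def test_linearity_at_zero_intercept(self):
        rng = np.random.default_rng(11)
        d = TraitDirection(name="t", beta=rng.standard_normal(100), intercept=0.0)
        x, y = rng.standard_normal(100), rng.standard_normal(100)
        assert predict_score(d, x + y) == pytest.approx(
            predict_score(d, x) + predict_score(d, y), abs=1e-10
        )

    def test_dimension_mismatch_rejected(self):
        d = TraitDirection(name="t", beta=np.ones(2))
        with pytest.raises(ContractError):
            predict_score(d, np.zeros(100))


def test_direction_json_round_trip(tmp_path, orth_directions):
    d = orth_directions["attr_orth"]
    path = tmp_path / "dir.json"
    d.save(path)
    back = TraitDirection.load(path)
    assert back.name == d.name
    assert back.scaled and back.orthogonalized_against == d.orthogonalized_against
    np.testing.assert_array_equal(back.beta, d.beta)
    np.testing.assert_array_equal(back.unit_step, d.unit_step)
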