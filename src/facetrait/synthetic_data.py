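"""Synthetic faces and Likert ratings with known ground truth.

The generator emulates the statistical structure of the two rating
experiments: an i.i.d. standard-normal face population in 100 dimensions,
two unit-norm ground-truth trait directions (attractiveness and
masculinity) at a controllable angle, and raters who map a latent trait
percept to a 1-9 Likert response through

    latent = b0 + (b1 + u1_p) * s + b2 * s^2 + u0_p + w_f + eps,

where ``s`` is the face's true trait score, ``u0_p``/``u1_p`` are rater
random intercept/slope, ``w_f`` a face-specific offset and ``eps``
residual noise; the latent value is affinely mapped, rounded and clipped
to the 1-9 scale.  With the default calibration (b0 = 5, b1 = 1, identity
affine map) a -3..+3 SD latent range covers ratings of roughly 2-8.

Every output is a deterministic function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateDataError
from .face_space import (
    N_DIMS,
    FaceSet,
    FaceVector,
    TransformSpec,
    transform_faces,
)
from .trait_model import RATING_COLUMNS, RatingMatrix, TraitDirection

TASK_OF = {"attr": "attractiveness", "masc": "sexual_dimorphism"}


@dataclass(frozen=True)
class GroundTruth:
    """True trait directions and rater/noise parameters of the generator."""

    beta_attr: np.ndarray  # unit norm
    beta_masc: np.ndarray  # unit norm
    cos_angle: float
    b0: float = 5.0  # latent intercept (Likert midpoint)
    b1: float = 1.0  # latent linear gain per trait SD
    b2: float = -0.05  # latent quadratic curvature
    sd_rater_intercept: float = 1.0
    sd_rater_slope: float = 0.2  # rater sensitivity to the trait score
    #: rater sensitivity to the exaggeration axis itself (validation designs)
    sd_rater_level_slope: float = 0.25
    sd_face: float = 0.3
    sd_resid: float = 0.7
    likert_scale: float = 1.0
    likert_shift: float = 0.0

    def __post_init__(self):
        for name in ("beta_attr", "beta_masc"):
            v = np.asarray(getattr(self, name), float)
            if abs(np.linalg.norm(v) - 1.0) > 1e-10:
                raise DegenerateDataError(f"{name} must have unit norm")
            v.flags.writeable = False
            object.__setattr__(self, name, v)
        achieved = float(self.beta_attr @ self.beta_masc)
        if abs(achieved - self.cos_angle) > 1e-8:
            raise DegenerateDataError(
                f"direction cosine {achieved} != declared cos_angle {self.cos_angle}"
            )

    def beta_true(self, direction: str) -> np.ndarray:
        if direction in ("attr", "attractiveness"):
            return self.beta_attr
        if direction in ("masc", "sexual_dimorphism"):
            return self.beta_masc
        raise ValueError(f"unknown direction {direction!r}")

    def to_dict(self) -> dict:
        return {
            "cos_angle": self.cos_angle,
            "b0": self.b0,
            "b1": self.b1,
            "b2": self.b2,
            "sd_rater_intercept": self.sd_rater_intercept,
            "sd_rater_slope": self.sd_rater_slope,
            "sd_rater_level_slope": self.sd_rater_level_slope,
            "sd_face": self.sd_face,
            "sd_resid": self.sd_resid,
            "likert_scale": self.likert_scale,
            "likert_shift": self.likert_shift,
            "beta_attr": self.beta_attr.tolist(),
            "beta_masc": self.beta_masc.tolist(),
        }


_SCENARIOS = {
    # study-condition defaults per scenario
    "exp1_model_building": dict(n_faces=400, n_raters=20),
    "exp1_validation": dict(n_faces=20, n_raters=16),
    "exp2_attr_orth": dict(n_faces=20, n_raters=16),
    "exp2_sexdim_orth": dict(n_faces=20, n_raters=16),
}


@dataclass(frozen=True)
class SimConfig:
    """Scenario sizes for a synthetic run."""

    scenario: str = "exp1_model_building"
    n_faces: int = 400
    n_raters: int = 20
    levels: tuple[float, ...] = (-3.0, -2.0, -1.0, 0.0, 1.0, 2.0, 3.0)
    seed: int = 0

    def __post_init__(self):
        if self.scenario not in _SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.n_faces < 1 or self.n_raters < 1:
            raise ValueError("n_faces and n_raters must be positive")

    @classmethod
    def for_scenario(cls, scenario: str, seed: int = 0, **overrides) -> "SimConfig":
        params = dict(_SCENARIOS[scenario])
        params.update(overrides)
        return cls(scenario=scenario, seed=seed, **params)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def sample_faces(n: int, seed: int, id_prefix: str = "face") -> FaceSet:
    """n faces with i.i.d. standard-normal coordinates, alternating sexes."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    coords = rng.standard_normal((n, N_DIMS))
    faces = [
        FaceVector(
            face_id=f"{id_prefix}_{i + 1:04d}",
            face_sex="male" if i % 2 == 0 else "female",
            coords=coords[i],
        )
        for i in range(n)
    ]
    return FaceSet(faces=faces, provenance={"generator": "sample_faces", "seed": seed})


def make_ground_truth(
    cos_angle: float = -0.4, seed: int = 0, **overrides
) -> GroundTruth:
    """Two unit directions with inner product ``cos_angle``.

    The first direction is a uniformly random unit vector; the second is
    rotated from it within a random 2-plane by arccos(cos_angle).
    """
    if not abs(cos_angle) < 1.0:
        raise ValueError("cos_angle must lie strictly inside (-1, 1)")
    rng = np.random.default_rng(seed)
    v1 = rng.standard_normal(N_DIMS)
    v1 /= np.linalg.norm(v1)
    w = rng.standard_normal(N_DIMS)
    w -= (w @ v1) * v1
    w /= np.linalg.norm(w)
    v2 = cos_angle * v1 + np.sqrt(1.0 - cos_angle**2) * w
    v2 /= np.linalg.norm(v2)
    return GroundTruth(
        beta_attr=v1, beta_masc=v2, cos_angle=cos_angle, **overrides
    )


def _latent_to_rating(latent: np.ndarray, truth: GroundTruth) -> np.ndarray:
    scaled = truth.likert_scale * latent + truth.likert_shift
    return np.clip(np.rint(scaled), 1, 9).astype(int)


def _draw_rating_grid(
    s: np.ndarray,
    base_codes: np.ndarray,
    truth: GroundTruth,
    n_raters: int,
    rng: np.random.Generator,
    levels: np.ndarray | None = None,
) -> np.ndarray:
    """(n_stimuli, n_raters) integer ratings for true trait scores ``s``.

    ``base_codes`` maps stimuli to source faces so exaggerated versions of
    one face share its random offset ``w_f``.  When the stimuli arise from
    a face transformation, ``levels`` carries the exaggeration level of
    each stimulus and raters additionally differ in their responsiveness
    to the transformation axis itself (``sd_rater_level_slope``) — the
    idiosyncratic exaggeration sensitivity that validation ratings show
    over and above trait sensitivity.
    """
    n_base = int(base_codes.max()) + 1
    u0 = rng.normal(0.0, truth.sd_rater_intercept, n_raters)
    u1 = rng.normal(0.0, truth.sd_rater_slope, n_raters)
    w = rng.normal(0.0, truth.sd_face, n_base)
    eps = rng.normal(0.0, truth.sd_resid, (s.size, n_raters))
    latent = (
        truth.b0
        + np.outer(s, truth.b1 + u1)
        + (truth.b2 * s**2)[:, None]
        + u0[None, :]
        + w[base_codes, None]
        + eps
    )
    if levels is not None:
        v1 = rng.normal(0.0, truth.sd_rater_level_slope, n_raters)
        latent += np.outer(np.asarray(levels, float), v1)
    return _latent_to_rating(latent, truth)


def _rater_ids(n_raters: int, prefix: str) -> tuple[list[str], list[str]]:
    ids = [f"{prefix}_p{i + 1:02d}" for i in range(n_raters)]
    sexes = ["male" if i % 2 == 0 else "female" for i in range(n_raters)]
    return ids, sexes


def _long_format(
    grid: np.ndarray,
    face_ids: list[str],
    face_sexes: list[str],
    levels: np.ndarray,
    rater_ids: list[str],
    rater_sexes: list[str],
    task: str,
) -> pd.DataFrame:
    n_f, n_r = grid.shape
    return pd.DataFrame(
        {
            "participant_id": np.repeat(rater_ids, n_f),
            "rater_sex": np.repeat(rater_sexes, n_f),
            "face_id": np.tile(face_ids, n_r),
            "face_sex": np.tile(face_sexes, n_r),
            "task": task,
            "level_sd": np.tile(levels, n_r),
            "rating": grid.T.reshape(-1),
        }
    )[list(RATING_COLUMNS)]


def simulate_ratings(
    faces: FaceSet,
    truth: GroundTruth,
    direction: str,
    n_raters: int,
    seed: int,
) -> tuple[RatingMatrix, pd.DataFrame]:
    """Ratings of un-exaggerated faces on one task (model-building design).

    The true percept of each face is ``beta_true . coords``; every rater
    rates every face once.  Returns the wide grid and the long trial table.
    """
    task = TASK_OF.get(direction, direction)
    beta = truth.beta_true(direction)
    rng = np.random.default_rng(seed)
    s = faces.coord_matrix() @ beta
    grid = _draw_rating_grid(s, np.arange(len(faces)), truth, n_raters, rng)
    rater_ids, rater_sexes = _rater_ids(n_raters, direction)
    matrix = RatingMatrix(
        values=grid,
        face_ids=faces.face_ids,
        rater_ids=rater_ids,
        face_sex=faces.face_sexes,
        rater_sex=rater_sexes,
        task=task,
    )
    trials = _long_format(
        grid,
        faces.face_ids,
        faces.face_sexes,
        np.zeros(len(faces)),
        rater_ids,
        rater_sexes,
        task,
    )
    return matrix, trials


def simulate_level_trials(
    truth: GroundTruth,
    n_participants: int,
    n_base_faces: int,
    levels: tuple[float, ...] = (-3, -2, -1, 0, 1, 2, 3),
    seed: int = 0,
    task: str = "sexual_dimorphism",
) -> pd.DataFrame:
    """Idealized validation design: the true percept equals the level.

    Stimuli are ``n_base_faces`` x ``levels`` with trait score exactly the
    exaggeration level, so the latent fixed effects are (b0, b1, b2) by
    construction.  Used for parameter-recovery checks.
    """
    rng = np.random.default_rng(seed)
    lv = np.asarray(levels, float)
    n_stim = n_base_faces * lv.size
    s = np.tile(lv, n_base_faces)
    base_codes = np.repeat(np.arange(n_base_faces), lv.size)
    grid = _draw_rating_grid(s, base_codes, truth, n_participants, rng)
    face_ids = [
        f"vbase_{b + 1:03d}:level:{v:+.1f}"
        for b in range(n_base_faces)
        for v in lv
    ]
    face_sexes = [
        "male" if b % 2 == 0 else "female"
        for b in range(n_base_faces)
        for _ in lv
    ]
    rater_ids, rater_sexes = _rater_ids(n_participants, "val")
    return _long_format(grid, face_ids, face_sexes, s, rater_ids, rater_sexes, task)


def simulate_experiment2(
    truth: GroundTruth,
    attr_direction: TraitDirection,
    masc_direction: TraitDirection,
    config: SimConfig,
) -> tuple[pd.DataFrame, FaceSet]:
    """Full validation experiment on orthogonalized fitted directions.

    20 novel base faces are exaggerated along the (orthogonalized, scaled)
    fitted attractiveness and sexual-dimorphism directions at the seven
    levels, giving 280 stimuli; four independent groups of raters each rate
    one task x transformation cell.  True percepts are computed from the
    *ground-truth* directions, so estimation error in the fitted
    directions propagates into the simulated ratings.
    """
    for d in (attr_direction, masc_direction):
        if not d.scaled:
            raise DegenerateDataError(f"direction {d.name!r} must be scaled")
    seqs = np.random.SeedSequence(config.seed).spawn(5)
    base = sample_faces(config.n_faces, seed=int(seqs[0].generate_state(1)[0] % 2**31),
                        id_prefix="novel")
    transforms = {
        "attr_orth": transform_faces(
            base, attr_direction, TransformSpec("attr_orth", config.levels)
        ),
        "masc_orth": transform_faces(
            base, masc_direction, TransformSpec("masc_orth", config.levels)
        ),
    }
    all_stimuli = FaceSet(
        faces=[f for fs in transforms.values() for f in fs],
        provenance={"scenario": "exp2", "seed": config.seed},
    )

    frames = []
    cells = [
        ("attractiveness", "attr_orth"),
        ("attractiveness", "masc_orth"),
        ("sexual_dimorphism", "attr_orth"),
        ("sexual_dimorphism", "masc_orth"),
    ]
    for (task, transform), seq in zip(cells, seqs[1:]):
        stimuli = transforms[transform]
        coords = stimuli.coord_matrix()
        s = coords @ truth.beta_true(task)
        n_levels = len(config.levels)
        base_codes = np.repeat(np.arange(config.n_faces), n_levels)
        rng = np.random.default_rng(seq)
        levels = np.tile(np.asarray(config.levels, float), config.n_faces)
        grid = _draw_rating_grid(
            s, base_codes, truth, config.n_raters, rng, levels=levels
        )
        rater_ids, rater_sexes = _rater_ids(
            config.n_raters, f"{task[:4]}_{transform}"
        )
        cell = _long_format(
            grid,
            stimuli.face_ids,
            stimuli.face_sexes,
            levels,
            rater_ids,
            rater_sexes,
            task,
        )
        cell["transform"] = transform
        frames.append(cell)
    trials = pd.concat(frames, ignore_index=True)
    return trials, all_stimuli


def recovery_report(
    truth: GroundTruth,
    fitted: TraitDirection,
    direction: str | None = None,
) -> dict[str, float]:
    """How well a fitted direction recovers its generating direction.

    Returns the cosine similarity between the true and fitted coefficient
    vectors and the scale error ``|beta_true . unit_step - 1|`` (the true
    trait-score change produced by one nominal SD-unit step, against its
    ideal of 1).
    """
    beta_true = truth.beta_true(direction if direction is not None else fitted.name)
    b = fitted.beta
    nb = np.linalg.norm(b)
    if nb < 1e-15:
        raise DegenerateDataError("fitted direction has zero coefficients")
    cosine = float(beta_true @ b / nb)
    step = fitted.unit_step if fitted.unit_step is not None else b / float(b @ b)
    scale_error = float(abs(beta_true @ step - 1.0))
    return {"cosine": cosine, "scale_error": scale_error}
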