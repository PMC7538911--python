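"""Trait directions fitted from Likert ratings.

A perceived trait (attractiveness, masculinity/femininity) is modelled as a
direction in face space: the ordinary-least-squares fit of standardized
mean rating scores onto the 100 face coordinates,

    score(x) ~= intercept + beta . x .

A fitted direction is rescaled so that one "unit step" displaces the
predicted standardized score by exactly +1 (the study's SD unit of
exaggeration), and can be orthogonalized against a nuisance direction so
that movement along the result leaves the nuisance model's predicted score
unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    ContractError,
    DegenerateDataError,
    DegenerateOrthogonalizationError,
    FormatError,
    UnderdeterminedFitError,
)
from .face_space import FaceSet, FaceVector

TASKS = ("attractiveness", "sexual_dimorphism")
RATING_MIN, RATING_MAX = 1, 9

#: column order of the long-format ratings file
RATING_COLUMNS = (
    "participant_id",
    "rater_sex",
    "face_id",
    "face_sex",
    "task",
    "level_sd",
    "rating",
)


@dataclass
class RatingMatrix:
    """Complete faces x raters grid of integer ratings on the 1-9 scale."""

    values: np.ndarray  # (n_faces, n_raters) integers in [1, 9]
    face_ids: list[str]
    rater_ids: list[str]
    face_sex: list[str]  # per face
    rater_sex: list[str]  # per rater
    task: str

    def __post_init__(self):
        v = np.asarray(self.values)
        if not np.issubdtype(v.dtype, np.integer):
            if not np.allclose(v, np.round(v)):
                raise FormatError("ratings must be integers")
            v = np.round(v).astype(int)
        if v.ndim != 2 or v.shape[0] < 2 or v.shape[1] < 2:
            raise FormatError("RatingMatrix needs at least 2 faces and 2 raters")
        if v.min() < RATING_MIN or v.max() > RATING_MAX:
            raise FormatError(
                f"ratings must lie in [{RATING_MIN}, {RATING_MAX}]; "
                f"found range [{v.min()}, {v.max()}]"
            )
        if len(self.face_ids) != v.shape[0] or len(self.face_sex) != v.shape[0]:
            raise FormatError("face metadata length mismatch")
        if len(self.rater_ids) != v.shape[1] or len(self.rater_sex) != v.shape[1]:
            raise FormatError("rater metadata length mismatch")
        if self.task not in TASKS:
            raise FormatError(f"task must be one of {TASKS}, got {self.task!r}")
        self.values = v

    @property
    def n_faces(self) -> int:
        return self.values.shape[0]

    @property
    def n_raters(self) -> int:
        return self.values.shape[1]

    def face_means(self) -> np.ndarray:
        return self.values.mean(axis=1)

    def subset_faces(self, keep: Sequence[bool]) -> "RatingMatrix":
        keep = np.asarray(keep, bool)
        return RatingMatrix(
            values=self.values[keep],
            face_ids=[i for i, k in zip(self.face_ids, keep) if k],
            rater_ids=list(self.rater_ids),
            face_sex=[s for s, k in zip(self.face_sex, keep) if k],
            rater_sex=list(self.rater_sex),
            task=self.task,
        )


@dataclass
class StandardizedScores:
    """Per-face mean ratings, z-scored across faces (mean 0, sample SD 1)."""

    face_ids: list[str]
    scores: np.ndarray
    task: str
    n_raters: int
    #: standardization blocks; z-scoring holds within each block
    blocks: np.ndarray | None = None

    def __post_init__(self):
        s = np.asarray(self.scores, float)
        if len(self.face_ids) != s.size:
            raise FormatError("face_ids / scores length mismatch")
        blocks = (
            np.zeros(s.size, dtype=int)
            if self.blocks is None
            else np.asarray(self.blocks)
        )
        for b in np.unique(blocks):
            sub = s[blocks == b]
            if abs(sub.mean()) > 1e-10 or abs(sub.std(ddof=1) - 1.0) > 1e-10:
                raise FormatError(
                    "standardized scores must have mean 0 and sample SD 1 "
                    "within each standardization block"
                )
        self.scores = s
        self.blocks = blocks

    @classmethod
    def concat(cls, parts: Sequence["StandardizedScores"]) -> "StandardizedScores":
        """Concatenate per-block scores (e.g. per-face-sex standardizations)."""
        if len({p.task for p in parts}) != 1:
            raise FormatError("cannot concatenate scores from different tasks")
        ids: list[str] = []
        scores: list[np.ndarray] = []
        blocks: list[np.ndarray] = []
        for b, p in enumerate(parts):
            ids.extend(p.face_ids)
            scores.append(p.scores)
            blocks.append(np.full(p.scores.size, b, dtype=int))
        return cls(
            face_ids=ids,
            scores=np.concatenate(scores),
            task=parts[0].task,
            n_raters=parts[0].n_raters,
            blocks=np.concatenate(blocks),
        )


@dataclass(frozen=True)
class TraitDirection:
    """A fitted perceptual dimension: linear weights over face coordinates."""

    name: str
    beta: np.ndarray
    intercept: float = 0.0
    unit_step: np.ndarray | None = None
    scaled: bool = False
    fitted_on: dict = field(default_factory=dict)
    orthogonalized_against: str | None = None

    def __post_init__(self):
        beta = np.asarray(self.beta, dtype=float)
        if beta.ndim != 1 or beta.size == 0:
            raise FormatError("beta must be a non-empty 1-d vector")
        if not np.all(np.isfinite(beta)):
            raise FormatError("beta must be finite")
        beta.flags.writeable = False
        object.__setattr__(self, "beta", beta)
        if self.unit_step is not None:
            step = np.asarray(self.unit_step, dtype=float)
            if step.shape != beta.shape:
                raise FormatError("unit_step must match beta in length")
            step.flags.writeable = False
            object.__setattr__(self, "unit_step", step)
        if self.scaled:
            gain = float(self.beta @ self.unit_step)
            if abs(gain - 1.0) > 1e-8:
                raise FormatError(
                    f"scaled direction must gain +1 predicted score per unit "
                    f"step; got {gain!r}"
                )

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "beta": self.beta.tolist(),
            "intercept": self.intercept,
            "unit_step": None if self.unit_step is None else self.unit_step.tolist(),
            "scaled": self.scaled,
            "fitted_on": self.fitted_on,
            "orthogonalized_against": self.orthogonalized_against,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "TraitDirection":
        return cls(
            name=d["name"],
            beta=np.asarray(d["beta"], float),
            intercept=float(d["intercept"]),
            unit_step=None if d.get("unit_step") is None else np.asarray(d["unit_step"], float),
            scaled=bool(d.get("scaled", False)),
            fitted_on=d.get("fitted_on", {}),
            orthogonalized_against=d.get("orthogonalized_against"),
        )

    @classmethod
    def load(cls, path: str | Path) -> "TraitDirection":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# long-format ratings file I/O
# ---------------------------------------------------------------------------

def read_ratings(path: str | Path) -> pd.DataFrame:
    """Read the long-format ratings file (one row per rating event)."""
    df = pd.read_csv(
        path,
        dtype={
            "participant_id": str,
            "rater_sex": str,
            "face_id": str,
            "face_sex": str,
            "task": str,
        },
    )
    if list(df.columns) != list(RATING_COLUMNS):
        raise FormatError(
            f"{path}: expected columns {list(RATING_COLUMNS)}, got {list(df.columns)}"
        )
    return df


def write_ratings(trials: pd.DataFrame, path: str | Path) -> None:
    trials[list(RATING_COLUMNS)].to_csv(Path(path), index=False, float_format="%.17g")


def ratings_to_matrix(trials: pd.DataFrame, task: str | None = None) -> RatingMatrix:
    """Pivot long-format trials (one level per face) to a faces x raters grid."""
    df = trials if task is None else trials[trials["task"] == task]
    tasks = df["task"].unique()
    if len(tasks) != 1:
        raise FormatError(f"expected a single task, found {sorted(tasks)}")
    wide = df.pivot(index="face_id", columns="participant_id", values="rating")
    if wide.isna().any().any():
        raise FormatError("incomplete design: some face x rater cells are empty")
    face_meta = df.drop_duplicates("face_id").set_index("face_id")["face_sex"]
    rater_meta = df.drop_duplicates("participant_id").set_index("participant_id")[
        "rater_sex"
    ]
    return RatingMatrix(
        values=wide.to_numpy(),
        face_ids=list(wide.index),
        rater_ids=list(wide.columns),
        face_sex=[face_meta[i] for i in wide.index],
        rater_sex=[rater_meta[i] for i in wide.columns],
        task=str(tasks[0]),
    )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def standardize_scores(ratings: RatingMatrix) -> StandardizedScores:
    """Mean rating per face over raters, then z-scored across faces.

    Uses the sample SD (n-1 denominator).  All faces sharing a mean raise
    :class:`DegenerateDataError` since z-scores would be undefined.
    """
    means = ratings.face_means()
    sd = means.std(ddof=1)
    if sd < 1e-12:
        raise DegenerateDataError(
            "all faces have the same mean rating; cannot standardize"
        )
    return StandardizedScores(
        face_ids=list(ratings.face_ids),
        scores=(means - means.mean()) / sd,
        task=ratings.task,
        n_raters=ratings.n_raters,
    )


def standardize_scores_by_face_sex(ratings: RatingMatrix) -> StandardizedScores:
    """Standardize separately within male and within female faces, then pool."""
    sexes = np.asarray(ratings.face_sex)
    parts = [
        standardize_scores(ratings.subset_faces(sexes == s))
        for s in sorted(set(ratings.face_sex))
    ]
    return StandardizedScores.concat(parts)


def fit_direction_from_arrays(
    coords: np.ndarray, scores: np.ndarray
) -> tuple[np.ndarray, float]:
    """OLS of scores on coordinates with intercept; returns (beta, intercept).

    Kept separate from :func:`fit_trait_direction` so small hand-checkable
    systems (any dimensionality) go through the same solver.
    """
    X = np.asarray(coords, float)
    y = np.asarray(scores, float)
    n, p = X.shape
    if n <= p:
        raise UnderdeterminedFitError(
            f"need more faces than dimensions: n={n} faces, p={p} dimensions"
        )
    design = np.column_stack([np.ones(n), X])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return coef[1:], float(coef[0])


def fit_trait_direction(
    faces: FaceSet,
    scores: StandardizedScores,
    sex_policy: str = "pooled",
) -> TraitDirection:
    """Best linear fit of standardized rating scores onto face coordinates.

    ``sex_policy='pooled'`` fits one direction to all faces jointly (scores
    are expected to have been standardized within face sex, see
    :func:`standardize_scores_by_face_sex`); ``'per_face_sex'`` is applied
    upstream by fitting on a single-sex subset.
    """
    if sex_policy not in ("pooled", "per_face_sex"):
        raise ContractError(f"unknown sex_policy {sex_policy!r}")
    if sex_policy == "per_face_sex" and len(set(faces.face_sexes)) > 1:
        raise ContractError(
            "per_face_sex policy fits one sex at a time; pass a single-sex FaceSet"
        )
    if faces.face_ids != scores.face_ids:
        if set(faces.face_ids) != set(scores.face_ids):
            raise AlignmentError("face ids of coordinates and scores do not match")
        order = {fid: k for k, fid in enumerate(scores.face_ids)}
        y = scores.scores[[order[fid] for fid in faces.face_ids]]
    else:
        y = scores.scores
    beta, intercept = fit_direction_from_arrays(faces.coord_matrix(), y)
    if np.allclose(beta, 0.0):
        raise DegenerateDataError("fitted coefficients are all zero")
    return TraitDirection(
        name=scores.task,
        beta=beta,
        intercept=intercept,
        fitted_on={
            "n_faces": len(faces),
            "task": scores.task,
            "sex_policy": sex_policy,
            "n_raters": scores.n_raters,
        },
    )


def scale_to_sd_units(direction: TraitDirection) -> TraitDirection:
    """Attach the SD-unit displacement: ``unit_step = beta / (beta . beta)``.

    Moving a face by one unit step then raises the predicted standardized
    score by exactly +1, which is what "+1 SD of exaggeration" means here.
    """
    denom = float(direction.beta @ direction.beta)
    if denom < 1e-24:
        raise DegenerateDataError("cannot scale an all-zero direction")
    return replace(
        direction, unit_step=direction.beta / denom, scaled=True
    )


def orthogonalize(target: TraitDirection, nuisance: TraitDirection) -> TraitDirection:
    """Remove from ``target`` its projection onto ``nuisance`` (Gram-Schmidt).

    The returned direction is re-scaled to SD units, so a one-level move
    still changes the target's predicted score by +1 while leaving the
    nuisance direction's predicted score exactly unchanged.
    """
    bt, bn = target.beta, nuisance.beta
    if bt.shape != bn.shape:
        raise ContractError("directions live in different dimensionalities")
    b_perp = bt - (bt @ bn) / (bn @ bn) * bn
    if np.linalg.norm(b_perp) < 1e-12 * np.linalg.norm(bt):
        raise DegenerateOrthogonalizationError(
            f"direction {target.name!r} is parallel to {nuisance.name!r}"
        )
    out = TraitDirection(
        name=target.name,
        beta=b_perp,
        intercept=target.intercept,
        fitted_on=dict(target.fitted_on),
        orthogonalized_against=nuisance.name,
    )
    return scale_to_sd_units(out)


def predict_score(direction: TraitDirection, face: FaceVector | np.ndarray) -> float:
    """Predicted standardized trait score: ``intercept + beta . coords``."""
    x = face.coords if isinstance(face, FaceVector) else np.asarray(face, float)
    if x.shape != direction.beta.shape:
        raise ContractError(
            f"face has {x.size} coordinates, direction {direction.beta.size}"
        )
    return float(direction.intercept + direction.beta @ x)
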