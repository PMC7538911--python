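"""Faces as points in a 100-dimensional feature space.

A face is represented by 100 coordinates — 50 shape dimensions followed by
50 reflectance dimensions — in a space where the population-average face is
the origin and each axis is measured in population-SD units.  This module
holds the containers (:class:`FaceVector`, :class:`FaceSet`), delimited-text
I/O, the level-wise exaggeration of faces along a fitted trait direction,
and the Euclidean distinctiveness measure used for averageness checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterator

import numpy as np
import pandas as pd

from .errors import ContractError, FormatError, ParseError

if TYPE_CHECKING:  # pragma: no cover
    from .trait_model import TraitDirection

N_DIMS = 100
#: column names of the faces file, in order
COORD_COLUMNS = tuple(f"dim_{i:03d}" for i in range(1, N_DIMS + 1))
FACE_SEXES = ("male", "female")


@dataclass(frozen=True)
class FaceVector:
    """One face: an identifier, a sex label, and 100 finite coordinates."""

    face_id: str
    face_sex: str
    coords: np.ndarray

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (N_DIMS,):
            raise FormatError(
                f"face {self.face_id!r}: expected {N_DIMS} coordinates, "
                f"got {coords.size}"
            )
        if not np.all(np.isfinite(coords)):
            raise FormatError(f"face {self.face_id!r}: non-finite coordinate")
        if self.face_sex not in FACE_SEXES:
            raise FormatError(
                f"face {self.face_id!r}: face_sex must be one of {FACE_SEXES}, "
                f"got {self.face_sex!r}"
            )
        coords.flags.writeable = False
        object.__setattr__(self, "coords", coords)


@dataclass
class FaceSet:
    """An ordered collection of faces with unique ids plus free-form provenance."""

    faces: list[FaceVector]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [f.face_id for f in self.faces]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate face_id(s): {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.faces)

    def __iter__(self) -> Iterator[FaceVector]:
        return iter(self.faces)

    @property
    def face_ids(self) -> list[str]:
        return [f.face_id for f in self.faces]

    @property
    def face_sexes(self) -> list[str]:
        return [f.face_sex for f in self.faces]

    def coord_matrix(self) -> np.ndarray:
        """(n_faces, 100) coordinate matrix in row order."""
        if not self.faces:
            return np.empty((0, N_DIMS))
        return np.array([f.coords for f in self.faces], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.coord_matrix(), columns=list(COORD_COLUMNS))
        df.insert(0, "face_sex", self.face_sexes)
        df.insert(0, "face_id", self.face_ids)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, provenance: dict | None = None) -> "FaceSet":
        faces = [
            FaceVector(
                face_id=str(row[0]),
                face_sex=str(row[1]),
                coords=np.asarray(row[2:], dtype=float),
            )
            for row in df[["face_id", "face_sex", *COORD_COLUMNS]].itertuples(
                index=False, name=None
            )
        ]
        return cls(faces=faces, provenance=provenance or {})


@dataclass(frozen=True)
class TransformSpec:
    """Which direction to exaggerate along and at which SD-unit levels."""

    direction_name: str
    levels: tuple[float, ...] = (-3.0, -2.0, -1.0, 0.0, 1.0, 2.0, 3.0)

    def __post_init__(self):
        levels = tuple(float(v) for v in self.levels)
        if len(levels) == 0:
            raise FormatError("TransformSpec.levels must be non-empty")
        if not all(math.isfinite(v) for v in levels):
            raise FormatError("TransformSpec.levels must all be finite")
        if list(levels) != sorted(levels):
            raise FormatError("TransformSpec.levels must be sorted ascending")
        object.__setattr__(self, "levels", levels)


def read_faces(path: str | Path) -> FaceSet:
    """Read a comma-delimited faces file into a :class:`FaceSet`.

    The file must have a header ``face_id,face_sex,dim_001,...,dim_100``;
    row order is preserved.
    """
    path = Path(path)
    df = pd.read_csv(
        path, dtype={"face_id": str, "face_sex": str}, float_precision="round_trip"
    )
    expected = ["face_id", "face_sex", *COORD_COLUMNS]
    if list(df.columns) != expected:
        n_coord = sum(c.startswith("dim_") for c in df.columns)
        raise FormatError(
            f"{path}: expected {N_DIMS} coordinate columns "
            f"(header face_id,face_sex,dim_001..dim_{N_DIMS:03d}), found {n_coord}"
        )
    coords = df[list(COORD_COLUMNS)]
    numeric = coords.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        row = df.loc[bad, "face_id"].iloc[0]
        raise ParseError(f"{path}: non-numeric coordinate in row face_id={row!r}")
    df[list(COORD_COLUMNS)] = numeric
    return FaceSet.from_frame(df, provenance={"source": str(path)})


def write_faces(faces: FaceSet, path: str | Path) -> None:
    """Write a :class:`FaceSet` to a faces file.

    Coordinates are serialized with 17 significant digits so that
    ``read_faces(write_faces(S))`` reproduces ``S`` exactly.
    """
    faces.to_frame().to_csv(Path(path), index=False, float_format="%.17g")


def transformed_face_id(source_id: str, direction_name: str, level: float) -> str:
    return f"{source_id}:{direction_name}:{level:+.1f}"


def base_face_id(face_id: str) -> str:
    """Source face id of a (possibly) transformed face id."""
    return face_id.split(":", 1)[0]


def transform_faces(
    faces: FaceSet, direction: "TraitDirection", spec: TransformSpec
) -> FaceSet:
    """Exaggerate every face along ``direction`` at each level of ``spec``.

    Each output face is ``coords + level * direction.unit_step``; one unit
    step moves the predicted trait score by +1 SD.  Output ids encode
    ``{source}:{direction_name}:{level:+.1f}``.
    """
    if not direction.scaled or direction.unit_step is None:
        raise ContractError(
            f"direction {direction.name!r} must be scaled to SD units before "
            "transforming faces (see trait_model.scale_to_sd_units)"
        )
    step = np.asarray(direction.unit_step, dtype=float)
    if step.shape != (N_DIMS,):
        raise ContractError(
            f"direction {direction.name!r} lives in {step.size} dimensions, "
            f"faces in {N_DIMS}"
        )
    out: list[FaceVector] = []
    for face in faces:
        for level in spec.levels:
            out.append(
                FaceVector(
                    face_id=transformed_face_id(
                        face.face_id, spec.direction_name, level
                    ),
                    face_sex=face.face_sex,
                    coords=face.coords + level * step,
                )
            )
    prov = dict(faces.provenance)
    prov["transformation"] = {
        "direction": spec.direction_name,
        "levels": list(spec.levels),
    }
    return FaceSet(faces=out, provenance=prov)


def averageness(
    face: FaceVector | np.ndarray, reference: FaceVector | np.ndarray | None = None
) -> float:
    """Distinctiveness of a face: Euclidean distance from the reference face.

    The default reference is the origin, i.e. the average face of the
    generator population.  Along any exaggeration ray this distance is a
    convex (U-shaped) function of the level.
    """
    x = face.coords if isinstance(face, FaceVector) else np.asarray(face, float)
    if reference is None:
        ref = np.zeros_like(x)
    else:
        ref = (
            reference.coords
            if isinstance(reference, FaceVector)
            else np.asarray(reference, float)
        )
    return float(np.linalg.norm(x - ref))
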