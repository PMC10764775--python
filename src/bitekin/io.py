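"""Reading, validating, calibrating and writing landmark trajectory tables.

File dialect
------------
A bite is a plain CSV with one row per landmarked frame and columns
``frame, time_ms, <name>_x, <name>_y`` for every landmark name, plus a
sidecar YAML file (same path with a ``.yaml`` suffix) holding per-bite
metadata: ``specimen``, ``bite``, ``algal_length_mm``, ``mm_per_pixel``,
``facing`` (left/right), ``units`` (px/mm), ``frame_step_ms`` and
``y_axis`` (up/down).

Digitization software typically uses image coordinates with the y axis
pointing down; the reader flips such tables to a y-up convention so that
"ventral" is decreasing y for an upright fish. Tables written by
:func:`write_landmark_table` are already y-up.

Missing data: a landmark row may be incomplete only at the end of the
sequence (digitization stops when the fish leaves lateral view); such a
terminal suffix is truncated with a logged warning. Interior gaps are
fatal — no interpolation is performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .errors import CalibrationError, LandmarkDataError
from .registry import DEFAULT_REGISTRY, REQUIRED_ROLES, LandmarkRegistry

log = logging.getLogger(__name__)

COORD_DECIMALS = 6  # storage precision for coordinates


@dataclass(frozen=True)
class CalibrationScale:
    """Pixel-to-millimetre scale from a ruler in the filming plane."""

    mm_per_pixel: float
    source: str = "ruler"

    def __post_init__(self) -> None:
        if not np.isfinite(self.mm_per_pixel) or self.mm_per_pixel <= 0:
            raise CalibrationError(
                f"mm_per_pixel must be positive, got {self.mm_per_pixel}"
            )


@dataclass(frozen=True)
class BiteMetadata:
    specimen: str = "unknown"
    bite_id: str = "bite"
    algal_length_mm: Optional[float] = None
    mm_per_pixel: Optional[float] = None
    facing: str = "left"
    units: str = "mm"
    frame_step_ms: float = 5.0
    y_axis: str = "up"

    def __post_init__(self) -> None:
        if self.facing not in ("left", "right"):
            raise LandmarkDataError(f"facing must be left/right, got {self.facing!r}")
        if self.units not in ("px", "mm"):
            raise LandmarkDataError(f"units must be px/mm, got {self.units!r}")
        if self.frame_step_ms <= 0:
            raise LandmarkDataError("frame_step_ms must be positive")


@dataclass
class LandmarkTrajectorySet:
    """Calibrated (or pixel-unit) 2D positions of named landmarks over time.

    ``data`` has columns ``frame, time_ms, <name>_x, <name>_y``. Time is
    strictly increasing with a constant step, coordinates are finite, and
    frames are unique.
    """

    data: pd.DataFrame
    meta: BiteMetadata = field(default_factory=BiteMetadata)
    registry: LandmarkRegistry = field(default_factory=lambda: DEFAULT_REGISTRY)

    def __post_init__(self) -> None:
        self.validate()

    # -- accessors ---------------------------------------------------------
    @property
    def n_frames(self) -> int:
        return len(self.data)

    @property
    def time_ms(self) -> np.ndarray:
        return self.data["time_ms"].to_numpy(float)

    @property
    def landmark_names(self) -> tuple:
        names = []
        for c in self.data.columns:
            if c.endswith("_x"):
                names.append(c[:-2])
        return tuple(names)

    def xy(self, name: str) -> np.ndarray:
        """(n_frames, 2) array of a landmark's coordinates."""
        try:
            return self.data[[f"{name}_x", f"{name}_y"]].to_numpy(float)
        except KeyError as exc:
            raise LandmarkDataError(f"landmark {name!r} not in table") from exc

    def track(self, role: str) -> np.ndarray:
        """(n_frames, 2) coordinates for an anatomical role."""
        return self.xy(self.registry.name(role))

    def has_role(self, role: str) -> bool:
        return (
            self.registry.has(role)
            and f"{self.registry.name(role)}_x" in self.data.columns
        )

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        df = self.data
        if len(df) == 0:
            raise LandmarkDataError("landmark table has no frames")
        for col in ("frame", "time_ms"):
            if col not in df.columns:
                raise LandmarkDataError(f"missing column {col!r}")
        for role in REQUIRED_ROLES:
            name = self.registry.name(role)
            if f"{name}_x" not in df.columns or f"{name}_y" not in df.columns:
                raise LandmarkDataError(
                    f"missing landmark columns for role {role!r} (name {name!r})"
                )
        if df["frame"].duplicated().any():
            raise LandmarkDataError("duplicate frame indices")
        t = df["time_ms"].to_numpy(float)
        if len(t) > 1:
            steps = np.diff(t)
            if np.any(steps <= 0):
                raise LandmarkDataError("time must be strictly increasing")
            if not np.allclose(steps, steps[0], rtol=0, atol=1e-6):
                raise LandmarkDataError("non-uniform time step")
        coord_cols = [c for c in df.columns if c.endswith(("_x", "_y"))]
        vals = df[coord_cols].to_numpy(float)
        if not np.all(np.isfinite(vals)):
            raise LandmarkDataError("non-finite coordinates after validation")

    def copy_with(self, **kw) -> "LandmarkTrajectorySet":
        meta = kw.pop("meta", self.meta)
        data = kw.pop("data", self.data.copy())
        return LandmarkTrajectorySet(data=data, meta=meta, registry=self.registry)


# ---------------------------------------------------------------------------
def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".yaml")


def _truncate_terminal_missing(df: pd.DataFrame, path: Path) -> pd.DataFrame:
    coord_cols = [c for c in df.columns if c.endswith(("_x", "_y"))]
    bad = df[coord_cols].isna().any(axis=1).to_numpy()
    if not bad.any():
        return df
    first_bad = int(np.argmax(bad))
    if not bad[first_bad:].all():
        raise LandmarkDataError(
            f"{path}: interior missing landmark values (frame {first_bad}); "
            "only a terminal missing suffix is supported"
        )
    if first_bad == 0:
        raise LandmarkDataError(f"{path}: no complete frames")
    log.warning(
        "%s: truncated %d terminal frame(s) with missing landmarks",
        path,
        int(bad.sum()),
    )
    return df.iloc[:first_bad].reset_index(drop=True)


def read_landmark_table(
    path, registry: LandmarkRegistry = DEFAULT_REGISTRY
) -> LandmarkTrajectorySet:
    """Read a bite CSV (+ YAML sidecar) into a validated trajectory set.

    Tables whose metadata declares ``y_axis: down`` (the image-coordinate
    convention; also the default when no sidecar is present) are flipped
    to y-up.
    """
    path = Path(path)
    if not path.exists():
        raise LandmarkDataError(f"no such file: {path}")
    df = pd.read_csv(path)
    side = _sidecar_path(path)
    meta_kw = {}
    if side.exists():
        raw = yaml.safe_load(side.read_text()) or {}
        mapping = {
            "specimen": "specimen",
            "bite": "bite_id",
            "algal_length_mm": "algal_length_mm",
            "mm_per_pixel": "mm_per_pixel",
            "facing": "facing",
            "units": "units",
            "frame_step_ms": "frame_step_ms",
            "y_axis": "y_axis",
        }
        for k, attr in mapping.items():
            if k in raw and raw[k] is not None:
                meta_kw[attr] = raw[k]
    else:
        meta_kw["units"] = "px"
        meta_kw["y_axis"] = "down"
    meta = BiteMetadata(**meta_kw)

    df = _truncate_terminal_missing(df, path)
    if meta.y_axis == "down":
        for c in df.columns:
            if c.endswith("_y"):
                df[c] = -df[c].astype(float)
        meta = replace(meta, y_axis="up")
    return LandmarkTrajectorySet(data=df, meta=meta, registry=registry)


def apply_calibration(
    lset: LandmarkTrajectorySet, scale: CalibrationScale
) -> LandmarkTrajectorySet:
    """Convert a pixel-unit trajectory set to millimetres.

    Calibration is linear, so any distance computed after calibration
    equals the pixel distance times ``mm_per_pixel``. Calling this on an
    already-calibrated (mm) set is an error: the guard prevents silently
    applying the scale twice.
    """
    if lset.meta.units == "mm":
        raise CalibrationError("trajectory set is already in mm")
    df = lset.data.copy()
    for c in df.columns:
        if c.endswith(("_x", "_y")):
            df[c] = df[c].astype(float) * scale.mm_per_pixel
    meta = replace(lset.meta, units="mm", mm_per_pixel=scale.mm_per_pixel)
    return LandmarkTrajectorySet(data=df, meta=meta, registry=lset.registry)


def write_landmark_table(lset: LandmarkTrajectorySet, path) -> Path:
    """Write a trajectory set as CSV + YAML sidecar (y-up convention).

    Coordinates are stored to 6 decimals; a write→read round trip
    reproduces them bit-identically at that precision.
    """
    path = Path(path)
    if lset.n_frames == 0:
        raise LandmarkDataError("refusing to write an empty trajectory set")
    df = lset.data.copy()
    for c in df.columns:
        if c.endswith(("_x", "_y")):
            df[c] = df[c].astype(float).round(COORD_DECIMALS)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=f"%.{COORD_DECIMALS}f")
    meta = lset.meta
    side = {
        "specimen": meta.specimen,
        "bite": meta.bite_id,
        "algal_length_mm": meta.algal_length_mm,
        "mm_per_pixel": meta.mm_per_pixel,
        "facing": meta.facing,
        "units": meta.units,
        "frame_step_ms": meta.frame_step_ms,
        "y_axis": meta.y_axis,
    }
    _sidecar_path(path).write_text(yaml.safe_dump(side, sort_keys=False))
    return path
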