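"""Motion quantities from landmark trajectories.

The primitives here are the standard planar-kinematics toolkit for
digitized feeding videos: per-step landmark displacement
``d_t = sqrt((x_t - x_{t-1})^2 + (y_t - y_{t-1})^2)``, pairwise landmark
distance, perpendicular distance to the benthos line ``ax + by + c = 0``
(``d = |ax + by + c| / sqrt(a^2 + b^2)``), three-point angles, first
differences of angle traces, Savitzky-Golay smoothing for detection, the
``t = 0`` alignment at the first frame in which the opened jaws begin to
close, and pectoral-fin spread/protraction metrics.

Angles are computed as the arccos of the normalized dot product of the
two arm vectors, clamped to [-1, 1] before the arccos so that exactly
collinear or coincident-direction configurations do not produce NaN from
rounding. Angles are reported in degrees and lie in [0, 180].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
from scipy.signal import savgol_filter

from .errors import DetectionError, GeometryError
from .io import LandmarkTrajectorySet

# Detection-time smoothing defaults: 5 samples (25 ms at 5 ms sampling),
# quadratic. Raw traces are always retained for reporting.
SMOOTH_WINDOW = 5
SMOOTH_ORDER = 2

# t=0 alignment: a local gape maximum counts as "open" if it exceeds this
# fraction of the overall maximum, and must be followed by this many
# strictly decreasing samples (robust to single-sample jitter).
OPEN_FRACTION = 0.2
SUSTAIN = 3


@dataclass(frozen=True)
class AngleDefinition:
    """An angle evaluated at ``vertex`` between rays to ``p`` and ``q``.

    Landmarks are referred to by role; the three roles must be distinct.
    """

    p: str
    vertex: str
    q: str
    name: str = ""

    def __post_init__(self) -> None:
        if len({self.p, self.vertex, self.q}) != 3:
            raise GeometryError("angle definition needs three distinct landmarks")


# The named angles tracked in every kinematic profile. "cranial" is the
# neurocranium-fulcrum-body angle whose decrease corresponds to cranial
# elevation; "imj" is the intramandibular angle (lower-jaw-tip, IMJ,
# jaw joint); "pelvic" and "girdle" track post-cranial rotation; "eki"
# and "iko" are the ventral out-lever angles used by the lever model.
STANDARD_ANGLES: Tuple[AngleDefinition, ...] = (
    AngleDefinition("neurocranium_anterior", "craniovertebral_fulcrum",
                    "neurocranium_reference", name="cranial"),
    AngleDefinition("lower_jaw_tip", "imj", "jaw_joint_ventral", name="imj"),
    AngleDefinition("pelvis", "craniovertebral_fulcrum",
                    "neurocranium_anterior", name="pelvic"),
    AngleDefinition("neurocranium_anterior", "craniovertebral_fulcrum",
                    "pectoral_girdle", name="girdle"),
    AngleDefinition("jaw_joint_ventral", "craniovertebral_fulcrum",
                    "pelvis", name="eki"),
    AngleDefinition("pelvis", "craniovertebral_fulcrum",
                    "ventral_posterior", name="iko"),
)


@dataclass(frozen=True)
class BenthosLine:
    """The substrate as a line ``ax + by + c = 0`` with ``a^2 + b^2 = 1``."""

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        n = float(np.hypot(self.a, self.b))
        if n == 0:
            raise GeometryError("degenerate benthos line: (a, b) == (0, 0)")
        if abs(n - 1.0) > 1e-9:
            object.__setattr__(self, "a", self.a / n)
            object.__setattr__(self, "b", self.b / n)
            object.__setattr__(self, "c", self.c / n)


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------
def displacement_per_step(track: np.ndarray) -> np.ndarray:
    """Per-timestep displacement of one landmark (mm/step), length n-1."""
    track = np.asarray(track, float)
    if track.ndim != 2 or track.shape[1] != 2:
        raise GeometryError("track must be an (n, 2) array")
    if len(track) < 2:
        raise GeometryError("displacement needs at least 2 frames")
    d = np.diff(track, axis=0)
    return np.hypot(d[:, 0], d[:, 1])


def pairwise_distance(track_i: np.ndarray, track_j: np.ndarray) -> np.ndarray:
    """Frame-wise distance between two landmarks sharing a time base (mm)."""
    a = np.asarray(track_i, float)
    b = np.asarray(track_j, float)
    if a.shape != b.shape:
        raise GeometryError("tracks must share the same time base/shape")
    d = a - b
    return np.hypot(d[:, 0], d[:, 1])


def fit_benthos_line(
    b1_track: np.ndarray,
    b2_track: np.ndarray,
    static_tolerance_mm: float = 0.5,
) -> BenthosLine:
    """Fit the substrate line through the two (static) benthos landmarks.

    Both landmarks are averaged over time (they should not move; an RMS
    per-frame spread beyond ``static_tolerance_mm`` indicates drift and
    is an error — RMS rather than max, so observation noise alone does
    not trip it) and the line through the mean points is the
    orthogonal-regression solution for two points.
    """
    b1 = np.asarray(b1_track, float)
    b2 = np.asarray(b2_track, float)
    for name, tr in (("benthos_1", b1), ("benthos_2", b2)):
        spread = float(np.sqrt(np.mean(np.sum((tr - tr.mean(axis=0)) ** 2, axis=1))))
        if spread > static_tolerance_mm:
            raise GeometryError(
                f"{name} moves by {spread:.3f} mm; benthos landmarks must be static"
            )
    p1 = b1.mean(axis=0)
    p2 = b2.mean(axis=0)
    d = p2 - p1
    n = np.hypot(*d)
    if n < 1e-9:
        raise GeometryError("benthos landmarks are coincident")
    # normal to the direction vector
    a, b = -d[1] / n, d[0] / n
    c = -(a * p1[0] + b * p1[1])
    return BenthosLine(a=float(a), b=float(b), c=float(c))


def distance_to_benthos(track: np.ndarray, line: BenthosLine) -> np.ndarray:
    """Perpendicular distance of a landmark to the benthos line (mm, >= 0)."""
    track = np.asarray(track, float)
    num = np.abs(line.a * track[:, 0] + line.b * track[:, 1] + line.c)
    return num / np.hypot(line.a, line.b)


def angle_series(
    p_track: np.ndarray, v_track: np.ndarray, q_track: np.ndarray
) -> np.ndarray:
    """Angle at the vertex between rays to p and q, per frame (degrees)."""
    p = np.asarray(p_track, float)
    v = np.asarray(v_track, float)
    q = np.asarray(q_track, float)
    u1 = p - v
    u2 = q - v
    n1 = np.linalg.norm(u1, axis=1)
    n2 = np.linalg.norm(u2, axis=1)
    bad = (n1 < 1e-12) | (n2 < 1e-12)
    if bad.any():
        raise GeometryError(
            f"degenerate angle (zero-length arm) at frame {int(np.argmax(bad))}"
        )
    cosang = np.einsum("ij,ij->i", u1, u2) / (n1 * n2)
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def angle_at_vertex(
    definition: AngleDefinition, lset: LandmarkTrajectorySet
) -> np.ndarray:
    """Evaluate a role-based angle definition on a trajectory set."""
    return angle_series(
        lset.track(definition.p),
        lset.track(definition.vertex),
        lset.track(definition.q),
    )


def angular_delta(angles: np.ndarray) -> np.ndarray:
    """First difference of an angle trace (degrees/step, length n-1)."""
    angles = np.asarray(angles, float)
    if angles.ndim != 1 or len(angles) < 2:
        raise GeometryError("angular_delta needs a 1-D series of >= 2 samples")
    return np.diff(angles)


def smooth(
    series: np.ndarray, window: int = SMOOTH_WINDOW, order: int = SMOOTH_ORDER
) -> np.ndarray:
    """Savitzky-Golay smoothing; ``window=1`` is the identity."""
    series = np.asarray(series, float)
    if window == 1:
        return series.copy()
    if window % 2 == 0 or window <= order:
        raise GeometryError("window must be odd and greater than order")
    if window > len(series):
        raise GeometryError("window longer than series")
    return savgol_filter(series, window_length=window, polyorder=order)


def align_t0(
    gape: np.ndarray,
    window: int = SMOOTH_WINDOW,
    order: int = SMOOTH_ORDER,
    open_fraction: float = OPEN_FRACTION,
    sustain: int = SUSTAIN,
) -> int:
    """Index of the first frame in which the opened jaws begin to close.

    Operates on the smoothed gape: the first local maximum that exceeds
    ``open_fraction`` of the overall maximum and is followed by
    ``sustain`` strictly decreasing samples. A monotone-decreasing trace
    is treated as already closing (index 0).
    """
    g = np.asarray(gape, float)
    if len(g) < 2:
        raise DetectionError("gape trace too short")
    gs = smooth(g, min(window, len(g) - (1 - len(g) % 2)), order) if len(g) >= window else g
    if np.ptp(gs) <= 0:
        raise DetectionError("no closure onset found: gape trace is flat")
    if np.all(np.diff(gs) <= 0):
        return 0
    gmax = float(np.max(gs))
    for i in range(len(gs)):
        if gs[i] < open_fraction * gmax:
            continue
        left_ok = i == 0 or gs[i] >= gs[i - 1]
        tail = gs[i : i + sustain + 1]
        right_ok = len(tail) > 1 and np.all(np.diff(tail) < 0)
        if i + sustain >= len(gs) and left_ok and len(tail) > 1 and np.all(np.diff(tail) < 0):
            return i
        if left_ok and right_ok:
            return i
    raise DetectionError("no closure onset found")


def fin_metrics(lset: LandmarkTrajectorySet) -> Tuple[np.ndarray, np.ndarray]:
    """Pectoral fin spread angle and per-step protraction.

    Spread is the angle leading-edge -> base -> trailing-edge (degrees).
    Protraction is the per-step displacement of the trailing-edge
    landmark along the facing direction (mm/step, positive = anterior),
    signed using the facing metadata.
    """
    for role in ("fin_base", "fin_leading_edge", "fin_trailing_edge"):
        if not lset.has_role(role):
            raise GeometryError(f"missing fin landmark role {role!r}")
    spread = angle_series(
        lset.track("fin_leading_edge"),
        lset.track("fin_base"),
        lset.track("fin_trailing_edge"),
    )
    m = lset.track("fin_trailing_edge")
    dx = np.diff(m[:, 0])
    sign = -1.0 if lset.meta.facing == "left" else 1.0
    return spread, sign * dx


# ---------------------------------------------------------------------------
# profile assembly
# ---------------------------------------------------------------------------
@dataclass
class BiteKinematicProfile:
    """Derived time series for one bite, on a common time base.

    ``angles`` holds the raw (unsmoothed) traces for every standard
    angle; smoothing is applied transiently inside detectors only.
    ``rel_time_ms`` is time re-expressed relative to t0, the first frame
    of jaw closing.
    """

    time_ms: np.ndarray
    gape: np.ndarray
    angles: Dict[str, np.ndarray]
    jaw_benthos: np.ndarray
    fin_spread: np.ndarray
    fin_protraction_delta: np.ndarray
    t0_index: int
    benthos: BenthosLine
    frame_step_ms: float
    meta: object = None

    def __post_init__(self) -> None:
        n = len(self.time_ms)
        for nm, tr in self.angles.items():
            if len(tr) != n:
                raise GeometryError(f"angle trace {nm!r} not on profile time base")
            if np.any((tr < -1e-9) | (tr > 180 + 1e-9)):
                raise GeometryError(f"angle trace {nm!r} outside [0, 180]")
        if len(self.gape) != n or len(self.jaw_benthos) != n:
            raise GeometryError("series not on profile time base")
        if np.any(self.gape < -1e-9):
            raise GeometryError("negative gape")

    @property
    def rel_time_ms(self) -> np.ndarray:
        return self.time_ms - self.time_ms[self.t0_index]

    @property
    def cranial_elevation(self) -> np.ndarray:
        """Cranial elevation relative to t0 (degrees, positive = dorsal).

        Elevating the neurocranium swings its anterior tip toward the
        dorsal body reference, so elevation is the *decrease* of the
        cranial angle from its value at t0.
        """
        a = self.angles["cranial"]
        return a[self.t0_index] - a

    def to_frame(self):
        import pandas as pd

        cols = {
            "time_ms": self.time_ms,
            "rel_time_ms": self.rel_time_ms,
            "gape_mm": self.gape,
            "jaw_benthos_mm": self.jaw_benthos,
            "fin_spread_deg": self.fin_spread,
        }
        for nm, tr in self.angles.items():
            cols[f"angle_{nm}_deg"] = tr
        df = pd.DataFrame(cols)
        prot = np.concatenate([[np.nan], self.fin_protraction_delta])
        df["fin_protraction_mm_per_step"] = prot
        return df


def compute_profile(lset: LandmarkTrajectorySet) -> BiteKinematicProfile:
    """Build the full kinematic profile for one calibrated bite."""
    gape = pairwise_distance(lset.track("upper_jaw_tip"), lset.track("lower_jaw_tip"))
    line = fit_benthos_line(lset.track("benthos_1"), lset.track("benthos_2"))
    angles = {d.name: angle_at_vertex(d, lset) for d in STANDARD_ANGLES}
    jaw_benthos = distance_to_benthos(lset.track("lower_jaw_tip"), line)
    spread, prot = fin_metrics(lset)
    t0 = align_t0(gape)
    t = lset.time_ms
    step = float(t[1] - t[0]) if len(t) > 1 else lset.meta.frame_step_ms
    return BiteKinematicProfile(
        time_ms=t,
        gape=gape,
        angles=angles,
        jaw_benthos=jaw_benthos,
        fin_spread=spread,
        fin_protraction_delta=prot,
        t0_index=t0,
        benthos=line,
        frame_step_ms=step,
        meta=lset.meta,
    )
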