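"""Bite phase segmentation and binary behaviour scoring.

A complete algae-cropping bite decomposes into five phases:

1. **Gape closure** — the jaws close around the algae (from t0, the
   first frame of closing, to the end of the first gape cycle).
2. **Ventral expansion** (optional) — with the jaws anchored to the
   benthos, the post-cranial body rotates dorsally; cranial elevation
   rises while the gape stays closed and the jaw tips stay put.
3. **Ventral pull** — swift ventral rotation of neurocranium and closed
   jaws with flexion of the intramandibular joint (IMJ), ending at the
   IMJ flexion extremum.
4. **Lateral head flick** — out-of-plane for a 2D pipeline; reported as
   an interval and flag only.
5. **Second gape cycle** — a fast re-opening with a suction burst that
   ingests the detached algae.

The detectors work on Savitzky-Golay-smoothed traces; all reported
series remain raw. Thresholds are configurable via
:class:`PhaseParams`; the defaults are operationalizations (the source
behaviours were scored by eye) chosen to sit above landmark noise and
below the smallest rotations of interest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .errors import DetectionError
from .io import LandmarkTrajectorySet
from .kinematics import BiteKinematicProfile, smooth

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PhaseParams:
    """Tunable thresholds for phase segmentation and behaviour scoring.

    k_sigma
        Multiplier on the closed-gape noise scale for the gape
        open/closed threshold (threshold = baseline + k_sigma * sigma).
    theta_min_deg
        Minimum cumulative cranial-elevation increase for a ventral
        expansion to count as present (boundary inclusive).
    anchor_tolerance_mm
        Maximum excursion of the jaw-tip-to-benthos distance during a
        candidate expansion (the jaws must stay anchored).
    delta_pull_deg
        Per-step cranial-elevation decrease (sustained for two steps)
        that marks the ventral-pull onset.
    v_suction_mm
        Minimum per-step approach speed of the algae tip toward the
        mouth midpoint, sustained for two steps, to score suction.
    proximity_max_mm
        Algae tip must be this close to the mouth for suction to count.
    """

    k_sigma: float = 3.0
    rel_floor: float = 0.02
    theta_min_deg: float = 1.5
    anchor_tolerance_mm: float = 0.5
    delta_pull_deg: float = 0.1
    v_suction_mm: float = 0.2
    proximity_max_mm: float = 5.0
    smooth_window: int = 5
    smooth_order: int = 2
    min_run: int = 3
    open_fraction: float = 0.2
    merge_gap: int = 0


@dataclass(frozen=True)
class GapeCycle:
    """One open-close excursion of the gape (sample indices)."""

    onset: int
    peak: int
    end: int


@dataclass(frozen=True)
class Phase:
    number: int
    present: bool
    start_ms: Optional[float] = None  # relative to t0
    end_ms: Optional[float] = None

    @property
    def duration_ms(self) -> Optional[float]:
        if not self.present:
            return None
        return self.end_ms - self.start_ms


@dataclass
class PhaseSegmentation:
    """The five phase intervals (times relative to t0) plus cut indices."""

    phases: Dict[int, Phase]
    cuts: Dict[str, int]  # sample indices: t0, c1, c2, c3, c4, end
    complete: bool  # second gape cycle present

    def __post_init__(self) -> None:
        if not self.phases[1].present:
            raise DetectionError("phase 1 must be present")
        prev_end = None
        for k in range(1, 6):
            ph = self.phases[k]
            if not ph.present:
                continue
            if prev_end is not None and abs(ph.start_ms - prev_end) > 1e-9:
                raise DetectionError(
                    f"phases not contiguous at phase {k} "
                    f"({ph.start_ms} vs {prev_end})"
                )
            if ph.end_ms < ph.start_ms:
                raise DetectionError(f"phase {k} has negative duration")
            prev_end = ph.end_ms

    def duration_ms(self, number: int) -> Optional[float]:
        return self.phases[number].duration_ms


@dataclass
class BiteSummary:
    """Per-bite scalar summary of the kinematic profile."""

    first_opening_ms: float
    second_opening_ms: Optional[float]
    full_bite_ms: float
    phase2_ms: Optional[float]
    cranial_elevation_phase1_deg: float
    cranial_elevation_phase2_deg: Optional[float]
    pelvic_rotation_phase1_deg: float
    girdle_change_phase2_deg: Optional[float]
    max_imj_flexion_deg: float
    min_jaw_benthos_mm: float
    suction_1: Optional[bool]
    suction_2: Optional[bool]
    ventral_expansion: bool
    algal_length_mm: Optional[float]


# ---------------------------------------------------------------------------
# gape cycles
# ---------------------------------------------------------------------------
def closed_threshold(gape: np.ndarray, params: PhaseParams = PhaseParams()) -> float:
    """Gape level separating open from closed.

    Baseline is the 5th percentile of the smoothed gape; the noise scale
    is a robust (MAD-based) estimate of the raw closed-segment gape
    about its median — with closed jaw tips nearly coincident the
    closed gape is folded landmark noise, so the raw values themselves,
    not smoothing residuals, carry the right scale. A small relative
    floor keeps the threshold positive on noise-free traces.
    """
    g = np.asarray(gape, float)
    gs = smooth(g, params.smooth_window, params.smooth_order)
    baseline = float(np.percentile(gs, 5))
    closed = g[gs <= np.percentile(gs, 25)]
    sigma = (
        1.4826 * float(np.median(np.abs(closed - np.median(closed))))
        if len(closed)
        else 0.0
    )
    thr = baseline + params.k_sigma * sigma
    floor = baseline + params.rel_floor * (float(np.max(gs)) - baseline)
    return max(thr, floor)


def detect_gape_cycles(
    gape: np.ndarray, params: PhaseParams = PhaseParams()
) -> List[GapeCycle]:
    """Open-close gape cycles as (onset, peak, end) sample indices.

    A cycle is a run of at least ``min_run`` samples above the closed
    threshold; the onset is the last at-or-below-threshold sample before
    the run (the jaws start opening between it and the first open
    sample), the end is the first at-or-below-threshold sample after it,
    and the peak is the gape argmax within the cycle. Crossings and the
    peak are located on the *raw* trace: the gape signal is large
    relative to landmark noise and the second opening is only a few
    samples long, which smoothing would smear; the threshold itself is
    noise-robust. A flat closed trace yields no cycles.
    """
    g = np.asarray(gape, float)
    if len(g) < max(3, params.smooth_window):
        return []
    thr = closed_threshold(g, params)
    open_mask = g > thr

    # above-threshold runs, merging runs split by <= merge_gap noisy samples
    runs: List[List[int]] = []
    n = len(g)
    i = 0
    while i < n:
        if not open_mask[i]:
            i += 1
            continue
        j = i
        while j < n and open_mask[j]:
            j += 1
        if runs and i - runs[-1][1] <= params.merge_gap:
            runs[-1][1] = j
        else:
            runs.append([i, j])
        i = j

    cycles: List[GapeCycle] = []
    for i, j in runs:
        if j - i < params.min_run:
            continue
        onset = max(i - 1, 0)
        end = min(j, n - 1)
        peak = onset + int(np.argmax(g[onset : end + 1]))
        cycles.append(GapeCycle(onset=onset, peak=peak, end=end))
    # a real cycle opens to a substantial fraction of the maximum gape;
    # folded landmark noise during the closed phases does not
    if cycles:
        gmax = max(g[c.peak] for c in cycles)
        cycles = [c for c in cycles if g[c.peak] >= params.open_fraction * gmax]
    return cycles


# ---------------------------------------------------------------------------
# behaviours
# ---------------------------------------------------------------------------
def detect_suction(
    lset: LandmarkTrajectorySet,
    cycles: List[GapeCycle],
    which: str,
    params: PhaseParams = PhaseParams(),
) -> Optional[bool]:
    """Score a suction event during the first or second gape cycle.

    True iff, within the chosen cycle, the algae-tip landmark approaches
    the mouth midpoint (midpoint of the jaw tips) faster than
    ``v_suction_mm`` per step for at least two consecutive steps while
    closer than ``proximity_max_mm``. Returns None (unknown) when no
    algae-tip landmark was digitized.
    """
    if which not in ("first", "second"):
        raise ValueError("which must be 'first' or 'second'")
    if not lset.has_role("algae_tip"):
        return None
    idx = 0 if which == "first" else 1
    if idx >= len(cycles):
        return False
    cyc = cycles[idx]
    tip = lset.track("algae_tip")
    mouth = 0.5 * (lset.track("upper_jaw_tip") + lset.track("lower_jaw_tip"))
    dist = np.linalg.norm(tip - mouth, axis=1)
    lo, hi = cyc.onset, cyc.end
    approach = dist[lo:hi] - dist[lo + 1 : hi + 1]  # positive = toward mouth
    near = dist[lo + 1 : hi + 1] < params.proximity_max_mm
    ok = (approach > params.v_suction_mm) & near
    return bool(np.any(ok[:-1] & ok[1:]))


def _pull_onset(elev_s: np.ndarray, w0: int, w1: int, delta: float) -> int:
    """First sample at/after the elevation argmax where a sustained
    (two-step) decline of at least ``delta`` per step begins."""
    m = w0 + int(np.argmax(elev_s[w0 : w1 + 1]))
    for k in range(m, w1):
        d1 = elev_s[k + 1] - elev_s[k]
        d2 = elev_s[k + 2] - elev_s[k + 1] if k + 2 <= w1 else d1
        if d1 <= -delta and d2 <= -delta:
            return k
    return m


def detect_ventral_expansion(
    profile: BiteKinematicProfile,
    cycles: List[GapeCycle],
    params: PhaseParams = PhaseParams(),
) -> Tuple[bool, Optional[Tuple[int, int]]]:
    """Detect the ventral-expansion phase between the gape cycles.

    Searches the window from first-cycle closure to the ventral-pull
    onset for a sustained rise of smoothed cranial elevation. Present
    iff the cumulative rise reaches ``theta_min_deg`` (inclusive) while
    the gape stays closed (guaranteed inside the window) and the
    jaw-tip-to-benthos distance stays within ``anchor_tolerance_mm`` of
    its window minimum (the jaws remain anchored). Returns the
    (start, end) sample indices of the interval when present.
    """
    if len(cycles) < 1:
        raise DetectionError("need at least one gape cycle")
    w0 = cycles[0].end
    w1 = cycles[1].onset if len(cycles) > 1 else len(profile.gape) - 1
    if w1 - w0 < 2:
        return False, None
    elev_s = smooth(profile.cranial_elevation, params.smooth_window, params.smooth_order)
    pull = _pull_onset(elev_s, w0, w1, params.delta_pull_deg)
    # rise start: the sample before the first climbing step
    start = None
    for k in range(w0, pull):
        if elev_s[k + 1] - elev_s[k] >= params.delta_pull_deg:
            start = k
            break
    if start is None or pull <= start:
        return False, None
    # cumulative rise from the raw trace (smoothing shrinks the
    # endpoints, which would make the threshold exclusive in practice);
    # the tiny tolerance keeps exact-threshold amplitudes inclusive
    rise = profile.cranial_elevation[pull] - profile.cranial_elevation[start]
    if rise < params.theta_min_deg - 0.01:
        return False, None
    jb = profile.jaw_benthos[start : pull + 1]
    if np.max(jb) - np.min(jb) > params.anchor_tolerance_mm:
        return False, None
    return True, (start, pull)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------
def segment_phases(
    profile: BiteKinematicProfile,
    cycles: List[GapeCycle],
    params: PhaseParams = PhaseParams(),
) -> PhaseSegmentation:
    """Cut one bite into the five phases.

    Requires at least one gape cycle (else the trace is not a bite).
    With a single cycle only phases 1-3 are segmented and a warning is
    logged. Boundaries: phase 1 runs from t0 to the expansion start (or
    closure end when no expansion); phase 2 to the ventral-pull onset;
    phase 3 to the IMJ-flexion extremum; phase 4 to the second-cycle
    opening onset; phase 5 spans the second cycle.
    """
    if len(cycles) == 0:
        raise DetectionError("no gape cycles: not a bite")
    t = profile.time_ms
    i_t0 = profile.t0_index
    complete = len(cycles) >= 2
    if not complete:
        log.warning("second gape cycle missing: partial segmentation (phases 1-3)")

    has_p2, interval = detect_ventral_expansion(profile, cycles, params)
    w1 = cycles[1].onset if complete else len(t) - 1
    elev_s = smooth(profile.cranial_elevation, params.smooth_window, params.smooth_order)
    if has_p2:
        i_c1, i_c2 = interval
    else:
        i_c1 = cycles[0].end
        i_c2 = _pull_onset(elev_s, cycles[0].end, w1, params.delta_pull_deg)
        if i_c2 < i_c1:
            i_c2 = i_c1

    # phase 3 ends at the IMJ flexion extremum (relative to first closure)
    imj = profile.angles["imj"]
    flex = np.abs(imj - imj[cycles[0].end])
    flex_s = smooth(flex, params.smooth_window, params.smooth_order)
    hi = w1 if w1 > i_c2 else len(t) - 1
    i_c3 = i_c2 + int(np.argmax(flex_s[i_c2 : hi + 1])) if hi > i_c2 else i_c2

    rel = lambda i: float(t[i] - t[i_t0])
    phases: Dict[int, Phase] = {
        1: Phase(1, True, rel(i_t0), rel(i_c1)),
        2: (
            Phase(2, True, rel(i_c1), rel(i_c2))
            if has_p2
            else Phase(2, False)
        ),
        3: Phase(3, True, rel(i_c1) if not has_p2 else rel(i_c2), rel(i_c3)),
    }
    # when phase 2 is absent, phase 1 abuts phase 3 at c1 == c2
    if not has_p2:
        phases[3] = Phase(3, True, rel(i_c1), rel(i_c3))
    cuts = {"t0": i_t0, "c1": i_c1, "c2": i_c2, "c3": i_c3}
    if complete:
        i_c4 = cycles[1].onset
        i_end = cycles[1].end
        phases[4] = Phase(4, True, rel(i_c3), rel(i_c4))
        phases[5] = Phase(5, True, rel(i_c4), rel(i_end))
        cuts.update(c4=i_c4, end=i_end)
    else:
        phases[4] = Phase(4, False)
        phases[5] = Phase(5, False)
        cuts.update(c4=i_c3, end=len(t) - 1)
    return PhaseSegmentation(phases=phases, cuts=cuts, complete=complete)


def _refined_peak_time(g: np.ndarray, t: np.ndarray, peak: int) -> float:
    """Sub-sample peak time via a parabolic vertex through the peak
    sample and its neighbours; falls back to the sample time at the
    trace edges or when the local curvature is not concave. The offset
    is clamped to one sample."""
    if peak <= 0 or peak >= len(g) - 1:
        return float(t[peak])
    y0, y1, y2 = g[peak - 1], g[peak], g[peak + 1]
    denom = y0 - 2 * y1 + y2
    if denom >= 0:
        return float(t[peak])
    offset = 0.5 * (y0 - y2) / denom
    offset = float(np.clip(offset, -1.0, 1.0))
    step = float(t[1] - t[0])
    return float(t[peak]) + offset * step


def summarize_bite(
    profile: BiteKinematicProfile,
    segmentation: PhaseSegmentation,
    cycles: List[GapeCycle],
    suction_1: Optional[bool] = None,
    suction_2: Optional[bool] = None,
) -> BiteSummary:
    """Scalar per-bite summary from the segmentation.

    Opening durations are onset-to-peak of each gape cycle; rotations
    are raw angle-trace changes over the phase intervals; maximum IMJ
    flexion is the largest excursion of the intramandibular angle from
    its value at first jaw closure, over phases 3-4.
    """
    t = profile.time_ms
    cuts = segmentation.cuts
    elev = profile.cranial_elevation
    pelvic = profile.angles["pelvic"]
    girdle = profile.angles["girdle"]
    imj = profile.angles["imj"]

    c0 = cycles[0]
    first_opening = _refined_peak_time(profile.gape, t, c0.peak) - float(t[c0.onset])
    second_opening = None
    if segmentation.complete:
        c1cyc = cycles[1]
        second_opening = _refined_peak_time(profile.gape, t, c1cyc.peak) - float(
            t[c1cyc.onset]
        )
    full = float(t[cuts["end"]] - t[c0.onset])

    has_p2 = segmentation.phases[2].present
    i_t0, i_c1, i_c2, i_c4 = cuts["t0"], cuts["c1"], cuts["c2"], cuts["c4"]
    flex = np.abs(imj - imj[c0.end])
    hi = i_c4 if i_c4 > i_c2 else len(t) - 1
    max_flex = float(np.max(flex[i_c2 : hi + 1])) if hi >= i_c2 else 0.0

    return BiteSummary(
        first_opening_ms=first_opening,
        second_opening_ms=second_opening,
        full_bite_ms=full,
        phase2_ms=segmentation.duration_ms(2),
        cranial_elevation_phase1_deg=abs(float(elev[i_c1] - elev[i_t0])),
        cranial_elevation_phase2_deg=(
            abs(float(elev[i_c2] - elev[i_c1])) if has_p2 else None
        ),
        pelvic_rotation_phase1_deg=abs(float(pelvic[i_c1] - pelvic[i_t0])),
        girdle_change_phase2_deg=(
            abs(float(girdle[i_c2] - girdle[i_c1])) if has_p2 else None
        ),
        max_imj_flexion_deg=max_flex,
        min_jaw_benthos_mm=float(np.min(profile.jaw_benthos[c0.onset : cuts["end"] + 1])),
        suction_1=suction_1,
        suction_2=suction_2,
        ventral_expansion=has_p2,
        algal_length_mm=getattr(profile.meta, "algal_length_mm", None),
    )


def analyze_bite(
    lset: LandmarkTrajectorySet,
    params: PhaseParams = PhaseParams(),
):
    """Full single-bite analysis: profile, cycles, segmentation, summary."""
    from .kinematics import compute_profile

    profile = compute_profile(lset)
    cycles = detect_gape_cycles(profile.gape, params)
    if not cycles:
        raise DetectionError("no gape cycles: not a bite")
    seg = segment_phases(profile, cycles, params)
    s1 = detect_suction(lset, cycles, "first", params)
    s2 = detect_suction(lset, cycles, "second", params) if seg.complete else None
    summary = summarize_bite(profile, seg, cycles, suction_1=s1, suction_2=s2)
    return profile, cycles, seg, summary
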