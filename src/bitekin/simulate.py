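"""Synthetic articulated-bite generator and behaviour simulator.

The generator builds a planar linkage with the geometry the analysis
assumes: a craniovertebral fulcrum K carrying a rigid neurocranium
(anterior tip A, jaw joint E and the jaw assembly), a set of
post-cranial points (dorsal reference L, pectoral girdle J, pelvis I,
posterior ventral point O) at fixed radii from K, a pectoral fin
(base G, leading edge H, trailing edge M), a horizontal benthos line
with two static landmarks, and an optional algae-tip landmark. The
lower jaw runs from E through the intramandibular joint P to the tip F;
the upper jaw tip C is the lower tip reflected about the jaw midline,
so the gape maps exactly to the jaw-opening angle.

A bite is scheduled as five phases driven by configurable durations and
rotation amplitudes, with defaults set to the kinematics of an
algae-cropping surgeonfish strike: a 120 ms first jaw opening, 80 ms
closure with 5.3 deg cranial elevation and 1.8 deg pelvic rotation, a
19.6 ms ventral expansion with 4.2 deg cranial elevation (jaws anchored,
post-cranial body rotating dorsally), a 60 ms ventral pull with up to
93 deg of intramandibular flexion, an idle head-flick interval (lateral
motion is out of plane and not simulated), and a fast 15.7 ms second
opening with a suction burst; the defaults total 416.8 ms of bite.

Rotations use cubic smoothstep ramps, so angular-change traces are
continuous and peak mid-phase. Gape ramps use truncated quarter-sine
profiles with non-zero velocity at the opening onset, at peak gape and
at the return to closed, matching the abrupt muscle-driven starts and
stops of jaw motion in real strikes. Rigid
segments are exactly rigid before observation noise; iid Gaussian noise
of configurable standard deviation is added per landmark per frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import GeometryError
from .io import BiteMetadata, LandmarkTrajectorySet, write_landmark_table
from .registry import DEFAULT_REGISTRY, LandmarkRegistry


def smoothstep(s: np.ndarray) -> np.ndarray:
    """Cubic smoothstep 3s^2 - 2s^3, clamped to [0, 1]."""
    s = np.clip(s, 0.0, 1.0)
    return s * s * (3.0 - 2.0 * s)


def _u(deg):
    r = np.radians(deg)
    return np.array([np.cos(r), np.sin(r)])


@dataclass(frozen=True)
class BiteSimConfig:
    """Study conditions for one simulated bite.

    Durations are in ms, amplitudes in degrees (gape in mm), segment
    lengths in mm. A phase duration of 0 disables that phase. The
    amplitude fields are defined as the changes in the corresponding
    *measured* angles over the phase, which is what the analysis
    recovers.
    """

    frame_step_ms: float = 5.0
    lead_ms: float = 10.0
    tail_ms: float = 10.0

    # phase durations (ms)
    phase1_opening_ms: float = 120.0
    phase1_closing_ms: float = 80.0
    phase2_ms: float = 19.6
    phase3_ms: float = 60.0
    phase4_ms: float = 81.5
    phase5_opening_ms: float = 15.7
    phase5_closing_ms: float = 40.0

    # amplitudes
    max_gape_mm: float = 4.0
    phase1_cranial_deg: float = 5.3
    phase1_pelvic_deg: float = 1.8
    phase2_cranial_deg: float = 4.2
    phase2_girdle_deg: float = 1.8
    phase2_pelvic_deg: float = 1.8
    phase2_posterior_deg: float = 3.0
    phase3_ventral_deg: float = 8.0
    imj_excursion_deg: float = 93.0

    # geometry: fulcrum height above the benthos and polar (radius mm,
    # direction deg) coordinates about K for each rigid point
    fulcrum_height_mm: float = 15.0
    r_A: float = 12.0
    dir_A: float = 175.0
    r_L: float = 20.0
    dir_L: float = 55.0
    r_J: float = 12.0
    dir_J: float = -55.0
    r_I: float = 15.0
    dir_I: float = -40.0
    r_O: float = 25.0
    dir_O: float = -22.0
    r_E: float = 8.0
    dir_E: float = 235.0
    jaw_dir: float = 250.0
    e_to_p_mm: float = 4.0
    p_to_f_mm: float = 3.5

    # fin geometry (base polar about K; edges polar about G)
    r_G: float = 9.0
    dir_G: float = -42.0
    fin_leading_len: float = 4.5
    fin_leading_dir: float = 105.0
    fin_trailing_len: float = 5.0
    fin_trailing_dir: float = -25.0
    fin_spread_deg: float = 40.0
    fin_protraction_mm: float = 1.5

    # algae / suction
    include_algae: bool = True
    suction_first: bool = True
    suction_second: bool = True
    suction_amp_mm_per_step: float = 0.5
    suction1_window_ms: float = 30.0
    suction2_window_ms: float = 20.0

    # observation model
    noise_sd_mm: float = 0.0
    seed: int = 0
    facing: str = "left"
    specimen: str = "sim"
    bite_id: str = "sim-bite"
    algal_length_mm: float = 3.0

    def __post_init__(self) -> None:
        for nm in ("e_to_p_mm", "p_to_f_mm", "r_A", "r_L", "r_J", "r_I",
                   "r_O", "r_E", "r_G", "max_gape_mm"):
            if getattr(self, nm) <= 0:
                raise GeometryError(f"{nm} must be positive")
        for nm in ("phase1_opening_ms", "phase1_closing_ms", "phase2_ms",
                   "phase3_ms", "phase4_ms", "phase5_opening_ms",
                   "phase5_closing_ms", "noise_sd_mm"):
            if getattr(self, nm) < 0:
                raise GeometryError(f"{nm} must be non-negative")
        if self.phase1_opening_ms == 0 or self.phase1_closing_ms == 0:
            raise GeometryError("the first gape cycle is mandatory")
        jaw_len = self.e_to_p_mm + self.p_to_f_mm
        if self.max_gape_mm >= 2 * jaw_len:
            raise GeometryError("max gape exceeds what the jaw length allows")
        if self.facing not in ("left", "right"):
            raise GeometryError("facing must be 'left' or 'right'")


@dataclass
class BiteGroundTruth:
    """Exact schedule behind one simulated bite (times in absolute ms)."""

    t_open1_ms: float
    t0_ms: float
    c1_ms: float  # end of first closure / start of expansion
    c2_ms: float  # ventral-pull onset
    c3_ms: float  # IMJ flexion extremum
    c4_ms: float  # second-cycle opening onset
    t_peak2_ms: float
    t_end_ms: float
    first_opening_ms: float
    second_opening_ms: Optional[float]
    phase2_ms: float
    full_bite_ms: float
    cranial_elevation_phase1_deg: float
    pelvic_rotation_phase1_deg: float
    cranial_elevation_phase2_deg: float
    girdle_change_phase2_deg: float
    dtheta2_deg: float
    dtheta3_deg: float
    imj_excursion_deg: float
    max_gape_mm: float
    levers_mm: Dict[str, float]
    min_jaw_benthos_mm: float
    has_phase2: bool
    has_second_cycle: bool
    suction_first: bool
    suction_second: bool

    def boundaries(self) -> Dict[str, float]:
        return {
            "t0": self.t0_ms,
            "c1": self.c1_ms,
            "c2": self.c2_ms,
            "c3": self.c3_ms,
            "c4": self.c4_ms,
            "end": self.t_end_ms,
        }


def simulate_bite(
    config: BiteSimConfig = BiteSimConfig(),
    registry: LandmarkRegistry = DEFAULT_REGISTRY,
) -> Tuple[LandmarkTrajectorySet, BiteGroundTruth]:
    """Simulate one bite; returns the landmark table and its ground truth."""
    cfg = config
    step = cfg.frame_step_ms

    # ---- event times (absolute ms) --------------------------------------
    t_open1 = cfg.lead_ms
    t0 = t_open1 + cfg.phase1_opening_ms
    c1 = t0 + cfg.phase1_closing_ms
    c2 = c1 + cfg.phase2_ms
    c3 = c2 + cfg.phase3_ms
    c4 = c3 + cfg.phase4_ms
    has_cycle2 = cfg.phase5_opening_ms > 0
    t_peak2 = c4 + cfg.phase5_opening_ms
    t_end = t_peak2 + cfg.phase5_closing_ms
    total = t_end + cfg.tail_ms
    n = int(math.floor(total / step)) + 1
    t = np.arange(n) * step

    # ---- scalar schedules ------------------------------------------------
    jaw_len = cfg.e_to_p_mm + cfg.p_to_f_mm
    gamma_max = 2.0 * math.degrees(math.asin(cfg.max_gape_mm / (2.0 * jaw_len)))

    def ramp01(lo, hi):
        if hi <= lo:
            return np.zeros(n)
        return np.clip((t - lo) / (hi - lo), 0.0, 1.0)

    # Truncated sine ramps: jaw opening/closing starts and stops with
    # non-zero velocity (abrupt muscle-driven onsets), so the closure
    # onset t0 is a well-defined kink rather than a flat plateau.
    a_open = 0.8 * 0.5 * np.pi
    c_close = 0.3

    def open_ramp(s):
        return np.sin(a_open * np.clip(s, 0, 1)) / np.sin(a_open)

    def close_ramp(s):
        s = np.clip(s, 0, 1)
        return np.cos(c_close + (0.5 * np.pi - c_close) * s) / np.cos(c_close)

    gamma = np.zeros(n)
    m = (t >= t_open1) & (t < t0)
    gamma[m] = gamma_max * open_ramp((t[m] - t_open1) / cfg.phase1_opening_ms)
    m = (t >= t0) & (t < c1)
    gamma[m] = gamma_max * close_ramp((t[m] - t0) / cfg.phase1_closing_ms)
    if has_cycle2:
        m = (t >= c4) & (t < t_peak2)
        gamma[m] = gamma_max * open_ramp((t[m] - c4) / cfg.phase5_opening_ms)
        if cfg.phase5_closing_ms > 0:
            m = (t >= t_peak2) & (t < t_end)
            gamma[m] = gamma_max * close_ramp((t[m] - t_peak2) / cfg.phase5_closing_ms)

    S1 = smoothstep(ramp01(t0, c1))          # phase-1 closure rotations
    S2 = smoothstep(ramp01(c1, c2))          # ventral expansion
    S3 = smoothstep(ramp01(c2, c3))          # ventral pull
    S4 = smoothstep(ramp01(c3, c4))          # head-flick interval (IMJ return)
    Ssp = smoothstep(ramp01(t0, c3))         # fin spread
    Spr = smoothstep(ramp01(c1, c3))         # fin protraction

    head = cfg.phase1_cranial_deg * S1 - cfg.phase3_ventral_deg * S3
    l_rot = cfg.phase2_cranial_deg * S2
    j_rot = cfg.phase2_girdle_deg * S2
    i_rot = -(cfg.phase1_cranial_deg - cfg.phase1_pelvic_deg) * S1 \
        + cfg.phase2_pelvic_deg * S2
    o_rot = cfg.phase2_posterior_deg * S2
    flex = np.where(t < c3, cfg.imj_excursion_deg * S3,
                    cfg.imj_excursion_deg * (1.0 - S4))
    if cfg.phase4_ms == 0:
        flex = np.where(t >= c3, 0.0, flex)

    # ---- positions -------------------------------------------------------
    K = np.array([0.0, cfg.fulcrum_height_mm])
    names = dict(DEFAULT_REGISTRY.names)
    pos: Dict[str, np.ndarray] = {nm: np.zeros((n, 2)) for nm in names.values()}

    G0 = K + cfg.r_G * _u(cfg.dir_G)
    H0 = G0 + cfg.fin_leading_len * _u(cfg.fin_leading_dir)

    mouth_mid = np.zeros((n, 2))
    tip = np.zeros((n, 2))
    tip_rest = np.array([-9.3, 0.6])
    grip_offset = None
    grip_ref_dir = None
    s1_total = 0.0
    s2_total = 0.0
    cap1, cap2 = 1.0, 2.0
    grip_len = 1.8  # free algae end protrudes this far beyond the jaw tips

    for k in range(n):
        tk = t[k]
        A = K + cfg.r_A * _u(cfg.dir_A - head[k])
        L = K + cfg.r_L * _u(cfg.dir_L + l_rot[k])
        J = K + cfg.r_J * _u(cfg.dir_J + j_rot[k])
        I = K + cfg.r_I * _u(cfg.dir_I + i_rot[k])
        O = K + cfg.r_O * _u(cfg.dir_O + o_rot[k])
        E = K + cfg.r_E * _u(cfg.dir_E - head[k])
        d_j = cfg.jaw_dir - head[k]
        d_l = d_j + gamma[k] / 2.0
        P = E + cfg.e_to_p_mm * _u(d_l)
        F = P + cfg.p_to_f_mm * _u(d_l + flex[k])
        # upper tip: lower tip rotated about E by -gamma (closed => C == F)
        g = math.radians(-gamma[k])
        R = np.array([[math.cos(g), -math.sin(g)], [math.sin(g), math.cos(g)]])
        C = E + R @ (F - E)

        prot = cfg.fin_protraction_mm * Spr[k]
        shift = np.array([-prot, 0.0])
        G = G0 + shift
        H = H0 + shift
        Mfin = G + cfg.fin_trailing_len * _u(cfg.fin_trailing_dir + cfg.fin_spread_deg * Ssp[k])

        pos[names["neurocranium_anterior"]][k] = A
        pos[names["neurocranium_reference"]][k] = L
        pos[names["pectoral_girdle"]][k] = J
        pos[names["pelvis"]][k] = I
        pos[names["ventral_posterior"]][k] = O
        pos[names["jaw_joint_ventral"]][k] = E
        pos[names["imj"]][k] = P
        pos[names["lower_jaw_tip"]][k] = F
        pos[names["upper_jaw_tip"]][k] = C
        pos[names["craniovertebral_fulcrum"]][k] = K
        pos[names["fin_base"]][k] = G
        pos[names["fin_leading_edge"]][k] = H
        pos[names["fin_trailing_edge"]][k] = Mfin
        pos[names["benthos_1"]][k] = np.array([-20.0, 0.0])
        pos[names["benthos_2"]][k] = np.array([20.0, 0.0])
        mouth_mid[k] = 0.5 * (C + F)

        # ---- algae tip ---------------------------------------------------
        if cfg.include_algae:
            if tk < c1:
                p = tip_rest.copy() if k == 0 else tip[k - 1].copy()
                if (
                    cfg.suction_first
                    and t0 <= tk <= min(t0 + cfg.suction1_window_ms, c1)
                    and s1_total < cap1
                ):
                    d = mouth_mid[k] - p
                    dist = np.linalg.norm(d)
                    stepv = min(cfg.suction_amp_mm_per_step, cap1 - s1_total,
                                max(dist - 0.3, 0.0))
                    if dist > 1e-9 and stepv > 0:
                        p = p + stepv * d / dist
                        s1_total += stepv
                tip[k] = p
            elif has_cycle2 and tk >= c4:
                # jaws reopen: the strand is released; it floats where it
                # was and is drawn in only by the suction burst
                p = tip[k - 1].copy()
                if (
                    cfg.suction_second
                    and tk <= c4 + cfg.suction2_window_ms
                    and s2_total < cap2
                ):
                    d = mouth_mid[k] - p
                    dist = np.linalg.norm(d)
                    stepv = min(cfg.suction_amp_mm_per_step, cap2 - s2_total,
                                max(dist - 0.15, 0.0))
                    if dist > 1e-9 and stepv > 0:
                        p = p + stepv * d / dist
                        s2_total += stepv
                tip[k] = p
            else:
                if grip_offset is None:
                    # once gripped, the digitized tip is the free end of
                    # the strand, a fixed length beyond the jaw tips
                    prev = tip[k - 1] if k > 0 else tip_rest
                    o_raw = prev - F
                    nrm = np.linalg.norm(o_raw)
                    grip_offset = (
                        grip_len * o_raw / nrm if nrm > 1e-9 else grip_len * _u(d_l + flex[k])
                    )
                    grip_ref_dir = d_l + flex[k]
                dd = math.radians((d_l + flex[k]) - grip_ref_dir)
                Rg = np.array([[math.cos(dd), -math.sin(dd)],
                               [math.sin(dd), math.cos(dd)]])
                tip[k] = F + Rg @ grip_offset

    if cfg.include_algae:
        pos[names["algae_tip"]] = tip
    else:
        pos.pop(names["algae_tip"], None)

    # ---- ground truth (noise-free) ---------------------------------------
    f_clean = pos[names["lower_jaw_tip"]]
    in_bite = (t >= t_open1) & (t <= t_end)
    min_jb = float(np.min(f_clean[in_bite, 1]))
    truth = BiteGroundTruth(
        t_open1_ms=t_open1,
        t0_ms=t0,
        c1_ms=c1,
        c2_ms=c2,
        c3_ms=c3,
        c4_ms=c4,
        t_peak2_ms=t_peak2 if has_cycle2 else None,
        t_end_ms=t_end if has_cycle2 else c4,
        first_opening_ms=cfg.phase1_opening_ms,
        second_opening_ms=cfg.phase5_opening_ms if has_cycle2 else None,
        phase2_ms=cfg.phase2_ms,
        full_bite_ms=(t_end if has_cycle2 else c4) - t_open1,
        cranial_elevation_phase1_deg=cfg.phase1_cranial_deg,
        pelvic_rotation_phase1_deg=cfg.phase1_pelvic_deg,
        cranial_elevation_phase2_deg=cfg.phase2_cranial_deg,
        girdle_change_phase2_deg=cfg.phase2_girdle_deg,
        dtheta2_deg=cfg.phase2_pelvic_deg,
        dtheta3_deg=abs(cfg.phase2_posterior_deg - cfg.phase2_pelvic_deg),
        imj_excursion_deg=cfg.imj_excursion_deg if cfg.phase3_ms > 0 else 0.0,
        max_gape_mm=cfg.max_gape_mm,
        levers_mm={"KL": cfg.r_L, "KE": cfg.r_E, "KI": cfg.r_I, "KO": cfg.r_O},
        min_jaw_benthos_mm=min_jb,
        has_phase2=cfg.phase2_ms > 0,
        has_second_cycle=has_cycle2,
        suction_first=cfg.suction_first and cfg.include_algae,
        suction_second=cfg.suction_second and cfg.include_algae and has_cycle2,
    )

    # ---- noise, facing, table -------------------------------------------
    rng = np.random.default_rng(cfg.seed)
    cols = {"frame": np.arange(n), "time_ms": t}
    for nm, arr in pos.items():
        out = arr.copy()
        if cfg.noise_sd_mm > 0:
            out = out + rng.normal(0.0, cfg.noise_sd_mm, size=out.shape)
        if cfg.facing == "right":
            out[:, 0] = -out[:, 0]
        cols[f"{nm}_x"] = out[:, 0]
        cols[f"{nm}_y"] = out[:, 1]
    meta = BiteMetadata(
        specimen=cfg.specimen,
        bite_id=cfg.bite_id,
        algal_length_mm=cfg.algal_length_mm,
        mm_per_pixel=None,
        facing=cfg.facing,
        units="mm",
        frame_step_ms=step,
        y_axis="up",
    )
    lset = LandmarkTrajectorySet(data=pd.DataFrame(cols), meta=meta, registry=registry)
    return lset, truth


# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class BehaviorSimConfig:
    """Bernoulli behaviour dataset: presence ~ logistic(beta0 + beta1 x)."""

    n: int = 500
    length_low_mm: float = 1.0
    length_high_mm: float = 6.0
    beta0: float = 6.2
    beta1: float = -2.0
    event: str = "ventral_expansion"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise GeometryError("n must be >= 1")
        if self.length_high_mm <= self.length_low_mm or self.length_low_mm <= 0:
            raise GeometryError("invalid algal-length range")

    @classmethod
    def from_crossing(cls, crossing_mm: float, slope: float, **kw) -> "BehaviorSimConfig":
        """Parameterize by the odds=0.5 crossing: beta0 = -crossing * slope."""
        return cls(beta0=-crossing_mm * slope, beta1=slope, **kw)

    @property
    def crossing_mm(self) -> float:
        return -self.beta0 / self.beta1


def simulate_behavior(config: BehaviorSimConfig) -> pd.DataFrame:
    """Draw per-bite algal lengths and Bernoulli behaviour outcomes."""
    rng = np.random.default_rng(config.seed)
    x = rng.uniform(config.length_low_mm, config.length_high_mm, size=config.n)
    p = 1.0 / (1.0 + np.exp(-(config.beta0 + config.beta1 * x)))
    y = rng.binomial(1, p)
    return pd.DataFrame(
        {
            "bite_id": [f"b{i:04d}" for i in range(config.n)],
            "algal_length_mm": x,
            "present": y,
            "event": config.event,
        }
    )


def make_fixture_suite(out_dir) -> Dict[str, Path]:
    """Write the standard fixture set used by tests and demos.

    All fixtures are regenerated bit-identically from fixed seeds:
    a default bite (landmark noise 0.05 mm), a bite without phase 2,
    a noise-free bite with the maximal IMJ excursion, and Bernoulli
    behaviour tables for both scored events.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}

    specs = {
        "default_bite": BiteSimConfig(noise_sd_mm=0.05, seed=1, bite_id="default_bite"),
        "no_phase2_bite": BiteSimConfig(
            phase2_ms=0.0, noise_sd_mm=0.05, seed=2, bite_id="no_phase2_bite",
            algal_length_mm=5.0,
        ),
        "imj93_bite": BiteSimConfig(noise_sd_mm=0.0, seed=3, bite_id="imj93_bite"),
    }
    for name, cfg in specs.items():
        lset, _ = simulate_bite(cfg)
        paths[name] = write_landmark_table(lset, out / f"{name}.csv")

    behav = {
        "behavior_phase2": BehaviorSimConfig.from_crossing(
            3.1, -2.0, event="ventral_expansion", seed=42
        ),
        "behavior_suction": BehaviorSimConfig.from_crossing(
            2.8, 2.0, event="suction", seed=43
        ),
    }
    for name, bcfg in behav.items():
        df = simulate_behavior(bcfg)
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    return paths
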