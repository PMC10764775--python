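"""Lever-based biomechanical model of the ventral-expansion phase.

Cranial rotation is treated as a motion *input* at the craniovertebral
fulcrum K, and the ventral side of the fish as a motion *output* system.
Out-levers run from K to the dorsal reference L (input lever) and to the
ventral attachment points E (jaw joint), I (pelvis) and O (posterior
ventral point). For a rotation of ``dtheta`` about K, a point at radius
``r`` travels a chord of ``2 r sin(dtheta / 2)`` (isosceles triangle
with apex at K), so:

* predicted input motion of L = ``2 * KL * sin(dtheta1 / 2)`` where
  dtheta1 is the observed cranial-rotation change;
* predicted ventral expansion = change of the distance EI (triangle EKI,
  law of cosines with levers KE, KI and the observed angle change
  dtheta2) plus the change of IO (triangle IKO with KI, KO, dtheta3).

For rigid planar rotation about K the predictions are exact; agreement
between predicted and observed motion across bites is quantified by an
ordinary least-squares (Gaussian GLM) regression of observed on
predicted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np

from .errors import GeometryError, StatsError
from .io import LandmarkTrajectorySet
from .kinematics import BiteKinematicProfile, pairwise_distance
from .phases import PhaseSegmentation

RIGIDITY_CV = 0.05  # within-bite coefficient of variation above which a lever is flagged

LEVER_ROLES: Dict[str, str] = {
    "KL": "neurocranium_reference",
    "KE": "jaw_joint_ventral",
    "KI": "pelvis",
    "KO": "ventral_posterior",
}


@dataclass(frozen=True)
class LeverSet:
    """Anatomical lever lengths from the fulcrum K, per specimen (mm)."""

    KL: float
    KE: float
    KI: float
    KO: float
    specimen: str = "unknown"
    flagged: tuple = ()

    def __post_init__(self) -> None:
        for nm in ("KL", "KE", "KI", "KO"):
            if getattr(self, nm) <= 0:
                raise GeometryError(f"lever {nm} must be positive")


@dataclass
class LeverObservation:
    """Predicted vs observed motion over one ventral-expansion interval."""

    bite_id: str
    dtheta1_deg: float  # cranial-rotation (input) change
    dtheta2_deg: float  # angle E-K-I change
    dtheta3_deg: float  # angle I-K-O change
    predicted_input_mm: float
    observed_input_mm: float
    predicted_output_mm: float
    observed_output_mm: float
    predicted_ei_mm: float
    observed_ei_mm: float
    predicted_io_mm: float
    observed_io_mm: float


@dataclass
class RegressionSummary:
    slope: float
    intercept: float
    t_value: float
    p_value: float
    r_squared: float
    n: int


@dataclass
class LeverModelFit:
    observations: List[LeverObservation]
    input_regression: Optional[RegressionSummary]
    output_regression: Optional[RegressionSummary]


# ---------------------------------------------------------------------------
def measure_levers(
    lset: LandmarkTrajectorySet, rigidity_cv: float = RIGIDITY_CV
) -> LeverSet:
    """Lever lengths as the median over frames of each distance from K.

    Segments are quasi-rigid, so the within-bite coefficient of
    variation should be small; levers exceeding ``rigidity_cv`` are
    flagged (not rejected).
    """
    k = lset.track("craniovertebral_fulcrum")
    lengths = {}
    flagged = []
    for lever, role in LEVER_ROLES.items():
        d = pairwise_distance(k, lset.track(role))
        med = float(np.median(d))
        lengths[lever] = med
        if med > 0 and float(np.std(d)) / med > rigidity_cv:
            flagged.append(lever)
    return LeverSet(specimen=lset.meta.specimen, flagged=tuple(flagged), **lengths)


def chord_displacement(lever_mm: float, dtheta_deg: float) -> float:
    """Chord travelled by a point at radius ``lever_mm`` rotating by
    ``dtheta_deg`` about the fulcrum: ``2 r sin(theta / 2)``."""
    if lever_mm <= 0:
        raise GeometryError("lever must be positive")
    if not 0.0 <= dtheta_deg <= 180.0:
        raise GeometryError(f"dtheta must be in [0, 180] degrees, got {dtheta_deg}")
    return 2.0 * lever_mm * math.sin(math.radians(dtheta_deg) / 2.0)


def _law_of_cosines(r1: float, r2: float, theta_deg: float) -> float:
    """Third side of a triangle with sides r1, r2 and included angle."""
    c = r1 * r1 + r2 * r2 - 2.0 * r1 * r2 * math.cos(math.radians(theta_deg))
    if c < -1e-9:
        raise GeometryError("law-of-cosines argument out of range")
    return math.sqrt(max(c, 0.0))


def predicted_ventral_expansion(
    levers: LeverSet,
    dtheta_eki_deg: float,
    dtheta_iko_deg: float,
    theta_eki_start_deg: float,
    theta_iko_start_deg: float,
) -> float:
    """Model-predicted ventral expansion: change of EI plus change of IO.

    Each term is the law-of-cosines distance evaluated at the start
    angle and at start+change, using the measured levers KE, KI, KO.
    Exact for rigid rotation about K.
    """
    ei0 = _law_of_cosines(levers.KE, levers.KI, theta_eki_start_deg)
    ei1 = _law_of_cosines(levers.KE, levers.KI, theta_eki_start_deg + dtheta_eki_deg)
    io0 = _law_of_cosines(levers.KI, levers.KO, theta_iko_start_deg)
    io1 = _law_of_cosines(levers.KI, levers.KO, theta_iko_start_deg + dtheta_iko_deg)
    return (ei1 - ei0) + (io1 - io0)


def fit_model_agreement(
    predicted: Sequence[float], observed: Sequence[float]
) -> RegressionSummary:
    """OLS (Gaussian GLM) of observed motion on model-predicted motion.

    Returns the slope, intercept, slope t statistic and p value, and
    R^2. Needs at least 3 pairs and a predictor with nonzero variance.
    """
    import statsmodels.api as sm

    x = np.asarray(predicted, float)
    y = np.asarray(observed, float)
    if x.shape != y.shape or x.ndim != 1:
        raise StatsError("predicted and observed must be 1-D and paired")
    if len(x) < 3:
        raise StatsError("need at least 3 paired values")
    if np.ptp(x) == 0 or np.var(x) == 0:
        raise StatsError("zero variance in predictor")
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    return RegressionSummary(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        t_value=float(res.tvalues[1]),
        p_value=float(res.pvalues[1]),
        r_squared=float(res.rsquared),
        n=len(x),
    )


# ---------------------------------------------------------------------------
def observe_bite(
    lset: LandmarkTrajectorySet,
    profile: BiteKinematicProfile,
    segmentation: PhaseSegmentation,
    levers: Optional[LeverSet] = None,
) -> Optional[LeverObservation]:
    """Predicted and observed input/output motion over the
    ventral-expansion interval of one bite.

    Start angles are taken at the first frame of phase 2 and changes
    over the whole interval (one observation per bite). Returns None
    when the bite has no phase 2.
    """
    if not segmentation.phases[2].present:
        return None
    if levers is None:
        levers = measure_levers(lset)
    i0, i1 = segmentation.cuts["c1"], segmentation.cuts["c2"]

    elev = profile.cranial_elevation
    eki = profile.angles["eki"]
    iko = profile.angles["iko"]
    d1 = abs(float(elev[i1] - elev[i0]))
    d2 = float(eki[i1] - eki[i0])
    d3 = float(iko[i1] - iko[i0])

    l_track = lset.track("neurocranium_reference")
    obs_input = float(np.linalg.norm(l_track[i1] - l_track[i0]))
    pred_input = chord_displacement(levers.KL, d1)

    ei = pairwise_distance(lset.track("jaw_joint_ventral"), lset.track("pelvis"))
    io = pairwise_distance(lset.track("pelvis"), lset.track("ventral_posterior"))
    obs_ei = float(ei[i1] - ei[i0])
    obs_io = float(io[i1] - io[i0])

    ei0 = _law_of_cosines(levers.KE, levers.KI, float(eki[i0]))
    ei1_ = _law_of_cosines(levers.KE, levers.KI, float(eki[i0]) + d2)
    io0 = _law_of_cosines(levers.KI, levers.KO, float(iko[i0]))
    io1_ = _law_of_cosines(levers.KI, levers.KO, float(iko[i0]) + d3)

    return LeverObservation(
        bite_id=lset.meta.bite_id,
        dtheta1_deg=d1,
        dtheta2_deg=d2,
        dtheta3_deg=d3,
        predicted_input_mm=pred_input,
        observed_input_mm=obs_input,
        predicted_output_mm=(ei1_ - ei0) + (io1_ - io0),
        observed_output_mm=obs_ei + obs_io,
        predicted_ei_mm=ei1_ - ei0,
        observed_ei_mm=obs_ei,
        predicted_io_mm=io1_ - io0,
        observed_io_mm=obs_io,
    )


def fit_lever_model(observations: List[LeverObservation]) -> LeverModelFit:
    """Regress observed on predicted motion across bites (input and
    ventral-output comparisons). Regressions need >= 3 observations."""
    obs = [o for o in observations if o is not None]
    reg_in = reg_out = None
    if len(obs) >= 3:
        reg_in = fit_model_agreement(
            [o.predicted_input_mm for o in obs], [o.observed_input_mm for o in obs]
        )
        reg_out = fit_model_agreement(
            [o.predicted_output_mm for o in obs], [o.observed_output_mm for o in obs]
        )
    return LeverModelFit(observations=obs, input_regression=reg_in, output_regression=reg_out)
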