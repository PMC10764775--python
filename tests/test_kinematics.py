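"""Motion primitives: displacements, distances, angles, smoothing, t0."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bitekin as bk
from bitekin import (
    BenthosLine,
    BiteSimConfig,
    GeometryError,
    align_t0,
    angle_series,
    angular_delta,
    displacement_per_step,
    distance_to_benthos,
    fin_metrics,
    fit_benthos_line,
    pairwise_distance,
    simulate_bite,
    smooth,
)

finite = st.floats(-100, 100, allow_nan=False)


# -- per-step displacement ---------------------------------------------------
def test_displacement_stationary_and_345():
    still = np.tile([2.0, 3.0], (6, 1))
    np.testing.assert_array_equal(displacement_per_step(still), np.zeros(5))
    track = np.array([[0.0, 0.0], [3.0, 4.0]])
    np.testing.assert_allclose(displacement_per_step(track), [5.0])
    with pytest.raises(GeometryError):
        displacement_per_step(track[:1])


def test_displacement_matches_elementwise_oracle(rng):
    track = np.cumsum(rng.normal(0, 1, (50, 2)), axis=0)
    d = displacement_per_step(track)
    expected = [
        np.sqrt((track[t, 0] - track[t - 1, 0]) ** 2 + (track[t, 1] - track[t - 1, 1]) ** 2)
        for t in range(1, len(track))
    ]
    np.testing.assert_allclose(d, expected)
    assert np.all(d >= 0)


# -- pairwise distance -------------------------------------------------------
def test_pairwise_distance_basics():
    a = np.zeros((4, 2))
    np.testing.assert_array_equal(pairwise_distance(a, a), np.zeros(4))
    b = a + [3.0, 4.0]
    np.testing.assert_allclose(pairwise_distance(a, b), np.full(4, 5.0))
    np.testing.assert_allclose(pairwise_distance(a, b), pairwise_distance(b, a))
    with pytest.raises(GeometryError):
        pairwise_distance(a, b[:2])


def test_gape_is_jaw_tip_distance_hand_computed():
    """Gape on a 3-frame fixture equals the hand-computed tip distance."""
    c = np.array([[0.0, 1.0], [0.0, 2.0], [1.0, 2.0]])
    f = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 0.0]])
    np.testing.assert_allclose(pairwise_distance(c, f), [1.0, 2.0, 2.0])


# -- benthos line ------------------------------------------------------------
def test_benthos_line_axis_aligned():
    b1 = np.tile([0.0, 0.0], (3, 1))
    b2 = np.tile([1.0, 0.0], (3, 1))
    line = fit_benthos_line(b1, b2)
    assert abs(line.a) < 1e-12 and abs(abs(line.b) - 1) < 1e-12 and abs(line.c) < 1e-12
    vert = fit_benthos_line(b1, np.tile([0.0, 1.0], (3, 1)))
    assert abs(abs(vert.a) - 1) < 1e-12 and abs(vert.b) < 1e-12


def test_benthos_line_jittered_vs_tls_oracle(rng):
    """With jittered benthos points the fitted line stays within the
    jitter bound of the true line (orthogonal residuals small)."""
    true_y = 2.0
    b1 = np.column_stack([np.full(40, -10.0), true_y + rng.normal(0, 0.05, 40)])
    b2 = np.column_stack([np.full(40, 10.0), true_y + rng.normal(0, 0.05, 40)])
    line = fit_benthos_line(b1, b2)
    # residual of the true anchor points
    for p in ([-10.0, true_y], [10.0, true_y]):
        d = abs(line.a * p[0] + line.b * p[1] + line.c)
        assert d < 0.05
    with pytest.raises(GeometryError):
        fit_benthos_line(b1, b1)


def test_distance_to_benthos_and_sign_invariance(rng):
    line = BenthosLine(0.0, 1.0, 0.0)  # y = 0
    pts = np.array([[2.0, 3.0], [5.0, 0.0], [-1.0, -4.0]])
    np.testing.assert_allclose(distance_to_benthos(pts, line), [3.0, 0.0, 4.0])
    flipped = BenthosLine(-0.0, -1.0, -0.0)
    np.testing.assert_allclose(
        distance_to_benthos(pts, line), distance_to_benthos(pts, flipped)
    )
    # random lines vs closest-point projection oracle
    for _ in range(20):
        theta = rng.uniform(0, 2 * np.pi)
        a, b = np.cos(theta), np.sin(theta)
        c = rng.uniform(-5, 5)
        ln = BenthosLine(a, b, c)
        p = rng.uniform(-10, 10, (1, 2))
        proj = p - (a * p[0, 0] + b * p[0, 1] + c) * np.array([[a, b]])
        np.testing.assert_allclose(
            distance_to_benthos(p, ln)[0], np.linalg.norm(p - proj), atol=1e-9
        )


# -- angles ------------------------------------------------------------------
def test_angle_right_and_straight():
    p = np.array([[1.0, 0.0]])
    v = np.array([[0.0, 0.0]])
    q = np.array([[0.0, 1.0]])
    np.testing.assert_allclose(angle_series(p, v, q), [90.0])
    np.testing.assert_allclose(angle_series(p, v, -p), [180.0])
    with pytest.raises(GeometryError, match="frame 0"):
        angle_series(v, v, q)


@given(
    px=finite, py=finite, qx=finite, qy=finite,
    vx=st.floats(-10, 10), vy=st.floats(-10, 10),
)
@settings(max_examples=100, deadline=None, derandomize=True)
def test_angle_matches_law_of_cosines_and_is_symmetric(px, py, qx, qy, vx, vy):
    p = np.array([[px, py]])
    v = np.array([[vx, vy]])
    q = np.array([[qx, qy]])
    la = np.linalg.norm(p - v)
    lb = np.linalg.norm(q - v)
    lc = np.linalg.norm(p - q)
    if la < 1e-6 or lb < 1e-6:
        return
    ang = angle_series(p, v, q)[0]
    cos_c = np.clip((la**2 + lb**2 - lc**2) / (2 * la * lb), -1, 1)
    # arccos conditioning near 0/180 deg limits agreement to ~1e-5 deg
    np.testing.assert_allclose(ang, np.degrees(np.arccos(cos_c)), atol=1e-4)
    np.testing.assert_allclose(ang, angle_series(q, v, p)[0], atol=1e-12)
    assert 0.0 <= ang <= 180.0


def test_angle_similarity_invariance(rng):
    """Rotation, translation and uniform scaling leave angles unchanged."""
    pts = rng.uniform(-5, 5, (3, 10, 2))
    base = angle_series(pts[0], pts[1], pts[2])
    th = 0.7
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    moved = [(p @ R.T) * 3.2 + [7.0, -4.0] for p in pts]
    np.testing.assert_allclose(base, angle_series(*moved), atol=1e-9)


def test_angular_delta():
    np.testing.assert_array_equal(angular_delta(np.full(6, 42.0)), np.zeros(5))
    ramp = np.linspace(10, 20, 6)
    np.testing.assert_allclose(angular_delta(ramp), np.full(5, 2.0))
    with pytest.raises(GeometryError):
        angular_delta(np.array([1.0]))


# -- smoothing ---------------------------------------------------------------
def test_smooth_identity_polynomial_and_noise(rng):
    x = np.linspace(0, 1, 41)
    series = 2 - 3 * x + 0.5 * x**2
    np.testing.assert_array_equal(smooth(series, window=1), series)
    np.testing.assert_allclose(smooth(series, 5, 2), series, atol=1e-10)
    truth = np.sin(2 * np.pi * x)
    noisy = truth + rng.normal(0, 0.2, len(x))
    sm = smooth(noisy, 5, 2)
    assert np.sqrt(np.mean((sm - truth) ** 2)) < np.sqrt(np.mean((noisy - truth) ** 2))
    with pytest.raises(GeometryError):
        smooth(series, 4, 2)
    with pytest.raises(GeometryError):
        smooth(series, 3, 5)
    with pytest.raises(GeometryError):
        smooth(series[:3], 5, 2)


# -- t0 alignment ------------------------------------------------------------
def test_align_t0_cases(clean_bite):
    tri = np.concatenate([np.linspace(0, 5, 11), np.linspace(5, 0, 11)[1:]])
    assert align_t0(tri) == 10
    assert align_t0(np.linspace(5, 0, 20)) == 0
    with pytest.raises(bk.DetectionError):
        align_t0(np.zeros(30))
    lset, truth = clean_bite
    prof = bk.compute_profile(lset)
    t0_detected = lset.time_ms[prof.t0_index]
    assert abs(t0_detected - truth.t0_ms) <= lset.meta.frame_step_ms


# -- fin metrics -------------------------------------------------------------
def test_fin_metrics_static_and_translation():
    lset, _ = simulate_bite(BiteSimConfig(seed=3))
    n = 8
    df = lset.data.iloc[:n].copy()
    for c in df.columns:
        if c.endswith(("_x", "_y")):
            df[c] = df[c].iloc[0]
    static = bk.LandmarkTrajectorySet(data=df.assign(
        frame=np.arange(n), time_ms=np.arange(n) * 5.0
    ), meta=lset.meta, registry=lset.registry)
    spread, prot = fin_metrics(static)
    np.testing.assert_allclose(prot, np.zeros(n - 1), atol=1e-12)
    assert np.ptp(spread) < 1e-9
    # trailing edge moving 1 mm anterior per step (facing left => -x)
    df2 = df.copy()
    df2["M_x"] = df2["M_x"].iloc[0] - np.arange(n) * 1.0
    moving = bk.LandmarkTrajectorySet(data=df2.assign(
        frame=np.arange(n), time_ms=np.arange(n) * 5.0
    ), meta=lset.meta, registry=lset.registry)
    _, prot2 = fin_metrics(moving)
    np.testing.assert_allclose(prot2, np.ones(n - 1))


def test_fin_schedule_recovered(clean_bite):
    """The generator's configured fin-spread change and total protraction
    are recovered from the traces."""
    lset, _ = clean_bite
    cfg = BiteSimConfig()
    spread, prot = fin_metrics(lset)
    assert abs(abs(spread[-1] - spread[0]) - cfg.fin_spread_deg) < 0.5
    # net anterior displacement of the trailing edge = configured
    # protraction minus the anterior component of the spread rotation
    rot_dx = cfg.fin_trailing_len * (
        np.cos(np.radians(cfg.fin_trailing_dir + cfg.fin_spread_deg))
        - np.cos(np.radians(cfg.fin_trailing_dir))
    )
    expected = cfg.fin_protraction_mm - rot_dx
    assert abs(np.sum(prot) - expected) < 0.05
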