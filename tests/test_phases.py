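"""Phase segmentation, gape cycles and behaviour scoring."""

import numpy as np
import pytest

import bitekin as bk
from bitekin import (
    BiteSimConfig,
    DetectionError,
    PhaseParams,
    analyze_bite,
    detect_gape_cycles,
    detect_ventral_expansion,
    simulate_bite,
)

STEP = 5.0


def _boundary_errors(seed, noise, quantized=False):
    lset, truth = simulate_bite(BiteSimConfig(noise_sd_mm=noise, seed=seed))
    _, _, seg, _ = analyze_bite(lset)
    t = lset.time_ms
    ref = lambda v: round(v / STEP) * STEP if quantized else v
    return [abs(t[seg.cuts[k]] - ref(v)) for k, v in truth.boundaries().items()]


# -- gape cycles -------------------------------------------------------------
def test_flat_trace_has_no_cycles():
    assert detect_gape_cycles(np.zeros(60)) == []


def test_two_triangular_pulses_two_cycles():
    g = np.zeros(60)
    g[10:21] = np.concatenate([np.linspace(0, 4, 6), np.linspace(4, 0, 6)[1:]])
    g[40:51] = np.concatenate([np.linspace(0, 3, 6), np.linspace(3, 0, 6)[1:]])
    cycles = detect_gape_cycles(g)
    assert len(cycles) == 2
    assert cycles[0].onset == 10 and cycles[0].peak == 15
    assert cycles[1].onset == 40 and cycles[1].peak == 45
    assert cycles[0].end <= cycles[1].onset


@pytest.mark.parametrize("seed", range(1, 11))
def test_default_bite_has_exactly_two_cycles(seed):
    lset, _ = simulate_bite(BiteSimConfig(noise_sd_mm=0.05, seed=seed))
    prof = bk.compute_profile(lset)
    assert len(detect_gape_cycles(prof.gape)) == 2


# -- suction -----------------------------------------------------------------
def test_suction_tristate(clean_bite):
    lset, truth = clean_bite
    _, cycles, seg, summary = analyze_bite(lset)
    assert summary.suction_1 is True and summary.suction_2 is True
    off, _ = simulate_bite(
        BiteSimConfig(suction_first=False, suction_second=False, noise_sd_mm=0.05, seed=4)
    )
    _, _, _, s_off = analyze_bite(off)
    assert s_off.suction_1 is False and s_off.suction_2 is False
    no_algae, _ = simulate_bite(BiteSimConfig(include_algae=False))
    _, _, _, s_na = analyze_bite(no_algae)
    assert s_na.suction_1 is None and s_na.suction_2 is None


def test_suction_constructed_fixture(clean_bite):
    """An algae tip moved 0.5 mm/step toward the mouth during the first
    opening scores suction; a stationary tip does not."""
    lset, _ = clean_bite
    prof = bk.compute_profile(lset)
    cycles = detect_gape_cycles(prof.gape)
    moving = lset.copy_with(data=lset.data.copy())
    mouth = 0.5 * (
        moving.data[["C_x", "C_y"]].to_numpy() + moving.data[["F_x", "F_y"]].to_numpy()
    )
    n = moving.n_frames
    tip = np.tile([-12.0, 0.5], (n, 1))
    lo, hi = cycles[0].onset + 2, cycles[0].onset + 10
    for k in range(1, n):
        tip[k] = tip[k - 1]
        if lo <= k <= hi:
            d = mouth[k] - tip[k - 1]
            tip[k] = tip[k - 1] + 0.5 * d / max(np.linalg.norm(d), 1e-9)
    moving.data["ALG_x"], moving.data["ALG_y"] = tip[:, 0], tip[:, 1]
    assert bk.detect_suction(moving, cycles, "first") is True
    still = lset.copy_with(data=lset.data.copy())
    still.data["ALG_x"], still.data["ALG_y"] = -12.0, 0.5
    assert bk.detect_suction(still, cycles, "first") is False


# -- ventral expansion -------------------------------------------------------
def test_ventral_expansion_amplitude_and_interval(clean_bite):
    lset, truth = clean_bite
    prof = bk.compute_profile(lset)
    cycles = detect_gape_cycles(prof.gape)
    present, interval = detect_ventral_expansion(prof, cycles)
    assert present
    lo, hi = interval
    t = lset.time_ms
    assert abs(t[lo] - truth.c1_ms) <= STEP
    assert abs(t[hi] - truth.c2_ms) <= STEP
    # amplitude 0 disables the phase entirely
    zero, _ = simulate_bite(BiteSimConfig(phase2_ms=0.0, noise_sd_mm=0.0, seed=0))
    prof0 = bk.compute_profile(zero)
    assert detect_ventral_expansion(prof0, detect_gape_cycles(prof0.gape))[0] is False


@pytest.mark.parametrize("amp,expected", [(0.4, False), (1.5, True), (4.2, True)])
def test_ventral_expansion_threshold_inclusive(amp, expected):
    """Detection at exactly theta_min is inclusive, and monotone in the
    phase-2 amplitude: once detected, larger amplitudes stay detected."""
    scale = amp / 4.2
    cfg = BiteSimConfig(
        phase2_cranial_deg=amp,
        phase2_pelvic_deg=1.8 * scale,
        phase2_girdle_deg=1.8 * scale,
        phase2_posterior_deg=3.0 * scale,
        noise_sd_mm=0.0,
    )
    lset, _ = simulate_bite(cfg)
    prof = bk.compute_profile(lset)
    present, _ = detect_ventral_expansion(prof, detect_gape_cycles(prof.gape))
    assert present is expected


# -- segmentation ------------------------------------------------------------
def test_default_bite_five_phases_within_one_sample(analyzed_clean):
    lset, truth, profile, cycles, seg, summary = analyzed_clean
    assert all(seg.phases[k].present for k in range(1, 6))
    t = lset.time_ms
    for key, tv in truth.boundaries().items():
        assert abs(t[seg.cuts[key]] - tv) <= STEP + 1e-9, key
    # boundaries monotone, phases contiguous from t0 to end of cycle 2
    starts = [seg.phases[k].start_ms for k in range(1, 6)]
    assert starts == sorted(starts)
    assert seg.phases[1].start_ms == 0.0


def test_phase2_absent_phase1_abuts_phase3():
    lset, _ = simulate_bite(BiteSimConfig(phase2_ms=0.0, noise_sd_mm=0.05, seed=3))
    _, _, seg, summary = analyze_bite(lset)
    assert not seg.phases[2].present
    assert summary.phase2_ms is None  # missing, not zero
    assert seg.phases[3].start_ms == seg.phases[1].end_ms
    assert not summary.ventral_expansion


def test_single_cycle_partial_segmentation(caplog):
    lset, _ = simulate_bite(BiteSimConfig(phase5_opening_ms=0.0, noise_sd_mm=0.0))
    with caplog.at_level("WARNING"):
        _, _, seg, summary = analyze_bite(lset)
    assert not seg.complete
    assert seg.phases[1].present and seg.phases[3].present
    assert not seg.phases[5].present
    assert summary.second_opening_ms is None
    assert any("partial" in r.message for r in caplog.records)


def test_no_cycles_is_not_a_bite():
    with pytest.raises(DetectionError):
        bk.segment_phases(None, [], PhaseParams())


def test_summary_durations_equal_boundary_differences(analyzed_clean):
    lset, truth, profile, cycles, seg, summary = analyzed_clean
    assert summary.phase2_ms == seg.phases[2].end_ms - seg.phases[2].start_ms
    for k in range(1, 6):
        ph = seg.phases[k]
        assert ph.duration_ms == ph.end_ms - ph.start_ms


def test_summary_recovers_configured_bite(analyzed_clean):
    """On the noise-free default bite every configured duration and
    rotation amplitude is recovered within a sample / half a degree."""
    lset, truth, profile, cycles, seg, summary = analyzed_clean
    assert abs(summary.first_opening_ms - truth.first_opening_ms) <= STEP
    assert abs(summary.second_opening_ms - truth.second_opening_ms) <= STEP
    assert abs(summary.phase2_ms - truth.phase2_ms) <= STEP
    assert abs(summary.full_bite_ms - truth.full_bite_ms) <= STEP
    assert abs(summary.cranial_elevation_phase1_deg - truth.cranial_elevation_phase1_deg) < 0.5
    assert abs(summary.cranial_elevation_phase2_deg - truth.cranial_elevation_phase2_deg) < 0.5
    assert abs(summary.pelvic_rotation_phase1_deg - truth.pelvic_rotation_phase1_deg) < 0.5
    assert abs(summary.girdle_change_phase2_deg - truth.girdle_change_phase2_deg) < 0.5
    assert abs(summary.max_imj_flexion_deg - truth.imj_excursion_deg) < 0.5
    assert abs(summary.min_jaw_benthos_mm - truth.min_jaw_benthos_mm) < 0.2
    assert summary.max_imj_flexion_deg >= 0


def test_boundary_recovery_across_seeds():
    """Parameter-recovery property: across 50 noisy bites the mean
    boundary error stays within one sample and no boundary drifts by
    more than two (errors measured against the grid-quantized true
    boundary, since the schedule is continuous in time)."""
    errs = []
    for seed in range(1, 51):
        errs.extend(_boundary_errors(seed, noise=0.05, quantized=True))
    errs = np.array(errs)
    assert errs.mean() <= STEP
    assert errs.max() <= 2 * STEP + 1e-9


def test_noise_monotonically_degrades_boundaries():
    means = []
    for noise in (0.0, 0.05, 0.2):
        errs = []
        for seed in range(1, 21):
            try:
                errs.extend(_boundary_errors(seed, noise))
            except bk.BitekinError:
                errs.append(5 * STEP)
        means.append(np.mean(errs))
    assert means[0] < means[1] < means[2]
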