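"""Detectors, characteristic indices and the firing-type decision logic."""

import numpy as np
import pytest

from motopic import (
    DetectionConfig,
    FiringType,
    RampProtocol,
    SyntheticTraceSpec,
    classify,
    classify_trajectory,
    detect_plateau,
    detect_spikes,
    fi_curve,
    generate_synthetic_trace,
)
from motopic.firing_analysis import characteristic_indices


@pytest.fixture()
def default_cfg():
    return DetectionConfig()


def test_empty_trace_has_no_events(default_cfg):
    traj = generate_synthetic_trace(SyntheticTraceSpec())
    assert len(detect_spikes(traj, default_cfg)) == 0
    assert not detect_plateau(traj, default_cfg).present


@pytest.mark.parametrize(
    "spikes",
    [(100.0, 110.0, 120.0), (1000.0, 1031.4, 1070.0, 2500.0)],
)
def test_spike_detector_recovers_prescribed_times_exactly(spikes, default_cfg):
    """Synthetic pulses are recovered at exactly the prescribed peak times."""
    traj = generate_synthetic_trace(SyntheticTraceSpec(spike_times=spikes))
    got = detect_spikes(traj, default_cfg).spike_times
    assert got == pytest.approx([round(s, 1) for s in spikes], abs=1e-9)


def test_plateau_detector_recovers_prescribed_window(default_cfg):
    traj = generate_synthetic_trace(
        SyntheticTraceSpec(spike_times=(100.0,), plateau=(150.0, 2400.0))
    )
    ev = detect_plateau(traj, default_cfg)
    assert ev.onset_time == pytest.approx(150.0, abs=1e-9)
    assert ev.offset_time == pytest.approx(2400.0, abs=1e-9)


def test_plateau_duration_guard_rejects_brief_excursions(default_cfg):
    """Gate excursions shorter than the minimum duration are not plateaus."""
    traj = generate_synthetic_trace(
        SyntheticTraceSpec(spike_times=(), plateau=(200.0, 205.0))
    )
    assert not detect_plateau(traj, default_cfg).present


def test_ttp_from_prescribed_events(default_cfg):
    """Plateau onset 50 units after the first spike gives TTP = 50."""
    ramp = RampProtocol()
    traj = generate_synthetic_trace(
        SyntheticTraceSpec(
            spike_times=(1000.0, 1030.0, 1060.0, 2000.0),
            plateau=(1050.0, 3000.0),
            ramp=ramp,
        )
    )
    spikes = detect_spikes(traj, default_cfg)
    plateau = detect_plateau(traj, default_cfg)
    ci = characteristic_indices(spikes, plateau, traj, ramp, default_cfg)
    assert ci.ttp == pytest.approx(50.0, abs=1e-9)


def test_tes_zero_when_last_spike_at_descending_crossing(default_cfg):
    """A train ending exactly at the descending recruitment crossing has TES = 0.

    With the symmetric default triangle, the crossing mirrors the first spike
    about the ramp apex.
    """
    ramp = RampProtocol()
    first = 1200.0
    t_cross = 2 * ramp.t_peak - first
    traj = generate_synthetic_trace(
        SyntheticTraceSpec(spike_times=(first, 1230.0, 1260.0, t_cross), ramp=ramp)
    )
    spikes = detect_spikes(traj, default_cfg)
    ci = characteristic_indices(
        spikes, detect_plateau(traj, default_cfg), traj, ramp, default_cfg
    )
    assert ci.tes == pytest.approx(0.0, abs=1e-6)


def test_sustained_synthetic_train_classifies_by_decision_table(default_cfg):
    """Last spike far past the crossing with a plateau from the first spike -> III."""
    ramp = RampProtocol()
    first = 1200.0
    spikes = tuple(np.arange(first, 3100.0, 25.0))
    traj = generate_synthetic_trace(
        SyntheticTraceSpec(spike_times=spikes, plateau=(1200.0, 3200.0), ramp=ramp)
    )
    ci = classify_trajectory(traj, ramp, default_cfg)
    assert ci.tes > default_cfg.tol_time  # sustained well past the crossing
    assert ci.firing_type == FiringType.III


def test_overlapping_spikes_rejected():
    with pytest.raises(ValueError):
        generate_synthetic_trace(SyntheticTraceSpec(spike_times=(100.0, 100.5)))
    with pytest.raises(ValueError):
        generate_synthetic_trace(SyntheticTraceSpec(spike_times=(100.0,), plateau=(500.0, 400.0)))


def test_decision_logic_mapping():
    """The label map honours the plateau-led decision table."""
    # no spikes
    assert classify((0, 0, 0), False, False) == (FiringType.NONPHYSIOLOGICAL, False)
    # no plateau: I unless firing dies well before the crossing
    assert classify((0, 0, 0), False, True) == (FiringType.I, False)
    assert classify((0, -1, -1), False, True) == (FiringType.II, False)
    # plateau at/before recruitment: III
    assert classify((0, 0, 1), True, True) == (FiringType.III, False)
    # delayed plateau: IV, full when sustained, partial otherwise
    assert classify((1, 1, 1), True, True) == (FiringType.IV_FULL, False)
    assert classify((1, 1, 1), True, True, plateau_early_offset=True) == (
        FiringType.IV_PARTIAL,
        False,
    )
    assert classify((1, 1, -1), True, True) == (FiringType.IV_PARTIAL, False)


def test_fi_curve_limbs_and_frequencies(default_cfg):
    ramp = RampProtocol()
    spikes = (1000.0, 1020.0, 1040.0, 2900.0, 2925.0)
    traj = generate_synthetic_trace(SyntheticTraceSpec(spike_times=spikes, ramp=ramp))
    curve = fi_curve(detect_spikes(traj, default_cfg), traj, ramp)
    assert len(curve.frequency) == 4
    assert curve.frequency[0] == pytest.approx(1 / 20.0)
    assert list(curve.limb[:2]) == ["ascending", "ascending"]
    assert list(curve.limb[-2:]) == ["descending", "descending"]
    assert np.all(curve.frequency > 0)


def test_noise_does_not_break_detection(default_cfg):
    """Seeded subthreshold noise leaves prominence-based detection exact."""
    spec = SyntheticTraceSpec(
        spike_times=(800.0, 900.0), noise_amplitude=0.02, seed=42
    )
    traj = generate_synthetic_trace(spec)
    got = detect_spikes(traj, default_cfg).spike_times
    assert len(got) == 2
    assert got == pytest.approx([800.0, 900.0], abs=0.2)
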