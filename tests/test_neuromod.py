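"""Neuromodulation scalings, PIC metrics under voltage clamp, robustness curve."""

import numpy as np
import pytest

from motopic import (
    ActiveParameters,
    NeuromodSetting,
    VAFactors,
    VClampProtocol,
    apply_neuromod,
    enhanced_simultaneous,
    invert_cable_parameters,
    pic_metrics,
    reduced_simultaneous,
    robustness_curve,
    simulate_vclamp,
    single_parameter,
)


def test_identity_and_simultaneous_arithmetic(active):
    assert apply_neuromod(active, NeuromodSetting()) == active
    up = apply_neuromod(active, enhanced_simultaneous())
    assert (up.g_ca, up.v1d, up.v2d) == pytest.approx((0.979, 0.063, 0.11))
    down = apply_neuromod(active, reduced_simultaneous())
    assert (down.g_ca, down.v1d, down.v2d) == pytest.approx((0.801, 0.077, 0.09))


def test_single_parameter_arithmetic(active):
    hi = apply_neuromod(active, single_parameter("single_gca", +0.2))
    lo = apply_neuromod(active, single_parameter("single_gca", -0.2))
    assert hi.g_ca == pytest.approx(1.068)
    assert lo.g_ca == pytest.approx(0.712)
    assert (hi.v1d, hi.v2d) == (active.v1d, active.v2d)


def test_nonpositive_v2d_rejected(active):
    with pytest.raises(ValueError):
        apply_neuromod(active, NeuromodSetting(delta_v2d=-1.0))
    with pytest.raises(ValueError):
        NeuromodSetting(delta_gca=1.5)
    with pytest.raises(ValueError):
        single_parameter("bogus", 0.1)


@pytest.fixture(scope="module")
def pic_runs(sysp, active):
    """Voltage-clamp PIC traces for default and scaled activation parameters."""
    cable = invert_cable_parameters(sysp, VAFactors(0.94, 0.38, 0.69))
    vc = VClampProtocol()
    runs = {}
    for name, setting in [
        ("default", NeuromodSetting()),
        ("gca_up", NeuromodSetting(delta_gca=+0.2)),
        ("gca_down", NeuromodSetting(delta_gca=-0.2)),
        ("sim_up", enhanced_simultaneous()),
        ("sim_down", reduced_simultaneous()),
    ]:
        a = apply_neuromod(active, setting)
        traj, pic = simulate_vclamp(cable, sysp, a, vc)
        runs[name] = (traj, pic)
    return runs, vc


def test_pic_metrics_orderings(pic_runs):
    """Excitatory scaling lowers the PIC onset voltage and raises its peak."""
    runs, vc = pic_runs
    thr = 0.01 * np.abs(runs["default"][1]).max()
    m = {k: pic_metrics(pic, traj.t, vc, thr) for k, (traj, pic) in runs.items()}
    assert m["gca_up"].onset_voltage < m["default"].onset_voltage < m["gca_down"].onset_voltage
    assert m["gca_up"].peak_amplitude > m["default"].peak_amplitude > m["gca_down"].peak_amplitude
    assert m["sim_up"].onset_voltage < m["default"].onset_voltage < m["sim_down"].onset_voltage
    assert m["sim_up"].peak_amplitude > m["default"].peak_amplitude > m["sim_down"].peak_amplitude


def test_pic_metrics_absent_when_blocked(pic_runs, sysp, active):
    runs, vc = pic_runs
    traj, _ = runs["default"]
    assert pic_metrics(np.zeros_like(traj.i_s), traj.t, vc, 0.01) is None


def test_robustness_curve_contract(sysp, active, ramp, detection):
    """Normalisation is 1 at delta = 0 and the input must contain the baseline."""
    curve = robustness_curve(
        [-0.2, 0.0], mode="single_gca", step=50.0,
        sys=sysp, active=active, ramp=ramp, config=detection,
    )
    assert curve.valid
    i0 = int(np.argmin(np.abs(curve.deltas)))
    assert curve.normalized[i0] == 1.0
    with pytest.raises(ValueError):
        robustness_curve([0.1, 0.2], mode="single_gca")
    with pytest.raises(ValueError):
        robustness_curve([0.0], mode="bogus")
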