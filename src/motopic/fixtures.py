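"""Synthetic trajectory generator for exercising detectors without ODE runs.

Builds a :class:`~motopic.dynamics.StateTrajectory` with stereotyped
spike-shaped pulses on the somatic voltage at prescribed times and a square
plateau window on the PIC gate, so spike/plateau detectors and the
characteristic-index pipeline can be tested against known ground truth.
Prescribed event times are quantised to the output grid so that the
piecewise-linear pulses are sampled exactly and detector recovery is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import RampProtocol, StateTrajectory

__all__ = ["SyntheticTraceSpec", "generate_synthetic_trace"]

REST = -0.5
SPIKE_PEAK = 0.5
#: half-width of the triangular spike pulse, in time units
SPIKE_HALF_WIDTH = 0.5


@dataclass
class SyntheticTraceSpec:
    """Prescription for one synthetic trajectory.

    ``spike_times`` are the desired upward zero-crossing times of the somatic
    voltage; ``plateau`` is an optional (onset, offset) window during which
    the PIC gate sits at 1.  ``noise_amplitude`` adds seeded Gaussian noise
    to the subthreshold voltage only (never near pulses), for robustness
    checks of the detectors.
    """

    spike_times: tuple[float, ...] = ()
    plateau: tuple[float, float] | None = None
    ramp: RampProtocol = field(default_factory=RampProtocol)
    dt: float = 0.1
    noise_amplitude: float = 0.0
    seed: int = 0
    min_isi: float = 2.0


def generate_synthetic_trace(spec: SyntheticTraceSpec) -> StateTrajectory:
    """Emit a trajectory whose detected events equal the prescribed ones.

    Raises ``ValueError`` for spike times outside the protocol window, spikes
    closer than ``min_isi``, or an inverted plateau window.
    """
    ramp = spec.ramp
    dt = spec.dt
    t = np.arange(0.0, ramp.t_end + dt / 2, dt)
    n = len(t)

    spikes = np.round(np.asarray(sorted(spec.spike_times), float) / dt) * dt
    if spikes.size:
        if spikes[0] < 0 or spikes[-1] > ramp.t_end:
            raise ValueError("spike times outside the protocol window")
        if np.any(np.diff(spikes) < spec.min_isi):
            raise ValueError("spikes closer than the minimum inter-spike interval")

    v_s = np.full(n, REST)
    if spec.noise_amplitude > 0:
        rng = np.random.default_rng(spec.seed)
        v_s += spec.noise_amplitude * rng.standard_normal(n)

    # Symmetric triangular pulse with its apex exactly at the prescribed
    # time, so peak-based detection recovers the time without bias.
    w = SPIKE_HALF_WIDTH
    for s in spikes:
        seg = (t >= s - 2 * w) & (t <= s + 2 * w)
        v_s[seg] = SPIKE_PEAK - (SPIKE_PEAK - REST) * np.abs(t[seg] - s) / (2 * w)

    m_d = np.zeros(n)
    v_d = np.full(n, REST)
    if spec.plateau is not None:
        onset, offset = spec.plateau
        if not 0 <= onset < offset <= ramp.t_end:
            raise ValueError("plateau window must satisfy 0 <= onset < offset <= t_end")
        onset = round(onset / dt) * dt
        offset = round(offset / dt) * dt
        inside = (t >= onset - dt / 4) & (t < offset - dt / 4)
        m_d[inside] = 1.0
        v_d[inside] = 0.3

    i_s = np.asarray(ramp.current(t), float)
    return StateTrajectory(
        t=t, v_s=v_s, v_d=v_d,
        n_s=np.zeros(n), m_d=m_d, n_d=np.zeros(n),
        i_s=i_s, valid=True,
    )
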