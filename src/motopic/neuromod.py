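"""Neuromodulation of the dendritic PIC and Type IV robustness analysis.

Monoaminergic neuromodulation (serotonin, norepinephrine) facilitates the
dendritic L-type calcium PIC.  It is modelled as fractional scalings of the
three activation parameters: the maximal conductance ``g_ca``, the
half-activation voltage ``v1d`` and the reciprocal activation slope ``v2d``.
The excitatory (PIC-facilitating) direction is ``g_ca`` up, ``v1d`` down
(leftward shift of the activation curve) and ``v2d`` up; the inhibitory
direction is the opposite.

Two read-outs are provided: PIC onset/amplitude metrics under somatic
voltage clamp (:func:`pic_metrics`) and the number of points in the VA space
that still produce fully hysteretic Type IV firing as the scalings vary
(:func:`robustness_curve`).  The robustness count defaults to the
physiological points — dendritic PIC locations mapped into VA space by the
exponential-decay curves — because that is the set whose Type IV membership
collapses under either direction of neuromodulation; a whole-cube variant is
available (on the full cube the Type IV volume shifts rather than vanishes).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .anatomy_map import distance_scan
from .cable_core import SystemProperties
from .dynamics import ActiveParameters, RampProtocol, VClampProtocol
from .firing_analysis import DetectionConfig, FiringType
from .va_space import count_type_iv, sweep_va_space

__all__ = [
    "NeuromodSetting",
    "PICMetrics",
    "RobustnessCurve",
    "apply_neuromod",
    "enhanced_simultaneous",
    "reduced_simultaneous",
    "single_parameter",
    "pic_metrics",
    "robustness_curve",
]

MODES = ("single_gca", "single_v1d", "single_v2d", "simultaneous")


@dataclass(frozen=True)
class NeuromodSetting:
    """Fractional changes applied to the PIC activation parameters.

    ``delta_gca=+0.2`` means a 20% increase of ``g_ca``, and so on.  The
    convenience constructors encode the directional conventions used
    throughout: *enhanced* = (g_ca up, v1d down, v2d up).
    """

    delta_gca: float = 0.0
    delta_v1d: float = 0.0
    delta_v2d: float = 0.0

    def __post_init__(self) -> None:
        for name in ("delta_gca", "delta_v1d", "delta_v2d"):
            if not -1.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} outside [-1, 1]")


def enhanced_simultaneous(magnitude: float = 0.10) -> NeuromodSetting:
    """Simultaneous excitatory setting: g_ca and v2d up, v1d down."""
    return NeuromodSetting(delta_gca=+magnitude, delta_v1d=-magnitude, delta_v2d=+magnitude)


def reduced_simultaneous(magnitude: float = 0.10) -> NeuromodSetting:
    """Simultaneous inhibitory setting: g_ca and v2d down, v1d up."""
    return NeuromodSetting(delta_gca=-magnitude, delta_v1d=+magnitude, delta_v2d=-magnitude)


def single_parameter(mode: str, delta: float) -> NeuromodSetting:
    """Setting that scales one activation parameter by ``delta``."""
    if mode == "single_gca":
        return NeuromodSetting(delta_gca=delta)
    if mode == "single_v1d":
        return NeuromodSetting(delta_v1d=delta)
    if mode == "single_v2d":
        return NeuromodSetting(delta_v2d=delta)
    raise ValueError(f"unknown single-parameter mode {mode!r}")


def apply_neuromod(active: ActiveParameters, setting: NeuromodSetting) -> ActiveParameters:
    """Return a copy of ``active`` with the PIC activation parameters scaled."""
    v2d = active.v2d * (1.0 + setting.delta_v2d)
    if v2d <= 0:
        raise ValueError("neuromodulation would make v2d nonpositive")
    return replace(
        active,
        g_ca=active.g_ca * (1.0 + setting.delta_gca),
        v1d=active.v1d * (1.0 + setting.delta_v1d),
        v2d=v2d,
    )


@dataclass
class PICMetrics:
    """PIC activation metrics measured at the soma under voltage clamp.

    ``onset_voltage`` is the ascending command voltage at which the PIC
    magnitude first exceeds the detection threshold; ``peak_amplitude`` is
    the maximum PIC magnitude on the ascending command.
    """

    onset_voltage: float
    peak_amplitude: float


def pic_metrics(
    i_pic: np.ndarray,
    t: np.ndarray,
    vclamp: VClampProtocol,
    threshold: float,
) -> PICMetrics | None:
    """Extract onset voltage and peak magnitude from a PIC trace.

    ``threshold`` is an absolute current magnitude (callers typically use a
    small fraction of the default-condition peak).  Returns None when the PIC
    never exceeds the threshold on the ascending command.
    """
    v_cmd = vclamp.command(t)
    ascending = (t >= vclamp.pre_relax) & (t <= vclamp.pre_relax + vclamp.duration / 2)
    mag = np.abs(i_pic)
    idx = np.nonzero(ascending & (mag > threshold))[0]
    if idx.size == 0:
        return None
    onset_v = float(v_cmd[idx[0]])
    peak = float(mag[ascending].max())
    return PICMetrics(onset_voltage=onset_v, peak_amplitude=peak)


@dataclass
class RobustnessCurve:
    """Type IV point counts over a range of neuromodulation strengths.

    ``normalized`` is the count divided by the count at delta = 0; the curve
    is flagged invalid when the baseline count is zero.  ``basis`` records
    whether points were counted along the physiological VA curve
    ("locations") or over the whole VA cube ("cube").
    """

    deltas: np.ndarray
    counts: np.ndarray
    normalized: np.ndarray
    mode: str
    basis: str
    resolution: float
    valid: bool = True

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"delta": self.deltas, "count": self.counts, "normalized": self.normalized}
        )


def _setting_for(mode: str, delta: float) -> NeuromodSetting:
    if mode == "simultaneous":
        # sign convention: positive delta = excitatory direction
        return NeuromodSetting(delta_gca=delta, delta_v1d=-delta, delta_v2d=delta)
    return single_parameter(mode, delta)


def robustness_curve(
    deltas,
    mode: str = "single_gca",
    basis: str = "locations",
    step: float = 5.0,
    resolution: int = 15,
    sys: SystemProperties | None = None,
    active: ActiveParameters | None = None,
    ramp: RampProtocol | None = None,
    config: DetectionConfig | None = None,
    progress: bool = False,
) -> RobustnessCurve:
    """Count fully hysteretic Type IV points at every neuromodulation delta.

    ``deltas`` must contain 0 (the normalisation baseline).  For
    ``mode="simultaneous"`` a positive delta applies (+d, -d, +d) to
    (g_ca, v1d, v2d) jointly, i.e. the excitatory direction.

    ``basis="locations"`` (default) counts points along the mean
    physiological VA curve sampled every ``step`` micrometres over
    [0, 2000] — the dendritic PIC locations; ``basis="cube"`` counts points
    of a ``resolution^3`` sweep of the whole VA cube.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if basis not in ("locations", "cube"):
        raise ValueError("basis must be 'locations' or 'cube'")
    deltas = np.asarray(sorted(deltas), float)
    if not np.any(np.isclose(deltas, 0.0)):
        raise ValueError("deltas must include 0 (baseline)")
    sys = sys or SystemProperties()
    active = active or ActiveParameters()
    ramp = ramp or RampProtocol()
    config = config or DetectionConfig()

    counts = np.empty(len(deltas), dtype=int)
    for i, d in enumerate(deltas):
        scaled = apply_neuromod(active, _setting_for(mode, float(d)))
        if basis == "locations":
            scan = distance_scan(sys, scaled, ramp, step=step, config=config)
            counts[i] = int(np.sum(scan.labels == FiringType.IV_FULL))
        else:
            grid = sweep_va_space(resolution, sys, scaled, ramp, config)
            counts[i] = count_type_iv(grid)
        if progress:
            print(f"  delta={d:+.2f}: {counts[i]} Type IV points")

    base = counts[np.argmin(np.abs(deltas))]
    valid = base > 0
    normalized = counts / base if valid else np.full(len(deltas), np.nan)
    return RobustnessCurve(
        deltas=deltas, counts=counts, normalized=normalized,
        mode=mode, basis=basis,
        resolution=step if basis == "locations" else resolution,
        valid=valid,
    )
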