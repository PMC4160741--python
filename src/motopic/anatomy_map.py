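"""Mapping dendritic path distance to voltage attenuation and firing type.

In real motoneurons the three VA factors are not free parameters: they all
equal 1 at the soma and decay roughly exponentially with path distance
``d_path`` along the dendrite, at rates that depend on signal direction and
frequency.  The decay constants ``eta`` (one per reconstructed cell and VA
factor, in micrometres) were obtained from single-exponential fits
``exp(-d_path/eta)`` to attenuation measured in five anatomically
reconstructed motoneurons; the mean over cells of those five exponentials
defines the physiological VA curve used here.  Scanning that curve and
classifying each point locates the dendritic PIC positions that produce each
firing type, in particular the fully hysteretic Type IV distance interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cable_core import SystemProperties, VAFactors, invert_cable_parameters
from .dynamics import ActiveParameters, RampProtocol, simulate_ramp
from .firing_analysis import DetectionConfig, FiringType, classify_trajectory

__all__ = [
    "EtaProfile",
    "DistanceScan",
    "physiological_va",
    "distance_scan",
    "type_iv_distance_range",
]


@dataclass(frozen=True)
class EtaProfile:
    """Exponential decay constants (micrometres) of the three VA factors.

    Five values per factor, one per reconstructed motoneuron.
    """

    eta_sd_dc: tuple[float, ...] = (2680.6, 3059.5, 2758.0, 1941.0, 2145.8)
    eta_ds_dc: tuple[float, ...] = (224.2, 144.7, 119.5, 143.9, 190.8)
    eta_sd_ac: tuple[float, ...] = (420.1, 437.1, 402.3, 373.1, 464.7)

    def __post_init__(self) -> None:
        for name in ("eta_sd_dc", "eta_ds_dc", "eta_sd_ac"):
            vals = getattr(self, name)
            if len(vals) != 5 or any(v <= 0 for v in vals):
                raise ValueError(f"{name} must hold five positive decay constants")


@dataclass
class DistanceScan:
    """Ordered per-distance records of VA triple, firing type and CIs."""

    d_path: np.ndarray
    va_sd_dc: np.ndarray
    va_ds_dc: np.ndarray
    va_sd_ac: np.ndarray
    labels: np.ndarray
    ttp: np.ndarray
    tes: np.ndarray
    dsf: np.ndarray
    metadata: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "d_path": self.d_path,
                "va_sd_dc": self.va_sd_dc,
                "va_ds_dc": self.va_ds_dc,
                "va_sd_ac": self.va_sd_ac,
                "firing_type": self.labels,
                "ttp": self.ttp,
                "tes": self.tes,
                "dsf": self.dsf,
            }
        )


def physiological_va(d_path: float, etas: EtaProfile | None = None) -> VAFactors:
    """Mean physiological VA triple at path distance ``d_path`` (micrometres).

    Each factor is the mean over the five cells of ``exp(-d_path/eta_j)`` —
    the mean of the per-cell exponential curves, not the exponential of the
    mean decay constant.  At ``d_path = 0`` all three factors equal 1.
    """
    if d_path < 0:
        raise ValueError("d_path must be nonnegative")
    etas = etas or EtaProfile()
    vals = [
        float(np.mean(np.exp(-d_path / np.asarray(e))))
        for e in (etas.eta_sd_dc, etas.eta_ds_dc, etas.eta_sd_ac)
    ]
    return VAFactors(va_sd_dc=vals[0], va_ds_dc=vals[1], va_sd_ac=vals[2])


def distance_scan(
    sys: SystemProperties | None = None,
    active: ActiveParameters | None = None,
    ramp: RampProtocol | None = None,
    d_min: float = 0.0,
    d_max: float = 2000.0,
    step: float = 5.0,
    config: DetectionConfig | None = None,
    etas: EtaProfile | None = None,
) -> DistanceScan:
    """Classify the model along the mean physiological VA curve.

    For every distance on the grid the VA triple is computed from the
    exponential fits, inverted to cable parameters, simulated under the ramp
    and classified; distances with an invalid inversion or a failed solve
    yield nonphysiological records.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    sys = sys or SystemProperties()
    active = active or ActiveParameters()
    ramp = ramp or RampProtocol()
    config = config or DetectionConfig()
    etas = etas or EtaProfile()

    ds = np.arange(d_min, d_max + step / 2, step)
    n = len(ds)
    vas = np.empty((n, 3))
    labels = np.full(n, FiringType.NONPHYSIOLOGICAL, dtype=object)
    ttp = np.full(n, np.nan)
    tes = np.full(n, np.nan)
    dsf = np.full(n, np.nan)

    for i, d in enumerate(ds):
        va = physiological_va(float(d), etas)
        vas[i] = va.as_tuple()
        cable = invert_cable_parameters(sys, va)
        if not cable.valid:
            continue
        traj = simulate_ramp(cable, sys, active, ramp)
        if not traj.valid:
            continue
        ci = classify_trajectory(traj, ramp, config)
        labels[i] = ci.firing_type
        ttp[i], tes[i], dsf[i] = ci.ttp, ci.tes, ci.dsf

    return DistanceScan(
        d_path=ds,
        va_sd_dc=vas[:, 0], va_ds_dc=vas[:, 1], va_sd_ac=vas[:, 2],
        labels=labels, ttp=ttp, tes=tes, dsf=dsf,
        metadata={
            "step": step,
            "ramp": (ramp.peak, ramp.duration, ramp.pre_relax),
            "g_ca": active.g_ca, "v1d": active.v1d, "v2d": active.v2d,
        },
    )


def type_iv_distance_range(scan: DistanceScan) -> dict | None:
    """Distance interval of fully hysteretic Type IV firing, or None.

    Returns the smallest and largest labelled distance, the range length and
    whether the labelled set is contiguous on the scan grid.
    """
    mask = scan.labels == FiringType.IV_FULL
    if not mask.any():
        return None
    d = scan.d_path[mask]
    idx = np.nonzero(mask)[0]
    contiguous = bool(np.all(np.diff(idx) == 1))
    return {
        "d_low": float(d.min()),
        "d_high": float(d.max()),
        "length": float(d.max() - d.min()),
        "contiguous": contiguous,
        "n_points": int(mask.sum()),
    }
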