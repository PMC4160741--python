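"""Firing-type labelling over the three-dimensional voltage-attenuation cube.

Every point of a uniform grid over (va_ds_dc, va_sd_dc, va_sd_ac) in
[0,1]^3 is inverted to cable parameters; points with no real, positive
solution are nonphysiological without simulation, the rest are simulated
under the triangular ramp and classified.  The resulting label volume is the
coordinate system in which PIC-location and neuromodulation effects are
measured (region fractions, Type IV point counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cable_core import CableParameters, SystemProperties, invert_va_arrays
from .dynamics import ActiveParameters, RampProtocol, simulate_ramp
from .firing_analysis import DetectionConfig, FiringType, classify_trajectory

__all__ = ["VAGrid", "sweep_va_space", "type_fractions", "count_type_iv"]


@dataclass
class VAGrid:
    """Labelled sweep of the VA cube.

    Axis order of the label array is (va_ds_dc, va_sd_dc, va_sd_ac).
    ``ttp/tes/dsf`` hold the raw characteristic indices (NaN where the point
    was not simulated).  ``metadata`` records the resolution, protocol and
    tolerances plus the number of solver failures.
    """

    va_ds_dc: np.ndarray
    va_sd_dc: np.ndarray
    va_sd_ac: np.ndarray
    labels: np.ndarray
    ttp: np.ndarray
    tes: np.ndarray
    dsf: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def n_points(self) -> int:
        return self.labels.size

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table with one row per grid point."""
        X, Y, Z = np.meshgrid(
            self.va_ds_dc, self.va_sd_dc, self.va_sd_ac, indexing="ij"
        )
        return pd.DataFrame(
            {
                "va_ds_dc": X.ravel(),
                "va_sd_dc": Y.ravel(),
                "va_sd_ac": Z.ravel(),
                "firing_type": self.labels.ravel(),
                "ttp": self.ttp.ravel(),
                "tes": self.tes.ravel(),
                "dsf": self.dsf.ravel(),
            }
        )

    def nearest_label(self, va_sd_dc: float, va_ds_dc: float, va_sd_ac: float) -> str:
        """Label of the grid point nearest to the given VA triple."""
        i = int(np.argmin(np.abs(self.va_ds_dc - va_ds_dc)))
        j = int(np.argmin(np.abs(self.va_sd_dc - va_sd_dc)))
        k = int(np.argmin(np.abs(self.va_sd_ac - va_sd_ac)))
        return str(self.labels[i, j, k])


def sweep_va_space(
    resolution: int = 21,
    sys: SystemProperties | None = None,
    active: ActiveParameters | None = None,
    ramp: RampProtocol | None = None,
    config: DetectionConfig | None = None,
    progress: bool = False,
) -> VAGrid:
    """Label every point of a ``resolution^3`` grid over the VA cube.

    The grid is cell-centered (points at ``(i + 1/2)/resolution``): each point
    represents an equal-volume cell of the cube, so label counts estimate
    region volume fractions without overweighting the degenerate cube faces
    (the VA factors 0 and 1 are singular inputs of the inversion).  The sweep
    is deterministic and its output is independent of evaluation order.
    """
    if resolution < 2:
        raise ValueError("resolution must be at least 2")
    sys = sys or SystemProperties()
    active = active or ActiveParameters()
    ramp = ramp or RampProtocol()
    config = config or DetectionConfig()

    ax = (np.arange(resolution) + 0.5) / resolution
    ADS, ASD, AAC = np.meshgrid(ax, ax, ax, indexing="ij")
    inv = invert_va_arrays(sys, ASD, ADS, AAC)

    labels = np.full(ADS.shape, FiringType.NONPHYSIOLOGICAL, dtype=object)
    ttp = np.full(ADS.shape, np.nan)
    tes = np.full(ADS.shape, np.nan)
    dsf = np.full(ADS.shape, np.nan)

    idx_valid = np.argwhere(inv["valid"])
    n_failures = 0
    for count, (i, j, k) in enumerate(idx_valid):
        cable = CableParameters(
            g_ms=inv["g_ms"][i, j, k],
            g_md=inv["g_md"][i, j, k],
            g_c=inv["g_c"][i, j, k],
            c_ms=inv["c_ms"][i, j, k],
            c_md=inv["c_md"][i, j, k],
        )
        traj = simulate_ramp(cable, sys, active, ramp)
        if not traj.valid:
            n_failures += 1
            continue
        ci = classify_trajectory(traj, ramp, config)
        labels[i, j, k] = ci.firing_type
        ttp[i, j, k] = ci.ttp
        tes[i, j, k] = ci.tes
        dsf[i, j, k] = ci.dsf
        if progress and (count + 1) % 500 == 0:
            print(f"  swept {count + 1}/{len(idx_valid)} valid points")

    return VAGrid(
        va_ds_dc=ax, va_sd_dc=ax, va_sd_ac=ax,
        labels=labels, ttp=ttp, tes=tes, dsf=dsf,
        metadata={
            "resolution": resolution,
            "n_invalid_inversion": int((~inv["valid"]).sum()),
            "n_solver_failures": n_failures,
            "ramp": (ramp.peak, ramp.duration, ramp.pre_relax),
            "tolerances": (config.tol_time, config.tol_freq_frac),
            "g_ca": active.g_ca, "v1d": active.v1d, "v2d": active.v2d,
        },
    )


def type_fractions(grid: VAGrid) -> dict[str, float]:
    """Percentage of grid points per firing type (sums to 100)."""
    total = grid.n_points
    out = {}
    flat = grid.labels.ravel()
    for ft in FiringType.ALL:
        out[ft] = 100.0 * float(np.sum(flat == ft)) / total
    return out


def count_type_iv(grid: VAGrid) -> int:
    """Number of fully hysteretic Type IV points (robustness normalisation basis)."""
    return int(np.sum(grid.labels.ravel() == FiringType.IV_FULL))
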