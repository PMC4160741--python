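"""Analytic mapping between system properties and two-compartment cable parameters.

A reduced motoneuron model with one somatic and one dendritic compartment is
fully determined by five passive cable parameters: the specific membrane
conductances ``G_m,S`` and ``G_m,D``, the specific capacitances ``C_m,S`` and
``C_m,D`` (each normalised to the respective compartment's membrane area), and
the coupling conductance ``G_C``.  These five parameters are in one-to-one
correspondence with five measurable *system properties* of the full
anatomical cell:

* ``r_N`` — input resistance normalised to somatic area,
* ``tau_m`` — the slowest (system) membrane time constant,
* three voltage-attenuation (VA) factors between soma and dendrite:
  ``VA_SD^DC`` (soma-to-dendrite, steady state), ``VA_DS^DC``
  (dendrite-to-soma, steady state) and ``VA_SD^AC`` (soma-to-dendrite at the
  dominant spectral frequency ``omega`` of an action potential).

:func:`invert_cable_parameters` evaluates the closed-form inversion from
(system properties, VA factors) to cable parameters;
:func:`forward_system_properties` is the independent forward circuit
computation used to verify the inversion (round-trip identity).
All quantities are dimensionless; time is measured in model time units.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SystemProperties",
    "VAFactors",
    "CableParameters",
    "InvalidReason",
    "invert_cable_parameters",
    "forward_system_properties",
    "invert_va_arrays",
]

#: Threshold below which the inversion denominator 1 - va_sd_dc*va_ds_dc (or a
#: VA factor appearing alone in a denominator) is treated as degenerate.
DEGENERACY_EPS = 1e-12


class InvalidReason:
    """Enumerated reasons an inversion can fail to give a physical model."""

    NONE = "none"
    NONPOSITIVE_CONDUCTANCE = "nonpositive_conductance"
    CMD_NOT_REAL = "cmd_not_real"
    CMS_NOT_REAL_OR_NONPOSITIVE = "cms_not_real_or_nonpositive"
    DEGENERATE_INPUT = "degenerate_input"


@dataclass(frozen=True)
class SystemProperties:
    """Global constants tying the reduced model to the anatomical cell.

    Parameters
    ----------
    r_n
        Input resistance normalised to somatic membrane area (dimensionless).
    tau_m
        System membrane time constant, in model time units.
    p
        Ratio of somatic to total membrane area, ``0 < p < 1``.
    omega
        Angular frequency of the dominant spectral component of an action
        potential, in radians per model time unit.  The default corresponds
        to 250 Hz with the model time unit read as one millisecond.
    """

    r_n: float = 0.198
    tau_m: float = 10.4
    p: float = 0.168
    omega: float = 2.0 * math.pi * 0.25

    def __post_init__(self) -> None:
        if not (self.r_n > 0 and self.tau_m > 0 and self.omega > 0):
            raise ValueError("r_n, tau_m and omega must be positive")
        if not 0.0 < self.p < 1.0:
            raise ValueError("p must lie strictly between 0 and 1")


@dataclass(frozen=True)
class VAFactors:
    """Triple of voltage-attenuation ratios, each in [0, 1].

    ``va_sd_dc`` and ``va_ds_dc`` are the steady-state soma-to-dendrite and
    dendrite-to-soma attenuations; ``va_sd_ac`` is the soma-to-dendrite
    attenuation at angular frequency ``omega``.
    """

    va_sd_dc: float
    va_ds_dc: float
    va_sd_ac: float

    def __post_init__(self) -> None:
        for name in ("va_sd_dc", "va_ds_dc", "va_sd_ac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v!r} outside [0, 1]")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.va_sd_dc, self.va_ds_dc, self.va_sd_ac)


@dataclass(frozen=True)
class CableParameters:
    """The five passive parameters of the reduced model plus a validity flag.

    ``valid`` is True only when all five parameters are strictly positive and
    finite; otherwise ``invalid_reason`` names the first failure encountered.
    """

    g_ms: float
    g_md: float
    g_c: float
    c_ms: float
    c_md: float
    valid: bool = True
    invalid_reason: str = InvalidReason.NONE

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.g_ms, self.g_md, self.g_c, self.c_ms, self.c_md)


def _invalid(reason: str) -> CableParameters:
    nan = float("nan")
    return CableParameters(nan, nan, nan, nan, nan, valid=False, invalid_reason=reason)


def invert_cable_parameters(sys: SystemProperties, va: VAFactors) -> CableParameters:
    """Closed-form inversion from system properties and VA factors to cable parameters.

    The conductances follow from the DC attenuation ratios and the input
    resistance; the dendritic capacitance follows from the AC attenuation at
    ``omega``; the somatic capacitance is fixed by requiring that the slowest
    eigenvalue of the passive two-compartment system equals ``-1/tau_m``.

    Degenerate inputs (``va_sd_dc * va_ds_dc = 1``, or a zero VA factor that
    appears alone in a denominator) and non-real or non-positive solutions
    return ``valid=False`` with a matching ``invalid_reason``; no exception is
    raised for in-domain input.
    """
    a_sd, a_ds, a_ac = va.as_tuple()
    r_n, tau, p = sys.r_n, sys.tau_m, sys.p

    den = 1.0 - a_sd * a_ds
    if abs(den) < DEGENERACY_EPS or a_sd < DEGENERACY_EPS or a_ac < DEGENERACY_EPS:
        return _invalid(InvalidReason.DEGENERATE_INPUT)

    g_ms = (1.0 - a_ds) / (r_n * den)
    g_md = p * a_ds * (1.0 - a_sd) / ((1.0 - p) * r_n * a_sd * den)
    g_c = p * a_ds / (r_n * den)
    if not (g_ms > 0 and g_md > 0 and g_c > 0) or not all(
        map(math.isfinite, (g_ms, g_md, g_c))
    ):
        return _invalid(InvalidReason.NONPOSITIVE_CONDUCTANCE)

    radicand = (g_c / a_ac) ** 2 - (g_c + (1.0 - p) * g_md) ** 2
    if radicand <= 0.0:
        return _invalid(InvalidReason.CMD_NOT_REAL)
    c_md = math.sqrt(radicand) / (sys.omega * (1.0 - p))

    num = (
        p * (1.0 - p) * tau * g_ms * g_md
        + p * g_ms * (tau * g_c - c_md)
        + p * p * g_ms * c_md
        + (1.0 - p) * (tau * g_c * g_md - g_c * c_md)
    )
    den_cms = p * ((1.0 - p) * (tau * g_md - c_md) + tau * g_c)
    if abs(den_cms) < DEGENERACY_EPS:
        return _invalid(InvalidReason.CMS_NOT_REAL_OR_NONPOSITIVE)
    c_ms = tau * num / den_cms
    if not (c_ms > 0 and math.isfinite(c_ms)):
        return _invalid(InvalidReason.CMS_NOT_REAL_OR_NONPOSITIVE)

    # The closed form pins one eigenvalue of the passive system at -1/tau_m;
    # a somatic capacitance that realises tau_m as the SYSTEM (slowest) time
    # constant only exists when the other eigenvalue is at least as fast.
    a11 = -(g_ms + g_c / p) / c_ms
    a22 = -(g_md + g_c / (1.0 - p)) / c_md
    lam_other = (a11 + a22) + 1.0 / tau  # trace = lam1 + lam2
    if lam_other > -1.0 / tau * (1.0 + 1e-9):
        return _invalid(InvalidReason.CMS_NOT_REAL_OR_NONPOSITIVE)

    return CableParameters(g_ms, g_md, g_c, c_ms, c_md)


def forward_system_properties(
    cable: CableParameters, sys: SystemProperties
) -> tuple[VAFactors, float, float]:
    """Recover (VA factors, r_N, tau_m) from cable parameters by circuit analysis.

    This is the verification oracle for :func:`invert_cable_parameters`: it
    never reuses the inversion formulas.  The DC attenuations are conductance
    dividers, the AC attenuation includes the dendritic capacitive admittance
    at ``omega``, the input resistance is the somatic Thevenin resistance with
    the dendrite folded in, and ``tau_m`` is minus the reciprocal of the
    slowest eigenvalue of the passive linearised system.
    """
    if not cable.valid:
        raise ValueError("forward_system_properties requires a valid cable")
    g_ms, g_md, g_c, c_ms, c_md = cable.as_tuple()
    p = sys.p

    va_sd_dc = g_c / ((1.0 - p) * g_md + g_c)
    va_ds_dc = g_c / (p * g_ms + g_c)
    va_sd_ac = g_c / abs(
        (1.0 - p) * g_md + g_c + 1j * sys.omega * (1.0 - p) * c_md
    )
    r_n_check = 1.0 / (g_ms + (g_c / p) * (1.0 - va_sd_dc))

    # Passive system matrix for (V_S, V_D); slowest eigenvalue -> tau_m.
    a11 = -(g_ms + g_c / p) / c_ms
    a12 = (g_c / p) / c_ms
    a21 = (g_c / (1.0 - p)) / c_md
    a22 = -(g_md + g_c / (1.0 - p)) / c_md
    tr, det = a11 + a22, a11 * a22 - a12 * a21
    disc = cmath.sqrt(tr * tr - 4.0 * det)
    lam_slow = (tr + disc.real) / 2.0  # less negative root
    tau_m_check = -1.0 / lam_slow

    va = VAFactors(
        min(va_sd_dc, 1.0), min(va_ds_dc, 1.0), min(va_sd_ac, 1.0)
    )
    return va, r_n_check, tau_m_check


def invert_va_arrays(
    sys: SystemProperties,
    a_sd: np.ndarray,
    a_ds: np.ndarray,
    a_ac: np.ndarray,
) -> dict[str, np.ndarray]:
    """Vectorised inversion over arrays of VA triples.

    Returns a dict with the five parameter arrays, a boolean ``valid`` mask
    and an integer ``reason`` code array (0 none, 1 degenerate input,
    2 nonpositive conductance, 3 C_m,D not real, 4 C_m,S invalid).  Used by
    the sweep machinery where constructing one dataclass per grid point would
    dominate the runtime.
    """
    a_sd, a_ds, a_ac = np.broadcast_arrays(
        np.asarray(a_sd, float), np.asarray(a_ds, float), np.asarray(a_ac, float)
    )
    r_n, tau, p = sys.r_n, sys.tau_m, sys.p
    reason = np.zeros(a_sd.shape, dtype=np.int8)

    den = 1.0 - a_sd * a_ds
    degen = (np.abs(den) < DEGENERACY_EPS) | (a_sd < DEGENERACY_EPS) | (
        a_ac < DEGENERACY_EPS
    )
    reason[degen] = 1
    with np.errstate(divide="ignore", invalid="ignore"):
        g_ms = (1.0 - a_ds) / (r_n * den)
        g_md = p * a_ds * (1.0 - a_sd) / ((1.0 - p) * r_n * a_sd * den)
        g_c = p * a_ds / (r_n * den)
        bad_g = ~degen & ~(
            (g_ms > 0) & (g_md > 0) & (g_c > 0)
            & np.isfinite(g_ms) & np.isfinite(g_md) & np.isfinite(g_c)
        )
        reason[bad_g] = 2

        radicand = (g_c / a_ac) ** 2 - (g_c + (1.0 - p) * g_md) ** 2
        bad_rad = (reason == 0) & ~(radicand > 0)
        reason[bad_rad] = 3
        c_md = np.sqrt(np.where(radicand > 0, radicand, np.nan)) / (
            sys.omega * (1.0 - p)
        )

        num = (
            p * (1.0 - p) * tau * g_ms * g_md
            + p * g_ms * (tau * g_c - c_md)
            + p * p * g_ms * c_md
            + (1.0 - p) * (tau * g_c * g_md - g_c * c_md)
        )
        den_cms = p * ((1.0 - p) * (tau * g_md - c_md) + tau * g_c)
        c_ms = tau * num / den_cms
        bad_cms = (reason == 0) & ~(
            (np.abs(den_cms) >= DEGENERACY_EPS) & (c_ms > 0) & np.isfinite(c_ms)
        )
        reason[bad_cms] = 4

        # -1/tau_m must be the slowest eigenvalue of the passive system
        a11 = -(g_ms + g_c / p) / c_ms
        a22 = -(g_md + g_c / (1.0 - p)) / c_md
        lam_other = (a11 + a22) + 1.0 / tau
        bad_tau = (reason == 0) & (lam_other > -1.0 / tau * (1.0 + 1e-9))
        reason[bad_tau] = 4

    valid = reason == 0
    for arr in (g_ms, g_md, g_c, c_ms, c_md):
        arr[~valid] = np.nan
    return {
        "g_ms": g_ms,
        "g_md": g_md,
        "g_c": g_c,
        "c_ms": c_ms,
        "c_md": c_md,
        "valid": valid,
        "reason": reason,
    }
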