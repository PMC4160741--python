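"""Spike and plateau detection, characteristic indices and firing-type labels.

Firing types are read off a triangular-ramp response through three
characteristic indices:

* **TTP** (time to plateau): dendritic plateau onset minus first spike time.
* **TES** (time to end of spiking): last spike time minus the moment the
  descending limb falls back to the recruitment current.  Positive TES means
  firing outlasts the ascending recruitment level (sustained firing).
* **DSF** (difference in spiking frequency): instantaneous firing rate on the
  descending limb at the recruitment current minus the rate of the first
  ascending interspike interval.  Positive DSF means counter-clockwise
  frequency-current hysteresis.

The decision logic is anchored on the dendritic plateau (PIC activation),
which is what physiologically separates the linear from the nonlinear types:
without a plateau the model fires Type I (or Type II when firing dies well
before the descending limb returns to the recruitment current); with a
plateau, an onset at or before recruitment gives Type III, while a delayed
onset gives Type IV — fully hysteretic when the plateau outlasts the
descending recruitment crossing with sustained firing (all snapped CI signs
positive, the (+,+,+) signature), partially hysteretic when the plateau
deactivates before that crossing.  Traces with no spikes (or an invalid
cable/trajectory) are nonphysiological.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import RampProtocol, StateTrajectory

__all__ = [
    "FiringType",
    "DetectionConfig",
    "SpikeTrain",
    "PlateauEvents",
    "CharacteristicIndices",
    "FICurve",
    "detect_spikes",
    "detect_plateau",
    "fi_curve",
    "characteristic_indices",
    "classify",
    "classify_trajectory",
]


class FiringType:
    """Firing-type labels (string enum)."""

    I = "I"
    II = "II"
    III = "III"
    IV_PARTIAL = "IV_partial"
    IV_FULL = "IV_full"
    NONPHYSIOLOGICAL = "nonphysiological"

    ALL = (I, II, III, IV_PARTIAL, IV_FULL, NONPHYSIOLOGICAL)


@dataclass(frozen=True)
class DetectionConfig:
    """Detector conventions and zero tolerances for the characteristic indices.

    ``spike_mode``
        ``"prominence"`` (default) detects spikes as somatic voltage peaks
        with local prominence at least ``spike_prominence`` inside a
        ``prominence_window`` around the peak.  Firing recruits through
        graded, low-amplitude action potentials whose peaks stay below any
        fixed voltage threshold that full plateau-riding spikes would also
        satisfy, so an amplitude-relative criterion is required; the window
        keeps the slow ramp-following depolarisation from registering.
        ``"crossing"`` uses classic upward crossings of ``spike_threshold``.
    ``min_isi``
        Refractory guard between detected spikes, in time units.
    ``plateau_threshold`` / ``plateau_min_duration``
        The dendritic PIC gate ``m_D`` must stay at or above the threshold
        for at least this long to count as a plateau epoch; the duration
        guard rejects the brief per-spike excursions of ``m_D`` that back-
        propagating somatic spikes produce.
    ``tol_ttp`` / ``tol_time`` / ``tol_freq_frac``
        Zero tolerances.  TTP below ``tol_ttp`` (a small numerical guard: the
        plateau either is or is not delayed past the first spike) snaps to
        zero; |TES| below ``tol_time`` snaps to zero — the graded spikes at
        the onset and offset of firing extend the apparent train by roughly
        an interspike interval at each end, so this tolerance absorbs that
        detector floor (about two recruitment ISIs); |DSF| below
        ``tol_freq_frac * F_asc`` snaps to zero (the final, stretching ISI of
        a dying train biases the descending frequency low by several percent).
        Calibrated so the worked-example VA triples reproduce their published
        labels and sign conventions.
    """

    spike_mode: str = "prominence"
    spike_prominence: float = 0.15
    prominence_window: float = 50.0
    spike_threshold: float = 0.0
    min_isi: float = 2.0
    plateau_threshold: float = 0.5
    plateau_min_duration: float = 10.0
    tol_ttp: float = 2.0
    tol_time: float = 70.0
    tol_freq_frac: float = 0.12


@dataclass
class SpikeTrain:
    """Ordered somatic spike times plus the ascending-limb recruitment point."""

    spike_times: np.ndarray
    recruitment_time: float | None = None
    recruitment_current: float | None = None

    def __len__(self) -> int:
        return len(self.spike_times)


@dataclass
class PlateauEvents:
    """Dendritic plateau onset/offset times (either may be absent).

    ``offset`` is None when the plateau persists to the end of the record.
    """

    onset_time: float | None = None
    offset_time: float | None = None

    @property
    def present(self) -> bool:
        return self.onset_time is not None


@dataclass
class CharacteristicIndices:
    """Raw CI values, their snapped signs and the resulting firing type."""

    ttp: float
    tes: float
    dsf: float
    f_asc: float
    firing_type: str
    plateau_absent: bool = False
    plateau_early_offset: bool = False  # plateau gone before the descending
    # limb returns to the recruitment current
    ambiguous: bool = False
    signs: tuple[int, int, int] = (0, 0, 0)  # snapped (ttp, dsf, tes)


@dataclass
class FICurve:
    """Per-spike instantaneous frequency records for F-I hysteresis plots."""

    time: np.ndarray = field(default_factory=lambda: np.empty(0))
    frequency: np.ndarray = field(default_factory=lambda: np.empty(0))
    current: np.ndarray = field(default_factory=lambda: np.empty(0))
    limb: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=object))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.time,
                "frequency": self.frequency,
                "current": self.current,
                "limb": self.limb,
            }
        )


def _upward_crossings(t: np.ndarray, x: np.ndarray, level: float) -> np.ndarray:
    """Linearly interpolated times of upward crossings of ``x`` through ``level``."""
    below = x[:-1] < level
    above = x[1:] >= level
    idx = np.nonzero(below & above)[0]
    if idx.size == 0:
        return np.empty(0)
    frac = (level - x[idx]) / (x[idx + 1] - x[idx])
    return t[idx] + frac * (t[idx + 1] - t[idx])


def _peak_times(t: np.ndarray, v: np.ndarray, config: DetectionConfig) -> np.ndarray:
    """Spike times as prominence-filtered local maxima (parabolic refinement)."""
    from scipy.signal import find_peaks

    dt = t[1] - t[0]
    wlen = max(3, 2 * int(round(config.prominence_window / (2 * dt))) + 1)
    idx, _ = find_peaks(
        v,
        prominence=config.spike_prominence,
        wlen=wlen,
        distance=max(1, int(round(config.min_isi / dt))),
    )
    if idx.size == 0:
        return np.empty(0)
    # quadratic sub-sample refinement of each peak position
    times = t[idx].astype(float)
    inner = (idx > 0) & (idx < len(v) - 1)
    ii = idx[inner]
    denom = v[ii - 1] - 2.0 * v[ii] + v[ii + 1]
    shift = np.zeros(ii.shape)
    nz = denom != 0
    shift[nz] = 0.5 * (v[ii - 1] - v[ii + 1])[nz] / denom[nz]
    times[inner] += np.clip(shift, -0.5, 0.5) * dt
    return times


def detect_spikes(
    traj: StateTrajectory, config: DetectionConfig | None = None
) -> SpikeTrain:
    """Detect somatic spikes and the ascending recruitment point.

    The default mode finds voltage peaks with sufficient local prominence,
    which catches the graded action potentials at recruitment as well as the
    full spikes riding a plateau; ``"crossing"`` mode uses upward threshold
    crossings instead.  A refractory guard of ``min_isi`` applies in both.
    """
    config = config or DetectionConfig()
    if config.spike_mode == "prominence":
        times = _peak_times(traj.t, traj.v_s, config)
    elif config.spike_mode == "crossing":
        times = _upward_crossings(traj.t, traj.v_s, config.spike_threshold)
    else:
        raise ValueError(f"unknown spike_mode {config.spike_mode!r}")
    if times.size:
        kept = [times[0]]
        for s in times[1:]:
            if s - kept[-1] >= config.min_isi:
                kept.append(s)
        times = np.array(kept)
    if times.size == 0:
        return SpikeTrain(spike_times=times)
    t0 = float(times[0])
    i_rec = float(np.interp(t0, traj.t, traj.i_s))
    return SpikeTrain(spike_times=times, recruitment_time=t0, recruitment_current=i_rec)


def detect_plateau(
    traj: StateTrajectory, config: DetectionConfig | None = None
) -> PlateauEvents:
    """Find the sustained dendritic plateau via the PIC gate ``m_D``.

    An epoch counts as a plateau when ``m_D`` stays at or above the threshold
    for at least ``plateau_min_duration``; onset is the start of the first
    such epoch and offset the end of the last one (None when the gate is
    still open at the end of the record).
    """
    config = config or DetectionConfig()
    above = traj.m_d >= config.plateau_threshold
    if not above.any():
        return PlateauEvents()
    d = np.diff(above.astype(np.int8))
    starts = traj.t[1:][d == 1]
    ends = traj.t[1:][d == -1]
    if above[0]:
        starts = np.concatenate([[traj.t[0]], starts])
    open_at_end = above[-1]
    if open_at_end:
        ends = np.concatenate([ends, [traj.t[-1]]])
    onset = offset = None
    for k, (s, e) in enumerate(zip(starts, ends)):
        if e - s >= config.plateau_min_duration:
            if onset is None:
                onset = float(s)
            last = k
            offset = None if (open_at_end and k == len(starts) - 1) else float(e)
    return PlateauEvents(onset_time=onset, offset_time=offset)


def fi_curve(spikes: SpikeTrain, traj: StateTrajectory, ramp: RampProtocol) -> FICurve:
    """Instantaneous frequency (1/preceding ISI) per spike, tagged by ramp limb."""
    sp = spikes.spike_times
    if len(sp) < 2:
        return FICurve()
    isi = np.diff(sp)
    times = sp[1:]
    freq = 1.0 / isi
    cur = np.interp(times, traj.t, traj.i_s)
    limb = np.where(times < ramp.t_peak, "ascending", "descending").astype(object)
    return FICurve(time=times, frequency=freq, current=cur, limb=limb)


def characteristic_indices(
    spikes: SpikeTrain,
    plateau: PlateauEvents,
    traj: StateTrajectory,
    ramp: RampProtocol,
    config: DetectionConfig | None = None,
) -> CharacteristicIndices:
    """Compute (TTP, TES, DSF), snap them at the tolerances, classify.

    With no spikes (or an invalid trajectory) the label is nonphysiological.
    A negative raw TTP (plateau preceding the first spike, the distal-PIC
    situation) counts as zero in the decision table, as does an absent
    plateau.
    """
    config = config or DetectionConfig()
    if not traj.valid or len(spikes) == 0:
        return CharacteristicIndices(
            ttp=0.0, tes=0.0, dsf=0.0, f_asc=np.nan,
            firing_type=FiringType.NONPHYSIOLOGICAL, plateau_absent=not plateau.present,
        )

    t_rec = spikes.recruitment_time
    i_rec = spikes.recruitment_current
    plateau_absent = not plateau.present
    ttp = 0.0 if plateau_absent else float(plateau.onset_time - t_rec)

    t_cross = ramp.descending_time_at(i_rec)
    last = float(spikes.spike_times[-1])
    tes = last - t_cross

    sp = spikes.spike_times
    if len(sp) >= 2:
        f_asc = 1.0 / (sp[1] - sp[0])
        idx = int(np.searchsorted(sp, t_cross))
        if last < t_cross:
            dsf = -f_asc  # firing ceased before the recruitment level
        elif 0 < idx < len(sp):
            dsf = 1.0 / (sp[idx] - sp[idx - 1]) - f_asc
        else:
            dsf = 0.0  # all spikes on one side of t_cross; no spanning pair
    else:
        f_asc = np.nan
        dsf = 0.0

    s_ttp = 1 if (not plateau_absent and ttp > config.tol_ttp) else 0
    s_tes = 0 if abs(tes) <= config.tol_time else (1 if tes > 0 else -1)
    ftol = config.tol_freq_frac * f_asc if np.isfinite(f_asc) else 0.0
    s_dsf = 0 if abs(dsf) <= ftol else (1 if dsf > 0 else -1)

    early_offset = (
        not plateau_absent
        and plateau.offset_time is not None
        and plateau.offset_time < t_cross
    )
    label, ambiguous = classify(
        (s_ttp, s_dsf, s_tes),
        plateau_present=not plateau_absent,
        any_spikes=True,
        plateau_early_offset=early_offset,
    )
    return CharacteristicIndices(
        ttp=ttp, tes=tes, dsf=dsf, f_asc=f_asc, firing_type=label,
        plateau_absent=plateau_absent, plateau_early_offset=early_offset,
        ambiguous=ambiguous, signs=(s_ttp, s_dsf, s_tes),
    )


def classify(
    signs: tuple[int, int, int],
    plateau_present: bool,
    any_spikes: bool,
    plateau_early_offset: bool = False,
) -> tuple[str, bool]:
    """Map plateau state and snapped CI signs to a firing type.

    The plateau (PIC activation) leads the decision: no plateau means a
    linear type (I, or II when spiking dies well before the descending limb
    reaches the recruitment current again); a plateau starting at or before
    recruitment means Type III; a delayed plateau means Type IV, fully
    hysteretic when it outlasts the descending recruitment crossing with
    sustained spiking, partially hysteretic when it deactivates before that
    crossing.  The returned flag marks combinations whose snapped sign triple
    deviates from the type's canonical signature — Type I (0,0,0),
    II (0,-,0), III (0,0,+), IV_full (+,+,+), IV_partial (+,+,<=0).
    """
    if not any_spikes:
        return FiringType.NONPHYSIOLOGICAL, False
    s_ttp, s_dsf, s_tes = signs

    if not plateau_present:
        if s_tes < 0:
            return FiringType.II, s_dsf > 0
        return FiringType.I, (s_dsf > 0 and s_tes > 0)

    if s_ttp == 0:
        return FiringType.III, s_tes < 0
    if plateau_early_offset:
        return FiringType.IV_PARTIAL, s_dsf < 0
    if s_tes > 0:
        return FiringType.IV_FULL, s_dsf <= 0
    return FiringType.IV_PARTIAL, s_dsf < 0


def classify_trajectory(
    traj: StateTrajectory,
    ramp: RampProtocol,
    config: DetectionConfig | None = None,
) -> CharacteristicIndices:
    """Convenience wrapper: detectors plus indices plus label for one trajectory."""
    config = config or DetectionConfig()
    spikes = detect_spikes(traj, config)
    plateau = detect_plateau(traj, config)
    return characteristic_indices(spikes, plateau, traj, ramp, config)
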