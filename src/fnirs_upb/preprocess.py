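"""Hemodynamic preprocessing: Beer–Lambert conversion, filtering, epoching.

The fixed pipeline order is: band-pass filter the optical density (0.01–0.1 Hz,
zero-phase Butterworth), convert to ΔHbO/ΔHbR with the modified Beer–Lambert
law, segment into −1..60 s task-locked epochs, baseline-correct each epoch to
the [−1, 0) s reference interval.  Filtering OD before or after the (linear)
Beer–Lambert conversion is mathematically equivalent; the OD-first order is the
default and a switch exposes the other.  Downstream analysis consumes ΔHbO
only; ΔHbR is carried for completeness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .io import Event, Recording

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class MBLLParams:
    """Modified Beer–Lambert constants.

    ``extinction`` holds molar extinction coefficients in cm^-1 M^-1, rows
    ordered by wavelength (780, 850 nm) and columns by chromophore (HbO, HbR);
    the defaults are the standard tabulated values.  ``dpf`` is the
    differential path-length factor per wavelength (dimensionless; default 6.0
    at both wavelengths, the conventional adult-forehead value).  Absolute µM
    scaling cancels downstream (features are min-max rescaled), so these
    defaults only need to be physiologically reasonable and invertible.
    """

    dpf780: float = 6.0
    dpf850: float = 6.0
    extinction: tuple[tuple[float, float], tuple[float, float]] = (
        (736.0, 1102.0),  # 780 nm: (HbO, HbR)
        (1058.0, 691.0),  # 850 nm: (HbO, HbR)
    )

    def __post_init__(self) -> None:
        if self.dpf780 <= 0 or self.dpf850 <= 0:
            raise ConfigurationError("differential path-length factors must be > 0")

    def coupling_matrix(self, separation_cm: float) -> np.ndarray:
        """2x2 matrix M with ΔOD = M @ (ΔHbO, ΔHbR), concentrations in µM."""
        if separation_cm <= 0:
            raise ConfigurationError("source-detector separation must be > 0")
        eps = np.asarray(self.extinction, dtype=float) * 1e-6  # per µM
        m = np.diag([self.dpf780, self.dpf850]) @ eps * separation_cm
        if abs(np.linalg.det(m)) < 1e-18:
            raise np.linalg.LinAlgError("extinction matrix is singular")
        return m


@dataclass
class HemoTimeSeries:
    """ΔHbO/ΔHbR concentration changes (µM), shape (n_samples, n_channels)."""

    time: np.ndarray
    hbo: np.ndarray
    hbr: np.ndarray
    sampling_rate: float
    events: list[Event] = field(default_factory=list)
    filtered: bool = False
    mbll: MBLLParams | None = None

    def __post_init__(self) -> None:
        if self.hbo.shape != self.hbr.shape or self.hbo.shape[0] != self.time.size:
            raise ValueError("hbo/hbr/time shapes are inconsistent")
        if not (np.all(np.isfinite(self.hbo)) and np.all(np.isfinite(self.hbr))):
            raise ValueError("non-finite concentration values")

    @property
    def n_channels(self) -> int:
        return self.hbo.shape[1]


@dataclass
class Epoch:
    """One channel's ΔHbO over the −1..60 s window around a task onset.

    ``x`` has ``n_pre`` pre-onset samples (the [−1, 0) baseline reference)
    followed by the [0, 60] s analysis window; ``dn`` is the sampling interval
    in seconds.  Sample counts follow the documented rounding rule
    N = floor(pre_s*fs) + floor(post_s*fs), with t = 0 aligned to the first
    sample at or after the event onset.
    """

    x: np.ndarray
    dn: float
    n_pre: int
    channel: int
    trial: int
    condition: str
    baseline_corrected: bool = False

    @property
    def n(self) -> int:
        return self.x.size

    @property
    def times(self) -> np.ndarray:
        return (np.arange(self.x.size) - self.n_pre) * self.dn

    @property
    def analysis_window(self) -> np.ndarray:
        """Samples with 0 <= t <= 60 s (the post-onset portion)."""
        return self.x[self.n_pre :]


# ---------------------------------------------------------------------------
# Modified Beer–Lambert law (forward and inverse)
# ---------------------------------------------------------------------------

def hemoglobin_to_od(
    hbo: np.ndarray,
    hbr: np.ndarray,
    separation_cm: float = 3.0,
    mbll: MBLLParams | None = None,
) -> np.ndarray:
    """Forward model: concentrations (µM) → ΔOD, shape (..., 2 wavelengths).

    This is the exact inverse of :func:`od_to_hemoglobin` and is what the
    synthetic generator uses to map programmed concentrations to optical
    density.
    """
    mbll = mbll or MBLLParams()
    m = mbll.coupling_matrix(separation_cm)
    conc = np.stack([hbo, hbr], axis=-1)
    return conc @ m.T


def od_to_hemoglobin(rec: Recording, mbll: MBLLParams | None = None) -> HemoTimeSeries:
    """Invert the modified Beer–Lambert law channel-wise.

    Solves the 2x2 system ΔOD(λ) = [ε_HbO(λ)·ΔHbO + ε_HbR(λ)·ΔHbR]·d·DPF(λ)
    per sample and channel; returns concentrations in µM.
    """
    mbll = mbll or MBLLParams()
    m = mbll.coupling_matrix(rec.layout.separation_cm)
    minv = np.linalg.inv(m)
    conc = rec.od @ minv.T  # (T, C, 2) -> (ΔHbO, ΔHbR)
    return HemoTimeSeries(
        time=rec.time,
        hbo=conc[:, :, 0],
        hbr=conc[:, :, 1],
        sampling_rate=rec.sampling_rate,
        events=list(rec.events),
        filtered=rec.filtered,
        mbll=mbll,
    )


# ---------------------------------------------------------------------------
# Band-pass filtering
# ---------------------------------------------------------------------------

def _design_bandpass(fs: float, low: float, high: float, order: int) -> np.ndarray:
    if not (0 < low < high < fs / 2):
        raise ConfigurationError(
            f"band edges must satisfy 0 < low < high < fs/2; got {low}, {high} at fs={fs}"
        )
    return signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass_array(
    x: np.ndarray,
    fs: float,
    low: float = 0.01,
    high: float = 0.1,
    order: int = 4,
    axis: int = 0,
) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth band-pass along *axis*."""
    sos = _design_bandpass(fs, low, high, order)
    padlen = 3 * (2 * sos.shape[0] + 1 - min((sos[:, 2] == 0).sum(), (sos[:, 5] == 0).sum()))
    if x.shape[axis] <= padlen:
        raise ValueError(
            f"signal length {x.shape[axis]} too short for zero-phase filtering; "
            f"need more than {padlen} samples"
        )
    return signal.sosfiltfilt(sos, x, axis=axis)


def bandpass_recording(
    rec: Recording, low: float = 0.01, high: float = 0.1, order: int = 4
) -> Recording:
    """Band-pass the optical density (the default, OD-first order)."""
    od = bandpass_array(rec.od, rec.sampling_rate, low, high, order, axis=0)
    return rec.copy_with(od=od, filtered=True)


def bandpass(
    h: HemoTimeSeries, low: float = 0.01, high: float = 0.1, order: int = 4
) -> HemoTimeSeries:
    """Band-pass concentrations (the alternative, concentration-domain order)."""
    return replace(
        h,
        hbo=bandpass_array(h.hbo, h.sampling_rate, low, high, order, axis=0),
        hbr=bandpass_array(h.hbr, h.sampling_rate, low, high, order, axis=0),
        filtered=True,
    )


# ---------------------------------------------------------------------------
# Epoching and baseline correction
# ---------------------------------------------------------------------------

def epoch(
    h: HemoTimeSeries,
    events: list[Event] | None = None,
    pre_s: float = 1.0,
    post_s: float = 60.0,
    allow_unfiltered: bool = False,
) -> list[Epoch]:
    """Segment ΔHbO into per-channel, per-trial epochs of −pre_s..post_s.

    Trials without ``pre_s`` seconds of pre-data or ``post_s`` seconds of
    post-data are rejected (logged with their trial index), not an error.
    Epoching unfiltered data is refused unless ``allow_unfiltered`` — the
    pipeline order (filter before epoching) is enforced by provenance flags.
    """
    if not h.filtered and not allow_unfiltered:
        raise ValueError(
            "refusing to epoch unfiltered data; band-pass first or pass allow_unfiltered=True"
        )
    events = h.events if events is None else events
    fs = h.sampling_rate
    n_pre = int(np.floor(pre_s * fs))
    n_post = int(np.floor(post_s * fs))
    dn = 1.0 / fs
    epochs: list[Epoch] = []
    for trial, ev in enumerate(sorted(events, key=lambda e: e.onset)):
        i0 = int(np.searchsorted(h.time, ev.onset))
        if i0 - n_pre < 0 or i0 + n_post > h.time.size:
            logger.info(
                "rejecting trial %d (onset %.3f s): insufficient pre/post data",
                trial,
                ev.onset,
            )
            continue
        for ch in range(h.n_channels):
            epochs.append(
                Epoch(
                    x=h.hbo[i0 - n_pre : i0 + n_post, ch].copy(),
                    dn=dn,
                    n_pre=n_pre,
                    channel=ch,
                    trial=trial,
                    condition=ev.condition,
                )
            )
    return epochs


def baseline_correct(e: Epoch) -> Epoch:
    """Subtract the mean over the [−1, 0) s reference interval (pre-onset samples).

    Idempotent: the corrected epoch's reference mean is 0, so a second
    application shifts by 0.
    """
    if e.n_pre < 1:
        raise ValueError("epoch has no pre-onset reference samples")
    shift = float(np.mean(e.x[: e.n_pre]))
    return Epoch(
        x=e.x - shift,
        dn=e.dn,
        n_pre=e.n_pre,
        channel=e.channel,
        trial=e.trial,
        condition=e.condition,
        baseline_corrected=True,
    )


def temporal_mean(e: Epoch) -> float:
    """Mean ΔHbO over the [0, 60] s analysis window (for ROI summary tables)."""
    w = e.analysis_window
    if w.size == 0:
        raise ValueError("empty analysis window")
    return float(np.mean(w))


def preprocess_recording(
    rec: Recording,
    mbll: MBLLParams | None = None,
    low: float = 0.01,
    high: float = 0.1,
    order: int = 4,
    od_first: bool = True,
) -> list[Epoch]:
    """Full preprocessing chain: filter, Beer–Lambert, epoch, baseline-correct."""
    if od_first:
        h = od_to_hemoglobin(bandpass_recording(rec, low, high, order), mbll)
    else:
        h = bandpass(od_to_hemoglobin(rec, mbll), low, high, order)
    return [baseline_correct(e) for e in epoch(h)]
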