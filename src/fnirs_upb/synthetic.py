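"""Synthetic dual-wavelength fNIRS recordings, purchase counts and Likert tables.

The generator emulates the block design of the shopping experiment: per
subject, two tasks of 5 trials each (1 s cue, 25 s task, 30 s rest), recorded
at 8.138 Hz on a 15-channel prefrontal montage at 780/850 nm.  Task-locked
ΔHbO is a boxcar convolved with a canonical double-gamma hemodynamic response,
scaled per channel by condition- and ROI-specific peak amplitudes; ΔHbR is
−1/3 of ΔHbO plus independent noise.  Concentrations are pushed through the
forward Beer–Lambert model and physiological noise (cardiac, respiratory and
Mayer-wave sinusoids with jittered frequency and random phase, very-low-
frequency drift, white noise) is added in optical-density units.

The default ROI contrast encodes the qualitative activation topography of the
study: during the promotion (Task 1) the prefrontal cortex is weakly activated
except the left VLPFC, while the control task (Task 2) drives strong OFC and
moderate mPFC/VLPFC activation with the DLPFC weakest; every Task-2 amplitude
exceeds every Task-1 amplitude, reflecting the globally lower prefrontal
activity under the promotion condition.

Randomness: a single root seed; subject ``i`` draws from the child stream
``SeedSequence((seed, i))``, the behavioral table from ``(seed, 1_000_001)``
and the Likert table from ``(seed, 1_000_002)``, so streams are independent
and any subject can be regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import CONDITIONS, ROI_LABELS, ChannelLayout, Event, Recording, default_layout
from .preprocess import ConfigurationError, MBLLParams, hemoglobin_to_od


@dataclass(frozen=True)
class HRFParams:
    """Canonical double-gamma hemodynamic response (gamma-pdf difference).

    ``peak_shape``/``undershoot_shape`` are gamma shape parameters with unit
    scale (seconds), giving a response peak near 5–6 s and an undershoot near
    16 s; ``undershoot_ratio`` is the relative undershoot depth.
    """

    peak_shape: float = 6.0
    undershoot_shape: float = 16.0
    undershoot_ratio: float = 1.0 / 6.0
    duration_s: float = 32.0

    def kernel(self, fs: float) -> np.ndarray:
        t = np.arange(0.0, self.duration_s, 1.0 / fs)
        h = stats.gamma.pdf(t, self.peak_shape) - self.undershoot_ratio * stats.gamma.pdf(
            t, self.undershoot_shape
        )
        return h / np.max(h)


@dataclass(frozen=True)
class NoiseParams:
    """Amplitudes (optical-density units) and centre frequencies (Hz) of the
    physiological components.  Each sinusoid gets a per-channel random phase
    and a relative frequency jitter; drift is a sum of very-low-frequency
    (< 0.01 Hz) sinusoids with random phases, i.e. energy the analysis
    band-pass is designed to remove."""

    cardiac_amp: float = 4e-3
    cardiac_freq: float = 1.1
    resp_amp: float = 2e-3
    resp_freq: float = 0.3
    mayer_amp: float = 1e-3
    mayer_freq: float = 0.1
    drift_amp: float = 5e-3
    white_amp: float = 1e-3
    freq_jitter: float = 0.1
    hbr_white_um: float = 0.01

    def __post_init__(self) -> None:
        for name in (
            "cardiac_amp",
            "resp_amp",
            "mayer_amp",
            "drift_amp",
            "white_amp",
            "hbr_white_um",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"noise amplitude {name} must be >= 0")


def _default_roi_amplitudes() -> dict[str, dict[str, float]]:
    return {
        "Task1": {"DLPFC": 0.02, "VLPFC_L": 0.25, "VLPFC_R": 0.03, "mPFC": 0.04, "OFC": 0.05},
        "Task2": {"DLPFC": 0.35, "VLPFC_L": 0.55, "VLPFC_R": 0.55, "mPFC": 0.60, "OFC": 0.80},
    }


@dataclass
class SyntheticConfig:
    """All generator parameters; identical seed ⇒ bit-identical output.

    ``roi_amplitudes`` maps condition → ROI → peak ΔHbO in µM.
    ``behavior_p`` is the per-item purchase probability per condition (counts
    are Binomial(4, p) per clothing category, 5 categories, so expected totals
    are 20·p: the defaults 0.3335/0.168 give ≈ 6.67 and ≈ 3.36 purchases).
    ``likert`` maps condition → (mean, SD) of the latent normal behind the
    rounded, clipped 1–5 responses.  ``trial_gain_sd`` is trial-by-trial
    multiplicative amplitude variability (physiological response variability).
    ``iti_s`` extends the rest period so consecutive task onsets are ≥ 61 s
    apart and the −1..60 s epoch never overlaps the next trial.
    ``initial_rest_s``/``inter_block_rest_s``/``tail_rest_s`` pad the
    recording before the first task block, between the two blocks (the break
    in which the protocol's self-report was administered) and after the last
    trial.  The defaults (120 s ≈ the band-pass filter's ~1/0.01 Hz settling
    time) make the two task blocks structurally identical — each with its own
    filter onset/offset transient — so trial-position effects are symmetric
    across conditions, and keep zero-phase edge artifacts away from every
    epoch.
    """

    n_subjects: int = 33
    sampling_rate: float = 8.138
    n_trials_per_task: int = 5
    cue_s: float = 1.0
    task_s: float = 25.0
    rest_s: float = 30.0
    iti_s: float = 6.0
    initial_rest_s: float = 120.0
    inter_block_rest_s: float = 120.0
    tail_rest_s: float = 120.0
    channel_count: int = 15
    roi_amplitudes: dict[str, dict[str, float]] = field(default_factory=_default_roi_amplitudes)
    hrf: HRFParams = field(default_factory=HRFParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    trial_gain_sd: float = 0.15
    behavior_p: dict[str, float] = field(default_factory=lambda: {"Task1": 0.3335, "Task2": 0.168})
    n_categories: int = 5
    max_per_category: int = 4
    likert: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"Task1": (3.53, 0.80), "Task2": (2.40, 0.90)}
    )
    likert_item_sd: float = 0.3
    n_likert_items: int = 3
    seed: int = 0

    def validate(self) -> None:
        for name in ("sampling_rate", "cue_s", "task_s", "rest_s"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if (
            self.iti_s < 0
            or self.tail_rest_s < 0
            or self.inter_block_rest_s < 0
            or self.initial_rest_s < self.cue_s
        ):
            raise ConfigurationError(
                "rest paddings must be >= 0 and initial_rest_s >= cue_s"
            )
        if self.n_trials_per_task < 1 or self.n_subjects < 1:
            raise ConfigurationError("counts must be >= 1")
        for cond in CONDITIONS:
            if cond not in self.roi_amplitudes:
                raise ConfigurationError(f"roi_amplitudes missing condition {cond}")
            for roi in ROI_LABELS:
                if roi not in self.roi_amplitudes[cond]:
                    raise ConfigurationError(f"roi_amplitudes[{cond}] missing ROI {roi}")
            p = self.behavior_p[cond]
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError("behavior probabilities must be in [0, 1]")
            mean, sd = self.likert[cond]
            if not 1.0 <= mean <= 5.0:
                raise ConfigurationError("likert mean must be within the 1..5 scale")
            if sd < 0:
                raise ConfigurationError("likert SD must be >= 0")

    @property
    def onset_to_onset_s(self) -> float:
        return self.cue_s + self.task_s + self.rest_s + self.iti_s


@dataclass
class GroundTruth:
    """What the generator actually programmed, for downstream validation."""

    conditions: list[str]  # per trial, in onset order
    onsets: np.ndarray  # task onsets (s), in onset order
    roi_of_channel: tuple[str, ...]
    amplitudes: dict[str, dict[str, float]]
    hbo_clean: np.ndarray  # noise-free ΔHbO (µM), (n_samples, n_channels)


def _subject_rng(seed: int, subject_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, subject_index)))


def generate_recording(
    config: SyntheticConfig,
    subject_index: int,
    layout: ChannelLayout | None = None,
    mbll: MBLLParams | None = None,
) -> tuple[Recording, GroundTruth]:
    """Generate one subject's dual-wavelength optical-density recording.

    Trials are blocked by condition (all Task 1 trials, then all Task 2
    trials), matching the study's task-per-block protocol.  Deterministic
    given ``(config.seed, subject_index)``.
    """
    config.validate()
    layout = layout or default_layout()
    if layout.n_channels != config.channel_count:
        raise ConfigurationError(
            f"layout has {layout.n_channels} channels, config expects {config.channel_count}"
        )
    mbll = mbll or MBLLParams()
    rng = _subject_rng(config.seed, subject_index)
    fs = config.sampling_rate
    n_trials = 2 * config.n_trials_per_task

    trial_pos = np.arange(n_trials)
    onsets = config.initial_rest_s + trial_pos * config.onset_to_onset_s
    onsets[config.n_trials_per_task :] += config.inter_block_rest_s
    conditions = ["Task1"] * config.n_trials_per_task + ["Task2"] * config.n_trials_per_task
    total_s = (
        onsets[-1]
        + config.task_s
        + config.rest_s
        + config.iti_s
        + config.hrf.duration_s
        + config.tail_rest_s
    )
    n_samples = int(np.ceil(total_s * fs))
    time = np.arange(n_samples) / fs

    # Single-trial response template: 25 s boxcar * double-gamma, peak-normalized.
    kernel = config.hrf.kernel(fs)
    boxcar = np.ones(int(round(config.task_s * fs)))
    template = np.convolve(boxcar, kernel)
    template /= np.max(template)

    roi_of_channel = layout.rois
    hbo = np.zeros((n_samples, layout.n_channels))
    gains = 1.0 + config.trial_gain_sd * rng.standard_normal((n_trials, layout.n_channels))
    gains = np.clip(gains, 0.0, None)
    for t_idx, (onset, cond) in enumerate(zip(onsets, conditions)):
        i0 = int(np.round(onset * fs))
        seg = slice(i0, min(i0 + template.size, n_samples))
        for ch, roi in enumerate(roi_of_channel):
            amp = config.roi_amplitudes[cond][roi]
            hbo[seg, ch] += amp * gains[t_idx, ch] * template[: seg.stop - seg.start]

    hbr = -hbo / 3.0
    if config.noise.hbr_white_um > 0:
        hbr = hbr + config.noise.hbr_white_um * rng.standard_normal(hbr.shape)

    od = hemoglobin_to_od(hbo, hbr, layout.separation_cm, mbll)

    od = od + _physiological_noise(rng, time, layout.n_channels, config.noise)

    events = [
        Event(onset=float(o), duration=config.task_s, condition=c)
        for o, c in zip(onsets, conditions)
    ]
    rec = Recording(time=time, od=od, layout=layout, events=events)
    gt = GroundTruth(
        conditions=conditions,
        onsets=onsets,
        roi_of_channel=roi_of_channel,
        amplitudes={c: dict(v) for c, v in config.roi_amplitudes.items()},
        hbo_clean=hbo,
    )
    return rec, gt


def _physiological_noise(
    rng: np.random.Generator, time: np.ndarray, n_channels: int, p: NoiseParams
) -> np.ndarray:
    """Additive OD noise, shape (n_samples, n_channels, 2 wavelengths)."""
    out = np.zeros((time.size, n_channels, 2))
    for amp, freq in (
        (p.cardiac_amp, p.cardiac_freq),
        (p.resp_amp, p.resp_freq),
        (p.mayer_amp, p.mayer_freq),
    ):
        if amp == 0:
            continue
        f = freq * (1.0 + p.freq_jitter * (2.0 * rng.random((n_channels, 2)) - 1.0))
        phase = rng.uniform(0.0, 2.0 * np.pi, (n_channels, 2))
        out += amp * np.sin(
            2.0 * np.pi * f[None, :, :] * time[:, None, None] + phase[None, :, :]
        )
    if p.drift_amp > 0:
        # Three sub-band (< 0.01 Hz) components emulating slow baseline drift.
        for f0 in (0.002, 0.005, 0.008):
            phase = rng.uniform(0.0, 2.0 * np.pi, (n_channels, 2))
            out += (p.drift_amp / 3.0) * np.sin(
                2.0 * np.pi * f0 * time[:, None, None] + phase[None, :, :]
            )
    if p.white_amp > 0:
        out += p.white_amp * rng.standard_normal(out.shape)
    return out


# ---------------------------------------------------------------------------
# Behavioral tables
# ---------------------------------------------------------------------------

CATEGORIES = ("knitwear", "coat", "vest", "pants", "suit")


def generate_behavior(config: SyntheticConfig) -> pd.DataFrame:
    """Purchase counts: one row per subject x condition x clothing category.

    Counts are Binomial(4, p_condition) per category (4 products per category,
    5 categories, hence totals 0..20 per task).  Columns: subject, condition,
    category, count.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1_000_001)))
    rows = []
    for subject in range(config.n_subjects):
        for cond in CONDITIONS:
            counts = rng.binomial(
                config.max_per_category, config.behavior_p[cond], config.n_categories
            )
            for cat, cnt in zip(CATEGORIES[: config.n_categories], counts):
                rows.append((subject + 1, cond, cat, int(cnt)))
    return pd.DataFrame(rows, columns=["subject", "condition", "category", "count"])


def generate_likert(config: SyntheticConfig) -> pd.DataFrame:
    """5-point Likert responses: one row per subject x condition x item.

    Each subject draws a latent condition score from a normal with the
    configured per-condition mean and SD (a between-subject SD, matching how
    group summaries are reported); the items add small independent normal
    noise (``likert_item_sd``) and are rounded to the nearest integer and
    clipped to 1..5.  Columns: subject, condition, item, response.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1_000_002)))
    rows = []
    for subject in range(config.n_subjects):
        for cond in CONDITIONS:
            mean, sd = config.likert[cond]
            latent = rng.normal(mean, sd)
            raw = latent + rng.normal(0.0, config.likert_item_sd, config.n_likert_items)
            resp = np.clip(np.rint(raw), 1, 5).astype(int)
            for item, r in enumerate(resp, start=1):
                rows.append((subject + 1, cond, item, int(r)))
    return pd.DataFrame(rows, columns=["subject", "condition", "item", "response"])
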