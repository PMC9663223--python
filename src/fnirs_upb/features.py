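"""Six time-domain features per epoch and the min-max rescaled feature matrix.

Per epoch (one channel, one trial, the baseline-corrected [0, 60] s window) the
features are:

* SM — signal mean, (1/N) Σ x[n]                                   (µM)
* SV — signal variance, Σ (x[n]−µ)² / (N−1)                        (µM²)
* KR — kurtosis, E[((x−µ)/σ)⁴] with σ = √SV (raw, not excess)      (–)
* SK — skewness, E[((x−µ)/σ)³]                                     (–)
* SS — signal slope: the mean of the per-sample slopes
       (x[n]−x[n−1])/Δn, which telescopes to
       (x[N−1]−x[0])/((N−1)·Δn); a least-squares slope is
       available as an alternative                                  (µM/s)
* SA — signal area, Σ x[n]·Δn (signed rectangle rule)              (µM·s)

A constant epoch has SV = 0, leaving KR/SK undefined; such epochs return
KR = SK = 0 with a degeneracy flag rather than silent NaN.  Features are
rescaled column-wise to [0, 1] with min-max fitted on training rows only
(fitting on all rows — the literal pooled rescale — exists as a comparison
mode but leaks test extrema into training).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import Epoch

logger = logging.getLogger(__name__)

FEATURE_NAMES = ("sm", "sv", "kr", "sk", "ss", "sa")


@dataclass(frozen=True)
class FeatureVector:
    sm: float
    sv: float
    kr: float
    sk: float
    ss: float
    sa: float
    degenerate: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([self.sm, self.sv, self.kr, self.sk, self.ss, self.sa])


def extract_features(e: Epoch, slope: str = "endpoint") -> FeatureVector:
    """Compute the six time-domain features on the epoch's [0, 60] s window.

    ``slope`` is ``"endpoint"`` (mean of instantaneous slopes) or
    ``"lstsq"`` (linear least-squares fit).
    """
    x = np.asarray(e.analysis_window, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 samples in the analysis window, got {n}")
    dn = e.dn
    sm = float(np.mean(x))
    sv = float(np.sum((x - sm) ** 2) / (n - 1))
    if sv > 0.0:
        z = (x - sm) / np.sqrt(sv)
        kr = float(np.mean(z**4))
        sk = float(np.mean(z**3))
        degenerate = False
    else:
        kr = sk = 0.0
        degenerate = True
    if slope == "endpoint":
        ss = float((x[-1] - x[0]) / ((n - 1) * dn))
    elif slope == "lstsq":
        t = np.arange(n) * dn
        ss = float(np.polyfit(t, x, 1)[0])
    else:
        raise ValueError(f"unknown slope mode {slope!r}")
    sa = float(np.sum(x) * dn)
    return FeatureVector(sm, sv, kr, sk, ss, sa, degenerate)


@dataclass
class FeatureMatrix:
    """Samples x 6 features with condition labels and per-row provenance.

    One row per (channel, trial) epoch — with 15 channels and 5 trials per
    task this yields 75 rows per class per subject, enough to support the
    repeated cross-validation scheme.  ``meta`` holds subject/channel/trial/
    condition per row.
    """

    X: np.ndarray
    labels: np.ndarray  # condition strings, "Task1" = UPB-positive
    meta: pd.DataFrame
    rescaled: bool = False
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        if self.X.shape != (self.labels.size, len(self.feature_names)):
            raise ValueError("feature matrix shape inconsistent with labels/names")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = self.meta.copy()
        for j, name in enumerate(self.feature_names):
            df[name] = self.X[:, j]
        return df


def build_feature_matrix(
    epochs: list[Epoch],
    subject: int = 1,
    sample_unit: str = "channel_trial",
    slope: str = "endpoint",
) -> FeatureMatrix:
    """Assemble the feature matrix for one subject.

    ``sample_unit="channel_trial"`` (default): one row per (channel, trial)
    epoch, 6 columns.  ``sample_unit="trial"``: one row per trial, channels
    concatenated into a 15x6 = 90-dimensional vector (the alternative reading
    in which a trial is the classification sample).
    """
    if not epochs:
        raise ValueError("no epochs supplied")
    conds = {e.condition for e in epochs}
    if len(conds) < 2:
        raise ValueError(
            f"feature matrix needs both conditions; got only {sorted(conds)}"
        )
    if sample_unit == "channel_trial":
        rows = [extract_features(e, slope=slope).as_array() for e in epochs]
        meta = pd.DataFrame(
            {
                "subject": subject,
                "channel": [e.channel + 1 for e in epochs],
                "trial": [e.trial for e in epochs],
                "condition": [e.condition for e in epochs],
            }
        )
        X = np.vstack(rows)
        labels = np.array([e.condition for e in epochs])
        return FeatureMatrix(X=X, labels=labels, meta=meta)
    if sample_unit == "trial":
        by_trial: dict[int, list[Epoch]] = {}
        for e in epochs:
            by_trial.setdefault(e.trial, []).append(e)
        rows, labels, trials = [], [], []
        for trial in sorted(by_trial):
            group = sorted(by_trial[trial], key=lambda e: e.channel)
            rows.append(
                np.concatenate([extract_features(e, slope=slope).as_array() for e in group])
            )
            labels.append(group[0].condition)
            trials.append(trial)
        names = tuple(
            f"ch{e.channel + 1:02d}_{name}"
            for e in sorted(by_trial[trials[0]], key=lambda e: e.channel)
            for name in FEATURE_NAMES
        )
        meta = pd.DataFrame({"subject": subject, "trial": trials, "condition": labels})
        return FeatureMatrix(
            X=np.vstack(rows), labels=np.array(labels), meta=meta, feature_names=names
        )
    raise ValueError(f"unknown sample_unit {sample_unit!r}")


# ---------------------------------------------------------------------------
# Min-max rescaling (fit on training rows, apply everywhere)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MinMaxScaler:
    """Column-wise min-max map Z' = (Z − min) / (max − min).

    Columns that are constant over the fitted rows map to 0 (logged warning);
    rows outside the fitted range map outside [0, 1] by design — the scaler
    never clips, so test-fold extrapolation stays visible.
    """

    mins: np.ndarray
    maxs: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        span = self.maxs - self.mins
        out = np.zeros_like(X, dtype=float)
        ok = span > 0
        out[:, ok] = (X[:, ok] - self.mins[ok]) / span[ok]
        return out


def fit_minmax(X: np.ndarray, rows: np.ndarray | None = None) -> MinMaxScaler:
    """Fit column minima/maxima on ``rows`` (default: all rows)."""
    sub = X if rows is None else X[rows]
    if sub.shape[0] == 0:
        raise ValueError("cannot fit min-max on an empty row subset")
    mins = sub.min(axis=0)
    maxs = sub.max(axis=0)
    constant = np.flatnonzero(maxs - mins == 0)
    if constant.size:
        logger.warning(
            "min-max: constant column(s) %s over fitted rows; mapping them to 0",
            constant.tolist(),
        )
    return MinMaxScaler(mins=mins, maxs=maxs)


def apply_minmax(scaler: MinMaxScaler, m: FeatureMatrix) -> FeatureMatrix:
    return FeatureMatrix(
        X=scaler.transform(m.X),
        labels=m.labels,
        meta=m.meta,
        rescaled=True,
        feature_names=m.feature_names,
    )
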