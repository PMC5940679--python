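"""Transcription-activity assays: incorporation curves, copy times, qRT-PCR.

Nascent-RNA labelling with clickable uridine analogues (EU in intact cells,
EUTP in run-on conditions with fixed nucleotide supply) produces a signal
that rises and saturates as label accumulates.  Each time course is fitted
with a saturating exponential

    S(t) = s_max * (1 - exp(-k t))

whose initial slope ``s_max * k`` is the transcription rate at t=0.  Two
conditions are compared by the ratio of the areas under their fitted curves
over a stated window (the observable "signal incorporated during the first W
minutes"), reported as a percent increase.

Also provided: the copy time of a transcription unit (length / polymerase
speed) and the standard 2^-ddCt relative-expression ratio for qRT-PCR.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.base import BaseEstimator, RegressorMixin

log = logging.getLogger(__name__)

__all__ = [
    "IncorporationCurve",
    "IncorporationFit",
    "SaturatingExponential",
    "TranscriptionUnit",
    "fit_incorporation",
    "percent_increase",
    "transcription_time",
    "delta_delta_ct",
    "read_ct_table",
]


@dataclasses.dataclass(frozen=True)
class IncorporationCurve:
    """A labelling time course: times in minutes, signal in fluorescence units."""

    times: np.ndarray
    signal: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "signal", s)
        if t.ndim != 1 or t.shape != s.shape:
            raise ValueError("times and signal must be 1-D and equally long")
        if len(t) < 4:
            raise ValueError("curve needs at least 4 points")
        if t[0] != 0 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing from 0")
        if np.any(s < 0):
            raise ValueError("signal must be non-negative")


@dataclasses.dataclass(frozen=True)
class IncorporationFit:
    """Saturating-exponential fit: S(t) = s_max (1 - exp(-k t))."""

    s_max: float
    k: float
    initial_rate: float
    rss: float

    def __post_init__(self) -> None:
        if self.s_max < 0 or self.k < 0:
            raise ValueError("s_max and k must be non-negative")
        if abs(self.initial_rate - self.s_max * self.k) > 1e-9 * max(1.0, self.initial_rate):
            raise ValueError("initial_rate must equal s_max * k")

    def auc(self, window: float) -> float:
        """Integral of the fitted curve over [0, window] minutes."""
        if self.k == 0:
            return 0.0
        return self.s_max * (window - (1 - math.exp(-self.k * window)) / self.k)


class SaturatingExponential(RegressorMixin, BaseEstimator):
    """Saturating-exponential regressor for incorporation time courses.

    Bounded least squares on (s_max, k) with a multi-start over log-spaced
    rate guesses; at each candidate k the amplitude is initialized by its
    conditional linear least-squares solution.

    Attributes: ``s_max_``, ``k_``, ``initial_rate_``, ``rss_``.
    """

    def __init__(self, n_starts: int = 12):
        self.n_starts = n_starts

    def fit(self, X, y):
        t = np.asarray(X, dtype=float)
        if t.ndim == 2 and t.shape[1] == 1:
            t = t[:, 0]
        s = np.asarray(y, dtype=float)
        if np.all(s == 0):
            raise ValueError("flat zero signal; nothing to fit")
        tmax = t[-1]
        ks = np.geomspace(0.01 / tmax, 10.0 / (t[1] if t[1] > 0 else tmax), self.n_starts)
        best = None
        for k0 in ks:
            b = 1 - np.exp(-k0 * t)
            denom = float(b @ b)
            s0 = max(float(b @ s) / denom, 1e-12) if denom > 0 else float(np.max(s))
            try:
                res = optimize.least_squares(
                    lambda p: p[0] * (1 - np.exp(-p[1] * t)) - s,
                    np.array([s0, k0]),
                    bounds=(0.0, np.inf),
                    xtol=1e-14,
                    ftol=1e-14,
                    gtol=1e-14,
                )
            except ValueError:
                continue  # occasional trust-region breakdown at extreme starts
            rss = 2.0 * res.cost
            if best is None or rss < best[0]:
                best = (rss, res.x)
        if best is None:
            raise RuntimeError("no incorporation-fit start converged")
        rss, (s_max, k) = best
        self.s_max_, self.k_ = float(s_max), float(k)
        self.initial_rate_ = self.s_max_ * self.k_
        self.rss_ = float(rss)
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        t = np.asarray(X, dtype=float)
        if t.ndim == 2 and t.shape[1] == 1:
            t = t[:, 0]
        return self.s_max_ * (1 - np.exp(-self.k_ * t))


def fit_incorporation(curve: IncorporationCurve) -> IncorporationFit:
    """Fit S(t) = s_max (1 - exp(-k t)) to an incorporation time course."""
    est = SaturatingExponential().fit(curve.times, curve.signal)
    return IncorporationFit(est.s_max_, est.k_, est.initial_rate_, est.rss_)


def percent_increase(
    fit_condition: IncorporationFit, fit_control: IncorporationFit, window: float
) -> float:
    """Percent extra signal incorporated by the condition over ``window`` min.

    100 * (AUC_condition / AUC_control - 1), with AUC the integral of the
    fitted curve over [0, window].  When both fits share k this equals the
    percent difference in s_max (and in initial rate) exactly.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    auc_ctrl = fit_control.auc(window)
    if auc_ctrl == 0:
        raise ValueError("control AUC is zero; ratio undefined")
    return 100.0 * (fit_condition.auc(window) / auc_ctrl - 1.0)


@dataclasses.dataclass(frozen=True)
class TranscriptionUnit:
    """A transcription unit: length in nucleotides, speed in nt/min."""

    length: float
    rate: float

    def __post_init__(self) -> None:
        if self.length <= 0 or self.rate <= 0:
            raise ValueError("length and rate must be positive")


def transcription_time(unit: TranscriptionUnit) -> tuple[float, int]:
    """Minutes to copy the unit: (raw, rounded half-up to whole minutes).

    A median human transcription unit (~14 kbp) at polymerization rates of
    1.1-2.5 x 10^3 nt/min is copied in 6-13 whole minutes.
    """
    raw = unit.length / unit.rate
    return raw, int(math.floor(raw + 0.5))


def read_ct_table(path) -> pd.DataFrame:
    """Read a 4-column TSV of (gene, condition, ct_target, ct_reference)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "condition", "ct_target", "ct_reference"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    return df


def delta_delta_ct(
    table: pd.DataFrame, condition: str, reference_condition: str
) -> pd.DataFrame:
    """Per-gene 2^-ddCt expression ratios between two conditions.

    For each gene, dCt = ct_target - ct_reference within a condition,
    ddCt = dCt(condition) - dCt(reference_condition), ratio = 2^-ddCt.
    Genes missing either condition are excluded with a logged list.
    Returns a DataFrame with columns gene, delta_delta_ct, ratio.
    """
    df = table.copy()
    for col in ("ct_target", "ct_reference"):
        if not np.all(np.isfinite(df[col])):
            raise ValueError(f"non-finite values in {col}")
    dct = (
        df.assign(dct=df.ct_target - df.ct_reference)
        .groupby(["gene", "condition"], sort=False)["dct"]
        .mean()
        .unstack("condition")
    )
    for cond in (condition, reference_condition):
        if cond not in dct.columns:
            raise ValueError(f"condition {cond!r} absent from table")
    missing = dct.index[dct[[condition, reference_condition]].isna().any(axis=1)].tolist()
    if missing:
        log.warning("genes missing a condition, excluded: %s", missing)
    kept = dct.dropna(subset=[condition, reference_condition])
    if kept.empty:
        raise ValueError("no gene present in both conditions")
    ddct = kept[condition] - kept[reference_condition]
    return pd.DataFrame(
        {"gene": kept.index, "delta_delta_ct": ddct.values, "ratio": 2.0 ** (-ddct.values)}
    ).reset_index(drop=True)
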