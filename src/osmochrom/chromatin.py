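"""Chromatin condensation and accessibility statistics.

Two readouts of chromatin state are quantified here:

* **DAPI coefficient of variation.** Heterochromatin shows up as bright DAPI
  foci against a smoother euchromatic background, so the per-nucleus
  coefficient of variation (CV = standard deviation / mean of pixel
  intensities inside the nuclear mask) rises with condensation and falls as
  chromatin decondenses.

* **Nuclease-digestion densitometry.** Micrococcal-nuclease digestion of
  accessible chromatin yields a ladder of mono-/di-/tri-nucleosomal DNA
  fragments plus a sub-nucleosomal smear.  A lane's densitometry profile on a
  log10(bp) migration axis is decomposed into Gaussian band components plus a
  smear component by non-negative least squares; the accessibility score is
  the smear plus mononucleosome share (the fully digested end of the ladder).
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Sequence

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator, TransformerMixin

log = logging.getLogger(__name__)

__all__ = [
    "NuclearImage",
    "CondensationStats",
    "GelLaneProfile",
    "FragmentDistribution",
    "GelBandMixture",
    "dapi_cv",
    "compare_cv_groups",
    "lane_densitometry",
    "accessibility_shift",
    "GroupComparison",
    "band_basis",
]


@dataclasses.dataclass(frozen=True)
class NuclearImage:
    """A 2-D intensity grid plus a binary mask delimiting the nucleus."""

    pixels: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        mk = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "mask", mk)
        if px.ndim != 2 or px.shape != mk.shape:
            raise ValueError("pixels and mask must be 2-D arrays of equal shape")
        if np.any(px < 0):
            raise ValueError("pixel intensities must be non-negative")
        if int(mk.sum()) < 25:
            raise ValueError("mask must cover at least 25 pixels")


@dataclasses.dataclass(frozen=True)
class CondensationStats:
    """Per-nucleus DAPI summary; cv = sd / mean over masked pixels."""

    mean_intensity: float
    sd_intensity: float
    cv: float

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be non-negative")
        if abs(self.cv - self.sd_intensity / self.mean_intensity) > 1e-12 * max(1.0, self.cv):
            raise ValueError("cv must equal sd/mean")


def dapi_cv(image: NuclearImage) -> CondensationStats:
    """Coefficient of variation of DAPI intensity within the nuclear mask.

    Uses the population standard deviation.  Scale-invariant: multiplying all
    intensities by a positive constant leaves the CV unchanged.
    """
    vals = image.pixels[image.mask]
    mean = float(vals.mean())
    if mean == 0:
        raise ValueError("mean masked intensity is zero; CV undefined")
    sd = float(vals.std(ddof=0))
    return CondensationStats(mean, sd, sd / mean)


@dataclasses.dataclass(frozen=True)
class GroupComparison:
    """Two-group summary (A vs B): means, SEMs and a two-sample test."""

    mean_a: float
    sem_a: float
    n_a: int
    mean_b: float
    sem_b: float
    n_b: int
    effect: float  # mean_a - mean_b
    statistic: float
    p_value: float
    method: str


def _as_values(group: Sequence) -> np.ndarray:
    return np.asarray(
        [g.cv if isinstance(g, CondensationStats) else float(g) for g in group], dtype=float
    )


def compare_cv_groups(
    group_a: Sequence, group_b: Sequence, method: str = "welch"
) -> GroupComparison:
    """Compare per-nucleus CV between two conditions.

    ``method`` is ``"welch"`` (default, Welch's t) or ``"mannwhitney"``.
    Each group needs at least 3 nuclei.  The effect is mean(A) - mean(B).
    """
    a, b = _as_values(group_a), _as_values(group_b)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 nuclei")
    if method == "welch":
        stat, p = stats.ttest_ind(a, b, equal_var=False)
    elif method == "mannwhitney":
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise ValueError(f"unknown method {method!r}")
    return GroupComparison(
        float(a.mean()),
        float(a.std(ddof=1) / math.sqrt(len(a))),
        len(a),
        float(b.mean()),
        float(b.std(ddof=1) / math.sqrt(len(b))),
        len(b),
        float(a.mean() - b.mean()),
        float(stat),
        float(p),
        method,
    )


@dataclasses.dataclass(frozen=True)
class GelLaneProfile:
    """Densitometry of one gel lane on a log10(bp) migration axis."""

    positions: np.ndarray  # log10 base pairs, strictly monotone
    intensities: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        ints = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "intensities", ints)
        if pos.ndim != 1 or pos.shape != ints.shape:
            raise ValueError("positions and intensities must be 1-D and equally long")
        if len(pos) < 20:
            raise ValueError("profile needs at least 20 points")
        d = np.diff(pos)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("positions must be strictly monotone")
        if np.any(ints < 0):
            raise ValueError("intensities must be non-negative")


@dataclasses.dataclass(frozen=True)
class FragmentDistribution:
    """Fragment-size decomposition of a digestion lane.

    ``accessibility = smear_fraction + band_fractions[0]`` — the
    sub-nucleosomal smear plus the mononucleosome band, i.e. the fully
    digested share of the lane.
    """

    band_fractions: tuple[float, ...]
    smear_fraction: float
    accessibility: float

    def __post_init__(self) -> None:
        w = (*self.band_fractions, self.smear_fraction)
        if any(x < 0 for x in w):
            raise ValueError("weights must be non-negative")
        if abs(sum(w) - 1.0) > 1e-6:
            raise ValueError("weights must sum to 1")
        if not (0 <= self.accessibility <= 1 + 1e-9):
            raise ValueError("accessibility must lie in [0, 1]")


def band_basis(
    positions: np.ndarray,
    band_centers_bp: Sequence[float] = (147.0, 320.0, 500.0),
    band_sigma_logbp: float = 0.05,
    smear_center_bp: float = 80.0,
    smear_sigma_logbp: float = 0.30,
) -> np.ndarray:
    """Design matrix of unit-integral Gaussian components on the log-bp axis.

    Columns: one per nucleosomal band (mono, di, tri by default) followed by
    the broad sub-nucleosomal smear.  Each column is normalized to unit
    trapezoidal integral over ``positions`` so fitted weights are mass
    fractions.
    """
    pos = np.asarray(positions, dtype=float)
    centers = [math.log10(c) for c in band_centers_bp]
    sigmas = [band_sigma_logbp] * len(centers)
    centers.append(math.log10(smear_center_bp))
    sigmas.append(smear_sigma_logbp)
    cols = []
    for mu, sg in zip(centers, sigmas):
        col = np.exp(-0.5 * ((pos - mu) / sg) ** 2)
        area = np.trapezoid(col, pos)
        if area <= 0:
            raise ValueError(f"band at log10bp={mu:.3f} has no mass on the profile axis")
        cols.append(col / area)
    return np.column_stack(cols)


class GelBandMixture(TransformerMixin, BaseEstimator):
    """Nucleosomal-ladder mixture model for gel-lane densitometry.

    Decomposes a lane profile into Gaussian nucleosomal bands plus a broad
    sub-nucleosomal smear by non-negative least squares on the log10(bp)
    axis; fitted weights are renormalized to mass fractions.

    Attributes
    ----------
    band_fractions_ : ndarray
        Mass fraction of each nucleosomal band (mono, di, tri, ...).
    smear_fraction_ : float
    accessibility_ : float
        ``smear_fraction_ + band_fractions_[0]``.
    rss_ : float
    """

    def __init__(
        self,
        band_centers_bp: Sequence[float] = (147.0, 320.0, 500.0),
        band_sigma_logbp: float = 0.05,
        smear_center_bp: float = 80.0,
        smear_sigma_logbp: float = 0.30,
    ):
        self.band_centers_bp = band_centers_bp
        self.band_sigma_logbp = band_sigma_logbp
        self.smear_center_bp = smear_center_bp
        self.smear_sigma_logbp = smear_sigma_logbp

    def fit(self, X, y=None):
        """Fit to a profile: X = positions (log10 bp), y = intensities."""
        pos = np.asarray(X, dtype=float)
        if pos.ndim == 2 and pos.shape[1] == 1:
            pos = pos[:, 0]
        ints = np.asarray(y, dtype=float)
        if np.all(ints == 0):
            raise ValueError("all-zero profile; no mass to decompose")
        lo, hi = float(np.min(pos)), float(np.max(pos))
        for c in self.band_centers_bp:
            if not (lo <= math.log10(c) <= hi):
                raise ValueError(f"band center {c} bp lies outside the profile range")
        basis = band_basis(
            pos,
            self.band_centers_bp,
            self.band_sigma_logbp,
            self.smear_center_bp,
            self.smear_sigma_logbp,
        )
        w, rnorm = optimize.nnls(basis, ints)
        total = w.sum()
        if total <= 0:
            raise ValueError("degenerate decomposition: zero total weight")
        w = w / total
        self.band_fractions_ = w[:-1]
        self.smear_fraction_ = float(w[-1])
        self.accessibility_ = float(w[-1] + w[0])
        self.rss_ = float(rnorm**2)
        self._basis_args = (pos,)
        return self

    def transform(self, X):
        """Return the fitted weight vector (bands..., smear) as one row."""
        return np.concatenate([self.band_fractions_, [self.smear_fraction_]])[None, :]


def lane_densitometry(profile: GelLaneProfile, band_model=None) -> FragmentDistribution:
    """Decompose a lane profile into band + smear mass fractions.

    ``band_model`` may be a :class:`GelBandMixture`, anything exposing the
    generator-style band attributes (``band_centers_bp``/``band_centers``,
    ``band_sigma_logbp``, ``smear_center_bp``, ``smear_sigma_logbp``), or
    None for the default 147/320/500 bp ladder.
    """
    if band_model is None:
        est = GelBandMixture()
    elif isinstance(band_model, GelBandMixture):
        est = band_model
    else:
        centers = getattr(band_model, "band_centers_bp", None)
        if centers is None:
            centers = getattr(band_model, "band_centers")
        est = GelBandMixture(
            band_centers_bp=tuple(centers),
            band_sigma_logbp=getattr(band_model, "band_sigma_logbp", 0.05),
            smear_center_bp=getattr(band_model, "smear_center_bp", 80.0),
            smear_sigma_logbp=getattr(band_model, "smear_sigma_logbp", 0.30),
        )
    est.fit(profile.positions, profile.intensities)
    return FragmentDistribution(
        tuple(float(x) for x in est.band_fractions_),
        est.smear_fraction_,
        est.accessibility_,
    )


def accessibility_shift(dist_a: FragmentDistribution, dist_b: FragmentDistribution) -> float:
    """Signed accessibility difference, A - B (positive = A more digested)."""
    return dist_a.accessibility - dist_b.accessibility
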