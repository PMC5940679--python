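"""Synthetic-data generators with known ground truth.

Every input the analysis stack consumes can be generated here with its
generating parameters returned alongside, so each downstream stage can be
tested as a round trip against known truth:

* FLIP decay traces from the three-state polymerase model;
* nuclei as a smooth euchromatic background plus bright heterochromatic
  Gaussian foci inside an elliptical mask;
* nuclease-digestion gel lanes as a nucleosomal ladder (mono/di/tri bands on
  a log-bp axis) plus a sub-nucleosomal smear;
* ChIP-seq peak tables with an IgG background, condition-specific peaks and
  an engineered cross-antibody containment fraction;
* paired incorporation time courses with a controlled initial-rate ratio.

Each generator is a pure function of its config (same config + seed gives
identical output) and draws all randomness from the single seed it is given.
"""

from __future__ import annotations

import dataclasses
import math
from typing import NamedTuple, Sequence

import numpy as np
from numpy.random import default_rng

from .assays import IncorporationCurve
from .chromatin import GelLaneProfile, NuclearImage, band_basis
from .flip import FLIPProtocol, FLIPTrace, PolIIKineticModel, simulate_flip
from .peaks import PeakRecord, PeakSet

__all__ = [
    "FLIPSimConfig",
    "ImageSimConfig",
    "GelSimConfig",
    "PeakSimConfig",
    "CurveSimConfig",
    "EUTP_PRESET",
    "SpotParams",
    "gen_flip_trace",
    "gen_nuclear_image",
    "gen_gel_lane",
    "gen_peak_tables",
    "gen_incorporation_curves",
]


@dataclasses.dataclass(frozen=True)
class FLIPSimConfig:
    """FLIP trace generation: kinetic model + protocol + measurement noise."""

    model: PolIIKineticModel
    protocol: FLIPProtocol = FLIPProtocol()
    n_molecules: int = 10_000
    noise_sd: float = 0.0
    mode: str = "deterministic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.mode not in ("deterministic", "stochastic"):
            raise ValueError(f"mode must be deterministic|stochastic, got {self.mode!r}")
        if self.mode == "stochastic" and self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1 in stochastic mode")


def gen_flip_trace(config: FLIPSimConfig) -> tuple[FLIPTrace, PolIIKineticModel]:
    """Simulate one FLIP trace; returns (trace, ground-truth model)."""
    trace = simulate_flip(
        config.model,
        config.protocol,
        noise_sd=config.noise_sd,
        seed=config.seed,
        mode=config.mode,
        n_molecules=config.n_molecules,
    )
    return trace, config.model


class SpotParams(NamedTuple):
    row: float
    col: float
    amplitude: float
    sigma: float


@dataclasses.dataclass(frozen=True)
class ImageSimConfig:
    """Synthetic nucleus: elliptical mask, flat background, bright foci."""

    width: int = 128
    height: int = 128
    nucleus_axes: tuple[float, float] = (50.0, 40.0)  # (col, row) semi-axes
    background_level: float = 100.0
    background_noise_sd: float = 5.0
    n_spots: int = 10
    spot_amplitude: float = 100.0
    spot_sigma: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_level < 0 or self.background_noise_sd < 0 or self.spot_amplitude < 0:
            raise ValueError("intensity parameters must be >= 0")
        if self.n_spots < 0:
            raise ValueError("n_spots must be >= 0")
        if self.spot_sigma <= 0:
            raise ValueError("spot_sigma must be positive")


def gen_nuclear_image(config: ImageSimConfig) -> tuple[NuclearImage, list[SpotParams]]:
    """Render a nucleus image; returns (image, true spot parameters)."""
    rng = default_rng(config.seed)
    rows = np.arange(config.height)[:, None]
    cols = np.arange(config.width)[None, :]
    cy, cx = (config.height - 1) / 2.0, (config.width - 1) / 2.0
    ax, ay = config.nucleus_axes
    mask = ((cols - cx) / ax) ** 2 + ((rows - cy) / ay) ** 2 <= 1.0

    img = np.full((config.height, config.width), config.background_level, dtype=float)
    if config.background_noise_sd > 0:
        img += rng.normal(0.0, config.background_noise_sd, img.shape)

    spots: list[SpotParams] = []
    while len(spots) < config.n_spots:
        r = rng.uniform(0, config.height)
        c = rng.uniform(0, config.width)
        if ((c - cx) / ax) ** 2 + ((r - cy) / ay) ** 2 > 1.0:
            continue  # spots live inside the nucleus only
        spots.append(SpotParams(r, c, config.spot_amplitude, config.spot_sigma))
        img += config.spot_amplitude * np.exp(
            -((rows - r) ** 2 + (cols - c) ** 2) / (2.0 * config.spot_sigma**2)
        )
    np.clip(img, 0.0, None, out=img)
    return NuclearImage(img, mask), spots


@dataclasses.dataclass(frozen=True)
class GelSimConfig:
    """Nucleosomal-ladder gel lane on a log10(bp) migration axis.

    Band centers default to the mono/di/tri-nucleosome convention of
    147/320/500 bp (a documented convention, not a calibration).  The
    sub-nucleosomal smear is a broad component centred at ``smear_center_bp``.
    """

    band_centers_bp: tuple[float, ...] = (147.0, 320.0, 500.0)
    band_weights: tuple[float, ...] = (0.5, 0.3, 0.2)
    smear_weight: float = 0.0
    band_sigma_logbp: float = 0.05
    smear_center_bp: float = 80.0
    smear_sigma_logbp: float = 0.30
    n_points: int = 400
    axis_range_bp: tuple[float, float] = (40.0, 1000.0)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.band_weights) != len(self.band_centers_bp):
            raise ValueError("one weight per band center required")
        if any(w < 0 for w in self.band_weights) or self.smear_weight < 0:
            raise ValueError("weights must be non-negative")
        if abs(sum(self.band_weights) + self.smear_weight - 1.0) > 1e-9:
            raise ValueError("band_weights + smear_weight must sum to 1")
        if self.n_points < 20:
            raise ValueError("need at least 20 profile points")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def gen_gel_lane(config: GelSimConfig) -> tuple[GelLaneProfile, dict[str, float]]:
    """Render a lane profile; returns (profile, true weights).

    Before noise the profile integrates to 1 over the migration axis.
    """
    rng = default_rng(config.seed)
    lo, hi = config.axis_range_bp
    pos = np.linspace(math.log10(lo), math.log10(hi), config.n_points)
    basis = band_basis(
        pos,
        config.band_centers_bp,
        config.band_sigma_logbp,
        config.smear_center_bp,
        config.smear_sigma_logbp,
    )
    weights = np.array([*config.band_weights, config.smear_weight])
    intensity = basis @ weights
    intensity /= np.trapezoid(intensity, pos)  # unit integrated intensity
    if config.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, config.noise_sd, len(pos))
        np.clip(intensity, 0.0, None, out=intensity)
    truth = {f"band_{int(c)}bp": w for c, w in zip(config.band_centers_bp, config.band_weights)}
    truth["smear"] = config.smear_weight
    return GelLaneProfile(pos, intensity), truth


@dataclasses.dataclass(frozen=True)
class PeakSimConfig:
    """Synthetic ChIP-seq peak tables across antibodies and conditions.

    Five labelled tables are produced: ``control`` and ``condition``
    (PhosphoS5-style, sharing one ``igg`` background), plus a
    ``total_antibody``/``s5_antibody`` pair whose interval overlap is
    engineered to hit ``containment_target`` exactly (rounded to a whole
    peak count).  ``n_contaminated`` condition/control peaks are placed on
    IgG intervals to exercise background subtraction.
    """

    n_control: int = 200
    n_condition: int = 300
    n_igg: int = 50
    n_total_antibody: int = 1000
    n_s5_antibody: int = 400
    containment_target: float = 0.9
    n_contaminated: int = 0
    fe_range: tuple[float, float] = (5.0, 60.0)
    logp_range: tuple[float, float] = (3.0, 30.0)
    genome_length: int = 50_000_000
    n_chroms: int = 5
    peak_width: tuple[int, int] = (150, 400)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.containment_target <= 1.0):
            raise ValueError("containment_target must lie in [0, 1]")
        for n in (self.n_control, self.n_condition, self.n_igg,
                  self.n_total_antibody, self.n_s5_antibody):
            if n < 0:
                raise ValueError("peak counts must be >= 0")
        if self.n_contaminated > min(self.n_control, self.n_condition):
            raise ValueError("n_contaminated cannot exceed the smaller sample count")
        if self.peak_width[0] < 2 or self.peak_width[1] < self.peak_width[0]:
            raise ValueError("invalid peak_width range")


def _make_record(rng, chrom, start, width, chrom_len, name, fe_range, logp_range) -> PeakRecord:
    end = min(start + width, chrom_len)
    fe = rng.uniform(*fe_range)
    logp = rng.uniform(*logp_range)
    return PeakRecord(
        chrom=chrom,
        start=int(start),
        end=int(end),
        name=name,
        score=int(min(1000, 10 * logp)),
        strand=".",
        fold_enrichment=float(fe),
        p_value=float(10.0 ** (-logp)),
        summit=int((end - start) // 2),
    )


def gen_peak_tables(config: PeakSimConfig) -> dict[str, PeakSet]:
    """Generate the five labelled peak tables with engineered overlaps.

    Peaks are laid out on a slot grid (one slot fits the widest peak plus
    its engineered-overlap partner and a guard gap) so that only the
    intended overlaps exist.  Raises if the requested counts exceed the
    genome's slot capacity.
    """
    rng = default_rng(config.seed)
    wmin, wmax = config.peak_width
    slot = 2 * wmax + 100  # room for a peak, its overlap partner, and a gap
    chrom_len = config.genome_length // config.n_chroms
    slots_per_chrom = chrom_len // slot
    total_slots = slots_per_chrom * config.n_chroms

    n_contained = round(config.containment_target * config.n_s5_antibody)
    if n_contained > config.n_total_antibody:
        raise ValueError("containment target needs more total-antibody peaks than configured")
    n_disjoint = (
        config.n_igg
        + config.n_control
        + config.n_condition
        - 2 * config.n_contaminated
        + config.n_total_antibody
        + (config.n_s5_antibody - n_contained)
    )
    if n_disjoint > total_slots:
        raise ValueError(
            f"requested {n_disjoint} disjoint peaks but the genome holds only "
            f"{total_slots} slots at minimum spacing"
        )

    chosen = rng.choice(total_slots, size=n_disjoint, replace=False)
    slot_iter = iter(chosen)

    def place(name: str) -> PeakRecord:
        s = next(slot_iter)
        chrom_i, slot_i = divmod(int(s), slots_per_chrom)
        width = int(rng.integers(wmin, wmax + 1))
        start = slot_i * slot + int(rng.integers(0, 50))
        return _make_record(
            rng, f"chr{chrom_i + 1}", start, width, chrom_len, name,
            config.fe_range, config.logp_range,
        )

    igg = [place(f"igg_{i}") for i in range(config.n_igg)]
    control = [place(f"ctrl_{i}") for i in range(config.n_control - config.n_contaminated)]
    condition = [place(f"cond_{i}") for i in range(config.n_condition - config.n_contaminated)]
    total = [place(f"total_{i}") for i in range(config.n_total_antibody)]
    s5_free = [place(f"s5_free_{i}") for i in range(config.n_s5_antibody - n_contained)]

    # contaminated sample peaks sit directly on IgG intervals
    for j in range(config.n_contaminated):
        host = igg[int(rng.integers(0, len(igg)))]
        for bucket, tag in ((control, "ctrl_cont"), (condition, "cond_cont")):
            bucket.append(
                PeakRecord(
                    host.chrom, host.start, host.end, f"{tag}_{j}",
                    host.score, ".", float(rng.uniform(*config.fe_range)),
                    float(10.0 ** (-rng.uniform(*config.logp_range))),
                    (host.end - host.start) // 2,
                )
            )

    # contained s5 peaks overlap a distinct total-antibody host each
    hosts = rng.choice(len(total), size=n_contained, replace=False)
    s5_contained = []
    for i, hi in enumerate(hosts):
        h = total[int(hi)]
        mid = (h.start + h.end) // 2
        width = int(rng.integers(wmin, wmax + 1))
        s5_contained.append(
            _make_record(
                rng, h.chrom, mid, width, chrom_len, f"s5_in_{i}",
                config.fe_range, config.logp_range,
            )
        )

    out = {
        "control": PeakSet(control, "control"),
        "condition": PeakSet(condition, "condition"),
        "igg": PeakSet(igg, "igg"),
        "total_antibody": PeakSet(total, "total_antibody"),
        "s5_antibody": PeakSet(s5_contained + s5_free, "s5_antibody"),
    }
    expected = {
        "control": config.n_control,
        "condition": config.n_condition,
        "igg": config.n_igg,
        "total_antibody": config.n_total_antibody,
        "s5_antibody": config.n_s5_antibody,
    }
    for k, n in expected.items():
        assert len(out[k]) == n, f"{k}: {len(out[k])} != {n}"
    return out


@dataclasses.dataclass(frozen=True)
class CurveSimConfig:
    """Paired incorporation curves with a controlled initial-rate ratio.

    Control follows ``S(t) = saturation_level * (1 - exp(-rate_constant t))``;
    the condition shares the rate constant with its amplitude scaled by
    ``baseline_rate_ratio``, so both the initial-rate ratio and the
    fitted-AUC ratio over any window equal ``baseline_rate_ratio`` exactly.
    """

    baseline_rate_ratio: float = 1.54
    saturation_level: float = 100.0
    rate_constant: float = 0.02  # per minute
    times: tuple[float, ...] = tuple(float(t) for t in range(0, 101, 10))
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.times)
        if t[0] != 0 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing, starting at 0")
        if self.noise_sd < 0 or self.saturation_level <= 0 or self.rate_constant <= 0:
            raise ValueError("invalid curve parameters")
        if self.baseline_rate_ratio <= 0:
            raise ValueError("baseline_rate_ratio must be positive")


# The shipped EUTP preset: hyposmotic-vs-control initial-rate ratio 1.54,
# 11 samples over 100 min, noise 1% of the control saturation level.
EUTP_PRESET = CurveSimConfig(noise_sd=1.0)


class IncorporationPair(NamedTuple):
    control: IncorporationCurve
    condition: IncorporationCurve
    true_ratio: float


def gen_incorporation_curves(config: CurveSimConfig) -> IncorporationPair:
    """Generate (control, condition) curves; returns the true rate ratio too."""
    rng = default_rng(config.seed)
    t = np.asarray(config.times, dtype=float)
    base = 1.0 - np.exp(-config.rate_constant * t)
    ctrl = config.saturation_level * base
    cond = config.saturation_level * config.baseline_rate_ratio * base
    if config.noise_sd > 0:
        ctrl = ctrl + rng.normal(0.0, config.noise_sd, len(t))
        cond = cond + rng.normal(0.0, config.noise_sd, len(t))
        ctrl = np.clip(ctrl, 0.0, None)
        cond = np.clip(cond, 0.0, None)
    return IncorporationPair(
        IncorporationCurve(t, ctrl), IncorporationCurve(t, cond), config.baseline_rate_ratio
    )
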