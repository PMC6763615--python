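"""Ground-truth simulators for phospho-array cohorts, membranes and IHC.

Every downstream stage of the pipeline (densitometry, profiling,
activation calling, clustering) is exercised against data generated here,
because the arrays' patient membranes are not public. The generator
emulates:

* a two-group tumour cohort (default 5 + 7 samples, mirroring a small
  neuroblastoma vs. CNS-tumour comparison) with lognormal latent
  phosphorylation levels and a log2 effect-size shift planted in a set of
  group-specific analytes;
* duplicate-spotted membranes with three positive-reference pairs, one
  PBS negative pair, a background plane with optional gradient, additive
  pixel noise and multiplicative duplicate-spot jitter;
* serial samples under per-analyte multiplicative inhibitor effects;
* ordinal IHC scores obtained by binning true levels at three cut points
  with optional one-level misclassification.

All generators are deterministic under the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortMatrix
from .errors import ConfigError, SaturationError
from .layouts import ArrayLayout, builtin_layout

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_cohort",
    "render_membrane",
    "simulate_serial",
    "simulate_ihc",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort and membrane renderer.

    Latent per-analyte phosphorylation levels are lognormal:
    log2(level) ~ Normal(base_log2_mean, base_log2_sd). Group effects add
    ``effect_size`` in log2 space to ``n_affected_analytes`` analytes per
    group (disjoint sets). Measured cohort values multiply the truth by
    2**Normal(0, measurement_log2_sd). Rendered spot pixels add
    ``level * gain`` uniformly over the duplicate discs, each disc jittered
    by a unit-mean lognormal factor with coefficient of variation
    ``duplicate_cv``.
    """

    n_samples: int = 12
    group_sizes: tuple[int, ...] = (5, 7)
    group_names: tuple[str, ...] = ("NB", "CNS")
    effect_size: float = 3.0
    n_affected_analytes: int = 6
    base_log2_mean: float = 8.0
    base_log2_sd: float = 1.0
    measurement_log2_sd: float = 0.25
    duplicate_cv: float = 0.05
    background_level: float = 500.0
    background_gradient: float = 0.0
    noise_sd: float = 5.0
    # PBS-only spots retain a small nonspecific residual above the membrane
    # background, as on real film; a perfectly blank negative would make any
    # negative-control-based cut-off collapse to pixel noise.
    reference_intensity: float = 4096.0
    negative_intensity: float = 30.0
    gain: float = 1.0
    spot_shape: str = "disc"
    bit_depth: int = 16
    allow_clipping: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.group_sizes) != self.n_samples:
            raise ConfigError(
                f"group_sizes {self.group_sizes} must sum to n_samples {self.n_samples}"
            )
        if len(self.group_names) != len(self.group_sizes):
            raise ConfigError("group_names and group_sizes must have equal length")
        if self.duplicate_cv < 0:
            raise ConfigError("duplicate_cv must be >= 0")
        if self.bit_depth not in (8, 16):
            raise ConfigError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        maxval = 2**self.bit_depth - 1
        for name in ("background_level", "reference_intensity", "negative_intensity"):
            v = getattr(self, name)
            if not (0 <= v <= maxval):
                raise ConfigError(f"{name}={v} outside [0, {maxval}] for {self.bit_depth}-bit")
        if self.spot_shape not in ("disc", "gaussian"):
            raise ConfigError(f"spot_shape must be 'disc' or 'gaussian', got {self.spot_shape!r}")

    @property
    def n_groups(self) -> int:
        return len(self.group_sizes)

    @property
    def max_value(self) -> int:
        return 2**self.bit_depth - 1


@dataclass(frozen=True)
class GroundTruth:
    """Latent truth behind a simulated cohort."""

    true_levels: pd.DataFrame
    affected_sets: dict[str, tuple[str, ...]]
    group_labels: pd.Series

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for group, analytes in self.affected_sets.items():
            overlap = seen.intersection(analytes)
            if overlap:
                raise ConfigError(f"affected sets overlap across groups: {sorted(overlap)}")
            seen.update(analytes)
        if (self.true_levels.to_numpy() <= 0).any():
            raise ConfigError("true levels must be strictly positive")


def _rng(config: SimulationConfig, salt: int = 0) -> np.random.Generator:
    return np.random.default_rng((config.seed, salt))


def simulate_cohort(
    config: SimulationConfig,
    layout: ArrayLayout | None = None,
) -> tuple[CohortMatrix, GroundTruth]:
    """Draw a two-or-more-group cohort of measured phospho-profiles.

    Returns the measured matrix (truth times multiplicative measurement
    noise) and the latent :class:`GroundTruth`.
    """
    layout = layout if layout is not None else builtin_layout("RTK")
    targets = list(layout.target_names)
    total_affected = config.n_affected_analytes * config.n_groups
    if total_affected > len(targets):
        raise ConfigError(
            f"{config.n_affected_analytes} affected analytes x {config.n_groups} groups "
            f"exceeds the {len(targets)} targets on the {layout.array_id} layout"
        )

    rng = _rng(config, salt=1)
    sample_ids = [f"S{i + 1:02d}" for i in range(config.n_samples)]
    groups = np.repeat(list(config.group_names), list(config.group_sizes))

    chosen = rng.choice(len(targets), size=total_affected, replace=False)
    affected_sets = {
        g: tuple(targets[j] for j in chosen[i * config.n_affected_analytes : (i + 1) * config.n_affected_analytes])
        for i, g in enumerate(config.group_names)
    }

    log2_levels = rng.normal(
        config.base_log2_mean, config.base_log2_sd, size=(config.n_samples, len(targets))
    )
    col_index = {t: j for j, t in enumerate(targets)}
    for g, analytes in affected_sets.items():
        rows = np.flatnonzero(groups == g)
        cols = [col_index[a] for a in analytes]
        log2_levels[np.ix_(rows, cols)] += config.effect_size

    truth = pd.DataFrame(2.0**log2_levels, index=sample_ids, columns=targets)
    noise = 2.0 ** rng.normal(0.0, config.measurement_log2_sd, size=truth.shape)
    measured = truth * noise

    group_labels = pd.Series(groups, index=sample_ids, name="group")
    meta = pd.DataFrame(
        {"group": groups, "patient_id": sample_ids, "timepoint": 0}, index=sample_ids
    )
    matrix = CohortMatrix(measured, meta)
    gt = GroundTruth(true_levels=truth, affected_sets=affected_sets, group_labels=group_labels)
    return matrix, gt


# ---------------------------------------------------------------------------
# Membrane rendering


def _spot_patch(
    shape: tuple[int, int], cx: float, cy: float, r: float, kind: str
) -> tuple[slice, slice, np.ndarray, int]:
    """Bounding-box slices and unit-sum spatial profile of one spot.

    The profile sums to 1 over the pixels whose centers fall inside the
    disc, so depositing ``total * profile`` gives an integrated density
    of exactly ``total``.
    """
    h, w = shape
    x0, x1 = max(0, int(np.floor(cx - r))), min(w, int(np.ceil(cx + r)) + 1)
    y0, y1 = max(0, int(np.floor(cy - r))), min(h, int(np.ceil(cy + r)) + 1)
    yy, xx = np.ogrid[y0:y1, x0:x1]
    mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
    n = int(mask.sum())
    if kind == "disc":
        prof = mask / n
    else:
        sigma = r / 2.0
        g = np.exp(-(((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2))) * mask
        prof = g / g.sum()
    return slice(y0, y1), slice(x0, x1), prof, n


def render_membrane(
    profile: dict[str, float] | pd.Series,
    layout: ArrayLayout,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, dict]:
    """Render one sample's membrane image from its true analyte levels.

    Each analyte spot deposits an integrated intensity of
    ``level * gain * n_pixels_of_its_disc`` spread over the disc (uniform
    by default, truncated-Gaussian optional), so integrated density above
    background is proportional to the latent level. Positive references
    render at ``reference_intensity`` and the negative control at
    ``negative_intensity``. Returns the integer image and a metadata dict
    with the saturated-pixel fraction.
    """
    profile = dict(profile)
    missing = [t for t in layout.target_names if t not in profile]
    if missing:
        raise ConfigError(f"profile missing levels for layout targets: {missing}")
    if rng is None:
        rng = _rng(config, salt=2)

    shape = layout.image_shape()
    h, w = shape
    xx = np.linspace(-0.5, 0.5, w)[None, :]
    image = config.background_level * (1.0 + config.background_gradient * xx) * np.ones(
        (h, 1)
    )

    cv = config.duplicate_cv
    if cv > 0:
        sigma = np.sqrt(np.log1p(cv**2))
        mu = -(sigma**2) / 2.0
    for analyte in layout.analytes:
        if analyte.kind == "target":
            level = float(profile[analyte.name])
        elif analyte.kind == "positive_reference":
            level = config.reference_intensity
        else:
            level = config.negative_intensity
        for spot in analyte.spots:
            jitter = float(rng.lognormal(mu, sigma)) if cv > 0 else 1.0
            ys, xs, prof, n_px = _spot_patch(
                shape, spot.center_x, spot.center_y, spot.radius, config.spot_shape
            )
            image[ys, xs] += (level * jitter * config.gain * n_px) * prof

    if config.noise_sd > 0:
        image = image + rng.normal(0.0, config.noise_sd, size=image.shape)

    maxval = config.max_value
    over = image > maxval
    under = image < 0
    if over.any() and not config.allow_clipping:
        raise SaturationError(
            f"{int(over.sum())} pixels exceed the {config.bit_depth}-bit maximum "
            "and clipping is disabled"
        )
    image = np.clip(image, 0, maxval)
    dtype = np.uint8 if config.bit_depth == 8 else np.uint16
    quantized = np.round(image).astype(dtype)
    meta = {
        "bit_depth": config.bit_depth,
        "saturated_fraction": float(over.mean()),
        "clipped_low_fraction": float(under.mean()),
        "saturated": bool(over.any()),
    }
    return quantized, meta


# ---------------------------------------------------------------------------
# Serial samples


def simulate_serial(
    n_timepoints: int,
    inhibitor_effects: dict[str, float],
    config: SimulationConfig,
    layout: ArrayLayout | None = None,
    baseline: dict[str, float] | pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate serial profiles under per-interval multiplicative effects.

    ``inhibitor_effects`` maps analyte name to the multiplicative change
    applied per interval (e.g. 0.25 for a strong inhibitor response);
    unlisted analytes are stationary (factor 1). Returns (measured, truth)
    DataFrames of shape n_timepoints x targets; measured adds
    multiplicative lognormal noise per timepoint.
    """
    if n_timepoints < 1:
        raise ConfigError("n_timepoints must be >= 1")
    for name, eff in inhibitor_effects.items():
        if eff <= 0:
            raise ConfigError(f"inhibitor effect for {name!r} must be positive, got {eff}")
    layout = layout if layout is not None else builtin_layout("RTK")
    targets = list(layout.target_names)
    unknown = sorted(set(inhibitor_effects) - set(targets))
    if unknown:
        raise ConfigError(f"inhibitor_effects name analytes absent from layout: {unknown}")

    rng = _rng(config, salt=3)
    if baseline is None:
        base = 2.0 ** rng.normal(config.base_log2_mean, config.base_log2_sd, size=len(targets))
        baseline_s = pd.Series(base, index=targets)
    else:
        baseline_s = pd.Series(dict(baseline)).reindex(targets)
        if baseline_s.isna().any():
            raise ConfigError("baseline must cover all layout targets")

    factors = pd.Series({t: inhibitor_effects.get(t, 1.0) for t in targets})
    truth_rows = [baseline_s]
    for _ in range(1, n_timepoints):
        truth_rows.append(truth_rows[-1] * factors)
    truth = pd.DataFrame(truth_rows, index=[f"T{t}" for t in range(n_timepoints)])
    noise = 2.0 ** rng.normal(0.0, config.measurement_log2_sd, size=truth.shape)
    measured = truth * noise
    return measured, truth


# ---------------------------------------------------------------------------
# Ordinal IHC scores


def simulate_ihc(
    true_levels: pd.Series | np.ndarray,
    cut_points: tuple[float, float, float],
    misclassification_prob: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Bin true levels into ordinal scores 0..3 ("-", "+", "++", "+++").

    Each score is perturbed by one level (up or down, clipped to the
    scale) with probability ``misclassification_prob``, emulating
    inter-observer variability in semi-quantitative scoring.
    """
    cuts = np.asarray(cut_points, dtype=float)
    if cuts.size != 3 or not np.all(np.diff(cuts) > 0):
        raise ConfigError(f"cut_points must be 3 strictly increasing values, got {cut_points}")
    if not (0 <= misclassification_prob <= 1):
        raise ConfigError("misclassification_prob must be in [0, 1]")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    levels = np.asarray(true_levels, dtype=float)
    scores = np.searchsorted(cuts, levels, side="right").astype(int)
    if misclassification_prob > 0:
        flip = rng.random(scores.shape) < misclassification_prob
        direction = rng.choice([-1, 1], size=scores.shape)
        scores = np.where(flip, np.clip(scores + direction, 0, 3), scores)
    return scores


IHC_SYMBOLS = ("-", "+", "++", "+++")


def ihc_symbol(score: int) -> str:
    """Map an ordinal score 0..3 to its conventional symbol."""
    return IHC_SYMBOLS[int(score)]
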