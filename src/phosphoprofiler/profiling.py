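"""Profile views: absolute, %-of-max, %-of-total and reference-normalized.

A single-sample phospho-profile can be reported on four scales that are
rank-identical to one another:

* absolute averaged net density (arbitrary units);
* percent of the maximal density on the membrane (the top analyte reads
  exactly 100);
* percent of the total summed density (the profile sums to 100);
* density divided by the mean positive-reference signal, which cancels
  exposure differences between membranes.

By default the percent views are computed over target analytes only, so
the constant-intensity reference spots cannot mask biology; pass
``include_controls=True`` at construction to change that.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .densitometry import MembraneQuantification
from .errors import DegenerateProfileError, NormalizationError
from .layouts import ArrayLayout

__all__ = [
    "PhosphoProfile",
    "normalize_to_reference",
    "to_percent_of_max",
    "to_percent_of_total",
    "rank_targets",
]


@dataclass
class PhosphoProfile:
    """One sample's averaged net densities over target analytes."""

    sample_id: str
    array_id: str
    values: pd.Series
    reference_value: float
    views: dict[str, pd.Series] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.values < 0).any():
            bad = self.values.index[self.values < 0].tolist()
            raise NormalizationError(f"profile has negative densities: {bad}")

    @classmethod
    def from_quantification(
        cls,
        quantification: MembraneQuantification,
        layout: ArrayLayout,
        sample_id: str = "sample",
        include_controls: bool = False,
    ) -> "PhosphoProfile":
        net = quantification.analyte_net
        ref_names = [a.name for a in layout.positive_references]
        reference_value = float(net.loc[ref_names].mean())
        if include_controls:
            values = net.copy()
        else:
            values = net.loc[list(layout.target_names)].copy()
        return cls(
            sample_id=sample_id,
            array_id=layout.array_id,
            values=values.astype(float),
            reference_value=reference_value,
        )


def normalize_to_reference(profile: PhosphoProfile) -> pd.Series:
    """Divide every density by the mean positive-reference density.

    A zero (or negative) reference signal indicates membrane failure and
    raises rather than producing infinities.
    """
    if not profile.reference_value > 0:
        raise NormalizationError(
            f"reference value {profile.reference_value} is not positive "
            f"(membrane failure for sample {profile.sample_id!r})"
        )
    view = profile.values / profile.reference_value
    profile.views["reference_normalized"] = view
    return view


def to_percent_of_max(profile: PhosphoProfile) -> pd.Series:
    """Rescale so the most phosphorylated analyte reads exactly 100."""
    vmax = float(profile.values.max())
    if vmax <= 0:
        raise DegenerateProfileError(
            f"all-zero profile for sample {profile.sample_id!r}: percent-of-max undefined"
        )
    view = (profile.values / vmax) * 100.0
    profile.views["percent_of_max"] = view
    return view


def to_percent_of_total(profile: PhosphoProfile) -> pd.Series:
    """Rescale so the profile sums to 100."""
    total = float(profile.values.sum())
    if total <= 0:
        raise DegenerateProfileError(
            f"all-zero profile for sample {profile.sample_id!r}: percent-of-total undefined"
        )
    view = (profile.values / total) * 100.0
    profile.views["percent_of_total"] = view
    return view


def rank_targets(profile: PhosphoProfile, k: int = 6) -> pd.DataFrame:
    """Top-k analytes by absolute density with all normalized views.

    Ties are broken by profile (layout) order, so the report is
    deterministic. Requesting more entries than there are analytes
    truncates with a warning.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    n = len(profile.values)
    if k > n:
        warnings.warn(
            f"requested top {k} of only {n} analytes; truncating to {n}", stacklevel=2
        )
        k = n
    pct_max = to_percent_of_max(profile)
    pct_total = to_percent_of_total(profile)
    try:
        ref_norm = normalize_to_reference(profile)
    except NormalizationError:
        ref_norm = pd.Series(np.nan, index=profile.values.index)
    report = pd.DataFrame(
        {
            "absolute": profile.values,
            "pct_max": pct_max,
            "pct_total": pct_total,
            "ref_norm": ref_norm,
        }
    )
    # stable mergesort keeps layout order among tied densities
    report = report.sort_values("absolute", ascending=False, kind="mergesort").head(k)
    report.index.name = "analyte"
    return report
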