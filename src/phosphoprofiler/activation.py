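"""Activation calling, grading, IHC concordance and serial comparison.

Two binary calling schemes from the antibody-array literature are
implemented:

* ``mean_sd`` — log2-transform the target densities and call analytes
  whose value exceeds the mean plus one sample standard deviation of the
  membrane's own distribution;
* ``neg_control_x3`` — call analytes whose (unfloored) background-
  subtracted signal exceeds three times the highest negative-control
  spot signal.

A four-level ordinal grading of the percent-of-max view complements the
binary calls ("poorly" / "to a lower extent" / "moderately" / "strongly"
activated), and is the scale compared against semi-quantitative IHC
scores via a cross-table, exact agreement and Kendall tau-b with a
permutation p-value. Serial samples are compared as per-interval log2
fold changes on the reference-normalized view.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .densitometry import MembraneQuantification
from .errors import (
    ComparisonError,
    ConfigError,
    InsufficientDataError,
    PairingError,
    SchemeError,
)
from .profiling import PhosphoProfile, normalize_to_reference, to_percent_of_max

__all__ = [
    "ActivationCall",
    "ActivationGrade",
    "IHCScore",
    "SerialComparison",
    "call_mean_sd",
    "call_negative_control",
    "grade_activation",
    "ihc_concordance",
    "compare_serial",
    "GRADE_LABELS",
    "DEFAULT_GRADE_CUTS",
]

GRADE_LABELS = ("poorly", "lower_extent", "moderately", "strongly")
DEFAULT_GRADE_CUTS = (10.0, 50.0, 80.0)


@dataclass(frozen=True)
class ActivationCall:
    analyte: str
    scheme: str
    activated: bool
    statistic: float
    threshold: float

    def __post_init__(self) -> None:
        if self.activated != (self.statistic > self.threshold):
            raise ValueError("activated flag inconsistent with statistic/threshold")


@dataclass(frozen=True)
class ActivationGrade:
    analyte: str
    grade: str
    pct_max: float


@dataclass(frozen=True)
class IHCScore:
    """Ordinal immunohistochemistry scores for one sample and analyte.

    IR is staining intensity, DIST the spatial distribution; both on the
    conventional 0..3 scale (-, +, ++, +++).
    """

    sample_id: str
    analyte: str
    IR: int
    DIST: int

    def __post_init__(self) -> None:
        for name, v in (("IR", self.IR), ("DIST", self.DIST)):
            if not 0 <= int(v) <= 3:
                raise ConfigError(f"{name} score must be in 0..3, got {v}")


def call_mean_sd(profile: PhosphoProfile, pseudocount: float = 1.0) -> list[ActivationCall]:
    """Mean-plus-SD cut-off on log2-transformed target densities.

    The statistic is log2(net density + pseudocount); the threshold is
    the mean plus one sample SD (ddof=1) of the statistics over the
    membrane's target analytes. Controls are excluded: including the
    bright references would inflate both mean and SD.
    """
    values = profile.values
    if int((values > 0).sum()) < 2:
        raise InsufficientDataError(
            "mean+SD scheme needs at least 2 positive target densities"
        )
    stats_log2 = np.log2(values + pseudocount)
    mean = float(stats_log2.mean())
    sd = float(stats_log2.std(ddof=1))
    threshold = mean + sd
    return [
        ActivationCall(
            analyte=str(a),
            scheme="mean_sd",
            activated=bool(s > threshold),
            statistic=float(s),
            threshold=threshold,
        )
        for a, s in stats_log2.items()
    ]


def call_negative_control(
    quantification: MembraneQuantification, factor: float = 3.0
) -> list[ActivationCall]:
    """Cut-off at ``factor`` times the highest negative-control signal.

    Signals are background-subtracted but unfloored, so the threshold
    remains meaningful even when global background subtraction would
    zero the weak spots.
    """
    spots = quantification.spots
    neg = spots[spots["analyte"].isin(_negative_names(quantification))]
    if neg.empty:
        raise SchemeError("quantification has no negative-control spot measurements")
    threshold = factor * float(neg["signal_density"].max())
    controls = set(_negative_names(quantification)) | set(
        quantification.flags.get("positive_references", [])
    )
    calls = []
    for analyte, signal in quantification.analyte_signal.items():
        if analyte in controls:
            continue
        calls.append(
            ActivationCall(
                analyte=str(analyte),
                scheme="neg_control_x3",
                activated=bool(signal > threshold),
                statistic=float(signal),
                threshold=threshold,
            )
        )
    return calls


def _negative_names(quantification: MembraneQuantification) -> list[str]:
    return list(quantification.flags.get("negative_controls", []))


def grade_activation(
    pct_max_view: pd.Series,
    cut_points: tuple[float, float, float] = DEFAULT_GRADE_CUTS,
) -> list[ActivationGrade]:
    """Four-level ordinal grading of the percent-of-max view.

    Defaults (10, 50, 80): below 10 %max is "poorly" activated, 10-50
    "to a lower extent", 50-80 "moderately", 80 and above "strongly".
    """
    cuts = np.asarray(cut_points, dtype=float)
    if cuts.size != 3 or not np.all(np.diff(cuts) > 0) or cuts[0] <= 0 or cuts[-1] >= 100:
        raise ConfigError(
            f"cut_points must be 3 strictly increasing values inside (0, 100), got {cut_points}"
        )
    # boundary convention: a value equal to a cut point falls in the upper bin
    bins = np.searchsorted(cuts, pct_max_view.to_numpy(dtype=float), side="right")
    return [
        ActivationGrade(analyte=str(a), grade=GRADE_LABELS[b], pct_max=float(v))
        for a, b, v in zip(pct_max_view.index, bins, pct_max_view.to_numpy())
    ]


# ---------------------------------------------------------------------------
# IHC concordance


def _kendall_tau_b(x: np.ndarray, y: np.ndarray) -> float:
    tau = stats.kendalltau(x, y, variant="b").statistic
    return float(tau)


def _permutation_pvalue(
    x: np.ndarray, y: np.ndarray, observed_tau: float, max_exact_n: int = 10, rng_seed: int = 0
) -> tuple[float, str]:
    """Two-sided permutation p-value for Kendall tau-b.

    Exhaustive over all n! orderings of y for n <= ``max_exact_n``
    (processed in chunks); seeded Monte-Carlo with 20,000 draws beyond.
    """
    n = len(x)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    sx = np.array([np.sign(x[i] - x[j]) for i, j in pairs])
    # tau-b denominator is permutation-invariant, so comparing numerators
    # is equivalent to comparing tau values (when the denominator is > 0).
    obs_num = float(np.sum(sx * np.array([np.sign(y[i] - y[j]) for i, j in pairs])))

    def chunk_counts(perm_iter) -> tuple[int, int]:
        hits = total = 0
        chunk: list[tuple] = []

        def flush(chunk: list[tuple]) -> tuple[int, int]:
            P = np.asarray(chunk)
            sy = np.sign(P[:, [i for i, _ in pairs]] - P[:, [j for _, j in pairs]])
            nums = sy @ sx
            return int(np.sum(np.abs(nums) >= abs(obs_num) - 1e-9)), len(chunk)

        for p in perm_iter:
            chunk.append(p)
            if len(chunk) >= 100_000:
                h, t = flush(chunk)
                hits += h
                total += t
                chunk = []
        if chunk:
            h, t = flush(chunk)
            hits += h
            total += t
        return hits, total

    if n <= max_exact_n:
        hits, total = chunk_counts(itertools.permutations(y))
        return hits / total, "exact"
    rng = np.random.default_rng(rng_seed)
    draws = 20_000
    perms = (tuple(rng.permutation(y)) for _ in range(draws))
    hits, total = chunk_counts(perms)
    return (hits + 1) / (total + 1), "monte_carlo"


def ihc_concordance(
    array_pct_max: pd.Series,
    ihc_scores: list[IHCScore],
    analyte: str,
    cut_points: tuple[float, float, float] = DEFAULT_GRADE_CUTS,
) -> dict:
    """Concordance between array percent-of-max values and ordinal IHC.

    ``array_pct_max`` is indexed by sample id. The report contains the
    cross-table of array grade bins versus IR, Kendall tau-b between the
    continuous %max values and IR with a permutation p-value (exact for
    n <= 10), and the exact-agreement fraction of grade bin versus IR.
    DIST is tabulated but not part of the headline statistic.
    """
    scores = [s for s in ihc_scores if s.analyte == analyte]
    ihc_by_sample = {s.sample_id: s for s in scores}
    array_samples = set(map(str, array_pct_max.index))
    ihc_samples = set(ihc_by_sample)
    unmatched = sorted(array_samples ^ ihc_samples)
    if unmatched:
        raise PairingError(
            f"array and IHC samples do not pair for {analyte!r}; unmatched: {unmatched}"
        )
    if len(array_samples) < 3:
        raise InsufficientDataError("concordance needs at least 3 paired samples")

    sample_ids = sorted(array_samples)
    x = array_pct_max.loc[sample_ids].to_numpy(dtype=float)
    ir = np.array([ihc_by_sample[s].IR for s in sample_ids])
    dist = np.array([ihc_by_sample[s].DIST for s in sample_ids])
    grades = np.searchsorted(np.asarray(cut_points, dtype=float), x, side="right")

    cross = pd.crosstab(
        pd.Series(grades, name="array_grade"), pd.Series(ir, name="IR")
    ).reindex(index=range(4), columns=range(4), fill_value=0)
    cross_dist = pd.crosstab(
        pd.Series(grades, name="array_grade"), pd.Series(dist, name="DIST")
    ).reindex(index=range(4), columns=range(4), fill_value=0)

    if np.ptp(ir) == 0 or np.ptp(x) == 0:
        tau, pvalue, pmethod = None, None, "undefined (constant variable)"
    else:
        tau = _kendall_tau_b(x, ir)
        pvalue, pmethod = _permutation_pvalue(x, ir, tau)

    agreement = float(np.mean(grades == ir))
    return {
        "analyte": analyte,
        "n": len(sample_ids),
        "samples": sample_ids,
        "cross_table_ir": cross,
        "cross_table_dist": cross_dist,
        "kendall_tau_b": tau,
        "p_value": pvalue,
        "p_method": pmethod,
        "exact_agreement": agreement,
    }


# ---------------------------------------------------------------------------
# Serial comparison


@dataclass
class SerialComparison:
    patient_id: str
    timepoints: list
    view: str
    trajectories: pd.DataFrame
    log2_fold_changes: pd.DataFrame
    diminished: list[str]

    def to_tidy(self) -> pd.DataFrame:
        """Tidy (patient, timepoint, analyte, value, log2fc) table."""
        rows = []
        for ti, tp in enumerate(self.timepoints):
            for analyte in self.trajectories.columns:
                fc = (
                    self.log2_fold_changes.iloc[ti - 1][analyte] if ti > 0 else math.nan
                )
                rows.append(
                    (self.patient_id, tp, analyte, self.trajectories.iloc[ti][analyte], fc)
                )
        return pd.DataFrame(
            rows, columns=["patient_id", "timepoint", "analyte", "value", "log2fc"]
        )


def compare_serial(
    profiles: list[PhosphoProfile],
    timepoints: list | None = None,
    view: str = "reference_normalized",
    flag_magnitude: float = 1.0,
    patient_id: str = "patient",
) -> SerialComparison:
    """Compare serial profiles of one patient as log2 fold changes.

    Profiles are ordered by timepoint and must come from the same array
    type. The default view is reference-normalized so exposure
    differences between membranes cancel. An analyte is flagged
    "diminished" when every interval decreases and the cumulative log2
    change is at most ``-flag_magnitude`` — the signature of an
    inhibitor markedly suppressing its target.
    """
    if len(profiles) < 2:
        raise ComparisonError("serial comparison needs at least 2 timepoints")
    array_ids = {p.array_id for p in profiles}
    if len(array_ids) > 1:
        raise ComparisonError(f"mixed array types cannot be compared: {sorted(array_ids)}")
    if timepoints is None:
        timepoints = list(range(len(profiles)))
    if len(timepoints) != len(profiles) or not all(
        timepoints[i] < timepoints[i + 1] for i in range(len(timepoints) - 1)
    ):
        raise ComparisonError("timepoints must be strictly increasing, one per profile")

    def view_of(p: PhosphoProfile) -> pd.Series:
        if view == "reference_normalized":
            return normalize_to_reference(p)
        if view == "percent_of_max":
            return to_percent_of_max(p)
        if view == "absolute":
            return p.values
        raise ComparisonError(f"unknown view {view!r}")

    traj = pd.DataFrame([view_of(p) for p in profiles], index=timepoints)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2v = np.log2(traj.where(traj > 0))
    fcs = log2v.diff().iloc[1:]
    fcs.index = timepoints[1:]

    diminished = []
    for analyte in traj.columns:
        col = fcs[analyte]
        if col.notna().all() and (col < 0).all() and col.sum() <= -flag_magnitude:
            diminished.append(str(analyte))

    return SerialComparison(
        patient_id=patient_id,
        timepoints=list(timepoints),
        view=view,
        trajectories=traj,
        log2_fold_changes=fcs,
        diminished=diminished,
    )
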