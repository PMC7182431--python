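"""Per-neuron calcium-imaging QC, response amplitudes and thermosensitivity calls.

Works on 340/380 nm excitation-ratio (Fura-2) traces sampled nominally at
1 Hz. All windows are defined in seconds and resolved against timestamps, so
irregular sampling is tolerated.

Quality control (all four criteria evaluated, every violation reported):

* mean fluorescence ratio over the baseline window (first 45 s) <= 0.7;
* sample SD over the baseline window <= 0.05;
* |pre-High-K+ mean (20 s before High-K+ onset) - baseline mean| <= 0.5,
  i.e. the signal recovered after the thermal challenge;
* High-K+ response amplitude (max during High-K+ minus pre-High-K+ mean)
  >= 0.5, i.e. the cell depolarizes like a healthy neuron.

A QC-passing neuron is called thermosensitive when its thermal response
amplitude — max ratio during the ramp plus a 10 s grace period, minus the
baseline mean — is >= 0.575 ratio units. Thresholds are inclusive exactly as
written. Percentages of sensitive cells are computed per coverslip over
QC-passing cells only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RatioTrace",
    "QCCriteria",
    "CellAssessment",
    "CoverslipSummary",
    "QC_CRITERION_NAMES",
    "compute_baseline_stats",
    "compute_response_amplitude",
    "compute_high_k_amplitude",
    "apply_qc",
    "assess_cell",
    "classify_cell",
    "summarize_coverslip",
    "select_collection_targets",
]

QC_CRITERION_NAMES = ("baseline_mean", "baseline_sd", "recovery", "high_k_amplitude")

CLASSIFICATION_THRESHOLD_FR = 0.575


@dataclass
class RatioTrace:
    """One neuron's fluorescence-ratio time series with epoch annotations."""

    cell_id: str
    times: np.ndarray
    fr: np.ndarray
    coverslip_id: str = "cs0"
    annotations: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fr = np.asarray(self.fr, dtype=float)
        if self.times.shape != self.fr.shape or self.times.ndim != 1:
            raise ValueError("times and fr must be 1-D arrays of equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"cell {self.cell_id}: times must be strictly increasing")
        if not np.all(np.isfinite(self.fr)) or np.any(self.fr < 0):
            raise ValueError(f"cell {self.cell_id}: fr must be finite and >= 0")


@dataclass(frozen=True)
class QCCriteria:
    """Inclusive quality-control thresholds, in fluorescence-ratio units."""

    baseline_mean_max: float = 0.7
    baseline_sd_max: float = 0.05
    recovery_diff_max: float = 0.5
    high_k_amplitude_min: float = 0.5
    baseline_window_s: float = 45.0
    pre_high_k_window_s: float = 20.0

    def __post_init__(self) -> None:
        for name in (
            "baseline_mean_max",
            "baseline_sd_max",
            "recovery_diff_max",
            "high_k_amplitude_min",
            "baseline_window_s",
            "pre_high_k_window_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class CellAssessment:
    """QC metrics, response amplitudes and class label for one neuron."""

    cell_id: str
    coverslip_id: str
    baseline_mean: float
    baseline_sd: float
    response_amplitude: float
    high_k_amplitude: float
    recovery_diff: float
    qc_pass: bool
    qc_failures: list[str]
    cell_class: str = "excluded"  # sensitive | insensitive | excluded


@dataclass
class CoverslipSummary:
    coverslip_id: str
    n_total: int
    n_pass_qc: int
    n_sensitive: int
    pct_sensitive: float
    mean_high_k_amplitude: float
    group_labels: dict[str, str] = field(default_factory=dict)


def _window_values(trace: RatioTrace, t0: float, t1: float, closed_right: bool = True):
    if closed_right:
        mask = (trace.times >= t0) & (trace.times <= t1)
    else:
        mask = (trace.times >= t0) & (trace.times < t1)
    return trace.fr[mask]


def compute_baseline_stats(trace: RatioTrace, criteria: QCCriteria = QCCriteria()):
    """Mean and sample SD of the ratio over the first ``baseline_window_s`` seconds."""
    t0 = trace.times[0]
    t1 = t0 + criteria.baseline_window_s
    if trace.times[-1] < t1:
        raise ValueError(
            f"cell {trace.cell_id}: baseline window ({criteria.baseline_window_s} s) "
            "extends past the recording"
        )
    vals = _window_values(trace, t0, t1, closed_right=False)
    if vals.size < 2:
        raise ValueError(f"cell {trace.cell_id}: too few samples in the baseline window")
    return float(np.mean(vals)), float(np.std(vals, ddof=1))


def compute_response_amplitude(trace: RatioTrace, criteria: QCCriteria = QCCriteria()) -> float:
    """Thermal response amplitude: peak ratio in [ramp start, ramp end + 10 s]
    minus the baseline mean. May be negative."""
    if "ramp" not in trace.annotations:
        raise ValueError(f"cell {trace.cell_id}: missing 'ramp' annotation")
    r0, r1 = trace.annotations["ramp"]
    vals = _window_values(trace, r0, r1 + 10.0)
    if vals.size == 0:
        raise ValueError(f"cell {trace.cell_id}: empty response window")
    baseline_mean, _ = compute_baseline_stats(trace, criteria)
    return float(np.max(vals) - baseline_mean)


def compute_high_k_amplitude(trace: RatioTrace, criteria: QCCriteria = QCCriteria()) -> float:
    """High-K+ amplitude: peak ratio during High-K+ minus the mean over the
    ``pre_high_k_window_s`` seconds preceding its onset."""
    if "high_k" not in trace.annotations:
        raise ValueError(f"cell {trace.cell_id}: missing 'high_k' annotation")
    h0, h1 = trace.annotations["high_k"]
    if trace.times[0] > h0 - criteria.pre_high_k_window_s:
        raise ValueError(
            f"cell {trace.cell_id}: fewer than {criteria.pre_high_k_window_s} s of data "
            "precede the High-K+ epoch"
        )
    pre = _window_values(trace, h0 - criteria.pre_high_k_window_s, h0, closed_right=False)
    during = _window_values(trace, h0, h1)
    if pre.size == 0 or during.size == 0:
        raise ValueError(f"cell {trace.cell_id}: empty High-K+ or pre-High-K+ window")
    return float(np.max(during) - np.mean(pre))


def apply_qc(trace: RatioTrace, criteria: QCCriteria = QCCriteria()):
    """Evaluate all four QC criteria; return (qc_pass, failures, recovery_diff).

    ``failures`` lists every violated criterion by name, in the fixed order
    ``baseline_mean, baseline_sd, recovery, high_k_amplitude``.
    """
    baseline_mean, baseline_sd = compute_baseline_stats(trace, criteria)
    h0, _ = trace.annotations.get("high_k", (None, None))
    if h0 is None:
        raise ValueError(f"cell {trace.cell_id}: missing 'high_k' annotation")
    pre = _window_values(trace, h0 - criteria.pre_high_k_window_s, h0, closed_right=False)
    recovery_diff = float(abs(np.mean(pre) - baseline_mean))
    high_k_amp = compute_high_k_amplitude(trace, criteria)

    failures = []
    if baseline_mean > criteria.baseline_mean_max:
        failures.append("baseline_mean")
    if baseline_sd > criteria.baseline_sd_max:
        failures.append("baseline_sd")
    if recovery_diff > criteria.recovery_diff_max:
        failures.append("recovery")
    if high_k_amp < criteria.high_k_amplitude_min:
        failures.append("high_k_amplitude")
    return (len(failures) == 0, failures, recovery_diff)


def classify_cell(
    assessment: CellAssessment, threshold_fr: float = CLASSIFICATION_THRESHOLD_FR
) -> str:
    """Label a QC-evaluated cell: excluded if QC failed, sensitive if the
    thermal response amplitude >= threshold (inclusive), else insensitive."""
    if not assessment.qc_pass:
        return "excluded"
    return "sensitive" if assessment.response_amplitude >= threshold_fr else "insensitive"


def assess_cell(
    trace: RatioTrace,
    criteria: QCCriteria = QCCriteria(),
    threshold_fr: float = CLASSIFICATION_THRESHOLD_FR,
) -> CellAssessment:
    """Full per-cell pipeline: QC, amplitudes, classification."""
    baseline_mean, baseline_sd = compute_baseline_stats(trace, criteria)
    qc_pass, failures, recovery_diff = apply_qc(trace, criteria)
    assessment = CellAssessment(
        cell_id=trace.cell_id,
        coverslip_id=trace.coverslip_id,
        baseline_mean=baseline_mean,
        baseline_sd=baseline_sd,
        response_amplitude=compute_response_amplitude(trace, criteria),
        high_k_amplitude=compute_high_k_amplitude(trace, criteria),
        recovery_diff=recovery_diff,
        qc_pass=qc_pass,
        qc_failures=failures,
    )
    assessment.cell_class = classify_cell(assessment, threshold_fr)
    return assessment


def summarize_coverslip(
    assessments: list[CellAssessment], group_labels: dict[str, str] | None = None
) -> CoverslipSummary:
    """Per-coverslip aggregation over QC-passing cells.

    ``pct_sensitive`` = 100 * n_sensitive / n_pass_qc. A coverslip with zero
    QC-passing cells gets NaN percentage and a warning; callers drop it from
    group statistics.
    """
    if not assessments:
        raise ValueError("no assessments supplied")
    coverslip_id = assessments[0].coverslip_id
    passing = [a for a in assessments if a.qc_pass]
    n_sensitive = sum(a.cell_class == "sensitive" for a in passing)
    if not passing:
        warnings.warn(
            f"coverslip {coverslip_id}: zero QC-passing cells; excluded from group statistics",
            stacklevel=2,
        )
        pct = float("nan")
        mean_hk = float("nan")
    else:
        pct = 100.0 * n_sensitive / len(passing)
        mean_hk = float(np.mean([a.high_k_amplitude for a in passing]))
    return CoverslipSummary(
        coverslip_id=coverslip_id,
        n_total=len(assessments),
        n_pass_qc=len(passing),
        n_sensitive=n_sensitive,
        pct_sensitive=pct,
        mean_high_k_amplitude=mean_hk,
        group_labels=dict(group_labels or {}),
    )


def select_collection_targets(
    assessments: list[CellAssessment],
    top_frac: float = 0.07,
    bottom_frac: float = 0.14,
):
    """Pick single-cell collection targets among QC-passing cells.

    Cells are ranked by thermal response amplitude; the top ``floor(0.07 n)``
    (minimum 1) are flagged as sensitive targets and the bottom
    ``floor(0.14 n)`` (minimum 1) as insensitive targets. Ties break stably by
    input order. The two sets are disjoint; with n < 8 a warning is issued.
    """
    passing = [a for a in assessments if a.qc_pass]
    n = len(passing)
    if n == 0:
        raise ValueError("no QC-passing cells to select from")
    if n < 8:
        warnings.warn(f"only {n} QC-passing cells; selection sets are minimal", stacklevel=2)
    desc = sorted(range(n), key=lambda i: (-passing[i].response_amplitude, i))
    asc = sorted(range(n), key=lambda i: (passing[i].response_amplitude, i))
    n_top = max(1, int(np.floor(top_frac * n)))
    n_bottom = max(1, int(np.floor(bottom_frac * n)))
    top_idx = desc[:n_top]
    top_ids = [passing[i].cell_id for i in top_idx]
    bottom_idx = [i for i in asc if i not in set(top_idx)][:n_bottom]
    bottom_ids = [passing[i].cell_id for i in bottom_idx]
    return top_ids, bottom_ids
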