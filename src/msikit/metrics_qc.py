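"""Diagnostic performance metrics, reproducibility correlation and run QC.

Assay performance is reported from a confusion table in which
Inconclusive calls are tallied separately and excluded from the
TP/FP/TN/FN cells — an inconclusive result is a withheld call, not an
error — so sensitivity, specificity, PPV, NPV and accuracy are computed
over conclusive calls only, with the inconclusive rate reported
alongside.  Reproducibility across replicates is summarized by Pearson's
r, and no-template-control (NTC) contamination thresholds are set at
mean + 2 SD of historical NTC replicates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .core_io import INCONCLUSIVE, MSI_H, MSS, NORMAL, ValidationError
from .features import FeatureVector

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN plus the separately tallied inconclusive calls."""

    tp: int
    fp: int
    tn: int
    fn: int
    inconclusive: int
    total: int

    def __post_init__(self) -> None:
        cells = (self.tp, self.fp, self.tn, self.fn, self.inconclusive, self.total)
        if any(v < 0 for v in cells):
            raise ValidationError(f"confusion counts must be nonnegative: {cells}")
        if self.tp + self.fp + self.tn + self.fn + self.inconclusive != self.total:
            raise ValidationError(
                f"counts {cells[:5]} do not sum to total {self.total}"
            )


@dataclass(frozen=True)
class PerformanceMetrics:
    """Fractional metrics; a ratio with zero denominator is None, never 0."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    accuracy: float | None
    inconclusive_rate: float | None

    def percent_summary(self) -> dict[str, str | None]:
        """Metrics formatted as whole percents (half-up), e.g. '96%'."""
        out: dict[str, str | None] = {}
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy",
                     "inconclusive_rate"):
            value = getattr(self, name)
            out[name] = None if value is None else f"{round_half_up_percent(value)}%"
        return out


@dataclass(frozen=True)
class NtcThresholds:
    """No-template-control contamination thresholds (mean + 2 SD)."""

    conc_threshold: float   # nM
    length_threshold: float  # bp
    n_replicates: int
    mean_conc: float
    sd_conc: float
    mean_len: float
    sd_len: float


def round_half_up_percent(fraction: float) -> int:
    """Round a fraction to the nearest whole percent, halves up (95.83 -> 96)."""
    return int(Decimal(fraction * 100).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def percent(numerator: int, denominator: int) -> int:
    """Whole-percent concordance fraction, e.g. 17/18 -> 94."""
    if denominator == 0:
        raise ValidationError("percent with zero denominator")
    return round_half_up_percent(numerator / denominator)


def confusion(
    calls: Mapping[str, str],
    truth: Mapping[str, str],
    positive_label: str = MSI_H,
) -> ConfusionCounts:
    """Tally calls against gold-standard truth.

    ``calls`` maps sample_id -> {MSI-H, MSS, Inconclusive}; ``truth`` maps
    sample_id -> {MSI-H, MSS} (Normal counts as MSS).  Inconclusive calls
    are counted separately and enter none of the four error cells.
    """
    tp = fp = tn = fn = inconclusive = 0
    for sid, call in calls.items():
        if sid not in truth:
            raise ValidationError(f"sample {sid!r} present in calls but not in truth")
        t = MSS if truth[sid] == NORMAL else truth[sid]
        if t not in (positive_label, MSS):
            raise ValidationError(f"sample {sid!r}: truth label {t!r} not usable")
        if call == INCONCLUSIVE:
            inconclusive += 1
        elif call == positive_label:
            if t == positive_label:
                tp += 1
            else:
                fp += 1
        else:
            if t == positive_label:
                fn += 1
            else:
                tn += 1
    return ConfusionCounts(tp, fp, tn, fn, inconclusive, len(calls))


def _ratio(num: int, den: int, name: str) -> float | None:
    if den == 0:
        log.warning("%s undefined (zero denominator); reported as absent", name)
        return None
    return num / den


def performance(counts: ConfusionCounts) -> PerformanceMetrics:
    """Standard diagnostic metrics over conclusive calls.

    sensitivity TP/(TP+FN); specificity TN/(TN+FP); PPV TP/(TP+FP);
    NPV TN/(TN+FN); accuracy (TP+TN)/(TP+FP+TN+FN); inconclusive rate
    inconclusive/total.
    """
    c = counts
    return PerformanceMetrics(
        sensitivity=_ratio(c.tp, c.tp + c.fn, "sensitivity"),
        specificity=_ratio(c.tn, c.tn + c.fp, "specificity"),
        ppv=_ratio(c.tp, c.tp + c.fp, "PPV"),
        npv=_ratio(c.tn, c.tn + c.fn, "NPV"),
        accuracy=_ratio(c.tp + c.tn, c.tp + c.fp + c.tn + c.fn, "accuracy"),
        inconclusive_rate=_ratio(c.inconclusive, c.total, "inconclusive rate"),
    )


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float | None:
    """Pearson product-moment correlation; None when variance vanishes."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("pearson_r needs two equal-length 1-D vectors")
    if x.size < 2:
        raise ValidationError("pearson_r needs at least two observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        log.warning("pearson_r undefined for a constant vector; reported as absent")
        return None
    return float(stats.pearsonr(x, y).statistic)


def ntc_thresholds(
    conc_replicates: Sequence[float],
    length_replicates: Sequence[float],
) -> NtcThresholds:
    """Contamination thresholds from historical NTC library replicates.

    Per dimension (library concentration in nM; library length in bp) the
    threshold is mean + 2 x sample SD (n-1 denominator).
    """
    conc = np.asarray(conc_replicates, dtype=float)
    length = np.asarray(length_replicates, dtype=float)
    if conc.size < 2 or length.size < 2:
        raise ValidationError("NTC thresholds need at least two replicates per metric")
    mean_c, sd_c = float(conc.mean()), float(conc.std(ddof=1))
    mean_l, sd_l = float(length.mean()), float(length.std(ddof=1))
    return NtcThresholds(
        conc_threshold=mean_c + 2 * sd_c,
        length_threshold=mean_l + 2 * sd_l,
        n_replicates=int(conc.size),
        mean_conc=mean_c,
        sd_conc=sd_c,
        mean_len=mean_l,
        sd_len=sd_l,
    )


@dataclass
class QcConfig:
    """Sample- and run-level QC thresholds.

    ``min_callable_loci`` is the minimum number of panel loci with at
    least one indel call for a sample to be evaluable (default 24 of 29).
    ``run_thresholds`` maps a pre-computed run metric name to its minimum
    acceptable value (e.g. cluster PF %, % >= Q30, mapped-read %); these
    metrics come from the sequencer summary and are checked as-is.
    """

    min_callable_loci: int = 24
    run_thresholds: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class QcResult:
    passed: bool
    reasons: tuple[str, ...]


def sample_qc(vector: FeatureVector, config: QcConfig | None = None) -> QcResult:
    """Per-sample QC: enough panel loci must have produced indel data."""
    config = config or QcConfig()
    reasons: list[str] = []
    if vector.callable_loci < config.min_callable_loci:
        reasons.append(
            f"insufficient callable loci ({vector.callable_loci} < "
            f"{config.min_callable_loci})"
        )
    return QcResult(passed=not reasons, reasons=tuple(reasons))


def run_qc(metrics: Mapping[str, float], config: QcConfig) -> QcResult:
    """Run-level QC: compare pre-computed sequencer metrics to thresholds."""
    reasons = [
        f"{name} = {metrics[name]} below threshold {threshold}"
        for name, threshold in config.run_thresholds.items()
        if name in metrics and metrics[name] < threshold
    ]
    missing = [name for name in config.run_thresholds if name not in metrics]
    reasons.extend(f"metric {name!r} missing from run summary" for name in missing)
    return QcResult(passed=not reasons, reasons=tuple(reasons))
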