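"""Six-step aptamer/sample outlier filter for aptamer-based proteomics.

The chain evaluates, in order:

1. low signal — more than 15% of samples below 2 SD above the dilution
   buffer's mean RFU;
2. calibration — maximum absolute deviation of an aptamer's plate
   calibration factor from the plate median above 0.5;
3. replicate noise — median coefficient of variation above 0.15;
4. distributional outliers — more than 15% of samples outside 1.5x the
   interquartile range of the aptamer's log10 values;
5. sample outliers — a sample with more than 15% of its aptamer values
   outside the per-aptamer fences;
6. shared outliers — a surviving aptamer whose fence violations occur in at
   least ~80% of the flagged sample outliers.

Criteria 1-4 are evaluated on the unfiltered matrix; an analyte flagged by
several criteria is reported under the first that fires.  Criteria needing
vendor auxiliary tables (buffer, calibration, CV) are skipped with a logged
warning when the table is absent.  Missing values are excluded from every
fraction's denominator.  Quartiles use linear interpolation (type 7).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import AnalyteMatrix, DegenerateInputError, StratomicsError

logger = logging.getLogger(__name__)

APTAMER_CRITERIA = (1, 2, 3, 4, 6)


@dataclass
class QCThresholds:
    """Cutoffs of the six-step chain; defaults are the standard values."""

    low_signal_sample_frac: float = 0.15
    buffer_sd_mult: float = 2.0
    calib_max_diff: float = 0.5
    cv_max: float = 0.15
    iqr_mult: float = 1.5
    iqr_sample_frac: float = 0.15
    shared_outlier_frac: float = 0.80

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if not value > 0:
                raise StratomicsError(f"QC threshold {name} must be positive")


@dataclass
class QCReport:
    """Audit record of one QC run."""

    aptamer_flags: pd.DataFrame      # bool column per criterion + removal_reason
    sample_flags: pd.Series          # criterion-5 flags
    surviving_counts: list[tuple[str, int]] = field(default_factory=list)
    thresholds: QCThresholds = field(default_factory=QCThresholds)
    skipped_criteria: tuple[int, ...] = ()

    def flagged_aptamers(self) -> pd.Index:
        return self.aptamer_flags.index[self.aptamer_flags["removal_reason"].notna()]

    def flagged_samples(self) -> pd.Index:
        return self.sample_flags.index[self.sample_flags]

    def to_frame(self) -> pd.DataFrame:
        """Flat audit table (one row per flagged entity)."""
        rows = []
        for apt in self.flagged_aptamers():
            rows.append(("aptamer", apt,
                         int(self.aptamer_flags.loc[apt, "removal_reason"])))
        for sample in self.flagged_samples():
            rows.append(("sample", sample, 5))
        return pd.DataFrame(rows, columns=["entity", "id", "criterion"])


def _check_matrix(matrix: AnalyteMatrix) -> None:
    if matrix.shape[1] < 4:
        raise DegenerateInputError(
            "QC needs >= 4 samples for interquartile-range criteria, got "
            f"{matrix.shape[1]}"
        )


def _log10_fences(data: pd.DataFrame, iqr_mult: float
                  ) -> tuple[pd.Series, pd.Series, pd.DataFrame]:
    """Per-aptamer [Q1 - k*IQR, Q3 + k*IQR] fences on log10 values and the
    log10 matrix itself (missing preserved)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        log10 = np.log10(data.to_numpy(dtype=float))
    log10 = pd.DataFrame(log10, index=data.index, columns=data.columns)
    q1 = log10.quantile(0.25, axis=1, interpolation="linear")
    q3 = log10.quantile(0.75, axis=1, interpolation="linear")
    iqr = q3 - q1
    return q1 - iqr_mult * iqr, q3 + iqr_mult * iqr, log10


def evaluate_aptamer_criteria(
    matrix: AnalyteMatrix,
    buffer_stats: pd.DataFrame | None = None,
    calibration: pd.DataFrame | None = None,
    cv: pd.Series | None = None,
    thresholds: QCThresholds | None = None,
) -> pd.DataFrame:
    """Boolean flag per aptamer for criteria 1, 2, 3 and 4.

    ``buffer_stats`` needs columns ``buffer_mean``/``buffer_sd`` indexed by
    aptamer; ``calibration`` is aptamer x plate; ``cv`` the per-aptamer
    median replicate CV.  A missing table skips its criterion (all-False
    column) with a warning.
    """
    thresholds = thresholds or QCThresholds()
    _check_matrix(matrix)
    data = matrix.data
    flags = pd.DataFrame(False, index=data.index,
                         columns=["crit1", "crit2", "crit3", "crit4"])
    n_nonmiss = data.notna().sum(axis=1)

    if buffer_stats is not None:
        stats = buffer_stats.reindex(data.index)
        covered = stats["buffer_mean"].notna() & stats["buffer_sd"].notna()
        if not covered.all():
            logger.warning("criterion 1: %d aptamers lack buffer stats, skipped",
                           int((~covered).sum()))
        threshold = (stats["buffer_mean"]
                     + thresholds.buffer_sd_mult * stats["buffer_sd"])
        below = data.lt(threshold, axis=0).sum(axis=1)
        frac = below / n_nonmiss
        flags["crit1"] = covered & (frac > thresholds.low_signal_sample_frac)
    else:
        logger.warning("criterion 1 skipped: no dilution-buffer statistics")

    if calibration is not None:
        calib = calibration.reindex(data.index)
        med = calib.median(axis=1)
        maxdiff = calib.sub(med, axis=0).abs().max(axis=1)
        flags["crit2"] = (maxdiff > thresholds.calib_max_diff).fillna(False)
    else:
        logger.warning("criterion 2 skipped: no plate calibration factors")

    if cv is not None:
        cv_al = cv.reindex(data.index)
        flags["crit3"] = (cv_al > thresholds.cv_max).fillna(False)
    else:
        logger.warning("criterion 3 skipped: no replicate CV table")

    if (data <= 0).any().any():
        bad = data.index[(data <= 0).any(axis=1)][0]
        raise StratomicsError(
            f"non-positive abundance for {bad!r}: log10 fences undefined"
        )
    lo, hi, log10 = _log10_fences(data, thresholds.iqr_mult)
    outside = log10.lt(lo, axis=0) | log10.gt(hi, axis=0)
    frac4 = outside.sum(axis=1) / n_nonmiss
    flags["crit4"] = frac4 > thresholds.iqr_sample_frac
    return flags


def evaluate_sample_criteria(matrix: AnalyteMatrix,
                             thresholds: QCThresholds | None = None) -> pd.Series:
    """Criterion-5 flag per sample: more than ``iqr_sample_frac`` of its
    aptamer values outside the per-aptamer log10 IQR fences."""
    thresholds = thresholds or QCThresholds()
    _check_matrix(matrix)
    data = matrix.data
    empty = data.notna().sum(axis=0) == 0
    if empty.any():
        raise DegenerateInputError(
            f"sample {data.columns[empty.to_numpy().nonzero()[0][0]]!r} has "
            "no non-missing values"
        )
    lo, hi, log10 = _log10_fences(data, thresholds.iqr_mult)
    outside = log10.lt(lo, axis=0) | log10.gt(hi, axis=0)
    frac = outside.sum(axis=0) / data.notna().sum(axis=0)
    return frac > thresholds.iqr_sample_frac


def run_qc(
    matrix: AnalyteMatrix,
    buffer_stats: pd.DataFrame | None = None,
    calibration: pd.DataFrame | None = None,
    cv: pd.Series | None = None,
    thresholds: QCThresholds | None = None,
) -> tuple[AnalyteMatrix, QCReport]:
    """Run the full six-step chain and return (filtered matrix, report)."""
    thresholds = thresholds or QCThresholds()
    data = matrix.data
    apt_flags = evaluate_aptamer_criteria(matrix, buffer_stats, calibration,
                                          cv, thresholds)
    sample_flags = evaluate_sample_criteria(matrix, thresholds)

    # criterion 6: among aptamers not already flagged, fence violations
    # shared by >= shared_outlier_frac of the flagged sample outliers
    crit6 = pd.Series(False, index=data.index)
    outlier_samples = sample_flags.index[sample_flags]
    if len(outlier_samples) > 0:
        lo, hi, log10 = _log10_fences(data, thresholds.iqr_mult)
        sub = log10[outlier_samples]
        outside = sub.lt(lo, axis=0) | sub.gt(hi, axis=0)
        share = outside.sum(axis=1) / len(outlier_samples)
        already = apt_flags.any(axis=1)
        crit6 = (share >= thresholds.shared_outlier_frac) & ~already

    flags = apt_flags.copy()
    flags["crit6"] = crit6
    order = ["crit1", "crit2", "crit3", "crit4", "crit6"]
    number = {"crit1": 1, "crit2": 2, "crit3": 3, "crit4": 4, "crit6": 6}
    reason = pd.Series(np.nan, index=data.index, dtype="float")
    for col in order:
        fire = flags[col] & reason.isna()
        reason[fire] = number[col]
    flags["removal_reason"] = reason

    counts: list[tuple[str, int]] = [("input", data.shape[0])]
    surviving = pd.Series(True, index=data.index)
    for col in order:
        surviving &= ~flags[col]
        counts.append((col, int(surviving.sum())))

    keep_apt = data.index[reason.isna()]
    keep_samples = sample_flags.index[~sample_flags]
    if len(keep_apt) == 0:
        raise StratomicsError("QC removed everything: no analytes survive")
    filtered = AnalyteMatrix(data.loc[keep_apt, keep_samples].copy(),
                             dataset=matrix.dataset, scale=matrix.scale)
    skipped = tuple(k for k, table in ((1, buffer_stats), (2, calibration),
                                       (3, cv)) if table is None)
    report = QCReport(aptamer_flags=flags, sample_flags=sample_flags,
                      surviving_counts=counts, thresholds=thresholds,
                      skipped_criteria=skipped)
    logger.info("QC: %d/%d aptamers and %d/%d samples retained",
                len(keep_apt), data.shape[0], len(keep_samples), data.shape[1])
    return filtered, report
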