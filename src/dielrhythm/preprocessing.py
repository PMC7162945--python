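"""Expression calling, normalization and per-series standardization.

The pipeline's inputs are normalized log-scale expression tables with a
parallel 0/1 detection mask (1 where the signal was distinguishable from
the local array background).  A transcript is *expressed* when it is
detected at a minimum number of time points; each expressed series is
Z-scored before network construction so that modules group series by
shape rather than level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .design import DielDesign

log = logging.getLogger(__name__)


class PreprocessingError(ValueError):
    pass


class DegenerateSeriesError(PreprocessingError):
    """A constant series cannot be Z-scored."""


@dataclass
class ExpressionMatrix:
    """Per-organ transcripts x time points expression table.

    ``values`` holds normalized log-scale measurements; ``detected`` is a
    same-shape 0/1 mask marking signal above local background.  Rows are
    transcript ids (unique), columns are ZT labels matching ``design``.
    """

    organ: str
    values: pd.DataFrame
    detected: pd.DataFrame
    design: DielDesign

    def __post_init__(self) -> None:
        if self.values.shape != self.detected.shape:
            raise PreprocessingError(
                f"values {self.values.shape} and mask {self.detected.shape} differ in shape"
            )
        if not self.values.index.equals(self.detected.index):
            raise PreprocessingError("values and mask transcript ids differ")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise PreprocessingError(f"duplicate transcript id {dup!r}")
        if self.values.shape[1] != self.design.n_timepoints:
            raise PreprocessingError(
                f"{self.values.shape[1]} columns but design has "
                f"{self.design.n_timepoints} time points"
            )

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.values.index)


@dataclass(frozen=True)
class ExpressionCallConfig:
    """Detection threshold for the expression call.

    The default (8 of 14) implements "detected in more than 7 of the 14
    time points".
    """

    min_detected_timepoints: int = 8

    def __post_init__(self) -> None:
        if self.min_detected_timepoints < 1:
            raise PreprocessingError("min_detected_timepoints must be >= 1")


def call_expressed(matrix: ExpressionMatrix, config: ExpressionCallConfig) -> set[str]:
    """Return ids detected at >= ``min_detected_timepoints`` samples."""
    if config.min_detected_timepoints > matrix.design.n_timepoints:
        raise PreprocessingError(
            "min_detected_timepoints exceeds the number of time points"
        )
    counts = matrix.detected.sum(axis=1)
    return set(counts.index[counts >= config.min_detected_timepoints])


def zscore_series(series: np.ndarray) -> np.ndarray:
    """Standardize one series to mean 0 and sample (ddof=1) SD 1.

    Raises
    ------
    DegenerateSeriesError
        If the series is constant; callers exclude such series from the
        network rather than silently zeroing them.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise PreprocessingError("need a 1-D series of length >= 2")
    sd = x.std(ddof=1)
    if sd == 0.0 or not np.isfinite(sd):
        raise DegenerateSeriesError("constant series cannot be Z-scored")
    return (x - x.mean()) / sd


def zscore_rows(values: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Z-score every row; degenerate (constant) rows are dropped and logged."""
    sd = values.std(axis=1, ddof=1)
    degenerate = list(values.index[(sd == 0.0) | ~np.isfinite(sd)])
    if degenerate:
        log.warning("excluding %d constant series from Z-scoring", len(degenerate))
    keep = values.drop(index=degenerate)
    z = keep.sub(keep.mean(axis=1), axis=0).div(sd.loc[keep.index], axis=0)
    return z, degenerate


def lowess_normalize(
    m: np.ndarray, a: np.ndarray, span: float = 0.3
) -> np.ndarray:
    """Intensity-dependent correction of two-color log-ratios.

    Fits a locally weighted (tricube) linear regression of the log-ratio
    M on the mean log-intensity A and returns the residuals M - fit(A),
    removing dye/intensity bias while preserving the biological signal.
    """
    m = np.asarray(m, dtype=float)
    a = np.asarray(a, dtype=float)
    if m.shape != a.shape or m.ndim != 1:
        raise PreprocessingError("M and A must be 1-D arrays of equal length")
    if m.size < 10:
        raise PreprocessingError("need at least 10 (M, A) pairs for LOWESS")
    if not 0.0 < span <= 1.0:
        raise PreprocessingError("span must be in (0, 1]")
    fit = _sm_lowess(m, a, frac=span, return_sorted=False)
    return m - fit


def collapse_replicates(replicates: list[ExpressionMatrix]) -> ExpressionMatrix:
    """Average replicate hybridizations into one matrix.

    Values are the per-cell mean across replicates; a cell counts as
    detected if it was detected in any replicate.
    """
    if not replicates:
        raise PreprocessingError("no replicates given")
    first = replicates[0]
    if len(replicates) == 1:
        return first
    for rep in replicates[1:]:
        if not rep.values.index.equals(first.values.index):
            raise PreprocessingError("replicate transcript ids differ")
        if list(rep.values.columns) != list(first.values.columns):
            raise PreprocessingError("replicate time columns differ")
        if rep.organ != first.organ:
            raise PreprocessingError("replicates come from different organs")
    values = sum(rep.values for rep in replicates) / len(replicates)
    detected = replicates[0].detected.astype(bool)
    for rep in replicates[1:]:
        detected = detected | rep.detected.astype(bool)
    return ExpressionMatrix(
        organ=first.organ,
        values=values,
        detected=detected.astype(int),
        design=first.design,
    )
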