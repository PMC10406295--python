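"""Seed-based correlation (SBC) baseline at the group level.

For a chosen seed ROI (classically the posterior cingulate cortex for the
default mode network), each subject contributes one row of seed-to-ROI
Pearson correlations. Correlations are Fisher-z transformed (atanh) for
variance stabilization, then each ROI gets a one-sample t statistic of
its z values against zero, with df = n_subjects - 1. An ROI is significant
when |t| strictly exceeds the two-sided Student-t critical value at the
chosen uncorrected alpha (default 1e-4); a Bonferroni mode divides a
familywise alpha by the number of tested ROIs instead.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import pearson_correlation
from .synthetic import CohortTimeSeries

__all__ = [
    "SeedMap",
    "seed_correlation_map",
    "fisher_z",
    "group_t_map",
    "critical_t",
    "threshold_seed_map",
    "run_sbc",
    "write_seed_map",
]

logger = logging.getLogger(__name__)


@dataclass
class SeedMap:
    """Group t statistics of Fisher-z seed correlations, per ROI."""

    seed_roi: str
    roi_ids: list[str]
    t_values: np.ndarray  # NaN for the seed itself (excluded from testing)
    mean_z: np.ndarray
    df: int
    critical_t: float | None = None
    alpha: float | None = None
    significant: np.ndarray | None = None

    def significant_rois(self) -> set[str]:
        if self.significant is None:
            raise ValueError("seed map has not been thresholded")
        return {r for r, s in zip(self.roi_ids, self.significant) if s}


def seed_correlation_map(cohort: CohortTimeSeries, seed_roi: str) -> np.ndarray:
    """(n_subjects, n_rois) matrix of per-subject seed-to-ROI correlations."""
    if seed_roi not in cohort.roi_ids:
        raise KeyError(f"seed ROI {seed_roi!r} not in cohort")
    j = cohort.roi_ids.index(seed_roi)
    out = np.empty((cohort.n_subjects, cohort.n_rois))
    for s, mat in enumerate(cohort.subjects):
        seed_ts = mat[:, j]
        for i in range(cohort.n_rois):
            out[s, i] = (
                1.0 if i == j else pearson_correlation(seed_ts, mat[:, i])
            )
    return out


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Variance-stabilizing atanh transform; |r| >= 1 is clamped with a warning."""
    arr = np.asarray(r, dtype=float)
    clamp = 1.0 - 1e-7
    if np.any(np.abs(arr) >= 1.0):
        warnings.warn("correlation magnitude >= 1 clamped before atanh", stacklevel=2)
        arr = np.clip(arr, -clamp, clamp)
    out = np.arctanh(arr)
    return float(out) if np.isscalar(r) else out


def group_t_map(
    corr_rows: np.ndarray,
    roi_ids: list[str],
    seed_roi: str,
    use_fisher_z: bool = True,
) -> SeedMap:
    """One-sample t statistics of (Fisher-z) seed correlations against 0.

    t_i = mean(z_i) / (sd(z_i) / sqrt(n)), df = n - 1. The seed column is
    excluded (NaN). Zero-variance ROIs get an infinite t with a warning.
    """
    corr_rows = np.asarray(corr_rows, dtype=float)
    n = corr_rows.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects for a group t-test")
    if corr_rows.shape[1] != len(roi_ids):
        raise ValueError("roi_ids length must match columns")
    seed_idx = roi_ids.index(seed_roi)
    # the seed is excluded from testing; keep its r = 1 column out of atanh
    tested = corr_rows.copy()
    tested[:, seed_idx] = 0.0
    z = fisher_z(tested) if use_fisher_z else tested
    mean = z.mean(axis=0)
    sd = z.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    degenerate = (sd == 0.0) & (np.arange(len(roi_ids)) != seed_idx)
    if np.any(degenerate):
        logger.warning(
            "%d ROI(s) with zero variance across subjects; t set to +/-inf",
            int(np.sum(degenerate)),
        )
        with np.errstate(invalid="ignore"):
            t[degenerate] = np.sign(mean[degenerate]) * np.inf
        t[degenerate & (mean == 0.0)] = 0.0
    t[seed_idx] = np.nan
    mean[seed_idx] = np.nan
    return SeedMap(
        seed_roi=seed_roi,
        roi_ids=list(roi_ids),
        t_values=t,
        mean_z=mean,
        df=n - 1,
    )


def critical_t(alpha_two_sided: float, df: int) -> float:
    """Two-sided Student-t critical value: the inverse CDF at 1 - alpha/2."""
    if not (0.0 < alpha_two_sided < 1.0):
        raise ValueError(f"alpha must lie in (0, 1), got {alpha_two_sided}")
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    return float(stats.t.ppf(1.0 - alpha_two_sided / 2.0, df))


def threshold_seed_map(
    seed_map: SeedMap,
    alpha: float = 0.0001,
    fwer_mode: bool = False,
) -> SeedMap:
    """Mark ROIs with |t| strictly greater than the critical value.

    ``fwer_mode`` applies a Bonferroni correction: the per-test level is
    alpha divided by the number of tested ROIs (the seed is not a test).
    """
    n_tests = len(seed_map.roi_ids) - 1
    level = alpha / n_tests if fwer_mode else alpha
    crit = critical_t(level, seed_map.df)
    with np.errstate(invalid="ignore"):
        sig = np.abs(seed_map.t_values) > crit
    sig[np.isnan(seed_map.t_values)] = False  # the seed itself
    seed_map.critical_t = crit
    seed_map.alpha = level
    seed_map.significant = sig
    return seed_map


def run_sbc(
    cohort: CohortTimeSeries,
    seed_roi: str,
    alpha: float = 0.0001,
    fwer_mode: bool = False,
    use_fisher_z: bool = True,
) -> SeedMap:
    """Full SBC baseline: correlation map -> Fisher z -> group t -> threshold."""
    rows = seed_correlation_map(cohort, seed_roi)
    seed_map = group_t_map(rows, cohort.roi_ids, seed_roi, use_fisher_z=use_fisher_z)
    return threshold_seed_map(seed_map, alpha=alpha, fwer_mode=fwer_mode)


def write_seed_map(seed_map: SeedMap, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "seed_map.tsv"
    pd.DataFrame(
        {
            "roi_id": seed_map.roi_ids,
            "mean_z": seed_map.mean_z,
            "t": seed_map.t_values,
            "significant": (
                seed_map.significant
                if seed_map.significant is not None
                else [""] * len(seed_map.roi_ids)
            ),
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.9g")
    return path
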