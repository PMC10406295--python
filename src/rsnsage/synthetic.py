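"""Synthetic multi-subject ROI time series with planted network structure.

Each ROI belongs to one of ``n_networks`` blocks. Within a block, every
ROI's time course mixes a shared latent signal with private noise:

    x_i(t) = sqrt(rho) * s_k(t) + sqrt(1 - rho) * e_i(t)

with s_k(t) ~ N(0, 1) shared by block k and e_i(t) ~ N(0, noise_sd^2)
private to ROI i. The expected within-block Pearson correlation is then
rho / (rho + (1 - rho) * noise_sd^2) and the expected between-block
correlation is zero, so downstream graph construction sees clean community
structure whose strength is controlled by a single knob.

Latent signals are i.i.d. over time: Pearson correlation and everything
downstream of it are invariant to temporal ordering, so band-limited BOLD
autocorrelation is deliberately not modelled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticConfig",
    "CohortTimeSeries",
    "simulate_subject",
    "simulate_cohort",
    "expected_within_correlation",
    "drop_initial_volumes",
    "write_cohort",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the planted-network cohort generator.

    Defaults mirror a 7-network, ~180-time-point resting-state setting at a
    reduced ROI count: 70 ROIs in 7 equal blocks of 10, 10 subjects,
    180 time points, within-block signal fraction 0.6, unit noise.
    """

    n_rois: int = 70
    n_networks: int = 7
    n_subjects: int = 10
    n_timepoints: int = 180
    rho: float = 0.6
    noise_sd: float = 1.0
    block_sizes: Sequence[int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.n_networks <= self.n_rois):
            raise ValueError(
                f"need 1 <= n_networks <= n_rois, got {self.n_networks} vs {self.n_rois}"
            )
        if not (0.0 <= self.rho <= 1.0):
            raise ValueError(f"rho must lie in [0, 1], got {self.rho}")
        if self.noise_sd <= 0:
            raise ValueError(f"noise_sd must be positive, got {self.noise_sd}")
        if self.n_timepoints < 3:
            raise ValueError(
                f"n_timepoints must be >= 3 for correlations, got {self.n_timepoints}"
            )
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.block_sizes is not None:
            sizes = list(self.block_sizes)
            if len(sizes) != self.n_networks:
                raise ValueError("block_sizes length must equal n_networks")
            if any(s < 1 for s in sizes):
                raise ValueError("block sizes must be positive")
            if sum(sizes) != self.n_rois:
                raise ValueError(
                    f"block_sizes sum to {sum(sizes)}, expected n_rois={self.n_rois}"
                )

    def resolved_block_sizes(self) -> list[int]:
        """Block sizes, distributing the remainder over the first blocks."""
        if self.block_sizes is not None:
            return list(self.block_sizes)
        base, extra = divmod(self.n_rois, self.n_networks)
        return [base + (1 if k < extra else 0) for k in range(self.n_networks)]

    def labels(self) -> np.ndarray:
        """ROI -> network index, contiguous blocks; block 0 is the planted DMN."""
        return np.repeat(np.arange(self.n_networks), self.resolved_block_sizes())


@dataclass
class CohortTimeSeries:
    """Per-subject ROI time-series matrices with shared ROI ordering."""

    subjects: list[np.ndarray]
    roi_ids: list[str]
    true_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.subjects:
            raise ValueError("cohort must contain at least one subject")
        shape = self.subjects[0].shape
        for s, mat in enumerate(self.subjects):
            if mat.shape != shape:
                raise ValueError(
                    f"subject {s} has shape {mat.shape}, expected {shape}"
                )
        if shape[1] != len(self.roi_ids):
            raise ValueError("roi_ids length must match matrix columns")
        for s, mat in enumerate(self.subjects):
            if np.any(np.var(mat, axis=0) == 0.0):
                bad = int(np.flatnonzero(np.var(mat, axis=0) == 0.0)[0])
                raise ValueError(
                    f"constant column for ROI {self.roi_ids[bad]!r} in subject {s}"
                )

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_timepoints(self) -> int:
        return self.subjects[0].shape[0]

    @property
    def n_rois(self) -> int:
        return self.subjects[0].shape[1]


def expected_within_correlation(rho: float, noise_sd: float) -> float:
    """Closed-form expected within-block correlation of the mixture model."""
    if rho == 1.0:
        return 1.0
    return rho / (rho + (1.0 - rho) * noise_sd**2)


def _subject_rng(config: SyntheticConfig, subject_index: int) -> np.random.Generator:
    # One stream per (cohort seed, subject counter): adding subjects never
    # perturbs earlier subjects.
    return np.random.default_rng(np.random.SeedSequence([config.seed, subject_index]))


def simulate_subject(
    config: SyntheticConfig,
    subject_index: int,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One subject's (n_timepoints, n_rois) matrix under the mixture model."""
    if rng is None:
        rng = _subject_rng(config, subject_index)
    labels = config.labels()
    latent = rng.standard_normal((config.n_timepoints, config.n_networks))
    noise = config.noise_sd * rng.standard_normal((config.n_timepoints, config.n_rois))
    x = np.sqrt(config.rho) * latent[:, labels] + np.sqrt(1.0 - config.rho) * noise
    # rho=1 collapses a block to identical columns; any exactly-constant
    # column (probability zero, but guard anyway) gets a tiny jitter so the
    # Pearson correlation stays defined.
    variances = np.var(x, axis=0)
    if np.any(variances == 0.0):
        for j in np.flatnonzero(variances == 0.0):
            x[0, j] += 1e-9
    return x


def simulate_cohort(config: SyntheticConfig) -> CohortTimeSeries:
    """Independent subjects sharing one planted partition (block 0 = DMN)."""
    subjects = [simulate_subject(config, s) for s in range(config.n_subjects)]
    roi_ids = [f"ROI{idx:03d}" for idx in range(config.n_rois)]
    return CohortTimeSeries(subjects=subjects, roi_ids=roi_ids, true_labels=config.labels())


def drop_initial_volumes(cohort: CohortTimeSeries, n_drop: int = 10) -> CohortTimeSeries:
    """Discard the first ``n_drop`` time points of every subject.

    Standard accounting for scanner equilibration: the leading volumes are
    excluded before any correlation is computed (e.g. 192 acquired time
    points leave 182 usable ones; 175 leave 165).
    """
    if n_drop < 0:
        raise ValueError("n_drop must be nonnegative")
    if cohort.n_timepoints - n_drop < 3:
        raise ValueError(
            f"dropping {n_drop} of {cohort.n_timepoints} time points leaves "
            "too few for correlation"
        )
    return CohortTimeSeries(
        subjects=[mat[n_drop:].copy() for mat in cohort.subjects],
        roi_ids=list(cohort.roi_ids),
        true_labels=None if cohort.true_labels is None else cohort.true_labels.copy(),
    )


def write_cohort(cohort: CohortTimeSeries, out_dir: str | Path, config: SyntheticConfig | None = None) -> Path:
    """Write one TSV per subject plus a manifest JSON; returns manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    for s, mat in enumerate(cohort.subjects):
        fname = f"subject_{s:03d}.tsv"
        df = pd.DataFrame(mat, columns=cohort.roi_ids)
        df.to_csv(out / fname, sep="\t", index=False, float_format="%.9g")
        files.append(fname)
    manifest = {
        "subject_files": files,
        "roi_ids": list(cohort.roi_ids),
        "true_labels": None
        if cohort.true_labels is None
        else [int(v) for v in cohort.true_labels],
        "config": None if config is None else {
            "n_rois": config.n_rois,
            "n_networks": config.n_networks,
            "n_subjects": config.n_subjects,
            "n_timepoints": config.n_timepoints,
            "rho": config.rho,
            "noise_sd": config.noise_sd,
            "block_sizes": None if config.block_sizes is None else list(config.block_sizes),
            "seed": config.seed,
        },
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path
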