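"""Temporal preprocessing of ROI series.

Three steps, applied per subject in fixed order:

1. high-pass filter each run (discrete-cosine drift regression,
   cutoff 1/128 Hz by default);
2. rescale every run so each region's temporal mean matches the first
   run's mean for that region (discounts global per-run signal
   differences);
3. concatenate runs in acquisition order.

The filter follows the SPM convention: the drift basis holds the
constant plus every DCT cosine whose period is at least ``1/cutoff``
seconds; filtering regresses the series on that basis and returns the
residuals with the original mean restored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

DEFAULT_HIGHPASS_HZ = 1.0 / 128.0
DEFAULT_TR_SECONDS = 2.0


@dataclass
class RunSeries:
    """One run's time x region matrix with its sampling interval."""

    subject_id: str
    run_index: int
    tr_seconds: float
    data: pd.DataFrame  # rows: volumes, columns: region names

    def __post_init__(self) -> None:
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if len(self.data) < 2:
            raise ValueError("a run needs at least 2 time points")
        if self.data.isna().any().any():
            raise ValueError("run data contains missing values")

    @property
    def n_volumes(self) -> int:
        return len(self.data)

    @property
    def region_names(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class SubjectSeries:
    """All runs of one subject, plus the group label."""

    subject_id: str
    group: str
    runs: list[RunSeries]

    def __post_init__(self) -> None:
        if not self.runs:
            raise ValueError("subject needs at least one run")
        first = self.runs[0]
        for run in self.runs[1:]:
            if run.tr_seconds != first.tr_seconds:
                raise ValueError("runs have mismatched tr_seconds")
            if run.region_names != first.region_names:
                raise ValueError("runs have mismatched region axes")

    @property
    def tr_seconds(self) -> float:
        return self.runs[0].tr_seconds

    @property
    def region_names(self) -> list[str]:
        return self.runs[0].region_names


@dataclass
class PreprocessConfig:
    highpass_cutoff_hz: float = DEFAULT_HIGHPASS_HZ
    normalize_mode: str = "mean"  # mean | zscore | off

    def __post_init__(self) -> None:
        if self.highpass_cutoff_hz <= 0:
            raise ValueError("highpass cutoff must be positive")
        if self.normalize_mode not in ("mean", "zscore", "off"):
            raise ValueError(f"unknown normalize_mode {self.normalize_mode!r}")


def dct_drift_basis(n_volumes: int, tr_seconds: float, cutoff_hz: float) -> np.ndarray:
    """Drift basis: constant column plus DCT-II cosines with period >= 1/cutoff.

    Cosine k over n volumes has period ``2 n tr / k`` seconds, so the basis
    holds k = 1 .. floor(2 n tr * cutoff).
    """
    nyquist = 1.0 / (2.0 * tr_seconds)
    if cutoff_hz >= nyquist:
        raise ValueError(
            f"cutoff {cutoff_hz:.4g} Hz is not below the Nyquist frequency {nyquist:.4g} Hz"
        )
    k_max = int(np.floor(2.0 * n_volumes * tr_seconds * cutoff_hz))
    t = np.arange(n_volumes)
    cols = [np.ones(n_volumes)]
    for k in range(1, k_max + 1):
        cols.append(np.sqrt(2.0 / n_volumes) * np.cos(np.pi * k * (2 * t + 1) / (2 * n_volumes)))
    return np.column_stack(cols)


def highpass_filter(run: RunSeries, cutoff_hz: float = DEFAULT_HIGHPASS_HZ) -> RunSeries:
    """Remove slow drift by projecting out the DCT basis; the mean is kept."""
    basis = dct_drift_basis(run.n_volumes, run.tr_seconds, cutoff_hz)
    if run.n_volumes < basis.shape[1] + 2:
        raise ValueError(
            f"run of {run.n_volumes} volumes too short for {basis.shape[1]} drift regressors"
        )
    X = run.data.to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(basis, X, rcond=None)
    resid = X - basis @ coef
    filtered = resid + X.mean(axis=0, keepdims=True)
    return replace(
        run, data=pd.DataFrame(filtered, columns=run.data.columns, index=run.data.index)
    )


def normalize_to_first_run(subject: SubjectSeries, mode: str = "mean") -> SubjectSeries:
    """Rescale runs 1.. so each region's statistics match the first run.

    ``mean``   — multiplicative rescale matching the temporal mean
                 (default; the first run is returned unchanged);
    ``zscore`` — match mean and standard deviation;
    ``off``    — identity.
    """
    if mode == "off":
        return subject
    if mode not in ("mean", "zscore"):
        raise ValueError(f"unknown normalize mode {mode!r}")
    ref = subject.runs[0].data
    ref_mean = ref.mean(axis=0)
    bad = ref_mean.index[np.isclose(ref_mean.to_numpy(dtype=float), 0.0)]
    if mode == "mean" and len(bad):
        raise ValueError(f"first-run mean is zero for region(s): {list(bad)}")
    new_runs = [subject.runs[0]]
    for run in subject.runs[1:]:
        if mode == "mean":
            scale = ref_mean / run.data.mean(axis=0)
            data = run.data * scale
        else:  # zscore: match mean and sd of the first run
            ref_sd = ref.std(axis=0, ddof=1)
            sd = run.data.std(axis=0, ddof=1)
            data = (run.data - run.data.mean(axis=0)) / sd * ref_sd + ref_mean
        new_runs.append(replace(run, data=data))
    return replace(subject, runs=new_runs)


def concatenate_runs(subject: SubjectSeries) -> pd.DataFrame:
    """Stack runs in order into one time x region matrix."""
    return pd.concat(
        [run.data for run in subject.runs], axis=0, ignore_index=True
    )


def preprocess_subject(
    subject: SubjectSeries, config: PreprocessConfig | None = None
) -> pd.DataFrame:
    """filter -> normalize -> concatenate, the pipeline's fixed order."""
    config = config or PreprocessConfig()
    filtered = replace(
        subject,
        runs=[highpass_filter(run, config.highpass_cutoff_hz) for run in subject.runs],
    )
    normalized = normalize_to_first_run(filtered, mode=config.normalize_mode)
    return concatenate_runs(normalized)


def runs_from_frames(
    subject_id: str,
    group: str,
    frames: Sequence[pd.DataFrame],
    tr_seconds: float = DEFAULT_TR_SECONDS,
) -> SubjectSeries:
    """Convenience constructor from a list of per-run DataFrames."""
    runs = [
        RunSeries(subject_id=subject_id, run_index=i, tr_seconds=tr_seconds, data=df)
        for i, df in enumerate(frames)
    ]
    return SubjectSeries(subject_id=subject_id, group=group, runs=runs)
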