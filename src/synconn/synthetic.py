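"""Synthetic multi-subject ROI time series with planted connectivity.

The generator emulates the structure of the study data: each group is a
set of subjects whose region series are drawn from a zero-mean Gaussian
graphical model whose partial correlations are planted at group-level
Fisher-Z values, on top of which sit (a) a task-evoked component — a
6-s boxcar at the stimulus onsets convolved with a double-gamma HRF,
shared across regions, (b) a slow cosine drift per region (removed by
the 1/128-Hz high-pass filter), (c) a constant offset of 100, and
(d) a per-run global gain (undone by first-run normalization).

Three template scenarios:

* ``normal``  — within-network pairs at Z=0.18, between at Z=0.002;
* ``leveled`` — every pair at one uniform level (0.045 or 0.052,
  the two patient-group overall means);
* ``other``   — three preserved edges (F3op/F3t–IPS 0.22, LPMC–AG 0.28,
  F3t–F3O 0.25) over a uniform abnormal baseline of 0.052.

All randomness flows from a single master seed via
``numpy.random.SeedSequence``; reruns are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .connectivity import pair_category
from .preprocess import RunSeries, SubjectSeries
from .regions import DEFAULT_SPHERE_RADIUS_MM, RegionCatalog, VoxelGrid, build_sphere_mask

# Published group-level Fisher-Z levels used as template defaults
NORMAL_WITHIN_Z = 0.18
NORMAL_BETWEEN_Z = 0.002
LPMC_LEVELED_Z = 0.045
F3_LEVELED_Z = 0.052
OTHER_BASELINE_Z = 0.052
PRESERVED_EDGES_Z = (
    (("L_F3op/F3t", "L_IPS"), 0.22),
    (("L_LPMC", "L_AG"), 0.28),
    (("L_F3t", "L_F3O"), 0.25),
)


@dataclass
class TemplateSpec:
    """Planted Fisher-Z structure for one group scenario."""

    scenario: str  # normal | leveled | other
    within_z: float = NORMAL_WITHIN_Z
    between_z: float = NORMAL_BETWEEN_Z
    leveled_z: float = F3_LEVELED_Z
    preserved_edges: tuple = PRESERVED_EDGES_Z
    baseline_z: float = OTHER_BASELINE_Z
    # optional extra coupling for the between-(I,III) block of the
    # "other" scenario (the increased III-I cross-talk); off by default
    between_i_iii_z: float | None = None

    def __post_init__(self) -> None:
        if self.scenario not in ("normal", "leveled", "other"):
            raise ValueError(f"unknown scenario {self.scenario!r}")


def normal_template() -> TemplateSpec:
    return TemplateSpec(scenario="normal")


def leveled_template(level_z: float = F3_LEVELED_Z) -> TemplateSpec:
    return TemplateSpec(scenario="leveled", leveled_z=level_z)


def other_template() -> TemplateSpec:
    return TemplateSpec(scenario="other")


def template_matrix(spec: TemplateSpec, catalog: RegionCatalog) -> np.ndarray:
    """Ground-truth partial correlation matrix, tanh of the planted Z."""
    p = len(catalog)
    nets = catalog.networks
    pc = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            cat = pair_category(nets[i], nets[j])
            if spec.scenario == "normal":
                z = spec.within_z if cat.startswith("within") else spec.between_z
            elif spec.scenario == "leveled":
                z = spec.leveled_z
            else:
                z = spec.baseline_z
                if spec.between_i_iii_z is not None and cat == "between-(I,III)":
                    z = spec.between_i_iii_z
            pc[i, j] = pc[j, i] = np.tanh(z)
    if spec.scenario == "other":
        for (name_a, name_b), z in spec.preserved_edges:
            try:
                a, b = catalog.index(name_a), catalog.index(name_b)
            except KeyError as exc:
                raise ValueError(f"preserved edge {name_a}-{name_b} not in catalog") from exc
            pc[a, b] = pc[b, a] = np.tanh(z)
    return pc


def precision_from_partials(
    pc: np.ndarray, min_eig: float = 1e-6, tol: float = 1e-6
) -> tuple[np.ndarray, float]:
    """Precision matrix with unit diagonal realising the planted partials.

    Sets omega_ij = -pc_ij.  If the result is not positive definite the
    off-diagonals are shrunk by the largest lambda in (0, 1] that makes
    the minimum eigenvalue >= ``min_eig`` (bisection); the returned
    matrix then realises partial correlations lambda * pc.  Returns
    (Omega, lambda).
    """
    pc = np.asarray(pc, dtype=float)
    if not np.allclose(pc, pc.T, atol=1e-10):
        raise ValueError("partial correlation matrix must be symmetric")
    off = pc - np.diag(np.diag(pc))
    if np.any(np.abs(off) >= 1.0):
        raise ValueError("off-diagonal partial correlations must be in (-1, 1)")

    def omega(lam: float) -> np.ndarray:
        return np.eye(len(pc)) - lam * off

    if np.linalg.eigvalsh(omega(1.0))[0] >= min_eig:
        return omega(1.0), 1.0
    lo, hi = 0.0, 1.0  # lo always feasible (identity), hi infeasible
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if np.linalg.eigvalsh(omega(mid))[0] >= min_eig:
            lo = mid
        else:
            hi = mid
    return omega(lo), lo


# ---------------------------------------------------------------------------
# Task design: boxcar (x) double-gamma HRF


@dataclass
class HRFParams:
    """Canonical double-gamma HRF (peak ~5 s, undershoot ~15 s)."""

    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_dispersion_s: float = 1.0
    undershoot_dispersion_s: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    duration_s: float = 32.0


def double_gamma_hrf(tr_seconds: float, params: HRFParams | None = None) -> np.ndarray:
    """Sample the double-gamma HRF at the TR grid, peak-normalized to 1."""
    from scipy.stats import gamma

    params = params or HRFParams()
    t = np.arange(0.0, params.duration_s, tr_seconds)
    peak = gamma.pdf(
        t, params.peak_delay_s / params.peak_dispersion_s, scale=params.peak_dispersion_s
    )
    under = gamma.pdf(
        t,
        params.undershoot_delay_s / params.undershoot_dispersion_s,
        scale=params.undershoot_dispersion_s,
    )
    h = peak - params.undershoot_ratio * under
    return h / np.max(np.abs(h))


def hrf_convolve(
    onsets_s: Sequence[float],
    n_volumes: int,
    tr_seconds: float,
    boxcar_duration_s: float = 6.0,
    hrf_params: HRFParams | None = None,
) -> np.ndarray:
    """Boxcar-times-HRF task regressor, truncated to the run length.

    Each stimulus contributes a ``boxcar_duration_s`` indicator from its
    onset, convolved with the sampled double-gamma HRF; the final
    regressor is rescaled so a single event peaks at 1.
    """
    if tr_seconds <= 0:
        raise ValueError("tr must be positive")
    onsets = np.asarray(list(onsets_s), dtype=float)
    if onsets.size and np.any(onsets < 0):
        raise ValueError("negative onset")
    box = np.zeros(n_volumes)
    for onset in onsets:
        start = int(np.floor(onset / tr_seconds))
        stop = int(np.ceil((onset + boxcar_duration_s) / tr_seconds))
        box[start : min(stop, n_volumes)] = 1.0
    if not box.any():
        return box
    h = double_gamma_hrf(tr_seconds, hrf_params)
    reg = np.convolve(box, h)[:n_volumes]
    # unit scale: one 6-s event's peak response
    single = np.convolve(
        np.ones(max(int(np.ceil(boxcar_duration_s / tr_seconds)), 1)), h
    )
    return reg / np.max(single)


# ---------------------------------------------------------------------------
# Subject and group simulation


@dataclass
class SimulationConfig:
    """Acquisition layout and nuisance-signal levels for the generator.

    Defaults give 5 runs of 100 volumes at TR 2 s per subject with a
    small common task component (0.2 x the unit noise scale), a slow
    drift well below the high-pass cutoff, and per-run gains the
    normalization step must undo.
    """

    n_subjects: int = 7
    n_runs: int = 5
    n_volumes_per_run: int = 100
    tr_seconds: float = 2.0
    task_amplitude: float = 0.2
    event_onsets_s: tuple | None = None  # None -> every 24 s from 12 s
    boxcar_duration_s: float = 6.0
    hrf_params: HRFParams = field(default_factory=HRFParams)
    drift_amplitude: float = 1.0
    drift_period_s: float = 300.0
    gain_range: tuple[float, float] = (0.9, 1.1)
    baseline_offset: float = 100.0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_runs", "n_volumes_per_run"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    def onsets(self) -> np.ndarray:
        if self.event_onsets_s is not None:
            return np.asarray(self.event_onsets_s, dtype=float)
        run_s = self.n_volumes_per_run * self.tr_seconds
        return np.arange(12.0, max(run_s - 20.0, 12.0), 24.0)


def simulate_subject(
    precision: np.ndarray,
    config: SimulationConfig,
    seed,
    subject_id: str = "sim",
    group: str = "sim",
    region_names: Sequence[str] | None = None,
) -> SubjectSeries:
    """Draw one subject's runs from the planted Gaussian graphical model.

    Per run: correlated noise with covariance inverse(precision), plus the
    shared task regressor, a random-phase cosine drift per region, an
    offset of 100, all scaled by the run's global gain.  Deterministic
    given the seed.
    """
    precision = np.asarray(precision, dtype=float)
    eigs = np.linalg.eigvalsh(precision)
    if eigs[0] <= 0:
        raise ValueError("precision matrix is not positive definite")
    cov = np.linalg.inv(precision)
    chol = np.linalg.cholesky(cov)
    p = precision.shape[0]
    if region_names is None:
        region_names = [f"region_{k}" for k in range(p)]
    rng = np.random.default_rng(seed)
    n = config.n_volumes_per_run
    task = config.task_amplitude * hrf_convolve(
        config.onsets(), n, config.tr_seconds, config.boxcar_duration_s, config.hrf_params
    )
    t_s = np.arange(n) * config.tr_seconds
    runs = []
    for run_index in range(config.n_runs):
        gain = rng.uniform(*config.gain_range)
        noise = rng.standard_normal((n, p)) @ chol.T
        phases = rng.uniform(0.0, 2.0 * np.pi, size=p)
        drift = config.drift_amplitude * np.cos(
            2.0 * np.pi * t_s[:, None] / config.drift_period_s + phases[None, :]
        )
        data = gain * (config.baseline_offset + noise + task[:, None] + drift)
        runs.append(
            RunSeries(
                subject_id=subject_id,
                run_index=run_index,
                tr_seconds=config.tr_seconds,
                data=pd.DataFrame(data, columns=list(region_names)),
            )
        )
    return SubjectSeries(subject_id=subject_id, group=group, runs=runs)


def simulate_group(
    spec: TemplateSpec,
    config: SimulationConfig,
    catalog: RegionCatalog,
    master_seed: int,
    group: str = "",
) -> tuple[list[SubjectSeries], dict]:
    """Simulate a group of subjects sharing one planted template.

    Per-subject seeds are spawned deterministically from the master seed;
    the metadata records the template, the shrinkage lambda (1.0 means
    the planted values are realised exactly), and the seeds.
    """
    group = group or spec.scenario
    pc = template_matrix(spec, catalog)
    precision, lam = precision_from_partials(pc)
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(config.n_subjects)
    subjects = []
    for k, child in enumerate(children):
        subjects.append(
            simulate_subject(
                precision,
                config,
                child,
                subject_id=f"{group}_{k + 1:02d}",
                group=group,
                region_names=catalog.names,
            )
        )
    metadata = {
        "group": group,
        "scenario": spec.scenario,
        "master_seed": int(master_seed),
        "shrinkage_lambda": float(lam),
        "template_partial_r": pc.tolist(),
        "template_z": np.arctanh(pc).tolist(),
        "n_subjects": config.n_subjects,
        "n_runs": config.n_runs,
        "n_volumes_per_run": config.n_volumes_per_run,
        "tr_seconds": config.tr_seconds,
    }
    return subjects, metadata


def render_volumes(
    subject: SubjectSeries,
    catalog: RegionCatalog,
    grid: VoxelGrid,
    radius_mm: float = DEFAULT_SPHERE_RADIUS_MM,
    background_noise_sd: float = 0.1,
    seed: int = 0,
) -> list:
    """Paint each region's series into its sphere of a 4-D NIfTI per run.

    Spheres must not overlap (each voxel carries exactly one region's
    signal); background voxels hold Gaussian noise.  Returns one
    ``nibabel.Nifti1Image`` per run.
    """
    import nibabel as nib

    masks = [build_sphere_mask(r.mni, radius_mm, grid) for r in catalog]
    seen: dict[tuple, str] = {}
    collisions = set()
    for region, mask in zip(catalog, masks):
        for vox in map(tuple, mask.voxel_indices):
            if vox in seen:
                collisions.add((seen[vox], region.name))
            seen[vox] = region.name
    if collisions:
        raise ValueError(f"overlapping spheres: {sorted(collisions)}")
    rng = np.random.default_rng(seed)
    images = []
    for run in subject.runs:
        n = run.n_volumes
        vol = rng.standard_normal((*grid.shape, n)).astype(np.float32)
        vol *= background_noise_sd
        for region, mask in zip(catalog, masks):
            series = run.data[region.name].to_numpy(dtype=np.float32)
            idx = mask.voxel_indices
            vol[idx[:, 0], idx[:, 1], idx[:, 2], :] = series[None, :]
        img = nib.Nifti1Image(vol, grid.affine)
        img.header.set_zooms((*img.header.get_zooms()[:3], run.tr_seconds))
        images.append(img)
    return images
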