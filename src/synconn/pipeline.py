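"""End-to-end orchestration, subject manifest handling, and reports.

`run_pipeline` executes the full analysis on a simulated four-group
cohort (Normal / LPMC / F3 / Other, 7 subjects each by default):
simulate -> high-pass filter -> first-run normalization -> run
concatenation -> partial correlation -> Fisher Z -> group averaging ->
network summaries and statistical tests.  Every output is reproducible
from the config plus the master seed alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .connectivity import (
    ConnectivityMatrix,
    group_average,
    partial_corr_matrix,
    regress_out,
)
from .group_stats import (
    AbnormalBaseline,
    NetworkSummary,
    boundary_effect_test,
    dunnett_test,
    leveling_summary,
    preserved_pair_test,
    summarize_networks,
    tukey_kramer,
)
from .preprocess import PreprocessConfig, preprocess_subject
from .regions import RegionCatalog, load_default_catalog, load_region_catalog
from .synthetic import (
    F3_LEVELED_Z,
    LPMC_LEVELED_Z,
    PRESERVED_EDGES_Z,
    SimulationConfig,
    leveled_template,
    normal_template,
    other_template,
    hrf_convolve,
    simulate_group,
)

KNOWN_GROUPS = ("Normal", "LPMC", "F3", "Other")


# ---------------------------------------------------------------------------
# Manifest (demographics table)


def load_manifest(table: str | Path | pd.DataFrame) -> pd.DataFrame:
    """Parse a subject/group manifest with demographics.

    Requires columns subject, group, age, laterality; group labels must
    be among Normal/LPMC/F3/Other.
    """
    df = table.copy() if isinstance(table, pd.DataFrame) else pd.read_csv(table)
    required = ["subject", "group", "age", "laterality"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    if len(df) == 0:
        raise ValueError("empty manifest")
    unknown = sorted(set(df["group"]) - set(KNOWN_GROUPS))
    if unknown:
        raise ValueError(f"unknown group label(s): {unknown}")
    return df


def load_default_manifest() -> pd.DataFrame:
    from importlib import resources

    with resources.as_file(
        resources.files("synconn.data").joinpath("patient_manifest.csv")
    ) as path:
        return load_manifest(path)


def _round_like_table(value: float, is_sd: bool) -> float:
    """Means to integers; SDs to one decimal below 10, integers above."""
    if is_sd and value < 10:
        return round(float(value), 1)
    return float(round(float(value)))


def demographic_summary(manifest: pd.DataFrame) -> pd.DataFrame:
    """Per-group mean and SD of age and laterality, table-style rounded."""
    rows = []
    for group, sub in manifest.groupby("group", sort=False):
        row = {"group": group, "n": len(sub)}
        for col in ("age", "laterality"):
            mean = sub[col].mean()
            sd = sub[col].std(ddof=1) if len(sub) > 1 else np.nan
            row[f"{col}_mean"] = _round_like_table(mean, is_sd=False)
            row[f"{col}_sd"] = (
                _round_like_table(sd, is_sd=True) if np.isfinite(sd) else np.nan
            )
            row[f"{col}_sd_defined"] = bool(np.isfinite(sd))
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cohort CSV round trip (one tidy file per subject and run)


def save_cohort_csv(subjects, out_dir: str | Path) -> pd.DataFrame:
    """Write per-run ROI series as tidy CSVs; returns the cohort manifest.

    Each file ``<subject>_run<k>.csv`` has columns
    subject, run, volume_index, <region names...>.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for subject in subjects:
        for run in subject.runs:
            df = run.data.copy()
            df.insert(0, "volume_index", np.arange(len(df)))
            df.insert(0, "run", run.run_index)
            df.insert(0, "subject", subject.subject_id)
            safe = subject.subject_id.replace("/", "-")
            df.to_csv(out_dir / f"{safe}_run{run.run_index}.csv", index=False)
        rows.append(
            {
                "subject": subject.subject_id,
                "group": subject.group,
                "n_runs": len(subject.runs),
                "tr_seconds": subject.tr_seconds,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "cohort.csv", index=False)
    return manifest


def load_cohort_csv(in_dir: str | Path):
    """Read a cohort written by :func:`save_cohort_csv`."""
    from .preprocess import RunSeries, SubjectSeries

    in_dir = Path(in_dir)
    manifest = pd.read_csv(in_dir / "cohort.csv")
    subjects = []
    for _, row in manifest.iterrows():
        runs = []
        safe = str(row["subject"]).replace("/", "-")
        for k in range(int(row["n_runs"])):
            df = pd.read_csv(in_dir / f"{safe}_run{k}.csv")
            data = df.drop(columns=["subject", "run", "volume_index"])
            runs.append(
                RunSeries(
                    subject_id=row["subject"],
                    run_index=k,
                    tr_seconds=float(row["tr_seconds"]),
                    data=data,
                )
            )
        subjects.append(
            SubjectSeries(subject_id=row["subject"], group=row["group"], runs=runs)
        )
    return subjects


# ---------------------------------------------------------------------------
# Pipeline configuration


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one full analysis run."""

    seed: int = 0
    out_dir: str | Path | None = None
    region_table: str | Path | None = None  # None -> packaged catalog
    n_subjects_per_group: int = 7
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    lpmc_level_z: float = LPMC_LEVELED_Z
    f3_level_z: float = F3_LEVELED_Z
    remove_task_design: bool = False
    make_plots: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        pre = PreprocessConfig(**raw.pop("preprocess", {}))
        return cls(simulation=sim, preprocess=pre, **raw)

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir", None)
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def group_templates(config: PipelineConfig) -> dict:
    return {
        "Normal": normal_template(),
        "LPMC": leveled_template(config.lpmc_level_z),
        "F3": leveled_template(config.f3_level_z),
        "Other": other_template(),
    }


# ---------------------------------------------------------------------------
# Stages


def analyze_group(
    subjects,
    catalog: RegionCatalog,
    pre: PreprocessConfig,
    group: str,
    task_regressor: np.ndarray | None = None,
) -> tuple[list[ConnectivityMatrix], ConnectivityMatrix, NetworkSummary]:
    """preprocess -> partial correlation -> Z -> group average -> summary.

    ``task_regressor`` (optional, length = total concatenated volumes)
    is regressed out of every region series before correlating.
    """
    subject_mats = []
    for subject in subjects:
        X = preprocess_subject(subject, pre)
        if task_regressor is not None:
            X = regress_out(X, task_regressor)
        subject_mats.append(
            partial_corr_matrix(X, region_names=catalog.names, subject_id=subject.subject_id)
        )
    z_mats = [m.to_z() for m in subject_mats]
    group_matrix = group_average(z_mats)
    summary = summarize_networks(z_mats, catalog, group=group)
    return z_mats, group_matrix, summary


def statistical_tests(
    summaries: dict[str, NetworkSummary], other_subject_matrices
) -> tuple[list, dict]:
    """The group-contrast battery on computed summaries.

    Leveling effect and abnormal baseline from the two agrammatic groups;
    Dunnett comparisons of each patient group against Normal (within
    pairs: decreased; between pairs: increased); Tukey-Kramer over the
    Other group's three between-network categories; preserved-pair tests
    of the Other group's subject-level Z against the baseline.
    """
    tests = []
    leveling = leveling_summary([summaries["LPMC"], summaries["F3"]])
    baseline = AbnormalBaseline(leveling["abnormal_baseline_candidate"])

    normal = summaries["Normal"]
    patients = {g: summaries[g] for g in ("LPMC", "F3", "Other")}
    tests += dunnett_test(
        normal.within_values,
        {g: s.within_values for g, s in patients.items()},
        tail="less",
    )
    tests += dunnett_test(
        normal.between_values,
        {g: s.between_values for g, s in patients.items()},
        tail="greater",
    )

    other = summaries["Other"]
    tests += tukey_kramer(
        {
            c: other.pair_values[c]
            for c in ("between-(I,II)", "between-(I,III)", "between-(II,III)")
        }
    )

    for (name_a, name_b), _ in PRESERVED_EDGES_Z:
        values = np.array(
            [m.pair_value(name_a, name_b) for m in other_subject_matrices]
        )
        tests.append(
            preserved_pair_test(
                values, baseline, comparison=f"Other: {name_a}-{name_b} > baseline"
            )
        )
    return tests, leveling


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full simulated four-group analysis; return the report bundle.

    The bundle holds per-group subject/group matrices, network summaries,
    and all test results; when ``config.out_dir`` is set, matrices,
    summary tables, test JSON, and a provenance log are written there.
    """
    catalog = (
        load_default_catalog()
        if config.region_table is None
        else load_region_catalog(config.region_table)
    )
    root = np.random.SeedSequence(config.seed)
    group_seeds = {
        g: int(s.generate_state(1, dtype=np.uint32)[0] % (2**31))
        for g, s in zip(KNOWN_GROUPS, root.spawn(len(KNOWN_GROUPS)))
    }
    sim = SimulationConfig(
        **{**asdict(config.simulation), "n_subjects": config.n_subjects_per_group,
           "hrf_params": config.simulation.hrf_params}
    )

    bundle: dict = {
        "catalog": catalog,
        "groups": {},
        "tests": [],
        "log": {
            "software_version": __version__,
            "seed": config.seed,
            "group_seeds": group_seeds,
            "config_hash": config.config_hash(),
        },
    }
    task_regressor = None
    if config.remove_task_design:
        per_run = hrf_convolve(
            sim.onsets(), sim.n_volumes_per_run, sim.tr_seconds, sim.boxcar_duration_s
        )
        task_regressor = np.tile(per_run, sim.n_runs)

    templates = group_templates(config)
    summaries: dict[str, NetworkSummary] = {}
    for group, spec in templates.items():
        try:
            subjects, meta = simulate_group(
                spec, sim, catalog, master_seed=group_seeds[group], group=group
            )
            z_mats, group_matrix, summary = analyze_group(
                subjects, catalog, config.preprocess, group, task_regressor=task_regressor
            )
        except Exception as exc:  # annotate failures with the stage context
            raise RuntimeError(f"pipeline failed in group {group!r}: {exc}") from exc
        summaries[group] = summary
        bundle["groups"][group] = {
            "metadata": meta,
            "subject_matrices": z_mats,
            "group_matrix": group_matrix,
            "summary": summary,
        }
        bundle["tests"].append(boundary_effect_test(summary))

    tests, leveling = statistical_tests(
        summaries, bundle["groups"]["Other"]["subject_matrices"]
    )
    bundle["tests"] += tests
    bundle["leveling"] = leveling

    if config.out_dir is not None:
        _write_bundle(bundle, summaries, Path(config.out_dir), config)
    return bundle


# ---------------------------------------------------------------------------
# Report output


def summary_table(summaries: dict[str, NetworkSummary]) -> pd.DataFrame:
    rows = []
    for group, s in summaries.items():
        for cat, mean in s.category_means.items():
            rows.append(
                {
                    "group": group,
                    "category": cat,
                    "mean_z": mean,
                    "sem": s.category_sems[cat],
                    "n_pairs": len(s.pair_values[cat]),
                }
            )
        rows.append(
            {
                "group": group,
                "category": "all-pairs",
                "mean_z": s.overall_mean,
                "sem": float("nan"),
                "n_pairs": 91,
            }
        )
    return pd.DataFrame(rows)


def _write_matrix(matrix: ConnectivityMatrix, path: Path, catalog_hash: str) -> None:
    matrix.to_frame().to_csv(path, float_format="%.6f")
    sidecar = {
        "scale": matrix.scale,
        "level": matrix.level,
        "n_subjects": matrix.n_subjects,
        "catalog_hash": catalog_hash,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def _write_bundle(bundle, summaries, out_dir: Path, config: PipelineConfig) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    catalog: RegionCatalog = bundle["catalog"]
    catalog_hash = hashlib.sha256(
        catalog.to_frame().to_csv(index=False).encode()
    ).hexdigest()[:16]
    for group, g in bundle["groups"].items():
        _write_matrix(g["group_matrix"], out_dir / f"matrix_{group}.csv", catalog_hash)
    summary_table(summaries).to_csv(out_dir / "network_summary.csv", index=False)
    records = [t.to_dict() for t in bundle["tests"]]
    (out_dir / "tests.json").write_text(json.dumps(records, indent=1))
    (out_dir / "leveling.json").write_text(json.dumps(bundle["leveling"], indent=1))
    (out_dir / "run_log.json").write_text(json.dumps(bundle["log"], indent=1))
    if config.make_plots:
        plot_group_report(bundle, out_dir)


def plot_matrix(matrix: ConnectivityMatrix, ax=None, vmax: float = 0.3):
    """Heatmap of a Z matrix with the diagonal blacked out."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    values = np.ma.masked_invalid(matrix.values)
    cmap = matplotlib.colormaps["RdBu_r"].copy()
    cmap.set_bad("black")
    im = ax.imshow(values, cmap=cmap, vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(matrix.n_regions))
    ax.set_yticks(range(matrix.n_regions))
    ax.set_xticklabels(matrix.region_names, rotation=90, fontsize=5)
    ax.set_yticklabels(matrix.region_names, fontsize=5)
    return im


def plot_group_report(bundle, out_dir: Path) -> None:
    """Matrices plus category bar graphs (mean Z with SEM bars) per group."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    groups = list(bundle["groups"])
    fig, axes = plt.subplots(2, len(groups), figsize=(4 * len(groups), 7))
    for col, group in enumerate(groups):
        g = bundle["groups"][group]
        plot_matrix(g["group_matrix"], ax=axes[0, col])
        axes[0, col].set_title(group)
        s: NetworkSummary = g["summary"]
        cats = list(s.category_means)
        axes[1, col].bar(
            range(len(cats)),
            [s.category_means[c] for c in cats],
            yerr=[s.category_sems[c] for c in cats],
            capsize=3,
        )
        axes[1, col].set_xticks(range(len(cats)))
        axes[1, col].set_xticklabels(cats, rotation=45, ha="right", fontsize=6)
        axes[1, col].set_ylabel("mean Z")
    fig.tight_layout()
    fig.savefig(out_dir / "group_report.png", dpi=120)
    plt.close(fig)
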