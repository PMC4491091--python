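"""Network-level summaries and the statistical tests of the analysis.

Summaries aggregate Fisher-Z connectivity over the six pair categories
of the three-network partition (within I/II/III, between each network
pair).  The tests:

* network-boundary effect — one-tailed Welch t of the 27 within-network
  pair values against the 64 between-network pair values;
* leveling summary — the overall mean Z over all 91 pairs per group,
  with the maximum across supplied groups as the candidate "abnormal
  connectivity" baseline;
* Dunnett many-to-one comparisons against a control group, family-wise
  adjusted through the Monte-Carlo max-t distribution;
* Tukey–Kramer all-pairs comparisons on the studentized-range
  distribution with the Kramer unequal-n adjustment;
* preserved-pair test — one-tailed one-sample t of subject-level Z for
  a single pair against the abnormal baseline.

Welch (unequal-variance) statistics are used for every two-sample
comparison.  Significance thresholds are annotations for reports, never
gates inside the computations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .connectivity import (
    BETWEEN_CATEGORIES,
    PAIR_CATEGORIES,
    WITHIN_CATEGORIES,
    ConnectivityMatrix,
    category_pair_values,
    group_average,
)
from .regions import RegionCatalog

DEFAULT_ABNORMAL_BASELINE_Z = 0.052


@dataclass
class TestResult:
    test: str
    statistic: float
    df: float | tuple[float, float]
    tail: str  # "one" or "two"
    p_value: float
    comparison: str
    unit: str  # "pairs" or "subjects"

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p-value out of range: {self.p_value}")

    def to_dict(self) -> dict:
        df = list(self.df) if isinstance(self.df, tuple) else self.df
        return {
            "test": self.test,
            "statistic": self.statistic,
            "df": df,
            "tail": self.tail,
            "p_value": self.p_value,
            "comparison": self.comparison,
            "unit": self.unit,
        }


@dataclass
class AbnormalBaseline:
    """Reference Z level regarded as typical abnormal connectivity."""

    z_value: float = DEFAULT_ABNORMAL_BASELINE_Z

    def __post_init__(self) -> None:
        if not np.isfinite(self.z_value):
            raise ValueError("baseline Z must be finite")


@dataclass
class NetworkSummary:
    """Per-category mean Z (+SEM over pairs) for one group."""

    group: str
    category_means: dict[str, float]
    category_sems: dict[str, float]
    pair_values: dict[str, np.ndarray]  # group-level Z per pair, by category
    overall_mean: float
    n_subjects: int | None = None
    subject_pair_values: dict[str, np.ndarray] = field(default_factory=dict)
    # subject_pair_values[cat]: (n_subjects, n_pairs_in_cat) when subject
    # matrices were supplied

    @property
    def within_values(self) -> np.ndarray:
        return np.concatenate([self.pair_values[c] for c in WITHIN_CATEGORIES])

    @property
    def between_values(self) -> np.ndarray:
        return np.concatenate([self.pair_values[c] for c in BETWEEN_CATEGORIES])


def summarize_networks(
    matrices: ConnectivityMatrix | Sequence[ConnectivityMatrix],
    catalog: RegionCatalog,
    group: str = "",
) -> NetworkSummary:
    """Aggregate a group matrix (or per-subject matrices) by pair category.

    Means and SEMs are over region pairs of the group-level Z matrix; when
    subject matrices are given, the per-subject pair values are retained
    for subject-level tests.
    """
    subject_pair_values: dict[str, np.ndarray] = {}
    if isinstance(matrices, ConnectivityMatrix):
        group_matrix = matrices.to_z()
        n_subjects = matrices.n_subjects
    else:
        mats = list(matrices)
        group_matrix = group_average(mats)
        n_subjects = len(mats)
        per_subj = [category_pair_values(m.to_z(), catalog) for m in mats]
        subject_pair_values = {
            c: np.stack([d[c] for d in per_subj]) for c in PAIR_CATEGORIES
        }
    if group_matrix.scale != "Z":
        raise ValueError("summary requires the Fisher-Z scale")
    pair_values = category_pair_values(group_matrix, catalog)
    means = {c: float(np.mean(v)) for c, v in pair_values.items()}
    sems = {
        c: float(stats.sem(v)) if len(v) > 1 else float("nan")
        for c, v in pair_values.items()
    }
    all_values = np.concatenate(list(pair_values.values()))
    return NetworkSummary(
        group=group,
        category_means=means,
        category_sems=sems,
        pair_values=pair_values,
        overall_mean=float(np.mean(all_values)),
        n_subjects=n_subjects,
        subject_pair_values=subject_pair_values,
    )


def boundary_effect_test(summary: NetworkSummary) -> TestResult:
    """One-tailed Welch t: within-network pair Z > between-network pair Z."""
    within = summary.within_values
    between = summary.between_values
    if len(within) < 2 or len(between) < 2:
        raise ValueError("need at least 2 pairs on each side")
    if np.ptp(within) == 0 and np.ptp(between) == 0:
        raise ValueError("degenerate input: zero variance on both sides")
    res = stats.ttest_ind(within, between, equal_var=False, alternative="greater")
    return TestResult(
        test="network-boundary (Welch t, one-tailed)",
        statistic=float(res.statistic),
        df=float(res.df),
        tail="one",
        p_value=float(res.pvalue),
        comparison=f"{summary.group}: within > between",
        unit="pairs",
    )


def leveling_summary(
    summaries: Mapping[str, NetworkSummary] | Sequence[NetworkSummary]
) -> dict:
    """Overall mean Z per group; the max is the candidate abnormal baseline."""
    if isinstance(summaries, Mapping):
        items = list(summaries.values())
    else:
        items = list(summaries)
    overall = {s.group: s.overall_mean for s in items}
    baseline = max(overall.values())
    return {"overall_mean_z": overall, "abnormal_baseline_candidate": baseline}


# ---------------------------------------------------------------------------
# Dunnett many-to-one comparisons (Monte-Carlo max-t)

_DUNNETT_NULL_CACHE: dict[tuple, np.ndarray] = {}


def _welch_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    nx, ny = len(x), len(y)
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    se2 = vx / nx + vy / ny
    t = (np.mean(x) - np.mean(y)) / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return float(t), float(df)


def _dunnett_null_max_t(
    sizes: tuple[int, ...], tail: str, n_mc: int, seed: int
) -> np.ndarray:
    """Sorted Monte-Carlo null distribution of the family max statistic.

    Samples all groups from one standard normal population (the exchange-
    able null), computes the Welch t of every treatment against the
    control, and records max |t| (two-tailed) or max t (one-tailed).
    Cached by (sizes, tail, n_mc, seed): the distribution depends only on
    the design, so repeated tests on the same design are cheap.
    """
    key = (sizes, tail, n_mc, seed)
    if key in _DUNNETT_NULL_CACHE:
        return _DUNNETT_NULL_CACHE[key]
    rng = np.random.default_rng(seed)
    n_control, *n_treat = sizes
    # vectorized over MC replicates: per group draw (n_mc, n_i)
    ctrl = rng.standard_normal((n_mc, n_control))
    cm = ctrl.mean(axis=1)
    cv = ctrl.var(axis=1, ddof=1)
    stat = np.full(n_mc, -np.inf)
    for n_i in n_treat:
        tr = rng.standard_normal((n_mc, n_i))
        tm = tr.mean(axis=1)
        tv = tr.var(axis=1, ddof=1)
        t = (tm - cm) / np.sqrt(tv / n_i + cv / n_control)
        stat = np.maximum(stat, np.abs(t) if tail == "two" else t)
    stat.sort()
    _DUNNETT_NULL_CACHE[key] = stat
    return stat


def dunnett_test(
    control: np.ndarray,
    treatments: Mapping[str, np.ndarray] | Sequence[np.ndarray],
    tail: str = "two",
    n_mc: int = 100_000,
    seed: int = 20150704,
) -> list[TestResult]:
    """Many-to-one comparisons vs. a control, max-t family-wise adjusted.

    Per comparison the statistic is the Welch t (treatment minus control);
    the adjusted p-value is the Monte-Carlo probability that the family
    maximum statistic exceeds the observed one under the null.  ``tail``:
    "two", "greater" (treatment > control) or "less".
    """
    if isinstance(treatments, Mapping):
        labels = list(treatments.keys())
        groups = [np.asarray(v, dtype=float) for v in treatments.values()]
    else:
        groups = [np.asarray(v, dtype=float) for v in treatments]
        labels = [f"group_{k}" for k in range(len(groups))]
    if not groups:
        raise ValueError("need at least one treatment group")
    control = np.asarray(control, dtype=float)
    if len(control) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least 2 observations")
    if tail not in ("two", "greater", "less"):
        raise ValueError(f"unknown tail {tail!r}")
    mc_tail = "two" if tail == "two" else "one"
    sizes = (len(control),) + tuple(len(g) for g in groups)
    null = _dunnett_null_max_t(sizes, mc_tail, n_mc, seed)
    results = []
    for label, g in zip(labels, groups):
        t, df = _welch_t(g, control)
        if tail == "two":
            observed = abs(t)
        elif tail == "greater":
            observed = t
        else:
            observed = -t
        # P(max-stat >= observed) with the +1 correction for MC p-values
        n_ge = len(null) - np.searchsorted(null, observed, side="left")
        p = (n_ge + 1) / (len(null) + 1)
        results.append(
            TestResult(
                test="Dunnett (Monte-Carlo max-t)",
                statistic=t,
                df=df,
                tail="two" if tail == "two" else "one",
                p_value=float(min(p, 1.0)),
                comparison=f"{label} vs control",
                unit="pairs",
            )
        )
    return results


# ---------------------------------------------------------------------------
# Tukey-Kramer all-pairs comparisons


def tukey_kramer(groups: Mapping[str, np.ndarray]) -> list[TestResult]:
    """All pairwise comparisons on the studentized-range distribution.

    Unequal group sizes use the Kramer adjustment: the standard error of a
    pair is sqrt(MSW/2 * (1/n_i + 1/n_j)) with MSW the pooled within-group
    mean square, df = N - k.
    """
    labels = list(groups.keys())
    data = {lab: np.asarray(v, dtype=float) for lab, v in groups.items()}
    if len(labels) < 2:
        raise ValueError("need at least 2 categories")
    for lab, v in data.items():
        if len(v) < 2:
            raise ValueError(f"category {lab!r} has fewer than 2 observations")
    k = len(labels)
    n_total = sum(len(v) for v in data.values())
    df_w = n_total - k
    msw = sum((len(v) - 1) * np.var(v, ddof=1) for v in data.values()) / df_w
    results = []
    for a in range(k):
        for b in range(a + 1, k):
            va, vb = data[labels[a]], data[labels[b]]
            se = np.sqrt(msw / 2.0 * (1.0 / len(va) + 1.0 / len(vb)))
            q = abs(np.mean(va) - np.mean(vb)) / se
            p = float(stats.studentized_range.sf(q, k, df_w))
            results.append(
                TestResult(
                    test="Tukey-Kramer (studentized range)",
                    statistic=float(q),
                    df=float(df_w),
                    tail="two",
                    p_value=min(p, 1.0),
                    comparison=f"{labels[a]} vs {labels[b]}",
                    unit="pairs",
                )
            )
    return results


def preserved_pair_test(
    subject_z: np.ndarray,
    baseline: AbnormalBaseline | float = DEFAULT_ABNORMAL_BASELINE_Z,
    comparison: str = "",
) -> TestResult:
    """One-tailed one-sample t: subject-level Z for one pair > baseline."""
    z = np.asarray(subject_z, dtype=float)
    if len(z) < 2:
        raise ValueError("need at least 2 subjects")
    if np.var(z) == 0:
        raise ValueError("zero variance across subjects")
    b = baseline.z_value if isinstance(baseline, AbnormalBaseline) else float(baseline)
    res = stats.ttest_1samp(z, b, alternative="greater")
    return TestResult(
        test="preserved-pair one-sample t (one-tailed)",
        statistic=float(res.statistic),
        df=float(len(z) - 1),
        tail="one",
        p_value=float(res.pvalue),
        comparison=comparison or f"pair Z > baseline {b}",
        unit="subjects",
    )
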