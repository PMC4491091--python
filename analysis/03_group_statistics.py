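"""Network summaries and the full statistical battery on the cohort.

Reads scratch/cohort/, recomputes per-group summaries, then runs the
boundary-effect tests, the leveling summary, Dunnett comparisons vs the
Normal group, the Tukey-Kramer contrast of the Other group's
between-network categories, and the preserved-pair tests.  Writes
results/network_summary.csv, results/tests.json, results/leveling.json.
"""

import json
from pathlib import Path

from synconn.group_stats import boundary_effect_test
from synconn.pipeline import (
    KNOWN_GROUPS,
    analyze_group,
    load_cohort_csv,
    statistical_tests,
    summary_table,
)
from synconn.preprocess import PreprocessConfig
from synconn.regions import load_default_catalog

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    catalog = load_default_catalog()
    summaries, tests = {}, []
    other_subject_matrices = None
    for group in KNOWN_GROUPS:
        subjects = load_cohort_csv(ROOT / "scratch" / "cohort" / group)
        z_mats, _, summary = analyze_group(subjects, catalog, PreprocessConfig(), group)
        summaries[group] = summary
        if group == "Other":
            other_subject_matrices = z_mats
        res = boundary_effect_test(summary)
        tests.append(res)
        print(f"boundary effect {group}: t={res.statistic:+.2f}, p={res.p_value:.2g}")

    battery, leveling = statistical_tests(summaries, other_subject_matrices)
    tests += battery
    print(
        "leveling: overall mean Z "
        + ", ".join(f"{g}={v:.3f}" for g, v in leveling["overall_mean_z"].items())
        + f"; abnormal baseline candidate {leveling['abnormal_baseline_candidate']:.3f}"
    )
    for t in battery:
        print(f"  {t.test}: {t.comparison}  p={t.p_value:.3g}")

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    summary_table(summaries).to_csv(results / "network_summary.csv", index=False)
    (results / "tests.json").write_text(json.dumps([t.to_dict() for t in tests], indent=1))
    (results / "leveling.json").write_text(json.dumps(leveling, indent=1))
    print(f"wrote network_summary.csv, tests.json, leveling.json under {results}")


if __name__ == "__main__":
    main()
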