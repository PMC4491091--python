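"""Render the connectivity-matrix heatmaps and category bar graphs.

One-shot driver over the seeded pipeline: re-runs the whole analysis via
run_pipeline (deterministic, same seed as the scripts before it) and
saves the combined figure to scratch/figures/group_report.png.
"""

from pathlib import Path

from synconn.pipeline import PipelineConfig, plot_group_report, run_pipeline

ROOT = Path(__file__).resolve().parents[1]
SEED = 20150704


def main() -> None:
    bundle = run_pipeline(PipelineConfig(seed=SEED))
    out = ROOT / "scratch" / "figures"
    out.mkdir(parents=True, exist_ok=True)
    plot_group_report(bundle, out)
    print(f"figure written to {out / 'group_report.png'}")


if __name__ == "__main__":
    main()
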