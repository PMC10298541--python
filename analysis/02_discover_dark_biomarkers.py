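#!/usr/bin/env python
"""Run the full dark-biomarker discovery workflow on the simulated cohorts.

Cohort 1 is the training cohort: per-gene TF regressions are fitted on 60%
of its primary samples, models with training PCC > 0.5 are retained, and the
same models score every cohort in mqTrans (residual) space.  Genes
non-differential in expression (p > 0.05) but differential in mqTrans space
(p < 0.05) are flagged dark per cohort; the three dark sets are intersected,
and the 50/40/20% reduced-training robustness scan reruns the chain on
sub-samples of the training set against the fixed test set.

Bulky outputs (mqTrans matrices, weight tables) stay in scratch/discovery/;
small summary tables are copied to results/discovery/.

Requires: 01_simulate_cohorts.py.
"""

import shutil
from pathlib import Path

from mqtrans.pipeline import CohortPaths, RunConfig, run_discovery

ROOT = Path(__file__).resolve().parents[1]
SEED = 1

SMALL_ARTIFACTS = (
    "cohort1.differential.tsv",
    "cohort2.differential.tsv",
    "cohort3.differential.tsv",
    "cohort1.dark.txt",
    "cohort2.dark.txt",
    "cohort3.dark.txt",
    "cohort1.models.summary.tsv",
    "intersection.dark.txt",
    "venn_counts.tsv",
    "robustness_overlap.tsv",
    "robustness_dark_sets.tsv",
    "manifest.json",
)


def main() -> None:
    cohort_dirs = sorted((ROOT / "scratch" / "cohorts").glob("cohort*"))
    if len(cohort_dirs) != 3:
        raise SystemExit("run analysis/01_simulate_cohorts.py first")
    config = RunConfig(
        cohorts=[CohortPaths.from_dir(d.name, d) for d in cohort_dirs],
        annotation=str(cohort_dirs[0] / "platform_annotation.tsv"),
        tf_registry=str(cohort_dirs[0] / "tf_registry.txt"),
        output_dir=str(ROOT / "scratch" / "discovery"),
        seed=SEED,
    )
    manifest = run_discovery(config)

    out = ROOT / "results" / "discovery"
    out.mkdir(parents=True, exist_ok=True)
    for name in SMALL_ARTIFACTS:
        src = Path(config.output_dir) / name
        if src.exists():
            shutil.copy(src, out / name)

    print(f"models retained: {manifest['n_models_retained']} / {manifest['n_models_fitted']}")
    print(f"dark biomarkers per cohort: {manifest['n_dark_per_cohort']}")
    print(f"shared by all three cohorts: {manifest['n_dark_intersection']}")
    print(f"robustness dark-set sizes at reduced fractions: {manifest['robustness']}")
    print(f"summary tables in {out}")


if __name__ == "__main__":
    main()
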