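#!/usr/bin/env python
"""Score the discovery run against the generator's ground truth.

Cross-tabulates the per-cohort dark calls and the three-cohort intersection
against the injected gene classes, answering: how many injected dark genes
does the procedure recover, and how often does it mislabel bright, passenger
or null genes as dark?  Writes results/discovery/truth_scores.tsv.

Requires: 02_discover_dark_biomarkers.py.
"""

from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    res = ROOT / "results" / "discovery"
    # keep_default_na: the class literal "null" must not be parsed as NaN
    truth = pd.read_csv(
        ROOT / "scratch" / "cohorts" / "cohort1" / "truth.tsv",
        sep="\t",
        keep_default_na=False,
    ).set_index("feature")["class"]

    rows = []
    for name in ("cohort1", "cohort2", "cohort3", "intersection"):
        dark = set((res / f"{name}.dark.txt").read_text().split())
        counts = truth[truth.index.isin(dark)].value_counts()
        row = {"set": name, "n_dark_called": len(dark)}
        for cls in ("dark", "bright", "passenger", "null"):
            row[f"n_{cls}"] = int(counts.get(cls, 0))
        row["dark_gene_recall"] = counts.get("dark", 0) / (truth == "dark").sum()
        rows.append(row)
    table = pd.DataFrame(rows)
    table.to_csv(res / "truth_scores.tsv", sep="\t", index=False,
                 float_format="%.4g")
    print(table.to_string(index=False))
    inter = table[table["set"] == "intersection"].iloc[0]
    print(
        f"\nThe three-cohort intersection keeps {inter.n_dark} of 30 injected "
        f"dark genes (recall {inter.dark_gene_recall:.2f}) and "
        f"{inter.n_null + inter.n_bright + inter.n_passenger} non-dark genes."
    )


if __name__ == "__main__":
    main()
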