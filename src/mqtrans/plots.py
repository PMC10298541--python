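"""Optional figure outputs: per-biomarker group box plots and Venn-style
dark-set counts.  Matplotlib is imported lazily so the rest of the package
works without a plotting backend."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .detection import DarkBiomarkerSet, intersect_dark
from .io_cohort import Label, SampleAnnotation


def biomarker_boxplot(
    expression: pd.DataFrame,
    mq: pd.DataFrame,
    annotations: Sequence[SampleAnnotation],
    features: Sequence[str],
    path: str | Path,
) -> None:
    """Side-by-side metastatic/primary box plots of each feature in both
    spaces (raw expression top row, mqTrans bottom row)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    met = [a.sample_id for a in annotations
           if a.label is Label.METASTATIC and a.sample_id in mq.columns]
    prim = [a.sample_id for a in annotations
            if a.label is Label.PRIMARY and a.sample_id in mq.columns]
    features = [f for f in features if f in mq.index]
    fig, axes = plt.subplots(2, max(len(features), 1),
                             figsize=(2.2 * max(len(features), 1), 6),
                             squeeze=False)
    for j, f in enumerate(features):
        for i, (mat, label) in enumerate(((expression, "expression"), (mq, "mqTrans"))):
            ax = axes[i][j]
            ax.boxplot(
                [mat.loc[f, met], mat.loc[f, prim]],
                tick_labels=["M", "P"],
            )
            if i == 0:
                ax.set_title(f, fontsize=8)
            if j == 0:
                ax.set_ylabel(label)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def venn_count_barplot(sets: Sequence[DarkBiomarkerSet], path: str | Path) -> None:
    """Bar chart of per-dataset dark-set sizes and the overall intersection."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = [s.dataset_id for s in sets] + ["intersection"]
    counts = [len(s.features) for s in sets] + [len(intersect_dark(sets))]
    fig, ax = plt.subplots(figsize=(1.2 * len(names) + 1, 3.5))
    ax.bar(names, counts)
    ax.set_ylabel("dark biomarkers")
    for x, c in enumerate(counts):
        ax.text(x, c, str(c), ha="center", va="bottom", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
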