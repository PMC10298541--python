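"""Reference-configuration benchmark runs: parameter recovery and null
calibration of the dark-biomarker procedure on synthetic cohorts.

These helpers run the full chain (split → fit → filter → mqTrans → detect)
on generated cohorts and score the calls against the generator's ground
truth.  They are used both by the test suite and by the reproduction script.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .detection import detect_dark
from .io_cohort import SampleAnnotation
from .regression import compute_mqtrans, filter_models, fit_gene_models, split_train_test
from .synthetic import (
    RegulatoryProgram,
    SyntheticTruth,
    TruthSpec,
    gene_feature_id,
    generate_cohort,
    tf_feature_id,
)

__all__ = ["run_cohort_analysis", "class_call_rates", "permuted_label_dark_rate"]


def run_cohort_analysis(
    program: RegulatoryProgram,
    spec: TruthSpec,
    seed: int,
    n_primary: int = 400,
    n_metastatic: int = 60,
    train_fraction: float = 0.6,
    n_predictors: int | None = 10,
    pcc_threshold: float = 0.5,
    permute_labels: bool = False,
) -> tuple[pd.DataFrame, SyntheticTruth, list]:
    """Generate one cohort and run the discovery chain on it.

    Returns the dual-space differential table (with a ``cls`` ground-truth
    column), the truth object, and the retained models.  With
    ``permute_labels`` the metastasis labels are shuffled across samples
    (generator stream seeded by the same seed), destroying any label/feature
    association while keeping the marginal data distribution — the global
    null for calibration checks.
    """
    matrix, annotations, truth = generate_cohort(
        program, spec, n_primary, n_metastatic, seed=seed
    )
    if permute_labels:
        rng = np.random.default_rng(seed + 1_000_003)
        labels = [a.label for a in annotations]
        perm = rng.permutation(len(labels))
        annotations = [
            SampleAnnotation(
                sample_id=a.sample_id,
                m_parameter=a.m_parameter,
                label=labels[j],
            )
            for a, j in zip(annotations, perm)
        ]
    train, test = split_train_test(annotations, train_fraction, seed)
    tfs = [tf_feature_id(i) for i in range(program.n_tf)]
    genes = [gene_feature_id(i) for i in range(spec.n_genes)]
    retained = filter_models(
        fit_gene_models(matrix[train], tfs, genes, n_predictors=n_predictors),
        pcc_threshold,
    )
    mq = compute_mqtrans(retained, matrix[test])
    table = detect_dark(matrix[test], mq, annotations)
    table["cls"] = table["feature"].map(truth.gene_class)
    return table, truth, retained


def class_call_rates(
    program: RegulatoryProgram,
    spec: TruthSpec,
    seeds: Sequence[int],
    **kwargs,
) -> dict[str, float]:
    """Dark-call rate per ground-truth class, pooled over seeds.

    ``sensitivity`` is the rate on dark genes; the other classes measure
    false dark calls.
    """
    calls: dict[str, list[bool]] = {"dark": [], "bright": [], "passenger": [], "null": []}
    for seed in seeds:
        table, _, _ = run_cohort_analysis(program, spec, seed, **kwargs)
        for cls, grp in table.groupby("cls"):
            calls[cls].extend(grp["is_dark"].tolist())
    return {cls: float(np.mean(v)) if v else float("nan") for cls, v in calls.items()}


def permuted_label_dark_rate(
    program: RegulatoryProgram,
    spec: TruthSpec,
    seeds: Sequence[int],
    **kwargs,
) -> float:
    """Pooled dark-call rate over all genes under label permutation."""
    rates = []
    for seed in seeds:
        table, _, _ = run_cohort_analysis(
            program, spec, seed, permute_labels=True, **kwargs
        )
        rates.append(table["is_dark"].mean())
    return float(np.mean(rates))
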