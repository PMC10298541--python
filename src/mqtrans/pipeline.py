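"""End-to-end discovery workflow: curate → partition → split → fit → filter →
mqTrans → dual-space detection → cross-cohort intersection → robustness scan.

The first configured cohort is the training cohort: models are fitted on its
primary training split and, by default, the *same* trained models are applied
to every other cohort (``retrain_per_dataset`` switches to per-cohort
retraining).  All tabular outputs are TSV with full-precision floats, so a
rerun under the same config and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .detection import (
    DarkBiomarkerSet,
    detect_dark,
    intersect_dark,
    robustness_overlap_table,
    robustness_scan,
    venn_counts,
)
from .io_cohort import (
    FeatureClass,
    Label,
    curate_labels,
    partition_features,
    read_expression_matrix,
    read_platform_annotation,
    read_sample_metadata,
    read_tf_registry,
    split_by_label,
    write_expression_matrix,
)
from .regression import (
    compute_mqtrans,
    filter_models,
    fit_gene_models,
    split_train_test,
    write_models,
)

logger = logging.getLogger("mqtrans")

__all__ = ["CohortPaths", "RunConfig", "run_discovery", "run_simulate"]


@dataclass
class CohortPaths:
    """Input file locations for one cohort."""

    cohort_id: str
    expression: str
    metadata: str

    @classmethod
    def from_dir(cls, cohort_id: str, directory: str | Path) -> "CohortPaths":
        d = Path(directory)
        return cls(
            cohort_id=cohort_id,
            expression=str(d / "expression.tsv"),
            metadata=str(d / "metadata.tsv"),
        )


@dataclass
class RunConfig:
    """Configuration of a discovery run; defaults follow the standard protocol
    (60% training split, PCC > 0.5 model retention, 0.05/0.05 dual thresholds,
    robustness at 50/40/20%)."""

    cohorts: list[CohortPaths]
    annotation: str
    tf_registry: str
    output_dir: str
    train_fraction: float = 0.6
    robustness_fractions: tuple[float, ...] = (0.5, 0.4, 0.2)
    alpha_orig: float = 0.05
    alpha_mq: float = 0.05
    pcc_threshold: float = 0.5
    estimator: str = "ols"
    #: per-target predictor screening budget (top-k TFs by |training
    #: correlation|); None fits on the full TF pool
    n_predictors: int | None = 10
    equal_var: bool = True
    retrain_per_dataset: bool = False
    seed: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0,1)")
        for a in (self.alpha_orig, self.alpha_mq, self.pcc_threshold):
            if not 0 < a < 1:
                raise ValueError("thresholds must be in (0,1)")
        for f in self.robustness_fractions:
            if not 0 < f < 1:
                raise ValueError("robustness fractions must be in (0,1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["cohorts"] = [CohortPaths(**c) for c in raw["cohorts"]]
        if "robustness_fractions" in raw:
            raw["robustness_fractions"] = tuple(raw["robustness_fractions"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["robustness_fractions"] = list(self.robustness_fractions)
        return d


def _require(path: str, what: str) -> Path:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"{what} not found: {path}")
    return p


def run_discovery(config: RunConfig) -> dict:
    """Execute the full workflow; returns a result summary and writes all
    artifacts (model tables, mqTrans matrices, differential tables, dark
    sets, Venn counts, robustness tables, manifest) under the output dir."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    annotation = read_platform_annotation(_require(config.annotation, "platform annotation"))
    registry = read_tf_registry(_require(config.tf_registry, "TF registry"))
    partition = partition_features(annotation, registry)
    tf_probes = sorted(partition.tf_probes)
    mrna_probes = sorted(partition.mrna_probes)
    logger.info(
        "feature partition: %d TF / %d mRNA / %d unmapped",
        len(tf_probes),
        len(mrna_probes),
        len(partition.probes_of(FeatureClass.UNMAPPED)),
    )

    cohorts = []
    for cp in config.cohorts:
        expr = read_expression_matrix(_require(cp.expression, "expression matrix"))
        meta = read_sample_metadata(_require(cp.metadata, "sample metadata"))
        ann = curate_labels(meta)
        prim, met, excl = split_by_label(ann)
        logger.info(
            "cohort %s: %d samples raw; %d primary / %d metastatic / %d excluded",
            cp.cohort_id,
            len(ann),
            len(prim),
            len(met),
            len(excl),
        )
        cohorts.append((cp.cohort_id, expr, ann))
    if not cohorts:
        raise ValueError("no cohorts configured")

    # --- train on the first cohort's primary training split
    train_id, train_expr, train_ann = cohorts[0]
    train_ids, test_ids = split_train_test(train_ann, config.train_fraction, config.seed)
    tf_avail = [p for p in tf_probes if p in train_expr.index]
    targets = [p for p in mrna_probes if p in train_expr.index]
    if not tf_avail or not targets:
        raise ValueError("training cohort lacks TF or mRNA features")
    models = fit_gene_models(
        train_expr[train_ids],
        tf_avail,
        targets,
        estimator=config.estimator,
        probe_to_symbols=partition.probe_to_symbols,
        n_predictors=config.n_predictors,
    )
    retained = filter_models(models, config.pcc_threshold)
    logger.info(
        "cohort %s: fitted %d models on %d training samples, retained %d at PCC > %g",
        train_id,
        len(models),
        len(train_ids),
        len(retained),
        config.pcc_threshold,
    )
    write_models(retained, out / f"{train_id}.models")

    dark_sets: list[DarkBiomarkerSet] = []
    for i, (cid, expr, ann) in enumerate(cohorts):
        if i == 0:
            eval_ids = test_ids
            cohort_models = retained
        else:
            eval_ids = [a.sample_id for a in ann if a.label is not Label.EXCLUDED]
            if config.retrain_per_dataset:
                tr, eval_ids = split_train_test(ann, config.train_fraction, config.seed)
                cohort_models = filter_models(
                    fit_gene_models(
                        expr[tr],
                        [p for p in tf_probes if p in expr.index],
                        [p for p in mrna_probes if p in expr.index],
                        estimator=config.estimator,
                        probe_to_symbols=partition.probe_to_symbols,
                        n_predictors=config.n_predictors,
                    ),
                    config.pcc_threshold,
                )
            else:
                cohort_models = retained
        mq = compute_mqtrans(cohort_models, expr[eval_ids])
        write_expression_matrix(mq, out / f"{cid}.mqtrans.tsv")
        table = detect_dark(
            expr[eval_ids], mq, ann, config.alpha_orig, config.alpha_mq, config.equal_var
        )
        _write_tsv(table, out / f"{cid}.differential.tsv")
        dark = sorted(table.loc[table["is_dark"], "feature"])
        (out / f"{cid}.dark.txt").write_text("".join(f + "\n" for f in dark))
        logger.info("cohort %s: %d dark biomarkers on %d evaluation samples",
                    cid, len(dark), len(eval_ids))
        dark_sets.append(
            DarkBiomarkerSet(cid, set(dark), config.alpha_orig, config.alpha_mq)
        )

    intersection = sorted(intersect_dark(dark_sets))
    (out / "intersection.dark.txt").write_text("".join(f + "\n" for f in intersection))
    _write_tsv(venn_counts(dark_sets), out / "venn_counts.tsv")
    logger.info("%d dark biomarkers shared by all %d cohorts", len(intersection), len(dark_sets))

    # --- reduced-training-fraction robustness on the training cohort
    scans = {}
    if config.robustness_fractions:
        scans = robustness_scan(
            train_expr,
            train_ann,
            tf_avail,
            targets,
            train_pool=train_ids,
            fixed_test=test_ids,
            fractions=config.robustness_fractions,
            seed=config.seed,
            main_fraction=config.train_fraction,
            pcc_threshold=config.pcc_threshold,
            alpha_orig=config.alpha_orig,
            alpha_mq=config.alpha_mq,
            equal_var=config.equal_var,
            dataset_id=train_id,
            n_predictors=config.n_predictors,
        )
        _write_tsv(
            robustness_overlap_table(dark_sets[0], scans),
            out / "robustness_overlap.tsv",
        )
        rows = []
        for frac in sorted(scans, reverse=True):
            for f in sorted(scans[frac].features):
                rows.append({"fraction": f"{frac:g}", "feature": f})
        _write_tsv(pd.DataFrame(rows, columns=["fraction", "feature"]),
                   out / "robustness_dark_sets.tsv")

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "n_models_fitted": len(models),
        "n_models_retained": len(retained),
        "n_dark_per_cohort": {s.dataset_id: len(s.features) for s in dark_sets},
        "n_dark_intersection": len(intersection),
        "robustness": {f"{f:g}": len(s.features) for f, s in scans.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def run_simulate(
    outdir: str | Path,
    n_cohorts: int = 1,
    n_primary: int = 400,
    n_metastatic: int = 60,
    seed: int = 1,
    program_seed: int = 0,
    **spec_kwargs,
) -> list[Path]:
    """Generate one or more synthetic cohorts sharing a single regulatory
    program and write them in the pipeline's input dialects."""
    from .synthetic import TruthSpec, build_program, generate_cohort, write_cohort

    spec = TruthSpec(**spec_kwargs)
    if spec.n_genes <= 0:
        raise ValueError("truth spec requests no genes")
    program = build_program(spec, program_seed=program_seed)
    outdir = Path(outdir)
    dirs = []
    for i in range(n_cohorts):
        matrix, ann, truth = generate_cohort(
            program, spec, n_primary, n_metastatic, seed=seed + i
        )
        d = outdir / f"cohort{i + 1}"
        write_cohort(matrix, ann, truth, program, d)
        dirs.append(d)
        logger.info("wrote synthetic cohort %s (%d features × %d samples)",
                    d, matrix.shape[0], matrix.shape[1])
    return dirs


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", lineterminator="\n")
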