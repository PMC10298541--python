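"""Synthetic primary/metastatic expression cohorts with a known TF→mRNA
regulatory program and ground-truth gene classes.

The generative model: TF expression is multivariate Gaussian (exchangeable
correlation, unit variance, per-TF means on a log2-microarray-like scale).
Each regulated gene is a sparse linear function of 3–8 TFs plus Gaussian
noise, with the noise level chosen so an oracle regression on primary samples
attains a target training PCC (default ≈ 0.7).  Metastatic samples shift a
designated subset of TFs upward by δ (in TF-SD units), and each gene belongs
to one of four classes that define how it responds:

* ``null`` — no shifted TF among its regulators; nothing changes.
* ``passenger`` — regulators shift and the gene simply tracks them: its
  expression shifts, but a primary-trained model predicts the shift, so the
  residual stays centred at zero.  Expression-DE, residual-null.
* ``bright`` — a TF-independent intercept shift in metastatic samples: the
  classic differentially expressed gene.
* ``dark`` — the metastatic intercept is compensated by exactly
  −(weights·δ over shifted regulators), so the marginal mean and variance of
  expression are preserved while the primary-trained model's residual mean
  shifts by +weights·δ.  This is regulatory rewiring invisible to raw
  differential expression.

All randomness flows from one integer seed through a single generator
stream; the regulatory program itself is drawn from a separate,
caller-supplied program seed so one program can be shared across cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_cohort import Label, SampleAnnotation, curate_labels

__all__ = [
    "RegulatoryProgram",
    "TruthSpec",
    "SyntheticTruth",
    "build_program",
    "generate_cohort",
    "reference_config",
    "write_cohort",
]

GENE_CLASSES = ("dark", "bright", "passenger", "null")


@dataclass
class TruthSpec:
    """Configuration of the injected ground truth."""

    n_shifted_tf: int = 10
    delta: float = 1.0  # TF group-mean shift, in TF-SD units
    n_dark: int = 30
    n_bright: int = 30
    n_passenger: int = 30
    n_null: int = 210
    bright_shift_sd: float = 0.8  # bright-gene intercept shift, in noise-SD units

    @property
    def n_genes(self) -> int:
        return self.n_dark + self.n_bright + self.n_passenger + self.n_null

    def class_of(self, gene_index: int) -> str:
        bounds = np.cumsum([self.n_dark, self.n_bright, self.n_passenger, self.n_null])
        for cls, b in zip(GENE_CLASSES, bounds):
            if gene_index < b:
                return cls
        raise IndexError(gene_index)


@dataclass
class RegulatoryProgram:
    """A fixed TF→gene linear program shared by all samples of a study."""

    n_tf: int
    tf_mean: np.ndarray  # per-TF mean expression
    tf_cov: np.ndarray  # TF covariance (positive semidefinite)
    predictor_sets: list[np.ndarray]  # per-gene TF index arrays
    weights: list[np.ndarray]  # per-gene weight vectors (match predictor sets)
    intercepts: np.ndarray
    noise_sd: np.ndarray  # per-gene residual noise SD, > 0

    def __post_init__(self) -> None:
        if len(self.predictor_sets) != len(self.weights):
            raise ValueError("predictor_sets and weights length mismatch")
        for s, w in zip(self.predictor_sets, self.weights):
            if len(s) != len(w):
                raise ValueError("weight vector support must equal predictor set")
        if np.any(self.noise_sd <= 0):
            raise ValueError("noise_sd must be positive")

    @property
    def n_genes(self) -> int:
        return len(self.predictor_sets)


@dataclass
class SyntheticTruth:
    """Ground truth attached to a generated cohort."""

    shifted_tfs: set[int]
    gene_class: dict[str, str]  # gene feature ID -> class
    delta: float
    n_primary: int
    n_metastatic: int
    seed: int
    #: expected metastatic-minus-primary mqTrans mean per dark gene
    expected_mq_shift: dict[str, float] = field(default_factory=dict)


def tf_feature_id(i: int) -> str:
    return f"TF_{i:04d}_at"


def gene_feature_id(i: int) -> str:
    return f"GENE_{i:04d}_at"


def tf_symbol(i: int) -> str:
    return f"TFSYM{i:04d}"


def gene_symbol(i: int) -> str:
    return f"GSYM{i:04d}"


def build_program(
    spec: TruthSpec,
    n_tf: int = 100,
    target_pcc: float = 0.7,
    tf_corr: float = 0.2,
    min_predictors: int = 3,
    max_predictors: int = 8,
    program_seed: int = 0,
) -> RegulatoryProgram:
    """Draw a regulatory program consistent with a truth specification.

    Dark and passenger genes get ``ceil(k/2)`` shifted TFs among their k
    predictors; null and bright genes get none (a bright gene's shift is
    TF-independent by construction).  Weight magnitudes are uniform on
    [0.5, 1.5] with random signs, except that the shifted-TF weights of a
    dark or passenger gene share one (random) common sign: the injected
    regulatory shift must act coherently, because sign-cancelling
    combinations would give a nominally "dark" gene a near-zero residual
    shift — statistically a null gene with a wrong ground-truth label.  The
    per-gene noise SD solves ``PCC² = signal_var / (signal_var + noise_var)``
    for the target PCC, where signal_var = wᵀΣw under the TF covariance Σ.
    """
    if spec.n_shifted_tf < 1 and spec.n_dark + spec.n_passenger > 0:
        raise ValueError("dark/passenger genes require at least one shifted TF")
    if spec.n_shifted_tf >= n_tf:
        raise ValueError("need at least one unshifted TF")
    rng = np.random.default_rng(program_seed)
    tf_mean = rng.normal(7.0, 1.0, size=n_tf)
    cov = np.full((n_tf, n_tf), tf_corr)
    np.fill_diagonal(cov, 1.0)

    shifted = np.arange(spec.n_shifted_tf)  # first block of TFs is shifted
    unshifted = np.arange(spec.n_shifted_tf, n_tf)

    predictor_sets: list[np.ndarray] = []
    weights: list[np.ndarray] = []
    noise_sd = np.empty(spec.n_genes)
    ratio = 1.0 / target_pcc**2 - 1.0
    for g in range(spec.n_genes):
        cls = spec.class_of(g)
        k = int(rng.integers(min_predictors, max_predictors + 1))
        if cls in ("dark", "passenger"):
            n_sh = min(-(-k // 2), len(shifted))
            chosen_sh = np.sort(rng.choice(shifted, size=n_sh, replace=False))
            chosen_un = np.sort(rng.choice(unshifted, size=k - n_sh, replace=False))
            chosen = np.concatenate([chosen_sh, chosen_un])
            sign_sh = rng.choice([-1.0, 1.0])
            signs = np.concatenate(
                [
                    np.full(n_sh, sign_sh),
                    rng.choice([-1.0, 1.0], size=k - n_sh),
                ]
            )
        else:
            chosen = np.sort(rng.choice(unshifted, size=k, replace=False))
            signs = rng.choice([-1.0, 1.0], size=k)
        w = rng.uniform(0.5, 1.5, size=k) * signs
        signal_var = float(w @ cov[np.ix_(chosen, chosen)] @ w)
        predictor_sets.append(chosen)
        weights.append(w)
        noise_sd[g] = np.sqrt(signal_var * ratio)
    intercepts = rng.normal(8.0, 1.0, size=spec.n_genes)
    return RegulatoryProgram(
        n_tf=n_tf,
        tf_mean=tf_mean,
        tf_cov=cov,
        predictor_sets=predictor_sets,
        weights=weights,
        intercepts=intercepts,
        noise_sd=noise_sd,
    )


def generate_cohort(
    program: RegulatoryProgram,
    spec: TruthSpec,
    n_primary: int = 400,
    n_metastatic: int = 60,
    seed: int = 1,
) -> tuple[pd.DataFrame, list[SampleAnnotation], SyntheticTruth]:
    """Simulate one primary/metastatic cohort under a regulatory program.

    Returns the features × samples expression matrix (TF rows first, then
    gene rows), curated sample annotations, and the ground truth.  The same
    (program, spec, sizes, seed) always produces the identical matrix.
    """
    if n_primary < 4 or n_metastatic < 4:
        raise ValueError("need at least 4 samples per group")
    if spec.n_genes != program.n_genes:
        raise ValueError("truth spec and program disagree on gene count")
    if spec.n_dark > 0 and spec.n_shifted_tf == 0:
        raise ValueError("dark genes require shifted TFs")
    rng = np.random.default_rng(seed)
    n = n_primary + n_metastatic
    is_met = np.zeros(n, dtype=bool)
    is_met[n_primary:] = True

    chol = np.linalg.cholesky(program.tf_cov)
    tf = program.tf_mean + rng.standard_normal((n, program.n_tf)) @ chol.T
    shifted = np.arange(spec.n_shifted_tf)
    tf[np.ix_(is_met, shifted)] += spec.delta

    genes = np.empty((n, spec.n_genes))
    truth_class: dict[str, str] = {}
    expected_shift: dict[str, float] = {}
    for g in range(spec.n_genes):
        cls = spec.class_of(g)
        preds = program.predictor_sets[g]
        w = program.weights[g]
        y = (
            program.intercepts[g]
            + tf[:, preds] @ w
            + rng.normal(0.0, program.noise_sd[g], size=n)
        )
        sh_mask = np.isin(preds, shifted)
        wdelta = float(w[sh_mask].sum() * spec.delta)
        if cls == "dark":
            y[is_met] -= wdelta  # compensate: marginal mean preserved
            expected_shift[gene_feature_id(g)] = wdelta
        elif cls == "bright":
            # scaled by delta so the whole truth collapses to null at delta=0
            y[is_met] += spec.bright_shift_sd * program.noise_sd[g] * spec.delta
        # passenger/null: no modification
        genes[:, g] = y
        truth_class[gene_feature_id(g)] = cls

    sample_ids = [f"P{i + 1:04d}" for i in range(n_primary)] + [
        f"M{i + 1:04d}" for i in range(n_metastatic)
    ]
    feature_ids = [tf_feature_id(i) for i in range(program.n_tf)] + [
        gene_feature_id(i) for i in range(spec.n_genes)
    ]
    matrix = pd.DataFrame(
        np.hstack([tf, genes]).T, index=feature_ids, columns=sample_ids
    )
    annotations = [
        SampleAnnotation(
            sample_id=s,
            m_parameter=1 if m else 0,
            label=Label.METASTATIC if m else Label.PRIMARY,
        )
        for s, m in zip(sample_ids, is_met)
    ]
    truth = SyntheticTruth(
        shifted_tfs=set(int(i) for i in shifted),
        gene_class=truth_class,
        delta=spec.delta,
        n_primary=n_primary,
        n_metastatic=n_metastatic,
        seed=seed,
        expected_mq_shift=expected_shift,
    )
    return matrix, annotations, truth


def reference_config() -> tuple[RegulatoryProgram, TruthSpec]:
    """The documented reference configuration.

    100 TFs of which 10 shift by δ = 1.0 SD in metastatic samples; 300 genes
    split 30 dark / 30 bright / 30 passenger / 210 null; noise calibrated for
    a training PCC ≈ 0.7.  Pair with 400 primary / 60 metastatic samples and
    seeds 1..20 for the standard benchmark.
    """
    spec = TruthSpec()
    program = build_program(spec, n_tf=100, target_pcc=0.7, program_seed=0)
    return program, spec


def write_cohort(
    matrix: pd.DataFrame,
    annotations: Sequence[SampleAnnotation],
    truth: SyntheticTruth,
    program: RegulatoryProgram,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write a cohort in the exact file dialects the readers consume.

    Produces expression.tsv, metadata.tsv, platform_annotation.tsv,
    tf_registry.txt and truth.tsv under ``outdir``; returns the path map.
    """
    from .io_cohort import write_expression_matrix

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "metadata": outdir / "metadata.tsv",
        "annotation": outdir / "platform_annotation.tsv",
        "tf_registry": outdir / "tf_registry.txt",
        "truth": outdir / "truth.tsv",
    }
    write_expression_matrix(matrix, paths["expression"])
    with paths["metadata"].open("w") as fh:
        fh.write("sample_id\tm_parameter\tmetastasis_date\tdiagnosis\n")
        for a in annotations:
            m = "" if a.m_parameter is None else str(a.m_parameter)
            fh.write(f"{a.sample_id}\t{m}\t{a.metastasis_date or ''}\t{a.diagnosis_text or ''}\n")
    with paths["annotation"].open("w") as fh:
        fh.write("probe_id\tgene_symbols\n")
        for i in range(program.n_tf):
            fh.write(f"{tf_feature_id(i)}\t{tf_symbol(i)}\n")
        for i in range(program.n_genes):
            fh.write(f"{gene_feature_id(i)}\t{gene_symbol(i)}\n")
    with paths["tf_registry"].open("w") as fh:
        for i in range(program.n_tf):
            fh.write(tf_symbol(i) + "\n")
    with paths["truth"].open("w") as fh:
        fh.write("feature\tclass\n")
        for feat, cls in truth.gene_class.items():
            fh.write(f"{feat}\t{cls}\n")
    return paths
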