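"""Dual-space differential testing and the dark-biomarker rule.

A *dark biomarker* is a gene that is non-differentially expressed between
metastatic and primary samples in raw expression space (p > alpha_orig) but
differentially expressed in mqTrans residual space (p < alpha_mq).  Both
thresholds default to 0.05 and both comparisons are strict.  The test is the
unpaired two-sample t-test, pooled-variance Student by default with a Welch
option.

No multiple-testing correction gates the dark call; Benjamini–Hochberg
q-values are reported as supplementary columns only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_cohort import Label, SampleAnnotation
from .regression import GeneModel, compute_mqtrans, filter_models, fit_gene_models

__all__ = [
    "DarkBiomarkerSet",
    "unpaired_ttest",
    "classify_dark",
    "detect_dark",
    "intersect_dark",
    "venn_counts",
    "robustness_scan",
]


@dataclass
class DarkBiomarkerSet:
    """Dark-biomarker calls for one dataset at given thresholds."""

    dataset_id: str
    features: set[str]
    alpha_orig: float = 0.05
    alpha_mq: float = 0.05


def unpaired_ttest(
    a: Sequence[float], b: Sequence[float], equal_var: bool = True
) -> tuple[float, float]:
    """Two-sided unpaired two-sample t-test.

    Pooled-variance Student test by default (df = |a|+|b|-2); set
    ``equal_var=False`` for the Welch variant.  Degenerate inputs where both
    groups are constant give (0, 1) when the constants are equal and
    (±inf, 0) when they differ — the limiting behaviour as the variance
    vanishes.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            return 0.0, 1.0
        return float(np.sign(a[0] - b[0]) * np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def classify_dark(
    p_orig: float | None,
    p_mq: float | None,
    alpha_orig: float = 0.05,
    alpha_mq: float = 0.05,
) -> bool:
    """True iff p_orig > alpha_orig and p_mq < alpha_mq (both strict).

    A missing p-value in either space makes the call False.
    """
    if p_orig is None or p_mq is None:
        return False
    if not (np.isfinite(p_orig) and np.isfinite(p_mq)):
        return False
    return p_orig > alpha_orig and p_mq < alpha_mq


def detect_dark(
    data: pd.DataFrame,
    mq: pd.DataFrame,
    annotations: Sequence[SampleAnnotation],
    alpha_orig: float = 0.05,
    alpha_mq: float = 0.05,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-feature dual-space differential table with the dark flag.

    ``data`` and ``mq`` are features × samples; one record is produced per
    mqTrans feature (rows of ``mq``), comparing metastatic vs. primary
    columns in both spaces.  Returns a DataFrame with columns feature,
    t_orig, p_orig, t_mq, p_mq, q_orig, q_mq, is_dark, reason.  Features with
    a degenerate test in either space are non-dark with a reason code rather
    than errors.
    """
    met = [a.sample_id for a in annotations if a.label is Label.METASTATIC]
    prim = [a.sample_id for a in annotations if a.label is Label.PRIMARY]
    met = [s for s in met if s in data.columns and s in mq.columns]
    prim = [s for s in prim if s in data.columns and s in mq.columns]
    if len(met) < 2 or len(prim) < 2:
        raise ValueError(
            f"need >=2 samples per group in both matrices, "
            f"got {len(prim)} primary / {len(met)} metastatic"
        )
    features = list(mq.index)
    t_orig, p_orig, r_orig = _ttest_rows(data.loc[features], met, prim, equal_var)
    t_mq, p_mq, r_mq = _ttest_rows(mq, met, prim, equal_var)

    reason = np.where(r_orig != "", "expression:" + r_orig, "")
    both = (r_orig != "") & (r_mq != "")
    reason = np.where(r_mq != "", np.where(both, reason + ";", reason) + "mqtrans:" + r_mq, reason)

    is_dark = np.array(
        [
            classify_dark(po, pm, alpha_orig, alpha_mq) and ro == "" and rm == ""
            for po, pm, ro, rm in zip(p_orig, p_mq, r_orig, r_mq)
        ]
    )
    return pd.DataFrame(
        {
            "feature": features,
            "t_orig": t_orig,
            "p_orig": p_orig,
            "t_mq": t_mq,
            "p_mq": p_mq,
            "q_orig": _bh(p_orig),
            "q_mq": _bh(p_mq),
            "is_dark": is_dark,
            "reason": reason,
        }
    )


def _ttest_rows(
    matrix: pd.DataFrame, met: list[str], prim: list[str], equal_var: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized row-wise metastatic-vs-primary t-tests with degeneracy codes."""
    A = matrix[met].to_numpy(dtype=float)
    B = matrix[prim].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(A, B, axis=1, equal_var=equal_var)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    reason = np.full(matrix.shape[0], "", dtype=object)
    degenerate = (np.ptp(A, axis=1) == 0) & (np.ptp(B, axis=1) == 0)
    for i in np.flatnonzero(degenerate):
        if A[i, 0] == B[i, 0]:
            t[i], p[i] = 0.0, 1.0
            reason[i] = "constant-equal-groups"
        else:
            t[i], p[i] = np.sign(A[i, 0] - B[i, 0]) * np.inf, 0.0
            reason[i] = "constant-unequal-groups"
    bad = ~np.isfinite(p)
    reason[bad & (reason == "")] = "undefined-test"
    return t, p, reason.astype(str)


def _bh(p: np.ndarray) -> np.ndarray:
    q = np.full_like(p, np.nan, dtype=float)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


# ---------------------------------------------------------------------------
# cross-dataset intersection


def intersect_dark(sets: Sequence[DarkBiomarkerSet]) -> set[str]:
    """Features dark in every dataset (plain set intersection)."""
    if not sets:
        raise ValueError("need at least one dark-biomarker set")
    out = set(sets[0].features)
    for s in sets[1:]:
        out &= s.features
    return out


def venn_counts(sets: Sequence[DarkBiomarkerSet]) -> pd.DataFrame:
    """Per-set sizes plus the overall intersection, for Venn-style reporting."""
    rows = [
        {"set": s.dataset_id, "n_dark": len(s.features)} for s in sets
    ]
    rows.append({"set": "intersection", "n_dark": len(intersect_dark(sets))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# reduced-training-fraction robustness scan


def robustness_scan(
    data: pd.DataFrame,
    annotations: Sequence[SampleAnnotation],
    predictors: Sequence[str],
    targets: Sequence[str],
    train_pool: Sequence[str],
    fixed_test: Sequence[str],
    fractions: Sequence[float],
    seed: int,
    main_fraction: float = 0.6,
    pcc_threshold: float = 0.5,
    alpha_orig: float = 0.05,
    alpha_mq: float = 0.05,
    equal_var: bool = True,
    dataset_id: str = "cohort",
    n_predictors: int | None = None,
) -> dict[float, DarkBiomarkerSet]:
    """Re-run the model-training → mqTrans → detection chain at reduced
    training fractions, keeping the testing set fixed.

    Each requested fraction is a fraction of the *full* primary sample set;
    the sub-sample is drawn from ``train_pool`` (the main run's training set,
    itself ``main_fraction`` of the primaries), so its size is
    ``round(|pool| * fraction / main_fraction)``.  A fraction equal to
    ``main_fraction`` uses the whole pool and reproduces the main run
    exactly; larger fractions are rejected.
    """
    train_pool = sorted(train_pool)
    fixed_test = list(fixed_test)
    if set(train_pool) & set(fixed_test):
        raise ValueError("train_pool and fixed_test must be disjoint")
    out: dict[float, DarkBiomarkerSet] = {}
    for frac in fractions:
        if frac > main_fraction:
            raise ValueError(
                f"fraction {frac} exceeds the main training fraction {main_fraction}"
            )
        n_sub = int(round(len(train_pool) * frac / main_fraction))
        if n_sub < 2:
            raise ValueError(f"fraction {frac} yields fewer than 2 training samples")
        rng = np.random.default_rng(seed)
        if n_sub == len(train_pool):
            sub = list(train_pool)
        else:
            idx = rng.choice(len(train_pool), size=n_sub, replace=False)
            sub = sorted(train_pool[i] for i in idx)
        models = fit_gene_models(data[sub], predictors, targets, n_predictors=n_predictors)
        retained = filter_models(models, pcc_threshold)
        mq = compute_mqtrans(retained, data[fixed_test])
        table = detect_dark(
            data[fixed_test], mq, annotations, alpha_orig, alpha_mq, equal_var
        )
        out[frac] = DarkBiomarkerSet(
            dataset_id=f"{dataset_id}@{frac:g}",
            features=set(table.loc[table["is_dark"], "feature"]),
            alpha_orig=alpha_orig,
            alpha_mq=alpha_mq,
        )
    return out


def robustness_overlap_table(
    main: DarkBiomarkerSet, scans: Mapping[float, DarkBiomarkerSet]
) -> pd.DataFrame:
    """Per-fraction dark-set sizes and overlap with the main run."""
    rows = [
        {
            "fraction": "main",
            "n_dark": len(main.features),
            "n_overlap_main": len(main.features),
        }
    ]
    for frac in sorted(scans, reverse=True):
        s = scans[frac]
        rows.append(
            {
                "fraction": f"{frac:g}",
                "n_dark": len(s.features),
                "n_overlap_main": len(s.features & main.features),
            }
        )
    return pd.DataFrame(rows)
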