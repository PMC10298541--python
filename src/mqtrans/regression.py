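"""Per-gene TF→mRNA regression models and mqTrans residual computation.

Each mRNA feature gets its own linear model predicting its expression from
the transcription-factor (TF) expression levels, fitted on *primary* training
samples only.  A model is retained when the Pearson correlation between its
fitted and observed target values on the training samples strictly exceeds a
threshold (default 0.5) and it has at least one non-zero weight.  The mqTrans
value of a retained gene in a sample is

    mqTrans(g, s) = predicted(g, s) - observed(g, s)

i.e. the signed residual of the primary-trained model, which quantifies how
far the sample's transcription regulation of ``g`` departs from the training
cohort's regulatory program.

The default estimator is ordinary least squares with intercept, solved by the
minimum-norm least-squares route so that rank-deficient designs (more TFs
than samples) are handled deterministically.  An L1-regularized (Lasso)
variant is available for sparse-weight fits.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_cohort import Label, SampleAnnotation

__all__ = [
    "GeneModel",
    "split_train_test",
    "fit_gene_model",
    "fit_gene_models",
    "filter_models",
    "compute_mqtrans",
    "write_models",
    "read_models",
    "exclude_self_predictors",
]

#: Weights with magnitude at or below this are counted as zero.
ZERO_WEIGHT_TOL = 1e-8


@dataclass
class GeneModel:
    """One mRNA's fitted TF regression.

    ``training_pcc`` is the Pearson correlation between fitted and observed
    target values over the training samples; it is NaN for unfittable models
    (constant target, or constant fit), which are never retained.
    """

    target_feature: str
    predictor_features: list[str]
    weights: np.ndarray
    intercept: float
    training_pcc: float
    n_nonzero: int

    def predict(self, tf_values: pd.DataFrame) -> np.ndarray:
        """Predicted target expression for samples in columns of ``tf_values``.

        ``tf_values`` must be a features × samples frame containing every
        predictor feature.
        """
        X = tf_values.loc[self.predictor_features].to_numpy(dtype=float)
        # row-weighted reduction instead of matmul: the result for a sample
        # must not depend on which other samples are present (BLAS blocking
        # makes `w @ X` width-dependent at the last bit)
        return self.intercept + np.add.reduce(self.weights[:, None] * X, axis=0)

    @property
    def fittable(self) -> bool:
        return bool(np.isfinite(self.training_pcc))


# ---------------------------------------------------------------------------
# train / test split


def split_train_test(
    annotations: Sequence[SampleAnnotation],
    fraction: float = 0.6,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Randomly split non-excluded samples into training and testing sets.

    The training set is ``floor(fraction * n_primary)`` primary samples drawn
    uniformly without replacement under ``seed``; the testing set is every
    remaining primary sample plus *all* metastatic samples.  Excluded samples
    appear in neither.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    primary = sorted(a.sample_id for a in annotations if a.label is Label.PRIMARY)
    metastatic = sorted(a.sample_id for a in annotations if a.label is Label.METASTATIC)
    if len(primary) < 2 or len(metastatic) < 1:
        raise ValueError(
            f"need >=2 primary and >=1 metastatic samples, "
            f"got {len(primary)} primary / {len(metastatic)} metastatic"
        )
    n_train = int(np.floor(fraction * len(primary)))
    if n_train == 0:
        raise ValueError(f"fraction {fraction} yields an empty training set")
    if n_train == len(primary):
        raise ValueError(
            f"fraction {fraction} leaves no primary samples for testing"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(primary))
    train = sorted(primary[i] for i in order[:n_train])
    test_primary = sorted(primary[i] for i in order[n_train:])
    return train, test_primary + metastatic


# ---------------------------------------------------------------------------
# fitting


def fit_gene_models(
    train: pd.DataFrame,
    predictors: Sequence[str],
    targets: Sequence[str],
    estimator: str = "ols",
    l1_alpha: float = 0.01,
    probe_to_symbols: Mapping[str, list[str]] | None = None,
    n_predictors: int | None = None,
) -> list[GeneModel]:
    """Fit one regression per target on the training expression matrix.

    ``train`` is features × training-samples.  For the default OLS estimator
    with a shared predictor set, all targets are solved in a single
    minimum-norm least-squares call, which is exactly equivalent to
    per-target normal-equation solves.  Targets with zero variance (or
    otherwise undefined training PCC) come back with ``training_pcc = NaN``
    and are dropped by :func:`filter_models`.

    ``n_predictors`` enables per-target predictor screening: only the top-k
    TFs by absolute Pearson correlation with the target (on the training
    samples) enter that target's model.  Screening keeps the residual space
    calibrated when the TF pool is large relative to the sample count —
    unscreened OLS spreads small spurious weights over every TF, and any
    group-level TF shift then leaks through those weights into the residuals
    of unrelated genes.

    When ``probe_to_symbols`` is given, predictor probes sharing a gene
    symbol with the target probe are excluded from that target's model to
    avoid self-prediction.
    """
    predictors = list(predictors)
    targets = list(targets)
    if not predictors:
        raise ValueError("no predictor features supplied")
    overlap = set(predictors) & set(targets)
    if overlap:
        raise ValueError(f"targets also listed as predictors: {sorted(overlap)[:3]}")
    if train.shape[1] < 2:
        raise ValueError("need at least 2 training samples")

    # drop features with missing values in the training set
    sub = train.loc[predictors + targets]
    keep = ~sub.isna().any(axis=1)
    predictors = [p for p in predictors if keep[p]]
    targets_ok = [t for t in targets if keep[t]]

    X = train.loc[predictors].to_numpy(dtype=float).T  # n_samples × p

    needs_exclusion: dict[str, list[str]] = {}
    if probe_to_symbols is not None:
        for t in targets_ok:
            tsyms = set(probe_to_symbols.get(t, ()))
            if tsyms:
                clash = [
                    p
                    for p in predictors
                    if tsyms & set(probe_to_symbols.get(p, ()))
                ]
                if clash:
                    needs_exclusion[t] = clash

    screened: dict[str, list[int]] = {}
    if n_predictors is not None and n_predictors < len(predictors):
        Yall = train.loc[targets_ok].to_numpy(dtype=float).T
        corr = _corr_matrix(X, Yall)  # p × n_targets
        for j, t in enumerate(targets_ok):
            order = np.argsort(-np.abs(np.nan_to_num(corr[:, j])), kind="stable")
            screened[t] = sorted(order[:n_predictors].tolist())

    batch = [
        t for t in targets_ok if t not in needs_exclusion and t not in screened
    ]
    models: dict[str, GeneModel] = {}
    if batch:
        Y = train.loc[batch].to_numpy(dtype=float).T
        for t, (w, b, pcc) in zip(
            batch, _solve(X, Y, estimator=estimator, l1_alpha=l1_alpha)
        ):
            models[t] = _make_model(t, predictors, w, b, pcc)
    for t in targets_ok:
        if t in models:
            continue
        clash = set(needs_exclusion.get(t, ()))
        idx = screened.get(t, range(len(predictors)))
        preds = [predictors[i] for i in idx if predictors[i] not in clash]
        if not preds:
            models[t] = GeneModel(t, [], np.empty(0), float("nan"), float("nan"), 0)
            continue
        Xi = train.loc[preds].to_numpy(dtype=float).T
        y = train.loc[[t]].to_numpy(dtype=float).T
        ((w, b, pcc),) = _solve(Xi, y, estimator=estimator, l1_alpha=l1_alpha)
        models[t] = _make_model(t, preds, w, b, pcc)

    dropped = [
        GeneModel(t, [], np.empty(0), float("nan"), float("nan"), 0)
        for t in targets
        if t not in models
    ]
    return [models[t] for t in targets if t in models] + dropped


def fit_gene_model(
    train: pd.DataFrame,
    predictors: Sequence[str],
    target: str,
    estimator: str = "ols",
    l1_alpha: float = 0.01,
) -> GeneModel:
    """Fit a single target's regression (see :func:`fit_gene_models`)."""
    (model,) = fit_gene_models(
        train, predictors, [target], estimator=estimator, l1_alpha=l1_alpha
    )
    return model


def _solve(
    X: np.ndarray, Y: np.ndarray, estimator: str, l1_alpha: float
) -> Iterable[tuple[np.ndarray, float, float]]:
    """Yield (weights, intercept, training_pcc) per column of Y."""
    n = X.shape[0]
    if estimator == "ols":
        design = np.hstack([np.ones((n, 1)), X])
        coef, *_ = np.linalg.lstsq(design, Y, rcond=None)
        fitted = design @ coef
        for j in range(Y.shape[1]):
            yield coef[1:, j], float(coef[0, j]), _pearson(fitted[:, j], Y[:, j])
    elif estimator == "lasso":
        from sklearn.linear_model import Lasso

        for j in range(Y.shape[1]):
            y = Y[:, j]
            if np.ptp(y) == 0:
                yield np.zeros(X.shape[1]), float(y[0]), float("nan")
                continue
            reg = Lasso(alpha=l1_alpha, max_iter=50_000)
            reg.fit(X, y)
            fitted = reg.predict(X)
            yield reg.coef_.copy(), float(reg.intercept_), _pearson(fitted, y)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")


def _corr_matrix(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pearson correlations between columns of X and columns of Y (p × m).

    Zero-variance columns yield NaN entries.
    """
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = np.sqrt((Yc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        return (Xc.T @ Yc) / np.outer(sx, sy)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = np.std(a), np.std(b)
    if sa == 0 or sb == 0 or not (np.isfinite(sa) and np.isfinite(sb)):
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def _make_model(
    target: str, predictors: list[str], w: np.ndarray, b: float, pcc: float
) -> GeneModel:
    return GeneModel(
        target_feature=target,
        predictor_features=list(predictors),
        weights=np.asarray(w, dtype=float),
        intercept=float(b),
        training_pcc=float(pcc),
        n_nonzero=int(np.sum(np.abs(w) > ZERO_WEIGHT_TOL)),
    )


def exclude_self_predictors(
    target: str,
    predictors: Sequence[str],
    probe_to_symbols: Mapping[str, list[str]],
) -> list[str]:
    """Predictor probes that do not share a gene symbol with the target probe."""
    tsyms = set(probe_to_symbols.get(target, ()))
    return [
        p for p in predictors if not (tsyms & set(probe_to_symbols.get(p, ())))
    ]


# ---------------------------------------------------------------------------
# filtering and residuals


def filter_models(
    models: Iterable[GeneModel], pcc_threshold: float = 0.5
) -> list[GeneModel]:
    """Retain models with training PCC strictly above the threshold and >=1
    non-zero weight.  Non-finite PCCs (unfittable models) never pass."""
    return [
        m
        for m in models
        if np.isfinite(m.training_pcc)
        and m.training_pcc > pcc_threshold
        and m.n_nonzero >= 1
    ]


def compute_mqtrans(
    models: Sequence[GeneModel], data: pd.DataFrame
) -> pd.DataFrame:
    """Residual (predicted − observed) matrix for every model over ``data``.

    ``data`` is features × samples and must contain every predictor and
    target feature of every model.  Each sample's column is computed
    independently of the others.
    """
    needed: set[str] = set()
    for m in models:
        needed.add(m.target_feature)
        needed.update(m.predictor_features)
    missing = needed - set(data.index)
    if missing:
        raise KeyError(f"data is missing required feature(s): {sorted(missing)[:5]}")
    rows = []
    index = []
    for m in models:
        predicted = m.predict(data)
        observed = data.loc[m.target_feature].to_numpy(dtype=float)
        rows.append(predicted - observed)
        index.append(m.target_feature)
    return pd.DataFrame(np.asarray(rows), index=index, columns=data.columns)


# ---------------------------------------------------------------------------
# serialization


def write_models(models: Sequence[GeneModel], prefix: str | Path) -> None:
    """Write a model set as ``<prefix>.weights.tsv`` (long format: target,
    predictor, weight) and ``<prefix>.summary.tsv`` (target, intercept,
    training_pcc, n_nonzero)."""
    prefix = Path(prefix)
    with open(f"{prefix}.weights.tsv", "w") as fh:
        fh.write("target\tpredictor\tweight\n")
        for m in models:
            for p, w in zip(m.predictor_features, m.weights):
                fh.write(f"{m.target_feature}\t{p}\t{float(w)!r}\n")
    with open(f"{prefix}.summary.tsv", "w") as fh:
        fh.write("target\tintercept\ttraining_pcc\tn_nonzero\n")
        for m in models:
            fh.write(
                f"{m.target_feature}\t{m.intercept!r}\t{m.training_pcc!r}\t{m.n_nonzero}\n"
            )


def read_models(prefix: str | Path) -> list[GeneModel]:
    """Read a model set written by :func:`write_models`."""
    prefix = Path(prefix)
    weights = pd.read_csv(f"{prefix}.weights.tsv", sep="\t")
    summary = pd.read_csv(f"{prefix}.summary.tsv", sep="\t")
    by_target = {t: g for t, g in weights.groupby("target", sort=False)}
    models = []
    for row in summary.itertuples(index=False):
        g = by_target.get(row.target)
        preds = list(g["predictor"]) if g is not None else []
        w = g["weight"].to_numpy(dtype=float) if g is not None else np.empty(0)
        models.append(
            GeneModel(
                target_feature=row.target,
                predictor_features=preds,
                weights=w,
                intercept=float(row.intercept),
                training_pcc=float(row.training_pcc),
                n_nonzero=int(row.n_nonzero),
            )
        )
    return models
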