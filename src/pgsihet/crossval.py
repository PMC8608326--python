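"""Replicated k-fold cross-validation predictability and external validation.

Per replicate, hybrids are randomly partitioned into k folds; each fold is
predicted from a model trained on the other k-1 folds, so every hybrid is
predicted exactly once per replicate. The replicate's predictability is
the single Pearson correlation between observed values and the pooled
out-of-fold predictions; the reported predictability is the mean over
replicates. The LASSO penalty-selection CV is nested inside each training
fold (no leakage), with fold seeds derived deterministically from
(seed, replicate, fold).

The marker subsample used by LASSO_SNP / GBLUP (and the kinships built
from it) is drawn once per model run from the outer seed, mirroring a
single up-front marker thinning rather than a per-fold redraw.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from pgsihet.gs_models import (
    LASSO_WIDTHS,
    MODEL_SPECS,
    ModelInputs,
    fit_gblup,
    fit_lasso_refit,
    predict_gblup,
    predict_linear,
)

log = logging.getLogger(__name__)


@dataclass
class CvSpec:
    """One cross-validation run: model x trait x heterosis type."""

    model: str
    trait: str = ""
    heterosis_type: str = "HPH"
    k: int = 10
    replicates: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in MODEL_SPECS:
            raise ValueError(f"unknown model {self.model!r}; valid: {MODEL_SPECS}")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class PredictabilityResult:
    """Per-replicate Pearson r values and their mean/sd."""

    r_values: list[float]
    spec: CvSpec
    n_excluded: int = 0

    @property
    def mean(self) -> float:
        vals = [r for r in self.r_values if np.isfinite(r)]
        return float(np.mean(vals)) if vals else float("nan")

    @property
    def sd(self) -> float:
        vals = [r for r in self.r_values if np.isfinite(r)]
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan")


def _derive_seed(*parts: int) -> int:
    """Deterministic sub-seed below 2^31 from (seed, replicate, fold...)."""
    mask = (1 << 64) - 1
    h = 0x9E3779B97F4A7C15
    acc = 0
    for p in parts:
        acc = ((acc ^ (int(p) & 0xFFFFFFFF)) * h) & mask
        acc ^= acc >> 31
    return acc % (2**31)


def kfold_partition(n: int, k: int, seed: int) -> np.ndarray:
    """Random partition of n individuals into k folds of size floor/ceil(n/k).

    Returns an array of fold labels in 0..k-1; seed-reproducible.
    """
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.empty(n, dtype=np.int64)
    for f, chunk in enumerate(np.array_split(perm, k)):
        folds[chunk] = f
    return folds


def _pearson(obs: np.ndarray, pred: np.ndarray) -> float:
    if np.std(obs) == 0 or np.std(pred) == 0:
        return float("nan")
    return float(pearsonr(obs, pred)[0])


def _fit_predict_fold(
    model: str,
    y: np.ndarray,
    ids: list[str],
    train: np.ndarray,
    test: np.ndarray,
    features: pd.DataFrame | None,
    kinships,
    inner_seed: int,
) -> np.ndarray:
    train_ids = [ids[i] for i in train]
    test_ids = [ids[i] for i in test]
    if model.startswith("GBLUP"):
        fit = fit_gblup(
            y[train], [k.subset(train_ids) for k in kinships], ids=train_ids
        )
        blocks = {k.source: k.block(test_ids, train_ids) for k in kinships}
        return predict_gblup(fit, blocks)
    fit = fit_lasso_refit(features.iloc[train], y[train], seed=inner_seed)
    return predict_linear(fit, features.iloc[test])


def _prepare_model_inputs(spec: CvSpec, inputs: ModelInputs):
    """Materialize the per-model feature frame / kinships once per run."""
    features = None
    kinships = None
    if spec.model == "GBLUP_A":
        kinships = [k.subset(inputs.ids) for k in inputs.gblup_kinships(spec.seed)]
    elif spec.model == "GBLUP_AD":
        kinships = [k.subset(inputs.ids) for k in inputs.gblup_ad_kinships(spec.seed)]
    elif spec.model == "LASSO_SNP":
        features = inputs.snp_features(spec.seed).loc[inputs.ids]
    else:
        features = inputs.window_features(LASSO_WIDTHS[spec.model]).loc[inputs.ids]
    return features, kinships


def cross_validate(spec: CvSpec, inputs: ModelInputs, y: np.ndarray) -> PredictabilityResult:
    """Replicated k-fold cross-validation predictability for one model."""
    y = np.asarray(y, dtype=np.float64)
    ids = list(inputs.ids)
    n = len(y)
    if n != len(ids):
        raise ValueError("y length != number of ids")
    features, kinships = _prepare_model_inputs(spec, inputs)
    r_values: list[float] = []
    n_excluded = 0
    for rep in range(spec.replicates):
        folds = kfold_partition(n, spec.k, _derive_seed(spec.seed, rep))
        pred = np.empty(n)
        for f in range(spec.k):
            test = np.flatnonzero(folds == f)
            train = np.flatnonzero(folds != f)
            pred[test] = _fit_predict_fold(
                spec.model, y, ids, train, test, features, kinships,
                inner_seed=_derive_seed(spec.seed, rep, f),
            )
        r = _pearson(y, pred)
        if not np.isfinite(r):
            n_excluded += 1
            warnings.warn(f"replicate {rep}: constant predictions, r recorded missing")
        r_values.append(r)
    return PredictabilityResult(r_values, spec, n_excluded)


def external_validate(
    fit,
    observed: pd.Series,
    *,
    features: pd.DataFrame | None = None,
    kinship_blocks: dict[str, np.ndarray] | None = None,
    training_ids: list[str] | None = None,
    plan=None,
) -> tuple[float, pd.DataFrame]:
    """Validate a fitted model on an independent test population.

    ``observed`` is indexed by test hybrid id. Test hybrids must be
    disjoint from the training hybrids (parents may overlap, as a CMS pool
    reused across populations does). Returns (Pearson r, scatter frame
    with observed/predicted and, when a plan is given, the male parent of
    each test hybrid for per-restorer grouping).
    """
    test_ids = list(observed.index)
    if len(test_ids) < 3:
        raise ValueError(f"need >= 3 test hybrids, got {len(test_ids)}")
    train_ids = training_ids if training_ids is not None else getattr(fit, "training_ids", None)
    if train_ids is not None:
        overlap = set(test_ids) & set(train_ids)
        if overlap:
            raise ValueError(f"test hybrids overlap training hybrids: {sorted(overlap)[:5]}")
    if features is not None:
        pred = predict_linear(fit, features.loc[test_ids])
    elif kinship_blocks is not None:
        pred = predict_gblup(fit, kinship_blocks)
    else:
        raise ValueError("pass features (LASSO) or kinship_blocks (GBLUP)")
    obs = observed.to_numpy(dtype=np.float64)
    r = _pearson(obs, pred)
    if not np.isfinite(r):
        raise ValueError("observed test values are constant; correlation undefined")
    scatter = pd.DataFrame({"observed": obs, "predicted": pred}, index=observed.index)
    if plan is not None:
        male = plan.frame.set_index("hybrid_id")["male_id"]
        scatter["male_id"] = male.reindex(scatter.index)
    return r, scatter
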