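"""GBLUP and LASSO prediction engines for heterosis.

Both engines share the generic marker model

    y = X beta + sum_k Z_k gamma_k + eps,   eps ~ N(0, I sigma^2).

GBLUP assumes gamma_k ~ N(0, phi^2 / m), so var(y) = K phi^2 + I sigma^2
with K = (1/m) Z Z^T the marker kinship; variance components are estimated
by REML (single kinship: profiled likelihood over the ratio lambda =
phi^2 / sigma^2 via one eigendecomposition of K; two kinships: Nelder-Mead
on the log ratios). Predictions for unobserved individuals come from the
train/test kinship blocks without estimating marker effects.

The LASSO engine treats window-level PGSI values (or a marker subsample)
as features: an L1 path is fitted, the penalty is chosen by seeded inner
10-fold cross-validation, and the selected variables are re-estimated by
ordinary least squares (ridge-stabilized normal equations); predictions
use only the re-estimated coefficients.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar

from pgsihet.genotype_io import CodedMarkerMatrix, subsample_markers

log = logging.getLogger(__name__)

MODEL_SPECS = ("GBLUP_A", "GBLUP_AD", "LASSO_SNP", "LASSO_100Kb", "LASSO_500Kb", "LASSO_1Mb")
LASSO_WIDTHS = {"LASSO_100Kb": 100_000, "LASSO_500Kb": 500_000, "LASSO_1Mb": 1_000_000}


@dataclass
class KinshipMatrix:
    """Marker-generated kinship K = (1/m) Z Z^T."""

    values: np.ndarray  # (n, n)
    individual_ids: list[str]
    source: str  # 'additive' | 'dominance'
    m: int  # marker count used

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.individual_ids)
        if self.values.shape != (n, n):
            raise ValueError("kinship shape inconsistent with ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kinship matrix is not symmetric")

    def subset(self, ids: list[str]) -> "KinshipMatrix":
        idx = [self.individual_ids.index(i) for i in ids]
        return KinshipMatrix(self.values[np.ix_(idx, idx)], list(ids), self.source, self.m)

    def block(self, row_ids: list[str], col_ids: list[str]) -> np.ndarray:
        ri = [self.individual_ids.index(i) for i in row_ids]
        ci = [self.individual_ids.index(i) for i in col_ids]
        return self.values[np.ix_(ri, ci)]


def _impute_codes(codes: CodedMarkerMatrix) -> np.ndarray:
    """Mean-impute missing marker codes per marker."""
    Z = codes.values.copy()
    if np.isnan(Z).any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            col_mean = np.nanmean(Z, axis=0)
        col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
        nan_r, nan_c = np.where(np.isnan(Z))
        Z[nan_r, nan_c] = col_mean[nan_c]
    return Z


def _kinship_from_codes(codes: CodedMarkerMatrix, source: str) -> KinshipMatrix:
    if codes.n_markers == 0:
        raise ValueError("cannot build a kinship from zero markers")
    Z = _impute_codes(codes)
    K = (Z @ Z.T) / codes.n_markers
    K = 0.5 * (K + K.T)
    return KinshipMatrix(K, list(codes.samples), source, codes.n_markers)


def additive_kinship(codes: CodedMarkerMatrix) -> KinshipMatrix:
    """K = (1/m) Z Z^T from additive codes (1/0/-1), no extra scaling."""
    if codes.coding != "additive":
        raise ValueError("additive_kinship requires additive codes")
    return _kinship_from_codes(codes, "additive")


def dominance_kinship(codes: CodedMarkerMatrix) -> KinshipMatrix:
    """K = (1/m) Z Z^T from centered heterozygosity-indicator codes."""
    if codes.coding != "dominance":
        raise ValueError("dominance_kinship requires dominance codes")
    return _kinship_from_codes(codes, "dominance")


@dataclass
class GblupFit:
    """REML-fitted GBLUP model (one or two kinships)."""

    variance_components: dict  # source -> phi^2, plus 'residual' -> sigma^2
    lambdas: dict  # source -> phi^2 / sigma^2
    beta: np.ndarray
    training_ids: list[str]
    kinships: list[KinshipMatrix]
    alpha: np.ndarray = field(repr=False, default=None)  # V0^-1 (y - X beta)
    X: np.ndarray = field(repr=False, default=None)
    y: np.ndarray = field(repr=False, default=None)
    reml_neg2ll: float = float("nan")


def _check_psd(K: KinshipMatrix, tol: float = 1e-6) -> None:
    w = np.linalg.eigvalsh(K.values)
    scale = max(abs(w[-1]), 1.0)
    if w[0] < -tol * scale:
        raise ValueError(
            f"{K.source} kinship is not positive semidefinite "
            f"(min eigenvalue {w[0]:.3g})"
        )


def fit_gblup(
    y: np.ndarray,
    kinships: list[KinshipMatrix] | KinshipMatrix,
    X: np.ndarray | None = None,
    ids: list[str] | None = None,
) -> GblupFit:
    """REML variance components and GLS fixed effects for GBLUP.

    ``y`` must be aligned with the kinship ids. ``X`` defaults to an
    intercept column.
    """
    if isinstance(kinships, KinshipMatrix):
        kinships = [kinships]
    y = np.asarray(y, dtype=np.float64)
    n = len(y)
    if n < 5:
        raise ValueError(f"GBLUP needs n >= 5, got {n}")
    for K in kinships:
        if K.values.shape[0] != n:
            raise ValueError("y length and kinship dimension differ")
        _check_psd(K)
    if ids is None:
        ids = list(kinships[0].individual_ids)
    if X is None:
        X = np.ones((n, 1))
    p = X.shape[1]

    def profile(V0: np.ndarray, logdetV0: float):
        Vi_X = np.linalg.solve(V0, X)
        Vi_y = np.linalg.solve(V0, y)
        XtViX = X.T @ Vi_X
        beta = np.linalg.solve(XtViX, X.T @ Vi_y)
        r = y - X @ beta
        Vi_r = np.linalg.solve(V0, r)
        quad = float(r @ Vi_r)
        sigma2 = quad / (n - p)
        _, logdetXtViX = np.linalg.slogdet(XtViX)
        neg2 = (n - p) * math.log(max(sigma2, 1e-300)) + logdetV0 + logdetXtViX
        return neg2, beta, sigma2, Vi_r

    if len(kinships) == 1:
        K = kinships[0]
        d, U = np.linalg.eigh(K.values)
        d = np.clip(d, 0.0, None)
        yt = U.T @ y
        Xt = U.T @ X

        def neg2_of(log10_lam: float) -> float:
            lam = 10.0 ** log10_lam
            v = 1.0 + lam * d
            Vi_Xt = Xt / v[:, None]
            XtViX = Xt.T @ Vi_Xt
            beta = np.linalg.solve(XtViX, Vi_Xt.T @ yt)
            r = yt - Xt @ beta
            quad = float((r * r / v).sum())
            sigma2 = quad / (n - p)
            _, logdetXtViX = np.linalg.slogdet(XtViX)
            return (n - p) * math.log(max(sigma2, 1e-300)) + float(np.log(v).sum()) + logdetXtViX

        res = minimize_scalar(neg2_of, bounds=(-6.0, 6.0), method="bounded",
                              options={"xatol": 1e-8})
        lam = 10.0 ** res.x
        lambdas = {K.source: lam}
        V0 = lam * K.values + np.eye(n)
        logdetV0 = float(np.log1p(lam * d).sum())
        neg2, beta, sigma2, Vi_r = profile(V0, logdetV0)
    else:
        if len(kinships) != 2:
            raise ValueError("fit_gblup supports one or two kinships")

        def neg2_of2(log10_lams) -> float:
            lams = 10.0 ** np.asarray(log10_lams)
            V0 = np.eye(n) + sum(l * K.values for l, K in zip(lams, kinships))
            sign, logdetV0 = np.linalg.slogdet(V0)
            if sign <= 0:
                return 1e12
            return profile(V0, logdetV0)[0]

        res = minimize(neg2_of2, x0=np.array([0.0, 0.0]), method="Nelder-Mead",
                       options={"maxiter": 500, "xatol": 1e-6, "fatol": 1e-8})
        lams = np.clip(10.0 ** res.x, 10.0 ** -6, 10.0 ** 6)
        lambdas = {K.source: float(l) for K, l in zip(kinships, lams)}
        V0 = np.eye(n) + sum(l * K.values for l, K in zip(lams, kinships))
        sign, logdetV0 = np.linalg.slogdet(V0)
        neg2, beta, sigma2, Vi_r = profile(V0, logdetV0)

    vc = {src: lam * sigma2 for src, lam in lambdas.items()}
    vc["residual"] = sigma2
    return GblupFit(
        variance_components=vc,
        lambdas=lambdas,
        beta=beta,
        training_ids=list(ids),
        kinships=kinships,
        alpha=Vi_r,  # V0^-1 (y - X beta); g_hat = sum_K lam_K K alpha
        X=X,
        y=y,
        reml_neg2ll=float(neg2),
    )


def predict_gblup(
    fit: GblupFit,
    kinship_cross: dict[str, np.ndarray] | np.ndarray,
    X_test: np.ndarray | None = None,
) -> np.ndarray:
    """Predict genomic values for test individuals from test x train kinship blocks.

    ``kinship_cross`` maps kinship source -> (n_test, n_train) block (a bare
    array is accepted for single-kinship fits).
    """
    if isinstance(kinship_cross, np.ndarray):
        if len(fit.kinships) != 1:
            raise ValueError("pass one cross block per kinship source")
        kinship_cross = {fit.kinships[0].source: kinship_cross}
    n_train = len(fit.training_ids)
    g = None
    for K in fit.kinships:
        try:
            block = kinship_cross[K.source]
        except KeyError:
            raise KeyError(f"missing cross kinship block for source {K.source!r}") from None
        block = np.asarray(block, dtype=np.float64)
        if block.shape[1] != n_train:
            raise ValueError("cross kinship block column count != training size")
        contrib = fit.lambdas[K.source] * (block @ fit.alpha)
        g = contrib if g is None else g + contrib
    n_test = g.shape[0]
    if X_test is None:
        X_test = np.ones((n_test, fit.X.shape[1]))
    return X_test @ fit.beta + g


@dataclass
class LassoFit:
    """LASSO-selected features with OLS re-estimated coefficients.

    Coefficients are stored on the standardized feature scale; use
    :func:`predict_linear` (or ``coefficients_original_scale``) rather than
    dotting raw features with them.
    """

    feature_keys: list[str]
    col_means: np.ndarray
    col_stds: np.ndarray
    alpha: float  # chosen L1 penalty
    selected: np.ndarray  # indices into feature_keys
    coef: np.ndarray  # refit coefficients, standardized scale, len == len(selected)
    intercept: float
    seed: int
    intercept_only: bool = False
    n_capped: int = 0

    @property
    def selected_keys(self) -> list[str]:
        return [self.feature_keys[i] for i in self.selected]

    def coefficients_original_scale(self) -> pd.Series:
        """Refit coefficients expressed per unit of the raw feature."""
        return pd.Series(
            self.coef / self.col_stds[self.selected],
            index=self.selected_keys,
        )


def _as_feature_frame(features) -> pd.DataFrame:
    if isinstance(features, pd.DataFrame):
        return features
    raise TypeError("features must be a pandas DataFrame (rows=individuals, columns=keys)")


def fit_lasso_refit(
    features: pd.DataFrame,
    y: np.ndarray,
    seed: int,
    n_alphas: int = 100,
    inner_cv: int = 10,
) -> LassoFit:
    """L1 path + seeded inner-CV penalty choice + OLS re-estimation.

    Features are column-standardized internally; missing cells are imputed
    with the training column mean. If the optimum selects nothing the fit
    degenerates to intercept-only (flagged, not an error).
    """
    from sklearn.linear_model import LassoCV
    from sklearn.model_selection import KFold

    features = _as_feature_frame(features)
    Xraw = features.to_numpy(dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n, m = Xraw.shape
    if n < 10:
        raise ValueError(f"LASSO fit needs n >= 10, got {n}")
    if len(y) != n:
        raise ValueError("y length != feature rows")

    col_means = np.nanmean(Xraw, axis=0)
    col_means = np.where(np.isfinite(col_means), col_means, 0.0)
    nan_r, nan_c = np.where(np.isnan(Xraw))
    X = Xraw.copy()
    X[nan_r, nan_c] = col_means[nan_c]
    col_stds = X.std(axis=0)
    usable = col_stds > 0
    col_stds_safe = np.where(usable, col_stds, 1.0)
    Xs = (X - col_means) / col_stds_safe
    Xs[:, ~usable] = 0.0

    k = min(inner_cv, n)
    cv = KFold(n_splits=k, shuffle=True, random_state=int(seed) % (2**31))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = LassoCV(alphas=n_alphas, cv=cv, max_iter=3000)
        model.fit(Xs, y)
    sel = np.flatnonzero(model.coef_ != 0.0)
    n_capped = 0
    if sel.size >= n - 1:
        keep = n // 2
        order = np.argsort(-np.abs(model.coef_[sel]), kind="stable")
        n_capped = sel.size - keep
        sel = np.sort(sel[order[:keep]])
        log.warning("fit_lasso_refit: capped selection to %d features (%d dropped)",
                    keep, n_capped)
    if sel.size == 0:
        log.warning("fit_lasso_refit: empty selection at optimal penalty; intercept-only")
        return LassoFit(
            feature_keys=list(features.columns),
            col_means=col_means,
            col_stds=col_stds_safe,
            alpha=float(model.alpha_),
            selected=sel,
            coef=np.empty(0),
            intercept=float(np.mean(y)),
            seed=int(seed),
            intercept_only=True,
        )
    # OLS re-estimation on the selected set, ridge-stabilized normal equations
    Zsel = Xs[:, sel]
    A = np.column_stack([np.ones(n), Zsel])
    AtA = A.T @ A + 1e-8 * np.eye(A.shape[1])
    coef_all = np.linalg.solve(AtA, A.T @ y)
    return LassoFit(
        feature_keys=list(features.columns),
        col_means=col_means,
        col_stds=col_stds_safe,
        alpha=float(model.alpha_),
        selected=sel,
        coef=coef_all[1:],
        intercept=float(coef_all[0]),
        seed=int(seed),
        n_capped=n_capped,
    )


def predict_linear(fit: LassoFit, features: pd.DataFrame) -> np.ndarray:
    """Predict with the re-estimated coefficients on new feature rows.

    Feature columns are aligned by key; unknown keys are an error; keys
    missing from ``features`` and NaN cells are imputed with the stored
    training column means.
    """
    features = _as_feature_frame(features)
    unknown = [c for c in features.columns if c not in set(fit.feature_keys)]
    if unknown:
        raise KeyError(f"unknown feature keys: {unknown[:5]}{'...' if len(unknown) > 5 else ''}")
    aligned = features.reindex(columns=fit.feature_keys)
    X = aligned.to_numpy(dtype=np.float64)
    nan_r, nan_c = np.where(np.isnan(X))
    X[nan_r, nan_c] = fit.col_means[nan_c]
    Xs = (X - fit.col_means) / fit.col_stds
    if fit.intercept_only or fit.selected.size == 0:
        return np.full(X.shape[0], fit.intercept)
    return fit.intercept + Xs[:, fit.selected] @ fit.coef


def save_fit(fit, path, model: str = "", seed: int | None = None) -> None:
    """Serialize a fitted model to a JSON artifact.

    GBLUP fits store variance components, lambdas and fixed effects;
    LASSO fits store the chosen penalty, the selected window/marker keys
    and their re-estimated coefficients (both on the standardized and the
    original feature scale) plus the intercept.
    """
    import json

    if isinstance(fit, GblupFit):
        payload = {
            "model": model or "GBLUP",
            "kind": "gblup",
            "variance_components": {k: float(v) for k, v in fit.variance_components.items()},
            "lambdas": {k: float(v) for k, v in fit.lambdas.items()},
            "fixed_effects": [float(b) for b in fit.beta],
            "n_training": len(fit.training_ids),
        }
    elif isinstance(fit, LassoFit):
        orig = fit.coefficients_original_scale()
        payload = {
            "model": model or "LASSO",
            "kind": "lasso",
            "seed": fit.seed,
            "alpha": float(fit.alpha),
            "intercept": float(fit.intercept),
            "intercept_only": bool(fit.intercept_only),
            "selected": {
                key: {
                    "coefficient_std_scale": float(fit.coef[i]),
                    "coefficient": float(orig.iloc[i]),
                }
                for i, key in enumerate(fit.selected_keys)
            },
        }
    else:
        raise TypeError(f"cannot serialize fit of type {type(fit).__name__}")
    if seed is not None:
        payload["seed"] = int(seed)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


@dataclass
class ModelInputs:
    """Everything the six model flavors may need, keyed by individual id.

    ``pgsi_by_width`` maps window width (bp) to a PGSI feature frame
    (rows = hybrid ids, columns = window keys). ``marker_codes`` are the
    additive codes of the individuals being modeled (hybrids for
    heterosis). Kinships are built lazily from codes when absent.
    """

    ids: list[str]
    pgsi_by_width: dict[int, pd.DataFrame] = field(default_factory=dict)
    marker_codes: CodedMarkerMatrix | None = None
    dominance_codes: CodedMarkerMatrix | None = None
    additive: KinshipMatrix | None = None
    dominance: KinshipMatrix | None = None
    snp_subsample_fraction: float = 0.0005
    use_all_markers_for_gblup: bool = False

    def gblup_kinships(self, seed: int) -> list[KinshipMatrix]:
        if self.additive is None:
            if self.marker_codes is None:
                raise ValueError("GBLUP needs an additive kinship or marker codes")
            codes = self.marker_codes
            if not self.use_all_markers_for_gblup:
                codes = subsample_markers(codes, self.snp_subsample_fraction, seed)
            self.additive = additive_kinship(codes)
        return [self.additive]

    def gblup_ad_kinships(self, seed: int) -> list[KinshipMatrix]:
        ks = list(self.gblup_kinships(seed))
        if self.dominance is None:
            if self.dominance_codes is None:
                raise ValueError("GBLUP_AD needs a dominance kinship or dominance codes")
            codes = self.dominance_codes
            if not self.use_all_markers_for_gblup:
                codes = subsample_markers(codes, self.snp_subsample_fraction, seed)
            self.dominance = dominance_kinship(codes)
        ks.append(self.dominance)
        return ks

    def snp_features(self, seed: int) -> pd.DataFrame:
        if self.marker_codes is None:
            raise ValueError("LASSO_SNP needs marker codes")
        sub = subsample_markers(self.marker_codes, self.snp_subsample_fraction, seed)
        cols = [f"{c}:{p}" for c, p in sub.marker_keys]
        return pd.DataFrame(sub.values, index=list(sub.samples), columns=cols)

    def window_features(self, width: int) -> pd.DataFrame:
        try:
            return self.pgsi_by_width[width]
        except KeyError:
            raise ValueError(
                f"no PGSI matrix at width {width} (have {sorted(self.pgsi_by_width)})"
            ) from None


def build_model(spec: str, y: np.ndarray, inputs: ModelInputs, seed: int = 0):
    """Dispatch one of the six model flavors to the right engine.

    GBLUP_A / GBLUP_AD -> :func:`fit_gblup` on marker kinships;
    LASSO_SNP -> :func:`fit_lasso_refit` on the marker subsample;
    LASSO_100Kb / LASSO_500Kb / LASSO_1Mb -> :func:`fit_lasso_refit` on the
    PGSI matrix of that window width.
    """
    if spec not in MODEL_SPECS:
        raise ValueError(f"unknown model spec {spec!r}; valid: {MODEL_SPECS}")
    y = np.asarray(y, dtype=np.float64)
    if spec == "GBLUP_A":
        ks = inputs.gblup_kinships(seed)
        return fit_gblup(y, [k.subset(inputs.ids) for k in ks], ids=inputs.ids)
    if spec == "GBLUP_AD":
        ks = inputs.gblup_ad_kinships(seed)
        return fit_gblup(y, [k.subset(inputs.ids) for k in ks], ids=inputs.ids)
    if spec == "LASSO_SNP":
        feats = inputs.snp_features(seed).loc[inputs.ids]
        return fit_lasso_refit(feats, y, seed=seed)
    width = LASSO_WIDTHS[spec]
    feats = inputs.window_features(width).loc[inputs.ids]
    return fit_lasso_refit(feats, y, seed=seed)
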