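"""Multi-environment phenotype integration (BLUEs) and heterosis.

Replicate-level observations are first collapsed to genotype x environment
means; those means are then fit with the linear mixed model

    y = Z g + E u + e,      u ~ N(0, sigma_u^2 I),   e ~ N(0, sigma_e^2 I),

with genotype effects g fixed and environment effects u random, estimated
by REML (profiled likelihood over the variance ratio). The fixed genotype
estimates are the BLUEs, already on the trait scale (the genotype design
carries the intercept). For a single environment the model degenerates to
plain genotype means.

Heterosis is computed from BLUEs as fractions:

    HPH = (F1 - HP) / HP,   HP = max(P1, P2)
    MPH = (F1 - MP) / MP,   MP = (P1 + P2) / 2

and multiplied by 100 only at export.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from pgsihet.genotype_io import CrossPlan

log = logging.getLogger(__name__)

TRAITS = ("PH", "NBP", "NSP", "NSS", "TSW", "GY")

REQUIRED_COLUMNS = ("sample_id", "environment", "replicate", "trait", "value")


def read_phenotypes(path) -> pd.DataFrame:
    """Read a long-format phenotype TSV (sample_id, environment, replicate, trait, value)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    return df


def _validate_records(records: pd.DataFrame) -> None:
    missing = set(REQUIRED_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"phenotype records missing columns: {sorted(missing)}")
    key = ["sample_id", "environment", "replicate", "trait"]
    if records.duplicated(subset=key).any():
        raise ValueError("duplicate (sample, environment, replicate, trait) rows")


@dataclass
class BlueFit:
    """BLUEs for one trait plus REML variance components."""

    blues: pd.Series  # index sample_id
    sigma2_env: float
    sigma2_resid: float
    trait: str


def fit_blue(records: pd.DataFrame, trait: str) -> BlueFit:
    """Integrate one trait across environments into per-genotype BLUEs."""
    _validate_records(records)
    sub = records[(records["trait"] == trait) & records["value"].notna()]
    if sub.empty:
        raise ValueError(f"no observations for trait {trait!r}")
    # step 1: replicate means per genotype x environment
    cell = (
        sub.groupby(["sample_id", "environment"], sort=False)["value"].mean().reset_index()
    )
    genotypes = list(dict.fromkeys(cell["sample_id"]))
    envs = list(dict.fromkeys(cell["environment"]))
    if len(envs) == 1:
        blues = cell.groupby("sample_id", sort=False)["value"].mean()
        return BlueFit(blues.reindex(genotypes), 0.0, float("nan"), trait)

    g_idx = pd.Categorical(cell["sample_id"], categories=genotypes).codes
    e_idx = pd.Categorical(cell["environment"], categories=envs).codes
    y = cell["value"].to_numpy(dtype=np.float64)
    n, p, q = len(y), len(genotypes), len(envs)
    if n <= p:
        # saturated (e.g. every genotype seen once): fall back to means
        log.warning("fit_blue(%s): no residual degrees of freedom; using genotype means", trait)
        blues = cell.groupby("sample_id", sort=False)["value"].mean()
        return BlueFit(blues.reindex(genotypes), 0.0, float("nan"), trait)

    # One-hot genotype design X and environment design E are never formed:
    # V0 = I + gamma E E^T is block compound-symmetric by environment, so
    # V0^-1 M = M - E diag(w) E^T M with w_e = gamma / (1 + gamma n_e),
    # and X^T V0^-1 X = diag(n_g) - G diag(w) G^T with G the genotype x
    # environment incidence-count matrix.
    n_env = np.bincount(e_idx, minlength=q).astype(np.float64)
    n_gen = np.bincount(g_idx, minlength=p).astype(np.float64)
    G = np.zeros((p, q))
    np.add.at(G, (g_idx, e_idx), 1.0)
    Xty = np.bincount(g_idx, weights=y, minlength=p)
    Ety = np.bincount(e_idx, weights=y, minlength=q)

    def gls(gamma: float):
        w = gamma / (1.0 + gamma * n_env)
        XtX = np.diag(n_gen) - G * w @ G.T
        rhs = Xty - G @ (w * Ety)
        beta = np.linalg.solve(XtX, rhs)
        r = y - beta[g_idx]
        Etr = np.bincount(e_idx, weights=r, minlength=q)
        quad = float(r @ r - (w * Etr) @ Etr)
        logdetV0 = float(np.log1p(gamma * n_env).sum())
        _, logdetXtX = np.linalg.slogdet(XtX)
        return beta, quad, logdetV0, logdetXtX

    def neg2_reml(log_gamma: float) -> float:
        gamma = math.exp(log_gamma)
        _, quad, logdetV0, logdetXtX = gls(gamma)
        sigma2 = quad / (n - p)
        return (n - p) * math.log(max(sigma2, 1e-300)) + logdetV0 + logdetXtX

    res = minimize_scalar(neg2_reml, bounds=(-12.0, 12.0), method="bounded",
                          options={"xatol": 1e-8})
    gamma = math.exp(res.x)
    beta, quad, _, _ = gls(gamma)
    sigma2_e = quad / (n - p)
    blues = pd.Series(beta, index=genotypes, name=trait)
    return BlueFit(blues, gamma * sigma2_e, sigma2_e, trait)


def fit_blues(records: pd.DataFrame, traits=None) -> pd.DataFrame:
    """BLUEs for several traits: sample_id x trait table."""
    if traits is None:
        traits = list(dict.fromkeys(records["trait"]))
    cols = {t: fit_blue(records, t).blues for t in traits}
    return pd.DataFrame(cols)


def compute_heterosis(blues: pd.DataFrame, plan: CrossPlan) -> pd.DataFrame:
    """Per-hybrid HPH and MPH per trait, as fractions.

    Returns a frame indexed by hybrid_id with columns '<trait>_HPH' and
    '<trait>_MPH'. Non-positive denominators yield NaN with a warning.
    """
    out: dict[str, list[float]] = {}
    hybrids = []
    n_bad_denom = 0
    traits = list(blues.columns)
    for t in traits:
        out[f"{t}_HPH"] = []
        out[f"{t}_MPH"] = []
    for row in plan:
        for who in (row.hybrid_id, row.female_id, row.male_id):
            if who not in blues.index:
                raise KeyError(f"sample {who!r} has no BLUE values")
        hybrids.append(row.hybrid_id)
        for t in traits:
            f1 = blues.at[row.hybrid_id, t]
            p1 = blues.at[row.female_id, t]
            p2 = blues.at[row.male_id, t]
            hp = max(p1, p2)
            mp = 0.5 * (p1 + p2)
            hph = (f1 - hp) / hp if hp > 0 else np.nan
            mph = (f1 - mp) / mp if mp > 0 else np.nan
            if (hp <= 0 or mp <= 0) and np.isfinite(f1):
                n_bad_denom += 1
            out[f"{t}_HPH"].append(hph)
            out[f"{t}_MPH"].append(mph)
    if n_bad_denom:
        warnings.warn(f"{n_bad_denom} heterosis values dropped: non-positive parental denominator")
    return pd.DataFrame(out, index=pd.Index(hybrids, name="hybrid_id"))


def heterosis_to_tsv(heterosis: pd.DataFrame, path) -> None:
    """Export heterosis as percentages rounded to 2 decimals (*_pct columns)."""
    pct = (heterosis * 100.0).round(2)
    pct.columns = [f"{c}_pct" for c in pct.columns]
    pct.to_csv(path, sep="\t")


def trait_correlation_matrix(table: pd.DataFrame, ids=None) -> pd.DataFrame:
    """Pairwise Pearson correlations between traits (pairwise-complete)."""
    df = table.loc[ids] if ids is not None else table
    return df.corr(method="pearson", min_periods=3)


def parent_offspring_correlation(
    blues: pd.DataFrame, plan: CrossPlan, side: str = "male"
) -> pd.Series:
    """Per-trait Pearson r between hybrid BLUEs and parental BLUEs.

    ``side`` is 'female', 'male' or 'midparent'.
    """
    if side not in ("female", "male", "midparent"):
        raise ValueError(f"side must be female/male/midparent, got {side!r}")
    rows_h, rows_p = [], []
    for row in plan:
        h = blues.loc[row.hybrid_id]
        if side == "female":
            p = blues.loc[row.female_id]
        elif side == "male":
            p = blues.loc[row.male_id]
        else:
            p = 0.5 * (blues.loc[row.female_id] + blues.loc[row.male_id])
        rows_h.append(h)
        rows_p.append(p)
    H = pd.DataFrame(rows_h).reset_index(drop=True)
    P = pd.DataFrame(rows_p).reset_index(drop=True)
    return H.corrwith(P, method="pearson")


def top_fraction_summary(
    heterosis: pd.DataFrame, trait: str, which: str = "HPH", fraction: float = 0.1
) -> tuple[float, list[str]]:
    """Mean heterosis of the top ``fraction`` of hybrids for one trait.

    Hybrids are ranked descending; ceil(fraction * n) are kept. Returns
    (mean, hybrid id list).
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    col = f"{trait}_{which}"
    if col not in heterosis.columns:
        raise KeyError(f"no column {col!r} in heterosis table")
    vals = heterosis[col].dropna().sort_values(ascending=False)
    if vals.empty:
        raise ValueError(f"all values missing for {col}")
    k = math.ceil(fraction * len(vals))
    top = vals.iloc[:k]
    return float(top.mean()), list(top.index)
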