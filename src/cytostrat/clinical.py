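"""Clinical association stages: the rule-based renal-response classifier,
group comparisons (Kruskal-Wallis + Dunn), Spearman screens with BH FDR,
multivariable linear/logistic models, repeated cross-validated elastic-net
attribution, and longitudinal mixed-effects trends.

Renal response at week 52 is only evaluable in patients with baseline
UPCR >= 1 g/g.  Complete response requires week-52 UPCR < 0.5, normal serum
creatinine (<= 1.3 mg/dL) or, if abnormal, < 125 % of baseline, and
prednisone < 10 mg/d; partial response requires a > 50 % reduction in UPCR
without meeting the complete UPCR criterion, creatinine <= 1.3 or <= 125 %
of baseline, and prednisone <= 15 mg/d; otherwise none.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold
from sklearn.preprocessing import StandardScaler
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("cytostrat")

NORMAL_CREATININE = 1.3  # mg/dL


# ---------------------------------------------------------------------------
# renal response classifier
# ---------------------------------------------------------------------------

@dataclass
class ResponseCall:
    """One patient's week-52 renal response with the rule trace that decided it."""

    call: str  # complete | partial | none | not_evaluable
    trace: list[str] = field(default_factory=list)


def classify_renal_response(
    baseline_upcr: float,
    wk52_upcr: float,
    wk52_creatinine: float,
    baseline_creatinine: float,
    wk52_prednisone: float,
) -> ResponseCall:
    """Apply the week-52 renal-response rules (see module docstring)."""
    vals = dict(baseline_upcr=baseline_upcr, wk52_upcr=wk52_upcr,
                wk52_creatinine=wk52_creatinine,
                baseline_creatinine=baseline_creatinine,
                wk52_prednisone=wk52_prednisone)
    missing = [k for k, v in vals.items() if v is None or (isinstance(v, float) and np.isnan(v))]
    if missing:
        return ResponseCall("not_evaluable", [f"missing:{','.join(missing)}"])
    if any(v < 0 for v in vals.values()):
        raise ValueError("negative clinical inputs")
    if baseline_upcr < 1.0:
        return ResponseCall("not_evaluable", ["baseline_upcr<1"])

    trace: list[str] = []
    if wk52_creatinine <= NORMAL_CREATININE:
        creat_complete = creat_partial = True
        trace.append("creatinine_normal(<=1.3)")
    else:
        creat_complete = wk52_creatinine < 1.25 * baseline_creatinine
        creat_partial = wk52_creatinine <= 1.25 * baseline_creatinine
        trace.append("creatinine_abnormal(vs_125%_baseline)")

    if wk52_upcr < 0.5 and creat_complete and wk52_prednisone < 10:
        trace.append("complete: upcr<0.5 & creatinine_ok & prednisone<10")
        return ResponseCall("complete", trace)
    if (wk52_upcr <= 0.5 * baseline_upcr and creat_partial and wk52_prednisone <= 15):
        trace.append("partial: >50%_upcr_reduction & creatinine_ok & prednisone<=15")
        return ResponseCall("partial", trace)
    trace.append("none: criteria unmet")
    return ResponseCall("none", trace)


def classify_responses(clinical: pd.DataFrame) -> pd.DataFrame:
    """Vectorized convenience wrapper over a clinical table."""
    calls = []
    for _, r in clinical.iterrows():
        c = classify_renal_response(
            r.get("upcr_baseline", np.nan), r.get("upcr_wk52", np.nan),
            r.get("creatinine_wk52", np.nan), r.get("creatinine_baseline", np.nan),
            r.get("prednisone_wk52", np.nan))
        calls.append(dict(sample_id=r["sample_id"], response=c.call,
                          trace=" | ".join(c.trace)))
    return pd.DataFrame(calls).set_index("sample_id")


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    kw_statistic: float
    kw_p: float
    pairwise: pd.DataFrame  # group_a, group_b, z, p, q (BH)


def compare_groups(values: pd.Series, groups: pd.Series) -> GroupComparison:
    """Tie-corrected Kruskal-Wallis omnibus plus Dunn's pairwise z tests
    with BH adjustment."""
    df = pd.DataFrame({"v": values, "g": groups}).dropna()
    names = sorted(df["g"].unique())
    arrays = [df.loc[df["g"] == g, "v"].to_numpy() for g in names]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise ValueError("need >=2 groups with >=2 samples")
    if df["v"].nunique() == 1:
        logger.info("compare_groups: all values tied; p = 1")
        pw = pd.DataFrame([
            dict(group_a=a, group_b=b, z=0.0, p=1.0, q=1.0)
            for a, b in itertools.combinations(names, 2)])
        return GroupComparison(0.0, 1.0, pw)
    H, p = stats.kruskal(*arrays)

    # Dunn: z from mean ranks with tie correction
    ranks = stats.rankdata(df["v"])
    n = len(df)
    mean_rank = {g: ranks[(df["g"] == g).to_numpy()].mean() for g in names}
    sizes = {g: (df["g"] == g).sum() for g in names}
    _, tie_counts = np.unique(df["v"], return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (12 * (n - 1))
    rows = []
    for a, b in itertools.combinations(names, 2):
        se = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1 / sizes[a] + 1 / sizes[b]))
        z = (mean_rank[a] - mean_rank[b]) / se
        rows.append(dict(group_a=a, group_b=b, z=z,
                         p=2 * stats.norm.sf(abs(z))))
    pw = pd.DataFrame(rows)
    pw["q"] = multipletests(pw["p"], method="fdr_bh")[1]
    return GroupComparison(float(H), float(p), pw)


# ---------------------------------------------------------------------------
# Spearman screen
# ---------------------------------------------------------------------------

def spearman_screen(features: pd.DataFrame, targets: pd.DataFrame,
                    q: float = 0.05) -> pd.DataFrame:
    """Spearman rho of every feature-target pair with BH FDR over all pairs."""
    rows = []
    for f in features.columns:
        for t in targets.columns:
            sub = pd.concat([features[f], targets[t]], axis=1).dropna()
            if len(sub) < 3 or sub.iloc[:, 0].nunique() <= 1 or sub.iloc[:, 1].nunique() <= 1:
                rows.append(dict(feature=f, target=t, rho=np.nan, p=np.nan))
                continue
            r, p = stats.spearmanr(sub.iloc[:, 0], sub.iloc[:, 1])
            rows.append(dict(feature=f, target=t, rho=r, p=p))
    tab = pd.DataFrame(rows)
    ok = tab["p"].notna()
    tab["q"] = np.nan
    if ok.any():
        tab.loc[ok, "q"] = multipletests(tab.loc[ok, "p"], method="fdr_bh")[1]
    tab["significant"] = tab["q"] <= q
    return tab


# ---------------------------------------------------------------------------
# multivariable models
# ---------------------------------------------------------------------------

@dataclass
class ModelResult:
    coefficient: float        # beta (linear) or OR (logistic) for the exposure
    ci_low: float
    ci_high: float
    p: float
    family: str
    n: int
    separation_flagged: bool = False


def multivariable(
    outcome: pd.Series,
    exposure: pd.Series,
    covariates: pd.DataFrame | None = None,
    family: str = "linear",
) -> ModelResult:
    """Covariate-adjusted model of outcome on a one-vs-rest exposure.

    Linear family reports beta with Wald 95 % CI; logistic reports the odds
    ratio (exponentiated coefficient and CI).  Quasi-separated logistic fits
    are re-fit with a small L2 penalty and flagged.
    """
    df = pd.DataFrame({"y": outcome, "x": exposure.astype(float)})
    if covariates is not None and len(covariates.columns):
        df = df.join(pd.get_dummies(covariates, drop_first=True).astype(float))
    df = df.dropna()
    X = sm.add_constant(df.drop(columns="y"))
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix not full rank")
    flagged = False
    if family == "linear":
        fit = sm.OLS(df["y"], X).fit()
        b, (lo, hi), p = fit.params["x"], fit.conf_int().loc["x"], fit.pvalues["x"]
    elif family == "logistic":
        try:
            with np.errstate(all="ignore"):
                fit = sm.Logit(df["y"], X).fit(disp=0, maxiter=200)
            if not fit.mle_retvals.get("converged", True) or np.abs(fit.params).max() > 15:
                raise np.linalg.LinAlgError
        except Exception:
            flagged = True
            logger.warning("logistic separation suspected; refitting with L2 penalty")
            fit = sm.Logit(df["y"], X).fit_regularized(
                alpha=1.0, L1_wt=0.0, disp=0, maxiter=500)
            fit = sm.GLM(df["y"], X, family=sm.families.Binomial()).fit(
                start_params=fit.params, maxiter=0)
        b, (lo, hi), p = fit.params["x"], fit.conf_int().loc["x"], fit.pvalues["x"]
        b, lo, hi = np.exp(b), np.exp(lo), np.exp(hi)
    else:
        raise ValueError("family must be 'linear' or 'logistic'")
    return ModelResult(float(b), float(lo), float(hi), float(p), family,
                       len(df), flagged)


# ---------------------------------------------------------------------------
# elastic-net attribution
# ---------------------------------------------------------------------------

def elastic_net_attribution(
    predictors: pd.DataFrame,
    response: pd.Series,
    *,
    l1_ratio: float = 0.5,
    alphas: np.ndarray | None = None,
    repeats: int = 10,
    folds: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Averaged standardized elastic-net coefficients over repeated CV.

    Per repeat, a ``folds``-fold cross-validation selects the penalty by
    minimum mean validation error; coefficients on standardized predictors
    are averaged over repeats, with the fraction of repeats selecting each
    predictor (nonzero coefficient) reported as ``selection_frequency``.
    """
    df = predictors.join(response.rename("_y")).dropna()
    if len(df) < folds:
        raise ValueError("fewer samples than folds")
    if len(df) < 3 * folds:
        logger.warning("elastic net: %d samples for %d folds is thin", len(df), folds)
    X = StandardScaler().fit_transform(
        pd.get_dummies(df.drop(columns="_y"), drop_first=True).astype(float))
    names = list(pd.get_dummies(df.drop(columns="_y"), drop_first=True).columns)
    y = df["_y"].to_numpy(dtype=float)
    y = (y - y.mean()) / (y.std() or 1.0)
    alphas = alphas if alphas is not None else np.logspace(-3, 1, 30)
    coefs = np.zeros((repeats, X.shape[1]))
    for r in range(repeats):
        cv = KFold(n_splits=folds, shuffle=True, random_state=seed * 1000 + r)
        enet = ElasticNetCV(l1_ratio=l1_ratio, alphas=alphas, cv=cv,
                            max_iter=5000).fit(X, y)
        coefs[r] = enet.coef_
    return pd.DataFrame({
        "coefficient": coefs.mean(axis=0),
        "sign": np.sign(coefs.mean(axis=0)),
        "selection_frequency": (coefs != 0).mean(axis=0),
    }, index=names).sort_values("coefficient", key=np.abs, ascending=False)


# ---------------------------------------------------------------------------
# longitudinal mixed model
# ---------------------------------------------------------------------------

@dataclass
class LongitudinalResult:
    fixed_effects: pd.DataFrame  # term, estimate, p
    used_mixed: bool


def mixed_longitudinal(
    values: pd.Series,
    timepoint: pd.Series,
    group: pd.Series,
    patient: pd.Series,
) -> LongitudinalResult:
    """Linear mixed model ``value ~ time * group`` with a random intercept
    per patient (Wald p-values); falls back to OLS with a warning when
    there is no within-patient replication or the random effect degenerates.
    """
    df = pd.DataFrame({"y": values, "t": timepoint.astype(float),
                       "g": group, "pid": patient}).dropna()
    g_levels = sorted(df["g"].unique())
    if len(g_levels) < 2:
        raise ValueError("need >=2 groups")
    df["gi"] = (df["g"] == g_levels[-1]).astype(float)
    X = sm.add_constant(pd.DataFrame({
        "t": df["t"], "g": df["gi"], "t:g": df["t"] * df["gi"]}))
    replicated = df.groupby("pid").size().max() > 1
    if replicated:
        try:
            with np.errstate(all="ignore"):
                fit = sm.MixedLM(df["y"], X, groups=df["pid"]).fit(reml=True)
            var_re = float(np.asarray(fit.cov_re).ravel()[0])
            if not np.isfinite(var_re):
                raise ValueError
            fe = pd.DataFrame({"estimate": fit.fe_params,
                               "p": fit.pvalues[fit.fe_params.index]})
            return LongitudinalResult(fe, used_mixed=True)
        except Exception:
            logger.warning("mixed model degenerate; falling back to OLS")
    else:
        logger.warning("no within-patient replication; falling back to OLS")
    fit = sm.OLS(df["y"], X).fit()
    fe = pd.DataFrame({"estimate": fit.params, "p": fit.pvalues})
    return LongitudinalResult(fe, used_mixed=False)
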