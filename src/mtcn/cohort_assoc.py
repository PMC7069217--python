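"""Cohort statistics: PCL-C scoring, group/age/sex association models,
Fisher exact enrichment, blood-count screens and clustering, parent-child
inheritance models, and minimal-detectable-effect power computation.

All regression models are ordinary least squares with two-sided t-tests on
single coefficients; relatedness between participants is deliberately not
modelled (reported, not corrected).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.cluster import hierarchy

from .qpcr_quant import inverse_normal_transform

__all__ = [
    "PclcResponse",
    "AssocResult",
    "OddsRatioResult",
    "score_pclc",
    "fit_group_model",
    "fisher_2x2",
    "min_detectable_f",
    "parent_child_model",
    "blood_screen",
    "joint_blood_model",
    "cluster_blood",
    "balance_checks",
    "BLOOD_MEASURES",
]

N_PCLC_ITEMS = 17

#: The 20 blood-count measures, named as reported.
BLOOD_MEASURES = (
    "WBC_x10.9_per_L", "RBC_x10.12_per_L", "HGB_g_per_L", "HCT_L_per_L",
    "MCV_fL", "PLT_x10.9_per_L", "MCH_pg", "MCHC_g_per_L", "RDW_percent",
    "MPV_fL", "NEU_percent", "LYM_percent", "MONO_percent", "EOS_percent",
    "BASO_percent", "NEU_x10.9_per_L", "LYM_x10.9_per_L", "MONO_x10.9_per_L",
    "EOS_x10.9_per_L", "BASO_x10.9_per_L",
)


@dataclass
class PclcResponse:
    participant_id: str
    items: list[int]
    total: int
    probable_ptsd: bool


@dataclass
class AssocResult:
    term: str
    beta: float
    se: float
    p: float
    n: int
    covariates: list[str] = field(default_factory=list)


@dataclass
class OddsRatioResult:
    table: np.ndarray
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    continuity_corrected: bool
    ci_method: str = "woolf"


def score_pclc(items, participant_id: str = "", cutoff: int = 30,
               item_range: tuple[int, int] = (0, 5)) -> PclcResponse:
    """Score a 17-item PCL-C response.

    Total is the item sum; ``probable_ptsd`` is True when total >= cutoff
    (inclusive).  With the default 0-5 item scale the attainable totals run
    0 to 85.  Raises on wrong item count or out-of-range ratings.
    """
    items = [int(v) for v in items]
    if len(items) != N_PCLC_ITEMS:
        raise ValueError(f"PCL-C requires {N_PCLC_ITEMS} items, got {len(items)}")
    lo, hi = item_range
    bad = [v for v in items if v < lo or v > hi]
    if bad:
        raise ValueError(f"item ratings outside [{lo}, {hi}]: {bad}")
    total = sum(items)
    return PclcResponse(participant_id, items, total, total >= cutoff)


def _check_design(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the dependent columns via QR pivoting
        _, r = np.linalg.qr(X)
        bad = [names[j] for j in range(X.shape[1]) if abs(r[j, j]) < 1e-10]
        raise ValueError(f"collinear design; offending columns: {bad or names}")


def _ols(y: np.ndarray, X: np.ndarray, names: list[str]) -> pd.DataFrame:
    n, k = X.shape
    if n <= k:
        raise ValueError(f"n={n} too small for {k} parameters")
    _check_design(X, names)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sigma2 = resid @ resid / (n - k)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = 2 * stats.t.sf(np.abs(t), n - k)
    return pd.DataFrame({"term": names, "beta": beta, "se": se, "p": p})


def _to_numeric(col: pd.Series) -> np.ndarray:
    """Encode a covariate column numerically: booleans as 0/1, two-level
    strings as an indicator for the lexicographically larger level."""
    if col.dtype == bool:
        return col.to_numpy(dtype=float)
    if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
        levels = sorted(pd.unique(col.astype(str)))
        if len(levels) > 2:
            raise ValueError(
                f"column {col.name!r} has {len(levels)} levels; encode manually")
        return (col.astype(str) == levels[-1]).to_numpy(dtype=float)
    return col.to_numpy(dtype=float)


def fit_group_model(
    data: pd.DataFrame,
    outcome: str,
    predictor: str,
    covariates: list[str] | None = None,
    interaction: str | None = None,
) -> list[AssocResult]:
    """OLS of ``outcome`` on ``predictor`` plus covariates, with an
    optional predictor x covariate interaction.

    Two-level string/boolean columns are encoded as 0/1 indicators (the
    lexicographically larger level is 1, e.g. M for sex, HS for group).
    Returns results for the predictor and, when requested, the interaction
    term.  Rows with missing values are dropped.
    """
    covariates = list(covariates or [])
    cols = [outcome, predictor] + covariates
    df = data[cols].dropna()
    y = df[outcome].to_numpy(dtype=float)
    xs = {c: _to_numeric(df[c]) for c in [predictor] + covariates}
    if np.ptp(xs[predictor]) == 0:
        raise ValueError(f"predictor {predictor!r} does not vary")

    names = ["intercept", predictor] + covariates
    X = [np.ones(len(df)), xs[predictor]] + [xs[c] for c in covariates]
    if interaction is not None:
        if interaction not in covariates:
            raise ValueError("interaction partner must be among covariates")
        names.append(f"{predictor}:{interaction}")
        X.append(xs[predictor] * xs[interaction])
    table = _ols(y, np.column_stack(X), names)

    wanted = [predictor] + ([f"{predictor}:{interaction}"] if interaction else [])
    out = []
    for term in wanted:
        row = table.loc[table["term"] == term].iloc[0]
        out.append(AssocResult(term=term, beta=float(row["beta"]),
                               se=float(row["se"]), p=float(row["p"]),
                               n=len(df), covariates=covariates))
    return out


def fisher_2x2(table) -> OddsRatioResult:
    """Fisher's exact test for a 2x2 table of nonnegative integer counts.

    Two-sided p sums hypergeometric probabilities no larger than that of
    the observed table (conditional on all margins).  The odds ratio is
    the sample cross-ratio; a 0.5 Haldane correction is applied (and
    flagged) when any cell is zero.  The 95% CI uses the Woolf log-OR
    normal method on the (possibly corrected) cells.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)):
            raise ValueError("counts must be integers")
        t = t.astype(int)
    if (t < 0).any():
        raise ValueError("counts must be nonnegative")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    n = a + b + c + d
    if min(a + b, c + d, a + c, b + d) == 0:
        raise ValueError("a table margin is zero: test undefined")

    hg = stats.hypergeom(n, a + b, a + c)
    support = np.arange(max(0, (a + b) + (a + c) - n), min(a + b, a + c) + 1)
    pmf = hg.pmf(support)
    p_obs = hg.pmf(a)
    p = float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())
    p = min(p, 1.0)

    corrected = 0 in (a, b, c, d)
    if corrected:
        aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d))
    else:
        aa, bb, cc, dd = a, b, c, d
    orr = (aa * dd) / (bb * cc)
    log_se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    z = stats.norm.ppf(0.975)
    ci = (float(np.exp(np.log(orr) - z * log_se)),
          float(np.exp(np.log(orr) + z * log_se)))
    return OddsRatioResult(table=t, odds_ratio=float(orr), ci_low=ci[0],
                           ci_high=ci[1], p=p, continuity_corrected=corrected)


def _power_single_coef(f: float, n: int, n_covariates: int,
                       alpha: float) -> float:
    u = 1
    v = n - n_covariates - 2
    lam = f * f * (u + v + 1)
    crit = stats.f.ppf(1 - alpha, u, v)
    return float(stats.ncf.sf(crit, u, v, lam))


def min_detectable_f(n: int, n_covariates: int, alpha: float = 0.05,
                     power: float = 0.8) -> float:
    """Minimal detectable Cohen's f for a single-coefficient test.

    Solves the noncentral-F power equation with numerator df 1,
    denominator df v = n - n_covariates - 2 and noncentrality
    lambda = f^2 (1 + v + 1) for the f giving the requested power.
    """
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must be in (0, 1)")
    v = n - n_covariates - 2
    if v < 1:
        raise ValueError(f"degenerate denominator df v={v}: n too small")
    lo, hi = 1e-8, 10.0
    if _power_single_coef(hi, n, n_covariates, alpha) < power:
        raise ValueError("requested power unattainable at this n")
    return float(optimize.brentq(
        lambda f: _power_single_coef(f, n, n_covariates, alpha) - power, lo, hi,
        xtol=1e-10))


def parent_child_model(
    cn: pd.Series,
    participants: pd.DataFrame,
    parent_predictor: str = "cn",
) -> AssocResult:
    """Regress child copy number on a parent predictor, controlling for
    age and sex of both parent and child.

    ``parent_predictor`` is ``"cn"`` (the parent's copy-number score) or
    ``"group"`` (the parent's exposure status indicator).  One pair is
    formed per recorded parent whose score and covariates are available.
    """
    meta = participants.set_index("id")
    pairs = []
    for _, child in participants.iterrows():
        if child["id"] not in cn.index:
            continue
        for col in ("mother_id", "father_id"):
            pid = child.get(col)
            if pd.isna(pid) or pid == "" or pid not in meta.index:
                continue
            if parent_predictor == "cn" and pid not in cn.index:
                continue
            parent = meta.loc[pid]
            pairs.append({
                "child_cn": cn[child["id"]],
                "parent_value": (cn[pid] if parent_predictor == "cn"
                                 else float(parent["group"] == "HS")),
                "child_age": child["age"],
                "child_male": float(child["sex"] == "M"),
                "parent_age": parent["age"],
                "parent_male": float(parent["sex"] == "M"),
            })
    df = pd.DataFrame(pairs).dropna()
    if len(df) and np.ptp(df["parent_value"].to_numpy(dtype=float)) == 0:
        raise ValueError("parent predictor does not vary across pairs")
    # covariates can be degenerate (e.g. parent_male when every linked
    # parent is a mother): drop them rather than fail
    covs = ["child_age", "child_male", "parent_age", "parent_male"]
    kept_covs = []
    for c in covs:
        if len(df) and np.ptp(df[c].to_numpy(dtype=float)) > 0:
            kept_covs.append(c)
        else:
            warnings.warn(f"covariate {c} is constant across pairs; dropped",
                          stacklevel=2)
    names = ["intercept", "parent_value"] + kept_covs
    n_params = len(names)
    if len(df) < max(3, n_params + 1):
        raise ValueError(f"only {len(df)} parent-child pairs; need >= {n_params + 1}")
    X = np.column_stack([np.ones(len(df))] + [df[c].to_numpy(dtype=float)
                                              for c in names[1:]])
    table = _ols(df["child_cn"].to_numpy(dtype=float), X, names)
    row = table.loc[table["term"] == "parent_value"].iloc[0]
    return AssocResult(term=f"parent_{parent_predictor}", beta=float(row["beta"]),
                       se=float(row["se"]), p=float(row["p"]), n=len(df),
                       covariates=names[2:])


def blood_screen(
    blood: pd.DataFrame,
    metadata: pd.DataFrame,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, float]:
    """Per-measure covariate screen of quantile-normalized blood counts.

    Each measure is inverse-normal transformed, then regressed on age, sex,
    group and probable-PTSD jointly; the beta/se/p of every covariate is
    reported per measure.  Returns the result table and the Bonferroni
    threshold alpha / (n_measures x 4 covariates).  Constant measures are
    dropped with a warning.
    """
    merged = blood.merge(metadata, left_on="participant_id", right_on="id")
    covs = {
        "age": merged["age"].to_numpy(dtype=float),
        "sex_male": (merged["sex"] == "M").to_numpy(dtype=float),
        "group_hs": (merged["group"] == "HS").to_numpy(dtype=float),
        "probable_ptsd": merged["probable_ptsd"].to_numpy(dtype=float),
    }
    measures = [m for m in BLOOD_MEASURES if m in blood.columns]
    rows, n_tested = [], 0
    for m in measures:
        vals = merged[m].to_numpy(dtype=float)
        if np.ptp(vals[np.isfinite(vals)]) == 0:
            warnings.warn(f"measure {m} is constant; dropped", stacklevel=2)
            continue
        y = inverse_normal_transform(vals)
        names = ["intercept"] + list(covs)
        X = np.column_stack([np.ones(len(y))] + list(covs.values()))
        table = _ols(y, X, names)
        n_tested += 1
        for cov in covs:
            r = table.loc[table["term"] == cov].iloc[0]
            rows.append({"measure": m, "covariate": cov, "beta": r["beta"],
                         "se": r["se"], "p": r["p"], "n": len(y)})
    threshold = alpha / (n_tested * len(covs)) if n_tested else np.nan
    out = pd.DataFrame(rows)
    if len(out):
        out["significant"] = out["p"] < threshold
    return out, threshold


def joint_blood_model(
    cn: pd.Series,
    blood: pd.DataFrame,
    metadata: pd.DataFrame,
) -> pd.DataFrame:
    """Regress normalized copy number on all blood measures jointly, plus
    age and sex.  Measures enter in their raw units.  Returns the
    per-measure coefficient table."""
    merged = blood.merge(metadata, left_on="participant_id", right_on="id")
    merged = merged[merged["participant_id"].isin(cn.index)]
    y = cn.loc[merged["participant_id"]].to_numpy(dtype=float)
    measures = [m for m in BLOOD_MEASURES if m in blood.columns]
    keep = [m for m in measures if np.ptp(merged[m].to_numpy(dtype=float)) > 0]
    for m in set(measures) - set(keep):
        warnings.warn(f"measure {m} is constant; dropped", stacklevel=2)
    names = ["intercept"] + keep + ["age", "sex_male"]
    X = np.column_stack(
        [np.ones(len(merged))]
        + [merged[m].to_numpy(dtype=float) for m in keep]
        + [merged["age"].to_numpy(dtype=float),
           (merged["sex"] == "M").to_numpy(dtype=float)]
    )
    table = _ols(y, X, names)
    table["n"] = len(merged)
    return table[table["term"].isin(keep)].reset_index(drop=True)


def cluster_blood(
    blood: pd.DataFrame,
    n_clusters: int = 2,
    max_missing: float = 0.2,
) -> tuple[np.ndarray, pd.Series, list[str]]:
    """Agglomerative hierarchical clustering of individuals over
    quantile-normalized blood measures (Euclidean distance, average
    linkage).

    Individuals missing more than ``max_missing`` of the measures are
    excluded.  Returns (linkage matrix, cluster labels indexed by
    participant id, excluded ids).
    """
    measures = [m for m in BLOOD_MEASURES if m in blood.columns]
    X = blood.set_index("participant_id")[measures].astype(float)
    frac_missing = X.isna().mean(axis=1)
    excluded = list(X.index[frac_missing > max_missing])
    X = X.loc[frac_missing <= max_missing].dropna()
    if len(X) < 3:
        raise ValueError("need at least 3 complete individuals to cluster")
    Z = np.column_stack([inverse_normal_transform(X[m].to_numpy())
                         for m in measures])
    linkage = hierarchy.linkage(Z, method="average", metric="euclidean")
    labels = hierarchy.fcluster(linkage, t=n_clusters, criterion="maxclust")
    return linkage, pd.Series(labels, index=X.index, name="cluster"), excluded


def balance_checks(
    metadata: pd.DataFrame,
    plate_assignment: pd.Series,
) -> pd.DataFrame:
    """Randomization checks: chi-squared tests of plate x {sex, group,
    probable_ptsd} and, per generation, a t-test of age by group and a
    Fisher exact test of sex by group.  Returns a tidy test table."""
    meta = metadata.set_index("id")
    plates = plate_assignment.reindex(meta.index).dropna()
    meta = meta.loc[plates.index]
    rows = []
    for var in ("sex", "group", "probable_ptsd"):
        if var not in meta.columns or meta[var].isna().all():
            continue
        ct = pd.crosstab(plates, meta[var])
        if ct.shape[1] < 2:
            continue
        chi2, p, dof, _ = stats.chi2_contingency(ct)
        rows.append({"test": "chi2", "variable": f"plate_x_{var}",
                     "statistic": chi2, "p": p, "n": int(ct.to_numpy().sum())})
    for gen, sub in metadata.groupby("generation"):
        hs = sub[sub["group"] == "HS"]
        ctrl = sub[sub["group"] == "CTRL"]
        if len(hs) >= 2 and len(ctrl) >= 2:
            tstat, p = stats.ttest_ind(hs["age"], ctrl["age"])
            rows.append({"test": "t", "variable": f"{gen}_age_by_group",
                         "statistic": tstat, "p": p, "n": len(sub)})
        tab = pd.crosstab(sub["group"], sub["sex"])
        if tab.shape == (2, 2) and tab.to_numpy().sum() > 0:
            try:
                res = fisher_2x2(tab.to_numpy())
                rows.append({"test": "fisher", "variable": f"{gen}_sex_by_group",
                             "statistic": res.odds_ratio, "p": res.p,
                             "n": len(sub)})
            except ValueError:
                pass
    return pd.DataFrame(rows, columns=["test", "variable", "statistic", "p", "n"])
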