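"""qPCR relative copy-number quantification.

Turns raw plate CT measurements into QC-filtered, plate-referenced ddCT
values, removes threshold-CT / batch / concentration effects by linear
regression, and rank-normalizes the residuals into the final copy-number
score used by all downstream association models.

Conventions
-----------
* A *run* is the set of wells sharing ``(plate_id, gene)``.
* ddCT = dCT(RNASEP) - dCT(MT_CYB), where dCT(gene) is the sample's mean
  CT minus the same-plate reference (REF) mean CT for that gene.  Higher
  ddCT therefore means relatively more mitochondrial template.
* An "undetermined" CT is represented as NaN.  For an NTC it counts as
  passing (no amplification); for a sample well it counts as failing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GENES",
    "ROLES",
    "QcReport",
    "VarianceDecomposition",
    "qc_filter",
    "compute_ddct",
    "residualize_cn",
    "inverse_normal_transform",
    "normalize_copy_number",
]

GENES = ("RNASEP", "MT_CYB")
ROLES = ("SAMPLE", "REF", "NTC")

#: QC reason codes
NTC_FAIL = "NTC_FAIL"
SAMPLE_CT_HIGH = "SAMPLE_CT_HIGH"
MISSING_REPLICATE = "MISSING_REPLICATE"


@dataclass
class QcReport:
    """Outcome of :func:`qc_filter`.

    ``discarded`` rows carry (plate_id, gene, sample_id, reason, n_wells);
    ``sample_id`` is empty when a whole run was discarded.
    """

    n_input: int = 0
    n_kept: int = 0
    discarded: list[dict] = field(default_factory=list)

    @property
    def n_discarded(self) -> int:
        return sum(d["n_wells"] for d in self.discarded)

    def to_frame(self) -> pd.DataFrame:
        cols = ["plate_id", "gene", "sample_id", "reason", "n_wells"]
        return pd.DataFrame(self.discarded, columns=cols)


@dataclass
class VarianceDecomposition:
    """Sequential (type-I) variance shares of the ddCT covariate model."""

    terms: list[str]
    shares: dict[str, float]
    pvalues: dict[str, float]
    r_squared: float
    n_used: int
    n_dropped: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "variance_share": [self.shares[t] for t in self.terms],
                "p_value": [self.pvalues[t] for t in self.terms],
            }
        )


def _validate_wells(wells: pd.DataFrame) -> pd.DataFrame:
    required = {"plate_id", "role", "sample_id", "gene", "ct"}
    missing = required - set(wells.columns)
    if missing:
        raise ValueError(f"plate table missing columns: {sorted(missing)}")
    bad_roles = set(wells["role"]) - set(ROLES)
    if bad_roles:
        raise ValueError(f"unknown well roles: {sorted(bad_roles)}")
    return wells


def qc_filter(
    wells: pd.DataFrame,
    ntc_min_ct: float = 38.0,
    sample_max_ct: float = 30.0,
) -> tuple[pd.DataFrame, QcReport]:
    """Apply run-level QC to a plate table.

    A run (all wells of one plate for one gene) is discarded whole when its
    NTC shows amplification at CT <= ``ntc_min_ct`` (NTC_FAIL) or when the
    run has no NTC at all (MISSING_REPLICATE).  Within surviving runs, a
    sample whose wells include any CT >= ``sample_max_ct`` (or an
    undetermined CT) has its wells for that run discarded (SAMPLE_CT_HIGH);
    other samples in the run are unaffected.

    Returns the kept wells (original order preserved) and a
    :class:`QcReport` accounting for every input well.
    """
    wells = _validate_wells(wells)
    report = QcReport(n_input=len(wells))
    drop_idx: set = set()

    for (plate, gene), run in wells.groupby(["plate_id", "gene"], sort=False):
        ntc = run[run["role"] == "NTC"]
        if ntc.empty:
            report.discarded.append(
                {"plate_id": plate, "gene": gene, "sample_id": "",
                 "reason": MISSING_REPLICATE, "n_wells": len(run)}
            )
            drop_idx.update(run.index)
            continue
        # NaN CT in an NTC means no amplification: passes.
        if (ntc["ct"].dropna() <= ntc_min_ct).any():
            report.discarded.append(
                {"plate_id": plate, "gene": gene, "sample_id": "",
                 "reason": NTC_FAIL, "n_wells": len(run)}
            )
            drop_idx.update(run.index)
            continue
        samples = run[run["role"] == "SAMPLE"]
        for sid, sub in samples.groupby("sample_id", sort=False):
            ct = sub["ct"]
            if ct.isna().any() or (ct >= sample_max_ct).any():
                report.discarded.append(
                    {"plate_id": plate, "gene": gene, "sample_id": sid,
                     "reason": SAMPLE_CT_HIGH, "n_wells": len(sub)}
                )
                drop_idx.update(sub.index)

    kept = wells.loc[~wells.index.isin(drop_idx)]
    report.n_kept = len(kept)
    assert report.n_kept + report.n_discarded == report.n_input
    return kept, report


def compute_ddct(
    kept: pd.DataFrame,
    discordance_cycles: float = 1.0,
) -> pd.DataFrame:
    """Compute per-sample ddCT values against each plate's REF wells.

    Replicates are aggregated by arithmetic mean; the plate REF is the mean
    of its triplicate per gene.  Replicate spread above
    ``discordance_cycles`` is flagged (``discordant`` column), not dropped.

    Returns a frame with one row per sample: mean CT and dCT per gene,
    ``ddct`` (= dCT RNASEP - dCT MT_CYB), plate and batch ids.

    Raises
    ------
    ValueError
        If a sample's wells span more than one plate (ambiguous reference)
        or a needed plate lacks a REF triplicate for either gene.
    """
    kept = _validate_wells(kept)
    samples = kept[kept["role"] == "SAMPLE"]
    refs = kept[kept["role"] == "REF"]
    if samples.empty:
        raise ValueError("no sample wells survived QC")

    ref_mean: dict[tuple, float] = {}
    ref_count = refs.groupby(["plate_id", "gene"])["ct"].agg(["mean", "count"])
    for (plate, gene), row in ref_count.iterrows():
        ref_mean[(plate, gene)] = float(row["mean"])
        if row["count"] < 3:
            raise ValueError(
                f"plate {plate} gene {gene}: REF has {int(row['count'])} "
                "wells, triplicate required"
            )

    rows = []
    for sid, sub in samples.groupby("sample_id", sort=False):
        plates = sub["plate_id"].unique()
        if len(plates) > 1:
            raise ValueError(
                f"sample {sid} split across plates {sorted(plates)}: "
                "reference is ambiguous"
            )
        plate = plates[0]
        batch = sub["batch_id"].iloc[0] if "batch_id" in sub.columns else None
        rec: dict = {"sample_id": sid, "plate_id": plate, "batch_id": batch}
        discordant = False
        for gene in GENES:
            cts = sub.loc[sub["gene"] == gene, "ct"]
            if cts.empty:
                rec = None
                break
            if (plate, gene) not in ref_mean:
                raise ValueError(f"plate {plate} has no REF wells for {gene}")
            if len(cts) > 1 and cts.max() - cts.min() > discordance_cycles:
                discordant = True
            mean_ct = float(cts.mean())
            rec[f"ct_{gene}"] = mean_ct
            rec[f"dct_{gene}"] = mean_ct - ref_mean[(plate, gene)]
        if rec is None:
            continue  # sample lost one gene to QC: cannot form ddCT
        rec["ddct"] = rec["dct_RNASEP"] - rec["dct_MT_CYB"]
        rec["discordant"] = discordant
        rows.append(rec)

    if not rows:
        raise ValueError("no sample retained both genes after QC")
    out = pd.DataFrame(rows)
    n_disc = int(out["discordant"].sum())
    if n_disc:
        warnings.warn(
            f"{n_disc} samples have replicate CT spread > "
            f"{discordance_cycles} cycles",
            stacklevel=2,
        )
    return out


def residualize_cn(
    ddct: pd.Series | np.ndarray,
    covariates: pd.DataFrame,
) -> tuple[pd.Series, VarianceDecomposition]:
    """Regress ddCT on ct_threshold + batch + dna_concentration; return
    residuals and a sequential sum-of-squares variance decomposition.

    Covariate columns used (when present): ``ct_threshold`` (numeric),
    ``batch_id`` (categorical; dropped with a warning if fewer than two
    levels), ``dna_concentration`` (numeric).  Shares are type-I sums of
    squares in that fixed order, divided by the total (centered) sum of
    squares; per-term p-values are F-tests against the full-model residual
    mean square.  Rows with any missing value are excluded and counted in
    ``n_dropped``.
    """
    y = pd.Series(np.asarray(ddct, dtype=float), index=covariates.index, name="ddct")
    order = [c for c in ("ct_threshold", "batch_id", "dna_concentration")
             if c in covariates.columns]
    if not order:
        raise ValueError("no recognised covariate columns")

    data = covariates[order].copy()
    data["ddct"] = y
    n_before = len(data)
    data = data.dropna()
    n_dropped = n_before - len(data)
    n = len(data)
    if n < len(order) + 2:
        raise ValueError(f"too few complete rows ({n}) to fit covariate model")

    # Build the design incrementally, term by term, tracking each term's
    # column block for the sequential decomposition.
    yv = data["ddct"].to_numpy()
    blocks: list[tuple[str, np.ndarray]] = []
    for term in order:
        if term == "batch_id":
            levels = pd.unique(data["batch_id"])
            if len(levels) < 2:
                warnings.warn("batch has a single level; term dropped", stacklevel=2)
                blocks.append(("batch_id", np.empty((n, 0))))
                continue
            dummies = pd.get_dummies(data["batch_id"], drop_first=True)
            blocks.append(("batch_id", dummies.to_numpy(dtype=float)))
        else:
            x = data[term].to_numpy(dtype=float)
            if np.ptp(x) == 0:
                warnings.warn(f"covariate {term} is constant; term dropped",
                              stacklevel=2)
                blocks.append((term, np.empty((n, 0))))
            else:
                blocks.append((term, x[:, None]))

    tss = float(np.sum((yv - yv.mean()) ** 2))
    X = np.ones((n, 1))
    rss_prev = tss
    seq_ss: dict[str, float] = {}
    term_df: dict[str, int] = {}
    for term, block in blocks:
        X = np.hstack([X, block])
        beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
        rss = float(np.sum((yv - X @ beta) ** 2))
        seq_ss[term] = rss_prev - rss
        term_df[term] = block.shape[1]
        rss_prev = rss

    rss_full = rss_prev
    df_resid = n - X.shape[1]
    if df_resid <= 0:
        raise ValueError("model saturated: no residual degrees of freedom")
    mse = rss_full / df_resid

    shares, pvals = {}, {}
    for term, _ in blocks:
        if term_df[term] == 0 or tss == 0:
            shares[term] = 0.0
            pvals[term] = float("nan")
            continue
        shares[term] = seq_ss[term] / tss
        f = (seq_ss[term] / term_df[term]) / mse if mse > 0 else np.inf
        pvals[term] = float(stats.f.sf(f, term_df[term], df_resid))

    beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
    resid = pd.Series(yv - X @ beta, index=data.index, name="residual")
    decomp = VarianceDecomposition(
        terms=[t for t, _ in blocks],
        shares=shares,
        pvalues=pvals,
        r_squared=1.0 - rss_full / tss if tss > 0 else 0.0,
        n_used=n,
        n_dropped=n_dropped,
    )
    return resid, decomp


def inverse_normal_transform(values) -> np.ndarray:
    """Rank-based inverse normal (Blom) transform.

    score_i = Phi^-1((rank_i - 3/8) / (n + 1/4)) with average ranks for
    ties, so the result is a monotone function of the input ranks and ties
    map to equal scores.

    Raises ``ValueError`` for fewer than 2 finite values or when all values
    are identical (no ordering information).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D array")
    if x.size < 2:
        raise ValueError("need at least 2 values")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values present")
    if np.ptp(x) == 0:
        raise ValueError("all values identical: ranks carry no information")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 3.0 / 8.0) / (x.size + 0.25))


def normalize_copy_number(
    ddct_table: pd.DataFrame,
    covariates: pd.DataFrame,
) -> tuple[pd.DataFrame, VarianceDecomposition]:
    """Residualize ddCT on technical covariates, then inverse-normal
    transform across the cohort.  Returns the ddCT table with ``residual``
    and ``cn_normalized`` columns added, plus the variance decomposition.
    """
    resid, decomp = residualize_cn(
        ddct_table["ddct"], covariates.loc[ddct_table.index]
    )
    out = ddct_table.loc[resid.index].copy()
    out["residual"] = resid
    out["cn_normalized"] = inverse_normal_transform(resid.to_numpy())
    return out, decomp
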