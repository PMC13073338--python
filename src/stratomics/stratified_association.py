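"""Discovery/replication association, IVW meta-analysis and DEP calling.

For each genotype stratum, samples are split 50/50 into discovery and
replication halves (stratified by case/control status).  Each analyte is
tested per half with logistic regression of AD status on age, sex and the
analyte (Wald two-sided p for the analyte term); the two stage estimates
are pooled with the inverse-variance-weighted fixed-effect model

    w_n = 1 / se_n^2,
    beta_pooled = sum(w_n beta_n) / sum(w_n),
    se_pooled   = sqrt(1 / sum(w_n)),
    chi2_{df=1} = (beta_pooled / se_pooled)^2,

with p_meta the upper tail of chi2 with one degree of freedom.  BH-FDR is
computed over p_meta within each (stratum x omics-type x model) family, and
an analyte is called differentially expressed when

    p_discovery <= alpha  and  p_replication <= alpha  and  FDR <= q
    and sign(beta_discovery) == sign(beta_replication).

Two sensitivity analyses are provided: a linear model with the analyte as
outcome (``analyte ~ status + age + sex``) and a joint analysis pooling
both halves.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .datatypes import DegenerateInputError, StratomicsError

logger = logging.getLogger(__name__)

MAX_ABS_BETA = 50.0   # larger estimates are treated as separation artifacts
MAX_ITER = 100
MIN_SAMPLES = 10


@dataclass
class AssociationResult:
    """Effect of one analyte in one stage under one model family."""

    analyte_id: str
    stratum: str
    stage: str          # discovery | replication | joint
    model: str          # logistic | linear
    beta: float
    se: float
    p: float
    n_used: int
    converged: bool
    reason: str = ""


@dataclass
class MetaResult:
    """IVW-pooled effect for one analyte in one stratum."""

    analyte_id: str
    stratum: str
    beta_pooled: float
    se_pooled: float
    chi2: float
    p_meta: float
    fdr: float = np.nan
    called: bool = False
    direction: str = ""


@dataclass
class ConcordanceSummary:
    """Agreement between two result sets over a matched analyte universe."""

    direction_agreement: float   # over analytes called in set A
    pearson_r_beta: float        # over all analytes finite in both
    r2_neglog10_p: float
    n_called: int
    n_common: int


# ----------------------------------------------------------------------
# Splitting
# ----------------------------------------------------------------------

def split_cohort(meta: pd.DataFrame, seed: int) -> pd.Series:
    """Random 50/50 discovery/replication split stratified by
    (stratum x status); deterministic under ``seed``.

    Within each cell the half sizes differ by at most one (discovery takes
    the extra sample).  Strata with fewer than 2 cases or 2 controls are
    excluded with a warning (label left missing).
    """
    if meta["status"].isna().any() or meta["stratum"].isna().any():
        raise StratomicsError("every sample needs status and stratum")
    rng = np.random.default_rng(seed)
    labels = pd.Series(pd.NA, index=meta.index, dtype="object", name="split")
    for stratum, group in meta.groupby("stratum", sort=True):
        counts = group["status"].value_counts()
        if counts.get("AD", 0) < 2 or counts.get("CO", 0) < 2:
            logger.warning("stratum %r has <2 cases or <2 controls: excluded "
                           "from split", stratum)
            continue
        for _, cell in group.groupby("status", sort=True):
            ids = np.array(sorted(cell.index))
            rng.shuffle(ids)
            half = (len(ids) + 1) // 2
            labels[ids[:half]] = "discovery"
            labels[ids[half:]] = "replication"
    return labels


# ----------------------------------------------------------------------
# Per-analyte fits
# ----------------------------------------------------------------------

def _design(meta: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    y = (meta["status"] == "AD").to_numpy(dtype=float)
    age = meta["age"].to_numpy(dtype=float)
    sex = (meta["sex"] == "M").to_numpy(dtype=float)
    return y, age, sex


def fit_association(values: pd.Series, meta: pd.DataFrame,
                    model: str = "logistic", stratum: str = "",
                    stage: str = "", analyte_id: str | None = None
                    ) -> AssociationResult:
    """Fit one analyte against case/control status, adjusted for age and sex.

    ``logistic``: status ~ age + sex + analyte, Wald two-sided p for the
    analyte term.  ``linear``: analyte ~ status + age + sex, the status
    coefficient is the AD-CO mean difference.  Samples with a missing
    analyte value are dropped casewise.  Non-convergence or separation
    yields ``converged=False`` with missing p.
    """
    analyte_id = analyte_id if analyte_id is not None else str(values.name)
    values = values.reindex(meta.index)
    keep = values.notna()
    x = values[keep].to_numpy(dtype=float)
    sub = meta.loc[keep]
    n_used = len(x)

    def failed(reason: str) -> AssociationResult:
        return AssociationResult(analyte_id, stratum, stage, model,
                                 np.nan, np.nan, np.nan, n_used, False, reason)

    if n_used < MIN_SAMPLES:
        return failed(f"only {n_used} usable samples")
    y, age, sex = _design(sub)
    if y.min() == y.max():
        raise DegenerateInputError(
            f"analyte {analyte_id!r}: only one outcome class present"
        )
    if np.ptp(x) == 0:
        return failed("zero-variance analyte")

    try:
        if model == "logistic":
            X = np.column_stack([np.ones_like(x), age, sex, x])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, X).fit(disp=0, maxiter=MAX_ITER,
                                         warn_convergence=False)
            converged = bool(fit.mle_retvals.get("converged", False))
            beta = float(fit.params[-1])
            se = float(fit.bse[-1])
            p = float(fit.pvalues[-1])
        elif model == "linear":
            X = np.column_stack([np.ones_like(x), y, age, sex])
            fit = sm.OLS(x, X).fit()
            converged = True
            beta = float(fit.params[1])
            se = float(fit.bse[1])
            p = float(fit.pvalues[1])
        else:
            raise StratomicsError(f"unknown model {model!r}")
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
        return failed("separation or singular design")

    if not converged or not np.isfinite(se) or se <= 0 or abs(beta) > MAX_ABS_BETA:
        return failed("did not converge")
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return AssociationResult(analyte_id, stratum, stage, model,
                             beta, se, p, n_used, True)


def fit_stage(matrix_data: pd.DataFrame, meta: pd.DataFrame,
              model: str = "logistic", stratum: str = "",
              stage: str = "") -> pd.DataFrame:
    """Fit every analyte of a matrix against one sample set; one row per
    analyte with beta/se/p/n_used/converged."""
    rows = []
    for analyte in matrix_data.index:
        res = fit_association(matrix_data.loc[analyte], meta, model=model,
                              stratum=stratum, stage=stage, analyte_id=analyte)
        rows.append((res.analyte_id, res.stratum, res.stage, res.model,
                     res.beta, res.se, res.p, res.n_used, res.converged,
                     res.reason))
    return pd.DataFrame(rows, columns=["analyte_id", "stratum", "stage",
                                       "model", "beta", "se", "p", "n_used",
                                       "converged", "reason"])


def joint_analysis(values: pd.Series, meta: pd.DataFrame,
                   model: str = "logistic", stratum: str = "",
                   analyte_id: str | None = None) -> AssociationResult:
    """Pooled fit over all samples of the stratum (stage ``joint``)."""
    return fit_association(values, meta, model=model, stratum=stratum,
                           stage="joint", analyte_id=analyte_id)


# ----------------------------------------------------------------------
# IVW meta-analysis
# ----------------------------------------------------------------------

def ivw_pool(betas: np.ndarray, ses: np.ndarray
             ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized fixed-effect pooling along the last axis.

    Returns (beta_pooled, se_pooled, chi2, p_meta).
    """
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if np.any(ses <= 0):
        raise StratomicsError("IVW pooling needs strictly positive SEs")
    w = 1.0 / ses ** 2
    beta_pooled = (w * betas).sum(axis=-1) / w.sum(axis=-1)
    se_pooled = np.sqrt(1.0 / w.sum(axis=-1))
    chi2 = (beta_pooled / se_pooled) ** 2
    p_meta = stats.chi2.sf(chi2, df=1)
    return beta_pooled, se_pooled, chi2, p_meta


def ivw_meta(discovery: AssociationResult,
             replication: AssociationResult) -> MetaResult:
    """Pool one discovery/replication pair; unconverged input yields a
    missing meta record."""
    if discovery.analyte_id != replication.analyte_id:
        raise StratomicsError("stage results refer to different analytes")
    if not (discovery.converged and replication.converged):
        return MetaResult(discovery.analyte_id, discovery.stratum,
                          np.nan, np.nan, np.nan, np.nan)
    beta, se, chi2, p = ivw_pool(
        np.array([discovery.beta, replication.beta]),
        np.array([discovery.se, replication.se]),
    )
    return MetaResult(discovery.analyte_id, discovery.stratum,
                      float(beta), float(se), float(chi2), float(p))


# ----------------------------------------------------------------------
# Multiple testing and calling
# ----------------------------------------------------------------------

def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment.

    Missing entries are excluded from the family and returned missing;
    values outside (0, 1] raise.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    if pv.size == 0:
        return out
    if np.any((pv <= 0) | (pv > 1)):
        raise StratomicsError("p-values must lie in (0, 1]")
    m = pv.size
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    restored = np.empty(m)
    restored[order] = adjusted
    out[mask] = restored
    return out


def meta_analyze(disc: pd.DataFrame, rep: pd.DataFrame,
                 alpha: float = 0.05, fdr_threshold: float = 0.05
                 ) -> pd.DataFrame:
    """Pool per-analyte discovery/replication tables, attach BH-FDR over the
    meta p-values (the table is one FDR family) and apply the calling rule.

    Returns one row per analyte with stage and pooled statistics; analytes
    unconverged in either stage carry missing pooled fields and are never
    called.
    """
    merged = disc.merge(rep, on="analyte_id", suffixes=("_disc", "_rep"))
    ok = merged["converged_disc"] & merged["converged_rep"]
    beta = np.full(len(merged), np.nan)
    se = np.full(len(merged), np.nan)
    chi2 = np.full(len(merged), np.nan)
    p_meta = np.full(len(merged), np.nan)
    if ok.any():
        b = merged.loc[ok, ["beta_disc", "beta_rep"]].to_numpy()
        s = merged.loc[ok, ["se_disc", "se_rep"]].to_numpy()
        beta[ok], se[ok], chi2[ok], p_meta[ok] = ivw_pool(b, s)
    result = pd.DataFrame({
        "analyte_id": merged["analyte_id"],
        "stratum": merged["stratum_disc"],
        "model": merged["model_disc"],
        "beta_disc": merged["beta_disc"], "se_disc": merged["se_disc"],
        "p_disc": merged["p_disc"],
        "beta_rep": merged["beta_rep"], "se_rep": merged["se_rep"],
        "p_rep": merged["p_rep"],
        "beta": beta, "se": se, "chi2": chi2, "p": p_meta,
    })
    result["fdr"] = bh_fdr(result["p"].to_numpy())
    return call_analytes(result, alpha=alpha, fdr_threshold=fdr_threshold)


def call_analytes(meta_results: pd.DataFrame, alpha: float = 0.05,
                  fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Apply the DEP/DEM rule: discovery and replication p <= alpha, FDR <=
    threshold, and stage effect signs agree.  ``direction`` follows the
    pooled effect's sign."""
    out = meta_results.copy()
    sign_ok = np.sign(out["beta_disc"]) == np.sign(out["beta_rep"])
    out["called"] = ((out["p_disc"] <= alpha)
                     & (out["p_rep"] <= alpha)
                     & (out["fdr"] <= fdr_threshold)
                     & sign_ok).fillna(False).astype(bool)
    out["direction"] = np.where(out["beta"] > 0, "up",
                                np.where(out["beta"] < 0, "down", ""))
    return out


# ----------------------------------------------------------------------
# Sensitivity concordance
# ----------------------------------------------------------------------

def sensitivity_concordance(set_a: pd.DataFrame,
                            set_b: pd.DataFrame) -> ConcordanceSummary:
    """Agreement between two result tables sharing an analyte universe.

    Direction agreement is computed over analytes called in ``set_a``;
    Pearson r of betas and R^2 of -log10 p over all analytes finite in
    both.  Requires >= 3 common analytes.
    """
    a = set_a.set_index("analyte_id")
    b = set_b.set_index("analyte_id")
    common = a.index.intersection(b.index)
    if len(common) < 3:
        raise DegenerateInputError(
            f"only {len(common)} common analytes: concordance undefined"
        )
    a, b = a.loc[common], b.loc[common]
    finite = (np.isfinite(a["beta"]) & np.isfinite(b["beta"])
              & np.isfinite(a["p"]) & np.isfinite(b["p"]))
    r = float(np.corrcoef(a.loc[finite, "beta"], b.loc[finite, "beta"])[0, 1])
    lp_a = -np.log10(a.loc[finite, "p"].to_numpy())
    lp_b = -np.log10(b.loc[finite, "p"].to_numpy())
    r2 = float(np.corrcoef(lp_a, lp_b)[0, 1] ** 2)
    if "called" in a.columns and a["called"].any():
        called = a.index[a["called"].fillna(False).astype(bool)]
        ok = (np.isfinite(a.loc[called, "beta"])
              & np.isfinite(b.loc[called, "beta"]))
        called = called[ok]
        agree = np.sign(a.loc[called, "beta"]) == np.sign(b.loc[called, "beta"])
        agreement = float(agree.mean()) if len(called) else np.nan
        n_called = int(len(called))
    else:
        agreement, n_called = np.nan, 0
    return ConcordanceSummary(direction_agreement=agreement,
                              pearson_r_beta=r, r2_neglog10_p=r2,
                              n_called=n_called, n_common=int(finite.sum()))
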