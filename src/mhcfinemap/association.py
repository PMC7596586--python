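"""Additive-dosage logistic association, omnibus and conditional tests.

The model throughout is binomial logistic regression: case/control status
on an intercept, the allele dosage(s) of interest, and covariates (by
default age, age squared, BMI and the top 20 principal components), with
additive allelic effects on the log-odds scale.

Three tests are exposed:

* per-marker Wald test of the dosage coefficient (biallelic scan);
* the omnibus test of a multiallelic amino-acid position: deviance of the
  covariates-only null against the model with the position's m residue
  dosages (m - 1 free columns, most frequent residue as reference),
  referred to a chi-squared distribution with m - 1 degrees of freedom;
* conditional versions of both, with lead-variant dosages appended to
  every design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.special import expit, log_expit
from scipy.stats import chi2, norm

from .data import DosageMatrix

__all__ = [
    "ModelFit",
    "AssocRecord",
    "OmnibusRecord",
    "DEFAULT_COVARIATES",
    "GENOME_WIDE_P",
    "Z95",
    "fit_logistic",
    "build_covariate_design",
    "single_variant_scan",
    "omnibus_position_test",
    "omnibus_scan",
    "conditional_scan",
    "select_lead",
]

#: genome-wide significance threshold (strict inequality).
GENOME_WIDE_P = 5.0e-8
#: fixed normal quantile for 95% CIs, so output reproduces bit for bit.
Z95 = 1.959964
DEFAULT_COVARIATES = ("age", "age2", "bmi") + tuple(f"pc{k}" for k in range(1, 21))

_MAX_ABS_BETA = 15.0   # quasi-separation guards
_MAX_SE = 100.0


@dataclass
class ModelFit:
    """A converged (or flagged) logistic fit.

    ``params``/``cov`` are indexed by retained design columns; columns
    dropped for rank deficiency are listed in ``dropped``.
    """

    params: pd.Series
    cov: pd.DataFrame
    loglik: float
    converged: bool
    n_iter: int
    n: int
    rank: int
    dropped: list[str] = field(default_factory=list)

    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov.to_numpy())), index=self.params.index)


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # sum y*eta - log(1 + exp(eta)), stable for large |eta|
    return float(np.sum(y * eta + log_expit(-eta)))


def fit_logistic(y, X: pd.DataFrame, max_iter: int = 100,
                 ll_tol: float = 1e-10, grad_tol: float = 1e-6) -> ModelFit:
    """Maximum-likelihood logistic fit by iteratively reweighted least squares.

    The design must include an intercept column. Rows with any missing
    value are dropped listwise. Rank-deficient designs are repaired by
    pivoted QR: dependent columns are removed and recorded in ``dropped``.
    Convergence requires relative log-likelihood change below ``ll_tol``
    and gradient max-norm below ``grad_tol``. Quasi-separated fits (any
    |beta| > 15 or SE > 100) are returned with ``converged=False``.
    """
    y = np.asarray(y, dtype=float)
    Xv = X.to_numpy(dtype=float)
    keep_rows = ~(np.isnan(Xv).any(axis=1) | np.isnan(y))
    y, Xv = y[keep_rows], Xv[keep_rows]
    n = len(y)

    # pivoted QR to detect and drop linearly dependent columns
    _, R, piv = linalg.qr(Xv, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(Xv.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    kept_idx = np.sort(piv[:rank])
    dropped = [X.columns[j] for j in piv[rank:]]
    Xv = Xv[:, kept_idx]
    names = [X.columns[j] for j in kept_idx]

    beta = np.zeros(Xv.shape[1])
    eta = Xv @ beta
    ll = _loglik(y, eta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        XtW = Xv.T * w
        try:
            beta = np.linalg.solve(XtW @ Xv, XtW @ z)
        except np.linalg.LinAlgError:
            break
        eta = Xv @ beta
        ll_new = _loglik(y, eta)
        grad = Xv.T @ (y - expit(eta))
        if abs(ll_new - ll) <= ll_tol * (abs(ll_new) + 1.0) and np.abs(grad).max() < grad_tol:
            converged = True
            ll = ll_new
            break
        ll = ll_new

    mu = expit(eta)
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    info = (Xv.T * w) @ Xv
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((Xv.shape[1], Xv.shape[1]), np.nan)
        converged = False
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    if np.abs(beta).max(initial=0.0) > _MAX_ABS_BETA or se.max(initial=0.0) > _MAX_SE:
        converged = False
    return ModelFit(
        params=pd.Series(beta, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        loglik=ll, converged=converged, n_iter=it, n=n, rank=rank, dropped=dropped,
    )


def build_covariate_design(cohort: pd.DataFrame,
                           covariates=DEFAULT_COVARIATES) -> pd.DataFrame:
    """Intercept + named covariate columns; ``age2`` is derived from age."""
    design = pd.DataFrame({"intercept": np.ones(len(cohort))}, index=cohort.index)
    for name in covariates:
        if name == "age2" and "age2" not in cohort.columns:
            design["age2"] = cohort["age"].to_numpy() ** 2
        elif name in cohort.columns:
            design[name] = cohort[name].to_numpy()
        else:
            raise KeyError(f"covariate {name!r} not in cohort table")
    return design


@dataclass
class AssocRecord:
    """Per-marker additive-dosage Wald result."""

    marker: str
    beta: float
    se: float
    or_: float
    ci_low: float
    ci_high: float
    p: float
    p_lrt: float
    n: int
    converged: bool
    flag: str = ""


@dataclass
class OmnibusRecord:
    """Deviance test of one multiallelic amino-acid position."""

    position: str
    m: int
    df: int
    deviance: float
    p: float
    n: int
    converged: bool
    flag: str = ""


def _records_frame(records) -> pd.DataFrame:
    df = pd.DataFrame([r.__dict__ for r in records])
    key = "marker" if records and isinstance(records[0], AssocRecord) else "position"
    return df.set_index(key) if len(df) else df


def _condition_columns(dosages: DosageMatrix, condition_on) -> pd.DataFrame:
    cols = {}
    for cid in condition_on:
        if cid not in dosages.variant_ids:
            raise KeyError(f"conditioned marker {cid!r} not in marker table")
        cols[f"cond_{cid}"] = dosages.dosages[cid].to_numpy()
    return pd.DataFrame(cols, index=dosages.sample_ids)


def single_variant_scan(dosages: DosageMatrix, cohort: pd.DataFrame,
                        covariates=DEFAULT_COVARIATES,
                        condition_on=(), marker_ids=None) -> pd.DataFrame:
    """Additive logistic Wald scan of each biallelic marker.

    Fits status ~ intercept + dosage + covariates (+ conditioned dosages)
    per marker. Markers whose fit fails or whose dosage is constant are
    emitted flagged, never silently dropped. Conditioning a scan on a
    marker flags that marker's own record ``self_conditioned``.
    """
    cohort = cohort.loc[dosages.sample_ids]
    y = cohort["status"].to_numpy(dtype=float)
    base = build_covariate_design(cohort, covariates)
    cond = _condition_columns(dosages, condition_on)
    if len(cond.columns):
        base = pd.concat([base, cond], axis=1)
    null_fit = fit_logistic(y, base)
    records = []
    ids = list(marker_ids) if marker_ids is not None else list(dosages.variant_ids)
    for vid in ids:
        d = dosages.dosages[vid].to_numpy(dtype=float)
        flag = ""
        if vid in condition_on:
            flag = "self_conditioned"
        if np.nanvar(d) == 0.0:
            records.append(AssocRecord(vid, np.nan, np.nan, np.nan, np.nan, np.nan,
                                       np.nan, np.nan, len(y), False,
                                       (flag + ";" if flag else "") + "monomorphic"))
            continue
        X = base.copy()
        X.insert(1, "dosage", d)
        fit = fit_logistic(y, X)
        if "dosage" not in fit.params.index:
            records.append(AssocRecord(vid, np.nan, np.nan, np.nan, np.nan, np.nan,
                                       np.nan, np.nan, fit.n, False,
                                       (flag + ";" if flag else "") + "collinear"))
            continue
        beta = float(fit.params["dosage"])
        se = float(fit.se()["dosage"])
        p = 2.0 * norm.sf(abs(beta / se)) if se > 0 else np.nan
        dev = max(2.0 * (fit.loglik - null_fit.loglik), 0.0)
        p_lrt = float(chi2.sf(dev, 1))
        with np.errstate(over="ignore"):  # separated fits may give inf bounds
            or_, lo, hi = np.exp([beta, beta - Z95 * se, beta + Z95 * se])
        records.append(AssocRecord(
            vid, beta, se, float(or_), float(lo), float(hi),
            float(p), p_lrt, fit.n, fit.converged, flag,
        ))
    return _records_frame(records)


def omnibus_position_test(dosages: DosageMatrix, group: list[str],
                          cohort: pd.DataFrame, position: str,
                          covariates=DEFAULT_COVARIATES,
                          condition_on=()) -> OmnibusRecord:
    """Deviance test of one amino-acid position with m residue markers.

    Null: intercept + covariates (+ conditioned dosages). Full: null plus
    the m - 1 residue dosage columns after dropping the most frequent
    residue as reference. Deviance = 2 (ll_full - ll_null) is referred to
    chi-squared with df equal to the rank of the added block (m - 1 when
    the residues are linearly independent of the null design; reductions
    are flagged).
    """
    if len(group) < 2:
        raise ValueError("omnibus group needs m >= 2 residues")
    cohort = cohort.loc[dosages.sample_ids]
    y = cohort["status"].to_numpy(dtype=float)
    base = build_covariate_design(cohort, covariates)
    cond = _condition_columns(dosages, condition_on)
    if len(cond.columns):
        base = pd.concat([base, cond], axis=1)
    means = {g: float(np.nanmean(dosages.dosages[g])) for g in group}
    reference = max(sorted(group), key=lambda g: means[g])
    added = [g for g in sorted(group) if g != reference]
    full = pd.concat(
        [base, dosages.dosages[added].astype(float)], axis=1
    )
    null_fit = fit_logistic(y, base)
    full_fit = fit_logistic(y, full)
    kept_added = [c for c in added if c in full_fit.params.index]
    df = len(kept_added)
    flag = "" if df == len(added) else "rank_reduced"
    if df == 0:
        return OmnibusRecord(position, len(group), 0, 0.0, np.nan,
                             full_fit.n, False, "untestable")
    deviance = 2.0 * (full_fit.loglik - null_fit.loglik)
    if deviance < -1e-8:
        flag = (flag + ";" if flag else "") + "negative_deviance"
    deviance = max(deviance, 0.0)
    p = float(chi2.sf(deviance, df))
    return OmnibusRecord(position, len(group), df, deviance, p,
                         full_fit.n, null_fit.converged and full_fit.converged, flag)


def omnibus_scan(dosages: DosageMatrix, groups: dict[str, list[str]],
                 cohort: pd.DataFrame, covariates=DEFAULT_COVARIATES,
                 condition_on=()) -> pd.DataFrame:
    """Omnibus test of every amino-acid position group."""
    records = [
        omnibus_position_test(dosages, members, cohort, pos, covariates, condition_on)
        for pos, members in groups.items()
    ]
    return _records_frame(records)


def conditional_scan(dosages: DosageMatrix, cohort: pd.DataFrame,
                     condition_on, covariates=DEFAULT_COVARIATES,
                     groups: dict[str, list[str]] | None = None,
                     marker_ids=None) -> dict[str, pd.DataFrame]:
    """Re-run the biallelic (and optionally omnibus) scans conditioned on leads.

    Identical to the unconditional scans with the conditioned marker
    dosages appended to every null and full design.
    """
    out = {"assoc": single_variant_scan(dosages, cohort, covariates,
                                        condition_on=tuple(condition_on),
                                        marker_ids=marker_ids)}
    if groups:
        out["omnibus"] = omnibus_scan(dosages, groups, cohort, covariates,
                                      condition_on=tuple(condition_on))
    return out


def select_lead(records: pd.DataFrame) -> str:
    """Lead marker: minimum p among converged records.

    Ties broken by larger |beta|, then lexicographically smaller id;
    deterministic. Raises if no converged record exists.
    """
    ok = records[records["converged"] & records["p"].notna()]
    if len(ok) == 0:
        raise ValueError("no converged association records")
    ranked = sorted(
        ok.index,
        key=lambda m: (ok.at[m, "p"], -abs(ok.at[m, "beta"]), str(m)),
    )
    return str(ranked[0])
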