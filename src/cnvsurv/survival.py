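"""Left-truncated Cox proportional-hazards regression on the age timescale.

The partial likelihood uses delayed entry (a subject is in the risk set at
age t only when entry_age < t <= exit_age), Efron's correction for tied
death ages, Newton-Raphson maximization (tolerance 1e-9 on the score norm),
and an optional cluster-robust (Lin-Wei sandwich) variance for familial
clustering. The risk-set bookkeeping is a single ascending sweep over death
ages with incremental add/remove of subjects, so fits scale as
O((n + deaths) * p^2).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import Z95

__all__ = [
    "AssocResult",
    "DegenerateCovariateError",
    "ConvergenceError",
    "cox_partial_loglik",
    "fit_cox",
    "test_regions",
]

logger = logging.getLogger(__name__)


class DegenerateCovariateError(ValueError):
    """Raised when a covariate carries no information (constant/collinear)."""


class ConvergenceError(RuntimeError):
    """Raised when Newton-Raphson fails to converge."""


@dataclass(frozen=True)
class AssocResult:
    """Hazard-ratio estimate for one exposure term with Wald precision."""

    term: str
    log_hr: float
    se_log_hr: float
    hr: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    n_events: int

    @classmethod
    def from_estimate(cls, term: str, log_hr: float, se: float, n: int,
                      n_events: int) -> "AssocResult":
        z = log_hr / se
        return cls(
            term=term, log_hr=float(log_hr), se_log_hr=float(se),
            hr=float(np.exp(log_hr)),
            ci_low=float(np.exp(log_hr - Z95 * se)),
            ci_high=float(np.exp(log_hr + Z95 * se)),
            p=float(2.0 * stats.norm.sf(abs(z))),
            n=int(n), n_events=int(n_events),
        )


# ---------------------------------------------------------------------------
# partial-likelihood machinery
# ---------------------------------------------------------------------------

def _risk_index(entry, exit_, event):
    """Death ages and per-subject join/leave indices into that grid."""
    death_times = np.unique(exit_[event == 1])
    join = np.searchsorted(death_times, entry, side="right")
    leave = np.searchsorted(death_times, exit_, side="right")
    return death_times, join, leave


def _buckets(idx, K):
    order = np.argsort(idx, kind="stable")
    svals = idx[order]
    bounds = np.searchsorted(svals, np.arange(K + 1))
    return [order[bounds[k]:bounds[k + 1]] for k in range(K)]


def _sweep(beta, X, entry, exit_, event, want="llgh"):
    """One pass over death ages.

    ``want``: "ll" (log-likelihood only), "llgh" (plus gradient/Hessian), or
    "resid" (score residuals at ``beta``).
    """
    n, p = X.shape
    eta = X @ beta
    w = np.exp(eta)
    death_times, join, leave = _risk_index(entry, exit_, event)
    K = death_times.size
    active = join < leave  # ever at risk at a death age
    joiners = _buckets(np.where(active, join, K), K)
    leavers = _buckets(np.where(active, leave, K + 1), K)
    ev = event == 1
    death_k = np.full(n, -1)
    death_k[ev] = np.searchsorted(death_times, exit_[ev])
    deaths = _buckets(np.where(ev, death_k, K), K)

    S = 0.0
    Sx = np.zeros(p)
    Sxx = np.zeros((p, p))
    ll = 0.0
    g = np.zeros(p)
    H = np.zeros((p, p))
    if want == "resid":
        a_k = np.zeros(K)
        b_k = np.zeros((K, p))
        fa_k = np.zeros(K)
        fb_k = np.zeros((K, p))
        mbar_k = np.zeros((K, p))

    need_xx = want == "llgh"
    for k in range(K):
        rm = leavers[k]
        if rm.size:
            wr = w[rm]
            S -= wr.sum()
            Sx -= wr @ X[rm]
            if need_xx:
                Sxx -= X[rm].T @ (wr[:, None] * X[rm])
        ad = joiners[k]
        if ad.size:
            wa = w[ad]
            S += wa.sum()
            Sx += wa @ X[ad]
            if need_xx:
                Sxx += X[ad].T @ (wa[:, None] * X[ad])
        D = deaths[k]
        m = D.size
        if m == 0:
            continue
        wD = w[D]
        XD = X[D]
        SD = wD.sum()
        SxD = wD @ XD
        SxxD = XD.T @ (wD[:, None] * XD) if need_xx else None
        ll += eta[D].sum()
        if want != "ll":
            g += XD.sum(axis=0)
        xbars = np.zeros((m, p))
        for l in range(m):
            f = l / m
            Sl = S - f * SD
            Sxl = Sx - f * SxD
            xbar = Sxl / Sl
            xbars[l] = xbar
            ll -= np.log(Sl)
            if want == "llgh":
                g -= xbar
                H -= (Sxx - f * SxxD) / Sl - np.outer(xbar, xbar)
            elif want == "resid":
                a_k[k] += 1.0 / Sl
                b_k[k] += xbar / Sl
                fa_k[k] += f / Sl
                fb_k[k] += f * xbar / Sl
        if want == "resid":
            mbar_k[k] = xbars.mean(axis=0)

    if want == "ll":
        return ll
    if want == "llgh":
        return ll, g, H
    # score residuals
    cumA = np.concatenate([[0.0], np.cumsum(a_k)])
    cumB = np.vstack([np.zeros(p), np.cumsum(b_k, axis=0)])
    U = np.zeros((n, p))
    j0 = np.where(active, join, 0)
    j1 = np.where(active, leave, 0)
    CA = cumA[j1] - cumA[j0]
    CB = cumB[j1] - cumB[j0]
    U -= w[:, None] * (X * CA[:, None] - CB)
    di = np.where(ev)[0]
    kd = death_k[di]
    U[di] += X[di] - mbar_k[kd]
    U[di] += (w[di] * fa_k[kd])[:, None] * X[di] - w[di][:, None] * fb_k[kd]
    return U


def cox_partial_loglik(beta, X, entry, exit_, event) -> float:
    """Efron partial log-likelihood with delayed entry at coefficient ``beta``."""
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != np.asarray(exit_).shape[0]:
        X = X.T
    beta = np.atleast_1d(np.asarray(beta, float))
    return float(_sweep(beta, X, np.asarray(entry, float), np.asarray(exit_, float),
                        np.asarray(event, int), want="ll"))


def _newton(X, entry, exit_, event, tol=1e-9, max_iter=100):
    p = X.shape[1]
    beta = np.zeros(p)
    ll, g, H = _sweep(beta, X, entry, exit_, event)
    for _ in range(max_iter):
        if np.max(np.abs(g)) < tol:
            return beta, ll, H
        try:
            delta = np.linalg.solve(-H, g)
        except np.linalg.LinAlgError as e:
            raise DegenerateCovariateError(f"singular information matrix: {e}") from e
        step = 1.0
        for _ in range(40):
            cand = beta + step * delta
            ll_new = _sweep(cand, X, entry, exit_, event, want="ll")
            if ll_new >= ll - 1e-12:
                break
            step /= 2.0
        else:
            raise ConvergenceError("line search failed (log-likelihood not improving)")
        beta = beta + step * delta
        ll, g, H = _sweep(beta, X, entry, exit_, event)
        # the score norm can floor above tol in float64 for large n; a
        # vanishing Newton step means the optimum is resolved to precision
        if np.max(np.abs(step * delta)) < 1e-10 * (1.0 + np.max(np.abs(beta))):
            return beta, ll, H
    if np.max(np.abs(g)) < tol:
        return beta, ll, H
    raise ConvergenceError(
        f"Newton-Raphson did not converge in {max_iter} iterations "
        f"(score norm {np.max(np.abs(g)):.3g})"
    )


# ---------------------------------------------------------------------------
# public fitting API
# ---------------------------------------------------------------------------

def _build_design(data: pd.DataFrame, exposure: str, adjustments: Sequence[str]):
    """Numeric design matrix: exposure first, categorical adjustments dummied."""
    cols = [exposure, *adjustments]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise KeyError(f"columns missing from data: {missing}")
    parts = []
    x = pd.to_numeric(data[exposure], errors="raise").astype(float)
    parts.append(x.rename(exposure))
    for col in adjustments:
        s = data[col]
        if pd.api.types.is_numeric_dtype(s) or pd.api.types.is_bool_dtype(s):
            parts.append(s.astype(float).rename(col))
        else:
            cat = pd.Categorical(s.astype(str), categories=sorted(s.astype(str).unique()))
            dummies = pd.get_dummies(
                pd.Series(cat, index=s.index), prefix=col, drop_first=True, dtype=float
            )
            for c in dummies.columns:
                # near-empty strata separate the partial likelihood; collapse
                # categories with < 2 subjects on either side into the reference
                if min(dummies[c].sum(), len(dummies) - dummies[c].sum()) < 2:
                    logger.info("collapsing rare category column %s into reference", c)
                    continue
                parts.append(dummies[c])
    X = pd.concat(parts, axis=1)
    # constant exposure is an error; constant adjustment columns are dropped
    if X[exposure].nunique() <= 1:
        raise DegenerateCovariateError(f"exposure {exposure!r} is constant")
    keep = [exposure] + [c for c in X.columns[1:] if X[c].nunique() > 1]
    dropped = [c for c in X.columns if c not in keep]
    if dropped:
        logger.info("dropping constant adjustment columns: %s", dropped)
    return X[keep]


def fit_cox(
    data: pd.DataFrame,
    exposure: str,
    adjustments: Sequence[str] = (),
    cluster: str | None = None,
    entry_col: str = "entry_age",
    exit_col: str = "exit_age",
    event_col: str = "event",
    tol: float = 1e-9,
    max_iter: int = 100,
) -> AssocResult:
    """Fit the delayed-entry Cox model and report the exposure term.

    When ``cluster`` names a grouping column, the standard error is the
    cluster-robust sandwich estimate; otherwise it is the model-based
    inverse-information standard error.
    """
    used = [entry_col, exit_col, event_col, exposure, *adjustments]
    if cluster:
        used.append(cluster)
    df = data[list(dict.fromkeys(used))].dropna()
    if df.empty:
        raise ValueError("no complete-case rows to fit")
    entry = df[entry_col].to_numpy(float)
    exit_ = df[exit_col].to_numpy(float)
    event = df[event_col].to_numpy(int)
    if np.any(entry >= exit_):
        raise ValueError("entry age must be strictly below exit age for all rows")
    if event.sum() < 1:
        raise ValueError("no events in the data")
    Xdf = _build_design(df, exposure, adjustments)
    X = Xdf.to_numpy(float)
    center = X.mean(axis=0)
    Xc = X - center  # centering leaves beta unchanged, stabilizes exp()

    beta, ll, H = _newton(Xc, entry, exit_, event, tol=tol, max_iter=max_iter)
    info = -H
    cov = np.linalg.inv(info)
    if cluster:
        U = _sweep(beta, Xc, entry, exit_, event, want="resid")
        groups = pd.factorize(df[cluster].astype(str))[0]
        Ug = np.zeros((groups.max() + 1, X.shape[1]))
        np.add.at(Ug, groups, U)
        cov = cov @ (Ug.T @ Ug) @ cov
    se = float(np.sqrt(cov[0, 0]))
    return AssocResult.from_estimate(
        term=exposure, log_hr=float(beta[0]), se=se,
        n=len(df), n_events=int(event.sum()),
    )


def test_regions(
    carriers: pd.DataFrame,
    data: pd.DataFrame,
    adjustments: Sequence[str] = (),
    cluster: str | None = None,
    sex_subset: str | None = None,
    sex_col: str = "sex",
    **fit_kwargs,
) -> pd.DataFrame:
    """One carrier-vs-noncarrier Cox fit per region, sorted by p-value.

    ``carriers`` is the binary samples x regions matrix (indexed by sample
    id) aligned to phenotype ``data`` via its ``sample_id`` column.
    ``sex_subset`` restricts to one sex and drops the sex adjustment
    (sex-stratified run). Regions with zero carriers among analyzable
    samples are skipped with a log entry.
    """
    pheno = data.set_index("sample_id") if "sample_id" in data.columns else data
    common = [s for s in carriers.index if s in pheno.index]
    missing = [s for s in carriers.index if s not in pheno.index]
    if missing:
        raise ValueError(f"samples absent from phenotype table: {missing}")
    merged = pheno.loc[common].copy()
    if sex_subset is not None:
        keep = merged[sex_col].astype(str) == sex_subset
        merged = merged[keep]
        adjustments = [a for a in adjustments if a != sex_col]
    rows = []
    for region_id in carriers.columns:
        x = carriers.loc[merged.index, region_id]
        if int(x.sum()) == 0:
            logger.warning("region %s: no carriers among analyzable samples; skipped",
                           region_id)
            continue
        dfr = merged.copy()
        dfr["__carrier__"] = x.to_numpy(float)
        res = fit_cox(dfr.reset_index(), "__carrier__", adjustments,
                      cluster=cluster, **fit_kwargs)
        rows.append({
            "region_id": region_id, "n_carriers": int(x.sum()),
            "frequency": float(x.mean()),
            "log_hr": res.log_hr, "se_log_hr": res.se_log_hr, "hr": res.hr,
            "ci_low": res.ci_low, "ci_high": res.ci_high, "p": res.p,
            "n": res.n, "n_events": res.n_events,
        })
    out = pd.DataFrame(rows)
    if not out.empty:
        out = out.sort_values("p", kind="stable").reset_index(drop=True)
    return out
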