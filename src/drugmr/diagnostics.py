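"""Heterogeneity and pleiotropy diagnostics, leave-one-out analysis,
statistical power, Benjamini-Hochberg FDR and meta-analytic pooling."""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .datatypes import DiagnosticsReport, HarmonizedInstrumentSet, MetaResult, MREstimate
from .errors import DomainError, InsufficientInstrumentsError, ScaleMismatchError
from .estimators import (
    EggerEstimator,
    IVWEstimator,
    InstrumentData,
    _Z975,
    _extract,
)

logger = logging.getLogger(__name__)


def cochran_q(X: InstrumentData) -> tuple[float, int, float]:
    """Cochran heterogeneity statistic over per-SNP Wald ratios.

    Q = sum_j w_j (r_j - beta_ivw_fixed)^2 compared to a chi-square with
    k - 1 degrees of freedom.  Q = 0 iff all ratios are equal.
    """
    bx, sx, by, sy, ids = _extract(X)
    if len(bx) < 2:
        raise InsufficientInstrumentsError(
            "Cochran Q needs >= 2 SNPs", n_selected=len(bx)
        )
    est = IVWEstimator(effects_model="fixed").fit(X)
    return est.q_, est.q_df_, est.q_p_


def egger_intercept_test(X: InstrumentData) -> tuple[float, float, float]:
    """MR-Egger intercept, its SE and its t-based p-value (k-2 df).

    A non-zero intercept is evidence of directional horizontal pleiotropy.
    """
    est = EggerEstimator().fit(X)
    return est.intercept_, est.intercept_se_, est.intercept_p_


def leave_one_out(
    X: HarmonizedInstrumentSet, effects_model: str = "auto", alpha: float = 0.05
) -> pd.DataFrame:
    """Re-estimate (IVW) after omitting each instrumental SNP in turn.

    Flags a SNP as influential when its omission flips the sign of the IVW
    estimate or moves the p-value across ``alpha``.  Returns one row per
    left-out SNP: variant_id, beta, se, pvalue, influential.
    """
    k = X.k
    if k < 2:
        raise InsufficientInstrumentsError(
            "leave-one-out needs >= 2 SNPs", n_selected=k
        )
    full = IVWEstimator(effects_model=effects_model).fit(X)
    rows = []
    for j in range(k):
        mask = np.ones(k, dtype=bool)
        mask[j] = False
        sub = IVWEstimator(effects_model=effects_model).fit(X.subset(mask))
        influential = (np.sign(sub.beta_) != np.sign(full.beta_)) or (
            (sub.pvalue_ < alpha) != (full.pvalue_ < alpha)
        )
        rows.append(
            {
                "variant_id": X.table["variant_id"].iloc[j],
                "beta": sub.beta_,
                "se": sub.se_,
                "pvalue": sub.pvalue_,
                "influential": bool(influential),
            }
        )
    return pd.DataFrame(rows)


def mr_power(
    n_outcome: float,
    r2_exposure: float,
    beta_true: float,
    alpha: float = 0.05,
    outcome_type: str = "continuous",
    case_fraction: Optional[float] = None,
) -> float:
    """Approximate power of the two-sample MR test.

    Uses the non-centrality-parameter normal approximation: for a continuous
    outcome lambda = |beta| * sqrt(N * R2); for a binary outcome (beta on the
    log-odds scale) lambda = |beta| * sqrt(N * R2 * K * (1-K)) with K the
    case fraction.  Power = 1 - Phi(z_{1-a/2} - lambda) + Phi(-z_{1-a/2} - lambda).
    """
    if not (0.0 < r2_exposure < 1.0):
        raise DomainError("r2_exposure must lie in (0, 1)")
    if n_outcome <= 0:
        raise DomainError("n_outcome must be positive")
    if not (0.0 < alpha < 1.0):
        raise DomainError("alpha must lie in (0, 1)")
    if outcome_type == "continuous":
        lam = abs(beta_true) * np.sqrt(n_outcome * r2_exposure)
    elif outcome_type == "binary":
        if case_fraction is None or not (0.0 < case_fraction < 1.0):
            raise DomainError("binary outcomes require case_fraction in (0, 1)")
        lam = abs(beta_true) * np.sqrt(
            n_outcome * r2_exposure * case_fraction * (1.0 - case_fraction)
        )
    else:
        raise DomainError(f"unknown outcome_type {outcome_type!r}")
    z = sps.norm.ppf(1.0 - alpha / 2.0)
    return float(sps.norm.sf(z - lam) + sps.norm.cdf(-z - lam))


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg q-values (step-up FDR adjustment).

    q_(i) = min_{j >= i} p_(j) * m / j on the sorted scale, mapped back to
    the input order.  Input p-values must lie in (0, 1].
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        raise DomainError("bh_fdr: empty p-value list")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise DomainError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def meta_combine(
    estimates: Iterable[MREstimate], model: str = "auto"
) -> MetaResult:
    """Pool several MR estimates of the same quantity.

    ``fixed`` weights each estimate by 1/se^2; ``random`` adds the
    DerSimonian-Laird between-study variance
    tau2 = max(0, (Q - (m-1)) / (sum w - sum w^2 / sum w)) to every
    variance; ``auto`` chooses random iff the meta-heterogeneity Q has
    p < 0.05.  Estimates must share a scale (beta vs log-OR).
    """
    ests = list(estimates)
    if not ests:
        raise DomainError("meta_combine: no estimates")
    scales = {e.scale for e in ests}
    if len(scales) > 1:
        raise ScaleMismatchError(f"mixed estimate scales: {sorted(scales)}")
    if model not in ("fixed", "random", "auto"):
        raise DomainError(f"unknown meta model {model!r}")
    b = np.array([e.beta for e in ests], float)
    v = np.array([e.se for e in ests], float) ** 2
    m = len(ests)
    if m == 1:
        logger.info("meta_combine: single estimate, passing through")
        e = ests[0]
        return MetaResult(
            model="fixed",
            beta=e.beta,
            se=e.se,
            ci_low=e.ci_low,
            ci_high=e.ci_high,
            pvalue=e.pvalue,
            tau2=0.0,
            q=0.0,
            q_p=1.0,
            n_studies=1,
        )

    w = 1.0 / v
    beta_f = float(np.sum(w * b) / np.sum(w))
    q = float(np.sum(w * (b - beta_f) ** 2))
    q_p = float(sps.chi2.sf(q, m - 1))
    tau2 = max(0.0, (q - (m - 1)) / (np.sum(w) - np.sum(w**2) / np.sum(w)))

    chosen = model
    if model == "auto":
        chosen = "random" if q_p < 0.05 else "fixed"
    if chosen == "random":
        wr = 1.0 / (v + tau2)
        beta = float(np.sum(wr * b) / np.sum(wr))
        se = float(np.sqrt(1.0 / np.sum(wr)))
        tau2_out = float(tau2)
    else:
        beta = beta_f
        se = float(np.sqrt(1.0 / np.sum(w)))
        tau2_out = 0.0
    p = float(2.0 * sps.norm.sf(abs(beta) / se))
    return MetaResult(
        model=chosen,
        beta=beta,
        se=se,
        ci_low=beta - _Z975 * se,
        ci_high=beta + _Z975 * se,
        pvalue=p,
        tau2=tau2_out,
        q=q,
        q_p=q_p,
        n_studies=m,
    )


def diagnostics_report(
    hset: HarmonizedInstrumentSet,
    steiger: Optional[pd.DataFrame] = None,
    fstat=None,
) -> DiagnosticsReport:
    """Assemble the full diagnostics bundle for one instrument set."""
    q, q_df, q_p = cochran_q(hset) if hset.k >= 2 else (0.0, 0, 1.0)
    rep = DiagnosticsReport(q=q, q_df=q_df, q_p=q_p, steiger=steiger, fstat=fstat)
    if hset.k >= 3:
        a, a_se, a_p = egger_intercept_test(hset)
        rep.egger_intercept = a
        rep.egger_intercept_se = a_se
        rep.egger_intercept_p = a_p
    if hset.k >= 2:
        rep.loo = leave_one_out(hset)
    return rep
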