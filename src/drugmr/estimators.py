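"""Causal-effect estimators for two-sample MR.

Each estimator is a scikit-learn-style class (``fit`` + trailing-underscore
fitted attributes, ``get_params``/``set_params`` via ``BaseEstimator``) whose
input ``X`` is a harmonized instrument set: a
:class:`~drugmr.datatypes.HarmonizedInstrumentSet`, a DataFrame with columns
``beta_exp, se_exp, beta_out, se_out``, or a ``(k, 4)`` array in that column
order.  Module-level functions (:func:`ivw`, :func:`egger`, ...) are thin
wrappers that fit the class and return an :class:`MREstimate`.

Notation: per SNP j the exposure association is ``b_Xj`` with standard error
``se_Xj`` and the outcome association ``b_Yj`` with ``se_Yj``.  The Wald
ratio is ``r_j = b_Yj / b_Xj`` with first-order standard error
``s_j = se_Yj / |b_Xj|`` and inverse-variance weight ``w_j = 1 / s_j**2``.
"""

from __future__ import annotations

from typing import Union

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator

from .datatypes import HarmonizedInstrumentSet, MREstimate
from .errors import (
    CollinearityError,
    ConvergenceError,
    InsufficientInstrumentsError,
    ZeroExposureEffectError,
)

InstrumentData = Union[HarmonizedInstrumentSet, pd.DataFrame, np.ndarray]

_Z975 = float(sps.norm.ppf(0.975))  # 1.959964...


def _extract(X: InstrumentData):
    """Return (b_x, se_x, b_y, se_y, variant_ids) as float arrays."""
    if isinstance(X, HarmonizedInstrumentSet):
        t = X.table
        ids = t["variant_id"].astype(str).to_numpy()
        arr = t[["beta_exp", "se_exp", "beta_out", "se_out"]].to_numpy(float)
    elif isinstance(X, pd.DataFrame):
        ids = (
            X["variant_id"].astype(str).to_numpy()
            if "variant_id" in X.columns
            else np.array([f"snp_{i}" for i in range(len(X))])
        )
        arr = X[["beta_exp", "se_exp", "beta_out", "se_out"]].to_numpy(float)
    else:
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 4:
            raise ValueError(
                "array input must be (k, 4): beta_exp, se_exp, beta_out, se_out"
            )
        ids = np.array([f"snp_{i}" for i in range(arr.shape[0])])
    if arr.shape[0] < 1:
        raise InsufficientInstrumentsError("empty instrument set", 0)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite values in instrument data")
    if np.any(arr[:, 1] <= 0) or np.any(arr[:, 3] <= 0):
        raise ValueError("standard errors must be strictly positive")
    return arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3], ids


def _ratios(bx, sx, by, sy, ids):
    if np.any(bx == 0):
        bad = ids[bx == 0].tolist()
        raise ZeroExposureEffectError(
            f"exposure effect exactly zero for SNP(s) {bad}; Wald ratio undefined"
        )
    r = by / bx
    s = sy / np.abs(bx)
    w = 1.0 / s**2
    return r, s, w


def ratio_estimates(X: InstrumentData) -> pd.DataFrame:
    """Per-SNP Wald ratios, first-order SEs and inverse-variance weights."""
    bx, sx, by, sy, ids = _extract(X)
    r, s, w = _ratios(bx, sx, by, sy, ids)
    return pd.DataFrame(
        {"variant_id": ids, "ratio": r, "ratio_se": s, "weight": w}
    )


def _normal_p(beta: float, se: float) -> float:
    return float(2.0 * sps.norm.sf(abs(beta) / se))


def _antithetic_normal(rng: np.random.Generator, n_boot: int, k: int):
    """Antithetic standard-normal draws: the draw set is closed under
    negation, which makes bootstrap SEs exactly invariant when all outcome
    effects change sign."""
    half = (n_boot + 1) // 2
    z = rng.standard_normal((half, k))
    return np.vstack([z, -z])[:n_boot]


def _weighted_median(r: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(r, kind="stable")
    rs, ws = r[order], w[order]
    c = (np.cumsum(ws) - 0.5 * ws) / np.sum(ws)
    return float(np.interp(0.5, c, rs))


def _weighted_median_rows(R: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Row-wise weighted median of draws ``R`` (n_boot, k), fixed weights."""
    order = np.argsort(R, axis=1, kind="stable")
    rs = np.take_along_axis(R, order, axis=1)
    ws = w[order]
    cw = np.cumsum(ws, axis=1)
    c = (cw - 0.5 * ws) / cw[:, -1:]
    # first index where c >= 0.5, then linear interpolation on (c, rs)
    j = np.argmax(c >= 0.5, axis=1)
    rows = np.arange(R.shape[0])
    out = rs[rows, j].copy()
    inner = j > 0
    if np.any(inner):
        ri, ji = rows[inner], j[inner]
        c0, c1 = c[ri, ji - 1], c[ri, ji]
        r0, r1 = rs[ri, ji - 1], rs[ri, ji]
        frac = (0.5 - c0) / (c1 - c0)
        out[inner] = r0 + frac * (r1 - r0)
    return out


def _mode_point(r: np.ndarray, w: np.ndarray, phi: float, n_grid: int = 512):
    """Weighted-kernel mode of the ratio distribution.

    Bandwidth h = phi * 0.9 * min(sd, 1.4826*mad) * k^(-1/5) (Silverman-type
    rule with a robust scale); the estimate is the argmax of the w-weighted
    Gaussian KDE over an ``n_grid``-point grid on [min r - 3h, max r + 3h],
    ties broken by the lowest grid index.  Degenerate spread (h = 0) returns
    the common ratio value.
    """
    k = len(r)
    sd = float(np.std(r, ddof=1)) if k > 1 else 0.0
    mad = 1.4826 * float(np.median(np.abs(r - np.median(r))))
    scales = [s for s in (sd, mad) if s > 0]
    if not scales:
        return float(r[0]), 0.0
    h = phi * 0.9 * min(scales) * k ** (-0.2)
    if h == 0:
        return float(r[0]), 0.0
    grid = np.linspace(r.min() - 3 * h, r.max() + 3 * h, n_grid)
    wn = w / np.sum(w)
    dens = np.exp(-0.5 * ((grid[:, None] - r[None, :]) / h) ** 2) @ wn
    return float(grid[int(np.argmax(dens))]), h


class _MRBase(BaseEstimator):
    """Shared machinery: input extraction, CI/p computation, MREstimate."""

    method_name = "base"
    min_snps = 1

    def _check(self, X: InstrumentData):
        bx, sx, by, sy, ids = _extract(X)
        if len(bx) < self.min_snps:
            raise InsufficientInstrumentsError(
                f"{self.method_name} needs >= {self.min_snps} SNPs, "
                f"got {len(bx)}",
                n_selected=len(bx),
            )
        return bx, sx, by, sy, ids

    def _finish(self, beta, se, pvalue=None, method=None, extra=None):
        self.beta_ = float(beta)
        self.se_ = float(se)
        self.ci_low_ = self.beta_ - _Z975 * self.se_
        self.ci_high_ = self.beta_ + _Z975 * self.se_
        self.pvalue_ = (
            _normal_p(self.beta_, self.se_) if pvalue is None else float(pvalue)
        )
        self.method_ = method or self.method_name
        self.extra_ = extra or {}
        return self

    def to_estimate(self, scale: str = "beta") -> MREstimate:
        return MREstimate(
            method=self.method_,
            beta=self.beta_,
            se=self.se_,
            ci_low=self.ci_low_,
            ci_high=self.ci_high_,
            pvalue=self.pvalue_,
            nsnp=self.nsnp_,
            scale=scale,
            extra=dict(self.extra_),
        )


class IVWEstimator(_MRBase):
    """Inverse-variance-weighted estimator, the primary MR method.

    beta = sum(w_j r_j) / sum(w_j) with fixed-effect SE sqrt(1/sum w_j);
    equivalently the zero-intercept weighted least-squares slope of b_Y on
    b_X with weights 1/se_Y^2.  Under ``effects_model="multiplicative_random"``
    the SE is inflated by max(1, sqrt(Q/(k-2))) for k >= 3, where Q is
    Cochran's heterogeneity statistic; ``"auto"`` (default) uses the random
    model iff Q's p-value < 0.05.  A single SNP degenerates to the Wald ratio.

    Fitted attributes: ``beta_``, ``se_``, ``ci_low_``, ``ci_high_``,
    ``pvalue_``, ``nsnp_``, ``q_``, ``q_df_``, ``q_p_``, ``method_``.
    """

    method_name = "ivw"
    min_snps = 1

    def __init__(self, effects_model: str = "auto"):
        self.effects_model = effects_model

    def fit(self, X: InstrumentData, y=None):
        if self.effects_model not in ("fixed", "multiplicative_random", "auto"):
            raise ValueError(f"unknown effects_model {self.effects_model!r}")
        bx, sx, by, sy, ids = self._check(X)
        r, s, w = _ratios(bx, sx, by, sy, ids)
        k = len(r)
        self.nsnp_ = k
        if k == 1:
            self.q_, self.q_df_, self.q_p_ = 0.0, 0, 1.0
            return self._finish(r[0], s[0], method="wald_ratio")
        sw = np.sum(w)
        beta = float(np.sum(w * r) / sw)
        se_fixed = float(np.sqrt(1.0 / sw))
        q = float(np.sum(w * (r - beta) ** 2))
        q_df = k - 1
        q_p = float(sps.chi2.sf(q, q_df))
        self.q_, self.q_df_, self.q_p_ = q, q_df, q_p

        model = self.effects_model
        if model == "auto":
            model = "multiplicative_random" if q_p < 0.05 else "fixed"
        if model == "multiplicative_random" and k >= 3:
            se = se_fixed * max(1.0, np.sqrt(q / (k - 2)))
            method = "ivw_random"
        else:
            se = se_fixed
            method = "ivw_fixed"
        return self._finish(beta, se, method=method, extra={"Q": q, "Q_p": q_p})


class EggerEstimator(_MRBase):
    """MR-Egger weighted regression with an unconstrained intercept.

    Each SNP is oriented so b_X >= 0, then b_Y is regressed on b_X with
    weights 1/se_Y^2.  The slope is the pleiotropy-corrected causal effect;
    a non-zero intercept indicates directional pleiotropy.  SEs come from
    the weighted-regression covariance scaled by max(1, sqrt(RSS_w/(k-2)));
    p-values use the t distribution with k-2 df.

    Fitted attributes add ``intercept_``, ``intercept_se_``, ``intercept_p_``.
    """

    method_name = "egger"
    min_snps = 3

    def fit(self, X: InstrumentData, y=None):
        bx, sx, by, sy, ids = self._check(X)
        k = len(bx)
        self.nsnp_ = k
        sign = np.where(bx < 0, -1.0, 1.0)
        x = bx * sign
        yv = by * sign
        w = 1.0 / sy**2
        if np.ptp(x) == 0:
            raise CollinearityError(
                "no variance in exposure effects after orientation"
            )
        X_design = np.column_stack([np.ones(k), x])
        WX = X_design * w[:, None]
        xtx = X_design.T @ WX
        coef = np.linalg.solve(xtx, WX.T @ yv)
        resid = yv - X_design @ coef
        rss_w = float(np.sum(w * resid**2))
        sigma = max(1.0, np.sqrt(rss_w / (k - 2)))
        cov = np.linalg.inv(xtx) * sigma**2
        alpha, beta = float(coef[0]), float(coef[1])
        se_a, se_b = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
        p_b = float(2.0 * sps.t.sf(abs(beta) / se_b, df=k - 2))
        p_a = float(2.0 * sps.t.sf(abs(alpha) / se_a, df=k - 2))
        self.intercept_ = alpha
        self.intercept_se_ = se_a
        self.intercept_p_ = p_a
        return self._finish(
            beta,
            se_b,
            pvalue=p_b,
            extra={
                "intercept": alpha,
                "intercept_se": se_a,
                "intercept_p": p_a,
            },
        )


class WeightedMedianEstimator(_MRBase):
    """Weighted-median estimator: consistent when valid instruments carry
    more than half of the total weight.

    The estimate interpolates the ratio order statistics at the 50% point of
    the normalized cumulative weights c_j = (cumsum(w) - w_j/2)/sum(w).  The
    SE is the standard deviation over ``n_boot`` parametric-bootstrap draws
    r_j* ~ Normal(r_j, s_j) (antithetic pairs, seeded).
    """

    method_name = "weighted_median"
    min_snps = 3

    def __init__(self, n_boot: int = 1000, seed: int = 0):
        self.n_boot = n_boot
        self.seed = seed

    def fit(self, X: InstrumentData, y=None):
        bx, sx, by, sy, ids = self._check(X)
        r, s, w = _ratios(bx, sx, by, sy, ids)
        k = len(r)
        self.nsnp_ = k
        beta = _weighted_median(r, w)
        rng = np.random.default_rng(self.seed)
        z = _antithetic_normal(rng, self.n_boot, k)
        boots = _weighted_median_rows(r[None, :] + s[None, :] * z, w)
        se = float(np.std(boots, ddof=1))
        if se == 0:  # all ratios identical and noise-free draws degenerate
            se = float(np.sqrt(1.0 / np.sum(w)))
        return self._finish(
            beta, se, extra={"n_boot": self.n_boot, "seed": self.seed}
        )


class WeightedModeEstimator(_MRBase):
    """Mode-based estimator: consistent when the largest group of
    instruments sharing one ratio value is valid (ZEMPA assumption).

    Point estimate is the argmax of a weighted Gaussian KDE of the ratios on
    a 512-point grid; bandwidth follows a Silverman-type robust rule scaled
    by ``phi``.  SE via the same antithetic parametric bootstrap as the
    weighted median (bandwidth recomputed per draw).
    """

    method_name = "weighted_mode"
    min_snps = 3

    def __init__(self, phi: float = 1.0, n_boot: int = 1000, seed: int = 0):
        self.phi = phi
        self.n_boot = n_boot
        self.seed = seed

    def fit(self, X: InstrumentData, y=None):
        bx, sx, by, sy, ids = self._check(X)
        r, s, w = _ratios(bx, sx, by, sy, ids)
        k = len(r)
        self.nsnp_ = k
        beta, h = _mode_point(r, w, self.phi)
        rng = np.random.default_rng(self.seed)
        z = _antithetic_normal(rng, self.n_boot, k)
        draws = r[None, :] + s[None, :] * z
        boots = np.empty(len(draws))
        for i, rb in enumerate(draws):
            boots[i] = _mode_point(rb, w, self.phi)[0]
        se = float(np.std(boots, ddof=1))
        if se == 0:
            se = float(np.sqrt(1.0 / np.sum(w)))
        return self._finish(
            beta,
            se,
            extra={
                "bandwidth": h,
                "phi": self.phi,
                "n_boot": self.n_boot,
                "seed": self.seed,
            },
        )


class MaximumLikelihoodEstimator(_MRBase):
    """Full-likelihood estimator treating the true per-SNP exposure effects
    as nuisance parameters.

    Model: b_Xj ~ N(gamma_j, se_Xj^2), b_Yj ~ N(beta * gamma_j, se_Yj^2),
    independent across SNPs and between samples.  The log-likelihood is
    maximised over (beta, gamma_1..gamma_k) starting from gamma_j = b_Xj and
    beta = IVW-fixed; the SE of beta comes from the observed information at
    the optimum (block inversion of the Hessian).
    """

    method_name = "max_likelihood"
    min_snps = 2

    def __init__(self, tol: float = 1e-8, max_iter: int = 500):
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X: InstrumentData, y=None):
        bx, sx, by, sy, ids = self._check(X)
        k = len(bx)
        self.nsnp_ = k
        wx = 1.0 / sx**2
        wy = 1.0 / sy**2

        def scaled_grad(beta, gamma):
            # gradient divided by the diagonal curvature = Newton step per
            # coordinate; scale-free, so tol means the same thing whether
            # standard errors are 1e-8 or 1
            ry = by - beta * gamma
            g_b = -np.sum(wy * gamma * ry)
            g_g = -wx * (bx - gamma) - beta * wy * ry
            h_b = max(np.sum(wy * gamma**2), 1e-300)
            h_g = wx + beta**2 * wy
            return max(abs(g_b) / h_b, float(np.max(np.abs(g_g / h_g))))

        # The negative log-likelihood is quadratic in gamma for fixed beta
        # and in beta for fixed gamma, so block-coordinate descent uses exact
        # updates; the blocks are weakly coupled and convergence is fast.
        beta = IVWEstimator(effects_model="fixed").fit(
            np.column_stack([bx, sx, by, sy])
        ).beta_
        gamma = bx.copy()
        n_iter = 0
        converged = False
        for n_iter in range(1, self.max_iter + 1):
            gamma = (wx * bx + beta * wy * by) / (wx + beta**2 * wy)
            denom_b = float(np.sum(wy * gamma**2))
            if denom_b == 0:
                raise ConvergenceError(
                    "all fitted exposure effects collapsed to zero",
                    last_iterate=np.concatenate([[beta], gamma]),
                )
            beta = float(np.sum(wy * gamma * by) / denom_b)
            if scaled_grad(beta, gamma) < self.tol:
                converged = True
                break
        if not converged:
            raise ConvergenceError(
                f"maximum-likelihood optimisation did not converge within "
                f"{self.max_iter} iterations "
                f"(scaled |grad|={scaled_grad(beta, gamma):.3g})",
                last_iterate=np.concatenate([[beta], gamma]),
            )
        # observed information; beta-block of the inverse via Schur complement
        i_bb = float(np.sum(wy * gamma**2))
        i_bg = (2.0 * beta * gamma - by) * wy  # d2(negll)/(dbeta dgamma_j)
        i_gg = wx + beta**2 * wy
        denom = i_bb - float(np.sum(i_bg**2 / i_gg))
        if denom <= 0:
            raise ConvergenceError(
                "observed information not positive definite", last_iterate=res.x
            )
        se = float(np.sqrt(1.0 / denom))
        return self._finish(beta, se, extra={"n_iter": n_iter})


# ---------------------------------------------------------------------------
# functional wrappers


def ivw(X: InstrumentData, effects_model: str = "auto", scale: str = "beta"):
    """IVW causal estimate (see :class:`IVWEstimator`)."""
    est = IVWEstimator(effects_model=effects_model).fit(X)
    return est.to_estimate(scale)


def egger(X: InstrumentData, scale: str = "beta") -> MREstimate:
    """MR-Egger slope estimate with intercept stored in ``extra``."""
    return EggerEstimator().fit(X).to_estimate(scale)


def weighted_median(
    X: InstrumentData, n_boot: int = 1000, seed: int = 0, scale: str = "beta"
) -> MREstimate:
    """Weighted-median estimate with parametric-bootstrap SE."""
    return (
        WeightedMedianEstimator(n_boot=n_boot, seed=seed)
        .fit(X)
        .to_estimate(scale)
    )


def weighted_mode(
    X: InstrumentData,
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
    scale: str = "beta",
) -> MREstimate:
    """Weighted-mode estimate with parametric-bootstrap SE."""
    return (
        WeightedModeEstimator(phi=phi, n_boot=n_boot, seed=seed)
        .fit(X)
        .to_estimate(scale)
    )


def max_likelihood(
    X: InstrumentData, tol: float = 1e-8, scale: str = "beta"
) -> MREstimate:
    """Maximum-likelihood estimate (see :class:`MaximumLikelihoodEstimator`)."""
    return MaximumLikelihoodEstimator(tol=tol).fit(X).to_estimate(scale)


ALL_ESTIMATORS = {
    "ivw": IVWEstimator,
    "egger": EggerEstimator,
    "weighted_median": WeightedMedianEstimator,
    "weighted_mode": WeightedModeEstimator,
    "max_likelihood": MaximumLikelihoodEstimator,
}
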