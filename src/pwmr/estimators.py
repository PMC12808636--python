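"""Two-sample MR estimators on harmonized summary data.

Estimators follow the scikit-learn convention: parameters are set in the
constructor, :meth:`fit` consumes a :class:`~pwmr.sumstats.HarmonizedDataset`
(or raw effect arrays) and exposes fitted attributes with a trailing
underscore (``beta_``, ``se_``, ``pval_`` ...).  The module-level functions
``wald_ratio``, ``ivw``, ``egger``, ``weighted_median`` and ``weighted_mode``
are thin wrappers returning an :class:`MREstimate`.

Methods
-------
Wald ratio
    Single-instrument estimate beta_y / beta_x with a delta-method SE
    (first-order ``se_y/|beta_x|`` by default; second-order available).
IVW
    Weighted regression of beta_y on beta_x through the origin with weights
    1/se_y^2; multiplicative random-effects dispersion max(1, Q/(k-1)) may
    inflate (never deflate) the SE.
MR-Egger
    Same regression with a free intercept; a nonzero intercept signals
    directional horizontal pleiotropy.
Weighted median / weighted mode
    Pleiotropy-robust consensus estimates over the per-SNP Wald ratios, with
    parametric-bootstrap standard errors.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .errors import EstimationError
from .sumstats import HarmonizedDataset, HarmonizedPair

Z95 = 1.959963984540054  # Phi^{-1}(0.975)


@dataclass
class MREstimate:
    """A causal-effect estimate in SD-outcome per SD-exposure units."""

    exposure_id: str
    outcome_id: str
    method: str  # wald | ivw | egger | weighted_median | weighted_mode
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int
    egger_intercept: float | None = None
    egger_intercept_pval: float | None = None
    model: str | None = None  # fixed | random (ivw)
    fdr_adjusted_p: float | None = None
    significant: bool | None = None

    @classmethod
    def from_beta_se(cls, beta: float, se: float, *, method: str, n_snp: int,
                     exposure_id: str = "", outcome_id: str = "", **kw) -> "MREstimate":
        pval = _normal_p(beta, se)
        return cls(exposure_id=exposure_id, outcome_id=outcome_id, method=method,
                   beta=beta, se=se, ci_low=beta - Z95 * se, ci_high=beta + Z95 * se,
                   pval=pval, n_snp=n_snp, **kw)


def ci_from_beta_pval(beta: float, pval: float) -> tuple[float, float]:
    """Recover the 95% normal CI implied by a point estimate and its p-value.

    Inverts the two-sided normal test: se = |beta| / Phi^{-1}(1 - p/2), then
    beta +/- 1.96 se.  Useful for checking the internal consistency of
    published estimate/CI/p triples.
    """
    z = stats.norm.isf(pval / 2)
    se = abs(beta) / z
    return beta - Z95 * se, beta + Z95 * se


def _normal_p(beta: float, se: float) -> float:
    if se == 0:
        return 1.0 if beta == 0 else 0.0
    return float(2.0 * stats.norm.sf(abs(beta / se)))


def _extract(data, y=None, se_x=None, se_y=None):
    """Accept a HarmonizedDataset or (beta_x, beta_y, se_x, se_y) arrays."""
    if isinstance(data, HarmonizedDataset):
        v = data.valid()
        if v.empty:
            raise EstimationError(
                f"no non-excluded pairs for {data.exposure_id} -> {data.outcome_id}")
        return (v["beta_x"].to_numpy(float), v["beta_y"].to_numpy(float),
                v["se_x"].to_numpy(float), v["se_y"].to_numpy(float),
                data.exposure_id, data.outcome_id)
    bx = np.asarray(data, dtype=float)
    by = np.asarray(y, dtype=float)
    sx = None if se_x is None else np.asarray(se_x, dtype=float)
    sy = np.asarray(se_y, dtype=float)
    return bx, by, sx, sy, "", ""


def _weighted_linear_fit(bx: np.ndarray, by: np.ndarray, w: np.ndarray,
                         intercept: bool) -> dict:
    """Weighted least squares of by on bx, shared by IVW and Egger.

    Returns the coefficient vector (intercept last absent when
    ``intercept=False``), fixed-weight standard errors, the weighted residual
    sum of squares (Cochran's Q for the no-intercept fit) and the residual
    degrees of freedom.
    """
    X = np.column_stack([np.ones_like(bx), bx]) if intercept else bx[:, None]
    XtW = X.T * w
    xtwx = XtW @ X
    cov = np.linalg.inv(xtwx)
    coef = cov @ (XtW @ by)
    resid = by - X @ coef
    rss = float(np.sum(w * resid**2))
    dof = len(bx) - X.shape[1]
    return {"coef": coef, "se_fixed": np.sqrt(np.diag(cov)), "rss": rss, "dof": dof}


# ---------------------------------------------------------------------------
# estimator classes
# ---------------------------------------------------------------------------

class _BaseMREstimator(BaseEstimator):
    """Shared fit plumbing; subclasses implement :meth:`_fit_arrays`."""

    method: str = ""
    min_snps: int = 1

    def fit(self, data, y=None, *, se_x=None, se_y=None):
        bx, by, sx, sy, exp_id, out_id = _extract(data, y, se_x, se_y)
        if len(bx) < self.min_snps:
            raise EstimationError(
                f"{self.method} requires at least {self.min_snps} instruments, "
                f"got {len(bx)}")
        self.exposure_id_, self.outcome_id_ = exp_id, out_id
        self.n_snp_ = len(bx)
        self._fit_arrays(bx, by, sx, sy)
        self.ci_low_ = self.beta_ - Z95 * self.se_
        self.ci_high_ = self.beta_ + Z95 * self.se_
        self.pval_ = _normal_p(self.beta_, self.se_)
        return self

    def _fit_arrays(self, bx, by, sx, sy):  # pragma: no cover - abstract
        raise NotImplementedError

    def to_estimate(self) -> MREstimate:
        kw = {}
        if hasattr(self, "intercept_"):
            kw["egger_intercept"] = self.intercept_
            kw["egger_intercept_pval"] = self.intercept_pval_
        if hasattr(self, "model_"):
            kw["model"] = self.model_
        return MREstimate(
            exposure_id=self.exposure_id_, outcome_id=self.outcome_id_,
            method=self.method, beta=float(self.beta_), se=float(self.se_),
            ci_low=float(self.ci_low_), ci_high=float(self.ci_high_),
            pval=float(self.pval_), n_snp=self.n_snp_, **kw)


class WaldRatio(_BaseMREstimator):
    """Single-instrument Wald ratio beta_y / beta_x."""

    method = "wald"
    min_snps = 1

    def __init__(self, se_order: str = "first"):
        self.se_order = se_order

    def _fit_arrays(self, bx, by, sx, sy):
        if len(bx) != 1:
            raise EstimationError("the Wald ratio takes exactly one instrument")
        bx, by, sy = float(bx[0]), float(by[0]), float(sy[0])
        if bx == 0:
            raise EstimationError("Wald ratio undefined: exposure beta is zero")
        self.beta_ = by / bx
        if self.se_order == "first":
            self.se_ = sy / abs(bx)
        elif self.se_order == "second":
            if sx is None:
                raise EstimationError("second-order Wald SE requires se_x")
            sx = float(sx[0])
            self.se_ = float(np.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4))
        else:
            raise ValueError(f"unknown se_order {self.se_order!r}")


class IVW(_BaseMREstimator):
    """Inverse-variance-weighted estimate (regression through the origin).

    ``model='auto'`` uses a fixed-effect SE below 4 instruments and
    multiplicative random effects otherwise; dispersion never deflates the SE.
    """

    method = "ivw"
    min_snps = 1

    def __init__(self, model: str = "auto"):
        self.model = model

    def _fit_arrays(self, bx, by, sx, sy):
        w = 1.0 / sy**2
        fit = _weighted_linear_fit(bx, by, w, intercept=False)
        self.beta_ = float(fit["coef"][0])
        se = float(fit["se_fixed"][0])
        self.q_ = fit["rss"]
        model = self.model
        if model == "auto":
            model = "fixed" if len(bx) < 4 else "random"
        if model == "random" and fit["dof"] > 0:
            phi = fit["rss"] / fit["dof"]
            se *= np.sqrt(max(1.0, phi))
        elif model not in {"fixed", "random"}:
            raise ValueError(f"unknown IVW model {self.model!r}")
        self.model_ = model
        self.se_ = se


class EggerRegression(_BaseMREstimator):
    """MR-Egger: weighted regression with a free pleiotropy intercept.

    Pairs are oriented so every exposure beta is positive before fitting
    (a joint sign flip, which leaves the causal slope unchanged).
    """

    method = "egger"
    min_snps = 3

    def __init__(self):
        pass

    def _fit_arrays(self, bx, by, sx, sy):
        sign = np.where(bx < 0, -1.0, 1.0)
        bx, by = bx * sign, by * sign
        w = 1.0 / sy**2
        fit = _weighted_linear_fit(bx, by, w, intercept=True)
        infl = np.sqrt(max(1.0, fit["rss"] / fit["dof"])) if fit["dof"] > 0 else 1.0
        self.beta_ = float(fit["coef"][1])
        self.se_ = float(fit["se_fixed"][1] * infl)
        self.intercept_ = float(fit["coef"][0])
        self.intercept_se_ = float(fit["se_fixed"][0] * infl)
        self.intercept_pval_ = _normal_p(self.intercept_, self.intercept_se_)


def _ratios_and_weights(bx, by, sy):
    ratios = by / bx
    se_ratio = sy / np.abs(bx)
    return ratios, 1.0 / se_ratio**2


def _weighted_percentile(x: np.ndarray, w: np.ndarray, q: float = 0.5) -> float:
    order = np.argsort(x, kind="mergesort")
    x, w = x[order], w[order]
    cum = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(q, cum, x))


class WeightedMedian(_BaseMREstimator):
    """Weighted median of per-SNP Wald ratios (50% breakdown point)."""

    method = "weighted_median"
    min_snps = 3

    def __init__(self, n_boot: int = 1000, seed: int = 1234):
        self.n_boot = n_boot
        self.seed = seed

    def _fit_arrays(self, bx, by, sx, sy):
        ratios, w = _ratios_and_weights(bx, by, sy)
        self.beta_ = _weighted_percentile(ratios, w)
        self.se_ = _bootstrap_se(self._point, bx, by, sx, sy,
                                 self.n_boot, self.seed)

    @staticmethod
    def _point(bx, by, sy):
        ratios, w = _ratios_and_weights(bx, by, sy)
        return _weighted_percentile(ratios, w)


def _default_mode_bandwidth(ratios: np.ndarray, w: np.ndarray) -> float:
    """Weighted MAD-based kernel bandwidth (Silverman-style rule)."""
    med = _weighted_percentile(ratios, w)
    mad = _weighted_percentile(np.abs(ratios - med), w)
    wsum = np.sum(w)
    mean = np.sum(w * ratios) / wsum
    sd = np.sqrt(np.sum(w * (ratios - mean) ** 2) / wsum)
    s = min(sd, 1.4826 * mad) if mad > 0 else sd
    return 0.9 * s * len(ratios) ** (-0.2)


def _mode_point(bx, by, sy, bandwidth_factor):
    ratios, w = _ratios_and_weights(bx, by, sy)
    h = bandwidth_factor * _default_mode_bandwidth(ratios, w)
    if h <= 0 or not np.isfinite(h):
        return _weighted_percentile(ratios, w)  # degenerate: all ratios equal
    lo, hi = ratios.min() - 3 * h, ratios.max() + 3 * h
    grid = np.linspace(lo, hi, 512)
    dens = np.sum(w[:, None] * np.exp(-0.5 * ((grid[None, :] - ratios[:, None]) / h) ** 2),
                  axis=0)
    return float(grid[np.argmax(dens)])


class WeightedMode(_BaseMREstimator):
    """Mode of the inverse-variance-weighted smoothed ratio density."""

    method = "weighted_mode"
    min_snps = 3

    def __init__(self, bandwidth_factor: float = 1.0, n_boot: int = 1000,
                 seed: int = 1234):
        self.bandwidth_factor = bandwidth_factor
        self.n_boot = n_boot
        self.seed = seed

    def _fit_arrays(self, bx, by, sx, sy):
        self.beta_ = _mode_point(bx, by, sy, self.bandwidth_factor)
        self.se_ = _bootstrap_se(
            lambda b, y, s: _mode_point(b, y, s, self.bandwidth_factor),
            bx, by, sx, sy, self.n_boot, self.seed)


def _bootstrap_se(point_fn, bx, by, sx, sy, n_boot: int, seed: int) -> float:
    """Parametric bootstrap over the per-SNP sampling distributions."""
    rng = np.random.default_rng(seed)
    k = len(bx)
    sx_eff = np.zeros(k) if sx is None else sx
    bx_star = rng.normal(bx, sx_eff, size=(n_boot, k))
    by_star = rng.normal(by, sy, size=(n_boot, k))
    bx_star = np.where(bx_star == 0, np.finfo(float).tiny, bx_star)
    est = np.array([point_fn(bx_star[i], by_star[i], sy) for i in range(n_boot)])
    return float(np.std(est, ddof=1))


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def wald_ratio(pair: HarmonizedPair, se_order: str = "first") -> MREstimate:
    """Wald-ratio estimate from one harmonized pair."""
    if pair.excluded:
        raise EstimationError(f"pair {pair.rsid} was excluded during harmonization")
    if pair.beta_x == 0:
        raise EstimationError(f"Wald ratio undefined for {pair.rsid}: exposure beta is zero")
    est = WaldRatio(se_order=se_order).fit(
        [pair.beta_x], [pair.beta_y], se_x=[pair.se_x], se_y=[pair.se_y])
    return est.to_estimate()


def ivw(data: HarmonizedDataset, model: str = "auto") -> MREstimate:
    return IVW(model=model).fit(data).to_estimate()


def egger(data: HarmonizedDataset) -> MREstimate:
    return EggerRegression().fit(data).to_estimate()


def weighted_median(data: HarmonizedDataset, n_boot: int = 1000,
                    seed: int = 1234) -> MREstimate:
    return WeightedMedian(n_boot=n_boot, seed=seed).fit(data).to_estimate()


def weighted_mode(data: HarmonizedDataset, bandwidth_factor: float = 1.0,
                  n_boot: int = 1000, seed: int = 1234) -> MREstimate:
    return WeightedMode(bandwidth_factor=bandwidth_factor, n_boot=n_boot,
                        seed=seed).fit(data).to_estimate()


def bh_fdr(pvals: Sequence[float], q: float = 0.05):
    """Benjamini-Hochberg step-up FDR control.

    Returns (adjusted p-values, rejection flags at level ``q``).
    """
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    reject, adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return adj, reject
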