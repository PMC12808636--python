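"""Bayesian colocalization of two traits via per-SNP approximate Bayes factors.

Under a single-causal-variant assumption per trait, the evidence for five
hypotheses about a cis region is combined from Wakefield's approximate Bayes
factors (ABFs): H0 no association with either trait; H1 causal variant for
trait 1 only; H2 for trait 2 only; H3 two distinct causal variants; H4 one
shared causal variant.  All accumulation happens in log space.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .errors import ConfigurationError, InputError
from .sumstats import SumStatTable

HYPOTHESES = ("H0", "H1", "H2", "H3", "H4")


@dataclass
class ColocConfig:
    """Priors and thresholds for ABF colocalization.

    p1/p2 are the per-SNP prior probabilities of being causal for each trait,
    p12 the prior of being causal for both; W1/W2 are the prior variances of
    the (standardized) effect sizes, 0.15^2 for quantitative traits.
    """

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5
    w1: float = 0.15**2
    w2: float = 0.15**2
    maf_min: float = 0.01
    window: int = 1_000_000
    h4_threshold: float = 0.75

    def __post_init__(self):
        if self.p12 < 0 or (self.p12 > min(self.p1, self.p2)):
            raise ConfigurationError("require 0 <= p12 <= min(p1, p2)")
        if not (0 < self.p1 < 1 and 0 < self.p2 < 1):
            raise ConfigurationError("p1 and p2 must lie in (0, 1)")


@dataclass
class ColocResult:
    pp: dict[str, float]  # posterior probability per hypothesis, sums to 1
    n_snps: int
    labf1: np.ndarray = field(repr=False)
    labf2: np.ndarray = field(repr=False)
    verdict: str = ""  # colocalized | distinct | underpowered


def log_abf(beta, se, w) -> np.ndarray | float:
    """Wakefield log approximate Bayes factor for one association.

    With V = se^2, z = beta/se and prior effect variance W:
    log ABF = 0.5 log(V/(V+W)) + 0.5 z^2 W/(V+W); positive values favour a
    real effect.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    if w < 0:
        raise ValueError("prior variance must be non-negative")
    v = se**2
    z2 = (beta / se) ** 2
    out = 0.5 * np.log(v / (v + w)) + 0.5 * z2 * w / (v + w)
    return out if out.ndim else float(out)


def coloc_posteriors(labf1, labf2, cfg: ColocConfig | None = None) -> ColocResult:
    """Posterior probabilities of H0..H4 from two aligned log-ABF vectors.

    Un-normalized weights (computed with log-sum-exp throughout):
    H0: 1; H1: p1*S1; H2: p2*S2; H3: p1*p2*(S1*S2 - S12); H4: p12*S12,
    with S1 = sum exp(labf1), S2 = sum exp(labf2), S12 = sum exp(labf1+labf2).
    """
    cfg = cfg or ColocConfig()
    l1 = np.asarray(labf1, dtype=float)
    l2 = np.asarray(labf2, dtype=float)
    if l1.shape != l2.shape or l1.ndim != 1:
        raise InputError("log-ABF vectors must be equal-length 1-D arrays")
    if l1.size == 0:
        raise InputError("empty log-ABF vectors")

    ls1 = logsumexp(l1)
    ls2 = logsumexp(l2)
    ls12 = logsumexp(l1 + l2)

    with np.errstate(divide="ignore"):
        lw = np.empty(5)
        lw[0] = 0.0
        lw[1] = np.log(cfg.p1) + ls1
        lw[2] = np.log(cfg.p2) + ls2
        # H3 sums over ordered pairs of distinct SNPs: S1*S2 - S12
        if l1.size == 1:
            lw[3] = -np.inf  # no two distinct SNPs exist
        else:
            diff = ls12 - (ls1 + ls2)  # <= 0 mathematically
            lw[3] = (np.log(cfg.p1) + np.log(cfg.p2) + ls1 + ls2
                     + np.log1p(-min(np.exp(diff), 1.0 - 1e-16)))
        lw[4] = np.log(cfg.p12) + ls12 if cfg.p12 > 0 else -np.inf

    pp_arr = np.exp(lw - logsumexp(lw))
    pp_arr /= pp_arr.sum()
    pp = {h: float(p) for h, p in zip(HYPOTHESES, pp_arr)}
    result = ColocResult(pp=pp, n_snps=int(l1.size), labf1=l1, labf2=l2)
    result.verdict = call_colocalization(result, cfg)
    return result


def call_colocalization(result: ColocResult, cfg: ColocConfig | None = None) -> str:
    """'colocalized' if PP.H4 > threshold, 'distinct' if PP.H3 > threshold,
    otherwise 'underpowered'."""
    cfg = cfg or ColocConfig()
    if result.pp["H4"] > cfg.h4_threshold:
        return "colocalized"
    if result.pp["H3"] > cfg.h4_threshold:
        return "distinct"
    return "underpowered"


def coloc_region(trait1: SumStatTable, trait2: SumStatTable,
                 cfg: ColocConfig | None = None,
                 chrom: str | None = None, start: int | None = None,
                 end: int | None = None) -> ColocResult:
    """Colocalize two traits over a region (or their full rsid intersection).

    SNPs are intersected by rsid; those with MAF < ``cfg.maf_min`` in either
    table are removed.  No sign alignment is needed (ABFs depend on z^2), but
    variants whose allele pairs cannot be reconciled are dropped.
    """
    cfg = cfg or ColocConfig()
    m = trait1.df.merge(trait2.df, on="rsid", suffixes=("_1", "_2"))
    if chrom is not None:
        m = m[m["chrom_1"] == str(chrom)]
    if start is not None:
        m = m[m["pos_1"] >= start]
    if end is not None:
        m = m[m["pos_1"] <= end]
    # allele sanity: the two studies must describe the same variant
    ok = ((m["ea_1"] == m["ea_2"]) & (m["nea_1"] == m["nea_2"])) | \
         ((m["ea_1"] == m["nea_2"]) & (m["nea_1"] == m["ea_2"]))
    m = m[ok]
    for side in ("1", "2"):
        eaf = m[f"eaf_{side}"]
        maf = np.minimum(eaf, 1 - eaf)
        m = m[maf.isna() | (maf >= cfg.maf_min)]
    if m.empty:
        raise InputError(
            f"no shared variants for colocalization of {trait1.trait_id!r} "
            f"and {trait2.trait_id!r}")
    l1 = log_abf(m["beta_1"].to_numpy(), m["se_1"].to_numpy(), cfg.w1)
    l2 = log_abf(m["beta_2"].to_numpy(), m["se_2"].to_numpy(), cfg.w2)
    return coloc_posteriors(l1, l2, cfg)
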