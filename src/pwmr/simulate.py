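"""Synthetic GWAS summary statistics with known causal truth.

Regional summary statistics are simulated directly on the z-score scale
rather than from individual-level genotypes: with standardized genotypes and
traits, the vector of true marginal z-scores in a region is
``sqrt(n) * R @ b`` where ``b`` holds the joint (per-SD-genotype) causal
effects and ``R`` the LD correlation matrix, and the sampling noise of the
observed z-scores is multivariate normal with covariance ``R`` (one draw per
trait per region, so LD structure appears in the noise).  Per-allele betas
and standard errors follow from the per-SNP variance 2*maf*(1-maf):
``se = 1/sqrt(2*maf*(1-maf)*n)``, ``beta = z * se``.

Scenario vocabulary mirrors the colocalization hypotheses (h0..h4) plus
pleiotropy, mediation and reverse-causation designs; defaults emulate a
proteomic exposure GWAS of N=35,559 and a childhood-BMI outcome GWAS of
N=39,620 with a single strong cis-pQTL per protein.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .instruments import GeneAnnotation, LDMatrix
from .sumstats import SumStatTable

CAUSAL_CONFIGS = {"h0", "h1", "h2", "h3", "h4", "pleiotropy", "mediation", "reverse"}

_NONPAL_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_PAL_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass(frozen=True)
class SimScenario:
    """Generative truth for one synthetic protein/outcome dataset."""

    causal_config: str = "h4"
    n_snps: int = 200
    rho: float = 0.9
    n_exp: int = 35_559
    n_out: int = 39_620
    n_med: int = 155_961
    maf_range: tuple[float, float] = (0.05, 0.5)
    #: effect of one SD of genotype on the exposure at a causal SNP
    #: (variance explained = causal_effect_exp**2)
    causal_effect_exp: float = math.sqrt(0.02)
    #: causal effect of exposure on outcome, SD/SD (reverse direction for
    #: the 'reverse' config)
    causal_effect_out: float = -0.26
    direct_pleiotropy: float = 0.0
    mediator_params: tuple[float, float] | None = None  # (a, b)
    n_instruments: int = 16
    palindromic_fraction: float = 0.0
    gene_id: str = "GENE1"
    chrom: str = "1"
    tss: int = 50_000_000
    #: rsid prefix, so regions of different proteins never share variant ids
    snp_prefix: str = "rs"
    seed: int = 0

    def __post_init__(self):
        if self.causal_config not in CAUSAL_CONFIGS:
            raise ConfigurationError(
                f"unknown causal_config {self.causal_config!r}; "
                f"choose from {sorted(CAUSAL_CONFIGS)}")
        lo, hi = self.maf_range
        if not (0.01 <= lo < hi <= 0.5):
            raise ConfigurationError("maf_range must satisfy 0.01 <= lo < hi <= 0.5")
        if not (0 <= self.rho < 1):
            raise ConfigurationError("rho must lie in [0, 1)")
        if self.causal_config == "mediation" and self.mediator_params is None:
            raise ConfigurationError("mediation config requires mediator_params=(a, b)")


@dataclass
class SimData:
    """Simulated tables plus the generative truth record."""

    exposure: SumStatTable
    outcome: SumStatTable
    ld: LDMatrix
    gene: GeneAnnotation
    truth: dict
    mediator: SumStatTable | None = None


@lru_cache(maxsize=32)
def _ar1_matrices(n_snps: int, rho: float):
    """AR(1) correlation matrix and its closed-form Cholesky factor."""
    idx = np.arange(n_snps)
    r = rho ** np.abs(idx[:, None] - idx[None, :])
    l = np.zeros((n_snps, n_snps))
    l[:, 0] = rho ** idx
    if n_snps > 1:
        scale = math.sqrt(1.0 - rho**2)
        for j in range(1, n_snps):
            l[j:, j] = scale * rho ** (idx[j:] - j)
    return r, l


def simulate_ld(n_snps: int, rho: float, seed: int | None = None) -> LDMatrix:
    """AR(1) LD: r[i][j] = rho^|i-j|; deterministic and positive definite."""
    if not (0 <= rho < 1):
        raise ConfigurationError("rho must lie in [0, 1)")
    r, _ = _ar1_matrices(n_snps, rho)
    rsids = [f"rs{i + 1:05d}" for i in range(n_snps)]
    return LDMatrix(rsids=rsids, r=r.copy())


def _z_to_table(trait_id, trait_type, rsids, chrom, pos, ea, nea, eaf, z, maf, n,
                rng, flip_fraction=0.3):
    """Build a SumStatTable from z-scores; randomly swap the reported effect
    allele in a fraction of rows to exercise downstream harmonization."""
    se = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)
    beta = z * se
    pval = np.maximum(2.0 * stats.norm.sf(np.abs(z)), 1e-320)
    ea, nea, eaf, beta = ea.copy(), nea.copy(), eaf.copy(), beta.copy()
    if flip_fraction > 0:
        flip = rng.random(len(z)) < flip_fraction
        ea[flip], nea[flip] = nea[flip], ea[flip].copy()
        eaf[flip] = 1.0 - eaf[flip]
        beta[flip] = -beta[flip]
    df = pd.DataFrame({
        "rsid": rsids, "chrom": chrom, "pos": pos, "ea": ea, "nea": nea,
        "eaf": eaf, "beta": beta, "se": se, "pval": pval,
        "n": np.full(len(z), n, dtype=np.int64),
    })
    return SumStatTable(trait_id=trait_id, df=df, trait_type=trait_type)


def simulate_sumstats(scenario: SimScenario) -> SimData:
    """Simulate paired (optionally tripled) GWAS tables for one scenario."""
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    m = sc.n_snps

    # region layout: block A is the cis region; 'reverse' adds an independent
    # block of genome-wide instruments for the outcome trait
    k = sc.n_instruments if sc.causal_config == "reverse" else 0
    total = m + k
    r_a, l_a = _ar1_matrices(m, sc.rho)
    r = np.eye(total)
    r[:m, :m] = r_a
    l = np.eye(total)
    l[:m, :m] = l_a

    rsids = np.array([f"{sc.snp_prefix}{i + 1:05d}" for i in range(total)],
                     dtype=object)
    step = max(1, 1_000_000 // max(m, 1))
    pos = np.concatenate([
        sc.tss - 500_000 + step * np.arange(m),
        120_000_000 + 100_000 * np.arange(k),
    ]).astype(np.int64)
    chrom = np.array([sc.chrom] * m + ["2"] * k, dtype=object)

    maf = rng.uniform(sc.maf_range[0], sc.maf_range[1], total)
    pal = rng.random(total) < sc.palindromic_fraction
    pair_idx = rng.integers(0, len(_NONPAL_PAIRS), total)

    joint_exp = np.zeros(total)
    joint_out = np.zeros(total)
    joint_med = None
    cee, ceo = sc.causal_effect_exp, sc.causal_effect_out
    c = m // 2
    pal[c] = False  # causal SNP kept non-palindromic so it always harmonizes
    truth: dict = {
        "causal_config": sc.causal_config, "seed": sc.seed,
        "n_exp": sc.n_exp, "n_out": sc.n_out,
        "causal_effect_exp": cee, "causal_effect_out": ceo,
        "var_explained_exp": cee**2, "gene_id": sc.gene_id, "tss": sc.tss,
    }

    if sc.causal_config == "h0":
        pass
    elif sc.causal_config == "h1":
        joint_exp[c] = cee
        truth["causal_rsid_exp"] = rsids[c]
    elif sc.causal_config == "h2":
        joint_out[c] = ceo * cee
        truth["causal_rsid_out"] = rsids[c]
    elif sc.causal_config == "h4":
        joint_exp[c] = cee
        joint_out[c] = ceo * cee
        truth["causal_rsid_exp"] = truth["causal_rsid_out"] = rsids[c]
    elif sc.causal_config == "h3":
        c1, c2 = m // 4, (3 * m) // 4
        pal[c1] = pal[c2] = False
        joint_exp[c1] = cee
        joint_out[c2] = ceo * cee
        truth["causal_rsid_exp"] = rsids[c1]
        truth["causal_rsid_out"] = rsids[c2]
    elif sc.causal_config == "pleiotropy":
        idx = np.unique(np.round(np.linspace(0, m - 1, sc.n_instruments)).astype(int))
        pal[idx] = False
        joint_exp[idx] = cee * rng.uniform(0.5, 1.5, len(idx))
        joint_out = ceo * joint_exp
        joint_out[idx] += sc.direct_pleiotropy
        truth["instrument_rsids"] = list(rsids[idx])
        truth["direct_pleiotropy"] = sc.direct_pleiotropy
    elif sc.causal_config == "mediation":
        a, b = sc.mediator_params
        joint_exp[c] = cee
        joint_med = a * joint_exp
        joint_out = b * joint_med
        truth.update(causal_rsid_exp=rsids[c], a=a, b=b, indirect=a * b)
    elif sc.causal_config == "reverse":
        joint_exp[c] = cee  # the protein keeps its own cis-pQTL
        inst = np.arange(m, total)
        joint_out_inst = cee * rng.uniform(0.5, 1.5, k)
        joint_out[inst] = joint_out_inst
        # outcome -> exposure causation propagates the instruments' effects
        joint_exp[inst] = ceo * joint_out_inst
        truth["causal_rsid_exp"] = rsids[c]
        truth["instrument_rsids"] = list(rsids[inst])
        truth["reverse_beta"] = ceo

    # allele assignment happens after the config branches so causal SNPs are
    # guaranteed non-palindromic (strand-unambiguous)
    ea = np.array([(_PAL_PAIRS if p else _NONPAL_PAIRS)[i % 4 if p else i][0]
                   for p, i in zip(pal, pair_idx)], dtype=object)
    nea = np.array([(_PAL_PAIRS if p else _NONPAL_PAIRS)[i % 4 if p else i][1]
                    for p, i in zip(pal, pair_idx)], dtype=object)
    eaf = maf.copy()  # effect allele reported as the minor allele

    def draw(joint, n):
        z_true = np.sqrt(n) * (r @ joint)
        return z_true + l @ rng.standard_normal(total)

    z_exp = draw(joint_exp, sc.n_exp)
    z_out = draw(joint_out, sc.n_out)

    exposure = _z_to_table(sc.gene_id, "exposure", rsids, chrom, pos, ea, nea,
                           eaf, z_exp, maf, sc.n_exp, rng, flip_fraction=0.0)
    outcome = _z_to_table("BMI", "outcome", rsids, chrom, pos, ea, nea, eaf,
                          z_out, maf, sc.n_out, rng, flip_fraction=0.3)
    mediator = None
    if joint_med is not None:
        z_med = draw(joint_med, sc.n_med)
        mediator = _z_to_table("pct_body_fat", "mediator", rsids, chrom, pos,
                               ea, nea, eaf, z_med, maf, sc.n_med, rng,
                               flip_fraction=0.3)

    ld = LDMatrix(rsids=list(rsids), r=r.copy())
    gene = GeneAnnotation(gene_id=sc.gene_id, chrom=sc.chrom, tss=sc.tss)
    return SimData(exposure=exposure, outcome=outcome, ld=ld, gene=gene,
                   truth=truth, mediator=mediator)


def make_phewas_table(instrument_rsids, categories, hits_per_category,
                      seed: int = 0, n_background: int = 50):
    """Local trait-association fixture for the confounder screen.

    Produces the requested number of genome-wide-significant hits per
    category for the given instrument rsid(s), plus non-significant
    background rows.  Returns (table, category_map).
    """
    if not categories:
        raise ConfigurationError("categories must be nonempty")
    rng = np.random.default_rng(seed)
    instrument_rsids = list(instrument_rsids)
    rows = []
    category_map: dict[str, str] = {}
    for cat, n_hits in zip(categories, hits_per_category):
        for j in range(n_hits):
            trait = f"{cat}_hit_{j + 1}"
            category_map[trait] = cat
            rsid = instrument_rsids[(len(rows)) % len(instrument_rsids)]
            rows.append((trait, rsid, 10 ** rng.uniform(-30, -9)))
    for j in range(n_background):
        cat = categories[j % len(categories)]
        trait = f"{cat}_background_{j + 1}"
        category_map[trait] = cat
        rsid = instrument_rsids[j % len(instrument_rsids)]
        rows.append((trait, rsid, 10 ** rng.uniform(-6, 0)))
    table = pd.DataFrame(rows, columns=["trait", "rsid", "pval"])
    return table, category_map


def simulate_study(base: SimScenario, n_proteins: int, n_causal: int = 1,
                   seed: int = 0, outcome_id: str = "BMI"):
    """Simulate a multi-protein study sharing one outcome GWAS.

    The first ``n_causal`` proteins follow ``base.causal_config`` (typically
    h4), the rest are null; each protein gets its own gene, rsid namespace
    and chromosome, and the per-region outcome statistics are stacked into a
    single outcome table.

    Returns ``(exposures, outcome, genes, lds, truths)`` keyed by protein id.
    """
    from .sumstats import concat_tables

    exposures, genes, lds, truths, outs = {}, {}, {}, {}, []
    for i in range(n_proteins):
        pid = f"P{i + 1}"
        sc = replace(base,
                     causal_config=base.causal_config if i < n_causal else "h0",
                     gene_id=pid, snp_prefix=f"{pid}_rs",
                     chrom=str(i % 22 + 1), seed=seed + i)
        sim = simulate_sumstats(sc)
        exposures[pid] = sim.exposure
        genes[pid] = sim.gene
        lds[pid] = sim.ld
        truths[pid] = sim.truth
        outs.append(sim.outcome)
    outcome = concat_tables(outs, trait_id=outcome_id, trait_type="outcome")
    return exposures, outcome, genes, lds, truths


# named presets at the scales of the study setting -------------------------

PRESETS: dict[str, SimScenario] = {
    # strong cis-pQTL (9% variance explained), small protective effect
    "paper_scale_eng": SimScenario(causal_config="h4",
                                   causal_effect_exp=0.30,
                                   causal_effect_out=-0.07),
    # weak instrument (0.36%), large effect, borderline colocalization power
    "paper_scale_fabp4": SimScenario(causal_config="h4",
                                     causal_effect_exp=0.06,
                                     causal_effect_out=-0.33),
    # 2% variance explained, effect -0.26
    "paper_scale_cadm1": SimScenario(causal_config="h4",
                                     causal_effect_exp=math.sqrt(0.02),
                                     causal_effect_out=-0.26),
    # one of many null proteins in a proteome-wide screen
    "null_535": SimScenario(causal_config="h0"),
}


def get_preset(name: str, seed: int | None = None) -> SimScenario:
    try:
        sc = PRESETS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown preset {name!r}; choose from {sorted(PRESETS)}") from None
    return replace(sc, seed=seed) if seed is not None else sc
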