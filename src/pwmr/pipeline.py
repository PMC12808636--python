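"""Proteome-wide MR orchestration.

Runs the full discovery workflow over many proteins: cis instrument
selection, harmonization against the outcome GWAS, Wald-ratio (single
instrument) or IVW (multiple instruments) estimation, BH-FDR across all
tested proteins, and — for FDR-significant proteins — colocalization, a
PheWAS-style confounder screen, two-step mediation, reverse MR and analytic
power.  Per-protein failures are recorded, never fatal.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .coloc import ColocConfig, ColocResult, coloc_region
from .errors import ConfigurationError, EstimationError, HarmonizationError, PwmrError
from .estimators import (MREstimate, bh_fdr, egger, ivw, wald_ratio,
                         weighted_median, weighted_mode)
from .instruments import (GeneAnnotation, Instrument, LDMatrix, find_proxy,
                          read_ld_matrix, select_cis_instruments)
from .mediation import MediationResult, two_step_mediation
from .power import PowerInput, mr_power
from .sumstats import (HarmonizedDataset, SumStatTable, harmonize,
                       read_sumstats, write_exclusion_audit)

logger = logging.getLogger(__name__)


@dataclass
class Thresholds:
    cis_window: int = 1_000_000
    p_max: float = 5e-8
    f_min: float = 10.0
    r2_clump: float = 0.001
    palindrome_maf: float = 0.42
    fdr_q: float = 0.05
    proxy_r2_min: float = 0.8
    phewas_p: float = 5e-8
    power_alpha: float = 0.05


@dataclass
class RunConfig:
    """Declarative run description (mirrors the YAML config file)."""

    exposures: list[dict]  # each: {id, path, ld (optional)}
    outcome: str
    genes: str  # TSV `gene_id chrom tss`
    mediator: str | None = None
    phewas_table: str | None = None
    phewas_categories: str | None = None  # TSV `trait category`
    reverse: bool = False
    thresholds: Thresholds = field(default_factory=Thresholds)
    coloc: ColocConfig = field(default_factory=ColocConfig)
    seed: int = 1234
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        thr = Thresholds(**raw.pop("thresholds", {}))
        cc = ColocConfig(**raw.pop("coloc", {}))
        try:
            cfg = cls(thresholds=thr, coloc=cc, **raw)
        except TypeError as e:
            raise ConfigurationError(f"bad config {path}: {e}") from None
        for ex in cfg.exposures:
            if not Path(ex["path"]).exists():
                raise ConfigurationError(f"exposure table not found: {ex['path']}")
        for p in (cfg.outcome, cfg.genes):
            if not Path(p).exists():
                raise ConfigurationError(f"input file not found: {p}")
        return cfg


@dataclass
class ProteinReport:
    protein_id: str
    status: str  # tested | no_instruments | not_testable | failed_harmonization | failed_estimation
    instruments: list[str] = field(default_factory=list)
    proxy_used: str | None = None
    discovery: MREstimate | None = None
    fdr_adjusted_p: float | None = None
    significant: bool | None = None
    coloc: ColocResult | None = None
    confounder_counts: dict | None = None
    mediation: MediationResult | None = None
    reverse: list[MREstimate] | None = None
    power: float | None = None
    error: str = ""


def screen_confounders(instrument_rsid: str, table: pd.DataFrame,
                       p_threshold: float = 5e-8,
                       category_map: dict[str, str] | None = None,
                       proxy_rsid: str | None = None) -> dict[str, int]:
    """Count distinct confounder traits per category for one instrument.

    ``table`` has columns `trait rsid pval`; traits not covered by
    ``category_map`` fall into an 'other' bucket (logged).  An rsid absent
    from the table yields all-zero counts.
    """
    category_map = category_map or {}
    counts = {c: 0 for c in sorted(set(category_map.values()))}
    counts.setdefault("other", 0)
    rsids = {instrument_rsid}
    if proxy_rsid:
        rsids.add(proxy_rsid)
    hits = table[table["rsid"].isin(rsids) & (table["pval"] <= p_threshold)]
    unknown = 0
    for trait in hits["trait"].unique():
        cat = category_map.get(trait)
        if cat is None:
            cat = "other"
            unknown += 1
        counts[cat] = counts.get(cat, 0) + 1
    if unknown:
        logger.warning("confounder screen: %d trait(s) without a category bucketed "
                       "as 'other'", unknown)
    return counts


def reverse_mr(outcome_instruments: HarmonizedDataset, n_boot: int = 1000,
               seed: int = 1234) -> list[MREstimate]:
    """IVW plus the three pleiotropy-robust estimates on one harmonized set.

    With fewer than three instruments only IVW (== Wald for one) is returned.
    """
    if outcome_instruments.n_valid < 1:
        raise EstimationError("reverse MR requires at least one harmonized instrument")
    out = [ivw(outcome_instruments)]
    if outcome_instruments.n_valid >= 3:
        out.append(egger(outcome_instruments))
        out.append(weighted_median(outcome_instruments, n_boot=n_boot, seed=seed))
        out.append(weighted_mode(outcome_instruments, n_boot=n_boot, seed=seed))
    return out


def _instrument_r2(instruments: list[Instrument]) -> float:
    """Variance in the (standardized) exposure explained by the instruments."""
    r2 = sum(2 * ins.eaf * (1 - ins.eaf) * ins.beta_x**2 for ins in instruments
             if np.isfinite(ins.eaf))
    return float(min(r2, 0.999))


def _discovery_estimate(hz: HarmonizedDataset, inst_rsids: list[str]) -> MREstimate:
    sub = hz.pairs[hz.pairs["rsid"].isin(inst_rsids) & ~hz.pairs["excluded"]]
    if sub.empty:
        raise HarmonizationError("no instrument survived harmonization")
    sub_ds = HarmonizedDataset(hz.exposure_id, hz.outcome_id, sub.reset_index(drop=True))
    if len(sub) == 1:
        return wald_ratio(next(sub_ds.iter_pairs()))
    est = ivw(sub_ds)
    return est


def _genome_wide_instruments(table: SumStatTable, p_max: float,
                             ld: LDMatrix | None, r2_clump: float) -> list[str]:
    """Greedy p-value clumping of genome-wide-significant SNPs (no cis filter)."""
    df = table.df[table.df["pval"] <= p_max]
    df = df.sort_values(["pval", "rsid"], kind="mergesort")
    kept: list[str] = []
    for r in df.itertuples(index=False):
        if ld is not None and r.rsid in ld and any(
                k in ld and ld.r2(r.rsid, k) > r2_clump for k in kept):
            continue
        kept.append(r.rsid)
    return kept


def run_proteome_mr(exposures: dict[str, SumStatTable], outcome: SumStatTable,
                    genes: dict[str, GeneAnnotation],
                    lds: dict[str, LDMatrix] | None = None, *,
                    mediator: SumStatTable | None = None,
                    phewas_table: pd.DataFrame | None = None,
                    category_map: dict[str, str] | None = None,
                    do_reverse: bool = False,
                    thresholds: Thresholds | None = None,
                    coloc_cfg: ColocConfig | None = None,
                    seed: int = 1234):
    """Run the proteome-wide analysis on in-memory tables.

    Returns ``(reports, summary, harmonized)`` where ``summary`` carries the
    attrition counts and ``harmonized`` the per-protein datasets (for the
    exclusion audit).
    """
    thr = thresholds or Thresholds()
    ccfg = coloc_cfg or ColocConfig()
    lds = lds or {}
    reports: list[ProteinReport] = []
    harmonized: list[HarmonizedDataset] = []

    for pid, table in exposures.items():
        rep = ProteinReport(protein_id=pid, status="tested")
        reports.append(rep)
        gene = genes.get(pid)
        if gene is None:
            rep.status, rep.error = "no_instruments", "no gene annotation"
            continue
        ld = lds.get(pid)
        insts = select_cis_instruments(table, gene, window=thr.cis_window,
                                       p_max=thr.p_max, f_min=thr.f_min,
                                       ld=ld, r2_clump=thr.r2_clump)
        if not insts:
            rep.status = "no_instruments"
            continue
        rep.instruments = [i.rsid for i in insts]

        # proxy substitution when the (single) instrument is missing downstream
        outcome_rsids = set(outcome.df["rsid"])
        usable = [i for i in insts if i.rsid in outcome_rsids]
        if not usable and ld is not None:
            try:
                proxy = find_proxy(insts[0].rsid, outcome, ld, r2_min=thr.proxy_r2_min)
            except PwmrError:
                proxy = None
            if proxy is not None and proxy in table:
                rec = table.record(proxy)
                insts = [Instrument(rsid=proxy, gene_id=gene.gene_id,
                                    beta_x=rec.beta, se_x=rec.se, eaf=rec.eaf,
                                    pval=rec.pval, n=rec.n,
                                    f_stat=(rec.beta / rec.se) ** 2,
                                    distance_to_tss=rec.pos - gene.tss)]
                rep.proxy_used = proxy
                rep.instruments = [proxy]
                usable = insts
        if not usable:
            rep.status, rep.error = "not_testable", \
                "instrument (and any proxy) absent from the outcome GWAS"
            continue

        try:
            hz = harmonize(table, outcome, palindrome_maf_threshold=thr.palindrome_maf)
            harmonized.append(hz)
            rep.discovery = _discovery_estimate(hz, rep.instruments)
        except HarmonizationError as e:
            rep.status, rep.error = "failed_harmonization", str(e)
            continue
        except (EstimationError, PwmrError) as e:
            rep.status, rep.error = "failed_estimation", str(e)
            continue

    # BH-FDR across all successfully tested proteins
    tested = [r for r in reports if r.status == "tested"]
    if tested:
        adj, rej = bh_fdr([r.discovery.pval for r in tested], q=thr.fdr_q)
        for r, a, s in zip(tested, adj, rej):
            r.fdr_adjusted_p = float(a)
            r.significant = bool(s)
            r.discovery.fdr_adjusted_p = float(a)
            r.discovery.significant = bool(s)

    # follow-up analyses for FDR-significant proteins
    for rep in tested:
        if not rep.significant:
            continue
        pid = rep.protein_id
        table, gene = exposures[pid], genes[pid]
        lead = rep.instruments[0]
        lead_pos = int(table.df.loc[table.df["rsid"] == lead, "pos"].iloc[0])
        try:
            rep.coloc = coloc_region(table, outcome, ccfg, chrom=gene.chrom,
                                     start=lead_pos - ccfg.window,
                                     end=lead_pos + ccfg.window)
        except PwmrError as e:
            rep.error = f"coloc failed: {e}"
        if phewas_table is not None:
            rep.confounder_counts = screen_confounders(
                lead, phewas_table, p_threshold=thr.phewas_p,
                category_map=category_map, proxy_rsid=rep.proxy_used)
        if mediator is not None:
            try:
                hz1 = harmonize(table, mediator, thr.palindrome_maf)
                step1 = _discovery_estimate(hz1, rep.instruments)
                med_inst = _genome_wide_instruments(mediator, thr.p_max,
                                                    lds.get(pid), thr.r2_clump)
                hz2 = harmonize(mediator, outcome, thr.palindrome_maf)
                step2 = _discovery_estimate(hz2, med_inst)
                rep.mediation = two_step_mediation(step1, step2,
                                                  total=rep.discovery)
            except PwmrError as e:
                rep.error = f"mediation failed: {e}"
        if do_reverse:
            try:
                out_inst = _genome_wide_instruments(outcome, thr.p_max,
                                                    lds.get(pid), thr.r2_clump)
                hz_rev = harmonize(outcome, table, thr.palindrome_maf)
                sub = hz_rev.pairs[hz_rev.pairs["rsid"].isin(out_inst)
                                   & ~hz_rev.pairs["excluded"]]
                if not sub.empty:
                    rep.reverse = reverse_mr(HarmonizedDataset(
                        outcome.trait_id, pid, sub.reset_index(drop=True)),
                        seed=seed)
            except PwmrError as e:
                rep.error = f"reverse MR failed: {e}"
        insts_now = [i for i in select_cis_instruments(
            table, gene, window=thr.cis_window, p_max=thr.p_max,
            f_min=thr.f_min, ld=lds.get(pid), r2_clump=thr.r2_clump)
            if i.rsid in rep.instruments]
        if insts_now:
            r2 = _instrument_r2(insts_now)
            if 0 < r2 < 1:
                rep.power = mr_power(PowerInput(
                    n_outcome=int(outcome.df["n"].iloc[0]), r2_exposure=r2,
                    beta=abs(rep.discovery.beta), alpha=thr.power_alpha))

    summary = {
        "n_proteins": len(reports),
        "no_instruments": sum(r.status == "no_instruments" for r in reports),
        "instrumented": sum(r.status != "no_instruments" for r in reports),
        "not_testable": sum(r.status == "not_testable" for r in reports),
        "failed_harmonization": sum(
            r.status in ("failed_harmonization", "not_testable") for r in reports),
        "failed_estimation": sum(r.status == "failed_estimation" for r in reports),
        "tested": len(tested),
        "significant": sum(bool(r.significant) for r in tested),
        "colocalized": sum(r.coloc is not None and r.coloc.verdict == "colocalized"
                           for r in reports),
    }
    return reports, summary, harmonized


# ---------------------------------------------------------------------------
# file-driven entry point and report writers
# ---------------------------------------------------------------------------

def _load_genes(path) -> dict[str, GeneAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return {r.gene_id: GeneAnnotation(r.gene_id, str(r.chrom), int(r.tss))
            for r in df.itertuples(index=False)}


def run_pwmr(config: RunConfig):
    """Load the inputs named in ``config``, run the analysis, write reports."""
    genes = _load_genes(config.genes)
    exposures: dict[str, SumStatTable] = {}
    lds: dict[str, LDMatrix] = {}
    for ex in config.exposures:
        pid = ex["id"]
        exposures[pid] = read_sumstats(ex["path"], trait_id=pid,
                                       trait_type="exposure",
                                       dialect=ex.get("dialect"))
        if ex.get("ld"):
            lds[pid] = read_ld_matrix(ex["ld"])
    outcome = read_sumstats(config.outcome, trait_type="outcome")
    mediator = (read_sumstats(config.mediator, trait_type="mediator")
                if config.mediator else None)
    phewas = category_map = None
    if config.phewas_table:
        phewas = pd.read_csv(config.phewas_table, sep="\t")
        if config.phewas_categories:
            cm = pd.read_csv(config.phewas_categories, sep="\t")
            category_map = dict(zip(cm["trait"], cm["category"]))

    reports, summary, harmonized = run_proteome_mr(
        exposures, outcome, genes, lds, mediator=mediator,
        phewas_table=phewas, category_map=category_map,
        do_reverse=config.reverse, thresholds=config.thresholds,
        coloc_cfg=config.coloc, seed=config.seed)

    if config.out_dir:
        write_reports(reports, summary, harmonized, config.out_dir)
    return reports, summary


def estimates_frame(reports: list[ProteinReport]) -> pd.DataFrame:
    """Flatten every MR estimate in the reports into the standard TSV layout."""
    rows = []

    def add(est: MREstimate | None, exposure, outcome):
        if est is None:
            return
        rows.append({
            "exposure": exposure, "outcome": outcome, "method": est.method,
            "nsnp": est.n_snp, "beta": est.beta, "se": est.se,
            "ci_low": est.ci_low, "ci_high": est.ci_high, "pval": est.pval,
            "egger_intercept": est.egger_intercept,
            "egger_intercept_pval": est.egger_intercept_pval,
            "fdr_adjusted_p": est.fdr_adjusted_p,
            "significant": est.significant,
        })

    for r in reports:
        add(r.discovery, r.protein_id, "outcome")
        for est in r.reverse or []:
            add(est, "outcome", r.protein_id)
    return pd.DataFrame(rows)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_reports(reports, summary, harmonized, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    estimates_frame(reports).to_csv(out / "estimates.tsv", sep="\t",
                                    index=False, na_rep=".")
    with open(out / "report.jsonl", "w") as fh:
        for r in reports:
            d = _jsonable(r)
            if r.coloc is not None:  # per-SNP ABFs are bulky; keep pp + verdict
                d["coloc"] = {"pp": _jsonable(r.coloc.pp),
                              "n_snps": r.coloc.n_snps,
                              "verdict": r.coloc.verdict}
            fh.write(json.dumps(d, sort_keys=True) + "\n")
    with open(out / "summary.json", "w") as fh:
        json.dump(_jsonable(summary), fh, indent=2, sort_keys=True)
    write_exclusion_audit(harmonized, out / "exclusions.tsv")
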