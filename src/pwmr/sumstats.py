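"""GWAS summary statistics: data model, I/O, and allele harmonization.

A summary-statistics table holds one row per variant with the effect allele
(ea), the other allele (nea), the effect-allele frequency (eaf), the additive
effect ``beta`` in SD units of the trait per effect-allele copy, its standard
error, the two-sided p-value and the GWAS sample size.

Harmonization aligns the exposure and outcome tables to a shared effect
allele.  Palindromic SNPs (A/T or C/G) are strand-ambiguous: those with an
intermediate minor allele frequency (MAF > 0.42 by default) are excluded, and
the remainder are oriented by effect-allele-frequency concordance between the
two studies.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, HarmonizationError, InputError

logger = logging.getLogger(__name__)

#: canonical column order of the on-disk summary-stat TSV
SUMSTAT_COLUMNS = ["rsid", "chrom", "pos", "ea", "nea", "eaf", "beta", "se", "pval", "n"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _complement(allele: str) -> str:
    """Reverse-strand complement of a single-base allele ('' if not a base)."""
    return _COMPLEMENT.get(allele, "")


def is_palindromic(ea: str, nea: str) -> bool:
    """True iff the allele pair is strand-ambiguous ({A,T} or {C,G}).

    Multi-base alleles (indels) are never palindromic in this sense; the
    palindrome logic simply does not apply to them.
    """
    pair = {str(ea).upper(), str(nea).upper()}
    return pair == {"A", "T"} or pair == {"C", "G"}


@dataclass(frozen=True)
class VariantRecord:
    """A single variant association for one trait."""

    rsid: str
    chrom: str
    pos: int
    ea: str
    nea: str
    eaf: float  # NaN when unavailable
    beta: float
    se: float
    pval: float
    n: int

    def zscore(self) -> float:
        return self.beta / self.se


@dataclass
class SumStatTable:
    """Per-variant association records for one trait.

    ``df`` has the columns of :data:`SUMSTAT_COLUMNS`, unique rsids, and has
    passed the row-level validity checks (se > 0, eaf in (0,1) or missing,
    pval in (0,1], n > 0, ea != nea).
    """

    trait_id: str
    df: pd.DataFrame
    trait_type: str = "exposure"  # exposure | outcome | mediator

    def __post_init__(self) -> None:
        if self.trait_type not in {"exposure", "outcome", "mediator"}:
            raise ConfigurationError(f"unknown trait_type {self.trait_type!r}")
        self.df = _validate_rows(self.df, context=self.trait_id)
        if self.df.empty:
            raise InputError(f"no valid summary-statistic rows for trait {self.trait_id!r}")

    def __len__(self) -> int:
        return len(self.df)

    def __contains__(self, rsid: str) -> bool:
        return rsid in set(self.df["rsid"])

    @property
    def rsids(self) -> list[str]:
        return list(self.df["rsid"])

    def record(self, rsid: str) -> VariantRecord:
        row = self.df.loc[self.df["rsid"] == rsid]
        if row.empty:
            raise KeyError(rsid)
        r = row.iloc[0]
        return VariantRecord(r.rsid, str(r.chrom), int(r.pos), r.ea, r.nea,
                             float(r.eaf), float(r.beta), float(r.se),
                             float(r.pval), int(r.n))

    def iter_records(self) -> Iterator[VariantRecord]:
        for r in self.df.itertuples(index=False):
            yield VariantRecord(r.rsid, str(r.chrom), int(r.pos), r.ea, r.nea,
                                float(r.eaf), float(r.beta), float(r.se),
                                float(r.pval), int(r.n))


def _validate_rows(df: pd.DataFrame, context: str = "") -> pd.DataFrame:
    """Coerce types, upper-case alleles, drop rows violating the invariants."""
    missing = [c for c in SUMSTAT_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"summary-stat table missing required columns {missing}")
    df = df.loc[:, SUMSTAT_COLUMNS].copy()
    df["rsid"] = df["rsid"].astype(str)
    df["chrom"] = df["chrom"].astype(str)
    df["ea"] = df["ea"].astype(str).str.upper()
    df["nea"] = df["nea"].astype(str).str.upper()
    for c in ("eaf", "beta", "se", "pval"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    df["pos"] = pd.to_numeric(df["pos"], errors="coerce")
    df["n"] = pd.to_numeric(df["n"], errors="coerce")

    ok = (
        df["se"].gt(0)
        & df["pval"].gt(0)
        & df["pval"].le(1)
        & df["beta"].notna()
        & df["pos"].gt(0)
        & df["n"].gt(0)
        & (df["ea"] != df["nea"])
        & (df["eaf"].isna() | (df["eaf"].gt(0) & df["eaf"].lt(1)))
    )
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("%s: dropped %d row(s) failing validity checks", context, n_bad)
    df = df.loc[ok].copy()

    n_dup = int(df["rsid"].duplicated().sum())
    if n_dup:
        logger.warning("%s: dropped %d duplicate rsid row(s)", context, n_dup)
        df = df.loc[~df["rsid"].duplicated()].copy()

    df["pos"] = df["pos"].astype(np.int64)
    df["n"] = df["n"].astype(np.int64)
    return df.reset_index(drop=True)


def read_sumstats(path, trait_id: str | None = None, trait_type: str = "exposure",
                  dialect: Mapping[str, str] | None = None, sep: str = "\t") -> SumStatTable:
    """Read a delimited summary-stat table.

    ``dialect`` maps the file's column headers onto the canonical names
    (e.g. ``{"SNP": "rsid", "effect_allele": "ea"}``); '.' encodes missing.
    """
    df = pd.read_csv(path, sep=sep, na_values=["."], dtype={"chrom": str},
                     float_precision="round_trip")
    if dialect:
        df = df.rename(columns=dict(dialect))
    missing = [c for c in SUMSTAT_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(
            f"{path}: missing required columns {missing}; supply a dialect mapping")
    if trait_id is None:
        import os
        trait_id = os.path.splitext(os.path.basename(str(path)))[0]
    return SumStatTable(trait_id=trait_id, df=df, trait_type=trait_type)


def write_sumstats(table: SumStatTable, path) -> None:
    """Write the canonical tab-delimited format ('.' for missing)."""
    # %.17g preserves doubles exactly across a write/read round trip
    table.df.to_csv(path, sep="\t", index=False, na_rep=".", float_format="%.17g")


def concat_tables(tables: list[SumStatTable], trait_id: str,
                  trait_type: str = "outcome") -> SumStatTable:
    """Stack per-region tables of the same trait into one table.

    Used to assemble a genome-wide outcome GWAS from independently simulated
    cis regions; rsids must not collide across regions.
    """
    df = pd.concat([t.df for t in tables], ignore_index=True)
    return SumStatTable(trait_id=trait_id, df=df, trait_type=trait_type)


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HarmonizedPair:
    """Exposure/outcome effects for one variant on a shared effect allele."""

    rsid: str
    ea: str
    beta_x: float
    se_x: float
    eaf_x: float
    beta_y: float
    se_y: float
    eaf_y: float
    action: str  # aligned | flipped | freq_inferred
    excluded: bool = False
    exclusion_reason: str = ""


@dataclass
class HarmonizedDataset:
    """All harmonized pairs for one exposure/outcome pair of GWAS.

    ``pairs`` keeps every intersecting rsid, excluded ones flagged with a
    reason; downstream estimators use :meth:`valid` only.
    """

    exposure_id: str
    outcome_id: str
    pairs: pd.DataFrame = field(repr=False)

    @property
    def n_valid(self) -> int:
        return int((~self.pairs["excluded"]).sum())

    def valid(self) -> pd.DataFrame:
        return self.pairs.loc[~self.pairs["excluded"]].reset_index(drop=True)

    def iter_pairs(self, include_excluded: bool = False) -> Iterator[HarmonizedPair]:
        src = self.pairs if include_excluded else self.valid()
        for r in src.itertuples(index=False):
            yield HarmonizedPair(r.rsid, r.ea, float(r.beta_x), float(r.se_x),
                                 float(r.eaf_x), float(r.beta_y), float(r.se_y),
                                 float(r.eaf_y), r.action, bool(r.excluded),
                                 r.exclusion_reason)

    def exclusions(self) -> pd.DataFrame:
        """Audit table `rsid exposure outcome reason` of excluded variants."""
        ex = self.pairs.loc[self.pairs["excluded"], ["rsid", "exclusion_reason"]].copy()
        ex.insert(1, "exposure", self.exposure_id)
        ex.insert(2, "outcome", self.outcome_id)
        return ex.rename(columns={"exclusion_reason": "reason"}).reset_index(drop=True)


def harmonize(exposure: SumStatTable, outcome: SumStatTable,
              palindrome_maf_threshold: float = 0.42) -> HarmonizedDataset:
    """Align outcome effects to the exposure's effect allele.

    Rules, applied to the rsid intersection of the two tables:

    * identical allele pair -> kept as is (``aligned``);
    * swapped allele pair (or its strand complement, for non-palindromic
      SNPs) -> outcome beta negated and eaf replaced by 1 - eaf (``flipped``);
    * palindromic SNPs: excluded when min(eaf, 1-eaf) > threshold in either
      table, or when eaf is missing in either; otherwise oriented by
      frequency concordance — flip iff |eaf_x - eaf_y| > |eaf_x - (1-eaf_y)|
      (``freq_inferred`` when the frequency rule flips or overrides the allele
      labels, ``aligned`` when labels and frequencies already agree);
    * irreconcilable allele pairs -> excluded (``allele_mismatch``).
    """
    if not (0 < palindrome_maf_threshold < 0.5):
        raise ConfigurationError("palindrome_maf_threshold must lie in (0, 0.5)")

    m = exposure.df.merge(outcome.df, on="rsid", suffixes=("_x", "_y"))
    if m.empty:
        raise HarmonizationError(
            f"no shared variants between exposure {exposure.trait_id!r} "
            f"and outcome {outcome.trait_id!r}")

    ea_x = m["ea_x"].to_numpy(dtype=object)
    nea_x = m["nea_x"].to_numpy(dtype=object)
    ea_y = m["ea_y"].to_numpy(dtype=object)
    nea_y = m["nea_y"].to_numpy(dtype=object)

    comp_ea_y = np.array([_complement(a) for a in ea_y], dtype=object)
    comp_nea_y = np.array([_complement(a) for a in nea_y], dtype=object)

    is_snp = np.array([len(a) == 1 and len(b) == 1 and len(c) == 1 and len(d) == 1
                       for a, b, c, d in zip(ea_x, nea_x, ea_y, nea_y)])
    pal_x = np.array([is_palindromic(a, b) for a, b in zip(ea_x, nea_x)])
    pal_y = np.array([is_palindromic(a, b) for a, b in zip(ea_y, nea_y)])

    same = (ea_y == ea_x) & (nea_y == nea_x)
    swap = (ea_y == nea_x) & (nea_y == ea_x)
    same_c = is_snp & (comp_ea_y == ea_x) & (comp_nea_y == nea_x)
    swap_c = is_snp & (comp_ea_y == nea_x) & (comp_nea_y == ea_x)

    eaf_x = m["eaf_x"].to_numpy(dtype=float)
    eaf_y = m["eaf_y"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        maf_x = np.minimum(eaf_x, 1.0 - eaf_x)
        maf_y = np.minimum(eaf_y, 1.0 - eaf_y)

    n_var = len(m)
    flip = np.zeros(n_var, dtype=bool)
    excluded = np.zeros(n_var, dtype=bool)
    reason = np.array([""] * n_var, dtype=object)
    action = np.array(["aligned"] * n_var, dtype=object)

    pal = pal_x & is_snp
    nonpal = ~pal

    # --- non-palindromic variants (and indels) ---------------------------
    aligned_np = nonpal & (same | same_c)
    flipped_np = nonpal & ~aligned_np & (swap | swap_c)
    mismatch_np = nonpal & ~aligned_np & ~flipped_np
    flip[flipped_np] = True
    action[flipped_np] = "flipped"
    excluded[mismatch_np] = True
    reason[mismatch_np] = "allele_mismatch"

    # --- palindromic SNPs ------------------------------------------------
    pal_setmatch = pal & pal_y & (same | swap)
    pal_mismatch = pal & ~pal_setmatch
    excluded[pal_mismatch] = True
    reason[pal_mismatch] = "allele_mismatch"

    with np.errstate(invalid="ignore"):
        pal_intermediate = pal_setmatch & (
            (maf_x > palindrome_maf_threshold) | (maf_y > palindrome_maf_threshold))
    excluded[pal_intermediate] = True
    reason[pal_intermediate] = "palindromic_intermediate_maf"

    pal_noeaf = pal_setmatch & ~pal_intermediate & (np.isnan(eaf_x) | np.isnan(eaf_y))
    excluded[pal_noeaf] = True
    reason[pal_noeaf] = "palindromic_missing_eaf"

    # orientation of retained palindromes from frequency concordance alone:
    # labels cannot distinguish strands for a palindromic pair
    pal_keep = pal_setmatch & ~pal_intermediate & ~pal_noeaf
    pal_flip = pal_keep & (np.abs(eaf_x - eaf_y) > np.abs(eaf_x - (1.0 - eaf_y)))
    flip[pal_flip] = True
    # freq_inferred unless labels and frequencies already agree with no flip
    freq_inferred = pal_keep & (pal_flip | ~same)
    action[freq_inferred] = "freq_inferred"

    n_pal_dropped = int(pal_noeaf.sum())
    if n_pal_dropped:
        logger.warning("harmonize(%s, %s): %d palindromic variant(s) without eaf excluded",
                       exposure.trait_id, outcome.trait_id, n_pal_dropped)

    beta_y = m["beta_y"].to_numpy(dtype=float).copy()
    beta_y[flip] = -beta_y[flip]
    eaf_y_out = eaf_y.copy()
    eaf_y_out[flip] = 1.0 - eaf_y_out[flip]

    pairs = pd.DataFrame({
        "rsid": m["rsid"],
        "chrom": m["chrom_x"],
        "pos": m["pos_x"],
        "ea": m["ea_x"],
        "nea": m["nea_x"],
        "beta_x": m["beta_x"].to_numpy(dtype=float),
        "se_x": m["se_x"].to_numpy(dtype=float),
        "eaf_x": eaf_x,
        "pval_x": m["pval_x"].to_numpy(dtype=float),
        "n_x": m["n_x"],
        "beta_y": beta_y,
        "se_y": m["se_y"].to_numpy(dtype=float),
        "eaf_y": eaf_y_out,
        "pval_y": m["pval_y"].to_numpy(dtype=float),
        "n_y": m["n_y"],
        "action": action,
        "excluded": excluded,
        "exclusion_reason": reason,
    })
    return HarmonizedDataset(exposure_id=exposure.trait_id,
                             outcome_id=outcome.trait_id, pairs=pairs)


def write_exclusion_audit(datasets: list[HarmonizedDataset], path) -> None:
    """Concatenate the per-dataset exclusion audits into one TSV."""
    frames = [d.exclusions() for d in datasets]
    audit = (pd.concat(frames, ignore_index=True) if frames
             else pd.DataFrame(columns=["rsid", "exposure", "outcome", "reason"]))
    audit.to_csv(path, sep="\t", index=False)
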