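"""cis-pQTL instrument selection, strength, LD clumping and proxy lookup.

A cis-pQTL is a variant associated with a circulating protein (p <= 5e-8 by
default) lying within 1 Mb of the transcription start site of the protein's
gene.  Instrument strength is measured by the single-SNP F-statistic
(beta/se)^2; F > 10 is the conventional weak-instrument cutoff.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, PwmrError
from .sumstats import SumStatTable


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    chrom: str
    tss: int  # 1-based bp

    def __post_init__(self):
        if self.tss <= 0:
            raise ConfigurationError(f"gene {self.gene_id}: tss must be positive")


@dataclass
class LDMatrix:
    """Pairwise variant correlations (r, not r^2) over an ordered rsid list."""

    rsids: list[str]
    r: np.ndarray

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        k = len(self.rsids)
        if self.r.shape != (k, k):
            raise ConfigurationError("LD matrix dimension does not match rsid count")
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise ConfigurationError("LD matrix must be symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-8):
            raise ConfigurationError("LD matrix must have unit diagonal")
        self._index = {rs: i for i, rs in enumerate(self.rsids)}

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._index

    def index(self, rsid: str) -> int:
        try:
            return self._index[rsid]
        except KeyError:
            raise PwmrError(f"rsid {rsid!r} not present in LD matrix") from None

    def r2(self, a: str, b: str) -> float:
        return float(self.r[self.index(a), self.index(b)] ** 2)


def read_ld_matrix(path) -> LDMatrix:
    """Read the plain-text LD format: header of rsids, then matrix rows."""
    with open(path) as fh:
        rsids = fh.readline().split()
        r = np.loadtxt(fh, ndmin=2)
    return LDMatrix(rsids=rsids, r=r)


def write_ld_matrix(ld: LDMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(" ".join(ld.rsids) + "\n")
        np.savetxt(fh, ld.r, fmt="%.10g")


@dataclass(frozen=True)
class Instrument:
    """A selected cis-pQTL with its exposure association and strength."""

    rsid: str
    gene_id: str
    beta_x: float
    se_x: float
    eaf: float
    pval: float
    n: int
    f_stat: float
    distance_to_tss: int


def f_statistic(beta: float, se: float) -> float:
    """Single-SNP instrument-strength F-statistic, (beta/se)^2."""
    if se <= 0:
        raise ValueError(f"standard error must be positive, got {se}")
    return (beta / se) ** 2


def select_cis_instruments(table: SumStatTable, gene: GeneAnnotation,
                           window: int = 1_000_000, p_max: float = 5e-8,
                           f_min: float = 10.0, ld: LDMatrix | None = None,
                           r2_clump: float = 0.001) -> list[Instrument]:
    """Select cis instruments for one protein.

    Variants pass when they sit on the gene's chromosome within ``window`` bp
    of the TSS, reach ``p_max``, and have F > ``f_min``.  With an LD matrix,
    survivors are greedily clumped by ascending p-value (ties broken by rsid)
    so every retained pair has r^2 <= ``r2_clump``.  Returns an empty list when
    nothing passes.
    """
    df = table.df
    dist = df["pos"].to_numpy(np.int64) - gene.tss
    with np.errstate(divide="ignore"):
        f = (df["beta"].to_numpy(float) / df["se"].to_numpy(float)) ** 2
    keep = (
        (df["chrom"].to_numpy(dtype=object) == gene.chrom)
        & (np.abs(dist) <= window)
        & (df["pval"].to_numpy(float) <= p_max)
        & (f > f_min)
    )
    cand = df.loc[keep].assign(f_stat=f[keep], distance_to_tss=dist[keep])
    cand = cand.sort_values(["pval", "rsid"], kind="mergesort").reset_index(drop=True)

    retained_idx: list[int] = []
    for i in range(len(cand)):
        rs_i = cand.at[i, "rsid"]
        if ld is not None and rs_i in ld:
            if any(cand.at[j, "rsid"] in ld
                   and ld.r2(rs_i, cand.at[j, "rsid"]) > r2_clump
                   for j in retained_idx):
                continue
        retained_idx.append(i)

    return [
        Instrument(rsid=cand.at[i, "rsid"], gene_id=gene.gene_id,
                   beta_x=float(cand.at[i, "beta"]), se_x=float(cand.at[i, "se"]),
                   eaf=float(cand.at[i, "eaf"]), pval=float(cand.at[i, "pval"]),
                   n=int(cand.at[i, "n"]), f_stat=float(cand.at[i, "f_stat"]),
                   distance_to_tss=int(cand.at[i, "distance_to_tss"]))
        for i in retained_idx
    ]


def find_proxy(rsid: str, outcome: SumStatTable, ld: LDMatrix,
               r2_min: float = 0.8) -> str | None:
    """Best LD proxy for ``rsid`` present in the outcome table.

    Returns the rsid itself when present (r^2 = 1), otherwise the outcome
    variant with maximal r^2 >= ``r2_min`` (ties broken by rsid string order),
    or None.
    """
    i = ld.index(rsid)  # raises if absent
    outcome_rsids = set(outcome.df["rsid"])
    if rsid in outcome_rsids:
        return rsid
    best: tuple[float, str] | None = None
    for cand in sorted(outcome_rsids):
        if cand not in ld:
            continue
        r2 = float(ld.r[i, ld.index(cand)] ** 2)
        if r2 >= r2_min and (best is None or r2 > best[0]):
            best = (r2, cand)
    return best[1] if best else None
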