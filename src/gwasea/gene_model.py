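"""Gene annotation model: transcript collapsing, boundary extension, SNP assignment.

Genes are read from UCSC refFlat annotation, collapsed to one record per gene
symbol spanning the most extreme transcript start/end over all isoforms, and
extended by fixed physical distances upstream and downstream (the defaults,
110 kb upstream / 40 kb downstream, capture the large majority of cis-acting
regulatory variation around a gene; a symmetric +/-50 kb alternative is common
for sparser genotyping panels).  Every SNP whose position falls inside a gene's
extended region is assigned to that gene; a SNP may belong to several
overlapping regions.

Coordinate convention: refFlat txStart is 0-based and txEnd 1-based (UCSC);
internally everything is 1-based with closed intervals, so a SNP exactly on a
region boundary is assigned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Smallest p-value substituted for p == 0 at load time (needed for the
#: normal-quantile transform, which is undefined at 0).
MIN_P = 1e-300

REFFLAT_N_COLUMNS = 11

SNP_COLUMNS = ("snp", "chrom", "pos", "p")


class InputError(ValueError):
    """Raised when an input file fails validation."""


@dataclass(frozen=True)
class GeneRecord:
    """A collapsed gene: one symbol, one chromosome, extreme transcript span."""

    gene_symbol: str
    chrom: str
    strand: str  # '+' or '-'
    tx_start: int  # 1-based inclusive
    tx_end: int  # 1-based inclusive

    def __post_init__(self) -> None:
        if self.tx_start >= self.tx_end:
            raise ValueError(
                f"{self.gene_symbol}: tx_start {self.tx_start} >= tx_end {self.tx_end}"
            )


@dataclass
class GeneRegion:
    """A gene with extended boundaries and (after assignment) its SNP indices."""

    gene: GeneRecord
    region_start: int
    region_end: int
    snp_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.intp))

    @property
    def n_snps(self) -> int:
        return int(len(self.snp_indices))

    @property
    def size_bp(self) -> int:
        return self.region_end - self.region_start + 1


@dataclass(frozen=True)
class BoundaryConfig:
    """Physical distances added around the extreme transcript boundaries.

    With ``strand_aware`` (default) "upstream" is 5' of the gene, so minus-strand
    genes are extended by ``upstream_bp`` on their right.  Disable it for exact
    symmetric-boundary behaviour regardless of strand.
    """

    upstream_bp: int = 110_000
    downstream_bp: int = 40_000
    strand_aware: bool = True

    def __post_init__(self) -> None:
        if self.upstream_bp < 0 or self.downstream_bp < 0:
            raise ValueError("boundary extensions must be non-negative")

    @classmethod
    def symmetric_50kb(cls, strand_aware: bool = False) -> "BoundaryConfig":
        return cls(upstream_bp=50_000, downstream_bp=50_000, strand_aware=strand_aware)


def normalize_chrom(chrom: str) -> str:
    """Strip an optional 'chr' prefix so 'chr1' and '1' compare equal."""
    c = str(chrom).strip()
    return c[3:] if c.lower().startswith("chr") else c


def load_refflat(path, max_span_bp: int = 1_000_000) -> list[GeneRecord]:
    """Read refFlat annotation and collapse transcripts into genes.

    One :class:`GeneRecord` is returned per retained gene symbol, spanning the
    minimum transcript start and maximum transcript end over all its isoforms.
    A gene is excluded when its transcripts lie on different chromosomes, or
    when it has two or more transcripts and the collapsed span exceeds
    ``max_span_bp`` (annotation artefacts: same symbol reused for distant
    loci), or when its transcripts disagree on strand.  Exclusions are logged.

    Raises
    ------
    InputError
        If a line does not have the 11 tab-separated refFlat columns or has
        non-numeric coordinates.
    """
    per_gene: dict[str, dict] = {}
    with open(path, "rt") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != REFFLAT_N_COLUMNS:
                raise InputError(
                    f"{path}: line {lineno}: expected {REFFLAT_N_COLUMNS} "
                    f"tab-separated refFlat columns, got {len(fields)}"
                )
            symbol, _name, chrom, strand = fields[0], fields[1], fields[2], fields[3]
            try:
                tx_start = int(fields[4]) + 1  # 0-based -> 1-based inclusive
                tx_end = int(fields[5])
            except ValueError as exc:
                raise InputError(
                    f"{path}: line {lineno}: non-integer transcript coordinate"
                ) from exc
            if strand not in ("+", "-"):
                raise InputError(f"{path}: line {lineno}: bad strand {strand!r}")
            chrom = normalize_chrom(chrom)
            entry = per_gene.setdefault(
                symbol,
                {"chroms": set(), "strands": set(), "start": tx_start, "end": tx_end, "n": 0},
            )
            entry["chroms"].add(chrom)
            entry["strands"].add(strand)
            entry["start"] = min(entry["start"], tx_start)
            entry["end"] = max(entry["end"], tx_end)
            entry["n"] += 1

    genes: list[GeneRecord] = []
    n_multi_chrom = n_span = n_strand = 0
    for symbol, entry in per_gene.items():
        if len(entry["chroms"]) > 1:
            n_multi_chrom += 1
            continue
        if entry["n"] >= 2 and entry["end"] - entry["start"] > max_span_bp:
            n_span += 1
            continue
        if len(entry["strands"]) > 1:
            n_strand += 1
            logger.warning("gene %s: transcripts disagree on strand; excluded", symbol)
            continue
        genes.append(
            GeneRecord(
                gene_symbol=symbol,
                chrom=next(iter(entry["chroms"])),
                strand=next(iter(entry["strands"])),
                tx_start=entry["start"],
                tx_end=entry["end"],
            )
        )
    logger.info(
        "load_refflat: %d genes retained; excluded %d multi-chromosome, "
        "%d span>%d bp, %d strand-conflict",
        len(genes), n_multi_chrom, n_span, max_span_bp, n_strand,
    )
    return genes


def read_snp_table(path) -> pd.DataFrame:
    """Read a SNP association table (columns SNP, CHR, POS, P, case-insensitive).

    Tab- or whitespace-delimited with a header line; extra columns are ignored.
    Rows with missing or out-of-range p-values are dropped (counted in the log);
    p == 0 is clamped to a tiny positive value so the z-transform is defined.
    Returns a DataFrame with columns ``snp, chrom, pos, p``.
    """
    df = pd.read_csv(path, sep=r"\s+", dtype={0: str})
    lower = {c.lower(): c for c in df.columns}
    required = {"snp": "snp", "chr": "chrom", "pos": "pos", "p": "p"}
    missing = [k for k in required if k not in lower]
    if missing:
        raise InputError(
            f"{path}: missing required column(s) {missing} "
            f"(have {list(df.columns)}; SNP/CHR/POS/P expected, case-insensitive)"
        )
    out = pd.DataFrame(
        {
            "snp": df[lower["snp"]].astype(str),
            "chrom": df[lower["chr"]].astype(str).map(normalize_chrom),
            "pos": pd.to_numeric(df[lower["pos"]], errors="coerce"),
            "p": pd.to_numeric(df[lower["p"]], errors="coerce"),
        }
    )
    n_in = len(out)
    out = out.dropna(subset=["pos", "p"])
    out = out[(out["p"] >= 0) & (out["p"] <= 1) & (out["pos"] >= 1)]
    n_dropped = n_in - len(out)
    if n_dropped:
        logger.warning("read_snp_table: dropped %d SNPs with invalid pos/p", n_dropped)
    n_zero = int((out["p"] == 0).sum())
    if n_zero:
        logger.warning("read_snp_table: clamped %d SNPs with p=0 to %g", n_zero, MIN_P)
        out.loc[out["p"] == 0, "p"] = MIN_P
    if out["snp"].duplicated().any():
        dups = out.loc[out["snp"].duplicated(), "snp"].head().tolist()
        raise InputError(f"{path}: duplicate SNP ids (e.g. {dups})")
    out["pos"] = out["pos"].astype(np.int64)
    return out.reset_index(drop=True)


def extend_boundaries(genes: list[GeneRecord], cfg: BoundaryConfig | None = None) -> list[GeneRegion]:
    """Extend each collapsed gene into its SNP-capture region.

    Plus-strand genes (and all genes when ``cfg.strand_aware`` is false) get
    ``upstream_bp`` added to the left and ``downstream_bp`` to the right; for
    minus-strand genes the two are mirrored.  Region starts are clipped to 1.
    """
    cfg = cfg or BoundaryConfig()
    regions = []
    for g in genes:
        if cfg.strand_aware and g.strand == "-":
            left, right = cfg.downstream_bp, cfg.upstream_bp
        else:
            left, right = cfg.upstream_bp, cfg.downstream_bp
        regions.append(
            GeneRegion(gene=g, region_start=max(1, g.tx_start - left), region_end=g.tx_end + right)
        )
    return regions


def assign_snps(regions: list[GeneRegion], snps: pd.DataFrame) -> list[GeneRegion]:
    """Fill ``snp_indices`` of each region with the table indices of SNPs inside it.

    Intervals are closed: a SNP exactly on a boundary is assigned.  Genes with
    zero SNPs keep an empty index array (they are excluded from scoring and
    enrichment later).  SNPs on chromosomes absent from the annotation are
    counted and logged.
    """
    out: list[GeneRegion] = []
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in snps.groupby("chrom", sort=False):
        order = np.argsort(sub["pos"].to_numpy(), kind="stable")
        idx = sub.index.to_numpy()[order]
        by_chrom[chrom] = (sub["pos"].to_numpy()[order], idx)

    region_chroms = {r.gene.chrom for r in regions}
    orphans = snps.loc[~snps["chrom"].isin(region_chroms)]
    if len(orphans):
        logger.warning(
            "assign_snps: %d SNPs on %d chromosome(s) absent from the annotation",
            len(orphans), orphans["chrom"].nunique(),
        )

    for r in regions:
        pos_sorted, idx_sorted = by_chrom.get(r.gene.chrom, (np.empty(0, np.int64), np.empty(0, np.intp)))
        lo = np.searchsorted(pos_sorted, r.region_start, side="left")
        hi = np.searchsorted(pos_sorted, r.region_end, side="right")
        out.append(replace(r, snp_indices=np.sort(idx_sorted[lo:hi])))
    n_empty = sum(1 for r in out if r.n_snps == 0)
    if n_empty:
        logger.info("assign_snps: %d genes have no SNPs in their extended boundaries", n_empty)
    return out


def regions_to_frame(regions: list[GeneRegion]) -> pd.DataFrame:
    """Per-gene region table (gene, chrom, strand, region_start, region_end, n_snps)."""
    return pd.DataFrame(
        {
            "gene": [r.gene.gene_symbol for r in regions],
            "chrom": [r.gene.chrom for r in regions],
            "strand": [r.gene.strand for r in regions],
            "region_start": [r.region_start for r in regions],
            "region_end": [r.region_end for r in regions],
            "n_snps": [r.n_snps for r in regions],
        }
    )


def write_regions(regions: list[GeneRegion], path) -> None:
    regions_to_frame(regions).to_csv(path, sep="\t", index=False)


def flatten_assignment(regions: list[GeneRegion]) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate per-gene SNP indices into (flat_indices, offsets).

    ``offsets`` has length ``len(regions) + 1``; gene ``i`` owns
    ``flat_indices[offsets[i]:offsets[i+1]]``.  This is the layout the scoring
    and simulation hot paths use (per-gene minima via ``np.minimum.reduceat``).
    """
    counts = np.array([r.n_snps for r in regions], dtype=np.intp)
    offsets = np.concatenate([[0], np.cumsum(counts)])
    if offsets[-1] == 0:
        return np.empty(0, dtype=np.intp), offsets
    flat = np.concatenate([r.snp_indices for r in regions if r.n_snps > 0])
    return flat.astype(np.intp, copy=False), offsets
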