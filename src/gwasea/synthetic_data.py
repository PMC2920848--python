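"""Self-contained synthetic genomes for testing and power simulation.

The generator emulates the structural features of a real GWAS genome that
drive confounding of best-SNP gene scores — log-normal gene sizes,
gamma-distributed per-gene SNP density (more SNPs => stochastically smaller
minimum p-value under the null), a controllable fraction of genes with no
SNPs in range, recombination-hotspot intervals, cumulative genetic and LD-unit
maps, and an LD-pruned "independent SNP" list.  SNP association p-values are
drawn i.i.d. Uniform(0,1): LD between markers is deliberately not modelled,
so the confounding exercised here is the size/density artefact plus the
planted map resources, not correlated p-values.

Two density presets bracket common study designs: a genotyped-scan-like map
(~1 SNP / 8 kb, symmetric +/-50 kb gene boundaries) and an imputed
meta-analysis-like map (~1 SNP / 1.3 kb, -110 kb/+40 kb boundaries).

Everything is deterministic given the spec's seed, and all emitted files
round-trip through this package's readers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covariates import compute_covariates
from .enrichment import GeneSet, write_gmt
from .gene_model import (
    BoundaryConfig,
    GeneRecord,
    GeneRegion,
    assign_snps,
    extend_boundaries,
    flatten_assignment,
)

CM_PER_MB = 1.13  # genome-average recombination rate
LDU_PER_MB = 15.0


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Parameters of a synthetic genome; defaults give a genotyped-scan-like map."""

    n_genes: int = 17_000
    n_chromosomes: int = 22
    gene_size_log_mean: float = math.log(24_000.0)  # median transcript span ~24 kb
    gene_size_log_sd: float = 1.0
    snp_density_mean: float = 1.0 / 8_000.0  # SNPs per bp
    snp_density_shape: float = 3.0  # gamma shape: ~10x density range across genes
    fraction_genes_no_snps: float = 0.0
    hotspot_rate_per_mb: float = 11.0
    map_marker_spacing_bp: int = 30_000
    map_noise: float = 0.1
    indep_fraction: float = 0.7
    overlap_fraction: float = 0.0  # fraction of genes whose extended region overlaps the previous gene's
    mean_extra_gap_bp: float = 30_000.0
    boundary: BoundaryConfig = field(
        default_factory=lambda: BoundaryConfig.symmetric_50kb(strand_aware=False)
    )
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1 or self.n_chromosomes < 1:
            raise ValueError("n_genes and n_chromosomes must be positive")
        if not (0 <= self.fraction_genes_no_snps < 1):
            raise ValueError("fraction_genes_no_snps must be in [0, 1)")
        if not (0 <= self.overlap_fraction < 1):
            raise ValueError("overlap_fraction must be in [0, 1)")
        for name in ("snp_density_mean", "snp_density_shape", "hotspot_rate_per_mb"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def genotyped_scan(cls, **kw) -> "SyntheticGenomeSpec":
        """~1 SNP/8 kb, +/-50 kb symmetric boundaries (genotyped single-scan-like)."""
        return cls(**kw)

    @classmethod
    def imputed_meta(cls, **kw) -> "SyntheticGenomeSpec":
        """~1 SNP/1.3 kb, -110 kb/+40 kb boundaries (imputed meta-analysis-like)."""
        kw.setdefault("snp_density_mean", 1.0 / 1_300.0)
        kw.setdefault("boundary", BoundaryConfig(110_000, 40_000, strand_aware=True))
        return cls(**kw)


@dataclass
class SyntheticGenome:
    """A generated genome: annotation, SNP map, covariate resources, fast-path layout."""

    spec: SyntheticGenomeSpec
    genes: list[GeneRecord]
    regions: list[GeneRegion]  # SNP indices assigned
    snps: pd.DataFrame  # snp, chrom, pos (no p)
    covariates: pd.DataFrame
    hotspots: pd.DataFrame
    genetic_map: pd.DataFrame
    ldu_map: pd.DataFrame
    indep_snp_ids: set[str]
    regions_disjoint: bool
    flat_idx: np.ndarray
    offsets: np.ndarray
    planted_density: np.ndarray = None  # per-gene SNP rate actually used (per bp)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def gene_symbols(self) -> list[str]:
        return [g.gene_symbol for g in self.genes]

    def draw_null_p(self, rng: np.random.Generator) -> np.ndarray:
        """One null association scan: i.i.d. Uniform(0,1) p-value per SNP."""
        return rng.uniform(size=self.n_snps)

    def null_associations(self, seed: int) -> pd.DataFrame:
        """Null SNP association table (snp, chrom, pos, p) for a given seed."""
        out = self.snps.copy()
        out["p"] = self.draw_null_p(np.random.default_rng([int(seed), 0xA550]))
        return out

    def null_score_stack(self, n_replicates: int, seed: int) -> np.ndarray:
        """(n_genes, n_replicates) matrix of null best-SNP p-values, rows in gene order."""
        from .scoring import min_p_per_gene

        rng = np.random.default_rng([int(seed), 0x57AC])
        out = np.empty((len(self.genes), n_replicates))
        for j in range(n_replicates):
            out[:, j] = min_p_per_gene(self.draw_null_p(rng), self.flat_idx, self.offsets)
        return out

    def to_files(self, outdir, seed: int | None = None) -> dict[str, str]:
        """Write the full fixture directory; returns {resource: path}.

        The SNP table's p-values are a null draw with ``seed`` (defaults to the
        genome spec's seed).
        """
        import os

        os.makedirs(outdir, exist_ok=True)
        seed = self.spec.seed if seed is None else seed
        paths = {k: os.path.join(outdir, v) for k, v in {
            "refflat": "genes.refflat",
            "snps": "associations.tsv",
            "hotspots": "hotspots.bed",
            "genetic_map": "genetic_map.tsv",
            "ldu_map": "ldu_map.tsv",
            "indep_snps": "indep_snps.txt",
        }.items()}

        with open(paths["refflat"], "wt") as fh:
            for g in self.genes:
                tx0 = g.tx_start - 1  # back to 0-based refFlat start
                fh.write(
                    "\t".join(
                        [
                            g.gene_symbol, f"{g.gene_symbol}.1", f"chr{g.chrom}", g.strand,
                            str(tx0), str(g.tx_end), str(tx0), str(g.tx_end),
                            "1", f"{tx0},", f"{g.tx_end},",
                        ]
                    )
                    + "\n"
                )

        assoc = self.null_associations(seed)
        assoc.rename(columns={"snp": "SNP", "chrom": "CHR", "pos": "POS", "p": "P"}).to_csv(
            paths["snps"], sep="\t", index=False, float_format="%.10g"
        )
        hs = self.hotspots.copy()
        hs["start"] = hs["start"] - 1  # closed 1-based -> half-open BED
        hs.to_csv(paths["hotspots"], sep="\t", index=False, header=False)
        self.genetic_map.to_csv(paths["genetic_map"], sep="\t", index=False, header=False,
                                float_format="%.8g")
        self.ldu_map.to_csv(paths["ldu_map"], sep="\t", index=False, header=False,
                            float_format="%.8g")
        with open(paths["indep_snps"], "wt") as fh:
            for sid in sorted(self.indep_snp_ids):
                fh.write(sid + "\n")
        return paths


def generate_genome(spec: SyntheticGenomeSpec) -> SyntheticGenome:
    """Build a synthetic genome deterministically from its spec."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_genes
    spans = np.exp(rng.normal(spec.gene_size_log_mean, spec.gene_size_log_sd, n))
    spans = np.clip(spans, 500, 1.5e6).astype(np.int64)
    density = rng.gamma(spec.snp_density_shape, spec.snp_density_mean / spec.snp_density_shape, n)
    if spec.fraction_genes_no_snps > 0:
        off = rng.random(n) < spec.fraction_genes_no_snps
        density[off] = 0.0
    strands = np.where(rng.random(n) < 0.5, "+", "-")

    left = max(spec.boundary.upstream_bp, spec.boundary.downstream_bp)
    right = left  # worst-case extension either side, for gap sizing
    min_gap = left + right + 1_000

    per_chrom = int(np.ceil(n / spec.n_chromosomes))
    genes: list[GeneRecord] = []
    overlaps_prev = np.zeros(n, dtype=bool)
    gi = 0
    for ci in range(spec.n_chromosomes):
        chrom = str(ci + 1)
        cursor = 100_000
        first = True
        n_on_chrom = 0
        while gi < n and n_on_chrom < per_chrom:
            if not first and rng.random() < spec.overlap_fraction:
                gap = int(rng.integers(1_000, max(2_000, min_gap // 4)))
                overlaps_prev[gi] = True
            else:
                gap = min_gap + int(rng.exponential(spec.mean_extra_gap_bp))
            tx_start = cursor + gap
            tx_end = tx_start + int(spans[gi])
            genes.append(
                GeneRecord(
                    gene_symbol=f"G{gi:05d}", chrom=chrom, strand=str(strands[gi]),
                    tx_start=tx_start, tx_end=tx_end,
                )
            )
            cursor = tx_end
            gi += 1
            n_on_chrom += 1
            first = False

    regions = extend_boundaries(genes, spec.boundary)

    # SNPs: Poisson count per extended region, uniform positions within it
    chroms_list, pos_list = [], []
    for r, dens in zip(regions, density):
        lam = dens * r.size_bp
        count = rng.poisson(lam) if lam > 0 else 0
        if count == 0:
            continue
        pos = np.unique(rng.integers(r.region_start, r.region_end + 1, size=count))
        chroms_list.append(np.full(len(pos), r.gene.chrom, dtype=object))
        pos_list.append(pos)
    if pos_list:
        snp_df = pd.DataFrame(
            {"chrom": np.concatenate(chroms_list), "pos": np.concatenate(pos_list)}
        )
    else:
        snp_df = pd.DataFrame({"chrom": pd.Series(dtype=object), "pos": pd.Series(dtype=np.int64)})
    snp_df["_c"] = snp_df["chrom"].astype(int)
    snp_df = snp_df.sort_values(["_c", "pos"], kind="stable").drop(columns="_c")
    snp_df = snp_df.drop_duplicates(["chrom", "pos"]).reset_index(drop=True)
    snp_df.insert(0, "snp", [f"rs{i + 1}" for i in range(len(snp_df))])

    regions = assign_snps(regions, snp_df)
    flat_idx, offsets = flatten_assignment(regions)

    # covariate resources
    chrom_len = {
        str(c + 1): max(
            [r.region_end for r in regions if r.gene.chrom == str(c + 1)] or [1_000_000]
        )
        + 200_000
        for c in range(spec.n_chromosomes)
    }
    hs_rows = []
    for chrom, L in chrom_len.items():
        k = rng.poisson(spec.hotspot_rate_per_mb * L / 1e6)
        centers = np.sort(rng.integers(1, L, size=k))
        for c in centers:
            hs_rows.append((chrom, max(1, c - 1_000), c + 1_000))
    hotspots = pd.DataFrame(hs_rows, columns=["chrom", "start", "end"])

    def _cumulative_map(rate_per_mb: float) -> pd.DataFrame:
        rows = []
        for chrom, L in chrom_len.items():
            pos = np.arange(1, L, spec.map_marker_spacing_bp, dtype=np.int64)
            d = np.diff(pos, prepend=0).astype(float)
            steps = rate_per_mb * d / 1e6
            steps *= np.clip(1.0 + spec.map_noise * rng.normal(size=len(steps)), 0.0, None)
            cum = np.cumsum(steps)
            rows.append(pd.DataFrame({"chrom": chrom, "pos": pos, "cum": cum}))
        return pd.concat(rows, ignore_index=True)

    genetic_map = _cumulative_map(CM_PER_MB)
    ldu_map = _cumulative_map(LDU_PER_MB)
    indep = set(snp_df.loc[rng.random(len(snp_df)) < spec.indep_fraction, "snp"])

    covs = compute_covariates(
        regions, snp_df, indep_snp_ids=indep, hotspots=hotspots,
        genetic_map=genetic_map, ldu_map=ldu_map,
    )

    return SyntheticGenome(
        spec=spec, genes=genes, regions=regions, snps=snp_df, covariates=covs,
        hotspots=hotspots, genetic_map=genetic_map, ldu_map=ldu_map,
        indep_snp_ids=indep, regions_disjoint=spec.overlap_fraction == 0.0,
        flat_idx=flat_idx, offsets=offsets, planted_density=density,
    )


def generate_null_associations(genome: SyntheticGenome, seed: int) -> pd.DataFrame:
    """Null association table for the genome (i.i.d. uniform p-values)."""
    return genome.null_associations(seed)


def generate_gene_sets(
    genome: SyntheticGenome,
    n_sets: int,
    size_range: tuple[int, int] = (10, 100),
    clustered_fraction: float = 0.0,
    seed: int = 0,
) -> list[GeneSet]:
    """Random gene sets over the genome's symbols.

    With ``clustered_fraction > 0``, that fraction of each set's slots is
    filled (where possible) with pairs of genes whose extended regions
    overlap — such pairs can be assigned the same best SNP and so exercise
    the physical-clustering pruning of the enrichment test.
    """
    rng = np.random.default_rng([int(seed), 0x6E75])
    symbols = np.array(genome.gene_symbols)
    # physically overlapping neighbour pairs (same chromosome, regions intersect)
    pairs = []
    for a, b in zip(genome.regions[:-1], genome.regions[1:]):
        if a.gene.chrom == b.gene.chrom and b.region_start <= a.region_end:
            pairs.append((a.gene.gene_symbol, b.gene.gene_symbol))
    sets = []
    lo, hi = size_range
    for si in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members: list[str] = []
        if clustered_fraction > 0 and pairs:
            n_pairs = min(int(round(clustered_fraction * size / 2)), len(pairs))
            chosen = rng.choice(len(pairs), size=n_pairs, replace=False)
            for ci in chosen:
                members.extend(pairs[ci])
            members = list(dict.fromkeys(members))  # adjacent pairs can share a gene
        pool = np.setdiff1d(symbols, np.array(members or ["_"], dtype=object))
        need = max(0, size - len(members))
        members.extend(rng.choice(pool, size=min(need, len(pool)), replace=False).tolist())
        sets.append(
            GeneSet(set_id=f"SET{si:04d}", description="synthetic", member_symbols=tuple(members))
        )
    return sets


def write_gene_sets(sets: list[GeneSet], path) -> None:
    write_gmt(sets, path)
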