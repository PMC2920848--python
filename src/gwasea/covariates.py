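"""Per-gene confounder covariates for the best-SNP score.

Under the null, a gene's best-SNP p-value is the minimum over however many
(partially correlated) SNPs its region contains, so region size, SNP density
and linkage structure systematically bias the raw score.  Six per-gene
properties quantify this:

======================  =============================================
``size_kb``             extended region size d_g, kb
``snps_per_kb``         assigned SNPs per kb, n_g
``indep_per_kb``        LD-pruned ("independent") SNPs per kb, u_g
``hotspots_per_kb``     recombination hotspots intersecting the region
                        per kb, h_g
``cm_per_kb``           genetic distance across the region, cM per kb
                        of marker span, c_g
``ldu_per_kb``          LD units across the region per kb of marker
                        span, l_g
======================  =============================================

All but ``size_kb`` are normalised per kilobase; the two map-based covariates
use the physical span between the outermost map markers inside the region.
Covariates whose resource is missing, or map covariates for genes with fewer
than two markers in range, are NaN (masked) and skipped or imputed downstream.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .gene_model import GeneRegion, InputError, normalize_chrom

logger = logging.getLogger(__name__)

COVARIATE_COLUMNS = [
    "size_kb", "snps_per_kb", "indep_per_kb", "hotspots_per_kb", "cm_per_kb", "ldu_per_kb",
]

#: Regression default: all but genetic distance (``cm_per_kb``), which is the
#: one property that is usually not a significant confounder once the others
#: are in the model.
DEFAULT_REGRESSION_COVARIATES = [
    "size_kb", "snps_per_kb", "indep_per_kb", "hotspots_per_kb", "ldu_per_kb",
]


def read_hotspots(path) -> pd.DataFrame:
    """BED-like 3-column hotspot intervals (chrom, start, end; half-open BED)."""
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                     names=["chrom", "start", "end"], usecols=[0, 1, 2])
    df["chrom"] = df["chrom"].astype(str).map(normalize_chrom)
    if (df["end"] <= df["start"]).any():
        raise InputError(f"{path}: hotspot intervals with end <= start")
    # BED half-open -> 1-based closed
    df["start"] = df["start"].astype(np.int64) + 1
    df["end"] = df["end"].astype(np.int64)
    return df


def read_cumulative_map(path) -> pd.DataFrame:
    """3-column cumulative map (chrom, pos, cumulative value), sorted per chromosome.

    Used for both the genetic (cM) and the LDU map.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                     names=["chrom", "pos", "cum"], usecols=[0, 1, 2])
    df["chrom"] = df["chrom"].astype(str).map(normalize_chrom)
    df["pos"] = df["pos"].astype(np.int64)
    for chrom, sub in df.groupby("chrom", sort=False):
        if not sub["pos"].is_monotonic_increasing:
            raise InputError(f"{path}: positions not sorted on chromosome {chrom}")
    return df


def read_indep_snps(path) -> set[str]:
    """One SNP id per line (the PLINK .prune.in dialect)."""
    with open(path, "rt") as fh:
        return {line.strip() for line in fh if line.strip()}


def _map_span_values(regions: list[GeneRegion], gmap: pd.DataFrame) -> np.ndarray:
    """Cumulative-map gradient per region: (cum_last - cum_first) / (kb between markers).

    NaN for genes with fewer than two map markers inside the region.  Invariant
    to adding a constant to the cumulative column.
    """
    out = np.full(len(regions), np.nan)
    by_chrom = {
        chrom: (sub["pos"].to_numpy(), sub["cum"].to_numpy())
        for chrom, sub in gmap.groupby("chrom", sort=False)
    }
    for i, r in enumerate(regions):
        if r.gene.chrom not in by_chrom:
            continue
        pos, cum = by_chrom[r.gene.chrom]
        lo = np.searchsorted(pos, r.region_start, side="left")
        hi = np.searchsorted(pos, r.region_end, side="right")
        if hi - lo < 2:
            continue
        span_kb = (pos[hi - 1] - pos[lo]) / 1000.0
        if span_kb <= 0:
            continue
        out[i] = (cum[hi - 1] - cum[lo]) / span_kb
    return out


def _hotspot_counts(regions: list[GeneRegion], hotspots: pd.DataFrame) -> np.ndarray:
    """Number of hotspot intervals intersecting each (closed) region."""
    out = np.zeros(len(regions))
    by_chrom = {}
    for chrom, sub in hotspots.groupby("chrom", sort=False):
        starts = np.sort(sub["start"].to_numpy())
        ends = np.sort(sub["end"].to_numpy())
        by_chrom[chrom] = (starts, ends)
    for i, r in enumerate(regions):
        if r.gene.chrom not in by_chrom:
            continue
        starts, ends = by_chrom[r.gene.chrom]
        # overlap <=> start <= region_end and end >= region_start
        n_start_ok = np.searchsorted(starts, r.region_end, side="right")
        n_end_before = np.searchsorted(ends, r.region_start, side="left")
        out[i] = n_start_ok - n_end_before
    return out


def compute_covariates(
    regions: list[GeneRegion],
    snps: pd.DataFrame,
    indep_snp_ids: set[str] | None = None,
    hotspots: pd.DataFrame | None = None,
    genetic_map: pd.DataFrame | None = None,
    ldu_map: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Covariate table indexed by gene symbol (NaN where a resource is missing)."""
    n = len(regions)
    size_kb = np.array([r.size_bp for r in regions], dtype=float) / 1000.0
    n_snps = np.array([r.n_snps for r in regions], dtype=float)

    out = pd.DataFrame(
        {
            "size_kb": size_kb,
            "snps_per_kb": n_snps / size_kb,
            "indep_per_kb": np.nan,
            "hotspots_per_kb": np.nan,
            "cm_per_kb": np.nan,
            "ldu_per_kb": np.nan,
        },
        index=pd.Index([r.gene.gene_symbol for r in regions], name="gene"),
    )

    if indep_snp_ids is not None:
        is_indep = snps["snp"].isin(indep_snp_ids).to_numpy()
        counts = np.array(
            [is_indep[r.snp_indices].sum() if r.n_snps else 0 for r in regions], dtype=float
        )
        out["indep_per_kb"] = counts / size_kb
    if hotspots is not None:
        out["hotspots_per_kb"] = _hotspot_counts(regions, hotspots) / size_kb
    if genetic_map is not None:
        out["cm_per_kb"] = _map_span_values(regions, genetic_map)
    if ldu_map is not None:
        out["ldu_per_kb"] = _map_span_values(regions, ldu_map)

    n_masked = int(out[COVARIATE_COLUMNS].isna().any(axis=1).sum())
    if n_masked:
        logger.info("compute_covariates: %d/%d genes have at least one masked covariate", n_masked, n)
    return out


def write_covariates(covs: pd.DataFrame, path) -> None:
    covs.reset_index().to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")
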