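"""Per-gene association scores from regional SNP p-values.

The gene score is the best (minimum) association p-value over all SNPs in the
gene's extended region — appropriate when one or a few causal variants per
gene are expected — mapped to a z-score via the one-tailed normal quantile
z = Phi^-1(1 - p), so smaller p means larger z.  The scoring reducer is
pluggable; best-SNP is the built-in default.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special

from .gene_model import GeneRegion, flatten_assignment

GENE_SCORE_COLUMNS = [
    "gene", "chrom", "n_snps", "best_snp", "p_best", "z_raw", "p_corrected",
]


def p_to_z(p):
    """One-tailed z-score for p in (0, 1]: z = Phi^-1(1 - p).

    Vectorised; p = 0.5 maps to 0, smaller p to larger z.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p must be in (0, 1]")
    # -ndtri(p) keeps full precision for small p, where it matters.
    out = -special.ndtri(p)
    return out if out.ndim else float(out)


def z_to_p(z):
    """Inverse of :func:`p_to_z`: p = 1 - Phi(z), computed as Phi(-z)."""
    z = np.asarray(z, dtype=float)
    out = special.ndtr(-z)
    return out if out.ndim else float(out)


def min_p_per_gene(p: np.ndarray, flat_idx: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    """Per-gene minimum of ``p[flat_idx]`` over the slices defined by ``offsets``.

    Genes with no SNPs (empty slice) get NaN.  This is the vectorised core used
    both by :func:`score_genes` and the power-simulation hot path.
    """
    n_genes = len(offsets) - 1
    out = np.full(n_genes, np.nan)
    nonempty = np.flatnonzero(np.diff(offsets) > 0)
    if len(nonempty) == 0:
        return out
    vals = p[flat_idx]
    out[nonempty] = np.minimum.reduceat(vals, offsets[nonempty])
    return out


def score_genes(
    regions: list[GeneRegion],
    snps: pd.DataFrame,
    reducer=None,
) -> pd.DataFrame:
    """Compute the per-gene score table from assigned regions.

    Returns a DataFrame indexed by gene symbol with columns ``chrom, n_snps,
    best_snp, p_best, z_raw, excluded_no_snps``.  Ties on the minimal p-value
    are broken by smallest position, then lexicographic SNP id, so results are
    deterministic.  Genes with no SNPs are retained with NaN scores and
    ``excluded_no_snps=True``.

    ``reducer``, if given, is a callable mapping the gene's SNP sub-table
    (columns snp/chrom/pos/p) to a scalar gene p-value; the best-SNP identity
    is then the argmin row regardless of the reducer's value.
    """
    p_arr = snps["p"].to_numpy()
    pos_arr = snps["pos"].to_numpy()
    snp_ids = snps["snp"].to_numpy()

    genes = [r.gene.gene_symbol for r in regions]
    chroms = [r.gene.chrom for r in regions]
    n_snps = np.array([r.n_snps for r in regions], dtype=int)

    p_best = np.full(len(regions), np.nan)
    best_snp = np.full(len(regions), None, dtype=object)
    for i, r in enumerate(regions):
        if r.n_snps == 0:
            continue
        idx = r.snp_indices
        sub_p = p_arr[idx]
        if reducer is not None:
            p_best[i] = float(reducer(snps.iloc[idx]))
        # deterministic argmin: p, then position, then snp id
        order = np.lexsort((snp_ids[idx], pos_arr[idx], sub_p))
        j = idx[order[0]]
        if reducer is None:
            p_best[i] = p_arr[j]
        best_snp[i] = snp_ids[j]

    with np.errstate(invalid="ignore"):
        z_raw = np.where(np.isnan(p_best), np.nan, -special.ndtri(np.where(np.isnan(p_best), 0.5, p_best)))

    out = pd.DataFrame(
        {
            "chrom": chroms,
            "n_snps": n_snps,
            "best_snp": best_snp,
            "p_best": p_best,
            "z_raw": z_raw,
            "excluded_no_snps": n_snps == 0,
        },
        index=pd.Index(genes, name="gene"),
    )
    return out


def score_genes_fast(
    p: np.ndarray, flat_idx: np.ndarray, offsets: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(p_best, z_raw) arrays straight from the flat assignment layout.

    No tie-breaking bookkeeping or best-SNP identity — the numeric fast path
    for simulations, where only the score values matter.
    """
    p_best = min_p_per_gene(p, flat_idx, offsets)
    z_raw = np.full_like(p_best, np.nan)
    ok = ~np.isnan(p_best)
    z_raw[ok] = -special.ndtri(p_best[ok])
    return p_best, z_raw


def write_gene_scores(scores: pd.DataFrame, path) -> None:
    """Gene-score TSV with fixed columns; NA for genes without SNPs."""
    df = scores.reset_index()
    for col in GENE_SCORE_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df[GENE_SCORE_COLUMNS].to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")
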