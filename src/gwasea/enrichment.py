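"""Gene-set enrichment test on corrected gene p-values.

The test asks whether a predefined gene set is over-represented among the
most significant genes in the genome.  Its ingredients:

* an **enrichment cutoff**: the corrected gene p-value at a given percentile
  of significance over all scored genes (default: the 95th percentile, i.e.
  the top 5% most significant genes form the "leading edge");
* **physical-clustering pruning**: within each subset of set members that
  share the same best SNP (physically proximal genes capturing one signal),
  only the gene with the most significant corrected score is kept, so one
  associated locus cannot be counted twice;
* the **leading-edge fraction**: the fraction of the pruned set's members
  beyond the cutoff;
* a **sampling null**: gene sets of the same (effective) size drawn uniformly
  from all scored genes, each pruned the same way; the nominal enrichment
  p-value is the fraction of sampled sets whose leading-edge fraction is at
  least the observed one.  When no two scored genes share a best SNP, the
  null is exactly hypergeometric and is evaluated in closed form.

Bonferroni correction across the sets tested in one batch is applied at the
end.  A one-tailed Mann-Whitney rank-sum variant of the statistic is provided
as a robustness check.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF_PERCENTILE = 95.0
DEFAULT_N_NULL = 10_000
DEFAULT_MAX_N_NULL = 1_000_000
DEFAULT_MIN_SET_SIZE = 10
ADAPTIVE_THRESHOLD = 1e-4


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    description: str
    member_symbols: tuple[str, ...]

    def __post_init__(self):
        if not self.member_symbols:
            raise ValueError(f"gene set {self.set_id}: empty member list")


@dataclass
class EnrichmentResult:
    set_id: str
    n_input: int
    n_no_snps: int
    n_pruned_clustering: int
    n_effective: int
    leading_edge_fraction: float
    cutoff_percentile: float
    cutoff_value: float
    p_nominal: float
    p_bonferroni: float
    n_null_sets_used: int
    method: str  # "cutoff" or "ranksum"
    null_method: str  # "sampled" or "hypergeom"
    below_min_size: bool = False

    def as_row(self) -> dict:
        return {
            "set": self.set_id,
            "n_genes": self.n_input,
            "n_no_snps": self.n_no_snps,
            "n_pruned_clustering": self.n_pruned_clustering,
            "n_effective": self.n_effective,
            "leading_edge_fraction": self.leading_edge_fraction,
            "p_nominal": self.p_nominal,
            "p_bonferroni": self.p_bonferroni,
            "method": self.method,
            "null_method": self.null_method,
            "n_null_sets": self.n_null_sets_used,
            "below_min_size": self.below_min_size,
        }


def read_gmt(path) -> list[GeneSet]:
    """GMT: tab-separated ``set_id <TAB> description <TAB> member1 <TAB> ...``."""
    sets: list[GeneSet] = []
    with open(path, "rt") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: GMT needs id, description, >=1 member")
            members = tuple(m for m in fields[2:] if m)
            sets.append(GeneSet(set_id=fields[0], description=fields[1], member_symbols=members))
    return sets


def write_gmt(sets: list[GeneSet], path) -> None:
    with open(path, "wt") as fh:
        for s in sets:
            fh.write("\t".join([s.set_id, s.description, *s.member_symbols]) + "\n")


def _scored_view(scores: pd.DataFrame) -> pd.DataFrame:
    """Genes usable by the enrichment test: has SNPs and a corrected p-value."""
    if "p_corrected" not in scores.columns or scores["p_corrected"].isna().all():
        raise ValueError(
            "score table has no corrected p-values; run a correction first "
            "(or use correction='none' upstream to copy p_best)"
        )
    return scores.loc[(~scores["excluded_no_snps"]) & scores["p_corrected"].notna()]


def enrichment_cutoff(scores: pd.DataFrame, cutoff_percentile: float = DEFAULT_CUTOFF_PERCENTILE) -> float:
    """Corrected-p value separating the top ``cutoff_percentile``-significant genes.

    ``cutoff_percentile=95`` means the leading edge is the 5% of scored genes
    with the smallest corrected p-values, genome-wide.
    """
    sub = _scored_view(scores)
    return float(np.percentile(sub["p_corrected"].to_numpy(), 100.0 - cutoff_percentile))


def prune_clustered_genes(
    set_members: list[str], scores: pd.DataFrame
) -> tuple[list[str], int]:
    """Collapse set members sharing a best SNP down to their most significant gene.

    ``set_members`` must already be restricted to scored genes.  Within each
    group of members assigned the same best SNP, the gene with the smallest
    corrected p-value is retained (ties: lexicographically smallest symbol).
    Returns the retained members (input order preserved) and the number pruned.
    """
    set_members = list(dict.fromkeys(set_members))  # dedupe, keep order
    if not set_members:
        return [], 0
    sub = scores.loc[set_members]
    best: dict[str, str] = {}
    best_p: dict[str, float] = {}
    for gene, row in sub.iterrows():
        snp = row["best_snp"]
        p = row["p_corrected"] if pd.notna(row.get("p_corrected", np.nan)) else row["p_best"]
        if snp not in best or (p, gene) < (best_p[snp], best[snp]):
            best[snp] = gene
            best_p[snp] = p
    retained = [g for g in set_members if best[sub.loc[g, "best_snp"]] == g]
    return retained, len(set_members) - len(retained)


def _substream(seed: int, set_id: str) -> np.random.Generator:
    """Independent generator for one gene set, stable under adding other sets."""
    return np.random.default_rng([int(seed), zlib.crc32(set_id.encode())])


def _match_members(gene_set: GeneSet, scores: pd.DataFrame):
    """Split members into scored / unscored-or-unknown, after whitespace normalization."""
    members = [m.strip() for m in gene_set.member_symbols]
    scored = _scored_view(scores)
    present = [m for m in dict.fromkeys(members) if m in scored.index]
    n_missing = len(set(members)) - len(present)
    return present, n_missing, scored


def _sampled_null_fractions(
    scored: pd.DataFrame,
    size: int,
    n_null: int,
    hit: np.ndarray,
    cluster: np.ndarray,
    p_vals: np.ndarray,
    cutoff: float,
    rng: np.random.Generator,
    prune_needed: bool,
) -> np.ndarray:
    """Leading-edge fractions of ``n_null`` random sets of ``size`` scored genes.

    Each sampled set is pruned for best-SNP sharing exactly like the observed
    set: within a cluster the smallest-p member is kept, and it is a hit iff
    that smallest p beats the cutoff.
    """
    n = len(scored)
    draws = np.empty((n_null, size), dtype=np.intp)
    for i in range(n_null):
        draws[i] = rng.choice(n, size=size, replace=False, shuffle=False)
    if not prune_needed:
        return hit[draws].mean(axis=1)
    # group members by (row, cluster): fraction = clusters-with-hit-min / clusters
    rows = np.repeat(np.arange(n_null), size)
    df = pd.DataFrame(
        {"row": rows, "cluster": cluster[draws.ravel()], "p": p_vals[draws.ravel()]}
    )
    grp = df.groupby(["row", "cluster"], sort=False)["p"].min()
    cutoff_hit = grp.to_numpy() < cutoff
    per_row = grp.index.get_level_values("row").to_numpy()
    n_clusters = np.bincount(per_row, minlength=n_null)
    n_hits = np.bincount(per_row, weights=cutoff_hit, minlength=n_null)
    return n_hits / n_clusters


def leading_edge_test(
    set_members,
    scores: pd.DataFrame,
    cutoff_percentile: float = DEFAULT_CUTOFF_PERCENTILE,
    n_null: int = DEFAULT_N_NULL,
    adaptive: bool = True,
    seed: int = 0,
    set_id: str = "",
    min_set_size: int = DEFAULT_MIN_SET_SIZE,
    max_n_null: int = DEFAULT_MAX_N_NULL,
    null_method: str = "auto",
) -> EnrichmentResult:
    """Leading-edge over-representation test for one gene set.

    ``set_members`` may be a :class:`GeneSet` or a plain list of symbols.
    ``null_method`` is ``"sampled"`` (Monte-Carlo, the general case),
    ``"hypergeom"`` (closed form; valid only when pruning is a no-op
    genome-wide), or ``"auto"`` (hypergeometric when provably valid).
    With ``adaptive``, the Monte-Carlo null is escalated tenfold whenever the
    estimate falls below 1e-4, up to ``max_n_null`` sampled sets.
    """
    gene_set = (
        set_members
        if isinstance(set_members, GeneSet)
        else GeneSet(set_id=set_id or "set", description="", member_symbols=tuple(set_members))
    )
    sid = set_id or gene_set.set_id
    present, n_missing, scored = _match_members(gene_set, scores)
    n_input = len(set(m.strip() for m in gene_set.member_symbols))

    cutoff = enrichment_cutoff(scores, cutoff_percentile)
    p_vals = scored["p_corrected"].to_numpy(dtype=float)
    hit = p_vals < cutoff
    cluster = pd.factorize(scored["best_snp"].to_numpy())[0]
    genome_prunable = len(np.unique(cluster)) < len(cluster)

    retained, n_pruned = prune_clustered_genes(present, scores)
    n_eff = len(retained)
    base = dict(
        set_id=sid,
        n_input=n_input,
        n_no_snps=n_missing,
        n_pruned_clustering=n_pruned,
        n_effective=n_eff,
        cutoff_percentile=cutoff_percentile,
        cutoff_value=cutoff,
        method="cutoff",
        below_min_size=n_input < min_set_size,
    )
    if n_eff == 0:
        logger.warning("leading_edge_test(%s): no scored genes; p set to 1", sid)
        return EnrichmentResult(
            leading_edge_fraction=0.0, p_nominal=1.0, p_bonferroni=1.0,
            n_null_sets_used=0, null_method="none", **base,
        )

    positions = scored.index.get_indexer(retained)
    k_obs = int(hit[positions].sum())
    frac_obs = k_obs / n_eff

    use_exact = null_method == "hypergeom" or (null_method == "auto" and not genome_prunable)
    if null_method == "hypergeom" and genome_prunable:
        raise ValueError(
            "hypergeometric null requested but some scored genes share a best SNP; "
            "the closed form is only valid when pruning is a no-op"
        )
    if use_exact:
        n_genome = len(scored)
        p_nom = float(stats.hypergeom.sf(k_obs - 1, n_genome, int(hit.sum()), n_eff))
        return EnrichmentResult(
            leading_edge_fraction=frac_obs, p_nominal=p_nom, p_bonferroni=p_nom,
            n_null_sets_used=0, null_method="hypergeom", **base,
        )

    rng = _substream(seed, sid)
    total = 0
    n_ge = 0
    batch = n_null
    while True:
        fracs = _sampled_null_fractions(
            scored, n_eff, batch, hit, cluster, p_vals, cutoff, rng,
            prune_needed=genome_prunable,
        )
        n_ge += int((fracs >= frac_obs).sum())
        total += batch
        p_nom = n_ge / total
        if not adaptive or p_nom >= ADAPTIVE_THRESHOLD or total * 10 > max_n_null:
            break
        batch = total * 9  # escalate total tenfold
    p_nom = max(p_nom, 1.0 / total)
    return EnrichmentResult(
        leading_edge_fraction=frac_obs, p_nominal=p_nom, p_bonferroni=p_nom,
        n_null_sets_used=total, null_method="sampled", **base,
    )


def _ranksum_p_from_ranksum(
    rank_sums: np.ndarray, sizes: np.ndarray, n_total: int, tie_term: float
) -> np.ndarray:
    """One-tailed Mann-Whitney p (members more significant) via the normal
    approximation with mid-ranks and tie correction, no continuity correction.

    ``rank_sums`` are sums of ascending mid-ranks of the members' corrected
    p-values, so smaller rank sums mean more significant sets.
    """
    n1 = sizes.astype(float)
    n2 = n_total - n1
    mu = n1 * (n_total + 1) / 2.0
    var = n1 * n2 / 12.0 * ((n_total + 1) - tie_term)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (rank_sums - mu) / np.sqrt(var)
    return stats.norm.cdf(z)


def ranksum_test(
    set_members,
    scores: pd.DataFrame,
    n_null: int = DEFAULT_N_NULL,
    adaptive: bool = True,
    seed: int = 0,
    set_id: str = "",
    min_set_size: int = DEFAULT_MIN_SET_SIZE,
    max_n_null: int = DEFAULT_MAX_N_NULL,
) -> EnrichmentResult:
    """Rank-sum alternative to the cutoff statistic.

    A one-tailed Mann-Whitney test asks whether the set's corrected p-values
    rank more significant than the rest of the genome; significance is then
    calibrated against randomly sampled, clustering-pruned sets of the same
    effective size (the analytic rank-sum p is used only as the ordering
    statistic, so its normal approximation does not need to be exact).
    """
    gene_set = (
        set_members
        if isinstance(set_members, GeneSet)
        else GeneSet(set_id=set_id or "set", description="", member_symbols=tuple(set_members))
    )
    sid = set_id or gene_set.set_id
    present, n_missing, scored = _match_members(gene_set, scores)
    n_input = len(set(m.strip() for m in gene_set.member_symbols))
    retained, n_pruned = prune_clustered_genes(present, scores)
    n_eff = len(retained)

    base = dict(
        set_id=sid, n_input=n_input, n_no_snps=n_missing,
        n_pruned_clustering=n_pruned, n_effective=n_eff,
        cutoff_percentile=np.nan, cutoff_value=np.nan,
        method="ranksum", below_min_size=n_input < min_set_size,
    )
    if n_eff == 0 or n_eff == len(scored):
        return EnrichmentResult(
            leading_edge_fraction=np.nan, p_nominal=1.0, p_bonferroni=1.0,
            n_null_sets_used=0, null_method="none", **base,
        )

    p_vals = scored["p_corrected"].to_numpy(dtype=float)
    ranks = stats.rankdata(p_vals)  # mid-ranks, ascending: significant = small
    n_total = len(p_vals)
    _, counts = np.unique(p_vals, return_counts=True)
    tie_term = float((counts**3 - counts).sum()) / (n_total * (n_total - 1))
    cluster = pd.factorize(scored["best_snp"].to_numpy())[0]
    genome_prunable = len(np.unique(cluster)) < len(cluster)

    positions = scored.index.get_indexer(retained)
    p_obs = float(
        _ranksum_p_from_ranksum(
            np.array([ranks[positions].sum()]), np.array([n_eff]), n_total, tie_term
        )[0]
    )

    rng = _substream(seed, sid)
    total = 0
    n_le = 0
    batch = n_null
    while True:
        draws = np.empty((batch, n_eff), dtype=np.intp)
        for i in range(batch):
            draws[i] = rng.choice(n_total, size=n_eff, replace=False, shuffle=False)
        if genome_prunable:
            rows = np.repeat(np.arange(batch), n_eff)
            df = pd.DataFrame(
                {"row": rows, "cluster": cluster[draws.ravel()],
                 "p": p_vals[draws.ravel()], "rank": ranks[draws.ravel()]}
            )
            idx = df.groupby(["row", "cluster"], sort=False)["p"].idxmin()
            kept = df.loc[idx]
            rank_sums = kept.groupby("row", sort=False)["rank"].sum().to_numpy()
            sizes = kept.groupby("row", sort=False)["rank"].size().to_numpy()
        else:
            rank_sums = ranks[draws].sum(axis=1)
            sizes = np.full(batch, n_eff)
        p_null = _ranksum_p_from_ranksum(rank_sums, sizes, n_total, tie_term)
        n_le += int((p_null <= p_obs).sum())
        total += batch
        p_nom = n_le / total
        if not adaptive or p_nom >= ADAPTIVE_THRESHOLD or total * 10 > max_n_null:
            break
        batch = total * 9
    p_nom = max(p_nom, 1.0 / total)
    return EnrichmentResult(
        leading_edge_fraction=np.nan, p_nominal=p_nom, p_bonferroni=p_nom,
        n_null_sets_used=total, null_method="sampled", **base,
    )


def bonferroni_adjust(results: list[EnrichmentResult]) -> list[EnrichmentResult]:
    """p_bonferroni = min(1, p_nominal * number of sets in this batch)."""
    m = len(results)
    for r in results:
        r.p_bonferroni = min(1.0, r.p_nominal * m)
    return results


def run_enrichment(
    sets: list[GeneSet],
    scores: pd.DataFrame,
    stat: str = "cutoff",
    cutoff_percentile: float = DEFAULT_CUTOFF_PERCENTILE,
    n_null: int = DEFAULT_N_NULL,
    adaptive: bool = True,
    seed: int = 0,
    min_set_size: int = DEFAULT_MIN_SET_SIZE,
    max_n_null: int = DEFAULT_MAX_N_NULL,
    null_method: str = "auto",
) -> list[EnrichmentResult]:
    """Test every set in a collection and Bonferroni-adjust over the batch."""
    results = []
    for s in sets:
        if stat == "ranksum":
            r = ranksum_test(
                s, scores, n_null=n_null, adaptive=adaptive, seed=seed,
                min_set_size=min_set_size, max_n_null=max_n_null,
            )
        else:
            r = leading_edge_test(
                s, scores, cutoff_percentile=cutoff_percentile, n_null=n_null,
                adaptive=adaptive, seed=seed, min_set_size=min_set_size,
                max_n_null=max_n_null, null_method=null_method,
            )
        results.append(r)
    return bonferroni_adjust(results)


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.as_row() for r in results])


def write_results(results: list[EnrichmentResult], path) -> None:
    results_to_frame(results).to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")
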