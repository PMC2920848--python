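"""Spike-in power and specificity simulations for the enrichment test.

Causal effects are modelled as a 1-df noncentral chi-square association
statistic (additive allelic test) with noncentrality parameter (NCP) chosen
to give a target single-SNP detection power — e.g. NCP = 10 corresponds to
~1% power at genome-wide significance (p <= 5e-8), NCP = 2.5 to ~1% power at
p <= 1e-4, i.e. effects far too weak for single-marker discovery.  Each
simulation run draws a fresh null background of uniform SNP p-values over a
fixed synthetic genome, assigns one spiked SNP to each causal gene (a random
SNP within the gene's extended boundaries), scores and regression-corrects
all genes, and applies the leading-edge enrichment test to the simulated
set.  Power is the fraction of runs whose nominal enrichment p-value reaches
the significance threshold (default 0.01).

The spiked chi-square statistic enters the background as a z-score (its
square root), mapped to a p-value with the same one-tailed convention used
for gene scores: p = 1 - Phi(sqrt(X)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .correction import stepwise_select
from .covariates import DEFAULT_REGRESSION_COVARIATES
from .enrichment import DEFAULT_CUTOFF_PERCENTILE
from .gene_model import GeneRegion
from .synthetic_data import SyntheticGenome

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimulationSpec:
    """One cell of the power-simulation grid."""

    set_size: int
    fraction_causal_in_set: float = 0.0
    total_causal_genes: int = 100
    ncp: float = 0.0
    n_runs: int = 1_000
    gsea_alpha: float = 0.01
    cutoff_percentile: float = DEFAULT_CUTOFF_PERCENTILE
    n_null: int = 10_000  # Monte-Carlo null size (only when the exact null is unavailable)
    seed: int = 0

    def __post_init__(self):
        if self.ncp < 0:
            raise ValueError("ncp must be >= 0")
        if not (0 <= self.fraction_causal_in_set <= 1):
            raise ValueError("fraction_causal_in_set must be in [0, 1]")
        if self.n_causal_in_set > self.total_causal_genes:
            raise ValueError("causal genes in set exceed total causal genes")
        if not (0 < self.gsea_alpha < 1):
            raise ValueError("gsea_alpha must be in (0, 1)")

    @property
    def n_causal_in_set(self) -> int:
        """Counts are integral: the fraction is rounded to the nearest gene."""
        return int(round(self.set_size * self.fraction_causal_in_set))


@dataclass
class PowerEstimate:
    spec: SimulationSpec
    power: float
    n_successes: int
    mc_stderr: float
    p_nominals: np.ndarray = field(repr=False, default=None)

    def as_row(self) -> dict:
        return {
            "set_size": self.spec.set_size,
            "fraction_causal": self.spec.fraction_causal_in_set,
            "n_causal_in_set": self.spec.n_causal_in_set,
            "total_causal": self.spec.total_causal_genes,
            "ncp": self.spec.ncp,
            "alpha": self.spec.gsea_alpha,
            "cutoff_percentile": self.spec.cutoff_percentile,
            "power": self.power,
            "stderr": self.mc_stderr,
            "n_runs": self.spec.n_runs,
            "seed": self.spec.seed,
        }


def power_single_snp(ncp: float, alpha: float) -> float:
    """Detection power of a single 1-df chi-square association test.

    P(chi2_1(ncp) exceeds the central upper-``alpha`` quantile) — used to
    translate NCP values into "power at significance level alpha" terms.
    """
    if ncp < 0:
        raise ValueError("ncp must be >= 0")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    q = stats.chi2.isf(alpha, df=1)
    if ncp == 0:
        return float(alpha)
    return float(stats.ncx2.sf(q, df=1, nc=ncp))


def draw_spike_chisq(ncp: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Noncentral chi-square (1 df) draws: X = (Z + sqrt(ncp))^2, Z ~ N(0,1)."""
    return (rng.normal(size=size) + np.sqrt(ncp)) ** 2


def spike_p_from_chisq(x) -> np.ndarray:
    """Spiked-SNP p-value: the statistic's square root taken as a z-score,
    p = 1 - Phi(sqrt(x)) (matching the one-tailed gene-score convention).
    """
    return special.ndtr(-np.sqrt(np.asarray(x, dtype=float)))


def spike_effects(
    snps: pd.DataFrame,
    regions: list[GeneRegion],
    causal_gene_ids: list[str],
    ncp: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Replace one random regional SNP p-value per causal gene with a spiked draw.

    Returns a copy of ``snps``; exactly one SNP per causal gene is modified.
    Raises if any causal gene has no SNPs in its extended boundaries.
    """
    by_symbol = {r.gene.gene_symbol: r for r in regions}
    missing = [g for g in causal_gene_ids if g not in by_symbol]
    if missing:
        raise ValueError(f"unknown causal genes: {missing[:5]}")
    empty = [g for g in causal_gene_ids if by_symbol[g].n_snps == 0]
    if empty:
        raise ValueError(f"causal genes with no SNPs in their boundaries: {empty[:5]}")
    out = snps.copy()
    p = out["p"].to_numpy(dtype=float, copy=True)
    for g in causal_gene_ids:
        r = by_symbol[g]
        j = r.snp_indices[rng.integers(r.n_snps)]
        p[j] = spike_p_from_chisq(draw_spike_chisq(ncp, 1, rng))[0]
    out["p"] = p
    return out


class _FastGenomeContext:
    """Precomputed arrays for the per-run hot path over a fixed genome."""

    def __init__(self, genome: SyntheticGenome, covariate_names=None):
        self.genome = genome
        counts = np.diff(genome.offsets)
        self.scored = np.flatnonzero(counts > 0)  # gene positions with >=1 SNP
        self.counts = counts
        self.offsets = genome.offsets
        self.flat_idx = genome.flat_idx
        names = covariate_names or [
            c for c in DEFAULT_REGRESSION_COVARIATES if c in genome.covariates.columns
        ]
        X = genome.covariates.iloc[self.scored][names].astype(float)
        self.X = X.apply(lambda col: col.fillna(col.mean()))
        self.n_scored = len(self.scored)

    def corrected_z(self, p_snp: np.ndarray) -> np.ndarray:
        """Standardised stepwise-regression residuals for all scored genes."""
        vals = p_snp[self.flat_idx]
        p_best = np.minimum.reduceat(vals, self.offsets[self.scored])
        z = -special.ndtri(p_best)
        model = stepwise_select(z, self.X)
        fitted = np.full(self.n_scored, model.coefficients["intercept"])
        for name in model.selected_covariates:
            fitted = fitted + model.coefficients[name] * self.X[name].to_numpy()
        resid = z - fitted
        resid = resid - resid.mean()
        sd = resid.std()
        return resid / sd if sd > 0 else resid


def _run_once(
    ctx: _FastGenomeContext, spec: SimulationSpec, run_index: int
) -> float:
    """One spike-in run; returns the nominal enrichment p-value of the simulated set."""
    rng = np.random.default_rng([int(spec.seed), int(run_index)])
    genome = ctx.genome
    p = genome.draw_null_p(rng)

    n_scored = ctx.n_scored
    if spec.set_size > n_scored:
        raise ValueError("set_size exceeds number of scored genes")
    set_pos = rng.choice(n_scored, size=spec.set_size, replace=False)
    n_in = spec.n_causal_in_set
    causal_in = set_pos[rng.choice(spec.set_size, size=n_in, replace=False)] if n_in else np.empty(0, int)
    n_out = spec.total_causal_genes - n_in
    if n_out > 0 and spec.ncp > 0:
        outside = np.setdiff1d(np.arange(n_scored), set_pos)
        if n_out > len(outside):
            raise ValueError("more causal genes than genes outside the set")
        causal_out = rng.choice(outside, size=n_out, replace=False)
    else:
        causal_out = np.empty(0, int)

    if spec.ncp > 0:
        causal = np.concatenate([causal_in, causal_out]).astype(int)
        if len(causal):
            gene_idx = ctx.scored[causal]
            slots = ctx.offsets[gene_idx] + rng.integers(0, ctx.counts[gene_idx])
            snp_j = ctx.flat_idx[slots]
            p[snp_j] = spike_p_from_chisq(draw_spike_chisq(spec.ncp, len(snp_j), rng))

    zc = ctx.corrected_z(p)
    cut = np.percentile(zc, spec.cutoff_percentile)
    hits = zc > cut
    k = int(hits[set_pos].sum())
    K = int(hits.sum())

    if genome.regions_disjoint:
        # no two genes can share a best SNP => sampling null is exactly hypergeometric
        return float(stats.hypergeom.sf(k - 1, n_scored, K, spec.set_size))
    # Monte-Carlo sampling null (clustering pruning would be needed for exactness;
    # with shared best SNPs, fall back to the fraction-based sampled null)
    frac_obs = k / spec.set_size
    rng_null = np.random.default_rng([int(spec.seed), int(run_index), 0x4E55])
    ge = 0
    for _ in range(spec.n_null):
        draw = rng_null.choice(n_scored, size=spec.set_size, replace=False, shuffle=False)
        ge += hits[draw].mean() >= frac_obs
    return max(ge / spec.n_null, 1.0 / spec.n_null)


def estimate_power(
    spec: SimulationSpec,
    genome: SyntheticGenome,
    ctx: _FastGenomeContext | None = None,
) -> PowerEstimate:
    """Estimate enrichment-test power (or, at NCP = 0, the false-positive rate).

    Each run reseeds from (spec.seed, run index), so runs are independent and
    two specs sharing a seed see common random backgrounds (useful for
    directional comparisons with common random numbers).
    """
    ctx = ctx or _FastGenomeContext(genome)
    p_noms = np.array([_run_once(ctx, spec, i) for i in range(spec.n_runs)])
    successes = int((p_noms <= spec.gsea_alpha).sum())
    power = successes / spec.n_runs
    stderr = float(np.sqrt(power * (1 - power) / spec.n_runs))
    return PowerEstimate(
        spec=spec, power=power, n_successes=successes, mc_stderr=stderr, p_nominals=p_noms
    )


def power_grid(
    specs: list[SimulationSpec], genome: SyntheticGenome
) -> pd.DataFrame:
    """Power estimates for a list of specs on one genome, as a tidy table."""
    ctx = _FastGenomeContext(genome)
    rows = []
    for spec in specs:
        est = estimate_power(spec, genome, ctx=ctx)
        rows.append(est.as_row())
        logger.info(
            "power: set=%d frac=%.3g ncp=%g -> %.3f +/- %.3f",
            spec.set_size, spec.fraction_causal_in_set, spec.ncp, est.power, est.mc_stderr,
        )
    return pd.DataFrame(rows)
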