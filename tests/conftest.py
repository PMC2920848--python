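import numpy as np
import pandas as pd
import pytest

from gwasea.synthetic_data import SyntheticGenomeSpec, generate_genome


@pytest.fixture(scope="session")
def tiny_genome():
    """Small disjoint-region genome used across modules (deterministic)."""
    return generate_genome(SyntheticGenomeSpec(n_genes=400, n_chromosomes=4, seed=1234))


@pytest.fixture(scope="session")
def overlap_genome():
    """Genome with overlapping extended regions (exercises clustering pruning)."""
    return generate_genome(
        SyntheticGenomeSpec(n_genes=300, n_chromosomes=3, overlap_fraction=0.3, seed=77)
    )


def make_scores(p_corrected, best_snp=None, p_best=None):
    """Build a minimal gene-score table directly (for enrichment unit tests)."""
    n = len(p_corrected)
    genes = [f"G{i:04d}" for i in range(n)]
    p_corrected = np.asarray(p_corrected, dtype=float)
    if p_best is None:
        p_best = p_corrected
    if best_snp is None:
        best_snp = [f"rs{i}" for i in range(n)]
    return pd.DataFrame(
        {
            "chrom": "1",
            "n_snps": 5,
            "best_snp": best_snp,
            "p_best": p_best,
            "z_raw": 0.0,
            "excluded_no_snps": False,
            "p_corrected": p_corrected,
            "z_corrected": 0.0,
        },
        index=pd.Index(genes, name="gene"),
    )
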