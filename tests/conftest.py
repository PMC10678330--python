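import numpy as np
import pandas as pd
import pytest

from postgwas import GenotypePanel, SyntheticScenario, generate_study

#: top-k used for desk-scale runs (full-scale studies use 100 on ~1,372
#: genes; the desk scenario prioritizes ~220, so the list length scales too)
DESK_TOP_K = 50


def tiny_scenario(seed: int, **overrides) -> SyntheticScenario:
    """A fast, small scenario for unit tests."""
    params = dict(
        seed=seed,
        n_chromosomes=2,
        chrom_length_bp=1_000_000,
        n_snps=160,
        n_samples=40,
        n_genes=150,
        true_gene_fraction=0.2,
        n_planted_hubs=5,
        n_causal_snps=12,
        ppi_attachment=8,
    )
    params.update(overrides)
    return SyntheticScenario(**params)


@pytest.fixture(scope="session")
def tiny_study():
    return generate_study(tiny_scenario(seed=7))


@pytest.fixture(scope="session")
def default_study():
    """One study at the default desk-scale conditions."""
    return generate_study(SyntheticScenario(seed=11))


def make_panel(dosages, positions=None, chroms=None) -> GenotypePanel:
    """Build a panel directly from a samples x variants dosage matrix."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n_samples, n_variants = dosages.shape
    if positions is None:
        positions = [1000 * (i + 1) for i in range(n_variants)]
    if chroms is None:
        chroms = ["1"] * n_variants
    variants = pd.DataFrame(
        {
            "variant_id": [f"rs{i + 1}" for i in range(n_variants)],
            "chrom": chroms,
            "pos": positions,
        }
    )
    return GenotypePanel(
        sample_ids=[f"S{i}" for i in range(n_samples)],
        variants=variants,
        dosages=dosages,
    )


def pearson_r2(x, y) -> float:
    """Direct-formula Pearson correlation squared (independent oracle)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    num = n * (x * y).sum() - x.sum() * y.sum()
    den = np.sqrt(n * (x * x).sum() - x.sum() ** 2) * np.sqrt(
        n * (y * y).sum() - y.sum() ** 2
    )
    return float((num / den) ** 2)
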