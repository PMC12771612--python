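import numpy as np
import pytest

from feralmix.genotype_io import GenotypeMatrix, MarkerInfo, SampleInfo
from feralmix.synthetic_panel import SimulationConfig, simulate_reference_panel


def make_markers(n, chrom="1", spacing=50_000, start=1, prefix="m"):
    return [
        MarkerInfo(f"{prefix}{i+1}", chrom, start + i * spacing, "A", "G")
        for i in range(n)
    ]


def make_matrix(dosage, chrom="1", spacing=50_000, group=None, role="query"):
    """GenotypeMatrix from a plain dosage array with generated metadata."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, L = dosage.shape
    samples = [SampleInfo(f"s{i+1}", group_label=group, role=role) for i in range(n)]
    return GenotypeMatrix(samples=samples, markers=make_markers(L, chrom, spacing),
                         dosage=dosage)


@pytest.fixture(scope="session")
def small_panel():
    """K=3 reference panel, 30 per cluster, 800 loci: shared by several tests."""
    cfg = SimulationConfig(n_clusters=3, fst=0.2, n_markers=800,
                          n_per_cluster=30, seed=42)
    panel, freqs = simulate_reference_panel(cfg)
    return panel, freqs
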