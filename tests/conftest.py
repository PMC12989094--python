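import numpy as np
import pandas as pd
import pytest

from namscan import (
    Chromosome,
    GenotypeMatrix,
    SimulationConfig,
    TruthSet,
    plant_qtls,
    simulate_nam_genotypes,
    simulate_phenotypes,
)


@pytest.fixture(scope="session")
def small_cfg():
    """A small two-chromosome panel: 4 families x 30 lines, 40 markers."""
    return SimulationConfig(
        n_families=4,
        lines_per_family=30,
        chromosomes=(
            Chromosome("1H", 500_000_000, 140.0),
            Chromosome("2H", 650_000_000, 155.0),
        ),
        markers_per_chromosome=20,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_panel(small_cfg):
    return simulate_nam_genotypes(small_cfg)


@pytest.fixture(scope="session")
def small_pheno(small_cfg, small_panel):
    geno, marker_map = small_panel
    truth = plant_qtls(geno, marker_map, small_cfg, n_qtls=1, trait="SL",
                       variance_explained=0.2)
    pheno = simulate_phenotypes(geno, truth, small_cfg)
    return pheno, truth


@pytest.fixture(scope="session")
def sparse_panel():
    """Markers ~15 cM apart: essentially unlinked, sharp localisation."""
    cfg = SimulationConfig(
        n_families=10,
        lines_per_family=30,
        chromosomes=(Chromosome("1H", 500_000_000, 300.0),),
        markers_per_chromosome=20,
        seed=7,
    )
    geno, marker_map = simulate_nam_genotypes(cfg)
    return cfg, geno, marker_map


def random_genotypes(n_lines, n_markers, seed, chrom="1H", spacing_bp=1_000_000):
    """Independent-marker dosage matrix drawn from the BC1S3 law (no LD)."""
    rng = np.random.default_rng(seed)
    dos = rng.choice([0.0, 1.0, 2.0], size=(n_lines, n_markers),
                     p=[23 / 32, 1 / 16, 7 / 32])
    lines = pd.Index([f"L{i:04d}" for i in range(n_lines)], name="line")
    markers = pd.Index([f"SNP_{chrom}_{j + 1:05d}" for j in range(n_markers)],
                       name="marker")
    geno = GenotypeMatrix(
        pd.DataFrame(dos, index=lines, columns=markers),
        pd.Series("FAM01", index=lines, name="family"),
    )
    marker_map = pd.DataFrame({
        "marker": markers,
        "chrom": chrom,
        "bp": (np.arange(n_markers) + 1) * spacing_bp,
        "cm": (np.arange(n_markers) + 1) * 50.0,
    })
    return geno, marker_map
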