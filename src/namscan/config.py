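"""Configuration objects shared across the pipeline.

The defaults describe a seedling salinity-screening experiment on a barley
NAM panel: 25 families of BC1S3 lines derived from crosses of diverse wild
donors to one recurrent elite parent, phenotyped under a control and a
seawater-stress treatment with four biological replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

TREATMENTS = ("C", "S")  # control, (salinity) stress

#: Raw traits the simulator produces.  GER is a germination count out of
#: ``seeds_per_replicate``; the rest are continuous (cm for lengths, g for
#: weights).  WCP, RSR, DW/FW ratio and Ger% are derived downstream.
DEFAULT_TRAITS = ("CL", "SL", "RL", "FW", "DW", "GER")

#: Multiplicative effect of the stress treatment on the trait mean
#: (stress mean = factor x control mean).  The length/weight factors emulate
#: the reductions typically seen under ~40% seawater irrigation at the
#: seedling stage: ~15% for coleoptile length, ~70% for shoot and root
#: length, ~57% for fresh weight, with dry weight and germination nearly
#: unaffected.
DEFAULT_TREATMENT_EFFECT: dict[str, float] = {
    "CL": 0.849,
    "SL": 0.305,
    "RL": 0.316,
    "FW": 0.429,
    "DW": 1.0,
    "GER": 0.97,
}

#: Control-treatment grand means, in trait units (cm, g, seed counts).
DEFAULT_TRAIT_MEANS: dict[str, float] = {
    "CL": 3.0,
    "SL": 10.0,
    "RL": 8.0,
    "FW": 0.5,
    "DW": 0.08,
    "GER": 14.7,
}


@dataclass(frozen=True)
class VarianceSpec:
    """Variance components of the generative ANOVA model, in trait units^2.

    sigma_g2   -- genotype (line) main effect
    sigma_gt2  -- genotype x treatment interaction
    sigma_rep2 -- replicate nested within treatment
    sigma_e2   -- residual
    """

    sigma_g2: float = 1.0
    sigma_gt2: float = 0.25
    sigma_rep2: float = 0.1
    sigma_e2: float = 0.5

    def validate(self) -> None:
        for name, v in asdict(self).items():
            if v < 0:
                raise ValueError(f"variance component {name} must be >= 0, got {v}")

    def scaled(self, factor: float) -> "VarianceSpec":
        return VarianceSpec(
            self.sigma_g2 * factor,
            self.sigma_gt2 * factor,
            self.sigma_rep2 * factor,
            self.sigma_e2 * factor,
        )


#: Per-trait variance components sized to the trait means above so that the
#: line-mean heritability of every trait lands in the realistic 0.7-0.9 band.
DEFAULT_VARIANCE_COMPONENTS: dict[str, VarianceSpec] = {
    "CL": VarianceSpec(0.09, 0.02, 0.01, 0.05),
    "SL": VarianceSpec(1.0, 0.25, 0.1, 0.5),
    "RL": VarianceSpec(0.8, 0.2, 0.08, 0.4),
    "FW": VarianceSpec(2.5e-3, 6e-4, 2.5e-4, 1.2e-3),
    "DW": VarianceSpec(6e-5, 1.5e-5, 6e-6, 3e-5),
    "GER": VarianceSpec(0.6, 0.15, 0.05, 0.8),
}


@dataclass(frozen=True)
class Chromosome:
    name: str
    length_bp: int
    length_cm: float

    def validate(self) -> None:
        if self.length_bp <= 0 or self.length_cm <= 0:
            raise ValueError(f"chromosome {self.name}: lengths must be positive")


#: Approximate physical/genetic lengths of the seven barley chromosomes.
BARLEY_CHROMOSOMES: tuple[Chromosome, ...] = (
    Chromosome("1H", 516_000_000, 139.0),
    Chromosome("2H", 665_000_000, 156.0),
    Chromosome("3H", 621_000_000, 158.0),
    Chromosome("4H", 610_000_000, 126.0),
    Chromosome("5H", 588_000_000, 165.0),
    Chromosome("6H", 561_000_000, 131.0),
    Chromosome("7H", 632_000_000, 151.0),
)


class ConfigurationError(ValueError):
    """Raised when a configuration object fails validation."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic NAM genotype/phenotype generator."""

    n_families: int = 25
    lines_per_family: int = 16
    chromosomes: tuple[Chromosome, ...] = BARLEY_CHROMOSOMES
    markers_per_chromosome: int = 300
    seed: int = 0
    n_replicates: int = 4
    traits: tuple[str, ...] = DEFAULT_TRAITS
    trait_means: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRAIT_MEANS)
    )
    treatment_effect: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TREATMENT_EFFECT)
    )
    variance_components: VarianceSpec | dict[str, VarianceSpec] = field(
        default_factory=lambda: dict(DEFAULT_VARIANCE_COMPONENTS)
    )
    seeds_per_replicate: int = 16
    missing_rate: float = 0.0
    #: probability a family's wild donor carries the non-elite allele at a
    #: marker; at 1.0 every marker segregates in every family.
    donor_allele_freq: float = 1.0

    def variance_spec(self, trait: str) -> VarianceSpec:
        if isinstance(self.variance_components, VarianceSpec):
            return self.variance_components
        try:
            return self.variance_components[trait]
        except KeyError:
            raise ConfigurationError(f"no variance components for trait {trait!r}")

    def validate(self) -> None:
        if self.n_families < 1 or self.lines_per_family < 1:
            raise ConfigurationError("n_families and lines_per_family must be >= 1")
        if self.markers_per_chromosome < 1:
            raise ConfigurationError("markers_per_chromosome must be >= 1")
        if not self.chromosomes:
            raise ConfigurationError("at least one chromosome is required")
        for chrom in self.chromosomes:
            chrom.validate()
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigurationError("missing_rate must be in [0, 1)")
        if not (0.0 <= self.donor_allele_freq <= 1.0):
            raise ConfigurationError("donor_allele_freq must be in [0, 1]")
        for trait in self.traits:
            if trait not in self.trait_means:
                raise ConfigurationError(f"trait {trait!r} has no mean")
            self.variance_spec(trait).validate()


@dataclass
class ScanConfig:
    """Parameters of the three-step multi-locus association scan."""

    n_subsamples: int = 100
    train_fraction: float = 0.8
    min_selection_count: int = 2
    alpha: float = 0.05
    seed: int = 0
    max_cofactors: int = 20
    max_selection_steps: int = 30
    collinearity_r: float = 0.99
    stratify_by_family: bool = False
    min_lines: int = 25
    max_missing_lines: float = 0.20

    def validate(self) -> None:
        if self.n_subsamples < 1:
            raise ConfigurationError("n_subsamples must be >= 1")
        if not (0.0 < self.train_fraction < 1.0):
            raise ConfigurationError("train_fraction must be in (0, 1)")
        if not (0.0 < self.alpha < 1.0):
            raise ConfigurationError("alpha must be in (0, 1)")
        if self.min_selection_count < 1:
            raise ConfigurationError("min_selection_count must be >= 1")
        if self.max_cofactors < 0:
            raise ConfigurationError("max_cofactors must be >= 0")


@dataclass
class QCConfig:
    """Marker quality-control thresholds for chip-style dosage matrices."""

    max_missing: float = 0.10
    max_het: float = 0.125
    require_polymorphic: bool = True

    def validate(self) -> None:
        for name in ("max_missing", "max_het"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
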