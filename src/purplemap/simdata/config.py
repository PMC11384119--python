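"""Configuration types for the F1 cross simulator.

Coordinates are genetic (cM) during simulation and converted to synthetic
physical coordinates at 1 cM = 1 Mb when files are emitted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

#: bp per cM on the synthetic physical scale.
BP_PER_CM = 1_000_000

#: Ordinal leaf-color classes, green through dark purple.
COLOR_CLASSES = ("green", "slight1", "slight2", "slight3", "dark_purple")


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class ChromosomeSpec:
    """One simulated chromosome: a name, a genetic length, a marker count."""

    name: str
    length_cm: float
    n_markers: int

    def __post_init__(self) -> None:
        if self.length_cm <= 0:
            raise ConfigurationError(f"chromosome {self.name}: zero or negative length")
        if self.n_markers < 1:
            raise ConfigurationError(f"chromosome {self.name}: needs >=1 marker")

    def marker_positions_cm(self) -> np.ndarray:
        """Evenly spaced, strictly increasing marker positions in cM."""
        step = self.length_cm / self.n_markers
        return (np.arange(self.n_markers) + 0.5) * step


def default_chromosomes() -> tuple[ChromosomeSpec, ...]:
    """Five 50-cM chromosomes with 100 markers each (500 markers total)."""
    return tuple(ChromosomeSpec(f"chr{i}", 50.0, 100) for i in range(1, 6))


@dataclass(frozen=True)
class CrossConfig:
    """Design of the simulated F1 pseudo-testcross.

    The purple parent is heterozygous (Aa) at every simulated locus, the
    green parent homozygous reference, so offspring dosage is 0 or 1 and
    segregates 1:1 at the causal locus.
    """

    n_offspring: int = 127
    chromosomes: tuple[ChromosomeSpec, ...] = field(default_factory=default_chromosomes)
    causal_chrom: str = "chr2"
    causal_cm: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_offspring < 2:
            raise ConfigurationError("n_offspring must be >= 2")
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate chromosome names")
        if self.causal_chrom not in names:
            raise ConfigurationError(
                f"causal locus chromosome {self.causal_chrom!r} not declared"
            )
        spec = self.chromosome(self.causal_chrom)
        if not (0 <= self.causal_cm <= spec.length_cm):
            raise ConfigurationError(
                f"causal position {self.causal_cm} cM outside {spec.name} "
                f"(0..{spec.length_cm} cM)"
            )

    def chromosome(self, name: str) -> ChromosomeSpec:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def causal_bp(self) -> int:
        return int(round(self.causal_cm * BP_PER_CM))


def _class_fraction(threshold: float, means: tuple[float, float], sigma: float) -> float:
    """P(liability < threshold) under the 50/50 aa|Aa genotype mixture."""
    return 0.5 * (
        norm.cdf((threshold - means[0]) / sigma) + norm.cdf((threshold - means[1]) / sigma)
    )


@dataclass(frozen=True)
class PhenotypeModel:
    """Liability-threshold model mapping causal genotype to a color class.

    liability = mean(genotype) + Normal(0, sigma); the four ordered
    thresholds cut the liability axis into the five COLOR_CLASSES.
    """

    genotype_means: tuple[float, float] = (0.0, 2.0)  # (aa, Aa)
    sigma: float = 0.6
    thresholds: tuple[float, float, float, float] = ()  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ConfigurationError("sigma must be positive")
        if self.genotype_means[1] <= self.genotype_means[0]:
            raise ConfigurationError("dominant (Aa) mean must exceed aa mean")
        if len(self.thresholds) != 4:
            raise ConfigurationError("exactly 4 class thresholds required")
        if not all(a < b for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise ConfigurationError("thresholds must be strictly increasing")

    @classmethod
    def calibrated(
        cls,
        green_fraction: float = 18 / 127,
        dark_fraction: float = 32 / 127,
        genotype_means: tuple[float, float] = (0.0, 2.0),
        sigma: float = 0.6,
    ) -> "PhenotypeModel":
        """Solve thresholds so the expected extreme-class fractions are exact.

        The lowest cut point makes E[green] = green_fraction and the highest
        makes E[dark_purple] = dark_fraction under the 1:1 genotype mixture;
        the two interior cut points are evenly spaced between them.
        """
        lo = genotype_means[0] - 10 * sigma
        hi = genotype_means[1] + 10 * sigma
        t1 = brentq(lambda t: _class_fraction(t, genotype_means, sigma) - green_fraction, lo, hi)
        t4 = brentq(
            lambda t: _class_fraction(t, genotype_means, sigma) - (1.0 - dark_fraction), lo, hi
        )
        t2 = t1 + (t4 - t1) / 3.0
        t3 = t1 + 2.0 * (t4 - t1) / 3.0
        return cls(genotype_means=genotype_means, sigma=sigma, thresholds=(t1, t2, t3, t4))

    @classmethod
    def default(cls) -> "PhenotypeModel":
        """Default model: expected (green, dark purple) counts (18, 32) at n=127."""
        return cls.calibrated()

    def expected_class_fractions(self) -> np.ndarray:
        """Expected fraction per color class under the 1:1 genotype mixture."""
        cuts = [-math.inf, *self.thresholds, math.inf]
        cdf = np.array([_class_fraction(c, self.genotype_means, self.sigma) for c in cuts[1:-1]])
        cdf = np.concatenate([[0.0], cdf, [1.0]])
        return np.diff(cdf)


@dataclass(frozen=True)
class BulkDesign:
    """Bulk and pool layout plus sequencing-depth/noise parameters."""

    k: int = 15  # individuals per extreme tail
    rna_pool_size: int = 5
    lambda_dna: float = 50.0
    # deeper RNA default: per-marker RNA depth is scaled by gene expression,
    # so a higher base rate keeps moderately expressed genes above the
    # per-pool depth filter of the ED layer
    lambda_rna: float = 100.0
    error_rate: float = 0.001

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ConfigurationError("tail size k must be >= 1")
        if self.k % self.rna_pool_size != 0:
            raise ConfigurationError("tail size k must be divisible by rna_pool_size")
        if self.lambda_dna <= 0 or self.lambda_rna <= 0:
            raise ConfigurationError("mean depths must be positive")
        if not (0 <= self.error_rate < 0.5):
            raise ConfigurationError("error rate must lie in [0, 0.5)")

    def validate_for(self, n_offspring: int) -> None:
        if 2 * self.k > n_offspring:
            raise ConfigurationError(
                f"2*k = {2 * self.k} exceeds population size {n_offspring}"
            )


@dataclass(frozen=True)
class ExprConfig:
    """Generator settings for the pooled gene-expression layer."""

    deg_fraction: float = 0.05
    log2fc_loc: float = 2.0
    log2fc_scale: float = 0.5
    dispersion: float = 0.05
    causal_log2fc: float = 3.0
    base_mean: float = 200.0
    mean_log_sigma: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.deg_fraction <= 1.0):
            raise ConfigurationError("deg_fraction must lie in [0, 1]")
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be positive")
        if self.base_mean <= 0:
            raise ConfigurationError("base_mean must be positive")
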