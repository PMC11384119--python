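"""F1 pseudo-testcross simulation under a Haldane recombination model."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import (
    BP_PER_CM,
    COLOR_CLASSES,
    ConfigurationError,
    CrossConfig,
    PhenotypeModel,
)


def haldane_recombination_fraction(d_cm: float | np.ndarray) -> float | np.ndarray:
    """Map a genetic distance in cM to a recombination fraction (Haldane)."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm) / 100.0))


@dataclass
class SimulatedPopulation:
    """An F1 population with genotypes at markers and at the causal locus.

    genotypes hold alt-allele dosage in {0, 1}: the green parent is
    homozygous reference everywhere, so the dosage equals the allele carried
    by the purple-parent gamete (stored separately as phase).
    """

    config: CrossConfig
    markers: pd.DataFrame  # columns: id, chrom, pos_cm, pos_bp, vclass
    genotypes: np.ndarray  # (n_offspring, n_markers) int8
    purple_gamete: np.ndarray  # (n_offspring, n_markers) int8, parental phase
    green_gamete: np.ndarray  # (n_offspring, n_markers) int8, all zero
    causal_dosage: np.ndarray  # (n_offspring,) int8
    liability: np.ndarray | None = None
    color_class: np.ndarray | None = None  # int codes into COLOR_CLASSES
    phenotype_model: PhenotypeModel | None = field(default=None, repr=False)

    @property
    def n_offspring(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    def class_counts(self) -> dict[str, int]:
        if self.color_class is None:
            raise ValueError("phenotypes not assigned yet")
        counts = np.bincount(self.color_class, minlength=len(COLOR_CLASSES))
        return dict(zip(COLOR_CLASSES, counts.tolist()))


def _marker_table(config: CrossConfig) -> pd.DataFrame:
    rows = []
    for spec in config.chromosomes:
        pos_cm = spec.marker_positions_cm()
        for j, p in enumerate(pos_cm):
            rows.append(
                {
                    "id": f"{spec.name}_m{j:04d}",
                    "chrom": spec.name,
                    "pos_cm": float(p),
                    "pos_bp": int(round(p * BP_PER_CM)),
                    # every 10th marker is an InDel, the rest SNPs
                    "vclass": "InDel" if j % 10 == 3 else "SNP",
                }
            )
    df = pd.DataFrame(rows)
    for name, sub in df.groupby("chrom"):
        if not sub["pos_bp"].is_monotonic_increasing or sub["pos_bp"].duplicated().any():
            raise ConfigurationError(f"marker positions not strictly increasing on {name}")
    return df


def _simulate_gametes(positions_cm: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Simulate n purple-parent gametes over ordered loci (Markov chain)."""
    m = positions_cm.size
    first = rng.random(n) < 0.5
    if m == 1:
        return first[:, None].astype(np.int8)
    r = haldane_recombination_fraction(np.diff(positions_cm))
    switches = rng.random((n, m - 1)) < r
    state = np.concatenate([first[:, None], switches], axis=1)
    return np.logical_xor.accumulate(state, axis=1).astype(np.int8)


def simulate_cross(config: CrossConfig, seed: int | None = None) -> SimulatedPopulation:
    """Simulate the F1 population: purple parent Aa x green parent aa.

    The causal locus is simulated jointly with the markers of its chromosome
    so linkage between markers and the trait follows the Haldane model.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    markers = _marker_table(config)

    genotype_blocks: list[np.ndarray] = []
    causal_dosage: np.ndarray | None = None
    for spec in config.chromosomes:
        pos = spec.marker_positions_cm()
        if spec.name == config.causal_chrom:
            aug = np.sort(np.append(pos, config.causal_cm))
            # stable index of the causal locus among augmented positions
            ci = int(np.searchsorted(aug, config.causal_cm))
            gam = _simulate_gametes(aug, config.n_offspring, rng)
            causal_dosage = gam[:, ci].copy()
            keep = np.ones(aug.size, dtype=bool)
            keep[ci] = False
            # a causal position coinciding with a marker yields two loci at
            # distance 0 (r=0, identical alleles); dropping the insert keeps
            # the marker perfectly linked, which is the intended limit
            gam = gam[:, keep]
        else:
            gam = _simulate_gametes(pos, config.n_offspring, rng)
        genotype_blocks.append(gam)

    purple = np.concatenate(genotype_blocks, axis=1)
    assert causal_dosage is not None
    green = np.zeros_like(purple)
    return SimulatedPopulation(
        config=config,
        markers=markers,
        genotypes=(purple + green).astype(np.int8),
        purple_gamete=purple,
        green_gamete=green,
        causal_dosage=causal_dosage.astype(np.int8),
    )


def assign_phenotypes(
    pop: SimulatedPopulation,
    model: PhenotypeModel | None = None,
    seed: int = 0,
    overwrite: bool = False,
) -> SimulatedPopulation:
    """Draw liabilities from the genotype-mean + Gaussian-noise model and bin
    them into the five ordinal color classes."""
    if pop.liability is not None and not overwrite:
        raise ValueError("liabilities already assigned; pass overwrite=True to redo")
    model = model or PhenotypeModel.default()
    rng = np.random.default_rng(seed)
    means = np.asarray(model.genotype_means)[pop.causal_dosage]
    liability = means + rng.normal(0.0, model.sigma, size=pop.n_offspring)
    classes = np.searchsorted(np.asarray(model.thresholds), liability, side="left")
    return replace(
        pop,
        liability=liability,
        color_class=classes.astype(np.int8),
        phenotype_model=model,
    )


def select_extremes(pop: SimulatedPopulation, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Pick the k lowest- and k highest-liability individuals.

    Ties are broken by individual index (lower index wins) so the selection
    is deterministic across runs.
    """
    if pop.liability is None:
        raise ValueError("phenotypes must be assigned before selecting extremes")
    n = pop.n_offspring
    if 2 * k > n:
        deficit = "both tails" if n < k else "upper tail"
        raise ValueError(
            f"cannot select {k} individuals per tail from {n} offspring ({deficit} deficient)"
        )
    ids = np.arange(n)
    low_order = np.lexsort((ids, pop.liability))
    high_order = np.lexsort((ids, -pop.liability))
    green_group = low_order[:k]
    purple_group = high_order[:k]
    return green_group, purple_group


def form_pools(group: np.ndarray, pool_size: int) -> list[np.ndarray]:
    """Split a ranked group into contiguous pools of pool_size members."""
    group = np.asarray(group)
    if group.size % pool_size != 0:
        raise ValueError(
            f"group of {group.size} not divisible into pools of {pool_size}"
        )
    return [group[i : i + pool_size] for i in range(0, group.size, pool_size)]
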