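"""Per-bulk sequencing depth simulation for the variant layers.

A variant table holds, per marker, ref/alt read counts for two bulks.  The
DNA layer samples depth ~ Poisson(lambda) at every marker; the RNA layer
scales lambda per marker by the expression weight of the containing gene, so
markers outside expressed genes receive zero RNA depth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cross import SimulatedPopulation


def simulate_bulk_depths(
    pop: SimulatedPopulation,
    bulk1: np.ndarray,
    bulk2: np.ndarray,
    lam: float,
    error_rate: float = 0.001,
    seed: int = 0,
    weights: np.ndarray | None = None,
    sample_names: tuple[str, str] = ("GP", "PP"),
) -> pd.DataFrame:
    """Simulate a two-bulk variant table over the population's markers.

    Per marker and bulk: depth ~ Poisson(lam * weight) and
    alt ~ Binomial(depth, f*(1-e) + (1-f)*e) with f the mean alt dosage / 2
    over the bulk members.

    Returns a table with columns chrom, pos, id, vclass, ref_<s1>, alt_<s1>,
    ref_<s2>, alt_<s2>; positions are 1-based synthetic bp.
    """
    if lam <= 0:
        raise ValueError("mean depth lambda must be positive")
    bulk1 = np.asarray(bulk1)
    bulk2 = np.asarray(bulk2)
    if bulk1.size == 0 or bulk2.size == 0:
        raise ValueError("bulks must be non-empty")
    if weights is None:
        weights = np.ones(pop.n_markers)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (pop.n_markers,):
        raise ValueError("weights must have one entry per marker")

    rng = np.random.default_rng(seed)
    out = pop.markers[["chrom", "pos_bp", "id", "vclass"]].rename(columns={"pos_bp": "pos"})
    out = out[["chrom", "pos", "id", "vclass"]].copy()
    for name, bulk in zip(sample_names, (bulk1, bulk2)):
        f = pop.genotypes[bulk].mean(axis=0) / 2.0
        p_alt = f * (1.0 - error_rate) + (1.0 - f) * error_rate
        depth = rng.poisson(lam * weights)
        alt = rng.binomial(depth, p_alt)
        out[f"ref_{name}"] = depth - alt
        out[f"alt_{name}"] = alt
    out.attrs["samples"] = list(sample_names)
    return out
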