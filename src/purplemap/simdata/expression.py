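"""Gene models and pooled expression counts for the RNA layers."""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..de import CountsMatrix
from .config import ConfigurationError, CrossConfig, ExprConfig
from .cross import SimulatedPopulation

#: half-span of a simulated gene around its marker, in bp
GENE_HALF_SPAN = 1000

#: markers whose within-chromosome index hits this residue are intergenic
INTERGENIC_RESIDUE = 9


def build_gene_models(pop_or_config: SimulatedPopulation | CrossConfig, markers: pd.DataFrame | None = None) -> tuple[pd.DataFrame, str]:
    """Lay one gene over most markers and return (gene table, causal gene id).

    Genes span marker +- GENE_HALF_SPAN bp.  One marker in ten is left
    intergenic (zero RNA depth there), except that the marker nearest the
    causal locus always carries a gene — the causal gene.

    Returns a table with 1-based inclusive start/end (GFF convention) plus
    the global marker row index each gene covers.
    """
    if isinstance(pop_or_config, SimulatedPopulation):
        config = pop_or_config.config
        markers = pop_or_config.markers
    else:
        config = pop_or_config
        if markers is None:
            raise ValueError("markers table required when passing a CrossConfig")

    causal_bp = config.causal_bp
    on_causal = markers["chrom"] == config.causal_chrom
    causal_marker_idx = int(
        (markers.loc[on_causal, "pos"] if "pos" in markers else markers.loc[on_causal, "pos_bp"])
        .sub(causal_bp)
        .abs()
        .idxmin()
    )

    pos_col = "pos_bp" if "pos_bp" in markers else "pos"
    rows = []
    for chrom, sub in markers.groupby("chrom", sort=False):
        for within, (gidx, row) in enumerate(sub.iterrows()):
            if within % 10 == INTERGENIC_RESIDUE and gidx != causal_marker_idx:
                continue
            pos = int(row[pos_col])
            rows.append(
                {
                    "gene_id": f"G_{chrom}_{within:04d}",
                    "chrom": chrom,
                    "start": max(1, pos - GENE_HALF_SPAN),
                    "end": pos + GENE_HALF_SPAN,
                    "marker_idx": gidx,
                }
            )
    genes = pd.DataFrame(rows)
    causal_gene_id = genes.loc[genes["marker_idx"] == causal_marker_idx, "gene_id"].iloc[0]
    return genes, causal_gene_id


def simulate_expression(
    pop: SimulatedPopulation,
    pools: list[tuple[str, str, np.ndarray]],
    genes: pd.DataFrame,
    causal_gene_id: str,
    expr: ExprConfig | None = None,
    seed: int = 0,
) -> tuple[CountsMatrix, dict]:
    """Simulate gene x pool negative-binomial counts with planted DEGs.

    pools: list of (sample name, class label 'green'|'purple', member indices).
    Null genes share one NB mean across classes; planted DEGs receive the
    configured fold change in purple pools; the causal gene's fold change is
    tied to the mean causal-locus dosage of each pool's members.

    Returns the counts matrix plus a truth record (planted DEGs, causal gene).
    """
    expr = expr or ExprConfig()
    classes = {c for _, c, _ in pools}
    for cls in ("green", "purple"):
        if sum(1 for _, c, _ in pools if c == cls) < 2:
            raise ConfigurationError(f"need >=2 pools of class {cls!r} for DE testing")
    if classes - {"green", "purple"}:
        raise ConfigurationError(f"unknown pool classes: {classes - {'green', 'purple'}}")

    rng = np.random.default_rng(seed)
    gene_ids = genes["gene_id"].to_numpy()
    n_genes = gene_ids.size
    base_mean = rng.lognormal(np.log(expr.base_mean), expr.mean_log_sigma, size=n_genes)

    causal_pos = int(np.flatnonzero(gene_ids == causal_gene_id)[0])
    eligible = np.flatnonzero(gene_ids != causal_gene_id)
    n_deg = int(round(expr.deg_fraction * n_genes))
    planted = rng.choice(eligible, size=min(n_deg, eligible.size), replace=False)
    signs = rng.choice([-1.0, 1.0], size=planted.size)
    lfc = np.zeros(n_genes)
    lfc[planted] = signs * np.abs(
        rng.normal(expr.log2fc_loc, expr.log2fc_scale, size=planted.size)
    )

    shape = 1.0 / expr.dispersion
    counts = {}
    for name, cls, members in pools:
        mu = base_mean.copy()
        if cls == "purple":
            mu = mu * np.power(2.0, lfc)
        mean_dosage = float(pop.causal_dosage[np.asarray(members)].mean())
        mu[causal_pos] *= 2.0 ** (expr.causal_log2fc * mean_dosage)
        lam = rng.gamma(shape, mu / shape)
        counts[name] = rng.poisson(lam)

    frame = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"))
    cm = CountsMatrix(frame, {name: cls for name, cls, _ in pools})
    truth = {
        "causal_gene": causal_gene_id,
        "causal_log2fc": expr.causal_log2fc,
        "planted_degs": {gene_ids[i]: float(lfc[i]) for i in planted},
        "base_means": dict(zip(gene_ids.tolist(), base_mean.tolist())),
    }
    return cm, truth


def expression_weights(
    markers: pd.DataFrame, genes: pd.DataFrame, base_means: dict[str, float]
) -> np.ndarray:
    """Per-marker RNA depth multipliers: gene mean expression, normalized to
    average 1 over genic markers; intergenic markers get 0."""
    w = np.zeros(len(markers))
    mu = genes["gene_id"].map(base_means).to_numpy(dtype=float)
    w[genes["marker_idx"].to_numpy()] = mu
    genic = w > 0
    if genic.any():
        w[genic] /= w[genic].mean()
    return w
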