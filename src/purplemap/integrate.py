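"""Three-way gene-set integration, enrichment, and correlation networks."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

REGIONS = ("A", "B", "C", "AB", "AC", "BC", "ABC")


@dataclass(frozen=True)
class VennPartition:
    """The 7-region decomposition of three gene sets.

    Region keys: single letters are exclusive regions (A = A only), pairs
    are exclusive pairwise intersections, ABC is the triple intersection.
    """

    regions: dict[str, frozenset]

    def sizes(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.regions.items()}

    def union_size(self) -> int:
        return sum(len(v) for v in self.regions.values())

    @property
    def triple(self) -> frozenset:
        return self.regions["ABC"]


def venn_partition(set_a: Iterable, set_b: Iterable, set_c: Iterable) -> VennPartition:
    """Exact 7-region decomposition of three sets; ABC holds the prime
    candidates shared by every layer."""
    a, b, c = set(set_a), set(set_b), set(set_c)
    regions = {
        "A": frozenset(a - b - c),
        "B": frozenset(b - a - c),
        "C": frozenset(c - a - b),
        "AB": frozenset((a & b) - c),
        "AC": frozenset((a & c) - b),
        "BC": frozenset((b & c) - a),
        "ABC": frozenset(a & b & c),
    }
    return VennPartition(regions)


def pathway_filter(
    genes: Iterable, annotation: Mapping[str, Iterable], pathway_ids: Iterable
) -> set:
    """Genes annotated to any of the listed pathways.

    annotation maps gene -> iterable of pathway ids.  Genes missing from the
    annotation are dropped (count logged).
    """
    if not annotation:
        raise ValueError("empty annotation map")
    genes = set(genes)
    wanted = set(pathway_ids)
    unannotated = sum(1 for g in genes if g not in annotation)
    if unannotated:
        logger.info("pathway_filter: %d/%d genes unannotated, dropped", unannotated, len(genes))
    return {g for g in genes if g in annotation and wanted & set(annotation[g])}


def enrichment_test(
    gene_set: Iterable,
    universe: Iterable,
    term_map: Mapping[str, Iterable],
    top_n: int = 20,
) -> pd.DataFrame:
    """Hypergeometric over-representation per term with BH correction.

    term_map maps term -> genes carrying it (restricted to the universe).
    Returns the full table ranked by p, with the top_n rows flagged.
    """
    gene_set = set(gene_set)
    universe = set(universe)
    if not gene_set <= universe:
        extra = sorted(gene_set - universe)[:5]
        raise ValueError(f"gene set not a subset of the universe (e.g. {extra})")
    N, n = len(universe), len(gene_set)
    rows = []
    for term, members in term_map.items():
        members = set(members) & universe
        K = len(members)
        k = len(members & gene_set)
        # upper tail: P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "overlap": k, "term_size": K, "set_size": n, "universe": N, "p_value": p})
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError("empty term map")
    table["q_value"] = multipletests(table["p_value"].to_numpy(), method="fdr_bh")[1]
    table = table.sort_values(["p_value", "term"], kind="mergesort").reset_index(drop=True)
    table["top"] = np.arange(len(table)) < top_n
    return table


def correlation_network(
    expression: pd.DataFrame,
    gene_set: Iterable,
    r_min: float = 0.8,
    p_max: float = 0.05,
    focal_gene: str | None = None,
) -> dict:
    """Pairwise Pearson network on log2(normalized + 1) across samples.

    Edges are retained when |r| >= r_min AND p < p_max (t-test on r with
    n - 2 df).  Zero-variance genes are excluded with a warning.  Returns
    {'edges': frame, 'focal': frame or None, 'excluded': [genes]}.
    """
    genes = [g for g in gene_set if g in expression.index]
    missing = set(gene_set) - set(genes)
    if missing:
        raise KeyError(f"genes absent from expression matrix: {sorted(missing)[:5]}")
    n_samples = expression.shape[1]
    if n_samples < 3:
        raise ValueError("correlation needs >=3 samples")

    X = np.log2(expression.loc[genes].to_numpy(dtype=float) + 1.0)
    sd = X.std(axis=1)
    excluded = [g for g, s in zip(genes, sd) if s == 0.0]
    if excluded:
        logger.warning("correlation_network: excluding zero-variance genes %s", excluded)
    kept = [g for g, s in zip(genes, sd) if s > 0.0]
    X = X[sd > 0.0]
    if len(kept) < 2:
        return {"edges": _empty_edges(), "focal": None, "excluded": excluded}

    r = np.corrcoef(X)
    df = n_samples - 2
    rows = []
    for i in range(len(kept)):
        for j in range(i + 1, len(kept)):
            rij = float(np.clip(r[i, j], -1.0, 1.0))
            if abs(rij) >= 1.0:
                p = 0.0
            else:
                t = rij * np.sqrt(df / (1.0 - rij**2))
                p = float(2.0 * stats.t.sf(abs(t), df))
            if abs(rij) >= r_min and p < p_max:
                rows.append(
                    {
                        "gene1": kept[i],
                        "gene2": kept[j],
                        "r": rij,
                        "p_value": p,
                        "sign": "positive" if rij > 0 else "negative",
                    }
                )
    edges = pd.DataFrame(rows, columns=["gene1", "gene2", "r", "p_value", "sign"])
    focal = None
    if focal_gene is not None:
        mask = (edges["gene1"] == focal_gene) | (edges["gene2"] == focal_gene)
        focal = edges[mask].copy()
        focal["partner"] = np.where(
            focal["gene1"] == focal_gene, focal["gene2"], focal["gene1"]
        )
    return {"edges": edges, "focal": focal, "excluded": excluded}


def _empty_edges() -> pd.DataFrame:
    return pd.DataFrame(columns=["gene1", "gene2", "r", "p_value", "sign"])


def min_significant_r(n_samples: int, alpha: float = 0.05) -> float:
    """Smallest |r| significant at two-sided alpha with n - 2 df."""
    df = n_samples - 2
    t_star = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(t_star / np.sqrt(df + t_star**2))
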