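"""Pooled-count normalization, DE calling, ordination, qPCR concordance.

The DE engine is a Welch t-test on log2(normalized + 1) per gene; fold
changes use a 0.5 pseudocount on normalized class means.  Both thresholds of
the DEG filter are strict inequalities (|log2FC| > 1, P < 0.05) and no
multiple-testing correction is applied in the headline filter, though BH
q-values are reported alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

LFC_PSEUDOCOUNT = 0.5
LOG_PSEUDOCOUNT = 1.0


@dataclass
class CountsMatrix:
    """Gene x sample non-negative integer counts with a sample->class map."""

    counts: pd.DataFrame
    classes: Mapping[str, str]

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.classes)
        if missing:
            raise ValueError(f"samples without a class label: {sorted(missing)}")

    def samples_of(self, cls: str) -> list[str]:
        return [s for s in self.counts.columns if self.classes[s] == cls]


#: fixed reference scale of the normalized matrix (counts-per-million-like);
#: anchoring to a constant makes DE results *exactly* invariant to scaling
#: any one sample's counts, which raw size-factor division is not (the
#: geometric-mean reference drifts by c^(1/m) through the pseudocounts)
NORMALIZED_SCALE = 1e6


def normalize_counts(matrix: CountsMatrix, min_positive_genes: int = 50) -> tuple[pd.DataFrame, pd.Series]:
    """Median-of-ratios size factors; returns (normalized matrix, factors).

    The reported factors are the raw median of per-gene ratios to the
    geometric-mean reference sample; the normalized matrix is additionally
    rescaled by the median per-sample factor-corrected library size onto the
    fixed NORMALIZED_SCALE.  Falls back to total-count scaling when fewer
    than min_positive_genes genes have all-positive counts.
    """
    counts = matrix.counts
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"all-zero sample(s): {', '.join(zero.index)}")
    positive = counts[(counts > 0).all(axis=1)]
    if len(positive) >= min_positive_genes:
        log_geomean = np.log(positive).mean(axis=1)
        ratios = np.log(positive).sub(log_geomean, axis=0)
        size_factors = np.exp(ratios.median(axis=0))
    else:
        logger.info(
            "normalize_counts: only %d all-positive genes; using total-count scaling",
            len(positive),
        )
        size_factors = totals / totals.mean()
    size_factors.name = "size_factor"
    anchor = float((totals / size_factors).median())
    normalized = counts / size_factors / anchor * NORMALIZED_SCALE
    return normalized, size_factors


def de_test(
    normalized: pd.DataFrame,
    classes: Mapping[str, str],
    control: str = "green",
    case: str = "purple",
) -> pd.DataFrame:
    """Per-gene Welch t-test of case vs control on log2(normalized + 1).

    Returns a frame indexed by gene with log2fc, p_value, q_value (BH), and
    per-class normalized means.  Genes with zero variance in both classes
    and equal means get p = 1 by convention.
    """
    ctrl_samples = [s for s in normalized.columns if classes[s] == control]
    case_samples = [s for s in normalized.columns if classes[s] == case]
    if len(ctrl_samples) < 2 or len(case_samples) < 2:
        raise ValueError("need >=2 replicates per class for the DE test")

    ctrl = normalized[ctrl_samples].to_numpy(dtype=float)
    cse = normalized[case_samples].to_numpy(dtype=float)
    mean_ctrl = ctrl.mean(axis=1)
    mean_case = cse.mean(axis=1)
    log2fc = np.log2((mean_case + LFC_PSEUDOCOUNT) / (mean_ctrl + LFC_PSEUDOCOUNT))

    log_ctrl = np.log2(ctrl + LOG_PSEUDOCOUNT)
    log_case = np.log2(cse + LOG_PSEUDOCOUNT)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(log_case, log_ctrl, axis=1, equal_var=False)
    p = np.asarray(p)
    degenerate = np.isnan(p)  # zero variance in both classes, equal means
    p[degenerate] = 1.0
    q = multipletests(p, method="fdr_bh")[1]

    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "p_value": p,
            "q_value": q,
            f"mean_{control}": mean_ctrl,
            f"mean_{case}": mean_case,
        },
        index=normalized.index,
    )


def filter_degs(results: pd.DataFrame, lfc_min: float = 1.0, p_max: float = 0.05) -> pd.DataFrame:
    """Strict-threshold DEG filter: |log2fc| > lfc_min AND p < p_max."""
    if results.empty:
        raise ValueError("empty DE results")
    keep = (results["log2fc"].abs() > lfc_min) & (results["p_value"] < p_max)
    out = results.loc[keep].copy()
    out["direction"] = np.where(out["log2fc"] > 0, "up", "down")
    return out


def pca_scores(normalized: pd.DataFrame, n_components: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample scores on the leading principal components.

    Computed on gene-centered log2(normalized + 1); the loading of largest
    magnitude on each component is made positive to fix the sign.
    Returns (scores frame indexed by sample, explained-variance fractions).
    """
    if normalized.shape[1] < 3:
        raise ValueError("PCA needs >=3 samples")
    X = np.log2(normalized.to_numpy(dtype=float) + LOG_PSEUDOCOUNT).T  # samples x genes
    X = X - X.mean(axis=0)
    if not np.any(X):
        raise ValueError("constant matrix: zero variance, PCA undefined")
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    k = min(n_components, S.size)
    for j in range(k):
        i_star = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i_star] < 0:
            U[:, j] *= -1.0
            Vt[j] *= -1.0
    scores = U[:, :k] * S[:k]
    evr = (S**2) / float(np.sum(S**2))
    frame = pd.DataFrame(
        scores, index=normalized.columns, columns=[f"PC{j + 1}" for j in range(k)]
    )
    return frame, evr[:k]


def qpcr_concordance(de_results: pd.DataFrame, qpcr: pd.DataFrame) -> dict:
    """Direction agreement between RNA-seq log2fc and qPCR ratios.

    qpcr: frame indexed by gene with columns 'green' and 'purple' holding
    relative expression per class (or a single 'ratio' column, purple/green).
    """
    if "ratio" in qpcr.columns:
        ratio = qpcr["ratio"]
    else:
        ratio = qpcr["purple"] / qpcr["green"]
    shared = de_results.index.intersection(ratio.index)
    if shared.empty:
        raise ValueError("no shared genes between DE results and qPCR table")
    seq_sign = np.sign(de_results.loc[shared, "log2fc"])
    qpcr_sign = np.sign(np.log2(ratio.loc[shared].astype(float)))
    agree = (seq_sign == qpcr_sign).astype(bool)
    table = pd.DataFrame(
        {"rnaseq_sign": seq_sign, "qpcr_sign": qpcr_sign, "agree": agree}, index=shared
    )
    return {"per_gene": table, "fraction_agreeing": float(agree.mean()), "n": int(len(shared))}
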