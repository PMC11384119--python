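"""End-to-end orchestration: simulate -> BSA/BSR -> DE -> integrate.

Every run is driven by one global seed; per-stage seeds are derived by
hashing the stage name with the global seed, so enabling or disabling one
stage never perturbs another stage's random stream.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, bsa, de, integrate
from .simdata import (
    BulkDesign,
    ChromosomeSpec,
    CrossConfig,
    ExprConfig,
    PhenotypeModel,
    assign_phenotypes,
    form_pools,
    select_extremes,
    simulate_bulk_depths,
    simulate_cross,
)
from .simdata.expression import build_gene_models, expression_weights, simulate_expression
from .simdata.promoter import make_promoter_fixture
from .simdata import emit

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "bsa", "bsr", "de", "integrate")


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed derived from the global seed and stage name."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big")


@dataclass
class AnalysisParams:
    """Knobs of the analysis stages (defaults match the module ledgers)."""

    power: int = bsa.DEFAULT_POWER
    window_bp: float = bsa.DEFAULT_WINDOW_BP
    min_depth: int = bsa.DEFAULT_MIN_DEPTH
    rule: str = bsa.DEFAULT_RULE
    multiplier: float | None = None
    lfc_min: float = 1.0
    p_max: float = 0.05
    r_min: float = 0.8


@dataclass
class RunConfig:
    """Full-run configuration: stage toggles plus per-stage parameters."""

    seed: int = 0
    out_dir: Path = Path("purplemap_out")
    stages: tuple[str, ...] = ALL_STAGES
    cross: CrossConfig = field(default_factory=CrossConfig)
    bulk: BulkDesign = field(default_factory=BulkDesign)
    expr: ExprConfig = field(default_factory=ExprConfig)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        need = {"bsa": "simulate", "bsr": "simulate", "de": "simulate"}
        for stage, dep in need.items():
            if stage in self.stages and dep not in self.stages:
                raise ValueError(f"stage {stage!r} requires {dep!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cross_raw = dict(raw.get("cross", {}))
        if "chromosomes" in cross_raw:
            cross_raw["chromosomes"] = tuple(
                ChromosomeSpec(**c) for c in cross_raw["chromosomes"]
            )
        return cls(
            seed=int(raw.get("seed", 0)),
            out_dir=Path(raw.get("out_dir", "purplemap_out")),
            stages=tuple(raw.get("stages", ALL_STAGES)),
            cross=CrossConfig(**cross_raw),
            bulk=BulkDesign(**raw.get("bulk", {})),
            expr=ExprConfig(**raw.get("expr", {})),
            analysis=AnalysisParams(**raw.get("analysis", {})),
        )


@dataclass
class SimBundle:
    """Everything the analysis stages consume, held in memory."""

    config: CrossConfig
    pop: object
    green_bulk: np.ndarray
    purple_bulk: np.ndarray
    pools: list
    genes: pd.DataFrame
    causal_gene_id: str
    counts: de.CountsMatrix
    truth: dict
    dna_table: pd.DataFrame
    rna_table: pd.DataFrame


def simulate_dataset(
    config: CrossConfig | None = None,
    bulk: BulkDesign | None = None,
    expr: ExprConfig | None = None,
    seed: int = 0,
    phenotype_model: PhenotypeModel | None = None,
) -> SimBundle:
    """Generate one complete synthetic dataset (population, bulks, variant
    tables for both layers, pooled expression counts, truth record)."""
    config = config or CrossConfig()
    bulk = bulk or BulkDesign()
    bulk.validate_for(config.n_offspring)

    pop = simulate_cross(config, seed=stage_seed(seed, "cross"))
    pop = assign_phenotypes(pop, phenotype_model, seed=stage_seed(seed, "phenotype"))
    green, purple = select_extremes(pop, bulk.k)
    pools = [
        (f"GP{i + 1}", "green", p) for i, p in enumerate(form_pools(green, bulk.rna_pool_size))
    ] + [
        (f"PP{i + 1}", "purple", p) for i, p in enumerate(form_pools(purple, bulk.rna_pool_size))
    ]

    genes, causal_gene_id = build_gene_models(pop)
    counts, truth = simulate_expression(
        pop, pools, genes, causal_gene_id, expr, seed=stage_seed(seed, "expression")
    )
    weights = expression_weights(pop.markers, genes, truth["base_means"])

    dna_table = simulate_bulk_depths(
        pop, green, purple, bulk.lambda_dna, bulk.error_rate,
        seed=stage_seed(seed, "dna_depths"), sample_names=("GP", "PP"),
    )
    rna_table = simulate_bulk_depths(
        pop, green, purple, bulk.lambda_rna, bulk.error_rate,
        seed=stage_seed(seed, "rna_depths"), weights=weights,
        sample_names=("RGP", "RPP"),
    )
    truth = dict(truth)
    truth.update(
        {
            "causal_chrom": config.causal_chrom,
            "causal_bp": config.causal_bp,
            "class_counts": pop.class_counts(),
        }
    )
    return SimBundle(
        config=config, pop=pop, green_bulk=green, purple_bulk=purple, pools=pools,
        genes=genes, causal_gene_id=causal_gene_id, counts=counts, truth=truth,
        dna_table=dna_table, rna_table=rna_table,
    )


@dataclass
class AnalysisResult:
    bsa_profile: bsa.EDProfile | None = None
    bsr_profile: bsa.EDProfile | None = None
    bsa_intervals: list = field(default_factory=list)
    bsr_intervals: list = field(default_factory=list)
    bsa_genes: set = field(default_factory=set)
    bsr_genes: set = field(default_factory=set)
    normalized: pd.DataFrame | None = None
    de_results: pd.DataFrame | None = None
    degs: pd.DataFrame | None = None
    venn: integrate.VennPartition | None = None
    network: dict | None = None
    recovery: dict | None = None


def _ed_layer(table: pd.DataFrame, genes: pd.DataFrame, params: AnalysisParams):
    profile = bsa.ed_profile(table, power=params.power, min_depth=params.min_depth)
    profile = bsa.smooth_profile(profile, window_bp=params.window_bp)
    intervals = bsa.call_regions(
        profile, rule=params.rule, multiplier=params.multiplier, by_class=True
    )
    joint = [iv for iv in intervals if iv.vclass == "all"]
    gene_set = bsa.genes_in_regions(joint, genes)
    return profile, intervals, gene_set


def analyze_dataset(
    bundle: SimBundle,
    params: AnalysisParams | None = None,
    stages: tuple[str, ...] = ALL_STAGES,
) -> AnalysisResult:
    """Run the enabled analysis stages over an in-memory dataset."""
    params = params or AnalysisParams()
    res = AnalysisResult()
    if "bsa" in stages:
        res.bsa_profile, res.bsa_intervals, res.bsa_genes = _ed_layer(
            bundle.dna_table, bundle.genes, params
        )
    if "bsr" in stages:
        res.bsr_profile, res.bsr_intervals, res.bsr_genes = _ed_layer(
            bundle.rna_table, bundle.genes, params
        )
    if "de" in stages:
        res.normalized, _ = de.normalize_counts(bundle.counts)
        res.de_results = de.de_test(res.normalized, bundle.counts.classes)
        res.degs = de.filter_degs(res.de_results, lfc_min=params.lfc_min, p_max=params.p_max)
    if "integrate" in stages and res.degs is not None:
        deg_set = set(res.degs.index)
        res.venn = integrate.venn_partition(res.bsa_genes, res.bsr_genes, deg_set)
        focal = bundle.causal_gene_id
        net_genes = sorted(deg_set | {focal})
        if res.normalized is not None and len(net_genes) >= 2:
            res.network = integrate.correlation_network(
                res.normalized, net_genes, r_min=params.r_min, focal_gene=focal
            )
        res.recovery = recovery_report(bundle, res)
    return res


def recovery_report(bundle: SimBundle, res: AnalysisResult) -> dict:
    """Compare the analysis output against the planted truth."""
    report: dict = {}
    truth = bundle.truth
    if res.bsa_intervals:
        joint = [iv for iv in res.bsa_intervals if iv.vclass == "all"]
        top = max(joint, key=lambda iv: iv.peak_value, default=None)
        if top is not None:
            same_chrom = top.chrom == truth["causal_chrom"]
            dist = abs(top.peak_pos - truth["causal_bp"]) if same_chrom else float("inf")
            report["causal_peak_distance_bp"] = dist
            report["causal_locus_recovered"] = bool(same_chrom and dist <= 2_000_000)
    if res.degs is not None:
        called = set(res.degs.index)
        planted = {g for g, fc in truth["planted_degs"].items() if abs(fc) > 1.0}
        planted_all = planted | {truth["causal_gene"]}
        tp = len(called & planted_all)
        report["deg_precision"] = tp / len(called) if called else 0.0
        report["deg_recall"] = (
            len(called & planted_all) / len(planted_all) if planted_all else 1.0
        )
    if res.venn is not None:
        report["causal_gene_in_triple_intersection"] = bundle.causal_gene_id in res.venn.triple
    return report


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_full(config: RunConfig) -> AnalysisResult:
    """Execute enabled stages, write all artifacts plus a hashed manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save_df(df: pd.DataFrame, rel: str, **kw) -> None:
        path = out / rel
        path.parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(path, sep="\t", index=kw.pop("index", False))
        written.append(path)

    bundle = None
    res = AnalysisResult()
    try:
        if "simulate" in config.stages:
            bundle = simulate_dataset(
                config.cross, config.bulk, config.expr, seed=config.seed
            )
            sim = out / "sim"
            sim.mkdir(exist_ok=True)
            written.append(emit.write_vcf(bundle.dna_table, sim / "bsa_pools.vcf", bundle.config))
            written.append(emit.write_vcf(bundle.rna_table, sim / "bsr_pools.vcf", bundle.config))
            written.append(emit.write_gff3(bundle.genes, sim / "genes.gff3"))
            emit.write_counts(bundle.counts, sim / "counts.tsv", sim / "classes.csv")
            written += [sim / "counts.tsv", sim / "classes.csv"]
            fixture = make_promoter_fixture(seed=stage_seed(config.seed, "promoter"))
            emit.write_promoter_fixture(fixture, sim / "promoter.fasta", sim / "primers.fasta")
            written += [sim / "promoter.fasta", sim / "primers.fasta"]
            written.append(emit.write_truth(bundle.truth, sim / "truth.json"))

        res = analyze_dataset(bundle, config.analysis, stages=config.stages)
        for layer, profile, intervals, genes in (
            ("bsa", res.bsa_profile, res.bsa_intervals, res.bsa_genes),
            ("bsr", res.bsr_profile, res.bsr_intervals, res.bsr_genes),
        ):
            if profile is None:
                continue
            save_df(bsa.profile_to_frame(profile), f"{layer}/ed_profile.tsv")
            save_df(bsa.intervals_to_bed(intervals), f"{layer}/intervals.bed")
            save_df(pd.DataFrame(sorted(genes), columns=["gene_id"]), f"{layer}/genes.tsv")
        if res.de_results is not None:
            save_df(res.de_results, "de/de_results.tsv", index=True)
            save_df(res.degs, "de/degs.tsv", index=True)
            scores, evr = de.pca_scores(res.normalized)
            scores["explained_variance"] = list(evr) + [np.nan] * (len(scores) - len(evr))
            save_df(scores, "de/pca_scores.tsv", index=True)
        if res.venn is not None:
            venn_path = out / "integrate" / "venn.json"
            venn_path.parent.mkdir(parents=True, exist_ok=True)
            venn_payload = {k: sorted(v) for k, v in res.venn.regions.items()}
            venn_path.write_text(json.dumps(venn_payload, indent=2, sort_keys=True) + "\n")
            written.append(venn_path)
            if res.network is not None:
                save_df(res.network["edges"], "integrate/edges.tsv")
        if res.recovery is not None:
            rec_path = out / "recovery.json"
            rec_path.write_text(json.dumps(res.recovery, indent=2, sort_keys=True) + "\n")
            written.append(rec_path)
    except Exception as exc:  # annotate the failing stage, keep partial output
        logger.error("pipeline failed: %s", exc)
        raise

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
        "parameters": {
            "cross": _jsonable(asdict(config.cross)),
            "bulk": asdict(config.bulk),
            "expr": asdict(config.expr),
            "analysis": asdict(config.analysis),
        },
        "outputs": {
            str(p.relative_to(out)): _sha256(p) for p in sorted(set(written))
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return res


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj
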