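"""Validated loaders for the pipeline's text formats.

VCF positions are 1-based on disk and kept 1-based in variant tables (the
region caller emits 0-based half-open BED); GFF3 start/end are 1-based
inclusive and converted where interval arithmetic needs half-open.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
import pysam

from .de import CountsMatrix

logger = logging.getLogger(__name__)


class InputError(ValueError):
    """A malformed or inconsistent input file."""


def read_variant_table(path: str | Path, samples: tuple[str, str] | None = None) -> pd.DataFrame:
    """Read a two-sample VCF with AD fields into a variant table.

    Returns columns chrom, pos (1-based), id, vclass, ref_<s>/alt_<s> per
    sample; multi-allelic records keep the first ALT depth and log a count.
    """
    path = Path(path)
    with pysam.VariantFile(str(path)) as vcf:
        file_samples = list(vcf.header.samples)
        if samples is None:
            samples = tuple(file_samples)
        if len(samples) != 2:
            raise InputError(f"{path}: expected exactly 2 samples, found {file_samples}")
        for s in samples:
            if s not in file_samples:
                raise InputError(f"{path}: sample {s!r} not in VCF ({file_samples})")
        rows = []
        n_multi = 0
        for rec in vcf:
            vclass = rec.info.get("VC")
            if vclass is None:
                ref, alts = rec.ref, rec.alts or ()
                indel = any(len(a) != len(ref) for a in alts)
                vclass = "InDel" if indel else "SNP"
            if rec.alts and len(rec.alts) > 1:
                n_multi += 1
            row = {
                "chrom": rec.chrom,
                "pos": rec.pos,
                "id": rec.id or f"{rec.chrom}:{rec.pos}",
                "vclass": vclass,
            }
            for s in samples:
                ad = rec.samples[s].get("AD")
                if ad is None or ad[0] is None:
                    raise InputError(f"{path}: missing AD for sample {s} at {rec.chrom}:{rec.pos}")
                row[f"ref_{s}"] = int(ad[0])
                row[f"alt_{s}"] = int(ad[1])
            rows.append(row)
    if n_multi:
        logger.info("read_variant_table: %d multi-allelic records, first ALT used", n_multi)
    if not rows:
        raise InputError(f"{path}: no variant records")
    table = pd.DataFrame(rows)
    table.attrs["samples"] = list(samples)
    return table


def read_gene_models(path: str | Path) -> pd.DataFrame:
    """Read gene features from a GFF3 file into (gene_id, chrom, start, end).

    Records are validated line by line so errors carry line numbers.
    """
    path = Path(path)
    rows = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise InputError(f"{path}:{lineno}: expected 9 columns, got {len(fields)}")
            chrom, _, ftype, start_s, end_s, _, _, _, attrs = fields
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise InputError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end < start:
                raise InputError(f"{path}:{lineno}: feature end {end} < start {start}")
            if ftype != "gene":
                continue
            gene_id = None
            for kv in attrs.split(";"):
                if kv.startswith("ID="):
                    gene_id = kv[3:]
                    break
            if gene_id is None:
                raise InputError(f"{path}:{lineno}: gene feature without ID attribute")
            rows.append({"gene_id": gene_id, "chrom": chrom, "start": start, "end": end})
    if not rows:
        raise InputError(f"{path}: no gene features")
    return pd.DataFrame(rows)


def load_counts(counts_path: str | Path, classes_path: str | Path) -> CountsMatrix:
    """Read a gene x sample counts TSV plus a sample->class CSV."""
    counts_path = Path(counts_path)
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    neg = counts.lt(0).any(axis=1)
    if neg.any():
        first = counts.index.get_indexer_for(counts.index[neg])[0]
        raise InputError(
            f"{counts_path}:{first + 2}: negative count for gene {counts.index[neg][0]!r}"
        )
    if not all(pd.api.types.is_integer_dtype(t) or pd.api.types.is_float_dtype(t) for t in counts.dtypes):
        raise InputError(f"{counts_path}: non-numeric count columns")
    classes = pd.read_csv(classes_path, index_col=0)["class"].to_dict()
    return CountsMatrix(counts, classes)


def read_gene_list(path: str | Path) -> set[str]:
    """One gene id per line; blank lines ignored."""
    with Path(path).open() as fh:
        return {line.strip() for line in fh if line.strip()}


def read_term_map(path: str | Path) -> dict[str, set[str]]:
    """TSV of (gene, term) pairs -> {term: genes}."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "term"])
    out: dict[str, set[str]] = {}
    for gene, term in df.itertuples(index=False):
        out.setdefault(term, set()).add(gene)
    return out


def check_chromosome_consistency(*frames_with_names: tuple[pd.DataFrame, str]) -> None:
    """Cross-file check: every input must agree on its chromosome universe."""
    universes = {name: set(df["chrom"].unique()) for df, name in frames_with_names}
    reference_name, reference = next(iter(universes.items()))
    for name, chroms in universes.items():
        unknown = chroms - reference
        if unknown:
            raise InputError(
                f"chromosomes in {name} unknown to {reference_name}: {sorted(unknown)}"
            )
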