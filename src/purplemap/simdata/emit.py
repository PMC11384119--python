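"""Plain-text emission of simulated datasets (VCF, GFF3, TSV, FASTA, JSON)."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ..de import CountsMatrix
from .config import BP_PER_CM, CrossConfig
from .promoter import PromoterFixture

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=purplemap-simulate
##INFO=<ID=VC,Number=1,Type=String,Description="Variant class (SNP or InDel)">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""


def write_vcf(table: pd.DataFrame, path: str | Path, config: CrossConfig | None = None) -> Path:
    """Write a two-sample variant table as an uncompressed VCF with AD fields."""
    path = Path(path)
    samples = table.attrs.get("samples") or [
        c[4:] for c in table.columns if c.startswith("ref_")
    ]
    with path.open("w") as fh:
        fh.write(_VCF_HEADER)
        if config is not None:
            for spec in config.chromosomes:
                length = int(spec.length_cm * BP_PER_CM)
                fh.write(f"##contig=<ID={spec.name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT")
        fh.write("\t" + "\t".join(samples) + "\n")
        for row in table.itertuples(index=False):
            ref, alt = ("A", "G") if row.vclass == "SNP" else ("AT", "A")
            fields = [
                row.chrom,
                str(row.pos),
                row.id,
                ref,
                alt,
                ".",
                "PASS",
                f"VC={row.vclass}",
                "GT:AD:DP",
            ]
            for s in samples:
                r = getattr(row, f"ref_{s}")
                a = getattr(row, f"alt_{s}")
                fields.append(f"./.:{r},{a}:{r + a}")
            fh.write("\t".join(fields) + "\n")
    return path


def write_gff3(genes: pd.DataFrame, path: str | Path) -> Path:
    """Write gene models (1-based inclusive start/end) as GFF3."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples(index=False):
            attrs = f"ID={row.gene_id};Name={row.gene_id}"
            fh.write(
                f"{row.chrom}\tpurplemap\tgene\t{row.start}\t{row.end}\t.\t+\t.\t{attrs}\n"
            )
    return path


def write_counts(cm: CountsMatrix, counts_path: str | Path, classes_path: str | Path) -> None:
    """Write the counts matrix as TSV and the sample->class map as CSV."""
    cm.counts.to_csv(counts_path, sep="\t")
    pd.Series(cm.classes, name="class").rename_axis("sample").to_csv(classes_path)


def write_promoter_fixture(fixture: PromoterFixture, alleles_path: str | Path, primers_path: str | Path) -> None:
    records = [
        SeqRecord(Seq(fixture.long_allele), id="promoter_long", description="insertion allele"),
        SeqRecord(Seq(fixture.short_allele), id="promoter_short", description="no-insertion allele"),
    ]
    SeqIO.write(records, str(alleles_path), "fasta")
    primers = [
        SeqRecord(Seq(fixture.forward_primer), id="primer_F", description=""),
        SeqRecord(Seq(fixture.reverse_primer), id="primer_R", description=""),
    ]
    SeqIO.write(primers, str(primers_path), "fasta")


def write_truth(truth: dict, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
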