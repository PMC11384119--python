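"""Assay-level arithmetic: pigment quantification, 2^-ddCt, AsODN filtering,
in-silico PCR, marker co-segregation, and cis-element scanning.

Promoter coordinates throughout: -1 is the base immediately 5' of the ATG's
A; intervals are inclusive on both ends.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq
from Bio.SeqUtils import gc_fraction
from scipy import stats

logger = logging.getLogger(__name__)

#: mass-conversion constant of the pigment formula, as printed in the source
#: protocol; its units are undocumented, so content values are in "formula
#: units" unless the caller supplies a unit-bearing extinction coefficient.
ANTHOCYANIN_CONSTANT = 465.2

GC_MIN, GC_MAX = 0.40, 0.60
BINDING_ENERGY_MAX = -8.0  # kcal/mol
PCR_MAX_AMPLICON = 5000
PRIMER_MIN_LEN = 15


@dataclass(frozen=True)
class AbsorbanceReading:
    """One spectrophotometric reading with its extraction parameters.

    The formula slots are named A530/A620/A650; instruments reading at
    520 nm map that value onto the A530 slot (alias handled by the caller).
    epsilon has no default — it must be supplied, with units chosen by the
    user, and the result is in matching formula units.
    """

    a530: float
    a620: float
    a650: float
    volume_ml: float
    dilution: float
    epsilon: float
    mass_g: float

    def __post_init__(self) -> None:
        for name in ("volume_ml", "dilution", "epsilon", "mass_g"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("a530", "a620", "a650"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def anthocyanin_content(reading: AbsorbanceReading) -> float:
    """content = (A * V * n * 465.2) / (epsilon * m) with
    A = (A530 - A620) - 0.1 * (A650 - A620)."""
    a = (reading.a530 - reading.a620) - 0.1 * (reading.a650 - reading.a620)
    if a < 0:
        logger.warning("anthocyanin_content: corrected absorbance is negative (%.4f)", a)
    return (a * reading.volume_ml * reading.dilution * ANTHOCYANIN_CONSTANT) / (
        reading.epsilon * reading.mass_g
    )


def relative_expression(
    ct: pd.DataFrame,
    reference_gene: str,
    calibrator_sample: str,
) -> pd.DataFrame:
    """2^-ddCt relative expression per (sample, gene).

    ct: long-format frame with columns sample, gene, ct (one row per
    technical replicate).  ddCt = (Ct_target,s - Ct_ref,s) -
    (Ct_target,cal - Ct_ref,cal), computed on replicate-mean Cts so the
    calibrator sample is exactly 1; the SD column reflects replicate spread.
    """
    required = {"sample", "gene", "ct"}
    if not required <= set(ct.columns):
        raise ValueError(f"Ct table needs columns {sorted(required)}")
    if (ct["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")

    mean_ct = ct.groupby(["sample", "gene"])["ct"].mean().unstack("gene")
    if reference_gene not in mean_ct.columns:
        raise ValueError(f"reference gene {reference_gene!r} absent from the table")
    missing_ref = mean_ct.index[mean_ct[reference_gene].isna()].tolist()
    if missing_ref:
        raise ValueError(f"reference gene not measured in sample(s): {missing_ref}")
    if calibrator_sample not in mean_ct.index:
        raise ValueError(f"calibrator sample {calibrator_sample!r} absent from the table")

    delta = mean_ct.sub(mean_ct[reference_gene], axis=0)
    ddct = delta.sub(delta.loc[calibrator_sample], axis=1)
    value = np.power(2.0, -ddct)

    rows = []
    for (sample, gene), grp in ct.groupby(["sample", "gene"]):
        if gene == reference_gene:
            continue
        ref_mean = mean_ct.loc[sample, reference_gene]
        cal_dct = delta.loc[calibrator_sample, gene]
        rep_vals = np.power(2.0, -((grp["ct"].to_numpy() - ref_mean) - cal_dct))
        rows.append(
            {
                "sample": sample,
                "gene": gene,
                "rel_expr": float(value.loc[sample, gene]),
                "sd": float(rep_vals.std(ddof=1)) if len(rep_vals) > 1 else np.nan,
                "n_replicates": int(len(rep_vals)),
            }
        )
    return pd.DataFrame(rows)


def asodn_filter(candidates: pd.DataFrame) -> pd.DataFrame:
    """Filter antisense-oligo candidates on GC content and binding energy.

    candidates: frame with columns sequence and binding_energy (kcal/mol,
    computed externally).  Pass iff 0.40 <= GC <= 0.60 (inclusive) AND
    binding_energy <= -8; failure reasons are itemized per candidate.
    """
    rows = []
    for row in candidates.itertuples(index=False):
        seq = row.sequence.upper()
        if re.search(r"[^ACGT]", seq):
            raise ValueError(f"non-ACGT characters in candidate {seq!r}")
        gc = gc_fraction(seq)
        reasons = []
        if not (GC_MIN <= gc <= GC_MAX):
            reasons.append(f"GC {gc:.2f} outside [{GC_MIN:.2f}, {GC_MAX:.2f}]")
        if row.binding_energy > BINDING_ENERGY_MAX:
            reasons.append(
                f"binding energy {row.binding_energy} > {BINDING_ENERGY_MAX} kcal/mol"
            )
        rows.append(
            {
                "sequence": seq,
                "gc_fraction": gc,
                "binding_energy": row.binding_energy,
                "passed": not reasons,
                "reasons": "; ".join(reasons),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class Amplicon:
    """One productive primer pairing on the plus strand (0-based, half-open)."""

    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


def _find_all(needle: str, haystack: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def insilico_pcr(
    template: str,
    forward_primer: str,
    reverse_primer: str,
    max_length: int = PCR_MAX_AMPLICON,
) -> list[Amplicon]:
    """Exact-match in-silico PCR: every productive pairing up to max_length.

    The forward primer anneals on the plus strand; the reverse primer
    anneals where its reverse complement occurs downstream.  Zero matches
    yield an empty list; multiple pairings yield a multi-band result.
    """
    template = template.upper()
    fwd = forward_primer.upper()
    rev = reverse_primer.upper()
    if len(fwd) < PRIMER_MIN_LEN or len(rev) < PRIMER_MIN_LEN:
        raise ValueError(f"primers must be >= {PRIMER_MIN_LEN} nt")
    rc_rev = str(Seq(rev).reverse_complement())
    amplicons = []
    for s in _find_all(fwd, template):
        for t in _find_all(rc_rev, template):
            end = t + len(rc_rev)
            if t >= s and 0 < end - s <= max_length:
                amplicons.append(Amplicon(start=s, end=end))
    return sorted(amplicons, key=lambda a: (a.start, a.end))


def cosegregation_test(table: pd.DataFrame, purple_classes: set[str] | None = None) -> dict:
    """Fisher test of long-band presence against the purple/green phenotype.

    table: frame with columns band ('long_present' or 'short_only') and
    color_class.  purple_classes names the classes counted as purple
    (default: any class other than 'green').
    """
    if not {"band", "color_class"} <= set(table.columns):
        raise ValueError("table needs columns band and color_class")
    bad = set(table["band"].unique()) - {"long_present", "short_only"}
    if bad:
        raise ValueError(f"unknown band patterns: {sorted(bad)}")
    if purple_classes is None:
        purple = table["color_class"] != "green"
    else:
        purple = table["color_class"].isin(purple_classes)
    if purple.all() or (~purple).all():
        raise ValueError("co-segregation test needs both phenotype groups")
    long_band = table["band"] == "long_present"
    contingency = np.array(
        [
            [int((purple & long_band).sum()), int((purple & ~long_band).sum())],
            [int((~purple & long_band).sum()), int((~purple & ~long_band).sum())],
        ]
    )
    _, p = stats.fisher_exact(contingency, alternative="two-sided")
    return {
        "contingency": contingency,
        "fisher_p": float(p),
        "all_purple_carry_long": bool((~long_band & purple).sum() == 0),
        "all_green_lack_long": bool((long_band & ~purple).sum() == 0),
    }


_IUPAC_CODES = frozenset("ACGTRYSWKMBDHVN")


def _iupac_regex(motif: str) -> str:
    parts = []
    for ch in motif.upper():
        if ch not in _IUPAC_CODES:
            raise ValueError(f"invalid IUPAC character {ch!r} in motif {motif!r}")
        bases = ambiguous_dna_values[ch]
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return "".join(parts)


def scan_cis_elements(
    sequence: str,
    motifs: dict[str, str],
    promoter_coords: bool = True,
) -> pd.DataFrame:
    """Scan both strands for IUPAC consensus motifs (overlapping hits).

    Positions report the 5'-most template base of each hit; with
    promoter_coords=True they are negative offsets relative to the ATG.
    """
    seq = sequence.upper()
    L = len(seq)
    rows = []
    for name, motif in motifs.items():
        for strand, pattern in (("+", _iupac_regex(motif)), ("-", _iupac_regex(str(Seq(motif).reverse_complement())))):
            for m in re.finditer(f"(?=({pattern}))", seq):
                start = m.start()
                pos = start - L if promoter_coords else start
                rows.append({"motif": name, "position": pos, "strand": strand, "match": m.group(1)})
    return pd.DataFrame(rows, columns=["motif", "position", "strand", "match"])


def promoter_span(coord_a: int, coord_b: int) -> int:
    """Inclusive bp count between two upstream promoter coordinates.

    Both coordinates are negative (e.g. -332 and -152); the span counts both
    boundary positions, so promoter_span(-332, -152) == 181.
    """
    if coord_a >= 0 or coord_b >= 0:
        raise ValueError("promoter coordinates are negative (upstream of ATG)")
    return abs(coord_a - coord_b) + 1
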