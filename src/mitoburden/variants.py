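"""Variant data model and the study's textual variant notations.

Substitutions are written ``G10398A`` (ref, 1-based position, alt) or
``10398 G>A``; single-base insertions are written ``Ins T at 2790`` and
denote material inserted immediately *after* the stated position.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from typing import Iterable

__all__ = [
    "Variant",
    "AnnotatedVariant",
    "PatientRecord",
    "ParseError",
    "parse_variant",
    "format_variant",
    "format_protein_change",
    "AA_ONE_TO_THREE",
    "AA_THREE_TO_ONE",
    "normalize_aa",
    "read_variant_tsv",
    "write_variant_tsv",
    "write_vcf",
]

SUBSTITUTION = "substitution"
INSERTION = "insertion"


class ParseError(ValueError):
    """A variant token that does not match any accepted notation."""


@dataclass(frozen=True, order=True)
class Variant:
    """A substitution or insertion at a 1-based circular genome position.

    For insertions ``ref`` is empty and ``alt`` is the sequence inserted
    immediately after ``position``.
    """

    position: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position must be >= 1")
        if self.ref:
            if len(self.ref) != 1 or len(self.alt) != 1:
                raise ValueError(f"substitution must be single-base: {self}")
            if self.ref == self.alt:
                raise ValueError(f"ref equals alt at {self.position}")
        elif not self.alt:
            raise ValueError("insertion must carry inserted sequence")

    @property
    def kind(self) -> str:
        return SUBSTITUTION if self.ref else INSERTION

    @property
    def key(self) -> tuple[int, str, str]:
        """Identity triple used for deduplication and catalogue lookup."""
        return (self.position, self.ref, self.alt)


_SUB_COMPACT = re.compile(r"^([ACGT])\s*(\d+)\s*([ACGT])$", re.I)
_SUB_ARROW = re.compile(r"^(?:m\.)?(\d+)\s*([ACGT])\s*>\s*([ACGT])$", re.I)
_INS = re.compile(r"^Ins\.?\s*(?:of\s+)?([ACGT]+)\s*(?:at\s*)?(\d+)(?:_\d+)?$", re.I)


def parse_variant(token: str) -> Variant:
    """Parse a variant token in any of the accepted notations.

    Accepts ``G10398A``, ``10398 G>A`` / ``10398G>A`` / ``m.10398G>A``
    and ``Ins T at 2790`` (case-insensitive).
    """
    tok = token.strip()
    if m := _SUB_COMPACT.match(tok):
        ref, pos, alt = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
        if ref == alt:
            raise ParseError(f"ref equals alt in {token!r}")
        return Variant(pos, ref, alt)
    if m := _SUB_ARROW.match(tok):
        pos, ref, alt = int(m.group(1)), m.group(2).upper(), m.group(3).upper()
        if ref == alt:
            raise ParseError(f"ref equals alt in {token!r}")
        return Variant(pos, ref, alt)
    if m := _INS.match(tok):
        return Variant(int(m.group(2)), "", m.group(1).upper())
    raise ParseError(f"unrecognized variant token {token!r}")


def format_variant(v: Variant) -> str:
    """Canonical text form; inverse of :func:`parse_variant`."""
    if v.kind == SUBSTITUTION:
        return f"{v.ref}{v.position}{v.alt}"
    return f"Ins {v.alt} at {v.position}"


AA_ONE_TO_THREE = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
    "*": "Ter", "X": "Xaa",
}
AA_THREE_TO_ONE = {three: one for one, three in AA_ONE_TO_THREE.items()}

# spelling variants seen in the packaged tables
_AA_ALIASES = {
    "Iso": "Ile", "IsoLeu": "Ile", "Isoleu": "Ile",
    "Ter": "Ter", "Stop": "Ter", "STOP": "Ter",
}


def normalize_aa(name: str) -> str:
    """Normalize an amino-acid name to its three-letter form.

    Handles one-letter codes, three-letter codes in any case, the
    spelling variants appearing in the packaged tables ("IsoLeu",
    "Iso"), and stray trailing punctuation.
    """
    tok = name.strip().strip(")").strip()
    if not tok:
        raise ValueError("empty amino-acid name")
    if len(tok) == 1 and tok.upper() in AA_ONE_TO_THREE:
        return AA_ONE_TO_THREE[tok.upper()]
    cap = tok[0].upper() + tok[1:].lower()
    if cap in _AA_ALIASES:
        return _AA_ALIASES[cap]
    if cap in AA_THREE_TO_ONE:
        return cap
    if tok in _AA_ALIASES:
        return _AA_ALIASES[tok]
    raise ValueError(f"unrecognized amino-acid name {name!r}")


def format_protein_change(ref_aa: str, codon_index: int, alt_aa: str) -> str:
    """``p.<ref><index><alt>`` in one-letter codes, e.g. ``p.A114T``.

    Stop codons are rendered as ``*``.
    """
    ref1 = AA_THREE_TO_ONE.get(normalize_aa(ref_aa), "*")
    alt1 = AA_THREE_TO_ONE.get(normalize_aa(alt_aa), "*")
    if ref1 == "*" or alt1 == "*":
        ref1 = "*" if normalize_aa(ref_aa) == "Ter" else ref1
        alt1 = "*" if normalize_aa(alt_aa) == "Ter" else alt1
    return f"p.{ref1}{codon_index}{alt1}"


EFFECT_SYN = "synonymous"
EFFECT_NONSYN = "non-synonymous"
EFFECT_RNA = "rna_gene"
EFFECT_NONCODING = "non_coding"
EFFECT_UNKNOWN = "unknown"  # codon effect not computable without sequence


@dataclass
class AnnotatedVariant:
    """A variant plus its gene-level and codon-level consequences."""

    variant: Variant
    gene: str | None
    complex: str | None
    effect: str
    codon_index: int | None = None
    ref_codon: str | None = None
    alt_codon: str | None = None
    ref_aa: str | None = None  # three-letter
    alt_aa: str | None = None
    protein_notation: str | None = None
    novel: bool | None = None
    frameshift: bool = False

    def __post_init__(self) -> None:
        if self.effect == EFFECT_SYN and self.ref_aa and self.alt_aa:
            if normalize_aa(self.ref_aa) != normalize_aa(self.alt_aa):
                raise ValueError(f"synonymous effect with differing amino acids: {self}")


@dataclass
class PatientRecord:
    """Per-subject variant list plus clinical fields carried verbatim."""

    patient_id: int
    variants: list[Variant] = field(default_factory=list)
    clinical: dict[str, str] = field(default_factory=dict)
    unresolved: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [v.key for v in self.variants]
        if len(keys) != len(set(keys)):
            raise ValueError(f"patient {self.patient_id}: duplicate variants")


def read_variant_tsv(path) -> dict[str, list[Variant]]:
    """Read a per-sample variant TSV (sample_id, position, ref, alt, kind)."""
    out: dict[str, list[Variant]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            v = Variant(int(row["position"]), row["ref"].strip(), row["alt"].strip())
            out.setdefault(row["sample_id"], []).append(v)
    return out


def write_variant_tsv(path, calls: dict[str, Iterable[Variant]]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sample_id", "position", "ref", "alt", "kind"])
        for sample, variants in calls.items():
            for v in sorted(variants):
                w.writerow([sample, v.position, v.ref, v.alt, v.kind])


def write_vcf(path, sample_id: str, variants: Iterable[Variant], genome, contig: str = "chrM") -> None:
    """Minimal single-sample VCF export (output only).

    Insertions need the anchor base, so the genome must carry sequence
    when any insertion is present.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig},length={genome.length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample_id}\n")
        for v in sorted(variants):
            if v.kind == SUBSTITUTION:
                pos, ref, alt = v.position, v.ref, v.alt
            else:
                anchor = genome.base(v.position)
                pos, ref, alt = v.position, anchor, anchor + v.alt
            fh.write(f"{contig}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t1\n")
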