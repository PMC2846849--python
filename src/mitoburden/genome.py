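"""Circular mitochondrial genome model.

Sequence-optional circular genome, strand-aware gene features, and the
vertebrate mitochondrial genetic code (translation table 2).  All
coordinates are 1-based inclusive and interpreted modulo the genome
length, matching the position numbering used on the human reference
mitogenome (NC_012920, 16 569 bp).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

__all__ = [
    "CircularGenome",
    "GeneFeature",
    "VERTEBRATE_MITO_CODE",
    "RCRS_LENGTH",
    "load_rcrs_features",
    "load_features_tsv",
    "read_fasta_genome",
    "feature_at",
    "codon_context",
    "translate",
    "reverse_complement",
]

DNA_ALPHABET = frozenset("ACGTN")
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Length of the revised Cambridge Reference Sequence (NC_012920).
RCRS_LENGTH = 16569

_BASES = "TCAG"


def _standard_code() -> dict[str, str]:
    aas = (
        "FFLLSSSSYY**CC*W"  # TTT..TGG
        "LLLLPPPPHHQQRRRR"
        "IIIMTTTTNNKKSSRR"
        "VVVVAAAADDEEGGGG"
    )
    return {
        a + b + c: aas[16 * i + 4 * j + k]
        for i, a in enumerate(_BASES)
        for j, b in enumerate(_BASES)
        for k, c in enumerate(_BASES)
    }


def _vertebrate_mito_code() -> dict[str, str]:
    code = _standard_code()
    # the four departures from the standard code
    code["TGA"] = "W"
    code["ATA"] = "M"
    code["AGA"] = "*"
    code["AGG"] = "*"
    return code


#: Codon -> one-letter amino acid ("*" = stop), vertebrate mitochondrial code.
VERTEBRATE_MITO_CODE: dict[str, str] = _vertebrate_mito_code()

assert len(VERTEBRATE_MITO_CODE) == 64
assert sum(1 for aa in VERTEBRATE_MITO_CODE.values() if aa != "*") == 60


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneFeature:
    """A strand-aware gene interval on a circular genome.

    ``start <= end`` except for a feature wrapping the origin, in which
    case the interval runs start..length then 1..end.  ``complex`` is an
    OXPHOS complex label (I/III/IV/V) for CDS features and "RNA" for
    tRNA/rRNA features.  ``incomplete_stop`` marks CDS whose final stop
    codon is completed post-transcriptionally; the trailing partial codon
    is excluded from codon arithmetic.
    """

    gene: str
    start: int
    end: int
    strand: str  # "H" | "L"
    kind: str  # "CDS" | "tRNA" | "rRNA"
    complex: str  # "I" | "III" | "IV" | "V" | "RNA"
    incomplete_stop: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("H", "L"):
            raise ValueError(f"strand must be H or L, got {self.strand!r}")
        if self.kind not in ("CDS", "tRNA", "rRNA"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if (self.kind != "CDS") != (self.complex == "RNA"):
            raise ValueError(
                f"{self.gene}: complex must be 'RNA' exactly for non-CDS features"
            )

    @property
    def wraps_origin(self) -> bool:
        return self.start > self.end

    def span(self, genome_length: int) -> int:
        """Number of bases covered, circularly."""
        if self.wraps_origin:
            return genome_length - self.start + 1 + self.end
        return self.end - self.start + 1

    def coding_span(self, genome_length: int) -> int:
        """Bases participating in complete codons (CDS only)."""
        n = self.span(genome_length)
        return n - n % 3 if self.incomplete_stop else n

    def contains(self, position: int, genome_length: int) -> bool:
        if self.wraps_origin:
            return position >= self.start or position <= self.end
        return self.start <= position <= self.end


@dataclass(frozen=True)
class CircularGenome:
    """A circular genome known at least by name and length.

    The sequence is optional: coordinate arithmetic (feature lookup,
    codon indexing) needs only the length, while codon extraction and
    translation require the sequence.
    """

    name: str
    length: int
    sequence: str | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("genome length must be positive")
        if self.sequence is not None:
            if len(self.sequence) != self.length:
                raise ValueError(
                    f"sequence length {len(self.sequence)} != declared length {self.length}"
                )
            bad = set(self.sequence) - DNA_ALPHABET
            if bad:
                raise ValueError(f"sequence contains non-ACGTN characters: {sorted(bad)}")

    def base(self, position: int) -> str:
        """Base at a 1-based circular position."""
        if self.sequence is None:
            raise ValueError(f"genome {self.name} has no sequence")
        return self.sequence[(position - 1) % self.length]

    def fetch(self, start: int, n: int) -> str:
        """``n`` bases starting at 1-based ``start``, wrapping the origin."""
        return "".join(self.base(start + i) for i in range(n))


def feature_at(features: Iterable[GeneFeature], position: int, genome_length: int) -> list[GeneFeature]:
    """All features whose circular interval contains ``position``.

    Overlap regions (e.g. ATPase8/ATPase6) return more than one feature;
    an intergenic position returns an empty list.
    """
    if not 1 <= position <= genome_length:
        raise ValueError(
            f"position {position} outside genome of length {genome_length}"
        )
    return [f for f in features if f.contains(position, genome_length)]


def codon_context(
    feature: GeneFeature, genome: CircularGenome, position: int
) -> tuple[int, int, str | None]:
    """Locate ``position`` within a CDS reading frame.

    Returns ``(codon_index, offset_in_codon, ref_codon)`` where
    codon_index is 1-based, offset is the 0/1/2 phase on the coding
    strand, and ref_codon is the coding-strand triplet (``None`` when
    the genome carries no sequence).  For L-strand features the frame is
    anchored at ``end`` and the codon is the reverse complement of the
    genomic triplet.
    """
    if feature.kind != "CDS":
        raise ValueError(f"{feature.gene} is {feature.kind}, not CDS")
    if not feature.contains(position, genome.length):
        raise ValueError(f"position {position} outside {feature.gene}")

    if feature.wraps_origin and position <= feature.end:
        # unwrap: express position on the linear extension past the origin
        position += genome.length

    if feature.strand == "H":
        idx0 = position - feature.start
    else:
        end = feature.end + (genome.length if feature.wraps_origin else 0)
        idx0 = end - position

    if idx0 >= feature.coding_span(genome.length):
        raise ValueError(
            f"position falls in the incomplete trailing codon of {feature.gene}"
        )

    codon_index = idx0 // 3 + 1
    offset = idx0 % 3

    ref_codon: str | None = None
    if genome.sequence is not None:
        if feature.strand == "H":
            codon_start = feature.start + 3 * (codon_index - 1)
            ref_codon = genome.fetch(codon_start, 3)
        else:
            end = feature.end + (genome.length if feature.wraps_origin else 0)
            codon_hi = end - 3 * (codon_index - 1)
            ref_codon = reverse_complement(genome.fetch(codon_hi - 2, 3))
    return codon_index, offset, ref_codon


def translate(codon: str, code: dict[str, str] = VERTEBRATE_MITO_CODE) -> str:
    """Amino acid (one-letter; ``*`` = stop, ``X`` = undetermined) for a codon."""
    codon = codon.upper()
    if len(codon) != 3 or set(codon) - DNA_ALPHABET:
        raise ValueError(f"not a codon: {codon!r}")
    if "N" in codon:
        return "X"
    return code[codon]


def load_features_tsv(path) -> list[GeneFeature]:
    """Read a gene feature table (TSV with the packaged column layout)."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        feats = [
            GeneFeature(
                gene=row["gene"],
                start=int(row["start"]),
                end=int(row["end"]),
                strand=row["strand"],
                kind=row["kind"],
                complex=row["complex"],
                incomplete_stop=row["incomplete_stop"] in ("1", "true", "True"),
            )
            for row in reader
        ]
    return feats


def load_rcrs_features() -> list[GeneFeature]:
    """The embedded 37-gene NC_012920 coding-region layout."""
    ref = resources.files("mitoburden.data") / "rcrs_features.tsv"
    with resources.as_file(ref) as path:
        return load_features_tsv(path)


def read_fasta_genome(path, name: str | None = None) -> CircularGenome:
    """Load a single-record FASTA as a CircularGenome."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected exactly one FASTA record, found {len(records)}")
    rec = records[0]
    seq = str(rec.seq).upper()
    return CircularGenome(name=name or rec.id, length=len(seq), sequence=seq)
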