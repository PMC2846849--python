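"""Synthetic genomes and cohorts with known planted truth.

Generates a small circular genome whose CDS features carry valid
reading frames under the vertebrate mitochondrial code (start codon, no
internal stop, stop or post-transcriptionally completed stop at the
end), then plants per-gene synonymous / non-synonymous substitutions
and RNA-gene insertions into case/control samples by independent
Bernoulli draws.  Every plant is verified at generation time and
recorded in a truth table, so downstream calling/annotation can be
checked exactly.

Reproducibility: one pseudo-random stream per sample, derived from the
master seed and the sample's index, so cohorts are byte-identical for a
given configuration regardless of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .calling import apply_variants
from .genome import (
    VERTEBRATE_MITO_CODE,
    CircularGenome,
    GeneFeature,
    reverse_complement,
    translate,
)
from .variants import EFFECT_NONSYN, EFFECT_RNA, EFFECT_SYN, Variant

__all__ = [
    "SimulationConfig",
    "GenePlan",
    "PlantedVariant",
    "mini_layout",
    "make_genome",
    "make_cohorts",
    "truth_gene_sets",
    "write_fasta",
]

_BASES = np.array(list("ACGT"))
_SENSE_CODONS = sorted(c for c, aa in VERTEBRATE_MITO_CODE.items() if aa != "*")
_STOP_CODONS = sorted(c for c, aa in VERTEBRATE_MITO_CODE.items() if aa == "*")
_START_CODONS = ("ATG", "ATA")


@dataclass(frozen=True)
class GenePlan:
    """Per-gene planting probabilities."""

    p_nonsyn: float = 0.0
    p_syn: float = 0.0
    p_insertion: float = 0.0  # RNA genes only

    def __post_init__(self) -> None:
        for p in (self.p_nonsyn, self.p_syn, self.p_insertion):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability outside [0,1]: {p}")


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to regenerate a synthetic study byte-for-byte."""

    seed: int
    genome_length: int = 2400
    features: tuple[GeneFeature, ...] | None = None  # None -> mini_layout
    n_cases: int = 12
    n_controls: int = 12
    gene_plans: Mapping[str, GenePlan] = field(default_factory=dict)

    def resolved_features(self) -> tuple[GeneFeature, ...]:
        if self.features is not None:
            return self.features
        return mini_layout(self.genome_length)


def mini_layout(genome_length: int = 2400) -> tuple[GeneFeature, ...]:
    """A small mitogenome-like layout: H- and L-strand CDS, a tRNA, an
    rRNA and an incomplete-stop CDS, with intergenic spacers."""
    if genome_length < 2000:
        raise ValueError("mini layout needs at least 2000 bp")
    feats = (
        GeneFeature("rrnS", 21, 320, "H", "rRNA", "RNA"),
        GeneFeature("NDA", 331, 930, "H", "CDS", "I"),
        GeneFeature("trnK", 941, 1010, "H", "tRNA", "RNA"),
        GeneFeature("COA", 1021, 1620, "L", "CDS", "IV"),
        GeneFeature("ATPA", 1631, 1930, "H", "CDS", "V"),
        GeneFeature("CYTB", 1941, 2240, "H", "CDS", "III", incomplete_stop=True),
    )
    if genome_length <= feats[-1].end:
        raise ValueError("genome too short for mini layout")
    return feats


def _coding_positions(feat: GeneFeature, genome_length: int) -> list[int]:
    """Genomic positions of the feature 5'->3' on its coding strand."""
    span = feat.span(genome_length)
    if feat.strand == "H":
        raw = [feat.start + i for i in range(span)]
    else:
        raw = [feat.end - i for i in range(span)]
    return [(p - 1) % genome_length + 1 for p in raw]


def make_genome(config: SimulationConfig) -> tuple[CircularGenome, tuple[GeneFeature, ...]]:
    """Random circular genome whose every CDS has a valid reading frame."""
    features = config.resolved_features()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0,)))
    seq = rng.choice(_BASES, size=config.genome_length).tolist()

    cds = [f for f in features if f.kind == "CDS"]
    covered: set[int] = set()
    for feat in cds:
        pos = set(_coding_positions(feat, config.genome_length))
        if pos & covered:
            raise ValueError(f"synthetic layouts must not overlap CDS ({feat.gene})")
        covered |= pos

    for feat in cds:
        span = feat.span(config.genome_length)
        n_coding = feat.coding_span(config.genome_length)
        if not feat.incomplete_stop and (span % 3 or span < 9):
            raise ValueError(f"{feat.gene}: CDS span {span} incompatible with framing")
        n_codons = n_coding // 3
        codons = [str(rng.choice(_START_CODONS))]
        body_end = n_codons if feat.incomplete_stop else n_codons - 1
        codons += [str(c) for c in rng.choice(_SENSE_CODONS, size=body_end - 1)]
        if not feat.incomplete_stop:
            codons.append(str(rng.choice(_STOP_CODONS)))
        coding = "".join(codons)
        if feat.incomplete_stop:  # trailing partial codon stays random
            coding += "".join(rng.choice(_BASES, size=span - n_coding))
        positions = _coding_positions(feat, config.genome_length)
        strand_seq = coding if feat.strand == "H" else coding  # coding-strand string
        for p, base in zip(positions, strand_seq):
            seq[p - 1] = base if feat.strand == "H" else {"A": "T", "T": "A", "C": "G", "G": "C"}[base]

    genome = CircularGenome("synthetic", config.genome_length, "".join(seq))
    _validate_frames(genome, features)
    return genome, features


def _cds_coding_sequence(genome: CircularGenome, feat: GeneFeature) -> str:
    s = "".join(genome.base(p) for p in range(feat.start, feat.start + feat.span(genome.length)))
    return s if feat.strand == "H" else reverse_complement(s)


def _validate_frames(genome: CircularGenome, features: Iterable[GeneFeature]) -> None:
    for feat in features:
        if feat.kind != "CDS":
            continue
        coding = _cds_coding_sequence(genome, feat)[: feat.coding_span(genome.length)]
        aas = [translate(coding[i : i + 3]) for i in range(0, len(coding), 3)]
        if coding[:3] not in _START_CODONS:
            raise ValueError(f"{feat.gene}: no start codon")
        internal = aas[:-1] if not feat.incomplete_stop else aas
        if "*" in internal:
            raise ValueError(f"{feat.gene}: internal stop codon")
        if not feat.incomplete_stop and aas[-1] != "*":
            raise ValueError(f"{feat.gene}: missing stop codon")


@dataclass(frozen=True)
class PlantedVariant:
    """Truth-table entry: what was planted, where, and why."""

    sample_id: str
    cohort: str  # "case" | "control"
    variant: Variant
    gene: str
    effect: str  # synonymous | non-synonymous | rna_gene


def _genomic_sub(feat: GeneFeature, genome: CircularGenome, codon_i: int, offset: int, alt_coding: str) -> Variant:
    """Convert a coding-strand change to a genomic substitution."""
    if feat.strand == "H":
        pos = feat.start + 3 * (codon_i - 1) + offset
        ref = genome.base(pos)
        alt = alt_coding
    else:
        pos = feat.end - 3 * (codon_i - 1) - offset
        ref = genome.base(pos)
        alt = reverse_complement(alt_coding)
    return Variant((pos - 1) % genome.length + 1, ref, alt)


def _plant_substitution(
    rng: np.random.Generator,
    genome: CircularGenome,
    feat: GeneFeature,
    want_nonsyn: bool,
    blocked: set[int],
) -> Variant | None:
    """Draw a single-base CDS change with the requested effect, avoiding
    blocked positions; verified against the genetic code at draw time."""
    n_codons = feat.coding_span(genome.length) // 3
    coding = _cds_coding_sequence(genome, feat)
    for _ in range(200):
        ci = int(rng.integers(2, n_codons))  # skip start and final codon
        codon = coding[3 * (ci - 1) : 3 * ci]
        off = int(rng.integers(0, 3))
        alts = [b for b in "ACGT" if b != codon[off]]
        alt_base = alts[int(rng.integers(0, 3))]
        new_codon = codon[:off] + alt_base + codon[off + 1 :]
        if translate(new_codon) == "*":
            continue
        changed = translate(new_codon) != translate(codon)
        if changed != want_nonsyn:
            continue
        v = _genomic_sub(feat, genome, ci, off, alt_base)
        if any(abs(v.position - q) < 2 for q in blocked):
            continue
        return v
    return None


def _plant_insertion(
    rng: np.random.Generator, feat: GeneFeature, genome: CircularGenome, blocked: set[int]
) -> Variant | None:
    for _ in range(50):
        pos = int(rng.integers(feat.start, feat.end))  # anchor inside the gene
        base = str(rng.choice(_BASES))
        # left-normalize through the homopolymer so calling recovers the
        # planted representation exactly
        while pos >= 1 and genome.base(pos) == base:
            pos -= 1
        if pos < 1 or any(abs(pos - q) < 2 for q in blocked):
            continue
        return Variant(pos, "", base)
    return None


def make_cohorts(
    genome: CircularGenome,
    features: Sequence[GeneFeature],
    config: SimulationConfig,
) -> tuple[dict[str, str], list[PlantedVariant]]:
    """Case/control sample sequences plus the planted truth table.

    Carrier draws are independent Bernoulli per gene per sample; planted
    variants within a sample are pairwise at least 2 bp apart so that
    alignment-based calling can recover them exactly.
    """
    if genome.sequence is None:
        raise ValueError("synthetic genome must carry sequence")
    by_gene = {f.gene: f for f in features}
    samples: dict[str, str] = {}
    truth: list[PlantedVariant] = []

    groups = [("case", config.n_cases), ("control", config.n_controls)]
    stream = 1
    for cohort, n in groups:
        for i in range(n):
            rng = np.random.default_rng(
                np.random.SeedSequence(config.seed, spawn_key=(stream, i))
            )
            sample_id = f"{cohort}{i + 1:03d}"
            planted: list[Variant] = []
            blocked: set[int] = set()
            for gene, plan in config.gene_plans.items():
                feat = by_gene[gene]
                wanted: list[tuple[str, float]] = [
                    (EFFECT_NONSYN, plan.p_nonsyn),
                    (EFFECT_SYN, plan.p_syn),
                    (EFFECT_RNA, plan.p_insertion),
                ]
                for effect, p in wanted:
                    if p == 0.0 or rng.random() >= p:
                        continue
                    if effect == EFFECT_RNA:
                        if feat.kind == "CDS":
                            raise ValueError(f"insertion plan on CDS gene {gene}")
                        v = _plant_insertion(rng, feat, genome, blocked)
                    else:
                        if feat.kind != "CDS":
                            raise ValueError(f"codon plan on non-CDS gene {gene}")
                        v = _plant_substitution(
                            rng, genome, feat, effect == EFFECT_NONSYN, blocked
                        )
                    if v is None:
                        raise RuntimeError(
                            f"could not place a {effect} variant in {gene}"
                        )
                    planted.append(v)
                    blocked.add(v.position)
            samples[sample_id] = apply_variants(genome.sequence, planted)
            truth.extend(
                PlantedVariant(sample_id, cohort, v, g, e)
                for v, g, e in _with_meta(planted, features, genome)
            )
        stream += 1
    return samples, truth


def _with_meta(planted, features, genome):
    by_pos = []
    for v in planted:
        gene, effect = None, EFFECT_RNA
        for f in features:
            if f.contains(v.position, genome.length):
                gene = f.gene
                if f.kind == "CDS" and v.kind == "substitution":
                    from .annotate import annotate

                    anns = [a for a in annotate(v, genome, list(features)) if a.gene == f.gene]
                    effect = anns[0].effect
                else:
                    effect = EFFECT_RNA
                break
        by_pos.append((v, gene, effect))
    return by_pos


def truth_gene_sets(
    truth: Iterable[PlantedVariant],
    sample_ids: Iterable[str],
    effect: str = EFFECT_NONSYN,
) -> tuple[dict[str, set[str]], dict[str, set[str]]]:
    """Per-sample qualifying-gene sets (cases, controls) from the truth
    table, ready for :func:`mitoburden.stats.carrier_table`.

    ``sample_ids`` must list every generated sample so that non-carriers
    appear with empty sets.
    """
    cases: dict[str, set[str]] = {}
    controls: dict[str, set[str]] = {}
    for sid in sample_ids:
        (cases if sid.startswith("case") else controls)[sid] = set()
    for rec in truth:
        target = cases if rec.cohort == "case" else controls
        if rec.effect == effect:
            target[rec.sample_id].add(rec.gene)
    return cases, controls


def write_fasta(path, records: Mapping[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
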