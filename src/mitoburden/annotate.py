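"""Codon-level variant annotation, novelty flagging and tallies.

Two classification pathways exist and are never mixed silently:

* sequence-based — recompute the codon from the reference sequence and
  translate both alleles (used for real/synthetic sequence input);
* record-based — compare the two amino-acid names printed in a variant
  record's change field (used to reproduce the packaged study tables,
  several of whose rows have codon columns inconsistent with their
  amino-acid columns).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .genome import (
    VERTEBRATE_MITO_CODE,
    CircularGenome,
    GeneFeature,
    codon_context,
    feature_at,
    reverse_complement,
    translate,
)
from .variants import (
    EFFECT_NONCODING,
    EFFECT_NONSYN,
    EFFECT_RNA,
    EFFECT_SYN,
    EFFECT_UNKNOWN,
    AA_ONE_TO_THREE,
    AnnotatedVariant,
    Variant,
    format_protein_change,
    normalize_aa,
)

__all__ = [
    "annotate",
    "effect_from_aa_pair",
    "flag_novelty",
    "tally",
    "reconcile",
    "complex_for_gene",
    "TallyReport",
    "ReconciliationReport",
    "RowComparison",
]


def complex_for_gene(gene: str) -> str:
    """OXPHOS complex from the gene symbol (ND*→I, CYB→III, CO*→IV,
    ATPase*→V, RNA genes→RNA)."""
    g = gene.upper().replace(" ", "").replace("-", "")
    if g.startswith("ND"):
        return "I"
    if g.startswith("CYB") or g.startswith("CYTB"):
        return "III"
    if g.startswith("COX") or g.startswith("CO"):
        return "IV"
    if g.startswith("ATP"):
        return "V"
    if "TRNA" in g or "RNA" in g or g in ("12S", "16S"):
        return "RNA"
    raise ValueError(f"cannot assign OXPHOS complex for gene {gene!r}")


def annotate(
    variant: Variant,
    genome: CircularGenome,
    features: Sequence[GeneFeature],
    code: Mapping[str, str] = VERTEBRATE_MITO_CODE,
    catalogue: set[tuple[int, str, str]] | None = None,
) -> list[AnnotatedVariant]:
    """One AnnotatedVariant per feature overlapping the variant.

    CDS substitutions get codon/amino-acid fields; tRNA/rRNA variants
    are classed ``rna_gene``; CDS insertions are gene-level only and
    flagged as frameshifts; variants outside every feature are classed
    ``non_coding``.
    """
    hits = feature_at(features, variant.position, genome.length)
    novel = None if catalogue is None else flag_novelty(variant, catalogue)
    if not hits:
        return [
            AnnotatedVariant(variant, None, None, EFFECT_NONCODING, novel=novel)
        ]

    out: list[AnnotatedVariant] = []
    for feat in hits:
        if feat.kind != "CDS":
            out.append(
                AnnotatedVariant(variant, feat.gene, feat.complex, EFFECT_RNA, novel=novel)
            )
            continue
        if variant.kind == "insertion":
            out.append(
                AnnotatedVariant(
                    variant, feat.gene, feat.complex, EFFECT_NONCODING,
                    novel=novel, frameshift=True,
                )
            )
            continue
        codon_index, offset, ref_codon = codon_context(feat, genome, variant.position)
        ann = AnnotatedVariant(
            variant, feat.gene, feat.complex, EFFECT_UNKNOWN,
            codon_index=codon_index, novel=novel,
        )
        if ref_codon is not None:
            if feat.strand == "H":
                alt_base = variant.alt
                exp_ref = ref_codon[offset]
            else:
                alt_base = reverse_complement(variant.alt)
                exp_ref = ref_codon[offset]
                if exp_ref != reverse_complement(variant.ref):
                    raise ValueError(
                        f"reference mismatch at {variant.position}: codon has "
                        f"{exp_ref}, variant ref {variant.ref}"
                    )
            if feat.strand == "H" and exp_ref != variant.ref:
                raise ValueError(
                    f"reference mismatch at {variant.position}: codon has "
                    f"{exp_ref}, variant ref {variant.ref}"
                )
            alt_codon = ref_codon[:offset] + alt_base + ref_codon[offset + 1:]
            ref_aa1 = translate(ref_codon, dict(code))
            alt_aa1 = translate(alt_codon, dict(code))
            ann.ref_codon = ref_codon
            ann.alt_codon = alt_codon
            ann.ref_aa = AA_ONE_TO_THREE[ref_aa1]
            ann.alt_aa = AA_ONE_TO_THREE[alt_aa1]
            ann.effect = EFFECT_SYN if ref_aa1 == alt_aa1 else EFFECT_NONSYN
            ann.protein_notation = format_protein_change(
                ann.ref_aa, codon_index, ann.alt_aa
            )
        out.append(ann)
    return out


def effect_from_aa_pair(ref_aa: str, alt_aa: str) -> str:
    """Classify a record's printed amino-acid change: synonymous iff the
    two normalized names are equal."""
    return EFFECT_SYN if normalize_aa(ref_aa) == normalize_aa(alt_aa) else EFFECT_NONSYN


def flag_novelty(variant: Variant, catalogue: set[tuple[int, str, str]]) -> bool:
    """True iff the identity triple is absent from the known catalogue."""
    return variant.key not in catalogue


@dataclass
class TallyReport:
    """Distribution of annotated variants over effects and complexes."""

    total_variants: int = 0
    by_effect: Counter = field(default_factory=Counter)
    by_complex: Counter = field(default_factory=Counter)
    novel_count: int = 0
    novel_nonsyn_count: int = 0

    def validate(self) -> None:
        if sum(self.by_effect.values()) != self.total_variants:
            raise ValueError("effect counts do not sum to total")
        if sum(self.by_complex.values()) != self.total_variants:
            raise ValueError("complex counts do not sum to total")
        if not (self.novel_nonsyn_count <= self.novel_count <= self.total_variants):
            raise ValueError("novelty counts inconsistent")


def tally(annotated: Iterable[AnnotatedVariant]) -> TallyReport:
    """Count effects, OXPHOS complexes and novelty over annotations."""
    rep = TallyReport()
    for ann in annotated:
        rep.total_variants += 1
        rep.by_effect[ann.effect] += 1
        cx = ann.complex if ann.complex else (
            complex_for_gene(ann.gene) if ann.gene else "none"
        )
        rep.by_complex[cx] += 1
        if ann.novel:
            rep.novel_count += 1
            if ann.effect == EFFECT_NONSYN:
                rep.novel_nonsyn_count += 1
    rep.validate()
    return rep


@dataclass
class RowComparison:
    variant: Variant
    columns: dict[str, tuple[str, str, bool]]  # name -> (recorded, computed, match)

    @property
    def mismatched(self) -> list[str]:
        return [c for c, (_, _, ok) in self.columns.items() if not ok]


@dataclass
class ReconciliationReport:
    rows: list[RowComparison]

    @property
    def mismatches(self) -> list[RowComparison]:
        return [r for r in self.rows if r.mismatched]

    def summary(self) -> str:
        lines = [f"{len(self.rows)} rows compared, {len(self.mismatches)} with mismatches"]
        for r in self.mismatches:
            cols = ", ".join(
                f"{c}: recorded {rec!r} vs computed {comp!r}"
                for c, (rec, comp, _) in r.columns.items()
                if c in r.mismatched
            )
            lines.append(f"  {r.variant.position} {r.variant.ref}>{r.variant.alt}: {cols}")
        return "\n".join(lines)


def reconcile(fixture_rows, computed: Mapping[tuple[int, str, str], AnnotatedVariant]) -> ReconciliationReport:
    """Column-by-column comparison of recorded vs computed annotation.

    Mismatches are reported, never raised: the packaged tables contain
    internally inconsistent rows that must surface, not crash.
    """
    rows = []
    for rec in fixture_rows:
        key = rec.variant.key
        comp = computed.get(key)
        cols: dict[str, tuple[str, str, bool]] = {}

        def cmp(name: str, recorded, computed_val) -> None:
            a = "" if recorded is None else str(recorded)
            b = "" if computed_val is None else str(computed_val)
            comparable = a and b and EFFECT_UNKNOWN not in (a, b)
            cols[name] = (a, b, a == b or not comparable)

        if comp is not None:
            cmp("gene", rec.gene, comp.gene)
            cmp("codon_index", rec.aa_position, comp.codon_index)
            cmp("ref_codon", rec.ref_codon, comp.ref_codon)
            cmp("alt_codon", rec.alt_codon, comp.alt_codon)
            cmp("ref_aa", rec.ref_aa and normalize_aa(rec.ref_aa), comp.ref_aa)
            cmp("alt_aa", rec.alt_aa and normalize_aa(rec.alt_aa), comp.alt_aa)
            cmp("effect", rec.effect, comp.effect)
        else:
            cols["gene"] = (str(rec.gene), "", False)
        # internal consistency of the record itself: codon column vs aa column
        if rec.ref_codon and rec.ref_aa and rec.alt_codon and rec.alt_aa:
            from .variants import AA_THREE_TO_ONE

            t_ref = translate(rec.ref_codon)
            t_alt = translate(rec.alt_codon)
            ok = (
                t_ref == AA_THREE_TO_ONE[normalize_aa(rec.ref_aa)]
                and t_alt == AA_THREE_TO_ONE[normalize_aa(rec.alt_aa)]
            )
            cols["codon_vs_aa"] = (
                f"{rec.ref_codon}>{rec.alt_codon}",
                f"{rec.ref_aa}>{rec.alt_aa}",
                ok,
            )
        rows.append(RowComparison(rec.variant, cols))
    return ReconciliationReport(rows)
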