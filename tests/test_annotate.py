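"""Annotation effects, novelty, tallies and table reconciliation."""

import random

import pytest

from mitoburden.annotate import (
    annotate,
    complex_for_gene,
    effect_from_aa_pair,
    flag_novelty,
    reconcile,
    tally,
)
from mitoburden.fixtures import load_fixture
from mitoburden.genome import reverse_complement, translate
from mitoburden.simulate import _cds_coding_sequence
from mitoburden.variants import (
    EFFECT_NONSYN,
    EFFECT_RNA,
    EFFECT_SYN,
    AA_THREE_TO_ONE,
    Variant,
    normalize_aa,
)


class TestComplexMapping:
    @pytest.mark.parametrize(
        "gene,cx",
        [("ND1", "I"), ("ND4L", "I"), ("CYB", "III"), ("CO1", "IV"),
         ("CO3", "IV"), ("ATPase6", "V"), ("ATPase8", "V"),
         ("tRNA-Leu", "RNA"), ("16S", "RNA")],
    )
    def test_prefix_mapping(self, gene, cx):
        assert complex_for_gene(gene) == cx

    def test_unknown_gene_rejected(self):
        with pytest.raises(ValueError):
            complex_for_gene("FOO1")


class TestAnnotateCoordinatesOnly:
    def test_10398_maps_to_nd3_codon_114(self, rcrs_coords, rcrs_features):
        anns = annotate(Variant(10398, "G", "A"), rcrs_coords, rcrs_features)
        assert len(anns) == 1
        ann = anns[0]
        assert (ann.gene, ann.complex, ann.codon_index) == ("ND3", "I", 114)

    def test_12308_is_rna_gene_without_protein_fields(self, rcrs_coords, rcrs_features):
        anns = annotate(Variant(12308, "A", "G"), rcrs_coords, rcrs_features)
        ann = anns[0]
        assert ann.effect == EFFECT_RNA
        assert ann.gene.startswith("tRNA-Leu")
        assert ann.protein_notation is None and ann.codon_index is None

    def test_overlap_yields_one_row_per_feature(self, rcrs_coords, rcrs_features):
        anns = annotate(Variant(8550, "A", "G"), rcrs_coords, rcrs_features)
        genes = {a.gene: a.codon_index for a in anns}
        assert set(genes) == {"ATPase8", "ATPase6"}
        # frames differ across the overlapping genes
        assert genes["ATPase8"] != genes["ATPase6"]

    def test_unfeatured_position_is_non_coding(self, rcrs_coords, rcrs_features):
        anns = annotate(Variant(16100, "T", "C"), rcrs_coords, rcrs_features)
        assert anns[0].effect == "non_coding" and anns[0].gene is None

    def test_rna_insertion_annotated_gene_level(self, rcrs_coords, rcrs_features):
        anns = annotate(Variant(2790, "", "T"), rcrs_coords, rcrs_features)
        assert anns[0].effect == EFFECT_RNA
        assert anns[0].gene == "16S"


class TestAnnotateWithSequence:
    def test_effect_matches_whole_protein_oracle(self, sim_genome):
        """Oracle: translate the entire CDS before and after the mutation."""
        genome, features = sim_genome
        rng = random.Random(13)
        cds_feats = [f for f in features if f.kind == "CDS"]
        for feat in cds_feats:
            coding = _cds_coding_sequence(genome, feat)[: feat.coding_span(genome.length)]
            protein = [translate(coding[i : i + 3]) for i in range(0, len(coding), 3)]
            for _ in range(60):
                if feat.strand == "H":
                    pos = rng.randrange(feat.start, feat.start + len(coding))
                else:
                    pos = rng.randrange(feat.end - len(coding) + 1, feat.end + 1)
                ref = genome.base(pos)
                alt = rng.choice([b for b in "ACGT" if b != ref])
                v = Variant(pos, ref, alt)
                anns = [a for a in annotate(v, genome, list(features)) if a.gene == feat.gene]
                assert len(anns) == 1
                mutated = genome.sequence[: pos - 1] + alt + genome.sequence[pos:]
                if feat.strand == "H":
                    mut_coding = mutated[feat.start - 1 : feat.start - 1 + len(coding)]
                else:
                    mut_coding = reverse_complement(
                        mutated[feat.end - len(coding) : feat.end]
                    )
                mut_protein = [
                    translate(mut_coding[i : i + 3]) for i in range(0, len(mut_coding), 3)
                ]
                oracle = EFFECT_SYN if mut_protein == protein else EFFECT_NONSYN
                assert anns[0].effect == oracle, (feat.gene, v)

    def test_protein_notation_from_codon_fields(self, sim_genome):
        genome, features = sim_genome
        feat = next(f for f in features if f.kind == "CDS" and f.strand == "H")
        pos = feat.start  # first codon, offset 0
        ref = genome.base(pos)
        alt = [b for b in "ACGT" if b != ref][0]
        ann = [a for a in annotate(Variant(pos, ref, alt), genome, list(features))
               if a.gene == feat.gene][0]
        assert ann.protein_notation is not None
        assert ann.protein_notation.startswith("p.")
        assert str(ann.codon_index) in ann.protein_notation

    def test_ref_mismatch_detected(self, sim_genome):
        genome, features = sim_genome
        feat = next(f for f in features if f.kind == "CDS" and f.strand == "H")
        pos = feat.start + 5
        wrong_ref = [b for b in "ACGT" if b != genome.base(pos)][0]
        alt = [b for b in "ACGT" if b not in (wrong_ref, genome.base(pos))][0]
        with pytest.raises(ValueError, match="mismatch"):
            annotate(Variant(pos, wrong_ref, alt), genome, list(features))


class TestEffectFromAaPair:
    @pytest.mark.parametrize(
        "ref,alt,effect",
        [("Ala", "Thr", EFFECT_NONSYN), ("Lys", "Lys", EFFECT_SYN),
         ("Trp", "Trp", EFFECT_SYN), ("IsoLeu", "Thr", EFFECT_NONSYN),
         ("Met", "Iso", EFFECT_NONSYN), ("Iso", "Ile", EFFECT_SYN)],
    )
    def test_pairs(self, ref, alt, effect):
        assert effect_from_aa_pair(ref, alt) == effect

    def test_unrecognized_name_reported(self):
        with pytest.raises(ValueError, match="Qux"):
            effect_from_aa_pair("Ala", "Qux")


class TestNovelty:
    def test_absent_from_catalogue_is_novel(self):
        cat = {(100, "A", "G")}
        assert flag_novelty(Variant(100, "A", "C"), cat) is True
        assert flag_novelty(Variant(100, "A", "G"), cat) is False

    def test_empty_catalogue_everything_novel(self):
        assert flag_novelty(Variant(1, "A", "G"), set()) is True


class TestTally:
    def test_empty_list_all_zero(self):
        rep = tally([])
        assert rep.total_variants == 0
        assert rep.novel_count == 0 and not rep.by_effect

    def test_fixture_pcg_tally(self):
        rows = load_fixture("pcg")
        effects = [r.effect for r in rows]
        complexes = [r.complex for r in rows]
        assert len(rows) == 132
        assert effects.count(EFFECT_NONSYN) == 42
        assert effects.count(EFFECT_SYN) == 82
        assert effects.count(EFFECT_RNA) == 8
        assert complexes.count("I") == 66
        assert complexes.count("III") == 12
        assert complexes.count("IV") == 26
        assert complexes.count("V") == 20
        novel = [r for r in rows if r.novel]
        assert len(novel) == 31
        assert sum(1 for r in novel if r.effect == EFFECT_NONSYN) == 13

    def test_fixture_control_tally(self):
        rows = load_fixture("control")
        assert len(rows) == 58
        assert sum(1 for r in rows if r.effect == EFFECT_NONSYN) == 14

    def test_permutation_invariance_and_additivity(self, rcrs_coords, rcrs_features):
        rows = load_fixture("pcg")
        anns = []
        for r in rows:
            a = annotate(r.variant, rcrs_coords, rcrs_features)[0]
            a.effect = r.effect  # record-based pathway
            a.novel = r.novel
            anns.append(a)
        rep = tally(anns)
        rng = random.Random(3)
        shuffled = anns[:]
        rng.shuffle(shuffled)
        rep2 = tally(shuffled)
        assert rep.by_complex == rep2.by_complex and rep.by_effect == rep2.by_effect
        left, right = tally(anns[:50]), tally(anns[50:])
        assert left.total_variants + right.total_variants == rep.total_variants
        assert left.by_complex + right.by_complex == rep.by_complex


@pytest.fixture(scope="module")
def report(rcrs_coords, rcrs_features):
    rows = load_fixture("pcg")
    computed = {}
    for r in rows:
        anns = annotate(r.variant, rcrs_coords, rcrs_features)
        computed[r.variant.key] = next(
            (a for a in anns if a.gene == r.gene), anns[0]
        )
    return rows, reconcile(rows, computed)


class TestReconcile:
    def test_every_row_appears_once(self, report):
        rows, rec = report
        assert len(rec.rows) == len(rows) == 132

    def test_consistent_row_10398_matches(self, report):
        rows, rec = report
        row = next(r for r in rec.rows if r.variant == Variant(10398, "G", "A"))
        assert row.mismatched == []

    def test_inconsistent_codon_vs_aa_flagged_not_raised(self, report):
        # printed codon change CCT>CCA cannot yield the printed Leu>Pro
        rows, rec = report
        row = next(r for r in rec.rows if r.variant == Variant(14000, "T", "A"))
        assert "codon_vs_aa" in row.mismatched

    def test_self_consistent_input_zero_mismatches(self, sim_genome):
        genome, features = sim_genome
        feat = next(f for f in features if f.kind == "CDS" and f.strand == "H")
        recs = []
        computed = {}
        for pos in range(feat.start, feat.start + 30):
            ref = genome.base(pos)
            alt = [b for b in "ACGT" if b != ref][0]
            v = Variant(pos, ref, alt)
            ann = [a for a in annotate(v, genome, list(features)) if a.gene == feat.gene][0]
            computed[v.key] = ann

            class Rec:  # engine-generated fixture row
                variant = v
                gene = ann.gene
                aa_position = ann.codon_index
                ref_codon = ann.ref_codon
                alt_codon = ann.alt_codon
                ref_aa = ann.ref_aa
                alt_aa = ann.alt_aa
                effect = ann.effect

            recs.append(Rec())
        rec_report = reconcile(recs, computed)
        assert rec_report.mismatches == []
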