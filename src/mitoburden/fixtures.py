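"""Loaders for the packaged study-table transcriptions.

The four TSV fixtures are verbatim transcriptions of the printed
case/control variant tables, the per-patient variant matrix and the
per-gene carrier counts — including the originals' typography quirks
(stray dots, "IsoLeu", "SerSer", a letter O for a zero, "At 15928").
The loaders normalize those quirks but never silently repair rows whose
columns contradict each other; reconciliation reports those instead.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from importlib import resources

from .annotate import complex_for_gene, effect_from_aa_pair
from .variants import (
    EFFECT_RNA,
    ParseError,
    PatientRecord,
    Variant,
)

__all__ = [
    "FixtureRow",
    "CarrierRow",
    "FixtureError",
    "load_fixture",
    "default_catalogue",
    "COHORT_SIZES",
]

logger = logging.getLogger(__name__)

#: study cohort sizes (cases, controls)
COHORT_SIZES = (35, 40)

_EXPECTED_ROWS = {
    "pcg": 132,
    "control": 58,
    "patients": 35,
    "carrier_counts": 13,
}

_FILES = {
    "pcg": "pcg_variants.tsv",
    "control": "control_variants.tsv",
    "patients": "patient_variants.tsv",
    "carrier_counts": "gene_carrier_counts.tsv",
}

# accepted aliases for the four fixtures
_ALIASES = {
    "table1": "pcg",
    "table2": "control",
    "table3": "patients",
    "table4_counts": "carrier_counts",
}


class FixtureError(RuntimeError):
    """A packaged fixture failed its integrity checks."""


_GENE_NORMALIZATION = {
    "16sRNA": "16S",
    "12sRNA": "12S",
    "tRNALys": "tRNA-Lys",
    "tRNAArg": "tRNA-Arg",
    "tRNALeu": "tRNA-Leu",
    "tRNAThr": "tRNA-Thr",
    "ATP6": "ATPase6",
    "ATP8": "ATPase8",
}


def normalize_gene(raw: str) -> str:
    g = raw.replace("*", "").strip()
    g = re.sub(r"\s+", "", g)
    return _GENE_NORMALIZATION.get(g, g)


_MISSING = {"-", "–", "—", ""}


def _clean(cell: str) -> str | None:
    cell = cell.strip()
    return None if cell in _MISSING else cell


def _parse_position(raw: str) -> int:
    # "At 15928" prefix quirk on two rows
    return int(re.sub(r"(?i)^at\s+", "", raw.strip()))


def _parse_aa_position(raw: str | None) -> int | None:
    if raw is None:
        return None
    # letter O printed for zero in one row ("4O")
    return int(raw.replace("O", "0"))


def _split_aa_change(raw: str | None) -> tuple[str | None, str | None]:
    if raw is None:
        return None, None
    if ">" in raw:
        ref, alt = raw.split(">", 1)
        return ref.strip(), alt.strip().rstrip(")")
    # "SerSer" quirk: a doubled three-letter name with the separator lost
    if len(raw) == 6 and raw[:3].lower() == raw[3:].lower():
        return raw[:3], raw[3:]
    raise FixtureError(f"cannot split amino-acid change {raw!r}")


def _split_codon_change(raw: str | None) -> tuple[str | None, str | None]:
    if raw is None:
        return None, None
    ref, alt = raw.split(">", 1)
    return ref.strip(), alt.strip().rstrip(")")


@dataclass
class FixtureRow:
    """One transcribed variant-table row, verbatim fields plus parsed views."""

    row_id: int
    variant: Variant
    gene_raw: str
    gene: str
    aa_position: int | None
    ref_codon: str | None
    alt_codon: str | None
    ref_aa: str | None
    alt_aa: str | None
    protein_change: str | None
    syn_label: str | None
    accession: str | None
    carrier_count: int | None = None

    @property
    def novel(self) -> bool:
        """Novelty in fixture mode = the row carries a GenBank accession."""
        return self.accession is not None

    @property
    def complex(self) -> str:
        return complex_for_gene(self.gene)

    @property
    def effect(self) -> str:
        """Record-based effect: compare the two printed amino-acid names;
        RNA-gene rows (no amino-acid field) are ``rna_gene``."""
        if self.ref_aa is None or self.alt_aa is None:
            return EFFECT_RNA
        return effect_from_aa_pair(self.ref_aa, self.alt_aa)


def _fixture_path(key: str):
    return resources.files("mitoburden.data") / _FILES[key]


def _parse_variant_row(row: dict, row_id: int) -> Variant:
    pos = _parse_position(row["position"])
    change = row["base_change"].strip()
    if change.lower().startswith("ins"):
        seq = change.split(None, 1)[1].strip()
        return Variant(pos, "", seq)
    m = re.match(r"^([ACGT])\s*>\s*([ACGT])$", change)
    if not m:
        raise ParseError(f"row {row_id}: bad base change {change!r}")
    return Variant(pos, m.group(1), m.group(2))


def _load_variant_table(key: str) -> list[FixtureRow]:
    rows: list[FixtureRow] = []
    with resources.as_file(_fixture_path(key)) as path, open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            row_id = int(row["row"].rstrip("."))  # "108." quirk
            variant = _parse_variant_row(row, row_id)
            ref_codon, alt_codon = _split_codon_change(_clean(row["codon_change"]))
            ref_aa, alt_aa = _split_aa_change(_clean(row["aa_change"]))
            carriers = row.get("carrier_count")
            rows.append(
                FixtureRow(
                    row_id=row_id,
                    variant=variant,
                    gene_raw=row["gene"],
                    gene=normalize_gene(row["gene"]),
                    aa_position=_parse_aa_position(_clean(row["aa_position"])),
                    ref_codon=ref_codon,
                    alt_codon=alt_codon,
                    ref_aa=ref_aa,
                    alt_aa=alt_aa,
                    protein_change=_clean(row["protein_change"]),
                    syn_label=_clean(row["syn_nonsyn"]),
                    accession=_clean(row["accession"]),
                    carrier_count=int(carriers) if carriers is not None else None,
                )
            )
    return rows


@dataclass
class CarrierRow:
    """A per-gene carrier-count row with the printed statistics kept as text."""

    gene: str
    case_carriers: int
    control_carriers: int
    printed_p: str
    printed_rr_ci: str
    table: "TwoByTwo" = field(init=False)

    def __post_init__(self) -> None:
        from .stats import TwoByTwo

        n_cases, n_controls = COHORT_SIZES
        self.table = TwoByTwo(
            self.case_carriers,
            self.control_carriers,
            n_cases - self.case_carriers,
            n_controls - self.control_carriers,
        )


_COUNT_PCT = re.compile(r"^(\d+)\s*(?:\([\d.]+%?\))?$")


def _parse_count(cell: str) -> int:
    m = _COUNT_PCT.match(cell.strip())
    if not m:
        raise FixtureError(f"cannot parse carrier count {cell!r}")
    return int(m.group(1))


def _load_carrier_counts() -> list[CarrierRow]:
    rows = []
    with resources.as_file(_fixture_path("carrier_counts")) as path, open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            rows.append(
                CarrierRow(
                    gene=normalize_gene(row["gene"]),
                    case_carriers=_parse_count(row["cases"]),
                    control_carriers=_parse_count(row["controls"]),
                    printed_p=row["p_value"].strip(),
                    printed_rr_ci=row["rr_ci"].strip(),
                )
            )
    return rows


_OTHER_SUB = re.compile(r"([ACGT])\s*>\s*([ACGT])\s*at\s*(\d+)", re.I)
_OTHER_INS = re.compile(r"Ins\.?\s*(?:of\s+)?([ACGT]+)\s*at\s*(\d+)", re.I)
_GENE_COLUMNS = (
    "ND1", "ND2", "CO1", "CO2", "ATPase8", "ATPase6",
    "CO3", "ND3", "ND4L", "ND4", "ND5", "CYB",
)


def _normalize_protein_token(tok: str) -> str:
    return re.sub(r"\s+", "", tok.replace("p.", "").strip())


def _load_patients() -> list[PatientRecord]:
    pcg_index: dict[tuple[str, str], Variant] = {}
    for r in _load_variant_table("pcg"):
        if r.protein_change is not None:
            pcg_index[(r.gene, _normalize_protein_token(r.protein_change))] = r.variant

    patients: list[PatientRecord] = []
    with resources.as_file(_fixture_path("patients")) as path, open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            pid = int(row["patient"])
            variants: dict[tuple[int, str, str], Variant] = {}
            unresolved: list[str] = []
            for gene in _GENE_COLUMNS:
                cell = _clean(row[gene])
                if cell is None:
                    continue
                for tok in cell.split(";"):
                    tok = tok.strip()
                    if tok in _MISSING or not tok:
                        continue
                    v = pcg_index.get((gene, _normalize_protein_token(tok)))
                    if v is None:
                        unresolved.append(f"{gene}:{tok}")
                    elif v.key in variants:
                        logger.info("patient %d: duplicate %s ignored", pid, tok)
                    else:
                        variants[v.key] = v
            other = _clean(row["other_changes"])
            if other is not None:
                for m in _OTHER_SUB.finditer(other):
                    v = Variant(int(m.group(3)), m.group(1).upper(), m.group(2).upper())
                    variants.setdefault(v.key, v)
                for m in _OTHER_INS.finditer(other):
                    v = Variant(int(m.group(2)), "", m.group(1).upper())
                    variants.setdefault(v.key, v)
            patients.append(
                PatientRecord(
                    patient_id=pid,
                    variants=list(variants.values()),
                    clinical={
                        "cup_disc_ratio": row["cup_disc_ratio"].strip(),
                        "corneal_diameter_mm": row["corneal_diameter_mm"].strip(),
                        "iop_mmhg": row["iop_mmhg"].strip(),
                    },
                    unresolved=unresolved,
                )
            )
    return patients


def load_fixture(name: str):
    """Load a packaged fixture by name.

    Accepted names: ``pcg`` / ``control`` (variant tables), ``patients``
    (per-patient matrix), ``carrier_counts`` (per-gene 2x2 counts), plus
    the aliases ``table1``–``table4_counts``.  Row counts are validated
    against the published totals; a mismatch raises :class:`FixtureError`.
    """
    key = _ALIASES.get(name, name)
    if key not in _EXPECTED_ROWS:
        raise KeyError(f"unknown fixture {name!r}")
    if key in ("pcg", "control"):
        rows = _load_variant_table(key)
    elif key == "patients":
        rows = _load_patients()
    else:
        rows = _load_carrier_counts()
    if len(rows) != _EXPECTED_ROWS[key]:
        raise FixtureError(
            f"fixture {key}: expected {_EXPECTED_ROWS[key]} rows, found {len(rows)}"
        )
    return rows


def default_catalogue() -> set[tuple[int, str, str]]:
    """The shipped known-variant catalogue: exactly the non-novel fixture
    variants (rows without a GenBank accession) from both cohort tables."""
    cat: set[tuple[int, str, str]] = set()
    for key in ("pcg", "control"):
        for r in load_fixture(key):
            if not r.novel:
                cat.add(r.variant.key)
    return cat
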