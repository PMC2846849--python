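"""Threshold-based pathogenicity calls and special-variant screens.

Scores are always external inputs (SIFT-style tolerance probabilities
and PolyPhen-style PSIC/PHAT score differences); only the published
thresholds are applied here.  Two fixed screens flag variants linked to
elevated reactive-oxygen-species production and the three primary LHON
mutations.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .variants import PatientRecord, Variant, parse_variant

__all__ = [
    "PathogenicityScores",
    "PathogenicityCall",
    "classify_scores",
    "screen_special_sets",
    "patient_risk_summary",
    "read_scores_tsv",
    "ROS_ASSOCIATED",
    "LHON_PRIMARY",
]

SIFT_DELETERIOUS_BELOW = 0.05
POLYPHEN_PROBABLY_ABOVE = 2.0
POLYPHEN_POSSIBLY_FROM = 1.5

#: variants associated with elevated ROS production
ROS_ASSOCIATED = frozenset(
    parse_variant(t).key for t in ("G10398A", "A12308G", "G13708A")
)
#: the three primary LHON mutations
LHON_PRIMARY = frozenset(
    parse_variant(t).key for t in ("G3460A", "G11778A", "T14484C")
)


@dataclass(frozen=True)
class PathogenicityScores:
    variant: Variant
    sift_score: float | None = None
    polyphen_score: float | None = None

    def __post_init__(self) -> None:
        if self.sift_score is None and self.polyphen_score is None:
            raise ValueError("at least one score must be present")
        if self.sift_score is not None and not 0.0 <= self.sift_score <= 1.0:
            raise ValueError(f"SIFT score outside [0,1]: {self.sift_score}")
        if self.polyphen_score is not None and self.polyphen_score < 0.0:
            raise ValueError(f"negative PolyPhen score: {self.polyphen_score}")


@dataclass(frozen=True)
class PathogenicityCall:
    sift_call: str  # deleterious | tolerated | absent
    polyphen_call: str  # probably_damaging | possibly_damaging | benign | absent
    combined: str  # pathogenic | not_pathogenic


def classify_scores(s: PathogenicityScores) -> PathogenicityCall:
    """Apply the published thresholds.

    SIFT < 0.05 is deleterious (exactly 0.05 is tolerated); PolyPhen
    > 2.0 probably damaging, 1.5–2.0 inclusive possibly damaging,
    < 1.5 benign.  The combined call is pathogenic iff SIFT says
    deleterious and PolyPhen says at least possibly damaging.
    """
    if s.sift_score is None:
        sift = "absent"
    else:
        sift = "deleterious" if s.sift_score < SIFT_DELETERIOUS_BELOW else "tolerated"

    if s.polyphen_score is None:
        poly = "absent"
    elif s.polyphen_score > POLYPHEN_PROBABLY_ABOVE:
        poly = "probably_damaging"
    elif s.polyphen_score >= POLYPHEN_POSSIBLY_FROM:
        poly = "possibly_damaging"
    else:
        poly = "benign"

    pathogenic = sift == "deleterious" and poly in ("probably_damaging", "possibly_damaging")
    return PathogenicityCall(sift, poly, "pathogenic" if pathogenic else "not_pathogenic")


def screen_special_sets(variants: Iterable[Variant]) -> dict[tuple[int, str, str], dict[str, bool]]:
    """Flag each variant for ROS association and primary-LHON identity.

    Depends only on the identity triple, never on annotation.
    """
    return {
        v.key: {
            "ros_associated": v.key in ROS_ASSOCIATED,
            "lhon_primary": v.key in LHON_PRIMARY,
        }
        for v in variants
    }


@dataclass
class RiskSummary:
    per_patient: dict[int, dict[str, bool]]
    n_pathogenic: int
    n_ros: int
    n_lhon: int
    pct_pathogenic: float
    pct_ros: float
    pct_lhon: float


def patient_risk_summary(
    cohort: Sequence[PatientRecord],
    pathogenic_keys: set[tuple[int, str, str]] | None = None,
) -> RiskSummary:
    """Per-patient any-pathogenic/any-ROS/any-LHON booleans and cohort
    counts with percentages (display rounding is left to callers)."""
    pathogenic_keys = pathogenic_keys or set()
    per_patient: dict[int, dict[str, bool]] = {}
    for pat in cohort:
        keys = {v.key for v in pat.variants}
        per_patient[pat.patient_id] = {
            "pathogenic": bool(keys & pathogenic_keys),
            "ros": bool(keys & ROS_ASSOCIATED),
            "lhon": bool(keys & LHON_PRIMARY),
        }
    n = len(per_patient)

    def count(flag: str) -> int:
        return sum(1 for f in per_patient.values() if f[flag])

    np_, nr, nl = count("pathogenic"), count("ros"), count("lhon")
    pct = lambda k: 100.0 * k / n if n else 0.0
    return RiskSummary(per_patient, np_, nr, nl, pct(np_), pct(nr), pct(nl))


def read_scores_tsv(path) -> list[PathogenicityScores]:
    """Scores TSV: position, ref, alt, sift_score, polyphen_score
    (empty cells = absent score)."""
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            v = Variant(int(row["position"]), row["ref"].strip(), row["alt"].strip())
            sift = row.get("sift_score", "").strip()
            poly = row.get("polyphen_score", "").strip()
            out.append(
                PathogenicityScores(
                    v,
                    float(sift) if sift else None,
                    float(poly) if poly else None,
                )
            )
    return out
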