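"""Variant identification by global pairwise alignment.

Samples (whole mitogenomes or amplicon windows) are aligned to the
reference with Needleman–Wunsch under linear gap penalties; mismatch
columns become substitutions and gap-in-reference runs become
insertions anchored after the preceding reference base (left
normalized).  Gap-in-sample runs are reported as uncovered reference,
never as deletions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .genome import DNA_ALPHABET, CircularGenome
from .variants import Variant

__all__ = [
    "Scoring",
    "AlignmentResult",
    "align_global",
    "call_variants",
    "call_sample",
    "apply_variants",
    "merge_window_calls",
    "read_sample_fasta",
]

logger = logging.getLogger(__name__)

GAP = "-"


@dataclass(frozen=True)
class Scoring:
    """Linear-gap scoring scheme; amplicons are near-identical so any
    sane scheme recovers isolated variants."""

    match: int = 1
    mismatch: int = -1
    gap: int = -2

    def __post_init__(self) -> None:
        if self.gap >= 0 or self.mismatch > self.match:
            raise ValueError(f"degenerate scoring scheme {self}")


@dataclass(frozen=True)
class AlignmentResult:
    aligned_ref: str
    aligned_sample: str
    score: int
    ref_offset: int = 1  # genomic position of the first reference column

    def __post_init__(self) -> None:
        if len(self.aligned_ref) != len(self.aligned_sample):
            raise ValueError("aligned strings must have equal length")


def _check_seq(name: str, seq: str) -> str:
    seq = seq.upper()
    if not seq:
        raise ValueError(f"{name} sequence is empty")
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValueError(f"{name} contains non-ACGTN characters: {sorted(bad)}")
    return seq


def align_global(
    ref_window: str,
    sample: str,
    scoring: Scoring = Scoring(),
    ref_offset: int = 1,
) -> AlignmentResult:
    """Optimal global alignment of ``sample`` against ``ref_window``.

    Tie-breaking is deterministic: match/mismatch is preferred over a
    gap, and a gap in the sample over a gap in the reference.  ``N``
    matches any base.
    """
    ref = _check_seq("reference", ref_window)
    smp = _check_seq("sample", sample)
    n, m = len(ref), len(smp)

    r = np.frombuffer(ref.encode(), dtype=np.uint8)
    s = np.frombuffer(smp.encode(), dtype=np.uint8)
    is_n = ord("N")
    sub = np.where(
        (r[:, None] == s[None, :]) | (r[:, None] == is_n) | (s[None, :] == is_n),
        np.int32(scoring.match),
        np.int32(scoring.mismatch),
    )

    g = scoring.gap
    H = np.empty((n + 1, m + 1), dtype=np.int32)
    H[0, :] = g * np.arange(m + 1, dtype=np.int32)
    H[:, 0] = g * np.arange(n + 1, dtype=np.int32)
    cols = np.arange(1, m + 1, dtype=np.int32)
    for i in range(1, n + 1):
        # vertical/diagonal candidates, then in-row horizontal closure:
        # H[i,j] = g*j + cummax(V[i,k] - g*k), exact under linear gaps
        v = np.maximum(H[i - 1, 1:] + g, H[i - 1, :-1] + sub[i - 1])
        v0 = H[i, 0]
        shifted = np.maximum.accumulate(
            np.concatenate(([v0], v - g * cols))
        )
        H[i, 1:] = np.maximum(v, (shifted[:-1] + g * cols))

    # traceback, preference order: diagonal, up (gap in sample), left
    out_r: list[str] = []
    out_s: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        h = H[i, j]
        if i > 0 and j > 0 and h == H[i - 1, j - 1] + sub[i - 1, j - 1]:
            out_r.append(ref[i - 1])
            out_s.append(smp[j - 1])
            i, j = i - 1, j - 1
        elif i > 0 and h == H[i - 1, j] + g:
            out_r.append(ref[i - 1])
            out_s.append(GAP)
            i -= 1
        else:
            out_r.append(GAP)
            out_s.append(smp[j - 1])
            j -= 1
    return AlignmentResult(
        aligned_ref="".join(reversed(out_r)),
        aligned_sample="".join(reversed(out_s)),
        score=int(H[n, m]),
        ref_offset=ref_offset,
    )


def _left_normalize(ref: str, anchor_idx: int, inserted: str) -> tuple[int, str]:
    """Shift an insertion left through identical bases (0-based anchor
    index into the ungapped reference window; -1 = before the window)."""
    while anchor_idx >= 0 and ref[anchor_idx] == inserted[-1]:
        inserted = inserted[-1] + inserted[:-1]
        anchor_idx -= 1
    return anchor_idx, inserted


def call_variants(alignment: AlignmentResult) -> list[Variant]:
    """Variants implied by an alignment; gap-in-sample runs are logged
    as uncovered reference and produce no calls."""
    ref_plain = alignment.aligned_ref.replace(GAP, "")
    calls: list[Variant] = []
    ref_idx = -1  # 0-based index of the last consumed reference base
    ins_run: list[str] = []
    uncovered: list[int] = []

    def flush_insertion() -> None:
        nonlocal ins_run
        if ins_run:
            anchor, seq = _left_normalize(ref_plain, ref_idx, "".join(ins_run))
            pos = alignment.ref_offset + anchor
            if anchor < 0:
                logger.warning("insertion before window start at %d dropped", pos)
            else:
                calls.append(Variant(pos, "", seq))
            ins_run = []

    for rb, sb in zip(alignment.aligned_ref, alignment.aligned_sample):
        if rb == GAP:
            ins_run.append(sb)
            continue
        flush_insertion()
        ref_idx += 1
        if sb == GAP:
            uncovered.append(alignment.ref_offset + ref_idx)
        elif rb != sb:
            if rb == "N" or sb == "N":
                logger.info("ambiguous base at %d ignored", alignment.ref_offset + ref_idx)
            else:
                calls.append(Variant(alignment.ref_offset + ref_idx, rb, sb))
    flush_insertion()
    if uncovered:
        logger.warning("%d reference positions uncovered by sample", len(uncovered))
    return calls


def call_sample(
    genome: CircularGenome,
    sample_seq: str,
    scoring: Scoring = Scoring(),
    ref_offset: int = 1,
    window_length: int | None = None,
) -> list[Variant]:
    """Align one sample sequence against a reference window and call."""
    if genome.sequence is None:
        raise ValueError("reference genome must carry sequence")
    length = window_length if window_length is not None else genome.length
    window = genome.fetch(ref_offset, length)
    aln = align_global(window, sample_seq, scoring, ref_offset=ref_offset)
    return call_variants(aln)


def merge_window_calls(per_window: Iterable[Iterable[Variant]]) -> list[Variant]:
    """Union of per-amplicon call sets, deduplicated by identity triple."""
    seen: dict[tuple[int, str, str], Variant] = {}
    for calls in per_window:
        for v in calls:
            seen.setdefault(v.key, v)
    return sorted(seen.values())


def apply_variants(sequence: str, variants: Sequence[Variant]) -> str:
    """Apply substitutions and insertions to a linear reference string.

    Positions are 1-based on the input sequence; insertions are placed
    immediately after their anchor position.  Conflicting variants at
    one position are rejected.
    """
    positions = [v.key for v in variants]
    if len(positions) != len(set(positions)):
        raise ValueError("duplicate variants")
    seq = list(sequence)
    for v in sorted(variants, key=lambda v: v.position, reverse=True):
        if not 1 <= v.position <= len(sequence):
            raise ValueError(f"position {v.position} outside sequence")
        if v.kind == "substitution":
            if seq[v.position - 1] != v.ref:
                raise ValueError(
                    f"ref mismatch at {v.position}: expected {v.ref}, "
                    f"found {seq[v.position - 1]}"
                )
            seq[v.position - 1] = v.alt
        else:
            seq.insert(v.position, v.alt)
    return "".join(seq)


def read_sample_fasta(path) -> dict[str, tuple[str, int]]:
    """Read sample sequences; ids may carry ``|ampliconN|<offset>``
    suffixes giving the window's 1-based genomic start (default 1)."""
    from Bio import SeqIO

    out: dict[str, tuple[str, int]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        offset = 1
        if len(parts) == 3:
            offset = int(parts[2])
        out[rec.id] = (str(rec.seq).upper(), offset)
    return out
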