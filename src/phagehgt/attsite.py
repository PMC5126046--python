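"""Attachment-site analysis for temperate phage integration.

A temperate phage with a circular genome integrates into the host chromosome
by site-specific recombination across a shared "core" sequence, producing
hybrid junctions attL and attR from the phage site attP and the bacterial
site attB. All four sites therefore carry the core at their junction; for
some phages the core is flanked by a pair of inverted repeats.

This module builds the circularized-phage attP junction from a prophage
span, finds the longest core common to all four att sequences at their
junctions, and scans for inverted-repeat arms around the core. Occurrence
"at the junction" means the occurrence touches or spans the junction offset
(s <= offset <= s + L) - a between-characters offset cannot be strictly
spanned by a single-nucleotide core, and single-nucleotide cores do occur.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .io import reverse_complement

logger = logging.getLogger("phagehgt.attsite")

ATT_NAMES = ("attL", "attR", "attB", "attP")


@dataclass
class AttContext:
    """The four att junction sequences, each with its junction offset.

    The offset is the index of the first character to the right of the
    junction (a position between characters, strictly inside the sequence).
    """

    attL: str
    attR: str
    attB: str
    attP: str
    offsets: dict[str, int]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ATT_NAMES:
            seq = getattr(self, name)
            off = self.offsets[name]
            if not (0 < off < len(seq)):
                raise ValueError(
                    f"{name}: junction offset {off} not strictly inside "
                    f"sequence of length {len(seq)}"
                )

    def sequences(self) -> dict[str, str]:
        return {name: getattr(self, name) for name in ATT_NAMES}


@dataclass
class InvertedRepeat:
    left_start: int  # 0-based starts in the searched sequence
    right_start: int
    length: int
    mismatches: int
    left_arm: str
    right_arm: str


@dataclass
class AttCore:
    core: str
    positions: dict[str, int]  # 0-based start of the junction occurrence per site
    left_arm: Optional[str] = None
    right_arm: Optional[str] = None
    arm_length: int = 0
    arm_mismatches: int = 0
    arm_positions: Optional[tuple[int, int]] = None


def build_attP(prophage_seq: str, window: int = 300) -> tuple[str, int]:
    """Circularize a prophage: last ``window`` bases + first ``window`` bases.

    Returns (junction sequence, junction offset). A prophage shorter than
    2*window is split into halves with a warning.
    """
    L = len(prophage_seq)
    if L < 2:
        raise ValueError("prophage sequence too short to circularize")
    if L < 2 * window:
        logger.warning(
            "build_attP: prophage length %d < 2*window (%d); using full halves",
            L,
            2 * window,
        )
        half = L // 2
        return prophage_seq[half:] + prophage_seq[:half], L - half
    return prophage_seq[-window:] + prophage_seq[:window], window


def build_att_context(
    host_left: str,
    prophage_seq: str,
    host_right: str,
    window: int = 300,
    provenance: dict | None = None,
) -> AttContext:
    """Derive attL/attR/attB/attP from a prophage and its host flanks.

    attL = host left flank + prophage start; attR = prophage end + host right
    flank; attB = host left flank + host right flank (the excised-host
    junction); attP = circularized prophage.
    """
    w = window
    left = host_left[-w:]
    right = host_right[:w]
    attL = left + prophage_seq[:w]
    attR = prophage_seq[-w:] + right
    attB = left + right
    attP, offP = build_attP(prophage_seq, window=w)
    return AttContext(
        attL=attL,
        attR=attR,
        attB=attB,
        attP=attP,
        offsets={
            "attL": len(left),
            "attR": min(w, len(prophage_seq)),
            "attB": len(left),
            "attP": offP,
        },
        provenance=provenance or {},
    )


def att_context_from_genome(
    genome_seq: str, span: tuple[int, int], window: int = 300
) -> AttContext:
    """att context from a genome sequence and a 1-based prophage span."""
    start, end = span
    if not (1 <= start <= end <= len(genome_seq)):
        raise ValueError(f"span {span} outside genome of length {len(genome_seq)}")
    return build_att_context(
        genome_seq[: start - 1],
        genome_seq[start - 1 : end],
        genome_seq[end:],
        window=window,
        provenance={"span": span},
    )


def _junction_occurrences(seq: str, offset: int, sub: str) -> list[int]:
    """Starts of occurrences of ``sub`` touching/spanning the junction offset."""
    L = len(sub)
    hits = []
    s = max(0, offset - L)
    limit = min(offset, len(seq) - L)
    while s <= limit:
        if seq[s : s + L] == sub:
            hits.append(s)
        s += 1
    return hits


def _occurrence_distance(start: int, length: int, offset: int) -> float:
    return abs(start + length / 2.0 - offset)


def find_core(ctx: AttContext, max_core: int = 50) -> Optional[AttCore]:
    """Longest string common to all four att sequences at their junctions.

    Candidates are junction-touching substrings of attP, searched from the
    longest length down; ties are broken by total occurrence distance to the
    offsets, then lexicographically. Returns None when no common
    junction-spanning string of length >= 1 exists.
    """
    seqs = ctx.sequences()
    attP, offP = ctx.attP, ctx.offsets["attP"]
    top = min(max_core, len(attP))
    for L in range(top, 0, -1):
        candidates: dict[str, tuple[float, dict[str, int]]] = {}
        for s in range(max(0, offP - L), min(offP, len(attP) - L) + 1):
            sub = attP[s : s + L]
            if sub in candidates:
                continue
            positions: dict[str, int] = {}
            total = 0.0
            for name, seq in seqs.items():
                occ = _junction_occurrences(seq, ctx.offsets[name], sub)
                if not occ:
                    positions = {}
                    break
                best = min(
                    occ, key=lambda p: _occurrence_distance(p, L, ctx.offsets[name])
                )
                positions[name] = best
                total += _occurrence_distance(best, L, ctx.offsets[name])
            if positions:
                candidates[sub] = (total, positions)
        if candidates:
            core = min(candidates, key=lambda c: (candidates[c][0], c))
            return AttCore(core=core, positions=candidates[core][1])
    return None


def find_inverted_repeats(
    seq: str,
    core_span: tuple[int, int],
    search_window: int = 200,
    min_arm: int = 5,
    max_mismatch: int = 1,
    max_arm: int = 50,
) -> Optional[InvertedRepeat]:
    """Highest-scoring inverted-repeat arm pair flanking a core.

    ``core_span`` is the 0-based half-open span of the core in ``seq``.
    Searches ``search_window`` bases left and right of the core for an arm
    pair where one arm is within ``max_mismatch`` Hamming mismatches of the
    reverse complement of the other. Score order: longest arm, then fewest
    mismatches, then closest to the core, then leftmost; deterministic.
    Arms are capped at ``max_arm`` bases. Returns None when nothing is found.
    """
    cs, ce = core_span
    left_region = seq[max(0, cs - search_window) : cs]
    right_region = seq[ce : ce + search_window]
    left_base = max(0, cs - search_window)
    if min(len(left_region), len(right_region)) < min_arm:
        return None
    la = np.frombuffer(left_region.encode(), dtype=np.uint8)
    # reverse-complement the whole right region once; a window of it maps
    # back to a (reversed) window of the original region
    rc_right = reverse_complement(right_region)
    ra = np.frombuffer(rc_right.encode(), dtype=np.uint8)
    top = min(max_arm, len(left_region), len(right_region))
    for L in range(top, min_arm - 1, -1):
        lw = np.lib.stride_tricks.sliding_window_view(la, L)  # (nl, L)
        rw = np.lib.stride_tricks.sliding_window_view(ra, L)  # (nr, L)
        mism = L - (lw[:, None, :] == rw[None, :, :]).sum(axis=2)
        ii, jj = np.nonzero(mism <= max_mismatch)
        if len(ii) == 0:
            continue
        best = None
        for i, j in zip(ii.tolist(), jj.tolist()):
            right_start_local = len(right_region) - j - L
            # distance from core: gap between arm and core on each side
            dist = (len(left_region) - (i + L)) + right_start_local
            key = (int(mism[i, j]), dist, i)
            if best is None or key < best[0]:
                best = (key, i, right_start_local)
        _, i, r_local = best
        left_start = left_base + i
        right_start = ce + r_local
        return InvertedRepeat(
            left_start=left_start,
            right_start=right_start,
            length=L,
            mismatches=int(mism[i, len(right_region) - r_local - L]),
            left_arm=seq[left_start : left_start + L],
            right_arm=seq[right_start : right_start + L],
        )
    return None


def analyze_att(
    ctx: AttContext,
    max_core: int = 50,
    search_window: int = 200,
    min_arm: int = 5,
    max_mismatch: int = 1,
) -> Optional[AttCore]:
    """Find the core and, if present, its inverted-repeat arms in attP."""
    core = find_core(ctx, max_core=max_core)
    if core is None:
        return None
    s = core.positions["attP"]
    ir = find_inverted_repeats(
        ctx.attP,
        (s, s + len(core.core)),
        search_window=search_window,
        min_arm=min_arm,
        max_mismatch=max_mismatch,
    )
    if ir is not None:
        core.left_arm = ir.left_arm
        core.right_arm = ir.right_arm
        core.arm_length = ir.length
        core.arm_mismatches = ir.mismatches
        core.arm_positions = (ir.left_start, ir.right_start)
    return core
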