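"""Pairwise alignment, identity, homology screening, ortholog pairing, synteny.

The screening stage of the pipeline: candidate transferred genes are found by
a seeded local-alignment search with a Karlin-Altschul-style E-value cutoff
(default 1e-5), gene-wise percent identity is computed from affine-gap global
alignments after removal of poorly aligned columns, and prophage pairs are
compared structurally by collinear-block (synteny) analysis.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from scipy.optimize import brentq

logger = logging.getLogger("phagehgt.seqcompare")


@dataclass(frozen=True)
class AlignParams:
    """Affine-gap scoring: a gap of length k costs open + (k-1)*extend."""

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0


DEFAULT_PARAMS = AlignParams()


@dataclass
class PairwiseAlignment:
    id_a: str
    id_b: str
    aligned_a: str
    aligned_b: str
    score: float
    params: AlignParams = DEFAULT_PARAMS

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned sequences differ in length")

    def __len__(self) -> int:
        return len(self.aligned_a)

    @property
    def ungapped_a(self) -> str:
        return self.aligned_a.replace("-", "")

    @property
    def ungapped_b(self) -> str:
        return self.aligned_b.replace("-", "")


@dataclass
class OrthologPair:
    gene_a: str
    gene_b: str
    percent_identity: float
    n_columns_compared: int
    n_columns_trimmed: int


@dataclass
class HomologyHit:
    query_id: str
    subject_id: str
    score: float
    expect: float
    identity: float


@dataclass
class SyntenyBlock:
    pairs: list[OrthologPair]
    orientation: int  # +1 collinear, -1 inverted


@dataclass
class DiscrepantRegion:
    side: str  # "a" or "b"
    genes: list[str]


@dataclass
class SyntenyReport:
    blocks: list[SyntenyBlock]
    discrepant_regions: list[DiscrepantRegion]


# ---------------------------------------------------------------------------
# Global alignment
# ---------------------------------------------------------------------------


def _make_aligner(params: AlignParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    return aligner


def global_align(
    a: str,
    b: str,
    params: AlignParams = DEFAULT_PARAMS,
    id_a: str = "a",
    id_b: str = "b",
) -> PairwiseAlignment:
    """Optimal global alignment under affine-gap scoring.

    Deterministic: the aligner's first co-optimal traceback is returned.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    aligner = _make_aligner(params)
    aln = next(iter(aligner.align(a.upper(), b.upper())))
    return PairwiseAlignment(
        id_a=id_a,
        id_b=id_b,
        aligned_a=str(aln[0]),
        aligned_b=str(aln[1]),
        score=float(aln.score),
        params=params,
    )


def percent_identity(aln: PairwiseAlignment, mode: str = "ungapped_columns") -> float:
    """Matches / counted columns * 100.

    ``ungapped_columns`` (default) counts only columns with no gap;
    ``all_columns`` counts every column.
    """
    matches = 0
    counted = 0
    for ca, cb in zip(aln.aligned_a, aln.aligned_b):
        gap = ca == "-" or cb == "-"
        if mode == "ungapped_columns" and gap:
            continue
        counted += 1
        if not gap and ca == cb:
            matches += 1
    if counted == 0:
        raise ValueError("percent identity undefined: zero counted columns")
    return 100.0 * matches / counted


def trim_conserved_blocks(
    aln: PairwiseAlignment,
    max_gap_fraction: float = 0.5,
    min_block_len: int = 10,
    min_conservation: float = 0.5,
) -> PairwiseAlignment:
    """Remove poorly aligned columns (simplified conserved-block filter).

    A column passes the gap test iff its gap fraction is strictly below
    ``max_gap_fraction`` (for a pairwise alignment the default 0.5 removes
    any gapped column). Maximal runs of passing columns form blocks; blocks
    shorter than ``min_block_len`` or with mean match fraction below
    ``min_conservation`` are removed.
    """
    n_seq = 2
    cols = list(zip(aln.aligned_a, aln.aligned_b))
    passing = [
        (sum(c == "-" for c in col) / n_seq) < max_gap_fraction for col in cols
    ]
    kept_idx: list[int] = []
    i = 0
    while i < len(cols):
        if not passing[i]:
            i += 1
            continue
        j = i
        while j < len(cols) and passing[j]:
            j += 1
        block = list(range(i, j))
        matches = sum(cols[k][0] == cols[k][1] for k in block)
        if len(block) >= min_block_len and matches / len(block) >= min_conservation:
            kept_idx.extend(block)
        i = j
    if not kept_idx:
        logger.warning(
            "trim_conserved_blocks: all %d columns removed (%s vs %s); "
            "identity undefined downstream",
            len(cols),
            aln.id_a,
            aln.id_b,
        )
    new_a = "".join(cols[k][0] for k in kept_idx)
    new_b = "".join(cols[k][1] for k in kept_idx)
    score = sum(
        aln.params.match if x == y else aln.params.mismatch
        for x, y in zip(new_a, new_b)
    )
    return PairwiseAlignment(
        id_a=aln.id_a,
        id_b=aln.id_b,
        aligned_a=new_a,
        aligned_b=new_b,
        score=score,
        params=aln.params,
    )


# ---------------------------------------------------------------------------
# Seeded homology search with Karlin-Altschul-style E-values
# ---------------------------------------------------------------------------

_KA_K = 0.1  # documented approximation; lambda is solved exactly


def karlin_altschul_lambda(params: AlignParams = DEFAULT_PARAMS) -> float:
    """Solve sum_ij p_i p_j exp(lambda * s_ij) = 1 for uniform base frequencies."""
    p_match, p_mismatch = 0.25, 0.75

    def f(lam: float) -> float:
        return (
            p_match * math.exp(lam * params.match)
            + p_mismatch * math.exp(lam * params.mismatch)
            - 1.0
        )

    return float(brentq(f, 1e-9, 10.0))


def _ungapped_extend(
    q: str, s: str, qi: int, si: int, k: int, params: AlignParams, xdrop: float = 20.0
) -> tuple[float, int, int, int]:
    """Extend a k-mer seed in both directions; returns (score, qstart, sstart, length)."""
    match, mismatch = params.match, params.mismatch
    # right extension (seed included)
    score = k * match
    best = score
    bq, bs = qi + k, si + k
    i, j = qi + k, si + k
    while i < len(q) and j < len(s):
        score += match if q[i] == s[j] else mismatch
        i += 1
        j += 1
        if score > best:
            best, bq, bs = score, i, j
        elif best - score > xdrop:
            break
    right_end_q = bq
    # left extension
    score = best
    best_left = score
    lq, ls = qi, si
    i, j = qi - 1, si - 1
    while i >= 0 and j >= 0:
        score += match if q[i] == s[j] else mismatch
        if score > best_left:
            best_left, lq, ls = score, i, j
        elif best_left - score > xdrop:
            break
        i -= 1
        j -= 1
    return best_left, lq, ls, right_end_q - lq


def search_homologs(
    queries: dict[str, str],
    database: dict[str, str],
    evalue_cutoff: float = 1e-5,
    word_size: int = 11,
    params: AlignParams = DEFAULT_PARAMS,
) -> list[HomologyHit]:
    """Seeded local-alignment search over an in-memory sequence database.

    k-mer seeds are extended without gaps; the best segment score per
    (query, subject) is converted to an E-value E = K*m*N*exp(-lambda*S)
    with N the total database length. Only hits with E < ``evalue_cutoff``
    are returned, sorted ascending by E.
    """
    if not database:
        logger.warning("search_homologs: empty database")
        return []
    lam = karlin_altschul_lambda(params)
    db_len = sum(len(s) for s in database.values())
    index: dict[str, list[tuple[str, int]]] = defaultdict(list)
    for sid, seq in database.items():
        seq = seq.upper()
        for pos in range(len(seq) - word_size + 1):
            index[seq[pos : pos + word_size]].append((sid, pos))
    hits: list[HomologyHit] = []
    for qid, qseq in queries.items():
        qseq = qseq.upper()
        best: dict[str, tuple[float, int, int, int]] = {}
        seen_diag: dict[str, set[int]] = defaultdict(set)
        for qpos in range(len(qseq) - word_size + 1):
            for sid, spos in index.get(qseq[qpos : qpos + word_size], ()):
                diag = qpos - spos
                if diag in seen_diag[sid]:
                    continue
                seen_diag[sid].add(diag)
                res = _ungapped_extend(
                    qseq, database[sid].upper(), qpos, spos, word_size, params
                )
                if sid not in best or res[0] > best[sid][0]:
                    best[sid] = res
        for sid, (score, lq, ls, length) in best.items():
            expect = _KA_K * len(qseq) * db_len * math.exp(-lam * score)
            if expect < evalue_cutoff:
                sseq = database[sid].upper()
                seg_q = qseq[lq : lq + length]
                seg_s = sseq[ls : ls + length]
                ident = (
                    100.0
                    * sum(x == y for x, y in zip(seg_q, seg_s))
                    / max(1, length)
                )
                hits.append(
                    HomologyHit(
                        query_id=qid,
                        subject_id=sid,
                        score=score,
                        expect=expect,
                        identity=ident,
                    )
                )
    hits.sort(key=lambda h: (h.expect, h.query_id, h.subject_id))
    return hits


def presence_matrix(
    queries: dict[str, str],
    genome_set: dict[str, dict[str, str]],
    evalue_cutoff: float = 1e-5,
    word_size: int = 11,
):
    """Genome x query presence/absence matrix from the homology screen.

    ``genome_set`` maps genome_id -> {gene_id: sequence}. Presence means at
    least one hit below the cutoff. Returns a boolean pandas DataFrame
    (rows: genomes, columns: queries); row/column totals via .sum().
    """
    import pandas as pd

    rows = {}
    for gid, genes in genome_set.items():
        hits = search_homologs(
            queries, genes, evalue_cutoff=evalue_cutoff, word_size=word_size
        )
        present = {h.query_id for h in hits}
        rows[gid] = {q: (q in present) for q in queries}
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(queries))


# ---------------------------------------------------------------------------
# Ortholog pairing and synteny
# ---------------------------------------------------------------------------


def _pair_stats(
    seq_a: str, seq_b: str, params: AlignParams, trim: bool
) -> tuple[float, int, int]:
    aln = global_align(seq_a, seq_b, params=params)
    n0 = len(aln)
    if trim:
        aln = trim_conserved_blocks(aln)
    if len(aln) == 0:
        return float("nan"), 0, n0
    return percent_identity(aln), len(aln), n0 - len(aln)


def pair_orthologs(
    genes_a: dict[str, str],
    genes_b: dict[str, str],
    min_identity: float = 50.0,
    params: AlignParams = DEFAULT_PARAMS,
    trim: bool = True,
) -> tuple[list[OrthologPair], list[str], list[str]]:
    """Reciprocal-best-hit one-to-one pairing by global-alignment identity.

    Ties are broken by longer aligned length, then lexicographic gene id.
    Returns (pairs, unpaired_a, unpaired_b).
    """
    stats: dict[tuple[str, str], tuple[float, int, int]] = {}
    for ga, sa in genes_a.items():
        for gb, sb in genes_b.items():
            stats[(ga, gb)] = _pair_stats(sa, sb, params, trim)

    def best_partner(g: str, others: list[str], forward: bool) -> str | None:
        candidates = []
        for o in others:
            ident, ncol, _ = stats[(g, o) if forward else (o, g)]
            if not math.isnan(ident) and ident >= min_identity:
                candidates.append((-ident, -ncol, o))
        if not candidates:
            return None
        return min(candidates)[2]

    best_a = {g: best_partner(g, list(genes_b), True) for g in genes_a}
    best_b = {g: best_partner(g, list(genes_a), False) for g in genes_b}
    pairs = []
    for ga, gb in best_a.items():
        if gb is not None and best_b.get(gb) == ga:
            ident, ncol, ntrim = stats[(ga, gb)]
            pairs.append(
                OrthologPair(
                    gene_a=ga,
                    gene_b=gb,
                    percent_identity=ident,
                    n_columns_compared=ncol,
                    n_columns_trimmed=ntrim,
                )
            )
    paired_a = {p.gene_a for p in pairs}
    paired_b = {p.gene_b for p in pairs}
    unpaired_a = [g for g in genes_a if g not in paired_a]
    unpaired_b = [g for g in genes_b if g not in paired_b]
    return pairs, unpaired_a, unpaired_b


def find_synteny(
    pairs: list[OrthologPair], order_a: list[str], order_b: list[str]
) -> SyntenyReport:
    """Partition genes into collinear blocks and discrepant (private) regions.

    A block is a maximal run of ortholog pairs consecutive in both gene
    orders with a consistent orientation (+1 same order, -1 inverted).
    Genes private to one prophage are grouped into maximal runs per side.
    """
    a_to_b = {p.gene_a: p.gene_b for p in pairs}
    pair_by_a = {p.gene_a: p for p in pairs}
    paired_a = [g for g in order_a if g in a_to_b]
    rank_b = {g: i for i, g in enumerate(g for g in order_b if g in set(a_to_b.values()))}

    blocks: list[SyntenyBlock] = []
    i = 0
    while i < len(paired_a):
        run = [paired_a[i]]
        orientation = 0
        j = i + 1
        while j < len(paired_a):
            step = rank_b[a_to_b[paired_a[j]]] - rank_b[a_to_b[paired_a[j - 1]]]
            if step not in (1, -1):
                break
            if orientation == 0:
                orientation = step
            elif step != orientation:
                break
            run.append(paired_a[j])
            j += 1
        blocks.append(
            SyntenyBlock(
                pairs=[pair_by_a[g] for g in run],
                orientation=orientation if orientation else 1,
            )
        )
        i = j

    discrepant: list[DiscrepantRegion] = []
    for side, order, paired in (
        ("a", order_a, set(a_to_b)),
        ("b", order_b, {p.gene_b for p in pairs}),
    ):
        run: list[str] = []
        for g in order:
            if g in paired:
                if run:
                    discrepant.append(DiscrepantRegion(side=side, genes=run))
                    run = []
            else:
                run.append(g)
        if run:
            discrepant.append(DiscrepantRegion(side=side, genes=run))
    return SyntenyReport(blocks=blocks, discrepant_regions=discrepant)
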