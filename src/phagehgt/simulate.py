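"""Synthetic genomes, prophages, att sites and qPCR data with known truth.

The generator emulates the statistical structure the screen assumes: pairs
of host genomes at a controlled synonymous divergence, an embedded candidate
prophage pair at a lower divergence (the transferred phage), resident phages
at a higher divergence, a compositionally distinct insert at the candidate
phage's 3' end, att cores (with inverted-repeat arms in attP) planted at the
prophage boundaries, and qPCR Ct tables generated from known copy ratios.

Default parameters are the study regime the screen was designed around:
candidate-phage dS 0.07, resident-phage dS 0.27, host-gene dS 0.10, att core
"ATGA", qPCR standards spanning 1e3..1e7 copies, phage:host copy ratio 2.90
and host:host ratio 1.01. Divergence is purely synonymous by default, so dS
is the only divergence axis; a mixed mode adds nonsynonymous changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from . import divergence
from .divergence import SENSE_CODONS, STOP_CODONS, translate_codon
from .inference import QpcrRun
from .io import GeneFeature, GenomeRecord, ProphageRegion, reverse_complement

_BASES = "ACGT"

# single-base synonymous (and nonsynonymous, stop-excluded) neighbours per codon
_SYN_NEIGHBOURS: dict[str, list[tuple[int, str]]] = {}
_NONSYN_NEIGHBOURS: dict[str, list[tuple[int, str]]] = {}
for _c in SENSE_CODONS:
    syn, non = [], []
    for _pos in range(3):
        for _b in _BASES:
            if _b == _c[_pos]:
                continue
            _mut = _c[:_pos] + _b + _c[_pos + 1 :]
            if _mut in STOP_CODONS:
                continue
            (syn if translate_codon(_mut) == translate_codon(_c) else non).append(
                (_pos, _b)
            )
    _SYN_NEIGHBOURS[_c] = syn
    _NONSYN_NEIGHBOURS[_c] = non


def ps_from_ds(ds: float) -> float:
    """Jukes-Cantor expected synonymous difference proportion at rate dS."""
    return 0.75 * (1.0 - math.exp(-(4.0 / 3.0) * ds))


@dataclass
class QpcrSimConfig:
    """Generation parameters for qPCR runs.

    ``ratios`` are true copy numbers of each gene relative to the
    calibrator. Standards span 10^3..10^7 copies in 10-fold steps.
    """

    ratios: dict[str, float] = field(
        default_factory=lambda: {
            "VA1gp3": 2.90,
            "VA1gp53": 3.21,
            "VA1gp62": 2.45,
            "ftsZ": 1.01,
        }
    )
    calibrator: str = "groEL"
    calibrator_copies: float = 1e5
    efficiency: float = 1.0
    intercept: float = 38.0
    # Ct noise 0.08 with triplicate standards reproduces the relative-copy
    # dispersion (cv ~6-9%) that the study design exhibits
    ct_noise_sd: float = 0.08
    n_standard_replicates: int = 3
    n_replicates: int = 9
    plates: int = 1
    plate_offsets: Optional[list[float]] = None
    standard_log10_range: tuple[int, int] = (3, 7)

    def __post_init__(self) -> None:
        if not (0.5 < self.efficiency < 1.5):
            raise ValueError(
                "efficiency must lie in (0.5, 1.5); 1.0 means 100% amplification"
            )


@dataclass
class PhageSpec:
    name: str
    n_genes: int = 8
    target_ds: float = 0.27


@dataclass
class SimConfig:
    """Study-design parameters for a full synthetic transfer scenario."""

    seed: int = 0
    n_host_genes: int = 8
    n_phage_genes: int = 8
    gene_length_mean: int = 600
    gene_length_sd: int = 90
    host_ds: float = 0.10
    candidate_ds: float = 0.07
    resident_phages: list[PhageSpec] = field(
        default_factory=lambda: [
            PhageSpec("resident1", 8, 0.27),
            PhageSpec("resident2", 8, 0.27),
            PhageSpec("resident3", 8, 0.27),
        ]
    )
    backbone_gc: float = 0.40  # endosymbiont chromosomes are AT-rich
    insert_length: int = 2000
    insert_gc: float = 0.60
    att_core: str = "ATGA"
    arm_length: int = 12
    arm_mismatches: int = 0
    flank_length: int = 300
    spacer_length: int = 50
    qpcr: QpcrSimConfig = field(default_factory=QpcrSimConfig)
    tree_newick: str = "((genomeA,other1),(other2,(other3,genomeB)));"
    carriers: tuple[str, str] = ("genomeA", "genomeB")

    def __post_init__(self) -> None:
        for ds in [self.host_ds, self.candidate_ds] + [
            p.target_ds for p in self.resident_phages
        ]:
            if not (0.0 <= ds < 1.0):
                raise ValueError(f"target dS {ds} outside the feasible range [0, 1)")


@dataclass
class SimTruth:
    """Ground truth sufficient to score every pipeline stage."""

    seed: int
    host_orthologs: dict[str, str]
    candidate_orthologs: dict[str, str]
    resident_orthologs: dict[str, dict[str, str]]
    generating_ds: dict[str, float]  # group -> target dS
    realized_ps: dict[tuple[str, str], float]
    insert_span: Optional[tuple[int, int]] = None  # 1-based, genome A contig
    att_core: str = ""
    att_arms: Optional[tuple[str, str]] = None
    prophage_span_a: Optional[tuple[int, int]] = None
    tree_newick: str = ""
    carriers: tuple[str, ...] = ()
    expected_label: str = ""


# ---------------------------------------------------------------------------
# Gene-pair evolution
# ---------------------------------------------------------------------------


def _codon_weights(gc: float) -> np.ndarray:
    """Sense-codon sampling weights for a target GC composition."""
    p = {"A": (1 - gc) / 2, "T": (1 - gc) / 2, "G": gc / 2, "C": gc / 2}
    w = np.array([p[c[0]] * p[c[1]] * p[c[2]] for c in SENSE_CODONS])
    return w / w.sum()


def random_cds(
    n_codons: int, rng: np.random.Generator, gc: float | None = None
) -> str:
    """Random sense-codon sequence with no stops.

    With ``gc`` set, codons are sampled with base composition biased toward
    that GC fraction (endosymbiont genomes are strongly AT-rich); otherwise
    codon frequencies are uniform.
    """
    if gc is None:
        idx = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    else:
        idx = rng.choice(len(SENSE_CODONS), size=n_codons, p=_codon_weights(gc))
    return "".join(SENSE_CODONS[i] for i in idx)


def _apply_substitutions(
    codons: list[str],
    n_mut: int,
    rng: np.random.Generator,
    neighbours: dict[str, list[tuple[int, str]]],
) -> None:
    """Apply n_mut single-base changes drawn uniformly from the available moves."""
    counts = np.array([len(neighbours[c]) for c in codons], dtype=float)
    for _ in range(n_mut):
        total = counts.sum()
        if total == 0:
            break
        i = rng.choice(len(codons), p=counts / total)
        pos, base = neighbours[codons[i]][rng.integers(len(neighbours[codons[i]]))]
        codons[i] = codons[i][:pos] + base + codons[i][pos + 1 :]
        counts[i] = len(neighbours[codons[i]])


def simulate_gene_pair(
    length: int,
    target_ds: float,
    seed: int | np.random.Generator = 0,
    target_dn: float = 0.0,
    gc: float | None = None,
) -> tuple[str, str, float]:
    """A coding-gene pair evolved to a target synonymous divergence.

    One copy receives a Poisson number of synonymous single-base
    substitutions with expectation S * pS_target, where S is the ancestral
    synonymous site count and pS_target the Jukes-Cantor proportion at
    ``target_ds``. With ``target_dn`` > 0 a corresponding number of
    nonsynonymous (never stop-creating) changes is also applied.
    Returns (cds_a, cds_b, realized pS).
    """
    if length % 3 != 0 or length <= 0:
        raise ValueError("gene length must be a positive multiple of 3")
    if not (0.0 <= target_ds < 1.0):
        raise ValueError(f"target dS {target_ds} infeasible")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cds_a = random_cds(length // 3, rng, gc=gc)
    codons = [cds_a[i : i + 3] for i in range(0, length, 3)]
    S = sum(divergence.synonymous_site_fractions(c)[0] for c in codons)
    N = 3 * len(codons) - S
    n_syn = rng.poisson(S * ps_from_ds(target_ds))
    mutated = list(codons)
    _apply_substitutions(mutated, int(n_syn), rng, _SYN_NEIGHBOURS)
    if target_dn > 0:
        n_non = rng.poisson(N * ps_from_ds(target_dn))
        _apply_substitutions(mutated, int(n_non), rng, _NONSYN_NEIGHBOURS)
    cds_b = "".join(mutated)
    aln = divergence.CodonAlignment.from_pair(cds_a, cds_b)
    res = divergence.ng86(aln)
    return cds_a, cds_b, res.pS


# ---------------------------------------------------------------------------
# Whole-study simulation
# ---------------------------------------------------------------------------


def _random_gc_sequence(length: int, gc: float, rng: np.random.Generator) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return "".join(rng.choice(list("ACGT"), size=length, p=probs))


def _gene_lengths(n: int, cfg: SimConfig, rng: np.random.Generator) -> list[int]:
    raw = rng.normal(cfg.gene_length_mean, cfg.gene_length_sd, size=n)
    return [max(90, 3 * int(round(x / 3))) for x in raw]


def _make_arm_pair(cfg: SimConfig, rng: np.random.Generator) -> tuple[str, str]:
    left = "".join(rng.choice(list("ACGT"), size=cfg.arm_length))
    right = reverse_complement(left)
    if cfg.arm_mismatches:
        pos = rng.choice(cfg.arm_length, size=cfg.arm_mismatches, replace=False)
        right_l = list(right)
        for p in pos:
            right_l[p] = rng.choice([b for b in "ACGT" if b != right_l[p]])
        right = "".join(right_l)
    return left, right


def simulate_study(config: SimConfig | None = None) -> tuple[GenomeRecord, GenomeRecord, SimTruth]:
    """Two host genomes realizing the three divergence groups, with truth.

    Genome A carries the candidate phage delimited by att cores (the core
    and inverted-repeat arms are planted so that attL/attR/attB/attP all
    share the core at their junctions); genome B carries the transferred
    copy plus the resident phages. The compositional insert sits at the
    candidate phage's 3' end in genome A.
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    realized: dict[tuple[str, str], float] = {}

    def gene_pairs(prefix_a: str, prefix_b: str, n: int, ds: float):
        out = []
        for i, L in enumerate(_gene_lengths(n, cfg, rng), start=1):
            a, b, ps = simulate_gene_pair(L, ds, seed=rng, gc=cfg.backbone_gc)
            ida, idb = f"{prefix_a}_{i:03d}", f"{prefix_b}_{i:03d}"
            realized[(ida, idb)] = ps
            out.append((ida, idb, a, b))
        return out

    host = gene_pairs("hostA", "hostB", cfg.n_host_genes, cfg.host_ds)
    cand = gene_pairs("phageX", "phageXt", cfg.n_phage_genes, cfg.candidate_ds)
    residents = {}
    for spec in cfg.resident_phages:
        res = []
        for i, (ida, _, seq_a, _) in enumerate(cand[: spec.n_genes], start=1):
            # resident phage genes diverge from the same ancestral phage genes
            codons = [seq_a[k : k + 3] for k in range(0, len(seq_a), 3)]
            S = sum(divergence.synonymous_site_fractions(c)[0] for c in codons)
            mutated = list(codons)
            _apply_substitutions(
                mutated, int(rng.poisson(S * ps_from_ds(spec.target_ds))), rng,
                _SYN_NEIGHBOURS,
            )
            idb = f"{spec.name}_{i:03d}"
            seq_b = "".join(mutated)
            aln = divergence.CodonAlignment.from_pair(seq_a, seq_b)
            realized[(ida, idb)] = divergence.ng86(aln).pS
            res.append((ida, idb, seq_b))
        residents[spec.name] = res

    spacer = lambda: _random_gc_sequence(cfg.spacer_length, cfg.backbone_gc, rng)  # noqa: E731
    arm_left, arm_right = _make_arm_pair(cfg, rng)
    core = cfg.att_core.upper()

    # --- genome A: host genes, then B | core armR pad genes insert pad armL | core B'
    chr_a: list[str] = []
    feats_a: list[GeneFeature] = []
    pos = 0

    def push(seq: str) -> tuple[int, int]:
        nonlocal pos
        chr_a.append(seq)
        start = pos + 1
        pos += len(seq)
        return start, pos

    for ida, _, seq_a, _ in host:
        push(spacer())
        s, e = push(seq_a)
        feats_a.append(GeneFeature(ida, "genomeA", "chrA", s, e, "+", cds=seq_a))
    push(spacer())
    b_left = _random_gc_sequence(cfg.flank_length, cfg.backbone_gc, rng)
    b_right = _random_gc_sequence(cfg.flank_length, cfg.backbone_gc, rng)
    # prevent chance extension of the planted core across the host/phage boundary
    b_left = _fix_boundary(b_left, -1, arm_left[-1] if arm_left else "", rng)
    b_right = _fix_boundary(b_right, 0, arm_right[0] if arm_right else "", rng)
    push(b_left)
    span_start, _ = push(core)
    push(arm_right)
    push(spacer())
    phage_gene_ids = []
    for ida, _, seq_a, _ in cand:
        s, e = push(seq_a)
        feats_a.append(GeneFeature(ida, "genomeA", "chrA", s, e, "+", cds=seq_a))
        phage_gene_ids.append(ida)
        push(spacer())
    insert_span = None
    if cfg.insert_length > 0:
        s, e = push(_random_gc_sequence(cfg.insert_length, cfg.insert_gc, rng))
        insert_span = (s, e)
        push(spacer())
    push(arm_left)
    span_end = pos  # prophage span ends just before the second core copy
    push(core)
    push(b_right)
    genome_a = GenomeRecord(
        genome_id="genomeA",
        contigs={"chrA": "".join(chr_a)},
        features=feats_a,
        metadata={"role": "donor host", "seed": cfg.seed},
    )
    genome_a.validate()
    prophage_a = ProphageRegion(
        phage_id="phageX",
        genome_id="genomeA",
        gene_ids=phage_gene_ids,
        span=("chrA", span_start, span_end),
        gene_module={g: "other" for g in phage_gene_ids},
    )

    # --- genome B: host orthologs + transferred phage + resident phages
    chr_b: list[str] = []
    feats_b: list[GeneFeature] = []
    pos_b = 0

    def push_b(seq: str) -> tuple[int, int]:
        nonlocal pos_b
        chr_b.append(seq)
        start = pos_b + 1
        pos_b += len(seq)
        return start, pos_b

    def place_genes(genes: list[tuple[str, str]]) -> None:
        for gid, seq in genes:
            push_b(spacer())
            s, e = push_b(seq)
            feats_b.append(GeneFeature(gid, "genomeB", "chrB", s, e, "+", cds=seq))

    place_genes([(idb, seq_b) for _, idb, _, seq_b in host])
    place_genes([(idb, seq_b) for _, idb, _, seq_b in cand])
    for spec_name, res in residents.items():
        place_genes([(idb, seq_b) for _, idb, seq_b in res])
    genome_b = GenomeRecord(
        genome_id="genomeB",
        contigs={"chrB": "".join(chr_b)},
        features=feats_b,
        metadata={"role": "recipient host", "seed": cfg.seed},
    )
    genome_b.validate()

    resident_ds = [p.target_ds for p in cfg.resident_phages]
    expected = (
        "recent_transfer"
        if resident_ds
        and cfg.candidate_ds <= 0.5 * min(resident_ds)
        and cfg.candidate_ds <= 1.5 * cfg.host_ds
        else "vertical_or_ancient"
    )
    truth = SimTruth(
        seed=cfg.seed,
        host_orthologs={ida: idb for ida, idb, _, _ in host},
        candidate_orthologs={ida: idb for ida, idb, _, _ in cand},
        resident_orthologs={
            name: {ida: idb for ida, idb, _ in res} for name, res in residents.items()
        },
        generating_ds={
            "host": cfg.host_ds,
            "candidate": cfg.candidate_ds,
            **{p.name: p.target_ds for p in cfg.resident_phages},
        },
        realized_ps=realized,
        insert_span=insert_span,
        att_core=core,
        att_arms=(arm_left, arm_right),
        prophage_span_a=(span_start, span_end),
        tree_newick=cfg.tree_newick,
        carriers=cfg.carriers,
        expected_label=expected,
    )
    return genome_a, genome_b, truth


def _fix_boundary(
    flank: str, idx: int, adjacent: str, rng: np.random.Generator
) -> str:
    """Force the flank base at the junction to differ from the phage-side base."""
    if not adjacent:
        return flank
    if flank[idx] != adjacent:
        return flank
    options = [b for b in "ACGT" if b != adjacent]
    chars = list(flank)
    chars[idx] = str(rng.choice(options))
    return "".join(chars)


# ---------------------------------------------------------------------------
# att fixtures
# ---------------------------------------------------------------------------


def _junction_strings(seq: str, off: int, min_len: int) -> set[str]:
    out: set[str] = set()
    for L in range(min_len, len(seq) + 1):
        for s in range(max(0, off - L), min(off, len(seq) - L) + 1):
            out.add(seq[s : s + L])
    return out


def make_att_fixture(
    core: str = "ATGA",
    flank_length: int = 60,
    arm_length: int = 0,
    arm_mismatches: int = 0,
    seed: int | np.random.Generator = 0,
    max_attempts: int = 50,
):
    """Four att junction sequences with a planted core (and optional arms).

    attB = B core B', attP = P core P', attL = B core P', attR = P core B',
    with random flanks B/B'/P/P'. The fixture guarantees an identifiable
    truth: flanks are resampled until the planted core is the unique
    longest string shared by all four sites at their junctions (random
    flanks occasionally create an equally long chance junction string, in
    which case the planted "truth" would be ambiguous). When ``arm_length``
    > 0 an inverted-repeat pair is planted in P and P' immediately around
    the core, as in attP sites that carry them.
    Returns (AttContext, truth dict).
    """
    from .attsite import AttContext

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    core = core.upper()
    if not core:
        raise ValueError("core must be non-empty")

    def flank(n: int) -> str:
        return "".join(rng.choice(list("ACGT"), size=n))

    for _ in range(max_attempts):
        B, Bp = flank(flank_length), flank(flank_length)
        P, Pp = flank(flank_length), flank(flank_length)
        arm_l = arm_r = ""
        if arm_length > 0:
            tmp_cfg = SimConfig(arm_length=arm_length, arm_mismatches=arm_mismatches)
            arm_l, arm_r = _make_arm_pair(tmp_cfg, rng)
            P = P[: -len(arm_l)] + arm_l
            Pp = arm_r + Pp[len(arm_r) :]
        # the bases flanking the core must differ between bacterial and phage
        # sides (adjust the bacterial flanks so planted arms stay intact)
        B = _fix_boundary(B, -1, P[-1], rng)
        Bp = _fix_boundary(Bp, 0, Pp[0], rng)
        off = len(B)
        ctx = AttContext(
            attL=B + core + Pp,
            attR=P + core + Bp,
            attB=B + core + Bp,
            attP=P + core + Pp,
            offsets={"attL": off, "attR": len(P), "attB": off, "attP": len(P)},
            provenance={"synthetic": True},
        )
        common = set.intersection(
            *(
                _junction_strings(s, ctx.offsets[n], len(core))
                for n, s in ctx.sequences().items()
            )
        )
        if common == {core}:
            return ctx, {
                "core": core,
                "arm_left": arm_l,
                "arm_right": arm_r,
                "core_start_attP": len(P),
            }
    raise RuntimeError(
        f"could not build an unambiguous att fixture for core {core!r} "
        f"in {max_attempts} attempts"
    )


# ---------------------------------------------------------------------------
# qPCR simulation
# ---------------------------------------------------------------------------


def simulate_qpcr(
    config: QpcrSimConfig | None = None, seed: int | np.random.Generator = 0
) -> list[QpcrRun]:
    """qPCR plates from known copy ratios.

    Standard Cts come from the curve implied by the amplification
    efficiency (slope = -1/log10(1+E)); sample Cts from true copies plus
    Gaussian Ct noise; per-plate offsets model plate effects.
    """
    cfg = config or QpcrSimConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    slope = -1.0 / math.log10(1.0 + cfg.efficiency)
    offsets = cfg.plate_offsets or [0.0] * cfg.plates
    if len(offsets) != cfg.plates:
        raise ValueError("plate_offsets length must equal the number of plates")
    genes = dict(cfg.ratios)
    genes[cfg.calibrator] = 1.0
    lo, hi = cfg.standard_log10_range
    runs: list[QpcrRun] = []
    for plate_i in range(cfg.plates):
        off = offsets[plate_i]
        std_rows = []
        for gene in genes:
            for l10 in range(lo, hi + 1):
                for _ in range(cfg.n_standard_replicates):
                    ct = cfg.intercept + slope * l10 + off
                    if cfg.ct_noise_sd > 0:
                        ct += rng.normal(0, cfg.ct_noise_sd)
                    std_rows.append(
                        {"gene": gene, "log10_copies": float(l10), "ct": ct}
                    )
        sample_rows = []
        for gene, ratio in genes.items():
            true_copies = cfg.calibrator_copies * ratio
            for rep in range(1, cfg.n_replicates + 1):
                ct = cfg.intercept + slope * math.log10(true_copies) + off
                if cfg.ct_noise_sd > 0:
                    ct += rng.normal(0, cfg.ct_noise_sd)
                sample_rows.append({"gene": gene, "replicate": rep, "ct": ct})
        runs.append(
            QpcrRun(
                plate_id=f"plate{plate_i + 1}",
                standards=pd.DataFrame(std_rows),
                samples=pd.DataFrame(sample_rows),
            )
        )
    return runs


def qpcr_runs_to_frame(runs: list[QpcrRun]) -> pd.DataFrame:
    """Flatten runs to the TSV layout (plate, gene, role, log10_copies, ct)."""
    rows = []
    for run in runs:
        for _, r in run.standards.iterrows():
            rows.append(
                {
                    "plate": run.plate_id,
                    "gene": r["gene"],
                    "role": "standard",
                    "log10_copies": r["log10_copies"],
                    "replicate": "",
                    "ct": r["ct"],
                }
            )
        for _, r in run.samples.iterrows():
            rows.append(
                {
                    "plate": run.plate_id,
                    "gene": r["gene"],
                    "role": "sample",
                    "log10_copies": "",
                    "replicate": r["replicate"],
                    "ct": r["ct"],
                }
            )
    return pd.DataFrame(rows)


def truth_to_json(truth: SimTruth) -> dict:
    d = asdict(truth)
    d["realized_ps"] = {f"{a}|{b}": v for (a, b), v in truth.realized_ps.items()}
    return d
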