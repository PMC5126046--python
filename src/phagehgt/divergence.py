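"""Nei-Gojobori (1986) synonymous/nonsynonymous divergence.

Implements the original (equal-pathway-weight) NG86 counting method with
Jukes-Cantor correction and codon-bootstrap standard errors:

* synonymous site fractions per codon, with single-base changes to stop
  codons excluded from both numerator and denominator;
* pathway-averaged synonymous/nonsynonymous difference counts per codon
  pair, excluding pathways that pass through a stop codon (when no legal
  pathway exists, the average over all pathways ignoring the stop rule is
  used and flagged);
* dS = -(3/4) ln(1 - (4/3) pS), and analogously dN; undefined (flagged)
  when the observed proportion reaches the Jukes-Cantor bound 3/4;
* variance by resampling codon columns with replacement (default 1000
  replicates), dropping and counting replicates where the statistic is
  undefined.

The synonymous rate dS is the pipeline's divergence clock: a phage pair
whose dS is far below that of the resident phages of the same genome, and
no higher than the host-gene dS, is a recent-transfer candidate.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

logger = logging.getLogger("phagehgt.divergence")

_BASES = "ACGT"
_STANDARD = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_STANDARD.stop_codons)
SENSE_CODONS = tuple(
    "".join(c) for c in itertools.product(_BASES, repeat=3)
    if "".join(c) not in STOP_CODONS
)
_AA = dict(_STANDARD.forward_table)  # sense codon -> amino acid


def translate_codon(codon: str) -> str:
    """One-letter amino acid, or '*' for a stop codon."""
    return "*" if codon in STOP_CODONS else _AA[codon]


class CodonError(ValueError):
    """Codon is not a sense codon of the genetic code in use."""


def _check_sense(codon: str) -> str:
    codon = codon.upper()
    if len(codon) != 3 or any(b not in _BASES for b in codon):
        raise CodonError(f"not an unambiguous codon: {codon!r}")
    if codon in STOP_CODONS:
        raise CodonError(f"stop codon not admissible: {codon}")
    return codon


@lru_cache(maxsize=None)
def synonymous_site_fractions(codon: str) -> tuple[float, float]:
    """(s, n) synonymous/nonsynonymous site counts for one codon.

    s sums, over the three positions, the fraction of admissible (non-stop)
    single-base changes that are synonymous; n = 3 - s.
    """
    codon = _check_sense(codon)
    aa = translate_codon(codon)
    s = 0.0
    for pos in range(3):
        syn = 0
        admissible = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if mut in STOP_CODONS:
                continue  # changes to stops excluded from numerator and denominator
            admissible += 1
            if translate_codon(mut) == aa:
                syn += 1
        if admissible:
            s += syn / admissible
    return s, 3.0 - s


@lru_cache(maxsize=None)
def pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float, bool]:
    """Pathway-averaged (sd, nd) between two sense codons.

    Averages synonymous/nonsynonymous step counts over all orderings of the
    differing positions, excluding pathways through stop codons. The third
    element is True when no stop-free pathway existed and the average was
    taken over all pathways ignoring the stop rule (logged once per pair).
    """
    a = _check_sense(codon_a)
    b = _check_sense(codon_b)
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0, False

    def walk(order: tuple[int, ...], allow_stops: bool):
        cur = a
        sd = nd = 0
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS and not allow_stops:
                return None
            if nxt in STOP_CODONS:
                # treat a stop intermediate as nonsynonymous in the fallback
                nd += 1
            elif translate_codon(nxt) == translate_codon(cur) and cur not in STOP_CODONS:
                sd += 1
            else:
                nd += 1
            cur = nxt
        return sd, nd

    legal = [r for r in (walk(o, False) for o in itertools.permutations(diff)) if r]
    fallback = not legal
    if fallback:
        logger.info(
            "pathway_differences(%s, %s): all pathways pass through stops; "
            "averaging over all orderings ignoring the stop exclusion",
            a,
            b,
        )
        legal = [walk(o, True) for o in itertools.permutations(diff)]
    sd = float(np.mean([x[0] for x in legal]))
    nd = float(np.mean([x[1] for x in legal]))
    return sd, nd, fallback


# ---------------------------------------------------------------------------
# Codon alignments and the NG86 estimate
# ---------------------------------------------------------------------------


@dataclass
class CodonAlignment:
    """Paired codon columns; gapped/ambiguous/stop columns removed on build."""

    id_a: str
    id_b: str
    columns: list[tuple[str, str]]
    n_dropped_gap: int = 0
    n_dropped_ambiguous: int = 0
    n_dropped_stop: int = 0

    @classmethod
    def from_pair(
        cls, cds_a: str, cds_b: str, id_a: str = "a", id_b: str = "b"
    ) -> "CodonAlignment":
        """Build from two aligned coding sequences of equal length.

        The inputs may contain gaps ('-'); columns are taken as consecutive
        triplets of alignment columns, so frames stay aligned when gap runs
        have lengths that are multiples of 3 (true for the pure-substitution
        generator in this package; see the methods note for the limitation).
        """
        a, b = cds_a.upper(), cds_b.upper()
        if len(a) != len(b):
            raise ValueError("aligned coding sequences must have equal length")
        cols: list[tuple[str, str]] = []
        ngap = nambig = nstop = 0
        usable = 3 * (len(a) // 3)
        for i in range(0, usable, 3):
            ca, cb = a[i : i + 3], b[i : i + 3]
            if "-" in ca or "-" in cb:
                ngap += 1
                continue
            if any(x not in _BASES for x in ca + cb):
                nambig += 1
                continue
            if ca in STOP_CODONS or cb in STOP_CODONS:
                nstop += 1
                continue
            cols.append((ca, cb))
        return cls(
            id_a=id_a,
            id_b=id_b,
            columns=cols,
            n_dropped_gap=ngap,
            n_dropped_ambiguous=nambig,
            n_dropped_stop=nstop,
        )

    def __len__(self) -> int:
        return len(self.columns)


@dataclass
class NGResult:
    """NG86 site counts, proportions, Jukes-Cantor rates, bootstrap SEs."""

    id_a: str
    id_b: str
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float  # NaN when flagged undefined
    dN: float
    se_dS: float = float("nan")
    se_dN: float = float("nan")
    n_reps: int = 0
    seed: int | None = None
    n_codons: int = 0
    dS_undefined: bool = False
    dN_undefined: bool = False
    n_pathway_fallback: int = 0
    n_boot_undefined: int = 0
    flags: list[str] = field(default_factory=list)


def _jc_correct(p: float) -> tuple[float, bool]:
    if p >= 0.75:
        return float("nan"), True
    return -0.75 * np.log1p(-(4.0 / 3.0) * p), False


def _column_arrays(aln: CodonAlignment) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Per-column (mean site count, sd, nd) arrays plus pathway-fallback count."""
    m = len(aln)
    s_bar = np.empty(m)
    sd = np.empty(m)
    nd = np.empty(m)
    n_fallback = 0
    for i, (ca, cb) in enumerate(aln.columns):
        sa, _ = synonymous_site_fractions(ca)
        sb, _ = synonymous_site_fractions(cb)
        s_bar[i] = 0.5 * (sa + sb)
        sd[i], nd[i], fb = pathway_differences(ca, cb)
        n_fallback += fb
    return s_bar, sd, nd, n_fallback


def ng86(
    aln: CodonAlignment,
    bootstrap_reps: int = 0,
    seed: int | None = None,
) -> NGResult:
    """NG86 estimate for one codon alignment.

    S and N are means of the two sequences' per-site sums; Sd and Nd sum the
    pathway-averaged differences over columns. With ``bootstrap_reps`` > 0,
    codon columns are resampled with replacement to give standard errors.
    """
    if len(aln) == 0:
        raise ValueError("ng86 requires at least one retained codon column")
    s_bar, sd, nd, n_fallback = _column_arrays(aln)
    m = len(aln)
    S = float(s_bar.sum())
    N = 3.0 * m - S
    Sd = float(sd.sum())
    Nd = float(nd.sum())
    pS = Sd / S if S > 0 else float("nan")
    pN = Nd / N if N > 0 else float("nan")
    dS, ds_undef = _jc_correct(pS) if S > 0 else (float("nan"), True)
    dN, dn_undef = _jc_correct(pN) if N > 0 else (float("nan"), True)
    flags = []
    if ds_undef:
        flags.append("dS_undefined")
        logger.warning(
            "ng86(%s, %s): pS=%.3f >= 3/4, dS undefined (Jukes-Cantor domain)",
            aln.id_a, aln.id_b, pS,
        )
    if dn_undef:
        flags.append("dN_undefined")
    res = NGResult(
        id_a=aln.id_a,
        id_b=aln.id_b,
        S=S,
        N=N,
        Sd=Sd,
        Nd=Nd,
        pS=pS,
        pN=pN,
        dS=dS,
        dN=dN,
        n_codons=m,
        dS_undefined=ds_undef,
        dN_undefined=dn_undef,
        n_pathway_fallback=n_fallback,
        flags=flags,
    )
    if bootstrap_reps > 0:
        se_ds, se_dn, n_undef = _bootstrap(
            s_bar, sd, nd, n_reps=bootstrap_reps, seed=seed
        )
        res.se_dS = se_ds
        res.se_dN = se_dn
        res.n_reps = bootstrap_reps
        res.seed = seed
        res.n_boot_undefined = n_undef
        if n_undef > bootstrap_reps / 2:
            res.flags.append("bootstrap_majority_undefined")
    return res


def _bootstrap(
    s_bar: np.ndarray,
    sd: np.ndarray,
    nd: np.ndarray,
    n_reps: int,
    seed: int | None,
) -> tuple[float, float, int]:
    m = len(s_bar)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, m, size=(n_reps, m))
    S = s_bar[idx].sum(axis=1)
    N = 3.0 * m - S
    Sd = sd[idx].sum(axis=1)
    Nd = nd[idx].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        pS = np.where(S > 0, Sd / S, np.nan)
        pN = np.where(N > 0, Nd / N, np.nan)
        dS = np.where(pS < 0.75, -0.75 * np.log1p(-(4.0 / 3.0) * np.minimum(pS, 0.749999)), np.nan)
        dN = np.where(pN < 0.75, -0.75 * np.log1p(-(4.0 / 3.0) * np.minimum(pN, 0.749999)), np.nan)
    n_undef = int(np.isnan(dS).sum())
    ds_ok = dS[~np.isnan(dS)]
    dn_ok = dN[~np.isnan(dN)]
    se_ds = float(np.std(ds_ok, ddof=1)) if len(ds_ok) > 1 else float("nan")
    se_dn = float(np.std(dn_ok, ddof=1)) if len(dn_ok) > 1 else float("nan")
    return se_ds, se_dn, n_undef


def bootstrap_se(
    aln: CodonAlignment,
    statistic: str = "dS",
    n_reps: int = 1000,
    seed: int | None = None,
) -> tuple[float, int]:
    """Codon-bootstrap standard error of dS or dN.

    Returns (SE, number of undefined replicates). Replicates where the
    statistic is undefined (saturation) are dropped; if more than half are
    undefined the SE is flagged with a warning.
    """
    if len(aln) < 2:
        raise ValueError("bootstrap requires at least 2 codon columns")
    if statistic not in {"dS", "dN"}:
        raise ValueError("statistic must be 'dS' or 'dN'")
    s_bar, sd, nd, _ = _column_arrays(aln)
    se_ds, se_dn, n_undef = _bootstrap(s_bar, sd, nd, n_reps=n_reps, seed=seed)
    if n_undef > n_reps / 2:
        logger.warning(
            "bootstrap_se(%s, %s): %d/%d replicates undefined; SE flagged",
            aln.id_a, aln.id_b, n_undef, n_reps,
        )
    return (se_ds if statistic == "dS" else se_dn), n_undef
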