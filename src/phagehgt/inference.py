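"""The statistical spine of the transfer screen.

Combines four strands of evidence into a transfer verdict for a candidate
phage pair (phage X resident in genome A, its putative transferred copy in
genome B):

1. Mann-Whitney U comparisons of percent-identity (and dS) distributions
   among three gene groups: the candidate pair, the candidate versus the
   other (resident) phages of genome B, and host orthologs of A and B. A
   recently transferred phage is *more* similar to its counterpart than
   resident phages are, and no less similar than the host background.
2. Dollo loss counting on a host phylogeny: under vertical descent (single
   gain at the carriers' MRCA), the number of independent losses required to
   explain the carrier pattern; transfers are favoured when that count is
   implausibly high.
3. qPCR copy-ratio tests: standard-curve quantification of phage vs host
   single-copy genes, plate-effect normalization by a calibrator gene, and a
   one-sample two-tailed t-test of the per-replicate ratio against the
   single-lysogen expectation of 1.
4. The verdict classifier: a pure function of the recorded statistics and
   configurable thresholds (defaults: separation p < 0.01, loss count >= 2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from . import divergence, seqcompare
from .io import read_table

logger = logging.getLogger("phagehgt.inference")


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------


@dataclass
class GroupComparison:
    n1: int
    n2: int
    u: float
    p_two_tailed: float
    method: str  # "exact" | "normal_approx"
    tie_correction: bool
    alternative: str = "two-sided"


def mann_whitney_u(
    g1: Sequence[float],
    g2: Sequence[float],
    mode: str = "auto",
    alternative: str = "two-sided",
) -> GroupComparison:
    """Mann-Whitney U with midranks for ties.

    ``auto`` uses the exact null distribution when n1+n2 <= 20 and there are
    no ties, otherwise the normal approximation with tie-corrected variance
    and continuity correction. U is reported for the first group.
    """
    x = np.asarray(g1, dtype=float)
    y = np.asarray(g2, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if mode == "auto":
        use_exact = (len(x) + len(y) <= 20) and not has_ties
    elif mode == "exact":
        if has_ties:
            raise ValueError("exact Mann-Whitney U is undefined with ties")
        use_exact = True
    elif mode == "normal":
        use_exact = False
    else:
        raise ValueError(f"unknown mode {mode!r}")
    res = stats.mannwhitneyu(
        x,
        y,
        alternative=alternative,
        method="exact" if use_exact else "asymptotic",
        use_continuity=True,
    )
    return GroupComparison(
        n1=len(x),
        n2=len(y),
        u=float(res.statistic),
        p_two_tailed=float(min(res.pvalue, 1.0)),
        method="exact" if use_exact else "normal_approx",
        tie_correction=(not use_exact) and has_ties,
        alternative=alternative,
    )


# ---------------------------------------------------------------------------
# Dollo loss counting
# ---------------------------------------------------------------------------


@dataclass
class PresenceTree:
    """A rooted host phylogeny plus the set of leaves carrying the phage."""

    tree: dendropy.Tree
    carriers: frozenset[str]

    @classmethod
    def from_newick(cls, newick: str, carriers: Sequence[str]) -> "PresenceTree":
        src = str(newick)
        if "(" not in src and Path(src).exists():
            tree = dendropy.Tree.get(path=src, schema="newick")
        else:
            tree = dendropy.Tree.get(data=src, schema="newick")
        tree.is_rooted = True
        leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
        missing = set(carriers) - leaves
        if missing:
            raise ValueError(f"carriers not in tree: {sorted(missing)}")
        return cls(tree=tree, carriers=frozenset(carriers))


def dollo_losses(ptree: PresenceTree) -> int:
    """Minimum independent losses under Dollo parsimony (single gain).

    Assuming one gain on the branch above the MRCA of all carriers, returns
    the number of maximal carrier-free subtrees inside the MRCA clade.
    """
    carriers = ptree.carriers
    if not carriers:
        raise ValueError("at least one carrier required")

    def has_carrier(node) -> bool:
        return any(
            lf.taxon.label in carriers for lf in node.leaf_iter()
        )

    if len(carriers) == 1:
        return 0
    mrca = ptree.tree.mrca(taxon_labels=list(carriers))
    losses = 0
    stack = [mrca]
    while stack:
        node = stack.pop()
        for child in node.child_nodes():
            if has_carrier(child):
                stack.append(child)
            else:
                losses += 1
    return losses


# ---------------------------------------------------------------------------
# qPCR: standard curves, copy ratios, plate normalization
# ---------------------------------------------------------------------------


@dataclass
class StandardCurve:
    slope: float
    intercept: float
    efficiency: float  # 1.0 == 100%
    r_squared: float

    def copies(self, ct: float | np.ndarray) -> float | np.ndarray:
        return 10.0 ** ((np.asarray(ct) - self.intercept) / self.slope)


@dataclass
class QpcrRun:
    """One qPCR plate: standard-series points and sample Cts.

    ``standards``: DataFrame(gene, log10_copies, ct);
    ``samples``: DataFrame(gene, replicate, ct).
    """

    plate_id: str
    standards: pd.DataFrame
    samples: pd.DataFrame


@dataclass
class CopyRatio:
    numerator: str
    denominator: str
    ratio_mean: float
    ratio_sd: float
    n: int
    t_statistic: float
    p_two_tailed: float
    expected: float = 1.0


def fit_standard_curve(points) -> StandardCurve:
    """Least-squares Ct = slope * log10(copies) + intercept.

    ``points`` is an iterable of (log10_copies, Ct) or a DataFrame with
    columns log10_copies, ct. Efficiency = 10^(-1/slope) - 1; a non-negative
    slope is an invalid curve.
    """
    if isinstance(points, pd.DataFrame):
        x = points["log10_copies"].to_numpy(dtype=float)
        y = points["ct"].to_numpy(dtype=float)
    else:
        arr = np.asarray(list(points), dtype=float)
        x, y = arr[:, 0], arr[:, 1]
    if len(x) < 3:
        raise ValueError("standard curve requires >= 3 points")
    if np.ptp(x) < 2.0:
        logger.warning(
            "standard curve spans only %.2f log10 units (< 2 recommended)", np.ptp(x)
        )
    res = stats.linregress(x, y)
    if res.slope >= 0:
        raise ValueError(f"invalid standard curve: slope {res.slope:.3f} >= 0")
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        efficiency=float(10.0 ** (-1.0 / res.slope) - 1.0),
        r_squared=float(res.rvalue**2),
    )


def copy_ratio_test(
    copies_num: Sequence[float],
    copies_den: Sequence[float],
    expected: float = 1.0,
    numerator: str = "num",
    denominator: str = "den",
) -> CopyRatio:
    """Per-replicate ratio and one-sample two-tailed t-test versus ``expected``.

    Replicates with zero denominator copies are dropped and logged; at least
    two usable replicates are required.
    """
    num = np.asarray(copies_num, dtype=float)
    den = np.asarray(copies_den, dtype=float)
    if len(num) != len(den):
        raise ValueError("numerator and denominator replicates must be paired")
    keep = den > 0
    if (~keep).any():
        logger.warning(
            "copy_ratio_test(%s:%s): dropped %d replicate(s) with zero "
            "denominator copies",
            numerator,
            denominator,
            int((~keep).sum()),
        )
    ratios = num[keep] / den[keep]
    if len(ratios) < 2:
        raise ValueError("copy-ratio test requires >= 2 usable replicates")
    sd = float(ratios.std(ddof=1))
    if sd == 0.0:
        # degenerate: no variance among replicates
        t_stat = 0.0 if ratios[0] == expected else float("inf")
        p = 1.0 if ratios[0] == expected else 0.0
    else:
        t = stats.ttest_1samp(ratios, expected)
        t_stat, p = float(t.statistic), float(t.pvalue)
    return CopyRatio(
        numerator=numerator,
        denominator=denominator,
        ratio_mean=float(ratios.mean()),
        ratio_sd=sd,
        n=len(ratios),
        t_statistic=t_stat,
        p_two_tailed=p,
        expected=expected,
    )


def read_qpcr_table(path) -> list[QpcrRun]:
    """Read a qPCR TSV (columns plate, gene, role, log10_copies, ct)."""
    df = read_table(path, required=("plate", "gene", "role", "ct"))
    runs = []
    for plate, sub in df.groupby("plate", sort=True):
        std = sub[sub["role"] == "standard"]
        if len(std) and "log10_copies" not in sub.columns:
            raise ValueError("standard rows require a log10_copies column")
        samples = sub[sub["role"] == "sample"].copy()
        if "replicate" not in samples.columns:
            samples["replicate"] = range(1, len(samples) + 1)
        runs.append(
            QpcrRun(
                plate_id=str(plate),
                standards=std[["gene", "log10_copies", "ct"]].reset_index(drop=True)
                if len(std)
                else pd.DataFrame(columns=["gene", "log10_copies", "ct"]),
                samples=samples[["gene", "replicate", "ct"]].reset_index(drop=True),
            )
        )
    return runs


def normalize_plate_effects(
    copies: pd.DataFrame, calibrator: str
) -> pd.DataFrame:
    """Scale each plate so its calibrator mean equals the cross-plate mean.

    ``copies`` has columns plate, gene, replicate, copies. The calibrator
    must be measured on every plate.
    """
    df = copies.copy()
    cal = df[df["gene"] == calibrator]
    plates = df["plate"].unique()
    missing = set(plates) - set(cal["plate"].unique())
    if missing:
        raise ValueError(f"calibrator {calibrator!r} absent from plates {sorted(missing)}")
    grand = cal["copies"].mean()
    plate_means = cal.groupby("plate")["copies"].mean()
    factors = grand / plate_means
    df["copies"] = df["copies"] * df["plate"].map(factors)
    return df


def analyze_qpcr_runs(
    runs: list[QpcrRun],
    calibrator: str = "groEL",
    expected: float = 1.0,
) -> tuple[dict[str, CopyRatio], dict[tuple[str, str], StandardCurve]]:
    """Standard-curve quantification and copy-ratio tests versus a calibrator.

    Fits a curve per (plate, gene), converts sample Cts to absolute copies,
    removes plate effects via the calibrator, then tests each gene's
    per-replicate ratio to the calibrator against ``expected``.
    """
    curves: dict[tuple[str, str], StandardCurve] = {}
    rows = []
    for run in runs:
        for gene, std in run.standards.groupby("gene"):
            curves[(run.plate_id, gene)] = fit_standard_curve(std)
        for _, row in run.samples.iterrows():
            curve = curves.get((run.plate_id, row["gene"]))
            if curve is None:
                raise ValueError(
                    f"no standard curve for gene {row['gene']!r} on plate {run.plate_id}"
                )
            rows.append(
                {
                    "plate": run.plate_id,
                    "gene": row["gene"],
                    "replicate": row["replicate"],
                    "copies": float(curve.copies(row["ct"])),
                }
            )
    copies = normalize_plate_effects(pd.DataFrame(rows), calibrator)
    ratios: dict[str, CopyRatio] = {}
    cal = copies[copies["gene"] == calibrator].set_index(["plate", "replicate"])[
        "copies"
    ]
    for gene, sub in copies[copies["gene"] != calibrator].groupby("gene"):
        sub = sub.set_index(["plate", "replicate"])
        common = sub.index.intersection(cal.index)
        ratios[gene] = copy_ratio_test(
            sub.loc[common, "copies"].to_numpy(),
            cal.loc[common].to_numpy(),
            expected=expected,
            numerator=gene,
            denominator=calibrator,
        )
    return ratios, curves


# ---------------------------------------------------------------------------
# Evidence assembly and the transfer verdict
# ---------------------------------------------------------------------------


@dataclass
class VerdictConfig:
    p_separation: float = 0.01  # candidate vs resident identity (two-tailed)
    p_not_lower: float = 0.05  # candidate vs host identity ("less" alternative)
    min_losses: int = 2  # parsimony bar when a tree is supplied


@dataclass
class TransferEvidence:
    """Per-group summaries feeding the verdict classifier."""

    candidate_identity: np.ndarray
    resident_identity: np.ndarray
    host_identity: np.ndarray
    candidate_ds: np.ndarray
    resident_ds: np.ndarray
    host_ds: np.ndarray
    tree: Optional[PresenceTree] = None
    candidate_label: str = "candidate"


@dataclass
class TransferVerdict:
    label: str  # recent_transfer | vertical_or_ancient | indeterminate
    statistics: dict
    reason: str = ""
    evidence: Optional[TransferEvidence] = None


def summarize_gene_pairs(
    pairs: Sequence[tuple[str, str]],
    ids: Sequence[tuple[str, str]] | None = None,
    trim: bool = True,
    params: seqcompare.AlignParams = seqcompare.DEFAULT_PARAMS,
) -> pd.DataFrame:
    """Identity and NG86 dS for a list of (cds_a, cds_b) gene pairs.

    Each pair is globally aligned, optionally trimmed, then scored for
    percent identity and NG86 dS. Gene pairs are treated as independent
    observations downstream (gene-level non-independence is flagged in the
    verdict record, not corrected).
    """
    rows = []
    ids = ids or [(f"a{i}", f"b{i}") for i in range(len(pairs))]
    for (sa, sb), (ia, ib) in zip(pairs, ids):
        aln = seqcompare.global_align(sa, sb, params=params, id_a=ia, id_b=ib)
        if trim:
            aln = seqcompare.trim_conserved_blocks(aln)
        if len(aln) == 0:
            rows.append({"gene_a": ia, "gene_b": ib, "identity": np.nan, "dS": np.nan})
            continue
        ident = seqcompare.percent_identity(aln)
        caln = divergence.CodonAlignment.from_pair(
            aln.aligned_a, aln.aligned_b, id_a=ia, id_b=ib
        )
        ds = divergence.ng86(caln).dS if len(caln) else np.nan
        rows.append({"gene_a": ia, "gene_b": ib, "identity": ident, "dS": ds})
    return pd.DataFrame(rows)


def classify_transfer(
    evidence: TransferEvidence, config: VerdictConfig | None = None
) -> TransferVerdict:
    """Label a candidate pair from the recorded statistics.

    recent_transfer iff (i) candidate-pair identity significantly exceeds
    candidate-vs-resident identity (MWU two-tailed p < p_separation with the
    candidate median higher), AND (ii) candidate identity is not
    significantly lower than host-ortholog identity (one-sided MWU p >=
    p_not_lower) or mean candidate dS <= mean host dS, AND (iii) the Dollo
    loss count >= min_losses when a tree is supplied. vertical_or_ancient
    iff (i) fails; otherwise indeterminate. Pure function of the evidence.
    """
    config = config or VerdictConfig()
    groups = {
        "candidate": np.asarray(evidence.candidate_identity, dtype=float),
        "resident": np.asarray(evidence.resident_identity, dtype=float),
        "host": np.asarray(evidence.host_identity, dtype=float),
    }
    groups = {k: v[~np.isnan(v)] for k, v in groups.items()}
    for name, vals in groups.items():
        if len(vals) == 0:
            return TransferVerdict(
                label="indeterminate",
                statistics={},
                reason=f"missing {name} gene group",
                evidence=evidence,
            )
    cand, res, host = groups["candidate"], groups["resident"], groups["host"]
    mwu_cr = mann_whitney_u(cand, res)
    mwu_ch_less = mann_whitney_u(cand, host, alternative="less")
    cand_ds = np.asarray(evidence.candidate_ds, dtype=float)
    host_ds = np.asarray(evidence.host_ds, dtype=float)
    res_ds = np.asarray(evidence.resident_ds, dtype=float)
    mean_cand_ds = float(np.nanmean(cand_ds)) if len(cand_ds) else np.nan
    mean_host_ds = float(np.nanmean(host_ds)) if len(host_ds) else np.nan
    loss_count = dollo_losses(evidence.tree) if evidence.tree is not None else None

    stats_rec = {
        "mean_identity": {k: float(v.mean()) for k, v in groups.items()},
        "mean_dS": {
            "candidate": mean_cand_ds,
            "resident": float(np.nanmean(res_ds)) if len(res_ds) else np.nan,
            "host": mean_host_ds,
        },
        "n": {k: int(len(v)) for k, v in groups.items()},
        "mwu_candidate_vs_resident": vars(mwu_cr),
        "mwu_candidate_vs_host_less": vars(mwu_ch_less),
        "loss_count": loss_count,
        "note": "gene-level observations may be non-independent (shared phylogeny)",
    }

    separated = (
        mwu_cr.p_two_tailed < config.p_separation
        and float(np.median(cand)) > float(np.median(res))
    )
    if not separated:
        return TransferVerdict(
            label="vertical_or_ancient",
            statistics=stats_rec,
            reason="candidate-pair identity not significantly above resident phages",
            evidence=evidence,
        )
    not_lower_than_host = mwu_ch_less.p_two_tailed >= config.p_not_lower or (
        not np.isnan(mean_cand_ds)
        and not np.isnan(mean_host_ds)
        and mean_cand_ds <= mean_host_ds
    )
    losses_ok = loss_count is None or loss_count >= config.min_losses
    if not_lower_than_host and losses_ok:
        return TransferVerdict(
            label="recent_transfer", statistics=stats_rec, evidence=evidence
        )
    reason = (
        "candidate identity significantly below host orthologs"
        if not not_lower_than_host
        else f"loss count {loss_count} below parsimony bar {config.min_losses}"
    )
    return TransferVerdict(
        label="indeterminate", statistics=stats_rec, reason=reason, evidence=evidence
    )


def evaluate_transfer(
    candidate_genes: dict[str, str],
    phage_sets_b: dict[str, dict[str, str]],
    host_genes_a: dict[str, str],
    host_genes_b: dict[str, str],
    transferred_phage: str,
    tree: Optional[PresenceTree] = None,
    config: VerdictConfig | None = None,
    min_identity: float = 50.0,
) -> TransferVerdict:
    """End-to-end evidence assembly for one candidate phage.

    Orthologs are paired (reciprocal best hit) between the candidate phage's
    genes and each phage gene set of genome B, and between the two host gene
    sets; identity/dS summaries of the three groups feed the classifier.
    """

    def group_frame(genes_b: dict[str, str]) -> pd.DataFrame:
        pairs, _, _ = seqcompare.pair_orthologs(
            candidate_genes, genes_b, min_identity=min_identity
        )
        seqs = [(candidate_genes[p.gene_a], genes_b[p.gene_b]) for p in pairs]
        return summarize_gene_pairs(seqs, ids=[(p.gene_a, p.gene_b) for p in pairs])

    cand_df = group_frame(phage_sets_b[transferred_phage])
    res_frames = [
        group_frame(genes)
        for name, genes in phage_sets_b.items()
        if name != transferred_phage
    ]
    res_df = (
        pd.concat(res_frames, ignore_index=True)
        if res_frames
        else pd.DataFrame(columns=["identity", "dS"])
    )
    host_pairs, _, _ = seqcompare.pair_orthologs(
        host_genes_a, host_genes_b, min_identity=min_identity
    )
    host_df = summarize_gene_pairs(
        [(host_genes_a[p.gene_a], host_genes_b[p.gene_b]) for p in host_pairs],
        ids=[(p.gene_a, p.gene_b) for p in host_pairs],
    )
    evidence = TransferEvidence(
        candidate_identity=cand_df["identity"].to_numpy(),
        resident_identity=res_df["identity"].to_numpy(),
        host_identity=host_df["identity"].to_numpy(),
        candidate_ds=cand_df["dS"].to_numpy(),
        resident_ds=res_df["dS"].to_numpy(),
        host_ds=host_df["dS"].to_numpy(),
        tree=tree,
        candidate_label=transferred_phage,
    )
    return classify_transfer(evidence, config=config)
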