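"""Genome/feature data model and readers/writers for external formats.

Coordinates are 1-based inclusive throughout (GenBank convention); GFF3 input,
which is already 1-based inclusive, is taken as-is, and minus-strand CDSs are
stored reverse-complemented so that ``cds`` is always the coding strand.

Pseudogenes and features whose CDS is not a clean open reading frame (length
not divisible by 3, internal stop codons, ambiguous codons) are retained in
the data model but excluded from codon-level analysis, with the reason logged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger("phagehgt.io")

STOP_CODONS = {"TAA", "TAG", "TGA"}
_UNAMBIGUOUS = set("ACGT")


class GenomeValidationError(ValueError):
    """A feature or record violates the genome data-model invariants."""


class TableSchemaError(ValueError):
    """A tabular input is missing required columns."""


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass
class GeneFeature:
    """An annotated coding gene.

    ``start``/``end`` are 1-based inclusive on the contig; ``cds`` is the
    nucleotide sequence on the coding strand (reverse-complemented for '-').
    """

    feature_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    product: str = ""
    cds: str = ""
    is_pseudo: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise GenomeValidationError(
                f"feature {self.feature_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in {"+", "-"}:
            raise GenomeValidationError(
                f"feature {self.feature_id}: strand must be '+' or '-', got {self.strand!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def codon_admissible(self, allow_pseudo: bool = False) -> tuple[bool, str]:
        """Whether this feature may enter codon (dS/dN) analysis.

        Returns (ok, reason); reason is empty when admissible.
        """
        if self.is_pseudo and not allow_pseudo:
            return False, "pseudogene"
        cds = self.cds.upper()
        if not cds:
            return False, "no CDS sequence"
        if len(cds) % 3 != 0:
            return False, f"CDS length {len(cds)} not divisible by 3"
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        internal = codons[:-1]
        if any(c in STOP_CODONS for c in internal):
            return False, "internal stop codon"
        return True, ""


@dataclass
class GenomeRecord:
    """A genome: contig sequences plus annotated features."""

    genome_id: str
    contigs: dict[str, str]
    features: list[GeneFeature] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def validate(self) -> None:
        seen: set[str] = set()
        for f in self.features:
            if f.feature_id in seen:
                raise GenomeValidationError(
                    f"duplicate feature_id {f.feature_id} in genome {self.genome_id}"
                )
            seen.add(f.feature_id)
            if f.contig_id not in self.contigs:
                raise GenomeValidationError(
                    f"feature {f.feature_id}: unknown contig {f.contig_id}"
                )
            if f.end > len(self.contigs[f.contig_id]) or f.start < 1:
                raise GenomeValidationError(
                    f"feature {f.feature_id}: span ({f.start}, {f.end}) outside "
                    f"contig {f.contig_id} of length {len(self.contigs[f.contig_id])}"
                )

    def feature(self, feature_id: str) -> GeneFeature:
        for f in self.features:
            if f.feature_id == feature_id:
                return f
        raise KeyError(feature_id)

    def coding_features(self, allow_pseudo: bool = False) -> list[GeneFeature]:
        """Features admissible to codon analysis; exclusions are logged."""
        kept = []
        for f in self.features:
            ok, reason = f.codon_admissible(allow_pseudo=allow_pseudo)
            if ok:
                kept.append(f)
            else:
                logger.info(
                    "genome %s: feature %s excluded from codon analysis (%s)",
                    self.genome_id,
                    f.feature_id,
                    reason,
                )
        return kept


@dataclass
class ProphageRegion:
    """An ordered, module-labelled gene list delimiting a prophage."""

    phage_id: str
    genome_id: str
    gene_ids: list[str]
    span: tuple[str, int, int]  # (contig_id, start, end), 1-based inclusive
    gene_module: dict[str, str] = field(default_factory=dict)

    def validate(self, genome: GenomeRecord) -> None:
        contig, start, end = self.span
        feats = [genome.feature(g) for g in self.gene_ids]
        starts = [f.start for f in feats]
        if starts != sorted(starts):
            raise GenomeValidationError(
                f"prophage {self.phage_id}: gene_ids not sorted by start coordinate"
            )
        for f in feats:
            if f.contig_id != contig or f.start < start or f.end > end:
                raise GenomeValidationError(
                    f"prophage {self.phage_id}: gene {f.feature_id} outside span"
                )


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_genome(
    path: str | Path,
    format: str = "genbank",
    gff3: str | Path | None = None,
    genome_id: str | None = None,
) -> GenomeRecord:
    """Read an annotated genome.

    ``format`` is ``"genbank"`` (flat file with CDS features) or
    ``"fasta+gff3"`` (``path`` is the FASTA; ``gff3`` names the annotation).
    All CDS features carry coding-strand sequence; coordinates are normalized
    to 1-based inclusive.
    """
    path = Path(path)
    if format == "genbank":
        return _read_genbank(path, genome_id)
    if format == "fasta+gff3":
        if gff3 is None:
            raise ValueError("fasta+gff3 format requires the gff3= argument")
        return _read_fasta_gff3(path, Path(gff3), genome_id)
    raise ValueError(f"unknown genome format {format!r}")


def _read_genbank(path: Path, genome_id: str | None) -> GenomeRecord:
    contigs: dict[str, str] = {}
    features: list[GeneFeature] = []
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # Biopython raises bare ValueError on bad records
        raise GenomeValidationError(f"cannot parse GenBank file {path}: {exc}") from exc
    if not records:
        raise GenomeValidationError(f"no records in GenBank file {path}")
    gid = genome_id or records[0].id
    for rec in records:
        contigs[rec.id] = str(rec.seq).upper()
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            q = feat.qualifiers
            fid = q.get("locus_tag", q.get("gene", [f"{rec.id}_{len(features)+1}"]))[0]
            strand = "-" if feat.location.strand == -1 else "+"
            start = int(feat.location.start) + 1  # Biopython is 0-based half-open
            end = int(feat.location.end)
            cds = str(feat.extract(rec.seq)).upper()
            features.append(
                GeneFeature(
                    feature_id=fid,
                    genome_id=gid,
                    contig_id=rec.id,
                    start=start,
                    end=end,
                    strand=strand,
                    product=q.get("product", [""])[0],
                    cds=cds,
                    is_pseudo="pseudo" in q or "pseudogene" in q,
                )
            )
    genome = GenomeRecord(genome_id=gid, contigs=contigs, features=features)
    genome.validate()
    return genome


def _read_fasta_gff3(fasta: Path, gff3: Path, genome_id: str | None) -> GenomeRecord:
    import gffutils

    contigs = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")
    }
    if not contigs:
        raise GenomeValidationError(f"no sequences in FASTA file {fasta}")
    gid = genome_id or fasta.stem
    try:
        db = gffutils.create_db(
            str(gff3),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:
        raise GenomeValidationError(f"cannot parse GFF3 file {gff3}: {exc}") from exc
    features: list[GeneFeature] = []
    for feat in db.features_of_type("CDS", order_by="start"):
        if feat.seqid not in contigs:
            raise GenomeValidationError(
                f"GFF3 feature {feat.id} on unknown contig {feat.seqid}"
            )
        fid = feat.attributes.get("ID", [feat.id or f"cds{len(features)+1}"])[0]
        strand = feat.strand if feat.strand in {"+", "-"} else "+"
        raw = contigs[feat.seqid][feat.start - 1 : feat.end]
        cds = reverse_complement(raw) if strand == "-" else raw
        pseudo = "pseudo" in feat.attributes or (
            feat.attributes.get("pseudo", ["false"])[0].lower() == "true"
        )
        features.append(
            GeneFeature(
                feature_id=fid,
                genome_id=gid,
                contig_id=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=strand,
                product=feat.attributes.get("product", [""])[0],
                cds=cds,
                is_pseudo=pseudo,
            )
        )
    genome = GenomeRecord(genome_id=gid, contigs=contigs, features=features)
    genome.validate()
    return genome


def extract_region(genome: GenomeRecord, span: tuple[str, int, int]) -> str:
    """Slice a contig, 1-based inclusive ends."""
    contig_id, start, end = span
    if contig_id not in genome.contigs:
        raise GenomeValidationError(f"unknown contig {contig_id}")
    contig = genome.contigs[contig_id]
    if start < 1 or end > len(contig) or start > end:
        raise GenomeValidationError(
            f"span ({start}, {end}) out of range for contig {contig_id} "
            f"of length {len(contig)}"
        )
    return contig[start - 1 : end]


# ---------------------------------------------------------------------------
# Writers / tables
# ---------------------------------------------------------------------------


def write_genome(
    genome: GenomeRecord, fasta_path: str | Path, gff3_path: str | Path
) -> None:
    """Write a genome as FASTA + GFF3 (round-trips through read_genome)."""
    with open(fasta_path, "w") as fh:
        for cid, seq in genome.contigs.items():
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for cid, seq in genome.contigs.items():
            fh.write(f"##sequence-region {cid} 1 {len(seq)}\n")
        for f in genome.features:
            attrs = [f"ID={f.feature_id}"]
            if f.product:
                attrs.append(f"product={f.product}")
            if f.is_pseudo:
                attrs.append("pseudo=true")
            fh.write(
                "\t".join(
                    [
                        f.contig_id,
                        "phagehgt",
                        "CDS",
                        str(f.start),
                        str(f.end),
                        ".",
                        f.strand,
                        "0",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def write_table(rows: Sequence[Mapping] | pd.DataFrame, path: str | Path) -> None:
    """Write tabular output as TSV (header-keyed, lossless round-trip)."""
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path, required: Iterable[str] = ()) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=list(required))
    missing = set(required) - set(df.columns)
    if missing:
        raise TableSchemaError(
            f"{path}: missing required columns {sorted(missing)}"
        )
    return df


def read_ortholog_table(path: str | Path) -> list[tuple[str, str]]:
    """Read a two-column ortholog pair table (columns gene_a, gene_b)."""
    df = read_table(path, required=("gene_a", "gene_b"))
    return list(zip(df["gene_a"].astype(str), df["gene_b"].astype(str)))


def read_config(path: str | Path) -> dict:
    """Read a JSON run-configuration file."""
    with open(path) as fh:
        return json.load(fh)
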