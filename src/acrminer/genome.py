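"""Genome annotations and directon segmentation.

A *directon* is a maximal run of consecutive protein-coding genes on the
same strand of one contig, with at most ``max_gap_bp`` nucleotides between
adjacent genes.  Directons act as a cheap proxy for co-transcribed units;
anti-CRISPR genes characteristically sit in short directons of small,
unannotated proteins.

Coordinates are 1-based inclusive throughout (the GFF3/GenBank convention);
the intergenic gap between adjacent genes is ``next.start - prev.end - 1``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO

__all__ = [
    "GeneRecord",
    "Directon",
    "Assembly",
    "parse_assembly",
    "build_directons",
    "directon_stats",
    "read_protein_fasta",
]


@dataclass(frozen=True)
class GeneRecord:
    """A protein-coding gene with 1-based inclusive coordinates."""

    gene_id: str
    protein_id: str
    contig_id: str
    start: int
    end: int
    strand: str  # "+" or "-"
    aa_length: int
    aa_sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(
                f"gene {self.gene_id}: end {self.end} < start {self.start}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if self.aa_length <= 0:
            raise ValueError(f"gene {self.gene_id}: aa_length must be positive")
        if self.aa_sequence is not None and len(self.aa_sequence) != self.aa_length:
            raise ValueError(
                f"gene {self.gene_id}: sequence length {len(self.aa_sequence)} "
                f"!= aa_length {self.aa_length}"
            )

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass(frozen=True)
class Directon:
    """Maximal same-strand run of genes with small intergenic gaps."""

    contig_id: str
    strand: str
    genes: tuple[GeneRecord, ...]

    @property
    def size(self) -> int:
        return len(self.genes)

    @property
    def start(self) -> int:
        return self.genes[0].start

    @property
    def end(self) -> int:
        return max(g.end for g in self.genes)

    @property
    def mean_gene_aa_length(self) -> float:
        return sum(g.aa_length for g in self.genes) / len(self.genes)

    @property
    def mean_spacing(self) -> float:
        if len(self.genes) == 1:
            return 0.0
        gaps = [
            max(0, b.start - a.end - 1)
            for a, b in zip(self.genes, self.genes[1:])
        ]
        return sum(gaps) / len(gaps)

    def transcription_order(self) -> tuple[GeneRecord, ...]:
        """Genes in 5'->3' order of the coding strand."""
        return self.genes if self.strand == "+" else self.genes[::-1]


@dataclass
class Assembly:
    """One genome assembly: contigs, genes and assembly-level flags."""

    assembly_id: str
    genes: list[GeneRecord] = field(default_factory=list)
    contig_lengths: dict[str, Optional[int]] = field(default_factory=dict)
    contig_sequences: dict[str, str] = field(default_factory=dict)
    is_viral: bool = False
    has_crispr: bool = False
    crispr_subtypes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for g in self.genes:
            if g.contig_id not in self.contig_lengths:
                self.contig_lengths[g.contig_id] = None
            length = self.contig_lengths[g.contig_id]
            if length is not None and g.end > length:
                raise ValueError(
                    f"gene {g.gene_id} extends past contig "
                    f"{g.contig_id} (length {length})"
                )
        self.genes.sort(key=lambda g: (g.contig_id, g.start, g.end))

    @property
    def protein_ids(self) -> list[str]:
        return [g.protein_id for g in self.genes]


GENE_TSV_COLUMNS = (
    "assembly",
    "contig",
    "gene_id",
    "start",
    "end",
    "strand",
    "aa_length",
)


def read_protein_fasta(path: str | Path) -> dict[str, str]:
    """Protein FASTA keyed by record id (the protein_id)."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def _attach_sequences(genes: list[GeneRecord], seqs: dict[str, str]) -> list[GeneRecord]:
    out = []
    for g in genes:
        seq = seqs.get(g.protein_id)
        if seq is not None:
            g = GeneRecord(
                g.gene_id, g.protein_id, g.contig_id, g.start, g.end,
                g.strand, len(seq), seq,
            )
        out.append(g)
    return out


def _parse_gff3(path: Path) -> tuple[str, list[GeneRecord], dict[str, Optional[int]]]:
    genes: list[GeneRecord] = []
    contig_lengths: dict[str, Optional[int]] = {}
    assembly_id = path.stem
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    contig_lengths[parts[1]] = int(parts[3])
                continue
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{path}:{lineno}: expected 9 tab-separated GFF3 columns, "
                    f"got {len(fields)}"
                )
            seqid, _source, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype != "CDS":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad coordinates") from exc
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            protein_id = attr.get("protein_id") or attr.get("ID")
            if protein_id is None:
                raise ValueError(f"{path}:{lineno}: CDS lacks protein_id/ID")
            gene_id = attr.get("ID", protein_id)
            aa_length = (end_i - start_i + 1) // 3 - 1  # exclude stop codon
            genes.append(
                GeneRecord(gene_id, protein_id, seqid, start_i, end_i,
                           strand, max(aa_length, 1))
            )
            contig_lengths.setdefault(seqid, None)
    return assembly_id, genes, contig_lengths


def _parse_genbank(path: Path) -> tuple[str, list[GeneRecord], dict[str, Optional[int]]]:
    genes: list[GeneRecord] = []
    contig_lengths: dict[str, Optional[int]] = {}
    assembly_id = path.stem
    n = 0
    for rec in SeqIO.parse(str(path), "genbank"):
        n += 1
        contig_lengths[rec.id] = len(rec.seq) or None
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            q = feat.qualifiers
            protein_id = (q.get("protein_id") or q.get("locus_tag") or [None])[0]
            if protein_id is None:
                raise ValueError(f"{path}: CDS lacks protein_id/locus_tag")
            gene_id = (q.get("locus_tag") or [protein_id])[0]
            start = int(feat.location.start) + 1  # Biopython is 0-based
            end = int(feat.location.end)
            strand = "+" if feat.location.strand != -1 else "-"
            translation = (q.get("translation") or [None])[0]
            if translation is not None:
                aa_length = len(translation)
            else:
                aa_length = max((end - start + 1) // 3 - 1, 1)
            genes.append(
                GeneRecord(gene_id, protein_id, rec.id, start, end, strand,
                           aa_length, translation)
            )
    if n == 0:
        raise ValueError(f"{path}: no GenBank records found")
    return assembly_id, genes, contig_lengths


def _parse_gene_tsv(path: Path) -> tuple[str, list[GeneRecord], dict[str, Optional[int]]]:
    genes: list[GeneRecord] = []
    assembly_id = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0] == GENE_TSV_COLUMNS[0]:
                continue  # header row
            if len(fields) != len(GENE_TSV_COLUMNS):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(GENE_TSV_COLUMNS)} "
                    f"columns, got {len(fields)}"
                )
            asm, contig, gene_id, start, end, strand, aa_length = fields
            assembly_id = assembly_id or asm
            try:
                genes.append(
                    GeneRecord(gene_id, gene_id, contig, int(start), int(end),
                               strand, int(aa_length))
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    if assembly_id is None:
        raise ValueError(f"{path}: empty gene table")
    return assembly_id, genes, {}


def parse_assembly(
    path: str | Path,
    format: str = "gene_tsv",
    protein_fasta: str | Path | None = None,
    contig_fasta: str | Path | None = None,
    is_viral: bool = False,
    has_crispr: bool = False,
) -> Assembly:
    """Parse genome annotations into an :class:`Assembly`.

    Supported dialects: ``gff3`` (CDS features with a ``protein_id``
    attribute), ``genbank`` flat files, and a 7-column ``gene_tsv``
    (assembly, contig, gene_id, start, end, strand, aa_length).  An
    optional protein FASTA keyed by protein_id supplies sequences; an
    optional contig FASTA supplies nucleotide sequence (needed for
    self-targeting detection).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    parsers = {"gff3": _parse_gff3, "genbank": _parse_genbank,
               "gene_tsv": _parse_gene_tsv}
    try:
        parser = parsers[format]
    except KeyError:
        raise ValueError(f"unknown format {format!r}; use one of {sorted(parsers)}")
    assembly_id, genes, contig_lengths = parser(path)
    if not genes:
        raise ValueError(f"{path}: no genes parsed")
    seen: set[str] = set()
    for g in genes:
        if g.protein_id in seen:
            raise ValueError(f"{path}: duplicate protein_id {g.protein_id}")
        seen.add(g.protein_id)
    if protein_fasta is not None:
        genes = _attach_sequences(genes, read_protein_fasta(protein_fasta))
    contig_sequences: dict[str, str] = {}
    if contig_fasta is not None:
        contig_sequences = read_protein_fasta(contig_fasta)
        for cid, seq in contig_sequences.items():
            contig_lengths[cid] = len(seq)
    return Assembly(
        assembly_id=assembly_id,
        genes=genes,
        contig_lengths=contig_lengths,
        contig_sequences=contig_sequences,
        is_viral=is_viral,
        has_crispr=has_crispr,
    )


def build_directons(
    assembly: Assembly | Iterable[GeneRecord], max_gap_bp: int = 100
) -> list[Directon]:
    """Partition genes into maximal same-strand runs.

    Adjacent genes on one contig extend the current run when they share its
    strand and the intergenic gap (``next.start - prev.end - 1``, clamped at
    0 for overlaps) is at most ``max_gap_bp`` — the bound is inclusive.
    """
    if max_gap_bp < 0:
        raise ValueError("max_gap_bp must be >= 0")
    genes = assembly.genes if isinstance(assembly, Assembly) else list(assembly)
    genes = sorted(genes, key=lambda g: (g.contig_id, g.start, g.end))
    directons: list[Directon] = []
    run: list[GeneRecord] = []

    def flush() -> None:
        if run:
            directons.append(Directon(run[0].contig_id, run[0].strand, tuple(run)))

    for g in genes:
        if run:
            prev = run[-1]
            gap = max(0, g.start - prev.end - 1)
            same = g.contig_id == prev.contig_id and g.strand == prev.strand
            if same and gap <= max_gap_bp:
                run.append(g)
                continue
            flush()
            run = []
        run = [g]
    flush()
    return directons


def directon_stats(directon: Directon) -> tuple[int, float, float]:
    """(size, mean protein length in aa, mean intergenic spacing in bp)."""
    if directon.size == 0:
        raise ValueError("empty directon")
    return directon.size, directon.mean_gene_aa_length, directon.mean_spacing


def directon_index(directons: Iterable[Directon]) -> dict[str, Directon]:
    """Map protein_id -> containing directon."""
    idx: dict[str, Directon] = {}
    for d in directons:
        for g in d.genes:
            if g.protein_id in idx:
                warnings.warn(f"protein {g.protein_id} in multiple directons")
            idx[g.protein_id] = d
    return idx
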