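"""Profile-hit tables, spacer sets, and derived per-protein flags.

Profile searches (CDD, pVOG, HTH-domain subsets, known-Acr databases) are
run externally; their tabular BLAST (outfmt 6) output is ingested here.
From those tables this module derives the binary flags the model consumes:
whether a protein is annotated, whether an HTH-domain protein sits just
downstream in the same directon, whether the protein is viral, and whether
its genome is self-targeting (one of its own CRISPR spacers matches its own
sequence exactly).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

from Bio.Seq import reverse_complement

from .genome import Directon

__all__ = [
    "ProfileHit",
    "SpacerSet",
    "MembraneTable",
    "load_hit_table",
    "load_membrane_table",
    "load_spacer_fasta",
    "is_annotated",
    "has_hth_downstream",
    "detect_self_targeting",
    "is_viral_protein",
    "ANNOTATION_EVALUE_MAX",
    "HTH_EVALUE_MAX",
    "UNINFORMATIVE_DESCRIPTIONS",
]

DATABASE_TAGS = {"CDD", "pVOG", "HTH", "knownAcr", "prokDB", "provirusDB", "virusDB"}

#: Default e-value cutoff for CDD/pVOG annotation and viral classification.
ANNOTATION_EVALUE_MAX = 1e-4
#: Default e-value cutoff for HTH-domain profile hits.
HTH_EVALUE_MAX = 5e-3

#: Descriptions that do not count as a real annotation.
UNINFORMATIVE_DESCRIPTIONS = (
    "hypothetical protein",
    "putative predicted product",
    "provisional",
)


@dataclass(frozen=True)
class ProfileHit:
    protein_id: str
    profile_id: str
    database_tag: str
    e_value: float
    profile_description: str = ""
    identity_pct: Optional[float] = None
    query_coverage_pct: Optional[float] = None

    def __post_init__(self) -> None:
        if self.database_tag not in DATABASE_TAGS:
            raise ValueError(f"unknown database_tag {self.database_tag!r}")
        if self.e_value < 0:
            raise ValueError("e_value must be >= 0")
        for pct in (self.identity_pct, self.query_coverage_pct):
            if pct is not None and not 0 <= pct <= 100:
                raise ValueError(f"percentage out of [0, 100]: {pct}")


@dataclass
class SpacerSet:
    assembly_id: str
    spacers: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for s in self.spacers:
            if not s or set(s.upper()) - set("ACGTN"):
                raise ValueError(f"bad spacer {s!r}")


class MembraneTable:
    """protein_id -> has >=1 predicted TM helix or signal peptide.

    Total over queried proteins: an absent id means "not membrane
    associated" (False), matching how TMHMM/SignalP tables only list
    positives.
    """

    def __init__(self, flags: Mapping[str, bool] | None = None) -> None:
        self._flags = dict(flags or {})

    def __getitem__(self, protein_id: str) -> bool:
        return bool(self._flags.get(protein_id, False))

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self._flags


OUTFMT6_NCOLS = 12


def load_hit_table(path: str | Path, database_tag: str) -> list[ProfileHit]:
    """Read a 12-column tabular BLAST table (optional 13th description).

    Columns follow outfmt 6: qseqid sseqid pident length mismatch gapopen
    qstart qend sstart send evalue bitscore.  Query coverage is estimated
    from the aligned query span when no explicit column is present.
    """
    hits: list[ProfileHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (OUTFMT6_NCOLS, OUTFMT6_NCOLS + 1):
                raise ValueError(
                    f"{path}:{lineno}: expected {OUTFMT6_NCOLS} or "
                    f"{OUTFMT6_NCOLS + 1} columns, got {len(fields)}"
                )
            try:
                qseqid, sseqid = fields[0], fields[1]
                pident = float(fields[2])
                evalue = float(fields[10])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            desc = fields[12] if len(fields) > OUTFMT6_NCOLS else ""
            hits.append(
                ProfileHit(
                    protein_id=qseqid,
                    profile_id=sseqid,
                    database_tag=database_tag,
                    e_value=evalue,
                    profile_description=desc,
                    identity_pct=pident,
                )
            )
    return hits


def load_membrane_table(path: str | Path) -> MembraneTable:
    """2-column TSV: protein_id <tab> 0/1 (or true/false)."""
    flags: dict[str, bool] = {}
    truthy = {"1", "true", "yes"}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            pid, val = line.split("\t")[:2]
            flags[pid] = val.lower() in truthy
    return MembraneTable(flags)


def load_spacer_fasta(path: str | Path, assembly_id: str) -> SpacerSet:
    from Bio import SeqIO

    spacers = [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")]
    return SpacerSet(assembly_id=assembly_id, spacers=spacers)


def _hits_by_protein(hits: Iterable[ProfileHit]) -> dict[str, list[ProfileHit]]:
    out: dict[str, list[ProfileHit]] = {}
    for h in hits:
        out.setdefault(h.protein_id, []).append(h)
    return out


def is_annotated(
    protein_id: str,
    hits: Iterable[ProfileHit],
    evalue_max: float = ANNOTATION_EVALUE_MAX,
) -> bool:
    """True iff the protein has a significant, informative CDD/pVOG hit.

    Hits whose description is "hypothetical protein", "putative predicted
    product" or "provisional" (case-insensitive substring match) do not
    count: such profiles convey no functional information.
    """
    for h in hits:
        if h.protein_id != protein_id or h.database_tag not in ("CDD", "pVOG"):
            continue
        if h.e_value > evalue_max:
            continue
        desc = h.profile_description.lower()
        if any(bad in desc for bad in UNINFORMATIVE_DESCRIPTIONS):
            continue
        return True
    return False


def has_hth_downstream(
    protein_id: str,
    directon: Directon,
    hth_hits: Iterable[ProfileHit],
    window: int = 3,
    evalue_max: float = HTH_EVALUE_MAX,
) -> bool:
    """True iff an HTH-domain gene lies 1..window genes downstream.

    "Downstream" is transcription order (the 3' direction of the directon's
    strand), and both genes must belong to the same directon — the classic
    Acr-then-Aca arrangement.
    """
    order = directon.transcription_order()
    ids = [g.protein_id for g in order]
    try:
        pos = ids.index(protein_id)
    except ValueError:
        raise ValueError(f"protein {protein_id} not in directon") from None
    hth_ok = {
        h.protein_id
        for h in hth_hits
        if h.database_tag == "HTH" and h.e_value <= evalue_max
    }
    for down in ids[pos + 1 : pos + 1 + window]:
        if down in hth_ok:
            return True
    return False


def detect_self_targeting(
    assembly_sequence: Mapping[str, str] | str | None,
    spacer_set: SpacerSet,
    both_strands: bool = True,
) -> Optional[bool]:
    """Exact-substring scan of each CRISPR spacer against the genome.

    Returns True on any exact match (either strand by default), False if no
    spacer matches, and None when no nucleotide sequence is available — the
    caller should treat None as "unknown", downstream code treats it as
    False.
    """
    if assembly_sequence is None or (
        isinstance(assembly_sequence, Mapping) and not assembly_sequence
    ):
        warnings.warn(
            f"assembly {spacer_set.assembly_id}: no sequence available; "
            "self-targeting unknown"
        )
        return None
    if isinstance(assembly_sequence, str):
        contigs = [assembly_sequence.upper()]
    else:
        contigs = [s.upper() for s in assembly_sequence.values()]
    for spacer in spacer_set.spacers:
        spacer = spacer.upper()
        probes = [spacer]
        if both_strands:
            probes.append(reverse_complement(spacer))
        for probe in probes:
            if any(probe in contig for contig in contigs):
                return True
    return False


def is_viral_protein(
    protein_id: str,
    hits: Iterable[ProfileHit],
    evalue_max: float = ANNOTATION_EVALUE_MAX,
) -> bool:
    """True iff the protein has a significant pVOG hit."""
    return any(
        h.protein_id == protein_id
        and h.database_tag == "pVOG"
        and h.e_value <= evalue_max
        for h in hits
    )
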