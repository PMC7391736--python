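"""Defining where to look for Acrs: viral genomes and putative proviruses.

Acrs live in phage genomes or in prophage-like regions of CRISPR-carrying
prokaryotes.  Rather than calling provirus boundaries, this module marks
directons containing pVOG-hit (viral) proteins plus their flanking
directons, merges nearby marked directons into provirus candidate blocks,
and flags a block as a predicted prophage when it holds at least two viral
hits within 3 kb of each other.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .annotations import ANNOTATION_EVALUE_MAX, ProfileHit
from .genome import Assembly, Directon, build_directons

__all__ = [
    "ProvirusBlock",
    "virus_related_directons",
    "merge_provirus_blocks",
    "build_search_space",
    "blocks_to_bed",
]


@dataclass(frozen=True)
class ProvirusBlock:
    contig_id: str
    directons: tuple[Directon, ...]
    n_virus_hits: int
    is_predicted_prophage: bool

    @property
    def start(self) -> int:
        return min(d.start for d in self.directons)

    @property
    def end(self) -> int:
        return max(d.end for d in self.directons)

    @property
    def protein_ids(self) -> set[str]:
        return {g.protein_id for d in self.directons for g in d.genes}


def _viral_proteins(
    pvog_hits: Iterable[ProfileHit], evalue_max: float
) -> set[str]:
    return {
        h.protein_id
        for h in pvog_hits
        if h.database_tag == "pVOG" and h.e_value <= evalue_max
    }


def virus_related_directons(
    assembly: Assembly,
    pvog_hits: Iterable[ProfileHit],
    evalue_max: float = ANNOTATION_EVALUE_MAX,
    directons: Optional[Sequence[Directon]] = None,
    max_gap_bp: int = 100,
) -> list[Directon]:
    """Directons with a significant viral hit, plus immediate neighbors.

    Neighbors are the directly adjacent directons on the same contig (one
    on either side, where they exist).  Returned in contig order.
    """
    if directons is None:
        directons = build_directons(assembly, max_gap_bp=max_gap_bp)
    viral = _viral_proteins(pvog_hits, evalue_max)
    by_contig: dict[str, list[Directon]] = {}
    for d in directons:
        by_contig.setdefault(d.contig_id, []).append(d)
    selected: list[Directon] = []
    seen: set[int] = set()
    for contig, ds in by_contig.items():
        ds.sort(key=lambda d: d.start)
        for i, d in enumerate(ds):
            if any(g.protein_id in viral for g in d.genes):
                for j in (i - 1, i, i + 1):
                    if 0 <= j < len(ds) and id(ds[j]) not in seen:
                        seen.add(id(ds[j]))
                        selected.append(ds[j])
    selected.sort(key=lambda d: (d.contig_id, d.start))
    return selected


def merge_provirus_blocks(
    directons: Sequence[Directon],
    virus_hit_proteins: Iterable[str] | None = None,
    max_block_gap: int = 500,
    prophage_window: int = 3000,
    distance: str = "midpoint",
) -> list[ProvirusBlock]:
    """Merge virus-related directons into provirus candidate blocks.

    Directons on the same contig whose spans are within ``max_block_gap``
    bp (inclusive) coalesce.  A block is a predicted prophage when at
    least two viral-hit genes lie within ``prophage_window`` bp of each
    other, measured between gene midpoints by default (``distance`` may be
    "edge" for edge-to-edge).
    """
    viral = set(virus_hit_proteins or ())
    by_contig: dict[str, list[Directon]] = {}
    for d in directons:
        by_contig.setdefault(d.contig_id, []).append(d)
    blocks: list[ProvirusBlock] = []
    for contig in sorted(by_contig):
        ds = sorted(by_contig[contig], key=lambda d: (d.start, d.end))
        groups: list[list[Directon]] = []
        for d in ds:
            if groups and d.start - max(x.end for x in groups[-1]) - 1 <= max_block_gap:
                groups[-1].append(d)
            else:
                groups.append([d])
        for grp in groups:
            hit_genes = [
                g for d in grp for g in d.genes if g.protein_id in viral
            ]
            prophage = False
            for i in range(len(hit_genes)):
                for j in range(i + 1, len(hit_genes)):
                    a, b = hit_genes[i], hit_genes[j]
                    if distance == "midpoint":
                        sep = abs(a.midpoint - b.midpoint)
                    else:
                        sep = max(
                            0, max(a.start, b.start) - min(a.end, b.end) - 1
                        )
                    if sep <= prophage_window:
                        prophage = True
            blocks.append(
                ProvirusBlock(
                    contig_id=contig,
                    directons=tuple(grp),
                    n_virus_hits=len(hit_genes),
                    is_predicted_prophage=prophage,
                )
            )
    return blocks


def build_search_space(
    assemblies: Sequence[Assembly],
    pvog_hits_by_assembly: Mapping[str, Iterable[ProfileHit]],
    evalue_max: float = ANNOTATION_EVALUE_MAX,
) -> set[str]:
    """Protein ids worth scoring for Acr activity.

    The union of (a) every protein of viral assemblies and (b) proteins
    inside provirus candidate blocks of CRISPR-containing prokaryotic
    assemblies.  Prokaryotes without a CRISPR-Cas system are excluded
    outright: without a resident system there is no pressure to retain an
    Acr and no self-targeting signal.
    """
    space: set[str] = set()
    for asm in assemblies:
        if asm.is_viral:
            space.update(asm.protein_ids)
            continue
        if not asm.has_crispr:
            continue
        hits = list(pvog_hits_by_assembly.get(asm.assembly_id, ()))
        related = virus_related_directons(asm, hits, evalue_max=evalue_max)
        viral = _viral_proteins(hits, evalue_max)
        for block in merge_provirus_blocks(related, viral):
            space.update(block.protein_ids)
    return space


def blocks_to_bed(blocks: Sequence[ProvirusBlock]) -> str:
    """BED text (0-based half-open; internal coordinates are 1-based
    inclusive, so start-1/end)."""
    lines = []
    for i, b in enumerate(blocks):
        name = "prophage" if b.is_predicted_prophage else "provirus_candidate"
        lines.append(
            f"{b.contig_id}\t{b.start - 1}\t{b.end}\t{name}_{i}\t{b.n_virus_hits}"
        )
    return "\n".join(lines) + ("\n" if lines else "")
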