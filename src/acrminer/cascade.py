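"""Heuristic enrichment cascade over candidate Acr families.

After model scoring and clustering, candidate families pass through a
fixed sequence of filters: the two hallmark requirements (a member with an
HTH gene downstream; a member in a self-targeting or virus genome), a
maximum mean directon size, a maximum prokaryotic homolog count, a virus
enrichment test (a virus hit, or a small prokaryote/provirus homolog
ratio), and a maximum HHblits annotation count.  Numeric cutoffs are
learnable from a positive set by a ten-threshold balanced-accuracy search;
the defaults are the values that search produced on the known-Acr set
(5 genes, 374 homologs, ratio 3, 52 HHblits hits).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .annotations import ProfileHit

__all__ = [
    "CandidateFamily",
    "FilterReport",
    "DEFAULT_CUTOFFS",
    "balanced_accuracy",
    "choose_cutoff",
    "hallmark_filter",
    "apply_cascade",
    "remove_known_acr_families",
    "consensus_sequence",
    "HeuristicCascade",
]

#: Cutoffs learned on the known-Acr positive set.
DEFAULT_CUTOFFS = {
    "max_mean_directon_size": 5.0,
    "max_prok_homologs": 374,
    "max_prok_provirus_ratio": 3.0,
    "max_hhblits_hits": 52,
}


@dataclass
class MemberFlags:
    protein_id: str
    hth_downstream: bool = False
    self_targeting: bool = False
    in_virus_genome: bool = False


@dataclass
class CandidateFamily:
    cluster_id: str
    members: list[MemberFlags] = field(default_factory=list)
    mean_directon_size: float = 1.0
    n_prok_homologs: int = 0
    n_provirus_homologs: int = 0
    n_virus_hits: int = 0
    n_hhblits_hits: int = 0
    contains_known_acr: bool = False

    def __post_init__(self) -> None:
        if self.mean_directon_size < 1:
            raise ValueError("mean_directon_size must be >= 1")
        for name in ("n_prok_homologs", "n_provirus_homologs",
                     "n_virus_hits", "n_hhblits_hits"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class StageCount:
    stage: str
    n_in: int
    n_out: int
    known_acr_retained: int


@dataclass
class FilterReport:
    stages: list[StageCount] = field(default_factory=list)

    def record(self, stage: str, before: Sequence[CandidateFamily],
               after: Sequence[CandidateFamily]) -> None:
        self.stages.append(
            StageCount(
                stage=stage,
                n_in=len(before),
                n_out=len(after),
                known_acr_retained=sum(f.contains_known_acr for f in after),
            )
        )

    def to_json(self) -> str:
        return json.dumps(
            [s.__dict__ for s in self.stages], indent=2
        )

    def to_text(self) -> str:
        lines = [f"{'stage':<22}{'in':>8}{'out':>8}{'known Acrs':>12}"]
        for s in self.stages:
            lines.append(
                f"{s.stage:<22}{s.n_in:>8}{s.n_out:>8}{s.known_acr_retained:>12}"
            )
        return "\n".join(lines)


def balanced_accuracy(
    frac_acrs_retained: float, frac_candidates_filtered: float
) -> float:
    """Mean of the fraction of known Acrs kept and candidates removed."""
    for v in (frac_acrs_retained, frac_candidates_filtered):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"fraction out of [0, 1]: {v}")
    return (frac_acrs_retained + frac_candidates_filtered) / 2.0


def choose_cutoff(
    acr_values: Sequence[float],
    candidate_values: Sequence[float],
    direction: str = "max",
) -> float:
    """Balanced-accuracy-optimal cutoff over a 10-threshold grid.

    Exactly ten evenly spaced thresholds spanning [min(acr), max(acr)]
    (both endpoints included) are evaluated; ``direction='max'`` keeps
    values <= cutoff, ``'min'`` keeps values >= cutoff.  Ties go to the
    most stringent threshold (smallest for 'max', largest for 'min').
    """
    acr = np.asarray(acr_values, dtype=float)
    cand = np.asarray(candidate_values, dtype=float)
    if acr.size == 0:
        raise ValueError("acr_values must be non-empty")
    lo, hi = float(acr.min()), float(acr.max())
    if lo == hi:
        grid = np.array([lo])
    else:
        grid = np.linspace(lo, hi, 10)
    if direction == "min":
        grid = grid[::-1]  # most stringent (largest) first
    elif direction != "max":
        raise ValueError("direction must be 'max' or 'min'")
    best_t, best_v = grid[0], -np.inf
    for t in grid:
        if direction == "max":
            kept = acr <= t
            removed = cand > t
        else:
            kept = acr >= t
            removed = cand < t
        v = balanced_accuracy(
            float(kept.mean()),
            float(removed.mean()) if cand.size else 0.0,
        )
        if v > best_v:
            best_t, best_v = t, v
    return float(best_t)


def hallmark_filter(families: Iterable[CandidateFamily]) -> list[CandidateFamily]:
    """Keep families with the two Acr hallmarks, each satisfiable by any
    member: one member with HTH downstream, and one member in a
    self-targeting or virus genome."""
    out = []
    for f in families:
        if not f.members:
            continue
        has_hth = any(m.hth_downstream for m in f.members)
        has_stv = any(m.self_targeting or m.in_virus_genome for m in f.members)
        if has_hth and has_stv:
            out.append(f)
    return out


def _directon_stage(families, cutoff):
    return [f for f in families if f.mean_directon_size <= cutoff]


def _homolog_stage(families, cutoff):
    return [f for f in families if f.n_prok_homologs <= cutoff]


def _enrichment_stage(families, ratio_cutoff):
    out = []
    for f in families:
        if f.n_virus_hits >= 1:  # virus override
            out.append(f)
        elif f.n_provirus_homologs > 0 and (
            f.n_prok_homologs / f.n_provirus_homologs <= ratio_cutoff
        ):
            out.append(f)
    return out


def _hhblits_stage(families, cutoff):
    return [f for f in families if f.n_hhblits_hits <= cutoff]


def apply_cascade(
    families: Sequence[CandidateFamily],
    cutoffs: Optional[Mapping[str, float]] = None,
) -> tuple[list[CandidateFamily], FilterReport]:
    """Run the full filter cascade and report per-stage counts.

    Stage order: hallmarks, mean directon size, prokaryotic homologs,
    virus enrichment (with the virus-hit override), HHblits hits.  A
    family with zero provirus homologs fails the ratio test unless the
    virus override applies.
    """
    c = dict(DEFAULT_CUTOFFS)
    if cutoffs:
        c.update(cutoffs)
    report = FilterReport()
    current = list(families)

    stages = [
        ("hallmarks", lambda fs: hallmark_filter(fs)),
        ("directon_size",
         lambda fs: _directon_stage(fs, c["max_mean_directon_size"])),
        ("prok_homologs",
         lambda fs: _homolog_stage(fs, c["max_prok_homologs"])),
        ("virus_enrichment",
         lambda fs: _enrichment_stage(fs, c["max_prok_provirus_ratio"])),
        ("hhblits",
         lambda fs: _hhblits_stage(fs, c["max_hhblits_hits"])),
    ]
    for name, fn in stages:
        nxt = fn(current)
        report.record(name, current, nxt)
        current = nxt
    return current, report


def remove_known_acr_families(
    families: Sequence[CandidateFamily],
    knownacr_hits: Iterable[ProfileHit],
    evalue_max: float = 1e-3,
) -> tuple[list[CandidateFamily], int]:
    """Drop families homologous to already-known Acrs.

    A family is removed when its cluster id or any member produced a
    knownAcr-database hit with e-value strictly below ``evalue_max``.
    Returns (survivors, number removed).
    """
    flagged: set[str] = set()
    for h in knownacr_hits:
        if h.database_tag == "knownAcr" and h.e_value < evalue_max:
            flagged.add(h.protein_id)
    out = []
    removed = 0
    for f in families:
        ids = {f.cluster_id} | {m.protein_id for m in f.members}
        if ids & flagged:
            removed += 1
        else:
            out.append(f)
    return out, removed


def consensus_sequence(alignment: Sequence[str]) -> str:
    """BLOSUM62-consensus of an aligned set of protein sequences.

    Per column, among the residues present (gaps ignored), the consensus
    letter maximizes the summed BLOSUM62 score against every residue in
    the column; ties break alphabetically; all-gap columns are skipped.
    """
    if not alignment:
        raise ValueError("empty alignment")
    ncol = len(alignment[0])
    if any(len(s) != ncol for s in alignment):
        raise ValueError("alignment rows must have equal length")
    blosum = substitution_matrices.load("BLOSUM62")
    out = []
    for j in range(ncol):
        column = [s[j].upper() for s in alignment if s[j] not in "-."]
        if not column:
            continue
        best_aa, best_score = None, -np.inf
        for aa in sorted(set(column)):
            score = sum(blosum[aa, other] for other in column)
            if score > best_score:
                best_aa, best_score = aa, score
        out.append(best_aa)
    return "".join(out)


class HeuristicCascade:
    """Fit/filter interface around the cascade.

    ``fit`` learns the four numeric cutoffs from a reference set of
    known-Acr families via the ten-threshold balanced-accuracy search;
    without fitting, the published defaults apply.  ``filter`` runs the
    cascade and stores the :class:`FilterReport` as ``report_``.
    """

    def __init__(self, cutoffs: Optional[Mapping[str, float]] = None) -> None:
        self.cutoffs = cutoffs

    def fit(
        self,
        acr_families: Sequence[CandidateFamily],
        candidate_families: Sequence[CandidateFamily],
    ) -> "HeuristicCascade":
        def vals(fams, attr):
            return [getattr(f, attr) for f in fams]

        def ratio(f):
            if f.n_provirus_homologs == 0:
                return float("inf") if f.n_prok_homologs else 0.0
            return f.n_prok_homologs / f.n_provirus_homologs

        acr_ratios = [ratio(f) for f in acr_families if ratio(f) != float("inf")]
        cand_ratios = [ratio(f) for f in candidate_families
                       if ratio(f) != float("inf")]
        self.cutoffs_ = {
            "max_mean_directon_size": choose_cutoff(
                vals(acr_families, "mean_directon_size"),
                vals(candidate_families, "mean_directon_size"), "max"),
            "max_prok_homologs": choose_cutoff(
                vals(acr_families, "n_prok_homologs"),
                vals(candidate_families, "n_prok_homologs"), "max"),
            "max_prok_provirus_ratio": choose_cutoff(
                acr_ratios or [0.0], cand_ratios, "max"),
            "max_hhblits_hits": choose_cutoff(
                vals(acr_families, "n_hhblits_hits"),
                vals(candidate_families, "n_hhblits_hits"), "max"),
        }
        return self

    def filter(
        self, families: Sequence[CandidateFamily]
    ) -> list[CandidateFamily]:
        cutoffs = getattr(self, "cutoffs_", None) or self.cutoffs
        survivors, self.report_ = apply_cascade(families, cutoffs)
        return survivors
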