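"""Per-protein feature vectors and genetic-algorithm feature selection.

Twelve features describe each candidate protein and its genomic context:
its length and mean Kyte–Doolittle hydrophobicity; whether it carries an
informative profile annotation; four directon-level statistics (size, mean
protein length, annotated fraction, membrane fraction, spacing); whether an
HTH-domain gene lies just downstream in the same directon; whether the host
genome is self-targeting; whether the protein is membrane associated; and
whether the genome is viral.  An 8-feature subset (the "final model" view)
drops the weakly informative ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .annotations import (
    ANNOTATION_EVALUE_MAX,
    HTH_EVALUE_MAX,
    MembraneTable,
    ProfileHit,
    has_hth_downstream,
    is_annotated,
)
from .genome import Assembly, Directon, GeneRecord, build_directons, directon_index

__all__ = [
    "FEATURE_NAMES",
    "FINAL_MODEL_FEATURES",
    "FeatureVector",
    "kyte_doolittle_mean",
    "isoelectric_point",
    "compute_feature_vector",
    "feature_matrix",
    "select_features_ga",
]

#: Canonical 12-feature order.
FEATURE_NAMES = (
    "protein_length",
    "directon_size",
    "directon_mean_protein_length",
    "mean_hydrophobicity",
    "protein_is_annotated",
    "directon_annotated_fraction",
    "hth_downstream",
    "self_targeting",
    "membrane_associated",
    "directon_membrane_fraction",
    "directon_spacing",
    "genome_is_viral",
)

#: The 8 features retained by feature selection for the final model.
FINAL_MODEL_FEATURES = (
    "self_targeting",
    "directon_annotated_fraction",
    "directon_mean_protein_length",
    "directon_size",
    "protein_is_annotated",
    "hth_downstream",
    "protein_length",
    "mean_hydrophobicity",
)

#: EMBOSS-style pKa values used for the isoelectric point.
PKA_POSITIVE = {"K": 10.8, "R": 12.5, "H": 6.5}
PKA_NEGATIVE = {"D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}
PKA_NTERM = 8.6
PKA_CTERM = 3.6


@dataclass(frozen=True)
class FeatureVector:
    protein_length: float
    directon_size: float
    directon_mean_protein_length: float
    mean_hydrophobicity: float
    protein_is_annotated: int
    directon_annotated_fraction: float
    hth_downstream: int
    self_targeting: int
    membrane_associated: int
    directon_membrane_fraction: float
    directon_spacing: float
    genome_is_viral: int

    def __post_init__(self) -> None:
        for name in ("directon_annotated_fraction", "directon_membrane_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} out of [0, 1]: {v}")

    def as_array(self, features: Sequence[str] = FEATURE_NAMES) -> np.ndarray:
        return np.array([getattr(self, f) for f in features], dtype=float)

    def final_model_view(self) -> np.ndarray:
        return self.as_array(FINAL_MODEL_FEATURES)


def kyte_doolittle_mean(aa_sequence: str) -> float:
    """Mean Kyte–Doolittle hydropathy over the 20 standard residues.

    Non-standard letters (X, B, Z, ...) are skipped with a warning.
    """
    if not aa_sequence:
        raise ValueError("empty sequence")
    vals = []
    skipped = 0
    for aa in aa_sequence.upper():
        try:
            vals.append(KYTE_DOOLITTLE[aa])
        except KeyError:
            skipped += 1
    if skipped:
        warnings.warn(f"skipped {skipped} non-standard residues")
    if not vals:
        raise ValueError("no standard residues in sequence")
    return float(np.mean(vals))


def _net_charge(counts: Mapping[str, int], ph: float) -> float:
    charge = 1.0 / (1.0 + 10 ** (ph - PKA_NTERM))
    charge -= 1.0 / (1.0 + 10 ** (PKA_CTERM - ph))
    for aa, pka in PKA_POSITIVE.items():
        charge += counts.get(aa, 0) / (1.0 + 10 ** (ph - pka))
    for aa, pka in PKA_NEGATIVE.items():
        charge -= counts.get(aa, 0) / (1.0 + 10 ** (pka - ph))
    return charge


def isoelectric_point(aa_sequence: str, tol: float = 1e-4) -> float:
    """pH of zero net charge, by bisection of the Henderson–Hasselbalch
    charge curve under EMBOSS pKa values (termini included)."""
    if not aa_sequence:
        raise ValueError("empty sequence")
    seq = aa_sequence.upper()
    counts = {aa: seq.count(aa) for aa in set(seq)}
    lo, hi = 0.0, 14.0
    if _net_charge(counts, lo) < 0 or _net_charge(counts, hi) > 0:
        warnings.warn("charge curve does not bracket zero; returning 7.0")
        return 7.0
    while hi - lo > 1e-8:
        mid = (lo + hi) / 2.0
        c = _net_charge(counts, mid)
        if abs(c) < tol:
            return mid
        if c > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


@dataclass
class AssemblyContext:
    """Resolved per-assembly context shared by all its proteins."""

    assembly: Assembly
    directon_of: Mapping[str, Directon]
    annotated: Mapping[str, bool]
    hth: Mapping[str, bool]
    membrane: MembraneTable
    self_targeting: bool
    is_viral: bool


def build_context(
    assembly: Assembly,
    hits: Iterable[ProfileHit],
    membrane: MembraneTable | None = None,
    self_targeting: Optional[bool] = None,
    max_gap_bp: int = 100,
    evalue_max: float = ANNOTATION_EVALUE_MAX,
    hth_evalue_max: float = HTH_EVALUE_MAX,
) -> AssemblyContext:
    """Precompute directons and per-protein flags for one assembly."""
    hits = list(hits)
    directons = build_directons(assembly, max_gap_bp=max_gap_bp)
    didx = directon_index(directons)
    by_protein: dict[str, list[ProfileHit]] = {}
    for h in hits:
        by_protein.setdefault(h.protein_id, []).append(h)
    annotated = {
        g.protein_id: is_annotated(
            g.protein_id, by_protein.get(g.protein_id, ()), evalue_max
        )
        for g in assembly.genes
    }
    hth_hits = [h for h in hits if h.database_tag == "HTH"]
    hth = {
        g.protein_id: has_hth_downstream(
            g.protein_id, didx[g.protein_id], hth_hits,
            evalue_max=hth_evalue_max,
        )
        for g in assembly.genes
    }
    return AssemblyContext(
        assembly=assembly,
        directon_of=didx,
        annotated=annotated,
        hth=hth,
        membrane=membrane or MembraneTable(),
        self_targeting=bool(self_targeting),
        is_viral=assembly.is_viral,
    )


def compute_feature_vector(protein: GeneRecord, ctx: AssemblyContext) -> FeatureVector:
    """Populate the 12 features for one protein; deterministic in inputs."""
    d = ctx.directon_of[protein.protein_id]
    members = [g.protein_id for g in d.genes]
    annotated_frac = float(np.mean([ctx.annotated[m] for m in members]))
    membrane_frac = float(np.mean([ctx.membrane[m] for m in members]))
    if protein.aa_sequence:
        hydro = kyte_doolittle_mean(protein.aa_sequence)
    else:
        raise ValueError(
            f"protein {protein.protein_id}: no sequence; cannot compute "
            "hydrophobicity"
        )
    return FeatureVector(
        protein_length=float(protein.aa_length),
        directon_size=float(d.size),
        directon_mean_protein_length=d.mean_gene_aa_length,
        mean_hydrophobicity=hydro,
        protein_is_annotated=int(ctx.annotated[protein.protein_id]),
        directon_annotated_fraction=annotated_frac,
        hth_downstream=int(ctx.hth[protein.protein_id]),
        self_targeting=int(ctx.self_targeting),
        membrane_associated=int(ctx.membrane[protein.protein_id]),
        directon_membrane_fraction=membrane_frac,
        directon_spacing=d.mean_spacing,
        genome_is_viral=int(ctx.is_viral),
    )


def feature_matrix(ctx: AssemblyContext) -> pd.DataFrame:
    """12-column feature table indexed by protein_id for one assembly."""
    rows = {
        g.protein_id: compute_feature_vector(g, ctx).as_array()
        for g in ctx.assembly.genes
    }
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=list(FEATURE_NAMES)
    )


# ---------------------------------------------------------------------------
# Genetic-algorithm feature selection


def _mask_fitness(mask, X, y, weights, families, seed, n_trees, n_folds, n_reps):
    from .classifier import family_grouped_cv

    cols = np.flatnonzero(mask)
    res = family_grouped_cv(
        X[:, cols], y, weights, families,
        n_folds=n_folds, n_reps=n_reps, seed=seed, n_trees=n_trees,
    )
    return res.mean_auc


def select_features_ga(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray,
    families: Optional[np.ndarray] = None,
    n_generations: int = 10,
    seed: int = 0,
    population_size: int = 50,
    crossover_rate: float = 0.5,
    mutation_rate: float = 0.1,
    elitism: int = 2,
    tournament_size: int = 3,
    n_trees: int = 50,
    n_folds: int = 3,
    n_reps: int = 1,
) -> np.ndarray:
    """Select a feature subset with a simple generational GA.

    Fitness is the mean family-grouped cross-validation weighted ROC-AUC of
    a small tree ensemble on the masked features.  Bit-masks evolve for
    ``n_generations`` with tournament selection, uniform crossover, bit-flip
    mutation and elitism.  Deterministic given ``seed``.

    Returns the best boolean mask over the columns of ``X``.
    """
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1")
    X = np.asarray(X, dtype=float)
    n_feat = X.shape[1]
    if n_feat < 2:
        raise ValueError("need at least 2 features")
    rng = np.random.default_rng(seed)
    if families is None:
        families = np.array([f"f{i % 6}" if yy else "" for i, yy in enumerate(y)])

    cache: dict[bytes, float] = {}

    def fitness(mask: np.ndarray) -> float:
        key = mask.tobytes()
        if key not in cache:
            cache[key] = _mask_fitness(
                mask, X, y, weights, families, seed, n_trees, n_folds, n_reps,
            )
        return cache[key]

    def random_mask() -> np.ndarray:
        m = rng.random(n_feat) < 0.5
        if not m.any():
            m[rng.integers(n_feat)] = True
        return m

    pop = [random_mask() for _ in range(population_size)]
    fits = np.array([fitness(m) for m in pop])
    for _gen in range(n_generations):
        order = np.argsort(-fits, kind="stable")
        next_pop = [pop[i].copy() for i in order[:elitism]]
        while len(next_pop) < population_size:
            # tournament selection of two parents
            parents = []
            for _ in range(2):
                contenders = rng.integers(population_size, size=tournament_size)
                parents.append(pop[contenders[np.argmax(fits[contenders])]])
            a, b = parents
            swap = rng.random(n_feat) < crossover_rate
            child = np.where(swap, b, a).copy()
            flip = rng.random(n_feat) < mutation_rate
            child = child ^ flip
            if not child.any():
                child[rng.integers(n_feat)] = True
            next_pop.append(child)
        pop = next_pop
        fits = np.array([fitness(m) for m in pop])
    best = int(np.argmax(fits))
    return pop[best]
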