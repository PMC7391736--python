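"""Redundancy weighting of training examples and candidate clusters.

Known Acr families are wildly unequal in size, so each family gets total
weight 1, split evenly over its sequence-similarity subfamilies and then
over subfamily members.  Negatives are de-redundified by keeping one
representative per cluster at weight 1, and the whole negative class is
down-scaled so both classes carry equal total weight.  Candidate clusters
from the prediction stage are weighted 1/n per member (or the equivalent
per-cluster variant) for summary statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "WeightedExample",
    "assign_family_weights",
    "negative_representatives",
    "rebalance_classes",
    "candidate_cluster_weights",
    "greedy_cluster",
    "weighted_mean_sd",
    "load_cluster_tsv",
    "write_cluster_tsv",
]


@dataclass
class WeightedExample:
    protein_id: str
    label: str  # "Acr" | "nonAcr"
    weight: float
    family_id: Optional[str] = None
    subfamily_id: Optional[str] = None
    cluster_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError("weight must be > 0")
        if self.label not in ("Acr", "nonAcr"):
            raise ValueError(f"bad label {self.label!r}")
        if self.label == "Acr" and self.family_id is None:
            raise ValueError("Acr examples must carry a family_id")


def assign_family_weights(
    hierarchy: Mapping[str, Mapping[str, Sequence[str]]],
) -> dict[str, float]:
    """Weights from a family -> subfamily -> members hierarchy.

    Each family starts at weight 1, divided evenly among subfamilies, then
    evenly among members, so per-family weights sum to exactly 1.
    """
    weights: dict[str, float] = {}
    for family, subfamilies in hierarchy.items():
        if not subfamilies:
            raise ValueError(f"family {family} has no subfamilies")
        share = 1.0 / len(subfamilies)
        for sub, members in subfamilies.items():
            if not members:
                raise ValueError(f"subfamily {family}/{sub} is empty")
            w = share / len(members)
            for m in members:
                weights[m] = w
    return weights


def negative_representatives(
    clusters: Mapping[str, Sequence[str]],
    lengths: Optional[Mapping[str, int]] = None,
) -> list[WeightedExample]:
    """One representative per negative cluster, weight 1.

    The longest member is chosen (requires ``lengths``); ties, or missing
    lengths, fall back to the lexicographically smallest id.
    """
    reps: list[WeightedExample] = []
    for cid in sorted(clusters):
        members = clusters[cid]
        if not members:
            continue
        if lengths:
            rep = min(members, key=lambda m: (-lengths.get(m, 0), m))
        else:
            rep = min(members)
        reps.append(
            WeightedExample(protein_id=rep, label="nonAcr", weight=1.0,
                            cluster_id=cid)
        )
    return reps


def rebalance_classes(examples: Iterable[WeightedExample]) -> list[WeightedExample]:
    """Scale negative weights so both classes have equal total weight."""
    examples = list(examples)
    pos = sum(e.weight for e in examples if e.label == "Acr")
    neg = sum(e.weight for e in examples if e.label == "nonAcr")
    if pos <= 0 or neg <= 0:
        raise ValueError("both classes must have positive total weight")
    scale = pos / neg
    out = []
    for e in examples:
        w = e.weight * scale if e.label == "nonAcr" else e.weight
        out.append(
            WeightedExample(e.protein_id, e.label, w, e.family_id,
                            e.subfamily_id, e.cluster_id)
        )
    return out


def candidate_cluster_weights(
    clusters: Mapping[str, Sequence[str]],
    per_cluster_normalized: bool = False,
) -> dict[str, float]:
    """Summary-statistic weights for predicted Acrs.

    Default: each member weighs 1/n where n is its cluster's size.  With
    ``per_cluster_normalized`` each cluster first gets 1/n_c (n_c = number
    of clusters) which is then split among members; the two differ only by
    the global constant 1/n_c, so weighted means are identical.
    """
    n_c = max(len(clusters), 1)
    weights: dict[str, float] = {}
    for cid, members in clusters.items():
        if not members:
            continue
        w = 1.0 / len(members)
        if per_cluster_normalized:
            w /= n_c
        for m in members:
            weights[m] = w
    return weights


def _kmer_set(seq: str, k: int) -> set[str]:
    if len(seq) < k:
        return {seq}
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def greedy_cluster(
    sequences: Mapping[str, str],
    min_coverage: float = 0.5,
    min_identity: float = 0.4,
    k: int = 4,
) -> dict[str, list[str]]:
    """Deterministic greedy centroid clustering by k-mer identity.

    A lightweight stand-in used for fixtures and tests: sequences are
    visited longest-first; each joins the first centroid whose k-mer
    containment (shared k-mers over the shorter sequence's k-mers, an
    alignment-free identity estimate) reaches ``min_identity`` and whose
    length ratio reaches ``min_coverage``, else it founds a new cluster.
    Externally produced cluster tables (e.g. mmseqs2) are the first-class
    input; this exists so tests need no external binary.
    """
    if not sequences:
        raise ValueError("no sequences")
    order = sorted(sequences, key=lambda s: (-len(sequences[s]), s))
    centroids: list[tuple[str, str, set[str]]] = []  # (id, seq, kmers)
    clusters: dict[str, list[str]] = {}
    for sid in order:
        seq = sequences[sid]
        kmers = _kmer_set(seq, k)
        placed = False
        for cid, cseq, ckmers in centroids:
            cov = min(len(seq), len(cseq)) / max(len(seq), len(cseq))
            if cov < min_coverage:
                continue
            denom = min(len(kmers), len(ckmers))
            ident = len(kmers & ckmers) / denom if denom else 0.0
            if ident >= min_identity:
                clusters[cid].append(sid)
                placed = True
                break
        if not placed:
            centroids.append((sid, seq, kmers))
            clusters[sid] = [sid]
    return clusters


def weighted_mean_sd(
    values: Sequence[float], weights: Sequence[float]
) -> tuple[float, float]:
    """Weighted mean and SD under the frequency-weight convention
    (population SD of the weighted distribution)."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.shape != weights.shape:
        raise ValueError("values and weights must have the same length")
    total = weights.sum()
    if total <= 0:
        raise ValueError("total weight must be > 0")
    mean = float(np.sum(weights * values) / total)
    var = float(np.sum(weights * (values - mean) ** 2) / total)
    return mean, math.sqrt(max(var, 0.0))


def load_cluster_tsv(path) -> dict[str, list[str]]:
    """2-column TSV (cluster_id, protein_id) -> cluster table."""
    clusters: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cid, pid = line.split("\t")[:2]
            clusters.setdefault(cid, []).append(pid)
    return clusters


def write_cluster_tsv(clusters: Mapping[str, Sequence[str]], path) -> None:
    with open(path, "w") as fh:
        for cid in sorted(clusters):
            for pid in clusters[cid]:
                fh.write(f"{cid}\t{pid}\n")
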