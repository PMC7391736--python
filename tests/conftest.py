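"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from acrminer.genome import Assembly, GeneRecord


def make_gene(
    gene_id: str,
    start: int,
    aa_length: int = 100,
    strand: str = "+",
    contig: str = "c1",
    seq: str | None = None,
) -> GeneRecord:
    """Gene whose nucleotide span is 3*aa_length + 3 (stop included)."""
    return GeneRecord(
        gene_id=gene_id,
        protein_id=gene_id,
        contig_id=contig,
        start=start,
        end=start + aa_length * 3 + 2,
        strand=strand,
        aa_length=aa_length,
        aa_sequence=seq,
    )


def random_contig_genes(rng: np.random.Generator, n: int, contig: str = "c1"):
    """n genes at random positions/strands on one contig."""
    genes = []
    pos = 1
    for i in range(n):
        pos += int(rng.integers(1, 400))
        aa = int(rng.integers(20, 300))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(make_gene(f"{contig}_g{i}", pos, aa, strand, contig))
        pos = genes[-1].end
    return genes


def oracle_directon_partition(genes, max_gap_bp: int = 100):
    """Brute-force grouping: test every adjacent pair independently and
    form connected runs (union of adjacent links)."""
    genes = sorted(genes, key=lambda g: (g.contig_id, g.start, g.end))
    links = []
    for a, b in zip(genes, genes[1:]):
        gap = max(0, b.start - a.end - 1)
        links.append(
            a.contig_id == b.contig_id
            and a.strand == b.strand
            and gap <= max_gap_bp
        )
    groups, current = [], [genes[0]] if genes else []
    for linked, g in zip(links, genes[1:]):
        if linked:
            current.append(g)
        else:
            groups.append(current)
            current = [g]
    if current:
        groups.append(current)
    return [tuple(g.protein_id for g in grp) for grp in groups]


def oracle_weighted_auc(scores, labels, weights=None) -> float:
    """O(n^2) weighted pairwise concordance; ties earn half credit."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    weights = np.ones(len(labels)) if weights is None else np.asarray(weights)
    num = den = 0.0
    for i in np.flatnonzero(labels == 1):
        for j in np.flatnonzero(labels == 0):
            w = weights[i] * weights[j]
            den += w
            if scores[i] > scores[j]:
                num += w
            elif scores[i] == scores[j]:
                num += 0.5 * w
    return num / den


def oracle_permutation_pvalue_exact(scores, labels, weights=None) -> float:
    """Exact p-value by enumerating every permutation of the scores."""
    obs = oracle_weighted_auc(scores, labels, weights)
    n_ge = 0
    total = 0
    for perm in itertools.permutations(scores):
        total += 1
        if oracle_weighted_auc(perm, labels, weights) >= obs:
            n_ge += 1
    return n_ge / total


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def toy_assembly():
    """Five genes, two directons on '+' (gap 50) and one on '-'."""
    genes = [
        make_gene("g1", 100, 100, "+"),
        make_gene("g2", 100 + 303 + 51, 100, "+"),  # gap 50 from g1
        make_gene("g3", 2000, 150, "-"),
        make_gene("g4", 5000, 80, "+"),
        make_gene("g5", 5000 + 243 + 20, 80, "+"),  # gap 19 from g4
    ]
    return Assembly(assembly_id="toy", genes=genes)
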