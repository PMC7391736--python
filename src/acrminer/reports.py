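"""Pipeline orchestration, candidate summaries, and the neighborhood matrix.

The presence-absence matrix mirrors how predicted Acr families recur in
genomic neighborhoods: each column is one neighborhood (the +/-10-gene
window around an anchor Acr, recursively extended around any further
predicted Acr inside the window) and each row one family; columns are
ordered by content similarity (Jaccard, average-linkage leaf order).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import pdist

from .annotations import detect_self_targeting, load_hit_table, load_spacer_fasta
from .cascade import CandidateFamily, MemberFlags, apply_cascade
from .classifier import predict_scores, train_forest
from .features import (
    FINAL_MODEL_FEATURES,
    build_context,
    feature_matrix,
    isoelectric_point,
)
from .genome import Assembly, parse_assembly
from .search_space import build_search_space
from .weighting import (
    candidate_cluster_weights,
    greedy_cluster,
    load_cluster_tsv,
    weighted_mean_sd,
)

__all__ = [
    "NeighborhoodMatrix",
    "build_presence_absence",
    "summarize_candidates",
    "run_pipeline",
]


@dataclass
class NeighborhoodMatrix:
    """Binary family-by-neighborhood table."""

    table: pd.DataFrame  # rows: family ids; columns: neighborhood ids

    @property
    def shape(self) -> tuple[int, int]:
        return self.table.shape

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t")


def _gene_positions(assemblies: Sequence[Assembly]) -> dict[str, tuple[str, str, int]]:
    pos: dict[str, tuple[str, str, int]] = {}
    for asm in assemblies:
        by_contig: dict[str, list] = {}
        for g in asm.genes:
            by_contig.setdefault(g.contig_id, []).append(g)
        for contig, genes in by_contig.items():
            for i, g in enumerate(sorted(genes, key=lambda g: g.start)):
                pos[g.protein_id] = (asm.assembly_id, contig, i)
    return pos


def build_presence_absence(
    top_families: Mapping[str, Sequence[str]],
    assemblies: Sequence[Assembly],
    window: int = 10,
) -> NeighborhoodMatrix:
    """Presence-absence matrix of families across genomic neighborhoods.

    A neighborhood starts as the ``window`` genes on each side of an anchor
    Acr; if another predicted Acr falls inside, the window extends around
    it too, to a fixed point.  Windows truncate at contig ends.  Identical
    extended windows collapse to one column.
    """
    positions = _gene_positions(assemblies)
    member_family: dict[str, str] = {}
    for fam, members in top_families.items():
        for m in members:
            member_family[m] = fam
    contig_genes: dict[tuple[str, str], list[str]] = {}
    for asm in assemblies:
        by_contig: dict[str, list] = {}
        for g in asm.genes:
            by_contig.setdefault(g.contig_id, []).append(g)
        for contig, genes in by_contig.items():
            contig_genes[(asm.assembly_id, contig)] = [
                g.protein_id for g in sorted(genes, key=lambda g: g.start)
            ]

    neighborhoods: dict[tuple, set[str]] = {}
    for fam, members in top_families.items():
        for anchor in members:
            if anchor not in positions:
                warnings.warn(f"anchor {anchor} has no coordinates; skipped")
                continue
            asm_id, contig, idx = positions[anchor]
            order = contig_genes[(asm_id, contig)]
            lo, hi = max(0, idx - window), min(len(order), idx + window + 1)
            changed = True
            while changed:
                changed = False
                for j in range(lo, hi):
                    if order[j] in member_family:
                        nlo = max(0, j - window)
                        nhi = min(len(order), j + window + 1)
                        if nlo < lo or nhi > hi:
                            lo, hi = min(lo, nlo), max(hi, nhi)
                            changed = True
            key = (asm_id, contig, lo, hi)
            neighborhoods[key] = set(order[lo:hi])

    fam_ids = sorted(top_families)
    col_ids = [f"{a}:{c}:{lo}-{hi}" for (a, c, lo, hi) in sorted(neighborhoods)]
    mat = np.zeros((len(fam_ids), len(col_ids)), dtype=int)
    for j, key in enumerate(sorted(neighborhoods)):
        content = neighborhoods[key]
        for i, fam in enumerate(fam_ids):
            if content & set(top_families[fam]):
                mat[i, j] = 1
    df = pd.DataFrame(mat, index=fam_ids, columns=col_ids)
    if df.shape[1] > 2:
        # order columns by Jaccard similarity of family content
        d = pdist(df.T.values, metric="jaccard")
        d = np.nan_to_num(d, nan=1.0)
        order = leaves_list(average(d))
        df = df.iloc[:, order]
    return NeighborhoodMatrix(table=df)


def summarize_candidates(
    candidates: pd.DataFrame, weights: Optional[Mapping[str, float]] = None
) -> dict:
    """Weighted summary statistics of a candidate table.

    ``candidates`` needs a ``protein_id`` column plus any of:
    protein_length, directon_size, directon_mean_protein_length,
    mean_hydrophobicity, isoelectric_point / aa_sequence,
    membrane_associated, species, crispr_subtype.
    """
    df = candidates.copy()
    if weights is not None:
        w = df["protein_id"].map(weights).fillna(0.0).to_numpy()
    elif "weight" in df:
        w = df["weight"].to_numpy(dtype=float)
    else:
        w = np.ones(len(df))
    if "isoelectric_point" not in df and "aa_sequence" in df:
        df["isoelectric_point"] = df["aa_sequence"].map(isoelectric_point)
    report: dict = {"n_candidates": int(len(df)), "total_weight": float(w.sum())}
    for col in (
        "protein_length",
        "directon_size",
        "directon_mean_protein_length",
        "isoelectric_point",
        "mean_hydrophobicity",
    ):
        if col in df:
            mean, sd = weighted_mean_sd(df[col].to_numpy(dtype=float), w)
            report[col] = {"weighted_mean": mean, "weighted_sd": sd}
    if "membrane_associated" in df:
        mean, _ = weighted_mean_sd(
            df["membrane_associated"].to_numpy(dtype=float), w
        )
        report["membrane_associated_fraction"] = mean
    for col in ("species", "crispr_subtype"):
        if col in df:
            tally: dict[str, float] = {}
            for val, wi in zip(df[col], w):
                tally[val] = tally.get(val, 0.0) + wi
            total = sum(tally.values()) or 1.0
            report[f"{col}_weighted_share"] = {
                k: v / total for k, v in sorted(tally.items())
            }
    return report


def run_pipeline(config: Mapping, outdir: str | Path, seed: int = 0) -> dict:
    """Run parse -> flags -> features -> train/score -> search space ->
    cluster weights -> cascade -> reports on files named in ``config``.

    ``config`` keys (paths): ``gene_table``, ``protein_fasta``,
    ``contig_fasta``, ``hit_tables`` (mapping database_tag -> path),
    ``spacer_fasta``, ``labels`` (training labels TSV), optional
    ``clusters``.  Every stage's output lands under ``outdir``; the
    returned manifest lists them.  Any stage failure raises with the stage
    name.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed, "outputs": {}}

    def stage(name):
        manifest["stage"] = name
        return name

    try:
        stage("parse")
        for key in ("gene_table", "hit_tables", "spacer_fasta", "labels"):
            if key not in config:
                raise KeyError(f"config missing required input {key!r}")
        asm = parse_assembly(
            config["gene_table"], "gene_tsv",
            protein_fasta=config.get("protein_fasta"),
            contig_fasta=config.get("contig_fasta"),
            has_crispr=True,
        )
        hits = []
        for tag, path in config["hit_tables"].items():
            hits.extend(load_hit_table(path, tag))

        stage("flags")
        spacers = load_spacer_fasta(config["spacer_fasta"], asm.assembly_id)
        st = detect_self_targeting(asm.contig_sequences or None, spacers)
        ctx = build_context(asm, hits, self_targeting=bool(st))

        stage("features")
        X = feature_matrix(ctx)
        X.to_csv(outdir / "features.tsv", sep="\t")
        manifest["outputs"]["features"] = str(outdir / "features.tsv")

        stage("train")
        labels_df = pd.read_csv(config["labels"], sep="\t").set_index("protein_id")
        y = labels_df.loc[X.index, "label"].to_numpy()
        Xf = X[list(FINAL_MODEL_FEATURES)].to_numpy()
        forest = train_forest(
            Xf, y, n_trees=int(config.get("n_trees", 200)), seed=seed
        )

        stage("score")
        scores = predict_scores(forest, Xf)
        score_df = pd.DataFrame(
            {"protein_id": X.index, "score": scores, "label": y}
        )
        score_df.to_csv(outdir / "scores.tsv", sep="\t", index=False)
        manifest["outputs"]["scores"] = str(outdir / "scores.tsv")

        stage("search_space")
        pvog = [h for h in hits if h.database_tag == "pVOG"]
        space = build_search_space([asm], {asm.assembly_id: pvog})
        (outdir / "search_space.txt").write_text(
            "\n".join(sorted(space)) + "\n"
        )
        manifest["outputs"]["search_space"] = str(outdir / "search_space.txt")

        stage("clustering")
        threshold = float(config.get("score_threshold", 0.5))
        predicted = [
            pid for pid, s in zip(X.index, scores)
            if s >= threshold and pid in space
        ]
        if "clusters" in config:
            clusters = load_cluster_tsv(config["clusters"])
            clusters = {
                cid: [m for m in members if m in predicted]
                for cid, members in clusters.items()
            }
            clusters = {c: m for c, m in clusters.items() if m}
        else:
            seqs = {
                g.protein_id: g.aa_sequence
                for g in asm.genes
                if g.protein_id in predicted and g.aa_sequence
            }
            clusters = greedy_cluster(seqs) if seqs else {}
        weights = candidate_cluster_weights(clusters)

        stage("cascade")
        viral_members = {
            h.protein_id for h in pvog if h.e_value <= 1e-4
        }
        fams = []
        for cid, members in clusters.items():
            flags = [
                MemberFlags(
                    protein_id=m,
                    hth_downstream=ctx.hth.get(m, False),
                    self_targeting=ctx.self_targeting,
                    in_virus_genome=asm.is_viral,
                )
                for m in members
            ]
            dsizes = [ctx.directon_of[m].size for m in members]
            # without external homolog searches, members inside provirus
            # blocks stand in for provirus homologs
            fams.append(CandidateFamily(
                cluster_id=cid,
                members=flags,
                mean_directon_size=float(np.mean(dsizes)) if dsizes else 1.0,
                n_provirus_homologs=sum(1 for m in members if m in space),
                n_virus_hits=sum(
                    1 for m in members
                    if m in viral_members or asm.is_viral
                ),
            ))
        survivors, report = apply_cascade(fams)
        (outdir / "filter_report.json").write_text(report.to_json())
        manifest["outputs"]["filter_report"] = str(outdir / "filter_report.json")

        stage("report")
        cand_rows = []
        for f in survivors:
            for m in f.members:
                g = next(g for g in asm.genes if g.protein_id == m.protein_id)
                cand_rows.append({
                    "protein_id": m.protein_id,
                    "protein_length": g.aa_length,
                    "directon_size": ctx.directon_of[m.protein_id].size,
                    "aa_sequence": g.aa_sequence,
                })
        summary = (
            summarize_candidates(pd.DataFrame(cand_rows), weights)
            if cand_rows else {"n_candidates": 0}
        )
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
        manifest["outputs"]["summary"] = str(outdir / "summary.json")
        manifest["survivors"] = sorted(f.cluster_id for f in survivors)
    except Exception as exc:
        raise RuntimeError(
            f"pipeline stage {manifest.get('stage')!r} failed: {exc}"
        ) from exc
    manifest.pop("stage", None)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
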