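"""Self-contained synthetic fixtures with Acr-like class structure.

The generator emulates the *feature-space* statistics that separate known
anti-CRISPR proteins from the background — short proteins in short, poorly
annotated directons with an HTH gene downstream, enriched in self-targeting
and viral genomes — using published class-conditional means.  It emits the
same artifacts the pipeline ingests (gene tables, protein/contig FASTA,
outfmt-6 hit tables, spacer FASTA, cluster and label tables) so every
parser and every stage can be exercised without downloads.  It makes no
attempt at realistic sequence evolution: sequences are random residues with
class-tilted hydropathy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .annotations import MembraneTable, ProfileHit, SpacerSet
from .cascade import CandidateFamily, MemberFlags
from .features import FINAL_MODEL_FEATURES, KYTE_DOOLITTLE
from .genome import Assembly, GeneRecord
from .weighting import assign_family_weights, rebalance_classes, WeightedExample

__all__ = [
    "SimConfig",
    "ACR_STATS",
    "NONACR_STATS",
    "generate_assembly",
    "generate_training_matrix",
    "generate_candidate_families",
    "write_fixture",
    "SyntheticAssembly",
]

#: Class-conditional feature means for known Acrs.
ACR_STATS = {
    "protein_length": 104.11,
    "directon_mean_protein_length": 119.27,
    "directon_size": 3.49,
    "mean_hydrophobicity": -0.48,
    "p_annotated": 0.0641,
    "directon_annotated_fraction": 0.22,
    "p_hth_downstream": 0.4008,
    "p_self_targeting": 0.3344,
    "p_membrane": 0.0256,
    "directon_membrane_fraction": 0.06,
    "directon_spacing": 18.37,
    "p_prokaryote": 0.8956,
}

#: Class-conditional feature means for the background (non-Acr) proteins.
NONACR_STATS = {
    "protein_length": 245.54,
    "directon_mean_protein_length": 251.71,
    "directon_size": 3.5,
    "mean_hydrophobicity": -0.15,
    "p_annotated": 0.6731,
    "directon_annotated_fraction": 0.69,
    "p_hth_downstream": 0.1181,
    "p_self_targeting": 0.1919,
    "p_membrane": 0.2781,
    "directon_membrane_fraction": 0.26,
    "directon_spacing": 13.7,
    "p_prokaryote": 0.8958,
}

#: Log-scale SD of protein lengths (matches the observed heavy right tail:
#: SD ~ 0.66 * mean for the positive class).
LENGTH_LOG_SIGMA = 0.6
#: SD of per-protein mean hydrophobicity.
HYDRO_SIGMA = 0.5
#: Family-level random effect SDs (log-length, hydrophobicity).
FAMILY_LOG_SIGMA = 0.15
FAMILY_HYDRO_SIGMA = 0.1
#: Beta concentration for directon annotated fraction.
FRACTION_CONCENTRATION = 4.0

_AA = sorted(KYTE_DOOLITTLE)
_HYDROPHOBIC = [a for a in _AA if KYTE_DOOLITTLE[a] > 0]


@dataclass
class SimConfig:
    """Knobs of the genome-level generator.

    Defaults reproduce the published class-conditional means; the planted
    Acr directons sit inside generated provirus context (a viral-hit
    directon nearby) so the search-space stage can find them.
    """

    n_contigs: int = 1
    genes_per_contig: int = 60
    n_acr_directons: int = 2
    p_self_targeting: float = ACR_STATS["p_self_targeting"]
    spacer_length: int = 32
    n_decoy_spacers: int = 3
    acr_stats: dict = field(default_factory=lambda: dict(ACR_STATS))
    nonacr_stats: dict = field(default_factory=lambda: dict(NONACR_STATS))

    def __post_init__(self) -> None:
        if self.genes_per_contig < 8 * self.n_acr_directons + 2:
            raise ValueError(
                "contig too small for the requested planted Acr directons"
            )


@dataclass
class SyntheticAssembly:
    """Generated assembly plus every side table and the ground truth."""

    assembly: Assembly
    hits: list[ProfileHit]
    spacer_set: SpacerSet
    membrane: MembraneTable
    labels: dict[str, int]
    families: dict[str, str]
    clusters: dict[str, list[str]]
    self_targeting: bool


def _random_protein(rng: np.random.Generator, length: int,
                    hydrophobic_tilt: float = 0.0) -> str:
    """Random residues; ``hydrophobic_tilt`` is the probability of drawing
    from the hydrophobic subset instead of uniformly (uniform draws average
    a Kyte-Doolittle mean of about -0.49)."""
    n_tilt = rng.binomial(length, hydrophobic_tilt) if hydrophobic_tilt else 0
    seq = list(rng.choice(_AA, size=length - n_tilt))
    seq += list(rng.choice(_HYDROPHOBIC, size=n_tilt))
    rng.shuffle(seq)
    return "".join(seq)


def _draw_length(rng: np.random.Generator, mean: float,
                 sigma: float = LENGTH_LOG_SIGMA, offset: float = 0.0) -> int:
    mu = np.log(mean) - (sigma**2 + (FAMILY_LOG_SIGMA**2 if offset else 0)) / 2
    return max(20, int(round(np.exp(mu + offset + sigma * rng.normal()))))


def _beta_params(mean: float, conc: float = FRACTION_CONCENTRATION):
    mean = min(max(mean, 1e-3), 1 - 1e-3)
    return mean * conc, (1 - mean) * conc


def generate_training_matrix(
    n_pos: int,
    n_neg: int,
    seed: int,
    config: Optional[dict] = None,
    n_families: Optional[int] = None,
) -> pd.DataFrame:
    """Labeled, weighted feature matrix for training experiments.

    The 8 final-model features are drawn from class-conditional
    distributions: log-normal lengths, Bernoulli flags, a Beta for the
    annotated fraction, a shifted Poisson for directon size, and a normal
    for hydrophobicity, with means set to the class-conditional defaults.
    Positives carry synthetic family ids (with mild family-level random
    effects on length and hydrophobicity) for grouped cross-validation;
    weights follow the family/subfamily scheme with class rebalancing.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("n_pos and n_neg must be >= 1")
    rng = np.random.default_rng(seed)
    acr = dict(ACR_STATS)
    non = dict(NONACR_STATS)
    if config:
        acr.update(config.get("acr_stats", {}))
        non.update(config.get("nonacr_stats", {}))
    if n_families is None:
        n_families = max(min(8, n_pos), round(n_pos / 25))
    fam_of = rng.integers(n_families, size=n_pos)
    # guarantee every family non-empty when feasible
    if n_pos >= n_families:
        fam_of[:n_families] = np.arange(n_families)
    fam_len_eff = rng.normal(0, FAMILY_LOG_SIGMA, size=n_families)
    fam_hyd_eff = rng.normal(0, FAMILY_HYDRO_SIGMA, size=n_families)

    rows = []
    for i in range(n_pos):
        f = int(fam_of[i])
        rows.append({
            "protein_id": f"acr_{i}",
            "label": 1,
            "family_id": f"fam{f}",
            "self_targeting": int(rng.random() < acr["p_self_targeting"]),
            "directon_annotated_fraction": rng.beta(
                *_beta_params(acr["directon_annotated_fraction"])),
            "directon_mean_protein_length": _draw_length(
                rng, acr["directon_mean_protein_length"], 0.4, fam_len_eff[f]),
            "directon_size": 1 + rng.poisson(acr["directon_size"] - 1),
            "protein_is_annotated": int(rng.random() < acr["p_annotated"]),
            "hth_downstream": int(rng.random() < acr["p_hth_downstream"]),
            "protein_length": _draw_length(
                rng, acr["protein_length"], LENGTH_LOG_SIGMA, fam_len_eff[f]),
            "mean_hydrophobicity": rng.normal(
                acr["mean_hydrophobicity"] + fam_hyd_eff[f], HYDRO_SIGMA),
        })
    for i in range(n_neg):
        rows.append({
            "protein_id": f"neg_{i}",
            "label": 0,
            "family_id": "",
            "self_targeting": int(rng.random() < non["p_self_targeting"]),
            "directon_annotated_fraction": rng.beta(
                *_beta_params(non["directon_annotated_fraction"])),
            "directon_mean_protein_length": _draw_length(
                rng, non["directon_mean_protein_length"], 0.4),
            "directon_size": 1 + rng.poisson(non["directon_size"] - 1),
            "protein_is_annotated": int(rng.random() < non["p_annotated"]),
            "hth_downstream": int(rng.random() < non["p_hth_downstream"]),
            "protein_length": _draw_length(
                rng, non["protein_length"], LENGTH_LOG_SIGMA),
            "mean_hydrophobicity": rng.normal(
                non["mean_hydrophobicity"], HYDRO_SIGMA),
        })
    df = pd.DataFrame(rows)

    # family/subfamily weights for positives, weight 1 negatives, rebalance
    hierarchy: dict[str, dict[str, list[str]]] = {}
    for pid, fam in zip(df[df.label == 1].protein_id, df[df.label == 1].family_id):
        hierarchy.setdefault(fam, {}).setdefault(f"{fam}.s0", []).append(pid)
    # split larger families into two subfamilies for realism
    for fam, subs in hierarchy.items():
        members = subs[f"{fam}.s0"]
        if len(members) >= 4:
            half = len(members) // 2
            subs[f"{fam}.s1"] = members[half:]
            subs[f"{fam}.s0"] = members[:half]
    pos_w = assign_family_weights(hierarchy)
    examples = [
        WeightedExample(pid, "Acr", pos_w[pid], family_id=fam)
        for pid, fam in zip(df[df.label == 1].protein_id,
                            df[df.label == 1].family_id)
    ] + [
        WeightedExample(pid, "nonAcr", 1.0)
        for pid in df[df.label == 0].protein_id
    ]
    weight_of = {e.protein_id: e.weight for e in rebalance_classes(examples)}
    df["weight"] = df.protein_id.map(weight_of)
    return df[
        ["protein_id", "label", "family_id", "weight", *FINAL_MODEL_FEATURES]
    ]


def _emit_hits(rng, hits, pid, tag, desc="", evalue_exp=(5, 30)):
    evalue = 10.0 ** -rng.uniform(*evalue_exp)
    hits.append(ProfileHit(
        protein_id=pid,
        profile_id=f"{tag}_{rng.integers(10_000)}",
        database_tag=tag,
        e_value=float(evalue),
        profile_description=desc,
        identity_pct=float(rng.uniform(30, 95)),
    ))


def generate_assembly(
    config: SimConfig, seed: int
) -> SyntheticAssembly:
    """Generate one prokaryotic assembly with planted Acr directons.

    Background directons follow the non-Acr statistics (long, mostly
    annotated proteins); each planted Acr directon holds 1-3 short,
    unannotated Acr genes followed by an HTH (Aca-like) gene, and sits
    directly next to a directon of pVOG-hit (viral) genes, so the region
    is recovered as a provirus candidate.  If the assembly is chosen
    self-targeting, one CRISPR spacer is copied verbatim from the contig.
    Byte-identical outputs for identical (config, seed).
    """
    rng = np.random.default_rng(seed)
    acr, non = config.acr_stats, config.nonacr_stats
    assembly_id = f"syn{seed}"
    genes: list[GeneRecord] = []
    hits: list[ProfileHit] = []
    membrane_flags: dict[str, bool] = {}
    labels: dict[str, int] = {}
    families: dict[str, str] = {}
    contig_seqs: dict[str, str] = {}
    self_targeting = bool(rng.random() < config.p_self_targeting)
    gid = 0

    def new_gene(contig, pos, strand, length, seq):
        nonlocal gid
        g = GeneRecord(
            gene_id=f"{assembly_id}_g{gid}",
            protein_id=f"{assembly_id}_g{gid}",
            contig_id=contig,
            start=pos,
            end=pos + length * 3 + 2,  # CDS includes stop codon
            strand=strand,
            aa_length=length,
            aa_sequence=seq,
        )
        gid += 1
        return g

    for c in range(config.n_contigs):
        contig = f"{assembly_id}_c{c}"
        pos = 1 + int(rng.integers(50, 200))
        n_background = config.genes_per_contig - config.n_acr_directons * 4
        # decide where the planted regions interleave with background
        plant_after = set(
            rng.choice(
                np.arange(5, max(6, n_background - 5)),
                size=config.n_acr_directons if c == 0 else 0,
                replace=False,
            ).tolist()
        )
        emitted = 0
        directon_left = 0
        strand = "+"
        while emitted < n_background:
            if directon_left == 0:
                directon_left = 1 + int(rng.poisson(non["directon_size"] - 1))
                strand = "+" if rng.random() < 0.5 else "-"
                pos += 102 + int(rng.exponential(300))
            else:
                pos += 1 + int(
                    min(100, rng.exponential(non["directon_spacing"]))
                )
            length = _draw_length(rng, non["protein_length"])
            seq = _random_protein(rng, length, hydrophobic_tilt=0.0955)
            g = new_gene(contig, pos, strand, length, seq)
            genes.append(g)
            labels[g.protein_id] = 0
            membrane_flags[g.protein_id] = rng.random() < non["p_membrane"]
            if rng.random() < non["p_annotated"]:
                _emit_hits(rng, hits, g.protein_id, "CDD",
                           desc=f"DUF{rng.integers(100, 4000)} domain protein")
            elif rng.random() < 0.15:
                _emit_hits(rng, hits, g.protein_id, "CDD",
                           desc="hypothetical protein")
            if rng.random() < non["p_hth_downstream"] * 0.5:
                _emit_hits(rng, hits, g.protein_id, "HTH",
                           desc="HTH domain", evalue_exp=(4, 20))
            pos = g.end
            directon_left -= 1
            emitted += 1

            if emitted in plant_after:
                # --- provirus context: a viral directon ---
                pos += 102 + int(rng.exponential(300))
                vstrand = "+"
                for _ in range(int(rng.integers(2, 4))):
                    length = _draw_length(rng, non["protein_length"])
                    seq = _random_protein(rng, length, 0.0955)
                    vg = new_gene(contig, pos, vstrand, length, seq)
                    genes.append(vg)
                    labels[vg.protein_id] = 0
                    membrane_flags[vg.protein_id] = False
                    _emit_hits(rng, hits, vg.protein_id, "pVOG",
                               desc="phage structural protein")
                    pos = vg.end + 1 + int(rng.integers(0, 60))
                # --- the Acr directon, adjacent (next directon) ---
                pos += 102 + int(rng.exponential(150))
                fam = f"{assembly_id}_acrfam{len(set(families.values()))}"
                n_acr_genes = int(rng.integers(1, 4))
                for _ in range(n_acr_genes):
                    length = _draw_length(rng, acr["protein_length"])
                    seq = _random_protein(rng, length, 0.0)
                    ag = new_gene(contig, pos, vstrand, length, seq)
                    genes.append(ag)
                    labels[ag.protein_id] = 1
                    families[ag.protein_id] = fam
                    membrane_flags[ag.protein_id] = (
                        rng.random() < acr["p_membrane"]
                    )
                    if rng.random() < acr["p_annotated"]:
                        _emit_hits(rng, hits, ag.protein_id, "CDD",
                                   desc=f"DUF{rng.integers(100, 4000)}")
                    pos = ag.end + 1 + int(
                        min(100, rng.exponential(acr["directon_spacing"]))
                    )
                # the Aca-like HTH gene closing the directon
                length = max(20, int(rng.normal(80, 15)))
                seq = _random_protein(rng, length, 0.0)
                hg = new_gene(contig, pos, vstrand, length, seq)
                genes.append(hg)
                labels[hg.protein_id] = 0
                membrane_flags[hg.protein_id] = False
                _emit_hits(rng, hits, hg.protein_id, "HTH",
                           desc="helix-turn-helix domain", evalue_exp=(4, 20))
                pos = hg.end
                directon_left = 0  # next background gene opens a new directon

        contig_len = pos + int(rng.integers(100, 400))
        contig_seqs[contig] = "".join(
            rng.choice(list("ACGT"), size=contig_len)
        )

    spacers = []
    first_contig = f"{assembly_id}_c0"
    seq0 = contig_seqs[first_contig]
    if self_targeting:
        off = int(rng.integers(0, len(seq0) - config.spacer_length))
        spacers.append(seq0[off : off + config.spacer_length])
    for _ in range(config.n_decoy_spacers):
        while True:
            decoy = "".join(rng.choice(list("ACGT"), size=config.spacer_length))
            if decoy not in seq0:
                break
        spacers.append(decoy)

    assembly = Assembly(
        assembly_id=assembly_id,
        genes=genes,
        contig_lengths={c: len(s) for c, s in contig_seqs.items()},
        contig_sequences=contig_seqs,
        is_viral=False,
        has_crispr=True,
    )
    clusters: dict[str, list[str]] = {}
    for pid, fam in families.items():
        clusters.setdefault(fam, []).append(pid)
    return SyntheticAssembly(
        assembly=assembly,
        hits=hits,
        spacer_set=SpacerSet(assembly_id=assembly_id, spacers=spacers),
        membrane=MembraneTable(membrane_flags),
        labels=labels,
        families=families,
        clusters=clusters,
        self_targeting=self_targeting,
    )


def generate_candidate_families(
    n_acr: int,
    n_background: int,
    seed: int,
) -> tuple[list[CandidateFamily], list[str]]:
    """Planted-truth candidate families for cascade experiments.

    Acr-like families are larger (known families have many members), with
    per-member hallmark probabilities near the known-Acr rates, small
    directons, few prokaryotic homologs relative to provirus homologs and
    few HHblits annotations.  Background families are mostly small (about
    half the real candidate clusters are singletons) with background
    hallmark rates and broadly distributed homolog counts.  Returns the
    families (shuffled) and the list of planted cluster ids.
    """
    rng = np.random.default_rng(seed)
    families: list[CandidateFamily] = []
    planted: list[str] = []

    for i in range(n_acr):
        cid = f"acr{i}"
        planted.append(cid)
        size = 1 + int(rng.poisson(5))
        members = [
            MemberFlags(
                protein_id=f"{cid}_m{j}",
                hth_downstream=rng.random() < 0.55,
                self_targeting=rng.random() < ACR_STATS["p_self_targeting"],
                in_virus_genome=rng.random() < 0.30,
            )
            for j in range(size)
        ]
        families.append(CandidateFamily(
            cluster_id=cid,
            members=members,
            mean_directon_size=float(
                np.clip(rng.normal(ACR_STATS["directon_size"], 0.8), 1, None)
            ),
            n_prok_homologs=int(rng.poisson(20)),
            n_provirus_homologs=1 + int(rng.poisson(10)),
            n_virus_hits=int(rng.poisson(0.8)),
            n_hhblits_hits=int(rng.poisson(8)),
            contains_known_acr=True,
        ))
    for i in range(n_background):
        cid = f"bg{i}"
        size = 1 + int(rng.poisson(2.8))
        members = [
            MemberFlags(
                protein_id=f"{cid}_m{j}",
                hth_downstream=rng.random() < NONACR_STATS["p_hth_downstream"],
                self_targeting=rng.random() < NONACR_STATS["p_self_targeting"],
                in_virus_genome=rng.random() < 0.05,
            )
            for j in range(size)
        ]
        families.append(CandidateFamily(
            cluster_id=cid,
            members=members,
            mean_directon_size=float(
                np.clip(rng.normal(NONACR_STATS["directon_size"], 1.5), 1, None)
            ),
            n_prok_homologs=int(np.exp(rng.normal(np.log(150), 1.5))),
            n_provirus_homologs=int(rng.poisson(1.0)),
            n_virus_hits=int(rng.poisson(0.05)),
            n_hhblits_hits=int(rng.poisson(20)),
            contains_known_acr=False,
        ))
    rng.shuffle(families)
    return families, planted


# ---------------------------------------------------------------------------
# Fixture serialization (round-trips through the package's own parsers)


def write_fixture(sim: SyntheticAssembly, outdir: str | Path) -> dict[str, Path]:
    """Write every generated artifact in its ingestion format."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    asm = sim.assembly
    paths: dict[str, Path] = {}

    gene_tsv = outdir / f"{asm.assembly_id}.genes.tsv"
    with open(gene_tsv, "w") as fh:
        fh.write("assembly\tcontig\tgene_id\tstart\tend\tstrand\taa_length\n")
        for g in asm.genes:
            fh.write(
                f"{asm.assembly_id}\t{g.contig_id}\t{g.gene_id}\t{g.start}\t"
                f"{g.end}\t{g.strand}\t{g.aa_length}\n"
            )
    paths["gene_tsv"] = gene_tsv

    prot_fa = outdir / f"{asm.assembly_id}.proteins.faa"
    with open(prot_fa, "w") as fh:
        for g in asm.genes:
            fh.write(f">{g.protein_id}\n{g.aa_sequence}\n")
    paths["protein_fasta"] = prot_fa

    contig_fa = outdir / f"{asm.assembly_id}.fna"
    with open(contig_fa, "w") as fh:
        for cid, seq in asm.contig_sequences.items():
            fh.write(f">{cid}\n{seq}\n")
    paths["contig_fasta"] = contig_fa

    by_tag: dict[str, list[ProfileHit]] = {}
    for h in sim.hits:
        by_tag.setdefault(h.database_tag, []).append(h)
    for tag, tag_hits in by_tag.items():
        p = outdir / f"{asm.assembly_id}.{tag}.hits.tsv"
        with open(p, "w") as fh:
            for h in tag_hits:
                fh.write(
                    f"{h.protein_id}\t{h.profile_id}\t{h.identity_pct:.1f}\t"
                    f"100\t0\t0\t1\t100\t1\t100\t{h.e_value:.3e}\t200.0\t"
                    f"{h.profile_description}\n"
                )
        paths[f"hits_{tag}"] = p

    spacer_fa = outdir / f"{asm.assembly_id}.spacers.fna"
    with open(spacer_fa, "w") as fh:
        for i, s in enumerate(sim.spacer_set.spacers):
            fh.write(f">spacer_{i}\n{s}\n")
    paths["spacer_fasta"] = spacer_fa

    cluster_tsv = outdir / f"{asm.assembly_id}.clusters.tsv"
    with open(cluster_tsv, "w") as fh:
        for cid in sorted(sim.clusters):
            for pid in sim.clusters[cid]:
                fh.write(f"{cid}\t{pid}\n")
    paths["cluster_tsv"] = cluster_tsv

    labels_tsv = outdir / f"{asm.assembly_id}.labels.tsv"
    with open(labels_tsv, "w") as fh:
        fh.write("protein_id\tlabel\tfamily_id\n")
        for g in asm.genes:
            fh.write(
                f"{g.protein_id}\t{sim.labels[g.protein_id]}\t"
                f"{sim.families.get(g.protein_id, '')}\n"
            )
    paths["labels_tsv"] = labels_tsv
    return paths
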