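"""Seeded generators for every pipeline input, with planted ground truth.

The generators emulate, at reduced scale, the data shapes of a
multicomponent-drug study: a compound table from a herbal-ingredient
database, a compound-target prediction export with confidence scores,
effector-process gene sets, a protein FASTA, and a protein x sample
intensity matrix over a six-arm animal design (control, disease model,
three dose arms and a positive-control drug arm, six animals per arm).

Two signals can be planted: a *relevant pathway* whose member targets
receive extra interacting compounds and higher prediction scores, and
*candidate proteins* following the disease-up / dose-monotone-down
profile.  Every generator is a pure function of (parameters, seed):
regeneration with the same arguments is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import Compound, GroupDesign, PathwayGeneSet, ProteinSeq, UsageError
from .io import write_design, write_fasta, write_gmt, write_table

# substream tags keep the network and proteome draws independent
_NET_STREAM = 11
_PROT_STREAM = 23
_MAP_STREAM = 37

HERBS = (
    "codonopsis_radix",
    "atractylodis_rhizoma",
    "crataegi_fructus",
    "nelumbinis_semen",
    "poria",
    "citri_pericarpium",
)

#: Dose-arm multipliers of the planted candidate profile, relative to control:
#: doubled in the disease model, then 0.9x / 0.7x / 0.5x of the model level
#: under increasing dose; the positive-control arm partially normalises.
CANDIDATE_PROFILE = {
    "control": 1.0,
    "model": 2.0,
    "low": 1.8,
    "medium": 1.4,
    "high": 1.0,
    "positive": 1.2,
}

DEFAULT_GROUPS = ("control", "model", "low", "medium", "high", "positive")
DEFAULT_LADDER = ["control", "model", "low", "medium", "high"]

AMINO_ACIDS = "ACDEFGHILMNPQSTVWY"  # the 18 non-K/R standard residues


@dataclass
class SyntheticTruth:
    """Ground truth planted by a generator, serialisable next to its outputs."""

    seed: int
    planted_pathway_id: str | None = None
    planted_accessions: tuple[str, ...] = ()
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "planted_pathway_id": self.planted_pathway_id,
            "planted_accessions": list(self.planted_accessions),
            "params": self.params,
        }

    def write(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def gen_compound_table(n_compounds: int, seed: int) -> list[Compound]:
    """Compound ids cycled over the six source herbs."""
    return [
        Compound(f"C{i + 1:04d}", HERBS[i % len(HERBS)]) for i in range(n_compounds)
    ]


def gen_network_instance(
    n_compounds: int = 50,
    n_targets: int = 80,
    n_pathways: int = 12,
    pathway_size: int = 8,
    seed: int = 0,
    background_degree: float = 3.0,
    score_range: tuple[float, float] = (20.0, 100.0),
    boost_compounds: int = 5,
    boost_score_range: tuple[float, float] = (60.0, 100.0),
    n_decoy_pathways: int = 0,
) -> tuple[pd.DataFrame, list[PathwayGeneSet], SyntheticTruth]:
    """Interaction table plus gene sets with one planted relevant pathway.

    Background: each target interacts with ``1 + Poisson(background_degree - 1)``
    distinct compounds, scores uniform over ``score_range`` (the default
    20..100 makes the usual 40 threshold bite).  The planted pathway's
    member targets each gain ``boost_compounds`` extra distinct compounds
    with scores from ``boost_score_range``; ``boost_compounds = 0`` plants
    nothing (null instance).  Decoy pathways are generated identically to
    real ones but are meant to be left off the effector list.
    """
    if min(n_compounds, n_targets, n_pathways, pathway_size) <= 0:
        raise UsageError("all sizes must be positive")
    if pathway_size > n_targets:
        raise UsageError("pathway_size exceeds n_targets")
    if background_degree < 1.0:
        raise UsageError("background_degree must be >= 1")
    rng = np.random.default_rng([_NET_STREAM, seed])
    compounds = [f"C{i + 1:04d}" for i in range(n_compounds)]
    targets = [f"T{i + 1:04d}" for i in range(n_targets)]

    total_sets = n_pathways + n_decoy_pathways
    gene_sets = []
    for j in range(total_sets):
        members = rng.choice(targets, size=pathway_size, replace=False)
        pid = f"PW{j + 1:02d}" if j < n_pathways else f"DECOY{j - n_pathways + 1:02d}"
        gene_sets.append(PathwayGeneSet(pid, f"process {pid}", frozenset(members.tolist())))
    planted_id = gene_sets[0].pathway_id

    edges: dict[tuple[str, str], float] = {}
    lo, hi = score_range
    for t in targets:
        k = min(1 + int(rng.poisson(background_degree - 1.0)), n_compounds)
        for c in rng.choice(compounds, size=k, replace=False):
            s = float(rng.uniform(lo, hi))
            key = (str(c), t)
            edges[key] = max(edges.get(key, 0.0), s)
    if boost_compounds > 0:
        blo, bhi = boost_score_range
        for t in sorted(gene_sets[0].members):
            have = {c for (c, tt) in edges if tt == t}
            free = [c for c in compounds if c not in have]
            take = min(boost_compounds, len(free))
            for c in rng.choice(free, size=take, replace=False):
                edges[(str(c), t)] = float(rng.uniform(blo, bhi))

    df = pd.DataFrame(
        [(c, t, s) for (c, t), s in edges.items()],
        columns=["compound_id", "target_id", "score"],
    ).sort_values(["compound_id", "target_id"], kind="mergesort").reset_index(drop=True)
    truth = SyntheticTruth(
        seed=seed,
        planted_pathway_id=planted_id,
        params={
            "n_compounds": n_compounds,
            "n_targets": n_targets,
            "n_pathways": n_pathways,
            "pathway_size": pathway_size,
            "background_degree": background_degree,
            "score_range": list(score_range),
            "boost_compounds": boost_compounds,
            "boost_score_range": list(boost_score_range),
            "n_decoy_pathways": n_decoy_pathways,
        },
    )
    return df, gene_sets, truth


def _random_sequence(rng: np.random.Generator, length: int, kr_freq: float) -> str:
    """Random protein sequence with K+R at frequency ``kr_freq``."""
    letters = list(AMINO_ACIDS) + ["K", "R"]
    p_other = (1.0 - kr_freq) / len(AMINO_ACIDS)
    probs = [p_other] * len(AMINO_ACIDS) + [kr_freq / 2, kr_freq / 2]
    return "".join(rng.choice(letters, size=length, p=probs))


def gen_proteome_instance(
    n_proteins: int = 300,
    n_planted: int = 3,
    n_per_group: int = 6,
    groups: tuple[str, ...] = DEFAULT_GROUPS,
    ladder: list[str] | None = None,
    seed: int = 0,
    cv: float = 0.10,
    profile: dict[str, float] | None = None,
    seq_len_range: tuple[int, int] = (50, 600),
    kr_freq: float = 0.11,
    base_log10_mean: float = 6.5,
    base_log10_sd: float = 0.6,
) -> tuple[list[ProteinSeq], pd.DataFrame, GroupDesign, SyntheticTruth]:
    """Protein FASTA, intensity matrix and group design with planted candidates.

    Sequences are random with lysine+arginine at natural frequency (~11%),
    which with lengths 50..600 leaves essentially every protein with at
    least one countable 6..30-mer.  Baseline abundances are log-normal
    (log10 mean 6.5, sd 0.6 — a plausible LFQ dynamic range); planted
    candidates scale group means by :data:`CANDIDATE_PROFILE`; measurement
    noise is multiplicative log-normal with the stated coefficient of
    variation (default 10%).
    """
    if n_planted > n_proteins:
        raise UsageError("more planted candidates than proteins")
    if n_planted < 0 or n_per_group < 2:
        raise UsageError("need n_planted >= 0 and n_per_group >= 2")
    if cv < 0:
        raise UsageError("cv must be >= 0")
    profile = dict(CANDIDATE_PROFILE if profile is None else profile)
    missing = [g for g in groups if g not in profile]
    if missing:
        raise UsageError(f"profile lacks multipliers for groups: {missing}")
    rng = np.random.default_rng([_PROT_STREAM, seed])
    accs = [f"P{i + 1:04d}" for i in range(n_proteins)]
    planted = tuple(sorted(rng.choice(accs, size=n_planted, replace=False).tolist()))

    lo, hi = seq_len_range
    seqs = [
        ProteinSeq(a, _random_sequence(rng, int(rng.integers(lo, hi + 1)), kr_freq))
        for a in accs
    ]

    samples = [f"{g}_{r + 1}" for g in groups for r in range(n_per_group)]
    design = GroupDesign(
        groups={s: s.rsplit("_", 1)[0] for s in samples},
        ladder=list(DEFAULT_LADDER if ladder is None else ladder),
    )
    base = 10.0 ** rng.normal(base_log10_mean, base_log10_sd, size=n_proteins)
    sigma = float(np.sqrt(np.log1p(cv * cv)))
    mat = np.empty((n_proteins, len(samples)))
    planted_set = set(planted)
    for i, acc in enumerate(accs):
        for j, s in enumerate(samples):
            g = design.groups[s]
            mult = profile[g] if acc in planted_set else 1.0
            noise = (
                float(rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma))
                if sigma > 0
                else 1.0
            )
            mat[i, j] = base[i] * mult * noise
    intensities = pd.DataFrame(mat, index=accs, columns=samples)
    truth = SyntheticTruth(
        seed=seed,
        planted_accessions=planted,
        params={
            "n_proteins": n_proteins,
            "n_planted": n_planted,
            "n_per_group": n_per_group,
            "groups": list(groups),
            "cv": cv,
            "profile": profile,
            "seq_len_range": list(seq_len_range),
            "kr_freq": kr_freq,
        },
    )
    return seqs, intensities, design, truth


def gen_mapping(
    targets: list[str],
    accessions: list[str],
    seed: int = 0,
    frac_mapped: float = 0.9,
    frac_isoform: float = 0.15,
) -> pd.DataFrame:
    """Target-to-accession mapping; some targets get a second (isoform) row.

    Each target maps to a distinct primary accession with probability
    ``frac_mapped``; mapped targets gain an extra accession (an isoform of
    the same gene product) with probability ``frac_isoform``.
    """
    if not 0 <= frac_mapped <= 1 or not 0 <= frac_isoform <= 1:
        raise UsageError("fractions must lie in [0, 1]")
    rng = np.random.default_rng([_MAP_STREAM, seed])
    pool = list(accessions)
    rng.shuffle(pool)
    rows = []
    for t in sorted(targets):
        if not pool:
            break
        if rng.uniform() < frac_mapped:
            rows.append((t, pool.pop()))
            if pool and rng.uniform() < frac_isoform:
                rows.append((t, pool.pop()))
    return pd.DataFrame(rows, columns=["target_id", "accession"])


def write_instance(
    outdir: str | Path,
    seed: int = 0,
    network_kwargs: dict | None = None,
    proteome_kwargs: dict | None = None,
    mapping_kwargs: dict | None = None,
) -> dict[str, Path]:
    """Generate and write a complete input instance; returns path map.

    Files: interactions.tsv, compounds.tsv, gene_sets.gmt, effectors.txt,
    proteome.fasta, intensities.tsv, design.tsv, mapping.tsv, truth.yaml.
    The effector list names every non-decoy pathway.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    interactions, gene_sets, net_truth = gen_network_instance(
        seed=seed, **(network_kwargs or {})
    )
    seqs, intensities, design, prot_truth = gen_proteome_instance(
        seed=seed, **(proteome_kwargs or {})
    )
    mapping = gen_mapping(
        sorted({t for s in gene_sets for t in s.members} | set(interactions["target_id"])),
        [p.accession for p in seqs],
        seed=seed,
        **(mapping_kwargs or {}),
    )
    compounds = gen_compound_table(net_truth.params["n_compounds"], seed)
    paths = {k: outdir / v for k, v in {
        "interactions": "interactions.tsv",
        "compounds": "compounds.tsv",
        "gene_sets": "gene_sets.gmt",
        "effectors": "effectors.txt",
        "fasta": "proteome.fasta",
        "intensities": "intensities.tsv",
        "design": "design.tsv",
        "mapping": "mapping.tsv",
        "truth": "truth.yaml",
    }.items()}
    write_table(interactions, paths["interactions"])
    write_table(
        pd.DataFrame(
            [(c.compound_id, c.herb) for c in compounds],
            columns=["compound_id", "herb"],
        ),
        paths["compounds"],
    )
    write_gmt(gene_sets, paths["gene_sets"])
    effector_ids = [s.pathway_id for s in gene_sets if not s.pathway_id.startswith("DECOY")]
    paths["effectors"].write_text("\n".join(effector_ids) + "\n", encoding="utf-8")
    write_fasta(seqs, paths["fasta"])
    out_int = intensities.copy()
    out_int.index.name = "accession"
    write_table(out_int, paths["intensities"], index=True)
    write_design(design, paths["design"])
    write_table(mapping, paths["mapping"])
    truth = SyntheticTruth(
        seed=seed,
        planted_pathway_id=net_truth.planted_pathway_id,
        planted_accessions=prot_truth.planted_accessions,
        params={"network": net_truth.params, "proteome": prot_truth.params},
    )
    truth.write(paths["truth"])
    return paths
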