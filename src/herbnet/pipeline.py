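"""End-to-end orchestration: simulate -> build -> score -> ibaq -> diff ->
enrich -> coverage -> discover, driven by one YAML config.

Every output table carries a header comment with the tool version and a
hash of the config, and a rerun with the same config and seed reproduces
all data outputs byte-identically (the manifest's wall-clock figures are
the only run-dependent output).  A failing stage aborts the run with the
stage named; files it had started writing keep a ``.partial`` suffix.
"""

from __future__ import annotations

import hashlib
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .core import GroupDesign, HerbnetError, UsageError
from .discovery import discover
from .ibaq import compute_ibaq, count_theoretical_peptides, differential, enrich
from .io import (
    read_design,
    read_fasta,
    read_gmt,
    read_intensity_matrix,
    read_interactions,
    read_mapping,
    write_ibaq,
    write_network,
    write_table,
)
from .network import build_network, extract_effector_subnetwork, restrict_to_effectors
from .overlap import annotate_network, coverage
from .scoring import score_pathways
from .simulate import DEFAULT_LADDER, write_instance

logger = logging.getLogger("herbnet")

STAGES = ["simulate", "build", "score", "ibaq", "diff", "enrich", "coverage", "discover"]

_TOP_KEYS = {"out_dir", "seed", "threshold", "weight", "alpha", "digestion",
             "simulate", "inputs", "ladder"}
_SIM_KEYS = {"enabled", "n_compounds", "n_targets", "n_pathways", "pathway_size",
             "n_decoy_pathways", "background_degree", "boost_compounds",
             "n_proteins", "n_planted", "n_per_group", "cv"}
_DIG_KEYS = {"min_len", "max_len", "proline_rule"}
_INPUT_KEYS = {"interactions", "gene_sets", "effectors", "fasta", "intensities",
               "design", "mapping"}

DEFAULT_CONFIG = {
    "out_dir": "herbnet_run",
    "seed": 0,
    "threshold": 40.0,
    "weight": 0.5,
    "alpha": 0.05,
    "digestion": {"min_len": 6, "max_len": 30, "proline_rule": True},
    "simulate": {"enabled": True},
    "inputs": {},
    "ladder": list(DEFAULT_LADDER),
}


class StageError(HerbnetError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class ConfigError(UsageError):
    """The pipeline configuration is invalid."""


def _check_keys(section: dict, allowed: set[str], where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown config key(s) in {where}: {sorted(unknown)}")


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Load, merge with defaults, and validate a pipeline config."""
    cfg = yaml.safe_load(Path(path).read_text(encoding="utf-8")) if path else {}
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a YAML mapping")
    _check_keys(cfg, _TOP_KEYS, "top level")
    merged = {**DEFAULT_CONFIG, **cfg}
    merged["digestion"] = {**DEFAULT_CONFIG["digestion"], **(cfg.get("digestion") or {})}
    merged["simulate"] = {**DEFAULT_CONFIG["simulate"], **(cfg.get("simulate") or {})}
    merged["inputs"] = dict(cfg.get("inputs") or {})
    for key, val in (overrides or {}).items():
        if val is not None:
            merged[key] = val
    _check_keys(merged["digestion"], _DIG_KEYS, "digestion")
    _check_keys(merged["simulate"], _SIM_KEYS, "simulate")
    _check_keys(merged["inputs"], _INPUT_KEYS, "inputs")
    if not 0.0 <= merged["weight"] <= 1.0:
        raise ConfigError("weight must lie in [0, 1]")
    if not 0.0 < merged["alpha"] < 1.0:
        raise ConfigError("alpha must lie in (0, 1)")
    if merged["threshold"] < 0:
        raise ConfigError("threshold must be >= 0")
    if not merged["simulate"].get("enabled", True):
        missing = [k for k in sorted(_INPUT_KEYS) if k not in merged["inputs"]]
        if missing:
            raise ConfigError(f"simulate disabled but inputs missing: {missing}")
        absent = [str(p) for p in merged["inputs"].values() if not Path(p).exists()]
        if absent:
            raise ConfigError(f"input file(s) not found: {absent}")
    return merged


def config_hash(config: dict) -> str:
    """Hash of the analysis-relevant config (output location excluded)."""
    content = {k: v for k, v in config.items() if k != "out_dir"}
    blob = yaml.safe_dump(content, sort_keys=True).encode("utf-8")
    return hashlib.sha256(blob).hexdigest()[:12]


class _StageFiles:
    """Write stage outputs under .partial names; commit renames them."""

    def __init__(self) -> None:
        self.pending: list[tuple[Path, Path]] = []

    def path(self, final: Path) -> Path:
        tmp = final.with_name(final.name + ".partial")
        self.pending.append((tmp, final))
        return tmp

    def commit(self) -> list[Path]:
        done = []
        for tmp, final in self.pending:
            if tmp.exists():
                tmp.replace(final)
            done.append(final)
        self.pending.clear()
        return done


def run_pipeline(config: dict) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    outdir = Path(config["out_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    chash = config_hash(config)
    header = f"herbnet {__version__} config={chash}"
    manifest: dict = {
        "version": __version__,
        "config_hash": chash,
        "seed": seed,
        "stages": {},
    }
    state: dict = {}

    def run_stage(name, fn):
        files = _StageFiles()
        t0 = time.perf_counter()
        try:
            rows = fn(files)
        except Exception as exc:
            logger.error("stage %s failed: %s", name, exc)
            raise StageError(name, exc) from exc
        written = files.commit()
        manifest["stages"][name] = {
            "rows": rows,
            "seconds": round(time.perf_counter() - t0, 4),
            "outputs": [str(p) for p in written],
        }
        logger.info("stage %s complete (%s rows)", name, rows)

    def stage_simulate(files):
        sim = config["simulate"]
        if sim.get("enabled", True):
            net_kwargs = {k: sim[k] for k in
                          ("n_compounds", "n_targets", "n_pathways", "pathway_size",
                           "n_decoy_pathways", "background_degree", "boost_compounds")
                          if k in sim}
            prot_kwargs = {k: sim[k] for k in
                           ("n_proteins", "n_planted", "n_per_group", "cv") if k in sim}
            paths = write_instance(outdir / "inputs", seed=seed,
                                   network_kwargs=net_kwargs, proteome_kwargs=prot_kwargs)
        else:
            paths = {k: Path(v) for k, v in config["inputs"].items()}
        state["paths"] = paths
        return len(paths)

    def stage_build(files):
        paths = state["paths"]
        interactions = read_interactions(paths["interactions"])
        gene_sets = read_gmt(paths["gene_sets"])
        effectors = [
            line.strip()
            for line in Path(paths["effectors"]).read_text(encoding="utf-8").splitlines()
            if line.strip()
        ]
        gene_sets = restrict_to_effectors(gene_sets, effectors)
        net = build_network(interactions, gene_sets, threshold=float(config["threshold"]))
        write_network(net, files.path(outdir / "network.graphml"))
        state["net"], state["gene_sets"] = net, gene_sets
        return len(net.ct_edges)

    def stage_score(files):
        scores = score_pathways(state["net"], weight=float(config["weight"]))
        write_table(scores, files.path(outdir / "scores.tsv"), header_comment=header)
        state["scores"] = scores
        return len(scores)

    def stage_ibaq(files):
        paths = state["paths"]
        seqs = read_fasta(paths["fasta"])
        dig = config["digestion"]
        counts = {
            p.accession: count_theoretical_peptides(
                p, min_len=int(dig["min_len"]), max_len=int(dig["max_len"]),
                proline_rule=bool(dig["proline_rule"]),
            )
            for p in seqs
        }
        intensities = read_intensity_matrix(paths["intensities"])
        table = compute_ibaq(intensities, counts)
        write_table(
            pd.DataFrame(sorted(counts.items()), columns=["accession", "n_peptides"]),
            files.path(outdir / "peptide_counts.tsv"), header_comment=header,
        )
        write_ibaq(table, files.path(outdir / "ibaq.tsv"), header_comment=header)
        state["ibaq"] = table
        state["design"] = read_design(paths["design"], ladder=list(config["ladder"]))
        return table.norm.shape[0]

    def stage_diff(files):
        design: GroupDesign = state["design"]
        ladder = design.ladder
        control, model, high = ladder[0], ladder[1], ladder[-1]
        alpha = float(config["alpha"])
        up = differential(state["ibaq"], design, (control, model), alpha=alpha)
        down = differential(state["ibaq"], design, (model, high), alpha=alpha)
        write_table(up, files.path(outdir / "diff_model_vs_control.tsv"), header_comment=header)
        write_table(down, files.path(outdir / "diff_high_vs_model.tsv"), header_comment=header)
        state["diff_up"], state["diff_down"] = up, down
        return len(up)

    def stage_enrich(files):
        up = state["diff_up"]
        selected = set(up.loc[(up["p"] < float(config["alpha"])) & (up["log2fc"] > 0),
                              "accession"])
        background = set(state["ibaq"].norm.index)
        mapping = read_mapping(state["paths"]["mapping"])
        state["mapping"] = mapping
        table = enrich(selected, background, state["gene_sets"], mapping=mapping)
        write_table(table, files.path(outdir / "enrichment.tsv"), header_comment=header)
        return len(table)

    def stage_coverage(files):
        net = state["net"]
        mapping = state["mapping"]
        identified = set(state["ibaq"].norm.index)
        diff = state["diff_up"]
        rows = []
        for gs in state["gene_sets"]:
            sub = extract_effector_subnetwork(net, gs)
            rep = coverage(sub, identified, mapping, diff, label=gs.pathway_id,
                           alpha=float(config["alpha"]))
            rows.append({
                "effector": rep.label,
                "n_predicted": rep.n_predicted,
                "n_identified": rep.n_identified,
                "identified_changed": rep.identified_changed,
                "unmapped": rep.unmapped,
                "ratio": rep.as_ratio(),
            })
        first_sub = extract_effector_subnetwork(net, state["gene_sets"][0])
        annotated = annotate_network(first_sub, identified, mapping, diff,
                                     alpha=float(config["alpha"]))
        write_network(annotated, files.path(outdir / "annotated_subnetwork.graphml"))
        write_table(pd.DataFrame(rows), files.path(outdir / "coverage.tsv"),
                    header_comment=header)
        return len(rows)

    def stage_discover(files):
        cands = discover(state["ibaq"], state["design"], alpha=float(config["alpha"]))
        write_table(cands, files.path(outdir / "candidates.tsv"), header_comment=header)
        state["candidates"] = cands
        return int(cands["passes"].sum())

    run_stage("simulate", stage_simulate)
    run_stage("build", stage_build)
    run_stage("score", stage_score)
    run_stage("ibaq", stage_ibaq)
    run_stage("diff", stage_diff)
    run_stage("enrich", stage_enrich)
    run_stage("coverage", stage_coverage)
    run_stage("discover", stage_discover)

    with open(outdir / "manifest.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest
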