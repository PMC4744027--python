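"""End-to-end pipeline: simulate or load data, delimit with every method,
compare against morphospecies, and estimate richness and turnover.

A single seed governs all stochastic stages, so two runs with the same
configuration produce identical report payloads. Outputs are plain-text
(TSV/JSON/FASTA/newick) with a provenance block recording the seed,
package version and a hash of the configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .congruence import (
    CongruenceReport,
    compare_partitions,
    motu_summary,
    pairwise_match_matrix,
    report_rows,
)
from .distclust import cluster_by_threshold, connection_limit, parsimony_networks
from .gmyc import fit_gmyc_single, gmyc_partition
from .partition import Partition
from .ptp import fit_ptp
from .richness import (
    STANDARD_METHODS,
    accumulation_curve,
    build_incidence,
    chao2,
    jackknife,
    level_occupancy,
    standardized_richness,
)
from .seqs import (
    collapse_haplotypes,
    mismatch_step_matrix,
    p_distance_matrix,
    read_alignment,
)
from .simulate import (
    SimParams,
    corrupt_morphospecies,
    metadata_frame,
    simulate_community,
    simulate_genealogy,
    simulate_sequences,
    species_tip_order,
    write_simulation,
)
from .trees import TimeTree, read_newick, ultrametricize_mpl

logger = logging.getLogger(__name__)

ALL_METHODS = ("networks", "distance", "gmyc", "ptp")


@dataclass
class RunConfig:
    """Either real input paths or simulation parameters, plus method knobs."""

    sim: Optional[SimParams] = None
    fasta: Optional[str] = None
    tree: Optional[str] = None
    metadata: Optional[str] = None
    methods: Tuple[str, ...] = ALL_METHODS
    threshold: float = 0.03
    confidence: float = 0.95
    max_steps: Optional[int] = None
    richness_methods: Tuple[str, ...] = STANDARD_METHODS
    richness_levels: Tuple[int, ...] = (1000, 2000)
    n_perm: int = 1000
    standardize_reps: int = 10000
    outdir: Optional[str] = None
    seed: int = 0
    write_outputs: bool = True

    def __post_init__(self):
        if self.sim is None and self.fasta is None:
            raise ValueError("config needs either input paths or SimParams")
        unknown = set(self.methods) - set(ALL_METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.pop("sim", None)
        if sim is not None:
            for key in ("abundance_model", "level_weights", "extra_methods"):
                if key in sim and isinstance(sim[key], list):
                    sim[key] = tuple(
                        tuple(v) if isinstance(v, list) else v for v in sim[key]
                    )
            sim = SimParams(**sim)
        for key in ("methods", "richness_methods", "richness_levels"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(sim=sim, **raw)

    def canonical_hash(self) -> str:
        """Hash of the result-determining configuration (output location and
        write toggles excluded)."""
        payload = dataclasses.asdict(self)
        payload.pop("outdir", None)
        payload.pop("write_outputs", None)
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunReport:
    partitions: Dict[str, Partition]
    fits: Dict[str, dict]
    congruence: Dict[str, CongruenceReport]
    match_names: List[str]
    match_matrix: np.ndarray
    summaries: Dict[str, dict]
    richness: Dict[str, dict]
    occupancy: Dict[str, dict]
    errors: Dict[str, str]
    provenance: Dict[str, object]
    paths: Dict[str, str] = field(default_factory=dict)

    def payload(self) -> dict:
        """Deterministic JSON-ready payload (no timestamps, no paths)."""
        return {
            "partitions": {
                name: {sp: p.label_of(sp) for sp in sorted(p.specimens)}
                for name, p in self.partitions.items()
            },
            "fits": self.fits,
            "congruence": {k: v.to_dict() for k, v in self.congruence.items()},
            "match_matrix": {
                "names": self.match_names,
                "values": self.match_matrix.tolist(),
            },
            "summaries": self.summaries,
            "richness": self.richness,
            "occupancy": self.occupancy,
            "errors": self.errors,
            "provenance": self.provenance,
        }


def _scaled_tree(tree: TimeTree, factor: float) -> TimeTree:
    out = tree.clone()
    for node in out.tree.preorder_node_iter():
        if node.parent_node is not None and node.edge.length is not None:
            node.edge.length *= factor
    return out


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every requested stage in dependency order."""
    errors: Dict[str, str] = {}
    fits: Dict[str, dict] = {}

    # ---------------------------------------------------------------- data
    if config.sim is not None:
        params = dataclasses.replace(config.sim, seed=config.seed)
        truth = simulate_community(params)
        tree = simulate_genealogy(truth, params)
        aln = simulate_sequences(tree, params)
        morpho = corrupt_morphospecies(
            truth,
            params.split_rate,
            params.lump_rate,
            seed=config.seed,
            species_order=species_tip_order(tree, truth),
        )
        meta = metadata_frame(truth, morpho)
        subst_tree = _scaled_tree(tree, params.mutation_rate)
        truth_partition: Optional[Partition] = truth.true_partition
    else:
        aln = read_alignment(config.fasta)
        meta = pd.read_csv(config.metadata, sep="\t")
        morpho = Partition(
            dict(zip(meta["specimen_id"], meta["morphospecies"]))
        )
        subst_tree = read_newick(config.tree) if config.tree else None
        tree = subst_tree
        truth = None
        truth_partition = None
    tree_methods = {"gmyc", "ptp"} & set(config.methods)
    if tree_methods and subst_tree is None:
        raise ValueError(
            f"methods {sorted(tree_methods)} need a tree but none was given"
        )
    logger.info("data: %d specimens, %d sites", aln.n, aln.length)

    partitions: Dict[str, Partition] = {"morphospecies": morpho}

    # ------------------------------------------------------------ sequences
    haplotypes = collapse_haplotypes(aln)
    partitions["haplotypes"] = haplotypes.to_partition()
    logger.info("haplotypes: %d of %d specimens", haplotypes.n_haplotypes, aln.n)

    if "distance" in config.methods:
        try:
            D = p_distance_matrix(aln)
            partitions["distance"] = cluster_by_threshold(D, config.threshold)
        except Exception as exc:  # noqa: BLE001 - recorded, run continues
            errors["distance"] = str(exc)
    if "networks" in config.methods:
        try:
            limit = connection_limit(
                aln.length, config.confidence, config.max_steps
            )
            steps = mismatch_step_matrix(haplotypes.alignment())
            partitions["networks"] = parsimony_networks(haplotypes, steps, limit)
            fits["networks"] = {
                "max_steps": limit.max_steps,
                "confidence": limit.confidence,
            }
        except Exception as exc:  # noqa: BLE001
            errors["networks"] = str(exc)

    # ----------------------------------------------------------------- trees
    if "gmyc" in config.methods:
        try:
            ultra = ultrametricize_mpl(subst_tree)
            gfit = fit_gmyc_single(ultra, seed=config.seed)
            partitions["gmyc"] = gmyc_partition(gfit)
            fits["gmyc"] = gfit.to_dict()
        except Exception as exc:  # noqa: BLE001
            errors["gmyc"] = str(exc)
    if "ptp" in config.methods:
        try:
            pfit = fit_ptp(subst_tree, seed=config.seed)
            partitions["ptp"] = pfit.partition
            fits["ptp"] = pfit.to_dict()
        except Exception as exc:  # noqa: BLE001
            errors["ptp"] = str(exc)

    for name, p in partitions.items():
        logger.info("%s: %d groups", name, p.n_groups)

    # ------------------------------------------------------------ congruence
    congruence = {
        name: compare_partitions(morpho, p)
        for name, p in partitions.items()
        if name != "morphospecies"
    }
    match_names = list(partitions)
    match_matrix = pairwise_match_matrix(partitions)
    summaries = {
        name: dataclasses.asdict(motu_summary(p)) for name, p in partitions.items()
    }

    # -------------------------------------------------------------- richness
    richness: Dict[str, dict] = {}
    occupancy: Dict[str, dict] = {}
    unit_sizes = (
        meta[meta["method"].isin(config.richness_methods)]
        .groupby("sampling_unit")["specimen_id"]
        .count()
        .to_dict()
    )
    meta_std = meta[
        meta["method"].isin(config.richness_methods)
        & meta["level"].isin(config.richness_levels)
    ]
    pool_sizes = meta_std.groupby("level")["specimen_id"].count().to_dict()
    n_draw = int(min(pool_sizes.values())) if pool_sizes else 0
    for name, p in partitions.items():
        try:
            inc = build_incidence(
                p, meta, config.richness_methods, config.richness_levels
            )
            entry = {
                "s_obs": inc.s_obs,
                "m_units": inc.m,
                "chao2": dataclasses.asdict(chao2(inc)),
                "jack1": dataclasses.asdict(jackknife(inc, 1)),
                "jack2": dataclasses.asdict(jackknife(inc, 2)),
            }
            curve = accumulation_curve(
                inc,
                {u: int(unit_sizes.get(u, 0)) for u in inc.unit_ids},
                "random",
                n_perm=config.n_perm,
                seed=config.seed + 101,
            )
            entry["accumulation_final_mean"] = float(curve.mean_species[-1])
            std = {}
            for level, size in sorted(pool_sizes.items()):
                sr = standardized_richness(
                    p,
                    meta_std,
                    level=level,
                    n_draw=n_draw,
                    reps=config.standardize_reps,
                    seed=config.seed + 211 + int(level),
                )
                std[str(level)] = dataclasses.asdict(sr)
            entry["standardized"] = std
            richness[name] = entry
            occupancy[name] = {
                "all": level_occupancy(p, meta, exclude_rare=False),
                "no_rare": level_occupancy(p, meta, exclude_rare=True),
            }
        except Exception as exc:  # noqa: BLE001
            errors[f"richness_{name}"] = str(exc)

    provenance = {
        "seed": config.seed,
        "version": __version__,
        "config_hash": config.canonical_hash(),
        "methods": list(config.methods),
        "n_specimens": aln.n,
        "alignment_length": aln.length,
    }
    if truth is not None:
        provenance["true_species_count"] = truth.species_count

    report = RunReport(
        partitions=partitions,
        fits=fits,
        congruence=congruence,
        match_names=match_names,
        match_matrix=match_matrix,
        summaries=summaries,
        richness=richness,
        occupancy=occupancy,
        errors=errors,
        provenance=provenance,
    )
    if config.outdir and config.write_outputs:
        _write_outputs(report, config, truth, tree, aln, morpho)
    return report


def _write_outputs(report, config, truth, tree, aln, morpho) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if truth is not None:
        params = dataclasses.replace(config.sim, seed=config.seed)
        write_simulation(outdir / "data", truth, tree, aln, morpho, params)
    rows = []
    for name, p in report.partitions.items():
        rows.extend(p.to_rows(name))
    pd.DataFrame(rows, columns=["specimen_id", "method", "group_label"]).to_csv(
        outdir / "partitions.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        report.match_matrix, index=report.match_names, columns=report.match_names
    ).to_csv(outdir / "match_matrix.tsv", sep="\t")
    table = report_rows(report.congruence)
    pd.DataFrame(table[1:], columns=table[0]).to_csv(
        outdir / "congruence.tsv", sep="\t", index=False
    )
    (outdir / "report.json").write_text(
        json.dumps(report.payload(), indent=2, sort_keys=True, default=float)
    )
    report.paths["outdir"] = str(outdir)
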