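"""File-based pipeline stages and the end-to-end runner.

Each stage reads its inputs from the configured output directory, runs one
analysis step, and writes its artifact(s) atomically with a commented
metadata header (tool version, seed, config hash) so that two runs with
the same configuration and master seed are byte-identical.  The chain:

    simulate → diffexp → network → cluster → enrich → extend_screen

``run_all`` executes all of it, stopping cleanly (with a log message) when
no protein is called differential.  The CLI in :mod:`mitonet.cli` is a
thin wrapper over these functions.
"""

from __future__ import annotations

import configparser
import hashlib
import json
import logging
import os
from collections.abc import Sequence
from dataclasses import dataclass, field, replace

import numpy as np

from . import __version__
from .diffexp import DifferentialResult, bootstrap_table, call_differential, normalize
from .enrichment import enrich
from .io_formats import (
    FormatError,
    Interactome,
    ValidationError,
    _atomic_write_text,
    _data_lines,
    _metadata_header,
    read_gmt,
    read_graphml,
    read_linkset,
    read_spot_table,
    read_string_tsv,
    to_graph,
    write_gmt,
    write_graphml,
    write_linkset,
    write_spot_table,
    write_string_tsv,
)
from .netcore import MCLParams, induce_network, mcl, ppi_enrichment
from .regnet import extend, extended_to_graph, screen_opposite
from .synthetic_data import Study, StudyParams, simulate_study

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "DEFAULT_CONTRASTS",
    "stage_simulate",
    "stage_diffexp",
    "stage_network",
    "stage_cluster",
    "stage_enrich",
    "stage_extend_screen",
    "run_all",
    "read_differential_tsv",
]

log = logging.getLogger("mitonet")

# numerator-vs-denominator pairs covering every group comparison of interest
DEFAULT_CONTRASTS: tuple[tuple[str, str], ...] = (
    ("Isch", "sham"),
    ("I/R", "sham"),
    ("PostC", "sham"),
    ("I/R", "Isch"),
    ("PostC", "Isch"),
    ("PostC", "I/R"),
)

ARTIFACTS = {
    "spots": "spots.csv",
    "gel_groups": "gel_groups.tsv",
    "interactome": "interactome.tsv",
    "annotations": "annotations.gmt",
    "linkset": "linkset.tsv",
    "truth_effects": "truth_effects.tsv",
    "truth_modules": "truth_modules.tsv",
    "truth_opposite_tfs": "truth_opposite_tfs.tsv",
    "differential": "differential.tsv",
    "network": "network.graphml",
    "ppi_enrichment": "ppi_enrichment.json",
    "clusters": "clusters.tsv",
    "enrichment": "enrichment.tsv",
    "extended_network": "extended_network.graphml",
    "tf_candidates": "tf_candidates.tsv",
}

_STAGE_OF_ARTIFACT = {
    "spots": "simulate",
    "gel_groups": "simulate",
    "interactome": "simulate",
    "annotations": "simulate",
    "linkset": "simulate",
    "differential": "diffexp",
    "network": "network",
    "ppi_enrichment": "network",
    "clusters": "cluster",
}


class PipelineError(RuntimeError):
    """A stage cannot run (e.g. a missing upstream artifact)."""


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of the pipeline in one place.

    ``seed`` is the master seed; each stage draws its own child seed from
    it deterministically, so stages are reproducible in isolation.
    """

    outdir: str = "mitonet_out"
    seed: int = 0
    threshold: float = 0.5
    n_boot: int = 1000
    log_base: float = 2.0
    score_cutoff: float = 0.4
    n_permutations: int = 1000
    reference_spot_id: str = "ALB"
    contrasts: tuple[tuple[str, str], ...] = DEFAULT_CONTRASTS
    mcl_params: MCLParams = field(default_factory=MCLParams)
    study: StudyParams = field(default_factory=StudyParams)

    def __post_init__(self):
        if not self.threshold > 0:
            raise ValidationError(f"threshold must be > 0, got {self.threshold}")
        if self.n_boot < 1:
            raise ValidationError("n_boot must be >= 1")

    # -- config-file parsing -------------------------------------------------

    _KNOWN = {
        "pipeline": {
            "outdir", "seed", "threshold", "n_boot", "log_base",
            "score_cutoff", "n_permutations", "reference_spot_id", "contrasts",
        },
        "mcl": {
            "inflation", "expansion", "pruning_threshold", "max_iterations",
            "convergence_epsilon", "self_loop_weight",
        },
        "simulate": {
            "n_spots", "cluster_sizes", "effect_magnitude", "n_gels_per_group",
            "noise_sd", "gel_scale_sd", "p_within", "p_background",
            "n_tfs", "targets_per_tf", "n_opposite_tfs", "n_decoy_terms",
        },
    }

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Parse a sectioned key=value config file; unknown keys are errors."""
        parser = configparser.ConfigParser()
        if not os.path.exists(path):
            raise PipelineError(f"config file not found: {path}")
        parser.read(path)
        for section in parser.sections():
            if section not in cls._KNOWN:
                raise ValidationError(f"unknown config section [{section}]")
            for key in parser[section]:
                if key not in cls._KNOWN[section]:
                    raise ValidationError(
                        f"unknown config key {key!r} in section [{section}]"
                    )
        kwargs: dict = {}
        if parser.has_section("pipeline"):
            sec = parser["pipeline"]
            for key, cast in [
                ("outdir", str), ("seed", int), ("threshold", float),
                ("n_boot", int), ("log_base", float), ("score_cutoff", float),
                ("n_permutations", int), ("reference_spot_id", str),
            ]:
                if key in sec:
                    kwargs[key] = cast(sec[key])
            if "contrasts" in sec:
                kwargs["contrasts"] = _parse_contrasts(sec["contrasts"])
        if parser.has_section("mcl"):
            sec = parser["mcl"]
            mkw: dict = {}
            for key, cast in [
                ("inflation", float), ("expansion", int),
                ("pruning_threshold", float), ("max_iterations", int),
                ("convergence_epsilon", float),
            ]:
                if key in sec:
                    mkw[key] = cast(sec[key])
            if "self_loop_weight" in sec:
                raw = sec["self_loop_weight"]
                mkw["self_loop_weight"] = "max" if raw == "max" else float(raw)
            kwargs["mcl_params"] = MCLParams(**mkw)
        if parser.has_section("simulate"):
            sec = parser["simulate"]
            skw: dict = {}
            for key, cast in [
                ("n_spots", int), ("effect_magnitude", float),
                ("n_gels_per_group", int), ("noise_sd", float),
                ("gel_scale_sd", float), ("p_within", float),
                ("p_background", float), ("n_tfs", int),
                ("targets_per_tf", int), ("n_opposite_tfs", int),
                ("n_decoy_terms", int),
            ]:
                if key in sec:
                    skw[key] = cast(sec[key])
            if "cluster_sizes" in sec:
                skw["cluster_sizes"] = tuple(
                    int(x) for x in sec["cluster_sizes"].replace(",", " ").split()
                )
            if "reference_spot_id" in kwargs:
                skw["reference_spot_id"] = kwargs["reference_spot_id"]
            kwargs["study"] = StudyParams(**skw)
        return cls(**kwargs)

    # -- helpers -------------------------------------------------------------

    def config_hash(self) -> str:
        # outdir excluded: where artifacts land must not change their content
        canonical = repr(replace(self, outdir=""))
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]

    def stage_seed(self, stage_index: int) -> np.random.SeedSequence:
        return np.random.SeedSequence(entropy=self.seed, spawn_key=(stage_index,))

    def metadata(self, stage: str) -> dict:
        return {
            "tool": f"mitonet {__version__}",
            "stage": stage,
            "seed": self.seed,
            "config": self.config_hash(),
        }

    def artifact(self, name: str) -> str:
        return os.path.join(self.outdir, ARTIFACTS[name])

    def require(self, name: str) -> str:
        path = self.artifact(name)
        if not os.path.exists(path):
            producer = _STAGE_OF_ARTIFACT.get(name, "simulate")
            raise PipelineError(
                f"missing upstream artifact {path!r}; run the {producer!r} "
                f"command first"
            )
        return path


def _parse_contrasts(text: str) -> tuple[tuple[str, str], ...]:
    out = []
    for chunk in text.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split(" vs ")
        if len(parts) != 2:
            raise ValidationError(f"cannot parse contrast {chunk!r} (use 'A vs B')")
        out.append((parts[0].strip(), parts[1].strip()))
    if not out:
        raise ValidationError("no contrasts specified")
    return tuple(out)


def _contrast_label(contrast: tuple[str, str]) -> str:
    return f"{contrast[0]} vs {contrast[1]}"


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: PipelineConfig) -> Study:
    """Generate the synthetic study and write all input + truth files."""
    os.makedirs(cfg.outdir, exist_ok=True)
    seed = int(cfg.stage_seed(0).generate_state(1)[0] % (2**31))
    study = simulate_study(seed=seed, params=cfg.study)
    meta = cfg.metadata("simulate")
    write_spot_table(
        study.table, cfg.artifact("spots"), cfg.artifact("gel_groups"), metadata=meta
    )
    write_string_tsv(study.interactome, cfg.artifact("interactome"), metadata=meta)
    write_gmt(study.annotations, cfg.artifact("annotations"), metadata=meta)
    write_linkset(study.linkset, cfg.artifact("linkset"), metadata=meta)

    lines = [_metadata_header(meta)]
    groups = list(study.true_effects.columns)
    lines.append("spot_id\t" + "\t".join(groups) + "\n")
    for spot in study.true_effects.index:
        vals = "\t".join(repr(float(v)) for v in study.true_effects.loc[spot])
        lines.append(f"{spot}\t{vals}\n")
    _atomic_write_text(cfg.artifact("truth_effects"), "".join(lines))

    lines = [_metadata_header(meta), "node\tmodule\n"]
    for node in sorted(study.true_modules):
        lines.append(f"{node}\t{study.true_modules[node]}\n")
    _atomic_write_text(cfg.artifact("truth_modules"), "".join(lines))

    lines = [_metadata_header(meta), "tf_id\n"]
    for tf in study.planted_opposite_tfs:
        lines.append(f"{tf}\n")
    _atomic_write_text(cfg.artifact("truth_opposite_tfs"), "".join(lines))
    log.info(
        "simulate: %d spots, %d gels, %d interactome edges, %d TF links",
        len(study.table.spot_ids),
        len(study.table.gel_ids),
        study.interactome.n_edges,
        len(study.linkset),
    )
    return study


def stage_diffexp(cfg: PipelineConfig) -> list[DifferentialResult]:
    """Normalize, bootstrap every spot×contrast, write differential.tsv."""
    table = read_spot_table(
        cfg.require("spots"), cfg.require("gel_groups"), cfg.reference_spot_id
    )
    norm = normalize(table)
    results = bootstrap_table(
        norm,
        cfg.contrasts,
        n_boot=cfg.n_boot,
        seed=cfg.stage_seed(1),
        threshold=cfg.threshold,
        log_base=cfg.log_base,
    )
    lines = [_metadata_header({**cfg.metadata("diffexp"), "log_base": cfg.log_base})]
    lines.append(
        "spot_id\tcontrast\tlogfc_point\teffect_size\tci_low\tci_high"
        "\tn_boot_used\tis_differential\n"
    )
    for r in results:
        lines.append(
            f"{r.spot_id}\t{_contrast_label(r.contrast)}\t{r.logfc_point!r}"
            f"\t{r.effect_size!r}\t{r.ci_low!r}\t{r.ci_high!r}"
            f"\t{r.n_boot_used}\t{str(r.is_differential).lower()}\n"
        )
    _atomic_write_text(cfg.artifact("differential"), "".join(lines))
    n_diff = sum(r.is_differential for r in results)
    log.info("diffexp: %d differential calls across %d contrasts", n_diff,
             len(cfg.contrasts))
    return results


def read_differential_tsv(path) -> list[DifferentialResult]:
    """Read back a differential.tsv written by :func:`stage_diffexp`."""
    results = []
    header = None
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if header is None:
            header = parts
            continue
        if len(parts) != 8:
            raise FormatError(f"expected 8 fields, found {len(parts)}", path, lineno)
        a, _, b = parts[1].partition(" vs ")
        results.append(
            DifferentialResult(
                spot_id=parts[0],
                contrast=(a, b),
                logfc_point=float(parts[2]),
                effect_size=float(parts[3]),
                ci_low=float(parts[4]),
                ci_high=float(parts[5]),
                n_boot=int(parts[6]),
                n_boot_used=int(parts[6]),
                is_differential=parts[7] == "true",
            )
        )
    return results


def _differential_union(cfg, results) -> frozenset:
    calls = call_differential(results, reference_spot_id=cfg.reference_spot_id)
    union: set = set()
    for spots in calls.values():
        union |= spots
    return frozenset(union)


def _effects_by_contrast(results) -> dict[str, dict[str, float]]:
    out: dict[str, dict[str, float]] = {}
    for r in results:
        out.setdefault(_contrast_label(r.contrast), {})[r.spot_id] = r.effect_size
    return out


def stage_network(cfg: PipelineConfig):
    """Induce the differential network, test PPI enrichment, export GraphML.

    Returns ``(network, enrichment)`` or ``None`` when nothing is
    differential (clean early stop for downstream stages).
    """
    results = read_differential_tsv(cfg.require("differential"))
    background = read_string_tsv(cfg.require("interactome"), cfg.score_cutoff)
    union = _differential_union(cfg, results)
    if not union:
        log.info(
            "network: no protein exceeds |logFC| > %.3g in any contrast; "
            "stopping early", cfg.threshold,
        )
        return None
    network, missing = induce_network(background, union)
    if missing:
        log.info("network: %d differential proteins absent from background", len(missing))
    enr = ppi_enrichment(
        background,
        union,
        n_permutations=cfg.n_permutations,
        seed=cfg.stage_seed(2),
    )
    effects = _effects_by_contrast(results)
    write_graphml(
        to_graph(network, node_effects=effects),
        cfg.artifact("network"),
        metadata=cfg.metadata("network"),
    )
    payload = {
        "observed_edges": enr.observed_edges,
        "null_mean": enr.null_mean,
        "p_value": enr.p_value,
        "n_permutations": enr.n_permutations,
        "n_nodes": network.n_nodes,
        "metadata": {k: str(v) for k, v in cfg.metadata("network").items()},
    }
    _atomic_write_text(
        cfg.artifact("ppi_enrichment"), json.dumps(payload, indent=2, sort_keys=True) + "\n"
    )
    log.info(
        "network: %d nodes, %d edges, PPI enrichment p = %.3g",
        network.n_nodes, network.n_edges, enr.p_value,
    )
    return network, enr


def _read_network_graphml(cfg) -> Interactome:
    g = read_graphml(cfg.require("network"))
    edges = [
        (u, v, d.get("weight", 1.0))
        for u, v, d in g.edges(data=True)
        if d.get("kind", "ppi") == "ppi"
    ]
    nodes = [n for n, d in g.nodes(data=True) if d.get("kind", "protein") == "protein"]
    return Interactome.from_edges(edges, nodes=nodes)


def stage_cluster(cfg: PipelineConfig):
    """Run MCL on the differential network and write the partition."""
    network = _read_network_graphml(cfg)
    partition = mcl(network, cfg.mcl_params)
    meta = {
        **cfg.metadata("cluster"),
        "inflation": cfg.mcl_params.inflation,
        "converged": str(partition.converged).lower(),
        "n_iterations": partition.n_iterations,
    }
    lines = [_metadata_header(meta), "node\tcluster\n"]
    for node in sorted(partition.node_to_cluster, key=str):
        lines.append(f"{node}\t{partition.node_to_cluster[node]}\n")
    _atomic_write_text(cfg.artifact("clusters"), "".join(lines))
    log.info(
        "cluster: %d clusters (sizes %s), converged=%s",
        partition.n_clusters, partition.sizes()[:10], partition.converged,
    )
    return partition


def read_clusters_tsv(path) -> dict[str, int]:
    mapping: dict[str, int] = {}
    header = None
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if header is None:
            header = parts
            continue
        if len(parts) != 2:
            raise FormatError(f"expected 2 fields, found {len(parts)}", path, lineno)
        mapping[parts[0]] = int(parts[1])
    return mapping


def stage_enrich(cfg: PipelineConfig):
    """Overrepresentation of every non-singleton cluster; one TSV."""
    clusters = read_clusters_tsv(cfg.require("clusters"))
    annotations = read_gmt(cfg.require("annotations"))
    background = read_string_tsv(cfg.require("interactome"), cfg.score_cutoff)
    annotated = annotations.universe()
    universe = frozenset(n for n in background.graph.nodes if n in annotated)
    by_cluster: dict[int, set] = {}
    for node, cid in clusters.items():
        by_cluster.setdefault(cid, set()).add(node)

    lines = [_metadata_header(cfg.metadata("enrich"))]
    lines.append(
        "cluster\tterm_id\tdescription\tk\tn\tK\tN\tstrength\tp_value\tfdr\n"
    )
    all_results = {}
    for cid in sorted(by_cluster):
        members = by_cluster[cid]
        if len(members) < 2 or not (members & universe):
            continue
        result = enrich(members, annotations, universe)
        all_results[cid] = result
        for row in result:
            lines.append(
                f"{cid}\t{row.term_id}\t{row.description}\t{row.k}\t{row.n}"
                f"\t{row.K}\t{row.N}\t{row.strength!r}\t{row.p_value!r}"
                f"\t{row.fdr!r}\n"
            )
    _atomic_write_text(cfg.artifact("enrichment"), "".join(lines))
    log.info("enrich: tested %d clusters against %d terms over a universe of %d",
             len(all_results), len(annotations), len(universe))
    return all_results


def stage_extend_screen(cfg: PipelineConfig):
    """Extend the network with TF links and screen for opposite regulation."""
    network = _read_network_graphml(cfg)
    linkset = read_linkset(cfg.require("linkset"))
    results = read_differential_tsv(cfg.require("differential"))
    effects = _effects_by_contrast(results)
    try:
        clusters = read_clusters_tsv(cfg.require("clusters"))
    except PipelineError:
        clusters = None

    extnet = extend(network, linkset, node_effects=effects)
    ir_label, postc_label = "I/R vs Isch", "PostC vs Isch"
    for label in (ir_label, postc_label):
        if label not in effects:
            raise PipelineError(
                f"contrast {label!r} is required for the opposite-regulation "
                f"screen but was not computed; add it to the contrasts list"
            )
    candidates = screen_opposite(
        extnet, effects[ir_label], effects[postc_label], threshold=cfg.threshold
    )
    write_graphml(
        extended_to_graph(extnet, partition=clusters),
        cfg.artifact("extended_network"),
        metadata=cfg.metadata("extend_screen"),
    )
    lines = [_metadata_header(cfg.metadata("extend_screen"))]
    lines.append(
        "tf_id\tn_targets_in_network\tn_opposite_targets\tis_opposite_candidate"
        "\topposite_target_ids\n"
    )
    for c in candidates:
        lines.append(
            f"{c.tf_id}\t{len(c.in_network_targets)}\t{len(c.opposite_targets)}"
            f"\t{str(c.is_opposite_candidate).lower()}"
            f"\t{','.join(c.opposite_targets)}\n"
        )
    _atomic_write_text(cfg.artifact("tf_candidates"), "".join(lines))
    n_opp = sum(c.is_opposite_candidate for c in candidates)
    log.info(
        "extend_screen: %d TFs connected to the network, %d with opposite-"
        "regulation targets", len(candidates), n_opp,
    )
    return candidates


def run_all(cfg: PipelineConfig) -> dict[str, str]:
    """Run the whole chain; returns artifact name → path for what was written."""
    stage_simulate(cfg)
    stage_diffexp(cfg)
    written = [
        "spots", "gel_groups", "interactome", "annotations", "linkset",
        "truth_effects", "truth_modules", "truth_opposite_tfs", "differential",
    ]
    if stage_network(cfg) is None:
        return {name: cfg.artifact(name) for name in written}
    stage_cluster(cfg)
    stage_enrich(cfg)
    stage_extend_screen(cfg)
    written += [
        "network", "ppi_enrichment", "clusters", "enrichment",
        "extended_network", "tf_candidates",
    ]
    return {name: cfg.artifact(name) for name in written}
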