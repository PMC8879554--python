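"""Synthetic data generators with known ground truth for every stage.

The generative model for spot tables mirrors a four-group 2D-gel design
(sham, ischemia, ischemia/revascularization, post-conditioning; three gels
per group): on the log2 scale an observation is

    log2 intensity(spot s, gel g in group G)
        = mu_s + effect[s][G] + gelscale_g + eps,
    eps ~ Normal(0, noise_sd),   gelscale_g ~ Normal(0, gel_scale_sd),

where ``gelscale_g`` is shared by every spot on gel ``g`` — exactly the
per-gel loading/staining factor that reference-spot (albumin) normalization
cancels.  The reference spot's true effect is forced to zero in all groups
and it carries no residual noise (an abundant loading control is measured
with negligible relative error), so normalization is exactly the right
correction rather than an approximate one.

Interactomes are planted-partition (stochastic block model) graphs with
STRING-style combined scores; annotations are one term per planted module
plus random decoys; regulatory linksets plant a chosen number of TFs whose
in-network targets all satisfy the opposite-regulation predicate.  Every
generator emits its ground truth alongside the data and is byte-for-byte
reproducible under a fixed seed.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import (
    AnnotationCollection,
    Interactome,
    RegulatoryLinkset,
    SpotIntensityTable,
    ValidationError,
)
from .regnet import is_opposite

__all__ = [
    "SimulationConfig",
    "NetworkSimConfig",
    "RegulatorySimConfig",
    "StudyParams",
    "Study",
    "simulate_spot_table",
    "simulate_interactome",
    "simulate_annotations",
    "simulate_linkset",
    "simulate_study",
]

DEFAULT_GROUPS = ("sham", "Isch", "I/R", "PostC")


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration for spot-intensity table generation.

    ``planted_effects`` maps spot id → (group label → true log2 effect,
    additive on the log2 scale).  Defaults reflect the emulated study
    design: 4 groups, 3 gels each.  ``noise_sd`` defaults to 0.20 log2
    units (~15% CV), a typical residual spread for normalized 2D-gel spot
    volumes from replicate animals; ``gel_scale_sd`` defaults to 1.0, a
    deliberately large gel-loading spread that normalization must remove.
    """

    n_spots: int = 300
    n_gels_per_group: int = 3
    groups: tuple[str, ...] = DEFAULT_GROUPS
    planted_effects: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    gel_scale_sd: float = 1.0
    noise_sd: float = 0.2
    reference_spot_id: str = "ALB"
    seed: int = 0
    baseline_log2_mean: float = 10.0
    baseline_log2_sd: float = 1.0

    def __post_init__(self):
        if self.n_spots < 1:
            raise ValidationError(f"n_spots must be >= 1, got {self.n_spots}")
        if self.n_gels_per_group < 2:
            raise ValidationError(
                f"n_gels_per_group must be >= 2, got {self.n_gels_per_group}"
            )
        if not self.groups or len(set(self.groups)) != len(self.groups):
            raise ValidationError("groups must be non-empty and unique")
        for sd_name in ("gel_scale_sd", "noise_sd", "baseline_log2_sd"):
            if getattr(self, sd_name) < 0:
                raise ValidationError(f"{sd_name} must be >= 0")
        spot_ids = set(self.spot_ids())
        for spot, per_group in self.planted_effects.items():
            if spot not in spot_ids:
                raise ValidationError(f"planted_effects names unknown spot {spot!r}")
            for group, eff in per_group.items():
                if group not in self.groups:
                    raise ValidationError(
                        f"planted_effects[{spot!r}] names unknown group {group!r}"
                    )
                if spot == self.reference_spot_id and eff != 0:
                    raise ValidationError(
                        "reference spot must have zero effect in all groups"
                    )

    def spot_ids(self) -> list[str]:
        """Measured spots S0001.. plus the reference spot (last row)."""
        width = max(4, len(str(self.n_spots)))
        ids = [f"S{i + 1:0{width}d}" for i in range(self.n_spots)]
        ids.append(self.reference_spot_id)
        return ids

    def gel_ids(self) -> list[str]:
        return [
            f"{group}_g{i + 1}"
            for group in self.groups
            for i in range(self.n_gels_per_group)
        ]


@dataclass(frozen=True)
class NetworkSimConfig:
    """Planted-partition (SBM) interactome configuration.

    ``p_within`` may be a single probability shared by all planted
    clusters, or one probability per cluster (useful for adding a sparse
    "background" block).  Combined scores are drawn uniformly from the
    integer ``score_range`` (STRING convention, 0–1000).
    """

    n_clusters: int
    cluster_sizes: tuple[int, ...]
    p_within: float | tuple[float, ...] = 0.5
    p_between: float = 0.02
    score_range: tuple[int, int] = (400, 999)
    seed: int = 0
    node_ids: tuple[str, ...] | None = None

    def __post_init__(self):
        if len(self.cluster_sizes) != self.n_clusters:
            raise ValidationError(
                f"cluster_sizes has {len(self.cluster_sizes)} entries for "
                f"n_clusters={self.n_clusters}"
            )
        if any(s < 1 for s in self.cluster_sizes):
            raise ValidationError("cluster sizes must be >= 1")
        pw = self.p_within_per_cluster()
        for p in pw:
            if not 0 <= self.p_between <= p <= 1:
                raise ValidationError(
                    f"need 0 <= p_between <= p_within <= 1, got "
                    f"p_between={self.p_between}, p_within={p}"
                )
        lo, hi = self.score_range
        if not 0 <= lo <= hi <= 1000:
            raise ValidationError(f"score_range {self.score_range} outside 0–1000")
        if self.node_ids is not None and len(self.node_ids) != sum(self.cluster_sizes):
            raise ValidationError(
                f"node_ids has {len(self.node_ids)} entries for "
                f"{sum(self.cluster_sizes)} planted nodes"
            )

    def p_within_per_cluster(self) -> tuple[float, ...]:
        if isinstance(self.p_within, (int, float)):
            return (float(self.p_within),) * self.n_clusters
        return tuple(float(p) for p in self.p_within)


@dataclass(frozen=True)
class RegulatorySimConfig:
    """TF→target linkset configuration with planted opposite-regulation TFs."""

    n_tfs: int = 20
    targets_per_tf: int = 3
    n_opposite_tfs: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_tfs < 0 or self.targets_per_tf < 1:
            raise ValidationError("n_tfs must be >= 0 and targets_per_tf >= 1")
        if self.n_opposite_tfs > self.n_tfs:
            raise ValidationError(
                f"n_opposite_tfs ({self.n_opposite_tfs}) exceeds n_tfs ({self.n_tfs})"
            )


def simulate_spot_table(
    config: SimulationConfig,
) -> tuple[SpotIntensityTable, pd.DataFrame]:
    """Generate a spot-intensity table plus its ground-truth effect table.

    Returns ``(table, truth)`` where ``truth`` is a spots×groups DataFrame
    of true log2 effects (zero where nothing was planted).  Identical
    configs (same seed) produce identical tables.
    """
    spots = config.spot_ids()
    gels = config.gel_ids()
    rng = np.random.default_rng(config.seed)

    mu = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, len(spots))
    mu[-1] = config.baseline_log2_mean + 4.0  # albumin-like: abundant reference
    gelscale = rng.normal(0.0, config.gel_scale_sd, len(gels))
    eps = rng.normal(0.0, config.noise_sd, (len(spots), len(gels)))
    # the reference spot is an ideal loading control: it carries the gel
    # scale but no residual noise, so dividing by it is exactly the right
    # correction rather than a noise-injecting one
    eps[-1, :] = 0.0

    truth = pd.DataFrame(0.0, index=spots, columns=list(config.groups))
    for spot, per_group in config.planted_effects.items():
        for group, eff in per_group.items():
            truth.loc[spot, group] = float(eff)
    truth.loc[config.reference_spot_id] = 0.0

    gel_groups = {g: g.rsplit("_g", 1)[0] for g in gels}
    effect_matrix = truth[[gel_groups[g] for g in gels]].to_numpy()
    log2_intensity = mu[:, None] + effect_matrix + gelscale[None, :] + eps
    intensities = pd.DataFrame(
        np.exp2(log2_intensity), index=spots, columns=gels, dtype=float
    )
    table = SpotIntensityTable(intensities, gel_groups, config.reference_spot_id)
    return table, truth


def simulate_interactome(
    config: NetworkSimConfig,
) -> tuple[Interactome, dict[str, int]]:
    """Planted-partition interactome; returns the graph and true labels.

    Edge probabilities: ``p_within[c]`` inside planted cluster ``c``,
    ``p_between`` across clusters.  Labels are 0-based cluster indices.
    """
    total = sum(config.cluster_sizes)
    if config.node_ids is not None:
        nodes = list(config.node_ids)
    else:
        width = max(4, len(str(total)))
        nodes = [f"N{i + 1:0{width}d}" for i in range(total)]
    labels: list[int] = []
    for c, size in enumerate(config.cluster_sizes):
        labels.extend([c] * size)
    pw = config.p_within_per_cluster()

    rng = np.random.default_rng(config.seed)
    u = rng.random((total, total))
    pairs = []
    for i in range(total):
        for j in range(i + 1, total):
            p = pw[labels[i]] if labels[i] == labels[j] else config.p_between
            if u[i, j] < p:
                pairs.append((i, j))
    lo, hi = config.score_range
    scores = rng.integers(lo, hi + 1, size=len(pairs))
    edges = [
        (nodes[i], nodes[j], int(s) / 1000.0) for (i, j), s in zip(pairs, scores)
    ]
    graph = Interactome.from_edges(edges, nodes=nodes)
    return graph, dict(zip(nodes, labels))


def simulate_annotations(
    true_clusters: Sequence[Sequence[str]] | Mapping[str, int],
    n_decoy_terms: int = 0,
    seed: int = 0,
    universe: Sequence[str] | None = None,
) -> AnnotationCollection:
    """One annotation term per planted cluster, plus random decoy terms.

    ``true_clusters`` is either a sequence of member collections or a
    node→label mapping.  Decoy members are drawn from ``universe`` (default:
    the union of all cluster members); decoy sizes never exceed it.
    """
    if isinstance(true_clusters, Mapping):
        grouped: dict[int, list[str]] = {}
        for node, label in true_clusters.items():
            grouped.setdefault(label, []).append(node)
        clusters = [sorted(grouped[label]) for label in sorted(grouped)]
    else:
        clusters = [sorted(c) for c in true_clusters]
    if not clusters or any(not c for c in clusters):
        raise ValidationError("clusters must be non-empty")
    if n_decoy_terms < 0:
        raise ValidationError("n_decoy_terms must be >= 0")

    if universe is None:
        pool = sorted({m for c in clusters for m in c})
    else:
        pool = sorted(set(universe))

    width = max(2, len(str(len(clusters))))
    terms: dict[str, tuple[str, frozenset]] = {}
    for i, members in enumerate(clusters):
        terms[f"CL{i + 1:0{width}d}"] = (
            f"planted module {i + 1}",
            frozenset(members),
        )
    rng = np.random.default_rng(seed)
    dwidth = max(2, len(str(max(n_decoy_terms, 1))))
    for i in range(n_decoy_terms):
        size = int(rng.integers(3, max(4, min(30, len(pool)) + 1)))
        size = min(size, len(pool))
        members = rng.choice(pool, size=size, replace=False)
        terms[f"DECOY{i + 1:0{dwidth}d}"] = (
            f"decoy term {i + 1}",
            frozenset(str(m) for m in members),
        )
    return AnnotationCollection(terms)


def simulate_linkset(
    config: RegulatorySimConfig,
    network_nodes: Sequence[str],
    effect_tables: tuple[Mapping[str, float], Mapping[str, float]],
    threshold: float = 0.5,
) -> tuple[RegulatoryLinkset, list[str]]:
    """Directed TF→target linkset with planted opposite-regulation TFs.

    The first ``n_opposite_tfs`` TFs draw *all* their targets from nodes
    satisfying the opposite-regulation predicate under the two contrast
    effect tables (revascularization-vs-ischemia, post-conditioning-vs-
    ischemia); the remaining TFs draw only from nodes that do not.  Raises
    when either pool is empty but needed, rather than silently under-
    planting.  Returns the linkset and the planted opposite TF ids.
    """
    nodes = sorted(set(network_nodes))
    if not nodes:
        raise ValidationError("network_nodes is empty")
    ir, postc = effect_tables
    eligible = [
        n
        for n in nodes
        if n in ir and n in postc and is_opposite(ir[n], postc[n], threshold)
    ]
    ineligible = [n for n in nodes if n not in eligible]
    if config.n_opposite_tfs > 0 and not eligible:
        raise ValidationError(
            "no network node satisfies the opposite-regulation predicate; "
            "cannot plant opposite TFs"
        )
    if config.n_tfs > config.n_opposite_tfs and not ineligible:
        raise ValidationError(
            "every network node is opposite-regulated; cannot plant "
            "non-opposite TFs"
        )

    rng = np.random.default_rng(config.seed)
    width = max(2, len(str(max(config.n_tfs, 1))))
    edges: list[tuple[str, str, str | None]] = []
    planted: list[str] = []
    for i in range(config.n_tfs):
        tf = f"TF{i + 1:0{width}d}"
        pool = eligible if i < config.n_opposite_tfs else ineligible
        k = min(config.targets_per_tf, len(pool))
        targets = rng.choice(pool, size=k, replace=False)
        for t in sorted(str(x) for x in targets):
            edges.append((tf, t, "sim"))
        if i < config.n_opposite_tfs:
            planted.append(tf)
    return RegulatoryLinkset(tuple(edges)), planted


# ---------------------------------------------------------------------------
# the full default study


@dataclass(frozen=True)
class StudyParams:
    """Conditions of the default synthetic study.

    300 measured spots of which 26 are differentially regulated at
    |logFC| >= 1, grouped into three dense interactome modules of sizes
    9/9/8 inside a sparse 300-node background; 20 TFs each targeting
    in-module proteins, 3 of them planted with exclusively
    opposite-regulated targets.  These mirror the scale of the emulated
    swine-heart study (26 differential proteins, 3 PPI clusters, 20
    predicted TFs, 3 opposite-regulation TFs).
    """

    n_spots: int = 300
    cluster_sizes: tuple[int, ...] = (9, 9, 8)
    effect_magnitude: float = 1.0
    n_gels_per_group: int = 3
    noise_sd: float = 0.2
    gel_scale_sd: float = 1.0
    p_within: float = 0.6
    p_background: float = 0.02
    score_range: tuple[int, int] = (400, 999)
    n_tfs: int = 20
    targets_per_tf: int = 3
    n_opposite_tfs: int = 3
    n_decoy_terms: int = 20
    reference_spot_id: str = "ALB"

    def __post_init__(self):
        if sum(self.cluster_sizes) > self.n_spots:
            raise ValidationError("planted modules larger than the spot count")
        if 2 * self.n_opposite_tfs > sum(self.cluster_sizes):
            raise ValidationError("not enough planted spots for the opposite pool")


@dataclass(frozen=True)
class Study:
    """A complete simulated study with all ground truth attached."""

    params: StudyParams
    seed: int
    table: SpotIntensityTable
    true_effects: pd.DataFrame  # spots × groups, log2 scale
    interactome: Interactome
    true_modules: Mapping[str, int]  # network node → module (0 = background)
    annotations: AnnotationCollection
    linkset: RegulatoryLinkset
    planted_differential: frozenset
    planted_opposite_tfs: tuple[str, ...]

    def true_contrast(self, group_a: str, group_b: str) -> dict[str, float]:
        """Ground-truth logFC (a vs b) per spot."""
        col = self.true_effects[group_a] - self.true_effects[group_b]
        return {spot: float(v) for spot, v in col.items()}


def simulate_study(seed: int = 0, params: StudyParams | None = None) -> Study:
    """Build the default synthetic study end to end.

    Effect layout (magnitude m = ``effect_magnitude``, groups sham / Isch /
    I/R / PostC, all effects relative to sham):

    * an *opposite pool* of ``2 * n_opposite_tfs`` planted spots with
      effects (Isch = ±m, I/R = 0, PostC = ±2m), so their
      I/R-vs-Isch and PostC-vs-Isch logFCs are ∓m and ±m — opposite signs,
      both above the 0.5 threshold;
    * the remaining planted spots with same-signed effects
      (I/R = PostC = ±m, Isch = 0), differential but never opposite;
    * all other spots null.

    Interactome modules, annotations and the TF linkset are planted on top
    of this layout with seeds spawned from the master seed.
    """
    params = params or StudyParams()
    ss = np.random.SeedSequence(seed)
    seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(4)]

    n_diff = sum(params.cluster_sizes)
    width = max(4, len(str(params.n_spots)))
    diff_spots = [f"S{i + 1:0{width}d}" for i in range(n_diff)]
    m = params.effect_magnitude
    n_pool = 2 * params.n_opposite_tfs
    effects: dict[str, dict[str, float]] = {}
    for j, spot in enumerate(diff_spots):
        sign = 1.0 if j % 2 == 0 else -1.0
        if j < n_pool:  # opposite-regulation pool
            effects[spot] = {"Isch": sign * m, "I/R": 0.0, "PostC": 2 * sign * m}
        else:
            effects[spot] = {"I/R": sign * m, "PostC": sign * m}

    sim_cfg = SimulationConfig(
        n_spots=params.n_spots,
        n_gels_per_group=params.n_gels_per_group,
        planted_effects=effects,
        gel_scale_sd=params.gel_scale_sd,
        noise_sd=params.noise_sd,
        reference_spot_id=params.reference_spot_id,
        seed=seeds[0],
    )
    table, truth = simulate_spot_table(sim_cfg)

    network_nodes = [s for s in sim_cfg.spot_ids() if s != params.reference_spot_id]
    background = [s for s in network_nodes if s not in set(diff_spots)]
    ordered = diff_spots + background
    net_cfg = NetworkSimConfig(
        n_clusters=len(params.cluster_sizes) + 1,
        cluster_sizes=(*params.cluster_sizes, len(background)),
        p_within=(*([params.p_within] * len(params.cluster_sizes)), params.p_background),
        p_between=params.p_background,
        score_range=params.score_range,
        seed=seeds[1],
        node_ids=tuple(ordered),
    )
    interactome, raw_labels = simulate_interactome(net_cfg)
    n_modules = len(params.cluster_sizes)
    true_modules = {
        node: (label + 1 if label < n_modules else 0)
        for node, label in raw_labels.items()
    }

    module_sets = [
        [n for n, lab in true_modules.items() if lab == c + 1]
        for c in range(n_modules)
    ]
    annotations = simulate_annotations(
        module_sets,
        n_decoy_terms=params.n_decoy_terms,
        seed=seeds[2],
        universe=network_nodes,
    )

    ir_truth = {s: effects.get(s, {}).get("I/R", 0.0) - effects.get(s, {}).get("Isch", 0.0)
                for s in diff_spots}
    postc_truth = {s: effects.get(s, {}).get("PostC", 0.0) - effects.get(s, {}).get("Isch", 0.0)
                   for s in diff_spots}
    reg_cfg = RegulatorySimConfig(
        n_tfs=params.n_tfs,
        targets_per_tf=params.targets_per_tf,
        n_opposite_tfs=params.n_opposite_tfs,
        seed=seeds[3],
    )
    linkset, planted_tfs = simulate_linkset(
        reg_cfg, diff_spots, (ir_truth, postc_truth)
    )

    return Study(
        params=params,
        seed=seed,
        table=table,
        true_effects=truth,
        interactome=interactome,
        true_modules=true_modules,
        annotations=annotations,
        linkset=linkset,
        planted_differential=frozenset(diff_spots),
        planted_opposite_tfs=tuple(planted_tfs),
    )
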