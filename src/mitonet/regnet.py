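"""Regulatory-network extension and the opposite-regulation TF screen.

The differential PPI network is extended with directed TF→target edges
from a regulatory linkset (e.g. a ChIP-seq-derived TF–target catalogue);
only edges whose target already sits in the PPI network are added, and a
TF with no in-network target never appears.  The screen then flags TFs
connected to at least one target whose logFC flips sign between the
revascularization-vs-ischemia and post-conditioning-vs-ischemia contrasts
with both magnitudes above the differential threshold — the signature of a
regulator whose program the two reperfusion strategies push in opposite
directions.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping
from dataclasses import dataclass, field

import networkx as nx

from .io_formats import Interactome, RegulatoryLinkset, ValidationError, to_graph

__all__ = [
    "ExtendedNetwork",
    "TFCandidate",
    "is_opposite",
    "extend",
    "screen_opposite",
    "extended_to_graph",
]


def is_opposite(lfc_a: float, lfc_b: float, threshold: float = 0.5) -> bool:
    """Strict opposite-regulation predicate.

    True iff the two contrast logFCs have opposite signs and both
    magnitudes strictly exceed the threshold.
    """
    return (lfc_a * lfc_b < 0) and abs(lfc_a) > threshold and abs(lfc_b) > threshold


@dataclass(frozen=True)
class ExtendedNetwork:
    """A PPI network plus directed TF→target regulatory edges.

    The PPI edge set is untouched by extension; every regulatory edge's
    target is a PPI node; TFs with zero in-network targets are absent.
    ``node_effects`` maps contrast label → node → logFC for annotation.
    """

    ppi: Interactome
    regulatory_edges: tuple[tuple[str, str], ...]
    node_effects: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def __post_init__(self):
        seen = set()
        for tf, target in self.regulatory_edges:
            if (tf, target) in seen:
                raise ValidationError(f"duplicate regulatory edge ({tf!r}, {target!r})")
            seen.add((tf, target))
            if not self.ppi.graph.has_node(target):
                raise ValidationError(
                    f"regulatory edge target {target!r} is not a PPI node"
                )

    @property
    def tfs(self) -> list[str]:
        return sorted({tf for tf, _t in self.regulatory_edges})

    def targets_of(self, tf: str) -> list[str]:
        return sorted(t for f, t in self.regulatory_edges if f == tf)


@dataclass(frozen=True)
class TFCandidate:
    """Screen result for one TF."""

    tf_id: str
    in_network_targets: tuple[str, ...]
    opposite_targets: tuple[str, ...]

    def __post_init__(self):
        if not set(self.opposite_targets) <= set(self.in_network_targets):
            raise ValidationError(
                f"opposite targets of {self.tf_id!r} not a subset of its targets"
            )

    @property
    def is_opposite_candidate(self) -> bool:
        return len(self.opposite_targets) > 0


def extend(
    network,
    linkset: RegulatoryLinkset,
    node_effects: Mapping[str, Mapping[str, float]] | None = None,
) -> ExtendedNetwork:
    """Add the linkset's TF→target edges whose target is a network node.

    ``network`` may be an :class:`Interactome` or an already-extended
    network (extension is idempotent: re-applying the same linkset changes
    nothing).
    """
    if isinstance(network, ExtendedNetwork):
        ppi = network.ppi
        existing = set(network.regulatory_edges)
        if node_effects is None:
            node_effects = network.node_effects
    elif isinstance(network, Interactome):
        ppi = network
        existing = set()
    else:
        raise TypeError(f"cannot extend {type(network).__name__}")
    if ppi.n_nodes == 0:
        raise ValidationError("cannot extend an empty network")
    kept = existing | {
        (tf, target)
        for tf, target in linkset.pairs
        if ppi.graph.has_node(target)
    }
    return ExtendedNetwork(
        ppi=ppi,
        regulatory_edges=tuple(sorted(kept)),
        node_effects=dict(node_effects or {}),
    )


def screen_opposite(
    extnet: ExtendedNetwork,
    contrast_ir_vs_isch: Mapping[str, float],
    contrast_postc_vs_isch: Mapping[str, float],
    threshold: float = 0.5,
) -> list[TFCandidate]:
    """Screen every TF for targets with opposite regulation in the two contrasts.

    Targets missing a logFC in either contrast are skipped with a warning
    (never treated as zero).  All TFs are returned, flagged; candidates
    sort first (by number of opposite targets descending, then tf id).
    """
    if not threshold > 0:
        raise ValidationError(f"threshold must be > 0, got {threshold}")
    skipped: set[str] = set()
    candidates = []
    for tf in extnet.tfs:
        targets = extnet.targets_of(tf)
        opposite = []
        for t in targets:
            if t not in contrast_ir_vs_isch or t not in contrast_postc_vs_isch:
                skipped.add(t)
                continue
            if is_opposite(
                contrast_ir_vs_isch[t], contrast_postc_vs_isch[t], threshold
            ):
                opposite.append(t)
        candidates.append(
            TFCandidate(
                tf_id=tf,
                in_network_targets=tuple(targets),
                opposite_targets=tuple(opposite),
            )
        )
    if skipped:
        warnings.warn(
            f"{len(skipped)} target(s) lack a logFC in one of the contrasts "
            f"and were skipped: {sorted(skipped)[:10]}"
        )
    candidates.sort(key=lambda c: (-len(c.opposite_targets), c.tf_id))
    return candidates


def extended_to_graph(
    extnet: ExtendedNetwork,
    partition: Mapping | None = None,
) -> nx.DiGraph:
    """Directed annotated graph view for GraphML export.

    PPI edges carry ``kind='ppi'`` (stored once, in sorted direction);
    regulatory edges carry ``kind='regulatory'``.  Nodes carry ``kind``
    (protein | tf), ``degree`` within the full extended network, optional
    ``cluster`` and per-contrast ``logfc_*`` attributes.
    """
    base = to_graph(extnet.ppi, partition=partition, node_effects=extnet.node_effects)
    g = nx.DiGraph()
    for node, attrs in base.nodes(data=True):
        g.add_node(node, **attrs)
    for u, v, attrs in base.edges(data=True):
        a, b = sorted((u, v), key=str)
        g.add_edge(a, b, **attrs)
    for tf, target in extnet.regulatory_edges:
        if not g.has_node(tf):
            g.add_node(tf, kind="tf")
        g.add_edge(tf, target, weight=1.0, kind="regulatory")
    for node in g.nodes:
        g.nodes[node]["degree"] = int(g.to_undirected(as_view=True).degree(node))
    return g
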