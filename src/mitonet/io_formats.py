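"""Readers and writers for the pipeline's external file formats.

Formats handled here:

* spot-intensity tables — CSV (rows = spots, columns = gels) with a
  two-column TSV sidecar mapping each gel to its experimental group;
* interactomes — STRING-download-style TSV edge lists with columns
  ``protein1``, ``protein2`` and an integer ``combined_score`` in 0–1000;
* annotation gene sets — GMT (term, description, tab-separated members);
* regulatory linksets — TSV of directed TF→target edges;
* GraphML — attribute-rich network export for downstream visualization.

All readers validate strictly and *reject* malformed input rather than
coercing it; error messages carry file coordinates (line numbers, and
row/column for tabular cells).  Lines beginning with ``#`` are treated as
comment/metadata lines in the line-oriented formats, so every writer can
prepend a commented provenance header without breaking its own reader.
"""

from __future__ import annotations

import math
import os
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "FormatError",
    "SpotIntensityTable",
    "Interactome",
    "AnnotationCollection",
    "RegulatoryLinkset",
    "read_spot_table",
    "write_spot_table",
    "read_string_tsv",
    "write_string_tsv",
    "read_gmt",
    "write_gmt",
    "read_linkset",
    "write_linkset",
    "to_graph",
    "write_graphml",
    "read_graphml",
]


class ValidationError(ValueError):
    """An in-memory object violates one of its invariants."""


class FormatError(ValueError):
    """A file could not be parsed; the message carries file coordinates."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f"{path}"
            if line is not None:
                loc += f", line {line}"
            loc = f" [{loc}]"
        super().__init__(f"{message}{loc}")
        self.path = path
        self.line = line


# ---------------------------------------------------------------------------
# atomic writing helpers


def _atomic_write_text(path, text: str) -> None:
    """Write ``text`` to ``path`` via a temp file + rename (never partial)."""
    tmp = f"{path}.tmp"
    with open(tmp, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(text)
    os.replace(tmp, path)


def _metadata_header(metadata: Mapping[str, object] | None) -> str:
    if not metadata:
        return ""
    return "".join(f"# {k}: {v}\n" for k, v in metadata.items())


def _data_lines(path):
    """Yield (lineno, stripped-line) skipping blanks and '#' comments."""
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            yield lineno, line


# ---------------------------------------------------------------------------
# domain containers


@dataclass(frozen=True)
class SpotIntensityTable:
    """Raw gel×spot fluorescence intensities with group labels.

    Parameters
    ----------
    intensities
        DataFrame indexed by spot id with one column per gel; values are
        non-negative fluorescence intensities on an arbitrary scale.
    gel_to_group
        Total mapping from gel id to experimental group label.
    reference_spot_id
        Identifier of the reference (albumin-like) spot used for
        normalization; must be present and strictly positive in every gel.
    """

    intensities: pd.DataFrame
    gel_to_group: Mapping[str, str]
    reference_spot_id: str

    def __post_init__(self):
        df = self.intensities
        if df.index.has_duplicates:
            dups = sorted(df.index[df.index.duplicated()].unique())
            raise ValidationError(f"duplicate spot ids: {dups}")
        if df.columns.has_duplicates:
            dups = sorted(df.columns[df.columns.duplicated()].unique())
            raise ValidationError(f"duplicate gel ids: {dups}")
        values = df.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValidationError("intensities contain non-finite values")
        if (values < 0).any():
            raise ValidationError("intensities contain negative values")
        if self.reference_spot_id not in df.index:
            raise ValidationError(
                f"reference spot {self.reference_spot_id!r} not in spot ids"
            )
        ref = df.loc[self.reference_spot_id]
        bad = [g for g in df.columns if not ref[g] > 0]
        if bad:
            raise ValidationError(
                f"reference spot {self.reference_spot_id!r} has non-positive "
                f"intensity in gels: {bad}"
            )
        missing = [g for g in df.columns if g not in self.gel_to_group]
        if missing:
            raise ValidationError(f"gels without a group label: {missing}")

    @property
    def spot_ids(self) -> list:
        return list(self.intensities.index)

    @property
    def gel_ids(self) -> list:
        return list(self.intensities.columns)

    @property
    def groups(self) -> list:
        seen = []
        for g in self.gel_ids:
            grp = self.gel_to_group[g]
            if grp not in seen:
                seen.append(grp)
        return seen

    def gels_in_group(self, group: str) -> list:
        return [g for g in self.gel_ids if self.gel_to_group[g] == group]


@dataclass(frozen=True)
class Interactome:
    """Weighted undirected PPI graph; edge weight = confidence in [0, 1]."""

    graph: nx.Graph

    def __post_init__(self):
        for u, v, data in self.graph.edges(data=True):
            if u == v:
                raise ValidationError(f"self-loop on node {u!r}")
            w = data.get("weight")
            if w is None or not (0.0 <= w <= 1.0):
                raise ValidationError(
                    f"edge ({u!r}, {v!r}) has weight {w!r} outside [0, 1]"
                )

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple],
        nodes: Iterable = (),
    ) -> "Interactome":
        """Build from ``(u, v, weight)`` triples plus optional extra nodes."""
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for u, v, w in edges:
            g.add_edge(u, v, weight=float(w))
        return cls(g)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def nodes(self) -> list:
        return list(self.graph.nodes)


@dataclass(frozen=True)
class AnnotationCollection:
    """Gene-set annotations: term id → (description, member set)."""

    terms: Mapping[str, tuple[str, frozenset]]

    def __post_init__(self):
        for term, (_desc, members) in self.terms.items():
            if not members:
                raise ValidationError(f"term {term!r} has an empty member set")

    def members(self, term: str) -> frozenset:
        return self.terms[term][1]

    def description(self, term: str) -> str:
        return self.terms[term][0]

    def universe(self) -> frozenset:
        out: set = set()
        for _desc, members in self.terms.values():
            out |= members
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms)

    def __contains__(self, term) -> bool:
        return term in self.terms


@dataclass(frozen=True)
class RegulatoryLinkset:
    """Directed TF→target edges with an optional source tag per edge."""

    edges: tuple[tuple[str, str, str | None], ...]

    def __post_init__(self):
        seen = set()
        for tf, target, _source in self.edges:
            if (tf, target) in seen:
                raise ValidationError(f"duplicate regulatory edge ({tf!r}, {target!r})")
            seen.add((tf, target))

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return [(tf, t) for tf, t, _s in self.edges]

    @property
    def tfs(self) -> list[str]:
        return sorted({tf for tf, _t, _s in self.edges})

    def __len__(self) -> int:
        return len(self.edges)


# ---------------------------------------------------------------------------
# spot tables


def read_spot_table(csv_path, group_map_path, reference_spot_id) -> SpotIntensityTable:
    """Read a spot-intensity CSV plus its gel→group sidecar TSV.

    The CSV's first column holds spot ids and its header row holds gel ids.
    Non-numeric or negative cells, duplicate ids, gels missing from the
    group map, and a missing reference spot are all rejected with
    coordinates in the error message.
    """
    header = None
    spot_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in _data_lines(csv_path):
        cells = line.split(",")
        if header is None:
            header = [c.strip() for c in cells]
            if len(header) < 2:
                raise FormatError("header has no gel columns", csv_path, lineno)
            continue
        if len(cells) != len(header):
            raise FormatError(
                f"expected {len(header)} fields, found {len(cells)}",
                csv_path,
                lineno,
            )
        spot_ids.append(cells[0].strip())
        row = []
        for j, cell in enumerate(cells[1:], start=1):
            try:
                value = float(cell)
            except ValueError:
                raise FormatError(
                    f"non-numeric intensity {cell!r} at row {len(rows) + 1}, "
                    f"column {j} (gel {header[j]!r})",
                    csv_path,
                    lineno,
                ) from None
            if not math.isfinite(value) or value < 0:
                raise FormatError(
                    f"invalid intensity {cell!r} (negative or non-finite) at "
                    f"row {len(rows) + 1}, column {j} (gel {header[j]!r})",
                    csv_path,
                    lineno,
                )
            row.append(value)
        rows.append(row)
    if header is None:
        raise FormatError("empty spot table", csv_path)
    gel_ids = header[1:]

    gel_to_group: dict[str, str] = {}
    saw_header = False
    for lineno, line in _data_lines(group_map_path):
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(
                f"expected 2 tab-separated fields, found {len(parts)}",
                group_map_path,
                lineno,
            )
        if not saw_header:
            saw_header = True
            if parts[0].strip().lower() in ("gel_id", "gel"):
                continue  # header row
        gel, group = parts[0].strip(), parts[1].strip()
        if gel in gel_to_group:
            raise FormatError(f"duplicate gel id {gel!r}", group_map_path, lineno)
        gel_to_group[gel] = group

    df = pd.DataFrame(rows, index=spot_ids, columns=gel_ids, dtype=float)
    return SpotIntensityTable(df, gel_to_group, reference_spot_id)


def write_spot_table(
    table: SpotIntensityTable,
    csv_path,
    group_map_path,
    metadata: Mapping[str, object] | None = None,
) -> None:
    lines = [_metadata_header(metadata)]
    lines.append("spot_id," + ",".join(str(g) for g in table.gel_ids) + "\n")
    for spot in table.spot_ids:
        vals = table.intensities.loc[spot]
        lines.append(
            str(spot) + "," + ",".join(repr(float(v)) for v in vals) + "\n"
        )
    _atomic_write_text(csv_path, "".join(lines))

    glines = [_metadata_header(metadata), "gel_id\tgroup\n"]
    for gel in table.gel_ids:
        glines.append(f"{gel}\t{table.gel_to_group[gel]}\n")
    _atomic_write_text(group_map_path, "".join(glines))


# ---------------------------------------------------------------------------
# STRING-style interactome TSV


def read_string_tsv(tsv_path, score_cutoff: float = 0.4) -> Interactome:
    """Read a STRING-download-dialect edge list into an :class:`Interactome`.

    Edges with ``combined_score / 1000 >= score_cutoff`` are retained;
    duplicate pairs collapse to the maximum score; self-pairs are dropped.
    """
    col_idx = None
    best: dict[tuple, int] = {}
    for lineno, line in _data_lines(tsv_path):
        parts = [p.strip() for p in line.split("\t")]
        if col_idx is None:
            required = ("protein1", "protein2", "combined_score")
            try:
                col_idx = tuple(parts.index(c) for c in required)
            except ValueError:
                missing = [c for c in required if c not in parts]
                raise FormatError(
                    f"header missing required columns {missing}", tsv_path, lineno
                ) from None
            continue
        if len(parts) <= max(col_idx):
            raise FormatError(
                f"expected at least {max(col_idx) + 1} fields, found {len(parts)}",
                tsv_path,
                lineno,
            )
        u, v, score_str = (parts[i] for i in col_idx)
        try:
            score = int(score_str)
        except ValueError:
            raise FormatError(
                f"malformed combined_score {score_str!r}", tsv_path, lineno
            ) from None
        if not 0 <= score <= 1000:
            raise FormatError(
                f"combined_score {score} outside 0–1000", tsv_path, lineno
            )
        if u == v:
            continue
        key = (u, v) if u <= v else (v, u)
        if score > best.get(key, -1):
            best[key] = score
    if col_idx is None:
        raise FormatError("empty interactome file (no header)", tsv_path)
    edges = [
        (u, v, score / 1000.0)
        for (u, v), score in sorted(best.items())
        if score / 1000.0 >= score_cutoff
    ]
    return Interactome.from_edges(edges)


def write_string_tsv(
    interactome: Interactome,
    tsv_path,
    metadata: Mapping[str, object] | None = None,
) -> None:
    lines = [_metadata_header(metadata), "protein1\tprotein2\tcombined_score\n"]
    edges = sorted(
        (min(str(u), str(v)), max(str(u), str(v)), d["weight"])
        for u, v, d in interactome.graph.edges(data=True)
    )
    for u, v, w in edges:
        lines.append(f"{u}\t{v}\t{int(round(w * 1000))}\n")
    _atomic_write_text(tsv_path, "".join(lines))


# ---------------------------------------------------------------------------
# GMT annotation sets


def read_gmt(path) -> AnnotationCollection:
    terms: dict[str, tuple[str, frozenset]] = {}
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) < 3:
            raise FormatError(
                "GMT line needs term, description and at least one member",
                path,
                lineno,
            )
        term, desc = parts[0].strip(), parts[1].strip()
        members = frozenset(p.strip() for p in parts[2:] if p.strip())
        if not members:
            raise FormatError(f"term {term!r} has no members", path, lineno)
        if term in terms:
            raise FormatError(f"duplicate term id {term!r}", path, lineno)
        terms[term] = (desc, members)
    return AnnotationCollection(terms)


def write_gmt(
    annotations: AnnotationCollection,
    path,
    metadata: Mapping[str, object] | None = None,
) -> None:
    lines = [_metadata_header(metadata)]
    for term in annotations:
        desc, members = annotations.terms[term]
        lines.append("\t".join([term, desc, *sorted(members)]) + "\n")
    _atomic_write_text(path, "".join(lines))


# ---------------------------------------------------------------------------
# regulatory linksets


def read_linkset(path) -> RegulatoryLinkset:
    edges: list[tuple[str, str, str | None]] = []
    seen: set[tuple[str, str]] = set()
    saw_header = False
    for lineno, line in _data_lines(path):
        parts = [p.strip() for p in line.split("\t")]
        if len(parts) not in (2, 3):
            raise FormatError(
                f"expected 2 or 3 tab-separated fields, found {len(parts)}",
                path,
                lineno,
            )
        if not saw_header:
            saw_header = True
            if parts[0].lower() == "tf":
                continue
        tf, target = parts[0], parts[1]
        source = parts[2] if len(parts) == 3 else None
        if (tf, target) in seen:
            raise FormatError(
                f"duplicate regulatory edge ({tf!r}, {target!r})", path, lineno
            )
        seen.add((tf, target))
        edges.append((tf, target, source))
    return RegulatoryLinkset(tuple(edges))


def write_linkset(
    linkset: RegulatoryLinkset,
    path,
    metadata: Mapping[str, object] | None = None,
) -> None:
    lines = [_metadata_header(metadata), "tf\ttarget\tsource\n"]
    for tf, target, source in linkset.edges:
        lines.append(f"{tf}\t{target}\t{'' if source is None else source}\n")
    _atomic_write_text(path, "".join(lines))


# ---------------------------------------------------------------------------
# GraphML export


def to_graph(
    interactome: Interactome,
    partition: Mapping | None = None,
    node_effects: Mapping[str, Mapping[str, float]] | None = None,
    node_kind: str = "protein",
) -> nx.Graph:
    """Annotated :class:`networkx.Graph` view of an interactome.

    Node attributes: ``kind``, ``degree`` (within this network), ``cluster``
    (if a partition is given) and one ``logfc_<contrast>`` attribute per
    contrast present in ``node_effects``.  Edge attributes: ``weight`` and
    ``kind='ppi'``.
    """
    g = nx.Graph()
    for node in interactome.graph.nodes:
        attrs: dict = {
            "kind": node_kind,
            "degree": int(interactome.graph.degree(node)),
        }
        if partition is not None and node in partition:
            attrs["cluster"] = int(partition[node])
        if node_effects:
            for contrast, effects in node_effects.items():
                if node in effects:
                    attrs[f"logfc_{contrast}"] = float(effects[node])
        g.add_node(node, **attrs)
    for u, v, data in interactome.graph.edges(data=True):
        g.add_edge(u, v, weight=float(data["weight"]), kind="ppi")
    return g


def write_graphml(graph: nx.Graph, path, metadata: Mapping[str, object] | None = None) -> None:
    g = graph.copy()
    if metadata:
        for k, v in metadata.items():
            g.graph[str(k)] = str(v)
    tmp = f"{path}.tmp"
    nx.write_graphml(g, tmp)
    os.replace(tmp, path)


def read_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)
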