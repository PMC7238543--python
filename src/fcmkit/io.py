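"""Readers and writers for the file formats stakeholder maps travel in.

Three formats are supported:

* **adjacency CSV** -- a square table whose first row and first column are the
  same factor labels; cell (row i, column j) is the signed weight of the edge
  i -> j (direction row -> column); blank or 0 means no edge.  A single
  signed number encodes both magnitude and sign: ``-4`` is an inhibitory edge
  of strength 4.
* **edge-list CSV** -- header ``source,target,weight,sign``; the sign column
  is optional (default excitatory) and a negative weight is also accepted as
  inhibitory shorthand.
* **GraphML** -- a directed graph as exported by diagram editors; the edge
  weight is taken from a numeric ``weight`` attribute if one is declared,
  otherwise from the first numeric token of the edge label.

All readers produce maps that satisfy the FuzzyCognitiveMap invariants or
raise a :class:`~fcmkit.errors.FormatError` subclass; factor identity is by
label after whitespace trimming and case folding.
"""

from __future__ import annotations

import math
import re
from pathlib import Path

import networkx as nx
import pandas as pd

from .errors import DuplicateEdgeError, FormatError, MapParseError, WeightRangeError
from .model import Edge, Factor, FuzzyCognitiveMap, normalize_label

__all__ = [
    "read_adjacency_csv",
    "write_adjacency_csv",
    "read_edge_list",
    "write_edge_list",
    "read_graphml",
    "write_graphml",
]

_NUM_RE = re.compile(r"[-−+]?\d+(?:\.\d+)?")


def _split_signed(value: float, where: str) -> tuple[float, int]:
    if value == 0 or math.isnan(value):
        raise MapParseError(f"{where}: zero/NaN is not a valid edge weight")
    sign = -1 if value < 0 else 1
    return abs(value), sign


def _new_map(name, polarity, participant_count, scaled) -> FuzzyCognitiveMap:
    return FuzzyCognitiveMap(
        name=name, polarity=polarity, participant_count=participant_count, scaled=scaled
    )


def _id_for(label: str, seen: dict[str, str]) -> str:
    """Stable short ids F01, F02, ... keyed by canonical label."""
    key = normalize_label(label)
    if key not in seen:
        seen[key] = f"F{len(seen) + 1:02d}"
    return seen[key]


def read_adjacency_csv(
    path: str | Path,
    *,
    name: str | None = None,
    polarity: str = "risk",
    participant_count: int = 1,
    scaled: bool = False,
) -> FuzzyCognitiveMap:
    """Read a square adjacency-matrix CSV into a map.

    Node order follows the file's row order.  Raises
    :class:`~fcmkit.errors.FormatError` for a non-square table or mismatched
    row/column labels, :class:`~fcmkit.errors.MapParseError` (with cell
    coordinates) for a non-numeric cell.
    """
    path = Path(path)
    name = name if name is not None else path.stem
    try:
        df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return _new_map(name, polarity, participant_count, scaled)
    if df.shape[0] != df.shape[1]:
        raise FormatError(
            f"{path}: adjacency table is not square "
            f"({df.shape[0]} rows x {df.shape[1]} columns)"
        )
    rows = [str(r) for r in df.index]
    cols = [str(c) for c in df.columns]
    if [normalize_label(r) for r in rows] != [normalize_label(c) for c in cols]:
        raise FormatError(
            f"{path}: row labels {rows} do not match column labels {cols}"
        )
    fcm = _new_map(name, polarity, participant_count, scaled)
    seen: dict[str, str] = {}
    ids = [fcm.add_factor(Factor(_id_for(r, seen), r, group=name)).id for r in rows]
    for i, r in enumerate(rows):
        for j, c in enumerate(cols):
            raw = str(df.iat[i, j]).strip()
            if raw == "":
                continue
            try:
                value = float(raw.replace("−", "-"))
            except ValueError as exc:
                raise MapParseError(
                    f"{path}: non-numeric cell at row {r!r}, column {c!r}: {raw!r}"
                ) from exc
            if value == 0:
                continue
            weight, sign = _split_signed(value, f"{path} cell ({r!r},{c!r})")
            fcm.add_edge(Edge(ids[i], ids[j], weight, sign))
    return fcm


def write_adjacency_csv(fcm: FuzzyCognitiveMap, path: str | Path) -> None:
    """Write a map as an adjacency CSV; round-trips through
    :func:`read_adjacency_csv` (factors, edges, weights, signs)."""
    path = Path(path)
    labels = fcm.labels()
    _, a = fcm.to_adjacency()
    if not fcm.scaled:
        a = a.astype(int)
    df = pd.DataFrame(a, index=labels, columns=labels)
    df.to_csv(path)


def read_edge_list(
    path: str | Path,
    *,
    name: str | None = None,
    polarity: str = "risk",
    participant_count: int = 1,
    scaled: bool = False,
) -> FuzzyCognitiveMap:
    """Read an edge-list CSV (source, target, weight[, sign]).

    Factors are the union of endpoints in order of first appearance.  On an
    unscaled read a weight outside {1..5} raises
    :class:`~fcmkit.errors.WeightRangeError` citing the row; a repeated
    (source, target) pair raises :class:`~fcmkit.errors.DuplicateEdgeError`.
    """
    path = Path(path)
    name = name if name is not None else path.stem
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return _new_map(name, polarity, participant_count, scaled)
    df.columns = [str(c).strip().lower() for c in df.columns]
    for col in ("source", "target", "weight"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    fcm = _new_map(name, polarity, participant_count, scaled)
    seen: dict[str, str] = {}
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        src_label, tgt_label = str(row.source).strip(), str(row.target).strip()
        try:
            value = float(str(row.weight).replace("−", "-"))
        except ValueError as exc:
            raise MapParseError(
                f"{path} row {row_no}: non-numeric weight {row.weight!r}"
            ) from exc
        weight, sign = _split_signed(value, f"{path} row {row_no}")
        if "sign" in df.columns:
            token = str(getattr(row, "sign")).strip()
            if token not in ("", "nan"):
                if token in ("+", "+1", "1"):
                    pass
                elif token in ("-", "−", "-1"):
                    sign = -sign  # column sign multiplies any sign on the weight
                else:
                    raise MapParseError(
                        f"{path} row {row_no}: unrecognized sign {token!r}"
                    )
        if not scaled and weight not in (1, 2, 3, 4, 5):
            raise WeightRangeError(
                f"{path} row {row_no}: weight {weight} outside {{1..5}}"
            )
        for label in (src_label, tgt_label):
            fid = _id_for(label, seen)
            if not fcm.has_factor(fid):
                fcm.add_factor(Factor(fid, label, group=name))
        try:
            fcm.add_edge(
                Edge(_id_for(src_label, seen), _id_for(tgt_label, seen), weight, sign)
            )
        except DuplicateEdgeError as exc:
            raise DuplicateEdgeError(f"{path} row {row_no}: {exc}") from exc
    return fcm


def write_edge_list(fcm: FuzzyCognitiveMap, path: str | Path) -> None:
    rows = [
        {
            "source": fcm.factor(e.source).label,
            "target": fcm.factor(e.target).label,
            "weight": e.weight if fcm.scaled else int(e.weight),
            "sign": "+" if e.sign > 0 else "-",
        }
        for e in fcm.edges
    ]
    pd.DataFrame(rows, columns=["source", "target", "weight", "sign"]).to_csv(
        path, index=False
    )


def _node_label(data: dict, node_id: str) -> str:
    for key in ("label", "name", "description"):
        value = data.get(key)
        if isinstance(value, str) and value.strip():
            return value.strip()
    return str(node_id)


def _edge_weight(data: dict, where: str) -> tuple[float, int]:
    value = data.get("weight")
    if value is None or (isinstance(value, str) and not _NUM_RE.search(value)):
        label = str(data.get("label", ""))
        match = _NUM_RE.search(label)
        if match is None:
            raise MapParseError(f"{where}: no recoverable numeric weight")
        value = match.group(0)
    try:
        number = float(str(value).replace("−", "-"))
    except ValueError as exc:
        raise MapParseError(f"{where}: weight {value!r} is not numeric") from exc
    return _split_signed(number, where)


def read_graphml(
    path: str | Path,
    *,
    name: str | None = None,
    polarity: str = "risk",
    participant_count: int = 1,
    scaled: bool = False,
) -> FuzzyCognitiveMap:
    """Read a directed GraphML file (diagram-editor export) into a map.

    Weight discovery order: a numeric ``weight`` edge attribute first, then
    the first numeric token of the edge label.  An undirected graph is an
    unsupported format; an edge with no recoverable number is a parse error
    naming the edge.
    """
    path = Path(path)
    name = name if name is not None else path.stem
    graph = nx.read_graphml(path)
    if not graph.is_directed():
        raise FormatError(f"{path}: undirected GraphML graphs are not supported")
    fcm = _new_map(name, polarity, participant_count, scaled)
    seen: dict[str, str] = {}
    node_ids: dict[str, str] = {}
    for node, data in graph.nodes(data=True):
        label = _node_label(data, node)
        fid = _id_for(label, seen)
        node_ids[node] = fid
        if not fcm.has_factor(fid):
            fcm.add_factor(Factor(fid, label, group=name))
    for u, v, data in graph.edges(data=True):
        weight, sign = _edge_weight(data, f"{path}: edge {u!r}->{v!r}")
        if not scaled and weight not in (1, 2, 3, 4, 5):
            raise WeightRangeError(
                f"{path}: edge {u!r}->{v!r} weight {weight} outside {{1..5}}"
            )
        fcm.add_edge(Edge(node_ids[u], node_ids[v], weight, sign))
    return fcm


def write_graphml(fcm: FuzzyCognitiveMap, path: str | Path) -> None:
    graph = nx.DiGraph(name=fcm.name)
    for f in fcm.factors:
        graph.add_node(f.id, label=f.label)
    for e in fcm.edges:
        graph.add_edge(e.source, e.target, weight=e.signed_weight)
    nx.write_graphml(graph, path)
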