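"""Readers and writers for edge lists, ternary status matrices, and GraphML.

Two plain-text formats carry a network losslessly:

* **edge list** — one row per pair with columns ``drug``, ``target`` and a
  ``status`` token or a numeric ``value`` (+ optional ``unit``, ``source``).
  By default UNKNOWN rows are omitted on write, mirroring real database
  exports that report determined (mostly active) pairs only; reading then
  restores the omitted pairs as UNKNOWN over the supplied universes.
* **status matrix** — a labelled CSV grid with cells ``1`` (active), ``0``
  (inactive) and ``?`` (unknown); always carries all n·m cells.

GraphML export (via networkx) writes the bipartite graph with node attribute
``part`` and edge attributes ``status`` and ``color`` (green/red/black for
active/inactive/unknown).
"""

from __future__ import annotations

import csv
import io as _stdio
import os
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence, TextIO, Union

import networkx as nx

from .core import ActivityRecord, EdgeColoredNetwork, InteractionStatus, build_network
from .errors import FormatError, VocabularyError

__all__ = [
    "EdgeListDialect",
    "read_edge_list",
    "write_edge_list",
    "read_status_matrix",
    "write_status_matrix",
    "export_graphml",
    "load_worked_example",
]

_CELL_TO_STATUS = {
    "1": InteractionStatus.ACTIVE,
    "0": InteractionStatus.INACTIVE,
    "?": InteractionStatus.UNKNOWN,
}
_STATUS_TO_CELL = {s: c for c, s in _CELL_TO_STATUS.items()}

_STATUS_COLOR = {
    InteractionStatus.ACTIVE: "green",
    InteractionStatus.INACTIVE: "red",
    InteractionStatus.UNKNOWN: "black",
}


def _default_vocabulary() -> dict:
    return {
        "active": InteractionStatus.ACTIVE,
        "inactive": InteractionStatus.INACTIVE,
        "unknown": InteractionStatus.UNKNOWN,
        "1": InteractionStatus.ACTIVE,
        "0": InteractionStatus.INACTIVE,
        "?": InteractionStatus.UNKNOWN,
    }


@dataclass(frozen=True)
class EdgeListDialect:
    """How an edge-list file is tokenised.

    ``status_vocabulary`` maps lowercase tokens to statuses (matched
    case-insensitively); ``value_unit`` is assumed for value rows that carry
    no ``unit`` column.
    """

    delimiter: str = "\t"
    status_vocabulary: dict = field(default_factory=_default_vocabulary)
    value_unit: str = "uM"

    def __post_init__(self) -> None:
        lowered = [str(k).strip().lower() for k in self.status_vocabulary]
        if len(set(lowered)) != len(lowered):
            raise FormatError("status vocabulary tokens must be pairwise distinct")

    def status_for(self, token: str) -> Optional[InteractionStatus]:
        return self.status_vocabulary.get(token.strip().lower())


def _open_maybe(path_or_buffer, mode: str):
    """Return (file, should_close)."""
    if isinstance(path_or_buffer, (str, os.PathLike)):
        return open(path_or_buffer, mode, encoding="utf-8", newline=""), True
    return path_or_buffer, False


def _content_lines(handle: TextIO):
    """Yield (line_number, raw_line) skipping blanks and '#' comments."""
    for lineno, raw in enumerate(handle, start=1):
        stripped = raw.strip()
        if not stripped or stripped.startswith("#"):
            continue
        yield lineno, raw.rstrip("\r\n")


def _parse_header(fields: Sequence, lineno: int) -> dict:
    names = [f.strip().lower() for f in fields]
    counts = {n: names.count(n) for n in names}
    dup = sorted(n for n, c in counts.items() if c > 1)
    if dup:
        raise FormatError(f"line {lineno}: ambiguous (duplicated) columns: {dup}")
    cols = {n: i for i, n in enumerate(names)}
    if "drug" not in cols or "target" not in cols:
        raise FormatError(f"line {lineno}: header must name 'drug' and 'target' columns")
    if "status" not in cols and "value" not in cols:
        raise FormatError(f"line {lineno}: header must name a 'status' or 'value' column")
    return cols


def read_edge_list(
    path,
    dialect: Optional[EdgeListDialect] = None,
    *,
    threshold: float = 10.0,
    direction: str = "at_most",
    drug_universe: Optional[Sequence] = None,
    target_universe: Optional[Sequence] = None,
    conflict_policy: str = "error",
) -> EdgeColoredNetwork:
    """Parse an edge list and assemble the network.

    The file must be UTF-8 with a header row; lines starting with ``#`` are
    ignored. Errors carry the offending line number. Pairs absent from the
    file become UNKNOWN over the given (or inferred) universes.
    """
    dialect = dialect or EdgeListDialect()
    handle, should_close = _open_maybe(path, "r")
    try:
        records = []
        cols = None
        for lineno, line in _content_lines(handle):
            fields = next(csv.reader([line], delimiter=dialect.delimiter))
            if cols is None:
                cols = _parse_header(fields, lineno)
                continue
            if len(fields) != len(cols):
                raise FormatError(
                    f"line {lineno}: expected {len(cols)} fields, found {len(fields)}"
                )

            def cell(name):
                i = cols.get(name)
                return fields[i].strip() if i is not None else ""

            status_token = cell("status")
            value_text = cell("value")
            status = None
            if status_token:
                status = dialect.status_for(status_token)
                if status is None:
                    raise VocabularyError(
                        f"line {lineno}: status token {status_token!r} is not in the vocabulary"
                    )
            value = None
            if value_text:
                try:
                    value = float(value_text)
                except ValueError:
                    raise FormatError(
                        f"line {lineno}: non-numeric value {value_text!r}"
                    ) from None
            if status is None and value is None:
                raise FormatError(f"line {lineno}: row carries neither a status nor a value")
            records.append(
                ActivityRecord(
                    drug_id=cell("drug"),
                    target_id=cell("target"),
                    value=value,
                    unit=cell("unit") or dialect.value_unit,
                    status=status,
                    source=cell("source") or None,
                )
            )
        if cols is None:
            raise FormatError("edge list has no header row")
    finally:
        if should_close:
            handle.close()
    return build_network(
        records,
        drug_universe=drug_universe,
        target_universe=target_universe,
        threshold=threshold,
        direction=direction,
        conflict_policy=conflict_policy,
    )


def write_edge_list(
    network: EdgeColoredNetwork,
    path,
    dialect: Optional[EdgeListDialect] = None,
    *,
    include_unknown: bool = False,
) -> None:
    """Write one row per pair in drug-major order.

    UNKNOWN rows are omitted unless ``include_unknown`` — the default mirrors
    actives/inactives-only database exports; with the flag set the round trip
    through :func:`read_edge_list` is lossless.
    """
    dialect = dialect or EdgeListDialect()
    handle, should_close = _open_maybe(path, "w")
    try:
        writer = csv.writer(handle, delimiter=dialect.delimiter, lineterminator="\n")
        writer.writerow(["drug", "target", "status"])
        for rec in network.to_records(include_unknown=include_unknown):
            writer.writerow([rec.drug_id, rec.target_id, rec.status.value])
    finally:
        if should_close:
            handle.close()


def read_status_matrix(path) -> EdgeColoredNetwork:
    """Read a labelled ternary CSV grid (cells ``1``/``0``/``?``).

    First row: target labels (the leading corner cell is ignored); first
    column: drug labels. Ragged rows, duplicate labels, and cells outside
    the ternary alphabet raise a format error naming the coordinates.
    """
    handle, should_close = _open_maybe(path, "r")
    try:
        rows = [(lineno, next(csv.reader([line]))) for lineno, line in _content_lines(handle)]
    finally:
        if should_close:
            handle.close()
    if not rows:
        raise FormatError("status matrix file is empty")
    header_lineno, header = rows[0]
    targets = [c.strip() for c in header[1:]]
    if not targets or any(not t for t in targets):
        raise FormatError(f"line {header_lineno}: header must list non-empty target labels")
    drugs, matrix_rows = [], []
    for lineno, fields in rows[1:]:
        if len(fields) != len(targets) + 1:
            raise FormatError(
                f"line {lineno}: ragged row — expected {len(targets) + 1} cells, "
                f"found {len(fields)}"
            )
        drug = fields[0].strip()
        if not drug:
            raise FormatError(f"line {lineno}: empty drug label")
        statuses = []
        for j, cell in enumerate(fields[1:]):
            token = cell.strip()
            if token not in _CELL_TO_STATUS:
                raise FormatError(
                    f"line {lineno}: cell {token!r} at row {drug!r}, column "
                    f"{targets[j]!r} is not one of 1, 0, ?"
                )
            statuses.append(_CELL_TO_STATUS[token].code)
        drugs.append(drug)
        matrix_rows.append(statuses)
    if not drugs:
        raise FormatError("status matrix has no drug rows")
    if len(set(drugs)) != len(drugs):
        raise FormatError("duplicate drug labels in status matrix")
    if len(set(targets)) != len(targets):
        raise FormatError("duplicate target labels in status matrix")
    return EdgeColoredNetwork(tuple(drugs), tuple(targets), matrix_rows)


def write_status_matrix(network: EdgeColoredNetwork, path) -> None:
    """Write the full labelled ternary grid (always all n·m cells)."""
    handle, should_close = _open_maybe(path, "w")
    try:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(["drug", *network.targets])
        for i, drug in enumerate(network.drugs):
            cells = [
                _STATUS_TO_CELL[network.status(drug, t)] for t in network.targets
            ]
            writer.writerow([drug, *cells])
    finally:
        if should_close:
            handle.close()


def to_graph(network: EdgeColoredNetwork, *, include_unknown: bool = False) -> nx.Graph:
    """The networkx bipartite graph view used by :func:`export_graphml`."""
    g = nx.Graph()
    for d in network.drugs:
        g.add_node(d, part="drug")
    for t in network.targets:
        g.add_node(t, part="target")
    for d in network.drugs:
        for t in network.targets:
            status = network.status(d, t)
            if status is InteractionStatus.UNKNOWN and not include_unknown:
                continue
            g.add_edge(d, t, status=status.value, color=_STATUS_COLOR[status])
    return g


def export_graphml(
    network: EdgeColoredNetwork, path, *, include_unknown: bool = False
) -> None:
    """Write the edge-colored bipartite graph as GraphML.

    One edge per non-UNKNOWN pair by default; with ``include_unknown`` every
    pair gets an edge, colored green/red/black by status.
    """
    nx.write_graphml(to_graph(network, include_unknown=include_unknown), path)


def load_worked_example() -> EdgeColoredNetwork:
    """The packaged 8-drug × 4-target illustrative network.

    19 pairs are active, 7 inactive and 6 unknown, so its completeness is
    26/32 = 0.8125.
    """
    text = resources.files("dtnet").joinpath("data/worked_example.csv").read_text("utf-8")
    return read_status_matrix(_stdio.StringIO(text))
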