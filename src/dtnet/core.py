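"""Domain types and constructors for edge-colored bipartite drug-target networks.

A drug-target dataset is modelled as a bipartite network whose node sets are a
drug list D and a target list T, with every one of the n·m pairs carrying
exactly one of three edge colors: **active** (the measured or estimated
activity meets the threshold), **inactive** (it does not), or **unknown** (the
pair has never been determined — the unknown-by-omission convention used by
interaction databases that report actives only).

The ternary status matrix is the single source of truth; the three binary
indicator matrices A+, A- and A* obtained by :func:`decompose` partition it
(they sum elementwise to the all-ones matrix). Transposing the network swaps
the drug and target perspectives without losing information — this duality is
what makes a target's polyspecificity equal to its polypharmacology in the
transposed network.
"""

from __future__ import annotations

import enum
import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import (
    BipartiteError,
    ConflictError,
    EntityLookupError,
    InvalidInputError,
    InvalidRecordError,
)

__all__ = [
    "InteractionStatus",
    "ActivityRecord",
    "EdgeColoredNetwork",
    "ColoredSubnetworks",
    "classify_activity",
    "build_network",
    "transpose",
    "decompose",
    "assemble_full_adjacency",
]


class InteractionStatus(enum.Enum):
    """Ternary status of one drug-target pair.

    Every pair carries exactly one of the three states; ``UNKNOWN`` arises
    only from absent data, never from a measurement.
    """

    ACTIVE = "active"
    INACTIVE = "inactive"
    UNKNOWN = "unknown"

    @property
    def code(self) -> int:
        """Integer code used in the backing matrix (+1 / 0 / -1)."""
        return _STATUS_TO_CODE[self]

    def __str__(self) -> str:
        return self.value


_STATUS_TO_CODE = {
    InteractionStatus.ACTIVE: 1,
    InteractionStatus.INACTIVE: 0,
    InteractionStatus.UNKNOWN: -1,
}
_CODE_TO_STATUS = {code: status for status, code in _STATUS_TO_CODE.items()}

#: Conversion factors to micromolar for the unit spellings we accept.
_UNIT_TO_UM = {
    "um": 1.0,
    "μm": 1.0,
    "µm": 1.0,
    "micromolar": 1.0,
    "nm": 1e-3,
    "nanomolar": 1e-3,
    "pm": 1e-6,
    "mm": 1e3,
    "millimolar": 1e3,
    "m": 1e6,
}


def _to_micromolar(value: float, unit: str) -> float:
    try:
        factor = _UNIT_TO_UM[unit.strip().lower()]
    except KeyError:
        raise InvalidInputError(f"unrecognised concentration unit: {unit!r}") from None
    return value * factor


def classify_activity(
    value: float,
    threshold: float = 10.0,
    direction: str = "at_most",
) -> InteractionStatus:
    """Binarize a measured activity against a potency threshold.

    Parameters
    ----------
    value
        Nonnegative activity readout in μM (e.g. an IC50).
    threshold
        Nonnegative activity cutoff in μM; the conventional range for
        potency readouts is 1-10 μM.
    direction
        ``"at_most"`` — active when ``value <= threshold`` (potency
        convention: lower concentration means stronger binding);
        ``"at_least"`` — active when ``value >= threshold``.
        The boundary is inclusive either way.

    Returns
    -------
    InteractionStatus
        ``ACTIVE`` or ``INACTIVE`` — never ``UNKNOWN``, which can arise
        only from the absence of a measurement.
    """
    for name, x in (("value", value), ("threshold", threshold)):
        if not (isinstance(x, (int, float)) and math.isfinite(x)) or x < 0:
            raise InvalidInputError(f"{name} must be a finite nonnegative number, got {x!r}")
    if direction == "at_most":
        hit = value <= threshold
    elif direction == "at_least":
        hit = value >= threshold
    else:
        raise InvalidInputError(f"direction must be 'at_most' or 'at_least', got {direction!r}")
    return InteractionStatus.ACTIVE if hit else InteractionStatus.INACTIVE


@dataclass(frozen=True)
class ActivityRecord:
    """One observed/estimated drug-target measurement or explicit status.

    At least one of ``value`` (a nonnegative potency readout, canonical unit
    μM) or ``status`` must be present. When both are present they must agree
    once the value is classified against the threshold — this is checked at
    network-construction time, where the threshold is known.
    """

    drug_id: str
    target_id: str
    value: Optional[float] = None
    unit: str = "uM"
    status: Optional[InteractionStatus] = None
    source: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "drug_id", str(self.drug_id).strip())
        object.__setattr__(self, "target_id", str(self.target_id).strip())
        if not self.drug_id or not self.target_id:
            raise InvalidRecordError("drug_id and target_id must be non-empty after trimming")
        if self.value is None and self.status is None:
            raise InvalidRecordError(
                f"record ({self.drug_id}, {self.target_id}) has neither a value nor a status"
            )
        if self.value is not None:
            if not math.isfinite(self.value) or self.value < 0:
                raise InvalidRecordError(
                    f"record ({self.drug_id}, {self.target_id}) has invalid value {self.value!r}"
                )
        if self.status is not None and not isinstance(self.status, InteractionStatus):
            raise InvalidRecordError(f"status must be an InteractionStatus, got {self.status!r}")

    def value_in_um(self) -> Optional[float]:
        """The measured value converted to μM, or None if status-only."""
        if self.value is None:
            return None
        return _to_micromolar(self.value, self.unit)


@dataclass(frozen=True, eq=False)
class EdgeColoredNetwork:
    """An n×m ternary drug-target interaction matrix with ordered labels.

    ``codes`` holds one int8 per pair: +1 active, 0 inactive, -1 unknown.
    The array is copied and frozen at construction; all derived quantities
    (degrees, completeness, bounds) are pure functions of it.
    """

    drugs: tuple
    targets: tuple
    codes: np.ndarray

    def __post_init__(self) -> None:
        drugs = tuple(str(d) for d in self.drugs)
        targets = tuple(str(t) for t in self.targets)
        if not drugs or not targets:
            raise InvalidInputError("need at least one drug and one target")
        if len(set(drugs)) != len(drugs):
            raise InvalidInputError("drug labels must be pairwise distinct")
        if len(set(targets)) != len(targets):
            raise InvalidInputError("target labels must be pairwise distinct")
        overlap = set(drugs) & set(targets)
        if overlap:
            raise BipartiteError(
                f"drug and target label sets must be disjoint; shared: {sorted(overlap)}"
            )
        codes = np.asarray(self.codes, dtype=np.int8).copy()
        if codes.shape != (len(drugs), len(targets)):
            raise InvalidInputError(
                f"status matrix shape {codes.shape} does not match "
                f"{len(drugs)} drugs x {len(targets)} targets"
            )
        if not np.isin(codes, (-1, 0, 1)).all():
            raise InvalidInputError("status codes must be in {+1, 0, -1}")
        codes.setflags(write=False)
        object.__setattr__(self, "drugs", drugs)
        object.__setattr__(self, "targets", targets)
        object.__setattr__(self, "codes", codes)
        object.__setattr__(self, "_drug_index", {d: i for i, d in enumerate(drugs)})
        object.__setattr__(self, "_target_index", {t: j for j, t in enumerate(targets)})

    # -- basic geometry -------------------------------------------------
    @property
    def n_drugs(self) -> int:
        return len(self.drugs)

    @property
    def n_targets(self) -> int:
        return len(self.targets)

    @property
    def shape(self) -> tuple:
        return self.codes.shape

    def drug_index(self, drug_id: str) -> int:
        try:
            return self._drug_index[drug_id]
        except KeyError:
            raise EntityLookupError(f"unknown drug: {drug_id!r}") from None

    def target_index(self, target_id: str) -> int:
        try:
            return self._target_index[target_id]
        except KeyError:
            raise EntityLookupError(f"unknown target: {target_id!r}") from None

    def status(self, drug_id: str, target_id: str) -> InteractionStatus:
        """Status of one pair, by label."""
        i = self.drug_index(drug_id)
        j = self.target_index(target_id)
        return _CODE_TO_STATUS[int(self.codes[i, j])]

    # -- views ----------------------------------------------------------
    def transpose(self) -> "EdgeColoredNetwork":
        """The m×n target-drug view: same information, swapped perspective."""
        return EdgeColoredNetwork(self.targets, self.drugs, self.codes.T)

    def indicator(self, status: InteractionStatus) -> np.ndarray:
        """Binary n×m indicator matrix of the given edge color."""
        return (self.codes == status.code).astype(np.int8)

    def decompose(self) -> "ColoredSubnetworks":
        return ColoredSubnetworks(
            a_plus=self.indicator(InteractionStatus.ACTIVE),
            a_minus=self.indicator(InteractionStatus.INACTIVE),
            a_star=self.indicator(InteractionStatus.UNKNOWN),
        )

    def to_records(self, include_unknown: bool = True) -> list:
        """Status-only records for every pair, drug-major order."""
        out = []
        for i, d in enumerate(self.drugs):
            for j, t in enumerate(self.targets):
                status = _CODE_TO_STATUS[int(self.codes[i, j])]
                if status is InteractionStatus.UNKNOWN and not include_unknown:
                    continue
                out.append(ActivityRecord(drug_id=d, target_id=t, status=status))
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EdgeColoredNetwork):
            return NotImplemented
        return (
            self.drugs == other.drugs
            and self.targets == other.targets
            and np.array_equal(self.codes, other.codes)
        )

    def __hash__(self) -> int:
        return hash((self.drugs, self.targets, self.codes.tobytes()))

    def __repr__(self) -> str:
        return (
            f"EdgeColoredNetwork({self.n_drugs} drugs x {self.n_targets} targets, "
            f"{int((self.codes == 1).sum())} active / "
            f"{int((self.codes == 0).sum())} inactive / "
            f"{int((self.codes == -1).sum())} unknown)"
        )


@dataclass(frozen=True, eq=False)
class ColoredSubnetworks:
    """The three binary biadjacency matrices A+, A-, A* of one network.

    They partition the pair set: elementwise ``a_plus + a_minus + a_star``
    is the all-ones matrix.
    """

    a_plus: np.ndarray
    a_minus: np.ndarray
    a_star: np.ndarray

    def __post_init__(self) -> None:
        mats = {}
        shape = None
        for name in ("a_plus", "a_minus", "a_star"):
            m = np.asarray(getattr(self, name), dtype=np.int8).copy()
            if shape is None:
                shape = m.shape
            elif m.shape != shape:
                raise InvalidInputError("the three indicator matrices must share one shape")
            if not np.isin(m, (0, 1)).all():
                raise InvalidInputError(f"{name} must be binary")
            m.setflags(write=False)
            mats[name] = m
        if not (mats["a_plus"] + mats["a_minus"] + mats["a_star"] == 1).all():
            raise InvalidInputError("indicator matrices must partition the pair set (sum to 1)")
        for name, m in mats.items():
            object.__setattr__(self, name, m)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ColoredSubnetworks):
            return NotImplemented
        return all(
            np.array_equal(getattr(self, n), getattr(other, n))
            for n in ("a_plus", "a_minus", "a_star")
        )


# ---------------------------------------------------------------------------
# constructors / free functions
# ---------------------------------------------------------------------------

def _record_status(
    rec: ActivityRecord, threshold: float, direction: str
) -> InteractionStatus:
    """Resolve one record to a status, checking value/status agreement."""
    if rec.value is None:
        return rec.status  # presence guaranteed by ActivityRecord invariant
    classified = classify_activity(rec.value_in_um(), threshold, direction)
    if rec.status is not None and rec.status is not classified:
        raise InvalidRecordError(
            f"record ({rec.drug_id}, {rec.target_id}): value {rec.value} {rec.unit} "
            f"classifies as {classified} but status {rec.status} was asserted"
        )
    return classified


def _resolve_conflict(pair, statuses, policy: str) -> InteractionStatus:
    distinct = set(statuses)
    if len(distinct) == 1:
        return statuses[0]
    if policy == "error":
        raise ConflictError(
            f"conflicting statuses for pair ({pair[0]}, {pair[1]}): "
            + ", ".join(sorted(s.value for s in distinct))
        )
    if policy == "any_active":
        if InteractionStatus.ACTIVE in distinct:
            return InteractionStatus.ACTIVE
        if InteractionStatus.INACTIVE in distinct:
            return InteractionStatus.INACTIVE
        return InteractionStatus.UNKNOWN
    if policy == "majority":
        counts = Counter(statuses).most_common()
        top = counts[0][1]
        winners = [s for s, c in counts if c == top]
        # ties break toward UNKNOWN: silent resolution must not invent signal
        return winners[0] if len(winners) == 1 else InteractionStatus.UNKNOWN
    raise InvalidInputError(
        f"conflict_policy must be 'error', 'any_active' or 'majority', got {policy!r}"
    )


def _check_universe(labels: Sequence, seen: set, kind: str) -> tuple:
    labels = tuple(str(x).strip() for x in labels)
    if len(set(labels)) != len(labels):
        raise InvalidInputError(f"{kind} universe labels must be pairwise distinct")
    missing = seen - set(labels)
    if missing:
        raise InvalidInputError(
            f"record {kind} labels outside the supplied universe: {sorted(missing)}"
        )
    return labels


def build_network(
    records: Iterable[ActivityRecord],
    drug_universe: Optional[Sequence] = None,
    target_universe: Optional[Sequence] = None,
    *,
    threshold: float = 10.0,
    direction: str = "at_most",
    conflict_policy: str = "error",
    missing_status: InteractionStatus = InteractionStatus.UNKNOWN,
    collision_policy: str = "error",
) -> EdgeColoredNetwork:
    """Assemble an edge-colored network from activity records.

    Every pair in ``drug_universe x target_universe`` receives a status.
    Pairs with no record default to ``missing_status`` — UNKNOWN by default
    (unknown-by-omission), or INACTIVE for decoy-style datasets that treat
    unreported pairs as inactive. Label order is first-seen order over the
    records, or the universe order when universes are given.

    Parameters
    ----------
    records
        Activity records; value-bearing records are classified against
        ``threshold`` (μM) with the given ``direction`` comparator.
    conflict_policy
        ``"error"`` (default) fails loudly on contradictory records for one
        pair; ``"any_active"`` keeps ACTIVE over INACTIVE over UNKNOWN;
        ``"majority"`` takes the most frequent status, ties to UNKNOWN.
    collision_policy
        When a label occurs on both sides, ``"error"`` rejects the input;
        ``"suffix"`` appends ``"#target"`` to the colliding target labels.
    """
    if missing_status not in (InteractionStatus.UNKNOWN, InteractionStatus.INACTIVE):
        raise InvalidInputError("missing_status must be UNKNOWN or INACTIVE")
    records = list(records)

    seen_drugs: dict = {}
    seen_targets: dict = {}
    resolved: list = []  # (drug, target, status)
    for rec in records:
        if not isinstance(rec, ActivityRecord):
            raise InvalidInputError(f"expected ActivityRecord, got {type(rec).__name__}")
        seen_drugs.setdefault(rec.drug_id, None)
        seen_targets.setdefault(rec.target_id, None)
        resolved.append((rec.drug_id, rec.target_id, _record_status(rec, threshold, direction)))

    if drug_universe is not None:
        drugs = _check_universe(drug_universe, set(seen_drugs), "drug")
    else:
        drugs = tuple(seen_drugs)
    if target_universe is not None:
        targets = _check_universe(target_universe, set(seen_targets), "target")
    else:
        targets = tuple(seen_targets)
    if not drugs or not targets:
        raise InvalidInputError(
            "cannot determine network dimensions: supply universes or non-empty records"
        )

    rename: dict = {}
    overlap = set(drugs) & set(targets)
    if overlap:
        if collision_policy == "suffix":
            rename = {t: f"{t}#target" for t in overlap}
            targets = tuple(rename.get(t, t) for t in targets)
        elif collision_policy != "error":
            raise InvalidInputError(
                f"collision_policy must be 'error' or 'suffix', got {collision_policy!r}"
            )
        # collision_policy == "error" falls through to the constructor check

    by_pair: dict = {}
    for d, t, status in resolved:
        by_pair.setdefault((d, rename.get(t, t)), []).append(status)

    codes = np.full((len(drugs), len(targets)), missing_status.code, dtype=np.int8)
    di = {d: i for i, d in enumerate(drugs)}
    ti = {t: j for j, t in enumerate(targets)}
    for pair, statuses in by_pair.items():
        codes[di[pair[0]], ti[pair[1]]] = _resolve_conflict(pair, statuses, conflict_policy).code
    return EdgeColoredNetwork(drugs, targets, codes)


def transpose(network: EdgeColoredNetwork) -> EdgeColoredNetwork:
    """The target-drug view of ``network`` (an involution)."""
    return network.transpose()


def decompose(network: EdgeColoredNetwork) -> ColoredSubnetworks:
    """Split a network into its active / inactive / unknown indicator matrices."""
    return network.decompose()


def assemble_full_adjacency(biadjacency: np.ndarray) -> np.ndarray:
    """Embed an n×m binary biadjacency block into the full (n+m)×(n+m)
    symmetric adjacency matrix ``[[0, A], [A', 0]]`` of the bipartite graph.

    The zero diagonal blocks encode that edges never link two drugs or two
    targets.
    """
    a = np.asarray(biadjacency)
    if a.ndim != 2:
        raise InvalidInputError("biadjacency must be a 2-D matrix")
    if not np.isin(a, (0, 1)).all():
        raise InvalidInputError("biadjacency entries must be 0 or 1")
    a = a.astype(np.int8)
    n, m = a.shape
    full = np.zeros((n + m, n + m), dtype=np.int8)
    full[:n, n:] = a
    full[n:, :n] = a.T
    return full
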