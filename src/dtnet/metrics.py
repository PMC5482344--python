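"""Degrees, profiles, completeness measures, and degree bounds.

The colored degree of an entity is the count of its pairs in one status
class. With status ACTIVE it is the degree of polypharmacology π̂_PP (for a
drug: how many targets it hits) or polyspecificity π̂_PS (for a target: how
many drugs hit it). The unknown-status degree ε̂ is the entity's local
uncertainty, and the three degrees of any entity sum to the size of the
opposite node set — two degrees of freedom per entity.

Because determinations can be missing, the observed active degree is only a
lower bound on the true one; assuming every unknown pair active gives the
upper bound. The interval ``[π̂, π̂ + ε̂]`` therefore brackets the true degree
whenever the determinations themselves are correct, and each new
determination can only tighten it.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .core import EdgeColoredNetwork, InteractionStatus
from .errors import InvalidInputError, UndefinedSimilarityError

__all__ = [
    "EntityProfile",
    "DegreeBounds",
    "CompletenessReport",
    "colored_degree",
    "profile_vector",
    "global_completeness",
    "local_uncertainty",
    "degree_bounds",
    "profile_distance",
    "summary_table",
    "round_half_up",
]

_SIDES = ("drug", "target")


def _entity_codes(network: EdgeColoredNetwork, entity_id: str, side: str) -> np.ndarray:
    """The ternary code vector of one entity's pairs (a row or a column)."""
    if side == "drug":
        return network.codes[network.drug_index(entity_id), :]
    if side == "target":
        return network.codes[:, network.target_index(entity_id)]
    raise InvalidInputError(f"side must be 'drug' or 'target', got {side!r}")


def colored_degree(
    network: EdgeColoredNetwork,
    entity_id: str,
    side: str,
    status: InteractionStatus,
) -> int:
    """Number of the entity's pairs carrying ``status``.

    With ``status=ACTIVE`` this is the degree of polypharmacology (drug side)
    or polyspecificity (target side).
    """
    vec = _entity_codes(network, entity_id, side)
    return int(np.count_nonzero(vec == status.code))


@dataclass(frozen=True)
class EntityProfile:
    """Per-entity 3-vector of (active, inactive, unknown) degrees.

    The components are nonnegative counts summing to the opposite side's
    cardinality; as Euclidean vectors these profiles support distances and
    cosine similarities for downstream clustering.
    """

    entity_id: str
    side: str
    active_degree: int
    inactive_degree: int
    unknown_degree: int

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.active_degree, self.inactive_degree, self.unknown_degree], dtype=float
        )


def profile_vector(network: EdgeColoredNetwork, entity_id: str, side: str) -> EntityProfile:
    """The (active, inactive, unknown) degree triple of one entity."""
    vec = _entity_codes(network, entity_id, side)
    return EntityProfile(
        entity_id=entity_id,
        side=side,
        active_degree=int(np.count_nonzero(vec == 1)),
        inactive_degree=int(np.count_nonzero(vec == 0)),
        unknown_degree=int(np.count_nonzero(vec == -1)),
    )


@dataclass(frozen=True)
class CompletenessReport:
    """Global determination counts and the completeness fraction C_DT."""

    mu_plus: int
    mu_minus: int
    mu_star: int

    @property
    def n_pairs(self) -> int:
        return self.mu_plus + self.mu_minus + self.mu_star

    @property
    def c_dt(self) -> float:
        """Fraction of all pairs whose status has been determined, in [0, 1]."""
        return (self.mu_plus + self.mu_minus) / self.n_pairs


def global_completeness(network: EdgeColoredNetwork) -> CompletenessReport:
    """Count determined and unknown pairs over the whole matrix.

    ``c_dt`` is 1 exactly when no pair is UNKNOWN and 0 when none is
    determined; the three counts always sum to n·m.
    """
    codes = network.codes
    return CompletenessReport(
        mu_plus=int(np.count_nonzero(codes == 1)),
        mu_minus=int(np.count_nonzero(codes == 0)),
        mu_star=int(np.count_nonzero(codes == -1)),
    )


def local_uncertainty(
    network: EdgeColoredNetwork,
    entity_id: str,
    side: str,
    *,
    normalize: bool = False,
) -> float:
    """Per-entity uncertainty ε̂: the number of the entity's undetermined pairs.

    Computed by rearrangement — opposite-side cardinality minus the active and
    inactive degrees — which equals the direct UNKNOWN count because the three
    colors partition the pair set. With ``normalize=True`` the count is divided
    by the opposite side's cardinality, giving a per-entity incompleteness
    fraction in [0, 1] (an extension beyond the plain counts).
    """
    opposite = network.n_targets if side == "drug" else network.n_drugs
    eps = (
        opposite
        - colored_degree(network, entity_id, side, InteractionStatus.ACTIVE)
        - colored_degree(network, entity_id, side, InteractionStatus.INACTIVE)
    )
    if normalize:
        return eps / opposite
    return int(eps)


@dataclass(frozen=True)
class DegreeBounds:
    """Interval guaranteed to contain an entity's true active degree.

    ``lower`` assumes every unknown pair inactive, ``upper`` assumes every
    unknown pair active; the width equals the entity's local uncertainty.
    """

    entity_id: str
    side: str
    lower: int
    upper: int

    @property
    def width(self) -> int:
        return self.upper - self.lower


def degree_bounds(network: EdgeColoredNetwork, entity_id: str, side: str) -> DegreeBounds:
    """Lower/upper bounds on the true polypharmacology or polyspecificity.

    The upper bound cannot exceed the opposite side's cardinality, a cap
    attained only in the complete bipartite case.
    """
    active = colored_degree(network, entity_id, side, InteractionStatus.ACTIVE)
    unknown = colored_degree(network, entity_id, side, InteractionStatus.UNKNOWN)
    return DegreeBounds(entity_id=entity_id, side=side, lower=active, upper=active + unknown)


def profile_distance(p: EntityProfile, q: EntityProfile, metric: str = "euclidean") -> float:
    """Distance or similarity between two entity profiles.

    ``euclidean`` — plain Euclidean distance between the 3-vectors, ≥ 0 and 0
    iff the vectors coincide. ``cosine_similarity`` — in [0, 1] since the
    components are counts; 1 for parallel vectors. Cosine against a zero
    vector is undefined and raises rather than silently returning a
    convention value that would corrupt downstream clustering.
    """
    if p.side != q.side:
        raise InvalidInputError(
            f"profiles must come from the same side, got {p.side!r} and {q.side!r}"
        )
    u, v = p.as_array(), q.as_array()
    if metric == "euclidean":
        return float(np.linalg.norm(u - v))
    if metric == "cosine_similarity":
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu == 0.0 or nv == 0.0:
            raise UndefinedSimilarityError(
                "cosine similarity is undefined for an all-zero profile vector"
            )
        return float(np.clip(np.dot(u, v) / (nu * nv), 0.0, 1.0))
    raise InvalidInputError(
        f"metric must be 'euclidean' or 'cosine_similarity', got {metric!r}"
    )


def summary_table(network: EdgeColoredNetwork) -> pd.DataFrame:
    """One row per entity (drugs first, then targets, in network order) with
    the colored degrees and degree bounds.

    Columns, in fixed order: entity, side, active, inactive, unknown,
    lower_bound, upper_bound.
    """
    rows = []
    for side, labels in (("drug", network.drugs), ("target", network.targets)):
        for label in labels:
            prof = profile_vector(network, label, side)
            b = degree_bounds(network, label, side)
            rows.append(
                {
                    "entity": label,
                    "side": side,
                    "active": prof.active_degree,
                    "inactive": prof.inactive_degree,
                    "unknown": prof.unknown_degree,
                    "lower_bound": b.lower,
                    "upper_bound": b.upper,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["entity", "side", "active", "inactive", "unknown", "lower_bound", "upper_bound"],
    )


def round_half_up(x: float, digits: int = 3) -> float:
    """Round with ties away from zero (so 0.8125 → 0.813 at 3 digits),
    matching how completeness fractions are conventionally printed."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
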