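"""Seeded generators of ground-truth and database-style incomplete networks.

``generate_random_network`` draws each pair's status independently from a
categorical distribution — a uniform-sampling idealisation that deliberately
ignores the target-class popularity bias of real interaction databases.
``mask_network`` turns a fully determined ground truth into the kind of
incomplete view a public database exposes: a chosen fraction of pairs loses
its determination, and optionally every inactive determination is withheld
(actives-only reporting). Statuses are hidden, never flipped, so bound
intervals computed on the masked view must bracket the true degrees.

Masks are nested across hide fractions for a fixed seed: the pairs are put in
one seeded random order and the first round(f·N) are hidden, so raising f
only ever hides more. That makes completeness non-increasing and bound widths
non-decreasing in f — exactly, not just in expectation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import EdgeColoredNetwork
from .errors import ConfigError, InvalidInputError

__all__ = ["GeneratorConfig", "generate_random_network", "mask_network"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the random ternary network generator.

    ``p_active``, ``p_inactive``, ``p_unknown`` are the per-pair status
    probabilities; they must sum to 1 within 1e-12. ``seed`` is mandatory —
    every draw is reproducible by contract.
    """

    n_drugs: int
    n_targets: int
    p_active: float
    p_inactive: float
    p_unknown: float
    seed: int

    def __post_init__(self) -> None:
        if int(self.n_drugs) < 1 or int(self.n_targets) < 1:
            raise ConfigError("n_drugs and n_targets must be >= 1")
        probs = (self.p_active, self.p_inactive, self.p_unknown)
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ConfigError(f"probabilities must lie in [0, 1], got {probs}")
        if abs(sum(probs) - 1.0) > 1e-12:
            raise ConfigError(f"probabilities must sum to 1, got {sum(probs)!r}")
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigError("seed is mandatory and must be an integer")


def generate_random_network(config: GeneratorConfig) -> EdgeColoredNetwork:
    """Draw a seeded random edge-colored network.

    Labels are ``d1..dn`` and ``t1..tm``; each of the n·m statuses is an
    independent categorical draw, and the same config always yields the same
    network.
    """
    rng = np.random.default_rng(config.seed)
    codes = rng.choice(
        np.array([1, 0, -1], dtype=np.int8),
        size=(config.n_drugs, config.n_targets),
        p=[config.p_active, config.p_inactive, config.p_unknown],
    )
    drugs = tuple(f"d{i}" for i in range(1, config.n_drugs + 1))
    targets = tuple(f"t{j}" for j in range(1, config.n_targets + 1))
    return EdgeColoredNetwork(drugs, targets, codes)


def mask_network(
    truth: EdgeColoredNetwork,
    hide_fraction: float,
    *,
    drop_inactives: bool = False,
    seed: int,
    mode: str = "exact",
) -> EdgeColoredNetwork:
    """Database-style incomplete view of a fully determined ground truth.

    Parameters
    ----------
    truth
        A network with no UNKNOWN pairs (else a precondition error).
    hide_fraction
        Fraction of pairs whose determination is withheld. In ``"exact"``
        mode exactly ``round(hide_fraction * n_pairs)`` pairs (half-up)
        become UNKNOWN, so masked counts are sharp; ``"bernoulli"`` hides
        each pair independently with this probability.
    drop_inactives
        Additionally hide every INACTIVE determination, emulating databases
        that report actives only.
    seed
        Seeds the hiding pattern; for a fixed seed, masks at increasing
        hide fractions are nested.

    Statuses are only ever replaced by UNKNOWN; ACTIVE is never flipped to
    INACTIVE or vice versa.
    """
    if (truth.codes == -1).any():
        raise InvalidInputError("ground truth must contain no UNKNOWN pairs")
    if not (0.0 <= hide_fraction <= 1.0):
        raise InvalidInputError(f"hide_fraction must lie in [0, 1], got {hide_fraction!r}")
    rng = np.random.default_rng(seed)
    n_pairs = truth.n_drugs * truth.n_targets
    codes = np.array(truth.codes, dtype=np.int8)
    flat = codes.reshape(-1)
    if mode == "exact":
        k = int(math.floor(hide_fraction * n_pairs + 0.5))
        order = rng.permutation(n_pairs)
        flat[order[:k]] = -1
    elif mode == "bernoulli":
        flat[rng.random(n_pairs) < hide_fraction] = -1
    else:
        raise InvalidInputError(f"mode must be 'exact' or 'bernoulli', got {mode!r}")
    if drop_inactives:
        flat[flat == 0] = -1
    return EdgeColoredNetwork(truth.drugs, truth.targets, codes)
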