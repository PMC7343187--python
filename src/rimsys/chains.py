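"""Stochastic simulation of poly-glutamate chain dynamics on RpsF.

The glutamate tail on one RpsF molecule is modelled as a discrete-time
Markov chain: at every step the RimK/RimB machinery either adds one
glutamate (probability ``p_add``), removes one terminal glutamate
(``p_cut``, a no-op at or below the protease floor of four residues),
releases the chain (``release_prob``, processive mode), or does nothing.
The protease:ligase activity ratio ``rho = p_cut / p_add`` is the primary
control: with no protease the chain lengths are capped-geometric
("exponential"), while increasing ``rho`` concentrates the distribution
sharply at the minimal cleavable length of four.

Capping convention: at ``max_length`` (default 100) additions are no-ops,
so processive-mode probability mass accumulates at the cap rather than
being renormalised; :func:`geometric_oracle` follows the same convention.
Released chains leave the simulation with their final length.

The cell-scale picture couples one RimABK complex to many RpsF substrates
through a finite shared glutamate pool (:func:`simulate_population`): the
complex binds one chain, works on it processively, and on release moves to
a uniformly random chain; cleaved glutamate returns to the pool and can be
re-incorporated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "ChainConfig",
    "PopulationConfig",
    "ChainLengthDistribution",
    "PopulationResult",
    "simulate_single_chain",
    "chain_length_distribution",
    "geometric_oracle",
    "simulate_population",
    "distribution_mode",
]


@dataclass(frozen=True)
class ChainConfig:
    """Per-step event probabilities and structural limits for one chain.

    ``p_add + p_cut + release_prob`` must not exceed 1; the remainder is the
    idle ("doing nothing") probability.  ``min_cut_length`` (default 4) is
    the hard protease floor and ``max_length`` (default 100) the chain cap.
    ``horizon`` bounds the number of steps in protease mode; processive
    chains (``release_prob > 0``, ``p_cut = 0``) normally terminate by
    release.
    """

    p_add: float
    p_cut: float = 0.0
    release_prob: float = 0.0
    min_cut_length: int = 4
    max_length: int = 100
    horizon: int = 10_000
    initial_length: int = 0
    n_sims: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_add", "p_cut", "release_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.p_add + self.p_cut + self.release_prob > 1.0 + 1e-12:
            raise ValueError("event probabilities must sum to <= 1")
        if self.min_cut_length < 0 or self.max_length < self.min_cut_length:
            raise ValueError("require 0 <= min_cut_length <= max_length")
        if not 0 <= self.initial_length <= self.max_length:
            raise ValueError("initial_length must be within [0, max_length]")
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")
        if self.horizon < 0:
            raise ValueError("horizon must be >= 0")

    @property
    def p_idle(self) -> float:
        return 1.0 - self.p_add - self.p_cut - self.release_prob

    @property
    def activity_ratio(self) -> float:
        """Protease:ligase activity ratio rho = p_cut / p_add."""
        if self.p_add == 0:
            return math.inf if self.p_cut > 0 else 0.0
        return self.p_cut / self.p_add

    @classmethod
    def from_activity_ratio(
        cls, rho: float, p_add: float = 0.05, **kwargs
    ) -> "ChainConfig":
        """Build a config from rho at a given ligase step probability."""
        if rho < 0:
            raise ValueError("rho must be >= 0")
        return cls(p_add=p_add, p_cut=rho * p_add, **kwargs)


@dataclass(frozen=True)
class ChainLengthDistribution:
    """Empirical probability mass over chain lengths 0..max_length."""

    pmf: tuple[float, ...]
    n_sims: int
    seed: int

    def __post_init__(self) -> None:
        p = np.asarray(self.pmf)
        if np.any(p < 0):
            raise ValueError("probability masses must be >= 0")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("probability masses must sum to 1")

    @property
    def max_length(self) -> int:
        return len(self.pmf) - 1

    def mean(self) -> float:
        return float(np.dot(np.arange(len(self.pmf)), self.pmf))


def simulate_single_chain(
    config: ChainConfig, rng: Optional[np.random.Generator] = None
) -> int:
    """Run one chain to release or to the step horizon; return its length."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    length = config.initial_length
    threshold_cut = config.p_add + config.p_cut
    threshold_rel = threshold_cut + config.release_prob
    for _ in range(config.horizon):
        u = rng.random()
        if u < config.p_add:
            if length < config.max_length:
                length += 1
        elif u < threshold_cut:
            if length > config.min_cut_length:
                length -= 1
        elif u < threshold_rel:
            break
    return length


def _simulate_batch(config: ChainConfig, rng: np.random.Generator) -> np.ndarray:
    """Vectorised replicate chains; same per-step law as the scalar walker."""
    n = config.n_sims
    lengths = np.full(n, config.initial_length, dtype=np.int32)
    active = np.ones(n, dtype=bool)
    t_cut = config.p_add + config.p_cut
    t_rel = t_cut + config.release_prob
    for _ in range(config.horizon):
        if not active.any():
            break
        u = rng.random(n)
        add = active & (u < config.p_add) & (lengths < config.max_length)
        cut = (
            active
            & (u >= config.p_add)
            & (u < t_cut)
            & (lengths > config.min_cut_length)
        )
        release = active & (u >= t_cut) & (u < t_rel)
        lengths[add] += 1
        lengths[cut] -= 1
        active[release] = False
    return lengths


def chain_length_distribution(config: ChainConfig) -> ChainLengthDistribution:
    """Empirical chain-length distribution over ``n_sims`` replicate chains.

    Deterministic for a given (config, seed).  The cell-scale study this
    emulates averaged 1,000,000 replicates; the default here is 100,000.
    """
    rng = np.random.default_rng(config.seed)
    lengths = _simulate_batch(config, rng)
    counts = np.bincount(lengths, minlength=config.max_length + 1)
    pmf = counts / counts.sum()
    return ChainLengthDistribution(tuple(pmf), config.n_sims, config.seed)


def geometric_oracle(
    q: float, max_length: int = 100
) -> tuple[np.ndarray, float]:
    """Closed-form capped-geometric law for the no-protease limit.

    With per-step extension probability ``q`` and termination probability
    ``1 - q``, ``P(L = k) = q**k * (1 - q)`` for ``k < max_length`` and the
    remaining mass ``q**max_length`` sits at the cap.  Returns the pmf and
    the uncapped mean ``q / (1 - q)``.
    """
    if not 0.0 <= q < 1.0:
        raise ValueError(f"extension probability must satisfy 0 <= q < 1, got {q}")
    k = np.arange(max_length + 1)
    pmf = q**k * (1.0 - q)
    pmf[max_length] = q**max_length
    return pmf, q / (1.0 - q)


def distribution_mode(dist: ChainLengthDistribution) -> int:
    """Modal chain length; ties break toward the smaller length."""
    return int(np.argmax(dist.pmf))


@dataclass(frozen=True)
class PopulationConfig:
    """Cell-scale setup: many RpsF chains, one machinery, shared pool.

    ``pool`` is the finite free-glutamate monomer count shared by all
    chains (``None`` = unlimited).  ``horizon`` counts machinery events;
    with ``n_complex`` > 1 the event budget scales proportionally (events
    remain strictly sequential, one at a time).
    """

    n_rpsf: int = 500
    n_complex: int = 1
    pool: Optional[int] = None
    horizon: int = 500_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rpsf < 1 or self.n_complex < 1:
            raise ValueError("n_rpsf and n_complex must be >= 1")
        if self.pool is not None and self.pool < 0:
            raise ValueError("glutamate pool must be >= 0")
        if self.horizon < 0:
            raise ValueError("horizon must be >= 0")


@dataclass(frozen=True)
class PopulationResult:
    lengths: tuple[int, ...]
    pool_remaining: Optional[int]
    fraction_unmodified: float
    fraction_modified: float
    mean_length: float


def simulate_population(
    chain_cfg: ChainConfig, pop_cfg: PopulationConfig
) -> PopulationResult:
    """Distribute a shared glutamate pool over many RpsF chains.

    The single complex works processively: each event applies add/cut/
    release/idle to the currently bound chain; release rebinds a uniformly
    random chain.  Additions draw one monomer from the pool and cleavage
    returns one, so ``sum(lengths) + pool`` is exactly conserved at every
    event.
    """
    rng = np.random.default_rng(pop_cfg.seed)
    lengths = np.zeros(pop_cfg.n_rpsf, dtype=np.int64)
    pool = math.inf if pop_cfg.pool is None else int(pop_cfg.pool)
    n_events = pop_cfg.horizon * pop_cfg.n_complex
    t_cut = chain_cfg.p_add + chain_cfg.p_cut
    t_rel = t_cut + chain_cfg.release_prob

    us = rng.random(n_events)
    hops = rng.integers(0, pop_cfg.n_rpsf, size=n_events + 1)
    hop_i = 0
    current = int(hops[hop_i])
    for u in us:
        if u < chain_cfg.p_add:
            if pool > 0 and lengths[current] < chain_cfg.max_length:
                lengths[current] += 1
                pool -= 1
        elif u < t_cut:
            if lengths[current] > chain_cfg.min_cut_length:
                lengths[current] -= 1
                pool += 1
        elif u < t_rel:
            hop_i += 1
            current = int(hops[hop_i])

    modified = lengths > 0
    return PopulationResult(
        lengths=tuple(int(x) for x in lengths),
        pool_remaining=None if pop_cfg.pool is None else int(pool),
        fraction_unmodified=float(np.mean(~modified)),
        fraction_modified=float(np.mean(modified)),
        mean_length=float(lengths.mean()),
    )
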