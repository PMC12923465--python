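"""Exact mathematics of the Ising network model on binary (0/1) nodes.

The model is parameterized in the convention common in network
psychometrics: each node ``i`` carries a threshold ``m_i`` (its intrinsic
tendency towards activation), each unordered pair ``(i, j)`` an edge
weight ``w_ij`` (the conditional association between the two nodes), and
a global inverse temperature ``beta`` controls how deterministic the
system is.  Node states are coded 0/1 (absent/present), not the physics
convention of -1/+1.

The energy of a full activation pattern ``a`` (a *microstate*) is the
Hamiltonian

    H(a) = - sum_{i<j} w_ij a_i a_j - sum_i m_i a_i

and microstate probabilities follow the Boltzmann distribution
``P(a) ∝ exp(-beta * H(a))``.  Everything in this module is exact: the
full distribution is obtained by enumerating all ``2**N`` microstates
(with a guard against infeasible sizes), using log-sum-exp throughout so
that large energies cannot overflow.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.special import expit, logsumexp

#: Largest node count for which exact enumeration over 2**N microstates
#: is attempted.  Empirical symptom networks are far below this.
ENUMERATION_GUARD = 25

#: Weight matrices asymmetric beyond this tolerance are rejected;
#: within it they are symmetrized by averaging (with a warning).
SYMMETRY_TOL = 1e-8

__all__ = [
    "ENUMERATION_GUARD",
    "EnumerationInfeasibleError",
    "IsingNetwork",
    "MicrostateDistribution",
    "as_microstate",
    "conditional_activation_probability",
    "count_microstates",
    "enumerate_microstates",
    "hamiltonian",
    "microstate_distribution",
    "scale_parameters",
]


class EnumerationInfeasibleError(ValueError):
    """Exact enumeration over 2**N microstates was refused (N too large).

    Use the ``simulate`` module (Glauber dynamics) for networks above
    the enumeration guard.
    """


@dataclass(frozen=True)
class IsingNetwork:
    """A fully specified Ising network.

    Parameters
    ----------
    labels
        Node names, one per node; must be unique.
    thresholds
        Vector ``m`` of per-node thresholds (length N).
    weights
        Symmetric ``N x N`` edge-weight matrix ``W`` with zero diagonal.
        Matrices asymmetric within :data:`SYMMETRY_TOL` are symmetrized
        by averaging with a warning; beyond it they are rejected.
        Nonzero diagonals (self-loops) are rejected.
    beta
        Inverse temperature (> 0); defaults to 1, the value under which
        logistic-regression estimates of ``m`` and ``W`` are identified.
    """

    labels: tuple[str, ...]
    thresholds: np.ndarray
    weights: np.ndarray
    beta: float = 1.0

    def __post_init__(self) -> None:
        labels = tuple(str(x) for x in self.labels)
        if len(labels) == 0:
            raise ValueError("network must have at least one node")
        if len(set(labels)) != len(labels):
            raise ValueError("node labels must be unique")
        m = np.array(self.thresholds, dtype=float).reshape(-1)
        w = np.array(self.weights, dtype=float)
        n = len(labels)
        if m.shape != (n,):
            raise ValueError(
                f"thresholds have length {m.size}, expected {n} (one per node)"
            )
        if w.shape != (n, n):
            raise ValueError(f"weights have shape {w.shape}, expected ({n}, {n})")
        if not np.all(np.isfinite(m)):
            raise ValueError("thresholds must be finite")
        if not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite")
        asym = np.max(np.abs(w - w.T)) if n > 1 else 0.0
        if asym > SYMMETRY_TOL:
            raise ValueError(
                f"weight matrix asymmetric (max |w_ij - w_ji| = {asym:.3g} "
                f"> {SYMMETRY_TOL:g})"
            )
        if asym > 0:
            warnings.warn(
                f"weight matrix asymmetric within tolerance "
                f"(max |w_ij - w_ji| = {asym:.3g}); symmetrized by averaging",
                UserWarning,
                stacklevel=3,
            )
            w = (w + w.T) / 2.0
        if np.any(np.diag(w) != 0.0):
            raise ValueError("weight matrix must have zero diagonal (no self-loops)")
        beta = float(self.beta)
        if not math.isfinite(beta) or beta <= 0:
            raise ValueError(f"beta must be a positive finite number, got {beta!r}")
        m.setflags(write=False)
        w.setflags(write=False)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "thresholds", m)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "beta", beta)

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def fingerprint(self) -> str:
        """Short stable checksum of the full parameter set."""
        h = hashlib.sha256()
        h.update("\x1f".join(self.labels).encode())
        h.update(self.thresholds.tobytes())
        h.update(self.weights.tobytes())
        h.update(np.float64(self.beta).tobytes())
        return h.hexdigest()[:16]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IsingNetwork):
            return NotImplemented
        return (
            self.labels == other.labels
            and self.beta == other.beta
            and np.array_equal(self.thresholds, other.thresholds)
            and np.array_equal(self.weights, other.weights)
        )

    def __hash__(self) -> int:
        return hash((self.labels, self.beta, self.thresholds.tobytes(),
                     self.weights.tobytes()))


@dataclass(frozen=True)
class MicrostateDistribution:
    """Exact Boltzmann distribution over all ``2**N`` microstates.

    Microstates are indexed canonically: a state ``a`` maps to the
    integer ``sum_i a_i * 2**i``, i.e. node 0 is the least-significant
    bit.
    """

    probabilities: np.ndarray
    energies: np.ndarray
    beta: float

    @property
    def n_nodes(self) -> int:
        return int(round(math.log2(self.probabilities.size)))


def as_microstate(state: Sequence[float] | np.ndarray, n_nodes: int) -> np.ndarray:
    """Validate a microstate vector: length ``n_nodes``, entries in {0, 1}."""
    a = np.asarray(state, dtype=float).reshape(-1)
    if a.shape != (n_nodes,):
        raise ValueError(
            f"microstate has length {a.size}, expected {n_nodes} (one entry per node)"
        )
    if not np.all((a == 0.0) | (a == 1.0)):
        raise ValueError("microstate entries must be exactly 0 or 1")
    return a


def hamiltonian(network: IsingNetwork, state: Sequence[float] | np.ndarray) -> float:
    """Energy ``H(a) = -1/2 a^T W a - a^T m`` of a microstate.

    For symmetric zero-diagonal ``W`` the quadratic form equals the
    pairwise sum over unordered node pairs.  The empty state has zero
    energy by construction.
    """
    a = as_microstate(state, network.n_nodes)
    return float(-0.5 * a @ network.weights @ a - a @ network.thresholds)


def conditional_activation_probability(
    network: IsingNetwork,
    state: Sequence[float] | np.ndarray,
    node_index: int,
) -> float:
    """Probability that one node is active given the state of the rest.

    Returns ``logistic(beta * (m_i + sum_{j != i} w_ij a_j))``.  The
    current value of ``a_i`` itself does not enter (``w_ii = 0``).
    """
    a = as_microstate(state, network.n_nodes)
    i = int(node_index)
    if not 0 <= i < network.n_nodes:
        raise IndexError(
            f"node_index {i} out of range for a {network.n_nodes}-node network"
        )
    field = network.thresholds[i] + network.weights[i] @ a
    return float(expit(network.beta * field))


def _check_enumeration_guard(n_nodes: int) -> None:
    if n_nodes > ENUMERATION_GUARD:
        raise EnumerationInfeasibleError(
            f"exact enumeration of 2**{n_nodes} microstates is infeasible "
            f"(guard at N = {ENUMERATION_GUARD}); use the simulate module "
            f"(Glauber dynamics) instead"
        )


@lru_cache(maxsize=16)
def _cached_states(n_nodes: int) -> np.ndarray:
    """All 2**N microstates as a (2**N, N) float array, node 0 = LSB.

    Cached for small N only; larger enumerations stream in chunks.
    """
    idx = np.arange(1 << n_nodes, dtype=np.int64)
    states = ((idx[:, None] >> np.arange(n_nodes)) & 1).astype(np.float64)
    states.setflags(write=False)
    return states


def enumerate_microstates(n_nodes: int) -> np.ndarray:
    """All microstates of an N-node network in canonical index order."""
    _check_enumeration_guard(n_nodes)
    if n_nodes <= 16:
        return _cached_states(n_nodes)
    idx = np.arange(1 << n_nodes, dtype=np.int64)
    return ((idx[:, None] >> np.arange(n_nodes)) & 1).astype(np.float64)


def _chunk_energies(network: IsingNetwork, states: np.ndarray) -> np.ndarray:
    half_w = 0.5 * network.weights
    return -(states @ half_w * states).sum(axis=1) - states @ network.thresholds


def all_energies(network: IsingNetwork) -> np.ndarray:
    """Hamiltonian of every microstate, in canonical index order."""
    n = network.n_nodes
    _check_enumeration_guard(n)
    if n <= 16:
        return _chunk_energies(network, _cached_states(n))
    total = 1 << n
    out = np.empty(total)
    chunk = 1 << 18
    cols = np.arange(n)
    for start in range(0, total, chunk):
        idx = np.arange(start, min(start + chunk, total), dtype=np.int64)
        states = ((idx[:, None] >> cols) & 1).astype(np.float64)
        out[start : start + idx.size] = _chunk_energies(network, states)
    return out


def microstate_distribution(network: IsingNetwork) -> MicrostateDistribution:
    """Exact Boltzmann distribution ``P(a) ∝ exp(-beta H(a))``.

    Normalization is done with log-sum-exp, so arbitrarily large
    energies cannot overflow; probabilities sum to one to within
    floating-point rounding.
    """
    energies = all_energies(network)
    log_w = -network.beta * energies
    probs = np.exp(log_w - logsumexp(log_w))
    return MicrostateDistribution(
        probabilities=probs, energies=energies, beta=network.beta
    )


def scale_parameters(
    network: IsingNetwork,
    threshold_multiplier: float,
    connectivity_multiplier: float,
) -> IsingNetwork:
    """New network with ``m' = t_mult * m`` and ``W' = c_mult * W``.

    Used to generate systematic variations of a baseline network
    (e.g. the 0.8 / 1 / 1.2 grids of weakened and strengthened
    thresholds and connectivity).  ``beta`` is unchanged and the input
    network is not modified.
    """
    t = float(threshold_multiplier)
    c = float(connectivity_multiplier)
    if not (math.isfinite(t) and math.isfinite(c)):
        raise ValueError("multipliers must be finite")
    return IsingNetwork(
        labels=network.labels,
        thresholds=t * network.thresholds,
        weights=c * network.weights,
        beta=network.beta,
    )


def count_microstates(n_nodes: int, n_active: int) -> int:
    """Number of microstates with exactly ``n_active`` active nodes: C(N, n)."""
    n_nodes = int(n_nodes)
    n_active = int(n_active)
    if n_nodes < 0:
        raise ValueError("n_nodes must be nonnegative")
    if not 0 <= n_active <= n_nodes:
        raise ValueError(
            f"n_active must be between 0 and {n_nodes}, got {n_active}"
        )
    return math.comb(n_nodes, n_active)
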