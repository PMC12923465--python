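"""Monte-Carlo machinery: Glauber dynamics, exact sampling, fixtures.

Glauber dynamics resamples one node at a time from its full
conditional (the logistic activation probability), which leaves the
Boltzmann distribution invariant; long chains therefore provide an
independent stochastic check of the analytically computed landscape.
Exact i.i.d. sampling draws microstates directly from the enumerated
distribution and is the workhorse for parameter-recovery and
group-comparison fixtures.

All routines are deterministic given their seed; one seed is split
into independent streams with ``numpy``'s ``SeedSequence``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import IsingNetwork, microstate_distribution
from .estimation import BinaryDataset

__all__ = [
    "ChainTrajectory",
    "glauber_chain",
    "random_network",
    "sample_exact",
    "synthetic_group_data",
]


@dataclass(frozen=True)
class ChainTrajectory:
    """Recorded Glauber trajectory (post burn-in).

    ``active_counts`` holds the macrostate ``n`` after each recorded
    sweep; ``states`` optionally holds the full microstates (only kept
    when requested, for small runs).
    """

    active_counts: np.ndarray
    sweeps: int
    burn_in: int
    seed: int
    final_state: np.ndarray
    states: np.ndarray | None = None

    def occupancy(self, n_nodes: int) -> np.ndarray:
        """Empirical distribution of the active count over 0..N."""
        return np.bincount(self.active_counts, minlength=n_nodes + 1) / max(
            self.active_counts.size, 1
        )


def glauber_chain(
    network: IsingNetwork,
    sweeps: int,
    seed: int,
    burn_in: int | None = None,
    record_states: bool = False,
) -> ChainTrajectory:
    """Run single-site Glauber dynamics and record the active count.

    Per sweep the nodes are visited in a fresh random order and each is
    resampled from its conditional activation probability given the
    current state of the rest.  Detailed balance makes the Boltzmann
    distribution stationary, so the recorded ``n`` values converge to
    ``P_SS(n)``.  Burn-in defaults to 10% of the requested sweeps; the
    initial state is drawn uniformly at random from the same stream.
    """
    sweeps = int(sweeps)
    if sweeps < 1:
        raise ValueError("sweeps must be >= 1")
    if burn_in is None:
        burn_in = sweeps // 10
    burn_in = int(burn_in)
    if not 0 <= burn_in < sweeps:
        raise ValueError("burn_in must satisfy 0 <= burn_in < sweeps")
    n = network.n_nodes
    beta = network.beta
    m = network.thresholds
    w = network.weights
    rng = np.random.default_rng(seed)
    a = rng.integers(0, 2, size=n).astype(np.float64)
    recorded = np.empty(sweeps - burn_in, dtype=np.int64)
    kept_states = (
        np.empty((sweeps - burn_in, n), dtype=np.int8) if record_states else None
    )
    exp = math.exp
    for sweep in range(sweeps):
        order = rng.permutation(n)
        u = rng.random(n)
        for k in range(n):
            i = order[k]
            field = beta * (m[i] + w[i] @ a)
            # logistic(field) without overflow for very negative fields
            if field >= 0:
                p = 1.0 / (1.0 + exp(-field))
            else:
                e = exp(field)
                p = e / (1.0 + e)
            a[i] = 1.0 if u[k] < p else 0.0
        if sweep >= burn_in:
            recorded[sweep - burn_in] = int(a.sum())
            if kept_states is not None:
                kept_states[sweep - burn_in] = a.astype(np.int8)
    return ChainTrajectory(
        active_counts=recorded,
        sweeps=sweeps,
        burn_in=burn_in,
        seed=int(seed),
        final_state=a.astype(np.int8),
        states=kept_states,
    )


def sample_exact(
    network: IsingNetwork, n_samples: int, seed: int
) -> BinaryDataset:
    """Draw i.i.d. microstates from the exact Boltzmann distribution.

    Enumerates the full distribution (subject to the enumeration
    guard) and samples canonical microstate indices categorically.
    ``n_samples = 0`` returns an empty dataset with a valid header.
    """
    n_samples = int(n_samples)
    if n_samples < 0:
        raise ValueError("n_samples must be >= 0")
    n = network.n_nodes
    if n_samples == 0:
        return BinaryDataset(
            values=np.empty((0, n), dtype=np.int8), labels=network.labels
        )
    dist = microstate_distribution(network)
    rng = np.random.default_rng(seed)
    idx = rng.choice(dist.probabilities.size, size=n_samples, p=dist.probabilities)
    values = ((idx[:, None] >> np.arange(n)) & 1).astype(np.int8)
    return BinaryDataset(values=values, labels=network.labels)


def random_network(
    n_nodes: int,
    seed: int,
    *,
    weight_scale: float = 0.3,
    threshold_scale: float = 0.5,
    threshold_shift: float = 0.0,
    beta: float = 1.0,
) -> IsingNetwork:
    """Random test network with Gaussian thresholds and weights.

    Weights ``w_ij ~ N(0, weight_scale^2)`` (symmetric, zero diagonal)
    and thresholds ``m_i ~ N(threshold_shift, threshold_scale^2)``
    emulate the magnitudes typical of estimated symptom networks.
    """
    rng = np.random.default_rng(seed)
    tri = rng.normal(0.0, weight_scale, size=(n_nodes, n_nodes))
    w = np.triu(tri, k=1)
    w = w + w.T
    m = rng.normal(threshold_shift, threshold_scale, size=n_nodes)
    return IsingNetwork(
        labels=tuple(f"s{i + 1}" for i in range(n_nodes)),
        thresholds=m,
        weights=w,
        beta=beta,
    )


def synthetic_group_data(
    base_network: IsingNetwork,
    threshold_shift,
    weight_multiplier: float,
    n_per_group: int,
    seed: int,
):
    """Two synthetic groups with a known parameter difference.

    Group A is sampled from ``base_network``; group B from the network
    with thresholds ``m + shift`` and weights ``W * multiplier``.
    Returns ``(data_a, data_b, truth)`` where ``truth`` records the
    generating networks and seeds — the ground truth for recovery and
    calibration tests.
    """
    shift = np.broadcast_to(
        np.asarray(threshold_shift, dtype=float), (base_network.n_nodes,)
    )
    shifted = IsingNetwork(
        labels=base_network.labels,
        thresholds=base_network.thresholds + shift,
        weights=base_network.weights * float(weight_multiplier),
        beta=base_network.beta,
    )
    seed_a, seed_b = np.random.SeedSequence(seed).spawn(2)
    data_a = sample_exact(base_network, n_per_group, seed_a)
    data_b = sample_exact(shifted, n_per_group, seed_b)
    truth = {
        "network_a": base_network,
        "network_b": shifted,
        "threshold_shift": np.array(shift),
        "weight_multiplier": float(weight_multiplier),
        "n_per_group": int(n_per_group),
        "seed": int(seed),
    }
    return data_a, data_b, truth
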