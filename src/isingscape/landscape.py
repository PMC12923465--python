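"""Macrostate distribution and the generalized potential landscape.

The macrostate of an Ising network is the number of active nodes,
``n = sum_i a_i`` — in symptom networks, the symptom count that clinical
practice already uses as a severity index.  Grouping the exact
Boltzmann distribution by ``n`` gives the steady-state distribution
``P_SS(n)``; the generalized potential (stability landscape) is

    U(n) = -ln P_SS(n).

Low potential marks stable states; local minima of ``U`` are the
system's phases, and the shape of ``U`` between minima quantifies how
hard it is to leave a phase.  ``U`` is defined only up to an additive
constant (the normalization of ``P_SS`` cancels in every metric built
from differences of ``U``); here it is reported for ``P_SS`` normalized
to sum one.

All quantities are computed analytically from the enumerated
distribution — no simulation is involved.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np

from .core import IsingNetwork, all_energies, count_microstates

__all__ = [
    "Landscape",
    "barrier_height",
    "locate_local_minima",
    "macrostate_distribution",
    "potential_landscape",
]


@dataclass(frozen=True)
class Landscape:
    """The stability landscape of one Ising network.

    Per macrostate ``n`` in ``0..N``: the number of contributing
    microstates ``C(N, n)``, the steady-state probability ``P_SS(n)``,
    and the potential ``U(n) = -ln P_SS(n)``.  A zero-probability
    macrostate (impossible with finite parameters) would carry the
    sentinel ``U = +inf`` and is excluded from minima scans.
    """

    n_values: np.ndarray
    microstate_counts: np.ndarray
    probabilities: np.ndarray
    potential: np.ndarray
    beta: float
    network_fingerprint: str

    @property
    def n_nodes(self) -> int:
        return int(self.n_values[-1])

    def expected_active_count(self) -> float:
        """Mean number of active nodes, ``sum_n n * P_SS(n)``."""
        return float(self.n_values @ self.probabilities)

    def to_frame(self):
        """Landscape as a pandas DataFrame (n, count, probability, potential)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "n": self.n_values,
                "count": self.microstate_counts,
                "probability": self.probabilities,
                "potential": self.potential,
            }
        )

    def to_tsv(self, path) -> None:
        """Write the landscape as TSV with 12-significant-digit decimals."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("n\tcount\tprobability\tpotential\n")
            for n, c, p, u in zip(
                self.n_values, self.microstate_counts,
                self.probabilities, self.potential,
            ):
                fh.write(f"{int(n)}\t{int(c)}\t{p:.12g}\t{u:.12g}\n")


@lru_cache(maxsize=16)
def _popcount_grouping(n_nodes: int):
    """Sort order and group boundaries of microstate indices by popcount."""
    idx = np.arange(1 << n_nodes, dtype=np.uint64)
    pc = np.bitwise_count(idx).astype(np.intp)
    order = np.argsort(pc, kind="stable")
    bounds = np.searchsorted(pc[order], np.arange(n_nodes + 2))
    order.setflags(write=False)
    bounds.setflags(write=False)
    return order, bounds


def _macrostate_log_probabilities(network: IsingNetwork) -> np.ndarray:
    n = network.n_nodes
    log_w = -network.beta * all_energies(network)
    order, bounds = _popcount_grouping(n)
    lw = log_w[order]
    counts = np.diff(bounds)
    # groupwise log-sum-exp via reduceat (every group is nonempty)
    gmax = np.maximum.reduceat(lw, bounds[:-1])
    sums = np.add.reduceat(np.exp(lw - np.repeat(gmax, counts)), bounds[:-1])
    log_q = gmax + np.log(sums)
    top = log_q.max()
    return log_q - (top + np.log(np.exp(log_q - top).sum()))


def macrostate_distribution(network: IsingNetwork) -> np.ndarray:
    """Steady-state distribution ``P_SS(n)`` over ``n = 0..N``.

    Computed by grouping the exact microstate distribution by the
    number of active nodes, entirely in log space.
    """
    return np.exp(_macrostate_log_probabilities(network))


def potential_landscape(network: IsingNetwork) -> Landscape:
    """Full stability landscape ``U(n) = -ln P_SS(n)`` of a network."""
    n = network.n_nodes
    log_p = _macrostate_log_probabilities(network)
    return Landscape(
        n_values=np.arange(n + 1),
        microstate_counts=np.array([count_microstates(n, k) for k in range(n + 1)]),
        probabilities=np.exp(log_p),
        potential=-log_p,
        beta=network.beta,
        network_fingerprint=network.fingerprint(),
    )


def _as_potential(landscape_or_potential) -> np.ndarray:
    if isinstance(landscape_or_potential, Landscape):
        return np.asarray(landscape_or_potential.potential, dtype=float)
    return np.asarray(landscape_or_potential, dtype=float).reshape(-1)


def locate_local_minima(
    potential: Landscape | Sequence[float] | np.ndarray,
    window: tuple[int, int] | None = None,
) -> list[int]:
    """Indices of local minima of ``U`` within an inclusive index window.

    A run of equal values is a minimum when the values flanking it
    (inside the window) are strictly larger, with one-sided comparison
    at the window edges; both ends of such a plateau are reported as
    candidates.  Infinite-potential entries (zero-probability states)
    are never minima.  The scan is deterministic and returns sorted
    indices.
    """
    u = _as_potential(potential)
    if window is None:
        window = (0, u.size - 1)
    lo, hi = int(window[0]), int(window[1])
    if lo > hi or lo < 0 or hi >= u.size:
        raise ValueError(f"window {window} is empty or out of range for size {u.size}")
    vals = u[lo : hi + 1]
    minima: list[int] = []
    i = 0
    size = vals.size
    while i < size:
        j = i
        while j + 1 < size and vals[j + 1] == vals[i]:
            j += 1
        if not math.isinf(vals[i]):
            left_ok = i == 0 or vals[i - 1] > vals[i]
            right_ok = j == size - 1 or vals[j + 1] > vals[j]
            if left_ok and right_ok:
                minima.append(lo + i)
                if j != i:
                    minima.append(lo + j)
        i = j + 1
    return minima


def barrier_height(
    landscape: Landscape | Sequence[float] | np.ndarray,
    from_minimum: int,
    to_minimum: int,
) -> float:
    """Height of the potential barrier separating two local minima.

    Returns ``max(U over the interior between the minima) - U[from]``;
    nonnegative by construction.  Both indices must be local minima of
    the full potential.  The metric is undefined on a single-well
    landscape (there is no second minimum to pass a barrier towards);
    passing indices that are not minima raises ``ValueError``.
    Adjacent minima have no interior and return 0 with a warning.
    """
    u = _as_potential(landscape)
    minima = set(locate_local_minima(u))
    i, j = int(from_minimum), int(to_minimum)
    for k in (i, j):
        if k not in minima:
            raise ValueError(
                f"index {k} is not a local minimum of the potential "
                f"(minima: {sorted(minima)})"
            )
    lo, hi = min(i, j), max(i, j)
    interior = u[lo + 1 : hi]
    if interior.size == 0:
        warnings.warn(
            "adjacent minima have no interior; barrier height is 0",
            UserWarning,
            stacklevel=2,
        )
        return 0.0
    return float(np.max(interior) - u[i])
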