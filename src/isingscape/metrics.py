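"""Cutoff-anchored phase-stability metrics.

A clinical symptom-count cutoff ``c`` splits the landscape into a
healthy portion (``n < c``) and a disorder portion (``n >= c``).  The
stability of the healthy phase is the depth of its leftmost local
minimum relative to the highest point to the right of that minimum
*within the healthy portion*; the disorder phase is scored
mirror-symmetrically from its rightmost local minimum.  The stability
difference (healthy minus disorder) is positive when the healthy phase
is the more stable of the two.

Unlike barrier height, these metrics remain defined when the landscape
has a single well, and they respect the clinical meaning of the cutoff.
Both metrics are differences of ``U`` values inside one portion, so
they are invariant to the additive constant in ``U``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import IsingNetwork, scale_parameters
from .landscape import Landscape, locate_local_minima, potential_landscape

__all__ = ["StabilityMetrics", "phase_stability", "stability_difference_of"]


@dataclass(frozen=True)
class StabilityMetrics:
    """Phase-stability summary of one landscape at one cutoff.

    ``reference_maximum_indices`` records where each portion's
    reference maximum was taken (``None`` for a phase whose stability
    is structurally zero).
    """

    cutoff: int
    healthy_stability: float
    disorder_stability: float
    stability_difference: float
    healthy_minimum_index: int
    disorder_minimum_index: int
    reference_maximum_indices: tuple[int | None, int | None] = (None, None)

    def to_dict(self) -> dict:
        return {
            "cutoff": self.cutoff,
            "healthy_stability": self.healthy_stability,
            "disorder_stability": self.disorder_stability,
            "stability_difference": self.stability_difference,
            "indices": {
                "healthy_minimum": self.healthy_minimum_index,
                "disorder_minimum": self.disorder_minimum_index,
                "healthy_reference_maximum": self.reference_maximum_indices[0],
                "disorder_reference_maximum": self.reference_maximum_indices[1],
            },
        }


def _potential_of(landscape) -> np.ndarray:
    if isinstance(landscape, Landscape):
        return np.asarray(landscape.potential, dtype=float)
    return np.asarray(landscape, dtype=float).reshape(-1)


def phase_stability(
    landscape: Landscape | Sequence[float] | np.ndarray,
    cutoff: int,
) -> StabilityMetrics:
    """Healthy- and disorder-phase stability of a landscape at a cutoff.

    The cutoff ``c`` is the smallest symptom count belonging to the
    disorder phase, so the healthy portion covers indices ``0..c-1``
    and the disorder portion ``c..N``.  Within the healthy portion the
    leftmost local minimum ``i*`` anchors the healthy phase; its
    stability is ``max(U[i*+1 .. c-1]) - U[i*]`` (0 when ``i*`` sits at
    the portion's right edge or the portion is flat to its right).
    The disorder phase mirrors this from the rightmost local minimum.
    Reference maxima never cross the cutoff; plateau minima resolve to
    the leftmost (healthy) / rightmost (disorder) plateau index.
    """
    u = _potential_of(landscape)
    n_max = u.size - 1  # number of nodes N
    c = int(cutoff)
    if not 1 <= c <= n_max:
        raise ValueError(f"cutoff must be in 1..{n_max}, got {c}")

    left_minima = locate_local_minima(u, (0, c - 1))
    i_star = min(left_minima)
    if i_star == c - 1:
        healthy = 0.0
        healthy_ref: int | None = None
    else:
        seg = u[i_star + 1 : c]
        healthy_ref = i_star + 1 + int(np.argmax(seg))
        healthy = float(u[healthy_ref] - u[i_star])

    right_minima = locate_local_minima(u, (c, n_max))
    j_star = max(right_minima)
    if j_star == c:
        disorder = 0.0
        disorder_ref: int | None = None
    else:
        seg = u[c:j_star]
        disorder_ref = c + int(np.argmax(seg))
        disorder = float(u[disorder_ref] - u[j_star])

    return StabilityMetrics(
        cutoff=c,
        healthy_stability=healthy,
        disorder_stability=disorder,
        stability_difference=healthy - disorder,
        healthy_minimum_index=i_star,
        disorder_minimum_index=j_star,
        reference_maximum_indices=(healthy_ref, disorder_ref),
    )


def stability_difference_of(
    model_or_data,
    cutoff: int,
    *,
    threshold_multiplier: float = 1.0,
    connectivity_multiplier: float = 1.0,
    ridge: float = 0.0,
) -> float:
    """Stability difference of a network, or of a dataset via estimation.

    Convenience composition: an :class:`~isingscape.core.IsingNetwork`
    (optionally rescaled by the two multipliers) — or a binary dataset,
    which is first turned into a network by nodewise logistic
    regression — is mapped to its landscape and scored at ``cutoff``.
    This is the canonical statistic that the inference module
    bootstraps.
    """
    if isinstance(model_or_data, IsingNetwork):
        network = model_or_data
    else:
        from .estimation import BinaryDataset, estimate_ising

        if not isinstance(model_or_data, BinaryDataset):
            raise TypeError(
                "expected an IsingNetwork or BinaryDataset, "
                f"got {type(model_or_data).__name__}"
            )
        network = estimate_ising(model_or_data, ridge=ridge)
    if threshold_multiplier != 1.0 or connectivity_multiplier != 1.0:
        network = scale_parameters(
            network, threshold_multiplier, connectivity_multiplier
        )
    return phase_stability(potential_landscape(network), cutoff).stability_difference
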