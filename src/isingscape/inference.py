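"""Uncertainty and group comparison for stability metrics.

The sampling distribution of the stability difference is typically
skewed, so interval estimation uses the bias-corrected and accelerated
(BCa) nonparametric bootstrap: persons are resampled with replacement,
the network is re-estimated and re-scored on each replicate, the bias
correction comes from the fraction of replicates below the point
estimate, and the acceleration from a jackknife over persons.  A
p-value is obtained by interval inversion: the smallest alpha at which
the (1 - alpha) BCa interval excludes the null value, searched on an
alpha grid of step 0.001.

Group contrasts difference the two groups' stability differences and
bootstrap them with stratified (within-group) resampling; a 2x2 grid
of parameter-swap landscapes (thresholds from one group crossed with
weights from the other) attributes an observed contrast to thresholds
versus connectivity.  A permutation test on raw symptom counts is
provided as a post hoc check of mean severity differences.

All randomness flows from a single seed through ``SeedSequence``
spawning: subsample seed, per-group bootstrap seeds, between-group
seed, and permutation seed are derived deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, NamedTuple

import numpy as np
from scipy.stats import norm

from .core import IsingNetwork
from .estimation import BinaryDataset, EstimationError, estimate_ising
from .landscape import Landscape, potential_landscape
from .metrics import StabilityMetrics, phase_stability

__all__ = [
    "BootstrapResult",
    "GroupComparison",
    "PermutationTestResult",
    "bootstrap_stability",
    "bootstrap_statistic",
    "compare_groups",
    "permutation_mean_difference",
]

#: Resolution of the alpha grid used for p-value-by-CI-inversion.
P_VALUE_GRID_STEP = 0.001

#: A bootstrap run with more than this fraction of failed replicates
#: is flagged invalid.
MAX_FAILED_FRACTION = 0.05


@dataclass(eq=False)
class BootstrapResult:
    """Point estimate with BCa bootstrap uncertainty.

    ``valid`` is False when more than 5% of replicates failed;
    ``degenerate`` marks a collapsed bootstrap distribution (zero
    standard error), for which the p-value is undefined (NaN).
    """

    statistic: str
    estimate: float
    b_resamples: int
    standard_error: float
    ci_low: float
    ci_high: float
    confidence_level: float
    p_value: float
    null_value: float
    n_failed_replicates: int
    seed: int
    valid: bool = True
    degenerate: bool = False
    replicates: np.ndarray = field(default=None, repr=False)

    def to_dict(self, include_replicates: bool = False) -> dict:
        out = {
            "statistic": self.statistic,
            "estimate": self.estimate,
            "B": self.b_resamples,
            "standard_error": self.standard_error,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "confidence_level": self.confidence_level,
            "p_value": self.p_value,
            "null_value": self.null_value,
            "n_failed_replicates": self.n_failed_replicates,
            "seed": self.seed,
            "valid": self.valid,
            "degenerate": self.degenerate,
        }
        if include_replicates and self.replicates is not None:
            out["replicates"] = [float(x) for x in self.replicates]
        return out


class PermutationTestResult(NamedTuple):
    """Observed mean difference and two-sided permutation p-value."""

    mean_difference: float
    p_value: float


def _bca_interval(
    replicates: np.ndarray,
    estimate: float,
    z0: float,
    accel: float,
    alpha: np.ndarray,
):
    """BCa interval endpoints for an array of alpha levels (vectorized)."""
    z_lo = norm.ppf(alpha / 2.0)
    z_hi = norm.ppf(1.0 - alpha / 2.0)
    p_lo = norm.cdf(z0 + (z0 + z_lo) / (1.0 - accel * (z0 + z_lo)))
    p_hi = norm.cdf(z0 + (z0 + z_hi) / (1.0 - accel * (z0 + z_hi)))
    lo = np.quantile(replicates, np.clip(p_lo, 0.0, 1.0))
    hi = np.quantile(replicates, np.clip(p_hi, 0.0, 1.0))
    return lo, hi


def bootstrap_statistic(
    strata_sizes: tuple[int, ...],
    statistic: Callable[[tuple[np.ndarray, ...]], float],
    b_resamples: int,
    seed: int,
    *,
    null_value: float = 0.0,
    confidence_level: float = 0.95,
    name: str = "statistic",
    acceleration: bool = True,
) -> BootstrapResult:
    """Generic stratified BCa bootstrap engine.

    ``statistic`` maps a tuple of per-stratum row-index arrays to a
    scalar; it is called on the full data for the point estimate, on
    ``b_resamples`` within-stratum resamples with replacement for the
    bootstrap distribution, and on delete-one-person jackknife index
    sets for the acceleration constant.  Replicates raising
    :class:`~isingscape.estimation.EstimationError` are dropped and
    counted; runs with more than 5% failures are flagged invalid.
    """
    if b_resamples < 100:
        raise ValueError("b_resamples must be >= 100")
    sizes = tuple(int(s) for s in strata_sizes)
    if any(s < 1 for s in sizes):
        raise ValueError("every stratum must contain at least one row")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    full = tuple(np.arange(s) for s in sizes)
    estimate = float(statistic(full))

    replicates = []
    n_failed = 0
    for _ in range(b_resamples):
        idx = tuple(rng.integers(0, s, size=s) for s in sizes)
        try:
            replicates.append(float(statistic(idx)))
        except EstimationError:
            n_failed += 1
    reps = np.array(replicates)
    valid = n_failed <= MAX_FAILED_FRACTION * b_resamples
    if reps.size < 2:
        raise EstimationError(
            f"bootstrap failed: only {reps.size} of {b_resamples} replicates "
            "succeeded"
        )
    se = float(np.std(reps, ddof=1))

    if se == 0.0:
        return BootstrapResult(
            statistic=name,
            estimate=estimate,
            b_resamples=b_resamples,
            standard_error=0.0,
            ci_low=estimate,
            ci_high=estimate,
            confidence_level=confidence_level,
            p_value=float("nan"),
            null_value=null_value,
            n_failed_replicates=n_failed,
            seed=int(seed),
            valid=valid,
            degenerate=True,
            replicates=reps,
        )

    # bias correction: fraction of replicates below the point estimate
    frac = (np.sum(reps < estimate) + 0.5 * np.sum(reps == estimate)) / reps.size
    frac = min(max(frac, 1.0 / (reps.size + 1)), reps.size / (reps.size + 1.0))
    z0 = float(norm.ppf(frac))

    accel = 0.0
    if acceleration:
        jack = []
        for stratum, size in enumerate(sizes):
            for leave in range(size):
                idx = tuple(
                    np.delete(full[s], leave) if s == stratum else full[s]
                    for s in range(len(sizes))
                )
                try:
                    jack.append(float(statistic(idx)))
                except EstimationError:
                    continue
        jack = np.array(jack)
        if jack.size >= 2:
            dev = jack.mean() - jack
            denom = np.sum(dev**2) ** 1.5
            if denom > 0:
                accel = float(np.sum(dev**3) / (6.0 * denom))

    alpha = 1.0 - confidence_level
    ci_low, ci_high = _bca_interval(reps, estimate, z0, accel, np.array([alpha]))
    ci_low, ci_high = float(ci_low[0]), float(ci_high[0])

    # p-value by interval inversion on the alpha grid
    grid = np.arange(P_VALUE_GRID_STEP, 1.0, P_VALUE_GRID_STEP)
    los, his = _bca_interval(reps, estimate, z0, accel, grid)
    excluded = (null_value < los) | (null_value > his)
    p_value = float(grid[np.argmax(excluded)]) if excluded.any() else 1.0

    return BootstrapResult(
        statistic=name,
        estimate=estimate,
        b_resamples=b_resamples,
        standard_error=se,
        ci_low=ci_low,
        ci_high=ci_high,
        confidence_level=confidence_level,
        p_value=p_value,
        null_value=null_value,
        n_failed_replicates=n_failed,
        seed=int(seed),
        valid=valid,
        degenerate=False,
        replicates=reps,
    )


def _stability_statistic(
    data: BinaryDataset, cutoff: int, ridge: float
) -> Callable[[tuple[np.ndarray, ...]], float]:
    values = data.values

    def statistic(indices: tuple[np.ndarray, ...]) -> float:
        subset = BinaryDataset(values=values[indices[0]], labels=data.labels)
        network = estimate_ising(subset, ridge=ridge)
        return phase_stability(
            potential_landscape(network), cutoff
        ).stability_difference

    return statistic


def bootstrap_stability(
    data: BinaryDataset,
    cutoff: int,
    b_resamples: int = 1000,
    seed: int = 0,
    *,
    null_value: float = 0.0,
    ridge: float = 0.0,
    confidence_level: float = 0.95,
) -> BootstrapResult:
    """BCa bootstrap of the stability difference of one dataset.

    Persons are resampled with replacement; each replicate re-estimates
    the Ising network and recomputes the stability difference at the
    given cutoff.  Reproducible given the seed.
    """
    return bootstrap_statistic(
        (data.person_count,),
        _stability_statistic(data, cutoff, ridge),
        b_resamples,
        seed,
        null_value=null_value,
        confidence_level=confidence_level,
        name="stability_difference",
    )


@dataclass
class GroupResult:
    """Per-group artifacts of a group comparison."""

    data: BinaryDataset
    network: IsingNetwork
    landscape: Landscape
    metrics: StabilityMetrics
    bootstrap: BootstrapResult | None


@dataclass
class GroupComparison:
    """Two-group stability-landscape comparison.

    ``between`` bootstraps the contrast (group A stability difference
    minus group B's) with stratified resampling.  ``swap_landscapes``
    holds the 2x2 grid keyed by ``(threshold_group, weight_group)``
    with values in {"a", "b"}; its diagonal equals the pure per-group
    landscapes, and comparing rows versus columns shows whether
    thresholds or connectivity drive the contrast.
    """

    group_a: GroupResult
    group_b: GroupResult
    between: BootstrapResult
    swap_landscapes: dict[tuple[str, str], Landscape]
    cutoff: int
    equalized: bool
    group_sizes: tuple[int, int]
    seed: int


def _equalize(
    data_a: BinaryDataset, data_b: BinaryDataset, rng: np.random.Generator
) -> tuple[BinaryDataset, BinaryDataset]:
    """Subsample the larger group without replacement to the smaller size."""
    na, nb = data_a.person_count, data_b.person_count
    if na == nb:
        return data_a, data_b
    if na > nb:
        keep = rng.choice(na, size=nb, replace=False)
        return BinaryDataset(values=data_a.values[keep], labels=data_a.labels), data_b
    keep = rng.choice(nb, size=na, replace=False)
    return data_a, BinaryDataset(values=data_b.values[keep], labels=data_b.labels)


def compare_groups(
    data_a: BinaryDataset,
    data_b: BinaryDataset,
    cutoff: int,
    b_resamples: int = 1000,
    seed: int = 0,
    *,
    equalize: bool = False,
    ridge: float = 0.0,
    confidence_level: float = 0.95,
    per_group_bootstrap: bool = True,
) -> GroupComparison:
    """Compare the stability landscapes of two groups.

    Optionally equalizes group sizes by seeded subsampling of the
    larger group (recommended, so that differences in the estimated
    networks are not driven by differences in power), estimates a
    network, landscape and stability metrics per group, bootstraps the
    per-group stability differences, and bootstraps the between-group
    contrast with independent within-group resampling.  Also emits the
    2x2 parameter-swap landscape grid.

    ``per_group_bootstrap=False`` skips the per-group intervals (the
    between-group test is unaffected); useful in simulation studies.
    """
    if data_a.labels != data_b.labels:
        raise ValueError("group datasets must share identical node labels")
    root = np.random.SeedSequence(seed)
    sub_ss, boot_a_ss, boot_b_ss, between_ss = root.spawn(4)
    if equalize:
        data_a, data_b = _equalize(
            data_a, data_b, np.random.default_rng(sub_ss)
        )

    results = {}
    for key, data, boot_ss in (
        ("a", data_a, boot_a_ss),
        ("b", data_b, boot_b_ss),
    ):
        network = estimate_ising(data, ridge=ridge)
        land = potential_landscape(network)
        met = phase_stability(land, cutoff)
        boot = None
        if per_group_bootstrap:
            boot = bootstrap_statistic(
                (data.person_count,),
                _stability_statistic(data, cutoff, ridge),
                b_resamples,
                boot_ss.generate_state(1)[0] % (2**31),
                confidence_level=confidence_level,
                name=f"stability_difference[{key}]",
            )
        results[key] = GroupResult(
            data=data, network=network, landscape=land, metrics=met, bootstrap=boot
        )

    values_a, values_b = data_a.values, data_b.values
    labels = data_a.labels

    def between_statistic(indices: tuple[np.ndarray, ...]) -> float:
        sub_a = BinaryDataset(values=values_a[indices[0]], labels=labels)
        sub_b = BinaryDataset(values=values_b[indices[1]], labels=labels)
        diff_a = phase_stability(
            potential_landscape(estimate_ising(sub_a, ridge=ridge)), cutoff
        ).stability_difference
        diff_b = phase_stability(
            potential_landscape(estimate_ising(sub_b, ridge=ridge)), cutoff
        ).stability_difference
        return diff_a - diff_b

    between = bootstrap_statistic(
        (data_a.person_count, data_b.person_count),
        between_statistic,
        b_resamples,
        between_ss.generate_state(1)[0] % (2**31),
        confidence_level=confidence_level,
        name="between_group_stability_difference",
    )

    swap = {}
    nets = {k: results[k].network for k in ("a", "b")}
    for t_key in ("a", "b"):
        for w_key in ("a", "b"):
            if t_key == w_key:
                swap[(t_key, w_key)] = results[t_key].landscape
            else:
                swap[(t_key, w_key)] = potential_landscape(
                    IsingNetwork(
                        labels=labels,
                        thresholds=nets[t_key].thresholds,
                        weights=nets[w_key].weights,
                        beta=nets[t_key].beta,
                    )
                )

    return GroupComparison(
        group_a=results["a"],
        group_b=results["b"],
        between=between,
        swap_landscapes=swap,
        cutoff=int(cutoff),
        equalized=bool(equalize),
        group_sizes=(data_a.person_count, data_b.person_count),
        seed=int(seed),
    )


def permutation_mean_difference(
    data_a: BinaryDataset,
    data_b: BinaryDataset,
    b_permutations: int = 10_000,
    seed: int = 0,
    *,
    equalize: bool = True,
) -> PermutationTestResult:
    """Two-sided permutation test on mean symptom counts.

    Group sizes are first equalized by seeded subsampling of the
    larger group; the statistic is the difference in mean per-person
    active-symptom counts (A minus B).  The null distribution permutes
    group labels ``b_permutations`` times; the two-sided p-value is
    ``(1 + #{|T_perm| >= |T_obs|}) / (B + 1)``.
    """
    if b_permutations < 1:
        raise ValueError("b_permutations must be >= 1")
    if data_a.person_count == 0 or data_b.person_count == 0:
        raise ValueError("both groups must be nonempty")
    root = np.random.SeedSequence(seed)
    sub_ss, perm_ss = root.spawn(2)
    if equalize:
        data_a, data_b = _equalize(data_a, data_b, np.random.default_rng(sub_ss))
    counts_a = data_a.symptom_counts().astype(float)
    counts_b = data_b.symptom_counts().astype(float)
    observed = float(counts_a.mean() - counts_b.mean())
    pooled = np.concatenate([counts_a, counts_b])
    na = counts_a.size
    rng = np.random.default_rng(perm_ss)
    exceed = 0
    for _ in range(b_permutations):
        perm = rng.permutation(pooled)
        t = perm[:na].mean() - perm[na:].mean()
        if abs(t) >= abs(observed) - 1e-15:
            exceed += 1
    p = (1.0 + exceed) / (b_permutations + 1.0)
    return PermutationTestResult(mean_difference=observed, p_value=p)
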