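"""Monte-Carlo estimation of pi by dart counting in a unit square.

``N_D`` points are sampled uniformly in the unit square; the fraction landing
inside the inscribed quarter circle (radius 1, centred on the origin corner)
estimates the area ratio pi/4, so ``pi_est = 4 * N_D_in / N_D``.  The module
also provides trial averaging, full ``N_D x n_T`` sweeps, the optimal
inside-count analysis (the integer count that best approximates a reference
pi at a given ``N_D``), and the forward-difference fluctuation diagnostic
``delta pi_est / delta N_D``.

Randomness policy: every public entry point takes an integer seed and builds
``numpy.random.Generator`` streams from a ``SeedSequence``; sweep cells use
spawned child sequences, so cells are independent and the whole grid is
reproducible bit-for-bit from one seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DartTrial",
    "SweepCell",
    "DeviationRecord",
    "pi_from_counts",
    "run_trial",
    "mean_over_trials",
    "sweep",
    "optimal_inside",
    "delta_per_unit_dots",
]


@dataclass(frozen=True)
class DartTrial:
    """One dart-counting trial: total dots, dots inside the quarter circle, pi_est."""

    n_dots: int
    n_inside: int
    pi_est: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not 0 <= self.n_inside <= self.n_dots:
            raise ValueError("n_inside must lie in [0, n_dots]")
        object.__setattr__(self, "pi_est", pi_from_counts(self.n_inside, self.n_dots))


@dataclass(frozen=True)
class SweepCell:
    """Trial-averaged pi_est at one (n_dots, n_trials) grid point."""

    n_dots: int
    n_trials: int
    mean_pi: float
    sd_pi: float
    rng_seed: int


@dataclass(frozen=True)
class DeviationRecord:
    """The most accurate achievable pi_est at a given n_dots."""

    n_dots: int
    best_inside: int
    best_pi: float
    deviation: float
    pi_reference: float


def pi_from_counts(n_inside: int, n_dots: int) -> float:
    """``4 * n_inside / n_dots`` — the quarter-circle counting estimator."""
    if n_dots < 1:
        raise ValueError("n_dots must be at least 1")
    if not 0 <= n_inside <= n_dots:
        raise ValueError("n_inside must lie in [0, n_dots]")
    return 4.0 * n_inside / n_dots


def run_trial(n_dots: int, rng: np.random.Generator) -> DartTrial:
    """Sample ``n_dots`` uniform points in [0,1)^2 and count x^2 + y^2 <= 1.

    The boundary counts as inside (a measure-zero convention fixed for
    determinism).
    """
    if n_dots < 1:
        raise ValueError("n_dots must be at least 1")
    pts = rng.random((n_dots, 2))
    n_inside = int(np.count_nonzero(pts[:, 0] ** 2 + pts[:, 1] ** 2 <= 1.0))
    return DartTrial(n_dots=n_dots, n_inside=n_inside)


def mean_over_trials(n_dots: int, n_trials: int, rng_seed: int) -> SweepCell:
    """Average ``pi_est`` over ``n_trials`` independent trials at fixed ``n_dots``.

    ``sd_pi`` is the sample standard deviation across trials (0.0 for a single
    trial, where the sample spread is undefined).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be at least 1")
    rng = np.random.default_rng(np.random.SeedSequence(rng_seed))
    estimates = np.array([run_trial(n_dots, rng).pi_est for _ in range(n_trials)])
    sd = float(np.std(estimates, ddof=1)) if n_trials > 1 else 0.0
    return SweepCell(
        n_dots=n_dots,
        n_trials=n_trials,
        mean_pi=float(estimates.mean()),
        sd_pi=sd,
        rng_seed=rng_seed,
    )


def sweep(
    n_dots_list: list[int], n_trials_list: list[int], rng_seed: int
) -> list[SweepCell]:
    """Full grid of trial-averaged estimates over ``n_dots_list x n_trials_list``.

    Each cell draws from its own child stream spawned from ``rng_seed``, so
    cells are statistically independent and the grid is reproducible.
    """
    if not n_dots_list or not n_trials_list:
        raise ValueError("n_dots_list and n_trials_list must be non-empty")
    children = np.random.SeedSequence(rng_seed).spawn(
        len(n_dots_list) * len(n_trials_list)
    )
    cells = []
    i = 0
    for n_dots in n_dots_list:
        for n_trials in n_trials_list:
            rng = np.random.default_rng(children[i])
            estimates = np.array(
                [run_trial(n_dots, rng).pi_est for _ in range(n_trials)]
            )
            sd = float(np.std(estimates, ddof=1)) if n_trials > 1 else 0.0
            cells.append(
                SweepCell(n_dots, n_trials, float(estimates.mean()), sd, rng_seed)
            )
            i += 1
    return cells


def optimal_inside(n_dots: int, pi_reference: float = math.pi) -> DeviationRecord:
    """The inside count that best approximates ``pi_reference`` at ``n_dots``.

    Minimizes ``|4k/n_dots - pi_reference|`` over integer ``k``; exact ties
    break toward the larger count.
    """
    if n_dots < 1:
        raise ValueError("n_dots must be at least 1")
    lo = math.floor(pi_reference * n_dots / 4.0)
    best = None
    for k in (lo, lo + 1):
        k = min(max(k, 0), n_dots)
        dev = abs(pi_from_counts(k, n_dots) - pi_reference)
        if best is None or dev < best[0] or (dev == best[0] and k > best[1]):
            best = (dev, k)
    dev, k = best
    return DeviationRecord(
        n_dots=n_dots,
        best_inside=k,
        best_pi=pi_from_counts(k, n_dots),
        deviation=dev,
        pi_reference=pi_reference,
    )


def delta_per_unit_dots(
    series: list[tuple[int, float]],
) -> list[tuple[int, float]]:
    """Forward difference quotients of ``pi_est`` per unit dot number.

    ``series`` is (n_dots, pi_est) sorted by n_dots; element ``i`` of the
    result pairs ``n_dots[i]`` with
    ``(pi_est[i+1] - pi_est[i]) / (n_dots[i+1] - n_dots[i])``.
    """
    if len(series) < 2:
        raise ValueError("series must contain at least two points")
    out = []
    for (n0, p0), (n1, p1) in zip(series, series[1:]):
        if n1 == n0:
            raise ValueError(f"duplicate n_dots value {n0}")
        if n1 < n0:
            raise ValueError("series must be sorted by n_dots")
        out.append((n0, (p1 - p0) / (n1 - n0)))
    return out
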