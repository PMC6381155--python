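"""Counting open and blocked growth configurations versus step number.

At step ``N_S`` the two-front growth model offers four orientation choices
per step, so the sample space holds ``4**N_S`` choice sequences.  This module
counts how many of them end open versus blocked:

* :func:`enumerate_exact` — exhaustive counts (merged over dynamically
  equivalent states, so it is exact while visiting far fewer than ``4**N_S``
  states);
* :func:`simulate_omega` — Monte-Carlo estimates via the inflation formula
  ``Omega_O = 4**N_S * (n_T - n_B)/n_T`` where ``n_B`` of ``n_T`` random
  trials ended blocked;
* :func:`omega_analytic` — the closed-form count of open configurations for
  the two-dimensional hexagonal-lattice self-avoiding walk,
  ``0.415 * sqrt(2 + sqrt 2)**(2*N_S + 1) * (2*N_S + 1)**(11/32)``;
* :func:`log_omega_difference` / :func:`crossover_step` — the entropy-like
  difference ``D = ln Omega_O - ln Omega_B`` and its zero crossing;
* :func:`summarize_observations` — motif-count and class histograms of
  observed lattices.

A trial blocked at step ``k`` stays in the blocked tally at every later step
(each blocked configuration formally spawns four children per step), which is
what keeps ``Omega_O + Omega_B = 4**N_S`` exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from . import hexgrowth
from .hexgrowth import ConfigClass, step_lite

__all__ = [
    "OmegaTable",
    "OmegaEstimate",
    "ObservationSummary",
    "ResourceLimitError",
    "MAX_EXACT_STEP",
    "enumerate_exact",
    "simulate_omega",
    "simulate_omega_series",
    "omega_analytic",
    "log_omega_difference",
    "crossover_step",
    "summarize_observations",
    "ALPHA_BIN_LABELS",
    "BETA_CLASS_LABELS",
]

#: Guard rail for exhaustive enumeration (4**12 ~ 1.7e7 choice sequences).
MAX_EXACT_STEP = 12


class ResourceLimitError(RuntimeError):
    """Raised when an exhaustive enumeration would exceed the guard rail."""


@dataclass(frozen=True)
class OmegaTable:
    """Exact configuration counts at one step number."""

    n_step: int
    omega_total: int
    omega_open: int
    omega_blocked: int
    n_half_left: int
    n_half_right: int
    n_full: int

    def __post_init__(self) -> None:
        if self.omega_total != 4**self.n_step:
            raise ValueError("omega_total must equal 4**n_step")
        if self.omega_open + self.omega_blocked != self.omega_total:
            raise ValueError("open + blocked must equal omega_total")
        if self.n_half_left + self.n_half_right + self.n_full != self.omega_blocked:
            raise ValueError("blocked must equal half_left + half_right + full")
        if min(self.omega_open, self.n_half_left, self.n_half_right, self.n_full) < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class OmegaEstimate:
    """Monte-Carlo estimate of the open/blocked counts at one step number."""

    n_step: int
    n_trials: int
    n_blocked_trials: int
    rng_seed: int
    omega_open_est: float = field(init=False)
    omega_blocked_est: float = field(init=False)

    def __post_init__(self) -> None:
        if not 0 <= self.n_blocked_trials <= self.n_trials:
            raise ValueError("n_blocked_trials must lie in [0, n_trials]")
        total = 4.0**self.n_step
        open_est = total * (self.n_trials - self.n_blocked_trials) / self.n_trials
        object.__setattr__(self, "omega_open_est", open_est)
        object.__setattr__(self, "omega_blocked_est", total - open_est)

    @property
    def blocked_fraction(self) -> float:
        return self.n_blocked_trials / self.n_trials


ALPHA_BIN_LABELS = ("<=10", "11-20", "21-30", ">=31")
BETA_CLASS_LABELS = ("open", "half_blocked", "full_blocked")


@dataclass(frozen=True)
class ObservationSummary:
    """Percentage summaries of observed lattices (motif counts and classes)."""

    alpha_bins: dict
    beta_classes: dict
    n_observations: int


def _classify_lite(left, right) -> ConfigClass:
    return hexgrowth.classify_lite(left[2], right[2])


def enumerate_exact(max_step: int) -> list[OmegaTable]:
    """Exact open/blocked counts for every step number 0..``max_step``.

    Semantically this applies every choice sequence in ``{1..4}**N_S`` through
    the growth rules; states that evolve identically are merged with
    multiplicities (a blocked front ignores its orientation, and fully blocked
    states are frozen), so the result is exact at a fraction of the cost.
    """
    if max_step < 0:
        raise ValueError("max_step must be non-negative")
    if max_step > MAX_EXACT_STEP:
        raise ResourceLimitError(
            f"exact enumeration is limited to {MAX_EXACT_STEP} steps "
            f"(4**{MAX_EXACT_STEP} sequences); use simulate_omega beyond that"
        )

    seed_occ = frozenset({hexgrowth.SEED_SITE})
    left0 = (hexgrowth.SEED_SITE, hexgrowth.LEFT_START, True)
    right0 = (hexgrowth.SEED_SITE, hexgrowth.RIGHT_START, True)

    rows = [OmegaTable(0, 1, 1, 0, 0, 0, 0)]
    level = {(seed_occ, left0, right0): 1}
    full_mass = 0
    for n in range(1, max_step + 1):
        nxt: dict = {}
        full_mass *= 4
        for (occ, lf, rf), mult in level.items():
            if lf[2] and rf[2]:
                for lo in (1, 2):
                    for ro in (1, 2):
                        child = step_lite(occ, lf, rf, lo, ro)
                        nxt[child] = nxt.get(child, 0) + mult
            else:
                # one front blocked: its orientation is a no-op, so the four
                # children collapse to two, each carrying double weight
                for o in (1, 2):
                    child = step_lite(occ, lf, rf, o, o)
                    nxt[child] = nxt.get(child, 0) + 2 * mult
        counts = {ConfigClass.OPEN: 0, ConfigClass.HALF_LEFT: 0, ConfigClass.HALF_RIGHT: 0}
        level = {}
        for key, mult in nxt.items():
            _occ, lf, rf = key
            cls = _classify_lite(lf, rf)
            if cls is ConfigClass.FULL:
                full_mass += mult  # frozen: contributes 4**(N-n) at later steps
            else:
                counts[cls] += mult
                level[key] = mult
        total = 4**n
        blocked = counts[ConfigClass.HALF_LEFT] + counts[ConfigClass.HALF_RIGHT] + full_mass
        rows.append(
            OmegaTable(
                n_step=n,
                omega_total=total,
                omega_open=total - blocked,
                omega_blocked=blocked,
                n_half_left=counts[ConfigClass.HALF_LEFT],
                n_half_right=counts[ConfigClass.HALF_RIGHT],
                n_full=full_mass,
            )
        )
    return rows


def _draw_block_steps(n_step: int, n_trials: int, rng_seed: int) -> np.ndarray:
    from ._kernel import block_steps  # deferred: numba compilation on first use

    rng = np.random.default_rng(rng_seed)
    lo = rng.integers(1, 3, size=(n_trials, n_step), dtype=np.int8)
    ro = rng.integers(1, 3, size=(n_trials, n_step), dtype=np.int8)
    return block_steps(lo, ro)


def simulate_omega(n_step: int, n_trials: int, rng_seed: int) -> OmegaEstimate:
    """Monte-Carlo estimate of the open/blocked counts at ``n_step``.

    Draws ``n_trials`` independent uniform choice sequences, runs the growth
    rules, and inflates the blocked-trial fraction to the full sample space.
    Reproducible for a given ``rng_seed``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be at least 1")
    if n_step < 1:
        raise ValueError("n_step must be at least 1")
    blocks = _draw_block_steps(n_step, n_trials, rng_seed)
    n_blocked = int(np.count_nonzero((blocks[:, 0] > 0) | (blocks[:, 1] > 0)))
    return OmegaEstimate(
        n_step=n_step, n_trials=n_trials, n_blocked_trials=n_blocked, rng_seed=rng_seed
    )


def simulate_omega_series(
    max_step: int, n_trials: int, rng_seed: int
) -> list[OmegaEstimate]:
    """One estimate per step number 1..``max_step`` from a single trial batch.

    A trial's class at step ``k`` depends only on its first ``k`` choices, so
    one batch simulated to ``max_step`` yields consistent estimates at every
    intermediate step (and the blocked fraction is non-decreasing in ``k``).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be at least 1")
    if max_step < 1:
        raise ValueError("max_step must be at least 1")
    blocks = _draw_block_steps(max_step, n_trials, rng_seed).astype(np.int64)
    blocks[blocks == 0] = np.iinfo(np.int64).max  # front never blocked
    first_block = blocks.min(axis=1)  # a trial is blocked once either front is
    out = []
    for n in range(1, max_step + 1):
        n_blocked = int(np.count_nonzero(first_block <= n))
        out.append(
            OmegaEstimate(
                n_step=n, n_trials=n_trials, n_blocked_trials=n_blocked, rng_seed=rng_seed
            )
        )
    return out


#: Connective constant of the honeycomb lattice, sqrt(2 + sqrt 2).
HONEYCOMB_CONNECTIVE_CONSTANT = math.sqrt(2.0 + math.sqrt(2.0))


def omega_analytic(n_step: int | float) -> float:
    """Closed-form open-configuration count for the hexagonal-lattice walk.

    ``0.415 * mu**(2*N_S + 1) * (2*N_S + 1)**(11/32)`` with ``mu`` the
    honeycomb connective constant ``sqrt(2 + sqrt 2)``; the prefactor and the
    enumeration exponent are taken as given.
    """
    if n_step < 0:
        raise ValueError("n_step must be non-negative")
    m = 2.0 * n_step + 1.0
    return 0.415 * HONEYCOMB_CONNECTIVE_CONSTANT**m * m ** (11.0 / 32.0)


def log_omega_difference(table: OmegaTable | OmegaEstimate) -> float:
    """``D = ln Omega_O - ln Omega_B`` for an exact row or a Monte-Carlo estimate.

    Raises ``ValueError`` when either count is zero — the difference is then
    undefined and is reported as missing rather than as an infinity.
    """
    if isinstance(table, OmegaEstimate):
        opened, blocked = table.omega_open_est, table.omega_blocked_est
    else:
        opened, blocked = table.omega_open, table.omega_blocked
    if opened <= 0 or blocked <= 0:
        raise ValueError(
            "ln(Omega_O) - ln(Omega_B) is undefined when either count is zero"
        )
    return math.log(opened) - math.log(blocked)


def crossover_step(series: Sequence[tuple[float, float]]) -> float:
    """Fractional step number where linearly interpolated ``D`` crosses zero.

    ``series`` holds ``(n_step, D)`` pairs in increasing step order.  An exact
    zero at a node returns that node; otherwise the first sign change is
    interpolated linearly.  Raises ``LookupError`` if ``D`` never crosses zero.
    """
    pts = [(float(n), float(d)) for n, d in series]
    if len(pts) < 1:
        raise LookupError("empty series")
    for i, (n, d) in enumerate(pts):
        if d == 0.0:
            return n
        if i > 0:
            n0, d0 = pts[i - 1]
            if (d0 > 0 > d) or (d0 < 0 < d):
                return n0 + d0 * (n - n0) / (d0 - d)
    raise LookupError("D never changes sign in the supplied series")


_CLASS_ALIASES = {
    "open": ConfigClass.OPEN,
    "half_left": ConfigClass.HALF_LEFT,
    "half_right": ConfigClass.HALF_RIGHT,
    "full": ConfigClass.FULL,
    "half": ConfigClass.HALF_LEFT,  # pooled anyway; side unknown
    "half_blocked": ConfigClass.HALF_LEFT,
    "full_blocked": ConfigClass.FULL,
}


def _coerce_class(value) -> ConfigClass:
    if isinstance(value, ConfigClass):
        return value
    try:
        return _CLASS_ALIASES[str(value).strip().lower()]
    except KeyError:
        raise ValueError(f"unknown configuration class {value!r}") from None


def summarize_observations(
    observations: Iterable[tuple[int, ConfigClass | str]],
) -> ObservationSummary:
    """Percentage histograms of observed lattices.

    ``alpha_bins`` bins the motif count (seed excluded) into the ranges
    <=10, 11-20, 21-30, >=31; ``beta_classes`` splits the configuration class
    into open / half-blocked (left and right pooled) / full-blocked.
    """
    obs = list(observations)
    if not obs:
        raise ValueError("at least one observation is required")
    alpha = dict.fromkeys(ALPHA_BIN_LABELS, 0)
    beta = dict.fromkeys(BETA_CLASS_LABELS, 0)
    for count, cls in obs:
        count = int(count)
        if count < 0:
            raise ValueError("motif counts must be non-negative")
        if count <= 10:
            alpha["<=10"] += 1
        elif count <= 20:
            alpha["11-20"] += 1
        elif count <= 30:
            alpha["21-30"] += 1
        else:
            alpha[">=31"] += 1
        c = _coerce_class(cls)
        if c is ConfigClass.OPEN:
            beta["open"] += 1
        elif c is ConfigClass.FULL:
            beta["full_blocked"] += 1
        else:
            beta["half_blocked"] += 1
    n = len(obs)
    return ObservationSummary(
        alpha_bins={k: 100.0 * v / n for k, v in alpha.items()},
        beta_classes={k: 100.0 * v / n for k, v in beta.items()},
        n_observations=n,
    )
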