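"""Honeycomb-lattice geometry and the two-front self-avoiding growth model.

The growth model describes how a lattice of blunt-ended three-point-star DNA
motifs extends from a single seed motif.  The seed occupies one vertex of the
honeycomb graph and exposes two sticky arms — a *left* and a *right* growth
front — plus one blunt (non-binding) arm.  At every step each still-active
front tries to hybridize a new motif onto the site its sticky arm points to.
The incoming motif binds with one arm, and an orientation choice (1 or 2)
decides which of its two remaining arms carries the next sticky end; the
other arm is blunt.  Growth is self-avoiding: a front whose target site is
already occupied becomes permanently blocked, and two fronts whose sticky
ends come to face each other across an edge hybridize to each other and close
the lattice, blocking both.

Coordinates
-----------
A honeycomb vertex is addressed as ``(u, v, s)`` with integer ``u, v`` and a
sublattice tag ``s`` in ``{"A", "B"}``.  The neighbours of ``(u, v, A)`` are
``(u, v, B)``, ``(u-1, v, B)`` and ``(u, v-1, B)``; symmetrically for B.
Every vertex has exactly three neighbours, all edges join A to B, and the
shortest cycle has length six.  For export, A-sites project to Cartesian
``(1.5*(u+v), sqrt(3)/2*(v-u))`` and B-sites sit one unit to the right of
their A partner, so the three arms of any motif point 120 degrees apart.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import NamedTuple, Sequence

__all__ = [
    "Site",
    "StepChoice",
    "Front",
    "MotifRecord",
    "GrowthState",
    "ConfigClass",
    "neighbors",
    "cartesian",
    "make_seed",
    "apply_step",
    "classify",
    "motif_count",
    "mirror",
    "config_name",
    "export_state",
]

SQRT3_2 = math.sqrt(3.0) / 2.0


class Site(NamedTuple):
    """One honeycomb vertex: integer axial coordinates plus sublattice tag."""

    u: int
    v: int
    s: str  # "A" or "B"


SEED_SITE = Site(0, 0, "A")
BLUNT_SITE = Site(0, 0, "B")  # seed's blunt arm points here (east)
LEFT_START = Site(-1, 0, "B")  # 120 deg, upper left
RIGHT_START = Site(0, -1, "B")  # 240 deg, lower left


def neighbors(site: Site) -> tuple[Site, Site, Site]:
    """The three honeycomb neighbours of ``site`` (always on the other sublattice)."""
    u, v, s = site
    if s == "A":
        return (Site(u, v, "B"), Site(u - 1, v, "B"), Site(u, v - 1, "B"))
    if s == "B":
        return (Site(u, v, "A"), Site(u + 1, v, "A"), Site(u, v + 1, "A"))
    raise ValueError(f"sublattice tag must be 'A' or 'B', got {s!r}")


def cartesian(site: Site) -> tuple[float, float]:
    """Project a lattice site to the fixed Cartesian embedding (unit edge length)."""
    u, v, s = site
    x = 1.5 * (u + v)
    y = SQRT3_2 * (v - u)
    if s == "B":
        x += 1.0
    return (x, y)


# Arm angles in the Cartesian embedding, in degrees.  A-site arms point at
# 0/120/240, B-site arms at 60/180/300; the tables below map an arm angle to
# the neighbour it reaches and back.
_ANGLE_OF_NEIGHBOR = {
    "A": {0: 0, 1: 120, 2: 240},  # index into neighbors() -> angle
    "B": {0: 180, 1: 300, 2: 60},
}


def arm_angle(site: Site, nbr: Site) -> int:
    """Angle (degrees) of the arm of ``site`` that points at neighbour ``nbr``."""
    nbs = neighbors(site)
    for i, cand in enumerate(nbs):
        if cand == nbr:
            return _ANGLE_OF_NEIGHBOR[site.s][i]
    raise ValueError(f"{nbr} is not a neighbour of {site}")


def neighbor_at_angle(site: Site, angle: int) -> Site:
    """The neighbour reached by the arm of ``site`` at ``angle`` degrees."""
    table = _ANGLE_OF_NEIGHBOR[site.s]
    for i, ang in table.items():
        if ang == angle % 360:
            return neighbors(site)[i]
    raise ValueError(f"site {site} has no arm at {angle} degrees")


class StepChoice(NamedTuple):
    """Orientation pair for one growth step: 2 per front, 4 combinations.

    Orientation 1 places the incoming motif's sticky (free) arm on the
    clockwise one of its two remaining arms, orientation 2 on the
    counter-clockwise one, viewed in the fixed Cartesian embedding.
    """

    left_orient: int
    right_orient: int

    @property
    def index(self) -> int:
        """Flat index 1..4: ``2*(left_orient-1) + right_orient``."""
        return 2 * (self.left_orient - 1) + self.right_orient

    @classmethod
    def from_index(cls, index: int) -> "StepChoice":
        if not 1 <= index <= 4:
            raise ValueError(f"choice index must be in 1..4, got {index}")
        return cls(left_orient=(index - 1) // 2 + 1, right_orient=(index - 1) % 2 + 1)

    def _validate(self) -> None:
        if self.left_orient not in (1, 2) or self.right_orient not in (1, 2):
            raise ValueError(f"orientations must be 1 or 2, got {self}")


ALL_CHOICES = tuple(StepChoice.from_index(i) for i in range(1, 5))


@dataclass(frozen=True)
class Front:
    """One growth front: the motif carrying the active sticky arm and its target."""

    side: str  # "left" or "right"
    anchor: Site
    target: Site
    status: str = "active"  # "active" or "blocked"; blocked is absorbing

    @property
    def active(self) -> bool:
        return self.status == "active"


@dataclass(frozen=True)
class MotifRecord:
    """One placed motif: where it sits and where its three arms point.

    ``free_arm`` records the sticky arm chosen when the motif was placed; once
    the next motif binds there the front's anchor moves on, but the record is
    not rewritten (arm history, not live binding state).  The seed has no
    bound arm and its two sticky arms live on the fronts, so both ``bound_arm``
    and ``free_arm`` are ``None`` for it.
    """

    site: Site
    role: str  # "seed", "left-path", or "right-path"
    bound_arm: Site | None
    free_arm: Site | None
    blunt_arm: Site


@dataclass(frozen=True)
class GrowthState:
    """Occupied sites plus the two growth fronts after ``n_steps`` steps."""

    occupied: dict  # Site -> MotifRecord
    left: Front
    right: Front
    n_steps: int
    history: tuple  # of StepChoice


class ConfigClass(str, Enum):
    """Lattice configuration class: how many growth arrows remain."""

    OPEN = "open"  # both fronts active (2 arrows)
    HALF_LEFT = "half_left"  # only the left front blocked (1 arrow)
    HALF_RIGHT = "half_right"  # only the right front blocked (1 arrow)
    FULL = "full"  # both fronts blocked (0 arrows)


def make_seed() -> GrowthState:
    """The step-0 state: a single seed motif with both fronts active.

    The seed sits at ``(0, 0, A)`` with its blunt arm pointing east; the left
    front targets the 120-degree neighbour ``(-1, 0, B)`` and the right front
    the 240-degree neighbour ``(0, -1, B)``.
    """
    seed = MotifRecord(
        site=SEED_SITE, role="seed", bound_arm=None, free_arm=None, blunt_arm=BLUNT_SITE
    )
    return GrowthState(
        occupied={SEED_SITE: seed},
        left=Front("left", SEED_SITE, LEFT_START),
        right=Front("right", SEED_SITE, RIGHT_START),
        n_steps=0,
        history=(),
    )


def _free_blunt(site: Site, bound: Site, orient: int) -> tuple[Site, Site]:
    """Split the two non-bound arms of a newly placed motif into (free, blunt)."""
    bound_angle = arm_angle(site, bound)
    if orient == 1:
        free_angle = (bound_angle - 120) % 360  # clockwise remaining arm
    elif orient == 2:
        free_angle = (bound_angle + 120) % 360
    else:
        raise ValueError(f"orientation must be 1 or 2, got {orient}")
    blunt_angle = (2 * bound_angle - free_angle) % 360  # the third arm
    return neighbor_at_angle(site, free_angle), neighbor_at_angle(site, blunt_angle)


# Lite fronts are (anchor, target, active) triples; the enumeration and
# Monte-Carlo paths run on these to avoid dataclass overhead, and apply_step
# wraps the same transition, so there is a single source of truth for the
# growth rules.
LiteFront = tuple[Site, Site, bool]


def step_lite(
    occ: frozenset,
    left: LiteFront,
    right: LiteFront,
    left_orient: int,
    right_orient: int,
) -> tuple[frozenset, LiteFront, LiteFront]:
    """Advance one growth step on the lite representation.

    Within a step the right front resolves before the left one.  For an
    active front: if its target is occupied the front blocks (self-avoidance);
    otherwise a motif is placed there and the orientation picks its sticky
    arm.  If that sticky arm faces the opposite front's anchor while the
    opposite front's sticky arm faces the new motif, the two sticky ends
    hybridize and both fronts block (lattice closure).  A sticky arm facing a
    blunt or bound arm of an occupied motif does not block immediately; the
    block surfaces at the next step when the target is found occupied.
    Blocked fronts ignore their orientation value.
    """
    occ2 = set(occ)
    fr = [left, right]
    orient = (left_orient, right_orient)
    for i, j in ((1, 0), (0, 1)):  # right front first, then left
        anchor, target, active = fr[i]
        if not active:
            continue
        if target in occ2:
            fr[i] = (anchor, target, False)
            continue
        free, _blunt = _free_blunt(target, anchor, orient[i])
        occ2.add(target)
        o_anchor, o_target, o_active = fr[j]
        if o_active and free == o_anchor and o_target == target:
            fr[i] = (target, free, False)
            fr[j] = (o_anchor, o_target, False)
        else:
            fr[i] = (target, free, True)
    return frozenset(occ2), fr[0], fr[1]


def _lite(front: Front) -> LiteFront:
    return (front.anchor, front.target, front.active)


def apply_step(
    state: GrowthState, choice: StepChoice, max_steps: int | None = None
) -> GrowthState:
    """Apply one step choice to ``state`` and return the successor state.

    ``max_steps``, when given, bounds the number of steps; exceeding it raises
    ``ValueError``.  Blocked fronts consume their orientation as a no-op, so
    every choice sequence in ``{1..4}**N`` is a valid trajectory.
    """
    choice = StepChoice(*choice)
    choice._validate()
    if max_steps is not None and state.n_steps >= max_steps:
        raise ValueError(f"cannot step past configured maximum of {max_steps} steps")

    old = {"left": state.left, "right": state.right}
    occ_set = frozenset(state.occupied)
    _new_occ, nl, nr = step_lite(
        occ_set, _lite(state.left), _lite(state.right), choice.left_orient, choice.right_orient
    )
    occupied = dict(state.occupied)
    fronts = {}
    for side, lite in (("left", nl), ("right", nr)):
        anchor, target, active = lite
        fronts[side] = Front(side, anchor, target, "active" if active else "blocked")
        if anchor != old[side].anchor:  # this front placed a motif at its old target
            bound = old[side].anchor
            free, blunt = _free_blunt(anchor, bound, choice[0] if side == "left" else choice[1])
            occupied[anchor] = MotifRecord(
                site=anchor,
                role=f"{side}-path",
                bound_arm=bound,
                free_arm=free,
                blunt_arm=blunt,
            )
    return GrowthState(
        occupied=occupied,
        left=fronts["left"],
        right=fronts["right"],
        n_steps=state.n_steps + 1,
        history=state.history + (choice,),
    )


def classify(state: GrowthState) -> ConfigClass:
    """Configuration class from the two front statuses."""
    return classify_lite(state.left.active, state.right.active)


def classify_lite(left_active: bool, right_active: bool) -> ConfigClass:
    if left_active and right_active:
        return ConfigClass.OPEN
    if right_active:
        return ConfigClass.HALF_LEFT
    if left_active:
        return ConfigClass.HALF_RIGHT
    return ConfigClass.FULL


def motif_count(state: GrowthState) -> int:
    """Number of placed motifs excluding the seed."""
    return len(state.occupied) - 1


def _mirror_site(site: Site) -> Site:
    # Reflection across the seed's blunt-arm axis (the Cartesian x-axis)
    # exchanges the axial coordinates.
    return Site(site.v, site.u, site.s)


_MIRROR_ROLE = {"seed": "seed", "left-path": "right-path", "right-path": "left-path"}


def mirror(state: GrowthState) -> GrowthState:
    """Reflect a state across the seed's blunt-arm axis, swapping left/right.

    The reflection flips chirality, so orientation values 1 and 2 swap in the
    recorded history.  ``mirror`` is an involution and exchanges the
    half-left and half-right classes.
    """
    occupied = {}
    for site, rec in state.occupied.items():
        m = _mirror_site(site)
        occupied[m] = MotifRecord(
            site=m,
            role=_MIRROR_ROLE[rec.role],
            bound_arm=None if rec.bound_arm is None else _mirror_site(rec.bound_arm),
            free_arm=None if rec.free_arm is None else _mirror_site(rec.free_arm),
            blunt_arm=_mirror_site(rec.blunt_arm),
        )

    def flip(front: Front, side: str) -> Front:
        return Front(side, _mirror_site(front.anchor), _mirror_site(front.target), front.status)

    history = tuple(
        StepChoice(left_orient=3 - c.right_orient, right_orient=3 - c.left_orient)
        for c in state.history
    )
    return GrowthState(
        occupied=occupied,
        left=flip(state.right, "left"),
        right=flip(state.left, "right"),
        n_steps=state.n_steps,
        history=history,
    )


def config_name(step: int, ancestor_indices: Sequence[int], current_index: int) -> str:
    """Pedigree name ``"N_S-<ancestor indices>-<current index>"``.

    A configuration is named by its step number, the concatenated choice
    indices of its ancestors (one per earlier step), and its own choice index,
    e.g. ``config_name(3, [3, 4], 2) == "3-34-2"``.  At step 1 the ancestor
    field is empty: ``"1--4"``.
    """
    if len(ancestor_indices) != step - 1:
        raise ValueError(
            f"expected {step - 1} ancestor indices for step {step}, got {len(ancestor_indices)}"
        )
    for idx in (*ancestor_indices, current_index):
        if not 1 <= int(idx) <= 4:
            raise ValueError(f"configuration indices must be in 1..4, got {idx}")
    ancestors = "".join(str(int(i)) for i in ancestor_indices)
    return f"{step}-{ancestors}-{int(current_index)}"


def export_state(state: GrowthState) -> dict:
    """JSON-ready document describing a growth state (for ``saw show``)."""
    xs, ys = zip(*(cartesian(s) for s in state.occupied))
    motifs = []
    for site, rec in state.occupied.items():
        x, y = cartesian(site)
        motifs.append(
            {
                "u": site.u,
                "v": site.v,
                "s": site.s,
                "role": rec.role,
                "bound_arm": None if rec.bound_arm is None else list(rec.bound_arm),
                "free_arm": None if rec.free_arm is None else list(rec.free_arm),
                "blunt_arm": list(rec.blunt_arm),
                "x": x,
                "y": y,
            }
        )
    fronts = {
        side: {
            "anchor": list(f.anchor),
            "target": list(f.target),
            "status": f.status,
        }
        for side, f in (("left", state.left), ("right", state.right))
    }
    return {
        "field_of_view": {
            "x_min": min(xs) - 1.0,
            "x_max": max(xs) + 1.0,
            "y_min": min(ys) - 1.0,
            "y_max": max(ys) + 1.0,
        },
        "n_steps": state.n_steps,
        "motif_count": motif_count(state),
        "class": classify(state).value,
        "motifs": motifs,
        "fronts": fronts,
        "history": [list(c) for c in state.history],
    }
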