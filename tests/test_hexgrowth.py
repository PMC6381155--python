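"""Lattice geometry and growth-rule tests for the two-front model."""

from collections import Counter
from itertools import product

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sawpi import hexgrowth
from sawpi.hexgrowth import (
    ALL_CHOICES,
    ConfigClass,
    Site,
    StepChoice,
    apply_step,
    classify,
    config_name,
    export_state,
    make_seed,
    mirror,
    motif_count,
    neighbors,
)


def grow(indices, **kw):
    state = make_seed()
    for i in indices:
        state = apply_step(state, StepChoice.from_index(i), **kw)
    return state


def enumerate_terminal(n_steps):
    """All 4**n_steps terminal states via apply_step (the brute-force oracle)."""
    for seq in product(ALL_CHOICES, repeat=n_steps):
        state = make_seed()
        for choice in seq:
            state = apply_step(state, choice)
        yield seq, state


sites = st.builds(
    Site,
    st.integers(-50, 50),
    st.integers(-50, 50),
    st.sampled_from(["A", "B"]),
)


class TestLatticeGeometry:
    @settings(max_examples=200, derandomize=True)
    @given(sites)
    def test_three_symmetric_bipartite_neighbors(self, site):
        nbs = neighbors(site)
        assert len(set(nbs)) == 3
        for nb in nbs:
            assert nb.s != site.s  # all edges join the A and B sublattices
            assert site in neighbors(nb)

    @settings(max_examples=100, derandomize=True)
    @given(sites)
    def test_no_four_cycles(self, site):
        # Bipartite rules out odd cycles; absence of 4-cycles means any two
        # neighbours share exactly one common neighbour (the site itself),
        # so the girth is at least 6.
        nbs = neighbors(site)
        for i in range(3):
            for j in range(i + 1, 3):
                common = set(neighbors(nbs[i])) & set(neighbors(nbs[j]))
                assert common == {site}

    def test_hexagon_closes_in_six_steps(self):
        # Walk 0 -> 120 -> 240 alternating arm turns traces one hexagon face.
        site = Site(0, 0, "A")
        path = [site]
        for angle in (0, 60, 120, 180, 240, 300):
            site = hexgrowth.neighbor_at_angle(site, angle)
            path.append(site)
        assert path[-1] == path[0]
        assert len(set(path[:-1])) == 6

    def test_cartesian_arms_are_120_degrees_apart(self):
        import math

        for site in (Site(0, 0, "A"), Site(3, -2, "B")):
            x0, y0 = hexgrowth.cartesian(site)
            angles = []
            for nb in neighbors(site):
                x1, y1 = hexgrowth.cartesian(nb)
                angles.append(math.degrees(math.atan2(y1 - y0, x1 - x0)) % 360)
            angles.sort()
            assert angles[1] - angles[0] == pytest.approx(120)
            assert angles[2] - angles[1] == pytest.approx(120)
            for nb in neighbors(site):
                x1, y1 = hexgrowth.cartesian(nb)
                assert math.hypot(x1 - x0, y1 - y0) == pytest.approx(1.0)


class TestSeedAndSteps:
    def test_seed_state(self):
        state = make_seed()
        assert len(state.occupied) == 1
        assert motif_count(state) == 0
        assert state.n_steps == 0
        assert classify(state) is ConfigClass.OPEN
        assert state.left.target != state.right.target
        seed_nbs = set(neighbors(hexgrowth.SEED_SITE))
        assert {state.left.target, state.right.target} < seed_nbs
        # the third neighbour is the blunt-arm direction
        blunt = state.occupied[hexgrowth.SEED_SITE].blunt_arm
        assert seed_nbs - {state.left.target, state.right.target} == {blunt}

    @pytest.mark.parametrize("index", [1, 2, 3, 4])
    def test_first_step_always_open_with_two_motifs(self, index):
        state = grow([index])
        assert classify(state) is ConfigClass.OPEN
        assert motif_count(state) == 2
        assert state.n_steps == 1

    def test_choice_index_round_trip(self):
        seen = set()
        for index in range(1, 5):
            choice = StepChoice.from_index(index)
            assert choice.index == index
            seen.add((choice.left_orient, choice.right_orient))
        assert seen == {(1, 1), (1, 2), (2, 1), (2, 2)}
        with pytest.raises(ValueError):
            StepChoice.from_index(5)

    def test_step_beyond_configured_maximum_raises(self):
        state = grow([1, 1])
        with pytest.raises(ValueError, match="maximum"):
            apply_step(state, StepChoice.from_index(1), max_steps=2)

    def test_blocked_state_is_absorbing(self):
        # Both fronts curling inward collide at step 3; closure blocks both.
        full = None
        for seq, state in enumerate_terminal(3):
            if classify(state) is ConfigClass.FULL:
                full = state
                break
        assert full is not None
        after = apply_step(full, StepChoice.from_index(2))
        assert after.occupied.keys() == full.occupied.keys()
        assert after.n_steps == full.n_steps + 1
        assert classify(after) is ConfigClass.FULL

    def test_simultaneous_target_right_front_wins(self):
        # The two fronts curl inward around the hexagon shared by the seed's
        # growth arms and target the same site at step 3: the right front
        # places its motif, the left front is blocked.
        counts = Counter(classify(s).value for _, s in enumerate_terminal(3))
        assert counts["open"] == 60
        assert counts["full"] == 2
        assert counts["half_left"] == 2
        assert counts.get("half_right", 0) == 0
        for _, state in enumerate_terminal(3):
            if classify(state) is ConfigClass.HALF_LEFT:
                # right placed 3 motifs, left only 2 before being blocked
                assert motif_count(state) == 5
                assert state.right.active and not state.left.active


class TestInvariants:
    def test_self_avoidance_and_motif_count_bound(self):
        # Every placement in the N=5 enumeration lands on a fresh site, the
        # motif count never exceeds 2*N_S, and equality holds iff the state
        # was open at every step.
        for seq, state in enumerate_terminal(5):
            n = motif_count(state)
            assert len(set(state.occupied)) == len(state.occupied) == n + 1
            assert n <= 10
            if classify(state) is ConfigClass.OPEN:
                assert n == 10

    def test_single_block_motif_count_formula(self):
        # A state blocked on one side at step k and open on the other has
        # (k - 1) + N_S motifs at step N_S.
        n_steps = 5
        checked = 0
        for seq, _ in enumerate_terminal(3):
            state = make_seed()
            block_step = {}
            for step, choice in enumerate(
                list(seq) + [StepChoice.from_index(1)] * (n_steps - 3), start=1
            ):
                state = apply_step(state, choice)
                for side in ("left", "right"):
                    front = getattr(state, side)
                    if not front.active and side not in block_step:
                        block_step[side] = step
            if len(block_step) == 1:
                (k,) = block_step.values()
                assert motif_count(state) == 2 * k - 1 + (n_steps - k)
                checked += 1
        assert checked > 0

    def test_classes_never_recover(self):
        rank = {
            ConfigClass.OPEN: 0,
            ConfigClass.HALF_LEFT: 1,
            ConfigClass.HALF_RIGHT: 1,
            ConfigClass.FULL: 2,
        }
        for seq in product(ALL_CHOICES, repeat=5):
            state = make_seed()
            prev = classify(state)
            for choice in seq:
                state = apply_step(state, choice)
                cur = classify(state)
                assert rank[cur] >= rank[prev]
                if rank[cur] == rank[prev] == 1:
                    assert cur is prev  # a half-block never switches sides
                prev = cur


class TestMirror:
    def test_involution_and_seed(self):
        assert mirror(make_seed()).occupied.keys() == make_seed().occupied.keys()
        state = grow([2, 3, 1, 4])
        double = mirror(mirror(state))
        assert double.occupied.keys() == state.occupied.keys()
        assert double.left == state.left and double.right == state.right
        assert double.history == state.history

    def test_mirror_swaps_half_classes_exactly(self):
        counts = Counter(classify(s).value for _, s in enumerate_terminal(4))
        mirrored = Counter(classify(mirror(s)).value for _, s in enumerate_terminal(4))
        assert mirrored["half_left"] == counts["half_right"]
        assert mirrored["half_right"] == counts["half_left"]
        assert mirrored["open"] == counts["open"]
        assert mirrored["full"] == counts["full"]
        assert counts["half_left"] != counts["half_right"]  # tie-break asymmetry

    def test_mirror_preserves_occupancy_count(self):
        state = grow([1, 2, 2, 1])
        assert len(mirror(state).occupied) == len(state.occupied)


class TestNamingAndExport:
    @pytest.mark.parametrize(
        "step, ancestors, current, expected",
        [
            (2, [3], 1, "2-3-1"),
            (3, [3, 4], 2, "3-34-2"),
            (1, [], 4, "1--4"),
        ],
    )
    def test_config_name(self, step, ancestors, current, expected):
        assert config_name(step, ancestors, current) == expected

    def test_config_name_rejects_bad_indices(self):
        with pytest.raises(ValueError):
            config_name(2, [5], 1)
        with pytest.raises(ValueError):
            config_name(2, [1], 0)
        with pytest.raises(ValueError):
            config_name(3, [1], 2)  # wrong ancestor count

    def test_export_state_document(self):
        state = grow([1, 3, 2])
        doc = export_state(state)
        assert doc["n_steps"] == 3
        assert doc["motif_count"] == motif_count(state)
        assert doc["class"] == classify(state).value
        assert len(doc["motifs"]) == len(state.occupied)
        assert len(doc["history"]) == 3
        roles = Counter(m["role"] for m in doc["motifs"])
        assert roles["seed"] == 1
        fov = doc["field_of_view"]
        for m in doc["motifs"]:
            assert fov["x_min"] <= m["x"] <= fov["x_max"]
            assert fov["y_min"] <= m["y"] <= fov["y_max"]
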