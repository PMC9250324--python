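import numpy as np
import pytest

from watermaze.geometry import rotate_xy, zone_of
from watermaze.strategy import (
    ClassifierParams,
    classify,
    detect_curves,
    detect_nonsense,
    detect_peripheral,
    merge_events,
)
from watermaze.synthetic import ArchetypeSpec, generate_archetype
from watermaze.tracks import Trajectory, headings

from conftest import PathMaker, make_traj


def series(pm, min_step=1.0):
    return headings(pm.traj(), min_step=min_step)


class TestDetectCurves:
    def test_sustained_left_arc_is_one_event_with_signed_magnitude(self):
        pm = PathMaker(step=2.0).straight(30).arc(-120.0).straight(30)
        events = detect_curves(series(pm))
        assert len(events) == 1
        assert events[0].magnitude == pytest.approx(-120.0, abs=1.0)

    @pytest.mark.parametrize("angle,expected", [(80.0, 0), (90.0, 0), (91.0, 1)])
    def test_threshold_is_strictly_greater_than_90(self, angle, expected):
        pm = PathMaker(step=2.0).straight(30).arc(angle).straight(30)
        assert len(detect_curves(series(pm))) == expected

    def test_three_separated_arcs_match_run_scan_oracle(self):
        pm = PathMaker(step=2.0)
        for _ in range(3):
            pm.straight(40).arc(100.0)
        pm.straight(40)
        h = series(pm)
        events = detect_curves(h)
        # oracle: scan maximal same-sign runs of the turn sequence directly
        signs = np.where(np.abs(h.turn) <= 0.5, 0, np.sign(h.turn)).astype(int)
        runs, i = [], 0
        while i < len(signs):
            if signs[i] == 0:
                i += 1
                continue
            j = i
            while j + 1 < len(signs) and signs[j + 1] == signs[i]:
                j += 1
            runs.append(abs(h.turn[i : j + 1].sum()))
            i = j + 1
        assert len(events) == sum(r > 90.0 for r in runs) == 3

    def test_straight_gap_splits_same_direction_arcs(self):
        pm = PathMaker(step=2.0).straight(30).arc(70.0).straight(30).arc(70.0).straight(30)
        # two 70-deg runs, neither above threshold, despite summing to 140
        assert len(detect_curves(series(pm))) == 0


class TestDetectNonsense:
    def test_alternating_sixty_degree_turns_are_one_zigzag(self):
        pm = PathMaker(step=3.0).straight(30)
        for sign in (1, -1, 1, -1):
            pm.arc(sign * 60.0).straight(12)
        events = detect_nonsense(series(pm))
        assert [e.subkind for e in events] == ["zigzag"]

    def test_inward_spiral_is_one_spiral_not_a_curve(self):
        pm = PathMaker(step=2.0).straight(30).arc(450.0, radius=8.0).straight(30)
        h = series(pm)
        nonsense = detect_nonsense(h)
        assert [e.subkind for e in nonsense] == ["spiral"]
        merged = merge_events(detect_curves(h), nonsense, [])
        assert len(merged) == 1 and merged[0].kind == "nonsense"

    def test_straight_track_has_no_events(self):
        pm = PathMaker(step=2.0).straight(80)
        assert detect_nonsense(series(pm)) == []

    def test_sub_threshold_alternation_is_not_zigzag(self):
        pm = PathMaker(step=3.0).straight(30)
        for sign in (1, -1, 1, -1):
            pm.arc(sign * 30.0).straight(12)  # bends below the 45-deg bar
        assert detect_nonsense(series(pm)) == []

    def test_two_alternating_bends_are_not_enough(self):
        pm = PathMaker(step=3.0).straight(30).arc(60.0).straight(12).arc(-60.0).straight(30)
        assert detect_nonsense(series(pm)) == []


class TestDetectPeripheral:
    @staticmethod
    def annulus_arc(radius, b0, b1, step_deg=1.0):
        b = np.arange(b0, b1 + step_deg / 2, step_deg)
        pts = np.column_stack([radius * np.sin(np.deg2rad(b)), radius * np.cos(np.deg2rad(b))])
        return make_traj(pts, dt=0.1)

    @pytest.mark.parametrize(
        "b0,b1,expected",
        [
            (100.0, 110.0, 0),  # 1 octant in zone 3
            (100.0, 150.0, 0),  # 2 octants
            (100.0, 190.0, 0),  # 3 octants: at the limit
            (100.0, 210.0, 1),  # 4 octants: exceeds "more than three"
        ],
    )
    def test_zone3_octant_limits(self, cfg, b0, b1, expected):
        traj = self.annulus_arc(60.0, b0, b1)
        assert len(detect_peripheral(traj, cfg)) == expected

    @pytest.mark.parametrize(
        "b0,b1,expected",
        [
            (185.0, 200.0, 0),  # 1 octant in zone 4
            (185.0, 215.0, 1),  # 2 octants: exceeds "one octant"
        ],
    )
    def test_zone4_octant_limits(self, cfg, b0, b1, expected):
        traj = self.annulus_arc(82.0, b0, b1)
        assert len(detect_peripheral(traj, cfg)) == expected

    def test_interior_track_has_no_peripheral_events(self, cfg):
        traj = self.annulus_arc(30.0, 0.0, 350.0)  # zone 2: not peripheral
        assert detect_peripheral(traj, cfg) == []

    def test_event_count_matches_episode_scan_oracle(self, cfg, rng):
        from watermaze.geometry import octant_of

        for seed in range(15):
            traj, _ = generate_archetype(ArchetypeSpec("J", seed=seed, start_octant=int(rng.integers(4, 7))), cfg)
            z = np.asarray(zone_of(traj.x, traj.y, cfg))
            o = np.asarray(octant_of(traj.x, traj.y, cfg))
            expected = 0
            for zone_id, limit in ((3, 3), (4, 1)):
                mask = (z == zone_id).astype(np.int8)
                d = np.diff(np.concatenate([[0], mask, [0]]))
                for s, e in zip(np.where(d == 1)[0], np.where(d == -1)[0]):
                    expected += np.unique(o[s:e]).size > limit
            assert len(detect_peripheral(traj, cfg)) == expected


class TestMergeEvents:
    def test_disjoint_events_sorted_by_time(self):
        pm = PathMaker(step=2.0).straight(30).arc(120.0).straight(40).arc(-120.0).straight(30)
        h = series(pm)
        merged = merge_events(detect_curves(h), detect_nonsense(h), [])
        assert len(merged) == 2
        assert merged[0].start_time < merged[1].start_time

    def test_spiral_subsumes_its_curve(self):
        pm = PathMaker(step=2.0).straight(30).arc(400.0, radius=8.0).straight(30)
        h = series(pm)
        merged = merge_events(detect_curves(h), detect_nonsense(h), [])
        assert len(merged) == 1 and merged[0].subkind == "spiral"


class TestClassify:
    def test_straight_to_platform_is_A(self, cfg):
        traj, _ = generate_archetype(ArchetypeSpec("A"), cfg)
        label = classify(traj, cfg)
        assert label.category == "A"
        assert label.effective and label.directionality == "direct" and label.n_changes == 0

    def test_wall_hugging_trial_is_J(self, cfg):
        traj, _ = generate_archetype(ArchetypeSpec("J"), cfg)
        label = classify(traj, cfg)
        assert label.category == "J" and not label.effective

    def test_two_changes_before_zone1_is_E(self, cfg):
        traj, _ = generate_archetype(ArchetypeSpec("E", n_curves=2, seed=2), cfg)
        label = classify(traj, cfg)
        assert label.category == "E"
        assert label.directionality == "indirect" and label.n_changes == 2

    def test_wide_ineffective_search_is_I(self, cfg):
        traj, _ = generate_archetype(ArchetypeSpec("I"), cfg)
        assert classify(traj, cfg).category == "I"

    def test_confined_ineffective_search_is_H(self, cfg):
        traj, _ = generate_archetype(ArchetypeSpec("H"), cfg)
        assert classify(traj, cfg).category == "H"

    def test_every_category_reachable(self, cfg):
        seen = set()
        for cat in "ABCDEFGHIJ":
            k = {"A": 0, "B": 1, "C": 4, "D": 7, "E": 1, "F": 4, "G": 7}.get(cat, 0)
            traj, truth = generate_archetype(ArchetypeSpec(cat, n_curves=k), cfg)
            seen.add(classify(traj, cfg).category)
        assert seen == set("ABCDEFGHIJ")

    @pytest.mark.parametrize(
        "n,expected",
        list(zip(range(11), "ABBBCCCDDDD")),
    )
    def test_direct_precision_band_boundaries(self, cfg, n, expected):
        traj, _ = generate_archetype(ArchetypeSpec(expected, n_curves=n), cfg)
        label = classify(traj, cfg)
        assert label.category == expected and label.n_changes == n

    @pytest.mark.parametrize("n,expected", list(zip(range(1, 11), "EEEFFFGGGG")))
    def test_indirect_precision_band_boundaries(self, cfg, n, expected):
        traj, _ = generate_archetype(ArchetypeSpec(expected, n_curves=n), cfg)
        label = classify(traj, cfg)
        assert label.category == expected and label.n_changes == n

    def test_direct_indirect_switch_on_event_placement(self, cfg):
        """The same change count yields B when committed after the zone-1
        arrival and E when committed before it."""
        b = classify(generate_archetype(ArchetypeSpec("B", n_curves=2, seed=7), cfg)[0], cfg)
        e = classify(generate_archetype(ArchetypeSpec("E", n_curves=2, seed=7), cfg)[0], cfg)
        assert b.n_changes == e.n_changes == 2
        assert (b.category, e.category) == ("B", "E")

    def test_censoring_post_arrival_samples_do_not_matter(self, cfg):
        traj, _ = generate_archetype(ArchetypeSpec("B", n_curves=1, seed=3), cfg)
        z = np.asarray(zone_of(traj.x, traj.y, cfg))
        idx = int(np.argmax(z == 0))
        # append a wild continuation after the first platform entry
        pm = PathMaker(start=(traj.x[idx], traj.y[idx]), heading=225.0, step=2.0)
        pm.straight(20).arc(200.0).straight(20)
        extra = np.asarray(pm.pts)[1:]
        keep = np.hypot(extra[:, 0], extra[:, 1]) < 88
        ext = Trajectory(
            t=np.arange(idx + 1 + keep.sum()) * 0.1,
            x=np.concatenate([traj.x[: idx + 1], extra[keep, 0]]),
            y=np.concatenate([traj.y[: idx + 1], extra[keep, 1]]),
        )
        assert classify(ext, cfg).category == classify(traj, cfg).category == "B"

    def test_label_invariant_under_rigid_rotation(self, cfg):
        for cat, k in [("B", 2), ("F", 5), ("J", 0), ("H", 0)]:
            traj, _ = generate_archetype(ArchetypeSpec(cat, n_curves=k, seed=11), cfg)
            theta = 97.0
            xr, yr = rotate_xy(traj.x, traj.y, theta)
            rot = Trajectory(t=traj.t, x=xr, y=yr, trial_duration=traj.trial_duration)
            assert classify(rot, cfg.rotated(theta)).category == cat

    def test_monotone_in_injected_changes(self, cfg):
        """More committed changes never move a direct label back toward A."""
        order = {c: i for i, c in enumerate("ABCD")}
        last = -1
        for n in (0, 1, 4, 7):
            cat = classify(generate_archetype(ArchetypeSpec("ABCD"[min(3, (n + 2) // 3)], n_curves=n), cfg)[0], cfg).category
            assert order[cat] >= last
            last = order[cat]

    def test_thigmotaxis_tolerance_allows_brief_departures(self, cfg):
        traj, _ = generate_archetype(ArchetypeSpec("J"), cfg)
        # nudge 3% of samples just inside zone 3
        n = traj.n
        k = max(1, int(0.03 * n))
        x, y = traj.x.copy(), traj.y.copy()
        r = np.hypot(x[:k], y[:k])
        x[:k], y[:k] = x[:k] / r * 70.0, y[:k] / r * 70.0
        nudged = Trajectory(t=traj.t, x=x, y=y, trial_duration=traj.trial_duration)
        assert classify(nudged, cfg).category == "J"
        strict = ClassifierParams(thigmotaxis_tol=0.0)
        assert classify(nudged, cfg, strict).category in "HI"
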