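"""Hypothesis costs, coupled assignment, and track linking."""

import numpy as np
import pytest

from ajtrack.graphs import Cell, CellGraph
from ajtrack.tracker import (
    FeatureScales,
    Hypothesis,
    TrackerWeights,
    apoptosis_cost,
    association_cost,
    boundary_costs,
    build_flow_network,
    distance_to_boundary,
    link_tracks,
    mitosis_cost,
    solve_min_cost_flow,
)


def make_cell(cid, x=0.0, y=0.0, area=10.0, perimeter=12.0, width=2.0, length=3.0,
              rotation=0.0, boundary=None):
    return Cell(id=cid, boundary=boundary or [0, 1, 2], perimeter=perimeter, area=area,
                centroid=np.array([0.0, y, x]), width=width, length=length,
                rotation=rotation)


SQUARE_BOUNDARY = np.array([[0, 0, 0], [0, 30, 0], [0, 30, 30], [0, 0, 30]], float)


def brute_force_optimum(net):
    """Exhaustive search over all valid hypothesis selections."""
    by_left: dict = {}
    for i, h in enumerate(net.hypotheses):
        by_left.setdefault(h.source, []).append(i)
    enter = by_left.get(None, [])
    best = [np.inf]

    def rec(k, used_right, cost):
        if cost >= best[0]:
            return
        if k == len(net.cells_t):
            total = cost
            for rcell in net.cells_t1:
                if rcell in used_right:
                    continue
                cands = [i for i in enter if net.hypotheses[i].targets[0] == rcell]
                if not cands:
                    return
                total += net.hypotheses[cands[0]].cost
            best[0] = min(best[0], total)
            return
        for i in by_left.get(net.cells_t[k], []):
            h = net.hypotheses[i]
            if any(t in used_right for t in h.targets):
                continue
            rec(k + 1, used_right | set(h.targets), cost + h.cost)

    rec(0, frozenset(), 0.0)
    return best[0]


class TestCosts:
    def test_identical_cells_association_is_offset_only(self):
        w = TrackerWeights()
        a, b = make_cell(0), make_cell(1)
        assert association_cost(a, b, w) == pytest.approx(w.association)

    def test_association_linear_in_centroid_displacement(self):
        w = TrackerWeights()
        scales = FeatureScales(centroid=2.0)
        base = make_cell(0)
        for delta in (0.5, 1.0, 2.0):
            moved = make_cell(1, x=delta)
            c = association_cost(base, moved, w, scales)
            assert c == pytest.approx(w.association + w.centroid * delta / 2.0)

    def test_association_matches_independent_formula(self, rng):
        """Dual implementation oracle over random cell pairs."""
        w = TrackerWeights(centroid=1.3, area=0.7, perimeter=0.9, width=0.4,
                           rotation=0.6, length=0.8, association=0.25)
        sc = FeatureScales(centroid=2.0, area=3.0, perimeter=1.5, width=0.5,
                           rotation=0.7, length=0.9)
        for _ in range(100):
            a = make_cell(0, *rng.uniform(0, 10, 2), *rng.uniform(1, 20, 4),
                          rotation=rng.uniform(-np.pi / 2, np.pi / 2))
            b = make_cell(1, *rng.uniform(0, 10, 2), *rng.uniform(1, 20, 4),
                          rotation=rng.uniform(-np.pi / 2, np.pi / 2))
            dr = abs(a.rotation - b.rotation) % np.pi
            expected = (
                w.association
                + w.centroid * np.linalg.norm(a.centroid - b.centroid) / sc.centroid
                + w.area * abs(a.area - b.area) / sc.area
                + w.perimeter * abs(a.perimeter - b.perimeter) / sc.perimeter
                + w.width * abs(a.width - b.width) / sc.width
                + w.rotation * min(dr, np.pi - dr) / sc.rotation
                + w.length * abs(a.length - b.length) / sc.length
            )
            assert association_cost(a, b, w, sc) == pytest.approx(expected, abs=1e-12)

    def test_mitosis_requires_adjacent_children(self):
        w = TrackerWeights()
        parent = make_cell(0, boundary=[0, 1, 2, 3])
        c1 = make_cell(1, boundary=[0, 1, 2, 3])
        c2 = make_cell(2, boundary=[1, 4, 5, 2])
        pos = np.array([[0, 0, 0], [0, 0, 1], [0, 1, 1], [0, 1, 0], [0, 0, 2], [0, 1, 2]], float)
        cg_adj = CellGraph(cells=[c1, c2], edges=[(1, 2)])
        cg_not = CellGraph(cells=[c1, c2], edges=[])
        assert mitosis_cost(parent, c1, c2, cg_not, pos, w) is None
        assert mitosis_cost(parent, c1, c2, cg_adj, pos, w) is not None

    def test_mitosis_of_exact_union_costs_offset_only(self):
        w = TrackerWeights()
        pos = np.array([[0, 0, 0], [0, 0, 1], [0, 1, 1], [0, 1, 0], [0, 0, 2], [0, 1, 2]], float)
        from ajtrack.graphs import polygon_moments

        union_ring = [0, 1, 4, 5, 2, 3]
        m = polygon_moments(pos[union_ring])
        parent = Cell(id=0, boundary=union_ring, perimeter=m["perimeter"], area=m["area"],
                      centroid=m["centroid"], width=m["width"], length=m["length"],
                      rotation=m["rotation"])
        c1 = make_cell(1, boundary=[0, 1, 2, 3])
        c2 = make_cell(2, boundary=[1, 4, 5, 2])
        cg = CellGraph(cells=[c1, c2], edges=[(1, 2)])
        cost = mitosis_cost(parent, c1, c2, cg, pos, w)
        assert cost == pytest.approx(w.mitosis, abs=1e-9)

    def test_boundary_cost_zero_on_boundary_and_proportional(self):
        w = TrackerWeights()
        on_edge = make_cell(0, x=0.0, y=15.0)
        enter, leave = boundary_costs(on_edge, SQUARE_BOUNDARY, w)
        assert enter == pytest.approx(0.0) and leave == pytest.approx(0.0)
        near = make_cell(1, x=2.0, y=15.0)
        far = make_cell(2, x=4.0, y=15.0)
        e1, _ = boundary_costs(near, SQUARE_BOUNDARY, w)
        e2, _ = boundary_costs(far, SQUARE_BOUNDARY, w)
        assert e2 == pytest.approx(2 * e1)

    def test_boundary_distance_matches_brute_force(self, rng):
        poly = rng.uniform(0, 20, size=(12, 3))
        for _ in range(20):
            p = rng.uniform(-5, 25, size=3)
            dists = []
            k = len(poly)
            for i in range(k):
                a, c = poly[i], poly[(i + 1) % k]
                for t in np.linspace(0, 1, 2001):
                    dists.append(np.linalg.norm(p - (a + t * (c - a))))
            assert distance_to_boundary(p, poly) == pytest.approx(min(dists), abs=1e-3)

    def test_apoptosis_cost_proportional_to_area(self):
        w = TrackerWeights()
        assert apoptosis_cost(make_cell(0, area=0.0), w) == 0.0
        c1 = apoptosis_cost(make_cell(0, area=5.0), w)
        c2 = apoptosis_cost(make_cell(0, area=10.0), w)
        assert c2 == pytest.approx(2 * c1)


class TestSolve:
    def _net(self, cells_t, cells_t1, edges_t1=(), gating=100.0):
        cg = CellGraph(cells=cells_t1, edges=list(edges_t1))
        return build_flow_network(cells_t, cells_t1, cg, np.zeros((3, 3)),
                                  SQUARE_BOUNDARY, SQUARE_BOUNDARY, TrackerWeights(),
                                  gating_radius=gating)

    def test_single_stationary_cell_associated(self):
        net = self._net([make_cell(0, x=15, y=15)], [make_cell(1, x=15, y=15)])
        sol = solve_min_cost_flow(net)
        assert [h.kind for h in sol] == ["association"]

    def test_two_stationary_cells_identity_matching(self):
        ct = [make_cell(0, x=10, y=10), make_cell(1, x=20, y=20)]
        c1 = [make_cell(10, x=10, y=10), make_cell(11, x=20, y=20)]
        sol = solve_min_cost_flow(self._net(ct, c1))
        pairs = {(h.source, h.targets[0]) for h in sol if h.kind == "association"}
        assert pairs == {(0, 10), (1, 11)}

    def test_empty_frame_rejected(self):
        with pytest.raises(ValueError):
            self._net([], [make_cell(0)])

    def test_matches_brute_force_on_random_instances(self, rng):
        """Exhaustive-enumeration oracle, <= 6 cells per frame."""
        for trial in range(100):
            n = int(rng.integers(1, 7))
            m = int(rng.integers(1, 7))
            ct = [make_cell(i, *rng.uniform(5, 25, 2), area=rng.uniform(5, 20)) for i in range(n)]
            c1 = [make_cell(100 + j, *rng.uniform(5, 25, 2), area=rng.uniform(5, 20))
                  for j in range(m)]
            edges = [(100 + a, 100 + b) for a in range(m) for b in range(a + 1, m)
                     if rng.uniform() < 0.4]
            net = self._net(ct, c1, edges)
            for a in ct:  # synthetic mitosis costs (fake polygons cannot merge)
                for j, k in edges:
                    net.hypotheses.append(
                        Hypothesis("mitosis", a.id, (j, k), float(rng.uniform(0, 10)))
                    )
            sol = solve_min_cost_flow(net)
            assert sum(h.cost for h in sol) == pytest.approx(brute_force_optimum(net), abs=1e-6)

    def test_conservation_identities(self, rng):
        for trial in range(20):
            n = int(rng.integers(1, 7))
            m = int(rng.integers(1, 7))
            ct = [make_cell(i, *rng.uniform(5, 25, 2)) for i in range(n)]
            c1 = [make_cell(100 + j, *rng.uniform(5, 25, 2)) for j in range(m)]
            sol = solve_min_cost_flow(self._net(ct, c1))
            kinds = [h.kind for h in sol]
            n_exp = sum(kinds.count(k) for k in ("association", "leave", "apoptosis", "mitosis"))
            m_exp = kinds.count("association") + kinds.count("enter") + 2 * kinds.count("mitosis")
            assert n_exp == n and m_exp == m

    def test_symmetric_ties_resolved_deterministically(self):
        ct = [make_cell(0, x=14, y=15), make_cell(1, x=16, y=15)]
        c1 = [make_cell(10, x=14, y=15), make_cell(11, x=16, y=15)]
        sols = [solve_min_cost_flow(self._net(ct, c1)) for _ in range(3)]
        keys = [{(h.kind, h.source, h.targets) for h in s} for s in sols]
        assert keys[0] == keys[1] == keys[2]

    def test_inflating_hypothesis_weight_removes_event_kind(self):
        """Sending one hypothesis family's weight to infinity drops it."""
        # an interior, tiny cell with no counterpart: apoptosis is cheapest
        ct = [make_cell(0, x=15, y=15), make_cell(1, x=16.5, y=15, area=0.5)]
        c1 = [make_cell(10, x=15, y=15)]

        def kinds(weights):
            net = build_flow_network(ct, c1, CellGraph(cells=c1, edges=[]),
                                     np.zeros((3, 3)), SQUARE_BOUNDARY, SQUARE_BOUNDARY,
                                     weights, gating_radius=100.0)
            return [h.kind for h in solve_min_cost_flow(net)]

        assert "apoptosis" in kinds(TrackerWeights())
        assert "apoptosis" not in kinds(TrackerWeights(apoptosis=1e9))


class TestLinkTracks:
    def test_three_frames_no_events(self):
        sols = [
            [Hypothesis("association", 0, (0,), 0), Hypothesis("association", 1, (1,), 0)],
            [Hypothesis("association", 0, (0,), 0), Hypothesis("association", 1, (1,), 0)],
        ]
        tracks = link_tracks(sols, [[0, 1]] * 3)
        assert len(tracks) == 2
        assert all(len(t.steps) == 3 for t in tracks)

    def test_mitosis_lineage_recorded(self):
        sols = [
            [Hypothesis("association", 0, (0,), 0)],
            [Hypothesis("mitosis", 0, (5, 6), 0)],
        ]
        tracks = link_tracks(sols, [[0], [0], [5, 6]])
        parent = tracks[0]
        assert parent.terminal == "mitosis" and len(parent.steps) == 2
        children = [t for t in tracks if t.origin == "mitosis-child"]
        assert len(children) == 2
        assert all(c.parent_track == parent.track_id for c in children)

    def test_double_claim_rejected(self):
        sols = [[Hypothesis("association", 0, (0,), 0), Hypothesis("apoptosis", 0, (), 0),
                 Hypothesis("enter", None, (1,), 0)]]
        with pytest.raises(ValueError, match="claimed twice"):
            link_tracks(sols, [[0], [0, 1]])

    def test_event_recovery_on_standard_sequence(self, standard_sequence, standard_cells):
        """Full tracking of the simulated tissue recovers every event."""
        per_frame, boundaries = standard_cells
        sols = []
        for t in range(len(per_frame) - 1):
            ct, _, _ = per_frame[t]
            c1, cg1, p1 = per_frame[t + 1]
            net = build_flow_network(ct, c1, cg1, p1, boundaries[t], boundaries[t + 1],
                                     TrackerWeights())
            sols.append(solve_min_cost_flow(net))
        tracks = link_tracks(sols, [[c.id for c in pf[0]] for pf in per_frame])
        n_mit = sum(1 for t in tracks if t.terminal == "mitosis")
        n_apo = sum(1 for t in tracks if t.terminal == "apoptosis")
        true_mit = sum(1 for e in standard_sequence.events if e["kind"] == "mitosis")
        true_apo = sum(1 for e in standard_sequence.events if e["kind"] == "apoptosis")
        assert n_mit == true_mit and n_apo == true_apo
        # partition property: every cell of every frame in exactly one track
        for fr, (cells, _, _) in enumerate(per_frame):
            claimed = [cid for t in tracks for (f, cid) in t.steps if f == fr]
            assert sorted(claimed) == sorted(c.id for c in cells)
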