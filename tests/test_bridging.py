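import itertools
import math

import numpy as np
import pytest

from ionphase import bridging, fixtures
from ionphase.cgmd import Configuration


def brute_force_bridges(snapshot, cutoff=11.0):
    """Independent triple-loop oracle for putative-bridge enumeration."""
    box = np.asarray(snapshot.box)

    def dist(i, j):
        d = snapshot.coords[i] - snapshot.coords[j]
        d -= box * np.round(d / box)
        return float(np.linalg.norm(d))

    args = [i for i, s in enumerate(snapshot.species) if s == "R"]
    cls = [i for i, s in enumerate(snapshot.species) if s == "CL"]
    found = set()
    for cl in cls:
        for a, b in itertools.combinations(args, 2):
            if snapshot.chain_ids[a] == snapshot.chain_ids[b]:
                continue
            if dist(cl, a) <= cutoff and dist(cl, b) <= cutoff:
                found.add((min(a, b), max(a, b), cl))
    return found


def manual_snapshot(positions, box=(200.0, 200.0, 200.0)):
    """positions: list of (species, chain, xyz)."""
    return Configuration(
        coords=np.array([p[2] for p in positions], dtype=float),
        species=[p[0] for p in positions],
        chain_ids=[p[1] for p in positions], box=box)


class TestReadWrite:
    def test_round_trip(self, tmp_path):
        snap = fixtures.ideal_gas_snapshot(20, (30, 30, 30), seed=3)
        path = tmp_path / "t.xyz"
        bridging.write_snapshots(path, [snap, snap])
        frames = bridging.read_snapshots(path)
        assert len(frames) == 2
        np.testing.assert_allclose(frames[0].coords, snap.coords, atol=1e-6)
        assert frames[0].species == snap.species
        assert frames[0].chain_ids == snap.chain_ids
        assert frames[0].box == pytest.approx(snap.box)

    def test_missing_box_errors(self, tmp_path):
        path = tmp_path / "bad.xyz"
        path.write_text("1\nno box here\nX 0 0 0 -1\n")
        with pytest.raises(ValueError, match="Lattice"):
            bridging.read_snapshots(path)

    def test_missing_chain_column_errors(self, tmp_path):
        path = tmp_path / "bad.xyz"
        path.write_text('1\nLattice="9 0 0 0 9 0 0 0 9"\nX 0 0 0\n')
        with pytest.raises(ValueError, match="chain"):
            bridging.read_snapshots(path)


class TestRdf:
    def test_ideal_gas_flat(self):
        snaps = [fixtures.ideal_gas_snapshot(500, (40, 40, 40), seed=s)
                 for s in range(8)]
        r, rho = bridging.rdf(snaps, "X", "X", dr=2.0, rmax=15.0)
        bulk = 500 / 40**3
        inner = rho[2:]  # small-r shells are noisy (few pairs)
        assert np.all(np.abs(inner - bulk) < 5 * bulk / 10)

    def test_planted_pair_single_bin(self):
        snap = manual_snapshot([("R", 0, (10, 10, 10)),
                                ("CL", -1, (17.3, 10, 10))])
        r, rho = bridging.rdf([snap], "R", "CL", dr=1.0, rmax=12.0)
        nz = np.nonzero(rho)[0]
        assert list(nz) == [7]  # 7.3 falls in bin [7, 8)

    def test_pair_count_conservation(self):
        # total bin counts equal the brute-force number of pairs in range
        snap = fixtures.ideal_gas_snapshot(60, (25, 25, 25), seed=9)
        rmax = 10.0
        r, rho = bridging.rdf([snap], "X", "X", dr=0.5, rmax=rmax)
        shell = 4 / 3 * np.pi * ((r + 0.25) ** 3 - (r - 0.25) ** 3)
        total = np.sum(rho * shell) * 60  # times n_centers
        box = np.asarray(snap.box)
        d = snap.coords[:, None, :] - snap.coords[None, :, :]
        d -= box * np.round(d / box)
        rr = np.linalg.norm(d, axis=-1)
        n_pairs = np.sum((rr > 1e-9) & (rr < rmax))
        assert total == pytest.approx(n_pairs)

    def test_empty_selection_errors(self):
        snap = fixtures.ideal_gas_snapshot(5, (20, 20, 20), seed=0)
        with pytest.raises(ValueError, match="empty species"):
            bridging.rdf([snap], "R", "CL")


class TestFractionWithin:
    def test_all_on_sites(self):
        pos = [("R", 0, (5, 5, 5)), ("CL", -1, (5.1, 5, 5)),
               ("R", 1, (30, 30, 30)), ("CL", -1, (30, 30.2, 30))]
        assert bridging.fraction_within([manual_snapshot(pos)]) == 1.0

    def test_none_in_range(self):
        pos = [("R", 0, (5, 5, 5)), ("CL", -1, (50, 50, 50))]
        assert bridging.fraction_within([manual_snapshot(pos)]) == 0.0

    def test_hand_counted_fraction(self):
        # 50 ion-frame instances, 37 within range by construction
        pos = [("R", 0, (100.0, 100.0, 100.0))]
        for i in range(37):
            pos.append(("CL", -1, (100.0 + 10.0 * math.cos(i),
                                   100.0 + 10.0 * math.sin(i), 100.0)))
        for i in range(13):
            pos.append(("CL", -1, (30.0 + 3.0 * i, 20.0, 15.0)))
        snap = manual_snapshot(pos, box=(300.0, 300.0, 300.0))
        assert bridging.fraction_within([snap], cutoff=11.0) == pytest.approx(
            37 / 50)


class TestEnumerate:
    def test_four_args_four_chains_gives_six(self):
        pos = [("CL", -1, (50.0, 50.0, 50.0))]
        for c in range(4):
            ang = 2 * np.pi * c / 4
            pos.append(("R", c, (50 + 8 * np.cos(ang), 50 + 8 * np.sin(ang),
                                 50.0)))
        configs = bridging.enumerate_putative_bridges(manual_snapshot(pos))
        assert len(configs) == 6

    def test_same_chain_excluded(self):
        pos = [("CL", -1, (50.0, 50.0, 50.0)),
               ("R", 0, (55.0, 50.0, 50.0)), ("R", 0, (45.0, 50.0, 50.0))]
        assert bridging.enumerate_putative_bridges(manual_snapshot(pos)) == []

    def test_brute_force_equivalence_random(self):
        rng = fixtures.rng(42)
        pos = []
        for i in range(40):
            pos.append(("R", i % 6, tuple(rng.uniform(0, 60, 3))))
        for _ in range(15):
            pos.append(("CL", -1, tuple(rng.uniform(0, 60, 3))))
        snap = manual_snapshot(pos, box=(60.0, 60.0, 60.0))
        configs = bridging.enumerate_putative_bridges(snap)
        got = {(min(c.arg_a, c.arg_b), max(c.arg_a, c.arg_b), c.cl)
               for c in configs}
        assert got == brute_force_bridges(snap)

    def test_geometry_invariants(self):
        rng = fixtures.rng(7)
        pos = [("R", i % 5, tuple(rng.uniform(0, 50, 3))) for i in range(30)]
        pos += [("CL", -1, tuple(rng.uniform(0, 50, 3))) for _ in range(10)]
        snap = manual_snapshot(pos, box=(50.0, 50.0, 50.0))
        for c in bridging.enumerate_putative_bridges(snap):
            assert c.d_near <= c.d_far <= 11.0
            assert c.R <= 22.0
            assert 0.0 <= c.d <= c.d_near + 1e-9


class TestClassify:
    def test_midpoint_is_true(self):
        # R = 9 (bin [8, 10)), Cl at midpoint: d_far = 4.5 < 8
        pos = [("R", 0, (50.0, 50, 50)), ("R", 1, (59.0, 50, 50)),
               ("CL", -1, (54.5, 50, 50))]
        labeled, counts = bridging.classify(
            bridging.enumerate_putative_bridges(manual_snapshot(pos)))
        assert counts == {"true": 1, "neutralizing": 0, "intermediate": 0}

    def test_collinear_beyond_is_neutralizing(self):
        # R = 5 (bin [4, 6)), Cl beyond one Arg: d_far = 8 >= 6
        pos = [("R", 0, (50.0, 50, 50)), ("R", 1, (55.0, 50, 50)),
               ("CL", -1, (47.0, 50, 50))]
        labeled, counts = bridging.classify(
            bridging.enumerate_putative_bridges(manual_snapshot(pos)))
        assert counts["neutralizing"] == 1

    def test_coulomb_sum_oracle_equivalence(self):
        # geometric rule == sign of (1/R - 1/d_far) at both bin edges
        rng = fixtures.rng(11)
        pos = [("R", i, tuple(rng.uniform(20, 45, 3))) for i in range(12)]
        pos += [("CL", -1, tuple(rng.uniform(20, 45, 3))) for _ in range(12)]
        snap = manual_snapshot(pos, box=(120.0, 120.0, 120.0))
        labeled, _ = bridging.classify(
            bridging.enumerate_putative_bridges(snap))
        assert labeled  # fixture dense enough to generate configurations
        for c in labeled:
            lo = math.floor(c.R / 2.0) * 2.0
            hi = lo + 2.0
            # Coulomb sum (units drop out): 1/R - 1/d_far, R in {lo, hi}
            neg_at_lo = 1.0 / lo - 1.0 / c.d_far < 0 if lo > 0 else False
            neg_at_hi = 1.0 / hi - 1.0 / c.d_far < 0
            if neg_at_lo and neg_at_hi:
                assert c.label == "true"
            elif not neg_at_lo and not neg_at_hi:
                assert c.label == "neutralizing"
            else:
                assert c.label == "intermediate"


class TestPerIonStatistics:
    def test_paper_probability_identity(self):
        assert bridging.p_at_least_one_true(0.8, 5) == pytest.approx(0.99968)

    def test_degenerate_probabilities(self):
        assert bridging.p_at_least_one_true(0.0, 7) == 0.0
        assert bridging.p_at_least_one_true(1.0, 1) == 1.0

    def test_zero_bridging(self):
        stats = bridging.per_ion_statistics([], n_frames=4, n_ions=10)
        assert stats["fraction_bridging"] == 0.0
        assert stats["p_true"] is None

    def test_counting_convention(self):
        pos = [("CL", -1, (50.0, 50.0, 50.0))]
        for c in range(3):
            pos.append(("R", c, (50.0 + 6 + c, 50.0, 50.0)))
        snap = manual_snapshot(pos)
        labeled, _ = bridging.classify(
            bridging.enumerate_putative_bridges(snap))
        stats = bridging.per_ion_statistics(labeled, n_frames=2, n_ions=5)
        # one bridging ion in one frame out of 2 x 5 instances
        assert stats["fraction_bridging"] == pytest.approx(1 / 10)
        assert stats["mean_configs_per_bridging_ion"] == pytest.approx(3.0)
        assert 0.0 <= stats["p_true"] <= 1.0
        assert 0.0 <= stats["p_at_least_one_true"] <= 1.0


class TestHeatmap:
    def test_symmetry_exact(self):
        rng = fixtures.rng(5)
        pos = [("R", i, tuple(rng.uniform(10, 40, 3))) for i in range(10)]
        pos += [("CL", -1, tuple(rng.uniform(10, 40, 3))) for _ in range(8)]
        snap = manual_snapshot(pos, box=(100.0, 100.0, 100.0))
        configs = bridging.enumerate_putative_bridges(snap)
        hm = bridging.heatmap(configs)
        mid = (len(hm.d_edges) - 1) // 2
        upper = hm.P[:, mid:]
        lower = hm.P[:, :mid][:, ::-1]
        np.testing.assert_allclose(upper, lower)

    def test_total_mass(self):
        pos = [("R", 0, (50.0, 50, 50)), ("R", 1, (58.0, 50, 50)),
               ("CL", -1, (54.0, 52.5, 50))]
        configs = bridging.enumerate_putative_bridges(manual_snapshot(pos))
        hm = bridging.heatmap(configs)
        assert hm.P.sum() == pytest.approx(len(configs))

    def test_single_config_occupied_cells(self):
        pos = [("R", 0, (50.0, 50, 50)), ("R", 1, (58.0, 50, 50)),
               ("CL", -1, (52.0, 53.0, 50))]  # x=2, d=3; mirror x=6
        configs = bridging.enumerate_putative_bridges(manual_snapshot(pos))
        hm = bridging.heatmap(configs, cell=1.0)
        occupied = np.argwhere(hm.P > 0)
        assert len(occupied) == 4  # (x, +-d) and (R-x, +-d)


class TestIsolatedThreeBead:
    def test_high_temperature_uniform(self):
        hm = bridging.isolated_three_bead(R=6.0, T=1e7, cell=1.0)
        # Boltzmann weight flat outside the repulsive cores: pick the
        # d in [7, 8) ring, fully inside the cutoff for x in [0, 6]
        mid = (len(hm.d_edges) - 1) // 2
        row = hm.P[:, mid + 7]
        x_centers = 0.5 * (hm.x_edges[:-1] + hm.x_edges[1:])
        inside = row[(x_centers > 0) & (x_centers < 6)]
        assert len(inside) >= 5
        assert inside.std() / inside.mean() < 0.02

    def test_x_mirror_symmetry(self):
        hm = bridging.isolated_three_bead(R=8.0, T=160.0, cell=0.5)
        # the two arginines are equivalent: argmax pair symmetric about R/2
        mid = (len(hm.d_edges) - 1) // 2
        p = hm.P
        x_centers = 0.5 * (hm.x_edges[:-1] + hm.x_edges[1:])
        com_x = float((p.sum(axis=1) * x_centers).sum() / p.sum())
        assert com_x == pytest.approx(4.0, abs=0.1)

    def test_low_temperature_contact_peak_refinement_oracle(self):
        coarse = bridging.isolated_three_bead(R=10.0, T=120.0, cell=0.5,
                                              oversample=6)
        fine = bridging.isolated_three_bead(R=10.0, T=120.0, cell=0.5,
                                            oversample=12)
        # doubled quadrature resolution must give the same peak cell
        assert coarse.peak_cell() == fine.peak_cell()
        # density maximum sits at contact distance from an arginine
        ix, id_ = coarse.peak_cell()
        x = 0.5 * (coarse.x_edges[ix] + coarse.x_edges[ix + 1])
        d = 0.5 * (coarse.d_edges[id_] + coarse.d_edges[id_ + 1])
        r_near = min(math.hypot(x, d), math.hypot(x - 10.0, d))
        sigma = 5.48
        assert r_near == pytest.approx(2 ** (1 / 6) * sigma * 0.95, rel=0.2)


class TestPlantedFixture:
    def test_planted_classes_recovered(self):
        planted = [(8.0, 2.0, "true"), (8.5, 1.0, "true"), (9.0, 0.5, "true"),
                   (5.0, 0.0, "collinear"), (4.5, 0.0, "collinear")]
        # build custom: three midpoint bridges (true) and two collinear
        # beyond-arg placements (neutralizing)
        snap_cfgs = [(8.0, 2.0, "x"), (8.5, 1.0, "x"), (9.0, 0.5, "x")]
        snap = fixtures.planted_bridges_snapshot(snap_cfgs, seed=1)
        configs = bridging.enumerate_putative_bridges(snap)
        labeled, counts = bridging.classify(configs)
        assert len(configs) == 3
        assert counts["true"] == 3

    def test_plant_none(self):
        snap = fixtures.planted_bridges_snapshot([], seed=0)
        assert bridging.enumerate_putative_bridges(snap) == []

    def test_seeded_reproducibility(self):
        a = fixtures.planted_bridges_snapshot([(8.0, 2.0, "x")], seed=5)
        b = fixtures.planted_bridges_snapshot([(8.0, 2.0, "x")], seed=5)
        np.testing.assert_array_equal(a.coords, b.coords)
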