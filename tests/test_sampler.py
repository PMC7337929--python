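import numpy as np
import pytest

from conftest import brute_force_viable
from pktopo.config import FULL_PROFILE, REDUCED_PROFILE, RunConfig
from pktopo.geometry import make_transform
from pktopo.motifs import parse_size_string
from pktopo.sampler import (MBB, build_grid, check_config_viability,
                            compute_mbb, count_pk,
                            enumerate_loop_conformations, loop_reach,
                            loop_viable, sample_kiss)

CFG = RunConfig()


class TestLoopClosure:
    def test_zero_nt_within_one_bond_reach(self):
        start = np.zeros(3)
        end = np.array([CFG.bond_length + CFG.closure_tol - 0.1, 0, 0])
        assert loop_viable(0, start, None, end, None, CFG)

    def test_zero_nt_beyond_reach(self):
        end = np.array([CFG.bond_length + CFG.closure_tol + 0.1, 0, 0])
        assert not loop_viable(0, np.zeros(3), None, end, None, CFG)

    def test_reach_bound_is_exact(self):
        """No n-nt loop ever closes across a gap beyond (2n+1) bonds plus
        the closure tolerance, however the gap is oriented."""
        rng = np.random.default_rng(11)
        for _ in range(200):
            n = int(rng.integers(0, 3))
            start = rng.normal(size=3) * 3
            prev = start + rng.normal(size=3)
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            end = start + u * (loop_reach(n, CFG) + rng.uniform(0.01, 5))
            assert not loop_viable(n, start, prev, end, None, CFG)

    def test_chain_geometry_of_accepted_conformations(self):
        start = np.zeros(3)
        prev = np.array([0.0, 0.0, -CFG.bond_length])
        end = np.array([8.0, 3.0, 2.0])
        ctx = np.array([[20.0, 20.0, 20.0]])
        got = 0
        for beads in enumerate_loop_conformations(2, start, prev, end, ctx,
                                                  CFG):
            got += 1
            steps = np.vstack([beads[0] - start,
                               np.diff(beads, axis=0)])
            assert np.allclose(np.linalg.norm(steps, axis=1),
                               CFG.bond_length, atol=1e-9)
            assert np.linalg.norm(beads[-1] - end) <= (CFG.bond_length
                                                       + CFG.closure_tol)
            if got > 20:
                break
        assert got > 0

    def test_pruning_matches_brute_force_oracle(self):
        """Pruned viability answers equal an unpruned full enumeration on
        random small instances, with and without context beads."""
        rng = np.random.default_rng(42)
        agree = 0
        for trial in range(200):
            n = 1 if trial % 2 else 0
            start = rng.normal(size=3) * 3
            prev = start + rng.normal(size=3)
            end = start + rng.normal(size=3) * rng.uniform(0, 14)
            ctx = (rng.normal(size=(4, 3)) * 6) if trial % 3 == 0 else None
            v = loop_viable(n, start, prev, end, ctx, CFG)
            assert v == brute_force_viable(n, start, prev, end, ctx, CFG)
            agree += 1
        assert agree == 200

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            loop_viable(-1, np.zeros(3), None, np.zeros(3), None, CFG)


class TestMBB:
    def test_adaptive_spacing(self):
        cfg = REDUCED_PROFILE.with_(grid_coarsen=1.0)
        assert compute_mbb(5, 1, 7, cfg).grid_spacing == 2.0
        assert compute_mbb(5, 3, 7, cfg).grid_spacing == 4.0

    def test_grid_count_cubic_box(self):
        mbb = MBB(center=np.zeros(3), half_extents=np.full(3, 24.0),
                  grid_spacing=3.0)
        assert mbb.T == 17 ** 3 == 4913

    def test_zero_loop_box_bounded_by_reach(self):
        cfg = REDUCED_PROFILE.with_(grid_coarsen=1.0)
        mbb = compute_mbb(3, 0, 3, cfg)
        # anchor offsets never exceed one bead radial distance (plus the
        # half-rise axial offset of a P bead)
        r_anchor = max(cfg.c4_radius, cfg.p_radius) + cfg.rise
        assert np.all(mbb.half_extents
                      <= loop_reach(0, cfg) + 2 * r_anchor)
        assert mbb.grid_spacing == 1.0

    def test_grid_covers_box(self):
        mbb = compute_mbb(4, 2, 4, REDUCED_PROFILE)
        pts = mbb.grid_points
        assert len(pts) == mbb.T
        # the translation grid spans the padded box on every axis, so no
        # boundary-viable configuration is clipped
        for ax, coords in enumerate(mbb.axis_points):
            assert coords[0] <= -(mbb.half_extents[ax])
            assert coords[-1] >= mbb.half_extents[ax]

    def test_full_profile_rotation_count(self):
        grid = build_grid(3, 0, 3, FULL_PROFILE)
        assert grid.R == 1800
        assert grid.N_tot == grid.R * grid.T


@pytest.fixture(scope="module")
def symmetric_counts(tiny_cfg):
    return count_pk(parse_size_string("3-1-1-1-3"), config=tiny_cfg)


class TestCountPK:

    def test_subset_monotonicity(self, symmetric_counts):
        c = symmetric_counts.subset_counts
        assert c["123"] <= c["12"] <= c["2"]
        assert c["123"] <= c["23"] <= c["2"]
        assert 0 < c["2"] <= symmetric_counts.n_total

    def test_enumeration_order_invariance(self, tiny_cfg):
        spec = parse_size_string("3-0-1-2-3")
        grid = build_grid(3, 1, 3, tiny_cfg)
        fwd = count_pk(spec, grid=grid, config=tiny_cfg)
        import copy
        rev = copy.copy(grid)
        rev.axes = list(reversed(grid.axes))
        bwd = count_pk(spec, grid=rev, config=tiny_cfg)
        assert fwd.subset_counts == bwd.subset_counts

    def test_unreachable_l1_gives_zero_n12(self, micro_cfg):
        """With L1 = 0 and 14-bp helices the two H2 anchor beads sit
        farther apart (39.7 A) than both zero-length linkers can bridge
        around H1's anchor pair (17.8 + 2 x 7.8 A), so by the triangle
        inequality no configuration can close L1 and L2 together."""
        vc = count_pk(parse_size_string("14-0-0-1-14"), config=micro_cfg)
        assert vc.subset_counts["2"] > 0
        assert vc.subset_counts["12"] == 0
        assert vc.subset_counts["123"] == 0

    def test_long_loops_barely_constrain(self, micro_cfg):
        vc = count_pk(parse_size_string("3-9-9-9-3"), config=micro_cfg)
        assert vc.subset_counts["2"] > 0
        assert vc.subset_counts["123"] / vc.subset_counts["2"] > 0.5

    def test_records_round_trip_with_flags(self, tiny_cfg):
        vc = count_pk(parse_size_string("3-1-1-1-3"), config=tiny_cfg,
                      record=True)
        assert len(vc.records) == vc.subset_counts["2"]
        n123 = sum(r["ok123"] for r in vc.records)
        assert n123 == vc.subset_counts["123"]

    def test_wrong_motif_type_rejected(self, tiny_cfg):
        with pytest.raises(ValueError):
            count_pk(parse_size_string("(3-3-3)-(1-1-1-1-1-2)"),
                     config=tiny_cfg)


class TestSampleKISS:
    def test_bit_reproducible_for_fixed_seed(self, tiny_cfg):
        spec = parse_size_string("(3-3-3)-(2-5-1-5-2-6)")
        a = sample_kiss(spec, n_samples=1500, seed=7, config=tiny_cfg)
        b = sample_kiss(spec, n_samples=1500, seed=7, config=tiny_cfg)
        assert a.subset_counts == b.subset_counts

    def test_subset_monotonicity(self, tiny_cfg):
        spec = parse_size_string("(3-3-3)-(2-5-1-5-2-6)")
        vc = sample_kiss(spec, n_samples=4000, seed=3, config=tiny_cfg)
        c = vc.subset_counts
        top = min(c["124"], c["234"], c["245"], c["246"])
        assert c["123456"] <= top <= c["24"] <= vc.n_total

    def test_hopeless_geometry_counts_zero(self, tiny_cfg):
        """Zero-length kissing linkers on long helices close essentially
        nowhere in the sampled grids (deterministic at this seed)."""
        spec = parse_size_string("(7-2-7)-(0-0-9-0-0-2)")
        vc = sample_kiss(spec, n_samples=300, seed=5, config=tiny_cfg)
        assert all(v == 0 for v in vc.subset_counts.values())

    def test_sample_count_validation(self, tiny_cfg):
        spec = parse_size_string("(3-3-3)-(2-5-1-5-2-6)")
        with pytest.raises(ValueError):
            sample_kiss(spec, n_samples=0, seed=1, config=tiny_cfg)


class TestCheckConfigViability:
    def test_empty_subset_vacuous(self, tiny_cfg):
        spec = parse_size_string("3-1-1-1-3")
        t = make_transform(0, 0, 0, (0, 0, 20))
        assert check_config_viability(t, spec, [], config=tiny_cfg)

    def test_unknown_label_rejected(self, tiny_cfg):
        spec = parse_size_string("3-1-1-1-3")
        t = make_transform(0, 0, 0, (0, 0, 20))
        with pytest.raises(ValueError, match="loop label"):
            check_config_viability(t, spec, ["9"], config=tiny_cfg)

    def test_pair_subset_is_conjunction_of_singles(self, tiny_cfg):
        """In independent mode {L1, L3} viability equals
        viability(L1) AND viability(L3)."""
        spec = parse_size_string("3-2-1-2-3")
        rng = np.random.default_rng(17)
        checked = 0
        for _ in range(40):
            t = make_transform(rng.uniform(0, np.pi),
                               rng.uniform(0, 2 * np.pi),
                               rng.uniform(0, 2 * np.pi),
                               rng.normal(size=3) * 12)
            v1 = check_config_viability(t, spec, ["1"], config=tiny_cfg)
            v3 = check_config_viability(t, spec, ["3"], config=tiny_cfg)
            v13 = check_config_viability(t, spec, ["1", "3"],
                                         config=tiny_cfg)
            assert v13 == (v1 and v3)
            checked += v1 or v3
        assert checked > 0

    def test_strict_mode_never_more_permissive(self, tiny_cfg):
        spec = parse_size_string("3-2-1-2-3")
        strict_cfg = tiny_cfg.with_(loop_loop_exclusion=True)
        rng = np.random.default_rng(23)
        for _ in range(20):
            t = make_transform(rng.uniform(0, np.pi),
                               rng.uniform(0, 2 * np.pi),
                               rng.uniform(0, 2 * np.pi),
                               rng.normal(size=3) * 10)
            strict = check_config_viability(t, spec, ["1", "2", "3"],
                                            config=strict_cfg)
            indep = check_config_viability(t, spec, ["1", "2", "3"],
                                           config=tiny_cfg)
            assert not (strict and not indep)
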