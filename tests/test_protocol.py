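import numpy as np
import pytest

from emassemble.gvm import GvmConfig
from emassemble.protocol import (RecombinationScheme, StagePlan, StructurePool,
                                 assembly_stage, gap_selection, pre_assembly_stage,
                                 prepare_em_setup, random_starts, recombine,
                                 ring_topology_starts, scoring_stage)
from emassemble.restraints import build_cx_restraints
from emassemble.structures import Assembly, RigidPose
from emassemble.synthetic import (RingSpec, ToySpec, make_benchmark_case,
                                  make_protocol_config, make_toy_assembly)


@pytest.fixture(scope="module")
def ring_case():
    spec = ToySpec(rings=(RingSpec(count=7, radius=28.0, z=0.0),),
                   beads_per_subunit=20, seed=0)
    return spec, make_benchmark_case(spec, resolutions=(40.0, 20.0))


class TestRandomStarts:
    def test_seed_reproducibility_and_divergence(self, ring_case):
        _, case = ring_case
        comps = [case.subunit] * 3
        box = (-np.full(3, 50.0), np.full(3, 50.0))
        p1 = random_starts(comps, 4, box, seed=1)
        p2 = random_starts(comps, 4, box, seed=1)
        np.testing.assert_array_equal(p1.assemblies[0].coordinates(),
                                      p2.assemblies[0].coordinates())
        p3 = random_starts(comps, 4, box, seed=2)
        assert not np.array_equal(p1.assemblies[0].coordinates(),
                                  p3.assemblies[0].coordinates())

    def test_positions_inside_box(self, ring_case):
        _, case = ring_case
        box = (np.array([-10.0, -20.0, 0.0]), np.array([10.0, 0.0, 30.0]))
        pool = random_starts([case.subunit], 50, box, seed=3)
        t = np.array([a.poses[0].translation for a in pool.assemblies])
        assert np.all(t >= box[0]) and np.all(t <= box[1])

    def test_orientation_uniformity(self, ring_case):
        """Mean of uniformly random rotation matrices tends to zero."""
        _, case = ring_case
        box = (-np.ones(3), np.ones(3))
        pool = random_starts([case.subunit], 2000, box, seed=4)
        mean_R = np.mean([a.poses[0].rotation for a in pool.assemblies], axis=0)
        assert np.abs(mean_R - np.trace(mean_R) / 3.0 * np.eye(3)).max() < 0.05

    def test_empty_box_rejected(self, ring_case):
        _, case = ring_case
        with pytest.raises(ValueError):
            random_starts([case.subunit], 1, (np.ones(3), np.ones(3)), seed=0)


class TestRingTopologyStarts:
    def test_exact_positional_symmetry(self, ring_case):
        _, case = ring_case
        pool = ring_topology_starts([case.subunit] * 7, [(0.0, 28.0, 12.0, 7)],
                                    5, seed=0)
        for asm in pool.assemblies:
            t = np.array([p.translation for p in asm.poses])
            radii = np.hypot(t[:, 0], t[:, 1])
            np.testing.assert_allclose(radii, radii[0], rtol=1e-9)
            np.testing.assert_allclose(t[:, 2], t[0, 2], atol=1e-9)
            ang = np.sort(np.arctan2(t[:, 1], t[:, 0]))
            gaps = np.diff(np.concatenate([ang, [ang[0] + 2 * np.pi]]))
            np.testing.assert_allclose(gaps, 2 * np.pi / 7, atol=1e-9)

    def test_radius_and_z_within_prior(self, ring_case):
        _, case = ring_case
        pool = ring_topology_starts([case.subunit] * 7, [(10.0, 35.0, 15.0, 7)],
                                    40, seed=1)
        for asm in pool.assemblies:
            t = np.array([p.translation for p in asm.poses])
            r = np.hypot(t[0, 0], t[0, 1])
            assert 20.0 <= r <= 50.0
            assert 5.0 <= t[0, 2] <= 15.0

    def test_seed_reproducibility(self, ring_case):
        _, case = ring_case
        a = ring_topology_starts([case.subunit] * 7, [(0.0, 28.0, 12.0, 7)], 3, 9)
        b = ring_topology_starts([case.subunit] * 7, [(0.0, 28.0, 12.0, 7)], 3, 9)
        np.testing.assert_array_equal(a.assemblies[2].coordinates(),
                                      b.assemblies[2].coordinates())

    def test_spec_mismatch_rejected(self, ring_case):
        _, case = ring_case
        with pytest.raises(ValueError):
            ring_topology_starts([case.subunit] * 6, [(0.0, 28.0, 12.0, 7)], 1, 0)


class TestStructurePool:
    def test_stable_sort_and_truncate(self, ring_case):
        _, case = ring_case
        pool = StructurePool()
        for i, e in enumerate([3.0, 1.0, 2.0, 1.0]):
            pool.add(Assembly([case.subunit]), scores={"e": e, "tag": i})
        pool.sort_by("e")
        assert [s["tag"] for s in pool.scores] == [1, 3, 2, 0]  # ties keep order
        assert len(pool.truncate(2)) == 2


class TestPreAssembly:
    def test_descent_and_truncation(self, ring_case):
        spec, case = ring_case
        rset = build_cx_restraints(list(case.subunit.backbone_indices), 7)
        pool = ring_topology_starts([case.subunit] * 7, [(0.0, 28.0, 12.0, 7)],
                                    12, seed=2)
        from emassemble.restraints import symmetry_energy
        pre_med = np.median([symmetry_energy(a, rset)[0] for a in pool.assemblies])
        plan = StagePlan(n_starts=12, n_preassembly=8, n_scoring=4, n_refine=2,
                         preassembly_max_iter=40)
        out = pre_assembly_stage(pool, rset, plan, orientation_only=True)
        assert len(out) == 8
        post_med = np.median(out.score_array("symmetry"))
        assert post_med < pre_med
        # sorted ascending
        assert np.all(np.diff(out.score_array("symmetry")) >= 0)

    def test_exact_rings_pass_through(self, ring_case):
        spec, case = ring_case
        rset = build_cx_restraints(list(case.subunit.backbone_indices), 7)
        ref, _ = make_toy_assembly(spec)
        pool = StructurePool()
        pool.add(ref.copy())
        plan = StagePlan(n_starts=1, n_preassembly=1, n_scoring=1, n_refine=1)
        out = pre_assembly_stage(pool, rset, plan, orientation_only=True)
        assert out.score_array("symmetry")[0] == pytest.approx(0.0, abs=1e-9)


class TestAssemblyAndScoring:
    def test_assembly_sorts_and_scoring_truncates(self, ring_case):
        spec, case = ring_case
        rset = build_cx_restraints(list(case.subunit.backbone_indices), 7)
        plan = StagePlan(n_starts=6, n_preassembly=6, n_scoring=3, n_refine=2,
                         assembly_max_iter=30)
        pool = ring_topology_starts([case.subunit] * 7, [(0.0, 28.0, 12.0, 7)],
                                    6, seed=5)
        setup = prepare_em_setup([case.subunit] * 7, case.coarse_map, 40.0,
                                 F=case.F_by_res[40.0],
                                 cap_atoms=1.25 * case.cap_atoms[40.0])
        out = assembly_stage(pool, setup, rset, plan)
        assert len(out) == 6 and out.n_dropped == 0
        e = out.score_array("assembly_total")
        assert np.all(np.diff(e) >= 0) and np.all(np.isfinite(e))
        cfg = GvmConfig(model_scale=case.gvm_model_scale)
        scored = scoring_stage(out, case.fine_map, cfg, plan)
        assert len(scored) == 3
        assert np.all(np.diff(scored.score_array("gvm")) >= 0)

    def test_order_independence(self, ring_case):
        """Per-structure minimization is independent of pool order."""
        spec, case = ring_case
        rset = build_cx_restraints(list(case.subunit.backbone_indices), 7)
        plan = StagePlan(n_starts=3, n_preassembly=3, n_scoring=2, n_refine=1,
                         assembly_max_iter=15)
        pool = ring_topology_starts([case.subunit] * 7, [(0.0, 28.0, 12.0, 7)],
                                    3, seed=6)
        setup = prepare_em_setup([case.subunit] * 7, case.coarse_map, 40.0,
                                 F=case.F_by_res[40.0],
                                 cap_atoms=1.25 * case.cap_atoms[40.0])
        out1 = assembly_stage(pool, setup, rset, plan)
        rev = StructurePool()
        for i in reversed(range(len(pool))):
            rev.add(pool.assemblies[i], dict(pool.scores[i]), dict(pool.provenance[i]))
        out2 = assembly_stage(rev, setup, rset, plan)
        np.testing.assert_allclose(np.sort(out1.score_array("assembly_total")),
                                   np.sort(out2.score_array("assembly_total")),
                                   rtol=1e-12)


class TestRecombination:
    def _pool_of(self, n, case):
        pool = StructurePool()
        rng = np.random.default_rng(0)
        for i in range(n):
            poses = [RigidPose(translation=rng.normal(size=3)) for _ in range(3)]
            pool.add(Assembly([case.subunit] * 3, poses), scores={"gvm": float(i)})
        return pool

    def test_paper_count_100_parents_2_patterns(self, ring_case):
        _, case = ring_case
        pool = self._pool_of(100, case)
        scheme = RecombinationScheme(blocks=[[0], [1], [2]], patterns=[[0], [2]])
        out = recombine(pool, scheme)
        # 100*99*2 = 19800 children + the 100 parents
        assert len(out) == 19800 + 100

    @pytest.mark.parametrize("P,m", [(2, 1), (5, 2), (10, 2)])
    def test_child_count_formula(self, ring_case, P, m):
        _, case = ring_case
        pool = self._pool_of(P, case)
        patterns = [[0], [2]][:m]
        scheme = RecombinationScheme(blocks=[[0], [1], [2]], patterns=patterns)
        out = recombine(pool, scheme)
        assert len(out) == P * (P - 1) * m + P

    def test_duplicate_children_removed(self, ring_case):
        _, case = ring_case
        pool = self._pool_of(2, case)
        # make both parents identical -> every child duplicates a parent
        pool.assemblies[1] = pool.assemblies[0].copy()
        scheme = RecombinationScheme(blocks=[[0], [1], [2]], patterns=[[0]])
        out = recombine(pool, scheme)
        assert len(out) == 2   # parents only

    def test_child_inherits_pattern_blocks(self, ring_case):
        _, case = ring_case
        pool = self._pool_of(2, case)
        scheme = RecombinationScheme(blocks=[[0], [1], [2]], patterns=[[2]])
        out = recombine(pool, scheme)
        child = out.assemblies[2]       # first child after the two parents
        i, j = out.provenance[2]["parents"]
        np.testing.assert_array_equal(child.poses[2].translation,
                                      pool.assemblies[j].poses[2].translation)
        np.testing.assert_array_equal(child.poses[0].translation,
                                      pool.assemblies[i].poses[0].translation)

    def test_invalid_scheme_rejected(self):
        with pytest.raises(ValueError):
            RecombinationScheme(blocks=[[0], [0, 1]], patterns=[[0]])
        with pytest.raises(ValueError):
            RecombinationScheme(blocks=[[0], [1]], patterns=[[0, 1]])


class TestGapSelection:
    def test_cuts_at_largest_relative_gap(self, ring_case):
        _, case = ring_case
        pool = StructurePool()
        for e in [10.0, 11.0, 12.0, 500.0, 600.0]:
            pool.add(Assembly([case.subunit]), scores={"gvm": e})
        out = gap_selection(pool, "gvm")
        assert len(out) == 3

    def test_fallback_without_gap(self, ring_case):
        _, case = ring_case
        pool = StructurePool()
        for e in np.linspace(1.0, 1.4, 40):
            pool.add(Assembly([case.subunit]), scores={"gvm": float(e)})
        out = gap_selection(pool, "gvm", fallback=32)
        assert len(out) == 32


class TestStagePlan:
    def test_counts_must_be_non_increasing(self):
        with pytest.raises(ValueError):
            StagePlan(n_starts=10, n_preassembly=20, n_scoring=5, n_refine=1)

    def test_paper_scale_preset(self):
        plan = StagePlan.paper_scale()
        assert (plan.n_starts, plan.n_preassembly, plan.n_scoring, plan.n_refine) \
            == (1_000_000, 500_000, 100_000, 1000)
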