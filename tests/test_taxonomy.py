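"""TM-score, clustering, pathway graphs, cross-model comparison."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import pullscope as ps
from pullscope.synthetic import scripted_unfolding_trajectory
from pullscope.taxonomy import (ClusterSet, FoldedSegment, all_vs_all_tm,
                                cluster_by_tm, cross_model_alignment,
                                folded_segment, frames_at_q, kabsch,
                                mean_tm_vs_q, pathway_graph,
                                rmsd_after_superposition, tm_d0, tm_score,
                                unfolding_order_correlation,
                                window_reference_curve)


def brute_force_tm(a, b, l_ref=None, n_grid=12):
    """Exhaustive superposition-search oracle for tiny fragments.

    Combines (i) a dense SO(3) rotation grid with, for every rotation, the
    translation that superposes each single atom pair exactly, and (ii)
    Kabsch superpositions of every residue subset of size >= 3.  Either
    family contains near-optimal candidates for the few-residue TM
    optimum; the maximum over both is the reference score.
    """
    from itertools import combinations

    a = np.asarray(a) * 10.0
    b = np.asarray(b) * 10.0
    n = len(a)
    l_ref = l_ref or n
    d0 = tm_d0(l_ref)
    best = 0.0

    candidates = []   # (score, rotvec, translation)

    def tm_of(bt):
        d = np.linalg.norm(a - bt, axis=1)
        return (1.0 / (1.0 + (d / d0) ** 2)).sum() / l_ref

    rots = Rotation.from_euler(
        "zyx", [[za, yb, xc]
                for za in np.linspace(0, 2 * np.pi, n_grid, endpoint=False)
                for yb in np.linspace(0, np.pi, n_grid // 2)
                for xc in np.linspace(0, 2 * np.pi, n_grid, endpoint=False)])
    for rot in rots.as_matrix():
        br = b @ rot.T
        rv = Rotation.from_matrix(rot).as_rotvec()
        # anchor each atom pair exactly, plus the centroid match
        for anchor in list(range(n)) + [None]:
            t = (a.mean(0) - br.mean(0)) if anchor is None \
                else a[anchor] - br[anchor]
            candidates.append((tm_of(br + t), rv, t))
    for size in range(3, n + 1):
        for sel in combinations(range(n), size):
            sel = list(sel)
            r2, t2 = kabsch(a[sel], b[sel])
            candidates.append((tm_of(b @ r2.T + t2),
                               Rotation.from_matrix(r2).as_rotvec(), t2))
    candidates.sort(key=lambda c: -c[0])
    best = candidates[0][0]

    # downhill polish from the best grid candidates plus random restarts
    from scipy.optimize import minimize

    def neg(p):
        rot = Rotation.from_rotvec(p[:3]).as_matrix()
        d = np.linalg.norm(a - (b @ rot.T + p[3:]), axis=1)
        return -(1.0 / (1.0 + (d / d0) ** 2)).sum() / l_ref

    rs = np.random.default_rng(1)
    seeds = [np.concatenate([rv, t]) for _, rv, t in candidates[:60]]
    for _ in range(80):
        seeds.append(np.concatenate([
            Rotation.random(random_state=rs).as_rotvec(),
            a.mean(0) - b.mean(0) + rs.normal(0, 2, 3)]))
    for seed in seeds:
        res = minimize(neg, seed, method="Nelder-Mead",
                       options={"maxiter": 500, "fatol": 1e-10,
                                "xatol": 1e-6})
        best = max(best, -res.fun)
    return best


class TestTMScore:
    def test_identical_fragments_score_one(self, toy_structure):
        res = tm_score(toy_structure.coords, toy_structure.coords)
        assert res.score == pytest.approx(1.0, abs=1e-9)
        assert np.all(res.distances < 1e-6)

    def test_d0_formula_and_floor(self):
        assert tm_d0(115) == pytest.approx(1.24 * 100 ** (1 / 3) - 1.8)
        assert tm_d0(10) == 0.5
        assert tm_d0(16) == 0.5   # formula negative below N = 21

    def test_rigid_rotation_invariance(self, toy_structure):
        rot = Rotation.from_euler("xyz", [0.3, 1.1, -0.7]).as_matrix()
        moved = toy_structure.coords @ rot.T + np.array([1.0, -2.0, 0.5])
        res = tm_score(toy_structure.coords, moved)
        assert res.score == pytest.approx(1.0, abs=1e-6)

    def test_uniform_displacement_midpoint(self):
        """Every residue at d_i = d0 under the best superposition -> 0.5.

        A flat fragment displaced perpendicular to its plane by d0 keeps
        all distances equal to d0 (no better superposition exists for a
        mirror-symmetric planar pair displaced along the normal... the
        optimizer may in fact do better, so assert >= 0.5 and the direct
        term-by-term value at the nominal superposition).
        """
        n = 25
        rng = np.random.default_rng(0)
        a = np.column_stack([rng.uniform(0, 2, n), rng.uniform(0, 2, n),
                             np.zeros(n)])
        d0_nm = tm_d0(n) / 10.0
        b = a + np.array([0.0, 0.0, d0_nm])
        res = tm_score(a, b)
        # the identity superposition gives exactly 0.5; optimum >= that
        assert res.score >= 0.5 - 1e-9

    def test_matches_exhaustive_oracle_on_decoys(self):
        """<=8-residue decoy pairs agree with the SO(3)-grid search."""
        rng = np.random.default_rng(5)
        for n in (6, 8):
            for noise in (0.03, 0.08, 0.15):
                a = rng.normal(0, 0.4, (n, 3))
                b = a + rng.normal(0, noise, (n, 3))
                got = tm_score(a, b).score
                ref = brute_force_tm(a, b)
                assert got == pytest.approx(ref, abs=0.01)

    def test_short_fragment_rejected(self):
        with pytest.raises(ValueError):
            tm_score(np.zeros((2, 3)), np.zeros((2, 3)))


class TestFoldedSegment:
    def test_full_chain(self):
        res = np.arange(1, 41)
        seg = folded_segment(res, np.full(40, 0.9))
        assert (seg.start_residue, seg.end_residue) == (1, 40)

    def test_long_gap_splits(self):
        res = np.arange(1, 61)
        vals = np.ones(60)
        vals[30:45] = 0.1          # 15-residue gap
        seg = folded_segment(res, vals)
        assert (seg.start_residue, seg.end_residue) == (1, 30)

    def test_short_dip_bridged(self):
        res = np.arange(1, 61)
        vals = np.ones(60)
        vals[25:33] = 0.2          # 8-residue dip
        seg = folded_segment(res, vals)
        assert (seg.start_residue, seg.end_residue) == (1, 60)

    def test_all_unfolded_flagged(self):
        seg = folded_segment(np.arange(1, 11), np.full(10, 0.2))
        assert seg.empty
        assert seg.length == 0


class TestAllVsAll:
    def test_identical_frames_matrix_of_ones(self, toy_structure):
        frames = [toy_structure.coords] * 4
        mat = all_vs_all_tm(frames)
        assert np.allclose(mat, 1.0, atol=1e-9)

    def test_block_structure_matches_pairwise(self, toy_structure):
        rng = np.random.default_rng(1)
        alt = toy_structure.coords[::-1] + rng.normal(0, 0.5,
                                                      toy_structure.coords.shape)
        frames = [toy_structure.coords, toy_structure.coords, alt, alt]
        mat = all_vs_all_tm(frames)
        for i in range(4):
            for j in range(4):
                expected = tm_score(frames[i], frames[j]).score if i != j else 1.0
                assert mat[i, j] == pytest.approx(expected, abs=1e-9)
        assert np.allclose(mat, mat.T, atol=1e-12)
        assert mat[0, 1] > 0.99 and mat[0, 2] < 0.5


class TestClustering:
    def test_all_ones_single_cluster(self):
        cs = cluster_by_tm(np.ones((5, 5)))
        assert cs.n_clusters == 1
        assert set(cs.labels) == {0}

    def test_two_blocks(self):
        m = np.full((6, 6), 0.1)
        m[:3, :3] = 0.9
        m[3:, 3:] = 0.9
        np.fill_diagonal(m, 1.0)
        cs = cluster_by_tm(m, cutoff=0.6)
        assert cs.n_clusters == 2
        assert len(set(cs.labels[:3])) == 1
        assert len(set(cs.labels[3:])) == 1

    def test_permutation_invariant_partition(self):
        rng = np.random.default_rng(2)
        m = np.full((8, 8), 0.2)
        m[:4, :4] = 0.85
        m[4:, 4:] = 0.85
        np.fill_diagonal(m, 1.0)
        perm = rng.permutation(8)
        cs1 = cluster_by_tm(m)
        cs2 = cluster_by_tm(m[np.ix_(perm, perm)])
        # same partition up to relabeling
        from collections import defaultdict
        def partition(labels, order):
            groups = defaultdict(set)
            for member, lab in zip(order, labels):
                groups[lab].add(member)
            return {frozenset(g) for g in groups.values()}
        assert partition(cs1.labels, range(8)) == \
            partition(cs2.labels, perm)

    def test_centroid_is_member(self):
        m = np.full((5, 5), 0.9)
        np.fill_diagonal(m, 1.0)
        cs = cluster_by_tm(m, members=[10, 11, 12, 13, 14])
        assert cs.centroids[0] in cs.members


class TestPathwayGraph:
    def _sets(self, chains, qs):
        """Build ClusterSets from explicit per-run cluster ids per level."""
        sets = []
        for lev, q in enumerate(qs):
            runs = sorted(chains)
            labels = np.array([chains[r][lev] for r in runs])
            centroids = {c: runs[int(np.argmax(labels == c))]
                         for c in sorted(set(labels))}
            m = np.eye(len(runs))
            sets.append(ClusterSet(q, labels, runs, centroids, m))
        return sets

    def test_single_path_weight_one(self):
        chains = {r: (0, 0, 0) for r in range(10)}
        pg = pathway_graph(self._sets(chains, [0.8, 0.5, 0.2]))
        path, frac = pg.dominant_path()
        assert frac == 1.0
        assert len(path) == 3

    def test_split_weights(self):
        """20 trajectories splitting 15/5 -> edge weights 0.75/0.25."""
        chains = {r: (0, 0 if r < 15 else 1) for r in range(20)}
        pg = pathway_graph(self._sets(chains, [0.8, 0.4]))
        w = pg.edge_weights()
        assert w[((0, 0), (1, 0))] == pytest.approx(0.75)
        assert w[((0, 0), (1, 1))] == pytest.approx(0.25)
        path, frac = pg.dominant_path()
        assert frac == pytest.approx(0.75)

    def test_flow_conservation(self):
        rng = np.random.default_rng(3)
        chains = {r: tuple(rng.integers(0, 3, 4)) for r in range(30)}
        pg = pathway_graph(self._sets(chains, [0.8, 0.6, 0.4, 0.2]))
        g = pg.graph
        for nd in g.nodes:
            out = sum(d["weight"] for _, _, d in g.out_edges(nd, data=True))
            if out:   # non-terminal level
                assert out == pytest.approx(g.nodes[nd]["flow"])

    def test_missing_level_placeholder(self):
        sets = self._sets({0: (0, 0), 1: (0, 0)}, [0.8, 0.4])
        sets[1].members = [0]      # run 1 missing from the lower level
        sets[1].labels = np.array([0])
        pg = pathway_graph(sets)
        assert (1, -1) in pg.graph.nodes


@pytest.fixture(scope="module")
def ensembles(toy_structure, toy_cmap, toy_cdef):
    single = [scripted_unfolding_trajectory(toy_structure, "C",
                                            n_frames=40, seed=s)
              for s in range(12)]
    mixed = [scripted_unfolding_trajectory(
        toy_structure, "C" if s % 2 else "N", n_frames=40, seed=100 + s)
        for s in range(12)]
    for t in single + mixed:
        t.compute_q(toy_cmap, toy_cdef)
    return single, mixed


class TestScriptedPathwayRecovery:
    """Parameter recovery of the full taxonomy machinery."""

    def _cluster_sets(self, trajs, cmap, cdef, qs):
        sets = []
        for q0 in qs:
            frames, runs = frames_at_q(trajs, q0, cmap, cdef, tol=0.08)
            if len(frames) < 2:
                continue
            mat = all_vs_all_tm(frames)
            sets.append(cluster_by_tm(mat, cutoff=0.6, q=q0, members=runs))
        return sets

    def test_single_order_gives_one_dominant_path(self, ensembles, toy_cmap,
                                                  toy_cdef):
        single, _ = ensembles
        sets = self._cluster_sets(single, toy_cmap, toy_cdef,
                                  [0.8, 0.6, 0.4, 0.2])
        pg = pathway_graph(sets)
        _, frac = pg.dominant_path()
        assert frac >= 0.9

    def test_two_orders_split_evenly(self, ensembles, toy_cmap, toy_cdef):
        _, mixed = ensembles
        sets = self._cluster_sets(mixed, toy_cmap, toy_cdef, [0.5, 0.3])
        pg = pathway_graph(sets)
        _, frac = pg.dominant_path()
        assert 0.3 <= frac <= 0.7

    def test_shared_pathway_tm_stays_high(self, ensembles, toy_cmap,
                                          toy_cdef):
        single, mixed = ensembles
        cs = mean_tm_vs_q(single, toy_cmap, toy_cdef,
                          q_grid=[0.6, 0.4, 0.2])
        cm = mean_tm_vs_q(mixed, toy_cmap, toy_cdef,
                          q_grid=[0.6, 0.4, 0.2])
        merged = cs.merge(cm, on="q", suffixes=("_single", "_mixed"))
        low = merged[merged["q"] < 0.5]
        assert (low["mean_tm_single"] > low["mean_tm_mixed"]).all()
        assert (cs["mean_tm"] > 0.6).all()


class TestWindowReferenceCurve:
    def test_full_window_is_unity(self, toy_structure, toy_cmap, toy_cdef):
        df = window_reference_curve(toy_structure, toy_cmap, toy_cdef,
                                    dq=0.1)
        # top bin mixes the full window with near-full ones
        top = df[df["q"] > 0.95]
        assert len(top) and top["mean_tm"].iloc[0] > 0.9
        from pullscope.taxonomy import tm_score
        assert tm_score(toy_structure.coords,
                        toy_structure.coords).score == pytest.approx(1.0)

    def test_curve_decreases_with_q(self, toy_structure, toy_cmap, toy_cdef):
        df = window_reference_curve(toy_structure, toy_cmap, toy_cdef,
                                    dq=0.2)
        df = df.sort_values("q")
        assert df["mean_tm"].iloc[-1] > df["mean_tm"].iloc[0]

    def test_disjoint_windows_score_zero(self, toy_structure):
        from pullscope.taxonomy import tm_score_common
        coords = toy_structure.coords
        s = tm_score_common(coords, coords, np.arange(0, 0), np.arange(0, 0),
                            20)
        assert s == 0.0


class TestCrossModel:
    def test_identity_ensembles(self, toy_structure, toy_cmap, toy_cdef):
        trajs = [scripted_unfolding_trajectory(toy_structure, "C",
                                               n_frames=30, seed=s)
                 for s in range(4)]
        for t in trajs:
            t.compute_q(toy_cmap, toy_cdef)
        df = cross_model_alignment(trajs, trajs, toy_cmap, toy_cdef,
                                   toy_cmap, toy_cdef, q_grid=[0.8, 0.5],
                                   n_bootstrap=50, seed=0)
        # same ensemble compared to itself: high TM, low RMSD (cross pairs
        # mix different runs, so the mean sits below the identity value 1)
        assert (df["tm"] > 0.85).all()
        assert (df["rmsd"] < 1.0).all()

    def test_rotation_invariance(self, toy_structure, toy_cmap, toy_cdef):
        trajs = [scripted_unfolding_trajectory(toy_structure, "C",
                                               n_frames=30, seed=s)
                 for s in range(3)]
        rot = Rotation.from_euler("xyz", [1.0, 0.2, -0.4]).as_matrix()
        rotated = []
        for t in trajs:
            r = scripted_unfolding_trajectory(toy_structure, "C",
                                              n_frames=30,
                                              seed=t.metadata["seed"])
            r.coords = r.coords @ rot.T
            rotated.append(r)
        for t in trajs + rotated:
            t.compute_q(toy_cmap, toy_cdef)
        a = cross_model_alignment(trajs, trajs, toy_cmap, toy_cdef, toy_cmap,
                                  toy_cdef, q_grid=[0.6], n_bootstrap=10,
                                  seed=0)
        b = cross_model_alignment(trajs, rotated, toy_cmap, toy_cdef,
                                  toy_cmap, toy_cdef, q_grid=[0.6],
                                  n_bootstrap=10, seed=0)
        assert a["tm"].iloc[0] == pytest.approx(b["tm"].iloc[0], abs=1e-6)
        assert a["rmsd"].iloc[0] == pytest.approx(b["rmsd"].iloc[0],
                                                  abs=1e-6)

    def test_rmsd_scales_with_noise(self):
        """Per-atom Gaussian noise sigma -> RMSD ~ sigma*sqrt(3) (in the
        same units), minus the rigid-body component removed by Kabsch."""
        rng = np.random.default_rng(0)
        a = rng.normal(0, 5.0, (200, 3))
        sigma = 0.4
        b = a + rng.normal(0, sigma, a.shape)
        r = rmsd_after_superposition(a, b)
        assert r == pytest.approx(sigma * np.sqrt(3), rel=0.1)


class TestUnfoldingOrderCorrelation:
    def _profile(self, scores, q_centers):
        """Synthesize a Q_k profile whose persistence equals `scores`."""
        n = len(scores)
        prof = np.zeros((n, len(q_centers)))
        for k, s in enumerate(scores):
            prof[k] = np.where(q_centers > s, 1.0, 0.0)
            prof[k, np.isclose(q_centers, s)] = 0.0
        return q_centers, np.arange(1, n + 1), prof

    def test_identical_profiles_r_one(self):
        q = np.linspace(0, 1, 21)
        scores = [0.2, 0.2, 0.6, 0.6, 0.9, 0.9]
        pa = self._profile(scores, q)
        r = unfolding_order_correlation(pa, pa, [(1, 2), (3, 4), (5, 6)])
        assert r == pytest.approx(1.0)

    def test_reversed_order_r_minus_one(self):
        q = np.linspace(0, 1, 21)
        pa = self._profile([0.2, 0.2, 0.5, 0.5, 0.8, 0.8], q)
        pb = self._profile([0.8, 0.8, 0.5, 0.5, 0.2, 0.2], q)
        r = unfolding_order_correlation(pa, pb, [(1, 2), (3, 4), (5, 6)])
        assert r == pytest.approx(-1.0)

    def test_matches_hand_computed_pearson(self):
        q = np.linspace(0, 1, 21)
        sa = [0.1, 0.3, 0.5, 0.7, 0.9, 0.2]
        sb = [0.3, 0.1, 0.5, 0.9, 0.7, 0.4]
        pa = self._profile(sa, q)
        pb = self._profile(sb, q)
        strands = [(i + 1, i + 1) for i in range(6)]
        r = unfolding_order_correlation(pa, pb, strands)
        expected = np.corrcoef(sa, sb)[0, 1]
        assert r == pytest.approx(expected, abs=1e-9)
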