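"""Structural taxonomy of unfolding pathways.

Partially unfolded conformations drawn from many pulling runs are
compared at matched values of the order parameter Q with the TM-score

    TM = (1/L) * sum_i 1 / (1 + (d_i/d0)^2),   d0 = 1.24 (N-15)^(1/3) - 1.8

(d0 in angstroms, floored at 0.5 A for short fragments), computed on the
C-alpha atoms of the ensemble's folded segment.  Same-sequence
conformations keep a fixed residue correspondence; only the rigid-body
superposition is optimized, by the standard iterative seed-fragment
search.  All-against-all TM matrices are clustered (average linkage, cut
at 1 - 0.6) and the cluster-to-cluster flow of trajectories across Q
levels forms the pathway graph whose heaviest chain is the dominant
unfolding route.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import networkx as nx
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .contacts import residue_profile

__all__ = [
    "FoldedSegment", "TMAlignmentResult", "ClusterSet", "PathwayGraph",
    "tm_d0", "kabsch", "tm_score", "all_vs_all_tm", "folded_segment",
    "frames_at_q", "mean_tm_vs_q", "window_reference_curve",
    "cluster_by_tm", "pathway_graph", "cross_model_alignment",
    "unfolding_order_correlation",
]


# ---------------------------------------------------------------------------
# TM-score
# ---------------------------------------------------------------------------

def tm_d0(l_ref: int) -> float:
    """Length normalization d0 in angstroms, floored at 0.5 A."""
    if l_ref < 3:
        raise ValueError("reference length must be >= 3")
    if l_ref <= 15:
        return 0.5
    return max(0.5, 1.24 * (l_ref - 15) ** (1.0 / 3.0) - 1.8)


def kabsch(a: np.ndarray, b: np.ndarray):
    """Optimal rotation+translation of b onto a (least-squares).

    Returns (rotation matrix, translation) such that b @ R.T + t ~= a.
    """
    ac = a.mean(axis=0)
    bc = b.mean(axis=0)
    h = (b - bc).T @ (a - ac)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    t = ac - bc @ rot.T
    return rot, t


def rmsd_after_superposition(a: np.ndarray, b: np.ndarray) -> float:
    rot, t = kabsch(a, b)
    d = a - (b @ rot.T + t)
    return float(np.sqrt((d ** 2).sum() / len(a)))


@dataclass
class TMAlignmentResult:
    """TM score with the superposition that achieved it."""

    score: float
    d0: float
    rotation: np.ndarray
    translation: np.ndarray
    distances: np.ndarray     # per-residue d_i, angstroms

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0 + 1e-12):
            raise ValueError("TM score out of [0, 1]")


def _tm_from_superposition(a, b, rot, t, d0, l_ref):
    d = np.linalg.norm(a - (b @ rot.T + t), axis=1)
    return float((1.0 / (1.0 + (d / d0) ** 2)).sum() / l_ref), d


def tm_score(a: np.ndarray, b: np.ndarray,
             l_ref: int | None = None) -> TMAlignmentResult:
    """TM score of two same-length C-alpha fragments (coordinates in nm).

    The correspondence is fixed (identical sequences); the superposition
    is searched with sliding seed fragments followed by iterative
    reselection of residues closer than d0, as in the reference TM-score
    procedure.
    """
    a = np.asarray(a, dtype=float) * 10.0   # nm -> A
    b = np.asarray(b, dtype=float) * 10.0
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("fragments must have identical (n, 3) shapes")
    n = len(a)
    if n < 3:
        raise ValueError("fragments must have at least 3 residues")
    l_ref = n if l_ref is None else int(l_ref)
    d0 = tm_d0(l_ref)

    best = (-1.0, None, None, None)
    seen = set()
    seeds = []
    frag_lengths = {n, max(3, n // 2), max(3, n // 4)}
    for fl in sorted(frag_lengths, reverse=True):
        stride = max(1, fl // 2)
        for off in range(0, n - fl + 1, stride):
            seeds.append(np.arange(off, off + fl))
    if n <= 10:
        # tiny fragments: exhaust every 3-residue subset as a seed
        from itertools import combinations
        seeds.extend(np.array(c) for c in combinations(range(n), 3))
    for sel in seeds:
        for _ in range(30):
            rot, t = kabsch(a[sel], b[sel])
            score, d = _tm_from_superposition(a, b, rot, t, d0, l_ref)
            if score > best[0]:
                best = (score, rot, t, d)
            new = np.where(d < d0)[0]
            if len(new) < 3:
                new = np.argsort(d)[:3]
            key = new.tobytes()
            if key == sel.tobytes() or key in seen:
                break
            seen.add(key)
            sel = new
    if n <= 10:
        best = _polish_small_fragment(a, b, d0, l_ref, best)
    score, rot, t, d = best
    return TMAlignmentResult(min(score, 1.0), d0, rot, t, d)


def _polish_small_fragment(a, b, d0, l_ref, best):
    """Multi-start local maximization of TM over SE(3) for tiny fragments,
    where the score landscape is spiky and fragment seeding misses optima.
    Coordinates here are already in angstroms."""
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation

    def neg_tm(p):
        rot = Rotation.from_rotvec(p[:3]).as_matrix()
        d = np.linalg.norm(a - (b @ rot.T + p[3:]), axis=1)
        return -(1.0 / (1.0 + (d / d0) ** 2)).sum() / l_ref

    seeds = []
    if best[1] is not None:
        seeds.append(np.concatenate([
            Rotation.from_matrix(best[1]).as_rotvec(), best[2]]))
    rs = np.random.default_rng(0)
    t0 = a.mean(axis=0) - b.mean(axis=0)
    for _ in range(60):
        seeds.append(np.concatenate([
            Rotation.random(random_state=rs).as_rotvec(),
            t0 + rs.normal(0.0, 2.0, 3)]))
    for s in seeds:
        res = minimize(neg_tm, s, method="Nelder-Mead",
                       options={"maxiter": 400, "fatol": 1e-10,
                                "xatol": 1e-6})
        if -res.fun > best[0]:
            rot = Rotation.from_rotvec(res.x[:3]).as_matrix()
            t = res.x[3:]
            d = np.linalg.norm(a - (b @ rot.T + t), axis=1)
            best = (-res.fun, rot, t, d)
    return best


def tm_score_common(a: np.ndarray, b: np.ndarray, idx_a, idx_b,
                    l_ref: int) -> float:
    """TM on the intersection of two residue windows; 0 if fewer than 3
    common residues.  Used by the sliding-window reference curve."""
    common_a = np.asarray(idx_a)
    common_b = np.asarray(idx_b)
    if len(common_a) < 3:
        return 0.0
    return tm_score(a[common_a], b[common_b], l_ref=l_ref).score


# ---------------------------------------------------------------------------
# folded segments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldedSegment:
    """Contiguous run of residues with mean per-residue Q above 0.5."""

    start_residue: int        # 1-based, inclusive
    end_residue: int
    mean_q: float
    empty: bool = False

    @property
    def length(self) -> int:
        return 0 if self.empty else self.end_residue - self.start_residue + 1


def folded_segment(residues: np.ndarray, profile_at_q: np.ndarray,
                   max_gap: int = 10, threshold: float = 0.5) -> FoldedSegment:
    """Largest contiguous folded segment of a per-residue Q profile.

    Runs of residues above the threshold may be merged across internal
    sub-threshold gaps of at most ``max_gap`` residues; a longer gap
    separates candidates, and the largest span wins.
    """
    residues = np.asarray(residues, dtype=int)
    vals = np.asarray(profile_at_q, dtype=float)
    above = np.where(np.nan_to_num(vals, nan=0.0) > threshold)[0]
    if len(above) == 0:
        return FoldedSegment(0, 0, 0.0, empty=True)
    # split where consecutive above-threshold residues are > max_gap+1 apart
    segments = []
    start = above[0]
    prev = above[0]
    for i in above[1:]:
        if residues[i] - residues[prev] > max_gap + 1:
            segments.append((start, prev))
            start = i
        prev = i
    segments.append((start, prev))
    best = max(segments, key=lambda s: residues[s[1]] - residues[s[0]])
    i0, i1 = best
    return FoldedSegment(int(residues[i0]), int(residues[i1]),
                         float(np.nanmean(vals[i0:i1 + 1])))


# ---------------------------------------------------------------------------
# ensembles at matched Q
# ---------------------------------------------------------------------------

def _traj_q(traj, cmap, cdef):
    if traj.q is None:
        traj.compute_q(cmap, cdef)
    return traj.q


def frames_at_q(trajectories, q_target: float, cmap, cdef,
                tol: float = 0.05):
    """One frame per trajectory: the frame whose Q is closest to the
    target, excluded (and logged) if farther than ``tol``.  Returns
    (coords list, run indices)."""
    frames, runs = [], []
    for run, traj in enumerate(trajectories):
        q = _traj_q(traj, cmap, cdef)
        k = int(np.argmin(np.abs(q - q_target)))
        if abs(q[k] - q_target) <= tol:
            frames.append(traj.coords[k])
            runs.append(run)
    return frames, runs


def all_vs_all_tm(frames, segment: FoldedSegment | None = None,
                  residues: np.ndarray | None = None) -> np.ndarray:
    """Symmetric TM matrix over an ensemble of same-length CA frames.

    With a segment, frames are restricted to its residues first
    (``residues`` gives the residue index of each row of a frame; default
    1-based consecutive numbering).
    """
    frames = list(frames)
    if len(frames) < 2:
        raise ValueError("need at least two frames")
    if segment is not None and not segment.empty:
        if residues is None:
            residues = np.arange(1, len(frames[0]) + 1)
        sel = np.where((residues >= segment.start_residue) &
                       (residues <= segment.end_residue))[0]
        frames = [f[sel] for f in frames]
    m = len(frames)
    mat = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            s = tm_score(frames[i], frames[j]).score
            mat[i, j] = mat[j, i] = s
    return mat


def mean_tm_vs_q(trajectories, cmap, cdef, q_grid=None, dq: float = 0.05,
                 profile_dq: float = 0.05):
    """Mean pairwise TM between trajectories as a function of Q.

    The folded segment at each Q is taken from the ensemble-average
    per-residue profile.  Returns a DataFrame (q, mean_tm, sem, n_traj);
    bins with fewer than two contributing trajectories are skipped.
    """
    if q_grid is None:
        q_grid = np.arange(0.1, 1.0 + 1e-9, 0.1)
    centers, residues, prof = residue_profile(trajectories, cmap, cdef,
                                              dq=profile_dq)
    rows = []
    for q0 in q_grid:
        b = int(np.argmin(np.abs(centers - q0)))
        # average profile over the neighbourhood of the target bin
        lo, hi = max(0, b - 1), min(len(centers), b + 2)
        vals = np.nanmean(prof[:, lo:hi], axis=1)
        if not np.any(np.nan_to_num(vals) > 0.5):
            continue
        seg = folded_segment(residues, vals)
        if seg.length < 3:
            continue
        frames, runs = frames_at_q(trajectories, q0, cmap, cdef, tol=dq)
        if len(frames) < 2:
            continue
        mat = all_vs_all_tm(frames, segment=seg, residues=residues)
        iu = np.triu_indices(len(frames), k=1)
        scores = mat[iu]
        rows.append({"q": float(q0), "mean_tm": float(scores.mean()),
                     "sem": float(scores.std(ddof=1) / np.sqrt(len(scores)))
                     if len(scores) > 1 else np.nan,
                     "n_traj": len(frames),
                     "segment": (seg.start_residue, seg.end_residue)})
    return pd.DataFrame(rows)


def window_reference_curve(native, cmap, cdef, dq: float = 0.1,
                           min_window: int = 5, max_pairs_per_bin: int = 40,
                           seed: int = 0) -> pd.DataFrame:
    """Structural-overlap baseline from sliding native windows.

    Every window (length, offset) of the native CA structure defines a
    partial structure; its Q against the full native map is the weight
    fraction of native pairs internal to the window.  Windows are binned
    by Q and TM-aligned all-against-all within bins (alignment on the
    residue intersection, normalized by the longer window).  Returns a
    DataFrame (q, mean_tm, n_windows).
    """
    coords = native.coords
    n = len(coords)
    res_i, res_j, w = cmap.res_i, cmap.res_j, cmap.weight
    total = cmap.total_weight
    windows = []
    for length in range(min_window, n + 1):
        for off in range(0, n - length + 1):
            lo, hi = off + 1, off + length       # 1-based inclusive
            inside = (res_i >= lo) & (res_i <= hi) & \
                     (res_j >= lo) & (res_j <= hi)
            q = float(w[inside].sum() / total)
            windows.append((lo, hi, q))
    qs = np.array([x[2] for x in windows])
    centers = np.arange(0.0, 1.0 + 1e-9, dq)
    rng = np.random.default_rng(seed)
    rows = []
    for c in centers:
        sel = np.where(np.abs(qs - c) <= dq / 2)[0]
        if len(sel) < 2:
            continue
        pairs = [(i, j) for ai, i in enumerate(sel) for j in sel[ai + 1:]]
        if len(pairs) > max_pairs_per_bin:
            pick = rng.choice(len(pairs), size=max_pairs_per_bin,
                              replace=False)
            pairs = [pairs[p] for p in pick]
        scores = []
        for i, j in pairs:
            lo1, hi1, _ = windows[i]
            lo2, hi2, _ = windows[j]
            lo, hi = max(lo1, lo2), min(hi1, hi2)
            l_ref = max(hi1 - lo1, hi2 - lo2) + 1
            if hi - lo + 1 < 3:
                scores.append(0.0)
                continue
            sel_idx = np.arange(lo - 1, hi)
            scores.append(tm_score_common(coords, coords, sel_idx, sel_idx,
                                          l_ref))
        rows.append({"q": float(c), "mean_tm": float(np.mean(scores)),
                     "n_windows": len(sel)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# clustering and pathway graphs
# ---------------------------------------------------------------------------

@dataclass
class ClusterSet:
    """Partition of an ensemble at one Q level."""

    q: float
    labels: np.ndarray            # cluster id per member, 0-based
    members: list                 # member ids (e.g. run indices)
    centroids: dict               # cluster id -> member id
    tm_matrix: np.ndarray

    @property
    def n_clusters(self) -> int:
        return len(self.centroids)

    def cluster_of(self, member) -> int:
        return int(self.labels[self.members.index(member)])


def cluster_by_tm(matrix: np.ndarray, cutoff: float = 0.6,
                  q: float = np.nan, members=None,
                  method: str = "average") -> ClusterSet:
    """Agglomerative clustering on distance 1 - TM, cut at 1 - cutoff.

    ``method`` selects the linkage ("average" by default; "single" gives
    the nearest-neighbour variant).  The centroid of each cluster is the
    member maximizing the mean TM to its cluster.
    """
    matrix = np.asarray(matrix, dtype=float)
    m = len(matrix)
    members = list(range(m)) if members is None else list(members)
    if m == 1:
        return ClusterSet(q, np.zeros(1, dtype=int), members,
                          {0: members[0]}, matrix)
    dist = 1.0 - matrix
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    z = linkage(squareform(dist, checks=False), method=method)
    raw = fcluster(z, t=1.0 - cutoff, criterion="distance")
    # relabel clusters by order of first appearance for determinism
    relabel: dict[int, int] = {}
    labels = np.empty(m, dtype=int)
    for i, r in enumerate(raw):
        if r not in relabel:
            relabel[r] = len(relabel)
        labels[i] = relabel[r]
    centroids = {}
    for c in range(len(relabel)):
        idx = np.where(labels == c)[0]
        mean_tm = matrix[np.ix_(idx, idx)].mean(axis=1)
        centroids[c] = members[idx[int(np.argmax(mean_tm))]]
    return ClusterSet(q, labels, members, centroids, matrix)


@dataclass
class PathwayGraph:
    """Q-levelled cluster-flow graph of unfolding routes."""

    graph: nx.DiGraph
    levels: list          # Q values, descending
    chains: dict          # run id -> tuple of (level, cluster) nodes

    def edge_weights(self):
        return {(u, v): d["weight"] for u, v, d in self.graph.edges(data=True)}

    def node_flow(self, node) -> float:
        return self.graph.nodes[node]["flow"]

    def dominant_path(self):
        """Most travelled full chain of clusters and the fraction of
        trajectories following it (ties: larger clusters, then lower ids).
        """
        counts: dict[tuple, int] = {}
        for chain in self.chains.values():
            counts[chain] = counts.get(chain, 0) + 1
        total = len(self.chains)

        def keyfun(item):
            chain, cnt = item
            sizes = tuple(self.graph.nodes[nd]["flow"] for nd in chain)
            ids = tuple(-nd[1] for nd in chain)
            return (cnt, sizes, ids)

        best = max(counts.items(), key=keyfun)
        return list(best[0]), best[1] / total


def pathway_graph(cluster_sets: list[ClusterSet]) -> PathwayGraph:
    """Build the trajectory-flow graph across descending Q levels.

    Each trajectory contributes one chain of (level, cluster) nodes; a
    trajectory missing from a level passes through a placeholder cluster
    (id -1) at that level.  Edge weights are fractions of all
    trajectories, so outgoing weights at a node sum to its flow.
    """
    if len(cluster_sets) < 2:
        raise ValueError("need cluster sets at >= 2 Q levels")
    cluster_sets = sorted(cluster_sets, key=lambda cs: -cs.q)
    runs = sorted({m for cs in cluster_sets for m in cs.members})
    total = len(runs)
    chains = {}
    for run in runs:
        chain = []
        for lev, cs in enumerate(cluster_sets):
            if run in cs.members:
                chain.append((lev, cs.cluster_of(run)))
            else:
                chain.append((lev, -1))
        chains[run] = tuple(chain)

    g = nx.DiGraph()
    for lev, cs in enumerate(cluster_sets):
        g.add_node((lev, -1), q=cs.q, flow=0.0, centroid=None)
        for c, cen in cs.centroids.items():
            g.add_node((lev, c), q=cs.q, flow=0.0, centroid=cen)
    for chain in chains.values():
        for nd in chain:
            g.nodes[nd]["flow"] += 1.0 / total
        for a, b in zip(chain[:-1], chain[1:]):
            if g.has_edge(a, b):
                g[a][b]["weight"] += 1.0 / total
            else:
                g.add_edge(a, b, weight=1.0 / total)
    for nd in list(g.nodes):
        if g.nodes[nd]["flow"] == 0.0:
            g.remove_node(nd)
    return PathwayGraph(g, [cs.q for cs in cluster_sets], chains)


# ---------------------------------------------------------------------------
# cross-model comparison
# ---------------------------------------------------------------------------

def cross_model_alignment(trajs_a, trajs_b, cmap_a, cdef_a, cmap_b, cdef_b,
                          q_grid=None, tol: float = 0.05,
                          n_bootstrap: int = 1000, seed: int = 0,
                          profile_dq: float = 0.05) -> pd.DataFrame:
    """TM and RMSD between two models' ensembles along Q, with bootstrap.

    The reference folded segment at each Q comes from model A's
    per-residue profile; both models' frames are restricted to it (the
    models must share residue numbering).  Returns a DataFrame
    (q, tm, tm_err, rmsd, rmsd_err, n_pairs).
    """
    if q_grid is None:
        q_grid = np.arange(0.1, 1.0 + 1e-9, 0.1)
    rng = np.random.default_rng(seed)
    centers, residues, prof = residue_profile(trajs_a, cmap_a, cdef_a,
                                              dq=profile_dq)
    rows = []
    for q0 in q_grid:
        b = int(np.argmin(np.abs(centers - q0)))
        lo, hi = max(0, b - 1), min(len(centers), b + 2)
        vals = np.nanmean(prof[:, lo:hi], axis=1)
        seg = folded_segment(residues, vals)
        if seg.length < 3:
            continue
        sel = np.where((residues >= seg.start_residue) &
                       (residues <= seg.end_residue))[0]
        fa, _ = frames_at_q(trajs_a, q0, cmap_a, cdef_a, tol=tol)
        fb, _ = frames_at_q(trajs_b, q0, cmap_b, cdef_b, tol=tol)
        if not fa or not fb:
            continue
        pairs = [(i, j) for i in range(len(fa)) for j in range(len(fb))]
        tms = np.empty(len(pairs))
        rmsds = np.empty(len(pairs))
        for k, (i, j) in enumerate(pairs):
            a = fa[i][sel]
            bcrd = fb[j][sel]
            tms[k] = tm_score(a, bcrd).score
            rmsds[k] = rmsd_after_superposition(a * 10.0, bcrd * 10.0)
        boots_tm = np.empty(n_bootstrap)
        boots_rm = np.empty(n_bootstrap)
        for r in range(n_bootstrap):
            pick = rng.integers(0, len(pairs), len(pairs))
            boots_tm[r] = tms[pick].mean()
            boots_rm[r] = rmsds[pick].mean()
        rows.append({"q": float(q0), "tm": float(tms.mean()),
                     "tm_err": float(boots_tm.std(ddof=1)),
                     "rmsd": float(rmsds.mean()),
                     "rmsd_err": float(boots_rm.std(ddof=1)),
                     "n_pairs": len(pairs),
                     "segment": (seg.start_residue, seg.end_residue)})
    return pd.DataFrame(rows)


def unfolding_order_correlation(profile_a, profile_b, strand_ranges) -> float:
    """Pearson correlation of strand persistence between two models.

    Each profile is the (q_centers, residues, matrix) triple from
    :func:`pullscope.contacts.residue_profile`; a residue's persistence
    is the Q at which its Q_k first drops below 0.5 scanning from Q = 1
    down, and a strand's score is the mean over its residues.
    """
    from .contacts import persistence_scores
    from scipy.stats import pearsonr

    (ca, ra, ma), (cb, rb, mb) = profile_a, profile_b
    if len(ra) != len(rb):
        raise ValueError("profiles must cover the same residues")
    pa = persistence_scores(ca, ma)
    pb = persistence_scores(cb, mb)
    sa, sb = [], []
    for (lo, hi) in strand_ranges:
        ia = np.where((ra >= lo) & (ra <= hi))[0]
        sa.append(pa[ia].mean())
        sb.append(pb[ia].mean())
    r, _ = pearsonr(sa, sb)
    return float(r)
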