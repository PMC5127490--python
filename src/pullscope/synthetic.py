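"""Synthetic inputs: toy folded structures and scripted unfolding ensembles.

The toy generator builds a compact, self-avoiding C-alpha chain with a
heterogeneous native contact map — a stand-in for an experimentally
determined beta-barrel domain so that the full pipeline can run without
any structure download.  Two motifs are provided: a two-layer beta
sandwich ("hairpin-barrel") and an antiparallel helix bundle.  All bond
lengths are exactly 0.38 nm, the canonical C-alpha virtual bond.

`scripted_unfolding_trajectory` produces idealized unfolding ensembles in
which residues peel off the folded core from the termini in a prescribed
order; these are the ground-truth pathways used to validate the taxonomy
stages.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from .structure import Structure, ca_structure_from_coords
from .trajectory import Trajectory

__all__ = [
    "generate_toy_structure",
    "toy_strand_ranges",
    "scripted_unfolding_trajectory",
]

BOND = 0.38          # nm, C-alpha virtual bond
STRAND_SPACING = 0.50  # nm between adjacent strands in a sheet
LAYER_SPACING = 0.62   # nm between the two sheets of the sandwich
PLEAT = 0.095          # nm, out-of-plane beta-pleat amplitude
RISE = float(np.sqrt(BOND ** 2 - (2 * PLEAT) ** 2))  # ~0.33 nm per residue


def _arc_path(p0: np.ndarray, p3: np.ndarray, m: int, up: np.ndarray,
              bond: float = BOND) -> np.ndarray:
    """Points of a circular arc from p0 to p3 in m chords of exact length
    ``bond``, bulging along ``up``.  Returns the m-1 interior points."""
    p0 = np.asarray(p0, float)
    p3 = np.asarray(p3, float)
    d = float(np.linalg.norm(p3 - p0))
    if m * bond <= d + 1e-12:
        raise ValueError("arc cannot span the gap with the given chord count")
    e1 = (p3 - p0) / d
    up = np.asarray(up, float)
    up = up - np.dot(up, e1) * e1
    up = up / np.linalg.norm(up)
    # each chord subtends 2*phi; the full arc subtends theta = 2*m*phi
    phi = brentq(lambda p: np.sin(m * p) - (d / bond) * np.sin(p),
                 1e-9, np.pi / m - 1e-9)
    r_arc = bond / (2.0 * np.sin(phi))
    theta = 2.0 * m * phi
    h = np.sqrt(max(r_arc ** 2 - (d / 2.0) ** 2, 0.0))
    # minor arc: center opposite the bulge; major arc: center on the bulge side
    center = (p0 + p3) / 2.0 + (h if theta > np.pi else -h) * up
    b0 = np.arctan2(np.dot(p0 - center, up), np.dot(p0 - center, e1))
    b3 = np.arctan2(np.dot(p3 - center, up), np.dot(p3 - center, e1))
    # winding direction that spans exactly theta and ends at p3
    sign = None
    for s in (1.0, -1.0):
        if abs((b0 + s * theta - b3 + np.pi) % (2 * np.pi) - np.pi) < 1e-9:
            sign = s
            break
    if sign is None:   # numerical tie; pick closer endpoint
        sign = min((1.0, -1.0), key=lambda s: abs(
            (b0 + s * theta - b3 + np.pi) % (2 * np.pi) - np.pi))
    pts = []
    for k in range(1, m):
        beta = b0 + sign * theta * k / m
        pts.append(center + r_arc * (np.cos(beta) * e1 + np.sin(beta) * up))
    return np.array(pts)


def _sandwich_layout(n: int) -> list[dict]:
    """Strand/turn segmentation of an n-residue two-layer beta sandwich."""
    k = int(np.clip(round(n / 10), 4, 8))
    if k % 2:
        k -= 1
    turn = 2                      # interior beads per turn
    s = (n - turn * (k - 1)) // k
    extra = n - turn * (k - 1) - s * k
    lengths = [s + (1 if i < extra else 0) for i in range(k)]
    return [{"n_strands": k, "lengths": lengths, "turn": turn}]


def toy_strand_ranges(n_residues: int, motif: str = "hairpin-barrel") -> list[tuple[int, int]]:
    """1-based residue ranges of the strands/helices of the toy motif."""
    if motif == "hairpin-barrel":
        layout = _sandwich_layout(n_residues)[0]
        ranges = []
        pos = 1
        for i, L in enumerate(layout["lengths"]):
            ranges.append((pos, pos + L - 1))
            pos += L + layout["turn"]
        return ranges
    if motif == "helix-bundle":
        k = 3
        turn = 2
        s = (n_residues - turn * (k - 1)) // k
        extra = n_residues - turn * (k - 1) - s * k
        ranges, pos = [], 1
        for i in range(k):
            L = s + (1 if i < extra else 0)
            ranges.append((pos, pos + L - 1))
            pos += L + turn
        return ranges
    raise ValueError(f"unknown motif {motif!r}")


def _build_sandwich(n: int) -> np.ndarray:
    layout = _sandwich_layout(n)[0]
    k = layout["n_strands"]
    lengths = layout["lengths"]
    turn = layout["turn"]
    per_layer = k // 2
    coords: list[np.ndarray] = []
    direction = 1.0
    for i, L in enumerate(lengths):
        layer = i // per_layer
        # second layer runs back so the crossover is a short hop in y
        col = i % per_layer if layer == 0 else per_layer - 1 - (i - per_layer)
        x = col * STRAND_SPACING
        y = layer * LAYER_SPACING
        # pleated strand: alternate y offsets like a real beta-strand
        def bead(j, z0):
            return np.array([x, y + PLEAT * (-1.0) ** j, z0 + direction * j * RISE])
        if coords:
            # turn arcs bulge sideways (never along the strand axis, which
            # would create near-collinear junction angles): within a layer
            # away from the other layer, at the layer crossover outward in x
            z_start = coords[-1][2]
            start = bead(0, z_start)
            same_layer = (i - 1) // per_layer == layer
            if same_layer:
                up = np.array([0.0, -1.0 if layer == 0 else 1.0, 0.0])
            else:
                up = np.array([1.0, 0.0, 0.0])
            coords.extend(_arc_path(coords[-1], start, turn + 1, up))
            coords.append(start)
            z0 = z_start
        else:
            z0 = 0.0
            coords.append(bead(0, z0))
        for j in range(1, L):
            coords.append(bead(j, z0))
        direction = -direction
    return np.array(coords[:n])


def _build_bundle(n: int) -> np.ndarray:
    k = 3
    turn = 2
    s = (n - turn * (k - 1)) // k
    extra = n - turn * (k - 1) - s * k
    radius = 0.23
    dtheta = np.deg2rad(100.0)
    chord = 2 * radius * np.sin(dtheta / 2.0)
    rise = np.sqrt(BOND ** 2 - chord ** 2)
    centers = [np.array([0.0, 0.0]), np.array([0.95, 0.0]),
               np.array([0.475, 0.82])]
    coords: list[np.ndarray] = []
    direction = 1.0
    for h in range(k):
        L = s + (1 if h < extra else 0)
        cx, cy = centers[h]
        pts = []
        for j in range(L):
            th = j * dtheta
            z = direction * j * rise
            pts.append(np.array([cx + radius * np.cos(th),
                                 cy + radius * np.sin(th), z]))
        if direction < 0:
            pts = [p + np.array([0.0, 0.0, (L - 1) * rise]) for p in pts]
        if coords:
            start = pts[0] + np.array([0.0, 0.0, coords[-1][2] - pts[0][2]])
            shift = start - pts[0]
            pts = [p + shift for p in pts]
            gap = np.linalg.norm(pts[0] - coords[-1])
            m = max(2, int(np.ceil(gap / BOND)) + 1)
            # arc over the end the previous helix reached
            up = np.array([0.0, 0.0, -direction])
            coords.extend(_arc_path(coords[-1], pts[0], m, up))
        coords.extend(pts)
        direction = -direction
    return np.array(coords[:n])


def _rebond(coords: np.ndarray, bond: float = BOND) -> np.ndarray:
    """Walk the chain re-imposing exact bond lengths, keeping directions."""
    out = np.empty_like(coords)
    out[0] = coords[0]
    for i in range(1, len(coords)):
        d = coords[i] - coords[i - 1]
        out[i] = out[i - 1] + bond * d / np.linalg.norm(d)
    return out


def generate_toy_structure(n_residues: int, motif: str = "hairpin-barrel",
                           seed: int = 0, jitter: float = 0.004) -> Structure:
    """Deterministic compact folded C-alpha chain.

    A small seeded jitter breaks the exact lattice symmetry (so that
    angles and dihedrals are generic) before bond lengths are restored to
    exactly 0.38 nm.
    """
    if n_residues < 20:
        raise ValueError("need at least 20 residues")
    if motif == "hairpin-barrel":
        coords = _build_sandwich(n_residues)
    elif motif == "helix-bundle":
        coords = _build_bundle(n_residues)
    else:
        raise ValueError(f"unknown motif {motif!r}")
    rng = np.random.default_rng(seed)
    coords = coords + rng.normal(0.0, jitter, size=coords.shape)
    coords = _rebond(coords)
    return ca_structure_from_coords(coords, label=f"toy-{motif}-{n_residues}-s{seed}")


# ---------------------------------------------------------------------------
# scripted unfolding ensembles
# ---------------------------------------------------------------------------

def scripted_unfolding_trajectory(structure: Structure, schedule,
                                  n_frames: int = 60, seed: int = 0,
                                  noise: float = 0.02) -> Trajectory:
    """Idealized unfolding with a prescribed peel order.

    ``schedule`` is a string over {'N', 'C'} of length n_residues - 1
    (shorter schedules are cycled): at each peel step the next residue is
    detached from the indicated terminus of the remaining folded core and
    laid out on an extended tail.  Frame k has round(k/(n_frames-1) *
    (n-1)) residues peeled, so the ensemble spans Q from ~1 down to ~0.
    Folded-core residues keep their native coordinates plus Gaussian noise
    of scale ``noise`` (nm).
    """
    x0 = structure.coords
    n = len(x0)
    rng = np.random.default_rng(seed)
    sched = "".join(schedule)
    while len(sched) < n - 1:
        sched += sched
    sched = sched[:n - 1]

    # cumulative fold boundaries after each peel step
    bounds = [(0, n - 1)]
    lo, hi = 0, n - 1
    for ch in sched:
        if ch.upper() == "N" and lo < hi:
            lo += 1
        elif hi > lo:
            hi -= 1
        bounds.append((lo, hi))

    frames = []
    centroid = x0.mean(axis=0)
    for k in range(n_frames):
        steps = int(round(k / max(n_frames - 1, 1) * (n - 1)))
        lo, hi = bounds[min(steps, len(bounds) - 1)]
        x = x0.copy()
        for (attach, idxs, sign) in (
                (lo, range(lo - 1, -1, -1), -1),
                (hi, range(hi + 1, n), +1)):
            base = x0[attach]
            d = base - centroid
            nd = np.linalg.norm(d)
            direction = d / nd if nd > 1e-9 else np.array([0.0, 0.0, float(sign)])
            for step, i in enumerate(idxs, start=1):
                wiggle = 0.05 * np.array([np.cos(2.1 * step), np.sin(2.1 * step), 0.0])
                x[i] = base + 0.36 * step * direction + wiggle
        x += rng.normal(0.0, noise, size=x.shape)
        frames.append(x)
    times = np.arange(n_frames, dtype=float) + 1.0
    return Trajectory(np.array(frames), times,
                      metadata={"kind": "scripted", "seed": seed,
                                "schedule": sched})
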