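"""A minimal one-bead-per-residue structure-based (Go) force field.

Only native contacts attract; everything else is repulsive.  The potential
is built from a reference C-alpha structure:

* harmonic bonds and angles, and a periodic dihedral term, at their native
  values;
* a 10-12 Lennard-Jones well, U = eps*w*[5 (r0/r)^12 - 6 (r0/r)^10], for
  each native pair, with its minimum at the native separation and a depth
  proportional to the heavy-atom contact count when a heavy-atom reference
  is supplied (energetic heterogeneity), else uniform;
* an excluded-volume r^-12 repulsion of diameter sigma_NC for all other
  pairs.

Reduced units: eps = 1 (one uniform contact), masses = 1, lengths nm,
k_B = 1.  Forces are exact gradients of the energy; a finite-difference
check lives in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .structure import Structure, RESOLUTION_CA

__all__ = ["GoModelParameters", "build_ca_go_model"]

# Reduced-unit bonded constants.  The bond constant is chosen so that the
# fastest (bond-stretch) mode is well resolved by the default 0.004 time
# step while remaining ~two orders of magnitude stiffer than any contact
# interaction; see docs/methods.md.
K_BOND = 500.0          # eps / nm^2
K_ANGLE = 40.0          # eps / rad^2
K_DIHEDRAL = 1.0        # eps
SIGMA_NC = 0.4          # nm, excluded-volume diameter
EPS_REPULSIVE = 1.0     # eps


@dataclass
class GoModelParameters:
    """Topology + parameters of a C-alpha Go model (reduced units)."""

    x0: np.ndarray                      # (n, 3) native coordinates, nm
    bond_idx: np.ndarray                # (nb, 2)
    bond_r0: np.ndarray
    bond_k: np.ndarray
    angle_idx: np.ndarray               # (na, 3)
    angle_t0: np.ndarray
    angle_k: np.ndarray
    dihedral_idx: np.ndarray            # (nd, 4)
    dihedral_p0: np.ndarray
    dihedral_k: np.ndarray
    pair_idx: np.ndarray                # (np, 2) native pairs
    pair_r0: np.ndarray
    pair_eps: np.ndarray                # eps * weight per pair
    rep_idx: np.ndarray                 # (nr, 2) repulsive pairs
    sigma_nc: float = SIGMA_NC
    eps_rep: float = EPS_REPULSIVE
    masses: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x0 = np.asarray(self.x0, dtype=float)
        if self.masses is None:
            self.masses = np.ones(len(self.x0))
        if np.any(self.bond_r0 <= 0) or (len(self.pair_r0) and
                                         np.any(self.pair_r0 <= 0)):
            raise ValueError("all reference distances must be positive")

    @property
    def n_beads(self) -> int:
        return len(self.x0)

    # ----- energies and forces -------------------------------------------

    def energy_terms(self, x: np.ndarray, include_repulsion: bool = True) -> dict:
        """Energy decomposition at configuration ``x``."""
        e = {}
        d = np.linalg.norm(x[self.bond_idx[:, 0]] - x[self.bond_idx[:, 1]], axis=1)
        e["bond"] = float(0.5 * (self.bond_k * (d - self.bond_r0) ** 2).sum())
        if len(self.angle_idx):
            t = _angles(x, self.angle_idx)
            e["angle"] = float(0.5 * (self.angle_k * (t - self.angle_t0) ** 2).sum())
        else:
            e["angle"] = 0.0
        if len(self.dihedral_idx):
            p = _dihedrals(x, self.dihedral_idx)
            dp = p - self.dihedral_p0
            u = (1 - np.cos(dp)) + 0.5 * (1 - np.cos(3 * dp))
            s1, _ = _collinearity_switch(x, self.dihedral_idx[:, 0],
                                         self.dihedral_idx[:, 1],
                                         self.dihedral_idx[:, 2])
            s2, _ = _collinearity_switch(x, self.dihedral_idx[:, 1],
                                         self.dihedral_idx[:, 2],
                                         self.dihedral_idx[:, 3])
            e["dihedral"] = float((self.dihedral_k * s1 * s2 * u).sum())
        else:
            e["dihedral"] = 0.0
        if len(self.pair_idx):
            r = np.linalg.norm(x[self.pair_idx[:, 0]] - x[self.pair_idx[:, 1]], axis=1)
            e["native"] = float((self.pair_eps *
                                 _u1012(r, self.pair_r0)).sum())
        else:
            e["native"] = 0.0
        if include_repulsion and len(self.rep_idx):
            r = np.linalg.norm(x[self.rep_idx[:, 0]] - x[self.rep_idx[:, 1]], axis=1)
            e["repulsion"] = float((self.eps_rep *
                                    _u_rep(r, self.sigma_nc)).sum())
        else:
            e["repulsion"] = 0.0
        e["total"] = sum(e.values())
        return e

    def energy(self, x: np.ndarray, include_repulsion: bool = True) -> float:
        return self.energy_terms(x, include_repulsion)["total"]

    def forces(self, x: np.ndarray, include_repulsion: bool = True) -> np.ndarray:
        """Analytic forces, -dU/dx, shape (n, 3)."""
        idx_parts: list[np.ndarray] = []
        vec_parts: list[np.ndarray] = []

        bi, bj = self.bond_idx[:, 0], self.bond_idx[:, 1]
        dv = x[bi] - x[bj]
        d = np.sqrt((dv * dv).sum(1))
        g = (self.bond_k * (d - self.bond_r0) / d)[:, None] * dv   # dU/dxi
        idx_parts += [bi, bj]
        vec_parts += [-g, g]

        if len(self.angle_idx):
            _angle_forces(x, self.angle_idx, self.angle_t0, self.angle_k,
                          idx_parts, vec_parts)
        if len(self.dihedral_idx):
            _dihedral_forces(x, self.dihedral_idx, self.dihedral_p0,
                             self.dihedral_k, idx_parts, vec_parts)

        if len(self.pair_idx):
            pi, pj = self.pair_idx[:, 0], self.pair_idx[:, 1]
            dv = x[pi] - x[pj]
            r = np.sqrt((dv * dv).sum(1))
            dudr = self.pair_eps * _du1012(r, self.pair_r0)
            g = (dudr / r)[:, None] * dv
            idx_parts += [pi, pj]
            vec_parts += [-g, g]

        if include_repulsion and len(self.rep_idx):
            ri_, rj_ = self.rep_idx[:, 0], self.rep_idx[:, 1]
            dv = x[ri_] - x[rj_]
            r = np.sqrt((dv * dv).sum(1))
            dudr = self.eps_rep * _du_rep(r, self.sigma_nc)
            g = (dudr / r)[:, None] * dv
            idx_parts += [ri_, rj_]
            vec_parts += [-g, g]

        idx = np.concatenate(idx_parts)
        vec = np.concatenate(vec_parts)
        n = len(x)
        f = np.empty_like(x)
        for k in range(3):
            f[:, k] = np.bincount(idx, weights=vec[:, k], minlength=n)
        return f


# ---------------------------------------------------------------------------
# pair potentials with a linearized core
#
# Below SOFTCORE_FRACTION of the reference distance the r^-12 walls are
# continued linearly (energy and force continuous), bounding the maximum
# force and curvature so a thermal collision cannot destabilize the 0.004
# time step (the unsoftened wall reaches omega*dt ~ 1 just below 0.9 r0).
# The continuation still climbs tens of eps within a tenth of a nm, so
# chain crossing remains thermally forbidden.
# ---------------------------------------------------------------------------

SOFTCORE_FRACTION = 0.9


def _u1012_raw(r, r0):
    s2 = (r0 / r) ** 2
    s10 = s2 ** 5
    return 5.0 * s10 * s2 - 6.0 * s10


def _du1012_raw(r, r0):
    s2 = (r0 / r) ** 2
    s10 = s2 ** 5
    return -60.0 / r * s10 * (s2 - 1.0)


def _u1012(r, r0):
    rs = SOFTCORE_FRACTION * r0
    rc = np.maximum(r, rs)
    u = _u1012_raw(rc, r0)
    return np.where(r < rs, u + _du1012_raw(rs, r0) * (r - rs), u)


def _du1012(r, r0):
    rs = SOFTCORE_FRACTION * r0
    return _du1012_raw(np.maximum(r, rs), r0)


def _u_rep_raw(r, sigma):
    return (sigma / r) ** 12


def _du_rep_raw(r, sigma):
    return -12.0 * (sigma / r) ** 12 / r


def _u_rep(r, sigma):
    rs = SOFTCORE_FRACTION * sigma
    rc = np.maximum(r, rs)
    u = _u_rep_raw(rc, sigma)
    return np.where(r < rs, u + _du_rep_raw(rs, sigma) * (r - rs), u)


def _du_rep(r, sigma):
    rs = SOFTCORE_FRACTION * sigma
    return _du_rep_raw(np.maximum(r, rs), sigma)


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _angles(x, idx):
    u = x[idx[:, 0]] - x[idx[:, 1]]
    v = x[idx[:, 2]] - x[idx[:, 1]]
    cu = np.linalg.norm(u, axis=1)
    cv = np.linalg.norm(v, axis=1)
    cos = np.clip((u * v).sum(1) / (cu * cv), -1.0, 1.0)
    return np.arccos(cos)


def _dihedrals(x, idx):
    b1 = x[idx[:, 1]] - x[idx[:, 0]]
    b2 = x[idx[:, 2]] - x[idx[:, 1]]
    b3 = x[idx[:, 3]] - x[idx[:, 2]]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2, axis=1)[:, None])
    return np.arctan2((m * n2).sum(1), (n1 * n2).sum(1))


def _cross(a, b):
    out = np.empty_like(a)
    out[:, 0] = a[:, 1] * b[:, 2] - a[:, 2] * b[:, 1]
    out[:, 1] = a[:, 2] * b[:, 0] - a[:, 0] * b[:, 2]
    out[:, 2] = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    return out


def _angle_forces(x, idx, t0, k, idx_parts, vec_parts):
    i, j, l = idx[:, 0], idx[:, 1], idx[:, 2]
    u = x[i] - x[j]
    v = x[l] - x[j]
    cu = np.sqrt((u * u).sum(1))
    cv = np.sqrt((v * v).sum(1))
    uh = u / cu[:, None]
    vh = v / cv[:, None]
    cos = np.clip((uh * vh).sum(1), -1.0, 1.0)
    sin = np.sqrt(np.maximum(1.0 - cos ** 2, 1e-12))
    theta = np.arccos(cos)
    dudt = k * (theta - t0)
    # dtheta/dxi = (cos*uh - vh) / (|u| sin); force = -dU/dtheta * dtheta/dx
    gi = (dudt / (cu * sin))[:, None] * (cos[:, None] * uh - vh)
    gl = (dudt / (cv * sin))[:, None] * (cos[:, None] * vh - uh)
    idx_parts += [i, l, j]
    vec_parts += [-gi, -gl, gi + gl]


#: sin^2 threshold of the dihedral collinearity switch: below this value of
#: sin^2(internal angle) the torsion smoothly switches off, bounding the
#: 1/|b_i x b_j|^2 torque arm.  Reference geometries keep internal angles
#: far from pi, so the switch is inert except in rare thermal excursions.
DIHEDRAL_SIN2_SWITCH = 0.09


def _collinearity_switch(x, i, j, l):
    """Switch s(theta) = min(1, sin^2/S) of the internal angle at bead j,
    plus ds/dtheta (0 on the flat branch)."""
    u = x[i] - x[j]
    v = x[l] - x[j]
    cu2 = (u * u).sum(1)
    cv2 = (v * v).sum(1)
    cos = (u * v).sum(1) / np.sqrt(cu2 * cv2)
    cos = np.clip(cos, -1.0, 1.0)
    sin2 = 1.0 - cos * cos
    on = sin2 < DIHEDRAL_SIN2_SWITCH
    s = np.where(on, sin2 / DIHEDRAL_SIN2_SWITCH, 1.0)
    sin = np.sqrt(np.maximum(sin2, 1e-12))
    dsdtheta = np.where(on, 2.0 * sin * cos / DIHEDRAL_SIN2_SWITCH, 0.0)
    return s, dsdtheta


def _angle_gradient_parts(x, i, j, l, dudt, idx_parts, vec_parts):
    """Scatter -dudt * dtheta/dx for the internal angle at bead j."""
    u = x[i] - x[j]
    v = x[l] - x[j]
    cu = np.sqrt((u * u).sum(1))
    cv = np.sqrt((v * v).sum(1))
    uh = u / cu[:, None]
    vh = v / cv[:, None]
    cos = np.clip((uh * vh).sum(1), -1.0, 1.0)
    sin = np.sqrt(np.maximum(1.0 - cos ** 2, 1e-12))
    gi = (dudt / (cu * sin))[:, None] * (cos[:, None] * uh - vh)
    gl = (dudt / (cv * sin))[:, None] * (cos[:, None] * vh - uh)
    idx_parts += [i, l, j]
    vec_parts += [-gi, -gl, gi + gl]


def _dihedral_forces(x, idx, p0, k, idx_parts, vec_parts):
    a, b, c, d = idx[:, 0], idx[:, 1], idx[:, 2], idx[:, 3]
    b1 = x[b] - x[a]
    b2 = x[c] - x[b]
    b3 = x[d] - x[c]
    n1 = _cross(b1, b2)
    n2 = _cross(b2, b3)
    sqb2 = (b2 * b2).sum(1)
    nb2 = np.sqrt(sqb2)
    m = _cross(n1, b2 / nb2[:, None])
    phi = np.arctan2((m * n2).sum(1), (n1 * n2).sum(1))
    dp = phi - p0
    u_phi = (1 - np.cos(dp)) + 0.5 * (1 - np.cos(3 * dp))
    dudphi = k * (np.sin(dp) + 1.5 * np.sin(3 * dp))

    # E = s1(theta1) s2(theta2) U(phi): the switches bound the otherwise
    # singular torque arm near collinear internal angles
    s1, ds1 = _collinearity_switch(x, a, b, c)
    s2, ds2 = _collinearity_switch(x, b, c, d)

    dudphi_eff = dudphi * s1 * s2
    sq1 = (n1 * n1).sum(1)
    sq2 = (n2 * n2).sum(1)
    fa = (-dudphi_eff * nb2 / sq1)[:, None] * n1
    fd = (dudphi_eff * nb2 / sq2)[:, None] * n2
    t1 = ((b1 * b2).sum(1) / sqb2)[:, None]
    t2 = ((b3 * b2).sum(1) / sqb2)[:, None]
    fb = -(1.0 + t1) * fa + t2 * fd
    fc = t1 * fa - (1.0 + t2) * fd
    idx_parts += [a, b, c, d]
    vec_parts += [fa, fb, fc, fd]

    if np.any(ds1 != 0.0):
        _angle_gradient_parts(x, a, b, c, k * u_phi * s2 * ds1,
                              idx_parts, vec_parts)
    if np.any(ds2 != 0.0):
        _angle_gradient_parts(x, b, c, d, k * u_phi * s1 * ds2,
                              idx_parts, vec_parts)


# ---------------------------------------------------------------------------
# builder
# ---------------------------------------------------------------------------

def build_ca_go_model(
    structure: Structure,
    heavy_reference: Structure | None = None,
    pair_cutoff_ca: float = 0.8,
    pair_cutoff_heavy: float = 0.6,
    min_separation: int = 4,
    eps_contact: float = 1.0,
) -> GoModelParameters:
    """Construct the Go model from a C-alpha reference structure.

    Native pairs are residue pairs with at least one heavy-atom pair inside
    ``pair_cutoff_heavy`` when ``heavy_reference`` is given (well depth
    proportional to the heavy-atom contact count), else C-alpha pairs
    inside ``pair_cutoff_ca``.
    """
    if structure.resolution != RESOLUTION_CA:
        raise ValueError("build_ca_go_model requires a CA-resolution structure")
    x0 = structure.coords
    n = len(x0)
    res = structure.residue_indices

    bond_idx = np.column_stack([np.arange(n - 1), np.arange(1, n)])
    bond_r0 = np.linalg.norm(x0[bond_idx[:, 0]] - x0[bond_idx[:, 1]], axis=1)
    bond_k = np.full(n - 1, K_BOND)

    if n >= 3:
        angle_idx = np.column_stack([np.arange(n - 2), np.arange(1, n - 1),
                                     np.arange(2, n)])
        angle_t0 = _angles(x0, angle_idx)
        angle_k = np.full(n - 2, K_ANGLE)
    else:
        angle_idx = np.zeros((0, 3), dtype=int)
        angle_t0 = angle_k = np.zeros(0)

    if n >= 4:
        dihedral_idx = np.column_stack([np.arange(n - 3), np.arange(1, n - 2),
                                        np.arange(2, n - 1), np.arange(3, n)])
        dihedral_p0 = _dihedrals(x0, dihedral_idx)
        dihedral_k = np.full(n - 3, K_DIHEDRAL)
    else:
        dihedral_idx = np.zeros((0, 4), dtype=int)
        dihedral_p0 = dihedral_k = np.zeros(0)

    # native pairs
    if heavy_reference is not None:
        hx = heavy_reference.coords
        hres = heavy_reference.residue_indices
        hdist = squareform(pdist(hx))
        counts: dict[tuple[int, int], int] = {}
        iu, ju = np.triu_indices(len(hx), k=1)
        close = hdist[iu, ju] < pair_cutoff_heavy
        for a, b in zip(iu[close], ju[close]):
            ra, rb = int(hres[a]), int(hres[b])
            if abs(ra - rb) >= min_separation:
                key = (min(ra, rb), max(ra, rb))
                counts[key] = counts.get(key, 0) + 1
        bead_of = {int(r): k for k, r in enumerate(res)}
        pairs, eps = [], []
        for (ra, rb), c in sorted(counts.items()):
            if ra in bead_of and rb in bead_of:
                pairs.append((bead_of[ra], bead_of[rb]))
                eps.append(eps_contact * c)
        pair_idx = np.array(pairs, dtype=int).reshape(-1, 2)
        pair_eps = np.array(eps, dtype=float)
    else:
        dist = squareform(pdist(x0))
        iu, ju = np.triu_indices(n, k=1)
        ok = (np.abs(res[iu] - res[ju]) >= min_separation) & \
             (dist[iu, ju] < pair_cutoff_ca)
        pair_idx = np.column_stack([iu[ok], ju[ok]])
        pair_eps = np.full(len(pair_idx), eps_contact)
    pair_r0 = np.linalg.norm(x0[pair_idx[:, 0]] - x0[pair_idx[:, 1]], axis=1) \
        if len(pair_idx) else np.zeros(0)

    # repulsive pairs: everything |i-j| >= 3 that is not a native pair
    native = set(map(tuple, pair_idx.tolist()))
    iu, ju = np.triu_indices(n, k=3)
    rep = [(a, b) for a, b in zip(iu, ju) if (a, b) not in native]
    rep_idx = np.array(rep, dtype=int).reshape(-1, 2)

    return GoModelParameters(
        x0=x0, bond_idx=bond_idx, bond_r0=bond_r0, bond_k=bond_k,
        angle_idx=angle_idx, angle_t0=angle_t0, angle_k=angle_k,
        dihedral_idx=dihedral_idx, dihedral_p0=dihedral_p0,
        dihedral_k=dihedral_k, pair_idx=pair_idx, pair_r0=pair_r0,
        pair_eps=pair_eps, rep_idx=rep_idx,
    )
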