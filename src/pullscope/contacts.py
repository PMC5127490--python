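"""Native-contact definitions and contact-based observables.

The global unfolding order parameter is the smoothed fraction of native
contacts

    Q(X) = (1/|S|) * sum_{(i,j) in S} w_ij / (1 + exp[beta0 (r_ij - lam r0_ij)])

where S is the set of native pairs, r0_ij the native distance, beta0 a
smoothing parameter and lam a fluctuation allowance.  Non-native contacts
are counted with the same sigmoid around a single characteristic length
R0, the mean native pair distance.

Each model resolution uses its own contact parameters; the shipped presets
are the conventional ones for heavy-atom, three-bead and one-bead models
of a ~100-residue beta protein.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.special import expit

from .structure import Structure

__all__ = [
    "ContactDefinition",
    "NativeContactMap",
    "CONTACT_PRESETS",
    "contact_definition",
    "build_native_contact_map",
    "native_fraction",
    "nonnative_count",
    "residue_profile",
    "persistence_scores",
    "off_native_ratio",
    "contact_map_at_Q",
]


@dataclass(frozen=True)
class ContactDefinition:
    """Parameters of the smoothed contact counters.

    Attributes
    ----------
    beta0 : float
        Sigmoid smoothing, 1/nm.
    lam : float
        Fluctuation factor multiplying the native distance.
    r_cut : float
        Native-contact cutoff in nm.
    min_separation : int
        Minimum residue-index separation |i - j| for an analysis contact.
    R0 : float or None
        Characteristic non-native length in nm.  The shipped presets carry
        the printed per-model values; if None it is taken from the contact
        map's mean native distance.
    """

    beta0: float = 50.0
    lam: float = 1.2
    r_cut: float = 1.2
    min_separation: int = 4
    R0: float | None = None

    def __post_init__(self) -> None:
        if self.beta0 <= 0 or self.r_cut <= 0:
            raise ValueError("beta0 and r_cut must be positive")
        if self.lam < 1.0:
            raise ValueError("lam must be >= 1")
        if self.min_separation < 1:
            raise ValueError("min_separation must be >= 1")


#: Contact parameters per model family (beta0 [1/nm], lam, r_cut [nm], R0 [nm]).
CONTACT_PRESETS: dict[str, ContactDefinition] = {
    "aa": ContactDefinition(50.0, 1.8, 0.48, 4, 0.24),
    "ha-go": ContactDefinition(50.0, 1.8, 0.48, 4, 0.24),
    "awsem": ContactDefinition(50.0, 1.2, 0.60, 4, 0.46),
    "ca-go": ContactDefinition(50.0, 1.2, 1.20, 4, 0.91),
}


def contact_definition(model: str, **overrides) -> ContactDefinition:
    """Return the preset :class:`ContactDefinition` for a model tag."""
    try:
        cdef = CONTACT_PRESETS[model.lower()]
    except KeyError:
        raise KeyError(f"unknown model tag {model!r}; "
                       f"known: {sorted(CONTACT_PRESETS)}") from None
    return replace(cdef, **overrides) if overrides else cdef


@dataclass
class NativeContactMap:
    """Reference pair list anchoring all Q computations.

    ``pair_i``/``pair_j`` index moieties; ``res_i``/``res_j`` are the
    1-based residue indices; ``r0`` native distances (nm); ``weight``
    contact multiplicities (1 for unweighted maps).
    """

    pair_i: np.ndarray
    pair_j: np.ndarray
    res_i: np.ndarray
    res_j: np.ndarray
    r0: np.ndarray
    weight: np.ndarray
    n_moieties: int
    residue_of_moiety: np.ndarray   # residue index per moiety
    resolution: str

    def __post_init__(self) -> None:
        for name in ("pair_i", "pair_j", "res_i", "res_j"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=int))
        self.r0 = np.asarray(self.r0, dtype=float)
        self.weight = np.asarray(self.weight, dtype=float)
        if np.any(self.weight < 1):
            raise ValueError("contact weights must be >= 1")

    @property
    def n_pairs(self) -> int:
        return len(self.pair_i)

    @property
    def total_weight(self) -> float:
        return float(self.weight.sum())

    @property
    def mean_r0(self) -> float:
        """Mean native pair distance <r0_ij> (unweighted over pairs)."""
        return float(self.r0.mean()) if self.n_pairs else np.nan

    def residue_pairs(self) -> set[tuple[int, int]]:
        """Unique native residue pairs (i < j)."""
        lo = np.minimum(self.res_i, self.res_j)
        hi = np.maximum(self.res_i, self.res_j)
        return set(zip(lo.tolist(), hi.tolist()))

    def residue_weights(self, residues: np.ndarray) -> np.ndarray:
        """Total native contact weight per residue (each pair counts for both)."""
        out = np.zeros(len(residues))
        index = {int(r): k for k, r in enumerate(residues)}
        for ri, rj, w in zip(self.res_i, self.res_j, self.weight):
            out[index[int(ri)]] += w
            out[index[int(rj)]] += w
        return out


def _check_congruent(coords: np.ndarray, cmap: NativeContactMap) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] != cmap.n_moieties:
        raise ValueError(
            f"frame has {coords.shape[0] if coords.ndim == 2 else '?'} moieties, "
            f"map expects {cmap.n_moieties}")
    return coords


def build_native_contact_map(
    structure: Structure,
    cdef: ContactDefinition,
    weighting: str = "none",
    heavy_reference: Structure | None = None,
    heavy_cdef: ContactDefinition | None = None,
) -> NativeContactMap:
    """Enumerate native contacts of a reference structure.

    With ``weighting="heavy-atom-count"`` (CA maps only) each CA-CA pair's
    weight is the number of heavy-atom pairs between the two residues that
    are within the heavy-atom cutoff in ``heavy_reference``.
    """
    coords = structure.coords
    res = structure.residue_indices
    n = len(coords)
    dist = squareform(pdist(coords))
    sep = np.abs(res[:, None] - res[None, :])
    iu, ju = np.triu_indices(n, k=1)
    ok = (sep[iu, ju] >= cdef.min_separation) & (dist[iu, ju] < cdef.r_cut)
    pi, pj = iu[ok], ju[ok]
    r0 = dist[pi, pj]
    weight = np.ones(len(pi))

    if weighting == "heavy-atom-count":
        if heavy_reference is None:
            raise ValueError("heavy-atom-count weighting requires heavy_reference")
        hdef = heavy_cdef or CONTACT_PRESETS["ha-go"]
        heavy_map = build_native_contact_map(heavy_reference, hdef)
        counts: dict[tuple[int, int], int] = {}
        for ri, rj in zip(heavy_map.res_i, heavy_map.res_j):
            key = (min(ri, rj), max(ri, rj))
            counts[key] = counts.get(key, 0) + 1
        keep, w = [], []
        for k in range(len(pi)):
            key = (min(res[pi[k]], res[pj[k]]), max(res[pi[k]], res[pj[k]]))
            c = counts.get(key, 0)
            if c > 0:
                keep.append(k)
                w.append(c)
        keep = np.array(keep, dtype=int)
        pi, pj, r0 = pi[keep], pj[keep], r0[keep]
        weight = np.array(w, dtype=float)
    elif weighting != "none":
        raise ValueError(f"unknown weighting {weighting!r}")

    if len(pi) == 0:
        warnings.warn("native contact map is empty", stacklevel=2)
    return NativeContactMap(pi, pj, res[pi], res[pj], r0, weight,
                            n_moieties=n, residue_of_moiety=res,
                            resolution=structure.resolution)


def _native_terms(coords: np.ndarray, cmap: NativeContactMap,
                  cdef: ContactDefinition) -> np.ndarray:
    """Smoothed occupancy of each native pair, in [0, 1]."""
    d = np.linalg.norm(coords[cmap.pair_i] - coords[cmap.pair_j], axis=1)
    return expit(-cdef.beta0 * (d - cdef.lam * cmap.r0))


def native_fraction(coords, cmap: NativeContactMap,
                    cdef: ContactDefinition) -> float:
    """Fraction of native contacts Q of a conformation, weighted."""
    coords = _check_congruent(coords, cmap)
    if cmap.n_pairs == 0:
        return np.nan
    terms = _native_terms(coords, cmap, cdef)
    return float((cmap.weight * terms).sum() / cmap.total_weight)


def _nonnative_candidates(cmap: NativeContactMap,
                          cdef: ContactDefinition) -> tuple[np.ndarray, np.ndarray]:
    """Moiety pairs meeting the separation rule that are not native."""
    res = cmap.residue_of_moiety
    n = cmap.n_moieties
    iu, ju = np.triu_indices(n, k=1)
    ok = np.abs(res[iu] - res[ju]) >= cdef.min_separation
    iu, ju = iu[ok], ju[ok]
    native = set(zip(cmap.pair_i.tolist(), cmap.pair_j.tolist()))
    mask = np.array([(a, b) not in native for a, b in zip(iu, ju)], dtype=bool)
    return iu[mask], ju[mask]


def _nonnative_terms(coords: np.ndarray, cmap: NativeContactMap,
                     cdef: ContactDefinition,
                     pairs: tuple[np.ndarray, np.ndarray] | None = None):
    if pairs is None:
        pairs = _nonnative_candidates(cmap, cdef)
    iu, ju = pairs
    r0 = cdef.R0 if cdef.R0 is not None else cmap.mean_r0
    d = np.linalg.norm(coords[iu] - coords[ju], axis=1)
    return iu, ju, expit(-cdef.beta0 * (d - cdef.lam * r0))


def nonnative_count(coords, cmap: NativeContactMap,
                    cdef: ContactDefinition) -> float:
    """Smoothed number of non-native contacts N_nn of a conformation."""
    coords = _check_congruent(coords, cmap)
    _, _, terms = _nonnative_terms(coords, cmap, cdef)
    return float(terms.sum())


# ---------------------------------------------------------------------------
# Q-binned ensemble observables
# ---------------------------------------------------------------------------

def _q_bin_centers(dq: float) -> np.ndarray:
    n = int(round(1.0 / dq))
    return np.linspace(0.0, 1.0, n + 1)


def _frame_iter(trajectories):
    """Yield (run_index, coords) over a list of trajectories or coord stacks."""
    for run, traj in enumerate(trajectories):
        frames = getattr(traj, "coords", traj)
        for coords in frames:
            yield run, coords


def residue_profile(trajectories, cmap: NativeContactMap,
                    cdef: ContactDefinition, dq: float = 0.01):
    """Per-residue native-contact fraction Q_k binned by total Q.

    Returns ``(q_centers, residues, profile)`` where ``profile`` has shape
    (n_residues, n_bins); empty bins are NaN, and residues with zero native
    contact weight are NaN everywhere (flagged, not zero).
    """
    residues = np.unique(cmap.residue_of_moiety)
    res_w = cmap.residue_weights(residues)
    index = {int(r): k for k, r in enumerate(residues)}
    centers = _q_bin_centers(dq)
    acc = np.zeros((len(residues), len(centers)))
    cnt = np.zeros(len(centers))

    row_i = np.array([index[int(r)] for r in cmap.res_i])
    row_j = np.array([index[int(r)] for r in cmap.res_j])

    for _, coords in _frame_iter(trajectories):
        coords = _check_congruent(coords, cmap)
        terms = cmap.weight * _native_terms(coords, cmap, cdef)
        q = terms.sum() / cmap.total_weight
        b = int(np.argmin(np.abs(centers - q)))
        per_res = np.zeros(len(residues))
        np.add.at(per_res, row_i, terms)
        np.add.at(per_res, row_j, terms)
        acc[:, b] += per_res
        cnt[b] += 1

    with np.errstate(invalid="ignore", divide="ignore"):
        profile = acc / cnt[None, :] / res_w[:, None]
    profile[:, cnt == 0] = np.nan
    profile[res_w == 0, :] = np.nan
    return centers, residues, profile


def persistence_scores(q_centers: np.ndarray, profile: np.ndarray) -> np.ndarray:
    """Q at which each residue's Q_k first drops below 0.5, scanning from
    Q = 1 downward.  Persistent residues therefore score low; a residue
    never observed below 0.5 gets 0, the most persistent end of the scale.
    """
    order = np.argsort(q_centers)[::-1]
    scores = np.zeros(profile.shape[0])
    for k in range(profile.shape[0]):
        for b in order:
            v = profile[k, b]
            if np.isfinite(v) and v < 0.5:
                scores[k] = q_centers[b]
                break
    return scores


def off_native_ratio(frames, cmap: NativeContactMap,
                     cdef: ContactDefinition) -> tuple[float, float]:
    """Thermal-average counts of (off-native residue pairs, native residue
    pairs with at least one surviving contact) over an ensemble of frames.

    An off-native pair is a residue pair holding a non-native contact that
    is a +-1 primary-sequence shift of some native residue pair and is not
    itself native.  A smoothed term > 0.5 marks a contact as present.
    """
    native_pairs = cmap.residue_pairs()
    shifted: set[tuple[int, int]] = set()
    for (m, n) in native_pairs:
        for cand in ((m - 1, n), (m + 1, n), (m, n - 1), (m, n + 1)):
            a, b = min(cand), max(cand)
            if (a, b) not in native_pairs and abs(a - b) >= cdef.min_separation:
                shifted.add((a, b))

    nn_pairs = _nonnative_candidates(cmap, cdef)
    res = cmap.residue_of_moiety
    n_off_total = 0.0
    n_nat_total = 0.0
    n_frames = 0
    for _, coords in _frame_iter([frames]):
        coords = _check_congruent(coords, cmap)
        iu, ju, terms = _nonnative_terms(coords, cmap, cdef, nn_pairs)
        present = terms > 0.5
        occupied = {(min(res[a], res[b]), max(res[a], res[b]))
                    for a, b in zip(iu[present], ju[present])}
        n_off_total += len(occupied & shifted)
        nat_terms = _native_terms(coords, cmap, cdef) > 0.5
        nat_occ = {(min(ri, rj), max(ri, rj))
                   for ri, rj, ok in zip(cmap.res_i, cmap.res_j, nat_terms) if ok}
        n_nat_total += len(nat_occ)
        n_frames += 1
    if n_frames == 0:
        raise ValueError("empty ensemble")
    return n_off_total / n_frames, n_nat_total / n_frames


def contact_map_at_Q(trajectories, cmap: NativeContactMap,
                     cdef: ContactDefinition, q_targets, dq: float = 0.01):
    """Residue-residue contact maps conditioned on total Q.

    For each target Q the native map entry (k, l) is the mean surviving
    contact weight divided by the native weight of that residue pair; the
    non-native entry is the fraction of frames in the bin with at least one
    non-native contact (smoothed term > 0.5) between the residues.

    Returns a dict target -> ``{"native": DataFrame, "nonnative": DataFrame,
    "n_frames": int}``; targets with empty bins map to None.
    """
    import pandas as pd

    q_targets = list(q_targets)
    res = cmap.residue_of_moiety
    nat_key = [(min(ri, rj), max(ri, rj))
               for ri, rj in zip(cmap.res_i, cmap.res_j)]
    nat_weight: dict[tuple[int, int], float] = {}
    for key, w in zip(nat_key, cmap.weight):
        nat_weight[key] = nat_weight.get(key, 0.0) + w
    nn_pairs = _nonnative_candidates(cmap, cdef)

    acc = {t: {"nat": {}, "nn": {}, "n": 0} for t in q_targets}
    for _, coords in _frame_iter(trajectories):
        coords = _check_congruent(coords, cmap)
        terms = cmap.weight * _native_terms(coords, cmap, cdef)
        q = terms.sum() / cmap.total_weight
        for t in q_targets:
            if abs(q - t) > dq:
                continue
            slot = acc[t]
            slot["n"] += 1
            for key, v in zip(nat_key, terms):
                slot["nat"][key] = slot["nat"].get(key, 0.0) + v
            iu, ju, nnterms = _nonnative_terms(coords, cmap, cdef, nn_pairs)
            present = nnterms > 0.5
            occ = {(min(res[a], res[b]), max(res[a], res[b]))
                   for a, b in zip(iu[present], ju[present])}
            for key in occ:
                slot["nn"][key] = slot["nn"].get(key, 0.0) + 1.0

    out = {}
    for t in q_targets:
        slot = acc[t]
        if slot["n"] == 0:
            warnings.warn(f"no frames in bin around Q={t}", stacklevel=2)
            out[t] = None
            continue
        nat_rows = [(k[0], k[1], v / slot["n"] / nat_weight[k])
                    for k, v in sorted(slot["nat"].items())]
        nn_rows = [(k[0], k[1], v / slot["n"])
                   for k, v in sorted(slot["nn"].items())]
        cols = ["residue_i", "residue_j", "value"]
        out[t] = {
            "native": pd.DataFrame(nat_rows, columns=cols),
            "nonnative": pd.DataFrame(nn_rows, columns=cols),
            "n_frames": slot["n"],
        }
    return out
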