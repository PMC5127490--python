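"""Langevin dynamics and force-spectroscopy protocols.

The integrator is the BAOAB splitting of Langevin dynamics: two velocity
half-kicks and two position half-drifts around one Ornstein-Uhlenbeck
velocity refresh.  In the zero-friction limit it reduces to velocity
Verlet and conserves a shadow energy; at finite friction it samples the
canonical ensemble at the thermostat temperature.  The thermostat time
constant is interpreted as the inverse friction coefficient.

All protocols are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .gomodel import GoModelParameters
from .trajectory import Trajectory

__all__ = [
    "ThermostatSettings",
    "PullingProtocol",
    "IntegrationError",
    "run_langevin",
    "run_pull",
    "run_temperature_scan",
    "perturb_and_relax",
]


class IntegrationError(RuntimeError):
    """Raised when coordinates become non-finite; carries the step index."""


#: Default residue pairs for the perturb-relax protocol on tSOD1-sized
#: (~110 residue) inputs: each pair spans two different beta-strands.
TSOD1_RELAX_PAIRS = [(13, 69), (20, 80), (35, 45), (60, 25), (95, 102)]


@dataclass(frozen=True)
class ThermostatSettings:
    """Temperature (reduced units), friction time constant, step and seed.

    ``friction_time`` is the Langevin time constant tau; the friction
    coefficient is gamma = 1/tau.  ``friction_time=None`` disables the
    thermostat (pure Hamiltonian dynamics).
    """

    temperature: float = 0.9
    friction_time: float | None = 12.0
    dt: float = 0.004
    seed: int = 0

    def __post_init__(self) -> None:
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")
        if self.dt <= 0:
            raise ValueError("time step must be positive")
        if self.friction_time is not None and self.friction_time <= 0:
            raise ValueError("friction time constant must be positive")


@dataclass(frozen=True)
class PullingProtocol:
    """Constant-velocity tether pulling.

    The N-terminal bead is restrained to its initial position with spring
    constant ``k``; the C-terminal bead is tethered to a reference point
    that moves with speed ``speed`` along the fixed initial axis from the
    N- to the C-terminal tether, so the tether separation grows.  The run
    ends once the extension delta-x reaches ``max_extension``.
    """

    k: float = 100.0                 # eps/nm^2 (reduced analogue of a stiff device)
    speed: float = 0.05              # nm per reduced time unit
    max_extension: float = 12.0      # nm
    pulled_bead: int = -1
    fixed_bead: int = 0

    def __post_init__(self) -> None:
        if self.k <= 0 or self.speed <= 0 or self.max_extension <= 0:
            raise ValueError("k, speed and max_extension must be positive")


def _baoab(model: GoModelParameters, thermo: ThermostatSettings,
           n_steps: int, report_every: int, x0: np.ndarray,
           rng: np.random.Generator, extra_force=None, stop=None,
           include_repulsion: bool = True):
    """Core BAOAB loop.

    ``extra_force(x, t)`` may add protocol forces (tethers, steering) and
    return per-step diagnostics; ``stop(diag)`` may terminate the run.
    Reported samples: coordinates, time, kinetic and potential energy, and
    the last diagnostics of each reporting interval.
    """
    dt = thermo.dt
    m = model.masses[:, None]
    x = np.array(x0, dtype=float)
    v = np.zeros_like(x)
    if thermo.temperature > 0:
        v = rng.normal(0.0, np.sqrt(thermo.temperature / m), size=x.shape)
    gamma = 0.0 if thermo.friction_time is None else 1.0 / thermo.friction_time
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(max(0.0, (1.0 - c1 * c1)) * thermo.temperature)

    def total_force(x, t):
        f = model.forces(x, include_repulsion=include_repulsion)
        diag = None
        if extra_force is not None:
            fe, diag = extra_force(x, t)
            f = f + fe
        return f, diag

    f, diag = total_force(x, 0.0)
    xs, ts, kes, pes, diags = [], [], [], [], []
    t = 0.0
    for step in range(1, n_steps + 1):
        v += 0.5 * dt * f / m
        x += 0.5 * dt * v
        if gamma > 0.0:
            v = c1 * v + c2 * np.sqrt(1.0 / m) * rng.standard_normal(x.shape)
        x += 0.5 * dt * v
        t = step * dt
        f, diag = total_force(x, t)
        v += 0.5 * dt * f / m
        if step % report_every == 0:
            if not np.all(np.isfinite(x)):
                raise IntegrationError(f"non-finite coordinates at step {step}")
            xs.append(x.copy())
            ts.append(t)
            kes.append(float(0.5 * (m * v * v).sum()))
            pes.append(model.energy(x, include_repulsion=include_repulsion))
            diags.append(diag)
            if stop is not None and stop(diag):
                break
    return np.array(xs), np.array(ts), np.array(kes), np.array(pes), diags, x, v


def run_langevin(model: GoModelParameters, thermostat: ThermostatSettings,
                 n_steps: int, report_every: int = 1000,
                 x0: np.ndarray | None = None,
                 include_repulsion: bool = True) -> Trajectory:
    """Plain constant-temperature dynamics from the native state (or x0)."""
    if n_steps <= 0:
        raise ValueError("n_steps must be positive")
    rng = np.random.default_rng(thermostat.seed)
    x0 = model.x0 if x0 is None else x0
    xs, ts, kes, pes, _, _, _ = _baoab(model, thermostat, n_steps,
                                       report_every, x0, rng,
                                       include_repulsion=include_repulsion)
    return Trajectory(xs, ts, metadata={
        "kind": "langevin", "temperature": thermostat.temperature,
        "seed": thermostat.seed, "kinetic_energy": kes,
        "potential_energy": pes, "dt": thermostat.dt,
    })


def run_pull(model: GoModelParameters, protocol: PullingProtocol,
             thermostat: ThermostatSettings, seed: int | None = None,
             report_every: int = 200,
             x0: np.ndarray | None = None) -> Trajectory:
    """Constant-velocity pulling; returns a trajectory with the
    force-extension record (time, delta-x, spring force along the axis)."""
    n = model.n_beads
    pulled = protocol.pulled_bead % n
    fixed = protocol.fixed_bead % n
    if pulled == fixed:
        raise ValueError("pulled and fixed bead coincide")
    thermo = thermostat if seed is None else replace(thermostat, seed=seed)
    rng = np.random.default_rng(thermo.seed)
    x0 = model.x0 if x0 is None else x0
    anchor_fixed = x0[fixed].copy()
    anchor_pulled = x0[pulled].copy()
    axis = anchor_pulled - anchor_fixed
    sep0 = float(np.linalg.norm(axis))
    axis = axis / sep0
    k = protocol.k
    v = protocol.speed

    def extra(x, t):
        f = np.zeros_like(x)
        f[fixed] = -k * (x[fixed] - anchor_fixed)
        ref = anchor_pulled + v * t * axis
        dv = ref - x[pulled]
        f[pulled] = k * dv
        ext = float(np.linalg.norm(x[pulled] - x[fixed]) - sep0)
        force = float(k * np.dot(dv, axis))
        return f, (ext, force)

    n_steps = int(np.ceil(1.25 * protocol.max_extension / (v * thermo.dt)))
    xs, ts, kes, pes, diags, _, _ = _baoab(
        model, thermo, n_steps, report_every, x0, rng, extra_force=extra,
        stop=lambda d: d[0] >= protocol.max_extension)
    ext = np.array([d[0] for d in diags])
    frc = np.array([d[1] for d in diags])
    return Trajectory(xs, ts, extension=ext, force=frc, metadata={
        "kind": "pull", "temperature": thermo.temperature, "seed": thermo.seed,
        "speed": v, "spring_k": k, "max_extension": protocol.max_extension,
        "kinetic_energy": kes, "potential_energy": pes, "dt": thermo.dt,
    })


def run_temperature_scan(model: GoModelParameters, temperatures,
                         n_steps: int, n_runs: int = 1,
                         thermostat: ThermostatSettings = ThermostatSettings(),
                         seed: int = 0, cmap=None, cdef=None,
                         report_every: int = 200, mode: str = "direct",
                         swap_every: int = 500, equilibration: float = 0.3):
    """Q time series across a temperature scan.

    ``direct`` mode runs ``n_runs`` independent trajectories from the
    native state at each temperature.  ``remd`` mode runs one replica per
    temperature with Metropolis neighbour swaps every ``swap_every`` steps
    (acceptance is logged in the result).  Returns a
    :class:`~pullscope.calibration.MeltingCurve`; the first
    ``equilibration`` fraction of each series is excluded from the
    mean/SEM but kept in the raw series.
    """
    from .calibration import MeltingCurve, block_average_sem
    from .contacts import native_fraction

    temperatures = np.sort(np.asarray(temperatures, dtype=float))
    if cmap is None or cdef is None:
        raise ValueError("cmap and cdef are required to compute Q")
    series: dict[float, list[np.ndarray]] = {float(T): [] for T in temperatures}
    acceptance = np.nan

    if mode == "direct":
        for i, T in enumerate(temperatures):
            for r in range(n_runs):
                th = replace(thermostat, temperature=float(T),
                             seed=seed + 1000 * i + r)
                traj = run_langevin(model, th, n_steps, report_every)
                q = np.array([native_fraction(c, cmap, cdef)
                              for c in traj.coords])
                series[float(T)].append(q)
    elif mode == "remd":
        rng = np.random.default_rng(seed)
        n_rep = len(temperatures)
        xs = [model.x0.copy() for _ in range(n_rep)]
        qs: list[list[float]] = [[] for _ in range(n_rep)]
        n_blocks = max(1, n_steps // swap_every)
        attempts = accepts = 0
        for blk in range(n_blocks):
            energies = []
            for i, T in enumerate(temperatures):
                th = replace(thermostat, temperature=float(T),
                             seed=seed + 7919 * blk + i)
                r = np.random.default_rng(th.seed)
                out = _baoab(model, th, swap_every, report_every, xs[i], r)
                xs[i] = out[5]
                for c in out[0]:
                    qs[i].append(native_fraction(c, cmap, cdef))
                energies.append(model.energy(xs[i]))
            for i in range(blk % 2, n_rep - 1, 2):
                attempts += 1
                b1, b2 = 1.0 / temperatures[i], 1.0 / temperatures[i + 1]
                delta = (b1 - b2) * (energies[i + 1] - energies[i])
                if delta <= 0 or rng.random() < np.exp(-delta):
                    accepts += 1
                    xs[i], xs[i + 1] = xs[i + 1], xs[i]
                    energies[i], energies[i + 1] = energies[i + 1], energies[i]
        for i, T in enumerate(temperatures):
            series[float(T)].append(np.array(qs[i]))
        acceptance = accepts / attempts if attempts else np.nan
    else:
        raise ValueError(f"unknown mode {mode!r}")

    means, sems = [], []
    for T in temperatures:
        chunks = []
        for q in series[float(T)]:
            burn = int(equilibration * len(q))
            chunks.append(q[burn:])
        allq = np.concatenate(chunks)
        means.append(float(allq.mean()))
        if len(allq) >= 64:
            sems.append(block_average_sem(allq))
        else:
            sems.append(float(allq.std(ddof=1) / np.sqrt(len(allq))))
    return MeltingCurve(temperatures, np.array(means), np.array(sems),
                        raw_series=series,
                        metadata={"mode": mode, "swap_acceptance": acceptance})


def perturb_and_relax(model: GoModelParameters, residue_pair: tuple[int, int],
                      thermostat: ThermostatSettings,
                      displacement: float = 1.5, seed: int = 0,
                      steer_steps: int = 5000, relax_steps: int = 20000,
                      k_steer: float = 200.0, report_every: int = 100,
                      cmap=None, cdef=None,
                      strand_ranges=None) -> Trajectory:
    """Mechanical perturbation followed by free relaxation.

    Stage 1 drives the separation of one residue pair from its native
    value to native + ``displacement`` (nm) with a moving harmonic
    distance restraint; stage 2 removes all restraints and records Q(t).
    ``residue_pair`` uses 1-based residue numbering.  If ``strand_ranges``
    (list of (start, end) residue ranges) is given, pairs on the same
    strand are rejected.
    """
    from .contacts import native_fraction

    i, j = residue_pair
    if strand_ranges is not None:
        for (a, b) in strand_ranges:
            if a <= i <= b and a <= j <= b:
                raise ValueError(f"residues {i} and {j} lie on the same strand")
    bi, bj = i - 1, j - 1
    n = model.n_beads
    if not (0 <= bi < n and 0 <= bj < n) or abs(bi - bj) < 2:
        raise ValueError("invalid or bonded-neighbour residue pair")

    rng = np.random.default_rng(seed)
    r_native = float(np.linalg.norm(model.x0[bi] - model.x0[bj]))
    total_t = steer_steps * thermostat.dt

    def steer(x, t):
        target = r_native + displacement * min(1.0, t / total_t)
        dv = x[bi] - x[bj]
        r = float(np.linalg.norm(dv))
        g = -k_steer * (r - target) / r * dv
        f = np.zeros_like(x)
        f[bi] = g
        f[bj] = -g
        return f, r

    out = _baoab(model, thermostat, steer_steps, report_every, model.x0, rng,
                 extra_force=steer) if displacement > 0 else \
        (None, None, None, None, None, model.x0.copy(), None)
    x_start = out[5]
    xs, ts, kes, pes, _, _, _ = _baoab(model, thermostat, relax_steps,
                                       report_every, x_start, rng)
    traj = Trajectory(xs, ts, metadata={
        "kind": "relax", "pair": (i, j), "displacement": displacement,
        "temperature": thermostat.temperature, "seed": seed,
        "kinetic_energy": kes, "potential_energy": pes, "dt": thermostat.dt,
    })
    if cmap is not None and cdef is not None:
        traj.compute_q(cmap, cdef)
    return traj
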