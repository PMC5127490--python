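"""Cross-model normalization: melting fits, relaxation times, work analysis.

Comparing force-spectroscopy results between models with different
resolutions requires putting temperature, time and force on common
scales:

* temperature — a two-state fit of the melting curve,
  <Q(T)> = q_u /(1+e^{dG/RT}) + q_f e^{dG/RT}/(1+e^{dG/RT}) with
  dG(T) = dH - T dS, gives the folding temperature T_f = dH/dS; every
  model is then simulated at the same fraction of its own T_f.
* time — the slow rate kappa_1 of a double-exponential fit to the Q
  autocorrelation after a perturb-and-relax experiment defines each
  model's clock, and pulling speeds obey v_a t_a = v_b t_b.
* force — a per-model scale factor alpha maps simulated forces so that
  the Jarzynski estimate of the unfolding free energy matches a
  reference model's value.

Standard errors of correlated series use Flyvbjerg-Petersen blocking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, least_squares
from scipy.special import expit, logsumexp

from .units import R_GAS

__all__ = [
    "MeltingCurve", "TwoStateFit", "RelaxationFit", "WorkEnsemble",
    "ForceScaleResult", "fit_two_state", "transition_width",
    "simulation_temperature", "q_autocorrelation", "fit_double_exponential",
    "characteristic_time", "normalized_pulling_speed", "pulling_work",
    "jarzynski_free_energy", "solve_force_scale", "block_average_sem",
    "integrated_autocorrelation_time", "trim_equilibration",
]


@dataclass
class MeltingCurve:
    """<Q> versus temperature with standard errors."""

    temperatures: np.ndarray
    mean_q: np.ndarray
    sem: np.ndarray | None = None
    raw_series: dict | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.mean_q = np.asarray(self.mean_q, dtype=float)
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if np.any((self.mean_q < -1e-9) | (self.mean_q > 1 + 1e-9)):
            raise ValueError("Q values must lie in [0, 1]")
        if self.sem is not None:
            self.sem = np.asarray(self.sem, dtype=float)


@dataclass
class TwoStateFit:
    """Result of the two-state melting fit.

    ``dH`` in kJ/mol and ``dS`` in kJ/(mol K) when fitted with the gas
    constant in those units; in reduced-unit fits pass gas_constant=1 and
    the same relations hold in reduced units.
    """

    q_f: float
    q_u: float
    dH: float
    dS: float
    gas_constant: float = R_GAS
    cov: np.ndarray | None = None
    residual_rms: float = np.nan

    def __post_init__(self) -> None:
        if self.q_f <= self.q_u:
            raise ValueError("fit collapsed: q_f must exceed q_u")
        if self.dH <= 0 or self.dS <= 0:
            raise ValueError("dH and dS must be positive")

    @property
    def T_f(self) -> float:
        """Folding temperature, where dG(T) = 0."""
        return self.dH / self.dS

    def folded_fraction(self, T) -> np.ndarray:
        T = np.asarray(T, dtype=float)
        return expit((self.dH - T * self.dS) / (self.gas_constant * T))

    def predict(self, T) -> np.ndarray:
        f = self.folded_fraction(T)
        return self.q_u + (self.q_f - self.q_u) * f

    def stderr(self) -> np.ndarray | None:
        if self.cov is None:
            return None
        return np.sqrt(np.diag(self.cov))

    def summary(self) -> str:
        se = self.stderr()
        lines = ["Two-state melting fit", "-" * 42]
        names = ["q_f", "q_u", "dH", "dS"]
        vals = [self.q_f, self.q_u, self.dH, self.dS]
        for k, (nm, v) in enumerate(zip(names, vals)):
            err = f" +/- {se[k]:.4g}" if se is not None else ""
            lines.append(f"{nm:>4s} = {v:.6g}{err}")
        lines.append(f" T_f = {self.T_f:.6g}")
        lines.append(f"rms residual = {self.residual_rms:.3g}")
        return "\n".join(lines)


def _two_state_model(params, T, R):
    q_f, q_u, dH, dS = params
    return q_u + (q_f - q_u) * expit((dH - T * dS) / (R * T))


def fit_two_state(curve: MeltingCurve, gas_constant: float = R_GAS,
                  window: tuple[float, float] | None = None) -> TwoStateFit:
    """Nonlinear least squares of the two-state melting curve.

    ``window`` restricts the fit to a temperature interval (the transition
    region); default uses all points.  Multi-start initialization over a
    grid of candidate T_f values guards against the shallow local minima
    of the four-parameter model.
    """
    T = curve.temperatures
    Q = curve.mean_q
    if window is not None:
        sel = (T >= window[0]) & (T <= window[1])
        T, Q = T[sel], Q[sel]
    if len(T) < 6:
        raise ValueError("need at least 6 temperature points bracketing T_f")
    R = gas_constant

    qf0, qu0 = float(Q.max()), float(Q.min())
    span = T.max() - T.min()
    best = None
    for tf0 in np.linspace(T.min() + 0.05 * span, T.max() - 0.05 * span, 10):
        for stiff in (5.0, 20.0, 80.0):
            dS0 = stiff * R
            p0 = [qf0, qu0, dS0 * tf0, dS0]
            try:
                res = least_squares(
                    lambda p: _two_state_model(p, T, R) - Q, p0,
                    bounds=([0, 0, 1e-12, 1e-12], [1.5, 1.5, np.inf, np.inf]),
                    xtol=1e-15, ftol=1e-15, gtol=1e-15)
            except ValueError:
                continue
            if best is None or res.cost < best.cost:
                best = res
    if best is None or not best.success and best.cost > 1e-3 * len(T):
        raise RuntimeError("two-state fit failed to converge from any start")
    p = best.x
    # covariance from the Jacobian at the optimum
    m, nfree = best.jac.shape
    dof = max(m - nfree, 1)
    s2 = 2 * best.cost / dof
    try:
        cov = s2 * np.linalg.inv(best.jac.T @ best.jac)
    except np.linalg.LinAlgError:
        cov = None
    rms = float(np.sqrt(2 * best.cost / m))
    return TwoStateFit(p[0], p[1], p[2], p[3], gas_constant=R, cov=cov,
                       residual_rms=rms)


def transition_width(fit: TwoStateFit) -> float:
    """Relative width dT/T_f of the melting transition in percent.

    Measured between the temperatures where the folded fraction
    f(T) = e^{dG/RT}/(1+e^{dG/RT}) passes 0.8 and 0.2, available in closed
    form: f = p gives dG = RT ln(p/(1-p)), so T_p = dH/(dS + R ln(p/(1-p))).
    """
    R = fit.gas_constant
    c = R * np.log(4.0)                  # ln(0.8/0.2)
    t80 = fit.dH / (fit.dS + c)
    t20 = fit.dH / (fit.dS - c)
    if t20 <= 0:
        raise ValueError("transition too broad: dS <= R ln 4")
    return 100.0 * (t20 - t80) / fit.T_f


def simulation_temperature(fit_or_tf, fraction: float = 0.9,
                           round_to_kelvin: bool = True) -> float:
    """Production temperature as a fraction of the folding temperature."""
    tf = fit_or_tf.T_f if hasattr(fit_or_tf, "T_f") else float(fit_or_tf)
    t = fraction * tf
    return float(np.round(t)) if round_to_kelvin else t


# ---------------------------------------------------------------------------
# relaxation times
# ---------------------------------------------------------------------------

def q_autocorrelation(series, max_lag: int | None = None) -> np.ndarray:
    """Normalized autocorrelation of a Q time series (FFT method).

    C(k) = <(Q(t)-Qbar)(Q(t+k)-Qbar)> / Var(Q), C(0) = 1.
    """
    x = np.asarray(series, dtype=float)
    if len(x) < 100:
        raise ValueError("need at least 100 samples")
    x = x - x.mean()
    var = np.dot(x, x) / len(x)
    if var <= 1e-300:
        raise ValueError("constant series: autocorrelation undefined")
    n = len(x)
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
    acf = acov / acov[0]
    if max_lag is not None:
        acf = acf[:max_lag + 1]
    return acf


@dataclass
class RelaxationFit:
    """A1 exp(-kappa1 t) + A2 exp(-kappa2 t), kappa1 <= kappa2."""

    A1: float
    A2: float
    kappa1: float
    kappa2: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.A1 < 0 or self.A2 < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.kappa1 <= 0 or self.kappa2 <= 0:
            raise ValueError("rates must be positive")
        if self.kappa1 > self.kappa2:
            raise ValueError("kappa1 must not exceed kappa2")

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.A1 * np.exp(-self.kappa1 * t) + \
            self.A2 * np.exp(-self.kappa2 * t)


def fit_double_exponential(acf, t=None) -> RelaxationFit:
    """Constrained double-exponential fit of a decaying series.

    Multi-start: rates are seeded from a single-exponential log-linear fit
    split by factors of ten in both directions.  Near-degenerate rates
    (within 1%) collapse to a flagged single-exponential report.
    """
    y = np.asarray(acf, dtype=float)
    t = np.arange(len(y), dtype=float) if t is None else np.asarray(t, float)

    pos = y > 1e-12
    if pos.sum() >= 3:
        slope = np.polyfit(t[pos], np.log(y[pos]), 1)[0]
        k0 = max(-slope, 1e-6)
    else:
        k0 = 1.0 / max(t[-1], 1.0)

    def resid(p):
        a1, a2, k1, dk = p
        return a1 * np.exp(-k1 * t) + a2 * np.exp(-(k1 + dk) * t) - y

    best = None
    a0 = max(y[0], 1e-6)
    for split in (3.0, 10.0, 100.0):
        for frac in (0.3, 0.5, 0.7):
            p0 = [frac * a0, (1 - frac) * a0, k0 / np.sqrt(split),
                  k0 * np.sqrt(split) - k0 / np.sqrt(split)]
            try:
                res = least_squares(resid, p0,
                                    bounds=([0, 0, 1e-12, 0],
                                            [np.inf, np.inf, np.inf, np.inf]),
                                    xtol=1e-15, ftol=1e-15)
            except ValueError:
                continue
            if best is None or res.cost < best.cost:
                best = res
    if best is None:
        raise RuntimeError("double-exponential fit failed")
    a1, a2, k1, dk = best.x
    k2 = k1 + dk
    degenerate = k2 <= k1 * 1.01
    if degenerate:
        k2 = k1
    return RelaxationFit(a1, a2, k1, max(k2, k1), degenerate=degenerate)


def characteristic_time(kappa1_values) -> float:
    """Model clock t = 1/<kappa1> from perturb-relax experiments."""
    k = np.mean(np.asarray(kappa1_values, dtype=float))
    if k <= 0:
        raise ValueError("mean slow rate must be positive")
    return 1.0 / k


def normalized_pulling_speed(v_ref: float, t_ref: float, t_model: float) -> float:
    """Pulling speed for a model so that v_model t_model = v_ref t_ref."""
    if v_ref <= 0 or t_ref <= 0 or t_model <= 0:
        raise ValueError("speeds and times must be positive")
    return v_ref * t_ref / t_model


# ---------------------------------------------------------------------------
# work and force scales
# ---------------------------------------------------------------------------

@dataclass
class WorkEnsemble:
    """Per-trajectory pulling work integrals at inverse temperature beta."""

    works: np.ndarray
    beta: float
    L: float = np.nan

    def __post_init__(self) -> None:
        self.works = np.atleast_1d(np.asarray(self.works, dtype=float))
        if not np.all(np.isfinite(self.works)):
            raise ValueError("non-finite work values")
        if self.beta <= 0:
            raise ValueError("beta must be positive")


def pulling_work(extension, force, L: float) -> float:
    """Trapezoidal work integral of the force-extension record up to L.

    A non-monotone extension record (thermal back-steps) is resampled onto
    a monotone grid by interpolation before integration.
    """
    x = np.asarray(extension, dtype=float)
    f = np.asarray(force, dtype=float)
    if x.max() < L:
        raise ValueError(f"extension reaches only {x.max():.3g} < L={L:.3g}")
    if np.any(np.diff(x) <= 0):
        grid = np.linspace(max(x.min(), 0.0), L, 4 * len(x))
        order = np.argsort(x, kind="stable")
        f = np.interp(grid, x[order], f[order])
        x = grid
    sel = x <= L
    xs, fs = x[sel], f[sel]
    w = np.trapezoid(fs, xs)
    if xs[-1] < L:   # close the last sliver up to L
        fL = np.interp(L, x, f)
        w += 0.5 * (fs[-1] + fL) * (L - xs[-1])
    return float(w)


def jarzynski_free_energy(works: WorkEnsemble) -> float:
    """dG = -(1/beta) ln< exp(-beta W) >, with log-sum-exp stabilization.

    A finite-sample upper-bound estimate of the unfolding free energy.
    """
    b = works.beta
    w = works.works
    return float(-(logsumexp(-b * w) - np.log(len(w))) / b)


@dataclass
class ForceScaleResult:
    """Force rescaling factor alpha and its convergence trace."""

    alpha: float
    dG_reference: float
    trace: np.ndarray | None = None   # alpha as a function of runs included

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")


def solve_force_scale(works: WorkEnsemble, dG_ref: float, beta_ref: float,
                      bracket=(1e-6, 1e6)) -> ForceScaleResult:
    """Solve ln<exp(-beta alpha W)> = -beta_ref dG_ref for alpha.

    The left side is the Jarzynski average of the rescaled work; alpha is
    found by Brent root-finding on a bracket.  The convergence trace
    reports alpha recomputed with the first k trajectories for k = 1..n.
    """
    if dG_ref <= 0:
        raise ValueError("dG_ref must be positive")
    b = works.beta

    def g(alpha, w):
        return -(logsumexp(-b * alpha * w) - np.log(len(w))) \
            - beta_ref * dG_ref

    w = works.works

    def solve(wsub):
        lo, hi = bracket
        if g(lo, wsub) * g(hi, wsub) > 0:
            raise ValueError("no sign change for alpha in the bracket")
        return brentq(lambda a: g(a, wsub), lo, hi, xtol=1e-12, rtol=1e-14)

    alpha = solve(w)
    trace = np.array([solve(w[:k]) for k in range(1, len(w) + 1)])
    return ForceScaleResult(alpha, dG_ref, trace)


# ---------------------------------------------------------------------------
# block averaging
# ---------------------------------------------------------------------------

def block_average_sem(series) -> float:
    """Standard error of the mean of a correlated series by
    Flyvbjerg-Petersen pairwise blocking.

    The estimate at blocking level l is std/sqrt(n_blocks); its own
    statistical error is est/sqrt(2(n_blocks-1)).  The plateau is the
    first level whose increase over the previous one is within twice that
    error; the value returned averages that level with the next two to
    damp blocking noise.  Without a plateau the deepest-level estimate is
    returned with a warning.
    """
    x = np.asarray(series, dtype=float)
    if len(x) < 64:
        raise ValueError("need at least 64 samples")
    estimates, nblocks = [], []
    while len(x) >= 2:
        estimates.append(float(x.std(ddof=1) / np.sqrt(len(x))))
        nblocks.append(len(x))
        if len(x) % 2:
            x = x[:-1]
        x = 0.5 * (x[0::2] + x[1::2])
        if len(x) < 4:
            break
    est = np.array(estimates)
    err = est / np.sqrt(2.0 * (np.array(nblocks) - 1))
    for i in range(len(est) - 1):
        if est[i + 1] - est[i] < 2.0 * err[i]:
            hi = min(i + 3, len(est))
            return float(est[i:hi].mean())
    warnings.warn("no blocking plateau; returning deepest-level estimate",
                  stacklevel=2)
    return float(est[-1])


def integrated_autocorrelation_time(series, c: float = 5.0) -> float:
    """Integrated autocorrelation time with a self-consistent window."""
    acf = q_autocorrelation(series)
    tau = 1.0
    for w in range(1, len(acf)):
        tau = 1.0 + 2.0 * acf[1:w + 1].sum()
        if w >= c * tau:
            break
    return float(max(tau, 1.0))


def trim_equilibration(series) -> np.ndarray:
    """Drop the initial stretch up to the integrated autocorrelation time."""
    x = np.asarray(series, dtype=float)
    tau = integrated_autocorrelation_time(x)
    return x[int(np.ceil(tau)):]
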