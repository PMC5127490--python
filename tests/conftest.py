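"""Shared fixtures: toy structures, contact maps, and a calibrated toy
folding temperature (computed once per session from a coarse melting scan).
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import pullscope as ps
from pullscope.dynamics import ThermostatSettings, run_temperature_scan


N_TOY = 40


@pytest.fixture(scope="session")
def toy_structure():
    return ps.generate_toy_structure(N_TOY, seed=1)


@pytest.fixture(scope="session")
def toy_cdef():
    return ps.contact_definition("ca-go")


@pytest.fixture(scope="session")
def toy_cmap(toy_structure, toy_cdef):
    return ps.build_native_contact_map(toy_structure, toy_cdef)


@pytest.fixture(scope="session")
def toy_model(toy_structure):
    return ps.build_ca_go_model(toy_structure)


@pytest.fixture(scope="session")
def toy_melt(toy_model, toy_cmap, toy_cdef):
    """Replica-exchange melting scan of the toy model plus its two-state
    fit (computed once per session)."""
    th = ThermostatSettings(friction_time=12.0, dt=0.004)
    # ladder brackets the full transition so both baselines anchor the fit
    temps = np.linspace(0.6, 1.6, 9)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        curve = run_temperature_scan(toy_model, temps, 20000, thermostat=th,
                                     seed=3, cmap=toy_cmap, cdef=toy_cdef,
                                     report_every=200, mode="remd",
                                     swap_every=1000)
        fit = ps.fit_two_state(curve, gas_constant=1.0)
    return {"curve": curve, "fit": fit}


@pytest.fixture(scope="session")
def toy_tf(toy_melt):
    """Folding temperature of the toy model."""
    return toy_melt["fit"].T_f


def brute_force_q(coords, cmap, cdef):
    """Independent double-loop evaluation of the native fraction."""
    total = 0.0
    for k in range(cmap.n_pairs):
        i, j = cmap.pair_i[k], cmap.pair_j[k]
        r = float(np.linalg.norm(coords[i] - coords[j]))
        total += cmap.weight[k] / (1.0 + np.exp(cdef.beta0 *
                                                (r - cdef.lam * cmap.r0[k])))
    return total / cmap.total_weight


def brute_force_nnn(coords, cmap, cdef):
    """Independent double-loop evaluation of the non-native count."""
    native = set(zip(cmap.pair_i.tolist(), cmap.pair_j.tolist()))
    res = cmap.residue_of_moiety
    r0 = cdef.R0 if cdef.R0 is not None else cmap.mean_r0
    total = 0.0
    n = cmap.n_moieties
    for i in range(n):
        for j in range(i + 1, n):
            if abs(res[i] - res[j]) < cdef.min_separation:
                continue
            if (i, j) in native:
                continue
            r = float(np.linalg.norm(coords[i] - coords[j]))
            arg = cdef.beta0 * (r - cdef.lam * r0)
            total += 1.0 / (1.0 + np.exp(min(arg, 500.0)))
    return total
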