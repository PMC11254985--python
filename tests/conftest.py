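"""Shared fixtures and independent numerical oracles.

The oracles integrate the full PK/PD ODE systems (including an elimination
accumulator for mass-balance checks) with a fixed-step classical RK4 scheme,
completely independently of the package's matrix-exponential / closed-form
solution routes.
"""

from __future__ import annotations

import numpy as np
import pytest

from apopkpd import (
    PdParameters,
    PkParametersSC,
    PkParametersSL,
    default_grid,
    default_pd_parameters,
    default_pk_parameters,
)

MIN_PER_H = 60.0


@pytest.fixture(scope="session")
def sc_typical() -> PkParametersSC:
    return default_pk_parameters("sc")


@pytest.fixture(scope="session")
def sl_typical() -> PkParametersSL:
    return default_pk_parameters("sl")


@pytest.fixture(scope="session")
def pd_typical() -> PdParameters:
    return default_pd_parameters()


@pytest.fixture(scope="session")
def grid() -> np.ndarray:
    return default_grid()


def rk4_states(rhs, x0, out_times_min, step_min=0.01):
    """Fixed-step RK4 integration reporting states at ``out_times_min``.

    ``out_times_min`` must be an integer multiple of ``step_min`` apart
    (true for the default 0.25-min grid).
    """
    x = np.asarray(x0, dtype=float).copy()
    out = np.empty((len(out_times_min), x.size))
    out[0] = x
    t = 0.0
    k = 1
    n_steps = int(round(out_times_min[-1] / step_min))
    for i in range(n_steps):
        h = step_min
        k1 = rhs(x)
        k2 = rhs(x + 0.5 * h * k1)
        k3 = rhs(x + 0.5 * h * k2)
        k4 = rhs(x + h * k3)
        x = x + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        t += h
        if k < len(out_times_min) and abs(t - out_times_min[k]) < 1e-9:
            out[k] = x
            k += 1
    assert k == len(out_times_min), "output grid not aligned with RK4 steps"
    return out


def sc_full_rhs(pk: PkParametersSC, pd_params: PdParameters):
    """States [A, C, Ce, eliminated]; time in minutes, rates in h^-1."""
    ka, kel, ke0 = pk.ka / MIN_PER_H, pk.kel / MIN_PER_H, pd_params.ke0 / MIN_PER_H
    v_ml = pk.volume_apparent * 1000.0

    def rhs(x):
        a, c, ce, _ = x
        return np.array([-ka * a, ka * a - kel * c, ke0 * (c / v_ml - ce), kel * c])

    return rhs


def sl_full_rhs(pk: PkParametersSL, pd_params: PdParameters):
    """States [T1, T2, T3, C, P, Ce, eliminated]; time in minutes."""
    ka, kel = pk.ka / MIN_PER_H, pk.kel / MIN_PER_H
    k12, k21 = pk.k12 / MIN_PER_H, pk.k21 / MIN_PER_H
    ke0 = pd_params.ke0 / MIN_PER_H
    v_ml = pk.volume_apparent * 1000.0

    def rhs(x):
        t1, t2, t3, c, p, ce, _ = x
        return np.array(
            [
                -ka * t1,
                ka * (t1 - t2),
                ka * (t2 - t3),
                ka * t3 - kel * c - k12 * c + k21 * p,
                k12 * c - k21 * p,
                ke0 * (c / v_ml - ce),
                kel * c,
            ]
        )

    return rhs


def sc_ce_closed_form(pk: PkParametersSC, pd_params: PdParameters, dose_mg, t_min):
    """Triple-exponential effect-site concentration for the SC model.

    Analytic convolution of the Bateman input through the link equation:
    ``Ce(t) = (D*F*ka*ke0/V) * sum_i exp(-l_i t) / prod_{j!=i}(l_j - l_i)``
    over the three distinct rates l = (ka, kel, ke0).
    """
    t_h = np.asarray(t_min) / MIN_PER_H
    rates = np.array([pk.ka, pk.kel, pd_params.ke0])
    scale = dose_mg * 1e6 * pk.bioavailability * pk.ka * pd_params.ke0 / (pk.volume_apparent * 1000.0)
    ce = np.zeros_like(t_h)
    for i, li in enumerate(rates):
        denom = np.prod([lj - li for j, lj in enumerate(rates) if j != i])
        ce += np.exp(-li * t_h) / denom
    return scale * ce
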