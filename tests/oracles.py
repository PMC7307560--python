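"""Independent numerical oracles for the test suite.

These deliberately re-derive the dynamics from the written model
equations (not via boombust.model internals) so solver cross-checks
stay independent of the implementation under test.
"""

import math

import numpy as np


def rk4_trajectory(params_dict, R0, C0, t_grid, dt=1e-3):
    """Classic fixed-step 4th-order Runge-Kutta integration.

    ``params_dict`` holds the eight rate parameters plus c_offset.
    Returns (R, C) arrays at the requested grid times.
    """
    r = params_dict["r"]
    r_slope = params_dict["r_slope"]
    a = params_dict["a"]
    h = params_dict["h"]
    m = params_dict["m"]
    e = params_dict["e"]
    d = params_dict["d"]
    C_d = params_dict["C_d"]
    c_off = params_dict.get("c_offset", 1.0 / 6.0)

    def rhs(y):
        R = max(y[0], 0.0)
        C = max(y[1], 0.0)
        f = a * R / (1.0 + a * h * R + m * max(C - c_off, 0.0))
        dR = (r - r_slope * R) * R - f * C
        dC = e * f * C - C * d * math.exp(-min(R * C_d, 700.0))
        return np.array([dR, dC])

    t_grid = np.asarray(t_grid, dtype=float)
    y = np.array([R0, C0], dtype=float)
    t = t_grid[0]
    out_R = [R0]
    out_C = [C0]
    for t_next in t_grid[1:]:
        while t < t_next - 1e-12:
            step = min(dt, t_next - t)
            k1 = rhs(y)
            k2 = rhs(y + 0.5 * step * k1)
            k3 = rhs(y + 0.5 * step * k2)
            k4 = rhs(y + step * k3)
            y = y + (step / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            t += step
        out_R.append(max(y[0], 0.0))
        out_C.append(max(y[1], 0.0))
    return np.array(out_R), np.array(out_C)


def logistic_closed_form(r, K, R0, t):
    """Logistic growth K / (1 + (K/R0 - 1) exp(-r t))."""
    t = np.asarray(t, dtype=float)
    return K / (1.0 + (K / R0 - 1.0) * np.exp(-r * t))


def exponential_decay(C0, d, t):
    return C0 * np.exp(-d * np.asarray(t, dtype=float))
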