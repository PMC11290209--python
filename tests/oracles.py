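"""Independent test oracles: a hand-coded fixed-step RK4 integrator, mole
bookkeeping, and an element-balance checker. Deliberately written without
reusing the package's solver path."""

from __future__ import annotations

import numpy as np

ATOMIC = {"C": 12.011, "H": 1.008, "O": 15.999, "N": 14.007}


def rk4(f, y0, t0, t1, h, record_every=None):
    """Classic fixed-step RK4. Returns (times, states) recorded every
    ``record_every`` (default: only endpoints)."""
    y = np.asarray(y0, dtype=float).copy()
    n = int(round((t1 - t0) / h))
    per = n if record_every is None else int(round(record_every / h))
    times, rec = [t0], [y.copy()]
    t = t0
    for k in range(1, n + 1):
        k1 = f(t, y)
        k2 = f(t + h / 2, y + h / 2 * k1)
        k3 = f(t + h / 2, y + h / 2 * k2)
        k4 = f(t + h, y + h * k3)
        y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t = t0 + k * h
        if k % per == 0:
            times.append(t)
            rec.append(y.copy())
    return np.array(times), np.array(rec)


def gas_moles(frac, c_l, env):
    """Total moles of one gas in a closed bottle: headspace (ideal gas law in
    the bottle's own unit system) plus dissolved."""
    return frac * env.P * env.V_G / (env.R * env.T) + c_l * env.V_L


def check_element_balance(coeffs, product_formula):
    """Verify that ``C co2 + a h2 + N nh3 -> product + w h2o`` conserves
    C, H and O exactly; returns the per-element imbalance dict."""
    left = {
        "C": coeffs["co2"],
        "O": 2 * coeffs["co2"],
        "H": 2 * coeffs["h2"] + 3 * coeffs["nh3"],
        "N": coeffs["nh3"],
    }
    right = {
        "C": product_formula.get("C", 0),
        "O": product_formula.get("O", 0) + coeffs["h2o"],
        "H": product_formula.get("H", 0) + 2 * coeffs["h2o"],
        "N": product_formula.get("N", 0),
    }
    return {el: left[el] - right[el] for el in ("C", "H", "O", "N")}
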