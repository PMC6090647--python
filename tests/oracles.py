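"""Independent oracles used by the test suite.

These deliberately re-derive the model arithmetic from the rate
equations with plain scalar Python, independent of the package's
vectorised implementation, so that agreement is meaningful.
"""

from __future__ import annotations

import math


def scalar_batch_rhs(state: dict, p: dict) -> dict:
    """Hand-evaluated batch derivatives from the rate equations."""
    X, S, PA, PYR, AA, SA = (state[k] for k in ("X", "S", "PA", "PYR", "AA", "SA"))
    qs = (p["rs_max"] * S / (p["Ks"] + S)
          * p["kipa"] / (p["kipa"] + PA)
          * p["kiaa"] / (p["kiaa"] + AA))
    u = qs * p["Yxs"] - p["ms"] * p["Yxs"]
    f = PYR / (PYR + p["K_pyr"])
    return {
        "X": u * X,
        "S": -qs * X,
        "PA": (p["K1"] * u + p["beta_pa"]) * X,
        "PYR": (p["K2"] * u + p["beta_pyr"] - p["K3"] * f) * X,
        "AA": (p["K4"] * u + p["beta_aa"] + p["K5"] * f) * X,
        "SA": (p["K6"] * u + p["beta_sa"] + p["K7"] * f) * X,
    }


def scalar_fedbatch_rhs(state: dict, p: dict, F: float, So: float) -> dict:
    """Hand-evaluated fed-batch derivatives (dilution D = F/V)."""
    d = scalar_batch_rhs(state, p)
    V = state["V"]
    D = F / V
    out = {
        "X": d["X"] - D * state["X"],
        "S": d["S"] + D * (So - state["S"]),
        "PA": d["PA"] - D * state["PA"],
        "PYR": d["PYR"] - D * state["PYR"],
        "AA": d["AA"] - D * state["AA"],
        "SA": d["SA"] - D * state["SA"],
        "V": F,
    }
    return out


def rk4_batch(state0: dict, p: dict, t_end: float, dt: float) -> dict:
    """Fixed-step classic Runge–Kutta integration of the batch model.

    Negative concentrations are clamped to zero inside the rate
    evaluation only (matching the package's non-negativity convention).
    """
    names = ("X", "S", "PA", "PYR", "AA", "SA")

    def rhs(y):
        s = dict(zip(names, y))
        for k in ("S", "PA", "PYR", "AA"):  # rates saturate at zero substrate
            s[k] = max(s[k], 0.0)
        d = scalar_batch_rhs(s, p)
        for k in ("PA", "PYR", "AA", "SA"):  # exhausted products stop draining
            if d[k] < 0.0 and s[k] < 1e-6:
                d[k] *= max(s[k], 0.0) / 1e-6
        return [d[k] for k in names]

    y = [state0[k] for k in names]
    n = int(round(t_end / dt))
    for _ in range(n):
        k1 = rhs(y)
        k2 = rhs([yi + 0.5 * dt * ki for yi, ki in zip(y, k1)])
        k3 = rhs([yi + 0.5 * dt * ki for yi, ki in zip(y, k2)])
        k4 = rhs([yi + dt * ki for yi, ki in zip(y, k3)])
        y = [yi + dt / 6.0 * (a + 2 * b + 2 * c + d)
             for yi, a, b, c, d in zip(y, k1, k2, k3, k4)]
    return dict(zip(names, y))


def brute_force_r2(observed_by_var: dict[str, list[float]],
                   simulated_by_var: dict[str, list[float]]) -> float:
    """Direct loop evaluation of the averaged coefficient of determination."""
    contributions = []
    for var, ys in observed_by_var.items():
        yhat = simulated_by_var[var]
        ybar = sum(ys) / len(ys)
        sse = sum((a - b) ** 2 for a, b in zip(ys, yhat))
        sst = sum((a - ybar) ** 2 for a in ys)
        contributions.append(1.0 - sse / sst)
    return sum(contributions) / len(contributions)


def monod_two_point(s1: float, r1: float, s2: float, r2: float) -> tuple[float, float]:
    """Closed-form (Ks, rs_max) through two points on a Monod curve.

    From r = rs_max*S/(Ks+S): Ks = s1*s2*(r2-r1)/(r1*s2 - r2*s1),
    rs_max = r1*(Ks+s1)/s1.
    """
    Ks = s1 * s2 * (r2 - r1) / (r1 * s2 - r2 * s1)
    rs_max = r1 * (Ks + s1) / s1
    return Ks, rs_max
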