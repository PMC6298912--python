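"""Independent brute-force oracles used by the tests.

These deliberately avoid every closed form used by the implementation:
perfusion parameters come from dense grid evaluation of the model curve
(argmax, finite-difference slope, trapezoidal integrals), and the Welch
p-value is cross-checked by label permutation.  Grids are scaled by the
bolus timescale exp(mu) so that the discretisation error stays far below
the comparison tolerances for any draw.
"""

from __future__ import annotations

import numpy as np

from ceusquant import BolusModelParams, evaluate_model


def _parabolic_vertex(x: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """Refine a grid argmax by fitting a parabola through 3 points."""
    if i == 0 or i == len(x) - 1:
        return float(x[i]), float(y[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(x[i]), float(y[i])
    h = x[i] - x[i - 1]
    return (float(x[i] + 0.5 * h * (y0 - y2) / denom),
            float(y1 - 0.125 * (y0 - y2) ** 2 / denom))


def grid_perfusion_oracle(p: BolusModelParams, time_origin: float = 0.0) -> dict:
    """All nine perfusion parameters by brute-force grid numerics."""
    scale = float(np.exp(p.mu))
    # wash-in window: uniform fine grid up to well past the peak
    dt = scale / 40000.0
    t = p.t0 + np.arange(1, int(3 * scale / dt)) * dt
    f = evaluate_model(p, t)
    i = int(np.argmax(f))
    t_peak, f_pk = _parabolic_vertex(t, f, i)
    pe = f_pk - p.O
    d = np.gradient(f, dt)
    j = int(np.argmax(d))
    t_ms, wir = _parabolic_vertex(t, d, j)
    f_ms = float(evaluate_model(p, t_ms)[0])
    t_i = t_ms - (f_ms - p.O) / wir
    rt = t_peak - t_i
    ttp = t_peak - time_origin
    # whole-bolus integrals on a geometric grid covering the support
    x = np.geomspace(scale * np.exp(-10 * p.sigma),
                     scale * np.exp(12 * p.sigma), 400_000)
    enh = evaluate_model(p, p.t0 + x) - p.O
    auc = float(np.trapezoid(enh, x))
    mtt = float(np.trapezoid(x * enh, x) / auc)
    # wash-in integral with exact endpoints
    tw = np.linspace(t_i, t_peak, 20_001)
    wiauc = float(np.trapezoid(evaluate_model(p, tw) - p.O, tw))
    return dict(pe=pe, wir=wir, ttp=ttp, rt=rt, auc=auc, mtt=mtt,
                pi=auc / mtt, wipi=wiauc / rt, wiauc=wiauc)


def permutation_p_value(x, y, n_perm: int = 10_000, seed: int = 0) -> float:
    """Two-sided permutation p-value of the Welch t statistic."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)

    def welch_t(a, b):
        va = a.var(ddof=1) / a.size
        vb = b.var(ddof=1) / b.size
        return (a.mean() - b.mean()) / np.sqrt(va + vb)

    t_obs = abs(welch_t(x, y))
    pooled = np.concatenate([x, y])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(welch_t(perm[: x.size], perm[x.size:])) >= t_obs:
            hits += 1
    return hits / n_perm


def random_bolus_params(rng: np.random.Generator) -> BolusModelParams:
    """A realistic random parameter draw for oracle comparisons."""
    return BolusModelParams(
        O=rng.uniform(0.0, 10.0),
        A=rng.uniform(10.0, 200.0),
        mu=rng.uniform(0.0, 3.0),
        sigma=rng.uniform(0.1, 1.5),
        t0=rng.uniform(0.0, 5.0),
    )
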