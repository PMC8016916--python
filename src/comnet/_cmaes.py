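"""Compact covariance-matrix-adaptation evolution strategy.

A standard (mu/mu_w, lambda) CMA-ES with rank-one and rank-mu covariance
updates and cumulative step-size adaptation, in the textbook
parameterisation.  Box constraints are enforced by projecting sampled
candidates onto the bounds.  Deterministic given the seed.
"""

from __future__ import annotations

import numpy as np


def cmaes_minimize(
    fun,
    x0,
    sigma0: float,
    bounds,
    popsize: int | None = None,
    max_gen: int = 100,
    seed: int | None = None,
    tol_f: float = 0.0,
    callback=None,
) -> dict:
    """Minimise ``fun`` over a box.

    Parameters
    ----------
    fun : callable taking a 1-d array, returning a finite float
        (non-finite values are replaced by a large penalty).
    x0 : initial mean.
    sigma0 : initial step size, in the units of the *normalised* space
        implied by ``bounds`` widths (each coordinate is scaled to unit
        width internally).
    bounds : sequence of (low, high) per coordinate.
    popsize : offspring per generation; default ``4 + 3 ln n``.

    Returns a dict with ``x`` (best point), ``f`` (its value), ``trace``
    (best-so-far value per generation, non-increasing) and ``n_evals``.
    """
    x0 = np.asarray(x0, dtype=float)
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    if (hi <= lo).any():
        raise ValueError("invalid bounds")
    width = hi - lo
    n = x0.size
    rng = np.random.default_rng(seed)

    def to_unit(x):
        return (x - lo) / width

    def from_unit(z):
        return lo + np.clip(z, 0.0, 1.0) * width

    def safe_f(x):
        v = fun(x)
        return float(v) if np.isfinite(v) else 1e12

    lam = popsize or int(4 + np.floor(3 * np.log(n)))
    mu = lam // 2
    w = np.log(mu + 0.5) - np.log(np.arange(1, mu + 1))
    w /= w.sum()
    mueff = 1.0 / np.sum(w**2)

    cc = (4 + mueff / n) / (n + 4 + 2 * mueff / n)
    cs = (mueff + 2) / (n + mueff + 5)
    c1 = 2 / ((n + 1.3) ** 2 + mueff)
    cmu = min(1 - c1, 2 * (mueff - 2 + 1 / mueff) / ((n + 2) ** 2 + mueff))
    ds = 1 + 2 * max(0.0, np.sqrt((mueff - 1) / (n + 1)) - 1) + cs
    chi_n = np.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n**2))

    m = to_unit(x0)
    sigma = float(sigma0)
    C = np.eye(n)
    ps = np.zeros(n)
    pc = np.zeros(n)

    best_x = from_unit(m)
    best_f = safe_f(best_x)
    n_evals = 1
    trace = []

    for gen in range(max_gen):
        vals, vecs = np.linalg.eigh(C)
        vals = np.maximum(vals, 1e-20)
        D = np.sqrt(vals)
        BD = vecs * D

        z = rng.standard_normal((lam, n))
        y = z @ BD.T
        xs_unit = np.clip(m + sigma * y, 0.0, 1.0)
        y_eff = (xs_unit - m) / sigma  # projection-consistent steps
        fs = np.empty(lam)
        for k in range(lam):
            fs[k] = safe_f(from_unit(xs_unit[k]))
        n_evals += lam

        order = np.argsort(fs)
        if fs[order[0]] < best_f:
            best_f = float(fs[order[0]])
            best_x = from_unit(xs_unit[order[0]])
        trace.append(best_f)

        sel = y_eff[order[:mu]]
        y_w = w @ sel
        m = np.clip(m + sigma * y_w, 0.0, 1.0)

        C_inv_sqrt = vecs @ np.diag(1.0 / D) @ vecs.T
        ps = (1 - cs) * ps + np.sqrt(cs * (2 - cs) * mueff) * (C_inv_sqrt @ y_w)
        h_sig = (np.linalg.norm(ps)
                 / np.sqrt(1 - (1 - cs) ** (2 * (gen + 1)))
                 / chi_n) < (1.4 + 2 / (n + 1))
        pc = (1 - cc) * pc + h_sig * np.sqrt(cc * (2 - cc) * mueff) * y_w
        rank_mu = sum(wk * np.outer(yk, yk) for wk, yk in zip(w, sel))
        C = ((1 - c1 - cmu) * C
             + c1 * (np.outer(pc, pc) + (not h_sig) * cc * (2 - cc) * C)
             + cmu * rank_mu)
        C = (C + C.T) / 2
        sigma *= np.exp((cs / ds) * (np.linalg.norm(ps) / chi_n - 1))
        sigma = float(np.clip(sigma, 1e-12, 1.0))

        if callback is not None:
            callback(gen, best_x, best_f)
        if tol_f and best_f <= tol_f:
            break

    return {"x": best_x, "f": best_f, "trace": trace, "n_evals": n_evals}
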