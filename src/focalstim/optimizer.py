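"""Interior-point minimization of the objective over the (amplitude, type) box.

The search treats both coordinates as continuous: amplitude in µA within the
region's window and pulse type as a real coordinate on [1, 5].  Coordinates
are scaled to the unit square internally; the interior-point solver
(trust-region with barrier handling of the bounds, line-search globalized)
starts from the box's minimum corner and stops when the step norm in scaled
coordinates falls below 1e-4.  The continuous optimum is then rounded to the
nearest stimulator-deliverable setting, which may be slightly less optimal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.optimize import Bounds, NonlinearConstraint, minimize

from focalstim.stimulus import (DEFAULT_AMPLITUDE_WINDOW, DEFAULT_RATIO20_WINDOW,
                                PulseParams, round_to_deliverable)

STEP_TOLERANCE = 1e-4
MAX_ITER = 500


@dataclass
class OptimizationResult:
    """Outcome of one bounded objective minimization."""

    x_star: tuple[float, float]          # (amplitude µA, type coordinate)
    f_star: float
    iterates: list[tuple[float, float, float]]   # (a, t, f) visited
    converged: bool
    step_tolerance: float = STEP_TOLERANCE
    n_evals: int = 0
    box: tuple[tuple[float, float], tuple[float, float]] = (
        DEFAULT_AMPLITUDE_WINDOW, (1.0, 5.0))

    def to_dict(self) -> dict:
        return {"x_star": list(self.x_star), "f_star": self.f_star,
                "iterates": [list(it) for it in self.iterates],
                "converged": self.converged, "step_tolerance": self.step_tolerance,
                "n_evals": self.n_evals, "box": [list(b) for b in self.box]}


def minimize_objective(
    f: Callable[[float, float], float],
    box: tuple[tuple[float, float], tuple[float, float]],
    x0: tuple[float, float] | None = None,
    tol: float = STEP_TOLERANCE,
    grad: Callable[[float, float], np.ndarray] | None = None,
    max_iter: int = MAX_ITER,
    multi_start: int = 0,
    pair=None,
) -> OptimizationResult:
    """Minimize ``f(a, t)`` over the box with an interior-point search.

    Parameters
    ----------
    f : callable
        Objective; must be finite over the box.
    box : ((a_lo, a_hi), (t_lo, t_hi))
    x0 : start point; defaults to the minimum corner (lowest amplitude and
        type), replicating the experimental initial condition.
    tol : step tolerance in scaled (unit-box) coordinates.
    grad : optional analytic gradient d f / d (a, t); finite differences
        otherwise.
    multi_start : number of additional random interior starts (off by
        default to preserve the single-start protocol).
    pair : optional :class:`focalstim.surrogate.SurrogatePair`
        When given, the |A - C| kink is handled exactly by the smooth
        epigraph program  min s + E(a, t)  s.t.  -s <= A(a, t) - C <= s,
        the standard interior-point treatment of an absolute value; the
        plain path (quasi-Newton on the nonsmooth f) can stall on the
        A = C valley.

    Returns
    -------
    OptimizationResult
        Best point found; ``f_star <= f(x0)`` always holds because the
        incumbent is the best over all accepted iterates.
    """
    (a_lo, a_hi), (t_lo, t_hi) = box
    lo = np.array([a_lo, t_lo])
    span = np.array([a_hi - a_lo, t_hi - t_lo])
    if x0 is None:
        x0 = (a_lo, t_lo)
    z0 = (np.asarray(x0, dtype=float) - lo) / span

    n_evals = 0

    def fz(z):
        nonlocal n_evals
        n_evals += 1
        x = lo + z * span
        val = f(x[0], x[1])
        if not np.isfinite(val):
            raise ValueError(f"objective non-finite at {tuple(x)}")
        return float(val)

    if grad is not None:
        def gz(z):
            x = lo + z * span
            return np.asarray(grad(x[0], x[1]), dtype=float) * span
        jac = gz
    else:
        jac = "2-point"

    if not np.isfinite(fz(z0)):
        raise ValueError("objective not finite at the starting point")

    iterates: list[tuple[float, float, float]] = []
    starts = [z0]
    if multi_start:
        rng = np.random.default_rng(0)
        starts += [rng.uniform(0.05, 0.95, 2) for _ in range(multi_start)]

    best = None
    for zs in starts:
        trace: list[tuple[float, float, float]] = []

        def record(zk, state=None):
            x = lo + np.clip(zk, 0, 1) * span
            trace.append((float(x[0]), float(x[1]), fz(np.clip(zk, 0, 1))))

        record(zs)
        if pair is not None:
            res = _minimize_epigraph(pair, zs, lo, span, tol, max_iter, record)
        else:
            res = minimize(
                fz, zs, jac=jac, bounds=Bounds(np.zeros(2), np.ones(2)),
                method="trust-constr", callback=record,
                options={"xtol": tol, "gtol": 1e-12, "maxiter": max_iter,
                         "initial_tr_radius": 0.1},
            )
        record(np.asarray(res.x)[:2])
        # incumbent: best accepted iterate (guards against a final step that
        # the solver reports but that did not improve f)
        bi = int(np.argmin([t[2] for t in trace]))
        cand = (trace[bi], res.status, trace)
        if best is None or cand[0][2] < best[0][2]:
            best = cand
            iterates = trace

    (a_best, t_best, f_best), status, trace = best
    # accepted iterates: the improving subsequence of the solver trace
    # (trust-region steps that failed to improve f are proposals, not moves)
    accepted: list[tuple[float, float, float]] = []
    for it in trace:
        if not accepted or it[2] < accepted[-1][2]:
            accepted.append(it)
    converged = status in (1, 2) and len(trace) <= max_iter + 2
    return OptimizationResult(
        x_star=(a_best, t_best), f_star=f_best, iterates=accepted,
        converged=bool(converged), step_tolerance=tol, n_evals=n_evals, box=box,
    )


def _minimize_epigraph(pair, z0, lo, span, tol, max_iter, record):
    """Interior-point solve of min s + E(a,t) s.t. -s <= A(a,t) - C <= s.

    Works in scaled coordinates z = (x - lo) / span with the slack s as a
    third variable; constraint Jacobians use the networks' analytic
    gradients.  Equivalent to minimizing |A - C| + E but smooth, so the
    trust-region steps do not collapse on the A = C valley.
    """
    def A_of(z):
        x = lo + z * span
        return float(pair.area_net(x[0], x[1]))

    def gA_of(z):
        x = lo + z * span
        return pair.area_net.gradient(x[0], x[1]) * span

    def E_of(z):
        x = lo + z * span
        return float(pair.ecc_net(x[0], x[1]))

    def gE_of(z):
        x = lo + z * span
        return pair.ecc_net.gradient(x[0], x[1]) * span

    def obj(v):
        return E_of(v[:2]) + v[2]

    def obj_grad(v):
        g = np.empty(3)
        g[:2] = gE_of(v[:2])
        g[2] = 1.0
        return g

    def cons_f(v):
        d = A_of(v[:2]) - pair.C
        return np.array([v[2] - d, v[2] + d])

    def cons_jac(v):
        gA = gA_of(v[:2])
        return np.array([[-gA[0], -gA[1], 1.0], [gA[0], gA[1], 1.0]])

    s0 = abs(A_of(z0) - pair.C) + 1e-3
    v0 = np.array([z0[0], z0[1], s0])
    bounds = Bounds(np.array([0.0, 0.0, 0.0]), np.array([1.0, 1.0, np.inf]))
    constr = NonlinearConstraint(cons_f, 0.0, np.inf, jac=cons_jac)

    def cb(vk, state=None):
        record(vk[:2])

    return minimize(obj, v0, jac=obj_grad, bounds=bounds, constraints=[constr],
                    method="trust-constr", callback=cb,
                    options={"xtol": tol, "gtol": 1e-12, "maxiter": max_iter})


def propose_stimulus(
    result: OptimizationResult,
    amplitude_window: tuple[float, float] | None = None,
    ratio20_window: tuple[float, float] = DEFAULT_RATIO20_WINDOW,
) -> PulseParams:
    """Round the continuous optimum to a stimulator-deliverable pulse.

    The deliverable point can be slightly less optimal than the continuous
    one; callers log both objective values.  Idempotent on already
    deliverable optima.
    """
    if amplitude_window is None:
        amplitude_window = result.box[0]
    a, t = result.x_star
    return round_to_deliverable(a, t, amplitude_window=amplitude_window,
                                ratio20_window=ratio20_window)
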