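"""Stochastic two-gene circuit with morphogen input.

Each cell carries intracellular morphogen M_in and two mutually antagonistic,
self-activating genes A and B (the hoxb1a/krox20 analogue).  Deterministic
kinetics:

    dM_in/dt = k_M (M_out - M_in) - S(M_in)
    dA/dt    = (1/tau) [ C_A (a + kappa_A M_in^m_A) / (1 + a + chi_B b + kappa_A M_in^m_A) - d_A A ]
    dB/dt    = (1/tau) [ C_B (b + w_B(M_in))        / (1 + chi_A a + b + w_B(M_in))        - d_B B ]

    where a = (A/K_A)^n_A and b = (B/K_B)^n_B are the self-activation Hill
    terms (K_A, K_B set the concentration scale of the stable states),

with w_B = kappa_B M^m_B (+ an optional low-M activation branch used by the
three-zone scenario) and S a saturating Hill sink standing in for
morphogen degradation by a second intracellular signal.  The shared
denominator implements mutual antagonism; at intermediate morphogen levels
the A/B subsystem is bistable, and the steeper morphogen dependence of B
(m_B > m_A) deepens the B basin posteriorly, which makes noise-driven A->B
switching far more likely than the reverse.

Stochastic integration is Euler-Maruyama with independent additive Gaussian
noise per channel; negative excursions are clipped to 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import root

from .params import GeneParams
from .scem_mechanics import CellExpressionState, Fate

__all__ = [
    "drift",
    "drift_arrays",
    "step_expression",
    "step_expression_arrays",
    "fate_of",
    "FixedPoint",
    "steady_states",
    "bistability_report",
]


def _sink(M, p: GeneParams):
    sp = p.S_params
    Mh = np.power(M, sp.h_S)
    return sp.V_S * Mh / (sp.K_S**sp.h_S + Mh)


def _w_A(M, p: GeneParams):
    return p.kappa_A * np.power(M, p.m_A)


def _w_B(M, p: GeneParams):
    w = p.kappa_B * np.power(M, p.m_B)
    if p.kappa_B_low > 0:
        w = w + p.kappa_B_low / (1.0 + np.power(M / p.K_low, p.h_low))
    return w


def drift_arrays(M_in, A, B, M_out, p: GeneParams):
    """Deterministic time-derivatives (dM_in, dA, dB); vectorised over cells."""

    An = np.power(A / p.K_A, p.n_A)
    Bn = np.power(B / p.K_B, p.n_B)
    wA = _w_A(M_in, p)
    wB = _w_B(M_in, p)
    den_A = 1.0 + An + p.chi_B * Bn + wA
    den_B = 1.0 + p.chi_A * An + Bn + wB
    dM = p.k_M * (M_out - M_in) - _sink(M_in, p)
    dA = (p.C_A * (An + wA) / den_A - p.d_A * A) / p.tau
    dB = (p.C_B * (Bn + wB) / den_B - p.d_B * B) / p.tau
    return dM, dA, dB


def drift(
    state: CellExpressionState, M_out_local: float, params: GeneParams
) -> tuple[float, float, float]:
    """Deterministic derivatives for one cell; inputs must be non-negative."""

    vals = (state.M_in, state.A, state.B, M_out_local)
    if min(vals) < 0:
        raise ValueError("concentrations must be >= 0")
    dM, dA, dB = drift_arrays(*map(np.float64, vals), params)
    return float(dM), float(dA), float(dB)


def step_expression_arrays(M_in, A, B, M_out, p: GeneParams, dt: float, rng):
    """In-place Euler-Maruyama update of the per-cell arrays.

    Returns the number of channel values clipped at zero this step (positivity
    guard; callers warn when clipping is frequent).
    """

    dM, dA, dB = drift_arrays(M_in, A, B, M_out, p)
    sq = np.sqrt(dt)
    n = len(M_in)
    M_in += dM * dt
    A += dA * dt
    B += dB * dt
    if p.eta_in > 0:
        M_in += p.eta_in * sq * rng.standard_normal(n)
    if p.eta_A > 0:
        A += p.eta_A * sq * rng.standard_normal(n)
    if p.eta_B > 0:
        B += p.eta_B * sq * rng.standard_normal(n)
    clipped = int(np.sum(M_in < 0) + np.sum(A < 0) + np.sum(B < 0))
    np.clip(M_in, 0.0, None, out=M_in)
    np.clip(A, 0.0, None, out=A)
    np.clip(B, 0.0, None, out=B)
    return clipped


def step_expression(
    state: CellExpressionState,
    M_out_local: float,
    params: GeneParams,
    dt: float,
    rng: np.random.Generator,
) -> CellExpressionState:
    """One stochastic update of a single cell's expression state."""

    if dt <= 0:
        raise ValueError("dt must be > 0")
    if min(state.M_in, state.A, state.B, M_out_local) < 0:
        raise ValueError("concentrations must be >= 0")
    M = np.array([state.M_in])
    A = np.array([state.A])
    B = np.array([state.B])
    step_expression_arrays(M, A, B, np.array([M_out_local]), params, dt, rng)
    return CellExpressionState(M_in=float(M[0]), A=float(A[0]), B=float(B[0]))


def fate_of(state: CellExpressionState, previous: Fate | None = None) -> Fate:
    """Dominant-gene readout: A if [A] > [B], B if [B] > [A].

    An exact tie keeps the previous fate (hysteresis); with no history the
    anterior default A is used.
    """

    if state.A > state.B:
        return Fate.A
    if state.B > state.A:
        return Fate.B
    return previous if previous is not None else Fate.A


# ---------------------------------------------------------------------------
# deterministic fixed-point analysis (clamped M_in)


@dataclass
class FixedPoint:
    A: float
    B: float
    stable: bool
    depth: float | None = None  # basin-radius surrogate, filled for bistable pairs
    converged: bool = True


def _ab_rhs(y, M, p: GeneParams):
    A, B = y
    _, dA, dB = drift_arrays(np.float64(M), np.float64(max(A, 0.0)), np.float64(max(B, 0.0)), np.float64(M), p)
    return [dA, dB]


def _jacobian(A, B, M, p: GeneParams, eps=1e-7):
    J = np.zeros((2, 2))
    f0 = np.array(_ab_rhs([A, B], M, p))
    for k, (dA_, dB_) in enumerate([(eps, 0.0), (0.0, eps)]):
        f1 = np.array(_ab_rhs([A + dA_, B + dB_], M, p))
        J[:, k] = (f1 - f0) / eps
    return J


def _relax_to_state(y0, M, p: GeneParams, t_max=400.0):
    """Deterministic relaxation of the clamped A/B subsystem (adaptive Euler)."""

    y = np.array(y0, dtype=float)
    t, dt = 0.0, 0.01 * p.tau
    while t < t_max:
        dy = np.array(_ab_rhs(y, M, p))
        step = min(dt, 0.2 / (np.max(np.abs(dy)) / (np.max(np.abs(y)) + 1e-3) + 1e-9))
        y = np.clip(y + dy * step, 0.0, None)
        t += step
        if np.max(np.abs(dy)) * p.tau < 1e-10:
            break
    return y


def steady_states(M_in_fixed: float, params: GeneParams, n_grid: int = 6) -> list[FixedPoint]:
    """Stable fixed points of the deterministic A/B subsystem at clamped M_in.

    Multi-start root finding over an n_grid x n_grid lattice of initial
    conditions spanning the accessible concentration range; duplicates are
    merged, stability is read from the numerical Jacobian, and for a bistable
    pair each state is assigned a basin-depth surrogate: the minimal fraction
    of the straight-line displacement toward the competing state from which
    deterministic relaxation escapes the basin (larger = deeper basin).
    """

    if M_in_fixed < 0:
        raise ValueError("M_in must be >= 0")
    p = params
    amax = 1.5 * max(p.C_A / p.d_A, p.C_B / p.d_B)
    starts = np.linspace(0.0, amax, n_grid)
    found: list[FixedPoint] = []
    any_failed = False
    for a0 in starts:
        for b0 in starts:
            sol = root(_ab_rhs, [a0, b0], args=(M_in_fixed, p), method="hybr", tol=1e-12)
            if not sol.success:
                any_failed = True
                continue
            A, B = np.clip(sol.x, 0.0, None)
            if np.max(np.abs(_ab_rhs([A, B], M_in_fixed, p))) > 1e-7:
                continue
            if any(abs(A - f.A) < 1e-5 and abs(B - f.B) < 1e-5 for f in found):
                continue
            eig = np.linalg.eigvals(_jacobian(A, B, M_in_fixed, p))
            found.append(FixedPoint(A=float(A), B=float(B), stable=bool(np.all(eig.real < 0))))
    if any_failed and not found:
        return [FixedPoint(A=np.nan, B=np.nan, stable=False, converged=False)]
    stable = [f for f in found if f.stable]
    if len(stable) == 2:
        y1 = np.array([stable[0].A, stable[0].B])
        y2 = np.array([stable[1].A, stable[1].B])
        for f, here, there in ((stable[0], y1, y2), (stable[1], y2, y1)):
            f.depth = _escape_fraction(here, there, M_in_fixed, p)
    return sorted(found, key=lambda f: f.A - f.B, reverse=True)


def _escape_fraction(here: np.ndarray, there: np.ndarray, M: float, p: GeneParams) -> float:
    """Minimal fraction along the line here->there from which relaxation leaves
    the basin of ``here``; a bisection-based basin-radius surrogate in [0, 1]."""

    def escapes(frac: float) -> bool:
        y = _relax_to_state(here + frac * (there - here), M, p)
        return np.linalg.norm(y - there) < np.linalg.norm(y - here)

    if not escapes(1.0):
        return 1.0
    lo, hi = 0.0, 1.0
    for _ in range(20):
        mid = 0.5 * (lo + hi)
        if escapes(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def bistability_report(M_values, params: GeneParams):
    """Tabulate the stable states and basin depths along a clamped-M sweep."""

    import pandas as pd

    rows = []
    for M in M_values:
        fps = [f for f in steady_states(M, params) if f.stable]
        fps = sorted(fps, key=lambda f: f.A - f.B, reverse=True)
        row = {"M_in": M, "n_stable_states": len(fps)}
        for label, f in zip(("1", "2"), fps):
            row[f"A_{label}"] = f.A
            row[f"B_{label}"] = f.B
            row[f"depth_{label}"] = f.depth
        rows.append(row)
    return pd.DataFrame(rows)
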