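"""Bayesian weight of evidence that the active representation is valid.

After each sample the automaton knows three counts: ``Z_cur`` attributes
currently observed, ``Z_rec`` attributes recalled by the active hippocampal
representation, and their intersection ``Z_com``.  The weight of evidence is

    B_Rep = log10( P[Z_com | Same, Z_cur, Z_rec] / P[Z_com | Diff, Z_cur, Z_rec] )

where *Same* means the active representation belongs to the current context
and *Diff* that it belongs to a different one.

Under *Same* the recalled attributes are a subset of the current context's
``N_A`` attributes, the sample is a uniform ``Z_cur``-subset, and the overlap
is hypergeometric.  Under *Diff* the recalled set belongs to another context;
only recalled attributes that are also present in the current context can be
sampled.  Writing ``m`` for the number of recalled attributes present in the
current context,

    Z_com | m  ~  Hypergeom(N_A, m, Z_cur)

and the distribution of ``m`` depends on the assumed relation between two
different contexts:

* ``shared_core`` (default): different contexts have exactly the ``N_Gen``
  general attributes in common, so ``m ~ Hypergeom(N_A, N_Gen, Z_rec)``.
* ``ensemble``: the two contexts' unique attributes are drawn independently
  from the non-general pool (exactly how the synthetic world builds
  unconstrained contexts), so they share ``u`` uniques by chance,
  ``u ~ Hypergeom(N_Ctx - N_Gen, N_A - N_Gen, N_A - N_Gen)``, and
  ``m | u ~ Hypergeom(N_A, N_Gen + u, Z_rec)``.

The decomposition into general / shared-unique / other attribute classes
collapses to the mixture above because the sample is uniform over all
``N_A`` attributes regardless of class.

All probabilities are computed with :mod:`scipy.stats` hypergeometric PMFs
(log-gamma based) and memoized per ``(Z_cur, Z_rec)`` query.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import hypergeom

from .params import ModelParams

__all__ = [
    "EvidenceQuery",
    "p_same",
    "p_diff",
    "p_same_pmf",
    "p_diff_pmf",
    "b_rep",
    "expected_z_com",
    "expected_b_rep",
    "brep_table",
    "ApproxCircuitParams",
    "calibrate_approx_circuit",
    "b_rep_approx",
]

#: Symmetric clamp for infinite log-odds, in log10 units.
B_CLAMP = 50.0


@dataclass(frozen=True)
class EvidenceQuery:
    """One evidence evaluation: observed, recalled and common counts."""

    z_cur: int
    z_rec: int
    z_com: int
    params: ModelParams

    def __post_init__(self):
        p = self.params
        if not (0 <= self.z_cur <= p.N_A and 0 <= self.z_rec <= p.N_A):
            raise ValueError(
                f"Z_cur={self.z_cur}, Z_rec={self.z_rec} must lie in [0, N_A={p.N_A}]"
            )
        if not 0 <= self.z_com <= min(self.z_cur, self.z_rec):
            raise ValueError(
                f"Z_com={self.z_com} outside [0, min(Z_cur, Z_rec)="
                f"{min(self.z_cur, self.z_rec)}]"
            )


def _validate(z_cur: int, z_rec: int, z_com: int, n_a: int) -> None:
    if not (0 <= z_cur <= n_a and 0 <= z_rec <= n_a):
        raise ValueError(f"Z_cur={z_cur}, Z_rec={z_rec} must lie in [0, N_A={n_a}]")
    if not 0 <= z_com <= min(z_cur, z_rec):
        raise ValueError(f"Z_com={z_com} outside [0, min(Z_cur, Z_rec)]")


# -- "Same" hypothesis ------------------------------------------------------


@lru_cache(maxsize=None)
def _p_same_pmf(z_cur: int, z_rec: int, n_a: int) -> np.ndarray:
    z = np.arange(n_a + 1)
    pmf = hypergeom.pmf(z, n_a, z_rec, z_cur)
    pmf.flags.writeable = False
    return pmf


def p_same_pmf(z_cur: int, z_rec: int, n_a: int) -> np.ndarray:
    """PMF of ``Z_com`` over ``0..N_A`` under the *Same* hypothesis."""
    return _p_same_pmf(z_cur, z_rec, n_a)


def p_same(z_com: int, z_cur: int, z_rec: int, n_a: int) -> float:
    """Hypergeometric probability of overlap ``z_com`` when the recalled
    attributes belong to the current context."""
    _validate(z_cur, z_rec, z_com, n_a)
    return float(_p_same_pmf(z_cur, z_rec, n_a)[z_com])


# -- "Diff" hypothesis ------------------------------------------------------


@lru_cache(maxsize=None)
def _p_diff_pmf(
    z_cur: int, z_rec: int, n_a: int, n_gen: int, n_ctx: int, model: str
) -> np.ndarray:
    ms = np.arange(n_a + 1)
    zs = np.arange(n_a + 1)
    # P(Z_com | m): overlap of the sample with the m recalled attributes
    # that are present in the current context.
    overlap = hypergeom.pmf(zs[None, :], n_a, ms[:, None], z_cur)
    if model == "shared_core":
        pm = hypergeom.pmf(ms, n_a, n_gen, z_rec)
    elif model == "ensemble":
        umax = n_a - n_gen
        us = np.arange(umax + 1)
        pu = hypergeom.pmf(us, n_ctx - n_gen, umax, umax)
        pm = np.zeros(n_a + 1)
        for u, w in zip(us, pu):
            if w > 0:
                pm += w * hypergeom.pmf(ms, n_a, n_gen + u, z_rec)
    else:  # pragma: no cover - guarded by ModelParams validation
        raise ValueError(f"unknown diff model {model!r}")
    pmf = pm @ overlap
    pmf.flags.writeable = False
    return pmf


def p_diff_pmf(z_cur: int, z_rec: int, p: ModelParams) -> np.ndarray:
    """PMF of ``Z_com`` over ``0..N_A`` under the *Diff* hypothesis."""
    return _p_diff_pmf(z_cur, z_rec, p.N_A, p.N_Gen, p.N_Ctx, p.diff_model)


def p_diff(z_com: int, z_cur: int, z_rec: int, p: ModelParams) -> float:
    """Probability of overlap ``z_com`` when the recalled set belongs to a
    different context of the ensemble."""
    _validate(z_cur, z_rec, z_com, p.N_A)
    return float(p_diff_pmf(z_cur, z_rec, p)[z_com])


# -- weight of evidence -----------------------------------------------------


def b_rep(
    z_cur: int,
    z_rec: int,
    z_com: int,
    p: ModelParams,
    *,
    ecout_silent: bool = False,
) -> float:
    """log10 odds that the active representation matches the current context.

    Exactly 0 when the entorhinal output layer is silent (no recalled
    attributes — including the cases where the pre-recurrent CA3 pattern was
    too small or downstream activity was suppressed by an evidence tie).
    Returns ``p.b_floor`` when the observation is impossible under *Same*
    (in particular whenever ``Z_cur - Z_com + Z_rec > N_A``), and the
    symmetric positive clamp when it is impossible under *Diff*.
    """
    if ecout_silent:
        return 0.0
    if z_rec > p.N_A:
        # More attributes recalled than any one context possesses: impossible
        # under "Same" (a representation corrupted by cross-context updating),
        # so the evidence is floored and the representation self-discredits.
        return p.b_floor
    _validate(z_cur, z_rec, z_com, p.N_A)
    ps = float(_p_same_pmf(z_cur, z_rec, p.N_A)[z_com])
    pd = float(p_diff_pmf(z_cur, z_rec, p)[z_com])
    if ps <= 0.0:
        return p.b_floor
    if pd <= 0.0:
        return abs(p.b_floor)
    value = math.log10(ps / pd)
    return float(np.clip(value, p.b_floor, abs(p.b_floor)))


def expected_z_com(z_cur: float, z_rec: float, n_a: int) -> float:
    """Expected overlap ``Z_cur * Z_rec / N_A`` under the *Same* hypothesis."""
    return z_cur * z_rec / n_a


def expected_b_rep(z_cur: int, z_rec: int, p: ModelParams) -> float:
    """Weight of evidence at the expected (real-valued) overlap.

    Linear interpolation of :func:`b_rep` between the two integer ``Z_com``
    values adjacent to ``Z_cur * Z_rec / N_A``.
    """
    ez = expected_z_com(z_cur, z_rec, p.N_A)
    lo = int(math.floor(ez))
    lo = min(lo, min(z_cur, z_rec))
    b_lo = b_rep(z_cur, z_rec, lo, p)
    if ez <= lo or lo >= min(z_cur, z_rec):
        return b_lo
    b_hi = b_rep(z_cur, z_rec, lo + 1, p)
    return b_lo + (ez - lo) * (b_hi - b_lo)


def brep_table(p: ModelParams, z_curs, z_recs):
    """Tidy table of exact ``B_Rep`` values over a grid (one row per
    ``(Z_cur, Z_rec, Z_com)`` triple)."""
    import pandas as pd

    rows = []
    for zc in z_curs:
        for zr in z_recs:
            for zm in range(min(zc, zr) + 1):
                rows.append((zc, zr, zm, b_rep(zc, zr, zm, p)))
    return pd.DataFrame(rows, columns=["Z_cur", "Z_rec", "Z_com", "B_Rep"])


# -- functional emulation of the evidence-computing circuit ----------------


@dataclass(frozen=True)
class ApproxCircuitParams:
    """Fitted parameters of the rate-coded evidence approximator.

    The circuit receives ``Z_lo = min(Z_cur, Z_rec)``, ``Z_hi = max(...)``
    and ``Z_com`` as firing rates.  An envelope cell transforms ``Z_com``
    into a power function (``env_gain * Z_com ** env_exp``) approximating the
    upper envelope of the exact curves (reached when ``Z_com = Z_lo =
    Z_hi``); a divisive-inhibition cell scales it down by
    ``1 + (Z_hi * (Z_lo - Z_com) / inh_scale) ** inh_exp``; the output cell
    adds a baseline leak so its rate can fall below baseline to signal
    invalidity; and an impossibility-detecting cell forces the floor whenever
    ``Z_lo + Z_hi - Z_com > N_A``.
    """

    env_exp: float
    env_gain: float
    inh_exp: float
    inh_scale: float
    baseline: float
    rmse: float
    grid_step: int


def _approx_eval(theta, z_lo, z_hi, z_com):
    baseline, log_env_gain, env_exp, log_inh_scale, inh_exp = theta
    env = np.exp(log_env_gain) * np.power(np.maximum(z_com, 0.0), env_exp)
    arg = np.maximum(z_hi * (z_lo - z_com), 0.0)
    # inhibition (arg / scale)**b computed in log space; zero when arg == 0
    with np.errstate(divide="ignore"):
        log_arg = np.log(np.where(arg > 0, arg, 1.0))
    inh = np.where(arg > 0, np.exp(inh_exp * (log_arg - log_inh_scale)), 0.0)
    return baseline + env / (1.0 + inh)


def calibrate_approx_circuit(
    p: ModelParams, *, grid_step: int = 5, z_min: int = 30
) -> ApproxCircuitParams:
    """Least-squares fit of the circuit against exact ``B_Rep`` values.

    The fit grid spans ``Z_lo, Z_hi`` from ``z_min`` to ``N_A`` in steps of
    ``grid_step`` with ``Z_com`` from 0 to ``Z_lo``; impossible points (those
    the dedicated impossibility cell handles) and clamped infinities are
    excluded from the residuals.
    """
    zs = range(z_min, p.N_A + 1, grid_step)
    pts = []
    for z_lo in zs:
        for z_hi in zs:
            if z_hi < z_lo:
                continue
            for z_com in range(z_lo + 1):
                if z_lo + z_hi - z_com > p.N_A:
                    continue
                exact = b_rep(z_hi, z_lo, z_com, p)
                if abs(exact) >= abs(p.b_floor):
                    continue
                pts.append((z_lo, z_hi, z_com, exact))
    arr = np.array(pts, dtype=float)
    z_lo, z_hi, z_com, exact = arr.T

    def residuals(theta):
        return _approx_eval(theta, z_lo, z_hi, z_com) - exact

    theta0 = np.array([-5.0, math.log(0.05), 1.5, math.log(2000.0), 1.5])
    fit = least_squares(residuals, theta0, max_nfev=20_000)
    if not fit.success:
        raise RuntimeError(
            f"circuit calibration did not converge: {fit.message}; "
            f"residual norm {np.linalg.norm(fit.fun):.3g}"
        )
    rmse = float(np.sqrt(np.mean(fit.fun**2)))
    baseline, log_eg, env_exp, log_s, inh_exp = fit.x
    return ApproxCircuitParams(
        env_exp=float(env_exp),
        env_gain=float(np.exp(log_eg)),
        inh_exp=float(inh_exp),
        inh_scale=float(np.exp(log_s)),
        baseline=float(baseline),
        rmse=rmse,
        grid_step=grid_step,
    )


def b_rep_approx(
    z_cur: int, z_rec: int, z_com: int, circ: ApproxCircuitParams, p: ModelParams
) -> float:
    """Evaluate the fitted circuit (a firing rate on the ``B_Rep`` scale)."""
    z_lo, z_hi = min(z_cur, z_rec), max(z_cur, z_rec)
    if z_lo + z_hi - z_com > p.N_A:
        return p.b_floor
    theta = (
        circ.baseline,
        math.log(circ.env_gain),
        circ.env_exp,
        math.log(circ.inh_scale),
        circ.inh_exp,
    )
    return float(_approx_eval(theta, float(z_lo), float(z_hi), float(z_com)))
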