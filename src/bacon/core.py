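"""Neuron-level primitives: membrane equation, linear sigmoid, KWTA.

Every cell in the network is an instantaneous rate or binary unit.  A cell's
depolarization follows a conductance-based steady state, its activation is a
clipped linear ("linear sigmoid") function of depolarization, and population
firing in dentate and CA3 is regulated by K-winners-take-all (KWTA)
competition with two tie-breaking regimes:

* ``keep_ties=False`` — independent uniform noise on ``(0, noise_eps)`` is
  added to every *nonzero* excitation so that ties cannot occur, and at most
  exactly ``k`` cells with strictly positive excitation win.  This is the
  regime of the afferent-driven competitions.
* ``keep_ties=True`` — no noise; the k-th highest excitation defines a
  cutoff and every cell at or above it wins, so more than ``k`` cells may
  fire.  This is the regime of the recurrent collateral iterations, where
  unresolved ties must be propagated rather than broken.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

__all__ = ["membrane_potential", "linsig", "kwta"]


def membrane_potential(ge, gi, e: float = 1.0):
    """Steady-state depolarization of a cell relative to rest.

    ``V = Ge * E / (1 + Ge + Gi)`` with ``Ge``/``Gi`` the total excitatory
    and inhibitory conductances relative to leak and ``E`` the excitatory
    reversal potential.  Accepts scalars or arrays.
    """
    ge = np.asarray(ge, dtype=float)
    gi = np.asarray(gi, dtype=float)
    if np.any(ge < 0) or np.any(gi < 0):
        raise ValueError("conductances must be non-negative")
    v = ge * e / (1.0 + ge + gi)
    return float(v) if v.ndim == 0 else v


def linsig(v, thrsh: float, mxat: float):
    """Linear sigmoid activation: 0 below ``thrsh``, 1 above ``mxat``,
    linear in between.  Accepts scalars or arrays."""
    if not thrsh < mxat:
        raise ValueError(f"linsig requires thrsh < mxat (got {thrsh} >= {mxat})")
    v = np.asarray(v, dtype=float)
    out = np.clip((v - thrsh) / (mxat - thrsh), 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def _as_arrays(excitation) -> tuple[np.ndarray, np.ndarray]:
    """Normalize an excitation map (dict or array) to (indices, values)."""
    if isinstance(excitation, Mapping):
        if not excitation:
            return np.empty(0, dtype=np.int64), np.empty(0)
        idx = np.fromiter(excitation.keys(), dtype=np.int64, count=len(excitation))
        val = np.fromiter(excitation.values(), dtype=float, count=len(excitation))
        return idx, val
    val = np.asarray(excitation, dtype=float)
    return np.arange(val.size, dtype=np.int64), val


def kwta(
    excitation,
    k: int,
    *,
    keep_ties: bool = False,
    rng: np.random.Generator | None = None,
    noise_eps: float = 1e-6,
) -> np.ndarray:
    """K-winners-take-all selection over an excitation map.

    Parameters
    ----------
    excitation:
        Either a 1-D array of excitation levels indexed by cell, or a mapping
        ``cell index -> excitation``.  Cells with excitation exactly zero are
        never selected (a silent cell cannot win).
    k:
        Winner count.
    keep_ties:
        Tie regime, see module docstring.
    rng:
        Random source for the tie-breaking noise (``keep_ties=False`` only).
        When omitted the selection is deterministic and residual ties are
        broken by lowest index.
    noise_eps:
        Noise half-width; must be far below the excitation quantum so that
        noise can only reorder exact ties.

    Returns
    -------
    numpy.ndarray
        Sorted winner cell indices.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    idx, val = _as_arrays(excitation)
    pos = val > 0
    idx, val = idx[pos], val[pos]
    if idx.size == 0:
        return np.empty(0, dtype=np.int64)

    if keep_ties:
        if idx.size <= k:
            return np.sort(idx)
        cutoff = np.partition(val, idx.size - k)[idx.size - k]
        return np.sort(idx[val >= cutoff])

    if rng is not None:
        val = val + rng.uniform(0.0, noise_eps, size=val.size)
    if idx.size <= k:
        return np.sort(idx)
    order = np.argpartition(-val, k - 1)[:k]
    return np.sort(idx[order])
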