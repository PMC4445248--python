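"""Anatomy and operating modes of the hippocampal network.

The network holds ``N_Hipp`` dentate cells and ``N_Hipp`` CA3 cells paired
one-to-one into dyads (dentate cell *i* drives CA3 cell *i* through a strong
non-plastic relay).  Each dentate and each CA3 cell is innervated by ``F``
entorhinal input cells, drawn uniformly and independently; these Hebbian
synapses are completely ineffective until potentiated.  Every CA3 cell
recurrently innervates every other, and every CA3 cell reaches every
entorhinal output cell, again through initially silent Hebbian synapses.

Three operating modes are implemented as three operations:

* :func:`create_representation` — all anatomical entorhinal synapses
  transmit regardless of potentiation; the ``K`` most innervated dentate
  cells win a noisy KWTA competition, their dyads become the permanent
  representation, and all co-active Hebbian synapses potentiate (entorhinal
  weights normalized to sum one per cell; recurrent and output weights fixed
  at one).
* :func:`recall_cycle` — read-only: dentate cells fire at rates equal to the
  fraction of their learned attributes currently observed, CA3 receives the
  dyad relay plus ``dpf`` times the potentiated direct pathway, a noisy KWTA
  produces the pre-recurrent pattern, and (if at least ``K_0`` cells fire)
  recurrent collateral iterations with tie-preserving KWTA settle the final
  pattern, which drives entorhinal output unless ties left more than ``K``
  cells active.
* :func:`update_representation` — the active representation's cells (never
  any new cells) potentiate synapses from every currently sampled or
  recalled attribute among their afferents, associating new attributes with
  an existing representation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .core import kwta
from .params import ModelParams

__all__ = [
    "HippocampalNet",
    "RepresentationRecord",
    "LesionConfig",
    "RecallResult",
    "DegenerateWorldError",
    "build_net",
    "create_representation",
    "recall_cycle",
    "update_representation",
    "representation_overlap",
]


class DegenerateWorldError(RuntimeError):
    """Fewer cells with positive excitation than winners required."""


@dataclass(frozen=True)
class LesionConfig:
    """Which dentate functions are switched off, per phase.

    ``dg_off_encoding`` silences the dentate relay during representation
    creation (CA3 winners are then chosen by direct-path innervation) and
    blocks dentate potentiation during creation and updating.
    ``dg_off_recall`` silences the dentate relay during recall, leaving only
    the direct pathway (scaled by ``dpf``).  ``dg_plasticity_off`` blocks
    dentate potentiation everywhere while leaving transmission intact.
    The flags are independent so that encoding- and recall-side
    inactivations can be combined factorially.
    """

    dg_off_encoding: bool = False
    dg_off_recall: bool = False
    dg_plasticity_off: bool = False


INTACT = LesionConfig()


@dataclass(frozen=True)
class RepresentationRecord:
    """The permanent representation of one context: exactly ``K`` dyads."""

    rep_id: int
    cells: frozenset
    created_at_zcur: int
    context_id: str | None = None  # bookkeeping only, never read by the algorithm


@dataclass(frozen=True)
class RecallResult:
    ptrn_o: frozenset
    x_po: int
    ptrn_fnl: frozenset
    ecout_active: frozenset
    active_rep: int | None


@dataclass
class HippocampalNet:
    """Connectivity, potentiation state and representation registry.

    Anatomical and potentiated synapses are stored as boolean incidence
    matrices (attribute x cell for the entorhinal pathways, cell x attribute
    for the output pathway).  Because potentiated entorhinal weights on a
    cell are always equal and sum to one, only the potentiation mask and the
    per-cell count are needed; a cell's recall-mode rate is then the count
    of active potentiated afferents divided by its total potentiated count.
    """

    params: ModelParams
    a_dg: np.ndarray  # (N_Ctx, N_Hipp) anatomical EC -> DG
    a_ca3: np.ndarray  # (N_Ctx, N_Hipp) anatomical EC -> CA3, independent
    p_dg: np.ndarray  # potentiated subset of a_dg
    p_ca3: np.ndarray  # potentiated subset of a_ca3
    w_out: np.ndarray  # (N_Hipp, N_Ctx) potentiated CA3 -> EC_out, weight 1
    rec_partners: dict = field(default_factory=dict)  # cell -> set of partner cells
    reps: list = field(default_factory=list)
    amyg_w: np.ndarray | None = None
    _rep_by_cells: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.amyg_w is None:
            self.amyg_w = np.zeros(self.params.N_Hipp)
        self._cnt_dg = self.p_dg.sum(axis=0)
        self._cnt_ca3 = self.p_ca3.sum(axis=0)

    # Per-cell potentiated-synapse counts, maintained incrementally: only
    # the columns touched by a creation/update are recounted.
    @property
    def cnt_dg(self) -> np.ndarray:
        return self._cnt_dg

    @property
    def cnt_ca3(self) -> np.ndarray:
        return self._cnt_ca3

    def _recount(self, cells: np.ndarray) -> None:
        self._cnt_dg[cells] = self.p_dg[:, cells].sum(axis=0)
        self._cnt_ca3[cells] = self.p_ca3[:, cells].sum(axis=0)

    def rep(self, rep_id: int) -> RepresentationRecord:
        return self.reps[rep_id]

    def match_rep(self, cells: frozenset) -> int | None:
        rec = self._rep_by_cells.get(cells)
        return rec.rep_id if rec is not None else None

    def copy(self) -> "HippocampalNet":
        """Independent deep copy (records are immutable and shared)."""
        return HippocampalNet(
            params=self.params,
            a_dg=self.a_dg.copy(),
            a_ca3=self.a_ca3.copy(),
            p_dg=self.p_dg.copy(),
            p_ca3=self.p_ca3.copy(),
            w_out=self.w_out.copy(),
            rec_partners={i: set(s) for i, s in self.rec_partners.items()},
            reps=list(self.reps),
            amyg_w=self.amyg_w.copy(),
            _rep_by_cells=dict(self._rep_by_cells),
        )


def build_net(p: ModelParams, seed: int | None = None,
              rng: np.random.Generator | None = None) -> HippocampalNet:
    """Draw random anatomical connectivity; no potentiation anywhere."""
    if p.F > p.N_Ctx:
        raise ValueError("F > N_Ctx: cannot draw F distinct afferents per cell")
    if rng is None:
        rng = np.random.default_rng(seed)
    a_dg = _random_incidence(rng, p.N_Ctx, p.N_Hipp, p.F)
    a_ca3 = _random_incidence(rng, p.N_Ctx, p.N_Hipp, p.F)
    return HippocampalNet(
        params=p,
        a_dg=a_dg,
        a_ca3=a_ca3,
        p_dg=np.zeros_like(a_dg),
        p_ca3=np.zeros_like(a_ca3),
        w_out=np.zeros((p.N_Hipp, p.N_Ctx), dtype=bool),
    )


def _random_incidence(rng, n_attr: int, n_cells: int, f: int) -> np.ndarray:
    """Boolean (n_attr, n_cells) matrix with exactly ``f`` True per column."""
    # Column-wise top-f of iid uniforms = uniform f-subset per cell.
    r = rng.random((n_cells, n_attr))
    idx = np.argpartition(r, f - 1, axis=1)[:, :f]
    out = np.zeros((n_attr, n_cells), dtype=bool)
    out[idx.ravel(), np.repeat(np.arange(n_cells), f)] = True
    return out


def _attr_array(active_ec) -> np.ndarray:
    return np.fromiter(sorted(active_ec), dtype=np.int64, count=len(active_ec))


def create_representation(
    net: HippocampalNet,
    active_ec,
    rng: np.random.Generator,
    lesion: LesionConfig = INTACT,
    *,
    context_id: str | None = None,
) -> RepresentationRecord:
    """Creation mode: select and wire a new permanent representation.

    All anatomical entorhinal synapses transmit (with equal unit strength,
    irrespective of potentiation); the ``K`` most excited dentate cells win
    the noisy KWTA and their CA3 dyad partners fire.  With the dentate relay
    lesioned during encoding, the KWTA instead operates on CA3's own direct
    anatomical innervation.  Co-active Hebbian synapses then potentiate:
    entorhinal weights per winning cell equal and summing to one, all
    ordered recurrent pairs among the winners, and every winner-to-output
    synapse for the active attributes.
    """
    p = net.params
    act = _attr_array(active_ec)
    anat = net.a_ca3 if lesion.dg_off_encoding else net.a_dg
    excitation = anat[act].sum(axis=0)
    winners = kwta(excitation, p.K, keep_ties=False, rng=rng, noise_eps=p.noise_eps)
    if winners.size < p.K:
        raise DegenerateWorldError(
            f"only {winners.size} cells with positive excitation; K={p.K} required"
        )

    block = np.ix_(act, winners)
    if not (lesion.dg_off_encoding or lesion.dg_plasticity_off):
        net.p_dg[block] |= net.a_dg[block]
    net.p_ca3[block] |= net.a_ca3[block]
    net._recount(winners)

    wset = set(int(c) for c in winners)
    for i in wset:
        net.rec_partners.setdefault(i, set()).update(wset - {i})

    net.w_out[np.ix_(winners, act)] = True

    rec = RepresentationRecord(
        rep_id=len(net.reps),
        cells=frozenset(wset),
        created_at_zcur=len(act),
        context_id=context_id,
    )
    net.reps.append(rec)
    net._rep_by_cells[rec.cells] = rec
    return rec


def _recurrent_counts(net: HippocampalNet, pattern) -> Counter:
    counts: Counter = Counter()
    for i in pattern:
        partners = net.rec_partners.get(i)
        if partners:
            counts.update(partners)
    return counts


def recall_cycle(
    net: HippocampalNet,
    active_ec,
    lesion: LesionConfig = INTACT,
    rng: np.random.Generator | None = None,
    params: ModelParams | None = None,
) -> RecallResult:
    """Recall mode: read-only pattern retrieval from the sampled attributes.

    ``params`` overrides the net's own parameters for this cycle (used by
    paired sweeps that re-test one network under several ``dpf`` values).
    """
    p = params if params is not None else net.params
    if len(active_ec) == 0:
        return RecallResult(frozenset(), 0, frozenset(), frozenset(), None)
    act = _attr_array(active_ec)

    if lesion.dg_off_recall:
        excitation = np.zeros(p.N_Hipp)
    else:
        cnt = net.cnt_dg
        excitation = np.divide(
            net.p_dg[act].sum(axis=0), cnt,
            out=np.zeros(p.N_Hipp), where=cnt > 0,
        )
    if p.dpf > 0:
        cnt3 = net.cnt_ca3
        excitation = excitation + p.dpf * np.divide(
            net.p_ca3[act].sum(axis=0), cnt3,
            out=np.zeros(p.N_Hipp), where=cnt3 > 0,
        )

    ptrn_o = kwta(excitation, p.K, keep_ties=False, rng=rng, noise_eps=p.noise_eps)
    x_po = int(ptrn_o.size)
    if x_po < p.K_0:
        return RecallResult(frozenset(int(c) for c in ptrn_o), x_po,
                            frozenset(), frozenset(), None)

    pattern = frozenset(int(c) for c in ptrn_o)
    current = pattern
    for _ in range(p.n_recurrent_iters):
        counts = _recurrent_counts(net, current)
        nxt = kwta(counts, p.K, keep_ties=True)
        current = frozenset(int(c) for c in nxt)
        if not current:
            break

    ptrn_fnl = current
    if len(ptrn_fnl) == 0 or len(ptrn_fnl) > p.K:
        ecout: frozenset = frozenset()
    else:
        cells = np.fromiter(ptrn_fnl, dtype=np.int64, count=len(ptrn_fnl))
        drive = net.w_out[cells].sum(axis=0)
        ecout = frozenset(int(a) for a in np.nonzero(drive >= p.ThrshCtx)[0])
    active_rep = net.match_rep(ptrn_fnl)
    return RecallResult(pattern, x_po, ptrn_fnl, ecout, active_rep)


def update_representation(
    net: HippocampalNet,
    rep: RepresentationRecord | int,
    sampled,
    recalled,
    lesion: LesionConfig = INTACT,
) -> None:
    """Update mode: associate sampled and recalled attributes with ``rep``.

    The representation's cell membership never changes; each cell potentiates
    synapses from every target attribute among its anatomical afferents
    (dentate via the backward relay mirror, skipped when dentate plasticity
    is off or the dentate is lesioned during encoding) and gains an output
    synapse for every target attribute.  Idempotent in the target set.
    """
    if isinstance(rep, int):
        rep = net.reps[rep]
    if net.reps[rep.rep_id] is not rep:
        raise ValueError(f"representation {rep.rep_id} is not registered in this net")
    target = set(sampled) | set(recalled)
    if not target:
        return
    t = _attr_array(target)
    cells = np.fromiter(rep.cells, dtype=np.int64, count=len(rep.cells))
    block = np.ix_(t, cells)
    if not (lesion.dg_plasticity_off or lesion.dg_off_encoding):
        net.p_dg[block] |= net.a_dg[block]
    net.p_ca3[block] |= net.a_ca3[block]
    net._recount(cells)
    net.w_out[np.ix_(cells, t)] = True


def representation_overlap(
    rep_a: RepresentationRecord, rep_b: RepresentationRecord
) -> float:
    """Fraction of shared cells, ``|A ∩ B| / K``."""
    if len(rep_a.cells) != len(rep_b.cells):
        raise ValueError("representations of unequal size")
    return len(rep_a.cells & rep_b.cells) / len(rep_a.cells)
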