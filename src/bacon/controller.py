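"""Per-sample session loop: sampling, recall, evidence, modes, fear.

A *session* is one uninterrupted visit to one context.  On every sample the
automaton (1) observes one new attribute into entorhinal working memory,
(2) runs a recall cycle, (3) evaluates the weight of evidence ``B_Rep`` for
the active representation, (4) decides its operating mode — recall, create
a representation, or update the active one — and executes it, (5) computes
conditionability and fear expression from the evidence, and (6) applies any
unconditioned stimulus.

Evidence thresholds gate everything: creation requires ``B_Rep < B_new``
(or a persistently silent hippocampus once ``Z_0`` attributes are sampled),
and is suppressed for the rest of the session once any representation
reached ``B_pv`` — until that representation itself is discredited by a
``B_Rep`` below ``B_new``.  Updating requires near-certainty
(``B_Rep >= B_add``) or a representation created this session, which is
valid by construction for the session's remainder.

During a creation session the evidence driving conditionability and fear is
the *expected* weight of evidence at ``Z_rec = Z_cur`` (every sampled
attribute is immediately associated with the new representation), so
conditionability rises gradually from the creation sample rather than
jumping to certainty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bayes import b_rep, expected_b_rep
from .core import linsig, membrane_potential
from .hippocampus import (
    INTACT,
    HippocampalNet,
    LesionConfig,
    RecallResult,
    create_representation,
    recall_cycle,
    update_representation,
)
from .params import ModelParams
from .world import Context, SampleStream, sample_stream

__all__ = [
    "CycleResult",
    "SessionState",
    "begin_session",
    "step",
    "run_session",
    "decide_mode",
    "condition_us",
    "fear_expression",
]


@dataclass(frozen=True)
class CycleResult:
    """Everything one sample step produced."""

    sample: int
    recall: RecallResult
    z_cur: int
    z_rec: int
    z_com: int
    b_rep: float
    b_used: float
    mode: str  # "recall" | "create" | "update"
    cnd: float
    fear: float
    us_applied: bool


@dataclass
class RepHistory:
    max_b: float = 0.0
    suppressing: bool = False
    released: bool = False


@dataclass
class SessionState:
    """Working memory and bookkeeping for one context visit."""

    context: Context
    stream: SampleStream
    rng: np.random.Generator
    params: ModelParams
    active_ec: set = field(default_factory=set)
    created_rep: int | None = None
    rep_history: dict = field(default_factory=dict)  # rep_id -> RepHistory
    ecout_ever_active: bool = False
    trace: list = field(default_factory=list)

    @property
    def z_cur(self) -> int:
        return len(self.active_ec)


def begin_session(
    net: HippocampalNet, ctx: Context, p: ModelParams, seed: int | None = None
) -> SessionState:
    """Fresh working memory and sampling order; the net persists unchanged."""
    rng = np.random.default_rng(seed)
    return SessionState(
        context=ctx, stream=sample_stream(ctx, rng=rng), rng=rng, params=p
    )


def _creation_suppressed(state: SessionState) -> bool:
    return any(h.suppressing and not h.released for h in state.rep_history.values())


def decide_mode(
    b: float,
    z_cur: int,
    x_po: int,
    state: SessionState,
    p: ModelParams,
) -> str:
    """Mode decision for the current cycle.

    Update whenever a representation was created this session or the active
    representation is near-certainly valid.  Otherwise create — at most once
    per session — when enough attributes have been sampled, creation is not
    suppressed by a probably-valid representation, and either the active
    representation is discredited or the hippocampus has stayed silent
    (pre-recurrent pattern below ``K_0`` with no recalled output so far).
    """
    if state.created_rep is not None or b >= p.B_add:
        return "update"
    if (
        state.created_rep is None
        and z_cur >= p.Z_0
        and not _creation_suppressed(state)
        and (
            b < p.B_new
            or (x_po < p.K_0 and not state.ecout_ever_active)
        )
    ):
        return "create"
    return "recall"


def condition_us(net: HippocampalNet, cells, cnd: float, p: ModelParams) -> None:
    """Potentiate CA3-to-amygdala synapses of the active cells by
    ``alpha * Cnd`` (additive; never decremented — no extinction)."""
    if cnd <= 0 or not cells:
        return
    idx = np.fromiter(cells, dtype=np.int64, count=len(cells))
    net.amyg_w[idx] += p.alpha * cnd


def fear_expression(net: HippocampalNet, cells, b_used: float, p: ModelParams) -> float:
    """Amygdala depolarization in [0, 1) driven by the active cells.

    The potentiated conductance is gated by the evidence: effective
    conductance is ``linsig(B | 0, B_add)`` times the summed weights, so no
    fear is expressed at or below zero evidence, and expression saturates at
    near-certainty.  Gating starts at zero rather than ``B_old`` (erring on
    the side of fear).
    """
    if not cells:
        return 0.0
    idx = np.fromiter(cells, dtype=np.int64, count=len(cells))
    ge = float(net.amyg_w[idx].sum())
    ge_eff = linsig(b_used, 0.0, p.B_add) * ge
    return membrane_potential(ge_eff, 0.0, p.E_rev)


def step(
    state: SessionState,
    net: HippocampalNet,
    p: ModelParams | None = None,
    lesion: LesionConfig = INTACT,
    us: bool = False,
) -> CycleResult:
    """Run one complete sample cycle; appends and returns its result."""
    if p is None:
        p = state.params

    attr = state.stream.next()
    state.active_ec.add(attr)
    z_cur = state.z_cur

    rec = recall_cycle(net, state.active_ec, lesion=lesion, rng=state.rng, params=p)
    z_rec = len(rec.ecout_active)
    z_com = len(state.active_ec & rec.ecout_active)
    if z_rec > 0:
        state.ecout_ever_active = True
    # Output activity that matches no registered representation carries no
    # evidence about any representation's validity.
    silent = z_rec == 0 or rec.active_rep is None
    b = b_rep(z_cur, z_rec, z_com, p, ecout_silent=silent)

    if rec.active_rep is not None:
        hist = state.rep_history.setdefault(rec.active_rep, RepHistory())
        hist.max_b = max(hist.max_b, b)
        if b >= p.B_pv:
            hist.suppressing = True
        if hist.suppressing and b < p.B_new:
            hist.released = True

    mode = decide_mode(b, z_cur, rec.x_po, state, p)
    active_cells = rec.ptrn_fnl
    if mode == "create":
        new_rep = create_representation(
            net, state.active_ec, state.rng, lesion, context_id=state.context.id
        )
        state.created_rep = new_rep.rep_id
        active_cells = new_rep.cells
    elif mode == "update":
        rep_id = state.created_rep if state.created_rep is not None else rec.active_rep
        if rep_id is not None:
            update_representation(
                net, rep_id, state.active_ec, rec.ecout_active, lesion
            )
            active_cells = net.reps[rep_id].cells

    if state.created_rep is not None:
        b_used = expected_b_rep(z_cur, z_cur, p)
    else:
        b_used = b

    cnd = float(linsig(b_used, p.B_old, p.B_add))
    fear = fear_expression(net, active_cells, b_used, p)
    if us:
        condition_us(net, active_cells, cnd, p)

    result = CycleResult(
        sample=z_cur,
        recall=rec,
        z_cur=z_cur,
        z_rec=z_rec,
        z_com=z_com,
        b_rep=b,
        b_used=b_used,
        mode=mode,
        cnd=cnd,
        fear=fear,
        us_applied=bool(us),
    )
    state.trace.append(result)
    return result


def run_session(
    net: HippocampalNet,
    ctx: Context,
    p: ModelParams,
    n_samples: int,
    seed: int | None = None,
    us_at: tuple[int, ...] = (),
    lesion: LesionConfig = INTACT,
) -> SessionState:
    """Convenience driver: run ``n_samples`` steps with optional shocks.

    ``us_at`` holds 1-based sample indices at which a shock is delivered
    (so ``us_at=(n_samples,)`` is a shock at the end of the session).
    """
    state = begin_session(net, ctx, p, seed=seed)
    us_set = set(us_at)
    for i in range(1, n_samples + 1):
        step(state, net, p, lesion=lesion, us=i in us_set)
    return state
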