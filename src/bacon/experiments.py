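"""Scripted, seeded replications of the model's benchmark simulations.

Each experiment builds its own worlds and networks from a base seed, runs
the per-sample session machinery, and returns tidy long-format tables
(``pandas.DataFrame``) so that summaries are traceable to individual cycle
results.  All randomness flows from the base seed through independent child
seeds, so every experiment is bit-reproducible given its arguments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .bayes import b_rep, expected_b_rep
from .controller import run_session
from .hippocampus import (
    INTACT,
    HippocampalNet,
    LesionConfig,
    build_net,
    create_representation,
    recall_cycle,
    representation_overlap,
    update_representation,
)
from .params import ModelParams
from .world import build_ensemble, sample_stream

__all__ = [
    "ExperimentSpec",
    "child_seeds",
    "familiarize",
    "run_pattern_separation",
    "run_z0_calibration",
    "run_recall_dynamics",
    "run_generalization",
    "run_misattribution",
    "run_conditioning_protocols",
    "run_lesion_suite",
]


@dataclass
class ExperimentSpec:
    """Declarative description of a multi-phase protocol."""

    name: str
    phases: list = field(default_factory=list)
    n_replicates: int = 1
    base_seed: int = 0
    overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("n_replicates >= 1 required")


def child_seeds(base_seed: int, n: int) -> np.ndarray:
    """Deterministic per-replicate seeds derived from one base seed."""
    return np.random.default_rng(base_seed).integers(0, 2**31 - 1, size=n)


# ---------------------------------------------------------------------------


def familiarize(
    net: HippocampalNet,
    ctx,
    target_zrec: int,
    p: ModelParams,
    rng: np.random.Generator,
    lesion: LesionConfig = INTACT,
) -> int:
    """Establish a representation of ``ctx`` knowing ``target_zrec`` attributes.

    One creation from ``Z_0`` randomly sampled attributes followed by one
    update whose target set is a random ``target_zrec``-superset of them;
    the representation then recalls exactly ``target_zrec`` attributes.
    Returns the representation id.
    """
    if target_zrec < p.Z_0:
        raise ValueError(f"target_zrec {target_zrec} below Z_0={p.Z_0}")
    order = rng.permutation(np.array(sorted(ctx.attrs)))
    created_with = set(int(a) for a in order[: p.Z_0])
    rep = create_representation(net, created_with, rng, lesion, context_id=ctx.id)
    known = set(int(a) for a in order[:target_zrec])
    update_representation(net, rep, known, created_with, lesion)
    return rep.rep_id


# ---------------------------------------------------------------------------


def run_pattern_separation(
    p: ModelParams,
    similarity: float,
    mode: str = "full_sampling",
    n_reps: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Overlap of the representations of two similar contexts.

    For each replicate a fresh network and two contexts at the stated
    similarity are built, representations of both are created — either from
    the full attribute sets (``full_sampling``) or from ``Z_0`` randomly
    sampled attributes each (``partial_sampling``) — and the cell overlap
    fraction is recorded.
    """
    if mode not in ("full_sampling", "partial_sampling"):
        raise ValueError(f"unknown mode {mode!r}")
    if similarity < p.min_similarity:
        raise ValueError("similarity below the general core fraction")
    overlaps = np.empty(n_reps)
    for r, s in enumerate(child_seeds(seed, n_reps)):
        rng = np.random.default_rng(s)
        ens = build_ensemble(p, int(rng.integers(2**31)))
        ctx_a = ens.add_context(rng=rng, cid="A")
        ctx_b = ens.add_context((ctx_a, similarity), rng=rng, cid="B")
        net = build_net(p, rng=rng)
        reps = []
        for ctx in (ctx_a, ctx_b):
            if mode == "full_sampling":
                active = set(ctx.attrs)
            else:
                active = set(sample_stream(ctx, rng=rng).draw(p.Z_0))
            reps.append(create_representation(net, active, rng, context_id=ctx.id))
        overlaps[r] = representation_overlap(reps[0], reps[1])
    return overlaps


def run_z0_calibration(p: ModelParams) -> tuple[int, int]:
    """Two threshold scans of the evidence model.

    Returns ``(a, b)``: the smallest ``Z_rec`` whose evidence at full
    sampling (``Z_cur = N_A``, ``Z_com = Z_rec``) reaches ``B_old`` — the
    minimum number of learned attributes that can ever support
    conditioning — and the smallest ``Z`` with expected evidence at
    ``Z_cur = Z_rec = Z`` reaching ``B_add`` — the sample count at which a
    creation-session automaton attains near-certainty.
    """
    a = next(
        (z for z in range(1, p.N_A + 1) if b_rep(p.N_A, z, z, p) >= p.B_old), None
    )
    b = next(
        (z for z in range(1, p.N_A + 1) if expected_b_rep(z, z, p) >= p.B_add), None
    )
    if a is None or b is None:
        raise RuntimeError(
            "no threshold crossing in 1..N_A: evidence model mis-calibrated"
        )
    return a, b


# ---------------------------------------------------------------------------


def run_recall_dynamics(
    p: ModelParams,
    similarity: float = 0.95,
    zrec_a: int = 95,
    zrec_b: int = 80,
    dpf_values: Sequence[float] | None = None,
    n_reps: int = 1,
    seed: int = 0,
    direct_only: bool = False,
) -> pd.DataFrame:
    """Per-sample composition of the CA3 patterns during recall of context A.

    The automaton is familiarized with two contexts A and B at the stated
    similarity (knowing ``zrec_a`` and ``zrec_b`` attributes of each), then
    tested in A, recording at each sample how many cells of each
    representation are active before and after recurrent input.  When
    ``dpf_values`` is given, every value is run on the *same* network and
    sampling order (paired design); ``direct_only`` additionally runs each
    dpf with the dentate relay silenced so only the direct path drives CA3.
    """
    dpfs = list(dpf_values) if dpf_values is not None else [p.dpf]
    rows = []
    for r, s in enumerate(child_seeds(seed, n_reps)):
        rng = np.random.default_rng(s)
        ens = build_ensemble(p, int(rng.integers(2**31)))
        ctx_a = ens.add_context(rng=rng, cid="A")
        ctx_b = ens.add_context((ctx_a, similarity), rng=rng, cid="B")
        net = build_net(p, rng=rng)
        rep_a = net.reps[familiarize(net, ctx_a, zrec_a, p, rng)]
        rep_b = net.reps[familiarize(net, ctx_b, zrec_b, p, rng)]
        order = rng.permutation(np.array(sorted(ctx_a.attrs)))
        kwta_seed = int(rng.integers(2**31))
        conditions = [(v, False) for v in dpfs]
        if direct_only:
            conditions += [(v, True) for v in dpfs if v > 0]
        for dpf, dg_off in conditions:
            pv = p.replace(dpf=dpf)
            lesion = LesionConfig(dg_off_recall=dg_off)
            krng = np.random.default_rng(kwta_seed)
            active: set = set()
            for i, attr in enumerate(order, start=1):
                active.add(int(attr))
                rec = recall_cycle(net, active, lesion=lesion, rng=krng, params=pv)
                rows.append(
                    dict(
                        replicate=r,
                        dpf=dpf,
                        pathway="direct" if dg_off else (
                            "indirect" if dpf == 0 else "mixed"
                        ),
                        sample=i,
                        a_in_o=len(rec.ptrn_o & rep_a.cells),
                        b_in_o=len(rec.ptrn_o & rep_b.cells),
                        a_in_fnl=len(rec.ptrn_fnl & rep_a.cells),
                        b_in_fnl=len(rec.ptrn_fnl & rep_b.cells),
                        n_fnl=len(rec.ptrn_fnl),
                    )
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------


def _test_fear(net, ctx, p, n_samples, seed):
    state = run_session(net, ctx, p, n_samples, seed=seed)
    return np.array([c.fear for c in state.trace])


def run_generalization(
    p: ModelParams,
    similarity: float = 0.90,
    prefam: str = "different",
    n_reps: int = 30,
    seed: int = 0,
    n_prefam: int = 95,
    n_cond: int = 80,
    n_test: int = 99,
) -> pd.DataFrame:
    """Generalization of conditioned fear to a similar context.

    Pre-exposure (``n_prefam`` samples) to either the later generalization
    context A (``prefam="test"``) or a maximally different context D
    (``prefam="different"``); conditioning by a shock at the end of a
    session in novel context B; then a test session in the generalization
    context A (similar to B at ``similarity``) recording fear per sample.
    """
    if prefam not in ("test", "different"):
        raise ValueError("prefam must be 'test' or 'different'")
    rows = []
    for r, s in enumerate(child_seeds(seed, n_reps)):
        rng = np.random.default_rng(s)
        ens = build_ensemble(p, int(rng.integers(2**31)))
        ctx_b = ens.add_context(rng=rng, cid="B")
        ctx_a = ens.add_context((ctx_b, similarity), rng=rng, cid="A")
        ctx_d = ens.add_context(rng=rng, cid="D")
        net = build_net(p, rng=rng)
        pre_ctx = ctx_a if prefam == "test" else ctx_d
        run_session(net, pre_ctx, p, n_prefam, seed=int(rng.integers(2**31)))
        run_session(net, ctx_b, p, n_cond, seed=int(rng.integers(2**31)),
                    us_at=(n_cond,))
        fear = _test_fear(net, ctx_a, p, n_test, int(rng.integers(2**31)))
        for i, f in enumerate(fear, start=1):
            rows.append(dict(replicate=r, prefam=prefam, sample=i, fear=f))
    return pd.DataFrame(rows)


def run_misattribution(
    p: ModelParams,
    us_timing: str = "early",
    prefam: str = "A",
    n_reps: int = 30,
    seed: int = 0,
    similarity: float = 0.95,
    n_prefam: int = 60,
    n_test: int = 99,
) -> pd.DataFrame:
    """Conditioning in a novel context B similar to a familiar context A.

    Pre-exposure (``n_prefam`` samples) to A (95% similar to B) or to a
    maximally different D; a conditioning session in B of 75 (*early*), 88
    (*middle*) or 95 (*late*) samples with the shock at the end; then test
    sessions in A and in B, reporting each replicate's whole-session mean
    fear and the settled fear over the final quarter of the test (after the
    automaton has identified the test context — the readout that separates
    which representation actually holds the association).  An early shock
    arrives while A's (mistaken) representation is still active; a late one
    only after B's own representation has been created.
    """
    cond_len = {"early": 75, "middle": 88, "late": 95}[us_timing]
    if prefam not in ("A", "D"):
        raise ValueError("prefam must be 'A' or 'D'")
    rows = []
    for r, s in enumerate(child_seeds(seed, n_reps)):
        rng = np.random.default_rng(s)
        ens = build_ensemble(p, int(rng.integers(2**31)))
        ctx_a = ens.add_context(rng=rng, cid="A")
        ctx_b = ens.add_context((ctx_a, similarity), rng=rng, cid="B")
        ctx_d = ens.add_context(rng=rng, cid="D")
        net = build_net(p, rng=rng)
        pre_ctx = ctx_a if prefam == "A" else ctx_d
        run_session(net, pre_ctx, p, n_prefam, seed=int(rng.integers(2**31)))
        run_session(net, ctx_b, p, cond_len, seed=int(rng.integers(2**31)),
                    us_at=(cond_len,))
        # Test sessions run on copies so the two tests are independent
        # (a test session can itself create or update representations).
        fear_a = _test_fear(net.copy(), ctx_a, p, n_test,
                            int(rng.integers(2**31)))
        fear_b = _test_fear(net.copy(), ctx_b, p, n_test,
                            int(rng.integers(2**31)))
        tail = max(1, n_test // 4)
        rows.append(dict(replicate=r, us_timing=us_timing, prefam=prefam,
                         fear_A=fear_a.mean(), fear_B=fear_b.mean(),
                         fear_A_end=fear_a[-tail:].mean(),
                         fear_B_end=fear_b[-tail:].mean()))
    return pd.DataFrame(rows)


def run_conditioning_protocols(
    p: ModelParams,
    variants: Sequence[dict] | None = None,
    n_reps: int = 30,
    seed: int = 0,
) -> pd.DataFrame:
    """Run a batch of generalization / misattribution protocol variants.

    Each variant is a dict with a ``protocol`` key (``"generalization"`` or
    ``"misattribution"``) plus keyword arguments for the corresponding
    runner; results are concatenated into one long table with a
    ``condition`` label.
    """
    if variants is None:
        variants = (
            [{"protocol": "generalization", "prefam": pre, "similarity": s}
             for pre in ("different", "test") for s in (0.85, 0.90, 0.95)]
            + [{"protocol": "misattribution", "us_timing": t, "prefam": pre}
               for t in ("early", "middle", "late") for pre in ("A", "D")]
        )
    frames = []
    for i, variant in enumerate(variants):
        kwargs = dict(variant)
        protocol = kwargs.pop("protocol")
        runner = {"generalization": run_generalization,
                  "misattribution": run_misattribution}[protocol]
        df = runner(p, n_reps=n_reps, seed=seed + i, **kwargs)
        df.insert(0, "condition", f"{protocol}:" + ",".join(
            f"{k}={v}" for k, v in sorted(variant.items()) if k != "protocol"))
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------

# condition name -> lesion during (filler encoding, conditioning, test).
# Chronic manipulations (toxin/knockout analogues: both_off, plasticity_off)
# also apply to the earlier filler encodings; acute ones are phase-specific.
LESION_CONDITIONS: dict[str, tuple[LesionConfig, LesionConfig, LesionConfig]] = {
    "intact": (INTACT, INTACT, INTACT),
    "both_off": (
        LesionConfig(dg_off_encoding=True, dg_off_recall=True),
        LesionConfig(dg_off_encoding=True, dg_off_recall=True),
        LesionConfig(dg_off_recall=True),
    ),
    "encoding_off": (INTACT, LesionConfig(dg_off_encoding=True), INTACT),
    "recall_off": (INTACT, INTACT, LesionConfig(dg_off_recall=True)),
    "plasticity_off": (
        LesionConfig(dg_plasticity_off=True),
        LesionConfig(dg_plasticity_off=True),
        LesionConfig(dg_plasticity_off=True),
    ),
}


def run_lesion_suite(
    p: ModelParams,
    n_reps: int = 10,
    seed: int = 0,
    similarity: float = 0.90,
    n_cond: int = 70,
    n_test: int = 60,
    n_filler: int = 2,
    dpf: float = 0.15,
) -> pd.DataFrame:
    """Factorial dentate-lesion experiment on conditioned fear.

    Each replicate first encodes ``n_filler`` unrelated contexts with the
    dentate intact (so that, when encoding is later lesioned, recall via the
    dentate is dominated by stale potentiation from those earlier
    encodings), then runs a conditioning session in a novel context A with a
    shock at the end and test sessions in A and in a similar context B,
    under each lesion condition.  Runs with a small positive direct-path
    factor so that a recall-side dentate lesion leaves the direct pathway
    operative.  Reports mean test fear per context and the discrimination
    index ``fear(A) - fear(B)``.
    """
    pv = p.replace(dpf=dpf)
    rows = []
    for r, s in enumerate(child_seeds(seed, n_reps)):
        base_rng = np.random.default_rng(s)
        world_seed = int(base_rng.integers(2**31))
        session_seeds = base_rng.integers(2**31, size=16)
        for condition, (lesion_fill, lesion_cond, lesion_test) in \
                LESION_CONDITIONS.items():
            rng = np.random.default_rng(world_seed)
            ens = build_ensemble(pv, int(rng.integers(2**31)))
            ctx_a = ens.add_context(rng=rng, cid="A")
            ctx_b = ens.add_context((ctx_a, similarity), rng=rng, cid="B")
            net = build_net(pv, rng=rng)
            for f in range(n_filler):
                filler = ens.add_context(rng=rng, cid=f"F{f}")
                familiarize(net, filler, min(pv.N_A, pv.Z_0 + 25), pv, rng,
                            lesion=lesion_fill)
            run_session(net, ctx_a, pv, n_cond, seed=int(session_seeds[0]),
                        us_at=(n_cond,), lesion=lesion_cond)
            fear_a = _test_fear_lesioned(net.copy(), ctx_a, pv, n_test,
                                         int(session_seeds[1]), lesion_test)
            fear_b = _test_fear_lesioned(net.copy(), ctx_b, pv, n_test,
                                         int(session_seeds[2]), lesion_test)
            rows.append(dict(replicate=r, condition=condition,
                             fear_A=fear_a, fear_B=fear_b,
                             discrimination=fear_a - fear_b))
    return pd.DataFrame(rows)


def _test_fear_lesioned(net, ctx, p, n_samples, seed, lesion):
    state = run_session(net, ctx, p, n_samples, seed=seed, lesion=lesion)
    return float(np.mean([c.fear for c in state.trace]))
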