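"""Synthetic attribute universe, contexts of controlled similarity, sampling.

A context is a fixed set of ``N_A`` attribute indices drawn from a universe
of ``N_Ctx`` possible attributes; every context contains the same ``N_Gen``
"general" attributes.  Contexts may be built unconstrained (uniques drawn
independently, so two contexts can share uniques by chance) or at an exact
stated similarity to a reference context, where similarity is the fraction
``|A ∩ B| / N_A`` of attributes in common.

During a visit, a context's attributes are observed serially, in uniformly
random order, without replacement — the :class:`SampleStream`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .params import ModelParams

__all__ = [
    "Context",
    "ContextEnsemble",
    "SampleStream",
    "StreamExhausted",
    "build_ensemble",
    "add_context",
    "sample_stream",
]


class StreamExhausted(RuntimeError):
    """All attributes of the context have been sampled."""


@dataclass(frozen=True)
class Context:
    id: str
    attrs: frozenset

    def __post_init__(self):
        object.__setattr__(self, "attrs", frozenset(int(a) for a in self.attrs))


@dataclass
class SampleStream:
    """Serial without-replacement sampler over one context's attributes."""

    context_id: str
    order: np.ndarray
    cursor: int = 0

    def next(self) -> int:
        if self.cursor >= self.order.size:
            raise StreamExhausted(
                f"all {self.order.size} attributes of {self.context_id} sampled"
            )
        attr = int(self.order[self.cursor])
        self.cursor += 1
        return attr

    def draw(self, n: int) -> list[int]:
        return [self.next() for _ in range(n)]

    @property
    def exhausted(self) -> bool:
        return self.cursor >= self.order.size


@dataclass
class ContextEnsemble:
    """The attribute universe: general core plus a growing set of contexts."""

    params: ModelParams
    rng_seed: int
    general_attrs: frozenset = field(init=False)
    contexts: list = field(default_factory=list)

    def __post_init__(self):
        rng = np.random.default_rng(self.rng_seed)
        gen = rng.choice(self.params.N_Ctx, size=self.params.N_Gen, replace=False)
        self.general_attrs = frozenset(int(a) for a in gen)

    # ------------------------------------------------------------------

    def add_context(
        self,
        similarity_to: tuple[Context, float] | None = None,
        *,
        seed: int | None = None,
        rng: np.random.Generator | None = None,
        cid: str | None = None,
    ) -> Context:
        """Add a context, optionally at exact similarity ``s`` to a reference.

        Without a reference, the ``N_A - N_Gen`` unique attributes are drawn
        uniformly from the non-general pool (independently of any other
        context).  With a reference ``(ctx, s)``, the new context shares
        exactly ``s * N_A`` attributes with it: the full general core plus
        ``s * N_A - N_Gen`` of the reference's uniques, the remainder being
        fresh draws excluding all of the reference's uniques so that the
        realized similarity is exact.
        """
        p = self.params
        if rng is None:
            rng = np.random.default_rng(seed)
        pool = np.array(sorted(set(range(p.N_Ctx)) - self.general_attrs))
        n_unique = p.N_A - p.N_Gen

        if similarity_to is None:
            uniques = rng.choice(pool, size=n_unique, replace=False)
            attrs = self.general_attrs | {int(a) for a in uniques}
        else:
            ref, s = similarity_to
            n_shared = s * p.N_A
            if abs(n_shared - round(n_shared)) > 1e-9:
                raise ValueError(f"similarity {s} * N_A = {n_shared} is not an integer")
            n_shared = int(round(n_shared))
            if n_shared < p.N_Gen:
                raise ValueError(
                    f"similarity {s} below the general core {p.N_Gen}/{p.N_A}: "
                    "contexts always share all general attributes"
                )
            ref_uniques = np.array(sorted(ref.attrs - self.general_attrs))
            n_shared_unique = n_shared - p.N_Gen
            shared = rng.choice(ref_uniques, size=n_shared_unique, replace=False)
            fresh_pool = np.array(sorted(set(pool.tolist()) - set(ref_uniques.tolist())))
            n_fresh = n_unique - n_shared_unique
            fresh = rng.choice(fresh_pool, size=n_fresh, replace=False)
            attrs = self.general_attrs | {int(a) for a in shared} | {int(a) for a in fresh}

        ctx = Context(id=cid or f"ctx{len(self.contexts)}", attrs=frozenset(attrs))
        assert len(ctx.attrs) == p.N_A
        self.contexts.append(ctx)
        return ctx

    # ------------------------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "seed": self.rng_seed,
            "general_attrs": sorted(self.general_attrs),
            "contexts": [
                {"id": c.id, "attrs": sorted(c.attrs)} for c in self.contexts
            ],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text: str, params: ModelParams) -> "ContextEnsemble":
        data = json.loads(text)
        ens = cls(params=params, rng_seed=data["seed"])
        ens.general_attrs = frozenset(data["general_attrs"])
        ens.contexts = [
            Context(id=c["id"], attrs=frozenset(c["attrs"])) for c in data["contexts"]
        ]
        return ens


# -- module-level operation wrappers ---------------------------------------


def build_ensemble(p: ModelParams, seed: int) -> ContextEnsemble:
    """Create an ensemble with a uniformly random general core and no contexts."""
    return ContextEnsemble(params=p, rng_seed=seed)


def add_context(
    ens: ContextEnsemble,
    similarity_to: tuple[Context, float] | None = None,
    seed: int | None = None,
    **kwargs,
) -> Context:
    return ens.add_context(similarity_to, seed=seed, **kwargs)


def sample_stream(
    ctx: Context, seed: int | None = None, rng: np.random.Generator | None = None
) -> SampleStream:
    """A uniformly random serial ordering of the context's attributes."""
    if rng is None:
        rng = np.random.default_rng(seed)
    order = rng.permutation(np.array(sorted(ctx.attrs)))
    return SampleStream(context_id=ctx.id, order=order)
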