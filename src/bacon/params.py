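"""Model parameters and their validation.

All structural and decision-theoretic constants of the automaton live in a
single immutable :class:`ModelParams` container.  The defaults describe the
reference configuration used throughout: a universe of ``N_Ctx`` elementary
contextual attributes, contexts of ``N_A`` attributes sharing a general core
of ``N_Gen``, a hippocampal layer of ``N_Hipp`` dentate/CA3 dyads, and the
log10 weight-of-evidence thresholds that gate representation creation,
updating, fear conditioning and fear expression.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["ModelParams", "ParameterError", "validate_params", "DIFF_MODELS"]

#: Supported generative models for the "different context" hypothesis used in
#: the weight-of-evidence denominator (see :mod:`bacon.bayes`).
DIFF_MODELS = ("shared_core", "ensemble")


class ParameterError(ValueError):
    """A parameter configuration violates a structural invariant."""


@dataclass(frozen=True)
class ModelParams:
    """Complete parameter set of the automaton.

    Attributes
    ----------
    N_Ctx:
        Number of possible contextual attributes (one entorhinal input cell
        and one output cell per attribute).
    N_Hipp:
        Number of dentate cells, and equally of CA3 cells (dyad pairing).
    N_A:
        Number of attributes composing each context.
    N_Gen:
        Number of "general" attributes common to every context.
    F:
        Number of entorhinal input cells innervating each dentate cell and,
        independently drawn, each CA3 cell.
    K:
        Winner count of the K-winners-take-all competitions.
    K_0:
        Minimum number of cells active in the pre-recurrent CA3 pattern for
        the recurrent collateral system to be engaged.
    Z_0:
        Minimum number of sampled attributes before a new representation may
        be created.
    ThrshCtx:
        Number of active potentiated CA3 inputs an entorhinal output cell
        needs in order to fire.
    B_old, B_new, B_add, B_pv:
        Evidence thresholds in log10 units: conditioning becomes possible at
        ``B_old``; creation may be triggered below ``B_new``; attributes may
        be added to a representation at ``B_add``; a representation reaching
        ``B_pv`` suppresses creation for the rest of the session.
    alpha:
        Amygdala learning rate (per-synapse weight increment at full
        conditionability).
    dpf:
        Direct-path factor: recall-mode strength of the direct entorhinal
        to CA3 pathway relative to the indirect (dentate) route.
    E_rev:
        Excitatory reversal potential (dimensionless; depolarizations are
        expressed relative to rest).
    noise_eps:
        Half-width of the additive uniform tie-breaking noise used by
        noisy K-winners-take-all selections, in excitation units.  Far below
        one synaptic weight so that noise can only reorder exact ties.
    n_recurrent_iters:
        Number of recurrent collateral cycles applied to reach the final
        CA3 pattern.
    b_floor:
        Finite stand-in for an infinitely negative weight of evidence
        (impossible observation under the "same context" hypothesis).
    diff_model:
        Generative model for the "different context" hypothesis:
        ``"ensemble"`` (default; unique attributes drawn independently from
        the non-general pool, allowing chance overlap — the exact Bayesian
        observer of how the synthetic world builds unconstrained contexts)
        or ``"shared_core"`` (different contexts share exactly the general
        core, the back-of-envelope variant in which evidence at full
        sampling is ``Z * log10(2)``).
    """

    N_Ctx: int = 1000
    N_Hipp: int = 10_000
    N_A: int = 100
    N_Gen: int = 50
    F: int = 60
    K: int = 60
    K_0: int = 15
    Z_0: int = 45
    ThrshCtx: int = 42
    B_old: float = 3.0
    B_new: float = -3.0
    B_add: float = 15.0
    B_pv: float = 3.0
    alpha: float = 0.025
    dpf: float = 0.0
    E_rev: float = 1.0
    noise_eps: float = 1e-6
    n_recurrent_iters: int = 2
    b_floor: float = -50.0
    diff_model: str = "ensemble"

    def __post_init__(self) -> None:
        validate_params(self)

    # -- derived conveniences -------------------------------------------------

    @property
    def min_similarity(self) -> float:
        """Smallest achievable pairwise context similarity, ``N_Gen / N_A``."""
        return self.N_Gen / self.N_A

    def replace(self, **changes: Any) -> "ModelParams":
        """Return a copy with ``changes`` applied (re-validated)."""
        return dataclasses.replace(self, **changes)

    # -- serialization --------------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, mapping: Mapping[str, Any]) -> "ModelParams":
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        unknown = set(mapping) - set(fields)
        if unknown:
            raise ParameterError(
                f"unknown parameter name(s): {', '.join(sorted(unknown))}"
            )
        coerced = {}
        for key, value in mapping.items():
            # YAML 1.1 reads bare scientific notation ("1e-06") as a string
            if isinstance(value, str) and fields[key] == "float":
                try:
                    value = float(value)
                except ValueError as exc:
                    raise ParameterError(f"{key}: not a number: {value!r}") from exc
            coerced[key] = value
        return cls(**coerced)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_file(cls, path: str | Path) -> "ModelParams":
        """Load from a flat JSON or YAML mapping; missing keys keep defaults."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a superset of JSON
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ParameterError(f"{path}: expected a flat mapping of parameters")
        return cls.from_dict(data)


def _check(condition: bool, relation: str) -> None:
    if not condition:
        raise ParameterError(f"parameter invariant violated: {relation}")


def validate_params(p: ModelParams) -> ModelParams:
    """Validate every structural invariant of a parameter set.

    Returns ``p`` unchanged when all invariants hold; raises
    :class:`ParameterError` naming the violated relation otherwise.
    """
    for name in ("N_Ctx", "N_Hipp", "N_A", "N_Gen", "F", "K", "K_0", "Z_0",
                 "ThrshCtx", "n_recurrent_iters"):
        value = getattr(p, name)
        _check(isinstance(value, (int,)) and not isinstance(value, bool),
               f"{name} must be an integer")
    _check(p.N_Gen >= 0, "N_Gen >= 0")
    _check(p.N_Gen <= p.N_A, "N_Gen <= N_A")
    _check(p.N_A <= p.N_Ctx, "N_A <= N_Ctx")
    _check(1 <= p.K, "K >= 1")
    _check(p.K_0 <= p.K, "K_0 <= K")
    _check(p.K <= p.N_Hipp, "K <= N_Hipp")
    _check(p.ThrshCtx <= p.K, "ThrshCtx <= K")
    _check(p.B_new < 0, "B_new < 0")
    _check(0 < p.B_old, "0 < B_old")
    _check(p.B_old <= p.B_pv, "B_old <= B_pv")
    _check(p.B_pv < p.B_add, "B_pv < B_add")
    _check(p.Z_0 <= p.N_A, "Z_0 <= N_A")
    _check(p.alpha > 0, "alpha > 0")
    _check(p.dpf >= 0, "dpf >= 0")
    _check(p.noise_eps > 0, "noise_eps > 0")
    _check(p.F >= 1, "F >= 1")
    _check(p.F <= p.N_Ctx, "F <= N_Ctx")
    _check(p.E_rev > 0, "E_rev > 0")
    _check(p.n_recurrent_iters >= 1, "n_recurrent_iters >= 1")
    _check(p.b_floor < p.B_new, "b_floor < B_new")
    _check(p.diff_model in DIFF_MODELS,
           f"diff_model in {{{', '.join(DIFF_MODELS)}}}")
    return p
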