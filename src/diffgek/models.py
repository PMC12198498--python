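"""The eight rate-sharing models for a two-condition comparison.

Each of the three kinetic rates (transcription alpha, splicing beta,
degradation gamma) can either be forced equal between the two conditions
("Same") or left free ("Any"), giving 2**3 = 8 candidate models M1..M8:

    =====  =====  =====  =====  ====
    model  alpha  beta   gamma    k
    =====  =====  =====  =====  ====
    M1     Same   Same   Same    32
    M2     Any    Same   Same    40
    M3     Same   Any    Same    40
    M4     Same   Same   Any     40
    M5     Any    Any    Same    48
    M6     Any    Same   Any     48
    M7     Same   Any    Any     48
    M8     Any    Any    Any     56
    =====  =====  =====  =====  ====

The parameter count k comprises 8 spline nodes per distinct rate curve,
plus per-condition initial conditions (u0, s0) and per-condition error
terms for the two species.  A single-condition fit has 3*8 + 2 + 2 = 28
parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import N_NODES

__all__ = ["ModelSpec", "MODELS", "MODEL_ORDER", "SINGLE_CONDITION", "RATES"]

RATES = ("alpha", "beta", "gamma")


@dataclass(frozen=True)
class ModelSpec:
    """Sharing pattern of the three rates between conditions.

    ``*_shared`` flags correspond to "Same" in the model table; a rate with
    the flag off ("Any") gets an independent spline per condition.
    """

    name: str
    alpha_shared: bool
    beta_shared: bool
    gamma_shared: bool
    n_conditions: int = 2

    def __post_init__(self) -> None:
        if self.n_conditions not in (1, 2):
            raise ValueError("only single- and two-condition modes are defined")

    def shared(self, rate: str) -> bool:
        return getattr(self, f"{rate}_shared")

    @property
    def n_free_rates(self) -> int:
        """Number of rates allowed to differ between conditions."""
        return sum(not self.shared(r) for r in RATES)

    @property
    def n_splines(self) -> int:
        """Number of distinct rate splines in the model."""
        if self.n_conditions == 1:
            return 3
        return 3 + self.n_free_rates

    @property
    def k(self) -> int:
        """Total number of model parameters.

        Single-condition mode: 3 splines * 8 nodes + (u0, s0) + 2 error
        terms = 28.  Two-condition mode: 8 nodes per distinct spline + 4
        initial conditions + 4 error terms, i.e. 32/40/48/56.
        """
        if self.n_conditions == 1:
            return 3 * N_NODES + 2 + 2
        return N_NODES * self.n_splines + 4 + 4

    @property
    def rate_calls(self) -> dict[str, bool]:
        """Per-rate differential flag (True = rate differs between conditions)."""
        if self.n_conditions == 1:
            return {r: False for r in RATES}
        return {r: not self.shared(r) for r in RATES}

    @property
    def is_differential(self) -> bool:
        return any(self.rate_calls.values())


MODELS: dict[str, ModelSpec] = {
    "M1": ModelSpec("M1", True, True, True),
    "M2": ModelSpec("M2", False, True, True),
    "M3": ModelSpec("M3", True, False, True),
    "M4": ModelSpec("M4", True, True, False),
    "M5": ModelSpec("M5", False, False, True),
    "M6": ModelSpec("M6", False, True, False),
    "M7": ModelSpec("M7", True, False, False),
    "M8": ModelSpec("M8", False, False, False),
}

MODEL_ORDER = tuple(MODELS)

SINGLE_CONDITION = ModelSpec("single", True, True, True, n_conditions=1)
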