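"""Equilibrium algebra for symmetric diprotic microspeciation.

A diprotic compound with two chemically identical basic sites (two
carboxylates, two phenolates, two thiolates) has macroscopic stepwise
protonation constants ``K1 >= K2`` defined on total bound-proton count,
and site-specific microconstants.  Mirror symmetry collapses the four
microconstants to two distinct values and ties them exactly to the
macroconstants:

    log k_first  = log K1 - log 2      (one site protonates, other empty)
    log k_second = log K2 + log 2      (one site protonates, other occupied)

The pair-interactivity parameter ``log eps = log k_first - log k_second``
measures how much protonation of one site depresses the basicity of its
neighbour.  A model compound (methyl ester, amide, S-methyl or O-methyl
ether) permanently mimics the microspecies whose substituted site is in
the protonated/blocked state, so its single protonation constant is
compared to ``log k_second``; the difference is the correction factor
quantifying the bias of the deductive method.

All constants are base-10 logarithms throughout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

LOG2 = math.log10(2.0)

_METHODS = ("nmr", "potentiometric")
_MODEL_TYPES = ("O_methyl", "amide", "S_methyl")


class CooperativityWarning(UserWarning):
    """Raised when log K1 - log K2 < 2 log 2 (cooperative protonation)."""


def _check_method(method: str) -> str:
    if method not in _METHODS:
        raise ValueError(f"method must be one of {_METHODS}, got {method!r}")
    return method


def _check_model_type(model_type: str) -> str:
    if model_type not in _MODEL_TYPES:
        raise ValueError(
            f"model_type must be one of {_MODEL_TYPES}, got {model_type!r}"
        )
    return model_type


@dataclass(frozen=True)
class MacroConstants:
    """Stepwise macroscopic protonation constants of one compound.

    Parameters
    ----------
    compound_id : str
        Registry identifier of the compound.
    method : {"nmr", "potentiometric"}
        Experimental method the constants were determined with.
    log_K : sequence of float
        Stepwise log10 protonation constants, log K1 ... log Kn.
    se_log_K : sequence of float
        Standard errors of each log K.
    symmetric : bool
        True if the compound is mirror-symmetric (two identical sites),
        which licenses the exact macro-to-micro transformation.
    """

    compound_id: str
    method: str
    log_K: tuple[float, ...]
    se_log_K: tuple[float, ...]
    symmetric: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "log_K", tuple(float(x) for x in self.log_K))
        object.__setattr__(
            self, "se_log_K", tuple(float(x) for x in self.se_log_K)
        )
        _check_method(self.method)
        if len(self.log_K) != len(self.se_log_K):
            raise ValueError("log_K and se_log_K must have equal length")
        if len(self.log_K) < 1:
            raise ValueError("at least one protonation site is required")
        if any(se < 0 for se in self.se_log_K):
            raise ValueError("standard errors must be non-negative")

    @property
    def n_sites(self) -> int:
        return len(self.log_K)


@dataclass(frozen=True)
class MicroConstants:
    """Species-specific protonation constants of a symmetric diprotic acid.

    ``log_k_first`` is the microconstant of protonating one site while the
    other is unprotonated; ``log_k_second`` of protonating one site while
    the other is already protonated.  For anticooperative systems (the
    usual case) ``log_k_first >= log_k_second``.
    """

    compound_id: str
    method: str
    log_k_first: float
    se_first: float
    log_k_second: float
    se_second: float

    def __post_init__(self) -> None:
        _check_method(self.method)
        if self.se_first < 0 or self.se_second < 0:
            raise ValueError("standard errors must be non-negative")
        if self.log_k_first < self.log_k_second:
            warnings.warn(
                f"{self.compound_id}: log_k_first < log_k_second "
                "(cooperative protonation, rare but admissible)",
                CooperativityWarning,
                stacklevel=2,
            )


@dataclass(frozen=True)
class Interactivity:
    """Pair-interactivity parameter log eps and its standard error."""

    value: float
    se: float


@dataclass(frozen=True)
class CorrectionRecord:
    """Bias of one model compound against its parent's microconstant.

    ``correction = log_K_model - log_k_second(parent)``: the amount by
    which the deductive estimate overshoots the true microconstant.
    """

    parent_id: str
    model_id: str
    model_type: str
    method: str
    log_K_model: float
    se_model: float
    correction: float
    se_correction: float
    log_eps: Interactivity

    def __post_init__(self) -> None:
        _check_method(self.method)
        _check_model_type(self.model_type)


def propagate_gaussian(partials: Iterable[tuple[float, float]]) -> float:
    """Gaussian (first-order) propagation of uncertainty.

    Parameters
    ----------
    partials : iterable of (derivative, se)
        Partial derivative of the output with respect to each input,
        paired with that input's standard error.

    Returns
    -------
    float
        ``sqrt(sum((derivative * se)**2))``.
    """
    total = 0.0
    for deriv, se in partials:
        if se < 0:
            raise ValueError("standard errors must be non-negative")
        total += (deriv * se) ** 2
    return math.sqrt(total)


def cumulative_beta(macro: MacroConstants) -> list[float]:
    """Cumulative protonation constants log beta_i = sum_{j<=i} log K_j."""
    out: list[float] = []
    acc = 0.0
    for lk in macro.log_K:
        acc += lk
        out.append(acc)
    return out


def macro_to_micro_symmetric(macro: MacroConstants) -> MicroConstants:
    """Exact macro-to-micro transformation for a mirror-symmetric diprotic.

    log k_first  = log K1 - log 2,  log k_second = log K2 + log 2.
    The log 2 shifts are exact statistical factors, so the standard
    errors pass through unchanged.

    Raises
    ------
    ValueError
        If the compound is not diprotic or not flagged symmetric.
    """
    if macro.n_sites != 2:
        raise ValueError(
            f"{macro.compound_id}: symmetric transformation requires exactly "
            f"2 sites, got {macro.n_sites}"
        )
    if not macro.symmetric:
        raise ValueError(
            f"{macro.compound_id}: compound not declared mirror-symmetric; "
            "microconstants cannot be derived from macroconstants alone"
        )
    lk1, lk2 = macro.log_K
    se1, se2 = macro.se_log_K
    if lk1 - lk2 < 2 * LOG2:
        warnings.warn(
            f"{macro.compound_id}: log K1 - log K2 < 2 log 2 implies "
            "cooperative protonation (negative log eps)",
            CooperativityWarning,
            stacklevel=2,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", CooperativityWarning)
        micro = MicroConstants(
            compound_id=macro.compound_id,
            method=macro.method,
            log_k_first=lk1 - LOG2,
            se_first=se1,
            log_k_second=lk2 + LOG2,
            se_second=se2,
        )
    return micro


def micro_to_macro_symmetric(micro: MicroConstants) -> MacroConstants:
    """Inverse of :func:`macro_to_micro_symmetric` (exact algebra)."""
    return MacroConstants(
        compound_id=micro.compound_id,
        method=micro.method,
        log_K=(micro.log_k_first + LOG2, micro.log_k_second - LOG2),
        se_log_K=(micro.se_first, micro.se_second),
        symmetric=True,
    )


def interactivity(micro: MicroConstants) -> Interactivity:
    """Pair-interactivity parameter log eps = log k_first - log k_second.

    Equivalently log K1 - log K2 - 2 log 2.  The standard error combines
    both microconstant errors by Gaussian propagation.
    """
    return Interactivity(
        value=micro.log_k_first - micro.log_k_second,
        se=propagate_gaussian([(1.0, micro.se_first), (1.0, micro.se_second)]),
    )


def correction_factor(
    model_logK: float, se_model: float, micro: MicroConstants
) -> tuple[float, float]:
    """Correction factor of a model compound: bias of the deductive method.

    The model compound's substituted site mimics the protonated/blocked
    state of one parent site, so its protonation constant estimates
    ``log_k_second`` of the parent; the correction factor is the signed
    discrepancy.

    Returns
    -------
    (correction, se_correction)
        ``model_logK - log_k_second`` and its propagated standard error.
    """
    corr = model_logK - micro.log_k_second
    se = propagate_gaussian([(1.0, se_model), (-1.0, micro.se_second)])
    return corr, se


def make_correction_record(
    parent_micro: MicroConstants,
    model_id: str,
    model_type: str,
    model_logK: float,
    se_model: float,
) -> CorrectionRecord:
    """Assemble a full :class:`CorrectionRecord` for one parent/model pair."""
    corr, se = correction_factor(model_logK, se_model, parent_micro)
    return CorrectionRecord(
        parent_id=parent_micro.compound_id,
        model_id=model_id,
        model_type=model_type,
        method=parent_micro.method,
        log_K_model=model_logK,
        se_model=se_model,
        correction=corr,
        se_correction=se,
        log_eps=interactivity(parent_micro),
    )
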