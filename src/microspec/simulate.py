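"""Synthetic titration experiments and compound registries.

Emulates the two experimental designs the analysis consumes: NMR-pH
titrations (~5 mmol/L titrand, 0.15 mol/L ionic strength, shifts read at
a grid of pH values) and potentiometric difference titrations (2 mL of
0.1 mol/L HCl titrated with 0.1 mol/L KOH, ~10 mmol/L titrand, usually
3 replicates).  Noise is additive homoscedastic Gaussian on the signal;
default magnitudes (0.002 ppm, 0.002 mL) reproduce the order of
magnitude of typical fitted-constant standard errors in such
experiments.  Every simulation returns the generating truth alongside
the dataset, so downstream estimates can be checked against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .speciation import (
    LOG2,
    MacroConstants,
    MicroConstants,
    interactivity,
    macro_to_micro_symmetric,
    micro_to_macro_symmetric,
)
from .titration import TitrationDataset, mass_balance_A, nmr_forward, pot_forward


@dataclass
class GeneratorConfig:
    """Ground truth and design of one simulated titration.

    Attributes
    ----------
    true_log_K : sequence of float
        Stepwise log K values generating the data.
    shift_params : dict
        Per-nucleus limiting shifts, ``{nucleus: (delta_L, delta_HL, ...,
        delta_HnL)}`` in ppm; each tuple has n+1 entries.
    pH_range, pH_points : grid of titration points.
    noise_sd_nmr : ppm, noise_sd_pot : mL
        Additive Gaussian noise standard deviations.
    replicates : independent repeat titrations (potentiometric).
    c_titrand, c_KOH : mol/L; v0_mL : initial volume in mL.
    """

    true_log_K: tuple[float, ...] = (5.22, 2.70)
    shift_params: dict = field(
        default_factory=lambda: {"CH2": (3.10, 3.25, 3.45)}
    )
    pH_range: tuple[float, float] = (0.5, 7.5)
    pH_points: int = 40
    noise_sd_nmr: float = 0.002
    noise_sd_pot: float = 0.002
    replicates: int = 1
    seed: int = 0
    c_titrand: float = 0.010
    c_KOH: float = 0.1
    v0_mL: float = 2.0
    temperature_K: float = 298.15
    ionic_strength: float = 0.15
    compound_id: str = "synthetic"
    pot_D: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd_nmr < 0 or self.noise_sd_pot < 0:
            raise ValueError("noise standard deviations must be >= 0")
        lo, hi = self.pH_range
        if not (lo < hi):
            raise ValueError("pH_range must be increasing")
        for nuc, deltas in self.shift_params.items():
            if len(deltas) != len(self.true_log_K) + 1:
                raise ValueError(
                    f"nucleus {nuc!r} needs {len(self.true_log_K) + 1} "
                    "limiting shifts (delta_L ... delta_HnL)"
                )

    @property
    def log_beta(self) -> np.ndarray:
        return np.cumsum(np.asarray(self.true_log_K, dtype=float))

    @property
    def A(self) -> float:
        """Mass-balance KOH volume per unit of deprotonation (mL)."""
        return mass_balance_A(self.c_titrand, self.v0_mL, self.c_KOH)


def _metadata(config: GeneratorConfig, flavor: str) -> dict:
    return {
        "flavor": flavor,
        "c_titrand": config.c_titrand,
        "c_KOH": config.c_KOH,
        "v0_mL": config.v0_mL,
        "temperature_K": config.temperature_K,
        "ionic_strength": config.ionic_strength,
        "symmetric": len(config.true_log_K) == 2,
    }


def simulate_nmr(config: GeneratorConfig) -> tuple[TitrationDataset, dict]:
    """Simulate an NMR-pH titration: shifts on the forward curve + noise."""
    rng = np.random.default_rng(config.seed)
    pH = np.linspace(*config.pH_range, config.pH_points)
    log_beta = config.log_beta
    rows = []
    for nuc, deltas in config.shift_params.items():
        clean = nmr_forward(pH, log_beta, deltas[0], deltas[1:])
        noisy = clean + rng.normal(0.0, config.noise_sd_nmr, size=pH.shape)
        for p, s in zip(pH, noisy):
            rows.append({"pH": p, "signal": s, "nucleus": nuc})
    dataset = TitrationDataset(
        compound_id=config.compound_id,
        flavor="nmr",
        points=pd.DataFrame(rows),
        metadata=_metadata(config, "nmr"),
    )
    truth = {
        "log_K": tuple(config.true_log_K),
        "log_beta": tuple(log_beta),
        "shift_params": dict(config.shift_params),
        "noise_sd": config.noise_sd_nmr,
        "seed": config.seed,
    }
    return dataset, truth


def simulate_pot(config: GeneratorConfig) -> tuple[TitrationDataset, dict]:
    """Simulate a potentiometric difference titration with replicates.

    The volume difference follows ``A * n_bar(pH) + D`` with ``A`` fixed
    by mass balance from the configured concentrations.  Each replicate
    gets an independent noise stream spawned from the single seed.
    """
    pH = np.linspace(*config.pH_range, config.pH_points)
    log_beta = config.log_beta
    clean = pot_forward(pH, log_beta, config.A, config.pot_D)
    streams = np.random.default_rng(config.seed).spawn(config.replicates)
    rows = []
    for rep, rng in enumerate(streams):
        noisy = clean + rng.normal(0.0, config.noise_sd_pot, size=pH.shape)
        for p, s in zip(pH, noisy):
            rows.append({"pH": p, "signal": s, "replicate": rep})
    dataset = TitrationDataset(
        compound_id=config.compound_id,
        flavor="potentiometric",
        points=pd.DataFrame(rows),
        metadata=_metadata(config, "potentiometric"),
    )
    truth = {
        "log_K": tuple(config.true_log_K),
        "log_beta": tuple(log_beta),
        "A": config.A,
        "D": config.pot_D,
        "noise_sd": config.noise_sd_pot,
        "replicates": config.replicates,
        "seed": config.seed,
    }
    return dataset, truth


def simulate_registry(
    n_parents: int,
    eps_range: tuple[float, float] = (0.4, 3.4),
    model_bias_law: tuple[float, float, float] = (-0.095, 0.098, 0.1),
    seed: int = 0,
    model_type: str = "O_methyl",
    method: str = "nmr",
    logk_second_range: tuple[float, float] = (2.0, 10.0),
    se_constants: float = 0.01,
) -> tuple[pd.DataFrame, dict]:
    """Synthetic parent/model compound registry with known correction law.

    Each parent is a mirror-symmetric diprotic with pair-interactivity
    log eps drawn uniformly from ``eps_range`` and a second microconstant
    drawn from ``logk_second_range``.  Its model compound's constant is
    placed at

        log K_model = log_k_second + b0 + b1 * ln(eps) + noise,

    with ``(b0, b1, noise_sd) = model_bias_law``, so the true correction
    factor follows the power-law-in-eps bias model the downstream
    regression estimates (the correction, a log-scale quantity, is
    linear in the natural log of eps).  The default law is O-methyl-like
    with scatter comparable to observed O-methyl corrections.

    Returns
    -------
    (registry, truth)
        ``registry`` in the constants-table dialect (columns compound_id,
        method, role, model_type, parent_id, log_K1, se_K1, log_K2,
        se_K2); ``truth`` stores (b0, b1), the drawn log eps values and
        the exact correction factors.
    """
    lo, hi = eps_range
    if not (0.0 < lo < hi <= 4.0):
        raise ValueError("eps_range must lie within (0, 4]")
    b0, b1, noise_sd = model_bias_law
    rng = np.random.default_rng(seed)
    log_eps = rng.uniform(lo, hi, size=n_parents)
    logk2nd = rng.uniform(*logk_second_range, size=n_parents)
    corr_true = (
        b0
        + b1 * np.log(10.0) * log_eps
        + rng.normal(0.0, noise_sd, size=n_parents)
    )
    rows = []
    for i in range(n_parents):
        parent = f"parent_{i:03d}"
        model = f"model_{i:03d}"
        # macroconstants of the symmetric parent from its microconstants
        log_k_first = logk2nd[i] + log_eps[i]
        rows.append(
            {
                "compound_id": parent,
                "method": method,
                "role": "parent",
                "model_type": "",
                "parent_id": "",
                "log_K1": log_k_first + LOG2,
                "se_K1": se_constants,
                "log_K2": logk2nd[i] - LOG2,
                "se_K2": se_constants,
            }
        )
        rows.append(
            {
                "compound_id": model,
                "method": method,
                "role": "model",
                "model_type": model_type,
                "parent_id": parent,
                "log_K1": logk2nd[i] + corr_true[i],
                "se_K1": se_constants,
                "log_K2": np.nan,
                "se_K2": np.nan,
            }
        )
    registry = pd.DataFrame(rows)
    truth = {
        "b0": b0,
        "b1": b1,
        "noise_sd": noise_sd,
        "log_eps": log_eps,
        "log_k_second": logk2nd,
        "correction": corr_true,
        "seed": seed,
    }
    return registry, truth
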