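"""Forward models and least-squares fitting for acid-base titration curves.

Two experiment flavors are supported:

* **NMR-pH titration** — the observed chemical shift of a nucleus is the
  population-weighted average of the limiting shifts of the protonation
  macrospecies,

      delta(pH) = (delta_L + sum_i delta_HiL * beta_i * [H+]^i)
                  / (1 + sum_i beta_i * [H+]^i),

  with ``[H+] = 10^-pH`` and cumulative constants ``beta_i``.

* **Potentiometric difference titration** — the blank-subtracted KOH
  volume is proportional to the average number of bound protons
  (the Bjerrum function n-bar),

      dV(pH) = A * n_bar(pH) + D,

  where ``A`` is the KOH volume per unit of deprotonation (mass balance:
  ``A = c_titrand * V0 / c_KOH``) and ``D`` an experimental correction
  offset.

Fitting is damped least squares on the stepwise log K scale; standard
errors come from the covariance at the optimum, except for replicated
potentiometric titrations where the per-constant standard error is the
standard deviation across replicate fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import lmfit
import numpy as np
import pandas as pd

from .speciation import MacroConstants


class FitWarning(UserWarning):
    pass


@dataclass
class TitrationDataset:
    """Observed (pH, signal) points for one titration experiment.

    ``points`` columns: ``pH``, ``signal`` (ppm for nmr, mL for
    potentiometric), optional ``nucleus`` (required for nmr) and
    ``replicate``.  ``metadata`` carries concentrations (mol/L), initial
    volume (mL), temperature (K) and ionic strength (mol/L) where known.
    """

    compound_id: str
    flavor: str
    points: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.flavor not in ("nmr", "potentiometric"):
            raise ValueError(f"unknown flavor {self.flavor!r}")
        pts = self.points
        if not {"pH", "signal"}.issubset(pts.columns):
            raise ValueError("points must have 'pH' and 'signal' columns")
        if not np.all(np.isfinite(pts["pH"].to_numpy(float))):
            raise ValueError("pH values must be finite")
        if self.flavor == "nmr" and "nucleus" not in pts.columns:
            raise ValueError("nmr points must carry a nucleus label")

    @property
    def replicate_ids(self) -> list:
        if "replicate" in self.points.columns:
            return sorted(self.points["replicate"].unique().tolist())
        return [0]


@dataclass
class NmrFitResult:
    """Result of a (possibly multi-nucleus) NMR titration fit."""

    log_beta: np.ndarray
    se_log_beta: np.ndarray
    macro: MacroConstants
    delta_L: dict
    delta_HiL: dict
    residual_sd: float
    converged: bool
    n_points: int
    n_params: int
    covar: Optional[np.ndarray] = None


@dataclass
class PotFitResult:
    """Result of a potentiometric difference-titration fit."""

    log_beta: np.ndarray
    se_log_beta: np.ndarray
    macro: MacroConstants
    A: float
    D: float
    residual_sd: float
    converged: bool
    n_points: int
    n_params: int
    n_replicates: int = 1
    covar: Optional[np.ndarray] = None
    replicate_fits: Optional[list] = None


def _species_weights(pH, log_beta) -> np.ndarray:
    """Relative populations of L, HL, ..., HnL at the given pH.

    Evaluated in log10 space with max-subtraction so extreme pH values
    cannot overflow.  Returns an array of shape (n+1, len(pH)).
    """
    pH = np.atleast_1d(np.asarray(pH, dtype=float))
    log_beta = np.asarray(log_beta, dtype=float)
    n = len(log_beta)
    i = np.arange(1, n + 1)
    # log10 weight of species H_iL relative to L; L itself has log-weight 0
    logw = np.vstack(
        [np.zeros_like(pH)] + [(log_beta[j - 1] - j * pH) for j in i]
    )
    logw -= logw.max(axis=0, keepdims=True)
    w = 10.0**logw
    return w / w.sum(axis=0, keepdims=True)


def nmr_forward(pH, log_beta, delta_L: float, delta_HiL: Sequence[float]):
    """Predicted chemical shift (ppm) at a given pH.

    The prediction is a convex combination of the limiting shifts
    ``delta_L`` (unprotonated) and ``delta_HiL[i-1]`` (i-times
    protonated), weighted by the species populations.
    """
    log_beta = np.asarray(log_beta, dtype=float)
    if len(delta_HiL) != len(log_beta):
        raise ValueError("need one limiting shift per protonation state")
    w = _species_weights(pH, log_beta)
    deltas = np.concatenate(([delta_L], np.asarray(delta_HiL, dtype=float)))
    out = deltas @ w
    return out if np.ndim(pH) else float(out[0])


def average_protonation(pH, log_beta):
    """Bjerrum function n_bar: mean number of bound protons at a given pH.

    Monotone non-increasing in pH, from n (acidic limit) to 0 (basic
    limit); equals 0.5 at pH = log K1 for a well-separated diprotic.
    """
    log_beta = np.asarray(log_beta, dtype=float)
    w = _species_weights(pH, log_beta)
    i = np.arange(len(log_beta) + 1)
    out = i @ w
    return out if np.ndim(pH) else float(out[0])


def pot_forward(pH, log_beta, A: float, D: float):
    """Predicted KOH volume difference (mL): ``A * n_bar(pH) + D``."""
    return A * average_protonation(pH, log_beta) + D


def mass_balance_A(
    c_titrand: float, v0_mL: float, c_KOH: float
) -> float:
    """KOH volume (mL) per unit of deprotonation from mass balance."""
    return c_titrand * v0_mL / c_KOH


# ---------------------------------------------------------------------------
# initial guesses


def _guess_logK(pH: np.ndarray, u: np.ndarray, n: int) -> np.ndarray:
    """Stepwise log K starting values from normalized titration progress.

    ``u`` approximates n_bar/n; a well-separated system crosses the
    level (i - 0.5)/n at pH = log K_i, so the pH of the nearest data
    point to each level crossing seeds log K_i.
    """
    guesses = []
    for i in range(1, n + 1):
        level = (i - 0.5) / n
        guesses.append(pH[np.argmin(np.abs(u - level))])
    return np.sort(np.asarray(guesses))[::-1]  # log K1 >= log K2 >= ...


def _plateaus(pH: np.ndarray, signal: np.ndarray) -> tuple[float, float]:
    """Signal levels at the basic (high-pH) and acidic (low-pH) ends."""
    order = np.argsort(pH)
    k = max(1, len(pH) // 10)
    high = float(np.mean(signal[order][-k:]))
    low = float(np.mean(signal[order][:k]))
    return high, low


def _check_determined(n_points: int, n_params: int) -> None:
    if n_points < n_params:
        raise ValueError(
            f"underdetermined fit: {n_points} points for {n_params} parameters"
        )
    if n_points < 3 * n_params:
        warnings.warn(
            f"only {n_points} points for {n_params} parameters; "
            "standard errors will be unreliable",
            FitWarning,
            stacklevel=3,
        )


def _stepwise_to_cumulative(params: lmfit.Parameters, n: int, covar):
    """log beta values and SEs from fitted stepwise log K parameters."""
    logk = np.array([params[f"logK{i}"].value for i in range(1, n + 1)])
    log_beta = np.cumsum(logk)
    se_logk = np.array(
        [
            params[f"logK{i}"].stderr
            if params[f"logK{i}"].stderr is not None
            else np.nan
            for i in range(1, n + 1)
        ]
    )
    if covar is not None:
        se_beta = np.array(
            [np.sqrt(covar[: i + 1, : i + 1].sum()) for i in range(n)]
        )
    else:
        se_beta = np.full(n, np.nan)
    return logk, se_logk, log_beta, se_beta


_FIT_KWS = dict(xtol=1e-14, ftol=1e-14, max_nfev=20000)


def fit_nmr(
    dataset: TitrationDataset,
    n: int,
    init: Optional[dict] = None,
) -> NmrFitResult:
    """Fit cumulative protonation constants to NMR shift vs pH data.

    All nuclei share one global set of constants (joint fit); each
    nucleus gets its own limiting shifts.  Unit-weight least squares;
    standard errors from the covariance at the optimum.

    Parameters
    ----------
    dataset : TitrationDataset
        Must have flavor ``"nmr"``.
    n : int
        Maximum number of protons that can bind.
    init : dict, optional
        Starting values; keys ``logK1..logKn`` and, per nucleus ``nuc``,
        ``("delta_L", nuc)`` / ``("delta_HiL", nuc)``.  Anything missing
        is guessed from the data.
    """
    if dataset.flavor != "nmr":
        raise ValueError("fit_nmr requires an nmr-flavor dataset")
    pts = dataset.points
    nuclei = sorted(pts["nucleus"].unique().tolist())
    n_params = n + len(nuclei) * (n + 1)
    _check_determined(len(pts), n_params)

    init = dict(init or {})
    params = lmfit.Parameters()

    # shared constants: average the per-nucleus level-crossing guesses
    guesses = []
    plateau = {}
    for nuc in nuclei:
        sub = pts[pts["nucleus"] == nuc]
        pH = sub["pH"].to_numpy(float)
        sig = sub["signal"].to_numpy(float)
        high, low = _plateaus(pH, sig)
        plateau[nuc] = (high, low)
        denom = low - high if low != high else 1.0
        u = np.clip((sig - high) / denom, 0.0, 1.0)
        guesses.append(_guess_logK(pH, u, n))
    logk0 = np.mean(guesses, axis=0)
    for i in range(1, n + 1):
        params.add(f"logK{i}", value=init.get(f"logK{i}", logk0[i - 1]))

    for j, nuc in enumerate(nuclei):
        high, low = plateau[nuc]
        dl = init.get(("delta_L", nuc), high)
        params.add(f"dL_{j}", value=dl)
        dhs = init.get(("delta_HiL", nuc))
        for i in range(1, n + 1):
            val = dhs[i - 1] if dhs is not None else high + (low - high) * i / n
            params.add(f"dH{i}_{j}", value=val)

    nuc_index = {nuc: j for j, nuc in enumerate(nuclei)}
    pH_all = pts["pH"].to_numpy(float)
    sig_all = pts["signal"].to_numpy(float)
    nuc_all = pts["nucleus"].map(nuc_index).to_numpy()

    def residuals(p):
        logk = np.array([p[f"logK{i}"].value for i in range(1, n + 1)])
        log_beta = np.cumsum(logk)
        res = np.empty_like(sig_all)
        for j in range(len(nuclei)):
            mask = nuc_all == j
            dl = p[f"dL_{j}"].value
            dh = [p[f"dH{i}_{j}"].value for i in range(1, n + 1)]
            res[mask] = sig_all[mask] - nmr_forward(
                pH_all[mask], log_beta, dl, dh
            )
        return res

    out = lmfit.minimize(residuals, params, method="leastsq", **_FIT_KWS)
    covar_k = out.covar[:n, :n] if out.covar is not None else None
    logk, se_logk, log_beta, se_beta = _stepwise_to_cumulative(
        out.params, n, covar_k
    )
    converged = bool(out.success)
    if not converged:
        warnings.warn(
            f"{dataset.compound_id}: NMR fit did not converge; "
            "partial result returned",
            FitWarning,
            stacklevel=2,
        )
    elif out.covar is None and np.sum(out.residual**2) > 0:
        warnings.warn(
            f"{dataset.compound_id}: covariance rank-deficient "
            "(indistinguishable constants?); standard errors unavailable",
            FitWarning,
            stacklevel=2,
        )
    dof = max(out.ndata - out.nvarys, 1)
    residual_sd = float(np.sqrt(np.sum(out.residual**2) / dof))
    delta_L = {
        nuc: out.params[f"dL_{j}"].value for nuc, j in nuc_index.items()
    }
    delta_HiL = {
        nuc: [out.params[f"dH{i}_{j}"].value for i in range(1, n + 1)]
        for nuc, j in nuc_index.items()
    }
    macro = MacroConstants(
        compound_id=dataset.compound_id,
        method="nmr",
        log_K=tuple(logk),
        se_log_K=tuple(np.nan_to_num(se_logk, nan=0.0)),
        symmetric=bool(dataset.metadata.get("symmetric", False)),
    )
    return NmrFitResult(
        log_beta=log_beta,
        se_log_beta=se_beta,
        macro=macro,
        delta_L=delta_L,
        delta_HiL=delta_HiL,
        residual_sd=residual_sd,
        converged=converged,
        n_points=out.ndata,
        n_params=out.nvarys,
        covar=out.covar,
    )


def _fit_pot_single(
    compound_id: str,
    pH: np.ndarray,
    vol: np.ndarray,
    n: int,
    init: Optional[dict],
    symmetric: bool,
) -> PotFitResult:
    n_params = n + 2
    _check_determined(len(pH), n_params)
    init = dict(init or {})

    high, low = _plateaus(pH, vol)
    denom = low - high if low != high else 1.0
    u = np.clip((vol - high) / denom, 0.0, 1.0)
    logk0 = _guess_logK(pH, u, n)

    params = lmfit.Parameters()
    for i in range(1, n + 1):
        params.add(f"logK{i}", value=init.get(f"logK{i}", logk0[i - 1]))
    params.add("A", value=init.get("A", (low - high) / n))
    params.add("D", value=init.get("D", high))

    def residuals(p):
        logk = np.array([p[f"logK{i}"].value for i in range(1, n + 1)])
        log_beta = np.cumsum(logk)
        return vol - pot_forward(pH, log_beta, p["A"].value, p["D"].value)

    out = lmfit.minimize(residuals, params, method="leastsq", **_FIT_KWS)
    covar_k = out.covar[:n, :n] if out.covar is not None else None
    logk, se_logk, log_beta, se_beta = _stepwise_to_cumulative(
        out.params, n, covar_k
    )
    converged = bool(out.success)
    if not converged:
        warnings.warn(
            f"{compound_id}: potentiometric fit did not converge; "
            "partial result returned",
            FitWarning,
            stacklevel=3,
        )
    dof = max(out.ndata - out.nvarys, 1)
    macro = MacroConstants(
        compound_id=compound_id,
        method="potentiometric",
        log_K=tuple(logk),
        se_log_K=tuple(np.nan_to_num(se_logk, nan=0.0)),
        symmetric=symmetric,
    )
    return PotFitResult(
        log_beta=log_beta,
        se_log_beta=se_beta,
        macro=macro,
        A=float(out.params["A"].value),
        D=float(out.params["D"].value),
        residual_sd=float(np.sqrt(np.sum(out.residual**2) / dof)),
        converged=converged,
        n_points=out.ndata,
        n_params=out.nvarys,
        covar=out.covar,
    )


def fit_pot(
    dataset: TitrationDataset,
    n: int,
    init: Optional[dict] = None,
) -> PotFitResult:
    """Fit protonation constants to a potentiometric difference titration.

    With a single titration the standard errors come from the regression
    covariance.  When the dataset carries replicate titrations, each
    replicate is fitted separately; the reported constants are the
    replicate means and the standard errors are the standard deviations
    across replicate fits (ddof=1) — the convention for repeated
    potentiometric determinations.
    """
    if dataset.flavor != "potentiometric":
        raise ValueError("fit_pot requires a potentiometric-flavor dataset")
    symmetric = bool(dataset.metadata.get("symmetric", False))
    reps = dataset.replicate_ids
    pts = dataset.points
    if len(reps) == 1 or "replicate" not in pts.columns:
        return _fit_pot_single(
            dataset.compound_id,
            pts["pH"].to_numpy(float),
            pts["signal"].to_numpy(float),
            n,
            init,
            symmetric,
        )

    fits = []
    for rep in reps:
        sub = pts[pts["replicate"] == rep]
        fits.append(
            _fit_pot_single(
                dataset.compound_id,
                sub["pH"].to_numpy(float),
                sub["signal"].to_numpy(float),
                n,
                init,
                symmetric,
            )
        )
    logk_mat = np.vstack([f.macro.log_K for f in fits])
    beta_mat = np.vstack([f.log_beta for f in fits])
    macro = MacroConstants(
        compound_id=dataset.compound_id,
        method="potentiometric",
        log_K=tuple(logk_mat.mean(axis=0)),
        se_log_K=tuple(logk_mat.std(axis=0, ddof=1)),
        symmetric=symmetric,
    )
    return PotFitResult(
        log_beta=beta_mat.mean(axis=0),
        se_log_beta=beta_mat.std(axis=0, ddof=1),
        macro=macro,
        A=float(np.mean([f.A for f in fits])),
        D=float(np.mean([f.D for f in fits])),
        residual_sd=float(np.mean([f.residual_sd for f in fits])),
        converged=all(f.converged for f in fits),
        n_points=int(sum(f.n_points for f in fits)),
        n_params=fits[0].n_params,
        n_replicates=len(fits),
        replicate_fits=fits,
    )
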