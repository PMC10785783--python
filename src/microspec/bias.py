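"""Bias statistics for model-compound microspeciation.

Given correction factors (model-compound log K minus the parent's true
second microconstant) grouped by model-compound type, this module
quantifies how biased the deductive method is:

* ``summarize_bias`` — MSE, squared bias and variance of the correction
  factors per model type (MSE with the n denominator, variance with
  n - 1; MSE = bias^2 + (n-1)/n * Var holds exactly).
* ``fit_correction_regression`` — the dependence of the correction
  factor on the parent's pair-interactivity.  The correction factor is
  itself the base-10 log of the multiplicative bias factor
  ``k_model / k_second``; modelling it as linear in the natural log of
  eps, ``corr = b0 + b1 * ln(eps)``, says that bias factor follows a
  power law in eps.  The model is fitted by weighted least squares with
  weights proportional to log eps (observation variance inversely
  proportional to log eps); being linear on the correction scale it
  admits negative observed corrections.
* ``bland_altman`` / ``method_effect_test`` — agreement between NMR and
  potentiometric determinations of the same constants: mean difference
  and limits of agreement, the difference-vs-mean trend, and a linear
  mixed model (log K ~ method, random intercept per parent compound)
  with a Wald F test for the method effect.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .speciation import (
    CorrectionRecord,
    MacroConstants,
    macro_to_micro_symmetric,
    interactivity,
    make_correction_record,
)


class BiasAnalysisWarning(UserWarning):
    pass


@dataclass(frozen=True)
class BiasSummary:
    """Per-model-type decomposition of correction-factor error."""

    model_type: str
    n: int
    mse: float
    bias_sq: float
    variance: float  # NaN when n < 2

    @property
    def mean_correction(self) -> float:
        return math.copysign(math.sqrt(self.bias_sq), 1.0)


@dataclass(frozen=True)
class RegressionEstimate:
    """Weighted fit of the correction factor on interactivity.

    ``b0`` and ``b1`` parametrize ``correction = b0 + b1 * ln(eps)``;
    ``prediction_band(log_eps)`` returns (fit, lower, upper) at 95%.
    """

    model_type: str
    b0: float
    b1: float
    se_b0: float
    se_b1: float
    n: int
    residual_scale: float
    cov: np.ndarray
    prediction_band: Callable[[np.ndarray], tuple[np.ndarray, np.ndarray, np.ndarray]]

    def predict(self, log_eps):
        z = math.log(10.0) * np.asarray(log_eps, dtype=float)
        return self.b0 + self.b1 * z


class MethodEffect(NamedTuple):
    """Wald F test of the measurement-method fixed effect."""

    F: float
    df1: int
    df2: int
    p: float


@dataclass(frozen=True)
class MethodComparison:
    """Bland-Altman agreement between NMR and potentiometric log K."""

    pairs: pd.DataFrame
    bland_altman_bias: float
    loa: tuple[float, float]
    trend_slope: float
    method_effect: Optional[MethodEffect] = None


# ---------------------------------------------------------------------------
# correction records from a constants table


def build_correction_records(table: pd.DataFrame) -> list[CorrectionRecord]:
    """Correction records from a constants table (parents + models).

    The table uses the registry dialect: columns ``compound_id, method,
    role, model_type, parent_id, log_K1, se_K1, log_K2, se_K2``.  Parent
    rows are mirror-symmetric diprotics; model rows are monoprotic, with
    ``log_K1`` their single protonation constant.  Microconstants are
    recomputed from the (unrounded) parent macroconstants; the model
    constant is compared to the parent's second microconstant.
    """
    records: list[CorrectionRecord] = []
    parents = table[table["role"] == "parent"]
    micro_by_key = {}
    for _, row in parents.iterrows():
        macro = MacroConstants(
            compound_id=row["compound_id"],
            method=row["method"],
            log_K=(float(row["log_K1"]), float(row["log_K2"])),
            se_log_K=(float(row["se_K1"]), float(row["se_K2"])),
            symmetric=True,
        )
        micro_by_key[(row["compound_id"], row["method"])] = (
            macro_to_micro_symmetric(macro)
        )
    for _, row in table[table["role"] == "model"].iterrows():
        key = (row["parent_id"], row["method"])
        if key not in micro_by_key:
            raise KeyError(
                f"model {row['compound_id']!r} references unknown parent "
                f"{key[0]!r} for method {key[1]!r}"
            )
        records.append(
            make_correction_record(
                micro_by_key[key],
                model_id=row["compound_id"],
                model_type=row["model_type"],
                model_logK=float(row["log_K1"]),
                se_model=float(row["se_K1"]),
            )
        )
    return records


def derive_micro_table(table: pd.DataFrame) -> pd.DataFrame:
    """Derived microconstants/interactivity/corrections for a whole table.

    One row per parent (microconstants and log eps) merged with one row
    per model compound (correction factor), mirroring the layout of a
    published constants table.
    """
    rows = []
    micro_by_key = {}
    for _, row in table[table["role"] == "parent"].iterrows():
        macro = MacroConstants(
            compound_id=row["compound_id"],
            method=row["method"],
            log_K=(float(row["log_K1"]), float(row["log_K2"])),
            se_log_K=(float(row["se_K1"]), float(row["se_K2"])),
            symmetric=True,
        )
        micro = macro_to_micro_symmetric(macro)
        micro_by_key[(row["compound_id"], row["method"])] = micro
        eps = interactivity(micro)
        rows.append(
            {
                "compound_id": row["compound_id"],
                "method": row["method"],
                "role": "parent",
                "log_k_first": micro.log_k_first,
                "se_first": micro.se_first,
                "log_k_second": micro.log_k_second,
                "se_second": micro.se_second,
                "log_eps": eps.value,
                "se_log_eps": eps.se,
            }
        )
    for rec in build_correction_records(table):
        rows.append(
            {
                "compound_id": rec.model_id,
                "method": rec.method,
                "role": "model",
                "parent_id": rec.parent_id,
                "model_type": rec.model_type,
                "log_K_model": rec.log_K_model,
                "se_model": rec.se_model,
                "correction": rec.correction,
                "se_correction": rec.se_correction,
                "log_eps": rec.log_eps.value,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# summaries and regression


def summarize_bias(
    records: Sequence[CorrectionRecord], model_type: str
) -> BiasSummary:
    """MSE / bias^2 / variance of correction factors of one model type.

    NMR and potentiometric records are pooled (counted separately).
    MSE uses the n denominator, the variance n - 1; the exact identity
    ``mse = bias_sq + (n-1)/n * variance`` follows.
    """
    corr = np.array(
        [r.correction for r in records if r.model_type == model_type]
    )
    n = len(corr)
    if n == 0:
        raise ValueError(f"no records of model type {model_type!r}")
    mse = float(np.mean(corr**2))
    bias_sq = float(np.mean(corr) ** 2)
    variance = float(np.var(corr, ddof=1)) if n >= 2 else float("nan")
    return BiasSummary(
        model_type=model_type, n=n, mse=mse, bias_sq=bias_sq, variance=variance
    )


def fit_correction_regression(
    records: Sequence[CorrectionRecord],
    model_type: str,
    weighting: str = "logeps",
) -> RegressionEstimate:
    """Weighted regression of the correction factor on interactivity.

    Model: ``correction = b0 + b1 * ln(eps)``.  The correction factor is
    the base-10 log of the multiplicative bias factor of the model
    compound, so this fit states that the bias factor is a power law in
    the interactivity eps; on the correction scale the model is linear,
    which keeps negative observed corrections admissible.  Observation
    variance is taken inversely proportional to log eps (weight =
    log eps) under the default weighting.  Records with ``log_eps <= 0``
    are excluded (their weight is undefined) with a warning.

    Returns estimates, standard errors and a 95% prediction band
    callable ``band(log_eps) -> (fit, lower, upper)``.
    """
    if weighting not in ("logeps", "none"):
        raise ValueError("weighting must be 'logeps' or 'none'")
    sel = [r for r in records if r.model_type == model_type]
    kept = [r for r in sel if r.log_eps.value > 0]
    if len(kept) < len(sel):
        warnings.warn(
            f"{model_type}: excluded {len(sel) - len(kept)} record(s) with "
            "log_eps <= 0 from the weighted regression",
            BiasAnalysisWarning,
            stacklevel=2,
        )
    if len(kept) < 3:
        raise ValueError(
            f"need at least 3 records with log_eps > 0, got {len(kept)}"
        )
    x = np.array([r.log_eps.value for r in kept])
    y = np.array([r.correction for r in kept])
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: all log_eps values are equal")
    w = x if weighting == "logeps" else np.ones_like(x)
    z = math.log(10.0) * x  # regressor: natural log of eps

    X = np.column_stack([np.ones_like(z), z])
    XtWX = X.T @ (w[:, None] * X)
    XtWX_inv = np.linalg.inv(XtWX)
    beta = XtWX_inv @ (X.T @ (w * y))
    b0, b1 = map(float, beta)
    n = len(x)
    dof = n - 2
    resid = y - X @ beta
    s2 = float(np.sum(w * resid**2) / dof) if dof > 0 else float("nan")
    pcov = s2 * XtWX_inv
    se_b0, se_b1 = map(float, np.sqrt(np.diag(pcov)))
    tcrit = scipy.stats.t.ppf(0.975, dof) if dof > 0 else float("nan")

    def prediction_band(xx):
        xx = np.asarray(xx, dtype=float)
        zz = math.log(10.0) * xx
        X0 = np.column_stack([np.ones_like(zz), zz])
        fit = X0 @ beta
        var_fit = np.einsum("ni,ij,nj->n", X0, pcov, X0)
        w_new = xx if weighting == "logeps" else np.ones_like(xx)
        var_pred = var_fit + s2 / w_new
        half = tcrit * np.sqrt(var_pred)
        return fit, fit - half, fit + half

    return RegressionEstimate(
        model_type=model_type,
        b0=b0,
        b1=b1,
        se_b0=se_b0,
        se_b1=se_b1,
        n=n,
        residual_scale=math.sqrt(s2) if s2 == s2 else float("nan"),
        cov=pcov,
        prediction_band=prediction_band,
    )


# ---------------------------------------------------------------------------
# method comparison


def pairs_from_constants(table: pd.DataFrame) -> pd.DataFrame:
    """Paired NMR/potentiometric log K values from a constants table.

    Keeps parent compounds determined by both methods; each stepwise
    constant (K1, K2) forms one pair.  Columns: ``compound_id``,
    ``constant``, ``logK_nmr``, ``logK_pot``.
    """
    parents = table[table["role"] == "parent"]
    rows = []
    for cid, grp in parents.groupby("compound_id"):
        methods = set(grp["method"])
        if not {"nmr", "potentiometric"}.issubset(methods):
            continue
        nmr = grp[grp["method"] == "nmr"].iloc[0]
        pot = grp[grp["method"] == "potentiometric"].iloc[0]
        for k in ("log_K1", "log_K2"):
            rows.append(
                {
                    "compound_id": cid,
                    "constant": k,
                    "logK_nmr": float(nmr[k]),
                    "logK_pot": float(pot[k]),
                }
            )
    return pd.DataFrame(rows)


def _as_pairs_frame(pairs) -> pd.DataFrame:
    if isinstance(pairs, pd.DataFrame):
        return pairs
    return pd.DataFrame(
        pairs, columns=["compound_id", "logK_nmr", "logK_pot"]
    )


def bland_altman(pairs, run_method_effect: bool = True) -> MethodComparison:
    """Bland-Altman agreement analysis of paired NMR/potentiometric log K.

    The difference is NMR minus potentiometry.  ``loa`` are the 95%
    limits of agreement (bias +/- 1.96 SD of the differences);
    ``trend_slope`` is the OLS slope of difference on mean, positive when
    NMR underestimates low constants and overestimates high ones.
    """
    df = _as_pairs_frame(pairs)
    if len(df) < 2:
        raise ValueError("need at least 2 pairs")
    diff = df["logK_nmr"].to_numpy(float) - df["logK_pot"].to_numpy(float)
    mean = (df["logK_nmr"].to_numpy(float) + df["logK_pot"].to_numpy(float)) / 2
    bias = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    loa = (bias - 1.96 * sd, bias + 1.96 * sd)
    slope = (
        float(np.polyfit(mean, diff, 1)[0]) if np.ptp(mean) > 0 else 0.0
    )
    effect = None
    if run_method_effect and "compound_id" in df.columns:
        effect = method_effect_test(df)
    return MethodComparison(
        pairs=df,
        bland_altman_bias=bias,
        loa=loa,
        trend_slope=slope,
        method_effect=effect,
    )


def method_effect_test(pairs) -> MethodEffect:
    """Mixed-effects test of the measurement-method effect on log K.

    Fits ``logK ~ method`` with a random intercept per parent compound
    (REML) and reports a Wald F test of the method fixed effect.  The
    denominator degrees of freedom follow the containment convention,
    ``df2 = n_obs - n_groups - 1``; for a balanced paired design this
    reduces to the paired-t degrees of freedom.
    """
    import statsmodels.formula.api as smf

    df = _as_pairs_frame(pairs)
    long = pd.concat(
        [
            pd.DataFrame(
                {
                    "compound_id": df["compound_id"],
                    "method": "nmr",
                    "logK": df["logK_nmr"],
                }
            ),
            pd.DataFrame(
                {
                    "compound_id": df["compound_id"],
                    "method": "potentiometric",
                    "logK": df["logK_pot"],
                }
            ),
        ],
        ignore_index=True,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm("logK ~ method", long, groups=long["compound_id"])
        fit = model.fit(reml=True)
    name = [p for p in fit.params.index if p.startswith("method")][0]
    coef = float(fit.params[name])
    se = float(fit.bse[name])
    F = (coef / se) ** 2
    n_obs = len(long)
    n_groups = long["compound_id"].nunique()
    df2 = n_obs - n_groups - 1
    p = float(scipy.stats.f.sf(F, 1, df2))
    return MethodEffect(F=float(F), df1=1, df2=int(df2), p=p)
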