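"""qPCR quantification: ΔΔCt relative expression, percent input, H3-relative
enrichment, and exponential-decay fitting of transcript levels.

Ct tables are long-format (sample, condition, target, replicate, ct).  The
amplification efficiency defaults to 2.0 (perfect doubling per cycle, the
classic ΔΔCt assumption) and is exposed everywhere.  Spike-in
normalisation needs no separate code path: the spiked RNA is simply used
as the reference target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

CT_COLUMNS = ["sample", "condition", "target", "replicate", "ct"]


class FitError(RuntimeError):
    """Nonlinear fit failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_params=None):
        super().__init__(message)
        self.last_params = last_params


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a long-format Ct CSV and validate it."""
    df = pd.read_csv(path, comment="#")
    return validate_ct_table(df)


def write_ct_table(df: pd.DataFrame, path: str | Path, header_note: str = "") -> None:
    with open(path, "w") as fh:
        if header_note:
            fh.write(f"# {header_note}\n")
        df.to_csv(fh, index=False)


def validate_ct_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    ct = df["ct"].to_numpy(dtype=float)
    if not np.all(np.isfinite(ct)) or (ct <= 0).any():
        raise ValueError("all Ct values must be finite and > 0")
    return df


@dataclass(frozen=True)
class RelativeExpressionResult:
    """ΔΔCt fold change of a target vs a reference gene, condition vs vehicle."""

    target: str
    reference: str
    condition: str
    vehicle: str
    fold: float                    # efficiency^(−mean ΔΔCt), geometric-mean fold
    sem: float                     # SEM of per-replicate fold values
    replicate_folds: tuple[float, ...]
    efficiency: float


def _delta_ct(df: pd.DataFrame, target: str, reference: str, condition: str) -> np.ndarray:
    """Per-replicate ΔCt = Ct_target − Ct_reference, paired on replicate index."""
    sel = df[df["condition"] == condition]
    tgt = sel[sel["target"] == target].set_index("replicate")["ct"]
    ref = sel[sel["target"] == reference].set_index("replicate")["ct"]
    if tgt.empty:
        raise ValueError(f"no Ct rows for target {target!r} in condition {condition!r}")
    if ref.empty:
        raise ValueError(f"no Ct rows for reference {reference!r} in condition {condition!r}")
    joined = pd.concat([tgt.rename("t"), ref.rename("r")], axis=1, join="inner")
    if joined.empty:
        raise ValueError(
            f"no paired replicates for {target!r}/{reference!r} in {condition!r}"
        )
    return (joined["t"] - joined["r"]).to_numpy(dtype=float)


def relative_expression(
    ct: pd.DataFrame,
    target: str,
    reference: str,
    condition: str,
    vehicle: str,
    efficiency: float = 2.0,
) -> RelativeExpressionResult:
    """ΔΔCt relative expression of ``condition`` vs ``vehicle``.

    Per replicate, ΔCt = Ct_target − Ct_reference; ΔΔCt subtracts the
    vehicle-mean ΔCt; the fold change is efficiency^(−ΔΔCt).  The summary
    fold uses the mean ΔΔCt (i.e. the geometric mean of replicate folds,
    so vehicle-vs-vehicle is exactly 1); the SEM is across replicate folds.
    """
    if efficiency <= 1:
        raise ValueError("efficiency must be > 1")
    validate_ct_table(ct)
    d_cond = _delta_ct(ct, target, reference, condition)
    d_veh = _delta_ct(ct, target, reference, vehicle)
    ddct = d_cond - d_veh.mean()
    folds = efficiency ** (-ddct)
    fold = float(efficiency ** (-ddct.mean()))
    sem = float(folds.std(ddof=1) / math.sqrt(len(folds))) if len(folds) > 1 else 0.0
    return RelativeExpressionResult(
        target=target, reference=reference, condition=condition, vehicle=vehicle,
        fold=fold, sem=sem, replicate_folds=tuple(folds), efficiency=efficiency,
    )


def percent_input(
    ct_chip: float,
    ct_input: float,
    input_fraction: float,
    ct_background: float | None = None,
    efficiency: float = 2.0,
) -> float:
    """ChIP-qPCR percent of input with optional background subtraction.

    The input Ct is first adjusted for its dilution: Ct' = ct_input −
    log_eff(1/input_fraction), the Ct the undiluted input would give.
    Percent input is then 100 · efficiency^(Ct' − ct_chip).  When a
    no-antibody control Ct is supplied, its percent-input value is
    subtracted on the percent scale and the result floored at zero.
    """
    if not (0 < input_fraction <= 1):
        raise ValueError("input_fraction must lie in (0, 1]")
    if efficiency <= 1:
        raise ValueError("efficiency must be > 1")
    adj = ct_input - math.log(1.0 / input_fraction, efficiency)
    pct = 100.0 * efficiency ** (adj - ct_chip)
    if ct_background is not None:
        pct -= 100.0 * efficiency ** (adj - ct_background)
    return max(pct, 0.0)


def relative_to_h3(percent_mark: float, percent_h3: float) -> float:
    """Histone-mark enrichment normalised to total H3 (both percent input).

    Returns NaN (undefined) when the H3 percent is zero.
    """
    if percent_h3 < 0 or percent_mark < 0:
        raise ValueError("percent-input values must be non-negative")
    if percent_h3 == 0:
        return math.nan
    return percent_mark / percent_h3


@dataclass(frozen=True)
class DecayFit:
    """Exponential decay fit y = A·exp(−k·t) (+ C)."""

    amplitude: float           # A, expression units
    rate: float                # k, per hour
    plateau: float | None      # C when fitted with a plateau
    half_life: float           # ln 2 / k, hours (inf when k = 0)
    rss: float
    no_decay: bool = False


def fit_exponential_decay(
    times,
    values,
    with_plateau: bool = False,
    tol: float = 1e-8,
) -> DecayFit:
    """Nonlinear least-squares fit of an exponential decay.

    Model: y = A·e^(−k·t), optionally plus a plateau C.  Initial values:
    A from the earliest time point, k from a log-linear regression of
    log y on t (clipped at 0), C = min(y).  k is bounded below by 0; a
    fit pinned at k ≈ 0 is flagged ``no_decay``.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and values must be 1-D and equal length")
    if len(np.unique(t)) < 3:
        raise ValueError("need at least 3 distinct time points")
    if (y <= 0).any():
        raise ValueError("values must be positive")

    a0 = float(y[np.argmin(t)])
    slope = float(np.polyfit(t, np.log(y), 1)[0])
    k0 = max(-slope, 0.0)

    if with_plateau:
        c0 = float(y.min())

        def model(tt, a, k, c):
            return a * np.exp(-k * tt) + c

        p0 = [a0, max(k0, 1e-6), c0]
        bounds = ([0, 0, 0], [np.inf, np.inf, np.inf])
    else:
        def model(tt, a, k):
            return a * np.exp(-k * tt)

        p0 = [a0, k0]
        bounds = ([0, 0], [np.inf, np.inf])

    try:
        popt, _ = curve_fit(model, t, y, p0=p0, bounds=bounds,
                            xtol=tol, ftol=tol, gtol=tol, maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"decay fit did not converge: {exc}", last_params=p0) from exc

    resid = y - model(t, *popt)
    rss = float(resid @ resid)
    k = float(popt[1])
    no_decay = k < 1e-8  # pinned at the k >= 0 bound within fit tolerance
    return DecayFit(
        amplitude=float(popt[0]),
        rate=k,
        plateau=float(popt[2]) if with_plateau else None,
        half_life=math.inf if no_decay else math.log(2) / k,
        rss=rss,
        no_decay=no_decay,
    )
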