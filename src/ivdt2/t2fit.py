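"""Mono-exponential T2 estimation from multi-echo decay curves.

The signal model is S(TE) = S0 * exp(-TE / T2).  Fits are initialised by
log-linear regression on the positive signals and refined by bounded
nonlinear least squares; the two primary aggregates are the whole-disc T2
(whole-disc ROI fit averaged over all slices) and the nuclear T2 (central
subregion of the central slice).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .subregions import WHOLE_DISC

__all__ = [
    "DecayFit",
    "fit_monoexponential",
    "fit_regions",
    "whole_disc_t2",
    "nuclear_t2",
    "subregion_t2_averaged",
]

T2_BOUNDS = (1.0, 2000.0)  # ms; physical-plausibility bounds for the NLLS step


@dataclass
class DecayFit:
    """Result of one mono-exponential fit."""

    s0: float
    t2: float
    residual_rms: float
    r_squared: float
    converged: bool


def _model(te, s0, t2):
    return s0 * np.exp(-te / t2)


def _loglinear(te: np.ndarray, sig: np.ndarray, bounds) -> tuple[float, float]:
    pos = sig > 0
    slope, intercept = np.polyfit(te[pos], np.log(sig[pos]), 1)
    s0 = float(np.exp(intercept))
    if slope >= 0:  # non-decaying data; start from the upper T2 bound
        return s0, bounds[1]
    return s0, float(np.clip(-1.0 / slope, *bounds))


def fit_monoexponential(echo_times, signals, *, exclude_first: bool = False,
                        offset: bool = False,
                        t2_bounds: tuple[float, float] = T2_BOUNDS) -> DecayFit:
    """Fit S(TE) = S0 exp(-TE/T2) to one decay curve.

    Parameters
    ----------
    echo_times, signals:
        Strictly increasing echo times (ms) and the matching signals.
    exclude_first:
        Drop the first echo before fitting (off by default; all 16 echoes
        are used).
    offset:
        Add a constant noise-floor term to the model (sensitivity checks
        only; off by default).

    Falls back to the log-linear estimate with ``converged=False`` if the
    nonlinear refinement fails.
    """
    te = np.asarray(echo_times, dtype=float)
    sig = np.asarray(signals, dtype=float)
    if te.shape != sig.shape or te.ndim != 1:
        raise ValueError("echo_times and signals must be matching 1-D arrays")
    if np.any(np.diff(te) <= 0):
        raise ValueError("echo_times must be strictly increasing")
    if exclude_first:
        te, sig = te[1:], sig[1:]
    if np.count_nonzero(sig > 0) < 3:
        raise ValueError("need at least 3 positive signal values to fit a decay")

    s0_init, t2_init = _loglinear(te, sig, t2_bounds)
    try:
        if offset:
            popt, _ = curve_fit(
                lambda t, s0, t2, c: _model(t, s0, t2) + c,
                te, sig, p0=[s0_init, t2_init, 0.0],
                bounds=([0.0, t2_bounds[0], -np.inf], [np.inf, t2_bounds[1], np.inf]),
                maxfev=10000, xtol=1e-12, ftol=1e-12,
            )
            s0, t2, _ = popt
        else:
            popt, _ = curve_fit(
                _model, te, sig, p0=[s0_init, t2_init],
                bounds=([0.0, t2_bounds[0]], [np.inf, t2_bounds[1]]),
                maxfev=10000, xtol=1e-12, ftol=1e-12,
            )
            s0, t2 = popt
        converged = True
    except RuntimeError:
        s0, t2, converged = s0_init, t2_init, False

    resid = sig - _model(te, s0, t2)
    ss_tot = float(np.sum((sig - sig.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return DecayFit(
        s0=float(s0),
        t2=float(t2),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        r_squared=r2,
        converged=converged,
    )


def fit_regions(region_means: pd.DataFrame, **fit_kwargs) -> pd.DataFrame:
    """Fit every (disc, slice, region) decay in a tidy region-mean table.

    Input columns: disc, slice, region, echo_time, mean_signal (the output
    of :func:`ivdt2.subregions.region_mean_signals`).  Returns one row per
    ROI with columns disc, slice, region, t2, s0, residual_rms, r_squared,
    converged.
    """
    rows = []
    for (disc, sl, region), g in region_means.groupby(["disc", "slice", "region"], sort=True):
        g = g.sort_values("echo_time")
        fit = fit_monoexponential(g["echo_time"].to_numpy(), g["mean_signal"].to_numpy(), **fit_kwargs)
        if not fit.converged:
            warnings.warn(f"T2 fit did not converge for disc {disc}, slice {sl}, region {region}")
        rows.append(
            {
                "disc": disc,
                "slice": int(sl),
                "region": int(region),
                "t2": fit.t2,
                "s0": fit.s0,
                "residual_rms": fit.residual_rms,
                "r_squared": fit.r_squared,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)


def whole_disc_t2(records: pd.DataFrame) -> pd.Series:
    """Whole-disc T2 per disc: the whole-disc ROI fit averaged over slices."""
    whole = records[records["region"] == WHOLE_DISC]
    if whole.empty:
        raise ValueError("no whole-disc fits in records")
    return whole.groupby("disc")["t2"].mean()


def nuclear_t2(records: pd.DataFrame, central_slice: int | None = None) -> pd.Series:
    """Nuclear T2 per disc: subregion 3 on the central slice (no averaging)."""
    if central_slice is None:
        central_slice = _central_slice(records)
    nuc = records[(records["region"] == 3) & (records["slice"] == central_slice)]
    if nuc.empty:
        raise ValueError(f"no region-3 fit on slice {central_slice}")
    return nuc.set_index("disc")["t2"]


def _central_slice(records: pd.DataFrame) -> int:
    slices = np.sort(records["slice"].unique())
    # third slice of a six-slice protocol; middle slice otherwise
    return int(slices[2]) if slices.size >= 3 else int(slices[slices.size // 2])


def subregion_t2_averaged(records: pd.DataFrame) -> pd.DataFrame:
    """Per-disc per-subregion T2 averaged over all slices.

    Returns a frame indexed by disc with one column per region 1..5.
    """
    sub = records[records["region"] > 0]
    return sub.pivot_table(index="disc", columns="region", values="t2", aggfunc="mean")
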