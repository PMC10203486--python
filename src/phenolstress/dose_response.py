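"""Sigmoidal concentration-viability fitting and EC50 extraction.

The model is the four-parameter logistic on log dose,

    response(d) = bottom + (top - bottom) / (1 + (d / EC50)^hill),

fitted by least squares with a deterministic multistart grid (hill in
{0.5, 1, 2, 4}, EC50 at dose quantiles) and bottom constrained >= 0. EC50 is
parameterized internally as log10(EC50) for numerical stability; its
standard error comes from the fit's curvature via the delta method. A
two-parameter variant fixes bottom = 0 and top at the mean response of the
lowest-dose group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)

__all__ = ["DoseResponseTable", "DoseResponseFit", "read_dose_response", "fit"]


@dataclass
class DoseResponseTable:
    """Nominal doses (ppm) with measured viability responses."""

    doses: np.ndarray
    responses: np.ndarray
    replicate: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.doses.shape != self.responses.shape:
            raise ValueError("doses and responses must align")
        if (self.doses <= 0).any():
            raise ValueError("doses must be strictly positive (log-scale model)")
        if (self.responses < 0).any():
            raise ValueError("responses must be non-negative")
        if len(np.unique(self.doses)) < 4:
            raise ValueError("need at least 4 distinct doses")


@dataclass
class DoseResponseFit:
    ec50: float
    hill: float
    top: float
    bottom: float
    r2: float
    se_ec50: float
    extrapolated: bool
    converged: bool
    predicted: np.ndarray


def read_dose_response(path: str | Path) -> DoseResponseTable:
    """Read a delimited table with columns dose_ppm, response[, replicate]."""
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("dose_ppm", "response"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    rep = df["replicate"].to_numpy() if "replicate" in df.columns else None
    return DoseResponseTable(doses=df["dose_ppm"].to_numpy(),
                             responses=df["response"].to_numpy(), replicate=rep)


def _model(logd: np.ndarray, bottom: float, top: float,
           log_ec50: float, hill: float) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logd - log_ec50)))


def fit(table: DoseResponseTable, model: str = "4pl",
        scale: str = "log") -> DoseResponseFit:
    """Least-squares logistic fit returning EC50, hill, r-squared and the
    standard error of EC50.

    ``model="4pl"`` fits (bottom, top, EC50, hill) with bottom >= 0;
    ``model="2pl"`` fixes bottom = 0 and top at the lowest-dose mean response
    and fits only (EC50, hill). ``scale`` selects the fitted scale:
    ``"log"`` (default) minimizes residuals of log response — the maximum
    likelihood choice for the multiplicative error typical of cell counts —
    while ``"linear"`` minimizes raw residuals; zero responses force the
    linear scale. ``r2`` is computed on the fitted scale. Raises on
    degenerate (constant) responses or non-convergence of every start.
    """
    d = table.doses
    y = table.responses
    if np.ptp(y) == 0:
        raise ValueError("degenerate response: all values equal")
    if scale not in ("log", "linear"):
        raise ValueError(f"unknown scale {scale!r}")
    if scale == "log" and (y <= 0).any():
        logger.warning("non-positive responses present; fitting on the "
                       "linear scale instead")
        scale = "linear"
    logd = np.log10(d)
    top0 = float(np.mean(y[d == d.min()]))
    ec50_starts = np.quantile(np.unique(d), [0.25, 0.5, 0.75])
    hill_starts = (0.5, 1.0, 2.0, 4.0)

    tiny = max(y[y > 0].min() if (y > 0).any() else 1.0, 1e-12) * 1e-9
    if model == "4pl":
        lower = [0.0, 0.0, logd.min() - 3.0, 0.05]
        upper = [np.inf, np.inf, logd.max() + 3.0, 50.0]
        make_p0 = lambda e, h: [0.0, top0, np.log10(e), h]
        func = _model
    elif model == "2pl":
        lower = [logd.min() - 3.0, 0.05]
        upper = [logd.max() + 3.0, 50.0]
        make_p0 = lambda e, h: [np.log10(e), h]
        func = lambda ld, log_ec50, hill: _model(ld, 0.0, top0, log_ec50, hill)
    else:
        raise ValueError(f"unknown model {model!r}; use '4pl' or '2pl'")

    if scale == "log":
        target = np.log(y)
        objective = lambda ld, *p: np.log(np.maximum(func(ld, *p), tiny))
    else:
        target = y
        objective = func

    best = None
    diagnostics = []
    for e0 in ec50_starts:
        for h0 in hill_starts:
            try:
                popt, pcov = curve_fit(objective, logd, target, p0=make_p0(e0, h0),
                                       bounds=(lower, upper), maxfev=20000)
            except (RuntimeError, ValueError) as exc:
                diagnostics.append(f"start(ec50={e0:.3g}, hill={h0}): {exc}")
                continue
            sse = float(np.sum((objective(logd, *popt) - target) ** 2))
            if best is None or sse < best[0]:
                best = (sse, popt, pcov)
    if best is None:
        raise RuntimeError("dose-response fit failed to converge from every start:\n"
                           + "\n".join(diagnostics))
    sse, popt, pcov = best
    if model == "4pl":
        bottom, top, log_ec50, hill = popt
        i_log = 2
    else:
        (log_ec50, hill), bottom, top = popt, 0.0, top0
        i_log = 0
    ec50 = float(10.0 ** log_ec50)
    var_log = float(pcov[i_log, i_log]) if np.isfinite(pcov[i_log, i_log]) else np.nan
    se_ec50 = float(np.log(10.0) * ec50 * np.sqrt(var_log)) if var_log >= 0 else np.nan
    sst = float(np.sum((target - target.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else np.nan
    extrapolated = not (d.min() <= ec50 <= d.max())
    if extrapolated:
        logger.warning("fitted EC50 %.4g lies outside the tested dose range "
                       "[%.4g, %.4g]", ec50, d.min(), d.max())
    return DoseResponseFit(ec50=ec50, hill=float(hill), top=float(top),
                           bottom=float(bottom), r2=float(r2), se_ec50=se_ec50,
                           extrapolated=extrapolated, converged=True,
                           predicted=func(logd, *popt))
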