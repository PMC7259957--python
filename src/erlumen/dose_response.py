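"""Inhibitory Hill fits of channel open probability versus luminal Ca2+.

Raising free Ca2+ on the luminal side of the InsP3R suppresses the
maximally-stimulated open probability.  The suppression is summarised by
a simple inhibitory Hill curve

    P_o(c) = P_max * [1 + (c / K_inh)^H_inh]^-1

with plateau ``P_max``, half-maximal inhibitory concentration ``K_inh``
(micromolar) and Hill coefficient ``H_inh``.  Fitting is plain nonlinear
least squares to the *mean* open probability at each concentration
(optionally 1/sem^2-weighted), with a deterministic multi-start grid and
standard errors from the local curvature at the optimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import FitError, ValidationError


@dataclass
class PoDataset:
    """Mean open probability versus luminal [Ca2+] (micromolar)."""

    ca_er_um: np.ndarray
    mean_po: np.ndarray
    sem: np.ndarray | None = None
    n: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ca_er_um = np.asarray(self.ca_er_um, dtype=float)
        self.mean_po = np.asarray(self.mean_po, dtype=float)
        if (self.ca_er_um <= 0).any():
            raise ValidationError("concentrations must be > 0")
        order = np.argsort(self.ca_er_um)
        self.ca_er_um = self.ca_er_um[order]
        self.mean_po = self.mean_po[order]
        if np.any(np.diff(self.ca_er_um) <= 0):
            raise ValidationError("concentrations must be distinct")
        if ((self.mean_po < 0) | (self.mean_po > 1)).any():
            raise ValidationError("open probabilities must lie in [0, 1]")
        if self.sem is not None:
            self.sem = np.asarray(self.sem, dtype=float)[order]
        if self.n is not None:
            self.n = np.asarray(self.n)[order]

    def to_dataframe(self) -> pd.DataFrame:
        out = {"ca_er_uM": self.ca_er_um, "mean_po": self.mean_po}
        if self.sem is not None:
            out["sem"] = self.sem
        if self.n is not None:
            out["n"] = self.n
        return pd.DataFrame(out)


@dataclass
class HillFit:
    """Fitted inhibitory Hill parameters with curvature standard errors."""

    p_max: float
    k_inh_um: float
    h_inh: float
    se_p_max: float = float("nan")
    se_k_inh: float = float("nan")
    se_h_inh: float = float("nan")
    rss: float = float("nan")
    n_points: int = 0
    descent_sampled: bool = True
    covariance: np.ndarray | None = field(default=None, repr=False)

    def predict(self, ca_er_um):
        return hill_po(ca_er_um, self.p_max, self.k_inh_um, self.h_inh)


def hill_po(ca_er_um, p_max: float, k_inh_um: float, h_inh: float):
    """Evaluate P_o = P_max [1 + (c / K_inh)^H]^-1 at c >= 0 (micromolar)."""
    c = np.asarray(ca_er_um, dtype=float)
    if (c < 0).any():
        raise ValidationError("concentration must be non-negative")
    if k_inh_um <= 0 or h_inh <= 0 or p_max <= 0:
        raise ValidationError("Hill parameters must be strictly positive")
    with np.errstate(over="ignore"):
        out = p_max / (1.0 + (c / k_inh_um) ** h_inh)
    return out if out.ndim else float(out)


def _residuals(theta: np.ndarray, c: np.ndarray, po: np.ndarray, w: np.ndarray):
    p_max, log_k, h = theta
    pred = p_max / (1.0 + np.exp(h * (np.log(c) - log_k)))
    return (pred - po) * w


def fit_hill(
    data: PoDataset,
    weights: str | None = None,
    fix_p_max: float | None = None,
    h_starts: tuple[float, ...] = (1.0, 2.0, 4.0),
) -> HillFit:
    """Least-squares fit of the inhibitory Hill curve to mean P_o.

    ``weights=None`` (default) fits the plain averages; ``weights='sem'``
    weights residuals by 1/sem.  The fit is a deterministic multi-start:
    K_inh is initialised at the first concentration where P_o falls below
    half its maximum, H from ``h_starts``, P_max at the largest observed
    mean.  Standard errors come from the Gauss-Newton curvature at the
    optimum.  Raises on flat (descent-free, H-unidentifiable) data.
    """
    c, po = data.ca_er_um, data.mean_po
    if c.size < 4:
        raise ValidationError("need at least 4 concentrations")
    if po.max() - po.min() < 1e-6 or po.max() <= 0:
        raise FitError("flat dataset: Hill parameters are unidentifiable")
    if weights == "sem":
        if data.sem is None:
            raise ValidationError("weights='sem' requires sem values")
        w = 1.0 / np.maximum(data.sem, 1e-6)
    elif weights is None:
        w = np.ones_like(po)
    else:
        raise ValidationError(f"unknown weighting {weights!r}")

    descent_sampled = po.min() < 0.6 * po.max()
    if not descent_sampled:
        warnings.warn(
            "descending limb poorly sampled; K_inh and H_inh weakly identified",
            stacklevel=2,
        )

    p_max0 = float(po.max())
    below = np.nonzero(po < 0.5 * p_max0)[0]
    k0 = float(c[below[0]]) if below.size else float(c[-1])

    best = None
    for h0 in h_starts:
        x0 = np.array([fix_p_max if fix_p_max is not None else p_max0, np.log(k0), h0])
        if fix_p_max is not None:

            def resid(th2, _pm=fix_p_max):
                return _residuals(np.concatenate(([_pm], th2)), c, po, w)

            sol = least_squares(
                resid,
                x0[1:],
                bounds=([np.log(c[0] * 1e-2), 1e-3], [np.log(c[-1] * 1e2), 50.0]),
            )
            theta = np.concatenate(([fix_p_max], sol.x))
        else:
            sol = least_squares(
                _residuals,
                x0,
                args=(c, po, w),
                bounds=(
                    [1e-6, np.log(c[0] * 1e-2), 1e-3],
                    [1.0, np.log(c[-1] * 1e2), 50.0],
                ),
            )
            theta = sol.x
        if not sol.success:
            continue
        if best is None or sol.cost < best[0].cost:
            best = (sol, theta)
    if best is None:
        raise FitError("Hill fit failed to converge from all starts")
    sol, theta = best
    p_max, log_k, h = theta
    rss = float(2.0 * sol.cost)

    # curvature standard errors on (p_max, K, h); delta method for K = exp(log_k)
    J = sol.jac
    dof = max(c.size - J.shape[1], 1)
    try:
        cov = np.linalg.inv(J.T @ J) * rss / dof
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        cov = None
        se = np.full(J.shape[1], np.nan)
    if fix_p_max is None:
        se_p, se_logk, se_h = se
    else:
        se_p = 0.0
        se_logk, se_h = se
    return HillFit(
        p_max=float(p_max),
        k_inh_um=float(np.exp(log_k)),
        h_inh=float(h),
        se_p_max=float(se_p),
        se_k_inh=float(np.exp(log_k) * se_logk),
        se_h_inh=float(se_h),
        rss=rss,
        n_points=int(c.size),
        descent_sampled=bool(descent_sampled),
        covariance=cov,
    )
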