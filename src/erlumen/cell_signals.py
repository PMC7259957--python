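"""Single-cell and population Ca2+-imaging analysis.

Fura-2 ratiometric traces (340/380 nm excitation ratio R, one frame every
2 s in the imaging experiments this package models) are normalized to the
mean ratio over the first 30 s (R/R0) and passed through a logic-test
classifier:

- *include* a cell only if every baseline frame lies in [0.75, 1.25] and
  every frame of the final 30 s of washout stays below 1.5 (the cell
  begins and ends at resting Ca2+);
- a *responder* reaches R/R0 >= 2.0 after agonist stimulation;
- a responder is *oscillating* when the coefficient of variation
  (s.d./mean x 100) over the window from the end of the initial Ca2+
  transient to the end of stimulation exceeds 15%;
- oscillating cells are sub-typed as 'periodic oscillation' versus
  'random spiking' by the dominant autocorrelation peak of the analysis
  window (a quantitative stand-in for a by-eye call).

Population responses to agonist are summarised by the maximal rise of the
baseline-subtracted ratio (dR_max) and the time constant tau of a single
exponential fitted to the rising phase, both normalized to control-group
means with unpaired t-tests for group comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import find_peaks
from scipy.stats import ttest_ind

from .errors import FitError, ValidationError

BASELINE_BAND = (0.75, 1.25)
WASHOUT_MAX = 1.5
RESPONDER_MIN = 2.0
CV_PERCENT_THRESHOLD = 15.0
AUTOCORR_PEAK_THRESHOLD = 0.4
POST_PEAK_FALLBACK_S = 20.0  # oscillation window start when no return toward baseline


@dataclass
class CellRatioTrace:
    """One cell's fluorescence-ratio time series with stimulus metadata."""

    time: np.ndarray  # s, uniform
    ratio: np.ndarray  # raw 340/380 ratio, > 0
    stim_start: float  # s
    stim_end: float  # s
    cell_id: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.ratio = np.asarray(self.ratio, dtype=float)
        if self.time.size != self.ratio.size:
            raise ValidationError("time and ratio must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValidationError("time must be strictly increasing")
        if (self.ratio <= 0).any():
            raise ValidationError("ratios must be positive")
        if not (self.time[0] <= self.stim_start < self.stim_end <= self.time[-1]):
            raise ValidationError("stimulus window must lie within the trace")


@dataclass
class ClassifiedCell:
    """Classifier output for one cell."""

    cell_id: str
    normalized: np.ndarray  # R/R0
    included: bool
    responder: bool | None  # None when excluded
    oscillating: bool | None  # defined only for responders
    pattern: str  # 'periodic oscillation' | 'random spiking' | 'none'
    cv_percent: float
    window: tuple[float, float] | None  # oscillation analysis window (s)


@dataclass
class PopulationResponse:
    """Exponential-rise summary of a population Delta-R trace."""

    dr_max: float
    tau_s: float
    se_dr_max: float
    se_tau: float
    t0: float  # rise origin (stimulus time), s


def normalize_ratio(
    trace: CellRatioTrace, baseline_window: float = 30.0
) -> np.ndarray:
    """R/R0: ratio divided by its mean over the first ``baseline_window`` s."""
    mask = trace.time < trace.time[0] + baseline_window
    if mask.sum() < 3:
        raise ValidationError("baseline window must contain at least 3 frames")
    r0 = trace.ratio[mask].mean()
    if r0 <= 0:
        raise ValidationError("baseline mean must be positive")
    return trace.ratio / r0


def cv_percent(values: np.ndarray) -> float:
    """Coefficient of variation, s.d./mean x 100 (sample s.d., ddof=1)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValidationError("need at least 2 values for a CV")
    m = values.mean()
    if m <= 0:
        raise ValidationError("CV undefined for non-positive mean")
    return float(values.std(ddof=1) / m * 100.0)


def _oscillation_window_start(
    time: np.ndarray,
    rr: np.ndarray,
    stim_start: float,
    baseline_mean: float,
) -> float:
    """Start of the oscillation-analysis window: the end of the initial
    Ca2+ transient.

    Defined as the first time after the first post-stimulus peak at which
    R/R0 falls below baseline + 50% of (first-peak - baseline); when the
    trace never returns that far, the window starts 20 s after the peak.
    """
    post = time >= stim_start
    idx_post = np.nonzero(post)[0]
    seg = rr[idx_post]
    peaks, _ = find_peaks(seg, height=RESPONDER_MIN)
    if peaks.size:
        peak_i = idx_post[peaks[0]]
    else:
        peak_i = idx_post[np.argmax(seg)]
    half_return = baseline_mean + 0.5 * (rr[peak_i] - baseline_mean)
    after = np.nonzero((time > time[peak_i]) & (rr < half_return))[0]
    if after.size:
        return float(time[after[0]])
    return float(time[peak_i] + POST_PEAK_FALLBACK_S)


def _dominant_autocorr_peak(x: np.ndarray) -> float:
    """Height of the largest local maximum of the normalized
    autocorrelation at lag > 0; -inf when no interior peak exists."""
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom <= 0:
        return float("-inf")
    acf = np.correlate(x, x, mode="full")[x.size - 1 :] / denom
    peaks, props = find_peaks(acf[1:])
    if peaks.size == 0:
        return float("-inf")
    return float(acf[1:][peaks].max())


def classify_cell(
    trace: CellRatioTrace,
    baseline_window: float = 30.0,
    washout_window: float = 30.0,
    strict_washout: bool = True,
) -> ClassifiedCell:
    """Apply the inclusion / responder / oscillation logic tests.

    ``strict_washout=True`` requires every frame of the final washout
    window below the threshold; ``False`` relaxes the test to the window
    mean.
    """
    rr = normalize_ratio(trace, baseline_window)
    t = trace.time
    base_mask = t < t[0] + baseline_window
    wash_mask = t > t[-1] - washout_window
    if not base_mask.any() or not wash_mask.any():
        raise ValidationError("trace shorter than required analysis windows")
    baseline_ok = bool(
        (rr[base_mask] >= BASELINE_BAND[0]).all()
        and (rr[base_mask] <= BASELINE_BAND[1]).all()
    )
    if strict_washout:
        washout_ok = bool((rr[wash_mask] < WASHOUT_MAX).all())
    else:
        washout_ok = bool(rr[wash_mask].mean() < WASHOUT_MAX)
    included = baseline_ok and washout_ok
    if not included:
        return ClassifiedCell(
            cell_id=trace.cell_id,
            normalized=rr,
            included=False,
            responder=None,
            oscillating=None,
            pattern="none",
            cv_percent=float("nan"),
            window=None,
        )

    post_mask = t >= trace.stim_start
    responder = bool(rr[post_mask].max() >= RESPONDER_MIN)
    if not responder:
        return ClassifiedCell(
            cell_id=trace.cell_id,
            normalized=rr,
            included=True,
            responder=False,
            oscillating=None,
            pattern="none",
            cv_percent=float("nan"),
            window=None,
        )

    start = _oscillation_window_start(t, rr, trace.stim_start, rr[base_mask].mean())
    start = min(start, trace.stim_end)  # keep a valid, possibly tiny, window
    win_mask = (t >= start) & (t <= trace.stim_end)
    if win_mask.sum() >= 2:
        cv = cv_percent(rr[win_mask])
    else:
        cv = 0.0
    oscillating = bool(cv > CV_PERCENT_THRESHOLD)
    if oscillating:
        peak = _dominant_autocorr_peak(rr[win_mask])
        pattern = (
            "periodic oscillation"
            if peak > AUTOCORR_PEAK_THRESHOLD
            else "random spiking"
        )
    else:
        pattern = "none"
    return ClassifiedCell(
        cell_id=trace.cell_id,
        normalized=rr,
        included=True,
        responder=True,
        oscillating=oscillating,
        pattern=pattern,
        cv_percent=cv,
        window=(float(start), float(trace.stim_end)),
    )


def classify_cells(traces: list[CellRatioTrace], **kwargs) -> pd.DataFrame:
    """Classify a collection of cells; one summary row per cell."""
    rows = []
    for tr in traces:
        c = classify_cell(tr, **kwargs)
        rows.append(
            {
                "cell_id": c.cell_id,
                "included": c.included,
                "responder": c.responder,
                "oscillating": c.oscillating,
                "pattern": c.pattern,
                "cv_percent": c.cv_percent,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# population response


def population_delta_r(
    time: np.ndarray,
    ratio: np.ndarray,
    stim_time: float,
    baseline_window: float = 90.0,
) -> np.ndarray:
    """Delta-R: population ratio minus its mean over the pre-agonist
    baseline (default the 90 s of stable baseline before stimulation)."""
    time = np.asarray(time, dtype=float)
    ratio = np.asarray(ratio, dtype=float)
    base = (time < stim_time) & (time >= stim_time - baseline_window)
    if base.sum() < 3:
        raise ValidationError("need at least 3 pre-stimulus baseline frames")
    return ratio - ratio[base].mean()


def fit_rise(
    time: np.ndarray, delta_r: np.ndarray, stim_time: float
) -> PopulationResponse:
    """Single-exponential fit to the rising phase of a Delta-R trace.

    Fits ``dR(t) = dR_max * (1 - exp(-(t - t0) / tau))`` with ``t0`` fixed
    at the stimulus time, over the samples from stimulus to the first
    maximum.  By construction the fitted curve reaches (1 - 1/e) * dR_max
    at ``t0 + tau``.
    """
    time = np.asarray(time, dtype=float)
    delta_r = np.asarray(delta_r, dtype=float)
    post = np.nonzero(time >= stim_time)[0]
    if post.size < 3:
        raise ValidationError("too few post-stimulus samples")
    seg = delta_r[post]
    peak_rel = int(np.argmax(seg))
    if peak_rel < 2 or seg[peak_rel] <= 0:
        raise FitError("no rise after stimulus")
    rise_idx = post[: peak_rel + 1]
    t_rise = time[rise_idx]
    y_rise = delta_r[rise_idx]

    def model(t, dr_max, tau):
        return dr_max * (1.0 - np.exp(-(t - stim_time) / tau))

    dr0 = float(seg[peak_rel])
    tau0 = max((t_rise[-1] - stim_time) / 3.0, 1e-3)
    try:
        popt, pcov = curve_fit(
            model,
            t_rise,
            y_rise,
            p0=[dr0, tau0],
            bounds=([0.0, 1e-6], [np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - scipy failure path
        raise FitError(f"exponential rise fit failed: {exc}") from exc
    se = np.sqrt(np.diag(pcov))
    return PopulationResponse(
        dr_max=float(popt[0]),
        tau_s=float(popt[1]),
        se_dr_max=float(se[0]),
        se_tau=float(se[1]),
        t0=float(stim_time),
    )


def normalize_to_control(
    groups: dict[str, np.ndarray], control: str
) -> pd.DataFrame:
    """Normalize each group's values by the control-group mean.

    Returns one row per group with normalized mean, s.e.m. and the
    unpaired two-sample t-test p-value against the control group.
    """
    if control not in groups:
        raise ValidationError(f"control group {control!r} not present")
    ctrl = np.asarray(groups[control], dtype=float)
    if ctrl.size == 0:
        raise ValidationError("control group is empty")
    cmean = ctrl.mean()
    if cmean <= 0:
        raise ValidationError("control mean must be positive")
    rows = []
    for name, values in groups.items():
        x = np.asarray(values, dtype=float)
        if x.size == 0:
            raise ValidationError(f"group {name!r} is empty")
        norm = x / cmean
        if name == control:
            t_stat, p_val = float("nan"), float("nan")
        else:
            t_stat, p_val = ttest_ind(x, ctrl, equal_var=True)
        rows.append(
            {
                "group": name,
                "n": x.size,
                "normalized_mean": norm.mean(),
                "normalized_sem": (
                    norm.std(ddof=1) / np.sqrt(x.size) if x.size > 1 else float("nan")
                ),
                "t_statistic": float(t_stat),
                "p_value": float(p_val),
            }
        )
    return pd.DataFrame(rows)
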