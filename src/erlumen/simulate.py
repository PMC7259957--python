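"""Seeded synthetic-data generators for every analysis stage.

Each generator draws from exactly the statistical structure its matching
analysis assumes — the spike-and-slab Poisson count model, two-state
Markov channel gating (optionally with the luminal-Ca2+ Hill inhibition
link), and archetypal Fura-2 ratio traces — and returns its ground truth
alongside the data.  All generators are bit-reproducible from
(config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from . import counts as counts_model
from .cell_signals import CellRatioTrace
from .counts import CountTable
from .dose_response import PoDataset, hill_po
from .errors import ValidationError
from .gating import CurrentTrace

# Gaussian low-pass: -3 dB at f_c requires sigma_t = sqrt(ln 2) / (2 pi f_c)
GAUSSIAN_SIGMA_COEFF = float(np.sqrt(np.log(2.0)) / (2.0 * np.pi))

# uninhibited Hill-inhibition defaults (plateau open probability, half-
# maximal inhibitory luminal Ca2+ in uM, Hill coefficient)
DEFAULT_P_MAX = 0.65
DEFAULT_K_INH_UM = 260.0
DEFAULT_H_INH = 2.3


# ---------------------------------------------------------------------------
# spectral counts


@dataclass
class CountSimConfig:
    """Generator settings for bait-vs-control spectral-count tables.

    The study-scale preset is 486 proteins x 3 blocks.  Effect and
    nuisance magnitudes (pi0 = 0.95, tau = 1, sigma_c = 0.6, block scales
    lognormal around 3) are the package's own choices of a sparse-positive
    enrichment regime; the count layout (p, C, both conditions) is fixed
    by the experimental design being emulated.
    """

    p: int = 486
    n_blocks: int = 3
    pi0: float = 0.95
    tau: float = 1.0
    sigma: float | np.ndarray = 0.6
    mu: np.ndarray | None = None  # per-block scale; lognormal(log 3, 0.3) if None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p < 2 or self.n_blocks < 1:
            raise ValidationError("need p >= 2 and at least one block")
        if not (0.0 <= self.pi0 <= 1.0):
            raise ValidationError("pi0 must lie in [0, 1]")
        if self.tau < 0:
            raise ValidationError("tau must be >= 0")
        sig = np.broadcast_to(np.asarray(self.sigma, dtype=float), (self.n_blocks,))
        if (sig <= 0).any():
            raise ValidationError("sigma must be positive")
        self.sigma = np.array(sig)
        if self.mu is not None:
            self.mu = np.asarray(self.mu, dtype=float)
            if self.mu.shape != (self.n_blocks,) or (self.mu <= 0).any():
                raise ValidationError("mu must be positive, one per block")


def paper_scale_counts() -> CountSimConfig:
    """The study-scale preset: 486 proteins, 3 blocks, sparse positives."""
    return CountSimConfig()


def simulate_counts(
    config: CountSimConfig, shifted: bool = False, seed: int | None = None
) -> tuple[CountTable, dict]:
    """Draw a count table from the generative model.

    With ``shifted=True`` the emitted counts are ``u ~ Poisson(lambda)``
    — the shifted scale on which the model's likelihood lives — so a fit
    with ``pseudo_count=0`` sees exactly the generative model (required
    for calibration studies).  Otherwise the raw-count emulation
    ``y = max(Poisson(lambda) - 1, 0)`` is emitted and the default
    ``pseudo_count=1`` fit applies.  Returns (table, truth) where truth
    records z, beta, alpha, mu and the rate array.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    p, C = config.p, config.n_blocks
    mu = (
        config.mu
        if config.mu is not None
        else np.exp(rng.normal(np.log(3.0), 0.3, size=C))
    )
    z = (rng.random(p) >= config.pi0).astype(np.int64)
    beta = np.where(z == 1, rng.normal(0.0, config.tau, size=p), 0.0)
    alpha = rng.normal(0.0, config.sigma[None, :], size=(p, C))
    t = np.array([0.0, 1.0])
    # identical log-rate clamp as the fitted likelihood, so the shifted-
    # scale generative model is exactly the model being fitted
    log_lam = (
        np.log(mu)[None, :, None]
        + alpha[:, :, None]
        + t[None, None, :] * beta[:, None, None]
    )
    lam = np.exp(np.clip(log_lam, -counts_model.LOG_RATE_CLAMP, counts_model.LOG_RATE_CLAMP))
    u = rng.poisson(lam)
    y = u if shifted else np.maximum(u - 1, 0)
    proteins = [f"P{i:04d}" for i in range(p)]
    blocks = [f"block{c + 1}" for c in range(C)]
    table = CountTable(proteins=proteins, blocks=blocks, y=y)
    truth = {
        "z": z,
        "beta": beta,
        "alpha": alpha,
        "mu": mu,
        "lambda": lam,
        "shifted": shifted,
    }
    return table, truth


# ---------------------------------------------------------------------------
# channel gating


@dataclass
class GatingSimConfig:
    """Two-state Markov channel generator settings.

    Defaults give the uninhibited channel: open probability 0.65 with a
    10 ms mean open time (so closing rate 100 /s, opening rate
    0.65/0.35 x 100 /s).  Setting ``ca_er_um`` rescales the opening rate
    so that the stationary open probability follows the inhibitory Hill
    curve at that luminal Ca2+ concentration.
    """

    n_channels: int = 1
    k_open: float = DEFAULT_P_MAX / (1.0 - DEFAULT_P_MAX) * 100.0  # /s, closed->open
    k_close: float = 100.0  # /s, open->closed (mean open time 10 ms)
    closed_level_pa: float = 0.0
    open_increment_pa: float = 2.0
    noise_sd_pa: float = 0.2
    sampling_rate: float = 5000.0  # Hz
    filter_cutoff: float = 1000.0  # Hz
    duration_s: float = 10.0
    ca_er_um: float | None = None  # Hill-inhibition link
    hill: tuple[float, float, float] = (DEFAULT_P_MAX, DEFAULT_K_INH_UM, DEFAULT_H_INH)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_open <= 0 or self.k_close <= 0:
            raise ValidationError("rates must be positive")
        if self.duration_s < 1.0:
            raise ValidationError("duration must be >= 1 s")
        if self.ca_er_um is not None:
            po = hill_po(self.ca_er_um, *self.hill)
            po = min(max(po, 1e-9), 1.0 - 1e-9)
            self.k_open = self.k_close * po / (1.0 - po)

    @property
    def p_open(self) -> float:
        return self.k_open / (self.k_open + self.k_close)


def _channel_path(
    rng: np.random.Generator, cfg: GatingSimConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Exact alternating-exponential sojourn path for one channel.

    Returns (event end times, event states 0/1) covering [0, duration],
    starting from the stationary state distribution.
    """
    T = cfg.duration_s
    state0 = int(rng.random() < cfg.p_open)
    rate = {0: cfg.k_open, 1: cfg.k_close}
    states = []
    ends = []
    t = 0.0
    s = state0
    mean_cycle = 1.0 / cfg.k_open + 1.0 / cfg.k_close
    batch = max(int(2.2 * T / mean_cycle) + 16, 32)
    while t < T:
        # draw sojourns in batches; alternate states deterministically
        d0 = rng.exponential(1.0 / rate[s], size=batch)
        d1 = rng.exponential(1.0 / rate[1 - s], size=batch)
        durs = np.empty(2 * batch)
        durs[0::2] = d0
        durs[1::2] = d1
        for d in durs:
            t += d
            states.append(s)
            ends.append(min(t, T))
            s = 1 - s
            if t >= T:
                break
    return np.asarray(ends), np.asarray(states, dtype=int)


def _path_open_time(ends: np.ndarray, states: np.ndarray) -> float:
    starts = np.concatenate(([0.0], ends[:-1]))
    return float(np.sum((ends - starts)[states == 1]))


def simulate_path_po(cfg: GatingSimConfig, seed: int | None = None) -> float:
    """Exact open-time fraction of one simulated channel path (no
    discretization, noise or filtering) — the per-trace open probability
    a perfect idealizer would measure."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    total_open = 0.0
    for _ in range(cfg.n_channels):
        ends, states = _channel_path(rng, cfg)
        total_open += _path_open_time(ends, states)
    return total_open / (cfg.n_channels * cfg.duration_s)


def simulate_trace(
    cfg: GatingSimConfig, seed: int | None = None
) -> tuple[CurrentTrace, np.ndarray]:
    """Simulate a noisy, filtered multi-channel current trace.

    N independent two-state chains are sampled exactly (exponential
    sojourns), discretized to the sampling grid, summed, scaled to
    current, Gaussian noise added, and low-pass filtered with a Gaussian
    FIR whose -3 dB point sits at the anti-aliasing cutoff.  Returns the
    trace and the true per-sample occupancy path.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n_samples = int(round(cfg.duration_s * cfg.sampling_rate))
    t_grid = (np.arange(n_samples) + 0.5) / cfg.sampling_rate
    level = np.zeros(n_samples, dtype=int)
    for _ in range(cfg.n_channels):
        ends, states = _channel_path(rng, cfg)
        idx = np.searchsorted(ends, t_grid, side="left")
        idx = np.minimum(idx, states.size - 1)
        level += states[idx]
    current = (
        cfg.closed_level_pa
        + level * cfg.open_increment_pa
        + rng.normal(0.0, cfg.noise_sd_pa, size=n_samples)
    )
    if cfg.filter_cutoff > 0 and cfg.noise_sd_pa > 0:
        sigma_samples = GAUSSIAN_SIGMA_COEFF / cfg.filter_cutoff * cfg.sampling_rate
        current = gaussian_filter1d(current, sigma_samples)
    trace = CurrentTrace(
        samples=current,
        sampling_rate=cfg.sampling_rate,
        filter_cutoff=cfg.filter_cutoff,
        closed_level=cfg.closed_level_pa,
        open_increment=cfg.open_increment_pa,
    )
    return trace, level


def simulate_po_dataset(
    concentrations_um: np.ndarray | None = None,
    n_traces: int = 10,
    trace_duration_s: float = 30.0,
    hill: tuple[float, float, float] = (
        DEFAULT_P_MAX,
        DEFAULT_K_INH_UM,
        DEFAULT_H_INH,
    ),
    seed: int = 0,
) -> tuple[PoDataset, dict]:
    """Mean open probability vs luminal Ca2+ from simulated gating.

    Defaults follow the dose-response sampling design this package uses
    throughout: 8 log-spaced concentrations from 0.07 to 600 uM spanning
    the plateau and the descending limb, n = 10 single-channel traces of
    30 s per concentration.  Per-trace open probabilities are the exact
    open-time fractions of simulated channel paths whose stationary open
    probability follows the Hill curve, so the only scatter is genuine
    gating (sampling) noise.  Returns (dataset, truth).
    """
    if concentrations_um is None:
        concentrations_um = np.logspace(np.log10(0.07), np.log10(600.0), 8)
    concentrations_um = np.asarray(concentrations_um, dtype=float)
    rng = np.random.default_rng(seed)
    means, sems, true_po = [], [], []
    for c in concentrations_um:
        cfg = GatingSimConfig(
            duration_s=trace_duration_s, ca_er_um=float(c), hill=hill
        )
        po_i = np.array(
            [
                simulate_path_po(cfg, seed=int(rng.integers(2**31 - 1)))
                for _ in range(n_traces)
            ]
        )
        means.append(po_i.mean())
        sems.append(po_i.std(ddof=1) / np.sqrt(n_traces))
        true_po.append(hill_po(float(c), *hill))
    dataset = PoDataset(
        ca_er_um=concentrations_um,
        mean_po=np.array(means),
        sem=np.array(sems),
        n=np.full(concentrations_um.size, n_traces),
    )
    truth = {"hill": hill, "true_po": np.array(true_po)}
    return dataset, truth


# ---------------------------------------------------------------------------
# single-cell Ca2+ traces


@dataclass
class CellSimConfig:
    """Archetypal Fura-2 trace generator settings.

    Frames every 2 s; default layout 30 s baseline, stimulation to 390 s,
    washout to 480 s.  ``fractions`` orders the archetypes
    (non-responder, smooth responder, periodic oscillator, random
    spiker) and must sum to 1.
    """

    n_cells: int = 40
    frame_interval_s: float = 2.0
    duration_s: float = 480.0
    stim_start_s: float = 30.0
    stim_end_s: float = 390.0
    baseline_noise_cv: float = 0.03
    fractions: tuple[float, float, float, float] = (0.3, 0.3, 0.2, 0.2)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_interval_s <= 0:
            raise ValidationError("frame interval must be positive")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValidationError("archetype fractions must sum to 1")


ARCHETYPES = ("non_responder", "smooth_responder", "periodic", "random_spiking")


def _archetype_profile(
    kind: str,
    t: np.ndarray,
    cfg: CellSimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Noise-free normalized (R/R0 scale) response profile for one cell."""
    rr = np.ones_like(t)
    t0, t1 = cfg.stim_start_s, cfg.stim_end_s
    stim = (t >= t0) & (t <= t1)
    ts = t[stim] - t0
    if kind == "non_responder":
        return rr
    if kind == "smooth_responder":
        # fast transient to ~3 settling on a modest plateau, washout decay
        transient = 2.0 * (1.0 - np.exp(-ts / 3.0)) * np.exp(-ts / 25.0)
        plateau = 0.3 * (1.0 - np.exp(-ts / 25.0))
        rr[stim] += transient + plateau
        wash = t > t1
        rr[wash] += 0.3 * np.exp(-(t[wash] - t1) / 20.0)
        return rr
    if kind == "periodic":
        transient = 2.2 * (1.0 - np.exp(-ts / 3.0)) * np.exp(-ts / 15.0)
        period = rng.uniform(36.0, 44.0)
        envelope = 1.0 - np.exp(-ts / 20.0)
        osc = 0.1 + 0.65 * (1.0 + np.sin(2.0 * np.pi * ts / period))
        rr[stim] += transient + envelope * osc
        wash = t > t1
        rr[wash] += 0.25 * np.exp(-(t[wash] - t1) / 15.0)
        return rr
    if kind == "random_spiking":
        transient = 2.2 * (1.0 - np.exp(-ts / 3.0)) * np.exp(-ts / 15.0)
        rr[stim] += transient
        # irregular spike train: heavy-tailed gaps defeat pseudo-periodicity
        spike_t = []
        tt = 20.0 + rng.lognormal(np.log(25.0), 0.8)
        while tt < (t1 - t0) - 5.0:
            spike_t.append(tt)
            tt += 6.0 + rng.lognormal(np.log(30.0), 0.8)
        for st in spike_t:
            amp = rng.uniform(1.0, 2.0)
            width = rng.uniform(1.5, 4.0)
            rr[stim] += amp * np.exp(-0.5 * ((ts - st) / width) ** 2)
        wash = t > t1
        rr[wash] += 0.1 * np.exp(-(t[wash] - t1) / 10.0)
        return rr
    raise ValidationError(f"unknown archetype {kind!r}")


def simulate_cells(
    config: CellSimConfig, seed: int | None = None
) -> tuple[list[CellRatioTrace], pd.DataFrame]:
    """Generate raw-ratio traces with known archetype labels.

    Each cell's profile is multiplied by a random per-cell gain (raw
    340/380 ratios differ between cells) and multiplicative baseline
    noise, so the classifier's scale invariance is actually exercised.
    Returns (traces, truth) with one truth row per cell.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_frames = int(round(config.duration_s / config.frame_interval_s)) + 1
    t = np.arange(n_frames) * config.frame_interval_s
    counts = np.floor(np.asarray(config.fractions) * config.n_cells).astype(int)
    # hand out remaining cells to the first archetypes
    while counts.sum() < config.n_cells:
        counts[int(np.argmax(np.asarray(config.fractions) * config.n_cells - counts))] += 1
    labels = [k for k, n in zip(ARCHETYPES, counts) for _ in range(n)]
    traces = []
    rows = []
    for i, kind in enumerate(labels):
        profile = _archetype_profile(kind, t, config, rng)
        gain = rng.uniform(0.8, 1.6)
        noise = 1.0 + rng.normal(0.0, config.baseline_noise_cv, size=n_frames)
        ratio = np.maximum(gain * profile * noise, 1e-3)
        traces.append(
            CellRatioTrace(
                time=t,
                ratio=ratio,
                stim_start=config.stim_start_s,
                stim_end=config.stim_end_s,
                cell_id=f"cell{i:03d}",
            )
        )
        rows.append({"cell_id": f"cell{i:03d}", "archetype": kind, "gain": gain})
    return traces, pd.DataFrame(rows)
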