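"""Hierarchical spike-and-slab Poisson model for bait-vs-control spectral counts.

Affinity-enrichment mass spectrometry compares spectral counts of each
protein eluted from bait-peptide beads (condition ``t = 1``) against beads
carrying a scrambled control peptide (``t = 0``), with biological blocks
(animals) providing replication.  Counts are modelled with a Poisson
log-linear likelihood,

    y_gct + 1 ~ Poisson(lambda_gct),
    log lambda_gct = log mu_c + alpha_gc + t * beta_g,

where ``mu_c`` is a fixed per-block plug-in scale, ``alpha_gc`` a
protein-by-block random effect (``alpha_gc ~ N(0, sigma_c^2)``) absorbing
between-block variation and over-dispersion, and ``beta_g`` the treatment
(enrichment) effect carrying a spike-and-slab prior

    beta_g ~ pi0 * delta_0 + (1 - pi0) * N(0, tau^2),
    pi0 ~ Beta(0.5, 0.5),   sigma_c^-2, tau^-2 ~ Gamma(1, 1).

The pseudo-count of 1 keeps the log-link away from log(0) and biases the
analysis conservatively (shrinking ratios toward 1).  Inference targets the
local false sign rate lfsr_g = P(beta_g <= 0 | Y): the posterior probability
that protein g is *not* preferentially bound by the bait.  Proteins with
lfsr at or below a threshold (default 0.2) are selected, and the mean lfsr
of the selected set estimates the global false sign rate of the selection.

Posterior sampling is Metropolis-within-Gibbs: exact conjugate draws for
(pi0, tau^2, sigma_c^2), exact gridded Gibbs for (z_g, beta_g) via 1-D
quadrature of the slab marginal, and adaptive random-walk Metropolis for
alpha_gc (step adapted during burn-in only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln, logsumexp

from .errors import NumericalError, ValidationError

# log-rates are clamped to this interval before exponentiation
LOG_RATE_CLAMP = 30.0

REQUIRED_COLUMNS = ("protein_id", "block_id", "condition", "count")


def _clamp_exp(log_rate: np.ndarray) -> np.ndarray:
    return np.exp(np.clip(log_rate, -LOG_RATE_CLAMP, LOG_RATE_CLAMP))


@dataclass
class CountTable:
    """Complete bait-vs-control spectral-count design.

    ``y`` has shape ``(p, C, 2)`` — proteins x blocks x condition
    (0 = scrambled control, 1 = bait).
    """

    proteins: list[str]
    blocks: list[str]
    y: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        p, c = len(self.proteins), len(self.blocks)
        if self.y.shape != (p, c, 2):
            raise ValidationError(
                f"count array shape {self.y.shape} does not match "
                f"{p} proteins x {c} blocks x 2 conditions"
            )
        if p < 2:
            raise ValidationError("need at least 2 proteins")
        if c < 1:
            raise ValidationError("need at least 1 block")
        if not np.issubdtype(self.y.dtype, np.integer):
            if not np.allclose(self.y, np.round(self.y)):
                raise ValidationError("counts must be integers")
            self.y = np.round(self.y).astype(np.int64)
        if (self.y < 0).any():
            raise ValidationError("counts must be non-negative")

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, impute_missing: bool = False
    ) -> "CountTable":
        """Build from a long-format frame with columns
        ``protein_id, block_id, condition, count``.

        The design must be complete — one count per (protein, block,
        condition) cell — unless ``impute_missing`` is set, in which case
        absent cells are filled with 0 (match-between-runs-style leniency).
        """
        missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing_cols:
            raise ValidationError(f"missing required columns: {missing_cols}")
        dup = df.duplicated(subset=["protein_id", "block_id", "condition"])
        if dup.any():
            cells = df.loc[dup, ["protein_id", "block_id", "condition"]]
            raise ValidationError(
                "duplicate cells: "
                + "; ".join(
                    f"({r.protein_id}, {r.block_id}, {r.condition})"
                    for r in cells.itertuples()
                )
            )
        conditions = sorted(df["condition"].unique())
        if conditions != [0, 1]:
            raise ValidationError(
                f"conditions must be exactly {{0, 1}}, got {conditions}"
            )
        proteins = sorted(df["protein_id"].astype(str).unique())
        blocks = sorted(df["block_id"].astype(str).unique())
        pivot = df.set_index(
            [df["protein_id"].astype(str), df["block_id"].astype(str), "condition"]
        )["count"]
        full = pd.MultiIndex.from_product(
            [proteins, blocks, [0, 1]], names=["protein_id", "block_id", "condition"]
        )
        aligned = pivot.reindex(full)
        if aligned.isna().any():
            if impute_missing:
                aligned = aligned.fillna(0)
            else:
                miss = aligned[aligned.isna()].index[:5].tolist()
                raise ValidationError(
                    f"missing (protein, block, condition) cells, e.g. {miss}; "
                    "pass impute_missing=True to fill with 0"
                )
        y = aligned.to_numpy().reshape(len(proteins), len(blocks), 2)
        return cls(proteins=proteins, blocks=blocks, y=y)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for gi, g in enumerate(self.proteins):
            for ci, c in enumerate(self.blocks):
                for t in (0, 1):
                    rows.append((g, c, t, int(self.y[gi, ci, t])))
        return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))


@dataclass
class ModelSpec:
    """Hyperparameters of the count model.

    ``pseudo_count`` is applied on the likelihood side only (the stored
    table is never shifted): the model evaluates the Poisson mass of
    ``y + pseudo_count`` at rate lambda.  Calibration data generated on
    the shifted scale should be fitted with ``pseudo_count = 0``.
    """

    pseudo_count: int = 1
    prior_pi0: tuple[float, float] = (0.5, 0.5)
    prior_precision: tuple[float, float] = (1.0, 1.0)  # Gamma(shape, rate)
    mu: np.ndarray | None = None  # per-block plug-in scale; computed if None

    def __post_init__(self) -> None:
        if self.pseudo_count < 0:
            raise ValidationError("pseudo_count must be >= 0")
        if min(self.prior_pi0) <= 0 or min(self.prior_precision) <= 0:
            raise ValidationError("hyperparameters must be strictly positive")
        if self.mu is not None:
            self.mu = np.asarray(self.mu, dtype=float)
            if (self.mu <= 0).any():
                raise ValidationError("mu must be strictly positive per block")


@dataclass
class ModelState:
    """One full set of model unknowns (mu is a fixed plug-in, not state)."""

    beta: np.ndarray  # (p,)
    z: np.ndarray  # (p,) 0/1
    alpha: np.ndarray  # (p, C)
    sigma2: np.ndarray  # (C,)
    tau2: float
    pi0: float

    def validate(self) -> None:
        if not np.all(self.beta[self.z == 0] == 0.0):
            raise ValidationError("z_g = 0 requires beta_g = 0 exactly")
        if (self.sigma2 <= 0).any() or self.tau2 <= 0:
            raise ValidationError("variances must be positive")
        if not (0.0 <= self.pi0 <= 1.0):
            raise ValidationError("pi0 must lie in [0, 1]")


@dataclass
class PosteriorDraws:
    """Post burn-in, thinned MCMC draws plus chain metadata."""

    proteins: list[str]
    blocks: list[str]
    beta: np.ndarray  # (n_draws, p)
    z: np.ndarray  # (n_draws, p)
    alpha: np.ndarray | None  # (n_draws, p, C) or None
    sigma2: np.ndarray  # (n_draws, C)
    tau2: np.ndarray  # (n_draws,)
    pi0: np.ndarray  # (n_draws,)
    seed: int
    n_iter: int
    burn_in: int
    thin: int
    alpha_acceptance: float
    n_clamped: int = 0

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]


@dataclass
class EnrichmentResult:
    """Per-protein lfsr, posterior summaries and the selected set."""

    table: pd.DataFrame  # protein_id, post_mean_beta, post_prob_slab, lfsr, selected
    threshold: float
    global_false_sign_rate: float  # mean lfsr over selected; nan if none selected

    @property
    def selected(self) -> list[str]:
        return self.table.loc[self.table["selected"], "protein_id"].tolist()


# ---------------------------------------------------------------------------
# plug-in scale and likelihood


def compute_mu_plugin(table: CountTable) -> np.ndarray:
    """Fixed per-block scale: mu_c = p^-1 sum_g (y_gc0 + y_gc1 + 2) / 2.

    The +2 matches the pseudo-count of 1 applied to each of the two
    conditions; with all counts zero mu_c = 1 exactly.
    """
    return ((table.y[:, :, 0] + table.y[:, :, 1] + 2) / 2.0).mean(axis=0)


def _rates(state: ModelState, mu: np.ndarray) -> np.ndarray:
    """lambda_gct = mu_c * exp(alpha_gc + t * beta_g), shape (p, C, 2)."""
    log_rate = (
        np.log(mu)[None, :, None]
        + state.alpha[:, :, None]
        + np.array([0.0, 1.0])[None, None, :] * state.beta[:, None, None]
    )
    return _clamp_exp(log_rate)


def log_likelihood(state: ModelState, table: CountTable, spec: ModelSpec) -> float:
    """Total Poisson log-mass of the shifted counts at the model rates."""
    mu = spec.mu if spec.mu is not None else compute_mu_plugin(table)
    lam = _rates(state, mu)
    if not np.all(np.isfinite(lam)):
        bad = np.argwhere(~np.isfinite(lam))[0]
        raise NumericalError(
            f"non-finite rate at (protein={table.proteins[bad[0]]}, "
            f"block={table.blocks[bad[1]]}, condition={bad[2]})"
        )
    s = table.y + spec.pseudo_count
    ll = float(np.sum(s * np.log(lam) - lam - gammaln(s + 1)))
    if not np.isfinite(ll):
        raise NumericalError("non-finite log-likelihood")
    return ll


# ---------------------------------------------------------------------------
# Gibbs updates


def gibbs_update_conjugates(
    state: ModelState, table: CountTable, spec: ModelSpec, rng: np.random.Generator
) -> ModelState:
    """Exact conjugate draws for pi0, tau^2 and sigma_c^2 (in place).

    pi0 | z       ~ Beta(a0 + #{z=0}, b0 + #{z=1})
    tau^-2 | beta ~ Gamma(shape + n_slab/2, rate + sum_slab beta^2 / 2)
    sigma_c^-2    ~ Gamma(shape + p/2,      rate + sum_g alpha_gc^2 / 2)
    """
    a0, b0 = spec.prior_pi0
    shape, rate = spec.prior_precision
    n_slab = int(state.z.sum())
    p = state.z.size
    state.pi0 = float(rng.beta(a0 + (p - n_slab), b0 + n_slab))
    ss_beta = float(np.sum(state.beta[state.z == 1] ** 2))
    prec_tau = rng.gamma(shape + n_slab / 2.0, 1.0 / (rate + ss_beta / 2.0))
    state.tau2 = float(1.0 / prec_tau)
    ss_alpha = np.sum(state.alpha**2, axis=0)  # (C,)
    prec_sig = rng.gamma(shape + p / 2.0, 1.0 / (rate + ss_alpha / 2.0))
    state.sigma2 = 1.0 / prec_sig
    return state


def _beta_grid(
    b: np.ndarray, c: np.ndarray, tau2: float, n_nodes: int
) -> np.ndarray:
    """Per-protein quadrature grids for the beta conditional.

    The (unnormalized) conditional log-density in beta is
    ``b * beta - c * exp(beta) - beta^2 / (2 tau^2)``; its likelihood mode
    is ``log(b / c)``.  Each grid spans the union of 0 and the mode padded
    by ``8 * max(sqrt(tau2), 1)``, so both the spike neighbourhood and the
    data-supported region are bracketed.
    """
    span = 8.0 * max(np.sqrt(tau2), 1.0)
    mode = np.log(np.maximum(b, 1e-12) / np.maximum(c, 1e-300))
    lo = np.minimum(0.0, mode) - span
    hi = np.maximum(0.0, mode) + span
    frac = np.linspace(0.0, 1.0, n_nodes)
    return lo[:, None] + (hi - lo)[:, None] * frac[None, :]


def slab_log_marginal_and_posterior(
    b: np.ndarray,
    c: np.ndarray,
    tau2: float,
    n_nodes: int = 400,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gridded slab marginal for each protein.

    For protein g the treated cells contribute, up to a beta-free constant,
    ``f_g(beta) = b_g * beta - c_g * exp(beta)`` with ``b_g = sum_c s_gc1``
    (shifted treated counts) and ``c_g = sum_c mu_c exp(alpha_gc)``.
    Returns ``(log_m1, grid, log_post)`` where ``log_m1`` approximates
    ``log int exp(f_g(beta)) N(beta; 0, tau^2) dbeta`` by the trapezoid
    rule and ``log_post`` is the unnormalized log-density on the grid.
    The spike mass on the same constant scale is ``f_g(0) = -c_g``.
    """
    grid = _beta_grid(b, c, tau2, n_nodes)
    log_post = (
        b[:, None] * grid
        - c[:, None] * np.exp(np.clip(grid, -LOG_RATE_CLAMP, LOG_RATE_CLAMP))
        - grid**2 / (2.0 * tau2)
    )
    dbeta = grid[:, 1] - grid[:, 0]
    # trapezoid weights: half weight at the end nodes
    w = np.full(grid.shape[1], 1.0)
    w[0] = w[-1] = 0.5
    log_m1 = (
        logsumexp(log_post + np.log(w)[None, :], axis=1)
        + np.log(dbeta)
        - 0.5 * np.log(2.0 * np.pi * tau2)
    )
    return log_m1, grid, log_post


def slab_inclusion_probability(
    b: np.ndarray, c: np.ndarray, tau2: float, pi0: float, n_nodes: int = 400
) -> np.ndarray:
    """P(z_g = 1 | rest) from the gridded marginal (vectorized over g)."""
    log_m1, _, _ = slab_log_marginal_and_posterior(b, c, tau2, n_nodes)
    log_m0 = -c  # f_g(0)
    with np.errstate(divide="ignore"):
        logit = (np.log1p(-pi0) + log_m1) - (np.log(pi0) + log_m0)
    return expit(logit)


def _treated_sufficient_stats(
    state: ModelState, table: CountTable, spec: ModelSpec, mu: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    s1 = table.y[:, :, 1] + spec.pseudo_count  # (p, C)
    b = s1.sum(axis=1).astype(float)
    c = np.sum(mu[None, :] * _clamp_exp(state.alpha), axis=1)
    return b, c


def update_beta_and_z(
    state: ModelState,
    table: CountTable,
    spec: ModelSpec,
    rng: np.random.Generator,
    n_nodes: int = 400,
) -> ModelState:
    """Exact gridded Gibbs draw of (z_g, beta_g) for every protein.

    z_g is drawn from its exact conditional using the quadrature slab
    marginal; given z_g = 1, beta_g is drawn from the gridded conditional
    by inverse-CDF (with uniform jitter within the sampled cell); given
    z_g = 0, beta_g = 0 exactly.
    """
    mu = spec.mu if spec.mu is not None else compute_mu_plugin(table)
    b, c = _treated_sufficient_stats(state, table, spec, mu)
    log_m1, grid, log_post = slab_log_marginal_and_posterior(
        b, c, state.tau2, n_nodes
    )
    log_m0 = -c
    with np.errstate(divide="ignore"):
        logit = (np.log1p(-state.pi0) + log_m1) - (np.log(state.pi0) + log_m0)
    p1 = expit(logit)
    z = (rng.random(p1.size) < p1).astype(np.int8)

    # inverse-CDF sampling on the grid for the slab proteins
    w = np.exp(log_post - log_post.max(axis=1, keepdims=True))
    cdf = np.cumsum(w, axis=1)
    u = rng.random(p1.size) * cdf[:, -1]
    idx = np.minimum(
        (cdf < u[:, None]).sum(axis=1), grid.shape[1] - 1
    )
    dbeta = grid[:, 1] - grid[:, 0]
    jitter = (rng.random(p1.size) - 0.5) * dbeta
    beta_slab = grid[np.arange(p1.size), idx] + jitter

    state.z = z.astype(np.int64)
    state.beta = np.where(z == 1, beta_slab, 0.0)
    return state


def update_alpha(
    state: ModelState,
    table: CountTable,
    spec: ModelSpec,
    rng: np.random.Generator,
    step: np.ndarray,
) -> tuple[ModelState, np.ndarray]:
    """One random-walk Metropolis sweep over all alpha_gc (vectorized).

    The exact conditional for alpha_gc is proportional to
    ``exp(d_gc * alpha - e_gc * exp(alpha) - alpha^2 / (2 sigma_c^2))``
    with ``d_gc = s_gc0 + s_gc1`` (shifted counts over both conditions)
    and ``e_gc = mu_c * (1 + exp(beta_g))``.  Returns the per-cell
    acceptance mask so the caller can adapt step sizes during burn-in.
    """
    mu = spec.mu if spec.mu is not None else compute_mu_plugin(table)
    s = table.y + spec.pseudo_count
    d = (s[:, :, 0] + s[:, :, 1]).astype(float)  # (p, C)
    e = mu[None, :] * (
        1.0 + _clamp_exp(state.beta)[:, None]
    )  # (p, C)

    def logf(a: np.ndarray) -> np.ndarray:
        return d * a - e * _clamp_exp(a) - a**2 / (2.0 * state.sigma2[None, :])

    prop = state.alpha + step * rng.standard_normal(state.alpha.shape)
    log_ratio = logf(prop) - logf(state.alpha)
    accept = np.log(rng.random(state.alpha.shape)) < log_ratio
    state.alpha = np.where(accept, prop, state.alpha)
    return state, accept


# ---------------------------------------------------------------------------
# sampler driver


def _initial_state(
    table: CountTable, spec: ModelSpec, mu: np.ndarray
) -> ModelState:
    s = table.y + spec.pseudo_count
    mean_s = s.mean(axis=2)  # (p, C)
    alpha0 = np.clip(np.log(np.maximum(mean_s, 0.5) / mu[None, :]), -5.0, 5.0)
    p = table.n_proteins
    return ModelState(
        beta=np.zeros(p),
        z=np.zeros(p, dtype=np.int64),
        alpha=alpha0,
        sigma2=np.full(table.n_blocks, 1.0),
        tau2=1.0,
        pi0=0.9,
    )


def run_mcmc(
    table: CountTable,
    spec: ModelSpec | None = None,
    n_iter: int = 4000,
    burn_in: int = 2000,
    thin: int = 1,
    seed: int = 0,
    n_nodes: int = 400,
    store_alpha: bool = True,
) -> PosteriorDraws:
    """Run the Metropolis-within-Gibbs sampler; deterministic given seed.

    Defaults: 4000 iterations, 2000 burn-in, no thinning, single chain.
    The alpha random-walk step is adapted toward ~40% acceptance during
    burn-in and frozen afterwards, so the post burn-in chain is a genuine
    fixed-kernel Markov chain.
    """
    if spec is None:
        spec = ModelSpec()
    if not (n_iter > burn_in >= 0):
        raise ValidationError("need n_iter > burn_in >= 0")
    if thin < 1:
        raise ValidationError("thin must be >= 1")
    rng = np.random.default_rng(seed)
    mu = spec.mu if spec.mu is not None else compute_mu_plugin(table)
    spec = ModelSpec(
        pseudo_count=spec.pseudo_count,
        prior_pi0=spec.prior_pi0,
        prior_precision=spec.prior_precision,
        mu=mu,
    )
    state = _initial_state(table, spec, mu)

    step = np.full(state.alpha.shape, 0.5)
    keep = (n_iter - burn_in) // thin
    p, C = table.n_proteins, table.n_blocks
    out_beta = np.empty((keep, p))
    out_z = np.empty((keep, p), dtype=np.int8)
    out_alpha = np.empty((keep, p, C)) if store_alpha else None
    out_sigma2 = np.empty((keep, C))
    out_tau2 = np.empty(keep)
    out_pi0 = np.empty(keep)

    n_acc = 0
    n_tot = 0
    k = 0
    for it in range(n_iter):
        state, accept = update_alpha(state, table, spec, rng, step)
        if it < burn_in:
            # Robbins-Monro step adaptation toward 40% acceptance
            step *= np.exp((accept.astype(float) - 0.4) / np.sqrt(it + 1.0))
            step = np.clip(step, 1e-3, 10.0)
        else:
            n_acc += int(accept.sum())
            n_tot += accept.size
        state = update_beta_and_z(state, table, spec, rng, n_nodes=n_nodes)
        state = gibbs_update_conjugates(state, table, spec, rng)
        if not (
            np.all(np.isfinite(state.beta))
            and np.all(np.isfinite(state.alpha))
            and np.isfinite(state.tau2)
        ):
            raise NumericalError(f"non-finite state at iteration {it}")
        if it >= burn_in and (it - burn_in) % thin == 0 and k < keep:
            out_beta[k] = state.beta
            out_z[k] = state.z
            if store_alpha:
                out_alpha[k] = state.alpha
            out_sigma2[k] = state.sigma2
            out_tau2[k] = state.tau2
            out_pi0[k] = state.pi0
            k += 1

    return PosteriorDraws(
        proteins=list(table.proteins),
        blocks=list(table.blocks),
        beta=out_beta[:k],
        z=out_z[:k],
        alpha=out_alpha[:k] if store_alpha else None,
        sigma2=out_sigma2[:k],
        tau2=out_tau2[:k],
        pi0=out_pi0[:k],
        seed=seed,
        n_iter=n_iter,
        burn_in=burn_in,
        thin=thin,
        alpha_acceptance=(n_acc / n_tot) if n_tot else float("nan"),
    )


def compute_lfsr(draws: PosteriorDraws, threshold: float = 0.2) -> EnrichmentResult:
    """Per-protein local false sign rate and threshold selection.

    lfsr_g is the fraction of posterior draws with beta_g <= 0; spike
    draws (beta_g = 0 exactly) count toward the event.  Proteins with
    lfsr_g <= threshold are selected (ties at the threshold included),
    and the mean lfsr over the selected set estimates the global false
    sign rate of the selection.
    """
    if draws.n_draws < 1:
        raise ValidationError("need at least one posterior draw")
    lfsr = np.mean(draws.beta <= 0.0, axis=0)
    post_mean = draws.beta.mean(axis=0)
    prob_slab = draws.z.mean(axis=0)
    selected = lfsr <= threshold
    global_rate = float(lfsr[selected].mean()) if selected.any() else float("nan")
    table = pd.DataFrame(
        {
            "protein_id": draws.proteins,
            "post_mean_beta": post_mean,
            "post_prob_slab": prob_slab,
            "lfsr": lfsr,
            "selected": selected,
        }
    )
    return EnrichmentResult(
        table=table, threshold=threshold, global_false_sign_rate=global_rate
    )
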