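"""Geographic cline models, likelihoods, MCMC fitting and model selection.

A geographic cline describes how an allele frequency or trait mean changes
along a one-dimensional transect.  The core shape is the hyperbolic-tangent
sigmoid

    p(x) = pmin + (pmax - pmin) * (1 + tanh(2 (x - c) / w)) / 2

with centre ``c`` (inflection location, km) and width ``w`` (inverse of the
maximal slope, km).  Outside an inner region [c - delta_L, c + delta_R] the
response may follow exponential tails that join the sigmoid continuously:

    left  (x < c - delta_L):  p = pmin + (p(c - delta_L) - pmin) * exp(4 tau_L (x - c + delta_L) / w)
    right (x > c + delta_R):  p = pmax - (pmax - p(c + delta_R)) * exp(-4 tau_R (x - c - delta_R) / w)

where tau in [0, 1] scales the tail decay relative to the central slope (the
HZAR-compatible convention).  Five tail modes (none / left / right / mirror /
independent) crossed with three frequency scaling modes (pmin, pmax fixed at
0 and 1, set to observed extremes, or estimated) give the 15-model frequency
family; trait clines use the 5 tail modes with estimated asymptotes.

Fitting uses per-parameter-bounded Gaussian random-walk Metropolis-Hastings
(replicate chains with distinct seeds), the MLE being the best visited state
refined by bounded local optimisation.  Models are compared by AICc, always
including a no-cline null; approximate 95% confidence intervals are the
connected set of parameter values whose profile log-likelihood lies within
2 units of the maximum (2 LLU).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln, xlogy

from .core import ValidationError

TAIL_MODES = ("none", "left", "right", "mirror", "independent")
SCALING_MODES = ("fixed01", "observed", "estimated")

_EPS = 1e-9


# ---------------------------------------------------------------- model form
@dataclass
class ClineModel:
    """A fully specified cline curve (all parameters fixed)."""

    centre: float
    width: float
    pmin: float = 0.0
    pmax: float = 1.0
    tail_mode: str = "none"
    delta_l: float = 0.0
    tau_l: float = 1.0
    delta_r: float = 0.0
    tau_r: float = 1.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValidationError("cline width must be > 0")
        if self.pmin > self.pmax:
            raise ValidationError("pmin must not exceed pmax")
        if self.tail_mode not in TAIL_MODES:
            raise ValidationError(f"unknown tail mode {self.tail_mode!r}")


def cline_value(x, m: ClineModel) -> np.ndarray:
    """Evaluate the cline response at transect position(s) ``x`` (km)."""
    dl = m.delta_l if m.tail_mode in ("left", "mirror", "independent") else np.inf
    dr = m.delta_r if m.tail_mode in ("right", "mirror", "independent") else np.inf
    return _cline_curve(
        np.asarray(x, dtype=float),
        np.array([[m.centre]]),
        np.array([[m.width]]),
        np.array([[m.pmin]]),
        np.array([[m.pmax]]),
        np.array([[dl]]),
        np.array([[m.tau_l]]),
        np.array([[dr]]),
        np.array([[m.tau_r]]),
    )[0]


def _cline_curve(x, c, w, pmin, pmax, dl, tl, dr, tr):
    """Vectorised cline curve: parameter columns (B, 1) against x (n,) -> (B, n)."""
    core = pmin + (pmax - pmin) * 0.5 * (1.0 + np.tanh(2.0 * (x - c) / w))
    xl = c - dl
    xr = c + dr
    with np.errstate(over="ignore", invalid="ignore"):
        sl = pmin + (pmax - pmin) * 0.5 * (1.0 + np.tanh(-2.0 * dl / w))
        sr = pmin + (pmax - pmin) * 0.5 * (1.0 + np.tanh(2.0 * dr / w))
        left = pmin + (sl - pmin) * np.exp(np.minimum(4.0 * tl * (x - xl) / w, 0.0))
        right = pmax - (pmax - sr) * np.exp(np.minimum(-4.0 * tr * (x - xr) / w, 0.0))
    p = np.where(x < xl, left, np.where(x > xr, right, core))
    return np.clip(p, np.minimum(pmin, pmax), np.maximum(pmin, pmax))


# ------------------------------------------------------------------ data
@dataclass
class FreqClineData:
    """Per-population allele counts along the transect."""

    x: np.ndarray  # distance_km
    count: np.ndarray  # counted-allele copies
    total: np.ndarray  # 2 x called individuals

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.count = np.asarray(self.count, dtype=float)
        self.total = np.asarray(self.total, dtype=float)
        if np.any(self.count < 0) or np.any(self.count > self.total):
            raise ValidationError("need 0 <= count <= total per population")
        keep = self.total > 0
        if not keep.all():
            warnings.warn("excluding populations with zero called alleles")
            self.x, self.count, self.total = self.x[keep], self.count[keep], self.total[keep]

    @property
    def n_obs(self) -> int:
        return len(self.x)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FreqClineData":
        return cls(df["distance_km"].to_numpy(), df["count"].to_numpy(), df["total"].to_numpy())


@dataclass
class TraitClineData:
    """Per-population trait summaries (mean, SD, n) along the transect."""

    x: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        if np.any(self.sd <= 0) or np.any(self.n < 1):
            raise ValidationError("trait summaries need sd > 0 and n >= 1")

    @property
    def n_obs(self) -> int:
        return len(self.x)

    @property
    def se(self) -> np.ndarray:
        return self.sd / np.sqrt(self.n)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TraitClineData":
        return cls(
            df["distance_km"].to_numpy(),
            df["mean"].to_numpy(),
            df["sd"].to_numpy(),
            df["n"].to_numpy(),
        )


# ------------------------------------------------------------- likelihoods
def loglik_freq(m: ClineModel, data: FreqClineData) -> float:
    """Binomial log-likelihood of per-population allele counts under the cline."""
    p = np.clip(cline_value(data.x, m), _EPS, 1.0 - _EPS)
    const = gammaln(data.total + 1) - gammaln(data.count + 1) - gammaln(data.total - data.count + 1)
    return float(np.sum(const + xlogy(data.count, p) + xlogy(data.total - data.count, 1.0 - p)))


def loglik_trait(m: ClineModel, data: TraitClineData) -> float:
    """Gaussian log-likelihood of population trait means (SE = sd / sqrt(n))."""
    mu = cline_value(data.x, m)
    se = data.se
    z = (data.mean - mu) / se
    return float(np.sum(-0.5 * np.log(2.0 * np.pi * se**2) - 0.5 * z**2))


# ----------------------------------------------------------- model selection
def aicc(lnl: float, k_params: int, n_obs: int) -> float:
    """Corrected Akaike information criterion; inf when n_obs <= k + 1."""
    if n_obs <= k_params + 1:
        warnings.warn(f"AICc undefined for k={k_params}, n={n_obs}; model excluded")
        return np.inf
    return -2.0 * lnl + 2.0 * k_params + 2.0 * k_params * (k_params + 1) / (n_obs - k_params - 1)


@dataclass
class TwoLLUInterval:
    """Connected parameter set with profile lnL within 2 units of the maximum."""

    low: float
    high: float
    lower_bounded: bool = True
    upper_bounded: bool = True

    @property
    def width(self) -> float:
        return self.high - self.low

    def contains(self, value: float) -> bool:
        return self.low <= value <= self.high


def two_llu_interval(values, lnls, mle_value, mle_lnl, drop: float = 2.0) -> TwoLLUInterval:
    """Interval around the MLE where the profile stays within ``drop`` lnL units.

    ``values``/``lnls`` form the explored profile; endpoints are linearly
    interpolated between profile points.  Sides where the profile never falls
    below the threshold are reported at the explored bound and flagged
    unbounded.
    """
    order = np.argsort(values)
    v = np.asarray(values, dtype=float)[order]
    l = np.asarray(lnls, dtype=float)[order]
    thresh = mle_lnl - drop
    i0 = int(np.argmin(np.abs(v - mle_value)))
    # walk right
    high, ub = v[-1], False
    j = i0
    while j + 1 < len(v) and l[j + 1] >= thresh:
        j += 1
    if j + 1 < len(v):
        high = v[j] + (v[j + 1] - v[j]) * (l[j] - thresh) / max(l[j] - l[j + 1], 1e-300)
        ub = True
    # walk left
    low, lb = v[0], False
    j = i0
    while j - 1 >= 0 and l[j - 1] >= thresh:
        j -= 1
    if j - 1 >= 0:
        low = v[j] - (v[j] - v[j - 1]) * (l[j] - thresh) / max(l[j] - l[j - 1], 1e-300)
        lb = True
    low = min(low, mle_value)
    high = max(high, mle_value)
    return TwoLLUInterval(float(low), float(high), lower_bounded=lb, upper_bounded=ub)


# ------------------------------------------------------------- model specs
@dataclass(frozen=True)
class ModelSpec:
    """A member of the cline model family: response kind x tails x scaling."""

    kind: str  # "freq" or "trait"
    tail_mode: str = "none"
    scaling: str = "fixed01"  # trait family conventionally uses "estimated"

    def __post_init__(self) -> None:
        if self.kind not in ("freq", "trait"):
            raise ValidationError("kind must be 'freq' or 'trait'")
        if self.tail_mode not in TAIL_MODES:
            raise ValidationError(f"unknown tail mode {self.tail_mode!r}")
        if self.scaling not in SCALING_MODES:
            raise ValidationError(f"unknown scaling mode {self.scaling!r}")

    @property
    def name(self) -> str:
        return f"{self.kind}/{self.tail_mode}/{self.scaling}"

    def param_names(self) -> list[str]:
        names = ["centre", "width"]
        if self.scaling == "estimated":
            names += ["pmin", "pmax"]
        if self.tail_mode in ("left",):
            names += ["delta_l", "tau_l"]
        elif self.tail_mode == "right":
            names += ["delta_r", "tau_r"]
        elif self.tail_mode == "mirror":
            names += ["delta", "tau"]
        elif self.tail_mode == "independent":
            names += ["delta_l", "tau_l", "delta_r", "tau_r"]
        return names

    @property
    def k_params(self) -> int:
        return len(self.param_names())


def frequency_model_specs() -> list[ModelSpec]:
    """The 15-model frequency family (5 tail modes x 3 scaling modes)."""
    return [ModelSpec("freq", t, s) for t in TAIL_MODES for s in SCALING_MODES]


def trait_model_specs() -> list[ModelSpec]:
    """The 5-model trait family (tail modes; asymptotes estimated)."""
    return [ModelSpec("trait", t, "estimated") for t in TAIL_MODES]


@dataclass
class _Context:
    """Data-derived bounds and fixed scaling values for a fit."""

    x0: float
    length: float
    obs_min: float
    obs_max: float
    pm_lo: float
    pm_hi: float
    w_min: float = 1e-2

    @classmethod
    def from_data(cls, spec: ModelSpec, data) -> "_Context":
        x0 = float(np.min(data.x))
        length = float(np.max(data.x) - x0)
        if length <= 0:
            raise ValidationError("populations must span a transect of positive length")
        # clines narrower than the sampling interval are unresolvable
        w_min = length / max(data.n_obs - 1, 1)
        if spec.kind == "freq":
            # "observed" scaling anchors: min/max observed deme frequencies
            f = data.count / data.total
            lo, hi = float(np.min(f)), float(np.max(f))
            return cls(x0, length, lo, hi, 0.0, 1.0, w_min)
        m_lo, m_hi = float(np.min(data.mean)), float(np.max(data.mean))
        r = max(m_hi - m_lo, 1e-6)
        return cls(x0, length, m_lo, m_hi, m_lo - r, m_hi + r, w_min)


def _param_bounds(spec: ModelSpec, ctx: _Context) -> tuple[np.ndarray, np.ndarray]:
    lows, highs = [], []
    L = ctx.length
    for name in spec.param_names():
        if name == "centre":
            lows.append(ctx.x0 - 0.25 * L)
            highs.append(ctx.x0 + 1.25 * L)
        elif name == "width":
            lows.append(ctx.w_min)
            highs.append(3.0 * L)
        elif name in ("pmin", "pmax"):
            lows.append(ctx.pm_lo)
            highs.append(ctx.pm_hi)
        elif name.startswith("delta"):
            lows.append(0.0)
            highs.append(L)
        else:  # tau
            lows.append(0.0)
            highs.append(1.0)
    return np.array(lows), np.array(highs)


def _theta_to_curve_args(spec: ModelSpec, ctx: _Context, theta: np.ndarray):
    """Map a (B, P) parameter block to the column vectors of ``_cline_curve``."""
    names = spec.param_names()
    col = {n: theta[:, i : i + 1] for i, n in enumerate(names)}
    B = theta.shape[0]
    one = np.ones((B, 1))
    c, w = col["centre"], col["width"]
    if "pmin" in col:
        pmin, pmax = col["pmin"], col["pmax"]
    elif spec.scaling == "observed":
        pmin, pmax = ctx.obs_min * one, ctx.obs_max * one
    else:
        pmin, pmax = 0.0 * one, one
    inf = np.full((B, 1), np.inf)
    if spec.tail_mode == "none":
        dl, tl, dr, tr = inf, one, inf, one
    elif spec.tail_mode == "left":
        dl, tl, dr, tr = col["delta_l"], col["tau_l"], inf, one
    elif spec.tail_mode == "right":
        dl, tl, dr, tr = inf, one, col["delta_r"], col["tau_r"]
    elif spec.tail_mode == "mirror":
        dl, tl, dr, tr = col["delta"], col["tau"], col["delta"], col["tau"]
    else:
        dl, tl, dr, tr = col["delta_l"], col["tau_l"], col["delta_r"], col["tau_r"]
    return c, w, pmin, pmax, dl, tl, dr, tr


def model_from_theta(spec: ModelSpec, ctx: _Context, theta: np.ndarray) -> ClineModel:
    c, w, pmin, pmax, dl, tl, dr, tr = _theta_to_curve_args(spec, ctx, theta[None, :])
    return ClineModel(
        centre=float(c[0, 0]),
        width=float(w[0, 0]),
        pmin=float(min(pmin[0, 0], pmax[0, 0])),
        pmax=float(max(pmin[0, 0], pmax[0, 0])),
        tail_mode=spec.tail_mode,
        delta_l=float(dl[0, 0]) if np.isfinite(dl[0, 0]) else 0.0,
        tau_l=float(tl[0, 0]),
        delta_r=float(dr[0, 0]) if np.isfinite(dr[0, 0]) else 0.0,
        tau_r=float(tr[0, 0]),
    )


def _make_loglik(spec: ModelSpec, ctx: _Context, data, batch_counts=None, batch_totals=None):
    """Return lnL(theta (B, P)) -> (B,); optionally per-row data batches."""
    x = np.asarray(data.x, dtype=float)
    if spec.kind == "freq":
        k = batch_counts if batch_counts is not None else data.count[None, :]
        n = batch_totals if batch_totals is not None else data.total[None, :]
        const = np.sum(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1), axis=1)

        def lnl(theta: np.ndarray) -> np.ndarray:
            args = _theta_to_curve_args(spec, ctx, theta)
            p = np.clip(_cline_curve(x, *args), _EPS, 1.0 - _EPS)
            out = const + np.sum(xlogy(k, p) + xlogy(n - k, 1.0 - p), axis=1)
            bad = _invalid_theta(spec, theta)
            out[bad] = -np.inf
            return out

    else:
        se = data.se
        const = float(np.sum(-0.5 * np.log(2.0 * np.pi * se**2)))
        mean = data.mean

        def lnl(theta: np.ndarray) -> np.ndarray:
            args = _theta_to_curve_args(spec, ctx, theta)
            mu = _cline_curve(x, *args)
            out = const - 0.5 * np.sum(((mean - mu) / se) ** 2, axis=1)
            bad = _invalid_theta(spec, theta)
            out[bad] = -np.inf
            return out

    return lnl


def _invalid_theta(spec: ModelSpec, theta: np.ndarray) -> np.ndarray:
    names = spec.param_names()
    bad = np.zeros(theta.shape[0], dtype=bool)
    if "pmin" in names:
        i, j = names.index("pmin"), names.index("pmax")
        bad |= theta[:, i] > theta[:, j]
    return bad


# ------------------------------------------------------------------ sampler
def _mh_chains(lnl_fn, lows, highs, init, n_steps, burnin, rng, adapt_every=50):
    """Random-walk Metropolis-Hastings, vectorised over batch rows.

    ``init`` is (B, P); proposals are componentwise Gaussian with a per-row
    scale multiplier adapted during burn-in towards ~30% acceptance.
    Out-of-bounds proposals are rejected.  Returns post-burn-in samples,
    their lnLs, the best visited state per row, and the acceptance rate.
    """
    cur = init.copy()
    B, P = cur.shape
    lnl_cur = lnl_fn(cur)
    scale = np.full((B, 1), 0.1)
    base = (highs - lows)[None, :]
    best = cur.copy()
    best_lnl = lnl_cur.copy()
    n_keep = n_steps
    samples = np.empty((n_keep, B, P))
    lnls = np.empty((n_keep, B))
    acc_win = np.zeros(B)
    n_acc = np.zeros(B)
    for t in range(burnin + n_steps):
        prop = cur + scale * base * rng.standard_normal((B, P)) * 0.1
        inb = np.all((prop >= lows) & (prop <= highs), axis=1)
        lnl_prop = np.where(inb, lnl_fn(prop), -np.inf)
        with np.errstate(invalid="ignore"):
            accept = np.log(rng.random(B)) < (lnl_prop - lnl_cur)
            # escape invalid starting states immediately
            accept |= np.isneginf(lnl_cur) & np.isfinite(lnl_prop)
        cur[accept] = prop[accept]
        lnl_cur[accept] = lnl_prop[accept]
        improved = lnl_cur > best_lnl
        best[improved] = cur[improved]
        best_lnl[improved] = lnl_cur[improved]
        if t < burnin:
            acc_win += accept
            if (t + 1) % adapt_every == 0:
                rate = acc_win / adapt_every
                scale *= np.exp((rate - 0.3))[:, None]
                scale = np.clip(scale, 1e-4, 10.0)
                acc_win[:] = 0.0
        else:
            samples[t - burnin] = cur
            lnls[t - burnin] = lnl_cur
            n_acc += accept
    return samples, lnls, best, best_lnl, n_acc / max(n_steps, 1)




def _order_scaling(spec: ModelSpec, names, theta: np.ndarray) -> np.ndarray:
    """Swap pmin/pmax columns where needed so starting states are valid."""
    if "pmin" in names:
        i, j = names.index("pmin"), names.index("pmax")
        lo = np.minimum(theta[:, i], theta[:, j])
        hi = np.maximum(theta[:, i], theta[:, j])
        theta[:, i], theta[:, j] = lo, hi
    return theta

# ------------------------------------------------------------------ fitting
@dataclass
class ClineFit:
    """A fitted cline model with its selection score and profile intervals."""

    spec: ModelSpec | None  # None marks the no-cline null
    model: ClineModel | None
    params: dict[str, float]
    lnl: float
    k: int
    n_obs: int
    aicc: float
    intervals: dict[str, TwoLLUInterval] = field(default_factory=dict)
    converged: bool = True
    accept_rates: tuple = ()

    @property
    def is_null(self) -> bool:
        return self.spec is None

    @property
    def name(self) -> str:
        return "no-cline" if self.is_null else self.spec.name


def fit_null_freq(data: FreqClineData) -> ClineFit:
    """Constant-frequency null model (k = 1)."""
    p = float(np.sum(data.count) / np.sum(data.total))
    pc = np.clip(p, _EPS, 1 - _EPS)
    const = gammaln(data.total + 1) - gammaln(data.count + 1) - gammaln(data.total - data.count + 1)
    lnl = float(np.sum(const + xlogy(data.count, pc) + xlogy(data.total - data.count, 1 - pc)))
    return ClineFit(None, None, {"p": p}, lnl, 1, data.n_obs, aicc(lnl, 1, data.n_obs))


def fit_null_trait(data: TraitClineData) -> ClineFit:
    """Constant-mean null model (k = 2, matching the trait family convention)."""
    w = 1.0 / data.se**2
    mu = float(np.sum(w * data.mean) / np.sum(w))
    lnl = float(
        np.sum(-0.5 * np.log(2 * np.pi * data.se**2) - 0.5 * ((data.mean - mu) / data.se) ** 2)
    )
    return ClineFit(None, None, {"mean": mu}, lnl, 2, data.n_obs, aicc(lnl, 2, data.n_obs))


def _refine(lnl_fn, theta0, lows, highs):
    """Polish the best visited state with bounded local optimisation."""
    res = minimize(
        lambda t: -lnl_fn(t[None, :])[0],
        np.clip(theta0, lows, highs),
        method="L-BFGS-B",
        bounds=list(zip(lows, highs)),
    )
    if np.isfinite(res.fun):
        return res.x, -res.fun
    return theta0, lnl_fn(theta0[None, :])[0]


def _profile_interval(lnl_fn, spec, names, theta_mle, lnl_mle, idx, lows, highs, grid_lo, grid_hi, n_grid=21):
    """2-LLU interval for parameter ``idx`` by true profile likelihood.

    Nuisance parameters are re-optimised at each grid value (warm-started from
    the neighbouring optimum); the profile is handed to ``two_llu_interval``.
    """
    others = [i for i in range(len(names)) if i != idx]
    lo = max(lows[idx], grid_lo)
    hi = min(highs[idx], grid_hi)
    if hi <= lo:
        lo, hi = lows[idx], highs[idx]
    grid = np.unique(np.concatenate([np.linspace(lo, hi, n_grid), [theta_mle[idx]]]))
    prof = np.empty_like(grid)

    def eval_at(v, start):
        th = start.copy()
        th[idx] = v
        if not others:
            return th, lnl_fn(th[None, :])[0]
        res = minimize(
            lambda q: -_with(th, others, q, lnl_fn),
            th[others],
            method="L-BFGS-B",
            bounds=[(lows[i], highs[i]) for i in others],
        )
        th[others] = res.x
        return th, -res.fun

    i_mle = int(np.argmin(np.abs(grid - theta_mle[idx])))
    start = theta_mle.copy()
    for j in range(i_mle, len(grid)):
        start, prof[j] = eval_at(grid[j], start)
    start = theta_mle.copy()
    for j in range(i_mle - 1, -1, -1):
        start, prof[j] = eval_at(grid[j], start)
    iv = two_llu_interval(grid, prof, theta_mle[idx], lnl_mle)
    # a profile still above threshold at a hard parameter bound is bounded by it
    if not iv.lower_bounded and np.isclose(grid[0], lows[idx]):
        iv = TwoLLUInterval(iv.low, iv.high, True, iv.upper_bounded)
    if not iv.upper_bounded and np.isclose(grid[-1], highs[idx]):
        iv = TwoLLUInterval(iv.low, iv.high, iv.lower_bounded, True)
    return iv


def _with(theta, idxs, vals, lnl_fn):
    th = theta.copy()
    th[idxs] = vals
    return lnl_fn(th[None, :])[0]


def fit_mcmc(
    spec: ModelSpec,
    data,
    chain_len: int = 100_000,
    burnin: int = 10_000,
    n_chains: int = 6,
    seed: int = 0,
    interval_params: tuple[str, ...] = ("centre", "width"),
    profile_points: int = 21,
) -> ClineFit:
    """Fit one cline model by replicate Metropolis-Hastings chains.

    The MLE is the highest-likelihood visited state refined by L-BFGS-B;
    2-LLU intervals come from profile likelihoods on a grid seeded by the
    chains' explored range.  Convergence is flagged (never raised) when the
    across-chain spread of per-chain best centres exceeds 5% of the pooled
    centre interval width.
    """
    if data.n_obs < 4:
        raise ValidationError("need at least 4 populations spanning the transect")
    ctx = _Context.from_data(spec, data)
    lows, highs = _param_bounds(spec, ctx)
    lnl_fn = _make_loglik(spec, ctx, data)
    names = spec.param_names()
    P = len(names)
    best_theta = None
    best_lnl = -np.inf
    chain_best_centres = []
    rates = []
    explored_lo = np.full(P, np.inf)
    explored_hi = np.full(P, -np.inf)
    for i in range(n_chains):
        rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
        init = (lows + (highs - lows) * rng.uniform(0.1, 0.9, size=(1, P))).reshape(1, P)
        init = _order_scaling(spec, names, init)
        samples, lnls, b, bl, rate = _mh_chains(lnl_fn, lows, highs, init, chain_len, burnin, rng)
        rates.append(float(rate[0]))
        chain_best_centres.append(float(b[0, names.index("centre")]))
        keep = lnls[:, 0] >= bl[0] - 8.0
        if keep.any():
            explored_lo = np.minimum(explored_lo, samples[keep, 0, :].min(axis=0))
            explored_hi = np.maximum(explored_hi, samples[keep, 0, :].max(axis=0))
        if bl[0] > best_lnl:
            best_lnl = float(bl[0])
            best_theta = b[0].copy()
    theta, lnl = _refine(lnl_fn, best_theta, lows, highs)
    intervals = {}
    span = explored_hi - explored_lo
    for pname in interval_params:
        if pname not in names:
            continue
        idx = names.index(pname)
        intervals[pname] = _profile_interval(
            lnl_fn,
            spec,
            names,
            theta,
            lnl,
            idx,
            lows,
            highs,
            explored_lo[idx] - 0.25 * span[idx],
            explored_hi[idx] + 0.25 * span[idx],
            n_grid=profile_points,
        )
    converged = True
    if "centre" in intervals and len(chain_best_centres) > 1:
        spread = max(chain_best_centres) - min(chain_best_centres)
        ref = intervals["centre"].width if intervals["centre"].width > 0 else ctx.length
        # floor at 1% of the transect: flat-topped profiles make tiny interval
        # widths meaningless as a convergence yardstick
        converged = spread < max(0.05 * ref, 0.01 * ctx.length)
    model = model_from_theta(spec, ctx, theta)
    params = dict(zip(names, theta))
    return ClineFit(
        spec,
        model,
        {k: float(v) for k, v in params.items()},
        float(lnl),
        spec.k_params,
        data.n_obs,
        aicc(lnl, spec.k_params, data.n_obs),
        intervals,
        converged,
        tuple(rates),
    )


def select_model(fits: list[ClineFit], include_null: bool = True) -> ClineFit:
    """Pick the minimum-AICc fit; ties go to the model with fewer parameters."""
    if not fits:
        raise ValidationError("no fits to select among")
    return min(fits, key=lambda f: (f.aicc, f.k))


def fit_family(
    data,
    kind: str = "freq",
    chain_len: int = 10_000,
    burnin: int = 2_000,
    n_chains: int = 3,
    seed: int = 0,
    specs: list[ModelSpec] | None = None,
    include_null: bool = True,
    interval_params: tuple[str, ...] = ("centre", "width"),
) -> tuple[ClineFit, pd.DataFrame]:
    """Fit the full model family plus the null; return (best fit, AICc table)."""
    if specs is None:
        specs = frequency_model_specs() if kind == "freq" else trait_model_specs()
    fits = []
    for i, spec in enumerate(specs):
        fits.append(
            fit_mcmc(
                spec,
                data,
                chain_len=chain_len,
                burnin=burnin,
                n_chains=n_chains,
                seed=seed + 1000 * i,
                interval_params=interval_params,
            )
        )
    if include_null:
        fits.append(fit_null_freq(data) if kind == "freq" else fit_null_trait(data))
    table = pd.DataFrame(
        {
            "model": [f.name for f in fits],
            "k": [f.k for f in fits],
            "lnL": [f.lnl for f in fits],
            "AICc": [f.aicc for f in fits],
        }
    ).sort_values("AICc", ignore_index=True)
    return select_model(fits), table


# ------------------------------------------------------------- batched scan
def scan_frequency_loci(
    x: np.ndarray,
    counts: np.ndarray,
    totals: np.ndarray,
    locus_ids: list[str] | None = None,
    specs: list[ModelSpec] | None = None,
    chain_len: int = 10_000,
    burnin: int = 2_000,
    n_chains: int = 2,
    seed: int = 0,
    refine: bool = True,
) -> pd.DataFrame:
    """Per-SNP geographic cline scan, vectorised across loci.

    For every locus (row of ``counts``/``totals``) each model in the family is
    fitted by batched Metropolis-Hastings sharing the transect positions
    ``x``; the per-locus winner (by AICc, against the constant-frequency
    null) is refined by local optimisation.  Returns one row per locus with
    the best model name, centre/width MLEs and the null comparison.
    """
    counts = np.asarray(counts, dtype=float)
    totals = np.asarray(totals, dtype=float)
    L = counts.shape[0]
    if specs is None:
        specs = frequency_model_specs()
    if locus_ids is None:
        locus_ids = [f"L{i}" for i in range(L)]
    data0 = FreqClineData(x, counts[0], totals[0])
    n_obs = data0.n_obs
    best_lnl = np.full((L, len(specs)), -np.inf)
    best_theta: list[np.ndarray | None] = [None] * len(specs)
    for si, spec in enumerate(specs):
        ctx = _Context.from_data(spec, data0)
        # observed scaling is per-locus; widen to the pooled range so a single
        # batched context stays valid, per-locus extremes set below
        lnl_fn_all = _make_loglik(spec, ctx, data0, batch_counts=counts, batch_totals=totals)
        if spec.scaling == "observed" and spec.kind == "freq":
            lnl_fn_all = _make_observed_batch_loglik(spec, x, counts, totals)
        lows, highs = _param_bounds(spec, ctx)
        P = len(lows)
        theta_best = None
        lnl_best = np.full(L, -np.inf)
        for ci in range(n_chains):
            rng = np.random.default_rng(np.random.SeedSequence([seed, si, ci]))
            init = lows + (highs - lows) * rng.uniform(0.1, 0.9, size=(L, P))
            init = _order_scaling(spec, spec.param_names(), init)
            _, _, b, bl, _ = _mh_chains(lnl_fn_all, lows, highs, init, chain_len, burnin, rng)
            better = bl > lnl_best
            if theta_best is None:
                theta_best = b
            else:
                theta_best[better] = b[better]
            lnl_best = np.maximum(lnl_best, bl)
        best_lnl[:, si] = lnl_best
        best_theta[si] = theta_best
    k = np.array([s.k_params for s in specs])
    pen = 2.0 * k + 2.0 * k * (k + 1) / (n_obs - k - 1)
    aiccs = -2.0 * best_lnl + pen[None, :]
    win = np.argmin(aiccs, axis=1)
    rows = []
    for li in range(L):
        si = int(win[li])
        spec = specs[si]
        d = FreqClineData(x, counts[li], totals[li])
        ctx = _Context.from_data(spec, d)
        lnl_fn = _make_loglik(spec, ctx, d)
        lows, highs = _param_bounds(spec, ctx)
        theta = best_theta[si][li]
        lnl = best_lnl[li, si]
        if refine:
            theta, lnl = _refine(lnl_fn, theta, lows, highs)
        null = fit_null_freq(d)
        best_aicc = aicc(lnl, spec.k_params, n_obs)
        model = model_from_theta(spec, ctx, theta)
        rows.append(
            {
                "locus": locus_ids[li],
                "best_model": spec.name,
                "centre": model.centre,
                "width": model.width,
                "lnL": float(lnl),
                "AICc": float(best_aicc),
                "null_AICc": null.aicc,
                "null_best": bool(null.aicc <= best_aicc),
            }
        )
    return pd.DataFrame(rows)


def _make_observed_batch_loglik(spec: ModelSpec, x, counts, totals):
    """Observed-scaling loglik with per-locus pmin/pmax = observed extremes."""
    with np.errstate(invalid="ignore"):
        freqs = counts / np.maximum(totals, 1)
    lo = freqs.min(axis=1)[:, None]
    hi = freqs.max(axis=1)[:, None]
    const = np.sum(
        gammaln(totals + 1) - gammaln(counts + 1) - gammaln(totals - counts + 1), axis=1
    )
    names = spec.param_names()

    def lnl(theta: np.ndarray) -> np.ndarray:
        col = {n: theta[:, i : i + 1] for i, n in enumerate(names)}
        B = theta.shape[0]
        one = np.ones((B, 1))
        inf = np.full((B, 1), np.inf)
        if spec.tail_mode == "none":
            dl, tl, dr, tr = inf, one, inf, one
        elif spec.tail_mode == "left":
            dl, tl, dr, tr = col["delta_l"], col["tau_l"], inf, one
        elif spec.tail_mode == "right":
            dl, tl, dr, tr = inf, one, col["delta_r"], col["tau_r"]
        elif spec.tail_mode == "mirror":
            dl, tl, dr, tr = col["delta"], col["tau"], col["delta"], col["tau"]
        else:
            dl, tl, dr, tr = col["delta_l"], col["tau_l"], col["delta_r"], col["tau_r"]
        p = np.clip(_cline_curve(x, col["centre"], col["width"], lo, hi, dl, tl, dr, tr), _EPS, 1 - _EPS)
        return const + np.sum(xlogy(counts, p) + xlogy(totals - counts, 1.0 - p), axis=1)

    return lnl


# --------------------------------------------------------- summary arithmetic
def centre_shift_km(genetic_centre: float, trait_centres) -> float:
    """Displacement of the genetic (hybrid-index) cline centre relative to the
    average morphological centre; positive values point toward speciesB."""
    return float(genetic_centre - np.mean(trait_centres))


def width_difference_km(width_a: float, width_b: float) -> float:
    """Signed difference between two cline widths (a minus b), km."""
    return float(width_a - width_b)
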