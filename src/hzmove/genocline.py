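"""Hybrid index and genomic clines.

The hybrid index h of an individual is its proportion of speciesB ancestry,
estimated here by supervised maximum likelihood against parental reference
allele frequencies: the dose of the counted allele at locus l is modelled as
Binomial(2, h * pB_l + (1 - h) * pA_l), and h is found by bounded 1-D
optimisation with a 2-log-likelihood-unit support interval.  With two
well-separated source taxa this is operationally equivalent to a K = 2 global
admixture coefficient (Q-score) for cline input.

The genomic cline of a locus describes how its probability of speciesB
ancestry departs from the genome-wide expectation h:

    phi(h) = h + 2 h (1 - h) * (alpha + beta * (2 h - 1)),  clamped to [0, 1].

Positive alpha marks excess speciesB ancestry (directional introgression from
the northern parental), negative alpha excess speciesA ancestry.  Per-locus
(alpha, beta) are sampled by Metropolis-Hastings under independent
Normal(0, 0.5^2) priors; a locus is a positive/negative outlier when the 95%
equal-tailed credible interval of alpha lies entirely above/below zero.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import xlogy

from .core import GenotypeMatrix, MISSING, ValidationError
from .geocline import TwoLLUInterval, two_llu_interval

_EPS = 1e-9


def genomic_cline_phi(h, alpha, beta) -> np.ndarray:
    """Expected speciesB ancestry probability at a locus given hybrid index h."""
    h = np.asarray(h, dtype=float)
    phi = h + 2.0 * h * (1.0 - h) * (alpha + beta * (2.0 * h - 1.0))
    return np.clip(phi, 0.0, 1.0)


@dataclass
class HybridIndex:
    individual: str
    h: float
    interval: TwoLLUInterval


def _h_loglik_grid(dose: np.ndarray, called: np.ndarray, pA: np.ndarray, pB: np.ndarray, grid: np.ndarray):
    """lnL(h) over a grid, for one individual's diagnostic-locus doses."""
    p = np.clip(grid[:, None] * pB[None, :] + (1 - grid[:, None]) * pA[None, :], _EPS, 1 - _EPS)
    d = np.where(called, dose, 0.0)
    m = np.where(called, 2.0 - dose, 0.0)
    return (xlogy(d[None, :], p) + xlogy(m[None, :], 1.0 - p)).sum(axis=1)


def hybrid_index(
    g: GenotypeMatrix,
    pA: pd.Series | np.ndarray,
    pB: pd.Series | np.ndarray,
    loci: list[str] | None = None,
    grid_size: int = 201,
) -> pd.DataFrame:
    """Maximum-likelihood hybrid index per individual with 2-LLU support.

    ``pA``/``pB`` are parental reference frequencies for ``loci`` (defaults
    to every locus in ``g``).  Returns a DataFrame with columns
    individual, pop_id, h, h_low, h_high.
    """
    if loci is not None:
        g = g.subset(locus_ids=loci)
    pA = np.asarray(pA.loc[g.loci] if isinstance(pA, pd.Series) else pA, dtype=float)
    pB = np.asarray(pB.loc[g.loci] if isinstance(pB, pd.Series) else pB, dtype=float)
    informative = np.isfinite(pA) & np.isfinite(pB) & (np.abs(pA - pB) > 1e-12)
    if not informative.any():
        raise ValidationError("no informative loci: parental frequencies all equal")
    pA, pB = pA[informative], pB[informative]
    geno = g.genotypes[:, informative]
    grid = np.linspace(0.0, 1.0, grid_size)
    rows = []
    for i, ind in enumerate(g.individuals):
        dose = geno[i].astype(float)
        called = geno[i] != MISSING
        lnl = _h_loglik_grid(dose, called, pA, pB, grid)
        j = int(np.argmax(lnl))
        lo, hi = max(grid[j] - 0.01, 0.0), min(grid[j] + 0.01, 1.0)

        def neg(h):
            return -float(_h_loglik_grid(dose, called, pA, pB, np.array([h]))[0])

        res = minimize_scalar(neg, bounds=(lo, hi), method="bounded")
        h_mle, lnl_max = float(res.x), -float(res.fun)
        if lnl[j] > lnl_max:  # grid edge beats interior polish
            h_mle, lnl_max = float(grid[j]), float(lnl[j])
        iv = two_llu_interval(grid, lnl, h_mle, lnl_max)
        rows.append(
            {
                "individual": ind,
                "pop_id": g.pops[i],
                "h": h_mle,
                "h_low": iv.low,
                "h_high": iv.high,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class GenomicClineParams:
    locus: str
    alpha_median: float
    alpha_low: float
    alpha_high: float
    beta_median: float
    outlier_class: str  # positive / negative / none


def classify_outliers(alpha_low: np.ndarray, alpha_high: np.ndarray) -> np.ndarray:
    """positive if the interval is entirely > 0, negative if entirely < 0."""
    return np.where(alpha_low > 0, "positive", np.where(alpha_high < 0, "negative", "none"))


def estimate_alpha(
    doses: np.ndarray,
    h: np.ndarray,
    locus_ids: list[str] | None = None,
    prior_sd: float = 0.5,
    chain_len: int = 4000,
    burnin: int = 1000,
    seed: int = 0,
    ci: float = 0.95,
) -> pd.DataFrame:
    """Per-locus genomic cline (alpha, beta) posteriors over hybrid individuals.

    ``doses`` is (n_individuals, n_loci) counted-allele dosage (0/1/2, -1
    missing) restricted to hybrid-zone individuals with hybrid index ``h``.
    One Metropolis-Hastings chain per locus runs vectorised across loci;
    monomorphic loci are skipped with a warning.  Returns a DataFrame with
    alpha median / equal-tailed CI, beta median and outlier class.
    """
    doses = np.asarray(doses, dtype=float)
    h = np.asarray(h, dtype=float)
    n, L = doses.shape
    if n < 10:
        raise ValidationError("need at least 10 hybrid individuals with defined h")
    if locus_ids is None:
        locus_ids = [f"L{i}" for i in range(L)]
    called = doses >= 0
    d = np.where(called, doses, 0.0)
    m = np.where(called, 2.0 - doses, 0.0)
    poly = np.array([(d[:, j][called[:, j]].std() > 0) for j in range(L)])
    if not poly.all():
        warnings.warn(f"skipping {int((~poly).sum())} monomorphic loci")

    hh = h[None, :]  # (1, n)
    two_h = 2.0 * hh * (1.0 - hh)
    lin = 2.0 * hh - 1.0

    def logpost(theta):  # theta (L, 2)
        a = theta[:, 0:1]
        b = theta[:, 1:2]
        phi = np.clip(hh + two_h * (a + b * lin), _EPS, 1.0 - _EPS)
        lnl = np.sum(xlogy(d.T, phi) + xlogy(m.T, 1.0 - phi), axis=1)
        prior = -0.5 * (theta[:, 0] ** 2 + theta[:, 1] ** 2) / prior_sd**2
        return lnl + prior

    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    cur = np.zeros((L, 2))
    lp_cur = logpost(cur)
    scale = np.full((L, 1), 0.2)
    samples = np.empty((chain_len, L, 2))
    acc_win = np.zeros(L)
    for t in range(burnin + chain_len):
        prop = cur + scale * rng.standard_normal((L, 2))
        lp_prop = logpost(prop)
        accept = np.log(rng.random(L)) < (lp_prop - lp_cur)
        cur[accept] = prop[accept]
        lp_cur[accept] = lp_prop[accept]
        if t < burnin:
            acc_win += accept
            if (t + 1) % 50 == 0:
                scale *= np.exp((acc_win / 50 - 0.3))[:, None]
                scale = np.clip(scale, 1e-3, 5.0)
                acc_win[:] = 0.0
        else:
            samples[t - burnin] = cur
    q_lo, q_hi = (1 - ci) / 2, 1 - (1 - ci) / 2
    a_med = np.median(samples[:, :, 0], axis=0)
    a_lo = np.quantile(samples[:, :, 0], q_lo, axis=0)
    a_hi = np.quantile(samples[:, :, 0], q_hi, axis=0)
    b_med = np.median(samples[:, :, 1], axis=0)
    cls = classify_outliers(a_lo, a_hi)
    out = pd.DataFrame(
        {
            "locus": locus_ids,
            "alpha_median": a_med,
            "alpha_low": a_lo,
            "alpha_high": a_hi,
            "beta_median": b_med,
            "outlier_class": cls,
            "polymorphic": poly,
        }
    )
    out.loc[~out["polymorphic"], "outlier_class"] = "none"
    return out
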