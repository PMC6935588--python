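"""Ohta's D statistics: variance partitioning of two-locus disequilibrium.

In a subdivided population the squared gametic disequilibrium of a locus pair
decomposes into within- and among-subpopulation variance components.  With
g_ij(k) the frequency of gamete (i, j) in subpopulation k, x_i(k), y_j(k) the
marginal allele frequencies and bars denoting unweighted means over
subpopulations:

    D2_IS  = E_k[ sum_ij (g_ij(k) - x_i(k) y_j(k))^2 ]   within-subpop LD
    D2_ST  = E_k[ sum_ij (x_i(k) y_j(k) - xbar_i ybar_j)^2 ]
    D2'_IS = E_k[ sum_ij (g_ij(k) - gbar_ij)^2 ]
    D2'_ST = sum_ij (gbar_ij - xbar_i ybar_j)^2
    D2_IT  = E_k[ sum_ij (g_ij(k) - xbar_i ybar_j)^2 ]    total

with the identity D2_IT = D2'_IS + D2'_ST.  A rising ratio D_IS:D_ST toward
one end of a transect of overlapping population windows is the signature of
recent introgression at an expanding hybrid-zone front.

The statistics are gametic: phased haplotypes are used directly; for unphased
genotypes two-locus gamete frequencies are estimated per subpopulation by EM
under random mating.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, ValidationError


@dataclass
class OhtaDecomposition:
    """Five variance components of squared LD for one locus pair."""

    d2_is: float
    d2_st: float
    d2p_is: float
    d2p_st: float
    d2_it: float
    n_subpops: int


@dataclass
class WindowSet:
    """An ordered window of populations along the transect."""

    pop_ids: tuple[str, ...]
    midpoint_km: float
    truncated: bool = False


def window_sets(
    pops: pd.DataFrame, set_size: int = 4, overlap: int = 1
) -> list[WindowSet]:
    """Tile populations (ordered by distance_km) into overlapping windows.

    Consecutive windows share ``overlap`` populations.  When the count does
    not divide evenly a final shorter window is appended and flagged.
    """
    if not set_size > overlap >= 0:
        raise ValidationError("need set_size > overlap >= 0")
    ordered = pops.sort_values("distance_km")
    ids = list(ordered["pop_id"])
    dist = ordered.set_index("pop_id")["distance_km"]
    n = len(ids)
    if n < set_size:
        raise ValidationError(f"need at least {set_size} populations, got {n}")
    step = set_size - overlap
    sets = []
    start = 0
    while start + set_size <= n:
        chunk = ids[start : start + set_size]
        sets.append(
            WindowSet(tuple(chunk), float(dist[list(chunk)].mean()), truncated=False)
        )
        start += step
    covered = start - step + set_size
    if covered < n:
        chunk = ids[covered - overlap :] if overlap else ids[covered:]
        sets.append(
            WindowSet(tuple(chunk), float(dist[list(chunk)].mean()), truncated=True)
        )
    return sets


def ohta_components(gamete_freqs: np.ndarray) -> OhtaDecomposition:
    """Decompose squared LD for one locus pair from per-subpop gamete tables.

    ``gamete_freqs`` has shape (n_subpops, n_alleles_locus1, n_alleles_locus2)
    and each subpopulation's table must sum to 1 (tolerance 1e-8).
    Subpopulations are weighted equally.
    """
    g = np.asarray(gamete_freqs, dtype=float)
    if g.ndim != 3 or g.shape[0] < 2:
        raise ValidationError("need per-subpop gamete tables for >= 2 subpops")
    sums = g.sum(axis=(1, 2))
    if np.any(np.abs(sums - 1.0) > 1e-8):
        raise ValidationError("gamete frequencies must sum to 1 per subpopulation")
    x = g.sum(axis=2)  # (S, A)
    y = g.sum(axis=1)  # (S, B)
    xy = x[:, :, None] * y[:, None, :]  # (S, A, B)
    xbar = x.mean(axis=0)
    ybar = y.mean(axis=0)
    gbar = g.mean(axis=0)
    xbyb = xbar[:, None] * ybar[None, :]
    d2_is = float(((g - xy) ** 2).sum(axis=(1, 2)).mean())
    d2_st = float(((xy - xbyb) ** 2).sum(axis=(1, 2)).mean())
    d2p_is = float(((g - gbar) ** 2).sum(axis=(1, 2)).mean())
    d2p_st = float(((gbar - xbyb) ** 2).sum())
    d2_it = float(((g - xbyb) ** 2).sum(axis=(1, 2)).mean())
    return OhtaDecomposition(d2_is, d2_st, d2p_is, d2p_st, d2_it, g.shape[0])


def em_gamete_freqs(dose1: np.ndarray, dose2: np.ndarray, n_iter: int = 50) -> np.ndarray:
    """2x2 gamete frequencies from unphased biallelic dosages by EM.

    Assumes random mating within the subpopulation; only double
    heterozygotes are ambiguous.  Missing dosages (negative) are dropped.
    """
    keep = (dose1 >= 0) & (dose2 >= 0)
    a, b = dose1[keep].astype(int), dose2[keep].astype(int)
    n = len(a)
    if n == 0:
        raise ValidationError("no jointly called individuals")
    p1 = a.mean() / 2.0
    q1 = b.mean() / 2.0
    p11 = p1 * q1  # freq of gamete (1, 1); start at linkage equilibrium
    n_dh = int(((a == 1) & (b == 1)).sum())
    # gamete counts from unambiguous genotypes; only the double heterozygote
    # (1, 1) leaves the gamete pair undetermined
    c = np.zeros((2, 2))
    for ai, bi in zip(a, b):
        if ai == 1 and bi == 1:
            continue
        if ai == 1:
            c[1, bi // 2] += 1
            c[0, bi // 2] += 1
        elif bi == 1:
            c[ai // 2, 1] += 1
            c[ai // 2, 0] += 1
        else:
            c[ai // 2, bi // 2] += 2
    for _ in range(n_iter):
        p10 = max(p1 - p11, 0.0)
        p01 = max(q1 - p11, 0.0)
        p00 = max(1.0 - p1 - q1 + p11, 0.0)
        denom = p11 * p00 + p10 * p01
        # E-step: a double het is (1,1)+(0,0) with prob w, else (1,0)+(0,1)
        w = p11 * p00 / denom if denom > 0 else 0.5
        p11_new = (c[1, 1] + n_dh * w) / (2.0 * n)
        if abs(p11_new - p11) < 1e-12:
            p11 = p11_new
            break
        p11 = p11_new
    p10 = max(p1 - p11, 0.0)
    p01 = max(q1 - p11, 0.0)
    p00 = max(1.0 - p11 - p10 - p01, 0.0)
    out = np.array([[p00, p01], [p10, p11]])
    return out / out.sum()


def _pair_components_phased(haps: list[np.ndarray], i_idx: np.ndarray, j_idx: np.ndarray):
    """Vectorised biallelic components for many pairs over phased subpops.

    ``haps`` is a list of (n_gametes, n_loci) 0/1 arrays, one per
    subpopulation.  Returns dict of component arrays of length n_pairs.
    """
    S = len(haps)
    P = len(i_idx)
    x1 = np.empty((S, P))
    y1 = np.empty((S, P))
    G = np.empty((2, 2, S, P))
    for k, hp in enumerate(haps):
        a = hp[:, i_idx].astype(float)
        b = hp[:, j_idx].astype(float)
        g11 = (a * b).mean(axis=0)
        ga = a.mean(axis=0)
        gb = b.mean(axis=0)
        x1[k] = ga
        y1[k] = gb
        G[1, 1, k] = g11
        G[1, 0, k] = ga - g11
        G[0, 1, k] = gb - g11
        G[0, 0, k] = 1.0 - ga - gb + g11
    X = np.stack([1.0 - x1, x1])  # (2, S, P)
    Y = np.stack([1.0 - y1, y1])
    XY = X[:, None, :, :] * Y[None, :, :, :]  # (2,2,S,P)
    Xb = X.mean(axis=1)  # (2, P)
    Yb = Y.mean(axis=1)
    XbYb = Xb[:, None, :] * Yb[None, :, :]  # (2,2,P)
    Gb = G.mean(axis=2)  # (2,2,P)
    d2_is = ((G - XY) ** 2).sum(axis=(0, 1)).mean(axis=0)
    d2_st = ((XY - XbYb[:, :, None, :]) ** 2).sum(axis=(0, 1)).mean(axis=0)
    d2p_is = ((G - Gb[:, :, None, :]) ** 2).sum(axis=(0, 1)).mean(axis=0)
    d2p_st = ((Gb - XbYb) ** 2).sum(axis=(0, 1))
    d2_it = ((G - XbYb[:, :, None, :]) ** 2).sum(axis=(0, 1)).mean(axis=0)
    return {
        "d2_is": d2_is,
        "d2_st": d2_st,
        "d2p_is": d2p_is,
        "d2p_st": d2p_st,
        "d2_it": d2_it,
    }


def pair_decomposition(
    g: GenotypeMatrix, pop_ids, locus_a: str, locus_b: str
) -> OhtaDecomposition:
    """Ohta decomposition for one locus pair over the given subpopulations.

    Uses true phase when the matrix carries haplotypes, otherwise per-subpop
    EM gamete-frequency estimates (random-mating assumption).
    """
    ia, ib = g.loci.index(locus_a), g.loci.index(locus_b)
    tables = []
    for pop in pop_ids:
        mask = g.pops == pop
        if not mask.any():
            continue
        if g.haplotypes is not None:
            hp = g.haplotypes[mask][:, :, [ia, ib]].reshape(-1, 2).astype(int)
            tab = np.zeros((2, 2))
            np.add.at(tab, (hp[:, 0], hp[:, 1]), 1.0)
            tables.append(tab / tab.sum())
        else:
            tables.append(em_gamete_freqs(g.genotypes[mask, ia], g.genotypes[mask, ib]))
    return ohta_components(np.stack(tables))


def dis_dst_profile(
    g: GenotypeMatrix,
    pops: pd.DataFrame,
    sets: list[WindowSet],
    loci: list[str],
    max_pairs: int = 50_000,
    seed: int = 0,
    ratio_of_means: bool = True,
) -> pd.DataFrame:
    """Mean D2_IS, D2_ST and their ratio per population window.

    Locus pairs among ``loci`` are uniformly subsampled (without replacement)
    to at most ``max_pairs`` with a seeded generator; pairs where either
    locus is monomorphic across the window's pooled gametes are dropped.
    Ratio = mean D2_IS / mean D2_ST (the stabler convention; set
    ``ratio_of_means=False`` for the mean of per-pair ratios), NaN when the
    denominator < 1e-12; windows with no polymorphic pair are omitted with a
    warning.
    """
    if g.haplotypes is None:
        raise ValidationError(
            "dis_dst_profile requires phase; estimate haplotypes first (em_gamete_freqs)"
        )
    locus_pos = np.array([g.loci.index(l) for l in loci])
    rng = np.random.default_rng(np.random.SeedSequence([seed, 21]))
    L = len(locus_pos)
    n_all = L * (L - 1) // 2
    iu = np.triu_indices(L, k=1)
    if n_all > max_pairs:
        pick = rng.choice(n_all, size=max_pairs, replace=False)
        i_idx, j_idx = iu[0][pick], iu[1][pick]
    else:
        i_idx, j_idx = iu
    rows = []
    for ws in sets:
        haps = []
        for pop in ws.pop_ids:
            mask = g.pops == pop
            if mask.any():
                haps.append(
                    g.haplotypes[mask][:, :, locus_pos].reshape(-1, len(locus_pos))
                )
        if len(haps) < 2:
            warnings.warn(f"window at {ws.midpoint_km:.0f} km has <2 sampled pops; omitted")
            continue
        pooled = np.concatenate(haps, axis=0)
        p = pooled.mean(axis=0)
        poly = (p > 0) & (p < 1)
        keep = poly[i_idx] & poly[j_idx]
        if not keep.any():
            warnings.warn(f"window at {ws.midpoint_km:.0f} km has no polymorphic pair; omitted")
            continue
        comp = _pair_components_phased(haps, i_idx[keep], j_idx[keep])
        mean_is = float(comp["d2_is"].mean())
        mean_st = float(comp["d2_st"].mean())
        if ratio_of_means:
            ratio = mean_is / mean_st if mean_st >= 1e-12 else np.nan
        else:
            ok = comp["d2_st"] >= 1e-12
            ratio = float((comp["d2_is"][ok] / comp["d2_st"][ok]).mean()) if ok.any() else np.nan
        rows.append(
            {
                "midpoint_km": ws.midpoint_km,
                "n_pairs": int(keep.sum()),
                "mean_D2_IS": mean_is,
                "mean_D2_ST": mean_st,
                "ratio": ratio,
            }
        )
    return pd.DataFrame(rows)


def bootstrap_neutral(
    g: GenotypeMatrix,
    pops: pd.DataFrame,
    sets: list[WindowSet],
    neutral_loci: list[str],
    n_sets: int = 20,
    set_size: int | None = None,
    max_pairs: int = 50_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """D_IS:D_ST profiles for bootstrap resamples of non-diagnostic loci.

    Each of ``n_sets`` resamples draws ``set_size`` loci with replacement
    (default: the size of the neutral panel).  Returns (per-replicate long
    table, across-replicate mean/sd per window midpoint).
    """
    if set_size is None:
        set_size = len(neutral_loci)
    if set_size > len(neutral_loci):
        warnings.warn("bootstrap set_size exceeds available loci; sampling with replacement")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 22]))
    frames = []
    for b in range(n_sets):
        chosen = list(
            pd.unique(rng.choice(np.asarray(neutral_loci, dtype=object), size=set_size, replace=True))
        )
        prof = dis_dst_profile(g, pops, sets, chosen, max_pairs=max_pairs, seed=int(rng.integers(2**31)))
        prof["replicate"] = b
        frames.append(prof)
    long = pd.concat(frames, ignore_index=True)
    agg = (
        long.groupby("midpoint_km")
        .agg(
            mean_ratio=("ratio", "mean"),
            sd_ratio=("ratio", "std"),
            mean_D2_IS=("mean_D2_IS", "mean"),
            mean_D2_ST=("mean_D2_ST", "mean"),
        )
        .reset_index()
    )
    return long, agg
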