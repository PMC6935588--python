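"""Synthetic hybrid-zone landscapes, genotypes and traits.

The generator emulates the statistical structure the downstream analyses
assume: ~34 populations of 3-10 trees arrayed south-to-north along a ~2,000 km
transect (southern parental species A, a central hybrid zone, northern
parental species B), thousands of biallelic SNPs of which a configurable
fraction are strongly divergent between the parental ranges, hybrid
individuals that are two-ancestry mosaics, and normally distributed traits
whose population means follow a sigmoid cline.

Ancestry mosaics are built without a linkage map: each individual draws an
admixture proportion q (Beta-distributed around the sigmoid expectation at its
position), then every haplotype copy of every locus draws its ancestry
independently as Bernoulli(q).  Variation of q among individuals inside a
population is what generates admixture linkage disequilibrium between
diagnostic loci.  Parental allele frequencies follow a Balding-Nichols-style
divergence model whose dispersion is controlled by ``fst_noise``.

Planting hooks (all off by default) let a known truth be embedded for
end-to-end validation: a fraction of divergent loci with excess speciesB
ancestry (positive genomic-cline alpha), fractions with locus-specific cline
centres displaced south or north of the genome-wide centre, and a
south-to-north gradient in within-population ancestry variance emulating the
elevated drift/recent-colonisation signal at an expanding front.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GROUPS, ConfigurationError, GenotypeMatrix
from .genocline import genomic_cline_phi


@dataclass
class SyntheticSpec:
    """Configuration of one synthetic data set.

    Counts and geometry default to the study-system scale: 5 + 16 + 13
    populations of 3-10 individuals on a 2,000 km transect, with a genetic
    cline at 1,500 km of width 150 km.  ``trait_defs`` rows are
    (name, parental mean A, parental mean B, within-population SD).
    """

    n_pops_speciesA: int = 5
    n_pops_hybrid: int = 16
    n_pops_speciesB: int = 13
    inds_per_pop_range: tuple[int, int] = (3, 10)
    n_loci: int = 2000
    frac_diagnostic: float = 0.10
    transect_extent_km: float = 2000.0
    trait_defs: list[tuple[str, float, float, float]] = field(
        default_factory=lambda: [("cone_length", 18.0, 9.0, 2.0), ("seed_weight", 0.28, 0.09, 0.04)]
    )
    cline_centre_km: float = 1500.0
    cline_width_km: float = 150.0
    fst_noise: float = 0.15
    seed: int = 0
    # trait cline location relative to the genetic cline (southward negative)
    trait_centre_offset_km: float = 0.0
    trait_width_km: float | None = 400.0
    # within-population ancestry concentration (Beta kappa), south -> north
    # across the hybrid band; equal values give no variance gradient
    ancestry_concentration: tuple[float, float] = (20.0, 20.0)
    # group bands as fractions of the transect (south, north edge per group);
    # the hybrid band must contain the cline centre for a resolvable cline
    band_fractions: tuple[tuple[float, float], ...] = ((0.0, 0.25), (0.30, 0.85), (0.90, 1.0))
    # planted truth among diagnostic loci (fractions of the diagnostic set):
    # introgressed loci carry excess speciesB ancestry in every admixed
    # individual via the genomic-cline map phi(q, alpha) -- a positive-alpha
    # plant whose signal lives in the hybrid-index dimension, fading at the
    # zone edges where individuals are effectively pure
    introgressed_frac: float = 0.0
    introgression_alpha: float = 0.8
    # alternative/additional plant: uniform-penetrance adaptive sweep, with an
    # optional northward sigmoid ramp (centre_km, width_km) and a northward
    # offset of the underlying ancestry sigmoid to keep the realised
    # frequency crossing on the genome-wide centre
    introgression_penetrance: float = 0.0
    penetrance_ramp: tuple[float, float] | None = None
    introgression_centre_shift_km: float = 0.0
    south_shift_frac: float = 0.0
    north_shift_frac: float = 0.0
    south_shift_km: float = 400.0
    north_shift_km: float = 200.0
    # fraction of individuals at the northern hybrid edge that are recent
    # lower-ancestry immigrants (the expanding-front signal: inflates
    # within-population ancestry variance, hence D2_IS, toward the north)
    front_immigrant_frac: float = 0.0
    front_immigrant_drop: float = 0.4

    def validate(self) -> None:
        if min(self.n_pops_speciesA, self.n_pops_hybrid, self.n_pops_speciesB) <= 0:
            raise ConfigurationError("every group needs at least one population")
        if not (0 < self.frac_diagnostic < 1):
            raise ConfigurationError("frac_diagnostic must be in (0, 1)")
        if not (0 < self.fst_noise < 1):
            raise ConfigurationError("fst_noise must be in (0, 1)")
        lo, hi = self.inds_per_pop_range
        if lo < 1 or hi < lo:
            raise ConfigurationError("invalid inds_per_pop_range")
        for name, ma, mb, sd in self.trait_defs:
            if ma == mb:
                raise ConfigurationError(f"parental means equal for trait {name}")
            if sd <= 0:
                raise ConfigurationError(f"trait SD must be > 0 ({name})")
        frac_sum = self.introgressed_frac + self.south_shift_frac + self.north_shift_frac
        if frac_sum > 1:
            raise ConfigurationError("planted locus fractions exceed the diagnostic set")


def _sigmoid(x, centre, width):
    return 0.5 * (1.0 + np.tanh(2.0 * (np.asarray(x, dtype=float) - centre) / width))


def generate_landscape(spec: SyntheticSpec) -> pd.DataFrame:
    """Place populations at strictly increasing latitude along the transect.

    Groups are ordered speciesA (south) -> hybrid -> speciesB (north); all
    populations share one meridian so great-circle distance is purely
    latitudinal (111.195 km per degree at R = 6371 km).
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    counts = (spec.n_pops_speciesA, spec.n_pops_hybrid, spec.n_pops_speciesB)
    n = sum(counts)
    km_per_deg = np.pi * 6371.0 / 180.0
    # populations evenly spaced (with jitter) inside each group's latitude
    # band; bands are ordered south to north with gaps between groups
    pos_parts = []
    for (lo, hi), cnt in zip(spec.band_fractions, counts):
        band = np.linspace(lo, hi, cnt) * spec.transect_extent_km
        if cnt > 1:
            step = band[1] - band[0]
            band = np.sort(band + rng.uniform(-0.3, 0.3, size=cnt) * step)
        pos_parts.append(band)
    pos = np.concatenate(pos_parts)
    pos = np.maximum.accumulate(pos) + np.arange(n) * 1e-6  # strictly increasing
    pos -= pos[0]
    lat0 = 20.0
    groups = (
        ["speciesA"] * spec.n_pops_speciesA
        + ["hybrid"] * spec.n_pops_hybrid
        + ["speciesB"] * spec.n_pops_speciesB
    )
    return pd.DataFrame(
        {
            "pop_id": [f"P{i + 1:02d}" for i in range(n)],
            "lat": lat0 + pos / km_per_deg,
            "lon": np.full(n, -105.0),
            "group": groups,
            "distance_km": pos,
        }
    )


def _parental_freqs(spec: SyntheticSpec, rng) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Balding-Nichols draws; diagnostic-truth loci get strongly diverged freqs."""
    L = spec.n_loci
    n_diag = int(round(spec.frac_diagnostic * L))
    is_diag = np.zeros(L, dtype=bool)
    is_diag[rng.choice(L, size=n_diag, replace=False)] = True
    F = spec.fst_noise
    shape = (1.0 - F) / F
    anc = rng.uniform(0.1, 0.9, size=L)
    pA = rng.beta(anc * shape, (1.0 - anc) * shape)
    pB = rng.beta(anc * shape, (1.0 - anc) * shape)
    # diagnostic-truth loci: near-fixed difference, oriented B-high
    pA[is_diag] = rng.beta(1.0, 30.0, size=n_diag)
    pB[is_diag] = rng.beta(30.0, 1.0, size=n_diag)
    return pA, pB, is_diag


def generate_genotypes(
    spec: SyntheticSpec, pops: pd.DataFrame
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Draw phased genotypes for every individual; return (matrix, locus truth).

    The truth table has one row per locus: parental frequencies, diagnostic
    flag and planted category (``neutral``, ``introgressed``, ``south`` or
    ``north``) with the locus-specific ancestry-cline centre.
    """
    spec.validate()
    if spec.n_loci < 10:
        raise ConfigurationError("n_loci must be >= 10 for a meaningful diagnostic quantile")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    pA, pB, is_diag = _parental_freqs(spec, rng)
    L = spec.n_loci

    # planted categories among the diagnostic-truth loci
    category = np.array(["neutral"] * L, dtype=object)
    diag_idx = np.flatnonzero(is_diag)
    n_diag = len(diag_idx)
    n_intro = int(round(spec.introgressed_frac * n_diag))
    n_south = int(round(spec.south_shift_frac * n_diag))
    n_north = int(round(spec.north_shift_frac * n_diag))
    perm = rng.permutation(diag_idx)
    category[perm[:n_intro]] = "introgressed"
    category[perm[n_intro : n_intro + n_south]] = "south"
    category[perm[n_intro + n_south : n_intro + n_south + n_north]] = "north"
    locus_centre = np.full(L, spec.cline_centre_km)
    locus_centre[category == "south"] -= spec.south_shift_km
    locus_centre[category == "north"] += spec.north_shift_km
    locus_centre[category == "introgressed"] += spec.introgression_centre_shift_km

    hyb_pos = pops.loc[pops["group"] == "hybrid", "distance_km"].to_numpy()
    hyb_lo = hyb_pos.min() if len(hyb_pos) else 0.0
    hyb_hi = hyb_pos.max() if len(hyb_pos) else spec.transect_extent_km
    k_s, k_n = spec.ancestry_concentration

    genos = []
    haps = []
    ind_ids: list[str] = []
    pop_ids: list[str] = []
    for _, row in pops.iterrows():
        n_ind = int(rng.integers(spec.inds_per_pop_range[0], spec.inds_per_pop_range[1] + 1))
        x = row["distance_km"]
        group = row["group"]
        if group == "speciesA":
            q_exp = 0.0
        elif group == "speciesB":
            q_exp = 1.0
        else:
            q_exp = float(_sigmoid(x, spec.cline_centre_km, spec.cline_width_km))
        # within-population spread of individual admixture proportions
        frac = 0.5 if hyb_hi <= hyb_lo else np.clip((x - hyb_lo) / (hyb_hi - hyb_lo), 0, 1)
        kappa = k_s + (k_n - k_s) * frac
        for i in range(n_ind):
            if group == "hybrid":
                # individual admixture spread only where admixture is active;
                # populations at the band edges are effectively pure and the
                # Beta tail would otherwise plant spurious F1-like outliers
                if 0.05 < q_exp < 0.95:
                    q = rng.beta(
                        max(q_exp * kappa, 1e-3), max((1.0 - q_exp) * kappa, 1e-3)
                    )
                else:
                    q = q_exp
                # recent southern-origin immigrants near the expanding front
                if spec.front_immigrant_frac > 0 and rng.random() < spec.front_immigrant_frac * frac:
                    q = max(q - spec.front_immigrant_drop, 0.02)
            else:
                q = q_exp
            # per-locus ancestry probability
            q_loc = np.full(L, q)
            shifted = (category == "south") | (category == "north")
            if spec.introgression_centre_shift_km != 0.0:
                shifted |= category == "introgressed"

            if group == "hybrid" and shifted.any():
                qs = _sigmoid(x, locus_centre[shifted], spec.cline_width_km)
                # blend locus cline with the individual's deviation from the
                # population expectation so individuals stay internally coherent
                dev = q - q_exp
                q_loc[shifted] = np.clip(qs + dev, 0.0, 1.0)
            intro = category == "introgressed"
            if group == "hybrid" and intro.any():
                if spec.introgression_penetrance > 0.0:
                    pi = spec.introgression_penetrance
                    if spec.penetrance_ramp is not None:
                        pi = pi * float(_sigmoid(x, *spec.penetrance_ramp))
                    q_loc[intro] = 1.0 - (1.0 - pi) * (1.0 - q_loc[intro])
                elif spec.introgression_alpha != 0.0:
                    q_loc[intro] = genomic_cline_phi(q_loc[intro], spec.introgression_alpha, 0.0)
            anc = rng.random((2, L)) < q_loc  # True = speciesB ancestry
            p = np.where(anc, pB, pA)
            h = (rng.random((2, L)) < p).astype(np.int8)
            haps.append(h)
            genos.append(h.sum(axis=0))
            ind_ids.append(f"{row['pop_id']}_i{i + 1}")
            pop_ids.append(row["pop_id"])
    gm = GenotypeMatrix(
        np.array(genos, dtype=np.int8),
        ind_ids,
        [f"snp{j + 1}" for j in range(L)],
        np.array(pop_ids, dtype=object),
        np.stack(haps, axis=0),
    )
    truth = pd.DataFrame(
        {
            "locus": gm.loci,
            "pA": pA,
            "pB": pB,
            "is_diagnostic": is_diag,
            "category": category,
            "centre_km": locus_centre,
        }
    ).set_index("locus")
    return gm, truth


def generate_traits(spec: SyntheticSpec, pops: pd.DataFrame) -> pd.DataFrame:
    """Per-population trait summaries along sigmoid clines between parental means.

    The trait cline centre is the genetic centre plus
    ``trait_centre_offset_km`` (negative = south, emulating a morphological
    cline lagging behind a northward-moved genetic cline); width defaults to
    ``trait_width_km``.  Individual values are Gaussian with the stated SD;
    summaries report the realised mean/SD/n.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 3]))
    centre = spec.cline_centre_km + spec.trait_centre_offset_km
    width = spec.trait_width_km or spec.cline_width_km
    rows = []
    for _, row in pops.iterrows():
        n = int(rng.integers(spec.inds_per_pop_range[0], spec.inds_per_pop_range[1] + 1))
        s = float(_sigmoid(row["distance_km"], centre, width))
        for name, ma, mb, sd in spec.trait_defs:
            mu = ma + (mb - ma) * s
            vals = rng.normal(mu, sd, size=n)
            rows.append(
                {
                    "pop_id": row["pop_id"],
                    "trait": name,
                    "mean": float(np.mean(vals)),
                    "sd": float(np.std(vals, ddof=1)) if n > 1 else sd,
                    "n": n,
                    "expected_mean": mu,
                }
            )
    return pd.DataFrame(rows)


def trait_cline_mean(spec: SyntheticSpec, x, trait_index: int = 0) -> np.ndarray:
    """Expected trait mean at position(s) x under the generating cline."""
    name, ma, mb, sd = spec.trait_defs[trait_index]
    centre = spec.cline_centre_km + spec.trait_centre_offset_km
    width = spec.trait_width_km or spec.cline_width_km
    return ma + (mb - ma) * _sigmoid(x, centre, width)


def frequency_cline_dataset(
    n_pops: int = 30,
    alleles_per_pop: int = 40,
    centre: float = 1500.0,
    width: float = 120.0,
    extent: float = 2000.0,
    seed: int = 0,
    flat_p: float | None = None,
):
    """Binomial allele counts on an even transect, from a clean cline (or a
    flat frequency when ``flat_p`` is given).  Returns (x, count, total)."""
    rng = np.random.default_rng(seed)
    x = np.linspace(0.0, extent, n_pops)
    p = np.full(n_pops, flat_p) if flat_p is not None else _sigmoid(x, centre, width)
    count = rng.binomial(alleles_per_pop, p)
    total = np.full(n_pops, alleles_per_pop)
    return x, count, total
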