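"""One-dimensional transect construction and diagnostic-SNP selection.

Populations sampled along a roughly latitudinal gradient are projected onto a
single axis: great-circle distance (haversine, R = 6371 km) from the
southernmost population.  Morphological sampling sites that do not coincide
with genetic sites are merged by averaging summaries within a small radius
(default 5 km, justified by pollen dispersal scales in pines).  Nearly
diagnostic SNPs are the loci in the upper tail of the absolute allele
frequency difference between the two pure parental groups.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, MISSING, ValidationError, validate_populations

EARTH_RADIUS_KM = 6371.0


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km on a sphere of radius 6371 km."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def great_circle_distances(pops: pd.DataFrame) -> pd.DataFrame:
    """Add ``distance_km``: great-circle distance from the southernmost population.

    The southernmost population is the one with minimum latitude (ties broken
    by minimum longitude); it receives distance 0 by construction.
    """
    pops = validate_populations(pops.copy())
    order = np.lexsort((pops["lon"].to_numpy(), pops["lat"].to_numpy()))
    south = pops.iloc[order[0]]
    pops["distance_km"] = haversine_km(
        south["lat"], south["lon"], pops["lat"].to_numpy(), pops["lon"].to_numpy()
    )
    pops.loc[pops.index[order[0]], "distance_km"] = 0.0
    return pops


def merge_within_radius(
    genetic_pops: pd.DataFrame,
    morph_pops: pd.DataFrame,
    morph_values: pd.DataFrame,
    radius_km: float = 5.0,
) -> pd.DataFrame:
    """Pair each genetic population with averaged morphological summaries.

    ``morph_values`` has one row per morphological population (``pop_id`` plus
    numeric summary columns).  All morphological populations within
    ``radius_km`` (inclusive boundary) of a genetic population are averaged;
    genetic populations with none in range are returned with NaN summaries and
    ``paired=False``.
    """
    validate_populations(genetic_pops)
    out_rows = []
    mlat = morph_pops["lat"].to_numpy()
    mlon = morph_pops["lon"].to_numpy()
    value_cols = [c for c in morph_values.columns if c != "pop_id"]
    morph_values = morph_values.set_index("pop_id")
    for _, g in genetic_pops.iterrows():
        d = haversine_km(g["lat"], g["lon"], mlat, mlon)
        near = morph_pops.loc[d <= radius_km, "pop_id"]
        row = {"pop_id": g["pop_id"], "n_morph_pops": len(near), "paired": len(near) > 0}
        if len(near):
            row.update(morph_values.loc[near, value_cols].mean().to_dict())
        else:
            row.update({c: np.nan for c in value_cols})
        out_rows.append(row)
    return pd.DataFrame(out_rows)


def group_allele_freqs(g: GenotypeMatrix, pop_groups: dict[str, str] | pd.Series) -> pd.DataFrame:
    """Per-group frequency of the counted allele at every locus.

    Frequencies are computed over non-missing genotypes with denominator
    2 x (non-missing individuals); a group with no calls at a locus gets NaN
    (flagged undefined, excluded downstream).
    """
    groups = np.array([pop_groups[p] for p in g.pops], dtype=object)
    out = {}
    geno = g.genotypes
    called = geno != MISSING
    for grp in pd.unique(groups):
        mask = groups == grp
        if not mask.any():
            continue
        counts = np.where(called[mask], geno[mask], 0).sum(axis=0)
        denom = 2.0 * called[mask].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[grp] = np.where(denom > 0, counts / np.maximum(denom, 1), np.nan)
    return pd.DataFrame(out, index=g.loci)


@dataclass
class DiagnosticSet:
    """Loci retained as nearly diagnostic between the parental groups."""

    table: pd.DataFrame  # locus, freqA, freqB, absdiff, retained
    quantile: float
    threshold: float

    @property
    def loci(self) -> list[str]:
        return list(self.table.index[self.table["retained"]])

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.index.name = "locus"
        out.to_csv(path, sep="\t")


def select_diagnostic(freqA: pd.Series, freqB: pd.Series, quantile: float = 0.90) -> DiagnosticSet:
    """Retain loci with |freqA - freqB| at or above the empirical quantile.

    The threshold is the type-7 (linear interpolation) quantile of |dp| over
    all loci with defined parental frequencies; ties at the threshold are kept.
    """
    if not 0.0 <= quantile <= 1.0:
        raise ValidationError("quantile must be in [0, 1]")
    freqA, freqB = freqA.align(freqB, join="inner")
    defined = freqA.notna() & freqB.notna()
    absdiff = (freqA - freqB).abs()
    if defined.sum() < 10:
        raise ValidationError("fewer than 10 loci with defined parental frequencies")
    threshold = float(np.quantile(absdiff[defined].to_numpy(), quantile))
    retained = defined & (absdiff >= threshold)
    table = pd.DataFrame(
        {"freqA": freqA, "freqB": freqB, "absdiff": absdiff, "retained": retained}
    )
    return DiagnosticSet(table=table, quantile=quantile, threshold=threshold)


def per_pop_counts(g: GenotypeMatrix, pops: pd.DataFrame, loci: list[str]) -> pd.DataFrame:
    """Long table of per-population allele counts for the given loci.

    Columns: locus, pop_id, distance_km, count (counted-allele copies over
    non-missing calls), total (2 x non-missing individuals).
    """
    sub = g.subset(locus_ids=loci)
    dist = pops.set_index("pop_id")["distance_km"]
    rows = []
    for pop in pops["pop_id"]:
        mask = g.pops == pop
        if not mask.any():
            continue
        geno = sub.genotypes[mask]
        called = geno != MISSING
        count = np.where(called, geno, 0).sum(axis=0)
        total = 2 * called.sum(axis=0)
        for j, locus in enumerate(sub.loci):
            rows.append(
                {
                    "locus": locus,
                    "pop_id": pop,
                    "distance_km": float(dist[pop]),
                    "count": int(count[j]),
                    "total": int(total[j]),
                }
            )
    return pd.DataFrame(rows)
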