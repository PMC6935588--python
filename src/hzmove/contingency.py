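"""Geographic x genomic cline classification and association testing.

Each nearly diagnostic SNP is classified along two axes: where its geographic
cline centre falls (inside the hybrid-index/Q-score centre interval, inside
the union of the morphological trait centre intervals, or neither — after
excluding loci whose best model is the no-cline null or whose centre exceeds
the transect length), and whether its genomic cline alpha marks it as a
positive outlier (excess speciesB ancestry), a negative outlier, or neither.
Association between the two classifications is tested with a Pearson 3x3
chi-square; per-cell percentage contributions to the statistic localise which
combinations drive it.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import ValidationError
from .geocline import TwoLLUInterval

GEO_CLASSES = ("overlap_Q", "overlap_morph", "neither")
ALPHA_CLASSES = ("positive", "negative", "none")
EXCLUDED = ("excluded_null", "excluded_offtransect")


@dataclass
class SnpClassification:
    locus: str
    geo_class: str
    alpha_class: str | None = None


def classify_geo(
    centre: float,
    null_best: bool,
    q_interval: TwoLLUInterval,
    morph_intervals: list[TwoLLUInterval],
    transect_length: float,
) -> str:
    """Classify one SNP's geographic cline centre.

    Exclusions first (null model won; centre beyond the transect length),
    then overlap with the Q-score centre interval, then with the union of
    morphological intervals.  A centre inside both (impossible when the Q and
    morph intervals are disjoint) is assigned to the nearer interval midpoint
    with a warning.
    """
    if null_best:
        return "excluded_null"
    if centre > transect_length:
        return "excluded_offtransect"
    in_q = q_interval.contains(centre)
    in_morph = any(iv.contains(centre) for iv in morph_intervals)
    if in_q and in_morph:
        warnings.warn(f"centre {centre:.1f} overlaps both Q and morph intervals")
        mid_q = 0.5 * (q_interval.low + q_interval.high)
        mids = [0.5 * (iv.low + iv.high) for iv in morph_intervals if iv.contains(centre)]
        mid_m = min(mids, key=lambda m: abs(m - centre))
        return "overlap_Q" if abs(centre - mid_q) <= abs(centre - mid_m) else "overlap_morph"
    if in_q:
        return "overlap_Q"
    if in_morph:
        return "overlap_morph"
    return "neither"


def build_table(classes: list[SnpClassification]) -> pd.DataFrame:
    """3x3 count table (geo classes x alpha classes); excluded loci dropped."""
    kept = [c for c in classes if c.geo_class in GEO_CLASSES]
    if not kept:
        raise ValidationError("no non-excluded loci to tabulate")
    table = pd.DataFrame(0, index=list(GEO_CLASSES), columns=list(ALPHA_CLASSES))
    for c in kept:
        if c.alpha_class not in ALPHA_CLASSES:
            raise ValidationError(f"locus {c.locus} lacks an alpha class")
        table.loc[c.geo_class, c.alpha_class] += 1
    return table


@dataclass
class ChisqResult:
    statistic: float
    df: int
    p_value: float
    contributions: pd.DataFrame  # percent of the statistic per cell
    deviations: pd.DataFrame  # sign of O - E per cell
    expected: pd.DataFrame


def chisq_with_contributions(table: pd.DataFrame | np.ndarray) -> ChisqResult:
    """Pearson chi-square (no continuity correction) with per-cell shares.

    Contribution of a cell = 100 * (O - E)^2 / E / X2; the sign of O - E
    indicates the direction of the deviation.  Any zero row/column total
    makes an expected count zero and raises.
    """
    obs = pd.DataFrame(table).astype(float)
    rowsum = obs.sum(axis=1)
    colsum = obs.sum(axis=0)
    total = float(obs.to_numpy().sum())
    if (rowsum <= 0).any() or (colsum <= 0).any():
        bad_r = list(rowsum.index[rowsum <= 0])
        bad_c = list(colsum.index[colsum <= 0])
        raise ValidationError(f"zero expected cells (rows {bad_r}, columns {bad_c})")
    expected = pd.DataFrame(
        np.outer(rowsum, colsum) / total, index=obs.index, columns=obs.columns
    )
    cells = (obs - expected) ** 2 / expected
    x2 = float(cells.to_numpy().sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(stats.chi2.sf(x2, df))
    contrib = 100.0 * cells / x2 if x2 > 0 else cells * 0.0
    signs = np.sign(obs - expected)
    return ChisqResult(x2, df, p, contrib, signs, expected)


def classify_all(
    geo_scan: pd.DataFrame,
    alpha_table: pd.DataFrame,
    q_interval: TwoLLUInterval,
    morph_intervals: list[TwoLLUInterval],
    transect_length: float,
) -> list[SnpClassification]:
    """Join a per-SNP geographic scan with genomic-cline outlier calls.

    ``geo_scan`` needs columns locus / centre / null_best (from
    ``geocline.scan_frequency_loci``); ``alpha_table`` needs locus /
    outlier_class (from ``genocline.estimate_alpha``).
    """
    alpha = alpha_table.set_index("locus")["outlier_class"]
    out = []
    for _, row in geo_scan.iterrows():
        geo = classify_geo(
            row["centre"], bool(row["null_best"]), q_interval, morph_intervals, transect_length
        )
        a = alpha.get(row["locus"])
        out.append(SnpClassification(row["locus"], geo, a if geo in GEO_CLASSES else None))
    return out
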