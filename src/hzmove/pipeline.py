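"""End-to-end orchestration of the hybrid-zone movement analysis.

Order of stages: transect construction -> diagnostic SNP selection -> hybrid
index -> geographic clines (traits, hybrid index, per-SNP) -> genomic clines
-> contingency -> Ohta D profile.  Every stage's outputs can be serialized to
an output directory together with a JSON manifest of parameters and seeds.
"""
from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import ConfigurationError, GenotypeMatrix, read_populations, read_traits
from .genocline import estimate_alpha, hybrid_index
from .geocline import (
    ClineFit,
    FreqClineData,
    ModelSpec,
    TraitClineData,
    centre_shift_km,
    fit_family,
    scan_frequency_loci,
)
from .ohtad import dis_dst_profile, window_sets
from .contingency import ChisqResult, build_table, chisq_with_contributions, classify_all
from .synthdata import SyntheticSpec, generate_genotypes, generate_landscape, generate_traits
from .transect import great_circle_distances, group_allele_freqs, per_pop_counts, select_diagnostic


@dataclass
class PipelineConfig:
    """Inputs and per-stage parameters for one pipeline run."""

    synthetic: SyntheticSpec | None = None
    genotypes_path: str | None = None
    populations_path: str | None = None
    traits_path: str | None = None
    out_dir: str | None = None
    seed: int = 0
    diagnostic_quantile: float = 0.90
    chain_len: int = 6000
    burnin: int = 1500
    n_chains: int = 2
    alpha_chain_len: int = 4000
    ohta_max_pairs: int = 5000
    window_size: int = 4
    window_overlap: int = 1
    run_ohta: bool = True
    run_genomic: bool = True

    def validate(self) -> None:
        if self.synthetic is None and self.genotypes_path is None:
            raise ConfigurationError("either a synthetic spec or input paths are required")
        if self.synthetic is None and (
            self.populations_path is None or self.traits_path is None
        ):
            raise ConfigurationError("real-data runs need genotype, population and trait files")


@dataclass
class PipelineResult:
    pops: pd.DataFrame
    diagnostic: object
    q_fit: ClineFit
    trait_fits: dict[str, ClineFit]
    snp_scan: pd.DataFrame
    alpha_table: pd.DataFrame | None
    table: pd.DataFrame | None
    chisq: ChisqResult | None
    ohta_profile: pd.DataFrame | None
    hybrid_indices: pd.DataFrame
    manifest: dict


def fit_trait_cline(
    df: pd.DataFrame, pops: pd.DataFrame, chain_len=6000, burnin=1500, n_chains=2, seed=0
) -> ClineFit:
    """Fit the 5-model trait family to one trait's per-population summaries.

    Decreasing traits (southern mean higher) are negated before fitting so the
    cline is non-decreasing; centre/width are unaffected by the sign flip.
    """
    merged = df.merge(pops[["pop_id", "distance_km"]], on="pop_id")
    south = merged.nsmallest(max(3, len(merged) // 4), "distance_km")["mean"].mean()
    north = merged.nlargest(max(3, len(merged) // 4), "distance_km")["mean"].mean()
    sign = 1.0 if north >= south else -1.0
    data = TraitClineData(
        merged["distance_km"].to_numpy(),
        sign * merged["mean"].to_numpy(),
        merged["sd"].to_numpy(),
        merged["n"].to_numpy(),
    )
    best, _ = fit_family(
        data, kind="trait", chain_len=chain_len, burnin=burnin, n_chains=n_chains, seed=seed
    )
    return best


class _PrefixPopMap:
    """Resolve an individual's population by '<pop_id>_' id prefix."""

    def __init__(self, pop_ids):
        self.pop_ids = sorted(pop_ids, key=len, reverse=True)

    def __getitem__(self, individual: str) -> str:
        for p in self.pop_ids:
            if individual.startswith(f"{p}_") or individual == p:
                return p
        raise KeyError(f"cannot assign individual {individual!r} to a population")


def load_genotype_file(path: str, pops: pd.DataFrame) -> GenotypeMatrix:
    """Read VCF or 0/1/2 TSV; individuals are mapped to populations by the
    '<pop_id>_' prefix of their sample ids."""
    mapping = _PrefixPopMap(pops["pop_id"])
    p = str(path)
    if p.endswith(".vcf") or p.endswith(".vcf.gz"):
        return GenotypeMatrix.from_vcf(p, mapping)
    return GenotypeMatrix.from_tsv(p, mapping)


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute the full analysis; returns in-memory results and writes files
    to ``cfg.out_dir`` when set."""
    cfg.validate()
    t0 = time.time()
    manifest: dict = {"version": __version__, "seed": cfg.seed, "stages": {}}

    # ---- inputs -----------------------------------------------------------
    if cfg.synthetic is not None:
        spec = cfg.synthetic
        pops = generate_landscape(spec)
        gm, truth = generate_genotypes(spec, pops)
        traits = generate_traits(spec, pops)
        manifest["input"] = {"synthetic": True, "n_loci": spec.n_loci}
    else:
        pops = read_populations(cfg.populations_path)
        traits = read_traits(cfg.traits_path)
        gm = load_genotype_file(cfg.genotypes_path, pops)
        manifest["input"] = {"synthetic": False, "genotypes": str(cfg.genotypes_path)}
    pops = great_circle_distances(pops)
    transect_length = float(pops["distance_km"].max())

    # ---- diagnostic selection --------------------------------------------
    pop_groups = pops.set_index("pop_id")["group"]
    freqs = group_allele_freqs(gm, pop_groups)
    diag = select_diagnostic(freqs["speciesA"], freqs["speciesB"], cfg.diagnostic_quantile)
    manifest["stages"]["diagnostic"] = {
        "threshold": diag.threshold,
        "n_retained": len(diag.loci),
    }

    # ---- hybrid index and Q cline ----------------------------------------
    # genome-wide hybrid index (the Q-score analogue uses ALL loci, not just
    # the nearly diagnostic subset); uninformative loci are dropped internally
    hi = hybrid_index(gm, freqs["speciesA"], freqs["speciesB"])
    hmean = hi.groupby("pop_id").agg(mean=("h", "mean"), sd=("h", "std"), n=("h", "size"))
    hmean = hmean.join(pops.set_index("pop_id")["distance_km"]).dropna()
    q_data = TraitClineData(
        hmean["distance_km"].to_numpy(),
        hmean["mean"].to_numpy(),
        np.maximum(hmean["sd"].fillna(0.02).to_numpy(), 0.02),
        hmean["n"].to_numpy(),
    )
    # the hybrid-index (Q-score) cline gets the full 15-model family: 5 tail
    # modes x 3 scaling modes, Gaussian likelihood on population means
    from .geocline import SCALING_MODES, TAIL_MODES

    q_specs = [ModelSpec("trait", t, s) for t in TAIL_MODES for s in SCALING_MODES]
    q_fit, _ = fit_family(
        q_data,
        kind="trait",
        specs=q_specs,
        chain_len=cfg.chain_len,
        burnin=cfg.burnin,
        n_chains=cfg.n_chains,
        seed=cfg.seed + 101,
    )

    # ---- trait clines -----------------------------------------------------
    trait_fits = {}
    for i, name in enumerate(sorted(traits["trait"].unique())):
        trait_fits[name] = fit_trait_cline(
            traits[traits["trait"] == name],
            pops,
            chain_len=cfg.chain_len,
            burnin=cfg.burnin,
            n_chains=cfg.n_chains,
            seed=cfg.seed + 201 + i,
        )
    manifest["stages"]["geoclines"] = {
        "q_centre": q_fit.model.centre if q_fit.model else None,
        "trait_centres": {k: f.model.centre for k, f in trait_fits.items() if f.model},
    }

    # ---- per-SNP geographic clines ---------------------------------------
    counts_long = per_pop_counts(gm, pops, diag.loci)
    piv_c = counts_long.pivot(index="locus", columns="pop_id", values="count")
    piv_t = counts_long.pivot(index="locus", columns="pop_id", values="total")
    dist = pops.set_index("pop_id").loc[piv_c.columns, "distance_km"].to_numpy()
    scan = scan_frequency_loci(
        dist,
        piv_c.to_numpy(),
        piv_t.to_numpy(),
        locus_ids=list(piv_c.index),
        chain_len=cfg.chain_len,
        burnin=cfg.burnin,
        n_chains=cfg.n_chains,
        seed=cfg.seed + 301,
    )

    # ---- genomic clines ---------------------------------------------------
    alpha_table = None
    table = None
    chisq = None
    if cfg.run_genomic:
        hyb_mask = gm.pop_mask(pops.loc[pops["group"] == "hybrid", "pop_id"])
        sub = gm.subset(individual_mask=hyb_mask, locus_ids=diag.loci)
        h_of = hi.set_index("individual")["h"]
        hvec = np.array([h_of[i] for i in sub.individuals])
        alpha_table = estimate_alpha(
            sub.genotypes.astype(float),
            hvec,
            locus_ids=sub.loci,
            chain_len=cfg.alpha_chain_len,
            seed=cfg.seed + 401,
        )
        q_iv = q_fit.intervals["centre"]
        morph_ivs = [f.intervals["centre"] for f in trait_fits.values()]
        classes = classify_all(scan, alpha_table, q_iv, morph_ivs, transect_length)
        try:
            table = build_table(classes)
            chisq = chisq_with_contributions(table)
        except Exception as e:  # degenerate margins on tiny runs
            warnings.warn(f"contingency table not testable: {e}")
        manifest["stages"]["contingency"] = {
            "chi2": None if chisq is None else chisq.statistic,
            "p": None if chisq is None else chisq.p_value,
        }

    # ---- Ohta D profile ---------------------------------------------------
    profile = None
    if cfg.run_ohta:
        sets = window_sets(pops, cfg.window_size, cfg.window_overlap)
        profile = dis_dst_profile(
            gm, pops, sets, diag.loci, max_pairs=cfg.ohta_max_pairs, seed=cfg.seed + 501
        )
        manifest["stages"]["ohta"] = {"n_windows": len(sets)}

    manifest["runtime_s"] = round(time.time() - t0, 2)

    result = PipelineResult(
        pops, diag, q_fit, trait_fits, scan, alpha_table, table, chisq, profile, hi, manifest
    )
    if cfg.out_dir:
        _write_outputs(cfg, result, gm, traits)
    return result


def _write_outputs(cfg: PipelineConfig, res: PipelineResult, gm: GenotypeMatrix, traits) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    res.pops.to_csv(out / "populations.csv", index=False)
    traits.to_csv(out / "traits.csv", index=False)
    gm.to_tsv(out / "genotypes.tsv")
    res.diagnostic.to_tsv(out / "diagnostic.tsv")
    res.snp_scan.to_csv(out / "snp_clines.tsv", sep="\t", index=False)
    res.hybrid_indices.to_csv(out / "hybrid_index.csv", index=False)
    if res.alpha_table is not None:
        res.alpha_table.to_csv(out / "genomic_clines.tsv", sep="\t", index=False)
    if res.ohta_profile is not None:
        res.ohta_profile.to_csv(out / "ohta_profile.csv", index=False)
    summary = {
        "q_centre": res.q_fit.model.centre,
        "q_interval": [res.q_fit.intervals["centre"].low, res.q_fit.intervals["centre"].high],
        "trait_fits": {
            k: {
                "centre": f.model.centre,
                "width": f.model.width,
                "interval": [f.intervals["centre"].low, f.intervals["centre"].high],
            }
            for k, f in res.trait_fits.items()
        },
        "centre_shift_km": centre_shift_km(
            res.q_fit.model.centre, [f.model.centre for f in res.trait_fits.values()]
        ),
    }
    if res.chisq is not None:
        summary["chi2"] = res.chisq.statistic
        summary["chi2_p"] = res.chisq.p_value
        summary["contingency"] = res.table.to_dict()
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    (out / "manifest.json").write_text(json.dumps(res.manifest, indent=2, default=float))
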