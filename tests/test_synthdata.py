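"""Synthetic landscape / genotype / trait generator."""
import numpy as np
import pandas as pd
import pytest

from hzmove.core import ConfigurationError
from hzmove.synthdata import (
    SyntheticSpec,
    frequency_cline_dataset,
    generate_genotypes,
    generate_landscape,
    generate_traits,
    trait_cline_mean,
)
from hzmove.transect import group_allele_freqs, select_diagnostic


class TestSpecValidation:
    def test_zero_populations_in_a_group(self):
        with pytest.raises(ConfigurationError):
            SyntheticSpec(n_pops_hybrid=0).validate()

    def test_degenerate_diagnostic_fraction(self):
        with pytest.raises(ConfigurationError):
            SyntheticSpec(frac_diagnostic=0.0).validate()

    def test_equal_parental_trait_means(self):
        with pytest.raises(ConfigurationError):
            SyntheticSpec(trait_defs=[("t", 5.0, 5.0, 1.0)]).validate()

    def test_nonpositive_trait_sd(self):
        with pytest.raises(ConfigurationError):
            SyntheticSpec(trait_defs=[("t", 1.0, 2.0, 0.0)]).validate()

    def test_too_few_loci_for_quantile(self):
        spec = SyntheticSpec(n_loci=5)
        pops = generate_landscape(SyntheticSpec())
        with pytest.raises(ConfigurationError):
            generate_genotypes(spec, pops)


class TestLandscape:
    def test_default_population_counts_and_order(self):
        pops = generate_landscape(SyntheticSpec())
        assert len(pops) == 34
        assert list(pops["group"].unique()) == ["speciesA", "hybrid", "speciesB"]
        assert pops["lat"].is_monotonic_increasing

    def test_minimal_one_pop_per_group(self):
        pops = generate_landscape(
            SyntheticSpec(n_pops_speciesA=1, n_pops_hybrid=1, n_pops_speciesB=1)
        )
        assert len(pops) == 3
        assert np.all(np.diff(pops["lat"]) > 0)

    def test_same_seed_is_identical(self):
        a = generate_landscape(SyntheticSpec(seed=9))
        b = generate_landscape(SyntheticSpec(seed=9))
        pd.testing.assert_frame_equal(a, b)


class TestGenotypes:
    def test_fixed_seed_fixes_every_byte(self):
        spec = SyntheticSpec(n_loci=100, seed=4)
        pops = generate_landscape(spec)
        g1, t1 = generate_genotypes(spec, pops)
        g2, t2 = generate_genotypes(spec, pops)
        np.testing.assert_array_equal(g1.genotypes, g2.genotypes)
        np.testing.assert_array_equal(g1.haplotypes, g2.haplotypes)
        pd.testing.assert_frame_equal(t1, t2)

    def test_parental_ancestry_at_diagnostic_loci(self):
        spec = SyntheticSpec(n_loci=400, seed=2)
        pops = generate_landscape(spec)
        gm, truth = generate_genotypes(spec, pops)
        diag = truth.index[truth["is_diagnostic"]]
        sub = gm.subset(locus_ids=list(diag))
        grp = pops.set_index("pop_id")["group"]
        groups = np.array([grp[p] for p in sub.pops])
        mean_a = sub.genotypes[groups == "speciesA"].mean() / 2.0
        mean_b = sub.genotypes[groups == "speciesB"].mean() / 2.0
        assert mean_a < 0.1 and mean_b > 0.9

    def test_diagnostic_filter_recovers_planted_truth(self):
        spec = SyntheticSpec(n_loci=2000, frac_diagnostic=0.1, seed=7)
        pops = generate_landscape(spec)
        gm, truth = generate_genotypes(spec, pops)
        freqs = group_allele_freqs(gm, pops.set_index("pop_id")["group"])
        ds = select_diagnostic(freqs["speciesA"], freqs["speciesB"], 0.90)
        true_set = set(truth.index[truth["is_diagnostic"]])
        recovered = len(set(ds.loci) & true_set) / len(true_set)
        assert recovered >= 0.90

    def test_hybrid_mosaics_carry_more_within_pop_ld_than_parentals(self):
        """Mean D2_IS between diagnostic pairs, averaged over 50 replicates."""
        from hzmove.ohtad import WindowSet, dis_dst_profile

        hyb_vals, par_vals = [], []
        for rep in range(50):
            spec = SyntheticSpec(
                n_loci=40,
                frac_diagnostic=0.5,
                n_pops_speciesA=2,
                n_pops_hybrid=4,
                n_pops_speciesB=2,
                inds_per_pop_range=(8, 8),
                cline_width_km=800.0,
                ancestry_concentration=(6.0, 6.0),
                seed=3000 + rep,
            )
            pops = generate_landscape(spec)
            gm, truth = generate_genotypes(spec, pops)
            diag = list(truth.index[truth["is_diagnostic"]])
            hyb_ids = tuple(pops.loc[pops["group"] == "hybrid", "pop_id"])
            par_ids = tuple(pops.loc[pops["group"] != "hybrid", "pop_id"])
            ph = dis_dst_profile(gm, pops, [WindowSet(hyb_ids, 0.0)], diag, max_pairs=60, seed=rep)
            pp = dis_dst_profile(gm, pops, [WindowSet(par_ids, 0.0)], diag, max_pairs=60, seed=rep)
            if len(ph) and len(pp):
                hyb_vals.append(ph["mean_D2_IS"].iloc[0])
                par_vals.append(pp["mean_D2_IS"].iloc[0])
        assert np.mean(hyb_vals) > 0
        assert np.mean(hyb_vals) > 2.0 * np.mean(par_vals)


class TestTraits:
    def test_centre_gives_parental_midpoint(self):
        spec = SyntheticSpec(trait_defs=[("t", 8.0, 12.0, 1.0)], cline_centre_km=1000.0)
        assert trait_cline_mean(spec, 1000.0) == pytest.approx(10.0)

    def test_tanh_displacement_example(self):
        spec = SyntheticSpec(
            trait_defs=[("t", 8.0, 12.0, 1.0)],
            cline_centre_km=1000.0,
            trait_width_km=400.0,
        )
        # 8 + 4 * (1 + tanh(1)) / 2
        assert trait_cline_mean(spec, 1200.0) == pytest.approx(11.523, abs=1e-3)

    def test_tiny_sd_pins_means_to_the_cline(self):
        spec = SyntheticSpec(
            trait_defs=[("t", 8.0, 12.0, 1e-9)], seed=1, inds_per_pop_range=(5, 5)
        )
        pops = generate_landscape(spec)
        traits = generate_traits(spec, pops)
        assert np.allclose(traits["mean"], traits["expected_mean"], atol=1e-6)

    def test_summaries_report_sample_sizes_in_range(self):
        spec = SyntheticSpec(seed=5)
        traits = generate_traits(spec, generate_landscape(spec))
        assert traits["n"].between(3, 10).all()
        assert set(traits["trait"]) == {"cone_length", "seed_weight"}


class TestFrequencyClineDataset:
    def test_deterministic_and_shaped(self):
        x1, k1, n1 = frequency_cline_dataset(seed=2)
        x2, k2, n2 = frequency_cline_dataset(seed=2)
        np.testing.assert_array_equal(k1, k2)
        assert len(x1) == 30 and (n1 == 40).all()

    def test_flat_option_has_no_gradient(self):
        x, k, n = frequency_cline_dataset(flat_p=0.4, seed=3, n_pops=50, alleles_per_pop=200)
        f = k / n
        lo, hi = f[:25].mean(), f[25:].mean()
        assert abs(hi - lo) < 0.05


class TestParameterRecovery:
    def test_cline_centre_recovered_from_generated_frequencies(self):
        """Fitting the cline to generated diagnostic frequencies covers the
        true centre within 2 LLU in >=90% of 20 replicate data sets."""
        from hzmove.geocline import FreqClineData, ModelSpec, fit_mcmc

        hits = 0
        for rep in range(20):
            spec = SyntheticSpec(
                n_pops_speciesA=5,
                n_pops_hybrid=20,
                n_pops_speciesB=5,
                inds_per_pop_range=(10, 10),
                n_loci=60,
                frac_diagnostic=0.5,
                cline_centre_km=1500.0,
                cline_width_km=300.0,
                band_fractions=((0.0, 0.15), (0.2, 0.9), (0.95, 1.0)),
                seed=500 + rep,
            )
            pops = generate_landscape(spec)
            gm, truth = generate_genotypes(spec, pops)
            diag = list(truth.index[truth["is_diagnostic"]])
            sub = gm.subset(locus_ids=diag)
            # mean diagnostic dose per population as a single frequency record
            counts, totals = [], []
            for p in pops["pop_id"]:
                d = sub.genotypes[sub.pops == p]
                counts.append(int(round(d.mean(axis=1).sum())))
                totals.append(2 * d.shape[0])
            data = FreqClineData(pops["distance_km"].to_numpy(), counts, totals)
            fit = fit_mcmc(
                ModelSpec("freq", "none", "fixed01"),
                data,
                chain_len=4000,
                burnin=1000,
                n_chains=2,
                seed=rep,
            )
            if fit.intervals["centre"].contains(1500.0):
                hits += 1
        assert hits >= 18
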