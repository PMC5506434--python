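import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crmarkers.consensus import PoissonBinomialNull, consensus_select
from crmarkers.diffexpr import strain_scan
from crmarkers.synthetic import (
    SimulationConfig,
    simulate_genesets,
    simulate_multistrain_study,
    simulate_qpcr_plate,
)


def null_config(seed, n_genes=3000):
    return SimulationConfig(
        n_strains=7, n_per_group=8, n_genes=n_genes, n_shared_effect=0,
        n_strain_specific=0, attenuated_strain_index=None, seed=seed,
    )


class TestMultistrainStudy:
    def test_same_seed_identical_output(self):
        cfg = SimulationConfig(n_genes=200, n_shared_effect=10, n_strain_specific=10, seed=42)
        s1, t1 = simulate_multistrain_study(cfg)
        s2, t2 = simulate_multistrain_study(cfg)
        pd.testing.assert_frame_equal(s1.values, s2.values)
        assert t1.shared_effect_genes == t2.shared_effect_genes
        assert t1.strain_specific_map == t2.strain_specific_map

    def test_design_shape_and_metadata(self):
        cfg = SimulationConfig(n_genes=100, n_shared_effect=5, n_strain_specific=5, seed=0)
        study, _ = simulate_multistrain_study(cfg)
        assert study.values.shape == (100, 7 * 2 * 8)
        counts = study.samples.groupby(["strain", "group"]).size()
        assert (counts == 8).all()
        assert study.samples["strain"].nunique() == 7

    def test_truth_partitions_genes(self):
        cfg = SimulationConfig(n_genes=500, n_shared_effect=20, n_strain_specific=30, seed=1)
        study, truth = simulate_multistrain_study(cfg)
        shared = set(truth.shared_effect_genes)
        specific = {g for m in truth.strain_specific_map.values() for g in m}
        nulls = set(truth.null_genes)
        assert shared | specific | nulls == set(study.genes)
        assert not (shared & specific) and not (shared & nulls) and not (specific & nulls)
        assert len(shared) == 20 and len(specific) == 30

    def test_null_per_strain_hit_fraction(self):
        study, _ = simulate_multistrain_study(null_config(seed=2, n_genes=4000))
        scan = strain_scan(study)
        fracs = scan.groupby("strain")["p_value"].apply(lambda p: (p < 0.01).mean())
        # 7 strains x 4000 genes; binomial MC error ~ 0.0016 per strain
        assert fracs.mean() == pytest.approx(0.01, abs=0.004)

    def test_attenuated_strain_has_smaller_effects(self):
        cfg = SimulationConfig(
            n_genes=400, n_shared_effect=100, n_strain_specific=0,
            noise_sd_log2=0.2, attenuated_strain_index=6, attenuation_factor=0.4, seed=3,
        )
        study, truth = simulate_multistrain_study(cfg)
        scan = strain_scan(study)
        shared = list(truth.shared_effect_genes)
        eff = scan[scan["gene"].isin(shared)].groupby("strain")["delta_log2"].apply(
            lambda d: np.abs(d).mean()
        )
        atten = eff["BALB/cJ"]
        others = eff.drop("BALB/cJ")
        assert atten == pytest.approx(0.4 * others.mean(), rel=0.15)

    def test_strain_specific_effect_confined_to_owner(self):
        cfg = SimulationConfig(
            n_genes=300, n_shared_effect=0, n_strain_specific=50,
            noise_sd_log2=0.2, attenuated_strain_index=None, seed=4,
        )
        study, truth = simulate_multistrain_study(cfg)
        scan = strain_scan(study).set_index(["gene", "strain"])
        for strain, genes in truth.strain_specific_map.items():
            for gene, fc in genes.items():
                assert scan.loc[(gene, strain), "delta_log2"] == pytest.approx(fc, abs=0.35)

    def test_heavy_tailed_noise_keeps_requested_sd(self):
        base = dict(n_genes=2000, n_shared_effect=0, n_strain_specific=0,
                    n_strains=1, n_per_group=8, attenuated_strain_index=None,
                    strain_offset_sd_log2=0.0, baseline_sd_log2=0.0, seed=5)
        gauss, _ = simulate_multistrain_study(SimulationConfig(**base))
        heavy, _ = simulate_multistrain_study(SimulationConfig(noise_df=4, **base))
        resid_g = gauss.values.sub(gauss.values.mean(axis=1), axis=0).to_numpy().ravel()
        resid_h = heavy.values.sub(heavy.values.mean(axis=1), axis=0).to_numpy().ravel()
        assert np.std(resid_h) == pytest.approx(np.std(resid_g), rel=0.1)
        # excess kurtosis distinguishes the t noise from Gaussian
        assert stats.kurtosis(resid_h) > stats.kurtosis(resid_g) + 0.5

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_genes=10, n_shared_effect=8, n_strain_specific=5).validate()
        with pytest.raises(ValueError):
            SimulationConfig(noise_sd_log2=0.0).validate()

    def test_null_consensus_counts_match_poisson_binomial(self):
        # the generator's central calibration: chance overlap across strains
        observed = {2: 0, 3: 0}
        expected = {2: 0.0, 3: 0.0}
        reps = 20
        for rep in range(reps):
            study, _ = simulate_multistrain_study(null_config(seed=100 + rep, n_genes=2000))
            scan = strain_scan(study)
            table = consensus_select(scan, alpha=0.01, k=2)
            null = PoissonBinomialNull.from_scan(scan, alpha=0.01)
            for k in observed:
                observed[k] += int((table["hit_count"] >= k).sum())
                expected[k] += null.expected_ge_k[k]
        for k in observed:
            bound = 4 * np.sqrt(expected[k]) + 2  # Poisson sampling slack
            assert abs(observed[k] - expected[k]) <= bound


class TestSimulatedGenesets:
    def test_same_seed_identical(self):
        genes = [f"g{i}" for i in range(500)]
        a = simulate_genesets(genes, n_sets=20, seed=9)
        b = simulate_genesets(genes, n_sets=20, seed=9)
        assert a.sets == b.sets

    def test_sizes_within_range(self):
        genes = [f"g{i}" for i in range(300)]
        coll = simulate_genesets(genes, n_sets=50, size_range=(5, 30), seed=10)
        sizes = [len(coll.members(s)) for s in coll]
        assert min(sizes) >= 5 and max(sizes) <= 30

    def test_factor_one_is_null(self):
        from crmarkers.enrichment import randomset_z

        rng = np.random.default_rng(11)
        genes = [f"g{i}" for i in range(1000)]
        selection = list(rng.choice(genes, 100, replace=False))
        zs = []
        for rep in range(40):
            coll = simulate_genesets(
                genes, n_sets=1, size_range=(40, 40),
                planted=(("SET:00000",), selection, 1.0), seed=200 + rep,
            )
            zs.append(randomset_z(genes, selection, coll)["z"].iloc[0])
        # planted-at-factor-1 z-scores behave like standard normal draws
        assert abs(np.mean(zs)) < 3 / np.sqrt(len(zs)) + 0.3
        assert 0.5 < np.std(zs) < 1.6

    def test_planted_enrichment_detected(self):
        from crmarkers.enrichment import randomset_z

        rng = np.random.default_rng(12)
        genes = [f"g{i}" for i in range(20_000)]
        selection = list(rng.choice(genes, 400, replace=False))
        # hypergeometric-moment oracle: weight 5 on 400 of 20k genes gives a
        # member probability of 2000/21600, so E[overlap] ~ 9.26 of 100 while
        # the null overlap has mean 2.0 and sd 1.40 -> E[z] ~ 5.2 with
        # per-replicate sampling sd ~ 2.1
        p_member = (400 * 5.0) / (400 * 5.0 + 19_600)
        mean0, sd0 = 100 * 400 / 20_000, np.sqrt(100 * 0.02 * 0.98 * 19_900 / 19_999)
        ez = (100 * p_member - mean0) / sd0
        zs = []
        for rep in range(10):
            coll = simulate_genesets(
                genes, n_sets=1, size_range=(100, 100),
                planted=(("SET:00000",), selection, 5.0), seed=300 + rep,
            )
            zs.append(randomset_z(genes, selection, coll)["z"].iloc[0])
        sd_z = np.sqrt(100 * p_member * (1 - p_member)) / sd0
        assert np.mean(zs) == pytest.approx(ez, abs=3 * sd_z / np.sqrt(len(zs)))
        assert sum(z > 4.34 for z in zs) >= 3  # detected in a majority-ish of reps

    def test_infeasible_sizes_rejected(self):
        with pytest.raises(ValueError):
            simulate_genesets(["g1", "g2"], n_sets=1, size_range=(3, 5))


class TestSimulatedQpcrPlate:
    panel = {"Scd4": -5.53, "Tfrc": 2.0, "Tuba8": 1.5}

    def test_same_seed_identical(self):
        a = simulate_qpcr_plate(self.panel, ["drugA"], seed=13)
        b = simulate_qpcr_plate(self.panel, ["drugA"], seed=13)
        pd.testing.assert_frame_equal(a, b)

    def test_plate_schema_and_reference_rows(self):
        plate = simulate_qpcr_plate(self.panel, ["drugA"], seed=14)
        assert set(plate.columns) == {"sample_id", "group", "gene", "ct", "is_reference"}
        per_sample_ref = plate[plate["is_reference"]].groupby("sample_id").size()
        assert (per_sample_ref == 3).all()  # three technical reps of the reference
        assert (plate["ct"] > 0).all()

    def test_inert_compound_rarely_significant(self):
        from crmarkers.crm_screen import ddct_fold_change
        from crmarkers.diffexpr import student_ttest

        sig = 0
        tests = 0
        for rep in range(10):
            plate = simulate_qpcr_plate(self.panel, ["inert"], concordant_map={},
                                        n_biological=4, seed=400 + rep)
            for gene in self.panel:
                _, dct_g, dct_c = ddct_fold_change(plate, gene, "compound:inert")
                _, p = student_ttest(dct_g, dct_c)
                tests += 1
                sig += p < 0.05
        assert sig / tests < 0.2  # nominal 5% plus MC slack

    def test_planted_concordant_gene_recovered(self):
        from crmarkers.crm_screen import classify_concordance, ddct_fold_change
        from crmarkers.diffexpr import student_ttest

        panel = {"Tfrc": 2.0}
        same = 0
        for rep in range(10):
            plate = simulate_qpcr_plate(
                panel, ["mimic"], concordant_map={"mimic": {"Tfrc": 2.0}},
                n_biological=8, noise_sd_biological=0.1, seed=500 + rep,
            )
            fold, dct_g, dct_c = ddct_fold_change(plate, "Tfrc", "compound:mimic")
            _, p = student_ttest(dct_g, dct_c)
            if classify_concordance(fold, p, 2.0) == "same":
                same += 1
        # planted 2-fold vs Ct noise 0.1 at n=8 -> essentially certain detection
        assert same >= 9
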