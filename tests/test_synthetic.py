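"""Generator contracts: determinism, similarity structure, prevalence,
NOAEL coupling and schema validity of the emitted tables."""

import numpy as np
import pytest
from scipy import stats

from oratox.dossier import SelectionRule, aggregate_dataset, studies_to_frame
from oratox.concordance import bulgheroni_table, noael_pairs
from oratox.synthetic import (
    ConfigError,
    GeneratorConfig,
    generate_acute_studies,
    generate_dossier,
    generate_fingerprints,
    generate_repeated_dose_studies,
    latent_toxicity,
)
from oratox.similarity import tanimoto_matrix


class TestConfig:
    def test_module_sizes_must_sum(self):
        with pytest.raises(ConfigError):
            GeneratorConfig(n_substances=10, n_modules=2, module_sizes=(4, 4))

    def test_default_sizes_partition(self):
        cfg = GeneratorConfig(n_substances=1059, n_modules=9)
        assert sum(cfg.module_sizes) == 1059
        assert len(cfg.module_sizes) == 9

    def test_infeasible_similarity_rejected(self):
        cfg = GeneratorConfig(n_substances=60, n_modules=2,
                              within_module_similarity=0.01)
        with pytest.raises(ConfigError, match="floor"):
            generate_fingerprints(cfg)


class TestFingerprints:
    def test_similarity_one_gives_identical_members(self):
        cfg = GeneratorConfig(seed=1, n_substances=40, n_modules=2,
                              within_module_similarity=1.0)
        subs = generate_fingerprints(cfg)
        F = np.array([s.fingerprint for s in subs])
        modules = cfg.module_assignment()
        for m in (0, 1):
            block = F[modules == m]
            assert (block == block[0]).all()
        # disjoint cores, no mutation: between-module similarity is 0
        sim = tanimoto_matrix(F)
        assert sim[modules == 0][:, modules == 1].max() == 0.0

    def test_deterministic_under_seed(self):
        cfg = GeneratorConfig(seed=7, n_substances=50, n_modules=3)
        a = generate_fingerprints(cfg)
        b = generate_fingerprints(cfg)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.fingerprint, rb.fingerprint)
            assert ra.descriptors == rb.descriptors
        c = generate_fingerprints(GeneratorConfig(seed=8, n_substances=50,
                                                  n_modules=3))
        assert any(
            not np.array_equal(ra.fingerprint, rc.fingerprint)
            for ra, rc in zip(a, c)
        )

    def test_within_similarity_meets_request(self):
        cfg = GeneratorConfig(seed=2, n_substances=120, n_modules=4,
                              within_module_similarity=0.9)
        F = np.array([s.fingerprint for s in generate_fingerprints(cfg)])
        modules = cfg.module_assignment()
        sim = tanimoto_matrix(F)
        iu, ju = np.triu_indices(len(F), k=1)
        same = modules[iu] == modules[ju]
        assert sim[iu, ju][same].mean() >= 0.9
        assert sim[iu, ju][~same].mean() < 0.7


class TestToxicityAssignment:
    def test_exact_prevalence_at_defaults(self):
        cfg = GeneratorConfig(seed=4)
        toxic, _ = latent_toxicity(cfg)
        assert toxic.sum() == 268
        assert len(toxic) == 1059
        assert abs(toxic.mean() - 0.253) < 0.02

    def test_full_clustering_makes_pure_toxic_modules(self):
        cfg = GeneratorConfig(seed=5, n_substances=200, n_modules=5,
                              clustering_strength=1.0)
        toxic, _ = latent_toxicity(cfg)
        modules = cfg.module_assignment()
        # a module that contains the first clustered toxicant is fully toxic
        full_modules = [
            m for m in range(5)
            if toxic[modules == m].all()
        ]
        assert full_modules  # at least one module is label-pure toxic

    def test_zero_clustering_independent_of_modules(self):
        # chi-squared independence: labels vs module id, 20 seeds
        rejections = 0
        for seed in range(20):
            cfg = GeneratorConfig(seed=seed, n_substances=1000, n_modules=5,
                                  clustering_strength=0.0)
            toxic, _ = latent_toxicity(cfg)
            modules = cfg.module_assignment()
            table = np.array([
                [np.sum(toxic & (modules == m)), np.sum(~toxic & (modules == m))]
                for m in range(5)
            ])
            _, p, _, _ = stats.chi2_contingency(table)
            rejections += p < 0.01
        assert rejections <= 2  # alpha = 0.01 under the null


class TestAcuteStudies:
    def test_tables_pass_schema_checks(self, tmp_path):
        from oratox.dossier import read_study_table, write_study_table

        cfg = GeneratorConfig(seed=6, n_substances=80, n_modules=4)
        d = generate_dossier(cfg)
        path = tmp_path / "studies.csv"
        write_study_table(d.acute_studies + d.repeated_studies, path)
        records = read_study_table(path)
        assert len(records) == len(d.acute_studies) + len(d.repeated_studies)

    def test_every_substance_has_klimisch1_key_study(self):
        cfg = GeneratorConfig(seed=6, n_substances=80, n_modules=4)
        subs = generate_fingerprints(cfg)
        studies = generate_acute_studies(subs, cfg)
        frame = studies_to_frame(studies)
        key1 = frame[(frame["klimisch"] == 1) & frame["key_study"]]
        assert set(key1["substance_id"]) == {s.substance_id for s in subs}

    def test_aggregated_labels_match_latent_classes(self):
        cfg = GeneratorConfig(seed=10)
        subs = generate_fingerprints(cfg)
        studies = generate_acute_studies(subs, cfg)
        agg = aggregate_dataset(studies, SelectionRule(max_klimisch=1))
        toxic, _ = latent_toxicity(cfg)
        labels = (agg["mean_value"] < 2000).to_numpy()
        assert labels.sum() == 268  # class preserved through noise + snapping

    def test_dose_grid_pileups_present(self):
        cfg = GeneratorConfig(seed=12)
        subs = generate_fingerprints(cfg)
        frame = studies_to_frame(generate_acute_studies(subs, cfg))
        # a continuous LD50 law would put zero mass on exact grid values
        at_2000 = (frame["value"] == 2000.0).mean()
        at_5000 = (frame["value"] == 5000.0).mean()
        assert at_2000 > 0.05
        assert at_5000 > 0.02
        censored = frame[frame["value"] == 2000.0]["qualifier"]
        assert (censored == "greater_equal").any()


class TestRepeatedDose:
    def test_perfect_correlation_no_shift_equal_pairs(self):
        cfg = GeneratorConfig(seed=1, n_substances=50, n_modules=2,
                              noael_correlation=1.0, shift_90d_log10=0.0,
                              discordant_fraction=0.0)
        subs = generate_fingerprints(cfg)
        pairs = noael_pairs(generate_repeated_dose_studies(subs, cfg))
        assert np.allclose(pairs["noael28"], pairs["noael90"])

    def test_discordant_fraction_binomial(self):
        cfg = GeneratorConfig(seed=2, n_substances=1000, n_modules=4,
                              discordant_fraction=0.05,
                              discordant_factor=10.0)
        subs = generate_fingerprints(cfg)
        pairs = noael_pairs(generate_repeated_dose_studies(subs, cfg))
        # injected pairs carry exactly the discordance factor
        injected = np.isclose(pairs["noael90"], 10.0 * pairs["noael28"],
                              rtol=1e-9)
        n_discordant = int(injected.sum())
        # Binomial(1000, 0.05): mean 50, sd ~6.9
        assert 25 <= n_discordant <= 75

    def test_npv_calibration(self):
        cfg = GeneratorConfig(seed=11, n_substances=5000, n_modules=5)
        subs = generate_fingerprints(cfg)
        rep = generate_repeated_dose_studies(subs, cfg)
        res = bulgheroni_table(rep, scope="all")
        assert res.npv_pct == pytest.approx(94.5, abs=2.0)
        assert res.ppv_pct == pytest.approx(33.7, abs=3.0)

    def test_90d_marginal_shifted_low(self):
        cfg = GeneratorConfig(seed=3, n_substances=800, n_modules=4)
        subs = generate_fingerprints(cfg)
        pairs = noael_pairs(generate_repeated_dose_studies(subs, cfg))
        assert np.log10(pairs["noael90"]).mean() < np.log10(pairs["noael28"]).mean()


class TestDeterminismAndNull:
    def test_streams_are_independent(self):
        # adding/removing a later stage never perturbs earlier artifacts
        cfg = GeneratorConfig(seed=13, n_substances=40, n_modules=2)
        a = generate_fingerprints(cfg)
        generate_repeated_dose_studies(a, cfg)  # consume the repeated stream
        b = generate_fingerprints(cfg)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.fingerprint, rb.fingerprint)

    def test_null_generator_gives_chance_knn_bac(self):
        # clustering_strength 0: no hidden leakage, KNN BAC ~ 0.5
        from oratox.evaluation import confusion
        from oratox.knn import knn_feature_column

        bacs = []
        for seed in range(20):
            cfg = GeneratorConfig(seed=seed, n_substances=1000, n_modules=5,
                                  clustering_strength=0.0)
            subs = generate_fingerprints(cfg)
            F = np.array([s.fingerprint for s in subs])
            ids = [s.substance_id for s in subs]
            y, _ = latent_toxicity(cfg)
            pred = knn_feature_column(F, ids, y)["knn"].to_numpy().astype(bool)
            bacs.append(confusion(y, pred).bac)
        assert np.mean(bacs) == pytest.approx(50.0, abs=5.0)
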