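"""Forward simulator: determinism, diagnosticity, mutation model, recovery."""

from __future__ import annotations

import numpy as np
import pytest

import satclone as sc
from satclone.simulate import SimConfig, simulate_dataset


def small_config(**kw):
    base = dict(
        n_loci=2, tracts_per_locus=1, n_diagnostic_snps_per_locus=1,
        maternal_allele_counts=2, paternal_allele_counts=2,
        n_origins=1, n_demes=2, deme_sizes=20, generations=5,
        mu=0.01, migration_rate=0.0, sample_sizes=5, seed=0, panel_size=10,
    )
    base.update(kw)
    return SimConfig(**base)


def _genome_keys(cohort):
    return [
        tuple(
            ind.genotypes[l].allele_multiset() for l in cohort.locus_names
        )
        for ind in cohort.individuals
    ]


class TestConfigValidation:
    def test_sample_larger_than_deme_rejected(self):
        with pytest.raises(sc.SatcloneError):
            small_config(deme_sizes=5, sample_sizes=10)

    def test_bad_rates_rejected(self):
        with pytest.raises(sc.SatcloneError):
            small_config(mu=1.5)
        with pytest.raises(sc.SatcloneError):
            small_config(migration_rate=-0.1)

    def test_config_file_round_trip(self, tmp_path):
        cfg = small_config(deme_sizes=[20, 30], sample_sizes=[4, 6], mu=0.02)
        path = tmp_path / "sim.cfg"
        cfg.to_file(path)
        assert SimConfig.from_file(path) == cfg


class TestParentalPools:
    def test_diagnostic_states_separate_species(self):
        maternal, paternal = sc.simulate_parental_pools(small_config(seed=4))
        mat_cat = sc.catalog_from_cohort(maternal)
        pat_cat = sc.catalog_from_cohort(paternal)
        for locus in mat_cat:
            diag = sc.diagnostic_sites(locus, mat_cat, pat_cat)
            assert len(diag) >= 1

    def test_single_allele_locus_monomorphic(self):
        cfg = small_config(maternal_allele_counts=[1, 2], seed=9)
        maternal, _ = sc.simulate_parental_pools(cfg)
        mat_cat = sc.catalog_from_cohort(maternal)
        assert len(mat_cat["L1"]) == 1
        for ind in maternal.individuals:
            g = ind.genotypes["L1"]
            assert g.alleles[0] == g.alleles[1]

    def test_panels_deterministic_under_seed(self, tmp_path):
        import satclone.io as sio

        cfg = small_config(seed=11)
        for run in ("a", "b"):
            maternal, paternal = sc.simulate_parental_pools(cfg)
            sio.write_genotype_table(maternal, tmp_path / f"m_{run}.tsv")
            sio.write_genotype_table(paternal, tmp_path / f"p_{run}.tsv")
        assert (tmp_path / "m_a.tsv").read_text() == (tmp_path / "m_b.tsv").read_text()
        assert (tmp_path / "p_a.tsv").read_text() == (tmp_path / "p_b.tsv").read_text()


class TestHybridOrigins:
    def test_founder_alleles_come_from_catalogs(self):
        cfg = small_config(n_origins=3, n_demes=3, maternal_allele_counts=3,
                           origin_distinguishing=True, seed=2)
        maternal, paternal = sc.simulate_parental_pools(cfg)
        mat_cat = sc.catalog_from_cohort(maternal)
        pat_cat = sc.catalog_from_cohort(paternal)
        founders = sc.simulate_hybrid_origins(maternal, paternal, cfg)
        assert len(founders) == 3
        for genome in founders:
            for (mat, pat), locus in zip(genome, cfg.loci()):
                assert any(a == mat for a in mat_cat[locus.name])
                assert any(a == pat for a in pat_cat[locus.name])

    def test_distinguishing_founders_have_distinct_maternal_sides(self):
        cfg = small_config(n_origins=2, maternal_allele_counts=2,
                           origin_distinguishing=True, seed=3)
        maternal, paternal = sc.simulate_parental_pools(cfg)
        f1, f2 = sc.simulate_hybrid_origins(maternal, paternal, cfg)
        assert any(a[0] != b[0] for a, b in zip(f1, f2))

    def test_too_few_maternal_alleles_rejected(self):
        cfg = small_config(n_origins=5, n_demes=5, maternal_allele_counts=2,
                           origin_distinguishing=True)
        maternal, paternal = sc.simulate_parental_pools(cfg)
        with pytest.raises(sc.SatcloneError):
            sc.simulate_hybrid_origins(maternal, paternal, cfg)


class TestClonalEvolution:
    def test_no_mutation_single_origin_one_clone(self):
        cfg = small_config(mu=0.0, seed=5)
        _, _, cohort, truth = simulate_dataset(cfg)
        assert truth.true_clone_count == 1
        assert len(set(_genome_keys(cohort))) == 1

    def test_no_mutation_clone_count_equals_origins_over_seeds(self):
        for seed in range(20):
            cfg = small_config(
                mu=0.0, n_origins=2, n_demes=2, maternal_allele_counts=2,
                origin_distinguishing=True, seed=seed,
            )
            _, _, cohort, truth = simulate_dataset(cfg)
            assert truth.true_clone_count == 2
            assert len(set(_genome_keys(cohort))) == 2

    def test_sample_size_conserved(self):
        cfg = small_config(n_demes=3, deme_sizes=[10, 20, 30],
                           sample_sizes=[3, 5, 7], seed=6)
        _, _, cohort, truth = simulate_dataset(cfg)
        assert len(cohort) == 15
        assert len(truth.lineage) == 15
        assert {ind.population for ind in cohort.individuals} == {
            "deme1", "deme2", "deme3"
        }

    def test_every_individual_maps_to_one_origin(self):
        cfg = small_config(n_origins=2, n_demes=2, maternal_allele_counts=2,
                           origin_distinguishing=True, seed=7, mu=0.05)
        _, _, cohort, truth = simulate_dataset(cfg)
        for ind in cohort.individuals:
            origin, events = truth.lineage[ind.individual_id]
            assert origin in (0, 1)

    def test_end_to_end_determinism(self, tmp_path):
        import satclone.io as sio

        cfg = small_config(mu=0.05, migration_rate=0.1, seed=13)
        outputs = []
        for run in ("a", "b"):
            _, _, cohort, truth = simulate_dataset(cfg)
            path = tmp_path / f"{run}.tsv"
            sio.write_genotype_table(cohort, path)
            truth.write(tmp_path / run)
            outputs.append(
                path.read_text()
                + (tmp_path / run / "truth_lineage.tsv").read_text()
            )
        assert outputs[0] == outputs[1]

    def test_all_simulated_alleles_phaseable(self):
        for seed in (1, 2, 3):
            cfg = small_config(mu=0.1, migration_rate=0.05, seed=seed)
            maternal, paternal, cohort, _ = simulate_dataset(cfg)
            phased = sc.phase_cohort(
                cohort, sc.catalog_from_cohort(maternal), sc.catalog_from_cohort(paternal)
            )
            assert len(phased.failures) == 0

    def test_recorded_mutation_events_explain_genotypes(self):
        cfg = small_config(mu=0.2, generations=4, seed=8, tract_length_range=(30, 30))
        _, _, cohort, truth = simulate_dataset(cfg)
        founder = truth.founder_genotypes[0]
        saw_mutant = False
        for ind in cohort.individuals:
            _, events = truth.lineage[ind.individual_id]
            # replay the recorded events on the founder genotype
            expected = {
                locus: {"maternal": dict(pair[0].tract_lengths),
                        "paternal": dict(pair[1].tract_lengths)}
                for locus, pair in zip(cohort.locus_names, founder)
            }
            for _, locus, side, tract, delta in events:
                expected[locus][side][tract] += delta
                saw_mutant = True
            for idx, locus in enumerate(cohort.locus_names):
                observed = sorted(
                    tuple(sorted(a.tract_lengths.items()))
                    for a in ind.genotypes[locus].alleles
                )
                replayed = sorted(
                    tuple(sorted(expected[locus][side].items()))
                    for side in ("maternal", "paternal")
                )
                assert observed == replayed
        assert saw_mutant

    def test_unbiased_random_walk_matches_monte_carlo_oracle(self):
        """Mean |tract deviation| after G generations ≈ direct ±1-walk oracle."""
        mu, gens = 0.05, 40
        # oracle: simulate the marginal walk directly
        rng = np.random.default_rng(77)
        steps = rng.random((20000, gens)) < mu
        signs = rng.integers(0, 2, size=(20000, gens)) * 2 - 1
        walks = np.abs((steps * signs).sum(axis=1))
        oracle_mean = walks.mean()
        oracle_se = walks.std(ddof=1) / np.sqrt(len(walks))

        # one tract, one locus; mutation hits one of the two allele sides
        per_sim_means = []
        for seed in range(25):
            cfg = SimConfig(
                n_loci=1, tracts_per_locus=1, maternal_allele_counts=1,
                paternal_allele_counts=1, n_origins=1, n_demes=1,
                deme_sizes=400, generations=gens, mu=2 * mu,  # per-locus rate, split over sides
                migration_rate=0.0, sample_sizes=25, seed=seed, panel_size=5,
                tract_length_range=(60, 60),
            )
            _, _, cohort, truth = simulate_dataset(cfg)
            founder = truth.founder_genotypes[0][0]
            f_lengths = sorted(a.tract_lengths["t1"] for a in founder)
            devs = []
            for ind in cohort.individuals:
                lengths = sorted(
                    a.tract_lengths["t1"] for a in ind.genotypes["L1"].alleles
                )
                devs.extend(abs(l - f) for l, f in zip(lengths, f_lengths))
            per_sim_means.append(np.mean(devs))
        sim_mean = float(np.mean(per_sim_means))
        sim_se = float(np.std(per_sim_means, ddof=1) / np.sqrt(len(per_sim_means)))
        assert abs(sim_mean - oracle_mean) < 3 * (sim_se + oracle_se)
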