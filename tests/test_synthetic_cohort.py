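"""Synthetic cohort generator: determinism, planted structure, emission model."""

import filecmp

import numpy as np
import pandas as pd
import pytest

from smorfval import smorf_catalog as cat, variant_effects as ve
from smorfval import synthetic_cohort as sc
from smorfval._seq import translate
from smorfval.constraint_model import MutationRateTable
from smorfval.errors import ConfigurationError, GenerationError


def tiny_cfg(**kw):
    defaults = dict(
        genome_length=60_000,
        n_genes=6,
        n_smorfs=20,
        n_array_snvs=300,
        n_gwas_snvs=80,
        seed=3,
    )
    defaults.update(kw)
    return sc.SimulationConfig(**defaults)


class TestGenerateGenome:
    def test_deterministic_given_seed(self):
        cfg = sc.SimulationConfig(genome_length=1000, seed=1)
        g1 = sc.generate_genome(cfg)
        g2 = sc.generate_genome(cfg)
        assert g1.sequence(cfg.chrom) == g2.sequence(cfg.chrom)

    def test_gc_one_gives_only_gc(self):
        cfg = sc.SimulationConfig(genome_length=500, gc_content=1.0, seed=0)
        seq = sc.generate_genome(cfg).sequence(cfg.chrom)
        assert set(seq) <= {"G", "C"}

    def test_gc_content_within_binomial_bound(self):
        cfg = sc.SimulationConfig(genome_length=100_000, gc_content=0.41, seed=2)
        seq = sc.generate_genome(cfg).sequence(cfg.chrom)
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert 0.39 <= gc <= 0.43

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ConfigurationError):
            sc.SimulationConfig(genome_length=0)


@pytest.fixture(scope="module")
def planted():
    cfg = tiny_cfg()
    rng = np.random.default_rng(cfg.seed)
    genome = sc.generate_genome(cfg, rng)
    return cfg, genome, sc.plant_orfs(cfg, genome, rng)


class TestPlantOrfs:
    def test_every_smorf_is_a_valid_orf(self, planted):
        cfg, genome, plant = planted
        for ent in plant.smorfs:
            prot = translate(ve.spliced_sequence(ent.model, genome))
            assert prot.startswith("M")
            assert prot.endswith("*")
            assert "*" not in prot[:-1]
            assert 10 <= ent.model.aa_length <= 150

    def test_minus_strand_spliced_sequence_begins_atg(self, planted):
        cfg, genome, plant = planted
        minus = [e for e in plant.smorfs if e.model.strand == "-"]
        assert minus, "expected some minus-strand entities"
        for ent in minus:
            assert ve.spliced_sequence(ent.model, genome).startswith("ATG")

    def test_sharing_classes_partition_smorfs(self, planted):
        cfg, _, plant = planted
        counts = pd.Series([e.sharing_class for e in plant.smorfs]).value_counts()
        assert counts.sum() == cfg.n_smorfs
        assert set(counts.index) <= {"exact", "jitter", "unique_a", "unique_b"}

    def test_prediction_sets_reflect_sharing(self, planted):
        cfg, _, plant = planted
        rep = cat.intersect_datasets(plant.predictions_a, plant.predictions_b)
        n_exact = sum(1 for e in plant.smorfs if e.sharing_class == "exact")
        n_jit = sum(1 for e in plant.smorfs if e.sharing_class == "jitter")
        assert rep.n_exact == n_exact
        assert len(rep.imperfect_a) == n_jit

    def test_fraction_shared_zero_gives_empty_intersection(self):
        cfg = tiny_cfg(fraction_exact=0.0, fraction_jitter=0.0, seed=5)
        rng = np.random.default_rng(cfg.seed)
        genome = sc.generate_genome(cfg, rng)
        plant = sc.plant_orfs(cfg, genome, rng)
        rep = cat.intersect_datasets(plant.predictions_a, plant.predictions_b)
        assert rep.n_exact == 0 and len(rep.imperfect_pairs) == 0

    def test_overfull_genome_raises(self):
        cfg = tiny_cfg(genome_length=2_000, n_smorfs=50)
        rng = np.random.default_rng(0)
        genome = sc.generate_genome(cfg, rng)
        with pytest.raises(GenerationError):
            sc.plant_orfs(cfg, genome, rng)


class TestSimulatePopulationVariants:
    def test_full_depletion_removes_class(self):
        cfg = tiny_cfg(
            selection_profile=sc.SelectionProfile(
                smorf_constrained_fraction=1.0, f_mis_constrained=0.0,
                f_lof_constrained=0.0,
            ),
            n_genes=0,
            seed=9,
        )
        co = sc.simulate_cohort(cfg, with_conservation=False, with_gwas=False)
        for ent in co.plant.smorfs:
            obs = ve.tabulate_observed(ent.model, co.genome, co.variants, maf_max=1.1)
            assert obs.n_mis == 0
            assert obs.per_class["stop_gain"] == 0

    def test_neutral_pooled_oe_near_one(self, neutral_cohort):
        """With no thinning, pooled observed/expected missense over all
        entities sits in [0.9, 1.1] (direct count oracle, expectation >> 1000)."""
        co = neutral_cohort
        from smorfval import constraint_model as cm

        total_obs, total_exp = 0, 0.0
        k = co.cfg.emission_constant
        for ent in co.plant.entities:
            obs = ve.tabulate_observed(ent.model, co.genome, co.variants)
            mu = cm.possible_mu_by_class(
                ent.model, co.genome, co.rate_table, co.methylation
            )
            total_obs += obs.n_mis
            total_exp += k * (mu[ve.MISSENSE] + mu[ve.STOP_LOSS])
        assert total_exp > 1000
        assert 0.9 <= total_obs / total_exp <= 1.1

    def test_doubling_sample_size_doubles_observation_rate(self):
        base = tiny_cfg(n_genes=0, n_smorfs=10, genome_length=30_000, seed=21,
                        n_genomes=10_000)
        double = tiny_cfg(n_genes=0, n_smorfs=10, genome_length=30_000, seed=21,
                          n_genomes=20_000)
        n1 = len(sc.simulate_cohort(base, with_conservation=False, with_gwas=False).variants)
        n2 = len(sc.simulate_cohort(double, with_conservation=False, with_gwas=False).variants)
        assert 1.8 <= n2 / n1 <= 2.2

    def test_overheated_rate_table_rejected(self):
        cfg = tiny_cfg()
        rng = np.random.default_rng(cfg.seed)
        genome = sc.generate_genome(cfg, rng)
        plant = sc.plant_orfs(cfg, genome, rng)
        broken = MutationRateTable.default().df.copy()
        broken.loc[broken["mu"].idxmax(), "mu"] = 1.0  # absurd rate -> p >= 1
        from smorfval.errors import DataError

        with pytest.raises(DataError):
            sc.simulate_population_variants(
                cfg, genome, plant.entities, MutationRateTable(broken), rng
            )


class TestConservationTrack:
    def test_full_coupling_rank_order(self):
        cfg = tiny_cfg(conservation_coupling=1.0, gerp_noise_sd=0.0, n_genes=0,
                       seed=13)
        rng = np.random.default_rng(cfg.seed)
        genome = sc.generate_genome(cfg, rng)
        plant = sc.plant_orfs(cfg, genome, rng)
        track_df = sc.simulate_conservation_track(cfg, plant.entities, genome, rng)
        from smorfval.conservation_and_selection import ConservationTrack, mean_conservation

        track = ConservationTrack(track_df)
        means = {
            e.model.id: mean_conservation(e.model, track).mean_gerp
            for e in plant.smorfs
        }
        fs = {e.model.id: e.f_mis for e in plant.smorfs}
        ids = list(means)
        order_by_score = sorted(ids, key=lambda i: -means[i])
        order_by_depletion = sorted(ids, key=lambda i: (fs[i], order_by_score.index(i)))
        assert order_by_score == order_by_depletion

    def test_neutral_background_mean_near_zero(self):
        cfg = tiny_cfg(genome_length=120_000, n_genes=0, n_smorfs=1, seed=17)
        rng = np.random.default_rng(cfg.seed)
        genome = sc.generate_genome(cfg, rng)
        plant = sc.plant_orfs(cfg, genome, rng)
        track = sc.simulate_conservation_track(cfg, plant.entities, genome, rng)
        entity_pos = set(plant.entities[0].model.genomic_positions().tolist())
        background = track[~track["start"].isin(entity_pos)]
        assert len(background) >= 1e5
        assert abs(background["score"].mean()) < 0.05

    def test_zero_coupling_decorrelates_score_from_depletion(self):
        from scipy import stats

        cfg = tiny_cfg(conservation_coupling=0.0, n_genes=0, n_smorfs=40,
                       genome_length=80_000, seed=19)
        rng = np.random.default_rng(cfg.seed)
        genome = sc.generate_genome(cfg, rng)
        plant = sc.plant_orfs(cfg, genome, rng)
        track_df = sc.simulate_conservation_track(cfg, plant.entities, genome, rng)
        from smorfval.conservation_and_selection import ConservationTrack, mean_conservation

        track = ConservationTrack(track_df)
        means = np.array(
            [mean_conservation(e.model, track).mean_gerp for e in plant.smorfs]
        )
        fs = np.array([e.f_mis for e in plant.smorfs])
        if np.std(fs) > 0:
            _, p = stats.pearsonr(means, fs)
            assert p > 0.01


class TestGwasUniverse:
    def test_unenriched_catalog_matches_background_proportion(self, small_cohort):
        co = small_cohort
        from smorfval import gwas_enrichment as ge

        universe = ge.ld_expand(co.arrays, co.ld_pairs)
        surviving = [
            e for e in co.plant.smorfs
            if e.decoy == "none" and e.expected_class != "excluded_category"
        ]
        index = ge.ExonIndex(
            [(e.model.chrom, s, x) for e in surviving for s, x in e.model.exons]
        )
        rng = np.random.default_rng(0)
        catalog = sc.draw_catalog(
            co.cfg, universe.snvs, universe.snvs.assign(ref="A", alt="G"),
            index, rng, enrichment_ratio=1.0, n_snvs=300, with_decoys=False,
        )
        q = index.contains(
            universe.snvs["chrom"].to_numpy(), universe.snvs["pos"].to_numpy()
        ).mean()
        observed, _ = ge.overlap_count(catalog, index)
        n = len(catalog)
        assert abs(observed - n * q) < 4 * np.sqrt(n * q * (1 - q)) + 2

    def test_catalog_p_values_significant_and_bins_covered(self, small_cohort):
        from smorfval import gwas_enrichment as ge

        catalog = ge.filter_catalog(small_cohort.catalog)
        assert (catalog["p_value"] < 5e-8).all()
        bins = set(ge.maf_bin_index(catalog["maf"].to_numpy()))
        assert bins >= {0, 1, 2, 3, 4}


class TestBundleReproducibility:
    def test_identical_config_writes_identical_files(self, tmp_path):
        cfg = tiny_cfg(genome_length=40_000, n_smorfs=12, n_genes=4, seed=8)
        b1 = sc.generate_bundle(cfg, tmp_path / "one")
        b2 = sc.generate_bundle(cfg, tmp_path / "two")
        for name in ("genome", "predictions_a", "predictions_b", "variants",
                     "conservation", "gwas_catalog", "arrays", "ld_pairs",
                     "truth", "refseq", "peptides", "methylation"):
            f1, f2 = getattr(b1, name), getattr(b2, name)
            assert filecmp.cmp(f1, f2, shallow=False), name

    def test_config_roundtrip(self, tmp_path):
        cfg = tiny_cfg(seed=4)
        cfg.to_yaml(tmp_path / "cfg.yaml")
        back = sc.SimulationConfig.from_yaml(tmp_path / "cfg.yaml")
        assert back == cfg
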