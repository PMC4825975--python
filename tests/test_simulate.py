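"""Synthetic-cohort generators: determinism, Mendelian bookkeeping, planted
structure, and the statistical properties promised to downstream stages."""

import numpy as np
import pytest
from scipy.stats import beta as beta_dist
from scipy.stats import chi2

from oligoheart.simulate import (
    BurdenSet,
    CohortConfig,
    ConfigError,
    ExpressionModuleSpec,
    MafSpectrum,
    gene_names,
    simulate_expression_atlas,
    simulate_panel,
    simulate_ppi_network,
    simulate_singleton_cohort,
    simulate_trio_cohort,
)


class TestPanel:
    def test_empty(self):
        assert len(simulate_panel(0)) == 0

    def test_degenerate_spectrum_all_half(self):
        panel = simulate_panel(10_000, MafSpectrum(kind="fixed", value=0.5), seed=0)
        assert (panel["maf"] == 0.5).all()

    def test_median_matches_analytic_quantile(self):
        spec = MafSpectrum(a=0.2, b=5.0)
        n = 100_000
        panel = simulate_panel(n, spec, seed=1)
        med_analytic = spec.median()
        emp = float(np.median(panel["maf"]))
        # MC standard error of the sample median: 1 / (2 f(m) sqrt(n))
        fm = 2 * beta_dist.pdf(2 * med_analytic, spec.a, spec.b)
        se = 1.0 / (2 * fm * np.sqrt(n))
        assert abs(emp - med_analytic) < 2 * se

    def test_deterministic_and_valid_spectrum_required(self):
        p1 = simulate_panel(500, seed=3)
        p2 = simulate_panel(500, seed=3)
        assert p1.equals(p2)
        with pytest.raises(ConfigError):
            MafSpectrum(a=-1.0)
        with pytest.raises(ConfigError):
            MafSpectrum(kind="fixed", value=0.7)


class TestTrioCohort:
    def test_no_planting_no_mendelian_violations(self):
        cfg = CohortConfig(
            seed=2, n_case_trios=10, n_control_trios=10, n_sites=2_000,
            rate_denovo=0, rate_comphet=0, rate_rarehom=0,
        )
        cohort = simulate_trio_cohort(cfg)
        assert cohort.mendelian_violations().sum() == 0
        assert len(cohort.truth.events) == 0

    def test_violations_exactly_at_planted_de_novo(self, small_noiseless_cohort):
        cohort = small_noiseless_cohort
        truth = cohort.truth.events
        n_denovo = (truth["mode"] == "de_novo").sum()
        viol = cohort.mendelian_violations()
        assert viol.sum() == n_denovo
        # each violating (site, trio) is a truth de novo record
        vids = {cohort.variant_id(s) for s, t in zip(*np.nonzero(viol))}
        assert vids == set(truth[truth["mode"] == "de_novo"]["variant_ids"])

    def test_parental_allele_frequency_tracks_panel(self):
        cfg = CohortConfig(
            seed=4, n_case_trios=100, n_control_trios=100, n_sites=200,
            maf_spectrum=MafSpectrum(kind="fixed", value=0.1),
            rate_denovo=0, rate_comphet=0, rate_rarehom=0,
        )
        cohort = simulate_trio_cohort(cfg)
        parents = cohort.gt[:, :, 1:]  # (sites, trios, 2)
        n_alleles = 2 * 2 * cohort.n_trios
        freqs = parents.sum(axis=(1, 2)) / n_alleles
        se = np.sqrt(0.1 * 0.9 / n_alleles)
        assert (np.abs(freqs - 0.1) < 3 * se).mean() > 0.98

    def test_byte_identical_given_seed(self, tmp_path):
        from oligoheart.io import write_trio_vcf

        cfg = CohortConfig(seed=9, n_case_trios=3, n_control_trios=3, n_sites=300,
                           planted_genes=tuple(gene_names(3)))
        for name in ("a", "b"):
            write_trio_vcf(simulate_trio_cohort(cfg), tmp_path / f"{name}.vcf", tmp_path / f"{name}.ped")
        assert (tmp_path / "a.vcf").read_bytes() == (tmp_path / "b.vcf").read_bytes()
        assert (tmp_path / "a.ped").read_bytes() == (tmp_path / "b.ped").read_bytes()

    def test_hardy_weinberg_in_founders(self):
        rejected = total = 0
        for seed in range(20):
            cfg = CohortConfig(seed=seed, n_case_trios=30, n_control_trios=30, n_sites=150,
                               maf_spectrum=MafSpectrum(kind="fixed", value=0.3),
                               rate_denovo=0, rate_comphet=0, rate_rarehom=0)
            cohort = simulate_trio_cohort(cfg)
            founders = cohort.gt[:, :, 1:].reshape(cohort.n_sites, -1)
            n = founders.shape[1]
            for s in range(cohort.n_sites):
                counts = np.bincount(founders[s], minlength=3)
                p = founders[s].sum() / (2 * n)
                exp = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
                if (exp > 0).all():
                    stat = ((counts - exp) ** 2 / exp).sum()
                    rejected += chi2.sf(stat, 1) < 0.001
                    total += 1
        assert rejected / total <= 0.02

    def test_unknown_planted_gene_rejected(self):
        with pytest.raises(ConfigError, match="planted_genes"):
            simulate_trio_cohort(CohortConfig(n_sites=100, planted_genes=("NOPE",), rate_denovo=1))

    def test_planting_requires_gene_list(self):
        with pytest.raises(ConfigError, match="non-empty"):
            simulate_trio_cohort(CohortConfig(n_sites=100, rate_denovo=1.0))


class TestSingletonCohort:
    def test_null_effect_no_systematic_difference(self):
        # no planted set: carrier-frequency difference is pure sampling noise
        rejections = 0
        n_seeds = 60
        for seed in range(n_seeds):
            cfg = CohortConfig(seed=seed, n_singleton_cases=80, n_singleton_controls=80,
                               n_singleton_sites=60)
            sc = simulate_singleton_cohort(cfg)
            case = sc.G[sc.y == 1].sum()
            ctrl = sc.G[sc.y == 0].sum()
            # binomial z on total allele counts
            tot = case + ctrl
            if tot == 0:
                continue
            z = (case - tot / 2) / np.sqrt(tot / 4)
            rejections += abs(z) > 3.29  # alpha ~ 0.001
        assert rejections <= 2

    def test_infinite_effect_perfect_separation(self):
        cfg = CohortConfig(
            seed=1, n_singleton_cases=20, n_singleton_controls=40, n_singleton_sites=300,
            burden_sets=(BurdenSet(genes=("G000002",), effect=float("inf")),),
        )
        sc = simulate_singleton_cohort(cfg)
        mask = (sc.variants["gene"] == "G000002").to_numpy() & (
            sc.variants["maf"].to_numpy() <= 0.03
        )
        assert mask.any()
        assert (sc.G[sc.y == 1][:, mask] >= 1).all()
        assert (sc.G[sc.y == 0][:, mask] == 0).all()

    def test_overlarge_effect_rejected(self):
        cfg = CohortConfig(
            seed=1, n_singleton_sites=300,
            maf_spectrum=MafSpectrum(kind="fixed", value=0.03),
            burden_sets=(BurdenSet(genes=("G000002",), effect=50.0),),
        )
        with pytest.raises(ConfigError, match="frequency above 1"):
            simulate_singleton_cohort(cfg)


class TestExpressionAtlas:
    def test_noiseless_module_perfectly_correlated(self):
        spec = [ExpressionModuleSpec("m", tuple(gene_names(50)[:10]), "tissue01", 2.0)]
        counts, design, assignment = simulate_expression_atlas(
            50, 5, spec, seed=0, noise_sd=0.0, base_log_sd=0.0, poisson=False
        )
        sub = counts.loc[list(spec[0].genes)].to_numpy(float)
        corr = np.corrcoef(np.log1p(sub))
        assert np.allclose(corr, 1.0)

    def test_independent_modules_uncorrelated_between(self):
        genes = gene_names(60)
        spec = [
            ExpressionModuleSpec("m1", tuple(genes[:10]), "tissue01", 3.0),
            ExpressionModuleSpec("m2", tuple(genes[10:20]), "tissue02", 3.0),
        ]
        counts, _, _ = simulate_expression_atlas(60, 10, spec, seed=1, libs_per_tissue=4)
        X = np.log1p(counts.to_numpy(float))
        c = np.corrcoef(X[:20])
        between = c[:10, 10:20]
        assert np.abs(between).mean() < 0.2

    def test_overlapping_modules_rejected(self):
        genes = gene_names(20)
        spec = [
            ExpressionModuleSpec("m1", tuple(genes[:5]), "tissue01"),
            ExpressionModuleSpec("m2", tuple(genes[4:8]), "tissue02"),
        ]
        with pytest.raises(ConfigError, match="two modules"):
            simulate_expression_atlas(20, 3, spec, seed=0)

    def test_counts_are_non_negative_integers(self):
        counts, _, _ = simulate_expression_atlas(30, 4, seed=2)
        assert (counts.to_numpy() >= 0).all()
        assert counts.dtypes.map(lambda d: np.issubdtype(d, np.integer)).all()


class TestPpiNetwork:
    def test_empty_module_pure_preferential_attachment(self):
        g = simulate_ppi_network(100, 3, seed=0)
        assert g.number_of_nodes() == 100
        assert not any(u == v for u, v in g.edges)

    def test_planted_clique_edges_present(self):
        clique = gene_names(500)[:5]
        g = simulate_ppi_network(500, 3, clique, seed=1)
        for i, u in enumerate(clique):
            for v in clique[i + 1 :]:
                assert g.has_edge(u, v)

    def test_heavy_tailed_degrees(self):
        ok = 0
        for seed in range(30):
            g = simulate_ppi_network(2_000, 3, seed=seed)
            degs = np.array([d for _, d in g.degree])
            ok += degs.max() >= 10 * np.median(degs)
        assert ok >= 29

    def test_module_size_validation(self):
        with pytest.raises(ConfigError):
            simulate_ppi_network(5, 2, gene_names(10), seed=0)
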