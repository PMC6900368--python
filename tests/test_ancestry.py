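"""Panel QC, LD pruning, PCA projection, and block-origin inference."""

import itertools

import numpy as np
import pandas as pd
import pytest

from kindredscope.ancestry import (
    LDPruneConfig,
    PhasedBlock,
    ReferencePanel,
    block_loglik,
    block_origin_posterior,
    ld_prune,
    pca_project,
    phased_block_loglik,
    population_posterior,
    qc_panel,
    rank_populations,
)
from kindredscope.simulate import (
    SimConfig,
    simulate_panel,
    simulate_phased_block,
)


def _qc_fixture():
    """100 sites: 2 tri-allelic, 3 chrX, 5 rare — disjoint defect sets."""
    rng = np.random.default_rng(0)
    chrom = ["1"] * 100
    alt = ["G"] * 100
    freq = rng.uniform(0.2, 0.8, size=(100, 2))
    for i in (0, 1):
        alt[i] = "G,T"
    for i in (2, 3, 4):
        chrom[i] = "X"
    for i in (5, 6, 7, 8, 9):
        freq[i] = 0.01
    snps = pd.DataFrame(
        {"chrom": chrom, "pos": np.arange(1, 101) * 10, "ref": ["A"] * 100, "alt": alt}
    )
    return snps, freq


class TestPanelQC:
    def test_defect_classes_removed(self):
        snps, freq = _qc_fixture()
        panel = qc_panel(snps, freq, ["P1", "P2"], maf_min=0.05)
        assert len(panel.snps) == 90
        assert not panel.snps["alt"].str.contains(",").any()
        assert not panel.snps["chrom"].isin({"X", "Y"}).any()

    def test_all_passing_panel_unchanged(self):
        snps = pd.DataFrame(
            {"chrom": ["1"] * 10, "pos": range(10, 110, 10),
             "ref": ["A"] * 10, "alt": ["G"] * 10}
        )
        freq = np.full((10, 2), 0.4)
        panel = qc_panel(snps, freq, ["P1", "P2"])
        assert len(panel.snps) == 10

    def test_maf_boundary_inclusive(self):
        snps = pd.DataFrame(
            {"chrom": ["1", "1"], "pos": [10, 20], "ref": ["A"] * 2, "alt": ["G"] * 2}
        )
        freq = np.array([[0.05, 0.05], [0.049, 0.049]])
        panel = qc_panel(snps, freq, ["P1", "P2"], maf_min=0.05)
        assert list(panel.snps["pos"]) == [10]


class TestLDPrune:
    def test_perfectly_correlated_pair_keeps_one(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 3, size=100).astype(float)
        G = np.column_stack([a, a])
        assert ld_prune(G, LDPruneConfig(window_snps=50, step_snps=5)) == [0]

    def test_independent_sites_all_retained(self):
        rng = np.random.default_rng(2)
        G = rng.binomial(2, 0.5, size=(500, 40)).astype(float)
        cfg = LDPruneConfig(window_snps=40, step_snps=5, r2_max=0.5)
        # verify the premise: no pair actually exceeds the cutoff
        corr = np.corrcoef(G.T) ** 2
        np.fill_diagonal(corr, 0.0)
        assert corr.max() < 0.5
        assert ld_prune(G, cfg) == list(range(40))

    def test_postcondition_verified_by_exhaustive_oracle(self):
        # 200 sites in correlated clusters
        rng = np.random.default_rng(3)
        base = rng.binomial(2, 0.5, size=(300, 40)).astype(float)
        cols = []
        for i in range(200):
            src = base[:, i % 40].copy()
            flip = rng.random(300) < 0.05
            src[flip] = rng.binomial(2, 0.5, size=flip.sum())
            cols.append(src)
        G = np.column_stack(cols)
        cfg = LDPruneConfig(window_snps=50, step_snps=5, r2_max=0.5)
        kept = ld_prune(G, cfg)
        # oracle: every in-window retained pair obeys the r^2 ceiling
        for a, b in itertools.combinations(kept, 2):
            if b - a < cfg.window_snps:
                r = np.corrcoef(G[:, a], G[:, b])[0, 1]
                assert r * r <= cfg.r2_max + 1e-12

    def test_tiny_input_returned_unchanged(self):
        assert ld_prune(np.zeros((10, 1)), LDPruneConfig()) == [0]


class TestPCA:
    def test_query_duplicating_panel_individual(self, small_panel):
        _, genos, _ = small_panel
        panel_g = genos[:100].astype(float)
        query = panel_g[3:4]
        pc_panel, pc_query = pca_project(panel_g, query, n_pcs=2)
        assert np.allclose(pc_query[0], pc_panel[3], atol=1e-6)

    def test_two_population_separation_and_query_placement(self):
        cfg = SimConfig(seed=21, n_populations=2, n_snps=500,
                        n_per_population=100, fst=0.1)
        panel, genos, labels = simulate_panel(cfg)
        rng = np.random.default_rng(22)
        # query drawn from population 1's generating frequencies
        query = rng.binomial(2, panel.freq[:, 0], size=(1, 500)).astype(float)
        pc_panel, pc_query = pca_project(genos.astype(float), query, n_pcs=2)
        a = pc_panel[np.array(labels) == "POP1", 0]
        b = pc_panel[np.array(labels) == "POP2", 0]
        # PC1 separates the populations with zero overlap
        assert a.max() < b.min() or b.max() < a.min()
        assert a.min() <= pc_query[0, 0] <= a.max()

    def test_degenerate_identical_panel(self):
        G = np.tile(np.array([0.0, 1.0, 2.0, 1.0, 0.0] * 4), (8, 1))
        pc_panel, pc_query = pca_project(G, G[:1], n_pcs=2)
        assert np.allclose(pc_panel, 0.0, atol=1e-8)

    def test_too_few_sites_is_error(self):
        with pytest.raises(ValueError):
            pca_project(np.zeros((5, 1)), np.zeros((1, 1)), n_pcs=2)


def _two_pop_panel(freqs):
    """Panel with explicit per-population frequencies (counts absent)."""
    s = len(freqs)
    snps = pd.DataFrame(
        {"chrom": ["1"] * s, "pos": np.arange(1, s + 1) * 10,
         "ref": ["A"] * s, "alt": ["G"] * s}
    )
    return ReferencePanel(
        populations=[f"P{i+1}" for i in range(np.asarray(freqs).shape[1])],
        snps=snps,
        freq=np.asarray(freqs, dtype=float),
    )


class TestBlockLoglik:
    def test_single_site_half_frequency_limit(self):
        panel = _two_pop_panel([[0.5, 0.9]])
        ll = block_loglik([1], panel, "P1", alpha=1e-9)
        assert ll == pytest.approx(np.log(0.5), abs=1e-6)

    def test_zero_count_allele_smoothed_finite(self):
        panel = _two_pop_panel([[0.0, 0.5]])
        alpha = 0.5
        ll = block_loglik([1], panel, "P1", alpha=alpha)
        total = panel.nominal_chromosomes
        assert ll == pytest.approx(np.log(alpha / (total + 2 * alpha)))

    def test_matches_per_site_product_oracle(self, rng):
        freqs = rng.uniform(0.1, 0.9, size=(20, 3))
        panel = _two_pop_panel(freqs)
        hap = rng.integers(0, 2, size=20)
        alpha, total = 0.5, panel.nominal_chromosomes
        expected = 0.0
        for s in range(20):
            c_alt = freqs[s, 1] * total
            c = c_alt if hap[s] == 1 else total - c_alt
            expected += np.log((c + alpha) / (total + 2 * alpha))
        assert block_loglik(hap, panel, "P2") == pytest.approx(expected)

    def test_absent_site_is_error(self):
        panel = _two_pop_panel([[0.5, 0.5]])
        with pytest.raises(KeyError):
            block_loglik([1, 0], panel, "P1", site_indices=[0, 7])

    def test_phased_block_sums_both_haplotypes(self):
        panel = _two_pop_panel([[0.3, 0.7], [0.6, 0.2]])
        block = PhasedBlock(
            sites=[("1", 10), ("1", 20)], hap_with_sv=[1, 0], hap_other=[0, 1]
        )
        joint = phased_block_loglik(block, panel, "P1")
        h0 = block_loglik([1, 0], panel, "P1", site_indices=[0, 1])
        h1 = block_loglik([0, 1], panel, "P1", site_indices=[0, 1])
        assert joint == pytest.approx(h0 + h1)


class TestPosterior:
    def test_symmetry_gives_uniform(self):
        post = population_posterior({f"P{i}": -10.0 for i in range(5)})
        assert all(p == pytest.approx(0.2) for p in post.probability.values())

    def test_domination_by_fifty_log_units(self):
        post = population_posterior({"A": 0.0, "B": -50.0, "C": -60.0})
        assert post.probability["A"] >= 1 - 1e-20

    def test_normalization_for_random_inputs(self, rng):
        for _ in range(50):
            ll = {f"P{i}": float(v) for i, v in enumerate(rng.normal(-100, 50, 6))}
            post = population_posterior(ll)
            assert sum(post.probability.values()) == pytest.approx(1.0, abs=1e-9)

    def test_all_minus_inf_is_error(self):
        with pytest.raises(ValueError):
            population_posterior({"A": -np.inf, "B": -np.inf})

    def test_label_equivariance(self):
        ll = {"A": -3.0, "B": -1.0, "C": -2.0}
        renamed = {"X": -3.0, "Y": -1.0, "Z": -2.0}
        p1 = population_posterior(ll).probability
        p2 = population_posterior(renamed).probability
        assert p1["A"] == pytest.approx(p2["X"])
        assert p1["B"] == pytest.approx(p2["Y"])

    def test_uninformative_site_changes_nothing(self):
        freqs = np.array([[0.3, 0.7], [0.6, 0.2]])
        with_extra = np.vstack([freqs, [0.5, 0.5]])
        p_base = _two_pop_panel(freqs)
        p_extra = _two_pop_panel(with_extra)
        hap_base, hap_extra = [1, 0], [1, 0, 1]
        post_base = population_posterior(
            {p: block_loglik(hap_base, p_base, p) for p in p_base.populations}
        )
        post_extra = population_posterior(
            {p: block_loglik(hap_extra, p_extra, p) for p in p_extra.populations}
        )
        for p in post_base.probability:
            assert post_base.probability[p] == pytest.approx(
                post_extra.probability[p], abs=1e-12
            )


class TestRanking:
    def test_descending_order(self):
        post = population_posterior({"A": -1.0, "B": -2.0, "C": -4.0})
        assert [r.population for r in rank_populations(post)] == ["A", "B", "C"]

    def test_tie_flagged_and_lexical(self):
        post = population_posterior({"B": -1.0, "A": -1.0})
        ranks = rank_populations(post)
        assert [r.population for r in ranks] == ["A", "B"]
        assert all(r.tied for r in ranks)

    def test_source_population_recovery_and_monotonicity(self, small_panel):
        panel, _, _ = small_panel
        rng = np.random.default_rng(77)
        reps = 60

        def recovery(n_sites):
            hits = 0
            for r in range(reps):
                src = panel.populations[r % len(panel.populations)]
                block, idx = simulate_phased_block(panel, src, n_sites, rng)
                post = block_origin_posterior(block, panel, site_indices=idx)
                if rank_populations(post)[0].population == src:
                    hits += 1
            return hits / reps

        # accuracy grows with block length; at 100 sites recovery is high
        r25, r100 = recovery(25), recovery(100)
        assert r100 >= r25
        assert r100 >= 0.9
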