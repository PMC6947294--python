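"""Determinism, truth-table emission and recovery properties of the
synthetic-data generators."""

import numpy as np
import pandas as pd
import pytest

from phylostress.divergence import ng86_ka_ks
from phylostress.gene_sets import build_stress_gene_set, overlap_stats, select_terms_by_keyword
from phylostress.phylostratigraphy import assign_pai_table
from phylostress.synthetic_data import (
    SimulationConfig,
    simulate_codon_pairs,
    simulate_network,
    simulate_ortholog_hits,
    simulate_stress_sets,
    simulate_taxonomy,
)
from phylostress.network_analysis import age_assortativity


@pytest.fixture(scope="module")
def lineage():
    cfg = SimulationConfig(seed=0)
    lin, _ = simulate_taxonomy(cfg)
    return lin


class TestConfig:
    def test_birth_distribution_defaults_to_probability_vector(self):
        cfg = SimulationConfig()
        p = np.asarray(cfg.birth_distribution)
        assert p.size == cfg.n_strata and p.sum() == pytest.approx(1.0)

    def test_invalid_distribution_rejected(self):
        with pytest.raises(ValueError, match="probability vector"):
            SimulationConfig(n_strata=3, birth_distribution=(0.5, 0.2))

    def test_minimal_two_stratum_lineage(self):
        lin, table = simulate_taxonomy(SimulationConfig(n_strata=2))
        assert len(lin) == 2 and lin.terminal_rank == 1


class TestTaxonomy:
    def test_default_chain_matches_retained_strata_count(self, lineage):
        assert len(lineage) == 15 and lineage.ranks == tuple(range(15))

    def test_terminal_contains_focal(self, lineage):
        assert lineage.focal_species in lineage.terminal.species

    def test_deterministic_under_seed(self):
        a = simulate_taxonomy(SimulationConfig(seed=5))[1]
        b = simulate_taxonomy(SimulationConfig(seed=5))[1]
        pd.testing.assert_frame_equal(a, b)


class TestOrthologHits:
    def test_noiseless_recovery_is_exact(self, lineage):
        cfg = SimulationConfig(seed=3, n_genes=400, detection_noise=0.0)
        hits, truth = simulate_ortholog_hits(cfg, lineage)
        ages = assign_pai_table(hits, 0.0, lineage, truth["gene_id"])
        merged = ages.merge(truth, on="gene_id")
        assert (merged["pai"] == merged["birth_rank"]).all()

    def test_full_noise_gives_terminal_everywhere(self, lineage):
        cfg = SimulationConfig(seed=3, n_genes=50, detection_noise=1.0)
        hits, truth = simulate_ortholog_hits(cfg, lineage)
        ages = assign_pai_table(hits, 0.0, lineage, truth["gene_id"])
        assert (ages["pai"] == lineage.terminal_rank).all()

    def test_misses_only_age_genes_upward(self, lineage):
        cfg = SimulationConfig(seed=4, n_genes=300, detection_noise=0.3)
        hits, truth = simulate_ortholog_hits(cfg, lineage)
        ages = assign_pai_table(hits, 0.5, lineage, truth["gene_id"])
        merged = ages.merge(truth, on="gene_id")
        assert (merged["pai"] >= merged["birth_rank"]).all()

    def test_deterministic_under_seed(self, lineage):
        cfg = SimulationConfig(seed=8, n_genes=100)
        a, _ = simulate_ortholog_hits(cfg, lineage)
        b, _ = simulate_ortholog_hits(cfg, lineage)
        pd.testing.assert_frame_equal(a, b)


class TestCodonPairs:
    def test_zero_branch_length_gives_identical_pair(self):
        cfg = SimulationConfig(seed=1, n_codons=50, branch_length=0.0)
        aligns, _ = simulate_codon_pairs(cfg, n_pairs=3, omega=0.5)
        for a in aligns:
            assert a.seq_focal == a.seq_relative
            assert ng86_ka_ks(a).status == "excluded_ks_zero"

    def test_omega_zero_forbids_nonsynonymous_changes(self):
        # amino-acid sequences must be untouched; NG86 may still count a
        # residual Ka when synonymous paths cross codon groups (Ser/Leu/Arg),
        # so the estimate is near-zero rather than identically zero
        from phylostress.divergence import AMINO_ACID

        cfg = SimulationConfig(seed=2, n_codons=400, branch_length=0.2)
        aligns, _ = simulate_codon_pairs(cfg, n_pairs=5, omega=0.0)
        for a in aligns:
            aa = lambda s: [AMINO_ACID[s[i : i + 3]] for i in range(0, len(s), 3)]
            assert aa(a.seq_focal) == aa(a.seq_relative)
            r = ng86_ka_ks(a)
            assert r.ka < 0.01 and r.di < 0.05

    def test_neutral_limit_mean_di_near_one(self):
        cfg = SimulationConfig(seed=6, n_codons=2000)
        aligns, _ = simulate_codon_pairs(cfg, n_pairs=12, omega=1.0)
        dis = [ng86_ka_ks(a).di for a in aligns]
        assert np.mean(dis) == pytest.approx(1.0, rel=0.15)

    def test_truth_table_emitted_with_drawn_classes(self):
        cfg = SimulationConfig(seed=7, n_codons=30)
        _, truth = simulate_codon_pairs(cfg, n_pairs=40)
        assert set(truth.columns) == {"gene_id", "omega", "class"}
        assert set(truth["class"]) <= set(cfg.omega_classes)


class TestNetwork:
    def ages(self, n=120, seed=0):
        rng = np.random.default_rng(seed)
        return {f"g{i}": int(rng.integers(0, 15)) for i in range(n)}

    def test_null_beta_near_zero_assortativity(self):
        rs = []
        for s in range(15):
            cfg = SimulationConfig(seed=s, n_edges=150, assortativity_strength=0.0)
            net = simulate_network(cfg, self.ages(seed=s))
            rs.append(age_assortativity(net).r_a)
        assert abs(np.mean(rs)) < 0.05

    def test_strong_beta_approaches_one(self):
        cfg = SimulationConfig(seed=1, n_edges=150, assortativity_strength=8.0)
        net = simulate_network(cfg, self.ages(seed=1))
        assert age_assortativity(net).r_a > 0.9

    def test_scores_pass_default_filter(self):
        cfg = SimulationConfig(seed=2, n_edges=60)
        net = simulate_network(cfg, self.ages(60, seed=2))
        assert net.n_edges == 60  # nothing lost at the 0.7 cutoff

    def test_infeasible_edge_count_rejected(self):
        cfg = SimulationConfig(seed=0, n_edges=100)
        with pytest.raises(ValueError, match="cannot place"):
            simulate_network(cfg, self.ages(5))

    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(seed=9, n_edges=80)
        a = simulate_network(cfg, self.ages(seed=4))
        b = simulate_network(cfg, self.ages(seed=4))
        assert sorted(a.graph.edges) == sorted(b.graph.edges)


class TestStressSets:
    @pytest.fixture(scope="class")
    def bundle(self):
        cfg = SimulationConfig(seed=0, n_genes=5000)
        genes = [f"g{i:05d}" for i in range(cfg.n_genes)]
        return cfg, simulate_stress_sets(cfg, genes)

    def test_planted_pairwise_intersections_exact(self, bundle):
        cfg, (sets, planted, _, _) = bundle
        ov = overlap_stats(sets)
        for a in planted.index:
            for b in planted.columns:
                assert ov["counts"].loc[a, b] == planted.loc[a, b]

    def test_sizes_match_design(self, bundle):
        cfg, (sets, _, _, _) = bundle
        for s in sets:
            assert len(s.genes) == cfg.set_sizes[s.stress]

    def test_keyword_roundtrip_reproduces_sets(self, bundle):
        _, (sets, _, ontology, annotations) = bundle
        for s in sets:
            terms = select_terms_by_keyword(ontology, s.stress)
            rebuilt = build_stress_gene_set(annotations, terms, name=s.stress)
            assert rebuilt.genes == s.genes

    def test_infeasible_design_rejected(self):
        cfg = SimulationConfig(
            seed=0,
            set_sizes={"a": 3, "b": 10},
            overlaps={("a", "b"): 5},
        )
        with pytest.raises(ValueError, match="infeasible"):
            simulate_stress_sets(cfg, [f"g{i}" for i in range(100)])
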