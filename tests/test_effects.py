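"""Similarity metrics, in-silico pair application, null distributions and
the ancestral/derived quartet."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from pcfm.effects import (AMINO_ACIDS, GAP_OR_STOP_DISTANCE, MIYATA_MATRIX,
                          PcfmTemplate, PlacementError, ancestral_states,
                          apply_pcfm, bonferroni_significant, build_null,
                          descendant_trajectories, hydropathy_diff,
                          miyata_mean, pair_effect, quartet_distances,
                          valid_positions)
from pcfm.pipeline import detect_in_alignment
from pcfm.seqio import CodingSequence, translate
from pcfm.simulate import (PlantedPair, SimConfig, make_control_pool,
                           plantable_edges, simulate)

PEPTIDE = st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=30)

ALL_TEMPLATES = [
    PcfmTemplate("deletion", 2, "deletion", 1, 26),
    PcfmTemplate("insertion", 1, "insertion", 2, 7),
    PcfmTemplate("deletion", 1, "insertion", 1, 32),
    PcfmTemplate("insertion", 2, "deletion", 2, 14),
]


class TestMiyataScale:
    def test_matrix_symmetric_with_zero_diagonal(self):
        for a in AMINO_ACIDS:
            assert MIYATA_MATRIX[(a, a)] == 0.0
            for b in AMINO_ACIDS:
                assert MIYATA_MATRIX[(a, b)] == MIYATA_MATRIX[(b, a)]

    def test_maximum_is_glycine_tryptophan(self):
        mx = max(MIYATA_MATRIX.items(), key=lambda kv: kv[1])
        assert mx[1] == GAP_OR_STOP_DISTANCE == 5.13
        assert set(mx[0]) == {"G", "W"}

    def test_published_reference_distances(self):
        # spot-checks against the published table (2-decimal precision)
        expected = {("A", "P"): 0.06, ("A", "G"): 0.91, ("A", "S"): 0.51,
                    ("A", "W"): 4.23, ("L", "I"): 0.14, ("R", "K"): 0.40}
        for pair, val in expected.items():
            assert MIYATA_MATRIX[pair] == pytest.approx(val, abs=0.011)

    def test_gap_stop_and_unknown_score_maximum(self):
        assert miyata_mean("AW", "A-") == pytest.approx((0 + 5.13) / 2)
        assert miyata_mean("A", "*") == 5.13
        assert miyata_mean("A", "X") == 5.13

    @given(PEPTIDE, PEPTIDE)
    @settings(max_examples=50, deadline=None)
    def test_symmetric_and_bounded(self, p1, p2):
        n = max(len(p1), len(p2))
        p1, p2 = p1.ljust(n, "A"), p2.ljust(n, "A")
        d = miyata_mean(p1, p2)
        assert d == miyata_mean(p2, p1)
        assert 0.0 <= d <= 5.13

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            miyata_mean("AA", "A")


class TestHydropathy:
    def test_extremes_reach_nine(self):
        assert hydropathy_diff("IIII", "RRRR") == pytest.approx(9.0)

    def test_identical_zero_and_reference_value(self):
        assert hydropathy_diff("GW", "GW") == 0.0
        assert hydropathy_diff("II", "VV") == pytest.approx(0.3)

    @given(PEPTIDE, PEPTIDE)
    @settings(max_examples=50, deadline=None)
    def test_symmetric_and_bounded(self, p1, p2):
        d = hydropathy_diff(p1, p2)
        assert d == hydropathy_diff(p2, p1)
        assert 0.0 <= d <= 9.0

    def test_no_scoreable_residue_rejected(self):
        with pytest.raises(ValueError):
            hydropathy_diff("-*", "AA")


class TestApplyPcfm:
    def test_template_validation(self):
        with pytest.raises(ValueError, match="divisible"):
            PcfmTemplate("deletion", 1, "insertion", 3, 5)
        with pytest.raises(ValueError, match="kind"):
            PcfmTemplate("dupe", 1, "deletion", 2, 5)

    def test_deletion_pair_edits_are_exact(self):
        cds = CodingSequence("g", "s", "ATGAAACCCGGGTTTTAA")
        tpl = PcfmTemplate("deletion", 2, "deletion", 1, 2)
        out = apply_pcfm(cds, 4, tpl, seed=0)
        # delete nt 4-5, keep 2, delete nt 8
        assert out.nt == "ATGACCCGGGTTTTAA"[:4] + "CC" + "CGGGTTTTAA"[1:]
        assert len(out.nt) == len(cds.nt) - 3

    def test_net_zero_template_preserves_length(self):
        cds = CodingSequence("g", "s", "ATG" + "AAACCCGGG" * 4 + "TAA")
        tpl = PcfmTemplate("insertion", 1, "deletion", 1, 0)
        out = apply_pcfm(cds, 6, tpl, seed=1)
        assert len(out.nt) == len(cds.nt)

    def test_placement_overrun_rejected(self):
        cds = CodingSequence("g", "s", "ATGAAATAA")
        with pytest.raises(PlacementError):
            apply_pcfm(cds, 4, PcfmTemplate("deletion", 2, "deletion", 1, 26))

    @pytest.mark.parametrize("tpl", ALL_TEMPLATES)
    def test_downstream_translation_restored(self, tpl):
        pool = make_control_pool(20, seed=6)
        rng = np.random.default_rng(7)
        for _ in range(50):
            g = pool[rng.integers(len(pool))]
            lo, hi = valid_positions(len(g.nt), tpl)
            pos = int(rng.integers(lo, hi))
            der = apply_pcfm(g, pos, tpl, rng)
            span_end = pos + tpl.ancestral_span
            k = -(-span_end // 3)
            assert translate(g.nt)[k:] == translate(der.nt)[k + tpl.net_offset // 3:]


class TestNullDistribution:
    def test_seed_reproducibility(self, del21_template):
        pool = make_control_pool(30, seed=2)
        a = build_null(pool, del21_template, "miyata", 200, seed=3)
        b = build_null(pool, del21_template, "miyata", 200, seed=3)
        assert np.array_equal(a.draws, b.draws)

    def test_percentile_boundaries(self, del21_template):
        pool = make_control_pool(30, seed=2)
        null = build_null(pool, del21_template, "miyata", 200, seed=3)
        low = null.with_observed(float(null.draws.min()) - 1e-9)
        high = null.with_observed(float(null.draws.max()))
        assert low.percentile_p == pytest.approx(1 / 201)
        assert high.percentile_p == 1.0

    def test_infeasible_template_rejected(self):
        tiny = [CodingSequence("g", "s", "ATGAAATAA")]
        with pytest.raises(ValueError, match="placement"):
            build_null(tiny, PcfmTemplate("deletion", 2, "deletion", 1, 50),
                       n_draws=10)

    def test_bonferroni_flags(self):
        assert bonferroni_significant([0.004, 0.2, 0.9], alpha=0.05) == \
            [True, False, False]


@pytest.fixture(scope="module")
def quartet_case(tree20, del21_template):
    edges = plantable_edges(tree20, min_leaves=2, max_leaves=5)
    cfg = SimConfig(tree=tree20, n_genes=1, gene_length_codons=200,
                    pairs=[PlantedPair(0, edges[0], del21_template)], seed=77)
    res = simulate(cfg)
    aln = res.alignments[0]
    pair = detect_in_alignment(aln, tree20)[0]
    return aln, tree20, pair


class TestQuartet:
    def test_states_defined_and_consistent(self, quartet_case):
        aln, phylo, pair = quartet_case
        q = ancestral_states(aln, phylo, pair)
        assert q.A and q.E
        # net -3 pair: the derived region is one codon shorter
        assert len(q.A) - len(q.E) == 1
        if q.n_substitutions == 0:
            assert q.A_mut is None and q.A_fr is None

    def test_no_substitution_branch_omits_intermediates(self, balanced4):
        base = "ATGAAACCCGGGTTTACTGACTAA"
        rows = {"a": "ATG--ACCCGGGTTTAC-GACTAA",
                "b": base, "c": base, "d": base}
        from pcfm.seqio import GeneAlignment
        aln = GeneAlignment("g", list("abcd"), rows)
        pair = detect_in_alignment(aln, balanced4)[0]
        q = ancestral_states(aln, balanced4, pair)
        assert q.n_substitutions == 0
        assert q.A_mut is None and q.A_fr is None
        # with no substitutions the derived region equals the pure
        # frameshift of the ancestor: d(A, E) is the full pair effect
        qd = quartet_distances(q, "miyata")
        assert set(qd.distances) == {("A", "E")}
        assert qd.hypothesis_subs_after is None

    def test_quartet_flags(self):
        from pcfm.effects import StateQuartet
        q = StateQuartet(A="GGG", E="GGG", A_mut="GGG", A_fr="WWW",
                         n_substitutions=1)
        qd = quartet_distances(q, "miyata")
        assert qd.hypothesis_subs_after is True  # d(A,E)=0 < d(A,A_fr)
        assert qd.distances[("A", "A_fr")] == pytest.approx(5.13)

    def test_descendant_trajectories(self, quartet_case):
        aln, phylo, pair = quartet_case
        traj = descendant_trajectories(aln, phylo, pair, "miyata")
        assert {t.species_id for t in traj} == set(pair.carrier_species)
        q = ancestral_states(aln, phylo, pair)
        from pcfm.effects import score_metric
        d_ae = score_metric("miyata", q.A, q.E)
        for t in traj:
            assert t.compensated == (t.distance_to_ancestor < d_ae)


class TestNullCalibration:
    def test_percentile_p_uniform_under_null(self, del21_template):
        pool = make_control_pool(100, seed=10)
        null = build_null(pool, del21_template, "miyata", 999, seed=11)
        rng = np.random.default_rng(12)
        feas = [(g, *valid_positions(len(g.nt), del21_template)) for g in pool]
        pvals = []
        for _ in range(300):
            g, lo, hi = feas[rng.integers(len(feas))]
            obs = pair_effect(g, int(rng.integers(lo, hi)), del21_template,
                              "miyata", rng)
            pvals.append(null.with_observed(obs).percentile_p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01
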