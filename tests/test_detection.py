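"""Pairing, postfiltering and positional statistics."""

import numpy as np
import pytest
from scipy import stats

from pcfm.detection import (DegenerateSpanError, PcfmRecord,
                            compare_position_distributions, pair_pcfms,
                            postfilter, relative_position)
from pcfm.indels import IndelEvent, infer_indels
from pcfm.pipeline import detect_in_alignment
from pcfm.seqio import GeneAlignment, quality_table


def make_event(kind, length, col_start, edge, gene_id="g"):
    return IndelEvent(
        gene_id=gene_id, kind=kind, length_nt=length,
        col_start=col_start, col_end=col_start + length,
        edge=frozenset(edge), descendant_species=frozenset(edge),
    )


def make_pair(kind5="deletion", len5=2, kind3="deletion", len3=1,
              edge5=("a", "b"), edge3=None, carriers=None,
              p1=30, p2=60, L=300):
    e5 = make_event(kind5, len5, p1, edge5)
    e3 = make_event(kind3, len3, p2 - len3, edge3 or edge5)
    return PcfmRecord(
        gene_id="g", indel_5p=e5, indel_3p=e3,
        spacer_nt=p2 - len3 - (p1 + len5), spacer_nt_ancestral=p2 - len3 - (p1 + len5),
        carrier_species=frozenset(carriers or edge5),
        p1=p1, p2=p2, cds_length=L,
    )


@pytest.fixture()
def quartet_alignment(balanced4):
    """One species (a) carries a compensatory deletion pair (2+1)."""
    #           0123456789...
    base = "ATGAAACCCGGGTTTACTGACTAA"
    rows = {
        "a": "ATG--ACCCGGGTTTAC-GACTAA",
        "b": base, "c": base, "d": base,
    }
    return GeneAlignment("g", list("abcd"), rows)


class TestPairPcfms:
    def test_compensatory_pair_detected(self, balanced4, quartet_alignment):
        aln = quartet_alignment
        events = infer_indels(aln, balanced4)
        quality = quality_table(aln)
        pairs = pair_pcfms(events, quality, aln)
        assert len(pairs) == 1
        p = pairs[0]
        assert p.combined_offset == -3
        assert p.carrier_species == frozenset("a")
        assert (p.indel_5p.length_nt, p.indel_3p.length_nt) == (2, 1)
        assert p.spacer_nt == 12

    def test_single_indel_gives_no_pair(self, balanced4):
        base = "ATGAAACCCGGGTAA"
        rows = {"a": "ATGAA-CCCGGGTAA", "b": base, "c": base, "d": base}
        aln = GeneAlignment("g", list("abcd"), rows)
        pairs = pair_pcfms(infer_indels(aln, balanced4), quality_table(aln), aln)
        assert pairs == []

    def test_three_frame_disrupting_indels_excluded(self, balanced4):
        # three 1-nt deletions restore the frame but the species is
        # considered unreliable and contributes nothing
        base = "ATGAAACCCGGGTTTAAACCCTAA"
        rows = {"a": "ATGA-ACC-GGGTT-AAACCCTAA",
                "b": base, "c": base, "d": base}
        aln = GeneAlignment("g", list("abcd"), rows)
        quality = quality_table(aln)
        assert quality["a"].passes  # frame is net-restored, ORF intact
        pairs = pair_pcfms(infer_indels(aln, balanced4), quality, aln)
        assert pairs == []

    def test_out_of_frame_species_fails_quality_and_contributes_nothing(
            self, balanced4):
        # two deletions with net offset -2 leave the carrier out of frame;
        # the quality filter removes it before pairing even runs
        base = "ATGAAACCCGGGTAA"
        rows = {"a": "ATGAA-CC-GGGTAA", "b": base, "c": base, "d": base}
        aln = GeneAlignment("g", list("abcd"), rows)
        quality = quality_table(aln)
        assert not quality["a"].passes
        pairs = pair_pcfms(infer_indels(aln, balanced4), quality, aln)
        assert pairs == []


class TestPostfilter:
    def test_filter_chain_is_nested(self):
        pairs = [
            make_pair(),                                    # del2+del1, 2 carriers
            make_pair(carriers=("a",), edge5=("a",)),       # 1 carrier
            make_pair(kind5="deletion", len5=4, kind3="deletion", len3=2),
            make_pair(edge3=("a",), edge5=("a", "b")),      # cross-edge
            make_pair(kind5="insertion", len5=1, kind3="deletion", len3=1),
        ]
        low = postfilter(pairs, "low_confidence")
        high = postfilter(pairs, "high_confidence")
        assert set(high) <= set(low) <= set(pairs)
        assert pairs[2] not in low      # length > 2
        assert pairs[3] not in low      # cross-edge
        assert pairs[1] in low and pairs[1] not in high  # carrier rule
        assert pairs[0] in high and pairs[4] in high

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            postfilter([], "strict")


class TestRelativePosition:
    @pytest.mark.parametrize("p1, p2, L, P", [
        (0, 30, 300, 0.0),
        (270, 300, 300, 1.0),
        (10, 20, 110, 0.1),
    ])
    def test_boundary_and_interior_values(self, p1, p2, L, P):
        pair = make_pair(p1=p1, p2=p2, L=L)
        assert relative_position(pair).P == pytest.approx(P, abs=1e-12)

    def test_full_span_degenerate(self):
        with pytest.raises(DegenerateSpanError):
            relative_position(make_pair(p1=0, p2=300, L=300))

    def test_extending_three_prime_flank_decreases_P(self):
        base = relative_position(make_pair(p1=100, p2=130, L=300)).P
        extended = relative_position(make_pair(p1=100, p2=130, L=400)).P
        assert extended < base


class TestPositionDistributions:
    def test_uniform_samples_usually_pass_ks(self):
        # under the null the one-sample KS p exceeds 0.05 for the vast
        # majority of seeds; check a fixed panel
        passing = 0
        for seed in range(10):
            obs = np.random.default_rng(seed).uniform(size=500)
            report = compare_position_distributions(obs, None, n_boot=5, seed=1)
            passing += report.ks_uniform_p > 0.05
        assert passing >= 9

    def test_identical_samples_have_zero_two_sample_stat(self):
        obs = [0.1, 0.4, 0.8]
        report = compare_position_distributions(obs, obs, n_boot=10, seed=0)
        assert report.ks_twosample_stat == 0.0

    def test_clustered_positions_reject_uniformity(self):
        obs = np.linspace(0.01, 0.05, 40)
        report = compare_position_distributions(obs, None, n_boot=10, seed=0)
        assert report.ks_uniform_p < 0.001

    def test_bootstrap_bands_bracket_density(self):
        rng = np.random.default_rng(3)
        obs = rng.uniform(size=300)
        report = compare_position_distributions(obs, None, n_boot=200, seed=4)
        assert np.all(report.density_ci_low <= report.density_ci_high)
        inside = (report.density >= report.density_ci_low) & \
                 (report.density <= report.density_ci_high)
        assert inside.mean() > 0.8

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            compare_position_distributions([], None)
        with pytest.raises(ValueError):
            compare_position_distributions([0.5], None, n_boot=0)


class TestDetectInAlignment:
    def test_gap_free_gene_yields_nothing(self, balanced4):
        base = "ATGAAACCCGGGTAA"
        aln = GeneAlignment("g", list("abcd"), {s: base for s in "abcd"})
        assert detect_in_alignment(aln, balanced4) == []

    def test_pseudogenized_rows_do_not_block_detection(self, balanced4,
                                                       quartet_alignment):
        aln = quartet_alignment
        rows = dict(aln.rows)
        # a carries the pair on its terminal edge; break d's start codon:
        # fewer than 4 passing species -> gene skipped entirely
        rows["d"] = "CTG" + rows["d"][3:]
        broken = GeneAlignment("g", list("abcd"), rows)
        assert detect_in_alignment(broken, balanced4) == []
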