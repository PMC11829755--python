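import math

import numpy as np
import pytest

from mztseq import (
    cluster_enrichment_at_threshold, fisher_right_tail, gene_max_score,
    optimize_threshold, pwm_from_counts, read_jaspar, score_site,
)
from mztseq._seq import revcomp


def random_pwm(rng, width=8):
    counts = rng.integers(0, 20, size=(4, width)).astype(float)
    counts[rng.integers(0, 4), :] += 5  # avoid zero columns
    return pwm_from_counts(counts, pseudocount=0.8)


class TestPWMConstruction:
    def test_pure_counts_no_pseudocount(self):
        pwm = pwm_from_counts(np.array([[10.0], [0], [0], [0]]), pseudocount=0)
        np.testing.assert_allclose(pwm.matrix[:, 0], [1, 0, 0, 0])

    def test_flat_counts_equal_background(self):
        pwm = pwm_from_counts(np.full((4, 3), 5.0))
        np.testing.assert_allclose(pwm.matrix, 0.25)

    def test_pseudocount_arithmetic(self):
        pwm = pwm_from_counts(np.array([[3.0], [1], [0], [0]]), pseudocount=1)
        assert pwm.matrix[0, 0] == pytest.approx(3.25 / 5)

    def test_zero_column_without_pseudocount_rejected(self):
        with pytest.raises(ValueError):
            pwm_from_counts(np.zeros((4, 2)), pseudocount=0)

    def test_jaspar_roundtrip(self, tmp_path):
        path = tmp_path / "motif.jaspar"
        path.write_text(
            ">MA0001.1 test\n"
            "A [ 10  0  2 ]\nC [ 0 10  2 ]\nG [ 0  0  4 ]\nT [ 0  0  2 ]\n"
        )
        pwms = read_jaspar(path)
        (pwm,) = pwms.values()
        assert pwm.width == 3
        assert pwm.consensus[:2] == "AC"


class TestScoring:
    def test_background_pwm_scores_zero(self):
        pwm = pwm_from_counts(np.full((4, 5), 2.0))
        assert score_site(pwm, "ACGTA") == pytest.approx(0.0)

    def test_two_position_arithmetic(self):
        m = np.array([[0.8, 0.8], [0.1, 0.1], [0.05, 0.05], [0.05, 0.05]])
        pwm = pwm_from_counts(m * 100, pseudocount=0)
        assert score_site(pwm, "AA") == pytest.approx(2 * math.log2(3.2), abs=1e-9)

    def test_consensus_maximizes_score(self, rng):
        pwm = random_pwm(rng)
        best = score_site(pwm, pwm.consensus)
        for _ in range(50):
            site = "".join(rng.choice(list("ACGT"), size=pwm.width))
            assert score_site(pwm, site) <= best + 1e-12

    def test_n_scores_as_background(self):
        pwm = pwm_from_counts(np.array([[10.0, 10], [0, 0], [0, 0], [0, 0]]), pseudocount=0.8)
        assert score_site(pwm, "NA") == pytest.approx(score_site(pwm, "AA") - score_site(pwm, "AN"))

    def test_matches_per_position_oracle(self, rng):
        for _ in range(20):
            pwm = random_pwm(rng, width=int(rng.integers(4, 12)))
            site = "".join(rng.choice(list("ACGT"), size=pwm.width))
            want = sum(
                math.log2(pwm.matrix["ACGT".index(b), j] / pwm.background["ACGT".index(b)])
                for j, b in enumerate(site)
            )
            assert score_site(pwm, site) == pytest.approx(want, abs=1e-9)

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            score_site(random_pwm(rng, 6), "ACGT")


class TestGeneMaxScore:
    def test_consensus_in_one_of_three_promoters(self, rng):
        pwm = random_pwm(rng, 10)
        bg = ["".join(rng.choice(list("ACGT"), size=60)) for _ in range(2)]
        planted = bg[0][:20] + pwm.consensus + bg[0][20:50]
        score = gene_max_score(pwm, bg + [planted])
        assert score >= score_site(pwm, pwm.consensus) - 1e-9

    def test_invariant_under_promoter_order_and_strand_flip(self, rng):
        pwm = random_pwm(rng, 8)
        proms = ["".join(rng.choice(list("ACGT"), size=50)) for _ in range(3)]
        a = gene_max_score(pwm, proms)
        assert gene_max_score(pwm, proms[::-1]) == pytest.approx(a)
        flipped = [revcomp(proms[0])] + proms[1:]
        assert gene_max_score(pwm, flipped) == pytest.approx(a)

    def test_reverse_strand_plant_found_only_with_both(self, rng):
        pwm = random_pwm(rng, 10)
        bg = "".join(rng.choice(list("ACGT"), size=60))
        rev_plant = bg[:20] + revcomp(pwm.consensus) + bg[20:]
        both = gene_max_score(pwm, [rev_plant], strands="both")
        fwd = gene_max_score(pwm, [rev_plant], strands="forward")
        assert both >= score_site(pwm, pwm.consensus) - 1e-9
        assert fwd < both

    def test_short_promoter_rejected(self, rng):
        with pytest.raises(ValueError, match="shorter"):
            gene_max_score(random_pwm(rng, 10), ["ACGT"])


class TestThreshold:
    def make_separated(self):
        scores = {f"c{i}": 12.0 for i in range(20)}
        scores.update({f"b{i}": 4.0 for i in range(80)})
        member = {g: g.startswith("c") for g in scores}
        return scores, member

    def test_separated_design_finds_discriminating_threshold(self):
        scores, member = self.make_separated()
        th = optimize_threshold(scores, member)
        assert 5 < th.threshold <= 12
        assert th.p_at_threshold < 0.05
        assert th.max_score_observed == 12.0

    def test_chosen_p_equals_exhaustive_rescan(self, rng):
        genes = [f"g{i}" for i in range(60)]
        scores = {g: float(rng.uniform(0, 15)) for g in genes}
        member = {g: bool(rng.random() < 0.3) for g in genes}
        th = optimize_threshold(scores, member)
        ps = []
        for t in sorted({s for s in scores.values() if s > 5}):
            has = {g: scores[g] >= t for g in genes}
            a = sum(member[g] and has[g] for g in genes)
            b = sum(member[g] and not has[g] for g in genes)
            c = sum(not member[g] and has[g] for g in genes)
            d = sum(not member[g] and not has[g] for g in genes)
            ps.append(fisher_right_tail(a, b, c, d))
        assert th.p_at_threshold == pytest.approx(min(ps), rel=1e-12)

    def test_permuted_labels_do_not_beat_planted(self, rng):
        scores, member = self.make_separated()
        planted_p = optimize_threshold(scores, member).p_at_threshold
        perm = rng.permutation(list(member.values()))
        shuffled = dict(zip(member, perm.tolist()))
        assert optimize_threshold(scores, shuffled).p_at_threshold >= planted_p

    def test_single_candidate_returned_unchanged(self):
        scores = {"a": 7.0, "b": 3.0, "c": 2.0}
        th = optimize_threshold(scores, {"a": True, "b": False, "c": False})
        assert th.threshold == 7.0

    def test_no_score_above_minimum_rejected(self):
        with pytest.raises(ValueError):
            optimize_threshold({"a": 4.0}, {"a": True})


class TestClusterEnrichment:
    def test_planted_cluster_attains_minimal_p(self):
        cluster_map = {f"a{i}": "A" for i in range(15)}
        cluster_map.update({f"c{i}": "C" for i in range(15)})
        cluster_map.update({f"b{i}": None for i in range(70)})
        scores = {"m": {g: (9.0 if g.startswith("a") else 1.0) for g in cluster_map}}
        table = cluster_enrichment_at_threshold(scores, {"m": 6.0}, cluster_map)
        best = table.loc[table.p.idxmin()]
        assert best.cluster == "A"
        assert (table[["a", "b", "c", "d"]].sum(axis=1) == 100).all()

    def test_motif_above_threshold_nowhere_gives_p_one(self):
        cluster_map = {"a": "A", "b": None, "c": None}
        scores = {"m": {g: 1.0 for g in cluster_map}}
        table = cluster_enrichment_at_threshold(scores, {"m": 6.0}, cluster_map)
        assert (table.p == 1.0).all()
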