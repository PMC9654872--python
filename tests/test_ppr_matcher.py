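"""PPR codes, PWM construction, exact p-values and window scanning."""

from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orgredit.orgdata import ValidationError
from orgredit.ppr_matcher import (
    PprCodeTable,
    PprMotif,
    PprProtein,
    PwmModel,
    build_pwm,
    extract_codes,
    predict_interactions,
    pwm_pvalue,
    scan_window,
)

ONE_HOT_A = [0.97, 0.01, 0.01, 0.01]


def one_hot_pwm(consensus):
    rows = []
    for base in consensus:
        row = [0.0] * 4
        row["ACGT".index(base)] = 1.0
        rows.append(row)
    return PwmModel(np.array(rows), pseudocount=0.0)


def random_pwm(rng, length, concentration=1.0):
    probs = rng.dirichlet([concentration] * 4, size=length)
    return PwmModel(probs, pseudocount=0.0)


def enumerate_tail(pwm, score):
    """Independent oracle: exact tail probability by full enumeration of
    all 4^L background sequences (vectorised, no DP)."""
    scores = np.zeros(1)
    probs = np.ones(1)
    for i in range(pwm.length):
        scores = (scores[:, None] + pwm.log_odds[i][None, :]).ravel()
        probs = (probs[:, None] * pwm.background[None, :]).ravel()
    keep = np.isfinite(scores) & (scores >= score - 1e-12)
    return float(probs[keep].sum())


class TestExtractCodes:
    def test_positional_extraction(self):
        motif_seq = "VTYTTLIDGLCKAGKLSEAMELFREMEEKGIKPND"
        protein = extract_codes("p1", [("P", motif_seq)])
        (motif,) = protein.motifs
        assert motif.triple == ("T", "T", "D")

    def test_order_preserved(self):
        protein = extract_codes("p1", [("P", "AGMDKF"), ("S", "SHQWLM")])
        assert [m.triple for m in protein.motifs] == [
            ("G", "K", "F"),
            ("H", "L", "M"),
        ]

    def test_short_motif_rejected(self):
        with pytest.raises(ValidationError, match="shorter than 5"):
            extract_codes("p1", [("P", "ACDE")])

    def test_protein_without_pls_motif_rejected(self):
        with pytest.raises(ValidationError, match="nucleotide-specifying"):
            PprProtein("p1", (PprMotif("E", "V", "T", "D"),))


class TestCodeTable:
    def table(self):
        return PprCodeTable(
            triples={("T", "N", "D"): ONE_HOT_A},
            pairs={("N", "N"): [0.01, 0.97, 0.01, 0.01]},
            singles={"S": [0.01, 0.01, 0.97, 0.01]},
        )

    def test_lookup_falls_back_triple_pair_single_background(self):
        table = self.table()
        assert table.lookup(PprMotif("P", "T", "N", "D"))[0] == 0.97
        assert table.lookup(PprMotif("P", "A", "N", "N"))[1] == 0.97
        assert table.lookup(PprMotif("P", "A", "A", "S"))[2] == 0.97
        assert (table.lookup(PprMotif("P", "A", "A", "A")) == 0.25).all()

    def test_tsv_round_trip(self, tmp_path):
        table = self.table()
        path = tmp_path / "codes.tsv"
        table.to_tsv(path)
        back = PprCodeTable.from_tsv(path)
        assert set(back.triples) == set(table.triples)
        assert set(back.pairs) == set(table.pairs)
        assert np.allclose(back.background, table.background)

    def test_unnormalised_vector_rejected(self):
        with pytest.raises(ValidationError, match="sum"):
            PprCodeTable(triples={("T", "N", "D"): [0.5, 0.5, 0.5, 0.5]})


class TestBuildPwm:
    def test_single_motif_column_equals_code_vector(self):
        table = PprCodeTable(triples={("T", "N", "D"): ONE_HOT_A})
        protein = PprProtein("p", (PprMotif("P", "T", "N", "D"),))
        pwm = build_pwm(protein, table, pseudocount=0.0)
        assert np.allclose(pwm.probs[0], ONE_HOT_A)

    def test_unknown_triple_uses_pair_vector(self):
        pair_vec = [0.01, 0.97, 0.01, 0.01]
        table = PprCodeTable(
            triples={("T", "N", "D"): ONE_HOT_A}, pairs={("Q", "E"): pair_vec}
        )
        protein = PprProtein("p", (PprMotif("P", "W", "Q", "E"),))
        pwm = build_pwm(protein, table, pseudocount=0.0)
        assert np.allclose(pwm.probs[0], pair_vec)

    def test_five_motif_pwm_matches_hand_assembly(self):
        vecs = {
            ("A", "A", "A"): [0.7, 0.1, 0.1, 0.1],
            ("C", "C", "C"): [0.1, 0.7, 0.1, 0.1],
            ("G", "G", "G"): [0.1, 0.1, 0.7, 0.1],
        }
        table = PprCodeTable(triples=vecs)
        motifs = (
            PprMotif("P", "A", "A", "A"),
            PprMotif("L", "C", "C", "C"),
            PprMotif("E", "A", "A", "A"),  # no column: deaminase arm
            PprMotif("S", "G", "G", "G"),
            PprMotif("DYW", "C", "C", "C"),  # no column
        )
        pwm = build_pwm(PprProtein("p", motifs), table, pseudocount=0.0)
        hand = np.array(
            [vecs[("A", "A", "A")], vecs[("C", "C", "C")], vecs[("G", "G", "G")]]
        )
        assert pwm.length == 3
        assert np.allclose(pwm.probs, hand)

    def test_empty_code_table_rejected(self):
        protein = PprProtein("p", (PprMotif("P", "T", "N", "D"),))
        with pytest.raises(ValidationError, match="empty code table"):
            build_pwm(protein, PprCodeTable())

    @settings(derandomize=True, max_examples=30)
    @given(pseudocount=st.floats(0.0, 10.0))
    def test_columns_stay_normalised_for_any_pseudocount(self, pseudocount):
        rng = np.random.default_rng(0)
        probs = rng.dirichlet([0.5] * 4, size=6)
        pwm = PwmModel(probs, pseudocount=pseudocount)
        assert np.allclose(pwm.probs.sum(axis=1), 1.0)


class TestScanWindow:
    def test_one_hot_consensus_found_once(self):
        pwm = one_hot_pwm("ACGT")
        window = "TTTTTACGTTTTTT"
        hits = scan_window(pwm, window, threshold_p=0.01)
        assert len(hits) == 1
        assert hits[0].offset == 5
        assert hits[0].p_value == pytest.approx((1 / 4) ** 4)

    def test_uniform_pwm_scores_zero_everywhere(self):
        pwm = PwmModel(np.full((4, 4), 0.25), pseudocount=0.0)
        window = "ACGTACGTACGT"
        assert scan_window(pwm, window, threshold_p=0.999) == []
        everything = scan_window(pwm, window, threshold_p=1.0)
        assert all(h.score == pytest.approx(0.0) for h in everything)
        assert all(h.p_value == 1.0 for h in everything)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_one_hot_hits_equal_string_matches(self, seed):
        rng = np.random.default_rng(seed)
        consensus = "".join(rng.choice(list("ACGT"), size=5))
        window = "".join(rng.choice(list("ACGT"), size=200))
        pwm = one_hot_pwm(consensus)
        hits = scan_window(pwm, window, threshold_p=(1 / 4) ** 5)
        expected = [
            i for i in range(len(window) - 4) if window[i : i + 5] == consensus
        ]
        assert sorted(h.offset for h in hits) == expected

    def test_hits_sorted_by_p_then_offset(self):
        rng = np.random.default_rng(4)
        pwm = random_pwm(rng, 6, concentration=0.3)
        window = "".join(rng.choice(list("ACGT"), size=100))
        hits = scan_window(pwm, window, threshold_p=1.0)
        keys = [(h.p_value, h.offset) for h in hits]
        assert keys == sorted(keys)

    def test_window_shorter_than_pwm_rejected(self):
        with pytest.raises(ValidationError, match="shorter"):
            scan_window(one_hot_pwm("ACGTAC"), "ACGT")

    def test_u_and_t_are_equivalent(self):
        pwm = one_hot_pwm("ACGT")
        assert (
            scan_window(pwm, "AACGUA", threshold_p=0.01)[0].offset
            == scan_window(pwm, "AACGTA", threshold_p=0.01)[0].offset
        )

    def test_padding_shifts_offsets_without_changing_scores(self):
        rng = np.random.default_rng(9)
        pwm = random_pwm(rng, 5, concentration=0.3)
        window = "".join(rng.choice(list("ACGT"), size=51))
        pad = "".join(rng.choice(list("ACGT"), size=7))
        base = scan_window(pwm, window, threshold_p=1.0)
        padded = scan_window(pwm, pad + window, threshold_p=1.0)
        inner = [h for h in padded if h.offset >= 7 and h.offset <= 7 + 51 - 5]
        assert {(h.offset - 7, round(h.score, 9)) for h in inner} >= {
            (h.offset, round(h.score, 9)) for h in base
        }


class TestPValues:
    def test_one_hot_maximum_score(self):
        pwm = one_hot_pwm("ACG")
        assert pwm_pvalue(pwm, pwm.max_score()) == pytest.approx(0.015625)

    def test_minimum_score_has_probability_one(self):
        rng = np.random.default_rng(2)
        pwm = random_pwm(rng, 5)
        min_score = float(pwm.log_odds.min(axis=1).sum())
        assert pwm_pvalue(pwm, min_score) == pytest.approx(1.0)

    def test_monotone_non_increasing_in_score(self):
        rng = np.random.default_rng(3)
        pwm = random_pwm(rng, 7)
        scores = np.linspace(
            pwm.log_odds.min(axis=1).sum(), pwm.max_score(), 50
        )
        pvals = [pwm_pvalue(pwm, s) for s in scores]
        assert all(a >= b for a, b in zip(pvals, pvals[1:]))

    @pytest.mark.parametrize("length", [3, 5, 8])
    @pytest.mark.parametrize("seed", [0, 1])
    def test_dp_matches_exhaustive_enumeration(self, length, seed):
        """The lattice DP must agree with full 4^L enumeration up to the
        documented discretization slack."""
        rng = np.random.default_rng(seed)
        pwm = random_pwm(rng, length, concentration=0.7)
        bound = pwm.discretization_bound
        idx = rng.integers(0, 4, size=(20, length))
        for seq in idx:
            score = float(pwm.log_odds[np.arange(length), seq].sum())
            p_dp = pwm_pvalue(pwm, score)
            assert enumerate_tail(pwm, score) <= p_dp + 1e-12
            assert p_dp <= enumerate_tail(pwm, score - bound) + 1e-12

    def test_nonuniform_background_enumeration(self):
        rng = np.random.default_rng(7)
        probs = rng.dirichlet([0.8] * 4, size=4)
        pwm = PwmModel(probs, background=[0.4, 0.1, 0.1, 0.4], pseudocount=0.0)
        score = pwm.max_score() * 0.5
        p_dp = pwm_pvalue(pwm, score)
        bound = pwm.discretization_bound
        assert enumerate_tail(pwm, score) <= p_dp + 1e-12
        assert p_dp <= enumerate_tail(pwm, score - bound) + 1e-12

    def test_decoy_calibration_hit_rate_tracks_threshold(self):
        """For background-drawn windows, the fraction of offsets with
        p <= t approximates t (Monte-Carlo, fixed seed)."""
        rng = np.random.default_rng(11)
        pwm = random_pwm(rng, 10, concentration=2.0)
        threshold = 0.01
        n_offsets = 0
        n_hits = 0
        for _ in range(200):
            window = "".join(rng.choice(list("ACGT"), size=120))
            hits = scan_window(pwm, window, threshold_p=threshold)
            n_hits += len(hits)
            n_offsets += 120 - pwm.length + 1
        rate = n_hits / n_offsets
        sigma = np.sqrt(threshold * (1 - threshold) / n_offsets)
        assert abs(rate - threshold) < 5 * sigma + 0.002


class TestPredictInteractions:
    def test_zero_proteins_give_empty_outputs(self, clean_truth):
        table = PprCodeTable(triples={("T", "N", "D"): ONE_HOT_A})
        result = predict_interactions(
            [], table, clean_truth.sites, clean_truth.genome, clean_truth.genes
        )
        assert result.table.empty
        assert result.n_proteins_hit == 0
        assert (result.summary["n_proteins"] == 0).all()
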