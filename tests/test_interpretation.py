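import numpy as np
import pytest

from g4scan.interpretation import (AttributionProfile, flank_perturbation,
                                   integrated_attributions,
                                   positional_attribution,
                                   select_reference_baselines,
                                   significant_kmers)
from g4scan.subtype_rules import find_motifs


class LinearTokenModel:
    """f(x) = sum_t w_t . x_t with per-base embeddings; attributions have
    the closed form (x - baseline) * w."""

    def __init__(self, length=12, d=6, seed=0):
        rng = np.random.default_rng(seed)
        self.w = rng.normal(size=(length, d))
        self.emb = {c: rng.normal(size=d) for c in "ACGU"}

        class _V:
            k = 1

        self.vocab = _V()

    def input_embeddings(self, seq):
        return np.stack([self.emb[c] for c in seq])

    def predict_from_embeddings(self, e):
        return float((self.w[: len(e)] * e).sum())

    def gradient_from_embeddings(self, e):
        return self.w[: len(e)].copy()


class TestIntegratedGradientsLinear:
    def test_closed_form_for_any_step_count(self):
        model = LinearTokenModel()
        seq, base = "GGGAGGGAGGGA", "AUCGAUCGAUCG"
        x = model.input_embeddings(seq)
        b = model.input_embeddings(base)
        expect = ((x - b) * model.w).sum(axis=1)
        for steps in (1, 3, 200):
            prof = integrated_attributions(model, seq, [base], steps=steps,
                                           motif_span=(999, 999))
            assert np.allclose(prof.raw_token_attributions, expect, atol=1e-10)

    def test_input_equal_to_baseline_is_all_zero(self):
        model = LinearTokenModel()
        prof = integrated_attributions(model, "ACGUACGUACGU", ["ACGUACGUACGU"],
                                       steps=10, motif_span=(999, 999))
        assert np.allclose(prof.raw_token_attributions, 0.0)

    def test_completeness_is_exact_for_linear_model(self):
        model = LinearTokenModel()
        prof = integrated_attributions(model, "GGGAGGGAGGGA", ["AUCGAUCGAUCG"],
                                       steps=5, motif_span=(999, 999))
        assert prof.completeness_gap < 1e-10

    def test_zero_steps_rejected(self):
        with pytest.raises(ValueError):
            integrated_attributions(LinearTokenModel(), "ACGUACGUACGU",
                                    ["ACGUACGUACGU"], steps=0)


class TestIntegratedGradientsMiniLm:
    def test_completeness_within_one_percent(self, trained_binary_model):
        clf = trained_binary_model["clf"]
        pos = [s for s, y in zip(trained_binary_model["x_test"],
                                 trained_binary_model["y_test"]) if y][:2]
        neg = [s for s, y in zip(trained_binary_model["x_test"],
                                 trained_binary_model["y_test"]) if not y][:3]
        for seq in pos:
            prof = integrated_attributions(clf, seq, neg, steps=200)
            denom = abs(prof.score_difference)
            if denom > 1e-3:
                assert prof.completeness_gap / denom < 0.01

    def test_motif_tokens_zeroed(self, trained_binary_model):
        clf = trained_binary_model["clf"]
        seq = next(s for s, y in zip(trained_binary_model["x_test"],
                                     trained_binary_model["y_test"]) if y)
        base = next(s for s, y in zip(trained_binary_model["x_test"],
                                      trained_binary_model["y_test"]) if not y)
        prof = integrated_attributions(clf, seq, [base], steps=20)
        assert prof.motif_span is not None
        ms, me = prof.motif_span
        for t, val in enumerate(prof.token_attributions):
            if t + 1 <= me and t + 6 >= ms:
                assert val == 0.0


class _RepStub:
    """Model stub with fixed scalar representations keyed by sequence."""

    def __init__(self, reps):
        self.reps = reps

    def representation(self, seq):
        return np.array([self.reps[seq]])


class TestBaselineSelection:
    def test_nearest_to_median(self):
        model = _RepStub({"a": 0.0, "b": 1.0, "c": 2.0, "d": 10.0})
        picked = select_reference_baselines(
            model, [("a", "a"), ("b", "b"), ("c", "c"), ("d", "d")], n=3)
        assert {pid for pid, _ in picked} == {"a", "b", "c"}

    def test_identical_representations_tie_break_by_id(self):
        model = _RepStub({"x": 1.0, "y": 1.0, "z": 1.0})
        picked = select_reference_baselines(
            model, [("z", "z"), ("x", "x"), ("y", "y")], n=2)
        assert [pid for pid, _ in picked] == ["x", "y"]

    def test_n_one_returns_median_nearest(self):
        model = _RepStub({"a": 0.0, "b": 5.0, "c": 6.0})
        picked = select_reference_baselines(
            model, [("a", "a"), ("b", "b"), ("c", "c")], n=1)
        assert picked[0][0] == "b"

    def test_set_smaller_than_n_rejected(self):
        with pytest.raises(ValueError):
            select_reference_baselines(_RepStub({"a": 0.0}), [("a", "a")], n=3)


def _profile(sequence, attributions, motif_span):
    attr = np.asarray(attributions, dtype=float)
    return AttributionProfile(
        sequence_id="p", sequence=sequence, k=6,
        token_attributions=attr, raw_token_attributions=attr.copy(),
        completeness_gap=0.0, score_difference=0.0, motif_span=motif_span)


class TestSignificance:
    def test_reference_like_scores_not_significant(self):
        rng = np.random.default_rng(0)
        ref = rng.normal(0, 1, 1000)
        seq = "AUCAUC" + "A" * 10  # no motif; all tokens testable
        profs = [_profile(seq, rng.normal(0, 1, 11), None) for _ in range(6)]
        table = significant_kmers(profs, ref)
        assert not table["significant"].any()

    def test_planted_outlier_token_is_significant(self):
        rng = np.random.default_rng(1)
        ref = rng.normal(0, 1, 1000)
        seq = "GUCAUCGUCAUCGUCA"
        profs = []
        for _ in range(8):
            attr = rng.normal(0, 1, len(seq) - 5)
            attr[0] = 10.0 + rng.normal(0, 0.1)  # token GUCAUC planted high
            profs.append(_profile(seq, attr, None))
        table = significant_kmers(profs, ref)
        assert bool(table.set_index("kmer").loc["GUCAUC", "significant"])
        assert profs[0].significant[0]

    def test_degenerate_identical_values(self):
        ref = np.zeros(100)
        profs = [_profile("AUCAUCAUCAUC", np.zeros(7), None) for _ in range(3)]
        table = significant_kmers(profs, ref)
        assert (table["p"] == 1.0).all()

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            significant_kmers([_profile("AUCAUCAUCAUC", np.zeros(7), None)],
                              np.array([]))


class TestPositionalProjection:
    def _sig_profile(self):
        seq = "A" * 10 + "GGGAGGGAGGGAGGG" + "A" * 10
        span = find_motifs(seq)[0]
        n_tok = len(seq) - 5
        attr = np.zeros(n_tok)
        attr[0], attr[1] = 0.2, 0.5  # two tokens covering early flank
        prof = _profile(seq, attr, span)
        prof.significant = np.zeros(n_tok, dtype=bool)
        prof.significant[[0, 1]] = True
        return prof, span

    def test_max_over_covering_significant_tokens(self):
        prof, span = self._sig_profile()
        table = positional_attribution(prof, k=1)
        # position 6 is inside tokens 1..6; tokens 0 and 1 cover it
        assert table.set_index("position").loc[6, "score"] == 0.5

    def test_positions_covered_only_by_nonsignificant_tokens_zero(self):
        prof, span = self._sig_profile()
        table = positional_attribution(prof, k=1)
        assert table.set_index("position").loc[9, "score"] == 0.0

    def test_motif_positions_zero(self):
        prof, span = self._sig_profile()
        table = positional_attribution(prof, k=1).set_index("position")
        for pos in range(span[0], span[1] + 1):
            assert table.loc[pos, "score"] == 0.0

    def test_window_limited_to_flank(self):
        prof, span = self._sig_profile()
        table = positional_attribution(prof, k=2, flank=5)
        assert table["position"].min() >= span[0] - 5
        assert table["position"].max() <= span[1] + 5

    def test_requires_significance_flags(self):
        prof = _profile("A" * 10 + "GGGAGGGAGGGAGGG", np.zeros(20), (11, 25))
        with pytest.raises(ValueError):
            positional_attribution(prof, k=1)


class TestFlankPerturbation:
    def test_oracle_invariance_and_bookkeeping(self, oracle):
        seq = "AGCA" + "A" * 6 + "GGGAGGGAGGGAGGG" + "A" * 6 + "CGUA"
        summary = flank_perturbation(oracle, [seq, seq], flank=10)
        assert summary.n_sequences == 2
        table = summary.table
        # only G>C and C>G cells exist
        assert set(table["mutation"]) <= {"G>C", "C>G"}
        # flank substitutions never touch the motif: oracle delta stays 0
        assert (table["mean_delta"] == 0.0).all()
        # both sequences carry the same bases: every cell counts 2
        assert (table["n"] == 2).all()

    def test_au_positions_not_perturbed(self, oracle):
        seq = "AU" * 5 + "GGGAGGGAGGGAGGG" + "AU" * 5
        summary = flank_perturbation(oracle, [seq], flank=10)
        assert summary.table.empty  # flanks contain no G or C

    def test_sequences_without_motif_skipped(self, oracle):
        summary = flank_perturbation(oracle, ["AUCAUCAUCAUCAUC"], flank=10)
        assert summary.n_skipped == 1 and summary.n_sequences == 0

    def test_gc_direction_with_g4hunter_backed_scorer(self):
        # with a scorer whose physics make flank guanines stabilizing
        # (G4Hunter window mean squashed to a probability), G>C flank
        # substitutions must lower the score and C>G must raise it
        from g4scan.scorers import g4hunter_window_scores

        class HunterProb:
            name = "hunterprob"

            def predict_prob(self, seq):
                s = g4hunter_window_scores(seq, window=60).sequence_score
                return (s + 4.0) / 8.0

        rng = np.random.default_rng(0)
        seqs = []
        for _ in range(10):
            flank = "".join(rng.choice(list("ACGU"), 20))
            flank2 = "".join(rng.choice(list("ACGU"), 20))
            seqs.append(flank + "GGGAGGGAGGGAGGG" + flank2)
        summary = flank_perturbation(HunterProb(), seqs, flank=15,
                                     min_wt_score=0.5)
        near = summary.table[summary.table["rel_position"].abs() <= 10]
        gc = near[near["mutation"] == "G>C"]
        cg = near[near["mutation"] == "C>G"]
        mean_gc = np.average(gc["mean_delta"], weights=gc["n"])
        mean_cg = np.average(cg["mean_delta"], weights=cg["n"])
        assert mean_gc < 0 < mean_cg

    def test_minilm_perturbation_summary_structure(self, trained_binary_model):
        clf = trained_binary_model["clf"]
        seqs = [s for s, y in zip(trained_binary_model["x_test"],
                                  trained_binary_model["y_test"]) if y][:8]
        summary = flank_perturbation(clf, seqs, flank=15, min_wt_score=0.7)
        table = summary.table
        assert set(table["mutation"]) <= {"G>C", "C>G"}
        assert (table["rel_position"].abs() <= 15 + 1).all()
        assert (table["n"] >= 1).all()
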