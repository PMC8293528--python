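"""Scoring rules, F_beta arithmetic, error breakdowns, gold-file IO."""

import itertools

import pytest

from residuefinder import (
    FN_CLASSES,
    FP_CLASSES,
    EvalResult,
    InvalidMentionError,
    error_breakdown,
    f_beta,
    load_gold_file,
    precision_recall,
    save_gold_file,
    score,
)


def brute_force_counts(extracted, gold, mode):
    """Enumeration oracle: walk every key on either side."""
    tp = fp = fn = 0
    for doc in set(extracted) | set(gold):
        e = dict(extracted.get(doc, {}))
        g = dict(gold.get(doc, {}))
        if mode == "single":
            e = {k: 1 for k in e}
            g = {k: 1 for k in g}
        for key in set(e) | set(g):
            ec, gc = e.get(key, 0), g.get(key, 0)
            tp += min(ec, gc)
            fp += max(ec - gc, 0)
            fn += max(gc - ec, 0)
    return tp, fp, fn


class TestScore:
    def test_set_rules_single_mode(self):
        result = score({"d": {"A64G": 1}}, {"d": {"A64G": 1, "S56": 1}})
        assert (result.tp, result.fp, result.fn) == (1, 0, 1)

    def test_empty_extraction(self):
        gold = {"d1": {"S56": 1}, "d2": {"A64G": 1, "G2": 1}}
        result = score({}, gold)
        assert (result.tp, result.fp, result.fn) == (0, 0, 3)

    def test_full_mode_multiset_intersection(self):
        result = score({"d": {"S56": 3}}, {"d": {"S56": 1}}, mode="full")
        assert (result.tp, result.fp, result.fn) == (1, 2, 0)

    def test_single_mode_clamps_counts(self):
        result = score({"d": {"S56": 3}}, {"d": {"S56": 1}}, mode="single")
        assert (result.tp, result.fp, result.fn) == (1, 0, 0)

    def test_iterables_accepted(self):
        result = score({"d": ["S56", "A64G"]}, {"d": ["S56"]})
        assert (result.tp, result.fp, result.fn) == (1, 1, 0)

    def test_unparseable_gold_key_names_document_and_key(self):
        with pytest.raises(InvalidMentionError, match=r"doc9.*S0"):
            score({"doc9": {"S56": 1}}, {"doc9": {"S0": 1}})

    def test_swap_symmetry_exchanges_fp_and_fn(self):
        extracted = {"d1": {"S56": 1, "A64G": 1}, "d2": {"G2": 1}}
        gold = {"d1": {"S56": 1, "T7": 1}, "d2": {}}
        forward = score(extracted, gold)
        backward = score(gold, extracted)
        assert (forward.tp, forward.fp, forward.fn) == (backward.tp, backward.fn, backward.fp)

    def test_agreement_with_enumeration_oracle_on_small_cases(self):
        keys = ["S56", "A64G", "G2"]
        cases = []
        for e_counts in itertools.product([0, 1, 2], repeat=3):
            cases.append(dict(k for k in zip(keys, e_counts) if k[1]))
        for i, e in enumerate(cases):
            g = cases[(i * 7 + 3) % len(cases)]
            for mode in ("single", "full"):
                result = score({"d": e}, {"d": g}, mode=mode)
                assert (result.tp, result.fp, result.fn) == brute_force_counts(
                    {"d": e}, {"d": g}, mode
                )


class TestPrecisionRecallF:
    def test_printed_worked_arithmetic(self):
        p, r = precision_recall(66, 3, 102)
        assert (round(p, 3), round(r, 3)) == (0.957, 0.393)
        p, r = precision_recall(1030, 2969, 151)
        assert (round(p, 3), round(r, 3)) == (0.258, 0.872)

    def test_keyword_screen_recall(self):
        _, r = precision_recall(265, 0, 64)
        assert round(r, 3) == 0.805

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            precision_recall(-1, 0, 0)

    def test_degenerate_denominators(self):
        assert precision_recall(0, 0, 0) == (1.0, 1.0)
        assert precision_recall(0, 0, 5) == (0.0, 0.0)

    def test_f1_is_harmonic_mean(self):
        p, r = 0.957, 0.393
        assert f_beta(p, r, 1) == pytest.approx(2 * p * r / (p + r))

    def test_beta_zero_reduces_to_precision(self):
        assert f_beta(0.39, 0.944, 0) == pytest.approx(0.39)

    def test_equal_p_r_fixed_point(self):
        for beta in (0.5, 1, 2, 10):
            assert f_beta(0.7, 0.7, beta) == pytest.approx(0.7)

    def test_beta_two_worked_example(self):
        assert round(f_beta(0.390, 0.944, 2), 3) == 0.735

    def test_negative_beta_rejected(self):
        with pytest.raises(ValueError):
            f_beta(0.5, 0.5, -1)

    def test_f_beta_tends_to_recall_for_large_beta(self):
        p, r = 0.2, 0.9
        values = [f_beta(p, r, b) for b in (1, 2, 4, 8, 16, 32, 64, 128)]
        assert values == sorted(values)
        assert values[-1] == pytest.approx(r, abs=2e-3)

    def test_eval_result_rounds_to_three_decimals(self):
        result = EvalResult(66, 3, 102)
        assert result.rounded() == {"P": 0.957, "R": 0.393, "F1": 0.557, "F2": 0.445}


class TestErrorBreakdown:
    def test_fn_cause_percentages(self):
        labels = ["in_image"] * 15 + ["regex_not_found"] * 7
        breakdown = error_breakdown(labels, FN_CLASSES)
        assert breakdown["in_image"][0] == 15
        assert round(breakdown["in_image"][1], 1) == 68.2
        assert round(breakdown["regex_not_found"][1], 1) == 31.8

    def test_multi_label_records_count_once_per_class(self):
        breakdown = error_breakdown(
            [["motif_name", "short_name"], "motif_name"], FP_CLASSES
        )
        assert breakdown["motif_name"][0] == 2
        assert breakdown["short_name"][0] == 1

    def test_single_record(self):
        assert error_breakdown(["motif_name"], FP_CLASSES) == {"motif_name": (1, 100.0)}

    def test_empty_input(self):
        assert error_breakdown([], FP_CLASSES) == {}

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="nonsense"):
            error_breakdown(["nonsense"], FP_CLASSES)


class TestGoldFiles:
    def test_round_trip(self, tmp_path):
        gold = {"d1": {"S56": 1, "A64G": 2}, "d2": {}, "d3": {"G2": 1}}
        path = tmp_path / "gold.tsv"
        save_gold_file(gold, path)
        assert load_gold_file(path) == gold

    def test_bad_key_names_line_and_document(self, tmp_path):
        path = tmp_path / "gold.tsv"
        path.write_text("docA\tS56,S0\n", encoding="utf-8")
        with pytest.raises(InvalidMentionError, match=r"docA.*S0"):
            load_gold_file(path)
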