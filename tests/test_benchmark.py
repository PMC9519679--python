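"""Tolerance matching, metrics and caller-combination selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import svharvest as sv
from svharvest import benchmark as bm


def rec(start, end, sv_type="DEL", length=None, **kw):
    if length is None and sv_type not in ("INS", "TRA"):
        length = end - start
    return sv.SVRecord(chrom="chr1H", start=start, end=end, sv_type=sv_type,
                       length=length, sample="s1", **kw)


class TestClassify:
    @pytest.mark.parametrize("length,expected", [
        (2, "INDEL"), (49, "INDEL"), (50, "A"), (150, "A"), (300, "A"),
        (301, "B"), (5_000, "B"), (5_001, "C"), (50_000, "C"), (50_001, "D"),
        (250_000, "D"), (250_001, "E"), (1_000_000, "E"),
    ])
    def test_length_bins(self, length, expected):
        r = rec(1_000, 1_000 + length)
        assert bm.classify_length_category(r) == expected

    def test_out_of_range(self):
        assert bm.classify_length_category(rec(0, 1)) == bm.OUT_OF_RANGE
        assert bm.classify_length_category(
            rec(0, 1_500_000)) == bm.OUT_OF_RANGE

    def test_unknown_length_insertion_uses_hint(self):
        r = rec(100, 100, sv_type="INS", category_hint="B")
        assert bm.classify_length_category(r) == "B"
        r2 = rec(100, 100, sv_type="INS")
        assert bm.classify_length_category(r2) == "A"

    def test_translocations_pool_categories(self):
        r = sv.SVRecord(chrom="chr1H", start=5, end=5, sv_type="TRA",
                        mate=("chr2H", 99))
        assert bm.classify_length_category(r) == "ABCDE"


class TestMatch:
    def test_within_tolerance_is_tp(self):
        truth = [rec(10_000, 10_200)]
        calls = [rec(10_005, 10_195)]
        res = bm.match_calls(truth, calls, "DEL")
        assert (res.tp, res.fp, res.fn) == (1, 0, 0)

    def test_breakpoint_beyond_tolerance_is_fp_and_fn(self):
        truth = [rec(10_000, 10_200)]
        calls = [rec(10_012, 10_212)]
        res = bm.match_calls(truth, calls, "DEL")
        assert (res.tp, res.fp, res.fn) == (0, 1, 1)

    def test_empty_calls(self):
        truth = [rec(1_000 + 500 * i, 1_100 + 500 * i) for i in range(7)]
        res = bm.match_calls(truth, [], "DEL")
        assert (res.tp, res.fp, res.fn) == (0, 0, 7)

    def test_indel_tolerances(self):
        truth = [rec(500, 510, sv_type="INDEL", length=10)]
        calls = [rec(501, 515, sv_type="INDEL", length=14)]
        res = bm.match_calls(truth, calls, "INDEL")
        assert res.tp == 1
        # length off by 6 bp exceeds the 5 bp INDEL tolerance
        calls = [rec(501, 517, sv_type="INDEL", length=16)]
        assert bm.match_calls(truth, calls, "INDEL").tp == 0

    def test_unknown_length_insertion_start_tolerance(self):
        truth = [rec(1_000, 1_000, sv_type="INS", length=120)]
        near = [rec(1_008, 1_008, sv_type="INS")]
        far = [rec(1_011, 1_011, sv_type="INS")]
        assert bm.match_calls(truth, near, "INS").tp == 1
        assert bm.match_calls(truth, far, "INS").tp == 0

    def test_translocation_both_breakpoints(self):
        t = [sv.SVRecord(chrom="chr1H", start=1_000, end=1_000,
                         sv_type="TRA", mate=("chr2H", 9_000))]
        good = [sv.SVRecord(chrom="chr1H", start=1_040, end=1_040,
                            sv_type="TRA", mate=("chr2H", 9_050))]
        bad = [sv.SVRecord(chrom="chr1H", start=1_040, end=1_040,
                           sv_type="TRA", mate=("chr2H", 9_060))]
        assert bm.match_calls(t, good, "TRA").tp == 1
        assert bm.match_calls(t, bad, "TRA").tp == 0

    def test_mixed_type_rejected(self):
        with pytest.raises(ValueError):
            bm.match_calls([rec(0, 100)], [rec(0, 100, sv_type="DUP")],
                           "DEL")

    @given(st.data())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_bookkeeping_identities(self, data):
        n_t = data.draw(st.integers(0, 12))
        n_c = data.draw(st.integers(0, 12))
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        truth = [rec(int(s), int(s) + 100)
                 for s in rng.integers(0, 5_000, n_t)]
        calls = [rec(int(s), int(s) + 100)
                 for s in rng.integers(0, 5_000, n_c)]
        res = bm.match_calls(truth, calls, "DEL", "A")
        assert res.tp + res.fn == len(truth)
        assert res.tp + res.fp == len(calls)
        assert len({i for i, _ in res.pairs}) == len(res.pairs)
        assert len({j for _, j in res.pairs}) == len(res.pairs)


class TestMetrics:
    def test_basic_arithmetic(self):
        m = bm.compute_metrics(bm.MatchResult(tp=8, fp=0, fn=2))
        assert m.sensitivity == pytest.approx(0.800)
        assert m.precision == pytest.approx(1.000)
        assert m.f1 == pytest.approx(0.889, abs=5e-4)

    def test_undefined_precision_propagates_as_missing(self):
        m = bm.compute_metrics(bm.MatchResult(tp=0, fp=0, fn=5))
        assert m.sensitivity == 0.0
        assert m.precision is None
        assert m.f1 is None

    def test_f1_closed_form(self):
        # sensitivity 89.0% / precision 99.1% combine to F1 = 0.938
        m = bm.compute_metrics(bm.MatchResult(tp=890, fp=8, fn=110))
        f1 = 2 * 0.991 * 0.890 / (0.991 + 0.890)
        assert abs(f1 - 0.938) < 5e-4
        assert m.f1 == pytest.approx(2 * m.precision * m.sensitivity
                                     / (m.precision + m.sensitivity))

    @given(st.integers(0, 500), st.integers(0, 500), st.integers(0, 500))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_f1_between_min_and_mean(self, tp, fp, fn):
        m = bm.compute_metrics(bm.MatchResult(tp=tp, fp=fp, fn=fn))
        if m.f1 is None:
            return
        lo, hi = sorted([m.sensitivity, m.precision])
        assert lo - 1e-12 <= m.f1 <= hi + 1e-12
        assert m.f1 <= (m.sensitivity + m.precision) / 2 + 1e-12


def _callsets(*specs):
    out = {}
    for name, starts in specs:
        out[name] = sv.CallSet(caller=name, records=[
            rec(s, s + 100, caller=name) for s in starts])
    return out


class TestCombination:
    def test_expression_parse_and_render(self):
        text = "Manta|GRIDSS|Pindel|Delly|(Lumpy&NGSEP)"
        expr = bm.CombinationExpr.parse(text)
        assert str(expr) == text
        assert expr.leaves() == ["Manta", "GRIDSS", "Pindel", "Delly",
                                 "Lumpy", "NGSEP"]

    def test_single_caller_identity(self):
        truth = sv.TruthSet(records=[rec(1_000, 1_100), rec(3_000, 3_100)])
        cs = _callsets(("X", [1_000, 5_000]))
        alone = bm.compute_metrics(
            bm.match_calls(truth.records, cs["X"].records, "DEL"))
        combo = bm.evaluate_combination(bm.CombinationExpr.leaf("X"), cs,
                                        truth, "DEL")
        assert combo == alone

    def test_or_union_bound(self):
        truth = sv.TruthSet(records=[rec(i * 1_000, i * 1_000 + 100)
                                     for i in range(1, 101)])
        x = _callsets(("X", [i * 1_000 for i in range(1, 61)]),
                      ("Y", [i * 1_000 for i in range(51, 101)]))
        expr = bm.CombinationExpr.parse("X|Y")
        m = bm.evaluate_combination(expr, x, truth, "DEL")
        assert m.sensitivity >= 0.60

    def test_or_never_decreases_tp_and_dedups(self):
        truth = sv.TruthSet(records=[rec(i * 1_000, i * 1_000 + 100)
                                     for i in range(1, 51)])
        cs = _callsets(("X", [i * 1_000 for i in range(1, 41)]),
                       ("Y", [i * 1_000 + 2 for i in range(30, 51)]))
        combined = bm.combine_callsets(bm.CombinationExpr.parse("X|Y"), cs,
                                       "DEL")
        res = bm.match_calls(truth.records, combined, "DEL")
        assert res.tp == 50          # union covers everything
        assert res.fp == 0           # overlapping calls deduplicated

    def test_and_intersects_fp_sets(self):
        truth = sv.TruthSet(records=[rec(i * 1_000, i * 1_000 + 100)
                                     for i in range(1, 21)])
        # both callers find all truth; FPs are disjoint
        cs = _callsets(("X", [i * 1_000 for i in range(1, 21)]
                        + [100_000, 110_000]),
                       ("Y", [i * 1_000 + 3 for i in range(1, 21)]
                        + [200_000, 210_000]))
        m = bm.evaluate_combination(bm.CombinationExpr.parse("X&Y"), cs,
                                    truth, "DEL")
        assert m.precision == 1.0


def _metrics(prec_by_cat):
    return {cat: bm.MetricTriple(sensitivity=0.8, precision=p,
                                 f1=0.8 if p is not None else None)
            for cat, p in prec_by_cat.items()}


class TestSelection:
    def _scenario(self, y_and_z_pass):
        # X passes everywhere; Y and Z each fail in one category but their
        # AND does (or does not) recover the precision floor
        truth_recs, x_recs, y_recs, z_recs = [], [], [], []
        for i in range(200):
            s = 10_000 + i * 2_000
            truth_recs.append(rec(s, s + 100, caller="truth"))
            x_recs.append(rec(s, s + 100, caller="X"))
            y_recs.append(rec(s, s + 100, caller="Y"))
            z_recs.append(rec(s, s + 100, caller="Z"))
        # disjoint FPs for Y and Z unless they must share them
        for i in range(40):
            y_fp = 600_000 + i * 3_000
            z_fp = 900_000 + i * 3_000 if not y_and_z_pass else y_fp
            y_recs.append(rec(y_fp, y_fp + 100, caller="Y"))
            z_recs.append(rec(z_fp, z_fp + 100, caller="Z"))
        truth = sv.TruthSet(records=truth_recs)
        callsets = {"X": sv.CallSet("X", x_recs),
                    "Y": sv.CallSet("Y", y_recs),
                    "Z": sv.CallSet("Z", z_recs)}
        per_caller = bm.benchmark_callers(callsets, truth, "DEL")
        return per_caller, callsets, truth

    def test_two_step_or_and(self):
        per_caller, callsets, truth = self._scenario(y_and_z_pass=False)
        expr = bm.select_best_combination(per_caller, callsets, truth, "DEL")
        assert str(expr) == "X|(Y&Z)"

    def test_all_pass_gives_or_of_all(self):
        truth = sv.TruthSet(records=[rec(i * 2_000, i * 2_000 + 100)
                                     for i in range(1, 101)])
        cs = _callsets(("A", [i * 2_000 for i in range(1, 80)]),
                       ("B", [i * 2_000 + 1 for i in range(20, 101)]),
                       ("C", [i * 2_000 for i in range(1, 101)]))
        per_caller = bm.benchmark_callers(cs, truth, "DEL")
        expr = bm.select_best_combination(per_caller, cs, truth, "DEL")
        assert str(expr) == "A|B|C"

    def test_failed_and_drops_to_step_one_only(self):
        per_caller, callsets, truth = self._scenario(y_and_z_pass=True)
        expr = bm.select_best_combination(per_caller, callsets, truth, "DEL")
        assert str(expr) == "X"

    def test_fallback_to_best_f1(self):
        truth = sv.TruthSet(records=[rec(i * 2_000, i * 2_000 + 100)
                                     for i in range(1, 51)])
        # single caller below the floor: no OR members, no AND possible
        cs = _callsets(("L", [i * 2_000 for i in range(1, 41)]
                        + [500_000 + i * 3_000 for i in range(20)]))
        per_caller = bm.benchmark_callers(cs, truth, "DEL")
        expr = bm.select_best_combination(per_caller, cs, truth, "DEL")
        assert str(expr) == "L"
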