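"""Filter cascade: interval relations, sample/call QC, control-overlap
exclusion, three-caller consensus, size and frequency filters — each checked
against an independent brute-force oracle on random instances."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cnvscreen as cs
from cnvscreen.core import IntervalRelation, relation
from cnvscreen.filters import (
    FilterThresholds,
    SampleMetrics,
    call_qc,
    consensus_intersect,
    control_overlap_filter,
    frequency_filter,
    sample_qc,
    size_filter,
)
from conftest import make_random_calls

EXCLUDING = (IntervalRelation.EXACT, IntervalRelation.CASE_WITHIN_OTHER)


# ---------------------------------------------------------------------------
# Interval relations
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "case, other, expected",
    [
        ((100, 200), (100, 200), IntervalRelation.EXACT),
        ((120, 180), (100, 200), IntervalRelation.CASE_WITHIN_OTHER),
        ((100, 200), (120, 180), IntervalRelation.OTHER_WITHIN_CASE),
        ((100, 200), (150, 250), IntervalRelation.PARTIAL),
        ((100, 200), (300, 400), IntervalRelation.NONE),
        ((100, 200), (100, 250), IntervalRelation.CASE_WITHIN_OTHER),
        ((100, 200), (200, 300), IntervalRelation.PARTIAL),
    ],
)
def test_relation_classification(case, other, expected):
    assert relation(*case, *other) is expected


@given(st.integers(1, 1000), st.integers(1, 1000), st.integers(1, 1000), st.integers(1, 1000))
@settings(max_examples=300, derandomize=True)
def test_relation_definitions_hold(a, b, c, d):
    cs_, ce = sorted((a, b))
    os_, oe = sorted((c, d))
    r = relation(cs_, ce, os_, oe)
    if r is IntervalRelation.EXACT:
        assert (cs_, ce) == (os_, oe)
    elif r is IntervalRelation.CASE_WITHIN_OTHER:
        assert os_ <= cs_ and ce <= oe and (cs_, ce) != (os_, oe)
    elif r is IntervalRelation.OTHER_WITHIN_CASE:
        assert cs_ <= os_ and oe <= ce
    elif r is IntervalRelation.PARTIAL:
        assert cs_ <= oe and os_ <= ce
        assert not (os_ <= cs_ and ce <= oe) and not (cs_ <= os_ and oe <= ce)
    else:
        assert ce < os_ or oe < cs_


# ---------------------------------------------------------------------------
# Sample QC
# ---------------------------------------------------------------------------


def _metrics(sample_id, call_rate=0.99, mean_x_lrr=0.0, recorded_sex="F"):
    return SampleMetrics(sample_id, call_rate, mean_x_lrr, recorded_sex)


def _callset_with_counts(counts: dict[str, int]) -> cs.CallSet:
    calls = []
    for sample, n in counts.items():
        for i in range(n):
            calls.append(
                cs.CnvCall(sample, "c", "1", 1000 * (i + 1), 1000 * (i + 1) + 500,
                           "DUP", 3, 10, 50.0)
            )
    return cs.CallSet(calls)


def test_call_rate_boundary():
    """Strict reading of 'less than 98% of the markers': 0.98 passes."""
    metrics = {"a": _metrics("a", call_rate=0.98), "b": _metrics("b", call_rate=0.979)}
    reports = {r.sample_id: r for r in sample_qc(_callset_with_counts({}), metrics)}
    assert reports["a"].passed
    assert not reports["b"].passed and "call_rate" in reports["b"].reasons


def test_cnv_count_outlier_rule_hand_computed():
    """Counts {5,5,5,5,25}: mean 9, population SD 8 -> cutoff 25; the strict
    '>' rule keeps the sample sitting exactly on the cutoff."""
    counts = {"a": 5, "b": 5, "c": 5, "d": 5, "e": 25}
    metrics = {s: _metrics(s) for s in counts}
    reports = {r.sample_id: r for r in sample_qc(_callset_with_counts(counts), metrics)}
    assert all(r.passed for r in reports.values())
    assert reports["e"].cnv_count == 25


def test_cnv_count_clear_outlier_removed():
    # counts {5,5,5,5,5,30}: mean 9.17, pop SD 9.32 -> cutoff 27.8 < 30
    counts = {s: 5 for s in "abcde"} | {"f": 30}
    metrics = {s: _metrics(s) for s in counts}
    reports = {r.sample_id: r for r in sample_qc(_callset_with_counts(counts), metrics)}
    assert not reports["f"].passed
    assert "cnv_count_outlier" in reports["f"].reasons
    assert all(reports[s].passed for s in "abcde")


def test_sex_concordance():
    metrics = {
        "m_ok": _metrics("m_ok", mean_x_lrr=-0.6, recorded_sex="M"),
        "f_ok": _metrics("f_ok", mean_x_lrr=0.0, recorded_sex="F"),
        "mismatch": _metrics("mismatch", mean_x_lrr=-0.6, recorded_sex="F"),
    }
    reports = {r.sample_id: r for r in sample_qc(_callset_with_counts({}), metrics)}
    assert reports["m_ok"].passed and reports["m_ok"].sex_called == "M"
    assert reports["f_ok"].passed and reports["f_ok"].sex_called == "F"
    assert not reports["mismatch"].passed
    assert "sex_mismatch" in reports["mismatch"].reasons


def test_single_sample_skips_count_rule(caplog):
    metrics = {"only": _metrics("only")}
    with caplog.at_level(logging.WARNING):
        reports = sample_qc(_callset_with_counts({"only": 50}), metrics)
    assert reports[0].passed
    assert any("skipped" in r.message for r in caplog.records)


# ---------------------------------------------------------------------------
# Call QC
# ---------------------------------------------------------------------------


def _call(conf, n_probes, start=1000, typ="DUP"):
    cn = 3 if typ == "DUP" else 1
    return cs.CnvCall("s", "c", "1", start, start + 5000, typ, cn, n_probes, conf)


@pytest.mark.parametrize(
    "conf, n_probes, kept",
    [
        (29.99, 50, False),
        (30.0, 4, True),
        (100.0, 3, False),
        (30.0, 3, False),
        (45.0, 10, True),
    ],
)
def test_call_qc_boundaries(conf, n_probes, kept):
    out, trace = call_qc(cs.CallSet([_call(conf, n_probes)]))
    assert (len(out) == 1) is kept
    assert len(trace.kept()) + len(trace.removed()) == 1


def test_call_qc_matches_predicate_oracle():
    rng = np.random.default_rng(7)
    calls = make_random_calls(rng, 1000, samples=tuple(f"s{i}" for i in range(20)))
    out, trace = call_qc(cs.CallSet(calls))
    expected = [c for c in calls if c.confidence >= 30.0 and c.n_probes >= 4]
    assert [c.key for c in out] == [c.key for c in expected]
    assert len(trace.records) == 1000


def test_call_qc_requires_confidence():
    with pytest.raises(cs.ValidationError, match="confidence"):
        call_qc(cs.CallSet([_call(None, 10)]))


def test_call_qc_idempotent():
    rng = np.random.default_rng(8)
    calls = make_random_calls(rng, 200)
    once, _ = call_qc(cs.CallSet(calls))
    twice, _ = call_qc(once)
    assert [c.key for c in twice] == [c.key for c in once]


# ---------------------------------------------------------------------------
# Control-overlap exclusion
# ---------------------------------------------------------------------------


def _overlap_oracle(case_calls, control_calls, thresholds, pooled=False):
    kept = []
    for c in case_calls:
        carriers = set()
        for k in control_calls:
            if k.type != c.type or k.chrom != c.chrom:
                continue
            if not pooled and k.caller_id != c.caller_id:
                continue
            if relation(c.start, c.end, k.start, k.end) in EXCLUDING:
                carriers.add(k.sample_id)
        if len(carriers) <= thresholds.control_carrier_exclusive:
            kept.append(c)
    return kept


def _dup(sample, caller, start, end):
    return cs.CnvCall(sample, caller, "1", start, end, "DUP", 3, 10, 50.0)


def test_control_overlap_exact_two_carriers_removed():
    case = cs.CallSet([_dup("p1", "c", 100_000, 200_000)], cohort="case")
    controls = cs.CallSet(
        [_dup("A", "c", 100_000, 200_000), _dup("B", "c", 100_000, 200_000)],
        cohort="control",
    )
    kept, trace = control_overlap_filter(case, controls)
    assert len(kept) == 0
    assert trace.removed("control_overlap")[0].reason == "control_carriers=2"


def test_control_overlap_single_carrier_kept():
    case = cs.CallSet([_dup("p1", "c", 100_000, 200_000)], cohort="case")
    controls = cs.CallSet([_dup("A", "c", 90_000, 250_000)], cohort="control")
    kept, _ = control_overlap_filter(case, controls)
    assert len(kept) == 1


def test_control_overlap_partial_never_excludes():
    case = cs.CallSet([_dup("p1", "c", 100_000, 200_000)], cohort="case")
    controls = cs.CallSet(
        [_dup(f"ctl{i}", "c", 150_000, 250_000) for i in range(10)], cohort="control"
    )
    kept, _ = control_overlap_filter(case, controls)
    assert len(kept) == 1


def test_control_overlap_stratified_by_caller():
    case = cs.CallSet([_dup("p1", "penn", 100_000, 200_000)], cohort="case")
    controls = cs.CallSet(
        [_dup("A", "penn", 100_000, 200_000), _dup("B", "quanti", 100_000, 200_000),
         _dup("C", "quanti", 100_000, 200_000), _dup("D", "penn", 100_000, 200_000)],
        cohort="control",
    )
    kept, _ = control_overlap_filter(case, controls)
    assert len(kept) == 0  # two same-caller carriers
    kept, _ = control_overlap_filter(
        cs.CallSet([_dup("p1", "penn", 100_000, 200_000)]),
        cs.CallSet([_dup("B", "quanti", 100_000, 200_000),
                    _dup("C", "quanti", 100_000, 200_000),
                    _dup("D", "penn", 100_000, 200_000)]),
    )
    assert len(kept) == 1  # only one penn carrier; quanti carriers don't count


def test_control_overlap_missing_stratum_error():
    case = cs.CallSet([_dup("p1", "penn", 100_000, 200_000)])
    controls = cs.CallSet([_dup("A", "quanti", 1_000, 2_000)])
    with pytest.raises(cs.StratificationError):
        control_overlap_filter(case, controls)


def test_control_overlap_matches_bruteforce_on_large_instance():
    rng = np.random.default_rng(11)
    cases = make_random_calls(
        rng, 500, caller_ids=("a", "b", "c"), samples=tuple(f"p{i}" for i in range(40))
    )
    controls = make_random_calls(
        rng, 2000, caller_ids=("a", "b", "c"), samples=tuple(f"k{i}" for i in range(200))
    )
    thr = FilterThresholds()
    kept, trace = control_overlap_filter(cs.CallSet(cases), cs.CallSet(controls), thr)
    expected = _overlap_oracle(cases, controls, thr)
    assert [c.key for c in kept] == [c.key for c in expected]
    assert len(trace.records) == 500


def test_control_overlap_pooled_mode():
    rng = np.random.default_rng(12)
    cases = make_random_calls(rng, 100, caller_ids=("a", "b"))
    controls = make_random_calls(rng, 400, caller_ids=("a", "b"), samples=("k1", "k2", "k3"))
    thr = FilterThresholds()
    kept, _ = control_overlap_filter(cs.CallSet(cases), cs.CallSet(controls), thr, pooled=True)
    expected = _overlap_oracle(cases, controls, thr, pooled=True)
    assert [c.key for c in kept] == [c.key for c in expected]


# ---------------------------------------------------------------------------
# Consensus
# ---------------------------------------------------------------------------


def _consensus_oracle(callsets):
    """Brute-force greedy triple enumeration (sorted order, used-marking)."""
    caller_ids = sorted(callsets)
    strata = {}
    for cid in caller_ids:
        for c in callsets[cid]:
            strata.setdefault((c.sample_id, c.chrom, c.type), {k: [] for k in caller_ids})[
                cid
            ].append(c)
    events = []
    for key in sorted(strata):
        groups = [sorted(strata[key][cid], key=lambda c: (c.start, c.end)) for cid in caller_ids]
        used_b, used_c = set(), set()
        for a in groups[0]:
            found = None
            for bi, b in enumerate(groups[1]):
                if bi in used_b:
                    continue
                for ci, c in enumerate(groups[2]):
                    if ci in used_c:
                        continue
                    s = max(a.start, b.start, c.start)
                    e = min(a.end, b.end, c.end)
                    if s <= e:
                        found = (bi, ci, s, e)
                        break
                if found:
                    break
            if found:
                bi, ci, s, e = found
                used_b.add(bi)
                used_c.add(ci)
                events.append((key[0], key[1], s, e, key[2]))
    return sorted(events)


def test_consensus_triple_intersection_arithmetic():
    mk = lambda cid, s, e: cs.CnvCall("p1", cid, "1", s, e, "DUP", 3, 10, 50.0)
    sets = {
        "a": cs.CallSet([mk("a", 100_000, 200_000)]),
        "b": cs.CallSet([mk("b", 150_000, 250_000)]),
        "c": cs.CallSet([mk("c", 120_000, 220_000)]),
    }
    events, trace = consensus_intersect(sets)
    (ev,) = events
    assert (ev.start, ev.end) == (150_000, 200_000)
    assert (ev.union_start, ev.union_end) == (100_000, 250_000)
    assert ev.min_n_probes == 10 and ev.min_confidence == 50.0
    assert len(trace.kept("consensus")) == 3


def test_consensus_requires_all_three_callers():
    mk = lambda cid, s, e: cs.CnvCall("p1", cid, "1", s, e, "DUP", 3, 10, 50.0)
    sets = {
        "a": cs.CallSet([mk("a", 100_000, 200_000)]),
        "b": cs.CallSet([mk("b", 150_000, 250_000)]),
        "c": cs.CallSet([]),
    }
    events, trace = consensus_intersect(sets)
    assert events == []
    assert {r.reason for r in trace.removed("consensus")} == {"missing_caller"}
    assert len(trace.records) == 2


def test_consensus_rejects_wrong_caller_count():
    with pytest.raises(cs.ConfigurationError):
        consensus_intersect({"a": cs.CallSet([]), "b": cs.CallSet([])})


def test_consensus_type_strata_independent():
    dup = cs.CnvCall("p1", "a", "1", 100, 200, "DUP", 3, 5, 50.0)
    dele = cs.CnvCall("p1", "b", "1", 100, 200, "DEL", 1, 5, 50.0)
    other = cs.CnvCall("p1", "c", "1", 100, 200, "DUP", 3, 5, 50.0)
    events, _ = consensus_intersect(
        {"a": cs.CallSet([dup]), "b": cs.CallSet([dele]), "c": cs.CallSet([other])}
    )
    assert events == []  # DEL vs DUP never consense


def test_consensus_matches_bruteforce_on_jittered_triples():
    rng = np.random.default_rng(13)
    for _ in range(100):
        sets = {cid: [] for cid in ("a", "b", "c")}
        seen = {cid: set() for cid in sets}
        for s in range(int(rng.integers(1, 4))):
            sample = f"s{s}"
            for _ in range(int(rng.integers(0, 4))):
                start = int(rng.integers(1, 10_000))
                length = int(rng.integers(50, 2_000))
                typ = "DUP" if rng.random() < 0.5 else "DEL"
                cn = 3 if typ == "DUP" else 1
                for cid in sets:
                    if rng.random() < 0.15:
                        continue  # caller missed the event
                    st_ = max(1, start + int(rng.integers(-30, 31)))
                    en = max(st_, start + length + int(rng.integers(-30, 31)))
                    k = (sample, st_, en, typ)
                    if k in seen[cid]:
                        continue
                    seen[cid].add(k)
                    sets[cid].append(
                        cs.CnvCall(sample, cid, "1", st_, en, typ, cn,
                                   int(rng.integers(4, 30)), float(rng.uniform(30, 90)))
                    )
        callsets = {cid: cs.CallSet(calls) for cid, calls in sets.items()}
        events, trace = consensus_intersect(callsets)
        got = sorted((e.sample_id, e.chrom, e.start, e.end, e.type) for e in events)
        assert got == _consensus_oracle(callsets)
        assert len(trace.records) == sum(len(v) for v in sets.values())


# ---------------------------------------------------------------------------
# Size & frequency filters
# ---------------------------------------------------------------------------


def _sized(length, start=100_000):
    return cs.CnvCall("s", "c", "1", start, start + length - 1, "DUP", 3, 10, 50.0)


def test_size_filter_boundary():
    kept, trace = size_filter([_sized(49_999), _sized(50_000, 300_000)])
    assert [c.length for c in kept] == [50_000]
    assert len(trace.records) == 2


def test_size_filter_keeps_validated_duplications():
    calls, _, _ = cs.table1_fixture()
    kept, _ = size_filter(calls)
    assert len(kept) == 3


def test_size_filter_empty_input():
    kept, trace = size_filter([])
    assert kept == [] and trace.records == []


def _freq_oracle(cnvs, db, thresholds=None):
    kept = []
    for c in cnvs:
        removed = any(
            r.chrom == c.chrom
            and r.matches_type(c.type)
            and relation(c.start, c.end, r.start, r.end) in EXCLUDING
            for r in db
        )
        if not removed:
            kept.append(c)
    return kept


def test_frequency_filter_exact_match_removed():
    db = [cs.FrequencyRecord("1", 100_000, 149_999, "DUP", "d1")]
    kept, trace = frequency_filter([_sized(50_000)], db)
    assert kept == []
    assert trace.removed("frequency_filter")[0].reason == "db:d1"


def test_frequency_filter_contained_record_does_not_remove():
    db = [cs.FrequencyRecord("1", 110_000, 120_000, "DUP", "d1")]
    kept, _ = frequency_filter([_sized(50_000)], db)
    assert len(kept) == 1


def test_frequency_filter_both_matches_either_type():
    db = [cs.FrequencyRecord("1", 90_000, 160_000, "BOTH", "d1")]
    kept, _ = frequency_filter([_sized(50_000)], db)
    assert kept == []
    db = [cs.FrequencyRecord("1", 90_000, 160_000, "DEL", "d1")]
    kept, _ = frequency_filter([_sized(50_000)], db)
    assert len(kept) == 1  # type-incompatible record never removes a DUP


def test_frequency_filter_matches_bruteforce():
    rng = np.random.default_rng(17)
    cnvs = make_random_calls(rng, 300)
    db = []
    for i in range(500):
        start = int(rng.integers(1, 500)) * 100 + 1
        end = start + int(rng.integers(1, 30)) * 100 - 1
        db.append(
            cs.FrequencyRecord("1", start, end, str(rng.choice(["DEL", "DUP", "BOTH"])), f"d{i}")
        )
    kept, trace = frequency_filter(cnvs, db)
    assert [c.key for c in kept] == [c.key for c in _freq_oracle(cnvs, db)]
    assert len(trace.records) == 300


def test_filters_are_idempotent_subsets():
    rng = np.random.default_rng(19)
    cnvs = make_random_calls(rng, 200)
    db = [cs.FrequencyRecord("1", 1, 10_000, "BOTH", "wide")]
    for filt in (
        lambda x: size_filter(x)[0],
        lambda x: frequency_filter(x, db)[0],
    ):
        once = filt(cnvs)
        assert set(c.key for c in once) <= set(c.key for c in cnvs)
        assert [c.key for c in filt(once)] == [c.key for c in once]
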