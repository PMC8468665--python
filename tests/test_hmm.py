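"""HMM caller: Viterbi optimality (vs exhaustive path enumeration), call
scoring (vs probe-by-probe re-summation), recovery of planted events and the
behaviour of the three caller profiles."""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import norm

import cnvscreen as cs
from cnvscreen.core import CN0_SD_SCALE, baf_clusters, baf_cluster_weights
from cnvscreen.hmm import (
    HmmParams,
    emission_loglik,
    viterbi_path,
    _log_initial,
    _log_transition,
)


def _single_chrom_layout(n_probes: int = 60, spacing: int = 5000) -> cs.GenomeLayout:
    pos = spacing * np.arange(1, n_probes + 1)
    return cs.GenomeLayout(
        chromosomes=(("1", int(pos[-1] + spacing)),), probes={"1": pos}
    )


def _sample_with_event(
    layout, cn, start_idx, n_event, noise_lrr, baf_sd, rng
) -> cs.IntensitySample:
    pos = layout.probes["1"]
    n = pos.size
    lrr = rng.normal(0.0, noise_lrr, n)
    k2 = rng.binomial(2, 0.5, n)
    baf = np.clip(k2 / 2 + rng.normal(0, baf_sd, n), 0, 1)
    sl = slice(start_idx, start_idx + n_event)
    mu = cs.core.DEFAULT_STATE_MEANS[cn]
    lrr[sl] = rng.normal(mu, noise_lrr, n_event)
    if cn == 0:
        baf[sl] = rng.uniform(0, 1, n_event)
    else:
        kc = rng.binomial(cn, 0.5, n_event)
        baf[sl] = np.clip(kc / cn + rng.normal(0, baf_sd, n_event), 0, 1)
    return cs.IntensitySample("s1", "case", "F", {"1": lrr}, {"1": baf})


def test_pure_diploid_yields_no_calls():
    layout = _single_chrom_layout(80)
    rng = np.random.default_rng(0)
    sample = _sample_with_event(layout, 3, 0, 0, 1e-6, 1e-6, rng)
    for params in cs.default_profiles().values():
        assert cs.viterbi_segment(sample, layout, params) == []


def test_planted_duplication_recovered_within_two_probes():
    layout = _single_chrom_layout(100)
    rng = np.random.default_rng(1)
    start_idx, n_event = 40, 30
    sample = _sample_with_event(layout, 3, start_idx, n_event, 0.15, 0.03, rng)
    params = cs.default_profiles()["quanti-like"]
    calls = cs.viterbi_segment(sample, layout, params)
    dups = [c for c in calls if c.type == "DUP"]
    assert len(dups) == 1
    pos = layout.probes["1"]
    true_start, true_end = pos[start_idx], pos[start_idx + n_event - 1]
    assert abs(np.searchsorted(pos, dups[0].start) - np.searchsorted(pos, true_start)) <= 2
    assert abs(np.searchsorted(pos, dups[0].end) - np.searchsorted(pos, true_end)) <= 2


def _enumerate_best_logprob(lrr, baf, params):
    """Independent oracle: brute-force maximum over all 5^n state paths."""
    e = emission_loglik(lrr, baf, params)
    n = e.shape[0]
    logT = _log_transition(params)
    logpi = _log_initial(params)
    paths = np.array(list(itertools.product(range(5), repeat=n)), dtype=np.int8)
    scores = logpi[paths[:, 0]] + e[np.arange(n)[None, :], paths].sum(axis=1)
    if n > 1:
        scores += logT[paths[:, :-1], paths[:, 1:]].sum(axis=1)
    return float(scores.max())


@pytest.mark.parametrize("instance", range(50))
def test_viterbi_matches_exhaustive_enumeration(instance):
    rng = np.random.default_rng(1000 + instance)
    n = int(rng.integers(4, 9))
    lrr = rng.normal(rng.choice([-0.6, 0.0, 0.4]), 0.3, n)
    baf = rng.uniform(0, 1, n)
    params = HmmParams(
        caller_id="t",
        lrr_sd=float(rng.uniform(0.08, 0.3)),
        baf_sd=float(rng.uniform(0.02, 0.06)),
        stay_prob=float(rng.uniform(0.9, 0.999)),
        baf_weight=float(rng.uniform(0.0, 1.0)),
    )
    path, lp = viterbi_path(lrr, baf, params)
    best = _enumerate_best_logprob(lrr, baf, params)
    assert lp == pytest.approx(best, abs=1e-9)


def test_score_diploid_data_never_favors_cnv():
    layout = _single_chrom_layout(40)
    pos = layout.probes["1"]
    # probes exactly at the diploid means: LRR 0, BAF at genotype clusters
    lrr = np.zeros(pos.size)
    baf = np.tile([0.0, 0.5, 0.5, 1.0], pos.size // 4)
    sample = cs.IntensitySample("s", "case", "F", {"1": lrr}, {"1": baf})
    params = cs.default_profiles()["penn-like"]
    call = cs.CnvCall("s", "penn-like", "1", int(pos[5]), int(pos[20]), "DUP", 3, 16, None)
    assert cs.score_call(call, sample, layout, params) <= 0


def test_strong_duplication_scores_above_30():
    layout = _single_chrom_layout(60)
    rng = np.random.default_rng(2)
    sample = _sample_with_event(layout, 3, 10, 30, 0.08, 0.02, rng)
    pos = layout.probes["1"]
    call = cs.CnvCall("s1", "q", "1", int(pos[10]), int(pos[39]), "DUP", 3, 30, None)
    for params in cs.default_profiles().values():
        assert cs.score_call(call, sample, layout, params) > 30


def test_score_equals_probe_by_probe_resummation():
    """Independent oracle: explicit per-probe log10 density ratio with
    scipy.stats.norm, mirroring the emission definition."""
    layout = _single_chrom_layout(50)
    rng = np.random.default_rng(3)
    sample = _sample_with_event(layout, 1, 15, 20, 0.2, 0.04, rng)
    pos = layout.probes["1"]
    params = HmmParams("t", lrr_sd=0.17, baf_sd=0.035, stay_prob=0.99, baf_weight=0.42)
    call = cs.CnvCall("s1", "t", "1", int(pos[15]), int(pos[34]), "DEL", 1, 20, None)

    def probe_loglik(x, b, cn):
        sd = params.lrr_sd * (CN0_SD_SCALE if cn == 0 else 1.0)
        ll_lrr = norm.logpdf(x, loc=params.state_means[cn], scale=sd)
        if cn == 0:
            ll_baf = 0.0
        else:
            centers = baf_clusters(cn)
            weights = baf_cluster_weights(cn)
            ll_baf = math.log(
                sum(w * norm.pdf(b, loc=c, scale=params.baf_sd) for w, c in zip(weights, centers))
            )
        return (1 - params.baf_weight) * ll_lrr + params.baf_weight * ll_baf

    expected = 0.0
    sl = layout.probe_slice("1", call.start, call.end)
    for x, b in zip(sample.lrr["1"][sl], sample.baf["1"][sl]):
        expected += (probe_loglik(x, b, 1) - probe_loglik(x, b, 2)) / math.log(10)
    assert cs.score_call(call, sample, layout, params) == pytest.approx(expected, abs=1e-9)


def test_score_requires_covered_probes():
    layout = _single_chrom_layout(20)
    lrr = np.full(20, np.nan)
    baf = np.full(20, np.nan)
    sample = cs.IntensitySample("s", "case", "F", {"1": lrr}, {"1": baf})
    params = cs.default_profiles()["penn-like"]
    call = cs.CnvCall("s", "penn-like", "1", 5000, 20000, "DUP", 3, 4, None)
    with pytest.raises(cs.InputError):
        cs.score_call(call, sample, layout, params)


def test_all_probes_missing_chromosome_gives_no_calls():
    layout = _single_chrom_layout(20)
    sample = cs.IntensitySample(
        "s", "case", "F", {"1": np.full(20, np.nan)}, {"1": np.full(20, np.nan)}
    )
    params = cs.default_profiles()["penn-like"]
    assert cs.viterbi_segment(sample, layout, params) == []


def test_three_callers_agree_on_strong_signal():
    layout = _single_chrom_layout(80)
    rng = np.random.default_rng(4)
    sample = _sample_with_event(layout, 3, 20, 30, 1e-4, 1e-4, rng)
    sets = cs.run_three_callers([sample], layout)
    assert set(sets) == {"penn-like", "quanti-like", "partition-like"}
    for cid, callset in sets.items():
        assert len(callset) == 1, cid
        assert callset.calls[0].type == "DUP"
        assert callset.calls[0].n_probes >= 1


def test_run_three_callers_deterministic(small_study):
    cfg, layout, truth, samples = small_study
    a = cs.run_three_callers(samples[:4], layout)
    b = cs.run_three_callers(samples[:4], layout)
    for cid in a:
        assert [c.key for c in a[cid]] == [c.key for c in b[cid]]


def test_duplicate_caller_ids_rejected(small_study):
    cfg, layout, truth, samples = small_study
    p = cs.HmmParams("same")
    q = cs.HmmParams("same", stay_prob=0.9)
    with pytest.raises(cs.ConfigurationError):
        cs.run_three_callers(samples[:1], layout, profiles={"a": p, "b": q})


def test_more_stay_prob_never_more_segments():
    """On a fixed noisy input, a stiffer chain can only merge or drop calls."""
    layout = _single_chrom_layout(120)
    rng = np.random.default_rng(6)
    sample = _sample_with_event(layout, 3, 30, 25, 0.25, 0.05, rng)
    counts = []
    for stay in (0.90, 0.95, 0.99, 0.995, 0.999):
        params = HmmParams("t", lrr_sd=0.18, baf_sd=0.04, stay_prob=stay, baf_weight=0.4)
        counts.append(len(cs.viterbi_segment(sample, layout, params)))
    assert counts == sorted(counts, reverse=True)


def test_sensitivity_and_false_calls_on_simulated_cohort():
    """50 samples, one planted >= 20-probe duplication each (LRR shift 0.4):
    sensitivity >= 0.9 with on average <= 1 false call per sample."""
    cfg = cs.SimulationConfig(
        seed=21,
        n_cases=50,
        n_controls=0,
        event_spec=[cs.EventSpec(3, (95_000, 110_000), n_case_carriers=50)],
    )
    layout = cs.make_genome(cfg)
    truth = {t.sample_id: t for t in cs.plant_truth(layout, cfg)}
    samples = cs.simulate_intensities(layout, truth.values(), cfg)
    params = cs.default_profiles()["quanti-like"]
    detected = 0
    false_calls = 0
    for s in samples:
        calls = cs.viterbi_segment(s, layout, params)
        t = truth[s.sample_id]
        hit = any(
            c.chrom == t.chrom and c.type == "DUP" and c.start <= t.end and t.start <= c.end
            for c in calls
        )
        detected += hit
        false_calls += sum(
            1
            for c in calls
            if not (c.chrom == t.chrom and c.start <= t.end and t.start <= c.end)
        )
    assert detected / len(samples) >= 0.9
    assert false_calls / len(samples) <= 1.0
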