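"""Five-state HMM segmentation of LRR/BAF tracks into copy-number calls.

The hidden states are the copy numbers 0-4 (CN 2 = diploid).  Per-probe
emission combines the two intensity tracks::

    log e(probe | CN) = (1 - w) * log N(lrr; mu_CN, sd_CN)
                        + w * log sum_k pi_k N(baf; k/CN, baf_sd)

with ``w = baf_weight``, Gaussian LRR per state (the CN=0 state uses a 3x
wider sd to absorb signal collapse) and the genotype-cluster BAF mixture of
the shared signal model (CN=0: uniform BAF, log-density 0).  Probes with a
missing LRR are skipped entirely; a probe with LRR but no BAF contributes its
LRR term at full weight.  Transitions are distance-independent: ``stay_prob``
on the diagonal and the remainder spread uniformly over the other 4 states,
so a transition simply spans skipped probes.

Each maximal run of non-diploid Viterbi states becomes a call, scored with a
log10 Bayes factor: the log10 likelihood ratio of the probes in the call
under the called state versus under CN 2.  Viterbi ties are broken toward
the diploid state (preference order CN 2, 1, 3, 0, 4), which favours fewer
calls.

Three bundled parameter profiles ("penn-like", "quanti-like",
"partition-like") emulate running three distinct calling programs over the
same intensity export; the programs themselves are not reimplemented.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import logsumexp

from .core import (
    CN0_SD_SCALE,
    CallSet,
    CnvCall,
    ConfigurationError,
    DEFAULT_STATE_MEANS,
    GenomeLayout,
    InputError,
    IntensitySample,
    SEX_CHROMOSOMES,
    baf_clusters,
    baf_cluster_weights,
    cnv_type_for,
)

STATES = (0, 1, 2, 3, 4)
DIPLOID = 2
#: State preference used to break Viterbi ties: diploid first, then the
#: states nearest diploid (deletion before duplication at equal distance).
TIE_ORDER = np.array([2, 1, 3, 0, 4])
LN10 = math.log(10.0)


@dataclass
class HmmParams:
    """Parameters of one emulated calling program."""

    caller_id: str
    state_means: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_STATE_MEANS))
    lrr_sd: float = 0.18
    baf_sd: float = 0.04
    stay_prob: float = 0.995
    baf_weight: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.stay_prob < 1:
            raise ConfigurationError("stay_prob must be strictly between 0 and 1")
        if self.lrr_sd <= 0 or self.baf_sd <= 0:
            raise ConfigurationError("lrr_sd and baf_sd must be positive")
        if not 0 <= self.baf_weight <= 1:
            raise ConfigurationError("baf_weight must be in [0, 1]")
        if set(self.state_means) != set(STATES):
            raise ConfigurationError("state_means must cover copy numbers 0-4")


def default_profiles() -> dict[str, HmmParams]:
    """Three distinct presets emulating the three calling programs.

    They differ in segmentation stiffness (stay_prob), assumed intensity
    noise and how much weight the BAF track carries.
    """
    return {
        "penn-like": HmmParams("penn-like", lrr_sd=0.13, baf_sd=0.030, stay_prob=0.999, baf_weight=0.50),
        "quanti-like": HmmParams("quanti-like", lrr_sd=0.14, baf_sd=0.032, stay_prob=0.995, baf_weight=0.45),
        "partition-like": HmmParams("partition-like", lrr_sd=0.16, baf_sd=0.035, stay_prob=0.99, baf_weight=0.40),
    }


# ---------------------------------------------------------------------------
# Emission model
# ---------------------------------------------------------------------------


def _lrr_loglik(lrr: np.ndarray, params: HmmParams) -> np.ndarray:
    """(n, 5) Gaussian LRR log-density per state."""
    out = np.empty((lrr.size, len(STATES)))
    for j, cn in enumerate(STATES):
        sd = params.lrr_sd * (CN0_SD_SCALE if cn == 0 else 1.0)
        out[:, j] = -0.5 * ((lrr - params.state_means[cn]) / sd) ** 2 - math.log(
            sd * math.sqrt(2 * math.pi)
        )
    return out


def _baf_loglik(baf: np.ndarray, params: HmmParams) -> np.ndarray:
    """(n, 5) genotype-cluster mixture BAF log-density per state.

    CN=0 has no genotype: BAF is uniform on [0, 1], log-density 0.
    Probes with missing BAF get 0 for every state (no contribution).
    """
    n = baf.size
    out = np.zeros((n, len(STATES)))
    ok = ~np.isnan(baf)
    b = baf[ok]
    sd = params.baf_sd
    norm = -math.log(sd * math.sqrt(2 * math.pi))
    for j, cn in enumerate(STATES):
        if cn == 0:
            continue
        centers = baf_clusters(cn)
        logw = np.log(baf_cluster_weights(cn))
        comp = (
            logw[None, :]
            - 0.5 * ((b[:, None] - centers[None, :]) / sd) ** 2
            + norm
        )
        out[ok, j] = logsumexp(comp, axis=1)
    return out


def emission_loglik(lrr: np.ndarray, baf: np.ndarray, params: HmmParams) -> np.ndarray:
    """(n, 5) combined per-probe emission log-density.

    Callers must pass probes with non-missing LRR; where BAF is missing the
    LRR term is used unweighted.
    """
    lrr = np.asarray(lrr, dtype=float)
    baf = np.asarray(baf, dtype=float)
    if lrr.shape != baf.shape:
        raise InputError("LRR and BAF arrays must align")
    ll = _lrr_loglik(lrr, params)
    w = params.baf_weight
    out = (1.0 - w) * ll + w * _baf_loglik(baf, params)
    baf_missing = np.isnan(baf)
    if baf_missing.any():
        out[baf_missing, :] = ll[baf_missing, :]
    return out


# ---------------------------------------------------------------------------
# Viterbi
# ---------------------------------------------------------------------------


def _log_transition(params: HmmParams) -> np.ndarray:
    k = len(STATES)
    switch = (1.0 - params.stay_prob) / (k - 1)
    logT = np.full((k, k), math.log(switch))
    np.fill_diagonal(logT, math.log(params.stay_prob))
    return logT


def _log_initial(params: HmmParams) -> np.ndarray:
    k = len(STATES)
    pi = np.full(k, (1.0 - params.stay_prob) / (k - 1))
    pi[DIPLOID] = params.stay_prob
    return np.log(pi)


def viterbi_path(
    lrr: np.ndarray, baf: np.ndarray, params: HmmParams
) -> tuple[np.ndarray, float]:
    """Most probable copy-number state sequence and its joint log-probability.

    Input arrays must contain no missing LRR values (the segmenter filters
    those out before calling).  Ties are broken toward diploid.
    """
    e = emission_loglik(lrr, baf, params)
    n = e.shape[0]
    if n == 0:
        return np.array([], dtype=int), 0.0
    logT = _log_transition(params)
    order = TIE_ORDER
    delta = _log_initial(params) + e[0]
    psi = np.empty((n, len(STATES)), dtype=np.int8)
    for t in range(1, n):
        scores = delta[:, None] + logT  # (from, to)
        sub = scores[order, :]
        best = np.argmax(sub, axis=0)  # first max -> earliest in preference order
        psi[t] = order[best]
        delta = sub[best, np.arange(len(STATES))] + e[t]
    last = int(order[np.argmax(delta[order])])
    path = np.empty(n, dtype=int)
    path[-1] = last
    for t in range(n - 1, 0, -1):
        path[t - 1] = psi[t, path[t]]
    return path, float(delta[last])


def score_call(
    call: CnvCall,
    sample: IntensitySample,
    layout: GenomeLayout,
    params: HmmParams,
) -> float:
    """log10 Bayes factor of the called state versus diploid over the call.

    Computed as the probe-wise emission log-likelihood difference between the
    called copy-number state and CN 2, summed over the observed probes inside
    the call interval and converted to base 10.
    """
    sl = layout.probe_slice(call.chrom, call.start, call.end)
    lrr = np.asarray(sample.lrr[call.chrom][sl], dtype=float)
    baf = np.asarray(sample.baf[call.chrom][sl], dtype=float)
    ok = ~np.isnan(lrr)
    if not ok.any():
        raise InputError(f"call covers zero observed probes: {call.key}")
    e = emission_loglik(lrr[ok], baf[ok], params)
    j = STATES.index(call.copy_number)
    return float((e[:, j] - e[:, DIPLOID]).sum() / LN10)


def viterbi_segment(
    sample: IntensitySample,
    layout: GenomeLayout,
    params: HmmParams,
    skip_chroms: Sequence[str] = SEX_CHROMOSOMES,
) -> list[CnvCall]:
    """Segment one sample into CNV calls.

    Probes with missing LRR are skipped (the distance-independent transition
    spans them).  Sex chromosomes are excluded by default: hemizygous male X
    would otherwise be reported as a chromosome-wide deletion, and sex is
    handled by the sample QC instead.  Calls are the maximal runs of
    non-diploid states, with ``n_probes`` the number of observed probes in
    the run and ``confidence`` its log10 Bayes factor.
    """
    calls: list[CnvCall] = []
    for chrom in layout.chrom_names:
        if chrom in skip_chroms:
            continue
        lrr_all = np.asarray(sample.lrr[chrom], dtype=float)
        baf_all = np.asarray(sample.baf[chrom], dtype=float)
        if lrr_all.shape != layout.probes[chrom].shape:
            raise InputError(f"intensity arrays misaligned with layout on chromosome {chrom}")
        ok = ~np.isnan(lrr_all)
        if not ok.any():
            continue
        pos = layout.probes[chrom][ok]
        path, _ = viterbi_path(lrr_all[ok], baf_all[ok], params)
        i = 0
        n = path.size
        while i < n:
            if path[i] == DIPLOID:
                i += 1
                continue
            j = i
            while j + 1 < n and path[j + 1] == path[i]:
                j += 1
            cn = int(path[i])
            call = CnvCall(
                sample_id=sample.sample_id,
                caller_id=params.caller_id,
                chrom=chrom,
                start=int(pos[i]),
                end=int(pos[j]),
                type=cnv_type_for(cn),
                copy_number=cn,
                n_probes=j - i + 1,
            )
            call.confidence = score_call(call, sample, layout, params)
            calls.append(call)
            i = j + 1
    calls.sort(key=CnvCall.sort_key)
    return calls


def run_caller(
    cohort: Sequence[IntensitySample],
    layout: GenomeLayout,
    params: HmmParams,
    cohort_tag: str | None = None,
) -> CallSet:
    calls: list[CnvCall] = []
    for sample in cohort:
        calls.extend(viterbi_segment(sample, layout, params))
    return CallSet(sorted(calls, key=CnvCall.sort_key), cohort=cohort_tag)


def run_three_callers(
    cohort: Sequence[IntensitySample],
    layout: GenomeLayout,
    profiles: Mapping[str, HmmParams] | None = None,
    cohort_tag: str | None = None,
) -> dict[str, CallSet]:
    """Run the three emulated calling programs over one cohort.

    Deterministic: no randomness is involved.  Post-hoc boundary jitter or
    false-positive injection (the simulator's caller-emulation mode) is never
    applied here.
    """
    profiles = dict(profiles) if profiles is not None else default_profiles()
    ids = [p.caller_id for p in profiles.values()]
    if len(set(ids)) != len(ids):
        raise ConfigurationError("caller_id values must be distinct")
    return {
        p.caller_id: run_caller(cohort, layout, p, cohort_tag=cohort_tag)
        for p in profiles.values()
    }
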