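"""Sample QC and the CNV filter cascade.

Stages (pipeline order): per-sample array QC, per-call quality filter,
control-overlap exclusion (per caller, per CNV type), three-caller consensus
intersection, size filter (>= 50 kb) and frequency-catalogue filter.  Every
stage is a pure subset operation (hence idempotent) and records a complete
per-call provenance trace: |kept| + |removed| = |input| at each stage.

Boundary semantics follow the quality criteria verbatim: calls are *excluded*
when the log10 Bayes factor is < 30 or the call covers <= 3 aberrant probes;
samples fail when < 98% of markers were generated; CNVs < 50 kb are removed.
The boundary-complement values (confidence 30, 4 probes, call rate 0.98,
50,000 bp) are therefore kept.

"Overlapping exactly or completely within" is implemented strictly: only an
EXACT coordinate match or full containment of the case CNV inside the other
interval excludes; partial overlap never does.  The same semantics drive both
the in-house-control filter and the frequency-database filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core import (
    CallSet,
    CnvCall,
    ConfigurationError,
    ConsensusCnv,
    GenomeLayout,
    IntensitySample,
    IntervalRelation,
    SampleQcReport,
    StratificationError,
    ValidationError,
    intersection,
    relation,
)

logger = logging.getLogger(__name__)

#: Mean X-chromosome LRR below which a sample is called male (hemizygous X
#: shifts LRR to about -0.6; diploid X sits at 0).
SEX_X_LRR_CUTOFF = -0.25


@dataclass
class FilterThresholds:
    """Defaults encode the published QC rules; every one is a config knob.

    ``min_probes_exclusive`` / ``control_carrier_exclusive`` are exclusive
    bounds: calls with ``n_probes <= 3`` are removed, case CNVs carried by
    ``> 1`` distinct controls are removed.
    """

    min_log_bf: float = 30.0
    min_probes_exclusive: int = 3
    min_call_rate: float = 0.98
    cnv_count_sd_mult: float = 2.0
    control_carrier_exclusive: int = 1
    min_length_bp: int = 50_000

    def __post_init__(self) -> None:
        for name in ("min_log_bf", "min_call_rate", "cnv_count_sd_mult"):
            if not np.isfinite(getattr(self, name)):
                raise ConfigurationError(f"{name} must be finite")
        if self.min_probes_exclusive < 0 or self.min_length_bp < 0:
            raise ConfigurationError("thresholds must be non-negative")


@dataclass
class TraceRecord:
    key: str
    stage: str
    decision: str  # kept | removed
    reason: str


class FilterTrace:
    """Ordered per-call provenance of every filter decision."""

    def __init__(self) -> None:
        self.records: list[TraceRecord] = []

    def record(self, key: str, stage: str, decision: str, reason: str) -> None:
        self.records.append(TraceRecord(key, stage, decision, reason))

    def extend(self, other: "FilterTrace") -> None:
        self.records.extend(other.records)

    def kept(self, stage: str | None = None) -> list[TraceRecord]:
        return [r for r in self.records if r.decision == "kept" and (stage is None or r.stage == stage)]

    def removed(self, stage: str | None = None) -> list[TraceRecord]:
        return [r for r in self.records if r.decision == "removed" and (stage is None or r.stage == stage)]

    def stage_counts(self) -> dict[str, tuple[int, int]]:
        out: dict[str, list[int]] = {}
        for r in self.records:
            k = out.setdefault(r.stage, [0, 0])
            k[0 if r.decision == "kept" else 1] += 1
        return {s: (k, r) for s, (k, r) in out.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.key, r.stage, r.decision, r.reason) for r in self.records],
            columns=["call_key", "stage", "decision", "reason"],
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Sample QC
# ---------------------------------------------------------------------------


@dataclass
class SampleMetrics:
    """Per-sample intensity-derived QC inputs."""

    sample_id: str
    call_rate: float
    mean_x_lrr: float
    recorded_sex: str
    cohort: str = "case"


def intensity_metrics(
    samples: Sequence[IntensitySample], layout: GenomeLayout, x_chrom: str = "X"
) -> dict[str, SampleMetrics]:
    out = {}
    for s in samples:
        out[s.sample_id] = SampleMetrics(
            sample_id=s.sample_id,
            call_rate=s.call_rate(),
            mean_x_lrr=s.mean_lrr(x_chrom) if x_chrom in s.lrr else float("nan"),
            recorded_sex=s.recorded_sex,
            cohort=s.cohort,
        )
    return out


def call_sex(mean_x_lrr: float) -> str:
    if np.isnan(mean_x_lrr):
        return "unknown"
    return "M" if mean_x_lrr < SEX_X_LRR_CUTOFF else "F"


def sample_qc(
    callsets: Mapping[str, CallSet] | CallSet,
    metrics: Mapping[str, SampleMetrics],
    thresholds: FilterThresholds | None = None,
) -> list[SampleQcReport]:
    """Per-sample array QC.

    A sample fails when (i) its probe call rate is below ``min_call_rate``,
    (ii) the sex called from mean X LRR contradicts the recorded sex, or
    (iii) its CNV count exceeds the cohort mean by more than
    ``cnv_count_sd_mult`` population standard deviations.  The CNV count is
    the mean per-caller raw call count.  With fewer than 2 samples the
    count-outlier rule is skipped with a warning.
    """
    thresholds = thresholds or FilterThresholds()
    if isinstance(callsets, CallSet):
        callsets = {"caller": callsets}
    sample_ids = sorted(metrics)
    n_callers = max(1, len(callsets))
    counts = {s: 0.0 for s in sample_ids}
    for cs in callsets.values():
        for c in cs:
            if c.sample_id in counts:
                counts[c.sample_id] += 1.0 / n_callers
    values = np.array([counts[s] for s in sample_ids], dtype=float)
    if len(sample_ids) < 2:
        logger.warning("sample QC: fewer than 2 samples; CNV-count outlier rule skipped")
        count_cutoff = float("inf")
    else:
        count_cutoff = float(values.mean() + thresholds.cnv_count_sd_mult * values.std())
    reports = []
    for s in sample_ids:
        m = metrics[s]
        reasons: list[str] = []
        if m.call_rate < thresholds.min_call_rate:
            reasons.append("call_rate")
        sex = call_sex(m.mean_x_lrr)
        if sex != "unknown" and sex != m.recorded_sex:
            reasons.append("sex_mismatch")
        if counts[s] > count_cutoff:
            reasons.append("cnv_count_outlier")
        reports.append(
            SampleQcReport(
                sample_id=s,
                call_rate=m.call_rate,
                sex_called=sex,
                cnv_count=counts[s],
                passed=not reasons,
                reasons=tuple(reasons),
            )
        )
    return reports


# ---------------------------------------------------------------------------
# Call QC
# ---------------------------------------------------------------------------


def call_qc(
    callset: CallSet, thresholds: FilterThresholds | None = None
) -> tuple[CallSet, FilterTrace]:
    """Exclude calls with log10 Bayes factor < 30 or <= 3 aberrant probes."""
    thresholds = thresholds or FilterThresholds()
    trace = FilterTrace()
    kept = []
    for c in callset:
        if c.confidence is None:
            raise ValidationError(f"call without confidence in call QC: {c.key}")
        if c.confidence < thresholds.min_log_bf:
            trace.record(c.key, "call_qc", "removed", f"log_bf<{thresholds.min_log_bf:g}")
        elif c.n_probes <= thresholds.min_probes_exclusive:
            trace.record(c.key, "call_qc", "removed", f"n_probes<={thresholds.min_probes_exclusive}")
        else:
            trace.record(c.key, "call_qc", "kept", "pass")
            kept.append(c)
    return CallSet(kept, cohort=callset.cohort), trace


# ---------------------------------------------------------------------------
# Control-overlap exclusion
# ---------------------------------------------------------------------------

_EXCLUDING = (IntervalRelation.EXACT, IntervalRelation.CASE_WITHIN_OTHER)


def _control_index(
    controls: Sequence[CnvCall],
) -> dict[tuple, IntervalTree]:
    trees: dict[tuple, IntervalTree] = {}
    for c in controls:
        tree = trees.setdefault((c.chrom,), IntervalTree())
        tree.addi(c.start, c.end + 1, c)
    return trees


def control_overlap_filter(
    case_calls: CallSet,
    control_calls: CallSet,
    thresholds: FilterThresholds | None = None,
    pooled: bool = False,
) -> tuple[CallSet, FilterTrace]:
    """Remove case CNVs present in more than ``control_carrier_exclusive``
    distinct in-house controls.

    A control *carries* a case CNV when it has >= 1 call of the same type
    (and, unless ``pooled``, from the same calling program) that matches the
    case call EXACTLY or fully contains it.  Duplications and deletions are
    filtered independently and, by default, separately per caller.
    """
    thresholds = thresholds or FilterThresholds()
    trace = FilterTrace()
    case_strata = {(c.caller_id if not pooled else "*", c.type) for c in case_calls}
    control_callers = {c.caller_id for c in control_calls}
    if not pooled:
        missing = {cal for cal, _ in case_strata} - control_callers
        if missing and len(control_calls) > 0:
            raise StratificationError(
                f"case calls from caller(s) {sorted(missing)} have no control stratum"
            )
    # index controls per stratum and chromosome
    index: dict[tuple, IntervalTree] = {}
    for c in control_calls:
        key = ("*" if pooled else c.caller_id, c.type, c.chrom)
        index.setdefault(key, IntervalTree()).addi(c.start, c.end + 1, c)
    kept = []
    for c in case_calls:
        key = ("*" if pooled else c.caller_id, c.type, c.chrom)
        carriers: set[str] = set()
        for iv in index.get(key, IntervalTree()).overlap(c.start, c.end + 1):
            ctl = iv.data
            if relation(c.start, c.end, ctl.start, ctl.end) in _EXCLUDING:
                carriers.add(ctl.sample_id)
        if len(carriers) > thresholds.control_carrier_exclusive:
            trace.record(
                c.key,
                "control_overlap",
                "removed",
                f"control_carriers={len(carriers)}",
            )
        else:
            trace.record(c.key, "control_overlap", "kept", "pass")
            kept.append(c)
    return CallSet(kept, cohort=case_calls.cohort), trace


# ---------------------------------------------------------------------------
# Three-caller consensus
# ---------------------------------------------------------------------------


def consensus_intersect(
    callsets: Mapping[str, CallSet],
    min_reciprocal_overlap: float = 0.0,
) -> tuple[list[ConsensusCnv], FilterTrace]:
    """Intersect the call sets of exactly three calling programs.

    For each (sample, chromosome, type) stratum, calls are matched greedily
    left-to-right: the first caller's calls are visited in positional order
    and joined with the first still-unused overlapping call of each other
    caller such that the triple intersection is non-empty.  The consensus
    interval is that triple intersection; confidence and probe support are
    the minima over the three source calls.  Each source call joins at most
    one consensus event.  ``min_reciprocal_overlap`` optionally requires every
    pairwise overlap to cover that fraction of the longer call (default off:
    any non-empty triple intersection qualifies).
    """
    if len(callsets) != 3:
        raise ConfigurationError("consensus requires exactly three call sets")
    trace = FilterTrace()
    caller_ids = sorted(callsets)
    strata: dict[tuple, dict[str, list[CnvCall]]] = {}
    for cid in caller_ids:
        for c in callsets[cid]:
            if c.caller_id != cid:
                raise ConfigurationError(
                    f"call set {cid!r} contains call from caller {c.caller_id!r}"
                )
            strata.setdefault((c.sample_id, c.chrom, c.type), {k: [] for k in caller_ids})[
                cid
            ].append(c)
    events: list[ConsensusCnv] = []
    matched: set[str] = set()

    def ok_pair(a: CnvCall, b: CnvCall) -> bool:
        inter = intersection(a.start, a.end, b.start, b.end)
        if inter is None:
            return False
        if min_reciprocal_overlap > 0:
            need = min_reciprocal_overlap * max(a.length, b.length)
            if inter[1] - inter[0] + 1 < need:
                return False
        return True

    for key in sorted(strata):
        by_caller = strata[key]
        a_list, b_list, c_list = (
            sorted(by_caller[cid], key=lambda c: (c.start, c.end)) for cid in caller_ids
        )
        used_b: set[int] = set()
        used_c: set[int] = set()
        for a in a_list:
            hit = None
            for bi, b in enumerate(b_list):
                if bi in used_b or not ok_pair(a, b):
                    continue
                ab = intersection(a.start, a.end, b.start, b.end)
                for ci, c in enumerate(c_list):
                    if ci in used_c or not ok_pair(a, c) or not ok_pair(b, c):
                        continue
                    abc = intersection(ab[0], ab[1], c.start, c.end)
                    if abc is None:
                        continue
                    hit = (bi, ci, b, c, abc)
                    break
                if hit:
                    break
            if hit is None:
                continue
            bi, ci, b, c, (s, e) = hit
            used_b.add(bi)
            used_c.add(ci)
            sources = (a, b, c)
            matched.update(x.key for x in sources)
            events.append(
                ConsensusCnv(
                    sample_id=a.sample_id,
                    chrom=a.chrom,
                    start=s,
                    end=e,
                    type=a.type,
                    min_confidence=min(x.confidence for x in sources),
                    min_n_probes=min(x.n_probes for x in sources),
                    union_start=min(x.start for x in sources),
                    union_end=max(x.end for x in sources),
                    source_keys=tuple(x.key for x in sources),
                    sources=sources,
                )
            )
    for cid in caller_ids:
        for c in callsets[cid]:
            if c.key in matched:
                trace.record(c.key, "consensus", "kept", "consensus_member")
            else:
                trace.record(c.key, "consensus", "removed", "missing_caller")
    events.sort(key=ConsensusCnv.sort_key)
    return events, trace


# ---------------------------------------------------------------------------
# Size and frequency filters
# ---------------------------------------------------------------------------


def size_filter(
    cnvs: Sequence, thresholds: FilterThresholds | None = None
) -> tuple[list, FilterTrace]:
    """Remove CNVs shorter than ``min_length_bp`` (default: < 50 kb)."""
    thresholds = thresholds or FilterThresholds()
    trace = FilterTrace()
    kept = []
    for c in cnvs:
        if c.length < thresholds.min_length_bp:
            trace.record(c.key, "size_filter", "removed", f"length<{thresholds.min_length_bp}")
        else:
            trace.record(c.key, "size_filter", "kept", "pass")
            kept.append(c)
    return kept, trace


def frequency_filter(
    cnvs: Sequence,
    db: Sequence,
    thresholds: FilterThresholds | None = None,
) -> tuple[list, FilterTrace]:
    """Remove CNVs with a completely or exactly overlapping catalogue record.

    A CNV is removed iff at least one record of compatible type (same type or
    BOTH) matches it EXACTLY or fully contains it; partial overlap and
    records lying inside the CNV never exclude.
    """
    trace = FilterTrace()
    index: dict[str, IntervalTree] = {}
    for r in db:
        index.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end + 1, r)
    kept = []
    for c in cnvs:
        hit = None
        for iv in index.get(c.chrom, IntervalTree()).overlap(c.start, c.end + 1):
            rec = iv.data
            if not rec.matches_type(c.type):
                continue
            if relation(c.start, c.end, rec.start, rec.end) in _EXCLUDING:
                hit = rec
                break
        if hit is not None:
            trace.record(c.key, "frequency_filter", "removed", f"db:{hit.source_id}")
        else:
            trace.record(c.key, "frequency_filter", "kept", "pass")
            kept.append(c)
    return kept, trace
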