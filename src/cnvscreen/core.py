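"""Core domain types for SNP-array copy-number screening.

Conventions used throughout the package
---------------------------------------
* Genomic coordinates are **1-based inclusive**; the length of an interval is
  ``end - start + 1``.  BED import/export converts to/from 0-based half-open.
* Chromosome names are stored without a ``chr`` prefix.
* Copy number (CN) states are the integers 0-4; CN 2 is diploid.  A call with
  CN < 2 is a deletion (``DEL``), CN > 2 a duplication (``DUP``).
* LRR is the log2 R ratio (normalized probe intensity); BAF is the B-allele
  frequency in [0, 1].  Missing probe values are ``NaN``.

The canonical LRR level per copy-number state and the BAF cluster structure
(genotype clusters at k/c for k B alleles out of c copies) are shared between
the simulator and the HMM caller, so that a correctly implemented caller can
separate the states it is asked to recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Mapping, Sequence

import numpy as np

CNV_TYPES = ("DEL", "DUP")
BIOTYPES = ("protein_coding", "lncRNA", "miRNA", "antisense", "other_noncoding")
NONCODING_BIOTYPES = ("lncRNA", "miRNA", "antisense", "other_noncoding")
SEX_CHROMOSOMES = ("X", "Y")

#: Mean LRR per copy-number state.  Diploid probes sit at 0; a single-copy
#: gain shifts the log2 ratio by roughly +0.4, a second gain to ~+0.68
#: (log2(c/2) saturating with dye response); hemizygous loss sits near -0.6
#: and homozygous loss collapses toward the noise floor.
DEFAULT_STATE_MEANS: dict[int, float] = {0: -3.0, 1: -0.60, 2: 0.0, 3: 0.40, 4: 0.68}

#: Scale factor applied to the LRR standard deviation of the CN=0 state: with
#: no DNA present the ratio is dominated by background noise.
CN0_SD_SCALE = 3.0


class CnvScreenError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CnvScreenError):
    """Invalid configuration (bad thresholds, sizes, duplicate caller ids...)."""


class ValidationError(CnvScreenError):
    """An input file or record violates an invariant; never silently repaired."""


class InputError(CnvScreenError):
    """A well-formed but unusable input (e.g. a call covering zero probes)."""


class PlacementError(CnvScreenError):
    """A simulated event could not be placed without overlap."""


class StratificationError(CnvScreenError):
    """Case/control call sets cannot be stratified consistently by caller."""


def normalize_chrom(name: str) -> str:
    """Strip a leading ``chr``/``Chr`` prefix from a chromosome name."""
    name = str(name).strip()
    if name.lower().startswith("chr"):
        return name[3:]
    return name


def chrom_sort_key(name: str) -> tuple[int, int | str]:
    """Natural chromosome ordering: numeric first, then X/Y/others."""
    try:
        return (0, int(name))
    except ValueError:
        return (1, name)


def cnv_type_for(copy_number: int) -> str:
    """Map a copy number to DEL/DUP; diploid has no CNV type."""
    if copy_number < 2:
        return "DEL"
    if copy_number > 2:
        return "DUP"
    raise ValidationError("copy number 2 is diploid and has no CNV type")


def baf_clusters(copy_number: int) -> np.ndarray:
    """BAF cluster centers for a copy-number state: k/c for k = 0..c B alleles.

    CN=2 gives {0, 1/2, 1}; CN=3 {0, 1/3, 2/3, 1}; CN=1 {0, 1};
    CN=4 {0, 1/4, 1/2, 3/4, 1}.  CN=0 has no genotype (signal is noise).
    """
    if copy_number == 0:
        return np.array([])
    return np.arange(copy_number + 1) / copy_number


def baf_cluster_weights(copy_number: int) -> np.ndarray:
    """Binomial(c, 1/2) genotype-cluster weights (population allele freq 1/2)."""
    if copy_number == 0:
        return np.array([])
    c = copy_number
    k = np.arange(c + 1)
    return np.array([math.comb(c, int(i)) for i in k]) * 0.5**c


# ---------------------------------------------------------------------------
# Interval arithmetic
# ---------------------------------------------------------------------------


class IntervalRelation(Enum):
    """Relation of a *case* interval to an *other* interval (1-based inclusive).

    ``EXACT``: both endpoints equal.  ``CASE_WITHIN_OTHER``: the case interval
    is strictly contained in (or equal to one side of) the other.  These two
    relations are the only ones that trigger the "overlapping exactly or
    completely within" exclusion rules; ``PARTIAL`` overlap never excludes.
    """

    EXACT = "exact"
    CASE_WITHIN_OTHER = "case_within_other"
    OTHER_WITHIN_CASE = "other_within_case"
    PARTIAL = "partial"
    NONE = "none"


def relation(
    case_start: int, case_end: int, other_start: int, other_end: int
) -> IntervalRelation:
    """Classify the relation between two 1-based inclusive intervals."""
    if case_start == other_start and case_end == other_end:
        return IntervalRelation.EXACT
    if other_start <= case_start and case_end <= other_end:
        return IntervalRelation.CASE_WITHIN_OTHER
    if case_start <= other_start and other_end <= case_end:
        return IntervalRelation.OTHER_WITHIN_CASE
    if case_start <= other_end and other_start <= case_end:
        return IntervalRelation.PARTIAL
    return IntervalRelation.NONE


def intervals_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start <= b_end and b_start <= a_end


def intersection(
    a_start: int, a_end: int, b_start: int, b_end: int
) -> tuple[int, int] | None:
    s, e = max(a_start, b_start), min(a_end, b_end)
    return (s, e) if s <= e else None


# ---------------------------------------------------------------------------
# Genome layout and intensity data
# ---------------------------------------------------------------------------


@dataclass(eq=False)
class GenomeLayout:
    """Chromosome lengths plus the sorted SNP-probe grid per chromosome.

    The layout is the shared substrate of simulation and calling: intensity
    arrays align 1:1 with ``probes[chrom]``.
    """

    chromosomes: tuple[tuple[str, int], ...]
    probes: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        self.chromosomes = tuple((normalize_chrom(n), int(l)) for n, l in self.chromosomes)
        lengths = dict(self.chromosomes)
        if set(self.probes) != set(lengths):
            raise ValidationError("probe chromosomes do not match chromosome list")
        probes = {}
        for name, pos in self.probes.items():
            pos = np.asarray(pos, dtype=np.int64)
            if pos.size < 4:
                raise ValidationError(f"chromosome {name}: fewer than 4 probes")
            if np.any(np.diff(pos) <= 0):
                raise ValidationError(f"chromosome {name}: probe positions not strictly increasing")
            if pos[0] < 1 or pos[-1] > lengths[name]:
                raise ValidationError(f"chromosome {name}: probe positions outside [1, length]")
            probes[name] = pos
        self.probes = probes

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.chromosomes)

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def n_probes(self) -> int:
        return int(sum(p.size for p in self.probes.values()))

    def autosomes(self) -> tuple[str, ...]:
        return tuple(n for n in self.chrom_names if n not in SEX_CHROMOSOMES)

    def probe_slice(self, chrom: str, start: int, end: int) -> slice:
        """Index slice of probes with position in [start, end]."""
        pos = self.probes[chrom]
        lo = int(np.searchsorted(pos, start, side="left"))
        hi = int(np.searchsorted(pos, end, side="right"))
        return slice(lo, hi)

    def probes_in(self, chrom: str, start: int, end: int) -> np.ndarray:
        return self.probes[chrom][self.probe_slice(chrom, start, end)]

    def median_spacing(self) -> float:
        gaps = np.concatenate([np.diff(p) for p in self.probes.values() if p.size > 1])
        return float(np.median(gaps))


@dataclass(eq=False)
class IntensitySample:
    """Per-probe LRR/BAF tracks of one array sample (NaN marks missing probes)."""

    sample_id: str
    cohort: str  # "case" | "control"
    recorded_sex: str  # "M" | "F"
    lrr: Mapping[str, np.ndarray]
    baf: Mapping[str, np.ndarray]

    def call_rate(self) -> float:
        total = sum(a.size for a in self.lrr.values())
        missing = sum(int(np.isnan(a).sum()) for a in self.lrr.values())
        return 1.0 - missing / total

    def mean_lrr(self, chrom: str) -> float:
        a = self.lrr.get(chrom)
        if a is None or np.all(np.isnan(a)):
            return float("nan")
        return float(np.nanmean(a))


# ---------------------------------------------------------------------------
# Calls, truth and tabular records
# ---------------------------------------------------------------------------


@dataclass
class TruthEvent:
    """A planted copy-number event (simulation ground truth)."""

    sample_id: str
    chrom: str
    start: int
    end: int
    copy_number: int
    cohort: str  # "case" | "control"
    label: str  # "ultra_rare" | "common_polymorphism"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"truth event start > end: {self}")
        if self.copy_number == 2:
            raise ValidationError("truth event copy number must differ from 2")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def type(self) -> str:
        return cnv_type_for(self.copy_number)


@dataclass
class CnvCall:
    """One caller's called copy-number segment for one sample."""

    sample_id: str
    caller_id: str
    chrom: str
    start: int
    end: int
    type: str
    copy_number: int
    n_probes: int
    confidence: float | None = None  # log10 Bayes factor vs diploid
    extra: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.chrom = normalize_chrom(self.chrom)
        if self.start > self.end:
            raise ValidationError(f"call start > end: {self.key}")
        if self.type not in CNV_TYPES:
            raise ValidationError(f"unknown CNV type {self.type!r}")
        if not 0 <= self.copy_number <= 4:
            raise ValidationError(f"copy number out of range: {self.copy_number}")
        if cnv_type_for(self.copy_number) != self.type:
            raise ValidationError(
                f"type {self.type} inconsistent with copy number {self.copy_number}"
            )
        if self.n_probes < 1:
            raise ValidationError("call must cover at least one probe")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def key(self) -> str:
        return f"{self.sample_id}|{self.caller_id}|{self.chrom}:{self.start}-{self.end}|{self.type}"

    def sort_key(self):
        return (self.sample_id, chrom_sort_key(self.chrom), self.start, self.end, self.type)


@dataclass
class CallSet:
    """A collection of CNV calls (typically one caller over one cohort)."""

    calls: list[CnvCall]
    cohort: str | None = None

    def __post_init__(self) -> None:
        seen: set[tuple] = set()
        for c in self.calls:
            k = (c.sample_id, c.caller_id, c.chrom, c.start, c.end, c.type)
            if k in seen:
                raise ValidationError(f"duplicate call record: {c.key}")
            seen.add(k)

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self) -> Iterator[CnvCall]:
        return iter(self.calls)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(sorted({c.sample_id for c in self.calls}))

    @property
    def caller_ids(self) -> tuple[str, ...]:
        return tuple(sorted({c.caller_id for c in self.calls}))

    def counts_per_sample(self, samples: Sequence[str] | None = None) -> dict[str, int]:
        counts: dict[str, int] = {s: 0 for s in (samples or ())}
        for c in self.calls:
            counts[c.sample_id] = counts.get(c.sample_id, 0) + 1
        return counts

    def subset(self, predicate) -> "CallSet":
        return CallSet([c for c in self.calls if predicate(c)], cohort=self.cohort)

    def sorted(self) -> "CallSet":
        return CallSet(sorted(self.calls, key=CnvCall.sort_key), cohort=self.cohort)


@dataclass
class FrequencyRecord:
    """One entry of a DGV-style CNV frequency catalogue."""

    chrom: str
    start: int
    end: int
    type: str  # DEL | DUP | BOTH
    source_id: str

    def __post_init__(self) -> None:
        self.chrom = normalize_chrom(self.chrom)
        if self.start > self.end:
            raise ValidationError(f"frequency record start > end: {self.source_id}")
        if self.type not in ("DEL", "DUP", "BOTH"):
            raise ValidationError(f"unknown frequency-record type {self.type!r}")

    def matches_type(self, cnv_type: str) -> bool:
        return self.type == "BOTH" or self.type == cnv_type


@dataclass
class ConsensusCnv:
    """A per-sample CNV supported by all three callers.

    ``start``/``end`` is the triple intersection (the most conservative span
    consistent with being called by all programs); the union of the three
    source intervals is retained for provenance.
    """

    sample_id: str
    chrom: str
    start: int
    end: int
    type: str
    min_confidence: float
    min_n_probes: int
    union_start: int
    union_end: int
    source_keys: tuple[str, ...]
    sources: tuple[CnvCall, ...] | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError("consensus intersection is empty")
        if len(self.source_keys) != 3:
            raise ValidationError("consensus requires exactly three source calls")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def key(self) -> str:
        return f"{self.sample_id}|consensus|{self.chrom}:{self.start}-{self.end}|{self.type}"

    def sort_key(self):
        return (self.sample_id, chrom_sort_key(self.chrom), self.start, self.end, self.type)


@dataclass
class GeneModel:
    """A gene annotation target (RefSeq-symbol style) with biotype."""

    symbol: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str

    def __post_init__(self) -> None:
        self.chrom = normalize_chrom(self.chrom)
        if self.start > self.end:
            raise ValidationError(f"gene {self.symbol}: start > end")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.symbol}: strand must be + or -")
        if self.biotype not in BIOTYPES:
            raise ValidationError(f"gene {self.symbol}: unknown biotype {self.biotype!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def promoter(self, promoter_bp: int = 2000) -> tuple[int, int]:
        """Strand-aware promoter window: ``promoter_bp`` upstream of the TSS."""
        if self.strand == "+":
            return (max(1, self.start - promoter_bp), self.start - 1)
        return (self.end + 1, self.end + promoter_bp)


EVIDENCE_FLAGS = (
    "embryonic_lower_urinary_tract_expression",
    "embryonic_kidney_expression",
    "urorectal_phenotype_report",
    "prior_disease_association",
)


@dataclass
class EvidenceRecord:
    """Per-gene prioritization evidence (embryonic expression / phenotype flags)."""

    symbol: str
    embryonic_lower_urinary_tract_expression: bool = False
    embryonic_kidney_expression: bool = False
    urorectal_phenotype_report: bool = False
    prior_disease_association: bool = False
    note: str = ""

    def flags(self) -> dict[str, bool]:
        return {f: bool(getattr(self, f)) for f in EVIDENCE_FLAGS}


@dataclass
class SampleQcReport:
    """Outcome of the per-sample array QC."""

    sample_id: str
    call_rate: float
    sex_called: str  # M | F | unknown
    cnv_count: float
    passed: bool
    reasons: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.passed != (len(self.reasons) == 0):
            raise ValidationError("QC report: passed flag inconsistent with reasons")
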