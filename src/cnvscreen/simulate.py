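"""Synthetic case-control SNP-array cohort generator.

Generates everything a genome-wide CNV screen consumes, at desk scale and
fully deterministically from one seed: a probe grid with realistic (~4.6 kb
median) marker spacing, planted copy-number truth (ultra-rare case events and
common polymorphisms shared by many controls), per-probe LRR/BAF intensity
tracks, a DGV-style frequency catalogue, a gene annotation and a gene-evidence
table.  A packaged fixture reproduces the three validated microduplications
(852,734 / 131,276 / 65,758 bp) with their gene content for worked examples.

Signal model
------------
Probes inside a CN=c segment draw ``LRR ~ Normal(mu_c, noise_sd_lrr)`` with
the state means of :data:`cnvscreen.core.DEFAULT_STATE_MEANS`, and BAF from
the CN-dependent genotype-cluster mixture (cluster centers k/c, binomial
weights at allele frequency 1/2) with standard deviation ``baf_sd``, clipped
to [0, 1].  CN=0 probes have no genotype and draw BAF uniformly.  Samples
recorded as male draw the whole X chromosome at CN=1 (hemizygous); this is
consumed only by the sex-concordance QC — CNV calling is autosomal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import yaml

from .core import (
    CallSet,
    CnvCall,
    ConfigurationError,
    DEFAULT_STATE_MEANS,
    EvidenceRecord,
    FrequencyRecord,
    GeneModel,
    GenomeLayout,
    IntensitySample,
    IntervalRelation,
    PlacementError,
    TruthEvent,
    cnv_type_for,
    intervals_overlap,
    relation,
)

logger = logging.getLogger(__name__)

# Independent deterministic random streams derived from the one config seed.
_STREAM_LAYOUT = 0
_STREAM_TRUTH = 1
_STREAM_INTENSITY = 2
_STREAM_FREQ_DB = 3
_STREAM_GENES = 4
_STREAM_EVIDENCE = 5
_STREAM_EMULATION = 6


def _rng(stream: int, seed: int) -> np.random.Generator:
    return np.random.default_rng([stream, seed])


@dataclass
class EventSpec:
    """One entry of the planted-event plan.

    ``ultra_rare`` events get independent coordinates per carrier;
    ``common_polymorphism`` events share one coordinate across all carriers
    (a segregating CNV polymorphism).
    """

    copy_number: int
    length_range: tuple[int, int]
    n_case_carriers: int = 0
    n_control_carriers: int = 0
    label: str = "ultra_rare"

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if lo <= 0 or hi < lo:
            raise ConfigurationError(f"invalid length range {self.length_range}")
        if self.copy_number == 2 or not 0 <= self.copy_number <= 4:
            raise ConfigurationError(f"invalid event copy number {self.copy_number}")
        if self.label not in ("ultra_rare", "common_polymorphism"):
            raise ConfigurationError(f"unknown event label {self.label!r}")
        if self.n_case_carriers + self.n_control_carriers < 1:
            raise ConfigurationError("event spec has no carriers")

    @property
    def n_carriers(self) -> int:
        return self.n_case_carriers + self.n_control_carriers


def default_event_spec() -> list[EventSpec]:
    """The default study plan: three ultra-rare case duplications spanning the
    validated-duplication length scale (~850 kb down to ~95 kb, all well above
    the 50 kb size filter and >= 20 probes so every caller profile's Bayes
    factor separates them), plus five common polymorphisms carried by 30% of
    cases and controls alike — two short enough to fail call QC, three long
    enough to survive it and be removed by the control-overlap filter."""
    return [
        EventSpec(3, (845_000, 855_000), n_case_carriers=1, label="ultra_rare"),
        EventSpec(3, (125_000, 135_000), n_case_carriers=1, label="ultra_rare"),
        EventSpec(3, (90_000, 100_000), n_case_carriers=1, label="ultra_rare"),
        EventSpec(3, (65_000, 75_000), 12, 60, "common_polymorphism"),
        EventSpec(1, (80_000, 90_000), 12, 60, "common_polymorphism"),
        EventSpec(3, (30_000, 38_000), 12, 60, "common_polymorphism"),
        EventSpec(1, (28_000, 34_000), 12, 60, "common_polymorphism"),
        EventSpec(3, (60_000, 70_000), 12, 60, "common_polymorphism"),
    ]


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort; identical seed+config means
    bit-identical outputs."""

    seed: int = 7
    n_cases: int = 40
    n_controls: int = 200
    noise_sd_lrr: float = 0.12
    baf_sd: float = 0.03
    missing_rate: float = 0.01
    event_spec: list[EventSpec] = field(default_factory=default_event_spec)
    caller_jitter_probes: int = 2
    caller_fp_rate: float = 0.02
    chromosomes: tuple[tuple[str, int, int], ...] = (
        ("1", 4_600_000, 1000),
        ("2", 3_700_000, 800),
        ("X", 920_000, 200),
    )

    def __post_init__(self) -> None:
        self.event_spec = [
            e if isinstance(e, EventSpec) else EventSpec(**e) for e in self.event_spec
        ]
        self.chromosomes = tuple((str(n), int(l), int(p)) for n, l, p in self.chromosomes)
        self.validate()

    def validate(self) -> None:
        if self.n_cases < 1 or self.n_controls < 0:
            raise ConfigurationError("cohort sizes must be positive")
        for rate, name in ((self.missing_rate, "missing_rate"), (self.caller_fp_rate, "caller_fp_rate")):
            if not 0 <= rate < 1:
                raise ConfigurationError(f"{name} must be in [0, 1)")
        for name, length, n in self.chromosomes:
            if length <= 0:
                raise ConfigurationError(f"chromosome {name}: non-positive length")
            if n < 4:
                raise ConfigurationError(f"chromosome {name}: need at least 4 probes")
        if self.caller_jitter_probes < 0:
            raise ConfigurationError("caller_jitter_probes must be >= 0")

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        return cls(**dict(d))

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return asdict(self)

    def case_ids(self) -> list[str]:
        return [f"case_{i + 1:03d}" for i in range(self.n_cases)]

    def control_ids(self) -> list[str]:
        return [f"ctrl_{i + 1:03d}" for i in range(self.n_controls)]


# ---------------------------------------------------------------------------
# Genome and truth
# ---------------------------------------------------------------------------


def make_genome(config: SimulationConfig) -> GenomeLayout:
    """Deterministic probe grid: a jittered regular spacing of L/(n+1) bp.

    The jitter is bounded below half the spacing, so positions stay strictly
    increasing; the median adjacent-probe gap equals the grid spacing.
    """
    rng = _rng(_STREAM_LAYOUT, config.seed)
    probes: dict[str, np.ndarray] = {}
    for name, length, n in config.chromosomes:
        spacing = length // (n + 1)
        if spacing < 3:
            raise ConfigurationError(f"chromosome {name}: too many probes for its length")
        base = spacing * np.arange(1, n + 1, dtype=np.int64)
        jitter = rng.integers(-(spacing // 3), spacing // 3 + 1, size=n)
        probes[name] = base + jitter
    return GenomeLayout(
        chromosomes=tuple((n, l) for n, l, _ in config.chromosomes), probes=probes
    )


def _place_interval(
    rng: np.random.Generator,
    layout: GenomeLayout,
    length: int,
    forbidden: Sequence[tuple[str, int, int]],
    attempts: int = 200,
) -> tuple[str, int, int] | None:
    """Pick an autosomal interval of ``length`` bp spanning >= 4 probes and
    not overlapping any interval in ``forbidden``."""
    autosomes = [c for c in layout.autosomes() if layout.lengths[c] >= length]
    if not autosomes:
        return None
    weights = np.array([layout.lengths[c] for c in autosomes], dtype=float)
    weights /= weights.sum()
    for _ in range(attempts):
        chrom = str(rng.choice(autosomes, p=weights))
        start = int(rng.integers(1, layout.lengths[chrom] - length + 2))
        end = start + length - 1
        if layout.probes_in(chrom, start, end).size < 4:
            continue
        if any(
            c == chrom and intervals_overlap(start, end, s, e) for c, s, e in forbidden
        ):
            continue
        return chrom, start, end
    return None


def plant_truth(layout: GenomeLayout, config: SimulationConfig) -> list[TruthEvent]:
    """Assign planted events to samples.

    Ultra-rare events are placed independently, one per carrier; common
    polymorphisms get a single shared coordinate for all carriers.  Carriers
    are drawn burden-balanced (least-loaded samples first, random tie-break),
    which keeps the per-sample CNV count distribution tight — the homogeneity
    that makes a mean + 2 SD count-outlier QC meaningful on real cohorts.
    Events within one sample never overlap.
    """
    rng = _rng(_STREAM_TRUTH, config.seed)
    cases, controls = config.case_ids(), config.control_ids()
    cohort_of = {s: "case" for s in cases} | {s: "control" for s in controls}
    load: dict[str, int] = {s: 0 for s in cases + controls}
    events_of: dict[str, list[tuple[str, int, int]]] = {s: [] for s in load}
    out: list[TruthEvent] = []

    def pick_carriers(pool: list[str], n: int, region: tuple[str, int, int]) -> list[str]:
        chrom, start, end = region
        order = list(pool)
        rng.shuffle(order)
        order.sort(key=lambda s: load[s])  # stable: keeps the shuffle within ties
        chosen = []
        for s in order:
            if len(chosen) == n:
                break
            if any(
                c == chrom and intervals_overlap(start, end, a, b)
                for c, a, b in events_of[s]
            ):
                continue
            chosen.append(s)
        return chosen if len(chosen) == n else []

    # Common polymorphisms are placed first; ultra-rare events then avoid all
    # polymorphic loci — an ultra-rare variant is by definition not a common
    # polymorphism, and this keeps the frequency catalogue orthogonal to the
    # planted candidates.
    poly_loci: list[tuple[str, int, int]] = []
    ordered = sorted(
        enumerate(config.event_spec), key=lambda t: t[1].label != "common_polymorphism"
    )
    def commit(region: tuple[str, int, int], carriers: list[str], spec: EventSpec) -> None:
        chrom, start, end = region
        for s in carriers:
            load[s] += 1
            events_of[s].append((chrom, start, end))
            out.append(
                TruthEvent(
                    sample_id=s,
                    chrom=chrom,
                    start=start,
                    end=end,
                    copy_number=spec.copy_number,
                    cohort=cohort_of[s],
                    label=spec.label,
                )
            )

    for i, spec in ordered:
        if spec.n_case_carriers > config.n_cases or spec.n_control_carriers > config.n_controls:
            raise PlacementError(f"event spec #{i}: more carriers than samples")
        if spec.label == "common_polymorphism":
            placed = False
            for _ in range(50):
                length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
                region = _place_interval(rng, layout, length, forbidden=[])
                if region is None:
                    break
                carriers = pick_carriers(cases, spec.n_case_carriers, region)
                carriers += pick_carriers(controls, spec.n_control_carriers, region)
                if len(carriers) == spec.n_carriers:
                    commit(region, carriers, spec)
                    poly_loci.append(region)
                    placed = True
                    break
            if not placed:
                raise PlacementError(f"could not place event spec #{i} ({spec.label})")
        else:
            for pool, n in ((cases, spec.n_case_carriers), (controls, spec.n_control_carriers)):
                # each carrier is distinct for one spec: least-loaded first
                order = list(pool)
                rng.shuffle(order)
                order.sort(key=lambda s: load[s])
                for carrier in order[:n]:
                    placed = False
                    for _ in range(50):
                        length = int(
                            rng.integers(spec.length_range[0], spec.length_range[1] + 1)
                        )
                        region = _place_interval(
                            rng, layout, length, forbidden=events_of[carrier] + poly_loci
                        )
                        if region is not None:
                            commit(region, [carrier], spec)
                            placed = True
                            break
                    if not placed:
                        raise PlacementError(f"could not place event spec #{i} ({spec.label})")
    out.sort(key=lambda e: (e.sample_id, e.chrom, e.start))
    return out


# ---------------------------------------------------------------------------
# Intensities
# ---------------------------------------------------------------------------


def _draw_baf(rng: np.random.Generator, copy_number: int, n: int, baf_sd: float) -> np.ndarray:
    if copy_number == 0:
        return rng.uniform(0.0, 1.0, size=n)
    k = rng.binomial(copy_number, 0.5, size=n)
    baf = k / copy_number + rng.normal(0.0, baf_sd, size=n)
    return np.clip(baf, 0.0, 1.0)


def simulate_intensities(
    layout: GenomeLayout, truth: Sequence[TruthEvent], config: SimulationConfig
) -> list[IntensitySample]:
    """Per-probe LRR/BAF tracks for every sample, from the planted truth."""
    if config.noise_sd_lrr <= 0:
        raise ConfigurationError("noise_sd_lrr must be positive")
    if config.baf_sd <= 0:
        raise ConfigurationError("baf_sd must be positive")
    for ev in truth:
        if ev.chrom not in layout.probes:
            raise ConfigurationError(f"truth event on unknown chromosome {ev.chrom}")
    rng = _rng(_STREAM_INTENSITY, config.seed)
    by_sample: dict[str, list[TruthEvent]] = {}
    for ev in truth:
        by_sample.setdefault(ev.sample_id, []).append(ev)

    samples: list[IntensitySample] = []
    ids = [(s, "case") for s in config.case_ids()] + [
        (s, "control") for s in config.control_ids()
    ]
    for i, (sample_id, cohort) in enumerate(ids):
        recorded_sex = "M" if i % 2 == 0 else "F"
        lrr: dict[str, np.ndarray] = {}
        baf: dict[str, np.ndarray] = {}
        for chrom in layout.chrom_names:
            n = layout.probes[chrom].size
            cn_base = 1 if (chrom == "X" and recorded_sex == "M") else 2
            lrr_c = rng.normal(DEFAULT_STATE_MEANS[cn_base], config.noise_sd_lrr, size=n)
            baf_c = _draw_baf(rng, cn_base, n, config.baf_sd)
            for ev in sorted(by_sample.get(sample_id, []), key=lambda e: (e.chrom, e.start)):
                if ev.chrom != chrom:
                    continue
                sl = layout.probe_slice(chrom, ev.start, ev.end)
                m = sl.stop - sl.start
                lrr_c[sl] = rng.normal(DEFAULT_STATE_MEANS[ev.copy_number], config.noise_sd_lrr, size=m)
                baf_c[sl] = _draw_baf(rng, ev.copy_number, m, config.baf_sd)
            if config.missing_rate > 0:
                miss = rng.random(n) < config.missing_rate
                lrr_c[miss] = np.nan
                baf_c[miss] = np.nan
            lrr[chrom] = lrr_c
            baf[chrom] = baf_c
        samples.append(
            IntensitySample(
                sample_id=sample_id,
                cohort=cohort,
                recorded_sex=recorded_sex,
                lrr=lrr,
                baf=baf,
            )
        )
    return samples


# ---------------------------------------------------------------------------
# Frequency catalogue, genes, evidence
# ---------------------------------------------------------------------------


def make_frequency_db(
    truth: Sequence[TruthEvent],
    layout: GenomeLayout,
    config: SimulationConfig,
    n_background: int = 40,
    locus_padding: int = 15_000,
) -> list[FrequencyRecord]:
    """DGV-style catalogue: every common polymorphism locus plus random
    background records.

    Polymorphism records are padded by ``locus_padding`` bp on both sides —
    real frequency catalogues aggregate the same locus from many studies with
    heterogeneous boundaries, so catalogue entries are typically wider than
    any one called segment.  Background records never exactly match or
    contain an ultra-rare planted event, so the frequency filter removes only
    common variation."""
    rng = _rng(_STREAM_FREQ_DB, config.seed)
    records: list[FrequencyRecord] = []
    seen: set[tuple] = set()
    rare = [(e.chrom, e.start, e.end) for e in truth if e.label == "ultra_rare"]
    k = 0
    for ev in truth:
        if ev.label != "common_polymorphism":
            continue
        locus = (ev.chrom, ev.start, ev.end, ev.type)
        if locus in seen:
            continue
        seen.add(locus)
        k += 1
        records.append(
            FrequencyRecord(
                ev.chrom,
                max(1, ev.start - locus_padding),
                min(layout.lengths[ev.chrom], ev.end + locus_padding),
                ev.type,
                f"dgv_poly_{k}",
            )
        )
    autosomes = list(layout.autosomes())
    weights = np.array([layout.lengths[c] for c in autosomes], dtype=float)
    weights /= weights.sum()
    i = 0
    while i < n_background:
        chrom = str(rng.choice(autosomes, p=weights))
        length = int(rng.integers(5_000, 45_000))
        start = int(rng.integers(1, layout.lengths[chrom] - length + 2))
        end = start + length - 1
        if any(
            c == chrom
            and relation(s, e, start, end)
            in (IntervalRelation.EXACT, IntervalRelation.CASE_WITHIN_OTHER)
            for c, s, e in rare
        ):
            continue
        i += 1
        records.append(
            FrequencyRecord(chrom, start, end, str(rng.choice(["DEL", "DUP", "BOTH"])), f"dgv_bg_{i}")
        )
    records.sort(key=lambda r: (r.chrom, r.start, r.end, r.source_id))
    return records


def make_gene_annotation(
    layout: GenomeLayout,
    truth: Sequence[TruthEvent],
    config: SimulationConfig,
    background_step: int = 150_000,
    background_density: float = 0.6,
) -> list[GeneModel]:
    """Synthetic gene annotation: two genes inside every ultra-rare planted
    event (so true candidates carry gene content) plus background genes tiled
    across the autosomes with gaps (gene deserts) left by the density knob."""
    rng = _rng(_STREAM_GENES, config.seed)
    genes: list[GeneModel] = []
    counter = 0

    def add(chrom: str, start: int, end: int, biotype: str) -> None:
        nonlocal counter
        counter += 1
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"GENE{counter:04d}", chrom, start, end, strand, biotype))

    seen_rare: set[tuple] = set()
    for ev in truth:
        if ev.label != "ultra_rare":
            continue
        locus = (ev.chrom, ev.start, ev.end)
        if locus in seen_rare:
            continue
        seen_rare.add(locus)
        span = ev.length
        g_len = max(2_000, span // 5)
        add(ev.chrom, ev.start + span // 6, ev.start + span // 6 + g_len - 1, "protein_coding")
        biotype = "protein_coding" if rng.random() < 0.7 else "lncRNA"
        add(ev.chrom, ev.start + (3 * span) // 5, ev.start + (3 * span) // 5 + g_len - 1, biotype)
    for chrom in layout.autosomes():
        length = layout.lengths[chrom]
        for anchor in range(background_step, length - 50_000, background_step):
            if rng.random() > background_density:
                continue
            g_len = int(rng.integers(5_000, 40_000))
            u = rng.random()
            biotype = (
                "protein_coding"
                if u < 0.65
                else "lncRNA"
                if u < 0.8
                else "miRNA"
                if u < 0.87
                else "antisense"
                if u < 0.94
                else "other_noncoding"
            )
            add(chrom, anchor, min(anchor + g_len - 1, length), biotype)
    genes.sort(key=lambda g: (g.chrom, g.start, g.symbol))
    return genes


def make_evidence_table(
    genes: Sequence[GeneModel],
    truth: Sequence[TruthEvent],
    config: SimulationConfig,
    background_rate: float = 0.05,
) -> list[EvidenceRecord]:
    """Expression/phenotype evidence: genes inside planted ultra-rare events
    get embryonic urinary-tract or kidney expression flags; a small random
    background of other genes carries incidental flags."""
    rng = _rng(_STREAM_EVIDENCE, config.seed)
    rare = [(e.chrom, e.start, e.end) for e in truth if e.label == "ultra_rare"]
    out: list[EvidenceRecord] = []
    for g in genes:
        inside = any(c == g.chrom and s <= g.start and g.end <= e for c, s, e in rare)
        if inside:
            if rng.random() < 0.5:
                out.append(
                    EvidenceRecord(
                        g.symbol,
                        embryonic_lower_urinary_tract_expression=True,
                        note="synthetic: embryonic bladder/urethra expression",
                    )
                )
            else:
                out.append(
                    EvidenceRecord(
                        g.symbol,
                        embryonic_kidney_expression=True,
                        note="synthetic: embryonic kidney expression",
                    )
                )
        elif rng.random() < background_rate:
            out.append(
                EvidenceRecord(
                    g.symbol,
                    prior_disease_association=rng.random() < 0.5,
                    urorectal_phenotype_report=rng.random() < 0.5,
                    note="synthetic: background literature flag",
                )
            )
    return [r for r in out if any(r.flags().values())]


# ---------------------------------------------------------------------------
# Caller-behaviour emulation (OFF by default in the calling module)
# ---------------------------------------------------------------------------


def emulate_caller_variation(
    callset: CallSet,
    layout: GenomeLayout,
    config: SimulationConfig,
    stream_offset: int = 0,
) -> CallSet:
    """Perturb a call set the way distinct calling programs disagree:
    boundaries jittered by up to ``caller_jitter_probes`` probe positions and
    short false-positive segments injected per sample at ``caller_fp_rate``.
    Used only to emulate caller discordance; real calling never applies it.
    """
    rng = _rng(_STREAM_EMULATION, config.seed + stream_offset)
    out: list[CnvCall] = []
    j = config.caller_jitter_probes
    for call in callset:
        pos = layout.probes[call.chrom]
        sl = layout.probe_slice(call.chrom, call.start, call.end)
        lo = max(0, sl.start + int(rng.integers(-j, j + 1)))
        hi = min(pos.size - 1, sl.stop - 1 + int(rng.integers(-j, j + 1)))
        if hi < lo:
            lo = hi
        out.append(
            CnvCall(
                call.sample_id,
                call.caller_id,
                call.chrom,
                int(pos[lo]),
                int(pos[hi]),
                call.type,
                call.copy_number,
                hi - lo + 1,
                call.confidence,
            )
        )
    for sample_id in callset.sample_ids:
        if rng.random() >= config.caller_fp_rate:
            continue
        chrom = str(rng.choice(list(layout.autosomes())))
        pos = layout.probes[chrom]
        n = int(rng.integers(4, 9))
        lo = int(rng.integers(0, pos.size - n))
        cn = int(rng.choice([1, 3]))
        caller = callset.calls[0].caller_id if callset.calls else "emulated"
        out.append(
            CnvCall(
                sample_id,
                caller,
                chrom,
                int(pos[lo]),
                int(pos[lo + n - 1]),
                cnv_type_for(cn),
                cn,
                n,
                float(rng.uniform(30, 60)),
            )
        )
    # drop duplicates the jitter may have created
    seen: set[tuple] = set()
    unique = []
    for c in out:
        k = (c.sample_id, c.caller_id, c.chrom, c.start, c.end, c.type)
        if k not in seen:
            seen.add(k)
            unique.append(c)
    return CallSet(sorted(unique, key=CnvCall.sort_key), cohort=callset.cohort)


# ---------------------------------------------------------------------------
# Worked-example fixture: the three validated microduplications
# ---------------------------------------------------------------------------

#: Exact lengths (bp, 1-based inclusive) of the three validated duplications.
FIXTURE_LENGTHS = {"5q23.2": 852_734, "10q23.31": 131_276, "1p36.21": 65_758}


def table1_fixture() -> tuple[list[CnvCall], list[GeneModel], list[EvidenceRecord]]:
    """The three validated microduplications with their gene content.

    Coordinates are synthetic (chosen to reproduce the exact published
    lengths); gene symbols, biotypes and embryonic-expression evidence follow
    the validated findings: dup5q23.2 (852,734 bp, de novo) with four
    non-coding RNAs and four coding genes, dup10q23.31 (131,276 bp) with
    MIR107 and two coding genes, dup1p36.21 (65,758 bp) with one antisense
    RNA and four coding genes.  The combined "MGC32805/PPIC" token is stored
    as a single non-coding entry, matching the published per-region grouping.
    """
    calls = [
        CnvCall("100243", "validated", "5", 121_576_001, 122_428_734, "DUP", 3, 186, 99.0),
        CnvCall("100295", "validated", "10", 91_190_001, 91_321_276, "DUP", 3, 29, 55.0),
        CnvCall("100009", "validated", "1", 16_040_001, 16_105_758, "DUP", 3, 14, 40.0),
    ]
    genes = [
        # dup5q23.2: 4 non-coding, 4 coding (synthetic placements, all inside)
        GeneModel("LINC02201", "5", 121_600_000, 121_640_000, "+", "lncRNA"),
        GeneModel("LOC101927357", "5", 121_700_000, 121_715_000, "-", "lncRNA"),
        GeneModel("LOC105379152", "5", 121_780_000, 121_800_000, "+", "lncRNA"),
        GeneModel("MGC32805/PPIC", "5", 121_860_000, 121_880_000, "-", "other_noncoding"),
        GeneModel("SNCAIP", "5", 121_900_000, 122_050_000, "+", "protein_coding"),
        GeneModel("PRDM6", "5", 122_100_000, 122_205_000, "+", "protein_coding"),
        GeneModel("SNX2", "5", 122_240_000, 122_300_000, "+", "protein_coding"),
        GeneModel("SNX24", "5", 122_310_000, 122_400_000, "+", "protein_coding"),
        # dup10q23.31: MIR107 sits inside PANK1, as in the genome
        GeneModel("PANK1", "10", 91_200_000, 91_260_000, "-", "protein_coding"),
        GeneModel("MIR107", "10", 91_218_000, 91_218_080, "-", "miRNA"),
        GeneModel("SLC16A12", "10", 91_270_000, 91_315_000, "+", "protein_coding"),
        # dup1p36.21: 4 coding + 1 antisense RNA
        GeneModel("FBLIM1", "1", 16_045_000, 16_075_000, "+", "protein_coding"),
        GeneModel("SLC25A34-AS1", "1", 16_076_000, 16_080_000, "-", "antisense"),
        GeneModel("SLC25A34", "1", 16_078_000, 16_082_000, "+", "protein_coding"),
        GeneModel("TMEM82", "1", 16_084_000, 16_090_000, "-", "protein_coding"),
        GeneModel("PLEKHM2", "1", 16_092_000, 16_104_000, "+", "protein_coding"),
    ]
    evidence = [
        EvidenceRecord(
            "SNCAIP",
            embryonic_kidney_expression=True,
            note="expressed in the developing mouse kidney at E15.5",
        ),
        EvidenceRecord(
            "MIR107",
            embryonic_kidney_expression=True,
            note="expressed in the embryonic mouse metanephros at E12.5",
        ),
        EvidenceRecord(
            "SLC16A12",
            embryonic_kidney_expression=True,
            note="expressed in the embryonic mouse kidney at E17.5",
        ),
        EvidenceRecord(
            "FBLIM1",
            embryonic_lower_urinary_tract_expression=True,
            note="strongly expressed in the embryonic mouse urethra at E15.5",
        ),
    ]
    return calls, genes, evidence
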