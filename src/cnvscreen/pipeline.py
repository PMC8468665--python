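"""End-to-end orchestration: simulate -> call -> QC -> filter -> prioritize.

The canonical stage order is::

    simulate, call, sample_qc, call_qc, control_filter, consensus,
    annotate, size_filter, frequency_filter, prioritize

Every stage writes its outputs (call sets, traces, tables) into a working
directory, so any contiguous prefix can be run, inspected, and the remaining
stages resumed later from the saved intermediates with an identical final
result.  Reports are regenerated byte-identically from the same config and
seed.  The size and frequency filters are pure subset operations and commute;
annotation is placed before the size filter in the canonical order.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import io as cio
from .annotate import (
    AnnotatedCnv,
    DEFAULT_WEIGHTS,
    GeneHit,
    annotate_all,
    gene_content_filter,
    prioritize,
)
from .core import (
    CallSet,
    ConfigurationError,
    GenomeLayout,
    InputError,
    IntensitySample,
    ValidationError,
)
from .filters import (
    FilterThresholds,
    FilterTrace,
    SampleMetrics,
    call_qc,
    consensus_intersect,
    control_overlap_filter,
    frequency_filter,
    intensity_metrics,
    sample_qc,
    size_filter,
)
from .hmm import default_profiles, run_three_callers
from .simulate import (
    SimulationConfig,
    make_evidence_table,
    make_frequency_db,
    make_gene_annotation,
    make_genome,
    plant_truth,
    simulate_intensities,
)

logger = logging.getLogger(__name__)

CANONICAL_STAGES = (
    "simulate",
    "call",
    "sample_qc",
    "call_qc",
    "control_filter",
    "consensus",
    "annotate",
    "size_filter",
    "frequency_filter",
    "prioritize",
)


@dataclass
class PipelineConfig:
    """One reproducible run: simulation plan, caller profiles, thresholds."""

    seed: int = 7
    simulation: SimulationConfig | None = None
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    promoter_bp: int = 2000
    weights: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    stages: tuple[str, ...] = CANONICAL_STAGES
    pooled_controls: bool = False
    min_reciprocal_overlap: float = 0.0
    write_intensities: bool = True

    def __post_init__(self) -> None:
        if self.simulation is None:
            self.simulation = SimulationConfig(seed=self.seed)
        elif isinstance(self.simulation, Mapping):
            d = dict(self.simulation)
            d.setdefault("seed", self.seed)
            self.simulation = SimulationConfig.from_dict(d)
        if isinstance(self.thresholds, Mapping):
            self.thresholds = FilterThresholds(**self.thresholds)
        self.stages = tuple(self.stages)
        if self.stages != CANONICAL_STAGES[: len(self.stages)]:
            raise ConfigurationError(
                "stages must be a contiguous prefix of the canonical order "
                f"{CANONICAL_STAGES}"
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls(**d)

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"] = self.simulation.to_dict()
        return d


def _caller_ids() -> list[str]:
    return sorted(default_profiles())


class PipelineRun:
    """Executes pipeline stages against a working directory.

    Intermediates are written after every stage; when a requested stage's
    inputs are not in memory they are loaded from the working directory, which
    is what makes prefix-rerun equivalence and the per-stage CLI work.
    """

    def __init__(self, config: PipelineConfig, workdir) -> None:
        self.config = config
        self.workdir = Path(workdir)
        self.workdir.mkdir(parents=True, exist_ok=True)
        (self.workdir / "traces").mkdir(exist_ok=True)
        self.state: dict = {}
        self.stage_counts: list[dict] = []

    # ------------------------------------------------------------------
    # artifact access (memory first, then the working directory)
    # ------------------------------------------------------------------

    def _path(self, name: str) -> Path:
        return self.workdir / name

    def _load(self, artifact: str):
        if artifact in self.state:
            return self.state[artifact]
        template = _ARTIFACT_FILES[artifact]
        p = self._path(template) if "{caller}" not in template else self.workdir
        value = _ARTIFACT_LOADERS[artifact](self, p)
        self.state[artifact] = value
        return value

    def _available(self, artifact: str) -> bool:
        if artifact in self.state:
            return True
        template = _ARTIFACT_FILES[artifact]
        if "{caller}" in template:
            return all(
                self._path(template.format(caller=c)).exists() for c in _caller_ids()
            )
        return self._path(template).exists()

    def _trace_path(self, stage: str) -> Path:
        return self.workdir / "traces" / f"{stage}.tsv"

    def _count(self, stage: str, n_in: int, n_out: int, unit: str) -> None:
        self.stage_counts.append({"stage": stage, "n_in": n_in, "n_out": n_out, "unit": unit})
        logger.info("stage=%s unit=%s n_in=%d n_out=%d", stage, unit, n_in, n_out)

    # ------------------------------------------------------------------
    # stages
    # ------------------------------------------------------------------

    def stage_simulate(self) -> None:
        cfg = self.config.simulation
        layout = make_genome(cfg)
        truth = plant_truth(layout, cfg)
        samples = simulate_intensities(layout, truth, cfg)
        genes = make_gene_annotation(layout, truth, cfg)
        db = make_frequency_db(truth, layout, cfg)
        evidence = make_evidence_table(genes, truth, cfg)
        metrics = intensity_metrics(samples, layout)
        self.state.update(
            layout=layout, truth=truth, samples=samples, genes=genes,
            frequency_db=db, evidence=evidence, metrics=metrics,
        )
        cio.write_layout(layout, self._path("layout.tsv"))
        cio.write_truth(truth, self._path("truth.bed"))
        cio.write_genes_tsv(genes, self._path("genes.tsv"))
        cio.write_frequency_db(db, self._path("frequency_db.tsv"))
        cio.write_evidence(evidence, self._path("evidence.tsv"))
        self._write_metrics(metrics)
        if self.config.write_intensities:
            cio.write_intensities(samples, layout, self._path("intensities.tsv"))
        self._count("simulate", len(samples), len(truth), "samples_in/truth_events_out")

    def _write_metrics(self, metrics: Mapping[str, SampleMetrics]) -> None:
        with open(self._path("metrics.tsv"), "w", newline="") as fh:
            fh.write("#cnvscreen-metrics\tv1\n")
            fh.write("sample_id\tcohort\trecorded_sex\tcall_rate\tmean_x_lrr\n")
            for s in sorted(metrics):
                m = metrics[s]
                fh.write(
                    f"{m.sample_id}\t{m.cohort}\t{m.recorded_sex}"
                    f"\t{m.call_rate:.6f}\t{m.mean_x_lrr:.4f}\n"
                )

    def stage_call(self) -> None:
        layout = self._load("layout")
        samples = self._load("samples")
        cases = [s for s in samples if s.cohort == "case"]
        controls = [s for s in samples if s.cohort == "control"]
        case_sets = run_three_callers(cases, layout, cohort_tag="case")
        control_sets = run_three_callers(controls, layout, cohort_tag="control")
        self.state["callsets_case"] = case_sets
        self.state["callsets_control"] = control_sets
        for cid, cs in case_sets.items():
            cio.write_callset(cs, self._path(f"calls_case_{cid}.tsv"))
        for cid, cs in control_sets.items():
            cio.write_callset(cs, self._path(f"calls_control_{cid}.tsv"))
        n_out = sum(len(c) for c in case_sets.values()) + sum(
            len(c) for c in control_sets.values()
        )
        self._count("call", len(samples), n_out, "samples_in/calls_out")

    def stage_sample_qc(self) -> None:
        metrics = self._load("metrics")
        case_sets = self._load("callsets_case")
        control_sets = self._load("callsets_control")
        reports: list = []
        passing: set[str] = set()
        for cohort, sets in (("case", case_sets), ("control", control_sets)):
            m = {k: v for k, v in metrics.items() if v.cohort == cohort}
            if not m:
                continue
            rep = sample_qc(sets, m, self.config.thresholds)
            reports.extend(rep)
            passing.update(r.sample_id for r in rep if r.passed)
        self.state["qc_reports"] = reports
        self.state["passing_samples"] = passing
        self.state["callsets_case"] = {
            cid: cs.subset(lambda c: c.sample_id in passing) for cid, cs in case_sets.items()
        }
        self.state["callsets_control"] = {
            cid: cs.subset(lambda c: c.sample_id in passing)
            for cid, cs in control_sets.items()
        }
        cio.write_qc_reports(sorted(reports, key=lambda r: r.sample_id), self._path("sample_qc.tsv"))
        self._count("sample_qc", len(reports), len(passing), "samples")

    def stage_call_qc(self) -> None:
        trace = FilterTrace()
        n_in = n_out = 0
        for cohort in ("case", "control"):
            sets = self._load(f"callsets_{cohort}")
            out = {}
            for cid, cs in sets.items():
                kept, t = call_qc(cs, self.config.thresholds)
                trace.extend(t)
                out[cid] = kept
                n_in += len(cs)
                n_out += len(kept)
                cio.write_callset(kept, self._path(f"calls_{cohort}_qc_{cid}.tsv"))
            self.state[f"callsets_{cohort}_qc"] = out
        trace.write(self._trace_path("call_qc"))
        self._count("call_qc", n_in, n_out, "calls")

    def stage_control_filter(self) -> None:
        case_sets = self._load("callsets_case_qc")
        control_sets = self._load("callsets_control_qc")
        trace = FilterTrace()
        out = {}
        n_in = n_out = 0
        for cid, cs in case_sets.items():
            controls = control_sets.get(cid)
            if controls is None:
                raise ConfigurationError(f"no control call set for caller {cid!r}")
            if self.config.pooled_controls:
                pooled = CallSet(
                    sorted(
                        (c for s in control_sets.values() for c in s),
                        key=lambda c: c.sort_key(),
                    ),
                    cohort="control",
                )
                kept, t = control_overlap_filter(cs, pooled, self.config.thresholds, pooled=True)
            else:
                kept, t = control_overlap_filter(cs, controls, self.config.thresholds)
            trace.extend(t)
            out[cid] = kept
            n_in += len(cs)
            n_out += len(kept)
            cio.write_callset(kept, self._path(f"calls_case_controlfiltered_{cid}.tsv"))
        self.state["callsets_case_filtered"] = out
        trace.write(self._trace_path("control_filter"))
        self._count("control_filter", n_in, n_out, "calls")

    def stage_consensus(self) -> None:
        case_sets = self._load("callsets_case_filtered")
        events, trace = consensus_intersect(
            case_sets, min_reciprocal_overlap=self.config.min_reciprocal_overlap
        )
        self.state["consensus"] = events
        cio.write_consensus(events, self._path("consensus.tsv"))
        trace.write(self._trace_path("consensus"))
        n_in = sum(len(cs) for cs in case_sets.values())
        self._count("consensus", n_in, len(events), "calls_in/consensus_out")

    def stage_annotate(self) -> None:
        events = self._load("consensus")
        genes = self._load("genes")
        annotated = annotate_all(events, genes, self.config.promoter_bp)
        kept, trace = gene_content_filter(annotated)
        self.state["annotated"] = kept
        self._write_annotated(kept, "annotated.tsv")
        trace.write(self._trace_path("gene_content"))
        self._count("annotate", len(annotated), len(kept), "cnvs")

    def stage_size_filter(self) -> None:
        annotated = self._load("annotated")
        kept, trace = size_filter(annotated, self.config.thresholds)
        self.state["annotated"] = kept
        self._write_annotated(kept, "annotated_size.tsv")
        trace.write(self._trace_path("size_filter"))
        self._count("size_filter", len(annotated), len(kept), "cnvs")

    def stage_frequency_filter(self) -> None:
        annotated = self._load("annotated")
        db = self._load("frequency_db")
        kept, trace = frequency_filter(annotated, db, self.config.thresholds)
        self.state["annotated"] = kept
        self._write_annotated(kept, "annotated_freq.tsv")
        trace.write(self._trace_path("frequency_filter"))
        self._count("frequency_filter", len(annotated), len(kept), "cnvs")

    def stage_prioritize(self) -> None:
        annotated = self._load("annotated")
        evidence = self._load("evidence")
        known = {g.symbol for g in self._load("genes")}
        ranked = prioritize(annotated, evidence, self.config.weights, known_symbols=known)
        self.state["candidates"] = ranked
        self._write_annotated(ranked, "candidates.tsv", ranked=True)
        self._count("prioritize", len(annotated), len(ranked), "cnvs")

    def _write_annotated(self, items: Sequence[AnnotatedCnv], name: str, ranked: bool = False) -> None:
        with open(self._path(name), "w", newline="") as fh:
            fh.write("#cnvscreen-annotated\tv1\n")
            cols = [
                "sample_id", "chrom", "start", "end", "type", "length",
                "min_confidence", "min_n_probes", "union_start", "union_end",
                "source_keys", "gene_hits", "priority_score",
            ]
            if ranked:
                cols = ["rank"] + cols
            fh.write("\t".join(cols) + "\n")
            for i, a in enumerate(items, start=1):
                c = a.cnv
                hits = ";".join(f"{h.gene.symbol}:{h.coverage}" for h in a.gene_hits)
                row = [
                    c.sample_id, c.chrom, str(c.start), str(c.end), c.type,
                    str(a.length),
                    f"{getattr(c, 'min_confidence', getattr(c, 'confidence', float('nan'))):.4f}",
                    str(getattr(c, "min_n_probes", getattr(c, "n_probes", 0))),
                    str(getattr(c, "union_start", c.start)),
                    str(getattr(c, "union_end", c.end)),
                    ",".join(getattr(c, "source_keys", ())) or "NA",
                    hits or "NA",
                    str(a.priority_score),
                ]
                if ranked:
                    row = [str(i)] + row
                fh.write("\t".join(row) + "\n")

    # ------------------------------------------------------------------
    # execution
    # ------------------------------------------------------------------

    def run_stages(self, stages: Sequence[str]) -> None:
        for s in stages:
            if s not in CANONICAL_STAGES:
                raise ConfigurationError(f"unknown stage {s!r}")
        stages = sorted(set(stages), key=CANONICAL_STAGES.index)
        # validate inputs of the first stage before doing any work
        first = stages[0]
        missing = [
            a for a in _STAGE_REQUIRES[first] if not self._available(a)
        ]
        if missing:
            raise ConfigurationError(
                f"stage {first!r} requires missing inputs: {missing} "
                f"(expected files in {self.workdir})"
            )
        for s in stages:
            getattr(self, f"stage_{s}")()

    def report(self) -> dict:
        qc = self.state.get("qc_reports", [])
        failed = [r.sample_id for r in qc if not r.passed]
        candidates = self.state.get("candidates", self.state.get("annotated", []))
        rep = {
            "software": "cnvscreen",
            "version": _version(),
            "seed": self.config.seed,
            "config": self.config.echo(),
            "stage_counts": self.stage_counts,
            "sample_qc": {"n_samples": len(qc), "n_failed": len(failed), "failed": sorted(failed)},
            "candidates": [
                {
                    "rank": i + 1,
                    "sample_id": a.cnv.sample_id,
                    "region": f"{a.cnv.chrom}:{a.cnv.start}-{a.cnv.end}",
                    "type": a.cnv.type,
                    "length": a.length,
                    "genes": list(a.symbols()),
                    "priority_score": a.priority_score,
                }
                for i, a in enumerate(candidates)
            ],
        }
        return rep

    def write_report(self) -> Path:
        p = self._path("report.json")
        with open(p, "w") as fh:
            json.dump(self.report(), fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")
        return p


def _version() -> str:
    from . import __version__

    return __version__


def run(config: PipelineConfig, workdir) -> dict:
    """Execute the configured stage prefix and return the run report."""
    runner = PipelineRun(config, workdir)
    runner.run_stages(config.stages)
    report = runner.report()
    runner.write_report()
    return report


# artifact name -> file in the working directory
_ARTIFACT_FILES = {
    "layout": "layout.tsv",
    "truth": "truth.bed",
    "samples": "intensities.tsv",
    "metrics": "metrics.tsv",
    "genes": "genes.tsv",
    "frequency_db": "frequency_db.tsv",
    "evidence": "evidence.tsv",
    "callsets_case": "calls_case_{caller}.tsv",
    "callsets_control": "calls_control_{caller}.tsv",
    "callsets_case_qc": "calls_case_qc_{caller}.tsv",
    "callsets_control_qc": "calls_control_qc_{caller}.tsv",
    "callsets_case_filtered": "calls_case_controlfiltered_{caller}.tsv",
    "consensus": "consensus.tsv",
    "annotated": "annotated.tsv",
}


def _load_callset_group(run_: PipelineRun, template: str) -> dict[str, CallSet]:
    out = {}
    for cid in _caller_ids():
        p = run_.workdir / template.format(caller=cid)
        if not p.exists():
            raise ConfigurationError(f"missing intermediate call set: {p}")
        out[cid] = cio.read_callset(p)
    return out


def _read_metrics(run_: PipelineRun, path: Path) -> dict[str, SampleMetrics]:
    out = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("sample_id\t") or not line.strip():
                continue
            p = line.rstrip("\n").split("\t")
            out[p[0]] = SampleMetrics(
                sample_id=p[0], cohort=p[1], recorded_sex=p[2],
                call_rate=float(p[3]), mean_x_lrr=float(p[4]),
            )
    return out


def _load_annotated(run_: PipelineRun, path: Path) -> list[AnnotatedCnv]:
    # prefer the furthest-progressed annotated table present
    for name in ("annotated_freq.tsv", "annotated_size.tsv", "annotated.tsv"):
        p = run_.workdir / name
        if p.exists():
            path = p
            break
    genes = {g.symbol: g for g in run_._load("genes")}
    out: list[AnnotatedCnv] = []
    from .core import ConsensusCnv

    with open(path) as fh:
        header: list[str] | None = None
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if header is None:
                header = parts
                continue
            d = dict(zip(header, parts))
            cnv = ConsensusCnv(
                sample_id=d["sample_id"],
                chrom=d["chrom"],
                start=int(d["start"]),
                end=int(d["end"]),
                type=d["type"],
                min_confidence=float(d["min_confidence"]),
                min_n_probes=int(d["min_n_probes"]),
                union_start=int(d["union_start"]),
                union_end=int(d["union_end"]),
                source_keys=tuple(d["source_keys"].split(",")) if d["source_keys"] != "NA" else ("", "", ""),
            )
            hits = []
            if d["gene_hits"] != "NA":
                for token in d["gene_hits"].split(";"):
                    sym, coverage = token.rsplit(":", 1)
                    if sym not in genes:
                        raise ValidationError(f"annotated table names unknown gene {sym!r}")
                    hits.append(GeneHit(genes[sym], coverage))
            a = AnnotatedCnv(cnv=cnv, gene_hits=hits)
            a.priority_score = int(d.get("priority_score", 0))
            out.append(a)
    return out


_ARTIFACT_LOADERS = {
    "layout": lambda r, p: cio.read_layout(p),
    "truth": lambda r, p: cio.read_truth(p),
    "samples": lambda r, p: cio.read_intensities(p, r._load("layout")),
    "metrics": _read_metrics,
    "genes": lambda r, p: cio.read_genes(p),
    "frequency_db": lambda r, p: cio.read_frequency_db(p),
    "evidence": lambda r, p: cio.read_evidence(p),
    "callsets_case": lambda r, p: _load_callset_group(r, "calls_case_{caller}.tsv"),
    "callsets_control": lambda r, p: _load_callset_group(r, "calls_control_{caller}.tsv"),
    "callsets_case_qc": lambda r, p: _load_callset_group(r, "calls_case_qc_{caller}.tsv"),
    "callsets_control_qc": lambda r, p: _load_callset_group(r, "calls_control_qc_{caller}.tsv"),
    "callsets_case_filtered": lambda r, p: _load_callset_group(
        r, "calls_case_controlfiltered_{caller}.tsv"
    ),
    "consensus": lambda r, p: cio.read_consensus(p),
    "annotated": _load_annotated,
}

_STAGE_REQUIRES = {
    "simulate": [],
    "call": ["layout", "samples"],
    "sample_qc": ["metrics", "callsets_case", "callsets_control"],
    "call_qc": ["callsets_case", "callsets_control"],
    "control_filter": ["callsets_case_qc", "callsets_control_qc"],
    "consensus": ["callsets_case_filtered"],
    "annotate": ["consensus", "genes"],
    "size_filter": ["annotated"],
    "frequency_filter": ["annotated", "frequency_db"],
    "prioritize": ["annotated", "evidence", "genes"],
}


# ---------------------------------------------------------------------------
# Plot export for manual review
# ---------------------------------------------------------------------------


def plot_call(
    sample: IntensitySample,
    region: tuple[str, int, int],
    layout: GenomeLayout,
    path,
    calls: Sequence | None = None,
    pad_bp: int = 100_000,
) -> Path:
    """Render LRR and BAF tracks around a region with call boundaries marked.

    This is the pipeline's stand-in for interactive visual inspection of
    candidate calls: it exports a deterministic per-call image for human
    review and applies no automated pass/fail.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chrom, start, end = region
    chrom = str(chrom)
    if chrom not in layout.probes:
        raise InputError(f"region {chrom}:{start}-{end}: unknown chromosome")
    lo = max(1, start - pad_bp)
    hi = min(layout.lengths[chrom], end + pad_bp)
    sl = layout.probe_slice(chrom, lo, hi)
    pos = layout.probes[chrom][sl]
    if pos.size == 0:
        raise InputError(f"region {chrom}:{start}-{end}: no probes in region")
    lrr = np.asarray(sample.lrr[chrom][sl], dtype=float)
    baf = np.asarray(sample.baf[chrom][sl], dtype=float)
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(9, 5), sharex=True, dpi=100)
    x = pos / 1e6
    ax1.scatter(x, lrr, s=4, color="#1f4e79")
    ax1.axhline(0.0, color="grey", lw=0.5)
    ax1.set_ylabel("LRR")
    ax1.set_title(f"{sample.sample_id}  {chrom}:{start:,}-{end:,}")
    ax2.scatter(x, baf, s=4, color="#7a1f4e")
    for y in (0.0, 1 / 3, 0.5, 2 / 3, 1.0):
        ax2.axhline(y, color="grey", lw=0.3)
    ax2.set_ylabel("BAF")
    ax2.set_ylim(-0.05, 1.05)
    ax2.set_xlabel(f"chromosome {chrom} (Mb)")
    for ax in (ax1, ax2):
        ax.axvline(start / 1e6, color="red", lw=0.8, ls="--")
        ax.axvline(end / 1e6, color="red", lw=0.8, ls="--")
        if calls:
            for c in calls:
                if c.chrom == chrom:
                    ax.axvspan(c.start / 1e6, c.end / 1e6, color="orange", alpha=0.15)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, format=path.suffix.lstrip(".") or "png", metadata={"Software": "cnvscreen"})
    plt.close(fig)
    return path
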