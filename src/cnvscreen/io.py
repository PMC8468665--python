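"""Tabular I/O for every artifact the pipeline touches.

All native formats are plain TSV with a versioned ``#cnvscreen-...`` header
line and round-trip bit-exactly (write -> read -> write is the identity).
Readers validate and reject malformed records with the offending line number;
they never silently repair.  Coordinates are 1-based inclusive in memory and
in the native TSVs; BED files use the standard 0-based half-open convention.

Supported formats: native call-set TSV, PennCNV ``.rawcnv`` (read-only), BED
(read/write), DGV-style frequency TSV, gene annotation (GFF3 via gffutils, or
BED6+biotype TSV), evidence TSV, genome-layout TSV, long-format intensity TSV
and the consensus/trace/QC tables the pipeline serializes.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    CallSet,
    CnvCall,
    ConsensusCnv,
    EvidenceRecord,
    EVIDENCE_FLAGS,
    FrequencyRecord,
    GeneModel,
    GenomeLayout,
    IntensitySample,
    SampleQcReport,
    TruthEvent,
    ValidationError,
    chrom_sort_key,
    cnv_type_for,
    normalize_chrom,
)

CALLSET_COLUMNS = (
    "sample_id",
    "caller_id",
    "chrom",
    "start",
    "end",
    "type",
    "copy_number",
    "n_probes",
    "confidence",
)

_TYPE_TOKENS = {
    "del": "DEL",
    "deletion": "DEL",
    "loss": "DEL",
    "dup": "DUP",
    "duplication": "DUP",
    "gain": "DUP",
    "both": "BOTH",
    "gain+loss": "BOTH",
    "gain/loss": "BOTH",
}


def _normalize_type(token: str, line_no: int, allow_both: bool = False) -> str:
    t = _TYPE_TOKENS.get(token.strip().lower())
    if t is None or (t == "BOTH" and not allow_both):
        raise ValidationError(f"line {line_no}: unknown type token {token!r}")
    return t


def _fmt_conf(conf: float | None) -> str:
    return "NA" if conf is None else f"{conf:.4f}"


# ---------------------------------------------------------------------------
# Call sets
# ---------------------------------------------------------------------------


def write_callset(callset: CallSet, path) -> None:
    with open(path, "w", newline="") as fh:
        cohort = callset.cohort if callset.cohort is not None else "NA"
        fh.write(f"#cnvscreen-callset\tv1\tcohort={cohort}\n")
        extras = sorted({k for c in callset for k in c.extra})
        fh.write("\t".join(CALLSET_COLUMNS + tuple(extras)) + "\n")
        for c in callset:
            row = [
                c.sample_id,
                c.caller_id,
                c.chrom,
                str(c.start),
                str(c.end),
                c.type,
                str(c.copy_number),
                str(c.n_probes),
                _fmt_conf(c.confidence),
            ] + [c.extra.get(k, "NA") for k in extras]
            fh.write("\t".join(row) + "\n")


def _read_native_callset(path) -> CallSet:
    calls: list[CnvCall] = []
    cohort: str | None = None
    with open(path) as fh:
        lines = fh.read().splitlines()
    header_idx = 0
    if lines and lines[0].startswith("#cnvscreen-callset"):
        m = re.search(r"cohort=(\S+)", lines[0])
        if m and m.group(1) != "NA":
            cohort = m.group(1)
        header_idx = 1
    if len(lines) <= header_idx:
        return CallSet([], cohort=cohort)
    columns = lines[header_idx].split("\t")
    missing = [c for c in CALLSET_COLUMNS if c not in columns]
    if missing:
        raise ValidationError(f"call-set file missing columns: {missing}")
    extras = [c for c in columns if c not in CALLSET_COLUMNS]
    seen: set[tuple] = set()
    for line_no, line in enumerate(lines[header_idx + 1 :], start=header_idx + 2):
        if not line.strip():
            continue
        fields = dict(zip(columns, line.split("\t")))
        if len(fields) != len(columns):
            raise ValidationError(f"line {line_no}: wrong number of columns")
        try:
            start, end = int(fields["start"]), int(fields["end"])
            cn = int(fields["copy_number"])
            n_probes = int(fields["n_probes"])
        except ValueError as exc:
            raise ValidationError(f"line {line_no}: {exc}") from exc
        if start > end:
            raise ValidationError(f"line {line_no}: start > end")
        conf = None if fields["confidence"] == "NA" else float(fields["confidence"])
        try:
            call = CnvCall(
                sample_id=fields["sample_id"],
                caller_id=fields["caller_id"],
                chrom=fields["chrom"],
                start=start,
                end=end,
                type=_normalize_type(fields["type"], line_no),
                copy_number=cn,
                n_probes=n_probes,
                confidence=conf,
                extra={k: fields[k] for k in extras if fields.get(k, "NA") != "NA"},
            )
        except ValidationError as exc:
            raise ValidationError(f"line {line_no}: {exc}") from exc
        k = (call.sample_id, call.caller_id, call.chrom, call.start, call.end, call.type)
        if k in seen:
            raise ValidationError(f"line {line_no}: duplicate call record {call.key}")
        seen.add(k)
        calls.append(call)
    return CallSet(calls, cohort=cohort)


_RAWCNV_RE = re.compile(
    r"^chr(?P<chrom>\S+):(?P<start>[\d,]+)-(?P<end>[\d,]+)"
    r"\s+numsnp=(?P<numsnp>[\d,]+)\s+length=(?P<length>[\d,]+)"
    r"\s+state\d+,cn=(?P<cn>\d)\s+(?P<sample>\S+)"
    r"\s+startsnp=\S+\s+endsnp=\S+(?:\s+conf=(?P<conf>\S+))?"
)


def _read_rawcnv(path) -> CallSet:
    """PennCNV .rawcnv dialect, e.g.
    ``chr1:100001-200000 numsnp=25 length=100,000 state5,cn=3 sampleA startsnp=rs1 endsnp=rs2``.
    """
    calls: list[CnvCall] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            m = _RAWCNV_RE.match(line.strip())
            if m is None:
                raise ValidationError(f"line {line_no}: unparseable rawcnv record")
            start = int(m["start"].replace(",", ""))
            end = int(m["end"].replace(",", ""))
            if start > end:
                raise ValidationError(f"line {line_no}: start > end")
            cn = int(m["cn"])
            if cn == 2:
                raise ValidationError(f"line {line_no}: diploid copy number in CNV record")
            conf = float(m["conf"]) if m["conf"] else None
            calls.append(
                CnvCall(
                    sample_id=m["sample"],
                    caller_id="penncnv",
                    chrom=normalize_chrom(m["chrom"]),
                    start=start,
                    end=end,
                    type=cnv_type_for(cn),
                    copy_number=cn,
                    n_probes=int(m["numsnp"].replace(",", "")),
                    confidence=conf,
                )
            )
    return CallSet(calls)


def read_callset(path, dialect: str = "native_tsv") -> CallSet:
    if dialect == "native_tsv":
        return _read_native_callset(path)
    if dialect == "penncnv_rawcnv":
        return _read_rawcnv(path)
    raise ValidationError(f"unknown call-set dialect {dialect!r}")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def write_bed(items: Sequence, path) -> None:
    """BED (0-based half-open).  Accepts CnvCall/ConsensusCnv/TruthEvent-like
    objects; the name column is ``sample|caller|type`` where available.
    Rows are stably sorted by (chrom, start)."""
    rows = []
    for it in items:
        caller = getattr(it, "caller_id", getattr(it, "label", "NA"))
        name = f"{getattr(it, 'sample_id', 'NA')}|{caller}|{getattr(it, 'type', 'NA')}"
        rows.append((it.chrom, it.start - 1, it.end, name))
    rows.sort(key=lambda r: (chrom_sort_key(r[0]), r[1]))
    with open(path, "w", newline="") as fh:
        fh.write("#cnvscreen-bed\tv1\tzero-based-half-open\n")
        for chrom, s0, e, name in rows:
            fh.write(f"{chrom}\t{s0}\t{e}\t{name}\n")


def read_bed(path) -> list[tuple[str, int, int, str]]:
    """Read BED lines back as (chrom, start, end, name) 1-based inclusive."""
    out = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValidationError(f"line {line_no}: BED needs >= 3 columns")
            s0, e = int(parts[1]), int(parts[2])
            if e <= s0:
                raise ValidationError(f"line {line_no}: empty BED interval")
            name = parts[3] if len(parts) > 3 else ""
            out.append((normalize_chrom(parts[0]), s0 + 1, e, name))
    return out


# ---------------------------------------------------------------------------
# Frequency database
# ---------------------------------------------------------------------------


def write_frequency_db(records: Sequence[FrequencyRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("#cnvscreen-frequency-db\tv1\n")
        fh.write("chrom\tstart\tend\ttype\tsource_id\n")
        for r in records:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.type}\t{r.source_id}\n")


def read_frequency_db(path) -> list[FrequencyRecord]:
    """Validated, sorted records.  Type tokens loss/gain etc. are normalized;
    overlapping records are kept as-is (no merging)."""
    records: list[FrequencyRecord] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    body = [
        (i, l)
        for i, l in enumerate(lines, start=1)
        if l.strip() and not l.startswith("#") and not l.startswith("chrom\t")
    ]
    for line_no, line in body:
        parts = line.split("\t")
        if len(parts) != 5:
            raise ValidationError(f"line {line_no}: expected 5 columns")
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise ValidationError(f"line {line_no}: {exc}") from exc
        if start > end:
            raise ValidationError(f"line {line_no}: start > end")
        records.append(
            FrequencyRecord(
                chrom=normalize_chrom(parts[0]),
                start=start,
                end=end,
                type=_normalize_type(parts[3], line_no, allow_both=True),
                source_id=parts[4],
            )
        )
    records.sort(key=lambda r: (chrom_sort_key(r.chrom), r.start, r.end, r.source_id))
    return records


# ---------------------------------------------------------------------------
# Genes and evidence
# ---------------------------------------------------------------------------

_BIOTYPE_ALIASES = {
    "protein_coding": "protein_coding",
    "lincrna": "lncRNA",
    "lncrna": "lncRNA",
    "mirna": "miRNA",
    "antisense": "antisense",
    "antisense_rna": "antisense",
}


def _normalize_biotype(token: str) -> str:
    return _BIOTYPE_ALIASES.get(token.strip().lower(), "other_noncoding") if token else "other_noncoding"


def write_genes_tsv(genes: Sequence[GeneModel], path) -> None:
    """BED6 + biotype column (0-based half-open starts, like any BED)."""
    with open(path, "w", newline="") as fh:
        fh.write("#cnvscreen-genes\tv1\tbed6+biotype\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.symbol}\t.\t{g.strand}\t{g.biotype}\n"
            )


def _read_genes_tsv(path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 7:
                raise ValidationError(f"line {line_no}: expected 7 columns (BED6+biotype)")
            try:
                genes.append(
                    GeneModel(
                        symbol=parts[3],
                        chrom=normalize_chrom(parts[0]),
                        start=int(parts[1]) + 1,
                        end=int(parts[2]),
                        strand=parts[5],
                        biotype=parts[6]
                        if parts[6] in ("protein_coding", "lncRNA", "miRNA", "antisense", "other_noncoding")
                        else _normalize_biotype(parts[6]),
                    )
                )
            except (ValueError, ValidationError) as exc:
                raise ValidationError(f"line {line_no}: {exc}") from exc
    return _check_unique_symbols(genes)


def _read_genes_gff3(path) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for feat in db.features_of_type("gene"):
        attrs = feat.attributes
        symbol = (attrs.get("Name") or attrs.get("gene_name") or [feat.id])[0]
        biotype = (attrs.get("biotype") or attrs.get("gene_biotype") or ["other_noncoding"])[0]
        genes.append(
            GeneModel(
                symbol=symbol,
                chrom=normalize_chrom(feat.seqid),
                start=feat.start,
                end=feat.end,
                strand=feat.strand if feat.strand in ("+", "-") else "+",
                biotype=biotype if biotype in ("protein_coding", "lncRNA", "miRNA", "antisense", "other_noncoding") else _normalize_biotype(biotype),
            )
        )
    return _check_unique_symbols(genes)


def _check_unique_symbols(genes: list[GeneModel]) -> list[GeneModel]:
    seen: set[str] = set()
    for g in genes:
        if g.symbol in seen:
            raise ValidationError(f"duplicate gene symbol {g.symbol!r}")
        seen.add(g.symbol)
    genes.sort(key=lambda g: (chrom_sort_key(g.chrom), g.start, g.symbol))
    return genes


def read_genes(path) -> list[GeneModel]:
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        return _read_genes_gff3(path)
    return _read_genes_tsv(path)


def write_evidence(records: Sequence[EvidenceRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("#cnvscreen-evidence\tv1\n")
        fh.write("symbol\t" + "\t".join(EVIDENCE_FLAGS) + "\tnote\n")
        for r in records:
            flags = "\t".join("1" if v else "0" for v in r.flags().values())
            fh.write(f"{r.symbol}\t{flags}\t{r.note}\n")


def read_evidence(path) -> list[EvidenceRecord]:
    records = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#") or line.startswith("symbol\t"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 5:
                raise ValidationError(f"line {line_no}: expected >= 5 columns")
            try:
                flags = [bool(int(p)) for p in parts[1:5]]
            except ValueError as exc:
                raise ValidationError(f"line {line_no}: {exc}") from exc
            records.append(
                EvidenceRecord(
                    parts[0], *flags, note=parts[5] if len(parts) > 5 else ""
                )
            )
    return records


# ---------------------------------------------------------------------------
# Layout, truth, intensities
# ---------------------------------------------------------------------------


def write_layout(layout: GenomeLayout, path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("#cnvscreen-layout\tv1\n")
        for name, length in layout.chromosomes:
            fh.write(f"#chromosome\t{name}\t{length}\n")
        fh.write("chrom\tpos\n")
        for name, _ in layout.chromosomes:
            for p in layout.probes[name]:
                fh.write(f"{name}\t{p}\n")


def read_layout(path) -> GenomeLayout:
    chromosomes: list[tuple[str, int]] = []
    probes: dict[str, list[int]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("#chromosome\t"):
                _, name, length = line.split("\t")
                chromosomes.append((name, int(length)))
                probes[name] = []
            elif line.startswith("#") or line == "chrom\tpos" or not line.strip():
                continue
            else:
                chrom, pos = line.split("\t")
                if chrom not in probes:
                    raise ValidationError(f"line {line_no}: probe on undeclared chromosome")
                probes[chrom].append(int(pos))
    return GenomeLayout(
        chromosomes=tuple(chromosomes),
        probes={c: np.array(p, dtype=np.int64) for c, p in probes.items()},
    )


def write_truth(events: Sequence[TruthEvent], path) -> None:
    """Truth as BED + extra columns (copy_number, cohort, label)."""
    with open(path, "w", newline="") as fh:
        fh.write("#cnvscreen-truth\tv1\tchrom start0 end name copy_number cohort label\n")
        for e in sorted(events, key=lambda e: (chrom_sort_key(e.chrom), e.start, e.sample_id)):
            fh.write(
                f"{e.chrom}\t{e.start - 1}\t{e.end}\t{e.sample_id}\t{e.copy_number}\t{e.cohort}\t{e.label}\n"
            )


def read_truth(path) -> list[TruthEvent]:
    out = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 7:
                raise ValidationError(f"line {line_no}: expected 7 columns")
            out.append(
                TruthEvent(
                    sample_id=parts[3],
                    chrom=normalize_chrom(parts[0]),
                    start=int(parts[1]) + 1,
                    end=int(parts[2]),
                    copy_number=int(parts[4]),
                    cohort=parts[5],
                    label=parts[6],
                )
            )
    return out


def write_intensities(samples: Sequence[IntensitySample], layout: GenomeLayout, path) -> None:
    """Long-format TSV: sample_id, cohort, recorded_sex, chrom, pos, lrr, baf."""
    frames = []
    for s in samples:
        for chrom in layout.chrom_names:
            frames.append(
                pd.DataFrame(
                    {
                        "sample_id": s.sample_id,
                        "cohort": s.cohort,
                        "recorded_sex": s.recorded_sex,
                        "chrom": chrom,
                        "pos": layout.probes[chrom],
                        "lrr": s.lrr[chrom],
                        "baf": s.baf[chrom],
                    }
                )
            )
    df = pd.concat(frames, ignore_index=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.4f", na_rep="NA")


def read_intensities(path, layout: GenomeLayout) -> list[IntensitySample]:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"chrom": str})
    samples = []
    for sample_id, g in df.groupby("sample_id", sort=False):
        lrr: dict[str, np.ndarray] = {}
        baf: dict[str, np.ndarray] = {}
        for chrom in layout.chrom_names:
            gc = g[g["chrom"] == chrom]
            pos = layout.probes[chrom]
            if len(gc) != pos.size or not np.array_equal(gc["pos"].to_numpy(), pos):
                raise ValidationError(
                    f"sample {sample_id}: intensity rows misaligned with layout on {chrom}"
                )
            lrr[chrom] = gc["lrr"].to_numpy(dtype=float)
            baf[chrom] = gc["baf"].to_numpy(dtype=float)
        samples.append(
            IntensitySample(
                sample_id=str(sample_id),
                cohort=str(g["cohort"].iloc[0]),
                recorded_sex=str(g["recorded_sex"].iloc[0]),
                lrr=lrr,
                baf=baf,
            )
        )
    return samples


# ---------------------------------------------------------------------------
# Consensus, QC reports, traces
# ---------------------------------------------------------------------------

CONSENSUS_COLUMNS = (
    "sample_id",
    "chrom",
    "start",
    "end",
    "type",
    "min_confidence",
    "min_n_probes",
    "union_start",
    "union_end",
    "source_keys",
)


def write_consensus(events: Sequence[ConsensusCnv], path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("#cnvscreen-consensus\tv1\n")
        fh.write("\t".join(CONSENSUS_COLUMNS) + "\n")
        for e in events:
            fh.write(
                "\t".join(
                    [
                        e.sample_id,
                        e.chrom,
                        str(e.start),
                        str(e.end),
                        e.type,
                        f"{e.min_confidence:.4f}",
                        str(e.min_n_probes),
                        str(e.union_start),
                        str(e.union_end),
                        ";".join(e.source_keys),
                    ]
                )
                + "\n"
            )


def read_consensus(path) -> list[ConsensusCnv]:
    out = []
    with open(path) as fh:
        lines = [l for l in fh.read().splitlines() if l.strip()]
    for line_no, line in enumerate(lines, start=1):
        if line.startswith("#") or line.startswith("sample_id\t"):
            continue
        p = line.split("\t")
        if len(p) != len(CONSENSUS_COLUMNS):
            raise ValidationError(f"line {line_no}: expected {len(CONSENSUS_COLUMNS)} columns")
        out.append(
            ConsensusCnv(
                sample_id=p[0],
                chrom=normalize_chrom(p[1]),
                start=int(p[2]),
                end=int(p[3]),
                type=p[4],
                min_confidence=float(p[5]),
                min_n_probes=int(p[6]),
                union_start=int(p[7]),
                union_end=int(p[8]),
                source_keys=tuple(p[9].split(";")),
            )
        )
    return out


def write_qc_reports(reports: Sequence[SampleQcReport], path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("#cnvscreen-sample-qc\tv1\n")
        fh.write("sample_id\tcall_rate\tsex_called\tcnv_count\tpassed\treasons\n")
        for r in reports:
            fh.write(
                f"{r.sample_id}\t{r.call_rate:.6f}\t{r.sex_called}\t{r.cnv_count:.2f}"
                f"\t{int(r.passed)}\t{','.join(r.reasons) or 'NA'}\n"
            )


def read_qc_reports(path) -> list[SampleQcReport]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("sample_id\t") or not line.strip():
                continue
            p = line.rstrip("\n").split("\t")
            reasons = () if p[5] == "NA" else tuple(p[5].split(","))
            out.append(
                SampleQcReport(
                    sample_id=p[0],
                    call_rate=float(p[1]),
                    sex_called=p[2],
                    cnv_count=float(p[3]),
                    passed=bool(int(p[4])),
                    reasons=reasons,
                )
            )
    return out
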