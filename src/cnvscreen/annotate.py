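"""Gene/promoter content annotation and evidence-based prioritization.

For every surviving CNV the annotator reports each gene as *fully* affected
(gene body contained in the CNV), *partially* affected (non-empty gene-body
overlap) or *promoter-only* (no gene-body overlap, but the strand-aware
promoter window — by default the 2 kb upstream of the TSS — overlaps).  CNVs
touching no gene or promoter are discarded; the remainder are ranked by
embryonic-expression and phenotype evidence of their genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .core import (
    BIOTYPES,
    EvidenceRecord,
    GeneModel,
    chrom_sort_key,
    intervals_overlap,
)
from .filters import FilterTrace

logger = logging.getLogger(__name__)

#: Default evidence weights: high expression in embryonic lower-urinary-tract
#: tissue (cloaca/urethra/bladder) counts double; embryonic kidney
#: expression, reported urorectal phenotypes and prior disease associations
#: count once each.
DEFAULT_WEIGHTS: dict[str, int] = {
    "embryonic_lower_urinary_tract_expression": 2,
    "embryonic_kidney_expression": 1,
    "urorectal_phenotype_report": 1,
    "prior_disease_association": 1,
}

COVERAGE_CLASSES = ("full", "partial", "promoter_only")


@dataclass
class GeneHit:
    gene: GeneModel
    coverage: str  # full | partial | promoter_only


@dataclass
class AnnotatedCnv:
    """A CNV with its gene content and (after prioritize) a priority score."""

    cnv: object  # ConsensusCnv or CnvCall-like: .chrom .start .end .type .key
    gene_hits: list[GeneHit] = field(default_factory=list)
    priority_score: int = 0

    @property
    def key(self) -> str:
        return self.cnv.key

    @property
    def length(self) -> int:
        return self.cnv.length

    # coordinate passthroughs so annotated CNVs flow through interval filters
    @property
    def chrom(self) -> str:
        return self.cnv.chrom

    @property
    def start(self) -> int:
        return self.cnv.start

    @property
    def end(self) -> int:
        return self.cnv.end

    @property
    def type(self) -> str:
        return self.cnv.type

    def body_hits(self) -> list[GeneHit]:
        return [h for h in self.gene_hits if h.coverage != "promoter_only"]

    def promoter_only_hits(self) -> list[GeneHit]:
        return [h for h in self.gene_hits if h.coverage == "promoter_only"]

    def biotype_counts(self) -> dict[str, int]:
        counts = {b: 0 for b in BIOTYPES}
        for h in self.body_hits():
            counts[h.gene.biotype] += 1
        return counts

    def symbols(self) -> tuple[str, ...]:
        return tuple(h.gene.symbol for h in self.gene_hits)


def annotate(cnv, genes: Sequence[GeneModel], promoter_bp: int = 2000) -> AnnotatedCnv:
    """Classify every gene overlapping a CNV (or its promoter window).

    Full containment of the gene body in the CNV is ``full``; any other
    non-empty gene-body overlap is ``partial``; a gene whose body lies outside
    but whose promoter window overlaps is ``promoter_only``.  Each gene
    appears at most once; hits are ordered by position.
    """
    hits: list[GeneHit] = []
    for g in genes:
        if g.chrom != cnv.chrom:
            continue
        if intervals_overlap(cnv.start, cnv.end, g.start, g.end):
            coverage = "full" if (cnv.start <= g.start and g.end <= cnv.end) else "partial"
            hits.append(GeneHit(g, coverage))
        else:
            ps, pe = g.promoter(promoter_bp)
            if ps <= pe and intervals_overlap(cnv.start, cnv.end, ps, pe):
                hits.append(GeneHit(g, "promoter_only"))
    hits.sort(key=lambda h: (h.gene.start, h.gene.end, h.gene.symbol))
    return AnnotatedCnv(cnv=cnv, gene_hits=hits)


def annotate_all(
    cnvs: Sequence, genes: Sequence[GeneModel], promoter_bp: int = 2000
) -> list[AnnotatedCnv]:
    return [annotate(c, genes, promoter_bp) for c in cnvs]


def gene_content_filter(
    annotated: Sequence[AnnotatedCnv],
) -> tuple[list[AnnotatedCnv], FilterTrace]:
    """Keep only CNVs spanning a gene- or promoter-coding region."""
    trace = FilterTrace()
    kept = []
    for a in annotated:
        if a.gene_hits:
            trace.record(a.key, "gene_content", "kept", "pass")
            kept.append(a)
        else:
            trace.record(a.key, "gene_content", "removed", "no_gene_or_promoter")
    return kept, trace


def count_biotypes(annotated: AnnotatedCnv | Sequence[AnnotatedCnv]) -> dict[str, int]:
    """Gene-body hit counts per biotype; promoter-only hits counted separately
    under the ``promoter_only`` key."""
    items = [annotated] if isinstance(annotated, AnnotatedCnv) else list(annotated)
    counts = {b: 0 for b in BIOTYPES}
    counts["promoter_only"] = 0
    for a in items:
        for b, n in a.biotype_counts().items():
            counts[b] += n
        counts["promoter_only"] += len(a.promoter_only_hits())
    return counts


def gene_scores(
    evidence: Sequence[EvidenceRecord], weights: Mapping[str, int] | None = None
) -> dict[str, int]:
    weights = dict(DEFAULT_WEIGHTS if weights is None else weights)
    scores: dict[str, int] = {}
    for r in evidence:
        s = sum(weights.get(f, 0) for f, v in r.flags().items() if v)
        scores[r.symbol] = max(scores.get(r.symbol, 0), s)
    return scores


def prioritize(
    annotated: Sequence[AnnotatedCnv],
    evidence: Sequence[EvidenceRecord],
    weights: Mapping[str, int] | None = None,
    known_symbols: set[str] | None = None,
) -> list[AnnotatedCnv]:
    """Rank CNVs by the best evidence score among their genes.

    The CNV score is the maximum single-gene score (a CNV is as interesting
    as its best gene).  Sort is stable descending by (score, length), ties
    broken by genomic position.  Evidence rows naming a symbol absent from
    the gene annotation (``known_symbols``, defaulting to the symbols seen in
    the annotated CNVs) are ignored with a logged warning.
    """
    known = (
        set(known_symbols)
        if known_symbols is not None
        else {h.gene.symbol for a in annotated for h in a.gene_hits}
    )
    for r in evidence:
        if r.symbol not in known:
            logger.warning("evidence for unknown gene symbol %r ignored", r.symbol)
    scores = gene_scores(evidence, weights)
    for a in annotated:
        a.priority_score = max((scores.get(s, 0) for s in a.symbols()), default=0)
    return sorted(
        annotated,
        key=lambda a: (
            -a.priority_score,
            -a.length,
            chrom_sort_key(a.cnv.chrom),
            a.cnv.start,
            a.cnv.end,
        ),
    )
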