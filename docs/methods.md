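# Methods

## Scope and model

`cnvscreen` implements a case–control CNV screen on SNP-array intensity
data.  The unit of evidence is the per-probe pair (LRR, BAF): the LogR ratio
shifts with total copy number, while the B-allele frequency collapses into
copy-number-specific genotype clusters.  The screen proceeds caller → QC →
control-overlap exclusion → three-caller consensus → gene-content/size/
frequency filtering → prioritization, with every per-call decision recorded
in a filter trace.

All coordinates are 1-based inclusive and the length of an interval is
`end − start + 1`; BED import/export converts to 0-based half-open.
Chromosome names are stored without a `chr` prefix.

## Signal model (shared by simulator and caller)

Mean LRR per copy-number state: CN0 −3.0, CN1 −0.60, CN2 0.0, CN3 +0.40,
CN4 +0.68.  These are conventional array signal levels: ~log2(c/2) for gains
with dye saturation, hemizygous loss near −0.6, and a collapsed noise floor
for homozygous deletions.  BAF for CN = c clusters at k/c for k = 0..c B
alleles, weighted Binomial(c, ½) (population allele frequency ½); CN0 has no
genotype and BAF is uniform on [0, 1].  The simulator draws
`LRR ~ N(μ_c, noise_sd_lrr)` and BAF from the cluster mixture with standard
deviation `baf_sd`, clipped to [0, 1]; probes go missing (both tracks NaN)
at `missing_rate`.

## HMM caller

Five hidden states (CN 0–4), emission
`(1 − w)·log N(LRR; μ_CN, σ_CN) + w·log Σ_k π_k N(BAF; k/CN, σ_BAF)` with
`w = baf_weight`.  Numerical choices:

* the CN0 LRR standard deviation is 3× the profile's `lrr_sd` (no DNA means
  the ratio is background-dominated);
* probes with missing LRR are skipped entirely; a probe with LRR but missing
  BAF contributes its LRR log-density unweighted;
* transitions are distance-independent: `stay_prob` on the diagonal, the
  remainder uniform over the other four states, so a transition simply spans
  skipped probes (distance-scaled transitions are a possible extension);
* Viterbi ties are broken toward the diploid state with preference order
  CN 2, 1, 3, 0, 4 (nearest-diploid, deletion before duplication), which
  favours fewer calls;
* the initial distribution puts `stay_prob` on CN2.

Each maximal non-diploid Viterbi run becomes a call with `n_probes` = number
of observed probes in the run, and a confidence defined as the **log₁₀ Bayes
factor**: the summed per-probe emission log-likelihood difference between the
called state and CN2, in base 10 so that the conventional quality threshold
of 30 applies directly.  On diploid-mean data this score is non-positive by
construction.

Sex chromosomes are excluded from calling by default: a hemizygous male X
would otherwise be reported as a chromosome-wide deletion.  Sex enters only
through the sample QC (below).

### The three caller profiles

Three parameter presets stand in for running three distinct calling
programs on one intensity export — the programs themselves are not
reimplemented.  They differ in segmentation stiffness and track weighting
but all carry an emission model calibrated near realistic array noise, the
way shipping callers do:

| profile | lrr_sd | baf_sd | stay_prob | baf_weight |
|---|---|---|---|---|
| penn-like | 0.13 | 0.030 | 0.999 | 0.50 |
| quanti-like | 0.14 | 0.032 | 0.995 | 0.45 |
| partition-like | 0.16 | 0.035 | 0.99 | 0.40 |

Detectability under these profiles bounds what the fixed log₁₀ BF ≥ 30 QC
can keep: at the default noise (`noise_sd_lrr = 0.12`) the weakest profile
accrues roughly 2 log₁₀ units per probe for a CN3 segment, so duplications
need ~15–20 probes (~70–90 kb at 4.6 kb spacing) to clear the threshold with
a comfortable margin.  A deliberately mis-calibrated emission model (e.g.
assuming `lrr_sd = 0.22` on 0.12-noise data) halves the per-probe evidence
and pushes genuinely detectable ~14-probe events under the threshold — the
profiles were therefore specified near the realistic noise level.

## Sample QC

A sample fails when (i) its probe call rate is below 0.98, (ii) the sex
called from intensities contradicts the recorded sex, or (iii) its CNV count
exceeds the cohort mean by more than 2 population standard deviations.
Boundary semantics mirror the strict-inequality phrasing of the rules: call
rate exactly 0.98 passes, a count exactly at mean + 2·SD passes.  The count
is the mean per-caller raw call count; with fewer than two samples the
outlier rule is skipped with a warning.  Sex is called male when the mean X
LRR is below −0.25 (hemizygous X sits near −0.6, diploid X near 0).  Note a
quirk of the mean + 2·SD rule: for a cohort of identical counts plus one
outlier of value x, the cutoff equals x exactly, so single extreme outliers
are kept under the strict `>`; the rule only bites when the cohort has
spread, which real burden distributions do.

## Filter cascade

* **Call QC** removes calls with log₁₀ BF < 30 or ≤ 3 supporting probes
  (confidence exactly 30 and 4 probes are kept).
* **Control overlap**: a case call is removed iff more than one *distinct*
  control sample (threshold configurable; the stricter ≥ 1 reading is a
  knob) has a call of the same type — and, by default, from the same caller
  — that matches it EXACTLY or fully contains it.  Partial overlap never
  excludes.  A pooled-across-callers mode is available.  Implemented over an
  interval tree; equivalent by test to the O(cases × controls) scan.
* **Consensus** requires the same (sample, chromosome, type) event from all
  three callers with a non-empty triple intersection; matching is greedy
  left-to-right with each source call joining at most one event.  The
  consensus interval is the triple intersection (the most conservative span
  supported by all three programs); the union is kept as provenance, and
  confidence/probe support are the minima over sources.  An optional
  reciprocal-overlap fraction (default off: any non-empty intersection
  qualifies) is provided.
* **Size filter** keeps length ≥ 50,000 bp, measured on the consensus
  interval (49,999 is removed).
* **Frequency filter** removes a CNV iff a catalogue record of compatible
  type (DEL/DUP/BOTH) matches it EXACTLY or fully contains it — the same
  strict-containment semantics as the control filter.  Records lying inside
  the CNV never exclude, and records are never merged.

The gene-content annotation step precedes the size filter in the canonical
stage order; since both are pure subset filters they commute and the final
candidate set does not depend on that placement.

## Annotation and prioritization

Genes overlap a CNV as `full` (gene body contained), `partial` (any other
non-empty gene-body overlap) or `promoter_only` (no body overlap but the
promoter window does).  The promoter is the 2,000 bp upstream of the TSS on
the gene's strand (configurable); promoter-only hits satisfy the
gene-content filter but are counted separately from gene-body biotype
counts.  Evidence weights default to: embryonic lower-urinary-tract
expression +2, embryonic kidney expression +1, urorectal phenotype report
+1, prior disease association +1; a gene's score is the sum of its flags and
a CNV scores the maximum over its genes.  Ranking is stable descending by
(score, length), ties broken by genomic position.  Evidence rows naming
symbols absent from the annotation are ignored with a logged warning.

## Synthetic cohort

The default study conditions (fixed once; all are `SimulationConfig` knobs):

* 40 cases and 200 controls over two autosomes plus X — 2,000 probes with a
  jittered-grid spacing of ~4.59 kb, a desk-scale stand-in for a
  ~640k-marker genome-wide array;
* `noise_sd_lrr = 0.12`, `baf_sd = 0.03`, `missing_rate = 0.01` — a clean
  modern array run;
* three ultra-rare CN3 case events at ~850 kb, ~130 kb and ~95 kb — the
  length scale of validated disease candidates, all ≥ 20 probes so every
  caller profile's Bayes factor separates them;
* five common polymorphism loci, each carried by 60/200 controls and 12/40
  cases at identical coordinates; two are short enough (< ~40 kb) to die at
  call QC and three long enough (60–90 kb) to survive it and exercise the
  control-overlap filter.

Design choices worth knowing:

* **Burden-balanced carrier assignment.** Polymorphism carriers are drawn
  least-loaded-first (random tie-break), keeping per-sample CNV counts in
  {1, 2}.  At desk scale, counts are so quantized that random assignment
  would make the mean + 2·SD count QC remove true carriers; balanced
  assignment emulates the tight per-sample burden of real cohorts, where the
  rule only flags genuinely aberrant samples.
* **Ultra-rare events avoid polymorphic loci** (they are placed after the
  polymorphisms and never overlap them) — an ultra-rare variant is by
  definition not a common polymorphism — and events within one sample never
  overlap.
* **Frequency-catalogue records are padded** ±15 kb around each polymorphism
  locus: real catalogues aggregate a locus from many studies with
  heterogeneous boundaries, so entries are wider than any one called
  segment.  This also makes the catalogue robust to single-probe boundary
  extensions of called segments, a real fragility of strict-containment
  filtering (all callers see the same noisy boundary probe, so a one-probe
  extension escapes both the control EXACT/within match and an unpadded
  record).
* Males (alternating recorded sex) draw the whole X at CN1; only the sex QC
  consumes this.
* Gene annotation: two genes inside every ultra-rare event plus background
  genes tiled at ~150 kb with deserts; evidence flags are attached to genes
  inside planted events (urinary tract or kidney expression) plus a sparse
  random background.
* Determinism: every generator draws from its own `numpy` stream derived
  from `(stream_id, seed)`, so identical seed + config is bit-identical, and
  adding one product does not perturb another.

A caller-emulation mode (`emulate_caller_variation`) can jitter call
boundaries by up to `caller_jitter_probes` probes and inject short false
positives at `caller_fp_rate` per sample, to mimic disagreement between
distinct programs; it is off everywhere except where a test exercises it.

**What the simulator does not emulate** — and hence what passing tests do
not show about real data: GC-content waves and batch effects in LRR,
population allele-frequency structure and LD (all SNPs are simulated at
allele frequency ½), mosaicism, genome-scale human coordinates and
segmental-duplication artifacts, parental genotypes (the de-novo/inherited
distinction is a label only), and real caller implementation differences
beyond parameter profiles.

## Worked-example fixture

The packaged fixture reproduces the three validated microduplications at
synthetic coordinates chosen so the 1-based inclusive lengths are exactly
852,734, 131,276 and 65,758 bp, with their gene content and biotypes:
dup5q23.2 with four non-coding RNAs and four coding genes, dup10q23.31 with
the miRNA MIR107 (placed inside PANK1, as in the genome) and two coding
genes, dup1p36.21 with one antisense RNA and four coding genes.  The
combined "MGC32805/PPIC" token is stored as a single non-coding entry,
following the per-region grouping of the validated findings (PPIC alone is a
coding gene; the fixture keeps the published grouping rather than resolving
it).  Evidence flags encode the reported embryonic expression (Fblim1 in the
urethra at E15.5; Sncaip and Slc16a12 in the kidney; Mir107 in the
metanephros), which makes dup1p36.21 the top-ranked candidate.

## Problem sizes and limitations

The bundled tests and the acceptance script run the full screen at the
default 240-sample, 2,000-probe scale (seconds to a couple of minutes on one
CPU) and verify the filters against brute-force oracles on hundreds of random
instances; Viterbi is checked against exhaustive path enumeration on short
chromosomes.  Known limitations: distance-independent transitions (no
probe-gap modelling), no GC correction, no population-BAF modelling, single
fixed allele frequency, no trio/inheritance analysis, and the strict
containment semantics of the overlap filters are deliberately faithful to
their textual definition — partial overlaps never exclude, which can let
boundary-jittered common variation through when the frequency catalogue has
tight boundaries.
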