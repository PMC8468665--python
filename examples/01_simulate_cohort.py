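"""Generate a synthetic case-control SNP-array cohort.

Builds the desk-scale probe grid, plants copy-number truth (ultra-rare case
duplications plus common polymorphisms shared with controls) and simulates
per-probe LRR/BAF tracks.  Everything is reproducible from one seed.
"""

from collections import Counter

import cnvscreen as cs

cfg = cs.SimulationConfig(seed=7)
layout = cs.make_genome(cfg)
truth = cs.plant_truth(layout, cfg)
samples = cs.simulate_intensities(layout, truth, cfg)

print(f"genome: {len(layout.chrom_names)} chromosomes, {layout.n_probes} probes")
print(f"median probe spacing: {layout.median_spacing():.0f} bp "
      "(mimics a genome-wide screening array)")
print(f"samples: {cfg.n_cases} cases + {cfg.n_controls} controls")

by_kind = Counter((t.label, t.cohort) for t in truth)
print("planted truth events:")
for (label, cohort), n in sorted(by_kind.items()):
    print(f"  {label:22s} in {cohort:8s}: {n}")

rare = [t for t in truth if t.label == "ultra_rare"]
print("ultra-rare case duplications (the events the screen must recover):")
for t in rare:
    print(f"  {t.sample_id}  {t.chrom}:{t.start:,}-{t.end:,}  CN={t.copy_number}  "
          f"{t.length:,} bp")
print(f"first sample call rate: {samples[0].call_rate():.4f} "
      "(fraction of probes with a measurement; QC requires >= 0.98)")
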