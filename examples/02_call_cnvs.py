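"""Segment one sample's LRR/BAF tracks with the three emulated HMM callers.

Each caller is the same 5-state copy-number HMM under a different parameter
profile (segmentation stiffness, assumed noise, BAF weight), standing in for
running three distinct calling programs over one intensity export.
"""

import cnvscreen as cs

cfg = cs.SimulationConfig(seed=7)
layout = cs.make_genome(cfg)
truth = cs.plant_truth(layout, cfg)
samples = cs.simulate_intensities(layout, truth, cfg)

carrier = next(t.sample_id for t in truth if t.label == "ultra_rare")
sample = next(s for s in samples if s.sample_id == carrier)
planted = [t for t in truth if t.sample_id == carrier]
print(f"sample {carrier} carries:")
for t in planted:
    print(f"  truth {t.label}: {t.chrom}:{t.start:,}-{t.end:,} CN={t.copy_number}")

for caller_id, params in cs.default_profiles().items():
    calls = cs.viterbi_segment(sample, layout, params)
    print(f"\n{caller_id} (stay_prob={params.stay_prob}, lrr_sd={params.lrr_sd}):")
    for c in calls:
        print(f"  {c.type} {c.chrom}:{c.start:,}-{c.end:,}  {c.n_probes} probes  "
              f"log10 Bayes factor {c.confidence:.1f}")
print("\nconfidence is the log10 likelihood ratio of the called state vs diploid;")
print("the call QC later removes calls with confidence < 30 or <= 3 probes.")
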