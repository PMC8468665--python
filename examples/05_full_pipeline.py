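"""One-call reproducible run of the whole screen.

simulate -> three-caller HMM calling -> sample QC -> call QC ->
control-overlap exclusion -> consensus -> gene annotation -> size filter ->
frequency filter -> prioritization.  All intermediates, filter traces and a
JSON report land in the working directory.
"""

import cnvscreen as cs

cfg = cs.PipelineConfig(seed=11, write_intensities=False)
report = cs.run(cfg, "scratch/example_run")

print("stage counts (inputs -> outputs):")
for s in report["stage_counts"]:
    print(f"  {s['stage']:17s} {s['n_in']:5d} -> {s['n_out']:5d}  ({s['unit']})")

qc = report["sample_qc"]
print(f"\nsample QC: {qc['n_failed']} of {qc['n_samples']} samples failed")
print(f"final candidates: {len(report['candidates'])}")
for c in report["candidates"]:
    print(f"  #{c['rank']}  {c['sample_id']}  {c['type']} {c['region']}  "
          f"{c['length']:,} bp  score {c['priority_score']}")
print("\nwith the default study conditions these are exactly the three planted")
print("ultra-rare duplications; every common polymorphism was filtered out.")
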