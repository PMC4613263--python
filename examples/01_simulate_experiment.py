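"""Generate a synthetic three-stage 2DE experiment and inspect its truth.

Builds 18 spot tables (stages P7, P90, P637 x 6 replicate gels) with 20%
of proteins truly regulated per stage, writes them to ./scratch/example/,
and prints the ground-truth regulation counts the later examples try to
recover.
"""

from collections import Counter

from spotdiff import synthdata

config = synthdata.SyntheticConfig(n_proteins=100, seed=1)
gels, truths = synthdata.generate_experiment(config)
synthdata.write_experiment(gels, truths, "scratch/example")

print(f"wrote {len(gels)} spot tables "
      f"({len(gels[0].spots)} spots on the first P7 gel)")
for stage in ("P7", "P637"):
    counts = Counter(t.true_direction for t in truths if t.stage == stage)
    print(f"truth {stage} vs P90: {dict(counts)}")
# 'up'/'down' are true fold changes outside the unchanged band [0.6, 1.67];
# 'absent_in_stage' proteins have volume 0 on every gel of that stage.
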