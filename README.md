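# spotdiff

Differential two-dimensional gel electrophoresis (2DE) analysis with
peptide-mass-fingerprint (PMF) identification.

## The problem

Classical expression proteomics separates a tissue lysate on 2DE gels —
proteins spread by isoelectric point (pI 3–10) and molecular weight
(roughly 10–100 kDa) — and asks which spots change abundance between
conditions. The workflow this package implements is the one used in
ontogenetic studies of the rat cerebellum: three postnatal stages (P7
juvenile, P90 adult baseline, P637 aged), six replicate gels per stage,
spot volumes compared stage-against-baseline, and each interesting spot
identified by MALDI-TOF peptide mass fingerprinting. The original raw gels
of such studies are rarely deposited, so `spotdiff` ships a first-class
synthetic-data generator that emulates the full experimental design with
known ground truth, making every stage of the pipeline testable offline.

It is a library for Python users (see `examples/`), with a thin `spotdiff`
CLI (`simulate`, `analyze`, `pmf-search`, `report`) for shell use.

## The statistics

**Spot volume quotient (SVQ).** After normalizing each gel to
parts-per-million of its total spot volume, a matched spot's quotient at a
compared stage is

    SVQ = mean(V_baseline) / mean(V_stage)

A spot is *up*-regulated at the compared stage when SVQ ≤ 0.6 and
*down*-regulated when SVQ ≥ 1.67 (inclusive cut-offs; the low quotient
means the baseline numerator is small).

**Multi condition coverage method.** Instead of gating on a test statistic,
a spot is accepted as regulated only if additionally its per-gel quotients
`mean(V_baseline)/v_i` pass the same cut-off, on the consensus side, in at
least 4 of the 6 stage gels (the **H** count). An exact two-sided
Mann–Whitney U-test (complete enumeration of all C(n+m, n) assignments for
combined samples ≤ 14) is computed and reported *in addition*, not as a
gate, and no multiple-testing correction is applied. Spots undetected in
every gel of one stage but present in ≥ 4 gels of the other are reported
*absent* rather than quantified; multi-spot proteins aggregate by the
arithmetic mean of member SVQs with a conflict flag.

**PMF scoring.** Each database protein is digested in silico (trypsin,
cleavage after K/R not before P, ≤ 1 missed cleavage, fixed
carbamidomethyl-C +57.021464 Da, variable oxidation-M +15.994915 Da) and
observed masses are matched within 60 ppm. The MOWSE-style score is
−10·log₁₀ P where P is the binomial upper-tail probability of the observed
number of matches given the protein's chance-match probability, and a hit
is significant when the score exceeds

    floor(−10·log10(alpha / N_sequences))

which is **59** for alpha = 0.05 against a 42,755-sequence rat database.

## Worked example

```python
from spotdiff import report, synthdata

gels, truths = synthdata.generate_experiment(
    synthdata.SyntheticConfig(n_proteins=100, seed=1))
comparisons, proteins = report.analyze_experiment(gels)
annotated = report.assign_groups(proteins, {})
print(report.overall_summary(annotated))
```

prints

```
                 P637  P7
Total              19  22
Up-regulated        8  12
Down-regulated      7   8
Absent              4   2
Absent-baseline     0   0
```

against a simulated truth of 21 regulated proteins at P7 and 18 at P637:
the coverage method recovers nearly all true changes with very few false
calls. Each regulated spot row carries its SVQ (`Control/PD` column), H
count and exact Mann–Whitney p-value (0.002165 = 2/924 is the smallest
achievable two-sided value for 6 vs 6). See `examples/` for the
simulation, differential, PMF and reporting walk-throughs.

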