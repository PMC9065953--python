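# invertype

Ecotype assignment for low-coverage ancient fish DNA from chromosomal
inversion genotypes, with deamination-based authenticity screening and
marine radiocarbon calibration.

## The problem

Atlantic cod along the Norwegian coast comprises two ecotypes that are
morphologically indistinguishable in archaeological bone: the migratory
Northeast Arctic cod (*skrei*, NEAC), which feeds in the Barents Sea and
migrates to coastal spawning grounds, and stationary coastal cod. The two
are, however, strongly differentiated at four large chromosomal inversions
(LG1, LG2, LG7, LG12), so even the sparse, damaged sequence data typical of
archaeological specimens can identify the ecotype. This package implements
the full desk-side analysis chain for such material:

1. **damage** — estimate terminal C→T / G→A deamination profiles from
   per-site read observations, fit the exponential decay
   r(k) = d₀·exp(−λk), and flag specimens consistent with authentic
   ancient DNA;
2. **genotype** — call each inversion AA/AB/BB from low-coverage pileup
   observations at inversion-diagnostic SNPs, using a per-base error
   likelihood P(obs|allele) = 1−e or e/3 and a uniform prior over the three
   states, with configurable handling of deamination-ambiguous reads;
3. **assign** — compute the posterior probability of each candidate
   population from the inversion genotypes via Hardy–Weinberg genotype
   probabilities, P(AA)=(1−f)², P(AB)=2f(1−f), P(BB)=f², treating
   inversions as independent loci (naive Bayes);
4. **calibrate** — calibrate marine radiocarbon dates against a `.14c`
   calibration curve with an ecotype-specific reservoir offset ΔR ± σ_ΔR
   (migratory −144 ± 46, stationary −164 ± 29 ¹⁴C yr), reporting highest
   posterior density (HPD) ranges;
5. **synth** — a first-class generator of synthetic panels, cohorts, read
   observations (with deamination, sequencing error, lognormal fragment
   lengths, Poisson coverage) and radiocarbon measurements, so the whole
   chain is testable end to end without any external data.

Inputs are plain TSV tables at the pileup level of abstraction (see
`invertype/io.py` for schemas); producing them from BAMs is a few lines of
pysam, documented in the same module. Candidate populations and their
inversion frequencies are data (a TSV), not code — the bundled tables are
synthetic/illustrative and real analyses must supply modern reference
frequencies.

## Worked example

Simulate a five-specimen cohort and run every stage:

```sh
invertype simulate --out demo/sim --seed 42 --n-specimens 5 \
    --sites-per-inversion 100 --coverage 8.0
invertype run-all \
    --panel demo/sim/panel.tsv --freqs demo/sim/frequencies.tsv \
    --obs demo/sim/observations.tsv --dates demo/sim/dates.tsv \
    --curve demo/sim/curve.14c --out demo/out
```

The report (also written to `demo/out/report.json`) starts:

```
specimen SIM0000
  damage: d0=0.287 lambda=0.236 [authentic-like]
  LG1: AA (AA=1.000 AB=0.000 BB=0.000; 100 sites, 794 reads)
  LG2: BB (AA=0.000 AB=0.000 BB=1.000; 100 sites, 753 reads)
  LG7: BB (AA=0.000 AB=0.000 BB=1.000; 100 sites, 796 reads)
  LG12: AA (AA=1.000 AB=0.000 BB=0.000; 100 sites, 765 reads)
  assignment: Lofoten_Coastal (NEAC=0.0000 Lofoten_Coastal=1.0000 West_Coastal=0.0000)
  cal 68.3%: 3468-3619, 3714-3827 cal BP
  cal 95.4%: 3429-3843 cal BP
```

Reading: the specimen's reads show a 29% terminal C→T rate decaying along
the read — the damage signature of genuinely old DNA; its four inversion
genotypes are called with essentially no uncertainty; under the cohort's
frequency table those genotypes have probability ~1 under the Lofoten
coastal population; and its radiocarbon date calibrates to 3429–3843 cal BP
at 95.4% (the split 68.3% range reflects a wiggle in the synthetic
calibration curve). The simulated truth for this specimen was
Lofoten_Coastal at 3552 cal BP — both recovered.

Each stage is also available separately (`invertype damage|genotype|assign|
calibrate`) and as plain Python functions (`invertype.profile_damage`,
`genotype_all`, `assign_ecotype`, `calibrate_date`, ...).

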