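# Methods

## Read-level generative model (synth)

Each specimen belongs to a population with haplotype-B frequency f per
inversion. Its genotype per inversion is a Hardy–Weinberg draw — the count
of B haplotypes is Binomial(2, f). Reads are generated per panel site:

* read count ~ Poisson(coverage_mean), default 0.5 per site — the
  low-coverage regime the genotype caller is designed for;
* each read carries one of the specimen's two chromosomes uniformly;
* fragment length ~ round(Lognormal(meanlog=4.0, sdlog=0.35)), mean
  ≈ 58 bp, a typical ancient-DNA extract; the site sits at a uniform
  position in the fragment, so dist5 + dist3 = read_len − 1;
* cytosine deamination is applied first (biochemical order): a true C
  becomes T with probability d₀·exp(−λ_d·dist5), a true G becomes A with
  d₀·exp(−λ_d·dist3). Defaults d₀ = 0.25, λ_d = 0.3 resemble
  well-preserved but clearly ancient material;
* uniform sequencing error e (default 0.01) then replaces the base with
  each of the other three with probability e/3.

Radiocarbon measurements are drawn as
m ~ Normal(μ_curve(t) + ΔR, √(σ_meas² + σ_curve²(t))). σ_ΔR is carried on
the record but not added to the generative noise; it enters the
calibration variance, mirroring how reservoir uncertainty is treated as a
calibration-model term rather than a property of the laboratory
measurement.

A single global seed drives everything; per-specimen substreams are
spawned from the specimen index, so cohorts are byte-reproducible and a
cohort prefix is unchanged by extending the cohort.

What the generator does **not** emulate: contamination from modern or
non-target DNA, reference bias, mapping and duplicate artefacts, base
qualities, indels, linkage between inversions, and within-inversion site
correlation. Passing parameter-recovery tests therefore demonstrates the
estimators are correct under their stated model, not that real
archaeological libraries meet that model.

## Damage profiling

The C→T rate at distance k from the 5' end is estimated at *C-context*
sites only: sites where C is a panel allele and T is not. At a C/T site an
observed T is ambiguous between the T allele and deaminated C, so such
sites are excluded from rate estimation altogether. Within C-context
sites, the denominator at distance k is the number of reads showing C or
T; reads carrying the other (non-C) allele are uninformative about
cytosine deamination and would dilute the rate by the allele frequency if
counted. Under this estimator rate5(0) → d₀(1−e) + e/3 ≈ d₀, which is what
the recovery tests check. The G→A series at the 3' end is the mirror
image.

The decay fit minimises Σ_k w_k (d₀e^{−λk} − r_k)² with w_k the
denominators, d₀ ∈ [0,1], λ ≥ 0 (trust-region least squares; log-linear
initialisation from the positive rates; an all-zero series short-circuits
to d₀ = 0). The sequencing-error floor (≈ e/3) is not subtracted, which
biases λ̂ slightly downward at large k; at the default parameters the bias
is well inside the ±0.1 recovery tolerance. No uncertainty is attached to
the fitted parameters.

A specimen is flagged "authentic-like" when d₀̂ ≥ 0.05 (inclusive) and
λ̂ > 0. The 0.05 floor is a screening default, not a published threshold:
fresh DNA shows essentially zero terminal C→T, while genuinely ancient
material is typically well above 10%. The flag is a heuristic; it cannot
prove antiquity.

Caveat on problem size: profiles here are computed from panel-site
observations only. At 0.5–1× coverage over a few hundred sites that is a
few hundred reads — far too few for a stable per-specimen fit (real
workflows profile damage genome-wide). Per-specimen damage estimates in
small demos are therefore noisy; the recovery tests use ~2×10⁵
observations, where the estimator's properties are the point.

## Inversion genotype calling

An inversion is a single biallelic super-locus. Per read,
P(obs | allele x) = 1 − e if the base matches x, else e/3; under AB each
chromosome is sampled with probability ½, so P(obs | AB) =
½P(obs|A) + ½P(obs|B). Site log-likelihood triples are summed over panel
sites (equivalently over all reads), normalised under a uniform prior into
a posterior over {AA, AB, BB}. A hard call requires posterior ≥ 0.95
(default) and ≥ 5 sites with data; otherwise "no-call".

Sites are treated as independent. Inside a non-recombining inversion this
overstates the effective number of observations, so posteriors are
anti-conservative as statements of confidence; the ranking of states — and
hence the hard calls the assignment stage consumes — is unaffected.
Per-read base qualities are not modelled; e is a single fixed error rate
(default 0.01, roughly Q20 post-filtering).

Deamination handling, `damage_mode`:

* `ignore` — use everything;
* `filter` (default, window k_d = 5) — drop reads whose base could be the
  other allele deaminated: an observed T at a C/T site with dist5 < k_d,
  an observed A at a G/A site with dist3 < k_d. Conservative: discards a
  small fraction of coverage, removes the bias toward T/A-carrying
  haplotypes on damaged material;
* `model` — no discarding; the emission becomes a deamination mixture,
  P(obs | C-allele) = (1−d)·P_err(obs|C) + d·P_err(obs|T) with
  d = d₀̂·exp(−λ̂·dist5) from the specimen's fitted damage parameters
  (mirrored for G/3'). This matches the generative model exactly but
  depends on a decent damage fit, hence is not the default.

## Population assignment

With modern haplotype-B frequencies f per (population, inversion), the
probability of a genotype under a population is its Hardy–Weinberg
probability. Populations are scored by the product over called inversions
(no-call inversions are skipped), times a prior (uniform by default),
normalised in log space — a naive-Bayes classifier over up to four loci.
`soft` mode marginalises the genotype-calling posterior instead of
plugging in the hard call and reduces to `hard` exactly when the calling
posteriors are degenerate.

Per-inversion probabilities are floored at 1e-9 (configurable) before the
log. Without the floor a population with f ∈ {0, 1} would be assigned
probability zero after a single discordant call, though single discordant
calls are exactly what sequencing error and residual damage produce.

A specimen is labelled with the top population when its posterior reaches
0.95 (default), else "unassigned". Candidate populations are whatever the
frequency table lists. Two tables ship with the package, both synthetic:
`strong_differentiation_frequencies()` — the documented recovery scenario,
three populations with near-fixed (0.98 vs 0.02) contrasts at ≥2 of the 4
loci per population pair (with four loci and three populations at least
one pair can differ at only two; near-fixation there keeps the expected
misassignment of that pair at the percent level) — and
`illustrative_frequencies()`, shaped like published ecotype contrasts for
demos. Neither is a measured dataset; real analyses must supply real
modern frequencies. Treating inversions as independent between loci
ignores any between-inversion linkage in the reference populations.

The "binomial probability" framing of ecotype identification is
implemented in its Hardy–Weinberg genotype form; an alternative reading —
binomial counts of B haplotypes per locus — differs only by the 2f(1−f)
vs C(2,1)f(1−f) bookkeeping and yields identical posteriors here.

## Radiocarbon calibration

For a marine determination m ± σ_m with reservoir offset ΔR ± σ_ΔR, the
expected measurement at calendar age t is μ_curve(t) + ΔR (the standard
marine-reservoir convention: ΔR shifts the marine curve mean additively),
with variance σ_m² + σ_ΔR² + σ_curve²(t) pooled in quadrature. The
posterior over a 1-year calendar grid spanning the curve, under a uniform
prior, is the normalised Gaussian likelihood including the 1/σ_tot(t)
factor. Curve mean and σ are interpolated linearly between grid points of
any `.14c`-layout file (comment lines `#`, comma- or whitespace-separated,
≥3 numeric columns, either ordering).

Consequence of the sign convention: a less negative ΔR (migratory,
−144) implies a smaller local reservoir correction, so the same ¹⁴C age
calibrates ~20 years *younger* than under the stationary offset (−164).

HPD sets are built greedily: grid years are ranked by posterior mass (ties
broken toward older years for determinism) and accumulated until the
requested coverage (defaults 0.683 and 0.954) is reached; contiguous runs
are merged and the attained coverage reported. On a discrete grid attained
coverage slightly exceeds the nominal level. No OxCal-style rounding is
applied by default; `--round 10` rounds reported endpoints for
presentation only. Sequence/phase modelling, diet-mixing corrections and
exact reproduction of OxCal's internal gridding are out of scope — the
algorithmic family matches, small numeric differences are expected.

## Problem sizes in the verification suite

The repeated-simulation checks use: 500 specimens × 400 sites at 0.5×
coverage for assignment recovery; ~2×10⁵ observations for damage-parameter
recovery; 1000 simulated dates on a synthetic wiggly curve (unit slope +
150-yr amplitude, 800-yr period sinusoid, σ_curve = 12) for HPD coverage;
instances up to 10 sites × 10 reads for the brute-force likelihood oracle
and the full 3⁴ genotype-configuration enumeration for the soft-assignment
oracle. These sizes give Monte-Carlo standard errors comfortably inside
the asserted tolerances.

## Known limitations

* Posterior calibration of genotype calls is optimistic (site
  independence); assignment posteriors inherit this through the hard
  calls.
* Damage profiling needs far more observations than a sparse panel
  provides at low coverage; per-specimen fits on small inputs are noisy.
* The assignment model has no admixture/hybrid class: a first-generation
  migratory × coastal cross will be forced into whichever pure class is
  closer or left unassigned.
* Calibration assumes a single marine reservoir; mixed marine–terrestrial
  diets are not modelled.
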