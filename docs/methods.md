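# Methods

## The site model

A CCGG/GGCC restriction site carries four cytosines: external (the
5'-most C of each strand) and internal. The model admits six methylation
configurations — unmethylated (U), hemimethylated external (HE), fully
methylated external (FE), hemimethylated internal (HI), fully methylated
internal (FI) and fully methylated (FM). Configurations mixing partial
external and internal methylation are excluded: they have not been
described for this site, and the enzymes' behaviour on them is unknown.
The admissible set lives in one constant (`site_model.STATE_ORDER` /
`ADMISSIBLE_PATTERNS`) so new enzyme-activity evidence can extend it.
Hemimethylated states do not record which strand carries the mark; the
two mirror configurations of HE (and of HI) are one equivalence class.

Digestion follows the documented enzyme sensitivities: *Hpa*II requires
no internal methylation and at most one methylated external cytosine
(U → cut, HE → cut, everything else uncut); *Msp*I requires unmethylated
external cytosines (U, HI, FI → cut). This yields the four digest
profiles and their preimages: (1,1) ← {U}, (1,0) ← {HE}, (0,1) ← {HI, FI},
(0,0) ← {FE, FM}.

A four-bit code (control-HpaII, control-MspI, stressed-HpaII,
stressed-MspI) is explained by every pair in preimage(control bits) ×
preimage(stressed bits); there are 36 explanations over the 16 codes.
Each explanation decomposes into exactly four per-cytosine events
(DM, DNM, MSP, NMSP), with external-position changes scored as CHG
context and internal-position changes as CG context. Under the
equal-probability assumption, a code's weight for an event is the **raw
sum** of that event's count over its explanations — not the average.
Raw sums are the convention that makes the per-sample denominator
Σ 4·n_explanations(code)·count(code) an event count, and every
characteristic a fraction of it.

Sequence mutations inside the restriction site, partial digestion,
co-migrating fragments and band-intensity information are outside the
model by design: the input is strictly binary presence/absence.

## Quantification and reporting

Event totals are integer matrix products of code counts with the weight
table; the identities M = DNM + MSP, NM = DM + NMSP, DM = DM-CG + DM-CHG
and DNM = DNM-CG + DNM-CHG hold exactly, and DM% + DNM% + MSP% + NMSP% =
100 before any rounding. Characteristics are kept at full precision
internally; report tables round half-away-from-zero to two decimals
(`round_half_up`), and all downstream computation — group means, n−1
standard deviations, clustering distances — uses the unrounded values.
Averaging pre-rounded percentages gives visibly different summary values,
which is why the rounding boundary sits at the report layer only.

The denominator is per-sample, so lines with different scoreable marker
yields remain comparable, and multiplying one sample's counts by any
positive integer leaves its characteristics unchanged (scale
equivariance, asserted in the tests).

Markers absent from all four tracks (code 0000) are scored by default
(`include_0000=True`); they are only identifiable with replicated
stressed samples, so the flag allows excluding them without touching the
rest of the pipeline.

**Baseline bias.** Codes whose explanation sets contain change events
(0101, 0000, …) contribute DM and DNM weight even when nothing changed:
a sample of markers drawn only from internally methylated sites has
DM% > 0 and DNM% > 0 under zero true change. This is an intrinsic
property of the equal-probability weighting, not a bug; the tests
document it, and the simulator's recovery guarantee is therefore a
monotone association with the true rates, not unbiasedness.

## Missing data

The input format requires explicit `NA` tokens; a marker with a missing
call in any of the four tracks is excluded for that sample, and the
number of dropped calls is logged to standard error. Nothing is imputed.

## Clustering and ANOVA

Clustering is Ward's method on squared Euclidean distances over the ten
characteristics (scipy's nearest-neighbour-chain implementation of the
Lance–Williams update). Merge heights are reported as raw Ward criterion
increments — the growth of total within-cluster sum of squares — which
for scipy's euclidean-scale heights h is h²/2; an exhaustive-search Ward
oracle in the test suite confirms the conversion. The automatic
truncation cuts the tree in the largest gap between successive merge
heights (ties at the earliest merge, minimum two clusters). Newick
export assigns each branch the difference between its child and parent
merge heights, so root-to-tip depth equals the final merge height.

ANOVA is plain one-way fixed-effects, reported with F, degrees of
freedom, p and variance explained (η² = SS_between/SS_total). It is
checked against a brute-force sum-of-squares oracle rather than any
published F value: stepwise model-selection ANOVAs over heterogeneous
characteristic sets are not reconstructible from their printed statistics
and are deliberately not reproduced.

## The simulator

`synthetic.simulate` emulates a paired control/stress MSAP experiment:
per marker and sample a control state is drawn from a configurable
distribution over the six states, then each cytosine flips independently
(methylated → unmethylated with the context's demethylation rate,
unmethylated → methylated with the context's de novo rate). A proposal
leaving the admissible space is redrawn for that site (rejection
sampling), and the rejection rate is recorded. Admissibility is judged
up to the strand-symmetry equivalence the state set declares: the mirror
of a hemimethylated pattern is canonicalised, not rejected, because
rejecting it would halve single-strand change rates for no modelling
reason. Realised events are recorded from the actual per-position
transitions (context depends only on external/internal position, so they
are mirror-invariant) before canonicalisation.

Defaults describe a realistic cereal experiment: 880 markers × 10
samples (the order of scoreable fragments per line in the packaged
dataset), a uniform control-state distribution (no empirical state
frequencies are established; the distribution is fully exposed in
`SimulationConfig`), and change rates p_dm_cg = 0.05, p_dm_chg = 0.015,
p_dnm_cg = 0.015, p_dnm_chg = 0.005 — demethylation exceeding de novo
methylation, and CG change roughly three times the CHG rate, matching
the orderings observed in Al-stressed cereals. The simulator produces
ideal binary tracks implied by the digestion model; it does not emulate
AFLP primer sampling, fragment-length distributions, scoring errors or
gel artifacts, so passing recovery tests says nothing about those error
sources in real data.

The recovery experiments in the test and acceptance suites use 5000
markers and five seeds per rate setting over the grid
p_dm_cg ∈ {0.01, 0.05, 0.10}; with one sample per run this keeps a full
grid under a few seconds while giving Monte-Carlo error well below the
effect being measured.

## Numerical and degenerate-input choices

* Percentages divide integer totals; a sample with denominator 0 (no
  scoreable markers) is an explicit error in `characteristics` and a
  logged warning in `event_totals`.
* `round_half_up` goes through `decimal` on the shortest float repr, so
  printed ties like 69.375 round up rather than to even.
* Singleton groups get a mean and an undefined (NaN) SD with a warning.
* Clustering requires ≥ 2 samples; identical samples merge at height 0.
* Explanation lists and serialised tables use the fixed state order
  U, HE, FE, HI, FI, FM and the binary code order 0000…1111, making every
  output byte-reproducible apart from timestamps in provenance headers.

## Known limitations

The equal-probability assumption over a code's explanations is a working
hypothesis, not an estimate; whole-genome bisulfite data restricted to
CCGG sites would calibrate per-state probabilities, and the weight table
is the single place such factors would enter. The six-state restriction
and the binary-band idealisation are shared with the scored data itself.
Characteristics are aggregate per sample: the method deliberately makes
no locus-wise methylation calls.
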