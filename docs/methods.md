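# Methods

This note documents the models, conventions and numerical choices behind
each stage of the pipeline, the design decisions taken where more than one
convention exists in the field, and what the synthetic-data generator does
and does not emulate.

## Input model and allele pairing

A marker dataset is a gapped FASTA alignment in which each record is one
phased allele of a diploid individual, labelled
`<locality>_<sex:F|M>_<sample>_<tag:a|b|ab>`. The `ab` tag marks a
homozygote: one record stands for both copies (and counts twice wherever
copy multiplicity matters — haplotype multiplicities, site counts).
Field datasets use many labelling dialects, so the loader accepts any regex
with named groups `locality`, `sex`, `sample`, `tag` plus a sex-code map.

An individual with exactly one `a` or `b` record is paired with a MISSING
second allele; such individuals are excluded from all pairwise-difference
analyses (an exclusion signal, never a zero). Males' two copies are
interpreted as {X, Y} *without assignment* — which copy sits on which
chromosome is not observable from one individual — females' as {X, X}.

Coordinates are 0-based half-open internally and 1-based in user-facing
reports.

### Variable and parsimony-informative sites

A column is variable when ≥2 distinct states are observed and
parsimony-informative when ≥2 states are each carried by ≥2 sequences. `N`
is missing for the sequence carrying it. The default gap policy excludes
every column containing a gap (the convention of the classic polymorphism
software this mirrors); `fifth_state` counting is available by flag.

## Step recoding

Parsimony networks count mutational steps, so characters must be scaled to
one mutation each:

- **Repeat tracts** (microsatellite-like) are recoded as one integer
  character: the copy number of the motif inside the annotated window, with
  gaps removed and only exact tandem copies counted (longest run; partial
  copies ignored — length comparisons against microsatellite genotyping
  imply integer copies). Distance contribution: |Δcopies|, the stepwise
  mutation model's step count.
- **Large indels** (≥10 bp by default) are one binary presence/absence
  character, scored per allele by gap fraction <0.5 inside the window;
  one step when states differ.
- **Everything else** forms the SNP vector, with the gap kept as a fifth
  character state, counted column-by-column (sub-threshold gaps are ordinary
  characters; this matches the "gap as fifth base" network option).
  `N` is missing: the column is skipped for a pair in which either allele
  carries it.

Annotated intervals are removed from the SNP vector; overlapping annotations
are rejected, as is recoding an already-recoded object. The resulting step
distance decomposes additively over characters and is a metric (property-
tested). Auto-detection of repeat tracts (≥3 exact tandem copies of a
primitive motif of 1–6 bp on the column-majority consensus) is provided as a
convenience; curated annotations are preferred when available, and the
repeat coordinates of real markers should be supplied by config rather than
guessed.

## Statistical-parsimony network

Identical recoded alleles collapse into haplotypes; ids `H_1, H_2, …` are
assigned by decreasing multiplicity with lexicographic tie-break, making the
labelling deterministic (ids are presentation labels, not an analysis
output).

**Connection limit.** Two haplotypes differing at *j* of *m* characters are
connected only if the probability that those *j* differences arose without
homoplasy (each differing site hit exactly once, no site hit twice) is at
least the confidence level (default 0.95). The probability is computed under
the classical pair-coalescent finite-sites model: coalescence time
t ~ Exp(1) (units of 2N generations), per-site changes Poisson(θt) with
two-state symmetric visibility (a site differs when hit an odd number of
times), and the per-site divergence parameter estimated from q̂ = j/m via
E[q] = θ/(1+2θ). The limit is the largest j whose conditional parsimony
probability clears the confidence; single-step connections are always
trusted (limit ≥ 1), and an explicit override is available. The numerator
has a closed form; the denominator is integrated numerically in log space
with a grid-located mode and a truncation point whose tail error is bounded
by e^(−T) (the integrand is dominated by e^(−t)). A Monte-Carlo simulation
of the same probability model cross-checks the integral in the tests. At
95% the limit grows from 2 at 100 characters to ~9 at 1000 — the order of
magnitude familiar from statistical-parsimony software, whose exact output
this package does not attempt to replicate byte-for-byte.

The limit is computed once per marker from the post-recoding character
count (SNP columns + repeat + indel characters); computing it on the raw
length instead is a caller's choice via the override.

**Construction.** Minimum-spanning network with tie retention: pairs are
processed by increasing step distance; at each distance level, every pair
whose endpoints are not connected through strictly smaller levels gains an
edge, so all equally parsimonious alternatives are kept (reticulations
survive). Pairs beyond the limit never connect, and disconnected
subnetworks emerge naturally. On small instances the construction is
verified against brute-force enumeration. Inference of unsampled
intermediate haplotypes is deliberately not performed: topology at the
resolution the analysis uses (allele mixing vs a separated male haplotype)
does not depend on it.

## Within-individual divergence (p_d)

p_d is computed on the raw nucleotide alignment (never on recoded steps) as
an integer count of differing sites between an individual's two alleles.
Two site policies are exposed because polymorphism software differs and
published means rarely state the choice:

- `pairwise` (default): skip sites gapped/`N` in either of the two alleles;
- `complete`: skip sites gapped/`N` in *any* allele of the marker.

Group summaries report n and mean per sex × region (or any subset), with an
optional region collapse (e.g. NW Europe vs refugia+Pannonian). A per-site
normalisation is deliberately absent by default: reported means in this
literature are counts, not π.

## Permutation ANOVA

The F statistic is kept as the test statistic but its null distribution is
built by permutation — p_d is discrete, bounded and skewed, so F-table
p-values are not trusted.

- **Sums of squares:** sequential (Type I) in the order sex → region →
  interaction, matching the default of the standard statistical environment;
  Type II is available by flag for unbalanced designs. Denominators always
  use the full-model residual mean square. Implementation: one QR
  factorisation of the blocked design matrix; a term's SS is the squared
  projection of the response onto its own Q columns. This makes the
  permutation loop a single matrix product over thousands of permuted
  responses.
- **Permutation scheme:** free shuffling of the response vector across all
  observations (Manly), regenerating the full F table per replicate;
  Freedman–Lane residual permutation is available by flag. 10,000
  replicates by default.
- **p-value:** (1 + #{F* ≥ F}) / (1 + n_perm), never exactly zero; an
  exhaustive enumeration over all n! orderings is provided for n ≤ 9 and
  agrees with the Monte-Carlo estimate within sampling error
  (property-tested), as is type-I calibration at α = 0.05 over hundreds of
  null datasets.
- Perfect separation (zero residual SS) yields F = ∞ with consistent
  comparisons; an SS below 10⁻¹² of the response's sum of squares is treated
  as zero. Empty cells in the two-way layout are an error naming the cell.

The study battery runs, per marker, a one-way sex test pooled over regions,
and for every marker with a full sex × two-level-region layout the two-way
test with the NW vs refugia+Pannonian dichotomy. The degrees of freedom
follow the per-marker sample sizes (e.g. 54 individuals → F₁,₅₂ one-way,
F₁,₅₀ two-way).

## The synthetic-data generator

Forward-in-time simulation of an XY system (not coalescent: the object of
interest is the X/Y inheritance mechanics, not neutral-theory expectations).
Daughters receive a recombinant of the mother's two X's and the father's X;
sons receive the maternal X and the father's Y. A male meiosis undergoes a
single uniform-point X–Y crossover with a per-deme probability, and the
transmitted copy is a random one of the two crossover products (the marker's
position relative to the sex-determining locus is left unspecified;
committing to one product would make one marker end permanently sex-linked).

**Demography.** One refugial deme (200 diploids) runs a 300-generation
burn-in from a single ancestral haplotype; a Pannonian deme (80) is founded
from it by 8 individuals; the NW deme (cap 40) is founded from the Pannonian
deme `t_split` generations before sampling and is *serially* bottlenecked —
re-founded by a single pair every 8 generations, with only the regrowth time
(doublings + 1 generations, doubling per generation) left before sampling.
The sampled NW deme stands for the expansion front: range-edge populations
are sampled soon after founding, and serial founder pairs make per-step Y
coalescence structural, which is what a range-wide single male haplotype
implies. Founding groups are resampled until both sexes are present (a
single-sex group cannot found a population). Offspring sex is a shuffled
half/half split per generation so small demes never lose one sex.

**Recombination regimes.** Refugial and Pannonian demes recombine
recurrently (`refugial_recomb_prob` = 0.2 per male meiosis — mixing
timescale far below the coalescent timescale, so X and Y pools stay
interchangeable there), while `male_recomb_prob` (r) governs the NW lineage
from its founding; `t_split` is therefore the time since X–Y recombination
arrest in the expansion lineage when r = 0. The default r = 0.001 models
*occasional* recombination: usually the NW male excess survives, but an
occasional crossover resets it — mirroring the rare-exception individuals
such data show.

**Mutation.** Per-site substitutions at 5·10⁻⁶ /site/generation (Poisson per
gamete, uniform target site, uniform different base); a repeat tract under
the stepwise model (±1 copy at 10⁻³ /generation, reflecting at zero); a
large indel segment (size drawn once per marker from 30–60 bp) whose
presence toggles at 10⁻⁴ /generation. Rates are desk-scale rescalings: with
these sizes the refugial within-individual difference is a few per kb and
the expansion region nearly monomorphic, the regime the analysis operates
in. The rescaling constraint is explicit: terminal-window mutation
opportunity (samples × generations since the last founder event × μL) must
stay well below one for a shared male haplotype, while refugial coalescent
opportunity stays at a few.

**Output.** Alignments render the backbone, the repeat tract (motif ×
copies, gap-padded to the sample maximum) and the indel segment (sequence or
gaps) as one fixed-width alignment; identical copies are written as single
`ab` records; allele tag order is randomised so tags carry no X/Y
information. Ground truth records each copy's chromosome (by transmission
slot), its founder ancestry (head segment) and every crossover event.

**What it does not emulate.** Markers are simulated as independent runs
sharing only the locality scheme, whereas real sex-linked loci on one
chromosome share a pedigree; there is no gene conversion, selection,
migration after founding, or calibration to the real ~200 ky / 15 ky
history; simulated Pannonian diversity comes out intermediate-low rather
than refugium-high, because the desk-scale Pannonian deme is
mutation-limited after its founding. Passing tests therefore demonstrate
that the *inference machinery* recovers the planted structure under the
stated mechanics — not that real data will show effects of the same size.

## Test design

Unit tests cover each module's contracts; property tests (hypothesis,
derandomised, plus seeded loops) cover the invariants: step distance is a
metric and decomposes; site counts match an exhaustive column oracle;
network construction matches brute-force enumeration on ≤6-haplotype
instances; sequential-SS F matches both a group-mean/Gram–Schmidt oracle and
an independent statistical package on random designs; exhaustive permutation
p equals the Monte-Carlo p within sampling error; type-I error is calibrated.
Simulator behaviour is checked at scaled-down sizes (300 bp, demes of 12–16,
80–100 generations) for replicate-heavy properties, and at the default study
scale for the fixed-Y pattern (20 replicate seeds). The acceptance
regression freezes the end-to-end numbers of one seeded simulated study
(three markers at 992/504/411 bp with 54/33/16 individuals); the generation
is byte-deterministic under a fixed seed, which is itself a tested contract.
The power of the two-way interaction test is tracked as a regression guard
(>0.5) at a scenario whose NW male/female mean p_d ratio (~4) matches the
effect scale such field data show, at the study sample sizes.
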