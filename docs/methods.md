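# Methods

## The assay in brief

Hairpin oxidative bisulfite sequencing ligates a hairpin linker onto
restriction-cut genomic DNA so that the Watson and Crick strands of a locus
stay covalently joined through bisulfite treatment. One amplicon read then
reports both strands of every CpG dyad, which makes the *symmetry* of
cytosine modifications observable: a dyad can be modified on both strands,
hemimethylated on either strand, or unmodified. Splitting the ligation into
a standard bisulfite (BS) and an oxidative bisulfite (oxBS) aliquot
separates 5mC from 5hmC: under BS both modifications read C, under oxBS
5hmC is oxidised and reads T, so only 5mC reads C.

The package implements the full desk side of this design: bisulfite-aware
alignment and methylation calling, restoration of double-strand (dyad)
information with UMI deduplication, conversion-rate QC from the linker
controls, and a stochastic model of methylation dynamics over cell
divisions fitted jointly to both treatment channels.

## Composite reference and alignment

A hairpin amplicon is represented as a composite reference: top arm, linker,
then the Crick arm reversed into read orientation. Coordinates are 0-based
and half-open in composite space throughout; dyads are indexed by the offset
of the top-strand C. The bottom-strand cytosine of the dyad at top offset
`p` sits at composite position `top_len + linker_len + (arm_len - 1 - (p+1))`.

Alignment uses Biopython's `PairwiseAligner` in semi-global mode (reference
end gaps free) with an asymmetric substitution matrix: a read T opposite a
reference C scores as a match because bisulfite conversion is
one-directional, while a read C opposite a reference T is a mismatch.
Degenerate UMI slots (`D`) match A/T/G at score zero and penalise C (a C in
a UMI slot can only be an error, since D excludes C precisely to make the
UMI conversion-immune). Non-control linker cytosines are T-masked in the
alignment reference because they are unmodified by construction and always
convert; the three control cytosines stay C so their state can be called
like a SNP. Mate 2 is reverse-complemented before alignment, which also
folds the G→A appearance of conversion on the opposite PCR strand back into
C→T space. Overlapping mate positions are merged by quality-weighted
majority; a disagreeing tie becomes N.

Sequence identity is the fraction of matching aligned columns, counting
C↔T (conversion-eligible) and D vs A/T/G as matches and counting gaps and N
as mismatches; soft-clipped (semi-global) ends are excluded. The retention
thresholds are 0.9 for single-copy amplicons, 0.8 for repetitive elements,
and 0.6 on the linker region alone for the conversion-rate analysis (the
degenerate loop depresses identity, so the whole-read filter would discard
usable linker evidence). The column-level score definition itself is this
package's own choice; the thresholds are honoured as published.

## Refolding and deduplication

Per dyad, the (top, bottom) call states map to classes: modified/modified →
both, modified/unmodified → hemi-top, unmodified/modified → hemi-bottom,
unmodified/unmodified → unmodified; any unknown member makes the dyad
unknown. Reads sharing a UMI are PCR clones of one ligation event and are
collapsed to a consensus molecule by per-dyad majority (positions fail
independently, so voting is per position rather than per whole pattern);
ties become unknown. Reads without a recoverable UMI pass through
uncollapsed and are exempt from deduplication.

UMI collisions between distinct molecules at the same locus are accepted
rather than salted with fragment endpoints, because amplicons are
fixed-locus and endpoints are uninformative; `umi_collision_probability`
reports the birthday-bound risk for a given UMI length and depth. With the
default 5 slots (3^5 = 243 combinations) collisions are likely beyond ~20
molecules; analyses that rely on exact molecule counts should use 10-12
slots.

Non-CpG methylation is carried per molecule as a rate and never enters the
dyad classes; it is a separate analysis channel.

## Conversion rates and the emission model

For each control cytosine the conversion rate is `n_T / n_total` over
informative (C or T) observations. All three rates are oriented in the
T-direction — the probability of *reading T* — so intended conversions and
errors share one scale and no sign conventions are needed. The six measured
rates (three controls × two treatments) become the emission parameters:
`P(read T | true base)` per strand, with strands read independently. Per
amplicon rates are used when the control has at least 200 observations
(configurable); below that, rates pooled across amplicons of the same
treatment are substituted. Emission parameters are plugged into the model
as known constants rather than co-estimated, since they are directly
measured per sample.

Reference values for the eight-amplicon mouse ESC panel are bundled in
`hpoxbs.presets`; the panel-mean oxBS 5hmC conversion is ~92.5%, and BS
false conversion of 5mC/5hmC sits in the ~5-10% band.

## The dyad-state model

A dyad occupies one of nine hidden states — ordered pairs over {u, m, h}
for (top, bottom) in the fixed order uu, um, mu, mm, uh, hu, mh, hm, hh.
Each cell division applies, in this order:

1. **replication** — one strand is retained uniformly at random; the new
   strand starts all-u;
2. **maintenance** (probability `mu`) — the new-strand position opposite an
   m template becomes m. Maintenance recognises only m templates: a
   hemi-hydroxylated dyad receives no maintenance boost, reflecting Dnmt1's
   preference for a 5mC-containing hemimethylated substrate. This is a
   modelling assumption, stated here because the event order and substrate
   scope matter;
3. **de novo** (probability `delta`, independently per strand) — any strand
   still u becomes m; this includes a new strand whose maintenance failed,
   so the combined methylation probability on a hemimethylated substrate is
   `mu + (1 - mu) * delta`, which is also how the "total activity" summary
   is defined;
4. **hydroxylation** (probability `eta`, per strand) — every m strand
   becomes h.

h is terminal: further oxidation to 5fC/5caC is not modelled, because both
treatments read those as T, indistinguishable from u in the observation
channel. The composition of the four events is a 9×9 row-stochastic matrix;
populations evolve by left-multiplication. Replication-dependent
(passive) dilution falls out of the model: with `mu = delta = 0` the
methylated-strand fraction halves per division.

Observed molecules are independent draws from the population marginal (each
sequenced molecule samples one cell); no per-read trajectory is inferred.
The BS and oxBS aliquots sample disjoint cells from the same population, so
the two multinomial channels share the hidden chain and their
log-likelihoods add. The default fit aggregates counts over the dyads of an
amplicon (per-CpG fitting is available by restricting the counts).

### Division schedule

Observation days are mapped to cumulative divisions assuming a 12 h mouse
ESC cycle: days 0/1/3/6 → 0/2/6/12 divisions. The cycle length is a
package default, fully configurable per run.

### Fitting

Efficiencies are piecewise-constant per inter-observation interval (a
constant-over-time mode is available and is the right choice when the
generating process is known to be time-homogeneous); the initial state
distribution contributes 8 free parameters via a softmax parameterisation,
and efficiencies are logit-parameterised so the box constraints are
implicit. Optimisation is L-BFGS-B with numeric gradients, 20 seeded
multi-starts by default (the first start at the centre of the parameter
space), and a likelihood tolerance of 1e-8. With a single observation time
only the initial distribution is estimated. Estimates within 1e-3 of 0 or 1
are flagged as boundary-pinned rather than rejected — near-zero de novo or
hydroxylation activity is a legitimate biological outcome. Optional
percentile bootstrap intervals resample the multinomial counts and refit,
warm-started at the point estimate.

### The naive estimator

The subtraction estimator `mean_BS - mean_oxBS` (total and per dyad class)
is provided as a baseline. It is unbiased only under error-free chemistry;
with realistic conversion errors (~7% of modified bases converting under
BS, ~8% of 5hmC surviving oxBS) it is biased low by roughly
`0.92·h - h ≈ -0.08·h` plus cross-terms from 5mC, and it can go negative
from sampling alone because the two aliquots sequence different cells.
Negative values are reported with a warning, never clipped. The
model-based estimate corrects for both effects; on simulated time courses
with measured error rates it is closer to truth than the subtraction in
the large majority of replicates (the test suite demands ≥90%).

## The simulator

The generator emulates the mouse ESC demethylation study design: a
population initialised from a serum/LIF-like, heavily methylated state
distribution (72% mm, 15% uu, small hemimethylated and hydroxylated
fractions; frozen in `presets.DEFAULT_INIT_DISTRIBUTION`), propagated
through the division schedule, sampled iid per molecule, converted with the
treatment chemistry, and emitted as paired FASTQ with the linker, its
controls and a uniformly drawn UMI per molecule. PCR duplication replicates
a molecule (with its UMI) a geometric number of times with mean
`1/(1 - rate)`; sequencing errors are uniform substitutions applied after
conversion.

Dyads within a molecule are independent by default — adequate because the
default fit aggregates over dyads anyway — with an optional common-state
mode tying all dyads of a molecule for pattern-map realism. Features of
real data that are *not* emulated: indels and homopolymer artefacts,
quality-score structure (constant Q40), chimeric reads, incomplete
restriction digestion, strand-biased conversion, and spatial correlation of
methylation along the amplicon. Passing tests therefore demonstrate
correctness of the computational pipeline under its stated error model, not
robustness to every artefact of a sequencing run.

## Problem sizes and numerical choices

Simulation-backed checks in the test suite use 4000-5000 molecules per time
point and 12-20 seeded replicates for parameter recovery and estimator
comparisons, and 75-200 molecules for read-level (FASTQ) round trips —
sizes chosen so each property is measured well inside binomial noise while
the whole suite stays quick on a laptop. Distribution and matrix identities
are asserted to 1e-9 (stochasticity) or 1e-12 (agreement with brute-force
enumeration). Ties in mate merging and in UMI consensus resolve to N /
unknown deliberately: ambiguity is propagated, not guessed.

## Known limitations

- The alignment is semi-global against a single composite reference;
  genome-wide mapping, indel realignment and quality recalibration are out
  of scope.
- The efficiency model assumes synchronous divisions at a known rate; if
  the true cycle length differs from the configured one, per-division
  efficiencies rescale accordingly (per-day products are preserved).
- Per-interval efficiencies from four time points are weakly constrained
  when intervals are short; the constant mode is markedly better
  identified.
- The original double-strand estimation tool this module reconstructs is
  described only at the level of its inputs and outputs in the literature
  this package follows; event order, the maintenance substrate scope and
  the total-activity combination rule documented above are this package's
  own, explicitly stated decisions.
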