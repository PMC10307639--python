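# Methods

## Data model and conventions

All coordinates are 0-based half-open. A breakend is (chromosome, position,
side): side `+` means the junction retains the sequence to the *left* of the
position (a fragment ending there), side `-` the sequence to the right. With
the two breakends of an intrachromosomal junction ordered by position, the
side pair maps to the orientation class — `(+,-)` DEL, `(-,+)` DUP, `(+,+)`
h2hINV, `(-,-)` t2tINV — and interchromosomal junctions are TRA. This matches
common cancer-SV BEDPE strand usage; VCF breakend ALT brackets are mapped per
mate (`t[p[` / `t]p]` → `+`, `]p]t` / `[p[t` → `-`) and positions shifted by
−1. BEDPE breakends are taken at the start of each interval: consensus SV
releases are point-resolved, and confidence intervals are ignored. Equal
positions with identical sides are a degenerate junction and rejected; equal
positions with opposite sides are ordered `+` before `-` (in the simulator
this configuration is exactly reference adjacency and is suppressed before it
reaches classification).

## Clustering

Each intrachromosomal SV occupies its footprint [min breakend, max breakend].
Two SVs are linked when their footprints overlap or lie within `gap_max` of
each other; clusters are connected components with at least `min_sv` members.
For interval graphs, components equal the groups of a sorted sweep, which is
the implementation; the test suite checks it against an O(n²)
pairwise-linkage union-find oracle. Defaults: `min_sv` 5 (the explicit
criterion), `gap_max` 1 Mb. The megabase tolerance is a transparent
approximation of upstream cluster definitions that are not restated
alongside the criteria; it is exposed as a tunable rather than guessed
tighter. Translocations never join clusters; they are consulted only by the
balanced filter.

The interleaving fraction — among member pairs with overlapping footprints,
the share where neither footprint contains the other — is a diagnostic of
random-rejoining geometry. A configurable `min_interleave` can gate calls
(reject reason `low_interleave`) but defaults to 0 (off) so that balanced
counts follow the four explicit criteria only.

## Copy-number statistics

The modal copy number of a chromosome is the *total*-CN value covering the
greatest summed segment length (minor CN is carried through but not used by
the criteria). Ties break toward the lower value, the conservative choice:
it can only enlarge the loss fraction and therefore reject, never admit, a
borderline cluster. The loss fraction of a cluster span counts bases with
total CN strictly below modal over CN-covered bases; bases uncovered by any
segment are excluded from both numerator and denominator and their fraction
reported (a warning fires above 10% uncovered), because consensus CN is
near-complete and silently counting gaps either way would bias the statistic.
Gains above modal are not loss (the criterion is one-sided) and are reported
as a separate diagnostic. The oscillation run length clips segments to the
span, merges adjacent equal-CN segments, and returns the longest run
alternating between exactly two values; it is a labelled diagnostic, not a
hard filter, since no fixed oscillation count defines the canonical contrast
here.

## Classification

All four criteria are evaluated without short-circuiting and every failure
becomes a reject reason; `balanced` means no reasons. When no chromoplexy
regions are supplied, that criterion is recorded as not evaluated rather than
silently passed — automated balanced counts are therefore an upper bound on
manually curated counts. A cluster failing only the loss criterion with an
oscillation run ≥ 7 merged segments (configurable) is labelled
`canonical_like`; the threshold is a heuristic contrast label, not a
canonical-chromothripsis caller. A span with zero CN coverage yields reason
`uncallable_span`. Criterion 2 rejects the cluster outright (no carving out
of the offending region), reflecting the plain reading of "no translocation
in the span".

## Gene impact

A gene is disrupted when any member-SV breakend lies within [start − pad,
end + pad), pad 5 kb by default; every overlapping gene is reported, one row
per (gene, call). Driver status comes from an exact-symbol match against a
supplied plain-text catalogue. Fusion candidates require one junction's two
breakends in two different (unpadded) gene bodies with compatible
orientation: the retained part of a gene is 5′ when gene strand equals
breakend side, 3′ otherwise, and a candidate pairs a 5′-retaining with a
3′-retaining partner. This retained-part test is this package's own standard
heuristic — disruption is defined by the window rule, but no detection rule
for fusions is prescribed upstream — and no reading-frame or expression
check is attempted.

## Simulator

The generative model follows the micronucleus mechanism: shattering of a
single-copy chromosome region, stochastic cytoplasmic loss, clustered
(one-daughter) versus dispersed (binomial) inheritance, and uniformly random
reassembly in the sequenced daughter. Defaults, chosen once as the study
conditions: focal chromosome chrY, 57,227,415 bp; shatter region 15–45 Mb
(the ~30 Mb scale of the modelled event); background ploidy 1;
`n_breakpoints` K = 10; `p_loss` 0 (per-fragment loss probability is a free
parameter of the model, not a measured value). Breakpoints are distinct
uniform integers. Junctions are derived from derivative adjacencies with
reference-adjacent co-oriented pairs suppressed (they reconstruct contiguous
sequence); correctness is proven in tests by exhaustive comparison against a
strand-aware string-reconstruction oracle over all ≤5-fragment derivatives.
CN inside the region is ploidy for retained fragments and ploidy − 1 for
lost ones, merged; conservation (retained length = CN excess over the
region) is asserted in tests. The RNG stream order per sample is fixed —
shatter, loss draws, daughter draws, permutation, flips — with daughter
draws consumed for every fragment so outputs are reproducible across
`p_loss` settings; same seed gives bit-identical files.

Truth labels: `balanced` when the realized loss fraction is below the 1%
threshold (and mode is not chromoplexy), `canonical` otherwise,
`chromoplexy` for chain samples. Chromoplexy mode places one breakpoint on
each of m ≥ 3 chromosomes and joins them cyclically into translocations with
flat CN; by construction it produces no intrachromosomal cluster, so it
exercises the caller's negative path (zero balanced calls), while the
translocation-in-span rejection itself is exercised by composing a chain
onto a shattered chromosome in the tests. Daughter B's fragments count
toward the partition ratio but are never assembled into a second derivative
(the sequencing readout is one daughter's chromosome), and cytoplasmic
fragments are excluded from the ratio (the imaging readout measures nuclear
signal). Fragments are single-copy — no replicative duplication, kataegis,
ecDNA circularization or multi-generation evolution — so simulated DUP
junctions carry no CN gain; passing tests therefore validate the
rearrangement/CN logic of the caller, not its behaviour on aneuploid, noisy
or purity-confounded real profiles.

## What the synthetic data does not emulate

Real consensus CN has measurement noise, subclonality and purity effects;
real SV calls have imprecise breakpoints, missed junctions and artifacts;
real tumours have genome-wide background rearrangements. The simulator
emulates none of these, so recovery rates on simulation are an upper bound
on real-data performance. The cohort-scale prevalence figures from large
tumour panels additionally depend on access-controlled inputs and a manual
curation step and are out of desk-scale reach; validation here is
property-based on the generative model.

## Numerical and design choices

* Loss criterion is strict (`loss_frac < max_loss_frac`); 0.009 passes,
  0.011 fails at the default 1%.
* Cluster span is [min breakend, max breakend] over members.
* Test-scale choices keep the suite and the acceptance script within
  seconds: 200/200/50 samples per mode at K = 10, 10⁵ Monte-Carlo draws,
  exhaustive oracles at ≤ 5 fragments / ≤ 6 CN segments. These sizes are
  the package's documented study conditions.
* Pipeline outputs are deterministic given inputs; reruns are bit-identical,
  and the run manifest echoes all parameters.
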