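# Methods

## Model and procedure

The package treats a metabolic network as a linear steady-state system:
fluxes `v` satisfy `S·v = 0` over non-boundary metabolites and per-reaction
bounds `lb ≤ v ≤ ub`. A species is *boundary* (exempt from steady state)
when its SBML `boundaryCondition` flag is set or its compartment equals the
configurable boundary token (default `b`, the compartment-suffix convention
of the first human genome-scale reconstruction). All linear programs are
solved with HiGHS via `scipy.optimize.linprog`; the solver is deterministic
for a fixed model, so reruns are bit-stable per platform.

The biosynthesis capacity of metabolite *m* is the FBA optimum of a unit
demand reaction `DM(m)` with bounds [0, 1000]. An existing unit export with
ample capacity (stoichiometry exactly `{m: −1}`, non-negative lower bound,
upper bound ≥ 1000) is reused so that genuine exchange reactions serve as
objectives; anything narrower (capacity-limited exports, non-unit
coefficients) would conflate transporter capacity with production rate and
is not reused.

The knockdown screen proceeds in three steps per gene:

1. **Isozyme classification.** Each reaction's GPR rule is evaluated with
   the gene absent and every other gene present. Reactions whose rule goes
   false are the gene's *falsified* reactions; a gene with none is
   *buffered* and can have no phenotype. AND nodes model complex subunits
   (either member's loss falsifies), OR nodes isozymes (either member
   suffices).
2. **Envelope-capped knockdown.** Under the production objective currently
   being evaluated, FVA gives each falsified reaction's attainable flux
   range `[v_min, v_max]`. The knockdown bounds are
   `[min(v_min/f, 0), max(v_max/f, 0)]` intersected with the original
   bounds. Reversible reactions therefore shrink on both sides: reduced
   enzyme abundance limits catalytic capacity in either direction. The
   alternative of dividing the raw model bounds by `f` is available as
   `envelope_mode="raw"`; the envelope variant is the default because raw
   bounds in genome-scale models are usually the generic ±1000 and carry no
   information about what the reaction can actually do under the objective.
3. **Impact call.** A metabolite counts as affected when its baseline
   maximal production exceeds `production_floor` and drops by a relative
   margin greater than `relative_drop_threshold` under the knockdown.
   Perturbed values are clamped to the baseline before comparison, since at
   degenerate optima the LP can return values a rounding error above it.

One gene is perturbed at a time; combined knockdowns are out of scope
(each cell is assumed to carry at most one new insertion in a metabolic
gene). Only objective *values* are used downstream; individual flux vectors
at alternate optima are non-unique and never compared.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `fold_reduction` | 70 | dimensionless | capacity division factor for falsified reactions; 70 reflects the measured expression drop caused by sense-oriented intronic L1 insertions |
| `relative_drop_threshold` | 1e-6 | relative | minimal relative production decrease counted as an effect (LP noise floor) |
| `production_floor` | 1e-9 | flux | minimal baseline production for a metabolite to be evaluated |
| `optimality_fraction` | 0 | fraction | FVA objective constraint `v_obj ≥ fraction·optimum`; 0 means only `v_obj ≥ 0` |
| `max_mismatch` | 1 | bases | Hamming tolerance of the TTAAAA target-site scan |
| `n_samples` | 100 000 | count | Monte Carlo samples in the enrichment null |
| default bound | ±1000 | flux | assigned when SBML declares none; only needs to dominate realistic capacities |

`optimality_fraction = 0` is the default because the flux envelopes are
meant to describe what each reaction *can* carry while the network is able
to run the objective at all, not while it is forced to run it optimally; a
fraction of 1 would make the envelope (and hence the knockdown) reflect
only optimal operating points. Both readings are runnable through the
configuration.

Metabolites are counted across organelles by a compartment-stripped key
(the id minus its trailing compartment token); the per-compartment detail
is retained in the impact table. Disease-map keys are additionally
case-folded, and an optional synonym TSV translates model keys to map keys,
because metabolite naming differs between reconstructions and metabolome
databases — name matching is the only reconstructable linkage, and
reproduction of any specific disease table depends on the user-supplied
association snapshot and on how much of each gene (introns, UTRs) the
supplied FASTA covers.

## Enrichment test

Target sites are all 6-mers within Hamming distance `max_mismatch` of
`TTAAAA` on the forward strand or of its reverse complement `TTTTAA`
(equivalently, a reverse-strand match); `N` bases match nothing and
overlapping sites are all kept. The null redistributes `m` insertions —
`m` defaulting to the number of observed insertions that map to model
genes — uniformly *across sites*, with replacement, so genes are weighted
by their site counts. A without-replacement switch exists; with `m` far
below the total site count the two are practically identical. Every
disease is scored on the same sample stream (as a shared-null design
requires), a gene hit twice in one sample contributes its affected set
once, and the test is one-sided for enrichment:
`p = (n + 1)/(N + 1)`, never zero, with floor `1/(N + 1)`.

Because the per-sample statistic is an integer count, the empirical p is
slightly conservative (its null distribution stacks on the achievable tail
values); the discreteness shrinks as the statistic's spread grows.

## Synthetic data and what it shows

The generators produce every input with known ground truth:

- **Toy networks** are independent linear chains with unit stoichiometry,
  uptake/export, and capacity 10, each conversion carrying a sole-gene,
  OR-pair, or AND-pair rule. Truth is analytic: an effective gene on step
  *j* affects exactly the metabolites downstream of *j*, and a buffered
  gene affects nothing. These hand-computable optima are the point; the
  generator does not attempt realistic branching, cofactor coupling, or
  genome-scale degeneracy, so passing tests demonstrate correctness of the
  procedure, not performance on a real reconstruction.
- **Sequences** are background-scrubbed until the scanner finds no site,
  then exact hexamers are planted at well-separated recorded positions
  (≥ 16 bp apart, so no 6-mer window touches two plants), with background
  bases adjacent to a plant re-drawn from {G, C} whenever they would create
  a spurious within-1 window. Planted-site recovery is therefore exact by
  construction, which is what makes scanner tests deterministic.
- **Insertion tables** draw genes per donor with probability tilted toward
  effective genes by a bias in [0, 1]: 0 is the uniform null, 1 hits
  effective genes only.
- **Disease maps** are random metabolite sets; optionally one disease's set
  is drawn from the truly-affected pool so enrichment has a planted signal.

Three pre-registered designs exercise the pipeline (`teflux.studies`):

- `toy` (3 chains × 4, mixed rules, exhaustive one-insertion-per-gene
  coverage): the LP screen must recover the planted effective-gene set and
  the gene→metabolite map exactly and deterministically.
- `calibration` (40 sole-gene chains × 8, 3 planted sites per gene, one
  donor with 80 uniform insertions, disease sets of 240 of the 320 keys):
  under this null the enrichment p-values must be uniform across
  replicates. The design choices are dictated by the discreteness argument
  above — equal per-gene site counts make the site-weighted null coincide
  with the uniform insertion generator, and many sole-gene chains with
  large disease sets give the count statistic enough spread (SD ≈ 10) that
  the uniformity of an inherently discrete p can be meaningfully tested at
  500 replicates.
- `power` (as calibration but 80% isozyme steps, bias-1 insertions, one
  disease planted from the affected pool): the planted disease must be
  detected (p ≤ 0.05) in nearly every replicate, since the null spreads
  insertions over the mostly-buffered gene set.

The replicate studies score sampled genes through the chains' analytic
impact map — the same map the LP screen provably computes on these
networks (the toy end-to-end test asserts exact equality) — which keeps
hundreds of replicates at desk scale; envelopes depend only on the model
and objective, never on the donor, so they are shared wherever reuse is
sound.

## Numerical choices

- Solver feasibility/optimality tolerances 1e-9; downstream assertions at
  1e-6 (`‖S·v‖∞`, envelope containment).
- FVA returns `(0, 0)` for blocked reactions; a sub-tolerance inverted
  range from solver jitter is collapsed to its midpoint.
- If a knockdown cap falls below a reaction's forced lower bound, the cap
  wins (the interval collapses to the cap) rather than producing an empty
  interval.
- The FVA implementation accepts a reaction subset: the screen only needs
  envelope entries for falsified reactions, and per metabolite it computes
  one baseline FBA, one restricted FVA over the union of falsified
  reactions of all effective hit genes, and one LP per effective gene.
- Infeasible and unbounded LPs raise distinct errors naming the objective;
  the pipeline aborts naming the stage and the input that failed.
- All randomness flows through `numpy.random.default_rng` seeds; derived
  seeds stay below 2³¹. Reports contain no timestamps, so reruns under the
  same seed are byte-identical (runtimes live only in the metadata file).

## Known limitations

- Genome-scale conclusions require the user's own reconstruction,
  insertion calls, gene sequences, and disease-association snapshot; the
  shipped generators are deliberately idealized (exact planted truth, no
  realistic gene structure).
- Effects of an insertion are modeled purely as a uniform fold-reduction of
  catalytic capacity; no element-type differences, no expression data, no
  insertion-position effects within a gene, and no interaction between
  multiple insertions.
- The target-site null captures only the hexamer-with-one-mismatch
  preference; chromatin state or expression-weighted insertion preference
  is not modeled.
- Genes whose falsified reactions carry no flux under any production
  objective are counted among the no-impact genes but additionally flagged
  (`n_effective_blocked`), since their lack of effect is structural
  (blocked reactions) rather than compensatory (alternative routes).
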