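# Methods

This note records the models, conventions and deliberately made choices
behind `hrmbarcode`, in the spirit of a statistical-software methods
appendix. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Melting model

The melt predictor treats a PCR amplicon as a two-stranded duplex whose
N−1 base-pair stacks can each be formed or broken. A microstate is any
subset *s* of the stacks with energy

E(s) = Σ_{i∈s} ΔG_i(T) + γ·runs(s) + ΔG_init,

where ΔG_i(T) = ΔH_i − T·ΔS′_i/1000 comes from the unified
nearest-neighbor stack table shipped as `data/nn_unified.json`
(ΔH in kcal/mol, ΔS in cal/mol·K), `runs(s)` is the number of maximal
helical runs, and ΔG_init collects the two terminal initiation terms.
Salt enters entropically, ΔS′ = ΔS + 0.368·ln[Na⁺] per stack, with
[Na⁺] the monovalent-equivalent molarity. Helicity is the
Boltzmann-expected fraction of formed stacks; Tm is the linear
interpolation of the 0.5 crossing on the acquisition grid. Additive
constants such as ΔG_init cancel in the Boltzmann average, so they affect
the two-state Tm estimate but not the helicity curve.

Two independent routes compute the same contract: an O(N)-per-temperature
transfer-matrix recursion (`helicity_curve`, rescaled each step so
100+ bp amplicons cannot overflow) and exact enumeration of all 2^(N−1)
states (`brute_force_helicity`, refused above N = 13). The suite holds
them to 1e−9 pointwise agreement; measured disagreement is ~1e−14.

**Cooperativity.** The junction penalty defaults to γ = 6 kcal/mol per
helical run. A pure zipper (γ = 0) leaves the stacks nearly independent,
which melts an 82 bp amplicon over more than 30 °C and leaves ~37 %
helicity at 97 °C — nothing like the sharp transitions an HRM instrument
records. γ = 6 suppresses isolated interior helices and fragmented
states, giving transitions a few °C wide with the −dF/dT peak close to
the 0.5 crossing. The value is a modeling choice on the stiff side of
the classical helix–coil cooperativity range, not a fit; it is
configurable (`junction_penalty_kcal`), and the enumeration oracle covers
any γ. Internal coil regions carry no loop-entropy term beyond γ, and
heteroduplexes/competitive equilibria are out of scope (mitochondrial
amplicons are effectively haploid). Absolute Tm values from other
predictors will differ; ranks and differences are the meaningful output.

**Two-state Tm.** `two_state_tm` is a screening estimate only:
Tm = ΔH/(ΔS + R·ln(C_T/x)) − 273.15 with total strand concentration
C_T (default 0.25 µM) and symmetry factor x = 1 for self-complementary
sequences, 4 otherwise — the standard convention, worth stating because it
shifts Tm by 1–3 °C. It is cross-checked in the suite against Biopython's
independent nearest-neighbor implementation with the same table and salt
correction.

**Grids.** The default temperature grid is 65–97 °C at 25 points per
degree, the acquisition density of HRM-capable qPCR instruments. Curves on
different grids refuse to be compared (`GridMismatchError`) rather than
being silently resampled. A Tm whose 0.5 crossing the grid does not
bracket is flagged (`tm_in_range=False`, NaN) instead of raising.

## Variant classes and design conventions

Substitutions are binned into the four HRM classes after canonicalizing
complementary pairs onto one representative: C/T ≡ G/A (class 1),
C/A ≡ G/T (class 2), C/G (class 3), A/T (class 4), in decreasing order of
typical Tm shift. Class 4 swaps conserve base-pair composition and are the
hardest calls; the suite verifies a matched class-1 swap separates curves
more than a class-4 swap.

Coordinates are 0-based half-open everywhere internally; only human-facing
reports are 1-based inclusive. Alignments are inputs, never recomputed.
Ambiguity codes are accepted in references: a species' majority base at a
column is taken over unambiguous observations, and degenerate positions
inside an amplicon expand to at most 4 haplotypes per species (warned).

In-silico PCR requires the 3′-terminal base of each primer to match
exactly regardless of the mismatch allowance (polymerase extension
requirement); among multiple placements the shortest product wins with a
warning. Candidate enumeration is exhaustive over conserved flank pairs
(product size 60–140 bp by default, wide enough for the 124 bp published
amplicon), ranked by informative-variant count, then shorter product, then
leftmost start — short products are preferred because degraded specimens
only amplify short fragments. `dedupe_candidates` keeps one representative
per distinct variant content, since sliding near-duplicates carry no new
information.

## Resolvability, panels and the identification tree

Two species are distinguishable under an amplicon when **every** pairing
of their haplotype curves differs by |ΔTm| ≥ 0.3 °C **or** max-absolute
curve distance ≥ 0.02 (both configurable). The defaults reflect
instrument-grade HRM resolution; no published numeric criterion exists for
"same melting curve", so the thresholds are stated rather than inherited.

Panel selection is greedy set cover over species pairs (ties broken by the
candidate ranking), with an exhaustive minimum-cardinality oracle for ≤ 12
candidates used in testing; the suite and acceptance script check
coverage-optimality of the greedy choice on 1000 random instances. Panel
order is selection order, which also minimizes expected assays per sample.

The decision tree runs the panel in order: at each node the still
unresolved species are grouped by single-linkage clustering on Tm with the
0.3 °C threshold; singletons become leaves, larger clusters descend,
groups left after the last assay are unresolved leaves.

## Observed data and classification

Raw traces are normalized between lines fitted in a pre-melt and a
post-melt window, clipped to [0, 1]; degenerate baselines raise rather
than return nonsense. Observed Tm uses the same 0.5-crossing convention
as predictions. Replicates are summarized as mean, sample SD (n−1) and a
Student-t 95 % CI half-width (t₀.₉₇₅,₂ = 4.3027 for triplicates) — the
defensible small-n choice.

Matching a sample to a reference cluster uses
|sample mean − ref mean| ≤ k·max(ref SD, SD floor) with defaults k = 3 and
floor = 0.15 °C; the floor guards near-zero reference SDs and the rule is
an explicit, configurable substitute for whatever undocumented grouping
instrument software applies. The nearest matching cluster wins. A sample
matching no cluster at an applicable node is NRC; exhausting the tree
inside a multi-species group (or missing data for a needed assay) yields
an ambiguous verdict carrying the group.

## Synthetic data: what it does and does not emulate

`simulate_haplotypes` builds a shared random background, writes fixed
segments (e.g. real primer footprints) and planted per-species variants
into it, keeps declared windows conserved, and adds within-species
divergence only outside protected columns. Everything is deterministic
under the model seed. `blowfly_reference_model` realizes the six-species
blowfly geometry: both published primer footprints embedded verbatim,
one GC-ladder of class-1 variants inside each amplicon (nested, so Tm is
monotone in ladder level) with *C. megacephala* = *C. albiceps* on the
82 bp ladder and *L. eximia* = *L. cuprina* on the 124 bp ladder, plus a
third ladder outside both amplicons so whole-barcode identities are
species-specific. The planted columns are synthetic stand-ins, not the
true COI positions, and the generator makes no attempt at phylogenetically
realistic evolution — passing tests demonstrate the pipeline's logic, not
performance on real BOLD alignments.

`classifier_reference_tms` states the benchmark conditions for classifier
recovery directly: six species × two amplicons with cluster means ≥ 0.5 °C
apart, the amplicon-1-merged pair split on amplicon 2, and a novel species
≥ 1 °C from every cluster. Replicate noise is Gaussian Tm jitter
(sd 0.1 °C in the benchmark), applied as a rigid curve shift when curves
are needed — per-point fluorescence noise is available for normalization
tests but is not the default, because the classifier contract is Tm-based.

Degradation is exponential fragmentation: an amplicon of length *a*
survives intact in one template copy with probability exp(−a/mean
fragment length), and amplification succeeds if any copy is intact.
Identical uniform draws are reused across lengths, so estimated success is
exactly monotone decreasing in length for a fixed model. This reproduces
the qualitative short-amplicon advantage for degraded specimens only;
wet-lab recovery percentages depend on chemistry and handling that the
mechanism does not model.

## Problem sizes

The default synthetic alignment is 380 columns × 6 species; exhaustive
candidate enumeration on it yields ~10⁵ raw candidates in ~10 s. The
oracle comparisons use 200 random sequences (N ≤ 13) for the melt model
and 1000 random instances (≤ 8 species × ≤ 6 candidates) for set cover;
the classifier study uses 1000 reference-species samples and 400 novel
samples. These sizes were chosen to exercise every code path at
desk scale.

## Known limitations

* Absolute predicted Tm is parameter-set dependent; only differences and
  ranks should be interpreted.
* No dimer/hairpin thermodynamics in primer QC beyond substring
  heuristics; no genome-wide specificity screening.
* No probabilistic species posteriors; the classifier is a deterministic
  tree walk with stated tolerances.
* Indel and multiallelic columns are flagged but not modeled
  thermodynamically (haplotypes of unequal length melt via their own
  curves; no heteroduplex treatment).
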