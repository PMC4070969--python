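# Methods

`trflpkit` implements the analysis chain used to fingerprint microbial
communities — here arbuscular mycorrhizal fungi (AMF) in rice roots — by
terminal restriction fragment length polymorphism (T-RFLP), together with a
synthetic-data generator that produces every input with known ground truth.
This note records the models, the defaults and why they were chosen, the
numerical decisions, and what the synthetic tests do and do not demonstrate
about real data.

## The measurement model

An ~800-bp fragment of the 18S rRNA gene is amplified with the AMF-specific
primers AML1 (forward, HEX-labeled) and AML2 (reverse, FAM-labeled), digested
with HinfI (recognition site `GANTC`, cut `G^ANTC`), and the fluorescent
*terminal* fragments sized on a capillary sequencer. Each community member
therefore contributes one HEX peak (5' end of the forward strand to the
first cut) and one FAM peak (same on the reverse complement); peak area is
taken as proportional to template abundance. The recognition site is
degenerate and, as an IUPAC class, its own reverse complement, so one scan
locates the sites on both strands.

Dye chemistry shifts apparent mobility: the package carries per-dye size
offsets (`dye_offsets`, default `(0, 0)` bp). The correction magnitude is
instrument- and chemistry-specific and must be calibrated by the user; the
default of zero simply reports true fragment lengths.

## Peak processing

Raw size-called peak tables pass through four steps:

1. **Dynamic-range QC** — a profile whose strongest peak height is outside
   2,000–8,000 rfu (bounds inclusive) is flagged `rerun`: in practice the
   template concentration would be adjusted and the capillary run repeated.
2. **Filtering** — peaks with height < 50 rfu or size outside [50, 600] bp
   (bounds inclusive) are removed. The amplitude threshold is a floor
   (exactly 50 rfu is kept); the size cuts mirror the strict "< 50 bp"
   exclusion wording, making the bounds themselves retained.
3. **Binning** — within each dye channel, a bin is seeded at the
   largest-area unassigned peak (area ties broken toward the smaller size)
   and absorbs every unassigned peak within 1.2 bp of the seed; this
   repeats until all peaks are assigned. The seed is by construction the
   bin's maximum-area member and becomes its representative size, so
   representatives end up pairwise more than 1.2 bp apart. Greedy seeding
   by area is deterministic and independent of input order. An alternative
   reading — labeling the bin by its largest *size* — exists in the
   literature; labeling by the tallest member was chosen because it is
   robust to shoulder peaks, and the window is configurable.
4. **Abundance filter** — bins contributing strictly less than 1% of the
   grand total area (both dyes pooled; the profile's "total fluorescence")
   are removed and relative abundances recalculated over the survivors.
   The strict inequality keeps a bin at exactly 1.0%.

Replicate runs of one digestion mixture are merged by `consensus_profile`:
bin representatives from all replicates are pooled, re-binned with the same
greedy algorithm, and each consensus bin's area is the sum of matched areas
divided by the number of replicates. Replicates are filtered *before*
averaging; a peak type present in only one of three replicates therefore
enters the consensus at a third of its area, which suppresses spurious
peaks without an explicit presence-count rule.

With double-end labeling every phylotype appears once per dye channel, so
community proportions are computed per channel (each channel renormalized),
not over the pooled two-channel profile — pooling channels would halve
every proportion and shift H' up by exactly one bit.

## In-silico typing

`predict_trf` reports the distance from each labeled 5' terminus to the
first cut (full amplicon length if uncut) — standard T-RF semantics, with
digestion assumed complete. `rflp_pattern` gives the full-digest fragment
multiset used to type clone libraries; distinct patterns are distinct
operational taxonomic units (OTUs), with `cluster_patterns` optionally
merging patterns that agree fragment-wise within a tolerance.

`assign_trfs` matches each observed bin to the nearest predicted fragment
of the same dye within a tolerance of 2 bp (boundary inclusive; exact
distance ties go to the smaller predicted size, for determinism).
Phylotypes predicted at identical sizes are pooled into one signal, since
their peaks are physically inseparable; with `require_both_dyes` a
phylotype is only reported present when both its HEX and FAM fragments are
matched, trading sensitivity for specificity when predictions are not
unique. Abundance estimates sum assigned relative areas per label within
each channel, renormalize over assigned signal, and average the two
channels.

## Diversity and rarefaction

Richness S is the number of retained T-RF bins. The Shannon–Weiner index is
computed in **bits**: H' = −Σ pᵢ log₂ pᵢ, and evenness E = H'/log₂(S)
(defined as 0 when S = 1, the conventional limit of the indeterminate
ratio). Most ecology packages default to natural logarithms; divide by
ln 2 ≈ 0.693 to compare.

Rarefaction of an N-clone library uses the exact hypergeometric
expectation E[Sₙ] = Σᵢ (1 − C(N−Nᵢ, n)/C(N, n)). The 95% interval uses the
exact variance of Sₙ (which requires the pairwise joint absence
probabilities C(N−Nᵢ−Nⱼ, n)/C(N, n)) with a normal approximation, since
the reference tool's internal interval construction is not documented; a
Monte-Carlo resampling route (subsampling without replacement, percentile
bounds) is provided as an independent alternative and the two agree within
Monte-Carlo error on 96-clone libraries.

## Ordination

* **PCA** on the binary phylotype incidence matrix: columns centered,
  covariance eigen-decomposed (no correlation rescaling — presence/absence
  columns share a scale), first two component scores reported with
  explained-variance proportions.
* **Metric MDS** on relative T-RF area rows: Euclidean distances embedded
  in two dimensions by SMACOF stress majorization. The original analysis
  used ALSCAL (interval-scaled MDS); its exact update rules are not
  published, so this package substitutes the standard majorization
  algorithm, whose raw stress Σ(d_ij − ||x_i − x_j||)² is provably
  nonincreasing per Guttman iteration. The start is the classical-scaling
  (principal coordinates) configuration rather than random, so results are
  reproducible; the seed only drives optional random restarts. Convergence:
  stress decrease < 1e-9 or 300 iterations. The final configuration is
  rotated to its principal axes. Correctness is checked by exact recovery:
  distances realizable in the plane must embed with stress and Procrustes
  error below 1e-6.

`group_dispersion` summarizes an ordination by group centroids and mean
within-group distance, quantifying visual "the groups separate" claims.

## Factorial statistics

`two_way_anova` fits the fixed-effects model y = μ + αᵢ + βⱼ + (αβ)ᵢⱼ + ε
by least-squares model comparison. For balanced data this reproduces the
classical decomposition (SS_A + SS_B + SS_AB + SS_E = SS_total); unbalanced
data get Type-II sums of squares, the natural choice when testing main
effects in the presence of interaction and identical to the classical
answer whenever the design is balanced. The response is centered before
fitting so a constant response yields exactly zero sums of squares and
F = 0 everywhere.

Tukey–Kramer comparisons use q = |mᵢ − mⱼ| / √(MS_E (1/nᵢ + 1/nⱼ)/2) with
p-values from the studentized range distribution (`scipy.stats.
studentized_range`, which integrates the range distribution numerically).
The compact letter display uses insert-and-absorb: one class initially
holds all groups, every significant pair (p ≤ α, default α = 0.05) splits
each class containing both, and subset classes are absorbed; the algorithm
guarantees two groups share a letter iff their comparison is not
significant, which the tests assert exhaustively. Letters may be assigned
across all A×B cells jointly (default, as in treatment tables where one
letter family spans every time×treatment cell) or within each level of
factor A.

## Synthetic data: what it emulates and what it does not

`generate_community` builds amplicons constructively rather than by
rejection: each ~800-bp sequence starts with AML1, ends with the reverse
complement of AML2, and carries two engineered `GANTC` sites — one at
position f−1 fixing the forward T-RF f, one at L−4−r fixing the reverse
T-RF r. Any accidental recognition site in the uniform-random background is
mutated away, so the engineered sites are provably the first cut on each
strand. Forward (and reverse) T-RFs of distinct phylotypes are placed in
[50, 600] bp with pairwise gaps strictly greater than `min_trf_separation`;
an infeasible request raises "cannot place fragments". Abundances default
to a symmetric Dirichlet draw; the bundled fixture instead fixes
(0.35, 0.25, 0.18, 0.13, 0.09) so that every phylotype sits well above the
1% area filter and recovery is well-posed.

`simulate_profiles` adds, per replicate: Gaussian size-call jitter
(default SD 0.15 bp — the size-call repeatability of capillary
instruments is a module choice, not a literature value), multiplicative
gamma area noise (CV 0.05 across replicates), a uniform rescaling so the
strongest peak height lands in the 2,000–8,000 rfu window (peak height =
area / constant width, width 1 bp), and Poisson(2) spurious peaks placed
uniformly in [50, 600] bp with areas uniform in (0, 2% of total signal) —
deliberately straddling the 1% filter so the filter is exercised in both
directions. `sample_clone_library` draws clones multinomially and types
them by RFLP pattern.

Not modeled, and therefore not validated by these tests: PCR amplification
bias, chimeras, partial digestion, pseudo-T-RFs, electrophoretic mobility
curvature, pull-up between dye channels, and stutter. Passing the
end-to-end recovery test shows the *computational* chain is faithful — that
known abundances survive filtering, binning, consensus and assignment to
within ±0.02 under realistic size jitter — not that T-RFLP itself is an
unbiased census of a real community.

## Problem sizes and determinism

The default pipeline simulates the 2×2 factorial field design (CS/SRI ×
control/compost) with 3 plots per treatment, 3 capillary runs per plot and
96 clones per library; one phylotype is restricted to SRI plots so the
binary incidence matrix has genuine variance (mirroring taxa intolerant of
continuous flooding). The test suite's simulation sizes (for example 2,000
null ANOVA replicates, 10,000 rarefaction resamples, 1,000 digest/binning
oracle trials) were chosen so Monte-Carlo bands are decisive while the
whole suite completes in well under a minute per module. All randomness
flows through `numpy.random.default_rng` seeds; identical seeds give
byte-identical outputs, which the pipeline test asserts file by file.
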