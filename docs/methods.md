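# Methods

## Structural contexts and the folding engines

Every nucleotide of an RNA in thermal equilibrium occupies one of five
mutually exclusive structural contexts per conformation: stem/paired (S),
hairpin loop (H), internal or bulge loop (I), multibranch loop (M), or the
external region (E, unpaired and not enclosed by any pair).  A *structural
profile* is the L × 5 matrix of Boltzmann-ensemble probabilities of these
contexts; its S column is the per-nucleotide base-pairing probability.
Loop type is decided by the number of helices branching off the loop that
contains the nucleotide: zero branches is a hairpin, one is an
internal/bulge loop, two or more a multibranch loop.  Bulges are counted
with internal loops, giving exactly the five-letter alphabet above.

Two backends implement the same interface.

**Basic backend.**  A McCaskill-style partition function over a minimal
energy model: each admissible pair (GC −3.0, AU −2.0, GU −1.0 kcal/mol)
contributes its energy additively, hairpin loops contain at least 3
unpaired bases, pair span is capped at `max_span` (default 40), and
RT = 0.6163 kcal/mol (37 °C).  There is no stacking, loop-length or
dangling-end term; the model exists to make the *mathematics* of the
pipeline exactly verifiable, not to reproduce thermodynamic measurements.
Inside/outside recursions give pair probabilities; the context profile is
computed exactly at any length by an O(n³) decomposition: for an unpaired
position u enclosed most closely by pair (p, q), the interval splits into
independent segments left and right of u, and the loop type follows from
the joint count of top-level helices in those segments (0 → H, 1 → I,
≥2 → M), tracked with an auxiliary "exactly one top-level helix" partition
function.  The probability of being unstructured — one minus the total
Boltzmann probability of conformations below the −2.5 kcal/mol free-energy
threshold — is computed exactly by a histogram DP over integer energies.
An exhaustive enumeration oracle (length ≤ 22) validates all of this to
1e-6 in the test suite; the two routes share no code beyond the energy
model.

**Turner backend.**  Delegates to the ViennaRNA library.  Pairing
probabilities use the plfold machinery with window 80 and span 40 — the
standard settings for local folding of probe-scale RNAs (`RNAplfold -u 1
-W 80 -L 40`); context profiles use the windowed unpaired-probability
computation split by loop type, which yields the five-context profile
*exactly* rather than by Boltzmann sampling (S = 1 − Σ unpaired
components).  Per-structure energies for the unstructuredness probability
are estimated from `n_samples` (default 1000, minimum 100) stochastic
backtracking samples, the one place the backend is stochastic.
Precomputed `RNAplfold` `_lunp` tables are accepted as input through the
IO layer for users who ran the external tool themselves.

Sequences longer than the window are folded in sliding windows and
per-window quantities averaged (the basic backend mirrors what the plfold
machinery does internally).

**Randomized profiles.**  The negative control replaces each position's
context distribution by five uniform random integers on [0, 32767]
normalized to sum 1 (all-zero draws are redrawn), from a seeded
`numpy` generator — a documented, reproducible stand-in for a classic libc
`rand()` stream.

## K-mer structural variability

For every occurrence of every k-mer (default k = 5, 1024 k-mers), the
occurrence statistic is the mean pairing probability over its k positions.
Per k-mer we report the sample SD (n−1 denominator) across occurrences;
k-mers with fewer than two occurrences are excluded from the SD
distribution.  "Center" of the distribution is the median (the mean is
reported alongside): on ≥10,000 uniform random 30–41 nt probes under the
Turner backend this center is ≈0.24.  The k-mer/intensity correlation
treats each occurrence as one point (a probe with m occurrences
contributes m points; a per-probe best-occurrence mode is available),
Pearson r with a two-sided p-value; fewer than 3 points or zero variance
is an error, not a number.

## The binding model

A protein is modelled by position-specific log-scale sequence weights
Φ (k × 4) and non-negative context weights Ψ (5), normalized to sum to 5
so the indifferent model has Ψ ≡ 1:

    score(w, a)   = exp(Σᵢ Φ[i, wᵢ]) · Ψ[a]
    score(s, π)   = Σ_windows exp(Σᵢ Φ[i, s_{t+i}]) · (p̄(t) · Ψ)

where p̄(t) is the window-mean context distribution.  Ψ is position-
independent within the window, and probes aggregate over windows by sum
(occupancy-style; max by flag).  The consensus (k-mer, context) maximizes
score; because the sequence part factorizes, the consensus k-mer is the
per-position argmax, with lexicographic tie-breaks (A<C<G<U, then context
order S,H,I,M,E) — verified against brute-force enumeration.  Preference
statistics at the consensus k-mer w use natural logs:
paired/unpaired = log(score(w,S) / max over {H,I,M,E}), and
loop/external = log(max over {H,I,M} / score(w,E)); the loop aggregate is
configurable (hairpin-only available by flag).  Both ratios are invariant
to the gauge freedom of adding a constant to a Φ row.

**Fitting** minimizes Σ(score − y)² + λ‖Φ‖² (λ default 1e-3) by L-BFGS-B
over Φ and log Ψ with box bounds (|Φ| ≤ 8, |log Ψ| ≤ 6) that keep the
exponentials finite.  Shifted-motif local optima are real in k-mer
landscapes, so the optimization is staged: a multi-start sequence-only
phase first (neutral start plus seeded random restarts), then the joint
fit warm-started at the best sequence solution with neutral context
weights plus random joint restarts.  The joint training objective
therefore never trails the sequence-only one, which matters for the
randomized-structure control (the structure weights must be free to learn
*nothing*).  `structure=False` pins Ψ ≡ 1.  The returned model is
gauge-fixed (Ψ summing to 5, compensated in Φ, predictions unchanged).
Fits require ≥ 50 probes and non-constant intensities.

## Evaluation

*In vitro*: train on Set A, predict Set B, Pearson r between predictions
and measured intensities after clamping outliers to mean ± 4 SD (z
configurable).  Clamping is a single pass; exact idempotence is impossible
once anything is clipped (the bounds themselves shrink), and iterating to
a fixed point degenerates on extreme one-sided outliers, so the single
pass is the defined behavior.

*In vivo*: positives are the central 40 nt of each peak; controls the
40-nt window starting 300 nt downstream of the peak end (strand-aware;
minus-strand cores are reverse-complemented and "downstream" runs toward
smaller coordinates).  Each core is folded with up to 150 nt of flank per
side, truncated at transcript bounds (no padding alphabet exists), and the
profile restricted to the core.  Peaks shorter than the core, and controls
out of bounds or overlapping their peak, are skipped and counted.  AUC is
the Mann–Whitney rank-sum form; ties contribute ½.

Paired per-experiment metrics are compared by the Wilcoxon signed-rank
test (two-sided default; a rank-sum variant is provided since both appear
in common use).  For the randomized-structure control the meaningful
question is one-sided — "does structure still improve prediction?" — and
only the one-sided form can return the p ≈ 1 that a null control should:
fitting five extra context weights on noise always costs a small,
consistent amount of held-out accuracy, so a two-sided test rejects at any
sample size even when the difference is negligible in magnitude.

## Structure-augmented affinity regression

RNA features extend k-mer occurrence counts (default k = 7) with five
context-weighted blocks: each occurrence adds, to every context column,
the mean probability of that context over its k positions, so the five
context features of a k-mer sum exactly to its count.  Protein features
are amino-acid k-mer counts (k = 4 default) over the observed vocabulary.
The interaction model predicts y_pq = d_pᵀ W f_q with W = ABᵀ of fixed
rank, fitted by alternating exact ridge updates in kernel form (each
update solves a small Sylvester system via eigendecompositions of the
P × P and Q × Q feature kernels).  Both kernels are normalized to unit
mean diagonal before the ridge is applied, and the normalization undone in
the returned factors: without this, the context blocks — which duplicate
the count signal — inflate the RNA kernel scale and make the same λ
under-regularize any augmented model, producing a spurious advantage even
for *randomized* context features.  AUPR for top-1%-vs-bottom-50%/99%
probe ranking uses the step-wise precision-at-each-recall estimator with
no interpolation.

## Synthetic data: what it emulates and what it does not

Generators are pure functions of seed and configuration.  Probes are
unique i.i.d.-uniform sequences, 30–41 nt, matching the probe design whose
structural variability the analyses quantify.  Intensities are planted
model scores plus Gaussian noise on the score scale.  The planted model
defaults to one consensus 5-mer at log-weight 1.5 per position and one
preferred context at weight 3 (of 5): strong enough that structure carries
real signal, weak enough that sequence alone does not saturate the
evaluations.  Pseudo-CLIP transcripts are uniform-random with the
consensus k-mer embedded either inside the loop of a designed GC-clamped
hairpin (`unpaired_loop`), inside one arm of a designed stem
(`paired_stem`), or bare (`any`); transcripts leave 400 nt downstream of
every site so the +300 nt control window always fits.  The protein panel
ties random amino-acid k-mers to random RNA k-mers through a planted
low-rank W; with structure loading, part of the RNA-side signal is a
context contrast (external minus stem) of the chosen k-mers, invisible to
count features.  The panel uses RNA 4-mers rather than 7-mers: at a few
hundred probes, distinct random probes share essentially no exact 7-mers,
the feature kernel degenerates to the identity and no regression method
could transfer to held-out probes; 4-mers keep every feature supported by
dozens of probes at this scale.

None of the generators emulate array-specific biases (spatial or dye
effects), crosslink-site biases, transcript expression, or competing
proteins.  Passing tests therefore demonstrate that the *methods* recover
planted sequence-and-structure signal under realistic folding, not that
real assays are free of the confounders listed.

## Problem sizes and numerical choices

The validation suite uses desk-scale versions of each analysis, chosen as
the smallest sizes at which the planted effects are statistically
unambiguous: 10,000 probes for the variability center; 2,000 probes for
sign recovery; 50 planted experiments (150 probes each) for the
preference-statistic distribution; 20 paired Set A/B experiments (400+400
probes) for the in vitro contrast; 200 peaks for the in vivo contrast; 20
seeded panel runs (20 proteins × 250 probes) for the regression contrast.
Enumeration is refused above length 22 (structure counts explode);
recursion-vs-oracle agreement is asserted at 1e-6 absolute.  Profile rows
are validated to sum to 1 within 1e-9.  All fits and generators take
explicit seeds; identical seeds give bitwise-identical outputs.

## Known limitations

The basic energy model ignores stacking and loop entropies, so its
*numbers* (unlike its math) are not comparable to Turner-energy outputs.
Local folding with W = 80 caps the structural horizon; long-range pairs in
real transcripts are invisible to both backends as configured.  The fitter
is a regularized least-squares stand-in for full k-mer model inference,
and the bilinear ridge a stand-in for similarity-space affinity
regression: both preserve the input/output contracts and the structural
feature construction, not the original algorithms' internals.  The
unstructuredness probability under the Turner backend is sampling-based
and carries O(1/√n_samples) error.
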