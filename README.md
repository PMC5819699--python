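# rbpstruct

RNA secondary-structure context analysis and sequence × structure k-mer
binding models for RNA-binding proteins (RBPs).

High-throughput in vitro assays of protein–RNA binding (RNAcompete-style)
measure binding intensities against hundreds of thousands of short RNA
probes that were *designed* to be unstructured.  Yet the Boltzmann ensemble
of even a 30–41 nt probe carries real structural variability, and that
variability correlates with protein binding.  `rbpstruct` provides a tested
pipeline to

* compute per-nucleotide base-pairing probabilities and full five-context
  structural profiles — stem/paired (S), hairpin loop (H), internal/bulge
  loop (I), multibranch loop (M), external (E) — with two interchangeable
  backends: a self-contained, exactly verifiable McCaskill-style partition
  function, and a ViennaRNA (Turner-energy) adapter equivalent to
  `RNAplfold -u 1 -W 80 -L 40`;
* quantify k-mer level structural variability (per-5-mer occurrence SDs of
  mean pairing probability) and correlate a k-mer's structural context with
  probe intensities;
* score, and fit by regularized least squares, sequence × structure k-mer
  binding models
  `score(w, a) = exp(Σᵢ Φ[i, wᵢ]) · Ψ[a]`,
  with structural-preference statistics (log paired/unpaired and
  loop/external score ratios at the consensus k-mer);
* evaluate binding prediction in vitro (Set A → Set B Pearson r with
  intensity clamping) and in vivo (peak cores vs 300-nt-downstream
  controls, 150-nt folding flanks, middle 40 nt, rank-sum AUC), including
  the randomized-structure negative control;
* build structure-augmented k-mer features (counts plus five
  context-weighted blocks) and fit a low-rank bilinear ridge regression
  from amino-acid k-mer content to RNA binding preferences;
* generate synthetic probes, intensities, pseudo-CLIP transcripts with
  sites planted in controlled structural contexts, and synthetic protein
  panels, so that every analysis is exercisable with no external data.

## Worked example

```python
import numpy as np
import rbpstruct as rb

# synthetic probes and Turner-energy structural profiles
probes = rb.random_probes(500, seed=1)
seqs = [p.seq for p in probes]
em = rb.EnergyModel(backend="turner")
profiles = rb.profiles_for_probes(seqs, em)

# intensities from a planted model preferring UGCAU in external context
planted = rb.default_planted_model("UGCAU", context="E")
table = rb.simulate_intensities(probes, profiles, planted, noise_sd=0.0, seed=2)

# fit a sequence x structure model and inspect it
res = rb.KmerBindingRegression(table.values, seqs, profiles, k=5).fit(seed=0)
print(res.summary())
r, p, n = rb.kmer_intensity_correlation("UGCAU", seqs, profiles, table.values)
print(f"UGCAU pairing vs intensity: r={r:.3f} (p={p:.2g}, n={n})")
```

Output:

```
Sequence x structure k-mer binding model
========================================
k:                  5
n probes:           500
structure weights:  fitted
objective (SSE+L2): 0.00955899
converged:          True (153 iterations)
consensus:          UGCAU in context E
Psi (S,H,I,M,E):    0.500, 0.500, 0.500, 0.500, 3.000
log paired/unpaired: -1.792
log loop/external:   -1.792
UGCAU pairing vs intensity: r=-0.572 (p=0.016, n=17)
```

The fit recovers the planted consensus k-mer and context weights exactly
(Ψ_E = 3 with the remaining weight spread evenly), the negative
paired/unpaired log-ratio says the protein prefers its k-mer unpaired, and
the negative occurrence-level correlation shows that probes whose UGCAU
sits in paired context bind less — the structural signal the pipeline is
built to detect.

A command-line interface mirrors the library (`rbpstruct annotate`,
`kmer-stats`, `fit`, `score`, `prefs`, `eval-invitro`, `eval-invivo`,
`simulate`, `ar-features`); see `rbpstruct --help`.

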