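# Methods

## Hidden-stop definition and frame conventions

A coding sequence is decomposed into in-frame codons starting at
nucleotide 0 (0-based, half-open coordinates throughout). Hidden stops
are stop triplets of the selected genetic code read in the shifted
registers:

* +1 frame — triplets starting at offsets 1, 4, 7, …;
* −1 frame — realised as offset +2 (offsets 2, 5, 8, …) within the same
  linear sequence. A bare CDS carries no upstream context, so the third
  register of the linear sequence is the standard surrogate for the −1
  shift.

Only complete triplets inside the sequence are scanned. Triplets
containing ambiguity letters (non-ACGT) are *masked*: excluded from both
the stop count and the position denominator. `hsc_frequency` is
therefore count / number of clean off-frame triplets scanned, a proper
rate in [0, 1] comparable across sequence lengths (length itself is not
a meaningful denominator since only every third offset is scanned). A
sequence shorter than 4 nt has no off-frame triplet and reports zero
positions rather than erroring.

Half-gene analysis splits the gene into codons [0, ⌊n/2⌋) and the rest;
a hidden stop belongs to the half containing its *starting* nucleotide,
which is unambiguous for junction-spanning triplets.

### Contribution scores

The per-codon contribution score operationalises "how much can this
codon participate in hidden stops". Across a dicodon junction, a shifted
stop triplet S overlaps the two codons in four possible roles; codon
c = n₁n₂n₃ scores one point for every (S, role) pair it matches:

| role              | condition        |
|-------------------|------------------|
| left partner, +1  | n₂n₃ = S[0..1]   |
| right partner, +1 | n₁ = S[2]        |
| left partner, −1  | n₃ = S[0]        |
| right partner, −1 | n₁n₂ = S[1..2]   |

Counting (stop, role) pairs rather than distinct stops is a design
choice; the definition is documented so users can compare against other
operationalisations in the literature. The score depends only on the
code's stop set.

## Codon-usage metrics

Usage counts pool all in-frame, unmasked codons across the input
sequences. The terminal codon of a sequence is dropped *iff* it is a
stop codon (default; switchable), since a CDS terminator is not codon
"usage"; internal stops, if present, are counted as given.

* RSCU(c) = count(c) / mean count over c's synonymous family; families
  with zero total count are reported as missing rather than 0/0.
* w(c) = count(c) / max count in family; stop codons are excluded.
  Zero-count codons are floored at w = 0.01 (configurable): a literal
  zero would collapse any downstream geometric mean, while 0.01 keeps
  "systematically avoided" codons strongly penalised. An entirely
  uncounted family gets the floor throughout, with a warning.
* CAI = exp(mean of ln w over the gene's eligible codons). Eligible
  means unmasked, not a stop, and not in a single-codon family (Met and
  Trp under the standard code), whose w ≡ 1 carries no information. The
  log-space form is required: the direct product underflows for genes
  beyond a few hundred codons.

A reference usage table can come from a codon/count TSV (two columns,
header optional, RNA letters accepted) or from a reference FASTA passed
through `codon_usage`.

## Coding-phase probabilities

For a window, each phase k ∈ {1,2,3} (start offsets 0, 1, 2) yields
complete codons whose reference frequencies multiply into a likelihood
fₖ; with a uniform prior over phases, Bayes' rule gives
pₖ = fₖ / (f₁+f₂+f₃). Implementation details:

* all products are log sums normalised with log-sum-exp, exact to
  rounding wherever the direct product does not underflow (tested
  against a direct-product oracle);
* codons with zero reference frequency are floored at 10⁻⁶ before the
  log — one unseen codon should dampen, not annihilate, a phase;
* incomplete trailing codons and masked codons are skipped;
* defaults: window N = 40 codons (span 3N+2 nt so every phase holds N
  codons), step 3 nt. These are package choices; sensible alternatives
  range from N = 20 (sharper localisation, noisier) to N = 100
  (smoother). The window must satisfy len ≥ 3N+2; windows start at
  0 … len−(3N+2) inclusive.

## Markov null models

Order-k chains (k ∈ {0,1,2}) capture mono-, di- and tri-nucleotide
statistics. Estimation is maximum likelihood with an additive
pseudocount (default 1) per transition; ambiguity letters break the
chain so no transition spans a masked base; contexts never observed fall
back to uniform. These are plain visible-state chains: the modelled
quantities are nucleotide k-mer statistics, for which hidden states add
nothing.

Simulation draws the initial context from the empirical context
distribution of the training data (avoiding an arbitrary fixed start)
and emits by inverse-CDF sampling from a `numpy` Generator, so output is
bit-for-bit reproducible per seed.

`hsc_null_comparison` trains on the query itself, simulates `n_sim`
(default 1000) length-matched sequences, and reports observed count,
simulated mean/sd, z-score, and a two-sided empirical p with the
add-one correction: p = min(1, 2·min(p_le, p_ge)) where each tail is
(1 + #as-or-more-extreme)/(n_sim+1). The correction keeps p > 0 under
finite simulation; when the simulated sd is 0 (degenerate chain) the
z-score is reported as missing. For an order-0 chain the exact
per-position hidden-stop rate is Σ_S ∏ⱼ P(S[j]); the simulator is tested
against this closed form.

## Correlation tests

Correlations are Pearson product-moment by default (the underlying
biological analyses are linear); Spearman is available as an option.
Significance uses t = r·√(n−2)/√(1−r²) with n−2 df at α = 0.05,
one-tailed:

* CUF vs contribution — tested for *positive* correlation (the ambush
  hypothesis predicts usage favours stop-prone codons). The pairing
  spans all 61 sense codons; codons absent from the input keep
  frequency 0 rather than being dropped, which would bias r on short
  genes.
* GC vs HSC frequency — tested for *negative* correlation (stop triplets
  are A/T-rich, so GC-rich genomes have fewer opportunities). Requires
  ≥ 5 sequences; x is the G+C fraction of unambiguous bases, y the
  both-frame hidden-stop rate per scanned position.

Both directions are switchable. Under the null (usage independent of
contribution) the one-tailed test must reject at the nominal 5% rate;
the acceptance script measures exactly this calibration with 2000
Dirichlet(1) replicate usage vectors.

## Synthetic-data generation

`generate_synthetic_cds` draws codons i.i.d. from prescribed weights.
With `forbid_internal_stops`, stop-codon weights are zeroed before
normalisation — distributionally identical to redrawing every stop draw,
and deterministic per seed. The generator reproduces prescribed codon
proportions exactly for deterministic weight vectors and within
multinomial error when sampled, and it underlies every test fixture: no
external sequence data is required anywhere.

What the generator does *not* emulate: real genes have amino-acid
composition constraints, autocorrelated codon usage, GC gradients along
the gene, and phylogenetic structure between sequences. Passing tests
demonstrate correctness of the computations and their calibration under
i.i.d. codon sampling, not biological conclusions about real genomes.

## Numerical and degenerate-input choices

* Frequencies, RSCU and w are exact ratios of counts; CAI and phase
  probabilities go through logs.
* Pearson r is undefined (error, not NaN) for zero-variance input or
  n < 3; |r| = 1 yields an infinite t flagged explicitly with p ∈ {0, 1}.
* Trailing partial codons are kept in the sequence (they can host part
  of an off-frame triplet near the 3′ end) but excluded from the codon
  list; validation flags, never rejects, so partial CDSs remain
  analysable.
* Report bundles are written with fixed table order and fixed float
  formatting (`%.10g`), so identical inputs and seed give byte-identical
  output.

## Problem sizes in the test suite

The suite runs entirely on generated data: scanner-oracle agreement on
1000 random sequences up to 3 kb; Markov closed-form check at 1000
simulations of 3 kb; k-mer recovery at 10⁵ nt; null-calibration at 2000
replicates. These sizes give standard errors small enough for the 3–4 SE
assertions used while keeping the whole suite around ten seconds.

## Known limitations

* The −1 frame of the *first* codon junction is approximated from the
  linear CDS; true −1 context upstream of the start codon is unknowable
  from a CDS alone.
* Contribution scores count combinatorial capacity, not realised usage
  in a particular genome.
* The Markov nulls preserve nucleotide statistics only — simulated
  sequences do not conserve the encoded protein.
* CAI quality depends entirely on the reference table; with small
  references many families hit the floor and CAI compresses upward.
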