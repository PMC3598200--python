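# hiddenstops

Analysis of hidden stop codons in coding DNA sequences.

A hidden stop codon (HSC; "off-frame stop", OSC) is a stop triplet that
appears when a coding sequence is read in the +1 or −1 shifted register.
Under the *ambush hypothesis*, hidden stops are selectively favoured
because they terminate accidentally frameshifted translation early,
sparing the cell the cost of producing aberrant, potentially cytotoxic
peptides. This package is for molecular-evolution and codon-usage-bias
researchers who want to quantify hidden stops in their sequences, relate
them to codon usage, and judge whether the observed counts exceed what
nucleotide composition alone predicts.

## What it computes

* **Hidden-stop scanning** in the +1 frame (triplets at nucleotide
  offsets 1, 4, 7, …) and the −1 frame (realised as offset +2 in the
  linear CDS), under any shipped NCBI genetic code table (1–6, 9–16,
  21–25 — stop sets differ between codes). Per-frame counts, positions,
  frequencies per scanned off-frame position, and a half-gene split
  (first vs second half of the codon sequence).
* **Per-codon contribution scores**: for a codon c = n₁n₂n₃, the number
  of (stop S, junction role) pairs across a dicodon junction in which c
  supplies part of an off-frame stop (e.g. suffix n₂n₃ = S[0..1] in the
  +1 frame). Depends only on the code's stop set.
* **Codon-usage statistics**: usage frequencies (CUF), RSCU,
  relative adaptiveness wᵢ = fᵢ / max f over the synonymous family, and
  the codon adaptation index CAI = (∏ᵢ wᵢ)^(1/L), the geometric mean of
  wᵢ over a gene's codons (computed in log space).
* **Correlation tests**: Pearson r between CUF and the contribution
  vector over the 61 sense codons, with the one-tailed t-test
  t = r·√(n−2)/√(1−r²) on n−2 degrees of freedom at α = 0.05; and, for
  5+ sequences, the correlation between G+C content and hidden-stop
  frequency (one-tailed for a negative trend — stop triplets are A/T
  rich).
* **Markov-chain null models** of orders 0–2 trained on the input
  sequence, resimulated to score the observed hidden-stop count with a
  z-score and an add-one-corrected empirical p-value.
* **Coding-phase probability profiles**: in a sliding window of N
  codons, the likelihood of each phase is fₖ = ∏ f(codonᵢ) under a
  reference usage table, and Bayes' formula pₖ = fₖ/(f₁+f₂+f₃) traces
  p₁/p₂/p₃ profiles whose peaks mark coding regions.

## Worked example

```sh
$ printf '>myGene\nATGTTAAAATGA\n>gcRich\nATGGCCGGCCTGGCGTGA\n' > demo.fa
$ hiddenstops run --fasta demo.fa --code 1 --out demo_out
wrote 7 files to demo_out
$ cat demo_out/hsc_summary.tsv
seq_id  hsc_plus1  hsc_minus1  hsc_total  n_pos_plus1  n_pos_minus1  freq_plus1    freq_minus1  first_half_plus1  second_half_plus1  first_half_minus1  second_half_minus1
myGene  1          0           1          3            3             0.3333333333  0            1                 0                  0                  0
gcRich  0          0           0          5            5             0             0            0                 0                  0                  0
TOTAL   1          0           1          8            8             0.125         0            1                 0                  0                  0
```

`myGene` (ATG TTA AAA TGA) carries one hidden stop: reading from offset
1 gives TGT **TAA** AAT, a +1-frame TAA starting at nucleotide 4, inside
the first half of the gene; the −1 register (GTT AAA ATG) is clean. The
GC-rich gene has none — its composition offers no A/T-rich stop
triplets off-frame. Three off-frame triplets were scanned per frame for
`myGene`, so the +1 frequency is 1/3.

```sh
$ cat demo_out/correlations.tsv
analysis             r               n   t_value        p_one_tailed  direction  significant_at_0.05
cuf_vs_contribution  -0.01902748584  61  -0.1461793562  0.5578609424  greater    0
```

Pooled usage of these two toy genes is uncorrelated with the
contribution scores (r ≈ −0.02, one-tailed p ≈ 0.56): no evidence here
that codon choice favours stop-prone codons, as expected for a
two-sequence toy input.

The same analyses are available as library functions
(`find_hidden_stops`, `codon_usage`, `cai`, `hsc_null_comparison`,
`phase_profile`, …); `hiddenstops codes` lists the shipped genetic code
tables, and `hiddenstops nullcmp` runs the Markov null comparison alone.

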