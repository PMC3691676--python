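# Methods

## Model and procedure

The package tests whether missense somatic mutations on one protein are
more spatially concentrated than expected by chance. The null model is
positional uniformity: each of the `n` observed mutations falls
independently on one of the `N` residues with probability `1/N`. The test
statistic is the span between order statistics of the mutation positions:
for the sorted positions `X(1) <= ... <= X(n)` and a pair `i < k`, the
span `C_ki = X(k) - X(i)` is small when the `k - i + 1` mutations between
them are packed into a short stretch.

Exact discrete span probabilities are replaced by the continuous limit:
after dividing by `N`, the span of uniform order statistics converges to
`Beta(k - i, i + n - k + 1)`, so the per-pair p-value is the regularized
incomplete beta function at `c`. All `n(n-1)/2` pairs are tested and
Bonferroni-adjusted (Benjamini-Hochberg optional); a pair is a cluster at
adjusted `p <= alpha`.

Because the test lives on a line but proteins fold, residues are first
remapped from 3D to 1D by metric multidimensional scaling on the
Euclidean Cα distance matrix, minimizing Kruskal's Stress-1 (the
representation function is the identity: Cα distances are already
metric). Order statistics need integer positions, so residues are
assigned ranks 1..N by their 1D coordinate; the uniform null is preserved
exactly on ranks. Clusters found in rank space are reported back in
canonical residue numbering as `(min, max)` of the residues they cover.

Across `k` structures, a second Bonferroni would be too conservative
(structures of one protein are nearly replicates), so each cluster's
p-value is restored to the raw scale, `P* = raw p x n(n-1)/2`, and
screened against a rough FDR threshold `rFDR = alpha (k+1) / (2k)`,
an approximation to FDR control for many positively correlated tests.
The screen is applied to all clusters of all structures in the run, and
`k` counts the structures actually analyzed in the current run. With
`k = 1` the screen reduces to the per-structure `alpha` rule.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.05 | significance level for adjusted pair p-values |
| `adjust` | `bonferroni` | pairwise multiplicity adjustment (`bh` optional) |
| `c_convention` | `span_plus_one` | Beta CDF evaluated at `(span+1)/N`; `span/N` optional |
| `mds_restarts` | 10 | SMACOF starts (classical scaling + 9 random) |
| `min_identity` | 0.6 | alignment identity floor for structure↔sequence reconciliation |
| `gap_open`, `gap_extend` | −10, −0.5 | affine gap penalties (BLOSUM62 score units) |
| `seed` | 0 | seeds every random draw in a run |

## Numerical and design choices

**Beta evaluation point.** The continuous CDF is 0 at `c = 0`, which
would make same-residue clusters (span 0) untestable even though a
residue hit many times is the strongest possible signal. We evaluate at
`c = (span + 1)/N`, the right edge of the discrete mass at `span`. This
upper-bounds the exact discrete probability (checked exhaustively for
`N <= 12`, `n <= 4`) — i.e. it is conservative in the direction of larger
p-values never being reported as smaller — and converges to the exact
value as `N` grows at fixed `span/N`. The approximation error is large at
small `N` (can exceed 50% relative for `N ~ 10`) and falls to ~10% by
`N ~ 100`; for realistic protein sizes it is accurate. `span/N` is
available for sensitivity analysis.

**Bonferroni divisor.** The divisor is the number of tested pairs,
`n(n-1)/2`, used identically in the adjustment and in the `P*`
back-multiplication so the two invert exactly. Adjusted p-values are not
capped at 1; capping would break the exact inversion and does not change
any significance decision.

**Exact oracle.** `pair_pvalue_exact` computes the discrete
`Pr(X(k) - X(i) <= span)` exactly by summing the joint pmf of the two
order statistics over value pairs, with the joint pmf obtained from
multinomial counts over five value regions (below/at/between/at/above).
Cost grows like `N * span * n^3`; it is guarded to `n <= 25`, `N <= 2000`
and meant for validation, not production scoring.

**1D MDS.** One-dimensional stress minimization is highly multimodal, so
SMACOF majorization is run from the classical (Torgerson) scaling
configuration plus random restarts, each followed by the closed-form
optimal dilation (Stress-1 as defined normalizes by the configuration
distances, so the best rescaling of a fixed shape is
`t* = Σδ²/Σδd`, giving `σ₁² = 1 − (Σδd)²/(Σd²Σδ²)`). The best candidate
by Stress-1 wins; the unoptimized classical configuration itself is a
candidate, so the result is never worse than classical scaling.
Convergence: stress-change tolerance 1e-9, 300 iterations max;
non-convergence returns the best iterate with a warning flag. Rank ties
(coincident coordinates) break toward the earlier canonical position.

**Reconciliation.** Global end-gap-free alignment (BLOSUM62, affine
gaps). Mismatched aligned residues stay in the mapping — point
substitutions between database sequences are common and harmless — but
overall identity below 60% (computed over the shorter sequence, so that a
short spurious overlap between unrelated proteins cannot pass) aborts
with a reconciliation error. Residues lacking a Cα atom, and mutations at
residues lacking coordinates, are excluded before testing; the linear
comparison run uses the same reduced residue set so 1D and 3D results are
comparable.

**Deduplication.** At most one mutation record per
`(sample_id, position, alt_aa)`; the caller is assumed to have harmonized
sample/cell-line identifiers across studies.

## Synthetic data

The generator produces geometrically plausible toy backbones: collinear
chains at the standard 3.8 Å Cα–Cα virtual bond length; ideal α-helices
(rise 1.5 Å/residue, 100°/residue, radius 2.3 Å); β-hairpins (two
antiparallel 3.8 Å strands 5 Å apart, so residues `i` and `N-i+1` are
spatial neighbors); and self-avoiding random coils (3.8 Å steps, 3.5 Å
clash distance). Mutation tables are drawn at residue level from the
uniform null or from a hotspot mixture in which designated residues carry
extra probability mass (total ≤ 1) and the remainder is uniform; sample
identifiers are assigned round-robin. Writers emit the same PDB/TSV/FASTA
dialects the pipeline parses, so synthetic fixtures exercise the real
readers.

What the generator does not emulate: sequence-dependent mutability (CpG
transitions, APOBEC context), nucleotide-level processes, real side-chain
packing, crystallographic disorder beyond simple missing residues, and
inter-structure correlation of real multi-structure proteins. Passing
calibration on synthetic data therefore shows the statistic is controlled
under its stated null, not that the uniformity assumption holds for any
particular gene.

Monte-Carlo calibration (`run_simulation`) draws mutation positions and
applies the all-pairs test directly on linear positions via a vectorized
batch path (cross-checked in the suite against the per-replicate code
path). Default calibration conditions used by the suite: `N = 200`,
`n = 10`, 5000 replicates, `alpha = 0.05`; the family-wise error rate
stays below `alpha` plus Monte-Carlo noise, reflecting the double
conservatism of Bonferroni and the upper-envelope Beta evaluation.

## Limitations

- The Beta approximation is anti-conservative nowhere but can be very
  conservative for small proteins or spans; exact evaluation is available
  only at validation scale.
- Rank linearization discards the magnitude of 1D gaps: two residues far
  apart on the embedded line are adjacent in rank if nothing falls
  between them. This is the price of keeping the uniform null exact.
- A 1D embedding of a globular domain necessarily distorts some
  distances (Stress-1 is reported for every run); clusters on strongly
  distorted structures should be inspected against the 3D structure.
- Overlapping significant pairs are reported individually, not merged,
  so cluster counts measure significant pairs, not disjoint regions.
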