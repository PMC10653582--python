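# Methods

This note documents the models and procedures implemented in `mutland`, the
parameters that matter, the design choices made where the design was open,
and what the synthetic-data tests do and do not demonstrate.

## Alignment model and preprocessing

Alignments are query-anchored: row 0 is the query, and columns where the
query carries a gap are removed at read time (the A3M convention, applied
uniformly to FASTA and Stockholm input), so every downstream quantity is
defined over the L query positions. A3M lowercase letters are insertion
states relative to the query and are dropped; Stockholm `.` is read as a
gap.

Undefined residues (X, U, and the ambiguity codes B and Z, which we treat
identically because their resolution semantics are the same) are replaced
by the most frequent canonical amino acid in their column, counting all
rows and excluding gaps, with ties broken alphabetically so the edit is
deterministic. A query position whose non-query column is entirely gaps —
the typical signature of an undefined leading residue that nothing aligned
to — is removed instead, shortening the query; every edit is logged as
(row, original position, old, new). The procedure is idempotent. The
replacement rule is applied to all rows, not only the query: non-query
undefined symbols would otherwise leak into frequency and distance
calculations.

Two policy gates run before prediction. Queries of at most `min_query_len`
residues (default 20) are skipped as too short to treat as proteins.
Alignments with fewer than `shallow_msa_threshold` sequences (default 200)
trigger an advisory to regenerate the MSA without the diversity-filter step
of the search protocol; the regeneration itself requires the external
search tool and is deliberately out of scope, so the flag is recorded in
the run report for external scripting.

## Alignment depth

Sequence weights follow the standard redundancy correction:
`π_s = 1 / #{t : D_H(s, t) < θ_ID}` with a strict inequality, the sequence
itself always counting (self-distance 0), so `π_s ∈ [1/N, 1]` and
`Neff = Σ π_s ∈ [1, N]`. The normalized Hamming distance counts a gap
against a residue as a mismatch and a gap against a gap as a match; the
latter is required for `D_H(s, s) = 0` on gapped rows. The strict
neighborhood test divides the mismatch count by L before comparing, so it
agrees bit-for-bit with `D_H < θ_ID` at boundary values such as 8/40 vs 0.2.

`θ_ID` defaults to 0.2 for human/eukaryote/prokaryote queries and 0.01 for
viral ones, where families are dominated by nearly identical strains and a
wider neighborhood would collapse Neff to 1; unknown taxa get the non-viral
default 0.2. `Lcov` counts columns whose gap fraction over all rows is
strictly below 0.30. Depth classes use `Neff/Lcov` by default (`Neff/L` is
also reported and can drive classification instead): ratio < 1 low,
ratio > 100 high, medium otherwise — the band definitions are strict
inequalities, so the boundary ratios 1 and 100 fall in medium.

The pairwise computation is exact and O(N²L); it is processed in row blocks
of 2048 purely to bound memory, with results independent of the block size.

## Conservation on the sequence tree

The tree is an average-linkage agglomerative hierarchy on the pairwise
Hamming-distance matrix. Average linkage resists the chaining that single
linkage exhibits on near-duplicate-heavy (e.g. viral) alignments; the
linkage method is a config knob. Because Hamming distances are multiples of
1/L, exact ties are common, and tie resolution in a linkage algorithm
depends on input order. Rows are therefore sorted lexicographically before
clustering: ties resolve by sequence content, and the tree — hence the
conservation profile — is invariant under permutation of the input rows by
construction.

A site is conserved when it segregates cleanly along the topology: at
least two anciently diverged subtrees, each internally homogeneous at the
site. "Ancient origin" has no agreed quantitative definition, so this
package operationalizes it as a height scan: merge heights are undone from
the root downward, each height h inducing a partition into subtrees, and
the conservation level of site i is `h*/h_root`, where h* is the greatest
height at which at least two subtrees of size ≥ m_min are each homogeneous
at i. Homogeneity ignores gaps, but a subtree that is all-gap at the site
carries no evidence and does not qualify; a column that is entirely gaps
below the query scores 0. A column in which all rows display one identical
residue scores exactly 1, and levels are bounded in [0, 1]. Degenerate
cases: a single-sequence alignment, or one with all rows identical, scores
1 everywhere (the shallow-MSA failure mode is handled upstream by the
pipeline policy, not here).

`m_min`, the smallest subtree admitted as homogeneity evidence, defaults to
`max(2, ceil(0.025 N))`. Two is the principled floor — a singleton leaf is
trivially homogeneous and says nothing about segregation — and the mild
scaling with N discounts accidental sister-pair homogeneity in large
alignments. Substantially larger gates degrade the estimator rather than
sharpen it: demanding two perfectly homogeneous clades of 5% of N makes
most moderately constrained sites score exactly 0, because a single
homoplasy anywhere in a large clade breaks strict homogeneity; the profile
then flattens into a zero-inflated mass instead of grading constraint.

## The landscape

For substitution b at position i, the evolutionary distance
`δ(i, b) = min_{s : x_i(s) = b} Σ_j c_j · 1[x_j(s) ≠ q_j] / Σ_j c_j`
is the least conservation-weighted change that accommodates the mutation;
the query is its own witness, so `δ(i, wt) = 0`, and a witness gap against
a query residue counts as a mismatch, consistent with the depth module.
If the profile is identically zero (no conserved signal anywhere), the
weighting falls back to uniform so the distance structure still ranks
substitutions.

Unobserved substitutions are imputed from the reduced alphabet. The shipped
table has 11 physicochemical classes — {AG} {ST} {P} {C} {DE} {NQ} {H} {KR}
{ILMV} {FY} {W} — grouping residues whose exchange is typically
conservative while keeping proline, cysteine, histidine and tryptophan
apart; the table is configurable. If another member of b's class is
observed at i, `raw(i, b)` is the minimal class-member distance plus a
penalty κ (default 0.2 · δ_max, with δ_max the largest observed distance in
the landscape); if not, `δ_max + κ`. The wild-type residue's own
zero-distance cell is masked out of the class minimum: the query's residue
is not evidence that its class tolerates substitution, and without that
mask an alignment with no variability at all would implausibly favor
same-class substitutions. Per-column weighted frequencies (pseudocount λ,
default 1 per class, gaps excluded from the denominator) are computed for
both the reduced and the full 20-letter alphabet; an optional blend weight
α (default 0) mixes a class-rarity term into the raw effect, kept as a
config point because the distance-dominant form is the documented default.

Final scores are `S(i, b) = −c_i · raw(i, b)`, with wild-type cells pinned
to exactly 0 and the whole matrix rescaled so its minimum is exactly −1.
Only ranks are meaningful — evaluation is rank-based, so sign and scale
conventions cancel. Multi-substitution variants score as the sum of their
single-substitution cells; additivity is the minimal documented default
and a config point, not a claim about epistasis.

## Evaluation protocol

Spearman ρ uses average ranks for ties; a constant input raises an
undefined-correlation error rather than reporting 0, so missing values stay
distinguishable from true zero correlation. `evaluate` excludes (and
counts) variants that fail to parse against the query or touch positions
outside the evaluated region — never silently scores them — and requires at
least two scoreable variants. Aggregation is two-stage: DMS experiments
average within their target protein first, then target means average within
each group (taxon, depth class), mirroring benchmark tables that weight
proteins rather than experiments; the flat per-DMS mean is emitted
alongside, and when exactly two protocol labels are present the per-target
paired mean difference Δρ̄ is reported, with unpaired targets an error.

The redundancy filter de-duplicates benchmark proteins from precomputed
pairwise records: a pair is redundant when identity reaches the cutoff
(default 0.2, configurable — no canonical value exists), except that
alignments shorter than 50 residues are ignored for pairs of sequences both
at least 180 residues long, preventing spurious short local alignments from
knocking out long proteins. Retention is greedy in input order. Generating
the pairwise alignments themselves is out of scope; the operation consumes
records.

## Synthetic data: what it emulates and what it does not

The generator evolves sequences down a pure-birth (Yule) tree from a random
root, which doubles as the query. Substitutions are proposed per site as a
Poisson process along each branch (`branch_scale` expected proposals per
site per unit branch length, default 1.0 with birth rate 1.0 — roughly
five proposals per site root-to-tip at N = 200, enough to randomize free
sites while leaving tree signal) and accepted with probability 1 − κ_i,
the per-site constraint (drawn uniform on [0, 1] unless specified). The
matched DMS table scores each substitution at site i as
`−κ_i · effect_size + N(0, dms_noise_sd)` (defaults 1.0 and 0.1). Depth
presets realize the three Neff/Lcov bands — low (N = 40 similar sequences
over L = 60, so Neff ≤ 40 < Lcov), medium (N = 300 divergent, L = 50,
ratio ≈ 5), high (N = 1500 divergent, L = 10, ratio ≈ 140) — and are
verified at generation time. All randomness flows through the spec's
single seed; a fixed seed reproduces the FASTA byte for byte.

The generator deliberately omits indels (so simulated alignments are
gap-free and Lcov = L), site-correlated epistasis, codon structure,
compositional bias and realistic phylogenies with rate variation. Passing
tests therefore demonstrate that the estimators recover the constraint
structure the generator encodes — not that they reach any particular
accuracy on real protein families, where alignment quality, gap structure
and epistasis all intrude.

## Problem sizes and numerical choices

The ground-truth recovery study runs 20 simulated alignments at N = 200,
L = 50 — large enough for stable tree estimation, small enough to keep the
whole study in seconds. The brute-force weight oracle covers 100 random
alignments at N ≤ 50, L ≤ 40 with exact (bitwise) equality required.
Landscape normalization pins wild-type cells before rescaling, so −1 and 0
are exact, not approximate; the neighborhood test in the weights divides
before comparing so boundary distances classify identically in the fast
and brute-force paths; all tie-breaks (undefined-residue replacement,
tree construction) are content-based and deterministic.

## Known limitations

Conservation levels quantize to the tree's merge heights, so very similar
constraints can share a level; the height-fraction definition of "ancient"
is one of several defensible choices. The class-fallback penalty κ is a
stand-in for the original method's behavior when a substitution is
unobserved, which is not recoverable in detail from the published
description. Scores are comparable within one landscape but not calibrated
across proteins; only ranks should be consumed. The O(N²) weight and tree
computations are exact but become the bottleneck above a few tens of
thousands of sequences.
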