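# Methods

This note documents the models and procedures implemented in paxkit, the
parameters that matter, the numerical conventions adopted where several
were defensible, and what the synthetic benchmarks do and do not
demonstrate.

## Quantification model

Both quantification routes assume that a protein's chance of being
observed by the mass spectrometer is proportional to how many of its
tryptic peptides fall inside the instrument's detectability window, so
dividing by that quantity removes protein-length bias.

*Digestion.* Complete tryptic digestion: cleavage C-terminal to K or R,
suppressed before proline (Keil rule), zero missed cleavages. The
detectability window defaults to 6–30 residues, the standard convention
for intensity-based absolute quantification; it is exposed as
`--min-len/--max-len` because instruments differ.

*Protein-centric route (iBAQ-style).* `raw(p) = I(p) / N_obs(p)` where
`I` is the group's summed precursor intensity and `N_obs` the observable
peptide count. Multi-member protein groups resolve to the first member
found in the proteome (the majority-leader convention used by group-based
search engines); the remaining members are discarded. Groups with no
mappable member, and proteins whose sequence yields no observable peptide,
are dropped and counted in the run report.

*Peptide-centric route (length-normalized).* `raw(p) = Σᵢ qᵢ·Lᵢ / L_obs(p)`
with `qᵢ` a peptide's intensity *or* spectral count, `Lᵢ` its length, and
`L_obs` the summed length of the observable peptides. "Corrected length"
is interpreted as this observable-only total: residues that complete
digestion can never place inside the window contribute nothing to the
denominator. This interpretation is a design choice — the alternative
(full sequence length) differs only by a protein-specific constant and
would change absolute ppm slightly but not the methodology.

*Normalization.* `ppm(p) = 10⁶ · raw(p) / Σ raw`. Proteins reported with
zero intensity are kept as explicit 0 ppm — quantified-but-undetected is
informative for integration and distinct from absent. The normalization is
scale-invariant, so unit differences between instruments cancel.

*Filters.* `CON_`/`REV_` prefixes (contaminants, reversed decoys) are
removed on the group id or any member id; peptide FDR threshold 0.01,
inclusive, with unscored peptides kept (assumed pre-filtered). All filters
are idempotent and log removal counts.

## Interaction z-score

Let `E` be the network edges with both endpoints quantified at > 0 ppm,
and `m_obs` the median of `|log₁₀(ppmₐ/ppm_b)|` over `E`. The null
distribution is produced by permuting the abundance values across the
quantified proteins (the network stays fixed) `n_shuffles = 500` times and
recomputing the median. Then

```
z = (mean(null) − m_obs) / sd(null)
```

so a dataset whose interacting pairs are *more* similar than chance scores
large and positive. Conventions fixed here because the statistic only
specifies "z-score of the observed median against the shuffled
distribution":

- sd uses the sample (n−1) denominator;
- the median of an even count is the mean of the two central values
  (numpy convention);
- log base 10, cosmetically: base and global rescaling cancel exactly in
  the ratio/median/z pipeline (asserted numerically to < 1e-9, and exposed
  via a `log_base` argument so the invariance is directly checkable);
- zero-ppm proteins are excluded (log undefined); shuffling permutes over
  the quantified set only, not the whole proteome, since the labels being
  shuffled are those of the dataset;
- protein ids are sorted before permutation and a named seeded generator
  (`numpy.random.default_rng(seed)`) is used, making the score
  bit-reproducible given (dataset, network, seed); the seed is stored in
  the result.

Degenerate cases raise: no quantified edge ("network does not overlap
dataset"), all shuffled medians identical ("degenerate null").

The tissue-specificity z-score standardizes each gene's
`log₁₀(ppm + 1)` row across tissues with the n−1 denominator; genes
constant across tissues get a zero row (flagged) rather than NaNs.

## Dataset integration

Datasets are scored, sorted by z descending (ties broken by name so input
order never matters), and merged greedily. Each remaining dataset is tried
at every weight of an 11-point grid {0.0, 0.1, …, 1.0} — "equally spaced
weights from 0 to 100%" is realized with both endpoints on the grid so a
useless dataset can be skipped (w = 0) and a dominant one can replace the
merge (w = 1). The candidate with the highest z wins; ties prefer the
smaller weight (the established merge). The same shuffle seed is used for
every candidate within one integration so weight selection compares like
with like.

`combine(a, b, w)` blends proteins present in both datasets in log space,
`10^((1−w)·log₁₀ a + w·log₁₀ b)` — a weighted geometric mean, appropriate
for log-distributed abundances — and carries one-sided proteins scaled by
their side's weight mass ((1−w) or w), then renormalizes to 1e6. The
boundary weights return exact copies. An arithmetic-mean variant was
considered and rejected as the default because it lets a single
high-abundance outlier dominate the merge; the log-space form treats
fold-changes symmetrically.

Because w = 0 is on the grid, the integrated z-score can never fall below
the best single dataset's z-score under the same seed — verified across
20 synthetic trios. The greedy search is cross-checked against brute-force
enumeration of every weight combination on the same grid (step-wise
scored, same seed); note that a greedy procedure is not guaranteed to
reach the global optimum of the *final* score over all weight
combinations, and empirically does not always do so — the procedure is
defined as the greedy one, and the exhaustive enumeration verifies its
implementation, not global optimality.

## Ortholog-domain usage analysis

Only strict one-to-one ortholog pairs enter; complex orthology groups are
excluded. Domains are extracted as 1-based inclusive subsequences and
aligned pairwise per shared domain name; when a domain type has several
instances, every cross-product is aligned and only the highest-scoring
instance pair is kept (ties: first annotated wins). Alignments below 40%
identity are dropped.

*Alignment.* Global Needleman–Wunsch with affine gaps via
`Bio.Align.PairwiseAligner`: BLOSUM62, gap open 10, gap extend 0.5 (the
EMBOSS needle/needleall defaults), first gap residue charged the open
penalty and each further residue the extend penalty, end gaps penalized
(strict global mode). Percent identity is identical columns over the full
alignment length, gap columns included in the denominator (EMBOSS
convention). Sequences may contain the 20 standard residues plus X
(scored as unknown by the matrix); anything else is an error. The
implementation is verified against exhaustive enumeration of all gapped
alignments for short sequences. The same aligner drives reciprocal
best-hit mapping (90% identity in both directions, ties for best hit
disqualify — no one-to-one claim on ambiguous evidence).

*Usage ratio.* Residues of interest ({C}, {M}, or {C, M}) are counted
among the ungapped residues of each aligned domain string; a pair lacking
the residue on either side is excluded (a ratio with a zero is neither
defined nor informative). Each qualifying domain pair contributes one row
by default; an `aggregate` flag averages ratios per ortholog pair instead,
since it is defensible either way and the choice affects effective sample
size.

*Correlation and presentation.* Spearman rank correlation (average ranks
for ties, two-sided p via the t approximation, `scipy.stats.spearmanr`)
between ratio and the abundance of the designated abundance-side protein.
The abundance dataset and side are explicit arguments — analyses of many
query species against several references all draw abundance from one
well-measured species. For plots, rows are sorted by abundance and split
into six near-equal bins (sizes differ by ≤ 1) with per-bin median and
quartiles. Correlation matrices across species carry significance stars at
p < 0.01 (*), < 0.001 (**), < 0.00001 (***).

## Synthetic data

The generators define the study conditions for all tests; each is a pure
function of (config, seed) with an independent substream per generator.
Defaults: 300 proteins, lengths ~ N(350, 120²) floored at 30, uniform
residue frequencies (the simplest null for composition analyses),
log₁₀ ppm ~ N(1.5, 1²) before renormalization (several orders of magnitude
of dynamic range, as real proteomes show), network density 1% of possible
pairs, peptide noise sd 0.2 in log₁₀ (about ±60% multiplicative error),
background ortholog substitution rate 5%, domain length 100.

Networks are drawn by rejection sampling: a candidate pair is accepted
with probability `exp(−c·|Δlog₁₀ ppm|)` with `c = edge_consistency`; c = 0
gives uniform random edges (the calibration null — z should then be an
approximately standard normal deviate), and c = 3 is used as the
"consistent network" condition, giving z-scores far above 5 at the default
density. The planted sulfur depletion replaces each C/M in the query-side
domain with leucine with probability `1 − 10^(−β·q)`, q the protein's
abundance quantile, so the expected log₁₀ ratio of the most abundant pair
is −β; β = 0.5 with 500 pairs is the detection condition and β = 0 the
specificity condition.

What passing these benchmarks shows: the pipeline arithmetic, filters,
search procedures, and statistics behave exactly as specified on data with
known structure, at realistic sizes and noise. What it does not show:
robustness to real mass-spectrometry pathologies (ionization bias,
missing-value structure, shared peptides between paralogs), to biased
residue composition, or to real network topology — the generator models
none of these.

## Problem sizes and numerics

The benchmark suite uses 120–500 protein proteomes, 500-shuffle nulls for
single scores and 100–200 for the integration grids, 100 calibration
seeds, 20 detection and 50 specificity seeds, and brute-force alignment
oracles up to length 8 — sizes at which every oracle is exact or every
stochastic rate estimate is stable, while the whole suite runs in minutes.
Floating-point conventions: ppm conservation is asserted to 1e-6 relative;
bit-level reproducibility is asserted for the z-score given a seed;
z-score invariances to scale and log base hold to < 1e-9 (they are exact
in real arithmetic). Degenerate inputs raise informative errors rather
than returning NaN: empty digests, all-zero abundance maps, non-overlapping
networks, constant ranks, constant tissue rows (the one case handled with
a flagged zero row instead, since a constant gene is common in wide
expression matrices and should not abort a whole analysis).

## Known limitations

- Protein groups sharing peptides are resolved by the leader heuristic;
  no peptide-level reassignment across groups.
- Binary vendor formats are out of scope; tables must be pre-extracted to
  TSV.
- The interaction network is unweighted; any confidence cutoff is applied
  by the user when producing the edge list.
- Integration assumes all datasets share one identifier namespace; no
  cross-namespace mapping happens inside `integrate`.
- The greedy weight search optimizes each merge step locally (by design);
  it does not guarantee the globally optimal weight vector.
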