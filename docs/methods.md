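# Methods

## Model and assumptions

The unit of analysis is a (track, mutation cohort) pair. A track W assigns
weights w_j ∈ [0, 1] to a subset of a protein's 1-based positions; the score
of the cohort's missense mutations against the track is S_W = Σ f_i z_i,
with f_i the mutation's subclonal fraction (read support) and z_i the track
weight at its position. The null model treats mutation positions as i.i.d.
draws from a per-position background λ renormalized over the track; the
score's mean and variance then follow in closed form from the first two
moments of the weight of a single draw, scaled by Σf and Σf². This
replaces position-shuffling permutation tests exactly in expectation and
removes their sampling noise; the trade-off is that significance rests on a
normal approximation to S_W, which is why the minimum-mutation calibration
below exists.

Key assumptions, and when they fail:

- **Independent mutation placement.** Mutations across samples are placed
  independently given λ. Kataegis-like clustered mutational processes
  violate this and would inflate Z scores.
- **Conditional covariance.** The covariance between two overlapping track
  scores is computed conditional on the q mutations observed in the overlap
  (q and F = Σf² come from the data, not from expectations). With no shared
  mutations the covariance is exactly 0.
- **Whole-gene independence.** The whole-gene statistic measures *how many*
  mutations a gene receives; subgene statistics condition on that count and
  measure *where* they fall. Under multinomial nulls the two are
  independent, so the whole-gene/subgene covariance is fixed at 0.

## Backgrounds

**Codon-level λ.** Each codon's unnormalized missense rate sums, over its
three sites, (bias factor) × (number of amino-acid-changing substitutions at
that site), where the bias factor is 1 for A/T and b for C/G. Nonsense and
synonymous changes contribute nothing. b defaults to 3.063 — the pan-cancer
relative frequency of C/G versus A/T mutations — and is an input constant,
never re-estimated. When no coding sequence is supplied for an isoform the
background over its tracks falls back to uniform (logged).

**Whole-gene λ.** From an individual × gene variant-count table: per
individual, genes are min-ranked ascending by count, ranks scaled as
(rank − 1)/(N − 1) (so they span [0, 1] exactly), floored into 0.01-wide
bins, averaged across individuals, then normalized. A floor of 1e-4 is
added before normalizing so the least-variable gene does not get λ = 0,
which would make any observed mutation there infinitely surprising. Tied
counts share the minimum rank; duplicating an individual leaves λ
unchanged.

## Track construction

- Interaction tracks transfer per-match-state ligand binding frequencies
  from domain annotations; positions with frequency 0 remain in the track
  (they inform the background mass).
- Domain tracks span the protein with 0/1 weights.
- Conservation weights are (non-gap fraction) × base-2 Jensen–Shannon
  divergence (equal ½ mixtures, no pseudo-counts) between the column's
  empirical amino-acid distribution and the BLOSUM62 marginal frequencies
  shipped with the package. The JSD variant is bounded in [0, 1], which the
  track contract requires; sequence-weighted or pseudo-counted estimators
  are deliberately not the default (the plain estimator is transparent and
  the weights only enter relatively).
- Families with ≥ 2 instances get an aggregate track pooling instance
  positions, taking the **maximum** weight where instances overlap
  (preserves the strongest binding signal); families with ≥ 40 instances
  are represented by their aggregate alone.

## Calibration and combination

**Minimum mutation count.** For each track, 1000 replicate score sums are
grown one mutation at a time (positions from λ^W, f ≡ 1) and Shapiro–Wilk
tested at each n up to 500; n* is the smallest n at which normality is no
longer rejected at p ≥ 5e-5, with 3 consecutive non-rejections required to
guard against single-n noise. Tracks that never pass are excluded
("never-normal"); constant-weight tracks are excluded up front. During a
fit the scan is capped at the track's observed mutation count — if no
n ≤ n_obs passes, the track is excluded either way, so the capped scan gives
the identical decision at a fraction of the cost. The full 500-deep
precompute remains available (`PerturbationModel.calibrate()`), cached by a
content hash of (weights, λ^W, parameters); the calibration random stream is
derived from that hash plus the seed, so results are independent of
calibration order.

**Confidence weights.** The four track groups present split the overall
confidence equally (absent groups' shares are redistributed — the
alternative, leaving shares idle, would penalize genes merely for lacking
annotation). Within the interaction and domain groups, c_i ∝ √m_i
(configurable to ∝ m_i); the root keeps small-but-precise interface tracks
competitive with long domain tracks.

**Combined score.** Z = Σc_iZ_i / √(c'Rc) over the included tracks, with R
the analytic correlation matrix (clipped to [−1, 1], projected to the PSD
cone in the rare numerically indefinite case). By default only tracks with
Z > 0 enter (k counts those) — the reporting rule for ranking candidate
genes. That positivity screen is a selection step, not part of the null
model: conditioning on Z > 0 forces the combined statistic's null mean to
≈ 0.8 regardless of k, so *null calibration* of the combination is assessed
with `positive_only=False`, where every calibrated mutated track combines
and the statistic is standard normal under the null (verified: |mean|
< 0.1, SD within [0.85, 1.15] on 2,000 synthetic null genes). Ranking uses
the positive-only rule unchanged.

**Whole-gene statistic.** One-hot simplification S = s·Σ_{i∈G} f_i,
E = s·λ_g·Σf, var = s·λ_g(1 − s·λ_g)·Σf², with subsample factor
s = 1/√n (n = cohort mutation count, configurable) so cohort-scale counts
do not swamp subgene signals; its null SD is therefore ≈ √s by design
(conservative). The Shapiro scan cannot certify a one-hot track with
λ_g ~ 1e-4 at 500 mutations, so admission uses the Bernoulli-sum rule of
thumb n·λ_g ≥ 10 instead. Genes absent from the variant-count universe
simply have no whole-gene track; their subgene tracks still combine.

**Gene score.** Maximum combined Z over the gene's isoforms, ties broken by
lexicographic isoform id for deterministic output.

## Mutation input and filtering

Mutation classes are matched case-insensitively through a MAF alias table;
silent and nonsense records are parsed and retained for reporting but never
scored. A missing subclonal fraction defaults to 1. With an expression
matrix supplied, mutations in genes expressed below 0.1 TPM in their sample
are removed (strictly below; 0.1 itself passes); samples absent from the
matrix fall back to the gene's mean TPM across other samples of the same
cancer type, and genes absent from the matrix pass (the filter removes only
genes with evidence of non-expression). FPKM input is converted to TPM
per sample.

## Synthetic data: what it emulates, and what it does not

The generator produces, per gene: a random coding sequence (hence a
codon-level λ with the C/G bias), two domain families whose match states
carry both a 0/1 domain track and an interaction track with
binding-frequency-like Beta(0.5, 0.5) weights, and a full-length
conservation track whose weights mix a Beta(2, 2) base with the position's
interaction weight (coefficient 0.5) — ligand-binding residues are
evolutionarily constrained, and this coupling is what makes the
between-track correlation correction do real work. Subclonal fractions are
uniform on (0.2, 1.0]. Null genes draw positions from λ; enriched genes
draw from λ multiplied by an effect (default conditions: 5×) on positions
with interaction weight ≥ 0.5. Mutation counts are either fixed per gene
(default 30, the planted-driver study condition) or multinomial across
genes ("background" mode, used for null-calibration studies so the
whole-gene count model is coherent). An individual × gene Poisson
variant-count table feeds the whole-gene background.

Not emulated: trinucleotide mutational signatures, indels and copy number,
sample-level mutation-rate heterogeneity, correlated (kataegis) placement,
and real domain architecture. Passing tests therefore demonstrate the
statistics are correct and powerful *under the stated model*, not that the
model captures every property of tumor sequencing data.

Study sizes used by the test suite and acceptance script — 50 oracle
fixtures at 20,000 shuffles; 1,000 precompute fixtures; 2,000 null genes
and 1,050-gene planted-driver cohorts at 30 mutations/gene — were chosen to
make Monte-Carlo error small relative to the tolerances being checked.

In the planted-driver evaluation the natural-variation input is omitted:
with counts fixed at 30 per gene the whole-gene statistic carries no signal
by construction and only adds noise to the combination.

## Numerical choices and degenerate inputs

- λ^W normalization asserted to 1e-12; λ restricted to an overlap X is
  renormalized over X (consistent with λ^W).
- Tracks with fewer than two distinct weights (or zero background mass over
  their positions) are degenerate: no Z, excluded, reported with a reason.
- Correlations are clipped to [−1, 1]; an indefinite correlation matrix is
  projected to the nearest PSD correlation matrix; a non-positive combined
  denominator raises with diagnostics rather than returning a value.
- Empty mutation sets give S = 0 with undefined Z; unscored genes are
  reported with no combined Z and rank below all scored genes.
- The normalized entropy uses K = all positively weighted interaction sites
  (not only mutated ones), so concentration is penalized against the full
  interface; the normalized value is independent of the log base. K = 1
  gives entropy 0.

## Known limitations

- Combined Z scores are a ranking statistic; they are not converted to
  p-values or FDR across genes.
- The background does not model trinucleotide signatures; a strong
  signature mismatched to the codon model can bias per-track Z.
- Domain (0/1) tracks require large mutation counts to pass the normality
  calibration — Bernoulli sums converge slowly — so in small cohorts the
  domain group often cannot contribute, exactly as the calibration intends.
- Conservation tracks built from small alignments use the plain JSD
  estimator; no small-sample correction is applied.
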