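# Methods

## Scope and data model

The package analyses sets of full-length ORFs: coding sequences that begin
with AUG, end with UAA/UAG/UGA, have length divisible by 3 and contain no
internal stop. All sequences are held internally as RNA codons (DNA input
is accepted and T mapped to U on read; any non-ACGU letter becomes N).
Codon counting for every downstream index excludes each ORF's start AUG
and terminal stop unless explicitly requested otherwise; internal AUG and
UGG codons are counted but carry no CAI weight and are excluded from GC3s.

## Filtering

Quality filtering of transcriptome-derived ORFs applies, in a fixed order
(first matching rule wins, so the report is independent of input order):

1. `not_full_length` — frame, start or stop violated;
2. `ambiguous_nucleotide` — any N;
3. `too_short` — length ≤ 300 bp (the default threshold `min_length_bp =
   301`; since valid ORFs are codon multiples this effectively keeps
   ≥ 303 bp, the first codon multiple above 300, and is configurable);
4. `internal_stop`;
5. `low_expression` — RPKM < 10 when expression filtering is enabled; a
   missing RPKM is treated conservatively as low expression (with a
   warning), since an unquantified transcript cannot be shown to be well
   supported;
6. `length_ratio_out_of_band` — length relative to a homologous
   protein-coding sequence outside the inclusive band [0.95, 1.05].
   Sequences with no homolog length pass: absence of a homology hit is not
   evidence of truncation.

The homolog-length table replaces an alignment step (BLASTx top hits);
computing those hits is out of scope, the table is consumed as input.

## Audic–Claverie test for observed vs expected counts

The pair and start-context analyses compare an observed count y against a
continuous expected count derived from marginal frequencies. The expected
count is rounded to the nearest integer x and treated as the count of an
equal-sized pseudo-library, under which the conditional law of y given x
is p(y|x) = C(x+y, y)/2^(x+y+1), i.e. NegBin(x+1, ½). Two-sided p =
min(1, 2·min(P(Y ≤ y), P(Y ≥ y))). Equal library sizes make the test
symmetric and reduce it to a closed form that scipy evaluates exactly via
negative-binomial tails; the test suite pins the implementation to
exact-rational tail sums for every x, y ≤ 50 at 1e−12.

Choices worth noting:

- Rounding (rather than flooring or a continuous gamma extension) of the
  non-integer expected count: unbiased on average and exactly testable.
- The 1e−10 floor applies to reported p-values only (a plotting
  convention); classification compares the raw p against α = 0.01, which
  is equivalent since the floor sits far below α.
- No multiple-testing correction by default: preferred/avoided calls are
  raw p < 0.01 over 3,721 pairs, matching the classical screening
  convention for this analysis; with ~20 of 3,721 expected false calls at
  the p-threshold alone, the additional 2-fold ratio requirement is what
  keeps the realized false-positive fraction near zero (measured ≈ 0.001
  on null data, a handful of small-expectation pairs per separation).
- Pairs with expected frequency 0 cannot be tested; they are flagged
  `degenerate` and left unbiased by convention.
- An observed count of 0 gives ratio 0 (an avoided candidate if p
  passes), not a missing value.

## CAI reference set

CAI requires a reference of highly expressed genes, and results depend on
it. The default reference is the pooled usage of the top 5% of sequences
by RPKM (`reference_from_top_rpkm`); when no RPKM is available the pooled
input is used, with a warning. The reference descriptor is carried on the
weights object and logged, because CAI values from different references
are not comparable. Zero-count codons in an observed family receive a 0.5
pseudo-count before w = x/x_max, so CAI never collapses to 0; families
wholly absent from the reference are excluded from the geometric mean.

## Positional analyses

Positional slices cod_1…cod_50 and cod_−1…cod_−50 pool, across sequences,
the codon at each position counted from just after the start AUG and just
before the stop. The positional CAI at a position is the geometric mean of
w over the pooled codons there — equivalent to the CAI of the pooled
position-sequence. (An arithmetic mean of per-gene w is a defensible
alternative; the geometric form was chosen for consistency with CAI
itself and the difference is second-order at these sample sizes.) The 5'
trend is fitted by OLS over positions 2–50 by default, excluding cod_1
because the start-context bias makes it an outlier by construction; a
perfectly flat profile returns slope 0, r = 0 by convention.

Start-context analysis tests the distribution of the codon following the
start AUG (or following every internal AUG, one observation per
occurrence) against the background sense-codon distribution of the same
sequences, with the same Audic–Claverie classification as pairs. The
Kozak window is the 13-mer n₉AUGn; windows with fewer than 9 upstream
bases are N-padded and N never enters the counts, so per-position column
sums can be below the window count. Information content is 2 − H(column)
bits against a uniform background, and the IUPAC consensus letter at each
position covers all bases at ≥ 25% relative frequency.

## Comparative analyses

The comparative feature space is RSCU over the 59 codons in multi-codon
families (64 minus AUG, UGG and the stops). Unobserved families in a row
are imputed at the neutral value 1.0 — neutrality adds no artifactual
between-row distance — and rows with more than 20% missing cells are
dropped. Clustering is complete-linkage on Euclidean distances
(scipy's deterministic tie-breaking, lower index first, gives
byte-identical trees); PCA is column-mean-centered without unit-variance
scaling, since RSCU cells already share one scale. Variance contribution
ratios are eigenvalue shares; a row's cos² for a component is its squared
score over its squared distance to the center, summing to 1 across all
components.

Gene-level relations report each gene's ENC against the expected curve
ENC\*(GC3s) with residuals and the fraction of genes below the curve, and
the Pearson correlation (with its t-based p) between CAI and GC3s.
Tertile grouping ranks genes by CAI or GC3s and splits them
low/mid/high with the remainder in the middle group — 1,066 genes give
355/356/355 — with ties broken by id. Category-proportion trends across
groups are flagged ('*' increasing, '^' decreasing) when the high and low
proportions differ by a two-sided two-proportion z-test at the 5% level
and the middle group is intermediate; Fisher's exact test is available for
small counts. ENC for a single gene substitutes a missing 3-fold class by
(F̄₂ + F̄₄)/2; if any other class is unobservable, ENC is undefined rather
than guessed, and sampling values above 61 are clamped to 61.

## The synthetic generator

`synthetic_data.generate` emulates the statistical structure the analyses
assume, not real biology. Per gene it draws an i.i.d. amino-acid sequence
(uniform over the 20 by default), then codons from per-amino-acid
probability vectors, with three optional modifiers:

- **positional ramp** — a mixing weight toward each family's designated
  preferred codon rising linearly over the first `length` (default 50)
  codons, a surrogate for the 5' translational ramp;
- **pair coupling** — when a trigger codon sits d+1 positions upstream,
  the within-family probability of the target codon is multiplied by the
  enrichment e and renormalized. This Markov scheme realizes an
  observed/expected ratio of about e/(1 + (e − 1)q), where q is the
  target's within-family base probability — about 2.3 in a 4-fold and 2.6
  in a 6-fold family at e = 4, and ≤ 2 in 2- and 3-fold families, where a
  nominal ×4 coupling is therefore undetectable by the 2-fold cutoff. The
  truth table stores the realized ratio (including the small correction
  for the trigger's marginal occupancy), not the nominal e;
- **start context** — an override distribution for the codon after AUG.

Defaults follow a filtered plant transcriptome: 1,066 genes, internal
length uniform on [100, 560] codons (mean ≈ 330), stop usage
UGA > UAA > UAG in the proportions 1.39 : 0.94 : 0.67, a 5–80 nt UTR and a
broad lognormal RPKM (median ≈ 20, so the RPKM ≥ 10 filter is genuinely
exercised). `gc3_codon_probs(t)` builds codon vectors whose third-position
GC probability is exactly t in every family, which is how the species
panel spans GC3s regimes.

What the generator does **not** emulate: realistic protein sequences
(amino acids are i.i.d., whereas the analyses condition on codons, not
proteins), amino-acid composition bias, expression-correlated codon bias,
assembly or quantification noise beyond the RPKM draw, and genuine
phylogenetic covariance between species (panel species are independent
draws). Passing tests therefore demonstrate that the estimators recover
known planted structure at realistic sample sizes — not that any
particular biological dataset shows such structure.

## Validation problem sizes

The acceptance script and test suite size each experiment so the property
under test has clear statistical margin while the whole run stays light:
planted-pair recovery uses ~3,000 genes (~9×10⁵ neighboring pairs, giving
a 4-fold-family target ≈ 3 sampling SDs of clearance over the 2-fold
cutoff); null calibration 1,000 genes; start-context experiments 1,066
genes; the ramp 800 genes; the species panel 10 species × 120 genes; GC3s
recovery ~10⁵ codons. The exact-oracle sweep covers all 2,601 (x, y)
pairs up to 50.

## Known limitations

- ENC on short single genes is noisy and occasionally undefined (missing
  degeneracy classes); pooled tables are the reliable use.
- The Audic–Claverie adaptation treats the expected count as a library of
  equal size; the original two-library form with N2 ≠ N1 is not exposed.
- High-frequency codon-pair screening (the 1.5×/60% rules) is a
  descriptive cutoff with no error control; on null data it still
  returns many pairs, as expected of a threshold on noisy context counts.
- The comparative module consumes per-species CDS sets or precomputed
  RSCU matrices; it does not fetch genomes or infer phylogenies.
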