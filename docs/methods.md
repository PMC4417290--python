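# Methods

## Model and assumptions

`her2sig` operationalises a nearest-reference view of treatment response:
trastuzumab-sensitive and -resistant phenotypes are assumed to leave a
reproducible transcriptional fingerprint over a small gene panel, shared
between cultured cell lines and tumors. A tumor is classified by the
Pearson correlation of its panel profile with each reference cell line;
the reference nearest to r = 1 transfers its sensitivity label to the
tumor (sensitive → pCR, resistant → non-pCR). The approach assumes

- the panel genes' *relative ordering* (not absolute level) carries the
  phenotype — Pearson is invariant to affine rescaling of a profile;
- cell lines are usable proxies for tumor tissue on these genes;
- a single nearest reference, not a class centroid, is the right unit of
  comparison (each cell line is an individually meaningful phenotype
  model; the decision cites one line, matching how the worked examples
  are reported).

## qPCR quantification

Relative expression is pure 2^−ΔCt against the 18S rRNA reference gene:
no PCR-efficiency correction (amplification efficiency fixed at 2 per
cycle) and no ΔΔCt calibrator sample. Technical replicates, when a Ct
table carries a `replicate` column, are mean-averaged on the Ct scale
before ΔCt is formed. Note the exact identity log2(2^−ΔCt) = −ΔCt: the
log2 expression used throughout is just the negated ΔCt, so no precision
is lost converting between spaces.

## Correlation scale and tie handling

The correlation space defaults to **log2**. Raw 2^−ΔCt values span several
orders of magnitude across a panel, and linear-space Pearson is then
dominated by the one or two highest expressors; log2 space weights genes
comparably. Linear-space correlation is available
(`classify_sample(..., space="linear")`) since the scale on which the
original worked-example correlations were computed is not documented, and
Spearman rank correlation (`measure="spearman"`) is available as a
monotone-invariant alternative; Pearson is the default because the worked
examples report signed product-moment-style r values.

Ties are resolved deterministically: within a sensitivity class the
alphabetically first cell line wins; across classes the default policy is
conservative (call non-pCR — do not over-promise response), with a
`report` policy that emits `ambiguous` instead. Exact cross-class ties
essentially occur only with degenerate (duplicated) references.

## Gene selection

`backward_eliminate` is greedy backward elimination: each round scores the
removal of every remaining gene by cohort accuracy and removes the gene
with the highest resulting accuracy provided it is **not below** the
current accuracy (accept-on-tie). Tied candidate genes are broken
alphabetically, making traces fully deterministic. Elimination stops when
every removal would strictly lower accuracy, or at `min_size` (default 3,
the floor below which Pearson correlation is undefined). Accept-on-tie
deliberately drives toward the smallest panel at equal performance; a
`strict` mode stops at the first non-improvement.

Accuracy is **resubstitution** accuracy — the cohort that guides the
search also scores it. This matches single-cohort signature discovery but
overestimates external performance; `leave_one_out_accuracy` re-runs the
elimination with each sample held out for a less biased figure.

Two consequences worth knowing:

- when accuracy saturates (e.g. 1.0 on an easy cohort), the accept-on-tie
  rule keeps removing genes whose loss costs nothing *on that cohort*,
  and the alphabetical tie-break decides which — truly informative genes
  can be discarded in favour of correlated noise genes that happen to
  preserve resubstitution accuracy;
- greedy elimination is a hill-climb over nested subsets. On synthetic
  10-gene panels (4 informative, class separation 2 log2 units, unit
  noise, 45-tumor cohorts) it attains the exhaustive best-subset accuracy
  in roughly 70–85% of replicates, and we verified on failing replicates
  that *no* backward chain with non-decreasing accuracy reaches the
  exhaustive optimum — the shortfall is structural, not a tie-break
  artefact. The greedy result is always a lower bound on the exhaustive
  best.

## Clustering validation

The validation procedure mirrors the Eisen-style microarray workflow:

1. **Log transform "when necessary"**: matrices declared linear are always
   log2-transformed; matrices of unknown scale are transformed when
   max/min > 50 (log-scale microarray data never spans a 50-fold range;
   linear-scale data essentially always does). The threshold is a
   documented heuristic, overridable by declaring the scale.
2. **Median centering**: one pass — subtract each gene row's median, then
   each sample column's median. After the pass column medians are exactly
   0; residual row medians are available as diagnostics. The pass is not
   iterated (median polish is a stronger operation than the single
   centering step described for this workflow).
3. **Clustering**: agglomerative clustering of samples on Euclidean
   distance, average linkage (UPGMA) by default — the convention of the
   clustering tools this procedure descends from; complete and single
   linkage are options. The tree is cut at the final merge into exactly
   two groups.
4. **Scoring**: both assignments of {group A, group B} to {pCR, non-pCR}
   are scored and the higher-accuracy mapping is reported, since an
   unsupervised two-group cut has no intrinsic orientation.

Order invariance: samples are put in canonical (sorted-by-id) order before
the linkage is computed, so the partition cannot depend on the column
order of the input file. This is the practical route to the deterministic
tie-break the procedure needs — tie-breaking on raw cluster indices would
itself depend on presentation order.

Note that per-array median centering absorbs any *uniform* per-sample
shift; a class signal that moves all genes in the same direction is
invisible after centering. Real signatures (and the synthetic generator)
have genes moving in both directions.

## Performance metrics

Sensitivity tp/(tp+fn), specificity tn/(tn+fp), PPV tp/(tp+fp), NPV
tn/(tn+fn), accuracy (tp+tn)/n, with pCR as the positive class.
Zero-denominator metrics are reported as undefined, never as 0.
Percentages are rendered half-up through a one-decimal intermediate
(81.48 → 81.5 → 82), matching how clinical tables are typically typeset
from spreadsheet output. Published source tables for this kind of 2×2
occasionally print predictive values from transposed ratios (e.g. a
"104%" NPV); `her2sig` always computes PPV/NPV from the standard
definitions above.

The per-gene two-group test is Mann–Whitney U, two-sided. For combined
n ≤ 20 the p-value is exact: all C(n, n₁) group assignments are
enumerated (midranks for ties) and p = Pr(|U − n₁n₂/2| ≥ |u_obs −
n₁n₂/2|); for tie-free data this equals the classical doubled-tail exact
p. Above n = 20 the normal approximation with tie and continuity
correction is used (via scipy). Frozen/FFPE concordance is per-gene
Pearson r over samples paired by id, requiring ≥ 3 shared pairs.

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes, in
log2 expression space (Gaussian noise in log2 = log-normal expression):

| parameter | default | meaning |
|---|---|---|
| `n_tumors` | 45 | cohort size (the targeted clinical series) |
| `pcr_fraction` | 18/45 | fraction drawn from the sensitive archetype |
| `panel_size` | 28 | measured genes |
| `n_informative` | 8 | genes whose means differ between archetypes |
| `archetype_separation` | 2.0 | class-mean difference, log2 units |
| `noise_sd` | 1.0 | per-gene noise, log2 units |
| `ffpe_attenuation` | 0.7 | multiplicative shrinkage of FFPE log2 signal |
| `ffpe_extra_sd` | 1.0 | added FFPE degradation noise, log2 units |
| baseline | −12 | mean log2 expression vs 18S (ΔCt ≈ 12 cycles) |

Informative genes alternate direction between archetypes (up in one
class, down in the other) so the class difference is not a uniform shift
— a centered statistic like Pearson, and median-centered clustering,
would both be blind to a pure offset. References are archetype + noise
(three per class, named after the real cell lines); tumors likewise, the
first round(pcr_fraction·n) drawn sensitive. Ct rendering inverts the
2^−ΔCt transform exactly (gene Ct = 12 − log2 expression), so the
generated Ct tables round-trip to the intended expression to machine
precision. FFPE copies are attenuation-scaled centered signal plus noise;
the implied population frozen/FFPE correlation per gene,
aσ/√(a²σ² + s²), is available analytically for calibration.

All randomness flows through `numpy` generators seeded from the mandatory
config seed with fixed per-operation stream offsets; nothing touches
global random state, and identical configs reproduce identical data
across platforms.

What the generator does **not** emulate: gene–gene correlation beyond the
archetype difference (an optional single-latent-factor block correlation
exists for stress tests), microarray probe effects, batch effects, or
realistic platform noise. Passing synthetic tests therefore demonstrates
the pipeline's correctness and its behaviour under the stated noise
model, not clinical performance on real cohorts.

## Numerical choices and degenerate inputs

- Pearson requires ≥ 3 points and non-constant vectors; constant profiles
  raise an error naming the offending panel context rather than returning
  NaN. Results are clipped to [−1, 1] against rounding drift.
- Correlation-based panel scoring is vectorised (one standardised matrix
  product per candidate panel), which keeps greedy elimination over a
  28-gene panel on a 45-tumor cohort well under a second; the exhaustive
  subset oracle is restricted to ≤ 16-gene panels.
- Profile construction with prescribed correlations to two references
  solves c₁ = α + βρ, c₂ = αρ + β in the centered/standardised reference
  space and fills the remainder with an orthogonal residual direction;
  targets are rejected as infeasible when the implied 3×3 correlation
  matrix is not positive semi-definite.
- File parsing is strict by default: duplicate measurements, ragged rows,
  blank cells and missing reference genes are hard errors with file/line
  context; nothing is silently imputed.

## Problem sizes used in the checks

The packaged test-suite checks run on cohorts of 12–100 tumors, panels of
6–28 genes, 50-replicate selection benchmarks and 500-pair concordance
simulations; the whole suite completes in well under a minute on one CPU.
These sizes were chosen as the smallest that make the statistical
assertions stable across the fixed seeds.

## Known limitations

- Resubstitution accuracy overstates external performance; the 8-gene
  signature's external validity must come from independent cohorts, not
  from the elimination trace.
- Greedy elimination can be structurally unable to reach the best subset
  (see above); treat the final panel as a good, not optimal, subset.
- The nearest-reference rule has no confidence measure; a call driven by
  r = 0.2 counts the same as one driven by r = 0.93. Probabilistic
  calibration is out of scope.
- The clustering validation assumes the two-group cut at the final merge
  corresponds to the response axis; with more structure in the data the
  top split may reflect something else entirely.
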