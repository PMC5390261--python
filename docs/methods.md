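# Methods

## The analysis model

`spcdelta` implements label-free quantitative proteomics by spectral
counting for a two-condition comparison (a gene knockdown against a vector
control) observed in up to three sample compartments — whole-cell lysate,
secretome (conditioned media), and tumor xenograft — each with 4 biological
× 2 technical replicates per condition.

**Identification.** The package consumes the output abstraction of a
database search: peptide-spectrum matches (PSMs) with assigned
probabilities and target/decoy flags. Peptide identifications are accepted
at probability strictly greater than 0.95; protein groups are accepted at
probability strictly greater than 0.99 with at least 2 unique peptides,
subject to a decoy-estimated protein-level FDR of at most 1%. Proteins that
cannot be distinguished by their spectra (identical peptide evidence) are
merged, proteins whose evidence is a strict subset of another's are
absorbed, and the remaining cover of the peptides is chosen greedily (most
uncovered peptides first; ties broken by more total peptides, then
lexicographically smallest lead accession). Greedy set cover is a
deterministic, reproducible reading of the parsimony principle; on all
small instances we test (≤ 6 proteins, ≤ 10 peptides) it coincides with
the exhaustive minimum cover. The decoy FDR estimator is D/T (decoys
retained over targets retained), the simplest estimator consistent with a
decoy-database search; when the fixed thresholds leave the FDR above the
bound, the probability threshold is raised by the smallest step (the next
retained probability value) that restores it. Probability models
(PeptideProphet/ProteinProphet, Percolator) are not reimplemented:
probabilities are inputs, a protein's probability is the maximum PSM
probability over its peptides, and a group's is the maximum over members.

**Quantitation.** The spectral count (SpC) of a protein in a sample is its
number of significant assigned MS/MS spectra. Normalized spectral counts
(NSpC) divide each sample's column by its total, so each column sums to 1;
NSpC is used for sample correlation and reporting. For testing and fold
changes, counts are pooled (summed) over all 8 replicates of each
condition within a compartment. With `n1, n2` the pooled counts of a
protein under control and knockdown, `t1, t2` the pooled totals, and
pseudocount `f`:

    Rsc = log2((n2 + f)/(n1 + f)) + log2((t1 − n1 + f)/(t2 − n2 + f))

positive when the protein is more abundant in the knockdown. The default
`f = 0.5` is the conventional half-count correction; it is configurable
because published tables alone cannot pin down the exact value an upstream
implementation used.

**Testing and calling.** Each protein's 2×2 table
`[[n1, t1−n1], [n2, t2−n2]]` is tested with the two-sided Fisher exact
test (minimum-likelihood convention: the p-value sums all outcomes whose
point probability does not exceed the observed one's; this is the dominant
convention and differs from the "doubling" alternative). Tables with a
degenerate margin return p = 1. P-values are adjusted by the
Benjamini–Hochberg step-up procedure *within each compartment*, because
each compartment is reported as an independent comparison. A protein is
called up (down) when Rsc > 1.8 (< −1.8), strictly, and its adjusted value
is below 0.05. Using the adjusted value is the stricter reading of
"corrected for multiple testing"; a raw-p switch (`use_adjusted=False`) is
kept because the convention is not always stated in published analyses.

**Curation.** Called proteins pass through a fixed sequence of exclusion
rules with first-matching-rule attribution, so per-rule counts plus the
retained count always equal the input count: not-significant, keratins
(sample-handling contaminants), entries without a reported accession,
peptide fragments, putative uncharacterized proteins, cDNA-like entries,
and — in the xenograft compartment only — skeletal-muscle proteins, which
are plausible contamination from excising the tumor from the host animal.
Keyword matching is case-insensitive on the description (keratins also
match gene symbols starting `KRT`). The skeletal-muscle keyword is
deliberately the literal phrase "skeletal muscle": muscle-associated gene
families (tropomyosins, nebulin) occur as genuine tumor signal and must
not be swept out by name alone. All keywords are configurable.

**Reporting.** Retained proteins are annotated from a gene→category map
(categories are data, never inferred by code; unmapped genes become
"Unknown function"), summarised as per-category percentages, and ranked
for the most extreme Rsc per direction (ties broken by lexicographically
smallest gene symbol). Sample similarity is the Pearson correlation of
NSpC profiles; samples are ordered by average-linkage hierarchical
clustering on the distance 1 − r with leaf order made deterministic by
pre-sorting sample ids.

## The synthetic-data generator

The generator emulates the study design so the statistical pipeline can be
exercised against known truth: two conditions × the configured
compartments × 4 biological × 2 technical replicates. Counts are
gamma-Poisson: each biological replicate draws a latent rate from a gamma
distribution with shape 1/dispersion, so the marginal per-sample count is
negative-binomial with the configured mean and `Var = m + dispersion·m²`;
technical replicates share the biological replicate's latent rate and
differ only by Poisson sampling noise, mirroring the smaller spread of
technical duplicates. The negative-binomial choice is a standard model for
overdispersed counts, not something the published analysis states; the
`dispersion → 0` limit recovers Poisson counts.

Defaults: 4 × 2 replicates, baseline mean 20 spectra per protein per
sample, dispersion 0.05 (modest overdispersion), per-protein baseline
abundances log-normal (σ = 0.8) around the baseline mean to mimic the wide
dynamic range of real proteomes. A configurable fraction of proteins is
truly differential with log2 fold changes uniform over the configured
range and signs alternating (half up, half down, as both directions are
reported in practice). Allocation of differential and nuisance proteins is
a deterministic stratified assignment from one seeded permutation, so the
classes are disjoint and outputs are bit-identical given config + seed.

Nuisance injection relabels allocated null proteins in place with the
descriptions/flags the curation rules key on, so injected records carry
simulated counts and flow through the entire pipeline. Accession-less
entries keep a unique internal accession (the join key) and blank the
`reported_accession` field, since an empty string cannot index a matrix
row. Skeletal-muscle contaminants receive counts only in xenograft
samples, matching the contamination mechanism they model.

The generated PSM tables model only the *output* of a search engine:
target PSM probabilities ~ Beta(40, 1) (concentrated near 1), decoys
~ Beta(2, 6), a configurable fraction of peptides shared between two
proteins to exercise parsimony. No spectra, retention times or scores are
simulated. Consequently, passing tests demonstrate the correctness and
calibration of the statistical pipeline under its own model assumptions —
they do not certify behaviour under real-data pathologies such as
peptide-level interference, saturation of spectral counts for abundant
proteins, shared-peptide quantitation ambiguity, or batch effects.

## Numerical and procedural choices

- Thresholds "greater than 95%/99%" and "Rsc > ±1.8" are strict
  inequalities; the boundary values are excluded.
- Fisher's exact test is delegated to `scipy.stats.fisher_exact`; the test
  suite verifies it against an independent exhaustive hypergeometric
  enumeration to 1e-9 over every 2×2 table with total ≤ 40 (≈ 135 000
  tables; the acceptance script enumerates totals ≤ 30) plus a seeded
  random sweep of tables with totals up to 200. BH is implemented directly
  from the step-up definition and cross-checked against
  `statsmodels.stats.multitest.multipletests`.
- Category percentages are rounded half-up to one decimal from the
  unrounded fractions. Rounded percentages sum to 100 only within
  0.05 × (number of categories).
- NSpC normalization refuses zero-total samples by name; correlation
  refuses zero-variance profiles by name; pooled counts exceeding their
  totals, probabilities outside [0, 1] and negative counts are errors.
- The null-calibration and recovery checks use 2 000 and 10 × 500 proteins
  respectively at the default replicate layout — sizes at which the
  binomial error bands in those checks are tight enough to be informative.
- The empty-call convention for the observed FDR is 0.0 (no calls, no
  false discoveries); sensitivity over zero true differentials is NaN.

## Known limitations

- Pooling replicates before a single Fisher test treats spectra as
  exchangeable across replicates; between-replicate overdispersion is not
  modelled in the test itself (no count GLM / negative-binomial regression
  alternative is provided). The combined |Rsc| gate and BH correction keep
  the realized null call rate far below nominal in the simulated designs,
  but the raw Fisher p-values themselves are anticonservative under strong
  overdispersion.
- The curation rules are keyword reconstructions of published exclusion
  classes; no contaminant-database (cRAP-style) lookup is performed.
- The packaged curated tables transcribe published lists exactly,
  including rows whose |Rsc| is below the stated calling threshold; they
  are reporting inputs only and are never re-filtered by the pipeline's
  thresholds.
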