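# Methods

## Statistical model

Protein-group LFQ intensities are treated as log10-normal within replicate
groups. For one bait-vs-reference contrast the per-protein model is

    x_ij = mu_i + delta_i * 1[j in A] + eps_ij,   eps_ij ~ N(0, sigma_i^2)

with equal residual variance in both groups; `delta_i` is estimated by the
difference of group means (log10 units; the volcano x-axis) and tested with
the pooled-variance two-sample Student's t statistic,
df = n_A + n_B − 2. P-values are two-sided and raw: with a handful of
planned contrasts and a fold-change co-criterion the pipeline follows the
convention of not adjusting; Benjamini–Hochberg q-values can be added
(`adjust_p`) without changing the classification.

A protein is classified `up`/`down` when p < `p_max` (default 0.05) and the
effect, converted to log2 units, satisfies |Δlog2| ≥ `min_log2_diff`
(default 3). For a log10 matrix the conversion is Δlog2 = d / log10 2, so
the matrix-unit cutoff is ≈ 0.9031; the conversion is written exactly this
way so the boundary value 3·log10 2 classifies as significant rather than
falling a float ulp short. Because "difference ≥ 3" can also be read in
matrix units, a strict mode (`difference_units="matrix"`) applies the
cutoff without conversion — the two readings differ by a factor of
log2 10 ≈ 3.32 and the default is the log2 reading. With `s0 > 0` the
rectangular rule is replaced by the SAM-style curve
−log10 p > −log10 p_max + s0 / (|Δlog2| − d0); the default is s0 = 0.

### Missingness and imputation

MaxQuant encodes "not quantified" as intensity 0; the reader stores the 0
verbatim and `log_transform` converts it to an explicit missing value.
Missingness in LFQ data is missing-not-at-random: low-abundance proteins
drop below the identification limit. Two consequences:

* **Replicate-presence rule.** A protein is kept when quantified in ≥ 2 of
  3 replicates of at least one condition group, or ≥ ⌈0.75 n⌉ for groups of
  n > 3 (so 5 of 6). `any_group` is the default because on/off candidates —
  proteins entirely absent from an uninduced control — are exactly the
  interesting ones; `all_groups` and `whole_row` modes exist for stricter
  designs. The ceiling (5 of 6, not 4) is one of two defensible readings of
  "≥ 75%" and is exposed through `ValidityRule.fraction_large`.
* **Downshifted-Gaussian imputation.** Per sample column with observed
  mean μ and sample SD σ (ddof = 1, observed cells only, recomputed fresh
  each run), each missing cell is drawn from N(μ − s·σ, (w·σ)²) with
  defaults w = 0.3, s = 1.9 — the Perseus defaults. A single seeded
  generator processes columns in sample order and missing cells in protein
  order, so a seed pins the entire matrix bitwise. A column with < 2
  observed values raises (σ is inestimable); σ = 0 imputes the constant μ
  with a warning. An order guard rejects imputation on a matrix that has
  not passed the replicate-presence filter, since imputing
  never-quantified rows would manufacture data.

## Interface contacts

For a two-chain model, residue pairs (i ∈ A, j ∈ B) are contacts when the
minimum heavy-atom (non-hydrogen, all atoms including side chains)
Euclidean distance is strictly below 8 Å; hydrogens and HETATM records are
excluded at parse time and author residue numbering is preserved. The PAE
matrix indexes residues in file order chain by chain and is deliberately
not symmetrized; a contact is high-confidence when
max(PAE_ij, PAE_ji) ≤ 5 Å (inclusive). The distance reduction uses one
`cdist` call over all atom pairs followed by a per-residue-pair minimum;
at the sizes involved (≤ ~700 residues) correctness is favoured over
spatial indexing, and tests require exact agreement with an O(n²)
brute-force oracle.

## Synthetic data

`simulate_lfq` emulates the study conditions: per-condition replicate
groups (3 by default, 6 supported), baseline log10 abundance
N(7.5, 1.0²), a configurable fraction of proteins (default 5%) enriched in
the bait condition by `effect_size_log2` (default 4, i.e. ≈ 1.2 log10
units), residual replicate noise SD 0.15 (log10), and logistic
left-censoring: a cell of log-abundance x is observed with probability
logistic(k·(x − m)), defaults m = 5.5 (baseline mean − 2 SD) and k = 1.5.
The logistic form is a smooth two-parameter stand-in for the
detection-limit process, chosen as an assumption of this package, not a
claim about the instrument: it reproduces the "missing = low abundance"
regime the downshifted imputation presumes. Annotation labels are injected
with configurable probabilities conditional on enrichment status
(defaults: mitochondrial 0.85 vs 0.15, outer-membrane 0.45 vs 0.03,
RNA-binding 0.30 vs 0.10), and flagged contaminant/decoy rows draw
intensities from the same model so filter tests see realistic tables.

What the simulator does **not** emulate: peptide-level aggregation,
between-sample normalization error, correlated protein covariation,
batch effects, or ratio compression. Passing recovery tests therefore
demonstrates the statistical chain is implemented correctly under its own
assumptions, not that those assumptions hold for any particular
instrument run.

`simulate_complex` builds two CA-trace chains on parallel 12 Å-spaced
lines: designed contact pairs sit at 6 Å (< 8) while every other
inter-chain pair is ≥ 10 Å by construction, so the designed set is exactly
the recoverable set; an optional random rigid-body transform exercises
rotation invariance. PAE is `pae_inside` (default 3 Å) on designed pairs,
`pae_outside` (default 12 Å) elsewhere, zero on the diagonal.

## Pipeline orchestration

`run_all` executes the comparison battery from a YAML config. Filtering
and imputation run per comparison restricted to that comparison's two
condition groups (pairwise, as Perseus analyses are typically set up), and
each comparison's imputation seed is derived from the run seed by CRC-32
of the comparison name — adding a comparison never changes another's
output. The manifest records per-stage counts (conserved:
rows_in = kept + dropped at every filter), parameters, a config hash and
SHA-256 checksums of every output file; reruns are byte-identical.

## Numerical choices and degenerate inputs

* p-values are clamped to the smallest positive double before −log10;
  zero pooled variance with equal means yields t = 0, p = 1, with unequal
  means an infinite t and clamped p plus a warning.
* Fractions in category summaries are also reported as half-up-rounded
  integer percentages (the conventional reporting style); exact fractions
  are kept alongside.
* TSV output writes missing cells as `NA` and floats at full double
  precision so read/write round-trips are lossless.
* Test and acceptance problem sizes — 20 × 1000-protein null simulations,
  10 × 2000-protein recovery runs, 10⁵ imputation draws, 50 random toy
  complexes — were chosen as the smallest sizes at which the Monte-Carlo
  tolerances quoted in the tests are stable.

## Known limitations

* Equal-variance Student's t only (no Welch, no moderated/limma-style
  variance shrinkage, no permutation FDR).
* One imputation realization per run; imputation uncertainty is not
  propagated into the p-values (as in the standard Perseus workflow).
* Annotation joins key on the first gene-name token (accession fallback);
  ambiguous or outdated gene symbols will silently miss.
* The contact caller analyzes one model; it does not ensemble over
  predictions or consume pLDDT.
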