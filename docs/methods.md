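# Methods

This note documents the models, numerical choices and known limitations of
`rfgwas`, in the order the pipeline runs them.

## Animal model and BLUP

The trait model is `y = Xb + Zu + e`, with `u ~ N(0, A σ²ₐ)` structured by
the numerator relationship matrix `A` and `e ~ N(0, I σ²ₑ)`. Variance
components are taken as known: the module's job is prediction, not REML,
and the variance ratio λ = σ²ₑ/σ²ₐ (5.25 for h² = 0.16) is an input.

`A` is built by the tabular method in topological (parents-first) order;
`A⁻¹` is assembled directly from pedigree structure by Henderson's rules
with inbreeding (Mendelian-sampling variance `d = 1/2 − (F_s + F_d)/4`
with both parents known, `3/4 − F_p/4` with one, 1 for founders).
Inbreeding coefficients come from the tabular diagonal; an independent
recursive-coancestry oracle cross-checks `A = 2·kinship` in the test
suite. The mixed-model equations are assembled dense (desk-scale pedigrees
of up to ~10⁴ animals) and inverted once, because prediction error
variances — hence accuracies `r = √(1 − PEV/σ²ₐ)` — need the diagonal of
the inverse coefficient matrix anyway.

Fixed effects: each categorical factor gets a reference-level constraint
(first observed level dropped); covariates are centred. A rank check walks
the factors in order and names the first confounded one rather than
failing with a generic singular-matrix error.

## Deregression

EBVs shrink toward the parent average, so using them directly as an
association response double-counts family information. The deregression
solves a 2×2 information system for the pair (parent average, individual):
modelling `(g_PA, g_i)` with relationship matrix `[[½, ½], [½, 1]]` gives
mixed-model equations whose unknown effective record counts `(z_PA, z_i)`
are solved in closed form from the reliabilities `(r²_PA, r²_i)`:

    (1 − r²_i)·v² − λ·v − 2λ²(1 − r²_PA) = 0,   v = z_i + 2λ,
    z_PA = 2v(1 − r²_i)/(1 − r²_PA) − 4λ.

The individual's right-hand side is then `y_i = −2λ·PA + v·EBV` and the
deregressed proof `dEBV = y_i/z_i`, with reliability
`r²* = z_i/(z_i + λ)` and weight `w = (1 − h²)/((c + (1 − r²*)/r²*)·h²)`.

Conventions that matter (both were found the hard way and are pinned by
tests):

- `r²_PA` enters on the scale of the PA effect's own variance (σ²ₐ/2), so
  the input is `(r²_s + r²_d)/2`. Feeding the σ²ₐ-scale `(r²_s + r²_d)/4`
  leaves ~35% residual shrinkage in the dEBVs.
- `z_PA` may legitimately be negative (stated parent reliability below
  what the individual's own data implies); clamping it distorts the
  round trip, so the exact solution is kept.
- With both parents unknown the model-consistent parent average is
  `EBV/2`, under which the system reduces exactly to the simple
  `dEBV = EBV/r²`; that simple mode is also available directly.

Calibration is asserted as unbiasedness: weighted regression of dEBV on
the simulated true breeding value has slope 1 (±0.1). The reverse
regression has slope equal to the dEBV reliability by construction and is
not a meaningful check. Caveat: parent-average removal presumes parents
carry information of their own; with record-less dams whose EBVs derive
from their offspring, the correction partially removes the individual's
own signal. Defaults: `c = 0.5`, reliability floor 0.1 (animals below it
are excluded and flagged); both are configuration, since neither constant
is universal.

## Genotype QC and imputation

Filter order is fixed — sample call rate (< 0.90), then SNP call rate
(< 0.90) and MAF (< 0.01) with allele frequencies recomputed after the
sample removals, then heterozygosity outliers (|het − mean| > 3 SD,
per-sample by default, per-SNP behind a flag) — and the three-stage pass
iterates to a fixed point. Iteration is what makes the filter idempotent:
a single 3-SD pass shrinks the SD and exposes new outliers on re-
application. The report records every removal with its one primary reason
in application order.

Missing calls are imputed with the per-SNP median of observed dosages;
the median of an even count is the midpoint, so 0.5/1.5 dosages can
appear and are left as-is (trees split on them like any numeric value).

## Random-forest selection

Regression forests use the convention of the classic R implementation:
mtry = max(1, ⌊0.10·p⌋) candidate SNPs per split, minimum node size 5,
5,000 trees at full scale. Importance is out-of-bag permutation
importance computed natively: for each tree, the OOB rows are predicted
once as a baseline, then re-predicted with each SNP column (only those
the tree actually splits on) permuted; the MSE increase is averaged over
all trees, with unused SNPs contributing zero for that tree.
Mean-decrease-in-impurity is available behind a flag. scikit-learn's
`permutation_importance` is not OOB-based and costs O(p) forest
predictions, so it is not used.

Selection is two-step with the floor rule `max(1, ⌊f·n⌋)`: per-chromosome
top fraction, then a forest refit on the survivors (mtry recomputed on
the reduced set) and a pooled top fraction. The rule makes candidate
counts depend only on per-chromosome SNP counts — 708,641 SNPs over 30
autosomes force 7,057–7,086 stage-1 SNPs and exactly 70 stage-2
candidates for any split with ≥ 100 SNPs per chromosome. Stage 2 may keep
a larger forest than a desk-scaled stage 1 (`n_trees_stage2`), since the
reduced panel is cheap and importance dilution among correlated tags is
the limiting noise there.

Subsamples for the common-SNP strategy are built greedily: random start,
then repeatedly the unselected animal with the lowest mean relationship
to the selected set, ties broken by the highest mean relationship to the
remaining animals (most representative of the rest), then by id. The
common strategy keeps SNPs present in the full-sample *stage-1* set and
in ≥ 1 subsample's stage-2 set (both thresholds configurable): a strict
all-runs intersection would make the common set a subset of the
highest-fraction set, which contradicts the observed behaviour of such
analyses where the common list is the longer one.

## Stepwise regression and the permutation bias test

Forward stepwise with partial-F entry and removal tests (defaults
entry = stay = 0.15, the convention of the software family this
procedure imitates); intercept always included, dosages unstandardised.
The R² increment at each entry is the sequential partial R² ("% dEBV");
increments sum to the total to 1e-10 (re-derived after any removal).
Zero-variance and collinear (R² on entered > 1 − 1e-10) candidates are
skipped with warnings.

The permutation test shuffles the response and refits the *same* selected
SNPs, recording **adjusted** R². The choice matters: the null raw R² of a
p-predictor model has mean p/(n − 1) — 0.053 at n = 396, p = 21, which
could never print as 0.00 — while adjusted R² is exactly centred at zero
with SD ≈ 0.017, printing 0.00 ± 0.02. The null is cross-checked against
the closed form R² ~ Beta(p/2, (n − p − 1)/2). A mode that re-runs the
stepwise selection on each shuffle is provided as the alternative reading
of "regressed to the same SNPs previously selected".

## LD and annotation

r² is the squared Pearson correlation of unphased 0/1/2 dosage vectors
(composite LD) — equivalent to haplotype r² under Hardy–Weinberg and
computable without phasing, which replaces a phase–reconstruct–then-
Haploview workflow; this is a documented deviation, and haplotype blocks
are out of scope. Monomorphic SNPs and pairs without overlapping calls
are skipped and counted. The decay table reports both the per-bin mean
and the cumulative mean up to each bin edge, covering both readings of
"average r² at a distance". Windows are 1-based inclusive
`[max(1, pos − 250 kb), pos + 250 kb]`; BED input is converted from
0-based half-open at the reader; chromosome labels are compared after
stripping any `chr` prefix, case-insensitively. Annotation reports any
≥ 1 bp overlap with its length.

## Synthetic herd generator

What it emulates: a multi-generation pedigree whose final cohort are
half-sib offspring of ~50 sires (1–30 offspring each, uniform), extra
phenotyped families to approach a realistic phenotyped count, a
low-heritability trait (0.16) with contemporary-group fixed effects and
an age covariate, a scaled-down HD SNP map (29 autosomes × 200 SNPs over
10 Mb each by default), and LD decaying to a mean r² ≈ 0.12 in the 250 kb
distance bin among founders.

Mechanisms and the reasoning behind them:

- **Founder LD** comes from a finite pool (default 30) of founder
  haplotypes that are mosaics of a few ancestral haplotypes (default 4),
  with segment switches a Poisson process along the chromosome (default
  2.5 × 10⁻⁶/bp). Close loci tend to copy the same ancestor (high r²);
  distant loci copy independent ancestors (r² near the 1/pool-size
  background). The two defaults were calibrated once against the 0.12 @
  250 kb target (measured 0.120 over 3 seeds) and are not revisited.
  No coalescent machinery is used by design.
- **Transmission** is gene dropping: founders draw two pool haplotypes;
  every other animal gets one recombined gamete per parent, crossovers
  Poisson with 1 Morgan per 100 Mb uniformly (no genetic map is assumed).
  Mendelian consistency is checked exhaustively in tests.
- **Trait architecture**: QTL are drawn from the panel itself (so
  selection can in principle find them exactly); raw N(0, σ) effects are
  rescaled so the QTL genic variance `Σ 2p q a²` equals a configured
  fraction (default 0.5) of a unit additive variance, the polygenic term
  carries the remainder (gene-dropped down the pedigree with
  Mendelian-sampling variance σ²_poly/2, inbreeding ignored — it is
  negligible in these pedigrees), and the residual variance implements
  the target h². Realized h² is within ±0.05 of target at n ≥ 1,000.
- **Fixed effects** are additive over sex, year, herd and genetic group
  (each factor contributing a quarter of the contemporary-group
  variance), so the main-effects animal model is exactly specified.
  Drawing an independent effect per interaction cell instead leaves
  unmodelled variance that overdisperses EBVs (calibration slope 0.64
  instead of 1.0) — with ~84 cells over a few hundred animals the full
  interaction is not estimable at desk scale.
- **Missingness** is completely at random (no informative mechanism is
  modelled); sexes are Bernoulli(½); `phenotype_parents` extends records
  to the parent generation, which the deregression round-trip requires.

What a green test therefore does *not* establish: behaviour under
genotyping error, informative missingness, selection on the trait,
maternal/permanent-environment effects, X-linked variation, or real
coalescent LD structure — none of which the generator produces.

## Determinism and scaling

All randomness descends from configuration seeds: generator stage k uses
`np.random.default_rng([seed, k])`; the pipeline derives integer
sub-seeds from `SeedSequence([master_seed, stage])` (first 31 bits) so
any stage can be re-run in isolation and whole runs are byte-identical
under a fixed master seed. Tests run forests of 80–500 trees and panels
of 450–5,000 SNPs (full-scale parameters stay at their 5,000-tree / 1%
defaults); the complete suite takes ~5 minutes on one CPU.

## Known limitations

- No REML/Gibbs variance estimation; maternal and permanent-environment
  effects and genomic relationship matrices are out of scope.
- The dense MME solve is O(n³) in pedigree size; fine to ~10⁴ animals,
  wrong tool beyond that.
- Parent-average deregression degrades when parents have no data of
  their own (see above); the simple mode is the safer default there.
- Forest importance at desk scale (few hundred trees) is noisy for QTL
  explaining ≲ 2% of the response; no conditional-importance variant is
  provided.
- No Hardy–Weinberg or Mendelian-error QC filters, no dominance or
  epistasis in the trait model, no haplotype blocks or D′.
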