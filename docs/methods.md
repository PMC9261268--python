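# Methods

## Record curation

A raw record is one literature CCS measurement of one ion: compound
name, InChIKey, SMILES, molecular formula, neutral monoisotopic mass,
adduct ([M+H]⁺ or [M+Na]⁺), CCS in Å² (N₂ buffer gas), IMS platform
(TWIMS or DTIMS) and a source tag. The InChIKey is the sole compound
identity; names differ between sources and are never used for matching.
Validation rejects (with a per-record reason, never an exception)
records with a malformed InChIKey, an unsupported adduct, or CCS ≤ 0.

Consolidation groups valid records by (InChIKey, adduct) and takes the
**median** over all contributing raw values — deliberately not the mean,
so a single outlying laboratory or a protomer-specific measurement does
not drag the consensus. An even count yields the mean of the two central
values. Replicate scatter is summarized as the RSD, the sample standard
deviation (n−1 denominator) over the mean × 100; a single measurement
has RSD 0 rather than NaN, which keeps downstream arithmetic clean.
Keys with RSD > 2 % are flagged: 2 % is about the reproducibility limit
of current commercial IMS instruments, so larger disagreement signals
protomers, calibration drift, or transcription errors rather than noise.

When a key carries more than one value on a platform, the cross-platform
audit compares **per-platform medians**: deviation = (DT − TW)/TW × 100.
The per-key consolidation, by contrast, takes the median over all raw
values regardless of platform — the alternative (median of per-platform
medians) differs only when one platform contributes ≥ 2 values and is
noted here as the rejected option, chosen against because it would weight
a single DT measurement equal to several independent TW laboratories.

## Descriptor selection

Descriptor computation is a pluggable backend mapping SMILES → fixed
column set. The shipped backends are the full RDKit 2-D descriptor list
(~210 columns) and a 7-column deterministic mock (atom/bond/ring/halogen
counts, exact mass, Crippen logP) for fast tests. Failed molecules are
reported by key, never silently dropped.

Selection stages, in order:

1. **Missing-value columns dropped** — any column with a NaN is removed
   before filtering (simplest defensible rule; imputation would
   manufacture chemistry).
2. **Near-zero-variance filter** — a column is removed if its variance
   is exactly zero, or if the frequency ratio of the two most common
   values exceeds 19 *and* distinct values are < 10 % of the row count
   (the caret `nearZeroVar` convention, matching the R workflows common
   in this field).
3. **Correlation filter** — keep descriptors with |Pearson r(x, CCS)| >
   0.6. The absolute value is used because an anti-correlated descriptor
   is exactly as informative as a correlated one; a signed mode is
   exposed for comparison.
4. **Auto-scaling** — z-scoring with mean and sample SD learned on the
   training rows only; prediction-time inputs are transformed with the
   stored parameters, never refit (leakage guard).
5. **Importance selection** (optional) — an XGBoost regressor with
   default settings and a recorded seed ranks the survivors by
   normalized gain importance; the smallest prefix whose cumulative
   importance reaches the configured fraction (0.99 or 0.95) is kept,
   ties broken by column order.

A VIF pruner (iteratively remove the highest-VIF column until all
VIF ≤ threshold; infinite VIFs first, ties by column order) supports
collinearity studies; it is not part of the default pipeline because
moderate collinearity does not hurt kernel or tree models, and the
richer descriptor set predicts better.

## Regression models

One model per adduct, never pooled: protonation barely perturbs the
neutral conformation while sodiation reorganizes it, so the descriptor →
CCS mapping differs between [M+H]⁺ and [M+Na]⁺.

**ε-SVR, RBF kernel.** Grid: C = c_base/N_MD with c_base ∈ {0.001,
0.005, 0.01, 0.025, 0.05, 0.1, 0.25, 0.5} and N_MD the retained
descriptor count, crossed with γ ∈ {1, 2, …, 256} (γ is not divided by
N_MD); ε = 0.1. These cost values are meaningful only on a standardized
target, so the SVR wrapper z-scores CCS internally at fit time and maps
predictions back to Å² — mirroring the default behavior of the standard
R SVM implementation whose conventions the grid follows.

**Gradient-boosted trees.** 576 combinations of η × max_depth ×
min_child_weight × subsample × colsample_bytree; per combination the
boosting-round count is the iteration minimizing the 10-fold CV RMSE
(early stopping after 20 stagnant rounds, cap 500).

**Tuning.** All combinations are evaluated exhaustively on the same
10-fold partition of the 70 % training split (train size = round-half-up
of 0.7·n; all randomness flows through explicit seeds, the global RNG is
never touched). RMSECV is pooled — the square root of the grand mean
squared out-of-fold residual — rather than a mean of per-fold RMSEs;
both aggregations rank near-identically but the pooled form is the
natural estimator of prediction error (the per-fold variant remains
available). Ties in the argmin resolve to the first grid entry
(smaller C, then smaller γ), making selection deterministic.

**Evaluation** on the untouched 30 % split: R²_p = 1 − SS_res/SS_tot,
RMSEP, MRE = median |pred − exp|/exp × 100, and the share of compounds
within 2/3/5 % relative error (strict inequality). Relative errors use
the **experimental** value as denominator throughout.

**Ablation.** `ablate_subset` retrains with identical hyperparameters
after removing a predicate-defined training class (e.g. halogenated
compounds) and evaluates both models on the same test partition,
stratified by the predicate — isolating the effect of training-set
chemical diversity from model capacity.

## m/z–CCS trends

The empirical backbone CCS = a·(m/z)^b is fitted by OLS on
(ln m/z, ln CCS) — closed-form and deterministic, unlike nonlinear least
squares, and equivalent for the multiplicative error structure CCS data
exhibit. Halogenated molecules (any F, Cl, Br, I; formula parse when a
formula is available, RDKit element scan of the SMILES otherwise) carry
more mass per unit atomic radius, so they sit below the curve; the
separation statistic is the mean signed relative residual of halogenated
points under the non-halogenated fit (negative = depressed).

## Screening

Database rationalization removes, in order: unscorable entries (no
SMILES or formula), multi-component SMILES (salts/mixtures), structures
containing a metal atom (alkali/alkaline-earth/transition metals,
lanthanides/actinides, Al, Ga, In, Tl, Sn, Pb, Bi, Po; B, Si, P, S, Se
and halogens are treated as non-metals), InChIKey duplicates (first
kept), and neutral masses outside [50, 1200] Da. Adduct m/z uses
charge-aware cation masses ([M+H]⁺: +1.007276; [M+Na]⁺: +22.989218 Da,
electron mass included). Matching applies |ppm| ≤ 5, |ΔCCS| ≤ 5 % (the
5 % tolerance reflects the models' validated prediction accuracy — ~95 %
of held-out predictions fall within 5 %), and optionally |ΔRT| when the
library carries retention times; matches are sorted by |ppm error|.
Each filter is a pure predicate, so tightening any tolerance provably
shrinks the match set.

## Synthetic data

The generator emulates the statistical structure of a multi-source CCS
compilation of plastic-related chemicals:

| parameter | default | meaning |
|---|---|---|
| `n_compounds` | 1000 | unique compounds (one adduct per run) |
| `mz_range` | 120–1000 Da | uniform ion m/z |
| `power_a`, `power_b` | 11.7, 0.484 | CCS backbone; spans ≈119–332 Å² over the m/z range, the span such compilations cover |
| `halogen_fraction` | 0.28 | share of halogenated compounds (~302/1076 in published compilations) |
| `halogen_depression` | 0.06 | multiplicative CCS deficit for halogenated compounds |
| `replicate_rsd` | 1.0 % | multiplicative between-measurement noise |
| `platform_offset_pct` | 1.15 % | mean |systematic DT vs TW offset| (half-normal, σ = 1.15·√(π/2) %) |
| `duplicate_fraction` | 0.23 | share of compounds with a second, DTIMS pseudo-source record |

Noise is multiplicative, not additive, because every tolerance in this
domain is relative. Note the *realized* DT–TW deviation also carries
two replicate-noise draws, so its observed mean |deviation| under
defaults is ≈1.6 %, larger than the systematic 1.15 % component alone.
Records carry format-valid but chemically meaningless InChIKeys, simple
alkane-like SMILES (parseable, with a chlorine when halogenated) and
formulas whose halogen count matches the planted label.

`generate_mock_descriptors` emits transforms of m/z and halogen count
(so the planted CCS law is learnable), i.i.d. Gaussian noise columns,
one constant column and one exact duplicate — the last two exist purely
to exercise the variance filter and VIF pruner.

What the generator does **not** emulate: real chemical structures and
therefore real descriptor geometry (descriptor collinearity structure,
chemical-class clustering), protomer-split CCS values, heavy-tailed
inter-laboratory disagreement, and adduct-specific conformational
effects. Passing tests on synthetic data validate the pipeline's
statistical machinery and its ability to recover planted effects; they
do not certify prediction accuracy on real chemicals — that requires
the published literature compilation, which is not redistributed here.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full workflow at
250–1,000 synthetic compounds — enough for the SVM grid's RMSECV
ordering to stabilize and for planted effects to exceed their standard
errors, while keeping the exhaustive 72-combination × 10-fold search
cheap. The 576-combination XGBoost search is exercised at reduced grid
size in the unit tests (full enumeration is asserted exactly); on real
compilations it runs in full. Tolerances asserted in tests: 1e-10 for
closed-form arithmetic (evaluation metrics, normal-equation fits), 1e-9
for noiseless parameter recovery, ±0.02 on the power-law exponent under
2 % noise at n=500.

## Known limitations

- Only positive-ion adducts [M+H]⁺ and [M+Na]⁺ are supported; acids and
  surfactants detected in negative mode need a separate model.
- Descriptors are computed on neutral structures; sodiated-ion
  conformations are therefore approximated, which is the main accuracy
  gap for [M+Na]⁺.
- One CCS per (compound, adduct): protomer pairs with distinct mobility
  collapse to a single prediction.
- No tautomer/structure standardization is applied to input SMILES;
  identity is whatever InChIKey the source supplied.
- Retention-time filtering is pass-through only; RT prediction is out of
  scope.
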