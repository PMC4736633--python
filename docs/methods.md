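# Methods

This note records the scientific and numerical choices behind the
package: the models, their defaults and units, what the synthetic
generators do and do not emulate, and the places where the design was
genuinely open.

## Sparse Bayesian kernel regression (RVM)

The regressor is y(x) = w₀ + Σₙ wₙ K(x, xₙ) with Gaussian noise
precision β and per-weight Gaussian priors of precision αᵢ. For fixed
(α, β) the weight posterior is exact: Σ = (βΦᵀΦ + A)⁻¹, μ = βΣΦᵀt.
Type-II maximum likelihood re-estimates γᵢ = 1 − αᵢΣᵢᵢ, αᵢ ← γᵢ/μᵢ²,
β ← (N − Σγᵢ)/‖t − Φμ‖², alternating with posterior updates.

**Kernel width conventions.** Kernel software disagrees on whether the
width divides the distance (k = e^{−d/σ}) or multiplies it
(k = e^{−σd}); both are implemented in `KernelSpec`. The historically
quoted Laplacian width σ = 0.044 for standardized descriptor vectors is
only sensible in the multiply convention (e^{−d/0.044} is numerically
zero at typical standardized distances of 10–20), so `multiply` is the
default. For RBF kernels the same two forms act on d².

**Defaults and rationale.**

| control | default | why |
| --- | --- | --- |
| αᵢ init | 1/N² | common flat sparse-Bayes start; the loop is insensitive to it |
| β init | 1/(0.1·var(t)) | assumes ~10% of target variance is noise at start |
| prune threshold on α | 10⁹ | concrete reading of "α → ∞"; a basis at α = 10⁹ has weight sd < 10⁻⁴·unit |
| tolerance | 10⁻³ on max \|Δ log α\| | α is a scale parameter; log scale is the natural metric |
| max iterations | 1000 | dying bases can take hundreds of slow multiplicative steps; reaching the cap is logged, not an error, and the fit is already accurate there |
| β clamp | 10¹² | keeps the noiseless/interpolating limit finite |

Linear algebra: the (βΦᵀΦ + A) solve is a Cholesky factorization with
jitter escalation 0 → 10⁻¹⁰ → 10⁻⁸ → 10⁻⁶ on failure, then a hard error
carrying the condition number. Pruned bases never return, so the active
set is monotone non-increasing; the algorithm contains no randomness.
Inputs are standardized by default (recorded in the model); the kernel
acts on the standardized space, which is the documented contract.
Serialization is a single JSON file; floats use shortest-repr encoding,
so round-trips are bit-exact.

## Feature selection

Each feature is cross-tabulated against the target binned into 5
equal-frequency classes (continuous features first into 10
equal-frequency bins; binary fingerprint bits keep their native two
levels). χ² = Σ(O−E)²/E is mapped to Cramér's V = √((χ²/n)/min(r−1,c−1))
— the standard form; a printed min(k−1) with k "rows or columns" is
ambiguous and can exceed 1, so min(r−1, c−1) is used. Ranking is by V
descending with lexicographic tie-break; the top k (120/150 classically,
clamped to the available column count) are selected. Expected cell
counts below 5 only warn: the statistic is used as a ranking heuristic,
not as inference, so no p-values are attached. Descriptors and
fingerprint bits are ranked jointly (no per-block quotas).

## Dataset assembly

* **Cleaning.** Unparseable SMILES, canonical-SMILES duplicates (first
  occurrence kept), activities outside [0, 7] pLD50, and molecules
  failing any descriptor are removed, each with a reason code.
* **Correlation filter.** Constant columns drop first; remaining
  columns are scanned in descending variance order (names break ties)
  and a column with |Pearson r| > 0.95 to any kept column is removed —
  deterministically keeping the higher-variance member of a redundant
  pair.
* **Split.** Activities are cut into 10 equal-frequency bins and 32.5%
  of each bin is sampled into the test set ("weighing the distribution"
  read as decile stratification — a stated choice, not a parity claim).
* **Seeds.** Every stage derives its own stream from the single config
  seed via splitmix64 on an FNV-hashed stage name, so reruns are
  byte-identical and stages are independently reproducible.
* Feature filtering and selection run before the split (the classical
  workflow order); selection is therefore not leakage-free with respect
  to the test set, which matches the procedure being emulated.

## Learners

All learners share one contract (fit on a feature table, finite
predictions, metadata echoing hyperparameters). The native kNN uses
inverse-distance weights 1/d over the k nearest in standardized
Euclidean space; ties at the k-th distance include all tied neighbours,
and zero-distance neighbours return their unweighted mean (1/d is
undefined there). RF, RBF-SVM and gradient boosting are scikit-learn
adapters pinned to the classical benchmark hyperparameters (RF 230
trees/105 predictors per node, clipped to the feature count; SVM
σ = 0.03125 = sklearn's gamma on standardized features, C = 2,
ε = 0.05; boosting shrinkage 0.1, depth 7, 69 rounds). The boosting
engine is sklearn's rather than an external XGBoost build. Approximate
GP and perceptron-ensemble learners are not shipped; `register_learner`
is the adapter slot for them. A published "10-puzzle heuristic" for RF
tuning has no public definition; fixed Table-style values plus config
overrides are provided instead.

## Consensus and applicability domain

Consensus is the unweighted mean of the member predictions (equal
contributions, no weighting), which by the per-sample triangle
inequality never has worse MAE than the average member. STD-DM(J) is
the sample standard deviation (M−1 divisor over the M models) of the
predictions for molecule J — the per-molecule ensemble-disagreement
reading of the formula; the alternative reading (N = number of test
molecules) conflicts with its per-molecule use. The AD margin "three
times the STD-DM value" names no reference population; the calibration
constant here is the mean training-set STD-DM, with the multiplier
(default 3) and the reference both config-exposed. Coverage is the
percentage of test molecules in-domain. Note that training-set STD-DM
is computed on in-sample predictions, where ensembles agree more than
out-of-sample; on hard datasets this makes the domain conservative.

## Validation statistics

R² = 1 − SSE/SST throughout (the coefficient-of-determination form;
the squared-Pearson variant differs only off the identity line, and the
printed two-line definition of R²adj is internally consistent only with
this form). R²adj = 1 − (1−R²)(n−1)/(n−p−1) with p taken as the number
of selected features — "parameters in the regression equation" is
undefined for kernel/forest models, so this conservative, deterministic
proxy is used and is overridable. q² = (SST−PRESS)/SST accumulates
PRESS from out-of-fold predictions over target-stratified folds seeded
by the pipeline rule. Flags: q² ≥ 0.5 and q²ext ≥ 0.5 acceptability,
R²adj − q²ext > 0.3 over-fit. The Wilcoxon comparison of paired
absolute errors drops zero differences, uses the exact null for n ≤ 25
and the continuity-corrected normal approximation above (scipy's
implementation; validated in the tests against 2ⁿ sign-assignment
enumeration).

## Interpretation

* **Sensitivity.** 7 grid levels per feature spanning the observed
  range; non-varied features held at their *median* (robust to the
  skewed distributions typical of molecular descriptors). Scores are
  response variances normalized to sum to 1, hence invariant to affine
  response rescaling.
* **Fragment alerts.** Counts over molecules carrying the bit, split at
  pLD50 = 3.0 (config-exposed); strict majority above → positive,
  below → negative, tie → undetermined. Cramér's V and the stepwise
  ΔR²adj (OLS, base = the selected feature set minus the candidate) are
  attached; a rank-deficient augmented design sets a collinearity flag.
* **Scaffolds.** Murcko frameworks only (ring systems + linkers, side
  chains removed); ring-assembly/bridge-assembly/side-chain
  representations are vendor-specific and out of scope. Molecules with
  absolute consensus error above 1.0 are tabulated; scaffolds with
  frequency ≥ 2 are reported with their training/test abundance.

## Descriptors and fingerprints

Descriptor names follow the MOE-style vocabulary but values are RDKit
analogues — no name-for-name numeric parity is claimed. Mapping:

| name | implementation |
| --- | --- |
| MW, SlogP, SMR, TPSA | RDKit MolWt, Crippen logP/MR, topological PSA |
| a_acc, a_don, b_rotN, rings | RDKit HBA/HBD/rotatable-bond/ring counts |
| logS | Delaney ESOL estimate (log mol/L) |
| vdw_vol | Zhao atomic-increment volume with bond/ring corrections (Å³) |
| KierFlex | κ₁κ₂ / heavy-atom count |
| Kier1–3, HallKierAlpha, chi0v/chi1v, balabanJ, bertzCT, fCsp3, labuteASA | RDKit graph descriptors |
| a_nF/a_nN/a_nO/a_nCl/a_nS, a_aro, a_heavy | element/aromatic/heavy-atom counts |
| pmi1–3 | single ETKDG conformer, fixed seed; embedding failure ⇒ descriptor_fail |

The bundled fingerprint dictionaries are curated in-house subsets (47
SubFP-style and 56 PubChem-style bits) covering the classical alert
bits — trifluoromethyl, alkylfluoride, hetero-N basic H, heterocyclic,
N-count rules, C=N neighbourhoods — plus generic functional-group and
bond-environment bits. The full official 881/307-bit dictionaries are
not redistributable here but load from a user-supplied tab-separated
file (`index<TAB>SMARTS-or-countrule<TAB>description`).

## Synthetic data: what a green test establishes

`gen_sinc` is the standard sparse-regression benchmark (x ~ U[−10,10],
t = sin(x)/x + N(0, 0.05²)). `gen_feature_table` plants k informative
±1-coefficient features among iid normals. `gen_toy_molecules` builds
benzene/pyridine/cyclohexane/biphenyl cores with up to three
substituents and assigns pLD50 = 2.5 + 1.5·[CF₃] + 0.6·[alkyl-F] −
0.8·[C=N] + 0.3·rings + N(0, 0.3); effect sizes were chosen once so the
CF₃ alert is recoverable at n = 400 without being trivially separable,
and ≥ 99% of activities land in the plausible [0, 7] band.

These generators reproduce the *statistical structures* the method
assumes — sparse smooth signal, planted associations, fragment-driven
activity — but not real toxicity data: no multi-modal mechanisms, no
descriptor covariance structure of a real chemical library, no assay
noise heterogeneity, and a feature dimension (~100) far below the
~1100-column descriptor+fingerprint tables of production runs. A green
suite therefore establishes algorithmic correctness and recoverability
under known ground truth, not field performance on external sets.

## Known limitations

* The RVM is the classical full-design iteration, O(N³) per update; it
  is comfortable to N ≈ 2000 but does not implement the fast sequential
  basis-addition variant needed for much larger training sets.
* Single-conformer 3-D descriptors ignore conformational ensembles;
  tautomers are not enumerated.
* AD calibration on in-sample ensemble disagreement is conservative
  (see above); a leverage/Williams-plot AD is intentionally not
  provided.
* q² uses one seeded fold partition; repeat-CV confidence intervals and
  y-randomization are out of scope.
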