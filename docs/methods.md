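# Methods

## Problem and model

DNA-binding proteins (DBPs) drive replication, transcription and
chromatin organisation; predicting whether a protein binds DNA from
sequence alone is a long-standing binary classification task. This
package implements a profile-based predictor: each protein is
represented not by its raw sequence but by its PSI-BLAST
position-specific scoring matrix (PSSM), the L × 20 matrix `P` whose
entry `P[i, j]` is the log-odds score of amino-acid type `j` at
position `i`. Three descriptors summarise `P`, each is compressed by a
two-level discrete wavelet transform (DWT) into a fixed 512-length
vector, and gradient-boosted or ensemble tree classifiers are trained
and scored by stratified 10-fold cross-validation.

## Descriptors

All encoders first normalise the column axis to the fixed ordering
`ARNDCQEGHILKMFPSTWYV`, re-mapping whatever order a profile file
declares, so a permuted file cannot silently misalign features.

**F-PSSM (400-d).** Negative scores carry little discriminative signal
and can make unrelated sequences look alike, so they are clamped to
zero first. The descriptor is the 20 × 20 residue-type composition
matrix `M[a, j] = (1/L) · Σ_{i: seq[i]=a} P⁺[i, j]`, flattened
row-major. The exact dimension formulation of this descriptor is not
fixed by convention in the literature; we adopt the residue-grouped
400-d form and expose it behind the descriptor registry so a variant
(e.g. 20-d column means) can be swapped in without touching the
pipeline. Positions carrying a non-standard residue letter (X, B, Z, U)
have no composition row and are skipped in the grouping sum; their
score rows still participate in every column-wise descriptor.

**PSSM-DPC (400-d).** A dipeptide-composition analogue on profile rows:
`D[i, j] = (1/L) · Σ_{k=1}^{L-1} P[k, i] · P[k+1, j]`, ordered
(1,1), (1,2), …, (20,20). The `1/L` prefactor is kept exactly as the
source formulation prints it even though the sum has L−1 terms; a
`denominator="L-1"` switch gives the per-pair mean for anyone who
prefers the unbiased convention. The two differ by the constant factor
L/(L−1) per protein, which tree classifiers are insensitive to.

**R-PSSM (110-d).** The 20 columns are collapsed to a reduced
10-letter alphabet by averaging physicochemically similar columns:
G1 = (F+Y+W)/3, G2 = (M+L)/2, G3 = (I+V)/2, G4 = (A+T+S)/3,
G5 = (N+H)/2, G6 = (Q+E+D)/3, G7 = (R+K)/2, G8 = C, G9 = G, G10 = P,
giving the L × 10 matrix `R`. Because the grouping acts on columns, no
sequence row is ever dropped. From `R` we take the standard 110
features: 100 pseudo-dipeptide terms
`D[s, t] = (1/(2(L−1))) · Σ_i (R[i, s] − R[i+1, t])²` (s, t = 1…10,
row-major) followed by the 10 per-column mean-square deviations
`(1/L) · Σ_i (R[i, s] − mean_s)²`. This is the established way to
obtain exactly 110 features from an L × 10 profile; the source
formulation states only the count.

## Wavelet compression

Each descriptor signal is decomposed by an orthogonal filter-bank DWT:
low-pass and high-pass convolution followed by dyadic downsampling,
applied twice, with the second pass consuming the level-1
approximation. The concatenation `[cA2, cD2, cD1]` is truncated, or
zero-padded at the tail, to exactly 512 entries.

Choices that were genuinely open and how we fixed them:

- **Mother wavelet:** Haar (`db1`) by default — its two-tap filters
  make small examples exactly computable by hand — configurable to
  `db2…db38`.
- **Boundary handling:** periodization, so coefficient counts halve
  exactly and energy conservation `‖x‖² = ‖cA‖² + ‖cD‖²` holds to
  1e−8 and is asserted in tests.
- **Signal per descriptor:** F-PSSM-DWT and PSSM-DPC-DWT transform
  their 400-d vectors (yielding 400 coefficients zero-padded to 512);
  R-PSSM-DWT transforms the flattened L × 10 reduced profile — a
  length-dependent signal mapped to a fixed-length vector, which is
  the point of the compression step. Without DWT the R-PSSM pipeline
  falls back to the 110-d vector.
- **The 512 mapping:** truncate-or-pad of `[cA2, cD2, cD1]` is the
  simplest deterministic, linear rule that always yields 512; the
  linearity and determinism are property-tested.

## Classifiers

Four algorithm families sit behind one train/predict contract:
`lixgb` (LightGBM), `xgb` (XGBoost), `ert` (ExtraTrees) and `adaboost`
(AdaBoost). Default hyperparameters are the published configuration —
eta (learning rate) 0.1, 500 estimators, max depth 8, L1 (alpha) and
L2 (lambda) regularisation 1 — with every other backend parameter at
its library default. Backend parameter-name translation
(eta→learning_rate, lambda→reg_lambda, alpha→reg_alpha) is an explicit
mapping recorded on the trained model; parameters without a
counterpart (e.g. regularisation for ExtraTrees, tree depth for
AdaBoost's default stumps) are dropped and logged. The decision
threshold is 0.5 with ties classified positive — a convention fixed
here for reproducibility.

## Evaluation

Metrics follow the error-rate (Chou-style) formulation with H⁺/H⁻ the
true class sizes and fp/fn the error counts:
Acc = 1 − (fn+fp)/(H⁺+H⁻), Sn = 1 − fn/H⁺, Sp = 1 − fp/H⁻, and
MCC = (1 − (fn/H⁺ + fp/H⁻)) / √((1 + (fp−fn)/H⁺)(1 + (fn−fp)/H⁻)),
which is algebraically identical to the textbook confusion-matrix MCC
— an identity the suite verifies on 10,000 random tables. Metrics with
an empty denominator are reported as NaN, never silently zero.

Cross-validation is stratified 10-fold with seed-controlled shuffling
(the original protocol's fold seed and stratification are unstated, so
exact fold-level numbers are unreproducible by anyone; stratification
is the right default for near-balanced data). The headline report is
the arithmetic mean of per-fold metrics — matching the stated protocol
— with the pooled-confusion alternative also computed; the two
coincide exactly when folds are equal-sized, which is asserted on
balanced data.

## Synthetic data

Real profiles require a PSI-BLAST search of NCBI nr per protein, so
the test bed is synthetic: integer scores uniform on [−10, 13] (the
typical log-odds range), lengths uniform on [50, 150] (short protein
range, kept modest for fast encoding), 200 proteins per class, and a
class-dependent mean shift of 5.0 added to the first five score
columns (A, R, N, D, C) of positive-class profiles. The shift size was
chosen once as roughly 0.7 σ of the score distribution — large enough
that a working pipeline clearly separates the classes, small enough
that a broken encoder does not. With the shift at 0 the two classes
are identically distributed and any classifier must sit at chance,
which the suite checks against the 99% binomial band around 0.5 at the
n actually used (400 samples → [0.436, 0.564]).

What the generator does **not** emulate: positional autocorrelation of
real profiles, composition bias of real sequences, length–class
dependence, and the alignment-depth dependence of score magnitudes.
Passing tests therefore demonstrate that the pipeline is implemented
correctly and can learn a class-conditional profile signal — not that
it attains any particular accuracy on real DBP benchmarks, which
additionally depends on profile quality.

## Problem sizes and numerics

The benchmark pipeline runs at 200 proteins/class with 10-fold CV and
the default 500-estimator models (≈10 s on one CPU); unit tests use
smaller models where only the protocol, not model quality, is under
test. Oracle comparisons use absolute tolerance 1e−9 (encoders, DWT
filter bank), 1e−10 (wavelet reconstruction) and 1e−8 (energy
conservation). Degenerate inputs fail loudly: profiles shorter than 2
residues are rejected by the pairwise encoders, single-class datasets
and NaN features are rejected at training time, and metrics with empty
denominators are NaN.

## Known limitations

- Published benchmark accuracies on PDB14189-scale data are not
  reproduced here: they require PSI-BLAST profiles for ~16k sequences
  and unstated fold seeds. The pipeline supports rerunning them if
  profiles and labels are supplied (`dbp-idwt run --pssm-dir …`).
- Profile generation itself (PSI-BLAST) is out of scope; `read_pssm`
  consumes externally produced ASCII profiles.
- The F-PSSM and R-PSSM constructions follow the established
  conventions described above where the source formulations are
  under-specified; alternatives slot in behind the descriptor
  registry.
- mRmR / SVM-RFE feature selection (reported as not helping) and
  deep-learning baselines are not implemented.
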