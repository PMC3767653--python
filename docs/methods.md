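# Methods

## Model

`vhsecleave` treats proteasomal cleavage-site prediction as binary
classification of residue windows. Each candidate scissile bond is
described by the `2h` residues flanking it (`P_h…P1 | P1'…P_h'`), each
residue by a subset of its eight VHSE descriptors — PCA scores of
auto-scaled hydrophobic (VHSE1/2), steric (VHSE3/4) and electronic
(VHSE5–8) property panels. The descriptor table is a fixed constant of the
method, embedded in `vhse.py`; the package deliberately does **not**
re-derive it by PCA, since the underlying raw property matrices are not
part of the method's public parameterization. The per-column variance
fractions sometimes quoted for the retained components (74.33 / 78.68 /
77.9 %) are likewise not checkable from the table alone and are recorded
here only as context.

Feature vectors are position-major (all selected components of the most
upstream residue first, components in ascending index), a fixed ordering
on which the weight interpretation depends. The default selection is
(1, 3, 5): one lead component per property block, giving `2h × 3`
features; `±14` windows yield 84.

The classifier is a soft-margin SVM (scikit-learn's libsvm backend).
Features are scaled to [0, 1] by training-set min/max (test values clip;
constant columns map to 0). The paper-era solver's ε is interpreted as
the optimizer's convergence tolerance (`tol`, default 1e-3) — a
classification SVM has no regression tube. For the linear kernel the
primal weights `w = Σ αᵢyᵢxᵢ` and bias are stored explicitly alongside
the support-vector expansion; the two decision routes agree to 1e-8 and
this identity is tested.

## Corpus construction

Ligands (TSV: `peptide, source_id`) are located in their source proteins
by exact first-occurrence match (multiplicity warns; absence drops the
record). The bond following the ligand's C-terminal residue is the
positive site; the bond following its middle residue — `ceil(L/2)`-th
residue, keeping the bond interior for even lengths — is the negative
site. Windows lacking full `±h` context are dropped per sample rather
than per protein, which generalizes the "discard sequences shorter than
the window" rule to any half-width. Duplicate `(window, label)` pairs are
collapsed; a window attested with both labels keeps only the cleavage
copy, because positive evidence outweighs the positional heuristic that
generated the negative. All drops are tallied by reason and written to a
drop log. Coordinates are 0-based in memory and 1-based in files.

## Hyperparameter search and evaluation

Cross-validation is stratified k-fold (default 10), shuffled once with a
required seed (default 20130909). Decision values are pooled over folds
before computing metrics, so each grid setting gets a single
MCC/AUC/Acc/Sen/Spe row; per-fold averaging is the main alternative
convention and would give slightly different numbers. The scaler is refit
inside each fold. Selection maximizes MCC with ties broken by AUC, then
smaller C, then smaller γ. The default grids are coarse log grids,
C ∈ 2^{−5..5}, γ ∈ 2^{−7..3} (step 2²).

Metrics follow the standard confusion-matrix definitions with cleavage as
the positive class; Acc/Sen/Spe are percentages, MCC returns 0 when any
marginal is empty, and AUC is the Mann–Whitney statistic with midrank
(half-credit) tie handling. Undefined rates return a `None` sentinel
rather than raising. Rank-AUC is cross-checked against trapezoidal ROC
integration, and MCC against an independent implementation, in the test
suite.

## Weight interpretation

`interpret.position_weights` reshapes a linear model's weight vector
through the feature map into a (position, component) grid. Weights are
reported in the scaled-feature space where the model lives; `raw_space`
divides each weight by its feature's training range for
per-descriptor-unit comparability. Whether published weight plots of this
kind are in scaled or raw space is generally ambiguous, so magnitude
comparisons with external figures are approximate by nature.

Residue preferences at position p score each amino acid a as
`Σ_k w(p,k) · scaledVHSE_k(a)` using the model's own scaler (so rankings
are invariant to the scaling choice); the top/bottom k (default 4) form
the favored/unfavored sets. Site favorability sums these scores over
supplied flanking residues, listed from the bond outward. With the
model's scaler and a full window this equals the decision value minus the
bias — an identity the tests verify numerically. The hydrophobicity
contrast is the mean upstream VHSE1 weight minus the mean downstream
VHSE1 weight, with per-side sign counts; positive values reproduce the
hydrophobic-before / hydrophilic-after signature of proteasomal
substrates.

## Synthetic data

The generator emulates the statistical structure of cleavage corpora, not
proteome biology: proteins are i.i.d. uniform over the 20 canonical
residues (uniformity maximizes descriptor variance per sample, sharpening
recovery tests; empirical frequencies can be supplied), and each bond
with full ±10 context receives a latent score

    s = β_P1·VHSE1(P1) + β_up·mean VHSE1(P2…P10)
        − β_down·mean VHSE1(P1'…P10') + N(0, noise_sd)

Bonds with `s > threshold` become planted sites, reported as 8–12-mer
ligands ending at the site. Defaults — 40 proteins × 300 residues, up to
1200 ligands, β_P1 = 2, β_up = β_down = 1, threshold = 2, zero noise —
select roughly the 15 % most favorable bonds and produce ≈2,200 labeled
windows, large enough for stable 10-fold CV yet fast (seconds on one
CPU). Setting all β to 0 with a permissive threshold yields a null corpus
whose labels carry no sequence signal, used as the calibration control.

What passing the recovery tests shows: the pipeline can localize a known
VHSE1-mediated rule and quantify its upstream/downstream asymmetry. What
it does not show: performance on real ligand data, where residue
composition is non-uniform, negatives are only heuristic, MHC binding
biases the positives, and effect sizes are far smaller.

## Numerical and design choices

- Non-canonical residues (B, J, O, U, X, Z) are rejected, never imputed;
  affected samples are dropped with logged counts. The descriptor table
  defines 20 rows and any imputation would be invented chemistry.
- Labels are +1 (cleavage) / −1 (non-cleavage) everywhere; prediction is
  by sign of the decision value, with 0 mapped to non-cleavage.
- Residue rankings break exact score ties alphabetically; an all-zero
  profile is flagged degenerate instead of producing an arbitrary order.
- Model files are single JSON documents (kernel, hyperparameters, scaler,
  support expansion, explicit weights, feature map, provenance hash of
  the training file); loading reconstructs decision values to 1e-12.
- CLI outputs are written via temp-file-plus-rename, so identical inputs
  and seeds reproduce byte-identical artifacts.
- Simulation streams derive from a single config seed
  (`default_rng([seed, stream])`), making every output a pure function of
  the configuration.

## Limitations

- The negative-site heuristic (ligand middles) mislabels any genuinely
  cleavable middle bond; on synthetic data this bounds attainable
  accuracy below 100 % by construction.
- Pooled-over-folds CV metrics are not comparable to per-fold means at
  the third decimal.
- RBF models are supported for training and prediction but are opaque to
  the weight-interpretation module by design.
- Reproducing published benchmark figures for this model family requires
  the corresponding deposited descriptor matrices; the package ships the
  ingestion pathway (`train --features`) but no external data.
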