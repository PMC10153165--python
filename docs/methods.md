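# Methods

This note documents the models implemented in `envi-covet`, the choices
made where the design was genuinely open, and what the synthetic data can
and cannot tell you about behavior on real tissue.

## COVET: the covariance environment

Each cell's niche is its k spatially nearest neighbors (Euclidean distance
on the segmented coordinates; default k = 8, the immediate neighborhood in
most tissues). The niche matrix Eᵢ ∈ ℝ^{k×g} is summarized by the
*shifted* covariance

Σᵢ = (1/k)(Eᵢ − X̄)ᵀ(Eᵢ − X̄),

with X̄ the mean expression over all cells of the dataset rather than the
niche's own mean. Using one common reference makes the matrices directly
comparable across cells while preserving positive semi-definiteness (each
Σᵢ is a Gramian); substituting the niche mean recovers the classic
covariance exactly, which the tests exploit as an oracle.

**Distances.** Treating each Σ as the covariance of a zero-mean Gaussian,
the exact optimal-transport metric is the Fréchet (Bures) distance
Tr Σᵢ + Tr Σⱼ − 2 Tr (Σᵢ½ Σⱼ Σᵢ½)½. Swapping the square root and product in
the cross term yields the AOT approximation, which collapses to
‖Σᵢ½ − Σⱼ½‖_F — Euclidean distance between matrix square roots. We report
the *unsquared* Frobenius norm (a true metric; the swapped-trace
expression is its square). Since the map is monotone, kNN graphs,
clusterings and embeddings built on either convention are identical. For
commuting matrices AOT² equals Fréchet exactly; on random 16×16 Gramian
benchmarks the two metrics' pairwise rankings agree at Spearman ≈ 0.99
(regression bound 0.95 in the test suite). The Bhattacharyya distance
(zero-mean Gaussian form, ½ ln det((A+B)/2) − ¼ ln det A det B) is provided
for cross-checks, with a ridge of 1e-6 × mean diagonal because COVET
matrices with k < g are rank-deficient.

**Numerical details.** Matrix square roots use symmetric
eigendecomposition; eigenvalues below 1e-12 × λ_max (including negative
round-off) are clipped to zero. The Fréchet cross term is computed in the
symmetrized form (Σᵢ½ Σⱼ Σᵢ½)½, which has the same trace as (ΣᵢΣⱼ)½ for PSD
inputs but avoids rooting a non-symmetric product. Pairwise AOT is a
single `pdist` over flattened MSQRs. kNN ties (e.g. gridded coordinates)
break by ascending cell index, making niches deterministic.

**Niche transform.** Raw counts are the default (the defining equations
act on expression directly); a `log1p` option exists and is what we use
for diffusion-component analyses. On raw counts the Frobenius geometry is
dominated quadratically by the highest-expressed genes, which makes the
leading diffusion component sensitive to which genes the random loadings
amplify; on log1p niches the pseudo-axis recovery on synthetic tissue is
stable across seeds (|Spearman| ≈ 0.999 with the generative axis).

**Averages and pseudo-axes.** The AOT (Fréchet) mean of a set of COVET
matrices is the square of the mean of their MSQRs. Pseudo-spatial axes are
diffusion components: a kNN graph (default k = 30) on flattened MSQRs with
a Gaussian kernel, a single global bandwidth equal to the median distance
to the ⌈k/2⌉-th neighbor, max-symmetrization, and eigendecomposition of
the row-normalized transition operator (via its symmetric conjugate); the
trivial constant eigenvector is dropped and each component's sign is fixed
so its correlation with the first input feature is non-negative. A global
bandwidth is used rather than a per-point adaptive one because the
adaptive kernel distorts ordering at boundary points (visible as endpoint
inversions on a 1-D path).

## MSSI: multiscale spectral similarity

MSSI adapts multiscale SSIM from image quality assessment to segmented
cells. The spatial kNN graph (default k = 8, matching the niche size; the
choice is exposed) replaces the pixel lattice, and image downsampling is
replaced by graph coarsening: heavy-edge matching pairs each node with its
heaviest-edged unmatched neighbor (peripheral, low-degree nodes matched
first), halving the node count per level; signals are mean-pooled with
weights proportional to the number of original cells per node, so values
at every level remain means over cells. Five levels (four coarsenings) are
used. Disconnected components coarsen independently; isolated nodes pass
through.

At each level the standard SSIM components are computed with
C1 = (0.01 M)², C2 = (0.03 M)², C3 = C2/2, where M is the maximum of the
two pooled signals at that level. Signals are min-max normalized once at
the original scale and never re-normalized after pooling; a constant
signal is left unnormalized (degenerate min-max). The luminance term
enters only at the coarsest level; contrast and structure at all levels;
exponents are the canonical MS-SSIM weights. A negative structure term
(anti-correlation) is clipped to zero, so anti-correlation at any level
gives MSSI = 0. Consequences asserted in the tests: range [0, 1],
symmetry, identity = 1, invariance to positive affine maps of either
input, and higher sensitivity to spatial scrambling than to iid noise at
matched per-cell correlation.

## ENVI: environmental variational inference

A conditional VAE with a binary auxiliary neuron c (0 spatial, 1
single-cell) appended to the encoder and expression-decoder inputs. The
encoder reads panel expression (single-cell profiles are reduced to the
imaged panel) and returns a diagonal Gaussian posterior; sampling uses the
reparameterization l = μ + ε·σ. Internally the encoder sees log1p counts —
a numerical-stability choice for a plain ReLU MLP on raw counts; all
likelihoods are still evaluated on the raw counts.

The expression decoder maps (latent, c) to count-distribution parameters:
the full transcriptome under the single-cell family for c = 1, the imaged
panel under the spatial family for c = 0. Only the first g_st rate units
of the output layer are shared between modalities; the remaining units
train exclusively on single-cell batches and absorb technology-specific
structure beyond what the auxiliary neuron can express. Rates use
softplus (+1e-6); success probabilities use sigmoid clamped to
[1e-6, 1 − 1e-6]. Non-rate parameters (NB p, ZINB dropout, normal scale)
are per-gene and separate per modality — the simpler of the two granularity
options the design allows.

The environment decoder maps the latent alone (no auxiliary neuron,
matching the defining equations) through its own trunk to
g_cov(g_cov+1)/2 outputs filling the lower triangle of a Cholesky factor
L; the Gramian L Lᵀ is the predicted COVET MSQR and the mean of an
identity-covariance Gaussian, so its log-likelihood is (up to constants)
−½ ‖Σ½ − L Lᵀ‖² — the squared AOT distance. g_cov is the COVET gene subset
(default 64 panel HVGs), not the full panel.

**Training.** MSQR targets for every spatial cell are computed once before
optimization. The loss is the negative ELBO: per-cell gene-summed count
log-likelihoods for both halves of the batch, the environment Gaussian
term for the spatial half, and β × the closed-form diagonal-Gaussian KL,
each averaged over cells. Batches draw half their cells from each
modality, sampled with replacement from a seeded generator; ADAM with a
constant learning rate (default 1e-4; an optional lower rate for the final
quarter of steps is available — the published schedule's wording on this
point is contradictory, so the constant rate is the default). Per-step
cost is independent of dataset size. Training is deterministic given the
seed in single-threaded execution.

**Inference.** Imputation encodes spatial cells with c = 0, takes the
posterior mean (deterministic; a sampling flag exists), decodes with
c = 1 under the single-cell family and returns the distribution mean
(NB: r(1−p)/p; ZINB additionally scaled by 1 − dropout). Niche inference
encodes dissociated cells with c = 1 and applies the environment decoder;
the outputs are MSQRs directly comparable under AOT.

**Implementation.** All networks run on `envi.autodiff`, a small
vectorized reverse-mode automatic-differentiation engine over numpy
arrays (the gamma-function terms of the NB/ZINB likelihoods differentiate
through `scipy.special.digamma`). Gradients are verified against finite
differences in the test suite. Compute is dominated by BLAS matmuls.

## Synthetic tissue

`generate_tissue` emulates a paired experiment on a laminar tissue. Cells
are uniform in the unit square; y is the band axis. Programs: n_zones
logistic zone bumps (transition width 0.03 of the axis) plus two opposing
linear gradients (strength 2.0) mimicking axial morphogen gradients —
together the discrete-layer and continuous-gradient regimes the methods
are used on. Activities get Gaussian noise (σ = 0.05) and are clipped at
zero. A non-negative gamma loading matrix maps programs to genes, with
each program's strong markers strided across the gene list so the imaged
panel (the first g_panel genes) contains markers of every program; rates
are scaled to a mean of 4 counts plus a 0.2 baseline — a FISH-like count
depth. Spatial counts are Poisson(rate); single-cell counts are
NB(r = 4, p = r/(r+rate)) (the r-failures/success-p convention with pmf
∝ (1−p)^k p^r, mean = rate), emulating overdispersed sequencing counts.

Eight unimaged genes duplicate the rate columns of randomly chosen panel
genes, giving imputation a noiseless ground truth. The first
min(n_spatial, n_sc) single-cell profiles re-draw the *same* generative
state (position, activity, rates) as the spatial cell with the same
index, enabling the matched-vs-shuffled niche-inference oracle; surplus
cells on either side are drawn fresh. All draws flow through one seeded
generator: identical arguments give bitwise-identical outputs.

What the generator does **not** model: segmentation error, optical
crowding, cell-density gradients, batch effects within a modality,
discrete cell types unrelated to position, or genes whose truth is not a
function of imaged programs. Passing tests therefore demonstrate that the
machinery recovers structure it is designed for; they do not quantify
robustness to imaging artifacts or to biology outside the panel's span.

`random_covariance_set` (Gramians of standard-normal g×g matrices,
default 64×64) and `random_count_datasets` (Poisson(10) spatial counts
over 128 genes; NB(10, 0.8) single-cell counts over 2048 genes, first 128
genes shared) reproduce the random benchmark inputs used for the metric
and trainer stress tests.

## Evaluation protocol

Imputation is scored per gene on log(x + 0.1) profiles with Pearson
correlation and with MSSI on the same coordinates; zero-variance genes
report NaN rather than a silent zero. Cross-validation partitions the
panel into folds (five-fold for hundreds-of-genes panels, leave-one-out
for small ones), removes each fold from the spatial panel *and the encoder
input*, retrains from scratch, and assembles predictions so every gene is
scored exactly once. Label transfer uses a kNN classifier (default k = 5,
Euclidean; vote ties go to the class with the smallest mean distance) and
is scored with balanced accuracy — macro-averaged per-class recall, the
conventional multi-class reading of averaging sensitivity and specificity.
A one-sided paired t-test across genes is provided for method comparison;
identical score vectors give p = 0.5 by convention.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run the model pipeline at a
reduced scale chosen as the package's standard desk-scale configuration:
2000 spatial + 2000 single-cell synthetic cells, 64-gene panel, 256-gene
transcriptome, and a latent-32 / 2×128-hidden / 2000-step / batch-256 /
lr 1e-3 training configuration. At this scale the end-to-end oracles are
comfortably cleared (duplicate-gene imputation Pearson(log1p) ≥ 0.9,
matched-cell niche AOT ≈ 0.65 of shuffled, |DC1–axis Spearman| ≈ 0.999)
and a full run takes about two minutes on one CPU. Full-size defaults
(latent 512, 3×1024, 2¹⁴ steps, batch 1024) are unchanged and used when no
explicit configuration is passed.

## Known limitations

* The AOT metric is an approximation; rank agreement with exact Fréchet is
  high but not perfect, and degrades as matrices become more
  non-commuting.
* MSSI's coarsening is one structure-preserving choice among many; scores
  are comparable only across runs using the same coarsener and k.
* The CVAE shares one latent across modalities; systematic biology present
  in only one modality can leak into the technology terms (shared output
  units vs single-cell-only units) in ways no synthetic check here
  exercises.
* Bhattacharyya distances depend on the ridge for rank-deficient COVET
  matrices (k < g); use AOT/Fréchet for quantitative work in that regime.
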