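# Methods

`ishnet` implements a two-part analysis of regional gene expression in
brain tissue: a semi-quantitative scoring schema for in situ
hybridization (ISH) section images, and a weighted gene co-expression
network analysis (WGCNA-style) of gene × sample expression matrices,
together with synthetic data generators that plant known ground truth
for both parts.

## ISH expression scoring

ISH stains tissue where a transcript is present, but stain darkness is
not proportional to copy number, so expression is scored on ordinal
scales rather than measured. Input images are 8-bit grayscale (0 =
strongest signal, 255 = white background); RGB inputs are converted by
the unweighted channel mean rounded half-up (the plain 8-bit conversion
of common image tools; ITU-R 601 luminance weighting is available as an
option). Each section comes with a matched Nissl-stained reference —
a pan-cellular stain whose positive pixels approximate the
cell-occupied area — and an integer label mask assigning pixels to
named anatomical regions of interest (ROIs).

Per ROI and section the schema computes:

* **Intensity scale L (0–7).** A fixed 8-bin pseudocolor lookup table
  partitions gray levels 0–255: 0–31 → 7 (red), 32–63 → 6 (dark
  orange), 64–95 → 5 (orange), 96–127 → 4 (yellow), 128–159 → 3
  (green), 160–175 → 2 (blue, RGB (0,123,255)), 176–191 → 1 (dark
  blue), 192–255 → 0 (black, no signal). The mean gray value of the
  ROI's *expressing* pixels is looked up in this table. Expressing
  pixels are those below the no-signal bin start (gray < 192,
  configurable); the pseudocolor rendering itself is purely a
  visualization and never enters the computation.
* **Density scale D (1–4).** The percentage Np of expressing ISH
  pixels relative to Nissl-positive pixels in the same ROI, binned
  0–5% → 1 (sparse), 5–20% → 2 (scattered), 20–70% → 3 (medium),
  >70% → 4 (wide-spread). The physical pixel area (0.17 μm² in the
  source imagery) cancels in the ratio and is kept only as a documented
  constant; Np is capped at 100 because numerator and denominator come
  from different images. A section with no expressing pixel records
  L = 0, D = 0.
* **Expression factor E (0–28).** Over the 2–3 sections of one
  sectioning plane, E is the mean of the per-section products
  L_i × D_i. The alternative product-of-averages reading
  E = mean(L) × mean(D) coincides whenever D is constant across
  sections and is exposed as a switch; the mean of products is the
  default because it matches the three-section worked form
  [L1·D1 + L2·D2 + L3·D3]/3. E is categorized as none (E = 0),
  very low (0 < E < 6), low [6, 11), moderate [11, 17), high [17, 22),
  very high [22, 28].

Boundary conventions: all bin lookups use lower-inclusive half-open
intervals (mean gray in [lo, hi+1), with 255 falling in the last bin;
Np and E bins half-open with the last bin closed). The published scale
definitions use strict inequalities that leave the boundary values
unassigned; the half-open convention makes every lookup total and
deterministic. Scoring contains no randomness at all.

Multi-plane combination (lateral/parasagittal/midsagittal) is not
prescribed by the schema; the package reports per-plane E and, when a
single value per structure is needed, an unweighted mean across planes
(the matrix builder averages duplicate gene–region records). Watershed
splitting of touching signal blobs is available as an option; it
affects only blob-level statistics, never the pixel counts that enter
Np. Images are assumed background-corrected upstream; the mean gray is
taken directly from the input values.

## Expression matrices and clustering

Scored records assemble into a genes × regions matrix of expression
factors (duplicates averaged, missing cells filled and flagged). Both
axes are clustered by average-linkage agglomeration, by default on
Euclidean distance of the raw E values — robust for small ordinal
matrices — with 1 − Pearson correlation and per-gene z-scoring
available as flags. Axis items are sorted lexicographically before
linkage so ties resolve deterministically by label. Exports are a
reordered matrix TSV, Newick dendrograms with branch lengths, and a
rendered heatmap; identical inputs re-export byte-identically.

## Weighted co-expression networks

For a genes × samples matrix (samples are brain regions or
structures; per-gene z-scoring is a flag, default on in the CLI since
relative expression profiles, not absolute levels, drive the analysis):

1. **Correlation.** Pearson correlation across samples (≥ 3 samples;
   zero-variance genes are an error naming the gene).
2. **Soft-threshold adjacency.** a_ij = |cor_ij|^β (unsigned, default)
   or ((1+cor_ij)/2)^β (signed). β defaults to 6, the conventional
   unsigned choice; a scale-free-fit scan reports the R² of the
   log-log connectivity fit for choosing β from data, but no fit is
   enforced. The diagonal is fixed to 0 so connectivity k_i = Σ_u a_iu
   excludes self-connections.
3. **Topological overlap.** tom_ij = (l_ij + a_ij) /
   (min(k_i, k_j) + 1 − a_ij), l_ij = Σ_{u≠i,j} a_iu·a_uj — the
   standard unsigned formula crediting shared neighbours as well as the
   direct edge. Denominators below 1e−12 are guarded; the diagonal is 1.
4. **Module detection.** Average-linkage clustering of 1 − TOM with a
   static cut: merge heights are min–max rescaled to [0, 1] and the
   tree is cut at `cut_height` *below the root* (default 0.25), i.e.
   branches fusing within the top quarter of the height range become
   separate modules. Anchoring the cut to the root makes one setting
   usable across datasets whose raw 1 − TOM heights occupy different
   ranges; in unstructured data merge heights pile up near the root, so
   the same cut shatters noise into sub-minimum fragments. Clusters
   smaller than `min_size` (default 16) are unassigned; modules whose
   eigengenes correlate above `merge_kme` (default 0.8) are merged
   iteratively; final ids are 1, 2, … by decreasing size. The full
   dynamic tree-cut algorithm is deliberately out of scope.
5. **Module summaries.** The module eigengene is the first right
   singular vector of the z-scored member submatrix (unit norm, sign
   oriented so the mean member correlation is non-negative), with
   variance explained reported. Module membership kME = |cor(gene,
   eigengene)| with two-sided p-values from the t-transform
   t = r·√((n−2)/(1−r²)) at n−2 degrees of freedom; p-values are raw by
   default (Benjamini–Hochberg available). Intramodular connectivity
   kIM_i sums a gene's adjacency to same-module genes; the top-kIM
   genes are the module's hubs. For module network plots, node and
   edge betweenness are computed on the thresholded module graph with
   edge length 1 − weight (floored at 1e−9 so equal-weight ties
   resolve to the direct edge), unnormalized over all source–target
   pairs, per component when disconnected.
6. **Module preservation (Z_summary).** For each reference module the
   test network yields two observed statistics: density = mean
   within-module adjacency, and connectivity = Pearson correlation
   between the reference and test within-module kIM vectors. Each is
   standardized against a null of `n_perm` (default 200) equally sized
   random gene sets drawn from the shared genes (seeded), and
   Z_summary is the mean of the two Z scores — a reduced form of the
   multi-statistic composite used in the WGCNA preservation framework,
   read on that framework's conventional thresholds: < 2 no evidence,
   2–10 weak, > 10 strong preservation. Genes are matched between
   datasets by exact name; modules with fewer than 3 shared genes are
   skipped with a warning. A degenerate null (e.g. identical reference
   and test data make the connectivity statistic exactly 1 for every
   gene set) gives Z = 0 for that statistic: an observation
   indistinguishable from its null carries no evidence. Note that
   Z_summary, being the mean of two nearly independent Z scores, has a
   null standard deviation of about 1/√2; the individual permutation
   Z statistics are the quantities that are standard normal under the
   null, and that is what the calibration tests check.

## Synthetic data

The generators replace two data sources that cannot ship with the
package: ISH section images of the kind curated in the Allen Brain
Atlas, and region × gene microarray matrices of the kind distributed
by the Allen Human Brain Atlas.

* **ISH fixtures.** Rectangular ROIs on a background drawn uniformly
  from gray 200–255; within each ROI exactly round(p × area) pixels —
  an exact count, not per-pixel Bernoulli draws, so density tests are
  exact — receive signal gray from N(μ, σ) clipped to [0, 191]
  (clipping bias is negligible when μ is ≥ 3σ from bin edges, which
  the fixture contract requires). The Nissl mate marks every ROI pixel
  positive. The truth table carries the planted (p, μ, L, D, E).
  These fixtures emulate the scoring-relevant features only: they have
  no anatomy, no staining gradients, no registration error, so passing
  round-trip tests validates the scoring arithmetic, not robustness to
  real histology.
* **Co-expression fixtures.** Module m has a latent factor u_m
  (standard normal over samples); member genes are
  √ρ·u_m + √(1−ρ)·ε, giving expected within-module correlation ρ and
  zero between modules; noise genes are pure ε. Defaults: module sizes
  (16, 40, 70) — spanning the size range typical of small
  co-expression studies — ρ = 0.8, 60 samples, and 600 background
  noise genes. The background size matters for the permutation null:
  when nearly all genes belong to a few strong modules, random gene
  sets themselves carry reproducible module structure across datasets,
  which inflates the null mean of both preservation statistics and
  biases Z scores downward; a background-dominated pool — the
  realistic regime, since a module of tens of genes is a tiny fraction
  of any transcriptome — keeps the null honest. Preservation pairs are
  two independent draws sharing the module layout, optionally with one
  module's test-side genes replaced by pure noise (the "scrambled",
  non-preserved condition). Because members within a module are
  exchangeable (equal loadings), these fixtures probe density-based
  preservation; they cannot emulate hub-gradient preservation, which
  real modules with kME gradients would show.

All generators are bit-reproducible under their seed.

## Problem sizes and limitations

The test and acceptance experiments run at desk scale: section images
of a few hundred pixels square with ROIs of 10⁴ pixels, networks of
~130 module genes plus 600 background genes over 60 samples, 200
permutations. These recover planted truth exactly (ISH round trip),
at adjusted Rand ≥ 0.9 (module detection), and separate preserved
(Z_summary > 10) from scrambled (< 2) modules.

What the package does **not** reproduce: the original atlas-scale
findings — specific module memberships, hub gene identities,
transcription-factor target predictions and GO enrichments of the
Allen Human Brain Atlas analysis — require the actual atlas downloads,
licensed TFBS software and external annotation databases. They are
replaced here by the synthetic property experiments above, which test
the machinery (scoring arithmetic, module detection, hub ranking by
intramodular connectivity, permutation preservation) rather than the
biological conclusions. Likewise ISH image quality control,
registration to a reference atlas and μm-calibrated morphometry are
out of scope; the label mask is taken as given.
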