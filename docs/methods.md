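# Methods

## Pipeline overview

The package implements the standard binary-graph analysis of resting-state
functional connectomes for a two-group (patient vs. control) design:

1. **ROI-level denoising.** Inputs are region-averaged BOLD series
   (volumes x 90 AAL regions, TR = 1 s). The first 10 volumes are
   discarded; subjects whose rigid-body motion exceeds 1.5 mm translation
   or 1.5 degrees rotation on any axis are excluded; each regional series
   is residualised on an intercept, a linear trend, the Friston-24 motion
   expansion (6 parameters, their one-volume lags, and both sets squared)
   and the global signal, then band-passed to 0.01-0.08 Hz. Framewise
   displacement (FD) follows the sum-of-absolute-differences convention
   with rotations converted to arc length on a 50 mm sphere; mean FD is
   carried forward as a subject-level covariate. The order discard ->
   nuisance regression -> band-pass is fixed; residualisation is an
   orthogonal projection and therefore idempotent.
2. **Network construction.** Pearson correlations between all region
   pairs, Fisher r-to-z (off-diagonal |r| >= 1 is clipped to 1 - 1e-7
   with a warning), then binarization at each sparsity S in
   0.032:0.01:0.492 by keeping the k = round(S x N(N-1)/2) largest
   weights (round half away from zero; grid values are generated from
   integer indices so no floating-point drift accumulates). Ranking is
   signed (most-positive correlations become edges); an absolute-value
   ranking is available via `rank="abs"`. Ties are broken by (i, j)
   index order, making the sweep fully deterministic; the 47 edge sets
   are nested by construction.
3. **Graph metrics.** Cp, Lp, E_glob, E_loc and the nodal metrics use the
   standard binary definitions. Conventions that differ between
   toolboxes are fixed as follows: Cp and E_loc average over all N nodes
   (degree < 2 contributes 0); Lp averages hop distance over *connected*
   ordered pairs and emits a fragmentation warning (the sparse end of
   the sweep can fragment); E_glob counts unreachable pairs as zero
   efficiency; betweenness is unnormalised with endpoints excluded.
   gamma, lambda, sigma normalise Cp and Lp by the mean over
   degree-preserving Maslov-Sneppen surrogates (double edge swaps, 10x
   the edge count per surrogate, swap proposals rejected if they would
   create self-loops or duplicate edges; a complete graph admits no swap
   and returns the observed values with a warning). The default
   ensemble size is 1000 surrogates per network; the heavy validation
   runs in this repository use 20-100 per network, which changes the
   normalising means by well under the group differences probed.
4. **AUC group inference.** Each subject's metric curve is integrated
   over the sweep by the trapezoid rule (the summation scheme is not
   canonical; trapezoid was chosen and is stated here). AUCs enter an
   OLS GLM with intercept, group (patient = 1), and mean-centred age,
   sex, education and mean FD; the reported statistic is the group
   coefficient's t with n - p degrees of freedom. Global metrics are
   tested uncorrected at alpha = 0.05; nodal metrics are
   Bonferroni-corrected within each metric (family = 90 nodes; the
   family definition is configurable). Zero-variance outcomes return
   t = 0, p = 1 with a warning rather than NaN.
5. **Network-based statistics.** Edge-wise t maps from the same GLM,
   thresholded at the t equivalent of two-tailed edge-level p < 0.01
   (configurable as a p or t value; the primary threshold is a free
   parameter of the method). The two directions (patient > control,
   patient < control) are run as separate one-tailed analyses, each
   FWE-controlled at 0.05. Component size is counted in edges;
   significance comes from the max-component-size distribution over
   permutations of the group labels (covariates stay attached to their
   subjects), with the +1-corrected p convention
   p = (1 + #{null >= obs}) / (1 + B), which is never zero and is
   monotone in the observed size. The default is B = 5000; validation
   runs use B = 1000 (resolution 0.001, ample at alpha = 0.05).

All heavy graph kernels (all-pairs BFS, per-neighbourhood efficiency,
Brandes betweenness, double-edge-swap nulls) are numba-compiled; a full
47-level sweep with a 20-surrogate ensemble per network runs in a few
seconds per subject on one CPU. networkx implementations serve as
independent oracles in the test suite, never as the computational path.

## The synthetic cohort

The generator emulates the study conditions the pipeline assumes: 30
patients and 24 healthy controls, 400 volumes at TR = 1 s (390 after
discard), 90 regions, signal content confined to 0.01-0.08 Hz. Each
region is a linear mixture of independent unit-variance band-limited
Gaussian latents, so the implied covariance is positive semi-definite by
construction:

* 6 spatial modules of 15 regions (primary coupling c = 0.70 in controls,
  0.56 in patients) with secondary loadings on a neighbouring module at
  0.643 c (overlapping communities);
* a global signal (coupling 0.20) and unit-variance private noise;
* 45 strong inter-module hub pairs (dedicated pair signals, coupling
  1.316 ~ pair correlation 0.5) forming a long-range backbone across a
  ring-plus-chords module graph;
* a tightly coupled mesiotemporal clique (bilateral hippocampus,
  parahippocampus, amygdala; shared signal, coupling 0.8) present in
  both groups;
* planted patient effects: (i) reduced within-module coupling in
  patients, which lowers the SNR of their correlation structure and
  thereby Cp and E_loc of the thresholded networks; (ii) two 15-edge
  chains of triangles with group-specific pair-signal amplitudes 1.2
  (an occipital/precuneus/fusiform cluster strengthened in patients, an
  inferior-frontal/temporal cluster weakened) — triangles rather than
  paths so the affected nodes keep interconnected neighbourhoods;
  (iii) a nodal deficit at the right amygdala: in patients 75% of its
  systematic signal content (module + clique) is replaced by an
  equal-variance private signal, stripping the node of its cliquish
  neighbourhood.

Regions carrying planted effects are excluded from the hub backbone so
the injected group differences are not confounded with hub structure.
Covariates are synthetic: age ~ N(55, 10) patients / N(42, 10) controls
(an age gap is deliberately present so covariate adjustment is
exercised), sex ~ Bernoulli(1/2), education ~ N(12, 3). Motion is a
mean-reverting AR(1) walk scaled by `motion_scale` (default 0.2 mm;
rotations scaled by 1/50 so both families contribute comparably to FD);
a configurable fraction of subjects can be forced over the QC bounds.
Every random stream derives from (cohort seed, subject index, stream
id), so cohorts are byte-reproducible and a subject's data do not depend
on cohort size.

Planted-effect magnitudes are free parameters, not estimates of any real
effect size; they were chosen so that recovery at a 15+12-subject scale
is unambiguous (group t around 4-7 for the targeted quantities).

### What the generator does and does not emulate

It reproduces the statistical structure the analysis depends on: a
band-limited modular covariance, small-world binary networks over the
sweep, hub edges, motion traces with a QC-relevant tail, and group
differences of the three kinds the pipeline is designed to detect.
It does not emulate scanner artefacts, physiological noise spectra,
spatial autocorrelation between neighbouring parcels, hemodynamic
response variation, or motion-BOLD coupling; passing recovery tests here
demonstrates the pipeline's correctness and sensitivity under its own
assumptions, not robustness to those real-data complications.

### Known limitation: normalized path length at the sparsest thresholds

On group-mean networks, gamma > 1 and sigma > 1 hold at every grid point
with wide margins, and lambda ~ 1 (sweep mean ~1.05) for s >= ~0.06. At
the three sparsest thresholds (128-208 edges on 90 nodes) lambda rises
to ~1.2-1.5: the sparse skeleton of a correlation-threshold graph is
more locally ordered than its degree-preserving null whenever it is
clustered enough to satisfy gamma > 1. This appears to be intrinsic to
latent-factor covariance models — configurations with rich-club signals,
extra cliques, orthogonal secondary partitions, coupling heterogeneity
(continuous and bimodal core-periphery), integration-hub mixtures and
stride-matching backbones were all evaluated and land in the same range
— whereas empirical connectomes escape it through high-degree hubs with
spatially graded correlation profiles that this model class cannot
produce at realistic couplings. The small-world acceptance check
therefore asserts gamma and sigma per grid point and lambda on the sweep
mean.

## Validation problem sizes

The repository's own validation runs use reduced but non-trivial sizes,
chosen as the smallest scales at which the probed effects are
unambiguous: planted-effect recovery on 15+12 subjects with
20-surrogate ensembles and 1000 NBS permutations; small-world recovery
on group means of the default 30+24 cohort with 100 surrogates per
network; error control on twenty 7+7 null cohorts (identical couplings,
no planted effects) with 300 NBS permutations each, checking the
uncorrected global rejection rate, approximate uniformity of null
p-values, and the NBS family-wise error rate.
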