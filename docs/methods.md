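# Methods

`homonet` analyses task-state functional connectivity of the human motor
network as a weighted graph and quantifies its interhemispheric
(homotopic) organization.  This note documents the models, the synthetic
data generator, the numerical conventions, and the limits of what the test
suite demonstrates.

## Analysis model

**Design.**  The block paradigm alternates left- and right-foot movement:
ten 16 s movement blocks separated by 20 s rests, a 26 s initial and a
22 s final rest, TR = 2 s.  These segments total 388 s (194 scans); the
nominal 396 s run length and the 4 s pre-scan lead-in are carried as
metadata only, because the per-cycle accounting that would reconcile them
is ambiguous and the paradigm is fully configurable through event files.
Condition regressors are boxcars convolved with a canonical double-gamma
HRF (peak delay 6 s, undershoot delay 16 s, dispersions 1 s, undershoot
ratio 1/6, 32 s support, peak normalized to 1).  The regressor sampled at
the TR serves, clipped at zero, as the per-scan weight vector of its
condition; the raw (signed) regressor is retained alongside.  Clipping
keeps the weights usable as non-negative correlation weights at the cost
of discarding the undershoot interval.

**Denoising.**  Fixed order: ROI extraction → bandpass → nuisance
regression.  The filter is a zero-phase (forward–backward) order-4
Butterworth bandpass, 0.008–0.09 Hz; zero-phase filtering avoids lag that
would distort block-weighted correlation.  Nuisance regression projects
each region's series on an intercept, the six motion parameters, the WM
and CSF series, and the first derivatives of WM/CSF only (the motion
parameters enter without derivatives).  Confounds are bandpassed with the
same filter *before* regression: regressing unfiltered confounds out of
filtered data can reintroduce removed frequencies.

**Connectivity.**  For each condition, edge weights are weighted Pearson
correlations

r_w(x, y) = Σᵢ wᵢ(xᵢ−x̄_w)(yᵢ−ȳ_w) / √(Σᵢ wᵢ(xᵢ−x̄_w)² Σᵢ wᵢ(yᵢ−ȳ_w)²),

with w the clipped condition regressor normalized to sum 1; constant
weights reduce this to ordinary Pearson.  Subject matrices are Fisher
transformed, z = atanh(r), and each edge is tested across subjects with a
one-sample two-sided t-test (random-effects; df = n−1).
Benjamini–Hochberg FDR at q = 0.05 over the n(n−1)/2 unique edges defines
the edge set; surviving positive-mean edges carry W = tanh(z̄), the
back-transformed group correlation.  W = tanh(z̄) rather than z̄ itself is
the default so that the distance map D = 1 − W stays in (0, 1]; the
mean-z convention is available as a configuration switch, and
significant negative-mean edges are excluded from W but reported.
Perfectly correlated series are clipped to |r| = 1 − 10⁻⁷ before the
transform; an edge whose across-subject variance is exactly zero with a
nonzero mean gets p = 0 with a warning (this arises only in synthetic
corner cases and avoids a hard failure).

**Graph metrics.**  Strength (row sums of W), distances D = 1 − W
(absent edges unreachable), Dijkstra shortest paths, Brandes-style
betweenness normalized by the number of intermediable pairs, global
efficiency (mean 1/d over ordered pairs, unreachable pairs contributing
0), strength assortativity (Pearson over edge endpoint strengths, both
orientations), weighted clustering (geometric-mean triangle rule with
weights scaled by the maximum), and weighted Newman–Girvan modularity

Q = Σ_c [ e_c/m − γ (a_c/2m)² ]

maximized by restarted Louvain (default 100 restarts, resolution γ = 1,
ties broken by lexicographically smallest assignment so a fixed seed is
fully reproducible; the stored Q is always re-evaluated from the
assignment by the direct formula).  Small-world references preserve the
degree sequence by edge rewiring (10 swaps per edge) with the original
weights reshuffled over the rewired edges.

**Homotopy statistics.**  For each region the incident link of maximal
weight is selected (per-region accounting: a link may be selected from
both ends, giving n selections for n regions; the deduplicated link count
is reported alongside).  The anchoring count is the number of paired
regions whose selection is their contralateral homolog, out of 24 paired
regions by default; isolated regions (possible after FDR thresholding)
are excluded from the denominator with a warning, and exact weight ties
break toward the lowest index and are flagged.  Module pairing counts
homotopic pairs whose members share a Louvain module; symmetry ratios
report per module the members whose homolog is a fellow member (k_m/n_m,
totals K/N with K = 2 × pairs co-located).

**Chance nulls.**  Both statistics are referred to label-exchangeable
nulls of this package's own definition (the original probability
computations they stand in for are not available, so no claim of
reproducing those values is made).  For anchoring, the null makes all
weights of the complete network i.i.d. (equivalently: a uniformly random
ordering of edge ranks); Monte Carlo redraws give
p = (1 + #{null ≥ obs})/(1 + n_perm).  An exact mode computes the
distribution of the anchoring count in closed recursion: processing edges
in descending weight order, the first edge incident to a region is its
strongest link, and conditional on the set of still-unanchored regions
the next relevant edge is uniform among edges touching that set — a
dynamic program over at most 2ⁿ subsets, practical for n ≤ 10 and
validated against literal m!-order enumeration.  For module pairing, node
labels are permuted over the fixed module-size vector (exact enumeration
for n ≤ 10).  Permutation p-values are valid by construction
(super-uniform under the null), which the suite checks empirically.

## Synthetic cohort

The generator emulates the study conditions end to end: 18 subjects,
28 regions (12 mirrored homotopic pairs — SMA, CMA, PMd, PMv, SFG, SPL,
IPC, S2, anterior insula, putamen, caudate, cerebellar hemisphere — plus
left M1, left S1, left thalamus and the midline cerebellar vermis), the
default block paradigm, 194 scans at TR = 2 s.  Node coordinates are
schematic mirror placements spanning the cranial–caudal axis, not
measured activation peaks.

Each subject's region × scan matrix is the sum of

1. correlated Gaussian noise: the matrix square root of the target
   correlation matrix applied to white noise, so the population
   correlation equals the planted structure exactly.  The target matrix
   has r_homotopic on the 12 pairs, r_intra within a hemisphere and
   r_other across; midline regions carry r_intra toward everything, since
   a midline structure such as the vermis interacts with both
   hemispheres.  Defaults r = 0.6/0.3/0.1.  The matrix is eigenvalue-
   checked at construction; a mild indefiniteness is repaired by clipping
   eigenvalues and re-normalizing (flagged in metadata), and a repair
   that would move any entry by more than 0.1 raises instead — strongly
   contrasted structures such as 0.7/0.7/0.0 are genuinely contradictory;
2. HRF-convolved task responses with laterality gains (contralateral 1.0,
   ipsilateral 0.5, midline 0.75) scaled by task_gain (default 0.5 in
   noise-SD units);
3. slow drift below the 0.008 Hz filter edge (random sinusoid at
   0.002–0.006 Hz plus a linear trend, amplitude 0.5);
4. motion-coupled nuisance: six smoothed-random-walk motion traces and
   two low-frequency WM/CSF series, injected with random per-region
   loadings (coupling 0.3) and returned verbatim in the confound table;
5. white measurement noise at 0.25 of the noise SD.

Rendering to 4D volumes paints each region's series into a 3 mm sphere on
a 2 mm grid (voxel-center-in-sphere rule, the same rule extraction uses)
over background noise, raising on overlapping or out-of-grid spheres.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: spatial autocorrelation and EPI artifacts,
scanner noise spectra, physiological rhythms, inter-subject variation in
coupling strength or HRF shape, and, most importantly, any segment-level
(cranial–caudal) community structure.  The coupling model has exactly
three levels; its modular organization is therefore hemispheric by
construction.  On such data, modularity at γ = 1 is maximized by the
two-hemisphere split (the 171 intra-hemisphere edges dominate the
objective; a pairs-as-modules partition scores Q < 0), so Louvain yields
two lateralized modules with zero co-located pairs even when homotopic
coupling is dominant edge-wise.  The bilateral multi-module organization
seen in real motor networks requires within-segment coupling the
three-level model cannot express; the strongest-link anchoring statistic,
by contrast, is driven purely by edge-wise dominance and recovers the
planted homotopic structure essentially perfectly.  The planted-recovery
suite reflects exactly this: anchoring ≥ 20/24 with permutation
p ≤ 0.01 in 20/20 replicates, while the module-composition check fails
on the generator's hemispheric partitions.

## Problem sizes and numerics

Simulation studies in the tests and the reproduction script use
18 subjects × 28 regions × 194 scans per cohort, 20 replicates for
recovery/control studies (n_perm = 999), and 200 replicates for null
calibration (n_perm = 199) — sizes chosen so each study is an honest
Monte Carlo at the study's own scale while a full run stays in the tens
of seconds on one CPU.  Other conventions: seeds are mandatory for every
stochastic step and spawned per subject/stage via `SeedSequence`;
Dijkstra and Louvain tie-breaks are by node index / lexicographic
assignment; the Fisher identity atanh(tanh z) = z is exact to 1e-12 only
for moderate |z| (float64 saturation near |r| = 1); filter edge
transients are avoided by zero-phase padding but remain visible in the
first/last ~20 scans of pure tones.

## Known limitations

- Weighted-correlation condition weighting follows the clipped
  HRF-regressor convention; other toolchains implement block-design
  weighting differently (e.g., per-block segmentation), and absolute edge
  weights are not comparable across conventions.
- The permutation nulls are this package's definitions of chance; they
  are exchangeability nulls on weights/labels, not generative nulls of
  BOLD data.
- Exact null modes are limited to n ≤ 10 regions (2ⁿ-state recursion,
  assignment enumeration).
- Real-data ingestion expects preprocessed (realigned, normalized) NIfTI
  plus user-supplied WM/CSF series; no mask estimation or motion
  correction is performed.
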