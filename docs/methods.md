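# Methods

`ctmorph` quantifies chromosome territories (CTs) and chromosome arms (CAs)
in single nuclei of 3D fluorescence z-stacks: segmentation of nuclei (DNA
stain) and FISH-labelled territories, morphometrics (volume, normalized
volume, mesh sphericity, territory overlap, focus-aware intensity), the
homolog-pairing call with conformation classes, replicate aggregation, and
the group-comparison statistics. Because suitable public embryo stacks with
ground truth do not exist at desk scale, every stage is validated against a
bundled synthetic-field simulator that emits exact truth tables.

## Coordinate and measurement conventions

Stacks are indexed `(channel, z, y, x)`, 0-based; `voxel_size` is µm per axis
`(z, y, x)` and may be anisotropic (confocal z step > xy pixel; the default
simulated geometry is 0.3 × 0.15 × 0.15 µm). The centre of voxel `i` is at
`i * voxel_size`. All distances are Euclidean in µm, volumes in µm³, areas in
µm². Connected components use 26-connectivity throughout.

## Synthetic field generator (`simgen`)

The generator emulates a blastoderm-style field of fluorescently labelled
nuclei; it is a study-condition definition, not an optics model.

* **Nuclei** — non-overlapping ellipsoids, mean radius `nucleus_radius_um`
  (default 2.0 µm; the validation protocols use 1.4–1.5 µm so several
  hundred nuclei fit one field) with ≤10% per-axis uniform jitter, placed by
  rejection sampling with centre separations above the sum of the maximum
  semi-axes (+5%). Nuclei keep one nucleus radius clear of the field border
  by default (`border_margin_factor`), so border-exclusion logic can be
  tested by overriding it. Exhausting the per-nucleus attempt budget raises
  a "field too crowded" error rather than silently under-filling.
* **Territories / FISH spots** — each territory channel carries, per
  nucleus, a configurable fraction of the nuclear volume
  (`territory_volume_fraction`). Diploid nuclei draw a pairing state with
  probability `pairing_fraction`; a paired state renders either one merged
  blob (probability `paired_mode_merged_prob`, default 0.5 — the
  "only one FISH signal" presentation) or two blobs with centre separation
  uniform in (0, 0.8] µm. Unpaired homologs are separated by 1.5–3× the
  0.8 µm threshold, capped at twice the eroded minimum semi-axis so both
  spots fit geometrically inside jittered nuclei; without the cap a nucleus
  10% smaller than the mean cannot host a 2.4 µm separation. The cap keeps
  truth labels unambiguous at the decision boundary.
* **Shape irregularity** — blob boundaries are modulated multiplicatively by
  smooth correlated noise (a 5³ Gaussian grid upsampled over the bounding
  box, amplitude 0.18 × `territory_irregularity`), followed by one
  volume-preserving rescale of the boundary radius to the ellipsoid's voxel
  count and a largest-component/fill-holes cleanup, so the mask stays
  connected and its volume stays within ~10% of the unperturbed shape.
* **Foci** — an optional intensity channel renders a pan-nuclear background
  (0.35) plus bright spherical foci (default two per diploid nucleus, one
  per haploid; radius 0.4 µm, intensity 3), emulating the dominant nuclear
  bodies seen in RNA Pol II stainings.
* **Optics and noise** — Gaussian PSF with per-axis physical sigma (default
  0.25/0.1/0.1 µm), then a Poisson draw at `photon_scale` photons per unit
  intensity (default 200 → SNR ≈ √200 ≈ 14) plus Gaussian read noise in
  photons, rescaled and clipped at 0. The absolute photon scale is a free
  choice — real acquisition settings vary by instrument — and only the
  resulting SNR matters to the downstream stages. Setting
  `photon_scale = 0` disables noise rather than producing a black image, so
  noiseless oracles are exact.

What the simulator does **not** model: realistic PSFs (Gibson–Lanni,
depth-dependent aberration), chromatin texture inside territories,
cross-channel bleed-through, mitotic figures, embryo-scale geometry, or
spot dropout. Consequently, passing recovery tests demonstrate correctness
of the measurement chain under idealized imaging, not segmentation
performance on difficult real data.

## Segmentation

Nuclei: Gaussian smoothing (0.2 µm), global Otsu, then watershed on the
smoothed Euclidean distance transform (computed with physical sampling so
anisotropy is respected), seeded at regional maxima thinned to a minimum
separation of `seed_min_distance_um` (default 1.5 µm ≈ one nuclear radius).
Components below `min_volume_um3` (default 5 µm³) are dropped; nuclei
touching the stack border are flagged and excluded by default because their
volumes are truncated. Labels are dense from 1.

Signals: per-nucleus Otsu on within-nucleus intensities, components above
`min_signal_volume_um3` (default 0.02 µm³). Fused spots are split by a
second, spot-scale watershed: seeds are EDT maxima greedily thinned to a
Euclidean separation of `split_min_separation_um` (default 1.0 µm). The
default sits between the 0.8 µm pairing threshold and the 1.2 µm minimum
unpaired separation: a dumbbell of paired homologs keeps one seed and stays
a single signal, while two unpaired spots bridged by PSF blur are recovered
as two. Signals are assigned to the nucleus containing their centroid —
simpler than majority voting and tie-free. Bright voxels outside every
nucleus are never reported but are counted in a diagnostics record.

## Morphometrics

* **Volume** is always the exact voxel count × voxel volume.
* **Sphericity** is π^⅓(6V)^⅔ / A with V and A taken from a marching-cubes
  mesh of the mask (physical spacing passed to the mesher, one light
  Gaussian smoothing pass at σ = 0.6 voxel). Using the mesh volume rather
  than the voxel count in the numerator keeps the statistic internally
  consistent: mixing voxel-count V with mesh A overshoots badly for small
  regions (up to ~2.8 for a single voxel; >1.1 for few-voxel blobs, because
  smoothing shrinks the 0.5 level set by ~σ²/r), whereas the
  mesh-consistent form is bounded and scores 0.98–1.0 for digital balls of
  radius ≥ 5 voxels and 0.81–0.82 for large cubes (closed form 0.806). The
  smoothing σ trades staircase-artifact suppression (which inflates the
  area of binary meshes) against corner rounding on polyhedra; 0.6 voxel
  keeps both the ball and the cube oracle within tolerance. Because the
  surface-area estimator of the commercial tool this replaces is unknown,
  absolute sphericities may differ from other software by a small constant;
  comparisons between groups measured with the same estimator are the
  supported use.
* **Normalized volume** is object volume / host nuclear volume; for
  paired-versus-unpaired comparisons, the unpaired side uses the combined
  volume of both homolog signals before normalization. Ratios above 1 warn
  (segmentation pathology) but are returned.
* **Overlap / intermixing** is counted voxelwise and reported as a percent
  of each territory's own volume, so the record is asymmetric in the
  percentages but symmetric in the intersection volume.
* **Focus-aware intensity** detects the k brightest connected bodies inside
  a nucleus (per-nucleus Otsu by default, a quantile or fixed threshold
  optionally) and reports their metrics plus the mean intensity with those
  foci excised — the operation used to separate nuclear-body signal from
  pan-nuclear polymerase recruitment (k = 2 for diploid, 1 for haploid).

## Pairing and conformations

A nucleus × target is **paired** when its two signal centroids lie ≤ 0.8 µm
apart in 3D (inclusive, exactly as stated) or when only one signal is
present; **unpaired** when two signals exceed the threshold; **ambiguous**
with zero or more than two signals (S-phase doublets or segmentation splits
are not adjudicated — ambiguous calls are excluded from percentages, and the
minimum pairwise distance is recorded). Centroid distance between segmented
signals replaces manual point picking; it is the reproducible surrogate.
Threshold monotonicity holds by construction: the paired set at threshold t
is a subset of the paired set at any t′ > t.

Arm and centromere calls for one chromosome cross into six conformation
classes (both/one/no arms paired × centromere paired/unpaired).

Replicate aggregation computes percent paired per replicate over
non-ambiguous calls and reports mean ± sample SD across replicates (error
bars describe between-replicate spread, not per-nucleus noise). Summaries
are flagged non-reportable below the configured minimums (defaults: 300
nuclei total, 3 replicates), with values still returned.

Single-signal calls cannot be distinguished from signal dropout; the
simulator does not emit dropout, and no correction is applied.

## Statistics

Mann-Whitney U (two-sided) uses exact enumeration for n₁+n₂ ≤ 12 without
ties, full permutation enumeration for small tied samples (so identical
samples give p = 1 exactly), and otherwise the normal approximation with
midrank tie correction and continuity correction. Fisher's exact test is
two-tailed (sum of hypergeometric probabilities ≤ the observed table's).
Levene's test defaults to the median-centred Brown–Forsythe variant
(`center="mean"` available); all-zero deviations return statistic 0, p = 1,
flagged. These run through `scipy.stats`; independent brute-force
enumeration oracles live in the test suite. No multiple-testing correction
is applied — p-values are per comparison.

Bimodality of a sample (e.g. normalized volumes of paired arms) is called
from a Gaussian KDE (Silverman bandwidth): interior local maxima with
density ≥ 5% of the global maximum count as modes; with ≥ 2 modes the
distribution is bimodal and the antimode is the density minimum between the
two highest modes. The prominence floor and bandwidth are exposed; samples
under 20 observations or with zero variance return unimodal, flagged. On a
0.2/0.6 (σ = 0.05, n = 500) two-Gaussian mixture this flags bimodality in
>95% of replicates with the antimode near 0.4; on a single Gaussian the
false-positive rate is below 10%.

## Pipeline and reproducibility

`run_pipeline` executes simulate-or-read → segment → measure → pair → stats
per replicate (replicate r uses seed `seed + r`), then writes tidy CSVs
(nuclei, signals, metrics, pairing calls, pairing summary, paired-versus-
unpaired combined volumes, test results), optional label TIFFs, a JSON
manifest (config hash, seed, library versions, per-stage counts) and a log.
Identical config + seed give byte-identical tables. Stack voxel sizes come
from an explicit override first, then OME metadata; a stack with neither is
an error.

## Validation protocol sizes

The canonical self-checks (shared by the test suite and
`scripts/acceptance.py`) use: a radius-2 µm digital ball and a 6 µm cube at
0.1 µm isotropic voxels for the geometry oracles; one 50-nucleus field
(24 × 420 × 420 voxels) for segmentation recovery; 3 replicates × 300
nuclei (18 × 660 × 660 voxels) at generating pairing fractions 0.2/0.5/0.8
for pairing recovery; 2,000 null pairs (n = 50 each) for Mann-Whitney
type-I calibration; 200 replicates each for the bimodal and unimodal
detection rates; and a 3-replicate × 40-nucleus demo pipeline run twice for
determinism. These sizes keep a full validation pass within a few minutes
on a single core while leaving the binomial recovery intervals tight enough
to detect percent-level call bias.

## Known limitations

* Recovery guarantees hold for the simulated regime (SNR ≥ 10,
  non-touching nuclei, spot-like signals); densely packed or low-SNR real
  stacks will need parameter adjustment and have no accuracy guarantee.
* Sphericity is estimator-dependent (see above); only within-study
  comparisons are meaningful.
* The pairing call reduces each signal to its centroid; extended,
  interdigitated territories at the whole-chromosome scale are summarized
  by a single point per signal.
* Nuclei are treated as independent units when pooled across replicates, as
  in the caption-style "n ≥ 300 nuclei" reporting; no nucleus-within-embryo
  hierarchical model is fitted.
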