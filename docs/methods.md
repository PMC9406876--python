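# Methods

This note records the models, parameter choices and numerical conventions
behind `senescan`, and what the synthetic validation does and does not
establish about real instrument data.

## The senescence score

Per-cell autofluorescence `AF` (mean intensity in the 480–560 nm band) and
diameter `D = (width + height)/2` are normalized to the arithmetic means of
the matched proliferating control of the *same cell model* (pooling
references across models is not supported by default: absolute AF levels
differ by 3–9× between models, and the method's portability rests on the
normalization). The S-index is

    SI = (nAF − 1) + w (nD − 1),  w = 5  (default "reconciled" variant)

**The two formula variants.** The formula as printed in the source method
carries a trailing `/2`. Applied to the published per-model population
means, the halved form yields 1.07 (HUVEC) and 0.77 (MSC), while the
reported mean SI values are 2.1 ± 0.4 and 1.6 ± 0.2; the un-halved sum
yields 2.14 and 1.54, matching the reports. We therefore default to the
un-halved ("reconciled") variant and keep `as_printed` behind
`MetricsConfig(si_variant="as_printed")`. Two of the four models (MearF
reported 3.3, computed 2.94; HuDe reported 3.0, computed 3.47) match
neither variant exactly from their printed means — whether the reported
values were averaged per cell or per sample is unknown; flagged, not
resolved.

**LAF gate.** Cells with `nAF ≥ 1.5` and `nD ≥ 1.1` (inclusive
comparisons; the same thresholds for every model) are counted as large
autofluorescent senescent cells. Inclusive boundaries make discretized
synthetic data deterministic and have measure zero on continuous data.

## Gating

Two single-cell gate modes on the area / aspect-ratio / roundness
features:

* **conventional** — `area ∈ [area_min, area_max]` and
  `aspect_ratio ≥ 0.6`. `area_max` defaults to the 97.5th percentile of
  the whole proliferating reference sample (`calibrate_area_max`) — the
  bound an analyst draws on the raw dot plot, which sits above the
  proliferating singles because the raw sample contains its own doublets.
* **extended** — `area ≥ area_min`, `aspect_ratio ≥ 0.3`, *no* upper area
  bound; candidates are singles iff circularity and shape ratio clear
  their minima, else multiplets.

The circularity/shape-ratio minima default to the 0.1th percentile of a
designated singles calibration sample (`calibrate_morphology`). This
percentile keeps ≥ 99% of true singles by construction while rejecting
rendered-aggregate shapes by a wide margin (aggregate shape ratios sit
roughly 5 standard deviations below the singles' range); a coarser cut
(e.g. 5%) would needlessly discard ~10% of genuine singles when both
features are thresholded.

On the default synthetic HUVEC mixture the conventional gate loses 15–25%
of the top-decile-area true singles that the extended gate retains —
inside the 10–43% loss range reported for conventional gating on real
merged samples.

**Viability.** Dead iff `DAPI > t_d`; apoptotic iff `Annexin > t_a` and
`DAPI ≤ t_d`; live otherwise; assigned only to single-gated events.
Thresholds default to Otsu on `log10(1+x)`; fixed values are accepted for
control-calibrated runs. The Otsu estimator works on the sorted sample
directly (no histogram): the threshold is the midpoint between the two
neighbouring values at the variance-optimal split, which places it in the
middle of the gap between well-separated modes instead of at a bin edge.

## Image features

The instrument vendor's feature definitions are proprietary; the
re-implementations here are documented approximations with the same
qualitative behaviour (high for round singles, low for aggregates):

* width/height: mask bounding-box extents × calibration (so
  `D = (W+H)/2` holds identically);
* aspect ratio: minor/major axis of the intensity-weighted moment ellipse;
* circularity: mean/SD of boundary-pixel distance to the centroid,
  capped at 30 — near-perfect disks have vanishing spread, so the raw
  ratio is dominated by pixelation noise; everything at the cap reads
  "as round as measurable";
* shape ratio: minimum thickness / length, thickness = 2 × min
  distance-to-background over the skeleton of the mask after a
  radius-2 morphological open/close (raw skeletons grow spurs from
  single-pixel boundary raggedness that would collapse the minimum),
  length = extent along the major axis.

At the ~40 px object sizes typical of IFC crops, roundness features are
stable to a few percent under sub-pixel placement and rotation — far below
the order-of-magnitude contrast between singles (circularity ~15–30) and
aggregates (~3) that the gate uses. Clipped-object detection is a
deterministic rule (segmentation mask touches the crop border), standing in
for the vendor's image classifier with the same functional role.

## Spillover compensation

Doxorubicin fluoresces maximally in Ch04 and leaks into the AF band. The
model is a single coefficient: `AF_corrected = max(0, AF − s·DOX)`
(negatives are unphysical; clamped events are logged). `s` is estimated on
a control saturated with the drug, using events above the median source
intensity: the default estimator is the median of target/source ratios
(robust to residual cellular background), with a zero-intercept
least-squares slope as the alternative. The estimate is accurate when the
spill dominates the control's own AF — the regime a massive-dose control
is designed to create.

## The classifier

Truth sets come from the S-index: non-senescent truth = control-sample
cells with `SI ≤ 0.8`; senescent truth = induced-sample cells with
`SI ≥ 1.2` (the source constraint is enforced via sample condition
metadata). Candidate features (default: AF, D, area, aspect ratio,
circularity, shape ratio) are z-standardized on the pooled truth, ranked
by |Rd|, and those with `|Rd| ≥ 0.5` (at most 10) enter a two-class LDA
with equal priors and shrinkage-regularized pooled covariance
(shrinkage 10⁻³ — the truth sets can be small). The offset places the
equal-posterior boundary at score 0, so `MLSC > 0` reads senescent.

The joint rule uses strict inequalities and an explicit `ambiguous` class:
senescent iff `MLSC > 0 ∧ SI > 0`, non-senescent iff both `< 0`. Because
non-senescent cells straddle `SI = 0` symmetrically, roughly half of them
are ambiguous by construction, and because the boundary is calibrated
between the truth *extremes*, borderline senescent cells (SI below ~1.1)
score negative: the senescent-call fraction is a deliberately conservative
estimate, with a near-zero false-positive rate on the proliferating side.

MLSC2 retrains on the outer deciles of MLSC within each first-pass class —
a deterministic, monotone-in-confidence stand-in for the density-based
extreme selection the original workflow applies by eye.

## Synthetic data

The generator's population means are the published per-model values
(AF senescent/proliferating: MearF 3789/1309, HUVEC 1915/907, MSC
1806/992, HuDe 8770/2892 a.u.; D: 29.5/24.4, 32.2/26.7, 28.6/25.0,
34.4/26.7 µm). The pericyte entry is a *synthetic calibration* — no AF/D
means were published for cardiac pericytes, so its values are chosen to
imply the reported ex-vivo mean SI of 2.2 — and is flagged as such in
`MODEL_STATS`.

Per-cell dispersion is not published (the printed ± values are
between-sample SDs), so the distributional forms are declared assumptions:
AF lognormal with CV 0.35 (proliferating) / 0.45 (senescent) — fluorescence
intensities are right-skewed; D truncated-normal with CV 0.08 / 0.12;
AF–D coupled through a Gaussian copula with ρ = 0.1 / 0.4 (senescent cells
couple size and autofluorescence more strongly). Default conditions are
pure-phenotype cultures (96% base + 2% apoptotic + 2% dead, the latter two
drawing AF/D from the base phenotype) so that sample means recover the
published values; `mixed` splits the live compartment.

Doublets/multiplets are built by pairing single draws — areas summed, AF
area-weighted over the union, bounding box from the disk geometry — with
their aspect-ratio/circularity/shape-ratio drawn from statistics of
actually rendered two/three-disk fixtures (`cluster_morphology_stats`),
keeping the feature-level and image-level generators consistent. Clipped
events lose part of their mask at the crop border. Default artifact rates:
5% doublets, 1% multiplets, 2% clipped. Viability channels are lognormal
around background (50 a.u.) or positive (5000 a.u.) levels. One root seed
per spec feeds named substreams (phenotype, features, artifacts,
viability, drug), so partial re-simulation is reproducible.

**What the generator does not emulate:** realistic brightfield texture,
focus variation, camera noise beyond the additive background, the
instrument's true (proprietary) feature definitions, and any per-cell
variance structure beyond the declared CVs. Consequences worth knowing:

* %LAF of a *pure* proliferating sample is ~1%, below the 5–15% band
  observed in real non-senescent cultures — real cultures contain a
  senescent minority that the pure condition deliberately omits (use
  `mixed` with a small `senescent_fraction` to emulate it).
* Fisher-Rd values for AF from 20-cell truth galleries fluctuate around
  1.5 (the per-cell AF spread is large and size–AF coupling moderate);
  diameter separates far more sharply on synthetic data than the
  published galleries suggest for real data.

Passing tests therefore demonstrate the pipeline's correctness and its
behaviour under the declared statistical structure — not instrument-level
performance.

## Numerical conventions and problem sizes

Comparisons at gate boundaries are inclusive (≥); the joint classifier
rule is strict (>) with an explicit ambiguous class. Reference statistics
require ≥ 100 events by default (overridable for tiny biopsy samples of
100–200 cells). Rd uses n−1 standard deviations; zero pooled spread maps
to 0 (equal means) or signed infinity (saturated). Feature-rank ties break
lexicographically. Simulated validation uses n = 20000 events per sample
for moment-recovery and scoring checks (Monte-Carlo error on mean SI
≈ 0.01) and n = 5000 per condition for classifier training; the whole
suite and the acceptance script each run in seconds.

## Known limitations

* FCS support is a minimal list-mode reader/writer (float/int data,
  $PnE antilog); keyword escaping and analysis segments are not
  implemented.
* The circularity/shape-ratio constructions approximate, not reproduce,
  the vendor's gates; fixed thresholds tuned on one instrument should be
  re-calibrated via the percentile helpers.
* The ex-vivo results of the source study (patient pericytes, mouse
  biopsies) require the study's cells; they are represented here only by
  the synthetic pericyte calibration and are not desk-reproducible.
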