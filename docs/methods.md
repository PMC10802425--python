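# Methods

`vagusmap` quantifies how organ-specific fiber groups are arranged over the
cross-section of a peripheral nerve — here the mid-cervical vagus under a
multi-pad cuff electrode — by mapping two independent kinds of evidence
onto one normalized circular cross-section and comparing their angular
statistics. This note records the model, its assumptions, the tunable
parameters, and the design choices made where the design was genuinely
open.

## Coordinate model

All maps live on the unit disk. Angles are degrees in [0, 360), measured
clockwise from the 12-o'clock direction when the section is viewed from
the cranial aspect, so "top of the nerve" is 0°. A raster of `grid_size²`
pixels (default 256) covers the square [−1, 1]²; a pixel belongs to the
disk iff its center is inside the unit circle. These conventions are fixed
arbitrarily but consistently; nothing downstream depends on the choice
except the sign of reported angles.

The cuff is a tube of inner diameter 2.7 mm carrying 14 pad pairs at fixed
angles (default equally spaced). A pair is a single angular position
because its two pads sit at the same angle on the two rings.

## Anatomical arm (fascicle co-registration)

Traced fascicles arrive as centroids + equivalent radii + organ labels in
millimetres. Each fascicle is projected onto the disk so that its **radial
distance to the nearest electrode pad is preserved** in cuff-radius units
(`r_norm = (R_cuff − d_nearest)/R_cuff`, clamped to [0, 1]), while its own
angle about the nerve centroid is kept. Preserving the electrode distance
is what anchors anatomy to the stimulation geometry; keeping the native
angle preserves circumferential ordering, which the sector back-projection
assumes. (An alternative — snapping each fascicle to its nearest pad's
angle — is available via `snap_to_pad_angle=True` for sensitivity
analysis.) The projected fascicle is rasterized as a filled disk; a group
map is the union over the group's fascicles.

Group membership follows a "contains fibers of that organ" reading:

| group | organ labels |
|---|---|
| cardiac_efferent | cardiac (pure cardiac fascicles are 100% efferent) |
| cardiac_afferent | cardiopulmonary (nodose-derived fibers to the heart) |
| pulmonary | pulmonary, cardiopulmonary, laryngopulmonary |
| laryngeal | recurrent_laryngeal, laryngopulmonary |

Note a structural consequence: the cardiac-afferent region is a subset of
the pulmonary region by construction, so their anatomical overlap is 100%
rather than an empirical estimate.

## Functional arm (sector back-projection)

Each stimulation trial yields a signed percent change per electrode pair:
window mean (heart rate, breathing rate, EtCO2) or window RMS (EMG)
during the on-period versus the immediately preceding off-period
(the full off-duration is the baseline window; the protocol does not fix a
shorter one). The disk is divided into 14 equal angular sectors, one per
pair, and each sector is painted with its pair's value. Per-sector mean
read-back returns the input table exactly because sectors partition the
disk.

The selectivity rule of the stimulation protocol — a response on fewer
than half of the 14 pairs — is implemented strictly as ≤ 6 effective pairs
(the inclusive ≤ 7 variant is a parameter, since "less than 50%, i.e. 7 of
14" is self-contradictory). A pair is *effective* when its |percent
change| exceeds a threshold (default 5%; the protocol never states one)
with the sign expected for the modality (efferent HR: negative; afferent
HR: either, since the reflex direction is an animal-level trait).
Titration multiplies the amplitude by 1 ± `step_fraction` (default 25%)
until the response is selective with at least one effective pair, erroring
out (with the explored trajectory) after `max_iters`.

## Alignment and atlases

Per-animal cuff rotation is unknown, so each animal's four maps are
rotated together by the negated center-of-mass (CoM) angle of its
cardiac-efferent map (|value|-weighted), pinning that group at 0°. Binary
maps are resampled nearest-neighbour and re-thresholded; response maps
bilinearly. This is legitimate because group-map CoM angles are
equivariant under rotation of the underlying fascicle coordinates (a
tested property). A side effect worth remembering when reading reports:
the cardiac-efferent angular variance across animals is deflated by
construction, and separations involving it inherit the convention.

Atlas maps average aligned per-animal maps pixel-wise. For binary sources
the mean is already the fraction of animals with that group present at the
location (0 = none, 1 = all), so no rescaling is applied; for response
sources the mean of absolute values is divided by its peak so bradycardic
and tachycardic animals reinforce rather than cancel. Region areas and
overlaps are computed on thresholded atlas supports (binary-sourced: > 0,
i.e. the union; response-sourced: > 0.5 of peak), both thresholds
adjustable.

## Angular statistics

CoMs are value-weighted pixel centroids in Cartesian coordinates,
reported in polar form. Separations between two groups are computed per
animal as the unsigned circular difference of CoM angles, in [0, 180].
The cohort summary uses **circular statistics of the signed differences**:
`mean_deg` is the folded absolute circular mean and `sd_deg` the circular
SD. Arithmetic averaging of folded separations would be biased low near
180° (folding makes every estimate ≤ 180, so noise only subtracts); the
circular mean is unbiased there, which the parameter-recovery tests rely
on.

Group locations are compared with a one-way fixed-effects ANOVA after
unwrapping: each group's angles map to the real line about that group's
circular mean, and the group means themselves are first unwrapped about
the pooled circular mean so that a null cohort straddling the 0°/360° seam
cannot be split into spuriously distant clusters. Pairwise comparisons use
Tukey–Kramer (α = 0.05; the multiple-comparison procedure is this
package's choice). A Watson–Williams circular F-test (with the standard
high-concentration correction) is available via
`angular_anova(..., method="watson_williams")` as a cross-check; the
linear-on-unwrapped-angles route is the default because at the observed
concentrations the two agree and the linear route composes with standard
post-hoc machinery. Type-I error of the default route calibrates to
0.03–0.07 at α = 0.05 under a common wrapped-normal null (tested).

Sample SD (n − 1) is used throughout; per-animal entries with an undefined
CoM (empty map) are excluded, and a separation needs ≥ 2 usable animals.

## Synthetic cohort generator

The generator produces nerves, ground truth, and stimulation responses
with the statistical structure the analysis assumes, so the full pipeline
can be tested for parameter recovery. What it emulates, and what it does
not:

**Counts and composition.** Per-nerve fascicle counts are rounded
Gaussians per organ group: 1.2±0.5 cardiac, 10.2±1.8 recurrent laryngeal,
10.4±1.9 pulmonary, 1.4±0.6 cardiopulmonary, 6±2 laryngopulmonary
(≈29 per nerve). Fiber classes are drawn per organ from the observed
compositions (pure cardiac: always efferent; pulmonary: 88.5% afferent /
9.6% mixed; cardiopulmonary: 71.4% afferent / 28.6% mixed; laryngeal:
64.7% efferent; laryngopulmonary: 56.7% afferent). Note these per-organ
compositions imply a global afferent fascicle share of ~53%; pooled counts
reported elsewhere give 47%, and the two cannot be reconciled exactly —
the generator follows the per-organ numbers.

**Geometry.** The nerve is a circle of radius `sqrt(2.68/π) ≈ 0.92` mm
(from the reported cross-sectional area of 2.68 mm²; the reported 6.63 mm
"diameter" is inconsistent with that area for a circle and is plausibly a
circumference — flagged, not resolved). Fascicle radii are log-normal,
median 0.15 mm with σ = 0.12 in the log, rescaled so total fascicle area
stays below 20% of the nerve area and floored at 0.07 mm (fascicles below
that equivalent radius would not be resolvable and traceable in the
imaging this emulates; the floor also keeps every present target above the
response-detection threshold, matching the observation that responses were
identified in every animal).

**Placement.** Each group has a planted angular center; cardiac-efferent
and cardiac-afferent (cardiopulmonary) centers sit 180° apart by default,
the pulmonary cluster coincides with the cardiac-afferent one, and the
laryngeal cluster sits 60° from the cardiac one. Angles are wrapped-normal
draws about the (per-animal-rotated) center, with per-group spreads:
cardiac 5° (a compact, branch-derived clump that never mixes with other
fascicles), cardiopulmonary 20°, others 30° (laryngeal fascicles are
widely spread in the real data). Fascicle overlap is resolved **radially
at the drawn angle** (uniform radius in the allowed annulus, with
fascicle-radius shrinking and small symmetric angular jitter only when a
column saturates), and the sparse cardiac/cardiopulmonary fascicles are
placed first. This keeps the realized angular distribution exactly the
planted one: rejection schemes that resample angles drift measurably away
from the crowded side of the nerve and would corrupt planted-separation
recovery. An unknown per-animal cuff rotation (uniform in [0, 360)) is
applied to all centers.

**Recruitment and responses.** Fascicle f is activated by pair j iff
`amplitude ≥ base_threshold(organ) × exp(d_fj / λ)`, with `d_fj` the
centroid-to-pad distance, base thresholds at distance zero anchored to the
observed selective amplitudes (cardiac efferent 1 mA, cardiac afferent
5 mA, laryngeal 0.2 mA, pulmonary 0.8 mA), and decay length λ = 0.5 mm.
The exponential distance scaling is an assumption (no cable or field
model); λ is set so the first selective amplitude typically recruits ~2
adjacent pairs, matching the observed 2.0±1.7 effective pairs. Pair
responses are `gain × activated fascicle area` plus Gaussian noise, with
gains per modality chosen so a typical activated fascicle (≈0.018 mm²)
reproduces the observed mean effects: −7.8% HR (efferent), +10.2% / −5.0%
HR (afferent tachy-/bradycardia, the direction being a per-animal trait
with P(tachycardia) = 0.6), −73% BR, EMG and EtCO2 effects well above
detection. Rate-like percent changes are floored at −100%. Per-modality
noise SDs (1–2%) sit below the 5% detection threshold, as monitor-derived
trial statistics do. Post-vagotomy logic follows the reflex circuit:
efferent responses vanish after distal vagotomy; afferent-mediated
bradycardia (via the contralateral efferents) is abolished by the second
vagotomy while tachycardia (sympathetic arc) persists. Afferent trace
responses carry an onset delay (default 2 s).

**What passing tests do and do not show.** The generator plants exactly
the structure the analysis looks for (clustered groups, a known
separation, distance-decay recruitment). Recovery therefore validates the
*pipeline* — co-registration, alignment, CoM statistics — not the
biological claim; real nerves add non-circular outlines, tracing errors,
fascicle merging/splitting along the nerve, electrode contact variability
and physiological drift, none of which are modeled. Cross-arm agreement in
the synthetic world is likewise a consistency check of the two mappings,
not evidence about tissue.

## Numerical choices

- Ties in nearest-pad assignment break to the lowest pair index (within
  1e-12 relative distance, so the all-equidistant center is pair 1).
- Sector boundaries are half-open; the boundary pixel goes to the sector
  whose interval's closed lower edge it is.
- Map rotation resamples via inverse coordinate mapping
  (`scipy.ndimage.map_coordinates`); binary maps re-threshold at 0.5.
  Alignment preserves binary pixel censuses to within ~2% at 256².
- A fascicle nominally outside the cuff circle lands on the rim
  (`r_norm` clamped); a fascicle exactly at the nerve center takes angle 0°.
- Empty-group maps are valid all-zero maps (logged); an empty
  cardiac-efferent map makes the animal unalignable and it is dropped from
  cohort statistics with a log message.
- Degenerate ANOVA inputs (zero variance everywhere) are flagged and the
  p-value reported as computed, with a warning.

## Problem sizes in the test suite

Monte-Carlo tests use 64² grids and the smallest replicate counts that
make the assertions statistically stable: 200 cohorts of N = 10 animals for
planted-separation recovery, 2000 simulated cohorts for ANOVA type-I
calibration, 200 animals for titration statistics, 500 replicates for the
separation-estimator bias check. These sizes are the package's own choice
of a stable-but-quick regression suite; the library itself has no
grid-size or cohort-size limits.

## Known limitations

- The circularization is the analysis's own idealization: non-circular
  nerve outlines and deformable registration are out of scope.
- Alignment to the cardiac-efferent CoM requires that group to be present
  and detected in every usable animal.
- The recruitment model is all-or-none per fascicle with exponential
  distance scaling; it reproduces selectivity phenomenology, not
  biophysics.
- Reported p-values for separations involving the alignment reference
  group are optimistic (its variance is pinned near zero by construction);
  reports carry a footnote to that effect.
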