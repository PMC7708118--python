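# Methods

## Coordinate convention and reference frame

All geometry lives in a right-handed anatomical frame: the Frankfurt
Horizontal (FH) plane is `z = 0` with `+z` cranial, the midsagittal
plane (MSP) is `x = 0` with `+x` toward the anatomical left, and `+y`
points anteriorly. The frame is built from four landmarks: FH is the
plane through the two porions and the orbitale (oriented so nasion is
cranial), the MSP normal is the porion–porion direction projected into
FH, and the origin is nasion's projection onto FH. Degenerate landmark
configurations (coincident porions, collinear points) raise a dedicated
error rather than producing a garbage frame.

## Condylar measurands

The condylar head is isolated by clipping the mandible with a plane
parallel to FH through the most caudal point of the sigmoid notch
(supplied as a landmark, or auto-detected as the minimum of the upper
silhouette envelope between the condylar and coronoid peaks in the
sagittal view; the landmark always wins when both are available). The
head is the connected component above the plane that contains the most
posterior point of the side — connectivity, not geometry, excludes the
coronoid process.

Linear measures are caliper distances between extreme vertices
(point-to-point, matching how a distance tool is used on landmarks);
an axis-extent variant is available through `depth_variant="extent"`
because the literal reading of "shortest distance between the most
posterior and the most anterior point" cannot be adjudicated against
published group means. Extreme-point ties are broken deterministically
(larger z, then y, then x), so results are invariant under vertex
reordering. Both inclination angles are reported unsigned in [0°, 90°]:
the antero-posterior angle after projecting the cranial and posterior
extremes onto the MSP, the medio-lateral angle after projecting the
medial and lateral extremes onto FH. Clipped volumes use the divergence
theorem on the capped region; the caps are triangulated in-house
(boundary-loop chaining plus ear clipping) so that no optional spatial-
index dependency is needed. Cut planes are nudged upward by 10⁻³ mm so
that faces exactly coplanar with the cut cannot produce degenerate
slivers below the mesh-processing merge tolerance; this is three orders
of magnitude below every stated tolerance.

## Mandible phantoms

The phantom grammar is chosen for closed-form ground truth, not
anatomical realism: per side an ellipsoidal condylar head (default
semiaxes 10 × 4 × 8 mm), a lofted neck from a small elliptical base on
the ramus top to the head's cross-section at the junction plane, a
conical coronoid process, a box ramus, and one shared box body whose
lower front edge carries menton. The ramus top between the processes is
flat and defines the notch level; a sculpted notch profile was
considered and rejected because a flat plateau keeps every component
volume exact while the silhouette detector still sees a genuine dip
(the notch depth parameter raises the coronoid apex above the plateau).

Head tilts are rigid rotations about the head centre. Because the
measured angles are chord angles of the rotated ellipsoid, the yaw and
pitch that realize requested inclination targets interact and are
solved numerically (nested bracketing and Brent root finding) so the
analytically implied angles equal the targets to ~1e-10; the reachable
(a-p, m-l) region depends on the semiaxes, and unreachable targets are
rejected with an explicit error. The cap sampling grid additionally
contains the exact polar/azimuthal coordinates of the four lateral
extreme points (the cranial extreme is the grid pole), which makes the
linear and angular ground truths exact at any mesh resolution; volumes
remain resolution-limited (inscribed meshes underestimate by ≈0.1–0.4%
at the default resolution 4, i.e. 128 azimuthal segments).

Closed-form volumes: boxes and elliptic cones are elementary; the
ellipsoid cap above a horizontal plane is the unit-sphere cap
`π(2/3 − t + t³/3)` scaled by `abc` after mapping the plane into sphere
coordinates; the neck loft's cross-section area is quadratic in height
(affine interpolation of two ellipses), so its volume is exact by
Simpson's rule. Components meet at shared planes with strictly disjoint
interiors, so the assembled mesh is watertight and its enclosed volume
is the sum of the parts.

Cephalometric ground truths are controlled by `menton_offset` (menton
slides along the body's lower front edge), `wits_mm` (B is placed so the
A/B projections onto the horizontal occlusal plane separate by exactly
that amount), and `ml_nl_deg` (the body depth is derived so the
gonion-to-menton line meets the nasal line at exactly that angle).

## Measurement-table simulator

Group sizes default to the published study composition: 65/22/24
(symmetric/moderate/strong asymmetry), 25/36/50 (Class I/II/III),
37/32/42 (hypo-/neutral/hyperdivergent), with the published per-group
means and SDs of the six measurands (side differences for the symmetry
scheme). Variables are drawn independently per variable because only
marginal moments are published; a per-group covariance matrix can be
supplied for sensitivity studies. The grouping variable itself (menton
deviation, Wits, ML-NL) is drawn from a normal truncated to the group's
class interval so labels are self-consistent.

What this does **not** emulate: the real measurands are correlated
within subjects (e.g. condylar volume with height), the published means
are rounded to one decimal, and real meshes carry segmentation noise.
Consequently multivariate discrimination under the independence
simulation is typically *stronger* than in the study's data — the
multi-variable classification rates are therefore checked only
qualitatively (extreme classes recovered better than intermediate
ones), while the single-variable transversal analysis, which depends
only on the published marginals, is reproduced quantitatively.

## Statistics

* **Pillai's trace**: V = tr(H(H+E)⁻¹) per effect, with
  s = min(p, q), m = (|p−q|−1)/2, n = (df_err−p−1)/2 and
  F = ((2n+s+1)/(2m+s+1))·(V/s)/(1−V/s) on (s(2m+s+1), s(2n+s+1)) df.
  Two-way designs use sum-to-zero coding and Type III hypotheses (the
  appropriate choice for the unbalanced 3×3 design; verified against
  statsmodels). Partial η² is reported as V/s. With p = 1 the statistic
  reduces exactly to the one-way ANOVA F.
* **Stepwise LDA**: forward selection with backward removal on partial
  F (defaults 3.84 / 2.71, common statistical-package defaults since no
  thresholds are published); Λ(S) = det(W_S)/det(T_S). Canonical
  functions solve B v = λ W v with scores normalized to unit pooled
  within-group variance; Λ·Π(1+λᵢ) = 1 holds to 1e-10 by construction
  and is asserted in tests. Classification uses Fisher linear functions
  with priors proportional to group sizes — with the published
  transversal parameters these priors empty the moderate group's
  decision region and give ≈63% overall accuracy, whereas equal priors
  do not produce that structure. Resubstitution (not cross-validated)
  tables match how the published rates are defined.
* **BCa bootstrap**: bias correction from the bootstrap distribution's
  fraction below the estimate, acceleration from jackknife skewness;
  with both set to zero the interval is exactly the percentile interval
  (asserted). Degenerate samples collapse to a zero-width interval with
  a flag. Intervals are computed per group, since CIs are reported per
  group.
* **Box's M** with the standard χ² scaling; **Pearson screen** flags
  |r| ≥ 0.9 (configurable) and reports zero-variance columns instead of
  crashing.

All SDs use the n−1 denominator. Every stochastic routine takes an
explicit seed; the pipeline derives child seeds from one master seed.

## Numerical choices and degenerate inputs

Wilks ratios use log-determinants; singular cross-product matrices
raise a rank-deficiency error naming the zero-variance or collinear
variables. Stepwise selection skips candidates that would make the
within matrix singular (a tolerance rule) and is guarded against
cycling. The Pillai F is undefined when V/s = 1 (perfect separation);
group cells must be non-empty and n must exceed the parameter count.
Angle operations raise on coincident projected points rather than
returning 0/0.

## Problem sizes used in the reproduction

The replicated discriminant simulation uses 4000–5000 replicate seeds
(the per-replicate Monte-Carlo SD of Wilks' Λ is ≈0.07, and its
expected value 0.753 sits near a one-decimal rounding boundary, so a
few thousand replicates are needed for a stable mean); the geometric
recovery suite uses a 20-phantom grid at mesh resolution 4; the MANOVA
type-I-error property uses 1000 simulated null datasets at the study's
group sizes. All of these complete in well under two minutes each on a
single CPU.

## Known limitations

* The phantom is schematic: no cortical/trabecular distinction, no
  teeth (the measured mandibular volume is defined without them), no
  fossa; it validates the measurement code, not segmentation quality.
* Auto notch detection assumes two clear processes in the sagittal
  silhouette; pathological or low-resolution meshes should supply notch
  landmarks.
* The occlusal plane for Wits is a least-squares fit to user-supplied
  occlusal points; which occlusal-plane variant the original workflow
  used is unknown, so absolute Wits values may differ by a constant for
  real data.
* Multivariate classification rates under the independence simulator
  are not comparable to correlated real data (see above).
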