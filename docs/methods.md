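# Methods

## The problem

The aspect ratio of a bird's wings, AR = WS² / A (wingspan squared over
total wing area), is the morphological quantity most closely tied to
long-distance flight efficiency and hence to dispersal ability.  Wingspan
(WS) is routinely recorded on specimen labels, but the total wing area A —
the projected surface of both wings plus the intervening body — has
traditionally required a prepared spread-wing specimen and a scaled
photograph.  `wingplan` implements a folded-wing alternative that needs
only two further linear measurements taken on an ordinary study skin: the
wing length WL (wrist joint to tip of the longest primary) and the wing
width S1 (wrist joint to tip of the first secondary), both highly
repeatable measurements that are already available at scale in trait
databases such as AVONET.

## Folded-wing geometric models

The wing planform is decomposed into two mirrored distal "hand-wings" of
extent WL and a medial rectangle ("medial box") of width WS − 2·WL and
depth S1.  The hand-wing is modelled as a simple shape spanned by WL and
S1; writing hand areas for both wings combined:

| model            | hand-wing shape                  | hand area          | total area                 |
|------------------|----------------------------------|--------------------|----------------------------|
| Triangle         | right triangle (legs WL, S1)     | WL·S1              | (WS − WL)·S1               |
| Ellipse          | half ellipse (axes 2·WL, S1) or quarter ellipse (semi-axes WL, S1) | (π/2)·WL·S1 | (π/2)·WL·S1 + (WS − 2WL)·S1 |
| Ellipse-Triangle | quarter ellipse over ⅔·S1 + triangle over ⅓·S1 | ((π+1)/3)·WL·S1 | ((π+1)/3)·WL·S1 + (WS − 2WL)·S1 |

The half- and quarter-ellipse shapes give the *same* area formula, which
is why a single Ellipse model covers wing outlines ranging from rounded
(jays, wrens) to straight-leading-edge pointed (gulls, swallows).  The
models are nested in a continuous mixture family: a fraction f of S1 is
elliptical and 1 − f triangular, giving hand area WL·S1·(f·π/2 + 1 − f).
f = 0, 2/3 and 1 reproduce the three named models; any other f is an
extension beyond the named geometries and is flagged as such
(`PlanformModel.is_extension`).  For fixed measurements the totals are
strictly ordered Triangle < Ellipse-Triangle < Ellipse, since
1 < (π+1)/3 < π/2.

Units: the canonical internal unit is cm (areas cm²); readers accept a
per-file `mm`/`cm` declaration and convert on ingest.  π is used at full
machine precision; rounding happens only at report time (1 decimal for
percentages, half away from zero, matching how such tables are printed).

**Degenerate geometry.**  WS < 2·WL (possible for very pointed wings with
measurement error) would make the medial box negative.  The default
policy is a hard error naming the specimen; an explicit clamp option
(`--clamp-box`) sets the box to zero and flags the record.  Silent
negative areas would corrupt every downstream ratio, so there is no quiet
path.  Missing measurements cause the row to be skipped with a warning,
never imputed.

## Spread-wing image workflow

The traditional method is re-implemented for comparison: threshold a
grayscale photograph of one spread wing (dark object on light ground),
fill enclosed holes, take the largest connected component's pixel count
over scale² as the single-wing area a, and reconstruct the two-winged
total as 2·a + c·(WS − 2·e) with root chord c and wing extent e.
Choices the original interactive workflow leaves open are fixed
deterministically and recorded in output metadata:

* automatic thresholding uses Otsu's between-class-variance criterion;
* components are 4-connected, the background flood in hole filling is
  8-connected (the standard complementary pair, preventing checkerboard
  leakage);
* a pixel is counted wholly in or out (no partial coverage); validation
  tolerances account for this, and the measured area error scales as
  O(perimeter / resolution).

Manual touch-ups (brush/eraser repairs of disarranged feathers) are out
of scope; externally edited masks can be supplied instead of an image.

## Comparison statistics

For paired per-specimen estimates (folded vs spread) of either area or
aspect ratio:

* **Discrepancy** D = Σᵢ [log₁₀(foldedᵢ) − log₁₀(spreadᵢ)].  Logs remove
  body-size scaling; the folded-minus-spread orientation makes an
  area-underestimating model negative.  Because AR = WS²/A with a shared
  wingspan, D(aspect ratio) = −D(area) exactly — the sign mirroring seen
  in interspecific validation tables.
* **Percent difference** 100·(folded_mean − spread_mean)/spread_mean, the
  spread-wing method as reference.  Whether the published tables used the
  ratio of means or the mean of per-specimen ratios is ambiguous at
  printed rounding; both are implemented (`diff_mode`), default
  ratio-of-means.
* **Coefficient of variation** 100·SD/mean with the n−1 sample SD.  Since
  the same specimens underlie both methods, the CV difference between
  methods isolates measurement-procedure noise.

## Phylogenetic GLS

Interspecific validation regresses one method's values on the other's
across species.  Residuals of cross-species regressions are not
independent; under Brownian trait evolution their covariance is
proportional to V, where V[i,j] is the root-to-MRCA path length of tips i
and j.  Pagel's λ multiplies the off-diagonal of V (λ = 1 Brownian,
λ = 0 independence) and is profiled by maximum likelihood over [0, 1]
(bounded scalar optimisation plus explicit endpoint checks; an 11-point
profile table is available for diagnostics).  REML is available as an
option; ML is the default.  Fits are exposed statsmodels-style
(`PhylogeneticGLS(...).fit()` → results with `params`, `bse`, `rsquared`,
`lam`, `llf`, `aicc`, `summary()`).

Numerical/definitional choices:

* λ transforms the full covariance (diagonal kept), as in the caper R
  package — not the correlation-matrix convention of nlme, which differs
  on non-ultrametric trees.  On ultrametric trees the two coincide, and
  the engine reproduces `nlme::gls` + `ape::corPagel` coefficients,
  standard errors and ML/REML log-likelihoods to 1e-10 on a frozen
  fixture (tests/test_pgls.py).
* Through-origin regressions (slope = bias indicator; slope 1 means no
  bias) define r² = 1 − RSS_V/TSS_V with the total sum of squares taken
  about zero in the V-metric: a centered TSS is incoherent without an
  intercept.  With an intercept, TSS is about the GLS-weighted mean.
* Slope standard errors use σ̂² = RSS_V/(n − k); the log-likelihood uses
  the ML variance RSS_V/n (REML: RSS_V/(n − p) with the design-matrix
  determinant correction).
* AICc = −2·logL + 2k + 2k(k+1)/(n−k−1) with k counting slopes + σ² (+ λ
  when profiled) — the common comparative-methods convention.  Published
  comparative tables sometimes count differently (e.g. df = 2 for an
  intercept+slope model), so k is overridable (`k_params`).
* A numerically singular λ-transformed covariance (effectively duplicate
  tips from zero-length terminal branches) is retried once with a ridge
  of 1e-10 × mean diagonal before failing.
* Species names are matched between table and tree after space/underscore
  normalisation; unmatched rows are dropped and reported.

## Synthetic ground truth

The generators provide oracles whose truth is known exactly:

* **Planforms** (`make_planform`): straight leading edge, trailing edge a
  quarter ellipse over f·S1 stacked on a triangle over (1−f)·S1, medial
  rectangle between the wings.  Component areas are closed-form and agree
  with the shoelace area of a densely discretised outline polygon to
  <1e-4 relative at 10⁴ vertices — an oracle independent of the
  estimators' algebra.  (Leading/trailing curvature is interchangeable
  for area.)
* **Rasters** (`rasterize`): binary pixel-centre sampling of a planform
  at a given px/cm, emitted with the exact stencil, so segmentation can
  be checked pixel-for-pixel and area recovery converges as
  O(perimeter/resolution).
* **Paired datasets** (`make_paired_dataset`): specimen series with a
  shared log-normal size factor (default individual CV 5%, a typical
  intraspecific size spread) and independent multiplicative log-normal
  measurement noise of stated CV per length.  "Spread" values are exact
  planform areas; "folded" values apply a chosen estimator to the noisy
  lengths.  With zero noise and a shape-matched estimator the two agree
  exactly.
* **Traits** (`simulate_lambda_brownian`): multivariate-normal tip values
  with covariance σ²·λ-transform(V), for λ/slope recovery experiments;
  `random_yule_phylogeny` supplies reproducible pure-birth trees whose
  terminal branches are extended by 5% of depth to keep V well
  conditioned.

All stochastic output is reproducible from integer seeds.

What the generators deliberately do **not** model: feather slotting and
wingtip gaps, camber and 3-D projection effects, photographic distortion,
or anti-aliased pixel coverage.  Passing tests therefore demonstrate the
correctness of the estimators, the image pipeline and the statistics on
idealised planforms — not that any geometric model fits a particular real
wing, which is an empirical question requiring paired specimen data.

## Validation problem sizes

The bundled validation (tests and `scripts/acceptance.py`) uses 100
random geometries for the estimator/polygon oracle; 50 px/cm rasters of
a 40 cm-wingspan planform for the image pipeline; a 50-tip simulated
phylogeny with 200 replicates (λ = 1, through-origin slope 1.1) plus 100
replicates at λ = 0 for PGLS recovery; and 40 synthetic species for the
end-to-end interspecific pipeline.  Note that a ±2·SE interval has
nominal t₄₉ coverage just under 95%, so observed coverage close to that
line is the expected behaviour of a correct implementation, and
percentages reported for the stochastic checks vary a little with the
seed.

## Reproducing the published interspecific regressions

Full reproduction of the published interspecific tables (e.g. Ellipse
area slope 1.04, r² .992, λ = 1 across 59 species; dispersal-distance
slope 2.94, r² .35 across 41 species) requires the validation study's
specimen-level measurement data and a phylogeny subset from
birdtree.org, neither of which is bundled.  The recipe with data in
hand:

1. `wingplan estimate specimens.csv -o folded.csv --model all` for the
   folded-wing areas and aspect ratios;
2. pair them with the spread-wing measurements and run
   `wingplan compare paired.csv` for discrepancies, percent differences
   and CVs;
3. `wingplan pgls paired_log.csv mcc_tree.nwk --x area_folded
   --y area_spread --through-origin` (and the log-log aspect-ratio /
   dispersal variant with an intercept) for the regression tables.

## Known limitations

* The folded-wing estimators assume WL captures the hand-wing extent and
  S1 the chord; species whose longest primary is far from the wingtip
  direction violate this silently.
* Interspecific residuals are phylogenetically structured (λ ≈ 1 in the
  published validation), i.e. model misfit is lineage-specific, not pure
  noise; per-clade calibration is outside scope.
* The image workflow measures whatever the threshold segments: shadows,
  rulers touching the wing, or torn vanes need external mask editing.
* λ is the only residual-correlation family implemented (no
  Ornstein-Uhlenbeck or Blomberg transforms).
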