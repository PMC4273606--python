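# Methods

## Co-transduction model

Cells exposed to a mixture of three colour-coded vectors are modelled as
acquiring vector copies independently, with per-vector copy numbers
Poisson-distributed at the vector's MOI.  The transduction probability per
vector is `p = 1 − exp(−MOI)`; the model is parameterised directly in `p`
(the "transduction rate per vector"), with MOI entering only through this
link.  Independence across vectors is assumed — the three vectors are
identical apart from the transgene, so no receptor competition or
saturation is modelled.  The colour class of a cell is the pattern of
vectors with ≥1 copy; the class distribution is always reported
conditional on transduction by at least one vector, since untransduced
cells are invisible in tissue.

Rate inference maximises the multinomial likelihood of the seven
labelled-class counts.  The equal-rate mode optimises a single `p` by
bounded 1-D minimisation (tolerance ~1e-10 on `p`); the per-vector mode
optimises (p_r, p_g, p_b) by L-BFGS-B with bounds [1e-9, 1] and three
starts, snapping to the boundary when the endpoint is at least as likely
(e.g. every labelled cell triple-positive gives `p = 1`, flagged
`at_boundary`, never an error).  95% intervals are profile-likelihood
(log-likelihood drop of χ²₀.₉₅,₁/2 ≈ 1.92), with per-parameter profiles
re-optimising the other two rates in per-vector mode.  Calibration is
verified by simulation: at n = 500 cells and p = 0.3 the median estimate
is within 0.02 of truth and empirical 95% coverage lies in [92%, 98%].

Goodness of fit is Pearson's chi-square over the seven labelled classes
(6 df when the expected fractions are externally specified).  When any
expected count falls below 5 the asymptotic reference is unreliable and a
multinomial Monte-Carlo p-value (add-one estimator) can be requested.
Note the degrees of freedom assume the expected fractions were *not*
fitted to the same counts; testing against self-fitted fractions is
anti-conservative by one degree of freedom.

Titration converts the transduced fraction f of a well into transducing
units per ml: `TU/ml = cells · f / volume`, or `cells · (−ln(1−f)) /
volume` with the Poisson multiple-hit correction.  Wells with f > 0.3 are
flagged as outside the linear range of the assay — a standard practice
cut-off; titration series should be read from the flagged table, not a
single well.

## Synthetic data

The generator encodes the statistical premise of combinatorial marking so
every pipeline stage is testable against known truth:

* copies per vector ~ independent Poisson(MOI);
* a per-cell expression factor shared across channels, lognormal with
  mean 1 and CV `expr_cv` (default 0.35 — a typical cell-to-cell spread
  of transgene expression);
* channel intensity `clip(expr_factor · copies · per_copy_strength ·
  (1 + ε) + autofluorescence, 0, 255)` with ε ~ N(0, `channel_cv`)
  (default 0.05) and additive autofluorescence (default 10 on the 8-bit
  scale);
* the truth class is exactly the pattern of nonzero copies.

Because the expression factor multiplies all channels equally, intensity
*ratios* — hue — depend only on the copy-number combination: the clonal
watermark.  This is an exact property of the noiseless generator and a
tested approximate property at small channel noise.  All intensities use
the 8-bit convention (the threshold 40 presupposes 8-bit display units).

Scenes are rendered in 2D: somata as randomly oriented ellipses at
non-overlapping centres (bucket-grid rejection sampling with a bounded
attempt budget; an unplaceable request raises an error naming the
achievable maximum), optional per-channel Gaussian blur (the label mask
is never blurred), and an optional 3×3 spectral mixing matrix defaulting
to identity.  Neurite rendering, 3D stacks and realistic optics
(PSF, bleaching) are deliberately out of scope; morphometry consumes SWC
skeletons, not rasters.  Consequences for interpretation: passing
round-trip tests shows the measurement and calling chain is faithful to
this intensity model, not that segmentation or unmixing would succeed on
real confocal stacks with overlapping somata or spectral bleed-through.

Neuron generators produce SWC trees rooted at the origin: a straight
radial neurite, a symmetric binary tree (depth levels of bifurcation
after the trunk), and a stochastic tree whose segment directions are
constrained never to point back toward the root.  That constraint makes
radial distance monotone along every edge, so endpoint-based Sholl
counting is exact for generated trees (see below).

## Image quantification and colour calling

Per-cell values are **mean** in-mask intensities per channel — the
statistic on which an 8-bit threshold of 40 is meaningful.  Images with
non-8-bit integer dtype are linearly rescaled by dtype range (percentile
scaling available by flag, logged).  "Distinguishable" cells are
operationalised as size/border filters: labels outside [min_area,
max_area] (an oversized region proxies merged bodies) or touching the
frame border are flagged with a reason and retained, never dropped.
Exclusion runs before classification and both counts are logged.

Colour calling applies **both** threshold readings: a channel is present
when its mean intensity ≥ 40, and a cell whose perceived brightness
(0.299·R + 0.587·G + 0.114·B) is below 40 is unlabelled regardless of
channel calls.  Both thresholds are independently configurable.  A
consequence of the luma weights worth knowing: a pure-blue cell can never
pass the brightness gate on its own (0.114 · 255 ≈ 29), so under the
default gates dim single-blue cells are called unlabelled and the
observed class distribution under-represents B.  The default synthetic
preset therefore uses per-copy strengths (180) and autofluorescence (20)
under which a one-copy blue cell reaches brightness 40.5; at weaker
expression the bias is real and the fitted rate reflects the *observed*
process, which is the honest behaviour.

Hue and saturation use the standard hexcone RGB→HSV conversion; hue is
undefined (and so reported) for black input and for unlabelled cells.
Clone grouping is single-linkage clustering on circular hue distance with
a cut at the hue tolerance.  On the circle this reduces exactly to
splitting the sorted hues at gaps larger than the tolerance (including
the wrap-around gap); cluster ids are assigned by ascending lowest member
hue, making the labelling independent of input order.  Cells below the
minimum brightness do not participate and stay unassigned (-1).

## Morphometry

Sholl profiles use the grid {start, start+step, …, ≤ end}, default
10/10/300 µm, distances 3-D Euclidean from the SWC root (2-D xy
projection by flag).  An edge contributes one crossing to each circle its
endpoint distances straddle, under the half-open rule
`d_min < r ≤ d_max`: a node lying exactly on a circle is counted with the
edge arriving from inside and not again with the edge leaving, so a touch
counts exactly once along a path (a straight radial neurite with nodes on
every circle yields exactly one crossing per circle).  Endpoint
straddling can miss a segment that dips inside a circle between its
endpoints; for trees whose radial distance is monotone along edges — all
generated trees, and morphologically typical reconstructions — the count
is exact, verified against a dense-sampling oracle.

Spine density is spines per µm of dendrite.  Bouton size classes are
half-open bins [0, w), [w, 2w), … with w = 3 µm², reported as
percentages summing to 100; empty input yields an empty, flagged table.
Group summaries of Sholl profiles (mean, SEM, n per radius) are emitted
as tidy tables; hypothesis testing (ANOVA, post-hoc) is delegated to
standard statistics packages.

## Pipeline, configuration, determinism

`RunConfig` resolves every stage parameter; unknown YAML keys fail fast.
Every CSV embeds the resolved version/seed/thresholds as `#`-prefixed
metadata lines before the header.  All randomness flows from the single
config seed through one `numpy` Generator passed explicitly between
stages — no global state — so one seed gives byte-identical tables.
Stage timings go to stderr logging only, never into outputs.

Problem sizes used by the test and acceptance suites — 10^5-cell
Monte-Carlo comparisons, 200 replicate fits of 500 cells, 200-cell
rendered scenes, 30-radius Sholl grids — were chosen as comfortable desk
scale for the statistics involved (binomial standard errors below half a
percentage point; interval-coverage resolution ~1.5%).

## Known limitations

* 2-D scenes only; no declumping of overlapping somata; no spectral
  unmixing or cross-microscope colour calibration.
* The chi-square test does not adjust degrees of freedom for fitted
  rates (documented above).
* Hue clustering assumes clones are separated in hue; clones with
  coincident copy-ratio directions are indistinguishable by construction.
* Saturated (clipped) intensities distort hue for very bright cells; the
  generator flags saturation and warns when it exceeds half the
  population.
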