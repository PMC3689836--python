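# Methods

## The dataset

The packaged measurement table (`bonylabyrinth/data/measurements.csv`)
transcribes, one row per taxon, the published per-specimen endocast
measurements for 36 therians: *Didelphis virginiana* (the marsupial
outgroup), four Cretaceous stem eutherians (*Kulbeckia*, *Ukhaatherium*,
*Zalambdalestes*, and a zhelestid; stored as the published per-taxon
averages and flagged `is_average`), and 31 crown placentals spanning
Afrotheria, Xenarthra, Laurasiatheria and Euarchontoglires. Columns
group into whole-labyrinth size (volume, length), cochlea (volume,
coiling in degrees, secondary-lamina extension, canal length, aqueduct
length, spire aspect ratio, basal angle), vestibule (aqueduct length,
stapedial ratio, sagittal labyrinthine index, the three inter-canal
plane angles) and per-canal measurements (arc radius, slender length,
lumen diameter, linear and angular deviation, arc aspect ratio). Empty
cells are missing values and stay missing through every computation.

Two annotation columns carry information that is anatomical rather than
metric: `habitat` (aquatic = manatee, Steller sea lion, bottlenose
dolphin, fossil balaenopterid; volant = the four bats; all others
terrestrial) and `lsc_entry`, the route by which the lateral
semicircular canal reaches the vestibule (secondary common crus,
posterior ampulla, or directly).

One cell is corrected: the printed human body mass of 8000 g is a
dropped-digit error (the same publication's radius/body-mass ratios for
*Homo*, 0.004 after ×100 scaling, require ≈ 80 kg, which is also what
the cited anthropometric reference gives). The fixture stores 80000 g.

The tree (`theria_tree.nwk`) encodes the published composite cladogram:
36 tips, internal nodes labeled A–e, with the polytomies the source
retains (a basal placental trichotomy; a trichotomy of the three
afrotherian lineages; bats + Ferae + ungulates unresolved within
Laurasiatheria; tree shrew + Glires + Primatomorpha unresolved within
Euarchontoglires). No branch lengths are published; every edge defaults
to 1.

## Derived indices

* Arc radius of curvature: `R = (arc height + arc width) / 4` — half
  the mean extent of the canal arc; symmetric in its arguments.
* Angular deviation: the published tables derive a canal's total angular
  deviation "trigonometrically" from its linear deviation and arc radius
  without printing the formula. We use the central angle subtending a
  chord of length *ld* on a circle of radius *R*,
  `θ = 2·arcsin(ld/2R)`, because it reproduces 92 of the 93 printed
  angular deviations of the non-averaged taxa within 0.6° (the one
  exception, the opossum's lateral canal, prints 23.7° where the formula
  gives 24.9°, most plausibly a typo); the alternative `arctan(ld/R)`
  does not come close. Inputs with *ld* > 2*R* are rejected as
  undefined.
* Substantiality: a deviation is substantial when *ld*/lumen diameter
  ≥ 1.0. The source states the rule both as "greater than 1" and as "a
  ratio of 1.0 or above"; the inclusive form is adopted.
* Volume contributions: cochlear % = 100·Vc/Vl, vestibular % defined as
  the complement so the two always sum to exactly 100.
* Radius/body-mass normalisation: 100 × mean of the three arc radii /
  body mass (g); missing mass propagates, never 0.
* Report rounding uses decimal half-up at the printed precision (2 dp
  for ratios); all internal computation is full precision.

Discrete character scoring for the cladogram: c1 = `lsc_entry`
(annotation); c2 lateral-canal position = high iff the sagittal
labyrinthine index exceeds 0; c3 = canal(s) of maximal arc radius, ties
reported as a polymorphic set rather than silently broken; c4 cochlear
spire = high iff aspect ratio > 0.55 (0.55 exactly is "flattened");
c5 coiling binned at 720° and 1080°; c6 cochlear contribution binned at
50% and 75%.

## Geometry operators and the synthetic generator

The geometric operators act on explicit 3-D centerlines and emulate what
a morphologist measures on a rendered endocast. Where the published
protocol is visual ("planes oriented perpendicular to the field of
view"), we substitute deterministic constructions:

* Canal plane: total least squares over the full centerline (the normal
  is the least-variance singular direction); rotation-invariant, with
  the RMS orthogonal residual reported. Collinear input is rejected.
* Arc height/width: extents along the principal axes of the points
  projected into the plane (width = major axis). The published
  measurement anchors its axes on anatomical landmarks we do not have;
  principal axes agree for near-elliptical arcs but cannot distinguish
  an arc whose "anatomical" aspect ratio exceeds 1 (the axes reorder),
  so recovery tests on aspect use arcs with aspect ≤ 1.
* Total linear deviation: the range (max − min) of signed orthogonal
  distances to the fitted plane. The statistic is not defined in the
  source; the range is the one choice that makes a one-sided bump
  (range ≈ bump height) and a symmetric sinusoidal warp of amplitude A
  (range = 2A) commensurate.
* Inter-plane angles: both normals are oriented toward the labyrinth
  centroid before taking the angle, which is what makes the obtuse
  printed angles (e.g. 109° between anterior and lateral canal planes
  in the opossum) well defined.
* Cochlear coiling: cumulative unwrapped azimuth about the spiral axis
  from the basal-most point; direction-independent. The profile
  (height along the axis; basal width = widest diameter of the first
  360° perpendicular to the axis; aspect = height/width) flags spirals
  with less than one full turn.
* Sagittal labyrinthine index: percentage of the posterior arc's
  orthogonal span lying on the ventral side of the lateral canal plane;
  the caller supplies the dorsal direction.
* No smoothing or resampling anywhere: operators consume the centerline
  as given.

The synthetic generator provides ground truth for all of the above: a
canal is an ellipse of given radius, aspect and plane, warped
out-of-plane by `A·sin(kt)` (k ≥ 2 keeps the warp orthogonal to the
plane harmonics over a full circle, so the realized total deviation is
exactly 2A) plus optional isotropic Gaussian noise; a cochlea is a
conical helix with linear taper and rise. A full bundle installs the
three canals at requested mutual plane angles (canal centres sit a fixed
offset from a hub along their normals, so the centroid-orientation
convention recovers the requested angles exactly; unrealizable angle
triples are rejected) and the cochlea at a requested basal angle to the
lateral canal. Presets put the parameters at the scale of an opossum, a
guinea pig and a dolphin. Generation is bit-reproducible for a fixed
seed.

When the spiral axis is not supplied, `pipeline.estimate_spiral_axis`
recovers it from the points alone: the accumulated oriented-area vector
seeds the direction (robust to spire height), then a few iterations of
(unwrap azimuths → subtract the fitted linear rise → re-fit the
flattened spiral's plane → circle-fit the basal turn for the axis
point) converge to well under 1° of the true axis for conical helices.
Closure, verified in the test suite: with zero noise, measured arc radii
agree with truth within 1%, plane angles within 1°, coiling within 2°
(with the truth axis; within ~0.6% with the estimated axis), linear
deviations within 5%; all measurements are rigid-motion invariant, and
discretization error shrinks quadratically in the sampling step
(checked at 32/128/512 points).

What the generator does not emulate: ampullae, lumen surfaces, the
vestibule itself, or segmentation noise structure — so passing closure
tests demonstrate the correctness of the measurement operators, not the
fidelity of any particular CT protocol.

## Statistics

All bivariate analyses use natural logarithms and pairwise deletion of
missing values. Correlation significance is the exact two-tailed *t*
transform with n − 2 df; `critical_r(28, 0.05)` = 0.374, the basis of
the published "0.38 or above is significant" rule of thumb.

The allometric fit is OLS of ln(labyrinth length, mm) on ln(body mass,
g) over the 28 extant species with a published mass — the domestic dog
is excluded (breed masses span an order of magnitude), as are all
fossil and Mesozoic taxa (no mass). The fitted line on the packaged
data is ln *BLL* = 0.1512·ln *BM* + 0.8143 (r² = 0.88); the published
slope (0.151) reproduces exactly at printed precision, the published
intercept (0.8212) does not — it evidently reflects unrounded
spreadsheet values that cannot be recovered from the printed tables,
and the same applies to the published correlations r = 0.95
(volume–mass, we get 0.94) and r = 0.02 (coiling–mass, we get 0.01);
length–mass r = 0.94 reproduces. Mass prediction inverts the line:
mass = exp((ln length − α)/β).

The habitat contrast compares vestibular percent contributions:
aquatic (n = 4) vs terrestrial non-volant taxa. The default terrestrial
set (n = 24) keeps the terrestrial fossils and the marsupial and drops
the Mesozoic stem eutherians — this is the set whose mean (44.8%) and
range (28–69%) match the published summary. Both the Welch test the
source describes and the pooled-variance test are reported: on these
data the F-test for variance equality is itself marginal (p = 0.055),
the Welch test gives p = 0.098 (df ≈ 3.3 — four aquatic taxa carry
almost no power for an unequal-variance test), and the pooled test
gives p = 0.0012. The published p = 0.007 lies between the two and is
not reproducible from the printed volumes under any defensible
grouping; the direction of the effect (aquatic vestibules relatively
smaller) is robust across every grouping variant exposed by the
configuration switches.

## Ancestral-state reconstruction

Discrete characters: uniform-cost Sankoff dynamic programming on the
multifurcating tree as given (polytomies are never resolved). An upward
pass computes per-node minimal subtree costs per state; a downward pass
adds the cost of the rest of the tree, and each node reports the full
set of states attainable in some most-parsimonious labeling — sets of
size > 1 are printed as '|'-joined "equivocal" states. Missing tips
contribute every state at no cost; polymorphic tips (e.g. a tie for
largest canal) contribute their observed set. The implementation is
checked against exhaustive enumeration over all internal labelings on
random 6-tip trees, and parsimony length is verified invariant under
rerooting.

Continuous traits: Brownian-motion maximum-likelihood point estimates,
i.e. GLS, equivalently weighted squared-change parsimony with weights
1/branch length. Each edge carries a Gaussian message (conditional
mean, effective length); the precision-weighted combination of all
messages arriving at a node is its marginal ML estimate. Two passes,
no iteration, polytomies native; zero-length branches are rejected. On
a star tree the root estimate reduces to the arithmetic mean; on a
balanced 4-tip tree it matches the numerical minimizer of the
squared-change criterion; across 200 seeded Brownian simulations on a
32-tip tree the root estimator is unbiased within Monte-Carlo error.

With unit branch lengths, the continuous reconstructions land on the
values the original Mesquite analysis reported for the deep nodes
(therian ancestor: coiling 685.6° vs reported 685°, cochlear
contribution 66.1% vs 66%; eutherian 580.2° vs 580°; placental 737.9°
vs 738°) — strong evidence the original analysis also used a
topology-only tree. As the source itself notes, these deep coiling
estimates are overestimates relative to the single-turn cochlea of the
Mesozoic outgroups: GLS on a topology-only tree averages over a very
wide extant range.

The six-character matrix reconstructs the published qualitative
findings: the secondary common crus is ancestral for Theria and
Eutheria and lost at crown Placentalia (the aardvark and dog re-acquire
it as reversals), and the anterior canal arc is the largest at every
labeled node except inside Paenungulata (the hyrax + manatee ancestor
and its parent), where posterior-dominant tips pull the optimum away.

## Problem sizes and determinism

Everything runs in seconds: the dataset is 36 taxa, the tree 36 tips,
the parsimony state spaces ≤ 3, and the synthetic validation uses
512–1024-point centerlines. The pipeline is deterministic for a fixed
configuration; the only randomness anywhere (generator noise, Brownian
simulations) flows through explicit integer seeds. Calibration
experiments in the test suite use 200 replicates, enough to bound the
root-estimator bias at 4 standard errors without noticeable runtime.

## Known limitations

* Fixture values carry the printed precision (2–3 significant figures);
  statistics that the source computed on unrounded spreadsheet values
  (regression intercept, two of the headline correlations, the contrast
  p-value) are reproducible only approximately, as detailed above.
* The geometric operators substitute deterministic constructions for
  anatomically anchored ones (principal axes for arc height/width, TLS
  planes for by-eye orientation); they are validated against synthetic
  truth, not against re-measured CT endocasts.
* Continuous ancestral estimates inherit the topology-only tree: they
  are averaging statements, not calibrated divergence-time inferences.
* Agility scores and hearing-range inference are out of scope; no
  phylogenetically corrected (independent-contrasts) regression is
  attempted, matching the source analysis.
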