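# Methods note

Model definitions, parameter defaults, and the numerical choices behind
`rascube`. Everything here is deterministic given the stated seeds.

## 1. Data model

A `CategoricalDataset` is a joint frequency table over named categorical
variables, exactly one of which is the dependent variable (DV). Tables are
stored sparsely (unique observed state tuples plus counts): with 20
five-state predictors the product state space has 5²⁰ ≈ 9.5 × 10¹³ cells
while real extracts observe at most a few thousand distinct rows. Raw
external class codes (e.g. NLCD land-cover codes) are mapped to 0-based
state indices through per-variable `rebin` maps, keeping the model algebra
independent of any coding scheme. Entropies are reported in **bits**.

## 2. Structures and degrees of freedom

A directed-system model structure is the IV component (one relation over
all predictors) plus zero or more predictive relations, each containing the
DV and at least one predictor, kept in canonical minimal form (subsumed
relations dropped; names sorted). String notation: `IV:N2Z5:S3Z5:Z4Z5`;
the independence model prints as `IV:Z5`.

Degrees of freedom follow standard hierarchical log-linear effect counting:
every nonempty variable subset contained in some relation contributes
∏(cardinality − 1) parameters. This is evaluated by inclusion–exclusion
over the relations' intersection lattice,

df = Σ over nonempty relation subsets T of (−1)^(|T|+1) (∏ card(∩T) − 1),

which never enumerates the IV component's powerset. Absolute df are
astronomical when 20 predictors are declared (the IV component alone has
5²⁰ − 1 parameters); all reported criteria therefore use **df differences**
between nested models, which are small integers.

Loop detection uses Graham reduction (repeatedly absorb relations contained
in others and delete variables unique to one relation); a structure is
loopless iff the reduction empties the hypergraph. For loopless structures
the reduction order also yields the junction factorisation (numerator
relations, separator intersections) used by the closed-form fit.

## 3. Fitting

The fitted model is the maximum-entropy joint q matching the data's
projection on every relation.

* **Closed form** (loopless structures): q = ∏ p(numerator) / ∏
  p(separator), with 0/0 → 0.
* **IPF** (structures with loops): from the uniform distribution, cyclically
  rescale q to each relation's observed projection; the convergence
  criterion is the ∞-norm of the worst margin deviation.

**Directed-system reduction.** Because every model contains the full IV
component, the maximum-entropy joint factorises as
q(IVs, DV) = p(IVs) · c(DV | predicting IVs). Fits therefore run on the
predicting-IVs ∪ {DV} subspace with the IV component shrunk accordingly;
the full joint is materialised lazily and sparsely on the observed IV
support. The test suite asserts exact equivalence (≤ 1e−8) between reduced
and literal full-scope fits, and exhaustively checks the closed form
against IPF (≤ 1e−9) on all loopless structures over ≤ 4 binary variables.
Log-likelihoods and ΔBIC/ΔAIC are computed from the **conditional**
log-likelihood differences (the shared IV-margin term cancels), avoiding
catastrophic cancellation between astronomically large absolute values.

**IPF defaults: tol = 1e−5, max_iter = 5000.** When the max-ent limit
contains zero cells not forced by any single margin (e.g. models such as
`IV:Z3Z5:Z4Z5` on data where some class transitions never occur), IPF
converges only at rate O(1/k): measured deviation ≈ 0.016/k on simulator
data, i.e. ~1.6 × 10⁻⁵ after 1000 cycles and ~1.6 × 10⁻⁷ after 100 000.
A 1e−8 tolerance is therefore unattainable in practical time on exactly the
model family the search visits, while 1e−5 is far below sampling noise at
the study's sample sizes (n ≈ 4000 gives margin standard errors ≈ 8 × 10⁻³)
and converges in ≤ ~1600 cycles. Both parameters are exposed on the API
and CLI; tests that need tighter fits pass explicit tolerances on
strictly-positive tables where convergence is geometric.

## 4. Metrics (search-report columns)

* `Inf` = [H(p_ind) − H(p_model)] / [H(p_ind) − H(p)]: 0 at the
  independence model, 1 at the saturated model. Since all models share the
  IV margin, this reduces to DV conditional-entropy ratios. If the data
  carry no DV information the denominator vanishes; a warning is issued and
  the 0/1 endpoint convention applied.
* `%ΔH(DV)` = 100 · [H(p(DV)) − H_q(DV | predictors)] / H(p(DV)).
* `ΔBIC`, `ΔAIC`: bottom minus model, natural-log likelihoods, larger is
  better. Entropy measures are in bits while likelihood criteria use
  natural logs — the conventional mixture, kept intentionally.
* Significance: G² = 2 ΔLL against χ² with Δdf, for nested pairs only
  (nesting verified structurally). The acceptance suite calibrates the
  type-I error at α = 0.05 over 1000 null replicates (n = 2000).
* `%Correct`: argmax of the fitted conditional per predictor state; ties go
  to the lowest DV state index; predictor states unseen in training fall
  back to the training DV marginal's argmax.
* `%Cover`: observed fraction of the predicting IVs' composite state space.

## 5. Beam search and selection

Level 0 is the independence model. Each level generates all "parents" of
the retained models — add a new dyadic {X, DV} relation, or add one IV to an
existing predictive relation — fits and scores them, and retains the best
`width` by the sort metric (default `%ΔH(DV)`; ΔBIC/ΔAIC/Inf available).
Duplicate structures are fitted once; non-converged fits are skipped with a
logged warning. A model is flagged significant when its G² p-values against
both the bottom and its recorded parent are below α and the parent is
itself significant. Defaults: width 3, levels 4 (API) / 3 (CLI), α 0.05.
Selection criteria: `max_metric_full_cover` (best metric among rows with
%Cover = 100 — the conservative default once deeper models require
predictions for unseen predictor states), `max_delta_bic`, or `manual`.

## 6. Space–time kernel pipeline

With T raster slices, each interior cell yields the row
Z1, N1, W1, E1, S1, …, S(T−1), Z(T), where Z(T) is the DV, N/W/E/S are the
von Neumann neighbours, and grid row 0 is the north edge. Border cells are
excluded; rows touching nodata are dropped and counted. Filters, in order:
(1) remove rows whose 21 values are all identical (static landscape carries
no transition information; note an all-EFO row is removed here even though
it contains the target class); (2) keep rows containing the target class
code (default 42, evergreen forest) anywhere. Rows are then stratified
50/50 on the DV (majority class downsampled without replacement), shuffled,
and split into equal train/test halves; the per-class cap `n_per_file` is
optional. Predictors collapse to five classes — WDA (water/developed/
agriculture), GRS, SHB, MFO, EFO — via a 15-code rebin map; the DV is
binary (EFO vs non-EFO). Raster IO uses the ESRI ASCII grid format
(plain-text header + matrix), read and written directly.

The pipeline driver (`rascube run`) derives all stage seeds from one root
seed via named `SeedSequence` substreams and writes `manifest.json` with the
seeds, per-stage row counts, and SHA-256 fingerprints of the intermediate
files, so any run is reproducible bitwise.

## 7. Succession simulator

Whole 5×5-cell patches (sizes configurable) follow a Markov chain that
emulates the clear-cut cycle: EFO with age ≥ `maturity_age` (default 2) is
harvested with `harvest_prob` (0.5) → GRS → SHB with `grs_to_shb` (0.8) →
EFO at age 1 with `shb_to_efo` (0.8). A `background_frac` (0.25) of patches
is static MFO/WDA. Initial forest ages are uniform on {1, …, maturity_age
+ 1}. Raw NLCD codes are emitted (42/71/52/43/82) so the full
extract/filter/rebin path is exercised; grids default to 100×100, T = 5,
epochs labelled 2001–2021. Patch-level transitions induce the spatial
autocorrelation the kernel exploits; patch boundaries supply mixed-state
rows.

`prob_next_efo(history)` is the chain-exact oracle for
P(next state = EFO | center-cell history): 0 after GRS/MFO/WDA,
`shb_to_efo` after SHB, 1 for immature forest, 1 − `harvest_prob` for
mature forest. Maturity is identified when the forest run started inside
the observed window or the window is at least `maturity_age` long;
otherwise the oracle declines to answer (`ValueError`).

**Conditional-recovery validation** (acceptance test 9) fits the
center-history model on *unfiltered, unstratified* rows sampled one per
patch. Three deliberate choices: (a) the row filters and 50/50
stratification are case-control-style selections whose conditionals
intentionally differ from the chain's, so the oracle comparison must use
raw sampling; (b) cells within a patch transition together, so one row per
patch keeps the binomial error model honest; (c) center-cell histories are
used (not neighbour composites) because neighbour states mix
patch-interior and patch-boundary cells whose stand ages differ, making a
single oracle value ill-defined. The two-epoch window (Z3, Z4) makes both
checked states identifiable: two consecutive EFO observations imply
maturity (window ≥ maturity_age), and SHB recovery is ageless.

## 8. Known limitations

* IPF's O(1/k) regime (zero cells not forced by single margins) limits
  attainable margin precision; the default tolerance is chosen relative to
  sampling noise, not machine precision.
* `%Cover` < 100 means some predictions fall back to the DV marginal; the
  default selection criterion avoids such models rather than modeling the
  unseen states.
* The simulator is patch-synchronous and spatially independent across
  patches; it validates recovery of temporal structure, not
  neighbour-interaction effects.
* Significance flags assume the χ² asymptotics of G²; with very sparse
  margins the test is approximate.
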