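# Methods

This note documents the models, formulas, numerical choices and known
limitations behind `algascreen`, in the order the pipeline runs.

## Growth kinetics

Growth is summarised by the specific growth rate μ (d⁻¹), the slope of
ln(density) against time over the exponential phase, and the generation
time T = 24 ln 2 / μ (hours; times are recorded in hours and the factor 24
converts to per-day rates in exactly one place). A non-positive μ has no
doubling time and raises a distinct `NoDoublingError` rather than returning
infinity.

The exponential window is chosen by exhaustive enumeration: every
contiguous window with at least `min_points` (default 3) observations
spanning at most `max_window_days` (default 3 — exponential growth in these
cultures rarely lasts longer) is scored by the r² of its least-squares
log-linear fit. The window with maximal r² wins; ties within 10⁻⁹ are
broken by preferring the larger window, then the earlier start. This is
deterministic and auditable, and on a noise-free exponential it recovers μ
to machine precision with r² = 1. A window of constant density has
undefined r² and is reported as μ = 0, r² = 0. The fit is invariant to
rescaling all densities by a positive constant, since only log-differences
enter.

When a strain has both OD and haemocytometer counts, the reader prefers OD;
a flag in the table (`measure`) switches this.

Report layer: μ printed to 2 decimals, hours to 1 decimal; all comparisons
use unrounded values.

## Fatty-acid nomenclature and profiles

Fatty acids are parsed from C\<X\>:\<Y\> shorthand with optional omega class
`(n-z)` and cis/trans qualifier. Chemically impossible unsaturation
(Y > X/2) is rejected. cis/trans isomers are distinct species in profiles
and clustering but share the same mass and double-bond count, so all fuel
indices treat them identically.

The mass term Mᵢ is the **methyl-ester** mass (the transesterified form
actually measured by GC-MS): a CX:Y acid esterifies to C(X+1)H(2X+2−2Y)O₂,
evaluated with atomic masses C = 12.011, H = 1.008, O = 15.999.

Profiles are compositional: wt% of total identified FAME, summing to 100
(tolerance 10⁻⁶). Normalisation removes the C19:0 internal standard (spiked
at 100 ppm) and rescales; it is idempotent, scale-invariant and
order-invariant. Unidentified peaks never enter a profile; their excluded
fraction is reported via a warning. Quantification against the internal
standard is available as an absolute-concentration output but never feeds
the indices, which use relative wt% only. Whether published wt% figures of
this kind are area-percent or standard-corrected mass-percent is generally
ambiguous; this package treats input values as relative abundances and
normalises whatever scale they arrive on.

## Biodiesel quality indices

With Nᵢ the wt%, Mᵢ the methyl-ester mass and Dᵢ the double-bond count:

| index | formula | units |
|---|---|---|
| SV | Σ 560 Nᵢ/Mᵢ | mg KOH/g |
| IV | Σ 254 Dᵢ Nᵢ/Mᵢ | g I₂/100 g |
| CN (default) | Σ (Nᵢ/100)(−7.8 + 0.302 Mᵢ − 20 Dᵢ) | — |
| CN (aggregate) | 46.3 + 5458/SV − 0.225 IV | — |
| DU | MUFA + 2·PUFA | wt% |
| LCSF | 0.1 N(C16:0) + 0.5 N(C18:0) + N(C20:0) + 1.5 N(C22:0) + 2 N(C24:0) | wt% |
| CFPP | 3.1417·LCSF − 16.477 | °C |

Two cetane-number methods are provided because published per-strain CN
tables are generally not consistent with the aggregate SV/IV form at high
iodine values while being close at low IV; the component-weighted form is
the default and the method used is recorded in all outputs. Printed CN
values from the reference collection are therefore treated as data, not as
recomputation targets.

LCSF includes only the *saturated* C16–C24 species (the standard
definition). Including unsaturated chains cannot reproduce the very low
LCSF observed for oleate-dominated strains, which settles the occasionally
loose phrasing "C16, C18, C20, C22, C24".

SV, IV, DU and LCSF are linear in composition; CFPP is affine in LCSF.

The ASTM D675 screen applies CN ≥ 47 and IV ≤ 120 *inclusively* (the
criteria are stated as a minimum and a maximum); no realistic profile sits
exactly on a threshold, so inclusivity does not change counts in practice.
Report rounding is half-away-from-zero (CFPP to integer °C), matching how
such tables are conventionally printed; Python's built-in banker's rounding
would differ on .5 cases. Screening counts are always recomputed from the
report rows, and strains missing either a profile or a growth fit are
listed as exclusions, never silently dropped.

## Profile clustering

Bray-Curtis dissimilarity BC(p,q) = Σ|pᵢ−qᵢ| / Σ(pᵢ+qᵢ) over the union of
species (absences are zeros); on the 100-wt% simplex it is symmetric,
bounded in [0,1] and zero iff the profiles coincide. UPGMA (unweighted
average linkage, delegated to scipy) merges the closest pair at its current
dissimilarity; **merge heights are the merge dissimilarity itself, not
halved**. Cophenetic distances use the same scale; only the cophenetic
correlation — which is scale-invariant — should be compared across
software. Strain labels are sorted before the distance computation so
residual ties resolve deterministically.

Bootstrap supports resample the fatty-acid **species columns** with
replacement (the only exchangeable axis of a strains × acids table), rebuild
the dendrogram, and score each node by the percentage of replicates
containing the same leaf set. A replicate in which some strain loses all
mass is uninformative and counts as no support. B = 0 returns the plain
dendrogram.

The analysis of a published collection would typically restrict to strains
sharing a phylotype with at least one other strain; that subset rule is an
input filter, not hard-coded.

## Copper toxicity bioassay

The 72-h static assay design: a concentration ladder
(0.01, 0.1, 0.32, 1.0, 3.2 mg·L⁻¹ Cu) plus a zero-copper control, each in
triplicate, followed by chlorophyll-a fluorescence at 24-h intervals.
Fluorescence is treated as proportional to biomass (no calibration curve),
so growth rates — the same exponential-window fit as above, restricted to
the 0–72 h window — depend only on fluorescence ratios and the analysis is
invariant to rescaling.

Percent inhibition is %I = (C − X)/C × 100 with C the mean control rate and
X the mean treated rate; percent-of-control is X/C × 100 and the two sum to
100 exactly. Negative %I (stimulation) passes through unclipped — it is
informative. A concentration is flagged `no_growth` when its mean rate is
≤ 0 or the mean final fluorescence does not exceed the initial; the flag
forces %I = 100 and percent-of-control = 0. A non-growing control is a hard
error (`ControlFailureError`).

Between-strain comparisons use the two-sample, two-tailed pooled-variance
Student's t-test (scipy). Zero variance in both groups returns (0, 1) for
equal means by convention. No EC50 curve is fitted: the assay reports %I
per concentration; dose-response curve fitting is a deliberate non-feature.

## Phylotyping

**Length filter.** Only sequences with ungapped length strictly greater
than 400 bp enter the analysis; exclusions are logged.

**Block cleaning** follows the Gblocks parameterisation in five steps:
classify columns (gap = any gap character; conserved = modal residue
frequency strictly greater than 50% of sequences; flank-conserved = ≥ 85%);
drop gap columns; reject runs of more than 8 contiguous non-conserved
columns; trim each block until both flanks are flank-conserved; keep blocks
of ≥ 10 columns. Kept columns are reported as an index map into the input,
in original order, and re-cleaning a cleaned alignment is a no-op. An empty
result is signalled with a warning, not an error.

**Distances.** p-distance (mismatches over pairwise-complete sites, gaps
and N deleted pairwise) by default, with the JC69 correction
−(3/4)·ln(1 − 4p/3) optional; saturated pairs (p ≥ 0.75) have no finite
JC69 distance and raise an error naming the pairs. p-distance is the
default because the sequences this stage targets are closely related
(phylotype work at 10⁻³ divergence), where the correction is negligible.

**Neighbour joining** is the plain Saitou–Nei algorithm: join the pair
minimising Q(i,j) = (n−2)d(i,j) − Σₖd(i,k) − Σₖd(j,k); branch lengths by
the rate-corrected split formula; negative branch lengths clamped to zero
with the deficit moved to the sister branch (logged); ties broken by the
lexicographically smallest member label; final three clusters joined by the
three-point formulas into the conventional trifurcating unrooted root. On
any additive matrix the topology and all branch lengths are recovered
exactly — the test suite checks this against a path-length oracle on random
5–7-leaf trees and cross-checks topology against an independent NJ
implementation. The variance-weighted BioNJ update is not implemented: on
clean or additive data the two agree, and for divergent data users should
prefer likelihood methods anyway.

**Bootstrap** resamples alignment columns with replacement, rebuilds the NJ
tree, and scores each internal edge by the percentage of replicates
containing its bipartition (canonicalised as the side not containing the
lexicographically smallest taxon, making the representation rooting- and
orientation-invariant). Supports attach to `node.support` and are written
as internal-node labels in Newick.

**Phylotype demarcation** interprets "branch lengths ≤ threshold" as
*patristic* (path-length) distance between leaves, with single-linkage
transitive closure; the default threshold is 0.001 substitutions/site. The
output is a partition and is monotone in the threshold (raising it never
splits a group). Alternatives (terminal branch length, cophenetic depth)
were considered and rejected because patristic distance is the only one
that is a metric on leaves and independent of rooting.

## Synthetic data

Each generator targets the statistical structure its downstream estimator
assumes; the defaults mirror the study designs above.

- **Growth**: density holds at n₀ through an optional lag, then follows
  logistic growth N(t) = K n₀ e^{μτ} / (K + n₀(e^{μτ} − 1)) with intrinsic
  rate μ (d⁻¹), sampled every 24 h for 168 h. Logistic saturation exists so
  the window-selection logic can be exercised; the lag defaults to 0.
  Noise is multiplicative lognormal with unit mean and configurable CV
  (OD noise is scale-proportional), so densities stay positive. With
  CV = 0 and K = ∞ the curve is exactly exponential and the fit recovers μ
  exactly.
- **FAME profiles**: each phylotype draws a base composition from a
  symmetric Dirichlet (concentration 1 by default — diffuse but proper);
  member strains multiply it componentwise by lognormal jitter
  (log-scale SD 0.1 by default, enough to blur but not break block
  structure) and renormalise to 100 wt%. SD = 0 yields identical members.
- **Dose-response**: mean rates follow the log-logistic (Hill) curve
  μ(c) = μ₀ / (1 + (c/EC50)^h) — the study itself fits no curve, but a
  monotone parametric family is needed to generate realistic inhibition
  panels; defaults μ₀ = 1 d⁻¹, EC50 = 0.3 mg/L, h = 2, the
  0.01/0.1/0.32/1.0/3.2 mg/L ladder, triplicates. Rates below a floor
  (0.05 d⁻¹) produce flat fluorescence — the no-growth regime. At c = EC50,
  noise-free, %I = 50 by construction.
- **Alignments**: a random bifurcating topology with exponential branch
  lengths (mean `subs_rate`), sequences evolved site-independently under
  Jukes-Cantor (equal rates — adequacy here means "NJ can recover the
  tree", not sequence realism). Gap columns are injected i.i.d. per column;
  near-identical twin tips emulate phylotype pairs. The true tree is
  returned alongside.

Seeding: one seed per config; per-strain/taxon sub-streams derive from
`numpy.random.SeedSequence` spawn keys, so adding a strain or phylotype
never reshuffles the values generated for existing ones, and a fixed seed
fixes every output byte-for-byte.

What the generators do **not** emulate: GC-MS chromatograms or instrument
drift, real 18S base composition or rate heterogeneity, pH dynamics or
copper speciation, and measurement-variance structure (no replicate
variance information is available to calibrate against — noise magnitudes
are free parameters). Passing recovery tests therefore demonstrates
correctness of the estimators under their assumed models, not robustness to
every feature of real data.

## Problem sizes and test design

Tests run at desk scale by choice: clustering oracles up to 7 leaves
(exhaustive brute-force UPGMA recomputation), NJ exactness on random 5–7
leaf additive trees, topology recovery at 8 taxa × 5000 sites, bootstrap
checks at 20–200 replicates (the production default stays 1,000). The
printed per-strain tables of the reference collection ship as package data
and anchor the formula-level checks (CFPP over all 34 strains, ASTM counts,
generation-time consistency, fast-grower counts).

## Known limitations

- Published per-strain CN/IV/SV/DU values cannot be recomputed without the
  underlying raw compositions; the package verifies the formulas on pure
  and constructed profiles and treats printed index values as inputs.
- Published dendrogram statistics (e.g. a cophenetic r for a specific
  strain subset) depend on the raw FAME table and subset rule; the package
  validates its clustering against brute-force oracles instead.
- Reproducing a published tree requires the deposited sequences and the
  original MUSCLE alignment; that is an integration exercise, not a unit
  property, and is out of scope here.
- The CN equation variant used for any given published table is often
  indeterminable; both common variants are provided and labelled.
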