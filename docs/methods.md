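# Methods

## The measurement model

A targeted-proteolysis experiment observes an ensemble of identical
substrate molecules being cut by a protease.  Every internal peptide
product is bounded by two scissile bonds; a bond is identified by its P1
residue (the residue N-terminal to the cut; the product's first residue is
the P1′ of the upstream cut, its last residue the P1 of the downstream
cut).  Products shorter or longer than the LC-MS peptide window are not
observed.  Intensities are label-free, acquired per replicate per time
point, with protease-free controls measured under the same design.

Coordinates are 1-based and inclusive throughout; a cleavage site is its
P1 index, so a substrate of length L has bonds P1 = 1…L−1.  A
recombinant→native numbering offset is carried by the substrate object so
results can be reported in native residue numbers (e.g. a protease
construct spanning natives 158–480 has offset +157).  The FASTA sequence
given is authoritative — no initiator-methionine trimming is applied,
since products starting at residue 2 are meaningful observations.

Peptides mapping to more than one substrate position are discarded by
default (configurable to "first occurrence"): a wrong coordinate would
contaminate every downstream per-site statistic, whereas discarding only
loses one observation.

## Filter stack

1. **Replicate QC.**  Per condition and time point, each sample's mean
   pairwise Pearson correlation against the other replicates is computed
   on jointly detected, log2-transformed intensities; samples with mean
   r < 0.4 are excluded.  If exclusion would leave fewer than two samples
   the best pair is kept with a warning.  Pairs with fewer than three
   joint detections carry no evidence and do not count against a sample.
2. **Score filter.**  Identification score ≥ 50 (≥ semantics at the
   boundary).
3. **Relevance (slope homogeneity).**  Classical ANCOVA on
   log2 intensity ~ time × group pooled over digest and control
   observations; the peptide is a relevant proteolytic product when the
   interaction (slope-difference) F-test with (1, n−4) degrees of freedom
   gives p < α (default 0.05).  Time enters as a continuous covariate;
   this is the standard reading of "homogeneity of regression slopes".
   The test is computed by direct least squares (full vs reduced residual
   sum of squares) and is cross-checked against a statsmodels OLS fit in
   the test suite.  When the control block has fewer than two detections
   the test is undefined; the peptide is then called relevant iff it was
   detected at all (enrichment over a silent control).
4. **Per-time significance.**  A one-sided Welch t-test (digest >
   control) on log2 intensities decides whether a peptide's average at a
   time point is kept or set to zero.  One-sided because proteolytic
   products can only be enriched over protease-free controls.

**Zeros and missing values.**  A zero intensity in label-free MS is a
non-detection, not a measured zero.  Zeros are therefore treated as
missing for correlations and significance tests, but as zeros when
averaging replicate intensities — the averaging semantics the
cut-frequency statistic requires.  Degenerate designs resolve explicitly:
no digest detection → not significant; silent control → significant iff
any digest detection; a single digest detection against a measured
control → not significant (insufficient evidence); two zero-variance
groups → compare means directly.  No multiple-testing correction is
applied by default (a plain per-test α of 0.05 matches common practice
for this assay); no normalization or imputation is performed.

## The relative cut frequency

For each peptide: average intensity per time point over retained
replicates (zeroed where not significant), then ratios referenced to the
first nonzero average along the time course.  For each P1 site and time
point, the frequency is the sum of the ratios of all peptides sharing
that bond.  A peptide contributes to **both** of its bounding bonds by
default — each internal product evidences two cuts — with a
C-terminal-only mode available, since published descriptions do not state
which convention their software uses.  The reference is per-peptide, not
per-site.  Frequencies are kept at full precision internally and rounded
to integers only in figure-style outputs.

Site classes bin the maximum frequency over time with descending lower
bounds; two presets mirror the published groupings (≥20 / 11–19 / 1–10 /
undetected, and ≥30 / 21–30 / 1–20 / undetected).  The boundary value
belongs to the higher class in both presets.

## Specificity

Windows span P5…P1 / P1′…P5′; positions beyond the termini are padded
with '-' which participates in normalization as its own category, so
columns near termini still sum to 100%.  The default weighting counts
each detected site once per time point; frequency weighting is optional
— published percentages do not state their weighting, so both are
provided and labelled.  Consensus is the per-position argmax, ties broken
alphabetically and flagged, positions below a support floor (default
10%) lowercased.  Conditions are compared by per-position total-variation
distance in percentage points.

## Structure and conservation tracks

Secondary structure is read from the coordinate file's HELIX/SHEET
records — i.e. "as assigned in the deposited structure" — rather than
recomputed; residues in neither record class are loops, and overlaps
resolve with helix precedence.  B-factors are averaged over heavy atoms;
altloc duplicates resolve to the highest-occupancy conformer.  Solvent
accessibility is Shrake–Rupley (probe 1.4 Å, 960 sphere points by
default) on the isolated chain; RSA divides by the Tien (2013)
theoretical maximum per residue type and is clipped to [0, 1] because a
free terminal residue can exceed the in-chain theoretical maximum.
Surface/buried is RSA ≥ 0.2 by default — an explicit stand-in rule, since
the figure legends this mirrors cite no cutoff.  Conservation symbols
follow Clustal conventions ('*' identical, ':' strong group, '.' weak
group) computed on alignment columns mapped through the reference row;
columns containing gaps are blank.

## Event ordering and the unfolding model

Sites are ranked by (onset time ascending, maximum frequency descending,
position ascending).  Onset is the first sampled time with frequency
> 0.  The ranked cuts are replayed on the intact chain, one global event
at a time, yielding an interval partition after every step — a model
hypothesis of sequential unfolding, not an observed per-molecule path.
The published narrative combines low-protease early events with
high-protease frequencies qualitatively; this package encodes the above
explicit rule instead, with the minimum-frequency threshold configurable.

## The digestion simulator

Each molecule carries independent exponential clocks, one per accessible
uncut bond; firing a cut can unlock gated bonds (conjunctive gates: all
prerequisites must have fired on that molecule).  Because the clocks are
independent and memoryless, the firing time of a site equals the firing
time of its slowest prerequisite plus a fresh Exp(k) delay; the simulator
samples exactly this representation in topological order of the
(acyclic) gate graph, vectorised over molecules.  This is an exact draw
from the event-driven process, not an approximation.  Protease
concentration is a global multiplier on all rates.  Products are the
maximal intervals between cuts; those within the detectable window (7–25
residues, matching a typical search window with minimum peptide length 7)
become observable, and all intervals are retained for residue
mass-balance checks.  Intensity = scale × abundance × LogNormal(0, σ)
independently per replicate, zeroed with the dropout probability and
below an absolute detection limit; control samples carry zero product
intensity.

Default noise conditions emulate label-free quantification: 4 replicates,
σ = 0.5 (≈50% CV), 10% dropout, detection limit at 1% of the ensemble.
The ensemble size (10,000 molecules) is a coarse stand-in for the ~10¹²
molecules of a real digest; the detection limit is therefore expressed as
a fraction of the ensemble, standing in for the instrument's dynamic
range relative to the substrate pool.

### Scenarios

* **three-wave** (default): a 346-residue pseudo-substrate with three
  fast surface sites (k = 0.03–0.05 s⁻¹), six second-wave sites gated on
  them (k = 5×10⁻⁴ s⁻¹), and a chained late C-terminal block
  (k = 2×10⁻⁴ s⁻¹), sampled at 11 time points from 0 to 7200 s.  The
  rate tiers are separated so the three waves onset in distinct parts of
  the sampling grid, giving the unfolding-order inference a known truth.
  Every adjacent site pair is 8–18 residues apart so that final products
  are detectable.
* **rate-recovery**: 120 ungated sites at every residue 30–149 of a
  180-mer, rates log-uniform over 0.001–0.1 s⁻¹ in a shuffled
  deterministic assignment, first sampling point 3 s, detection limit
  0.2%.  At the first sampled time every detected peptide has ratio 1, so
  a site's frequency counts its detected partner products; the design
  keeps that count in its discriminating regime (neither floor nor
  saturation) and gives each site ~18 potential partners inside the
  length window so no single partner's rate dominates.  Under these
  conditions the Spearman correlation between true rates and
  first-time-point frequencies is ≈0.93–0.94.
* **convergence**: one shared 8-site set on a 110-mer — four fast ungated
  sites with Lys at P1 and four chained gated sites with Ala at P1.  The
  gated ("folded") condition unlocks the Ala sites stepwise; the ungated
  ("denatured") condition shows all sites from the first time point, so
  the P1 residue-type distributions start 50 percentage points apart and
  converge to zero distance as the gates open.
* **single-site**: one ungated bond; its cut fraction follows
  1 − e^(−kt) exactly, the simulator's closed-form check.

Kinetic constants are free parameters of each scenario (the assay this
emulates reports no rate constants); the values above were fixed at
design time with the rationale given and are not tuned per run.

### What the simulator does not emulate

No m/z, charge state, retention time or spectral interference; no
sequence-dependent cleavage preference (rates are assigned, not derived
from residues); no missed identification of co-eluting products; no
between-run matching artefacts; no protease self-digestion.  Passing
tests therefore demonstrate the correctness and calibration of the
statistics on data with the assumed structure — not robustness to every
failure mode of real LC-MS data.  In particular the published site
counts and P1 percentages for the real substrates derive from deposited
raw data and are outside what desk-scale simulation can or should
reproduce.

## Numerical choices

* Ratios of an all-zero average series are all zero; the reference index
  is the first strictly positive average.
* The ANCOVA F-test returns NaN (not-testable) for rank-deficient
  designs (fewer than two distinct time points with observations per
  group); a saturated perfect fit returns p = 0 when the interaction
  explains residual variance and p = 1 otherwise.
* Histogram bins are [0, w), [w, 2w), …; an all-zero profile set yields
  a single zero bin.
* Fragment merging treats abutting intervals (gap 0) as one fragment.
* Uncut regions are maximal runs of zero-frequency bonds reported as
  residue intervals (first P1, last P1 + 1).
* All randomness flows through numpy Generators seeded explicitly;
  identical seeds give byte-identical outputs (checked in the pipeline
  round-trip test).

## Problem sizes

The validation suite uses 10,000-molecule ensembles for law, recovery
and convergence checks, 20 simulation seeds for gate-pair ordering,
1,000 null simulations for test calibration, 1,000 random interval sets
for the fragment oracle, and 200 simulated peptides for the statistic
oracle — sizes at which the binomial/Monte-Carlo error bands quoted with
each check are meaningful while the whole suite stays fast.
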