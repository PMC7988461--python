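# Methods

## The assay being modelled

Oxysterols and cholestenoic acids circulate at ng/mL levels amid a
million-fold excess of cholesterol, and most carry no ionisable group, so
direct electrospray LC-MS is insensitive to them.  The workflow implemented
here charge-tags them: cholesterol oxidase converts the 3β-hydroxy-5-ene
function shared by most sterols to a 3-oxo-4-ene, and Girard's reagent P
(GP, a pyridinium acetohydrazide) condenses with the ketone, losing water
and leaving a fixed positive charge that boosts ESI response by orders of
magnitude.

Each sample is processed twice:

* **Fraction A** — oxidase treatment, then derivatisation with the
  ring-deuterated **[2H5]GP**.  Everything with a 3β-hydroxy-5-ene *or* a
  native oxo group is tagged.
* **Fraction B** — no oxidase, **[2H0]GP**.  Only native 3-oxo-4-ene (and
  7-oxo) sterols are tagged.

Both fractions are combined into one LC-MS injection; the 5 × (2H−H) mass
offset between the GP variants keeps them separable in m/z.  For any redox
pair that shares a fraction-A derivative (e.g. 7α-hydroxycholesterol and
7α-hydroxycholest-4-en-3-one), the 3-oxo form is read from fraction B and
the 3β-hydroxy form from the difference A − B.  Sterols with no natural
3-oxo analogue (24S-HC, 25-HC, (25R)26-HC, 7β-HC, the dehydrated triol) are
fraction-A-only; 7-oxocholesterol is quantified from fraction B alone.

Quantification is single-point stable-isotope dilution.  With PA the peak
area, Rf the response factor and C the concentration, the model is

    PA_u / PA_l = (Rf_u / Rf_l) · (C_u / C_l) + constant,

where *u* is the endogenous (unlabelled) analyte and *l* the co-processed
deuterated standard of certified amount.  In single-point mode the constant
is zero and the relation is inverted directly; in standard-addition mode
slope and intercept are fitted over ≥ 3 spiked levels and the endogenous
concentration is the x-intercept magnitude (intercept/slope).  Rf ratios
default to 1: for an exact isotopologue pair this is the physics, for a
surrogate standard it is an assumption, which is why every reported value
carries a tier — *absolute* (authentic labelled standard), *semi*
(structurally similar surrogate), *approximate* (presumptive
identification), or *identified only* (no concentration).

## Mass calculus

Derivative ion formulas are built by elemental bookkeeping: −H2 when the
oxidase converts a 3β-hydroxy-5-ene, −H2O for the triol that dehydrates
during derivatisation, +GP cation, −H2O for hydrazone condensation.  All
m/z values are computed from a single hard-coded table of NIST monoisotopic
masses, with one electron mass subtracted for the cation.  The deuteriums
of [2H5]GP sit on the pyridine ring, so the diagnostic MSn neutral loss is
[2H5]-pyridine (84.0736 u) in fraction A and pyridine (79.0422 u) in
fraction B — the published 1-decimal MRM levels (455.4, 462.4, 461.4,
471.4, 501.3) are reproduced only under this assignment.  Diagnostic MS3
fragments (353.3 for the 24-hydroxy epimers, 427.3/455.3 for the
dihydroxy-oxo acids, matched at ±0.3 u) live in a static library; no
fragmentation prediction is attempted.

One reconciliation worth recording: the M+1 isotopologue of the
[2H6](25R)26-HC derivative computes to 546.4778 at full precision, while
the assay literature prints 546.4777 — the printed figure follows from
adding a rounded 13C–12C spacing to the already-rounded monoisotopic value.
The package reports the full-precision number; the two agree at 0.19 ppm.

## The synthetic-data generator

No public raw data exist for this assay, so the package ships a generator
whose defaults encode the study conditions and whose ground truth makes the
pipeline testable end to end.

**Sample model.**  A `TrueSampleState` holds free and esterified ng/mL per
analyte.  The `SRM1950_like` preset uses pooled-plasma order-of-magnitude
values (cholesterol 1.54 mg/mL with ~25% free; 24S-HC 60 ng/mL total,
~25% free; (25R)26-HC 160 ng/mL total, ~16% free; C27 acid 25R epimers 3–6×
the 25S epimers).  `CSF_QC_like` has abundant cholestenoic acids
(7αH,3O-CA ≈ 20 ng/mL combined) and sub-ng/mL free oxysterols.  `ACOX2`
inverts the 25R/25S acid ratios; `CTX` zeroes (25R)26-HC and elevates
7α-HCO.  Workup arithmetic: a 50 µL (plasma) or 20 µL (CSF) aliquot of the
certified standard mix; alkaline hydrolysis releases the esterified pool
and removes a configurable 20% of every 7-hydroxy species — analyte and its
exact labelled surrogate alike, which is what lets isotope dilution cancel
the loss (the base lability of these skeletons is described only
qualitatively in the assay literature; 20% is a declared default).  Ex-vivo autoxidation increments for 7α-HC, 7β-HC, 7-OC
and the triol default to zero and, when a scenario enables them, are drawn
once per run, with labelled counterparts scaled by the
[2H7]cholesterol/cholesterol ratio — emulating the irreproducible artifact
formation that degrades those analytes' precision.

**Instrument model.**  17-min gradient sampled at 1 Hz (MS1) with MS3
scans interleaved on a 2-s cycle; Gaussian peaks of σ = 0.03 min split
60/40 into syn/anti hydrazone conformers 0.3 min apart (doublets are
observed in the real chromatograms; the ratio is not published — both
numbers are declared defaults, and a split of 1.0 collapses the doublet for
diagnostic scenarios); labelled species elute 0.05 min early.  Retention
times are nominal values on a 0.05-min grid chosen to reproduce the named
co-elutions (24R-HC 0.15 min before (25R)26-HC; each redox pair exactly
co-eluting).  The 13C envelope is deterministic, not sampled: the M+k
satellite carries `binom.pmf(k, 34, 0.0107)` of the monoisotopic area.
Under this convention the monoisotopic channel integrates to
`amount × area_per_ng` exactly and the M+1 leak under a co-eluting
1-Da-heavier channel is `donor area × 34·p·(1−p)^33`; the (1−p)^34
attenuation that physically affects the M channel is absorbed into
`area_per_ng` and cancels in every ratio, because all GP derivatives here
are C34.  Centroids closer than m/z / (resolving power 120 000) merge into
one intensity-weighted centroid — this is what makes the
[2H6]-M+1 / [2H7] interference and the [2H5]-impurity / [2H6] interference
emerge from the data rather than being injected by fiat.  The [2H5]
impurity of the [2H6](25R)26-HC standard is always present at 15%.
Stochastic elements (additive centroid noise, optional per-peak area
jitter) flow from a single seed; identical seeds give byte-identical
serialised runs.

**What the generator does not emulate** — and hence what green tests do
not establish about real data: peak tailing and saturation, ion
suppression and other matrix effects, retention-time drift between runs,
real isotope-envelope deviations (the deliberate satellite convention
above), chemical noise, and any inter-laboratory variability.  Recovery
results on synthetic data validate the *bookkeeping* — fraction logic,
interference algebra, calibration arithmetic — not chromatographic
robustness.

## Signal extraction and interference handling

Reconstructed-ion chromatograms sum centroids within a closed ±5 ppm
window (the published figure windows; ±3 ppm is used in the CSF figures
and is configurable).  Peaks are local maxima near the expected retention
time; boundaries run to the flanking local minimum or the 1%-of-apex
crossing, whichever comes first; areas are trapezoidal, with no smoothing
by default (a 3-point moving average sits behind a flag) and no baseline
subtraction beyond the boundary rule.  The syn/anti doublet is merged into
one measurement; more than two aligned candidates flags co-elution and
keeps the two largest.  Apex alignment is enforced at ±0.1 min — tighter
than chromatographic reproducibility strictly requires, but necessary to
refuse the neighbouring epimer 0.15 min away (otherwise a sample genuinely
lacking (25R)26-HC would have 24R-HC silently reported in its place).

Two interference mechanisms are handled:

* **M+1 under a 1-Da-heavier channel.**  The 13C satellite of the [2H6]
  standard is 3 mDa from the [2H7]24R-HC channel — unresolved at
  R = 120 000.  The algebraic correction subtracts
  `donor area × 34·p·(1−p)^33`, floored at zero and flagged.  It is exact
  only when donor and target are integrated over the same time window and
  the window's m/z tolerance covers the unresolved doublet (±10 ppm here,
  since the satellite sits 5.4 ppm off-channel).  The correction is chained:
  the [2H5] impurity first corrects the [2H6] standard, which then corrects
  the [2H7]24R channel.
* **MRM rescue.**  The 24R/S epimers fragment to m/z 353.3 while
  (25R)26-HC does not (< 1% relative abundance), so the
  [M]+ → [M−Py]+ → 353.3 trace is transparent to the co-eluter.  24R-HC
  and its standard are marked `prefer_mrm` and quantified on this channel
  by default; the RIC route with algebraic correction remains available.
  Analyte and standard always use the same channel type, so the MS3 yield
  cancels.

## Quantification bookkeeping

Concentrations refer to the original fluid volume (ng/mL of plasma or CSF;
µg/mL scale for cholesterol): the amount of standard is divided by the
sample volume at the quantification step.  The halving of each extract into
fractions A and B cancels because analyte and standard split identically —
asserted by the end-to-end recovery tests.  Where two labelled standards
become indistinguishable after derivatisation ([2H7]7α-HC and
[2H7]7α-HCO share the fraction-A derivative and retention time), the
fraction-A reference is their merged peak with the summed certified
amount.  Epimer-mixture standards are split once per lot by measured area
fraction: the certified 80 ng/mL of [2H7]24R/S-HC partitions 35.44 : 44.56
between 24S and 24R; the [2H3] acid standard is split 50:50 in the absence
of a certified ratio (declared assumption).  Negative A − B differences
are clipped to zero and flagged.  Percent free = 100 × free/total from a
paired non-hydrolysed/hydrolysed analysis; values above 100% are reported
and flagged rather than truncated, since imperfect degradation correction
genuinely produces them.

## QC metrics

%CV uses the sample (n−1) standard deviation.  Accuracy is
100 × (1 − |measured − predicted|/predicted) against the calibration-line
prediction.  Apparent extraction efficiency is the recovered fraction of an
added unlabelled spike (the generator's `analyte_recovery` knob models
matrix-bound losses the free-solution standards do not share).  Batch
agreement between two estimates is 100 × min/max (the literature reports
agreement percentages without stating a formula; this is the declared
choice).  The lower limit of quantification from a technical dilution
ladder is the smallest expected concentration deviating < 30% from its
measured value *with every higher level also passing* — the strict reading
of "lowest concentration at which"; a single failing level above caps the
LLOQ regardless of lower levels.

## Numerical choices and problem sizes

Simulated runs use a 17-min, 1 Hz MS1 grid (1021 scans) with all nominal
retention times on the 0.05-min sampling grid, so every Gaussian shares
the same sampling phase and trapezoidal areas cancel exactly in ratios.
Test and acceptance studies use single runs for noiseless recovery and 10
seeded replicates at 5% per-peak area CV for precision — sizes at which
the full pipeline (simulate → extract → quantify) completes in well under
a second per run.  Replicate precision is assessed on the measured
per-fraction quantities for A − B pairs (the difference of two similar
numbers inherits both errors; the deconvolved value is covered by the
median-error bound instead), matching how the assay's own precision claims
were made on combined fraction-A measurements.

## Known limitations

Single-point isotope dilution only (no external multi-point calibration,
by design of the method); no curve-fit deconvolution of overlapping peaks
and no cross-run retention alignment; generic treatment of unidentified
[M+2]+ interferents (they are not modelled as named species); 25-hydroxy-
vitamin D3 is out of scope (its accurate extraction needs a different
solvent); mzML export is write-only; and the synthetic-data caveats listed
above.
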