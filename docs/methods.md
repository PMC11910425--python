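# Methods

## Scope and model

`metalrisk` implements the standard screening battery for heavy-metal
contamination at a multi-compartment industrial site: soil pollution
indices, Hakanson ecological risk, USEPA three-route human exposure,
soil-to-plant transfer, and wastewater correlation/compliance statistics.
All computations are deterministic point estimates on site-by-analyte
concentration tables; no probabilistic (Monte-Carlo) exposure assessment is
attempted, and no spatial or temporal structure is modelled.

## Indices and classifiers

*I*<sub>geo</sub> = log₂(*C*ₘ / 1.5 *B*ₘ); the factor 1.5 buffers natural
background fluctuation.  EF double-normalises against a conservative
reference metal, Fe by default (configurable).  CF = *C*ₘ/*B*ₘ and
PLI is the geometric mean of a site's CFs, computed in log space so that
extreme contamination factors cannot overflow.  ER = *T*ᵣ · CF and
PERI = Σ ER over the metals with a configured toxic-response factor; Fe and
Mn have none and are excluded, as is conventional.

The published band tables leave some boundary values unassigned; the
classifiers close them so every scheme partitions the real line (verified
by a dense-sampling partition test):

* *I*<sub>geo</sub>: left-closed bands [k−1, k); a value of exactly 0 falls
  in class 1.
* EF: the "Significantly" band keeps its printed closed edges [5, 20], so
  "Very Strongly" is (20, 40] and "Extremely" (40, ∞).
* CF: the conventional "Moderate" band fills the printed gap [1, 3);
  [3, 6] retains its printed closed edges.
* PERI: the scale has no counterpart of the ER "High" band;
  "Considerable" jumps to "Very high" at 600.
* EF additionally carries a boolean anthropogenic-influence flag
  (EF > 1.5), which is a stricter screen than the first band edge at 2.

## Reference constants

Backgrounds default to global average-shale values (Cr 90, Cd 0.3, Ni 68,
Cu 45, Zn 95, Pb 20, Fe 47200, Mn 850 mg/kg).  This choice is corroborated
internally: inverting the packaged ecological-risk table with these
backgrounds reproduces the published concentration extremes exactly
(Pb 109.52, Cd 35.1 mg/kg) and the published six-metal means to within
0.5%.

Reference doses are a documented standard USEPA-style table (oral values
from IRIS/RSL screening practice; dermal = oral × ABS_GI where an
absorption fraction is published; inhalation RfC-derived).  They are
deliberately config-overridable: published route-level hazard quotients
from any given study depend on that study's working RfDs, which are rarely
printed, so from-scratch HQ values computed with the defaults are *not*
expected to match any particular published table.  The aggregation
arithmetic (HI as a sum of HQs, total CR as a sum of route risks) is what
the package guarantees and what the reproduction tests pin down.

## Exposure model conventions

Default equations are the standard USEPA forms.  Two deliberate variants
exist behind the `literal_equations` flag, reproducing a published variant
of the equations verbatim for comparability:

* inhalation CDI: default divides by the particle emission factor
  (PEF, 1.36 × 10⁹ m³/kg), which the literal variant omits in favour of a
  repeated exposure-frequency term and the mass conversion factor; the two
  differ by exactly EF × CF × PEF.
* ingestion CR: the literal variant multiplies by the dermal adherence
  factor AF; the default excludes it, consistent with the ingestion CDI.

The dermal slope factor is defined as CSF_oral / ABS_GI, so the
CSF_d × ABS_GI product in the dermal-risk equation cancels to CSF_oral;
the reduction is applied directly and recorded in the aggregation notes
rather than hidden.  The averaging time defaults to 365 × 70 days for both
endpoint classes (as in the tabulated exposure parameters this package
mirrors); `noncancer_averaging_time="ed365"` switches the
non-carcinogenic CDIs to the conventional AT = ED × 365.  The child dermal
absorption fraction (0.001, versus adult 0.01) follows the same tabulated
source and is overridable.  The hazard index is reported both as the
dermal-only sum (matching the published aggregation) and as an all-routes
sum, clearly labelled.

## Transfer and correlation statistics

TF = *C*<sub>plant</sub>/*C*<sub>soil</sub> per site and metal; summaries
use the sample (n−1) standard deviation, which reproduces the published
per-metal spreads.  Pearson correlations are computed pairwise on complete
observations (with five-site panels, listwise deletion is wasteful); a
pair with fewer than three complete observations or zero variance is
reported as missing with a reason instead of a NaN.  Guideline intervals
(e.g. a 100–150 mg/kg band) use the upper bound for exceedance ratios and
the full interval for verdicts.

## Synthetic-data generator

The generator emulates the study conditions the packaged fixture reflects:
five sites, eight metals, right-skewed positive concentrations.

* **Soil**: per-metal lognormal draws times an anthropogenic enrichment
  factor ≥ 1.  Defaults are mean-matched to the published per-metal means
  and coefficients of variation (log-sd = √ln(1+CV²)); enrichment defaults
  to max(1, published mean / shale background), making Cr, Fe and Mn
  background-like and Cd (×73) and Zn (×29) heavily enriched.
* **Plant**: soil × TF draw × unit-mean multiplicative lognormal noise
  (default log-sd 0.10).  TF distributions are moment-matched to the
  published per-metal TF means and standard deviations.
* **Wastewater**: Gaussian copula over lognormal marginals.  Pearson
  correlation on the lognormal scale is attenuated relative to the copula
  parameter, so the copula correlation is set analytically from the target:
  ρ = ln(1 + r √((e^{σ₁²}−1)(e^{σ₂²}−1))) / (σ₁σ₂).  Published pair targets
  (e.g. Cu–Zn 0.92, Cu–Fe 0.90, Cd–Zn −0.39) fill the known entries; the
  unpublished pairs carry plausible moderate values, labelled synthetic in
  the source, and the matrix is repaired to positive semidefinite by
  eigenvalue clipping with diagonal renormalisation (repair tolerance
  1e−8; matrices with minimum eigenvalue below −0.05 are rejected rather
  than silently distorted).  Marginal medians are synthetic
  untreated-effluent scales (0.02–1.8 mg/L), since no per-site wastewater
  metal concentrations are published.  The physicochemical panel is drawn
  uniformly within ranges spanning the published values.

The three compartments consume independent child streams of the seed, so
generating one table does not perturb another.  What passing tests show:
marginal shapes, correlation structure, enrichment contrasts and the
pipeline's end-to-end behaviour.  What they do not show: spatial
autocorrelation between sites, seasonal structure, censoring at detection
limits, or analytical measurement error — real field data have all four.

## Numerical choices and degenerate inputs

* Concentrations must be finite and strictly positive; missing cells are
  genuinely absent (NaN), never zero, and are skipped, not imputed.
* Analytes lacking a required constant are skipped with a logged warning
  and surfaced through the alignment report; pipeline stages with unmet
  inputs are recorded as skipped with a reason, never silently dropped.
* Published-comparison tests compare at the printed precision (two
  decimals for indices, 3–4 significant figures for risks); internal
  storage is full double precision, and CSV output uses repr precision so
  write/read round trips are lossless.
* PLI and PERI require non-empty inputs; classifiers reject non-finite
  values; the cancer-risk container enforces risks in [0, 1).

## Problem sizes

The packaged fixture is five sites × eight metals.  Statistical
calibration checks run at the smallest sizes at which the targeted
tolerances are statistically meaningful: correlation recovery at 200
sites (±0.05 on r), identity-correlation bounds at 500, lognormal
parameter recovery at 10⁴ draws (within two standard errors).

## Known limitations

* Point-estimate exposure only; no age-integrated or mutagenic-adjusted
  slope factors.
* No mg/L ↔ mg/kg conversion: wastewater metals are never fed to the
  soil-based indices.
* Guideline registries cover the eight packaged metals; other analytes
  pass through with "uncovered" flags rather than errors.
* The correlation module reports sample r and n only; significance
  screening across many pairs is left to the user's multiplicity policy.
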