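# Methods

This note records the models, conventions, and numerical choices behind
`mzcanvas`, and what the synthetic test bed does and does not establish
about behavior on real data.

## Mass arithmetic and ion conventions

All masses are monoisotopic. Residue masses come from the standard
amino-acid table (via pyteomics); the composite constants are pinned in
`constants.py`: proton 1.007276 Da, water 18.010565 Da, NH₃ 17.026549 Da,
isotope spacing 1.0033548 Da. Five-decimal agreement with published
reference values (e.g. glycine peptide 75.03203 Da, y1 of a C-terminal
lysine 147.11280 Th) is asserted in the tests.

z ions are modeled as the z-dot radical species actually observed in ETD,
z = y − 16.018724 Da; c = b + NH₃. Neutral-loss satellite series (−H₂O,
−NH₃), a-ions, immonium and internal fragments are deliberately out of
scope for this version: they multiply the ion space without changing the
localization logic the package exists for, and can be layered on later.

Modifications are positioned mass deltas (0 = N-terminus, 1..n residues,
n+1 = C-terminus), at most one per position. A modification at or before a
cleavage point belongs to the N-terminal-side fragment (b/c), otherwise to
the C-terminal side (y/z). This makes the effect of moving a modification
strictly local: only ions whose cleavage point lies between the two sites
change, which is the information content of site localization and is
checked by a brute-force fragment-diff test.

Spectrum annotation matches each theoretical ion to its nearest peak within
a ppm tolerance (default 10 ppm, configurable). One peak may satisfy
several ions (overlapping series happen in real spectra); each ion gets at
most one peak; equidistant candidates resolve to the lower-m/z peak for
determinism.

## Averagine isotope model

Envelope scoring and the synthetic generator share one isotope model: the
averagine average-residue composition implies an expected heavy-isotope
count λ ≈ 5.363·10⁻⁴ per Da of neutral mass (summed single-substitution
probabilities of ¹³C, ¹⁵N, ²H, ¹⁷O, ³³S over the averagine formula), and
relative abundances of the 0,1,2,… isotope peaks follow Poisson(λ). This is
the standard low-mass approximation; it ignores sulfur-count variance and
fine structure, which is acceptable below ~5 kDa where the package
operates. Sharing the model between detector and generator is intentional:
detection tests then measure the detector's grouping and linking logic, not
a model mismatch.

## MS1 feature detection

Per spectrum, envelope detection is greedy highest-intensity-first: each
unused peak seeds candidate envelopes at every charge in `charge_range`
(default 1–6) by collecting unused peaks at spacings k·1.0033548/z within
`spacing_tol_ppm` (default 10). Among charges reaching ≥ `min_isotopes`
(default 2) peaks and an averagine cosine ≥ `min_score` (default 0.9), the
winner has the most isotopes, then the best score, then the lowest charge —
the isotope-count-first rule matters because a z-charged envelope always
contains a plausible z/2 sub-envelope at doubled spacing. Every peak joins
at most one envelope (audited by test).

Features link same-charge envelopes across consecutive MS1 scans when
monoisotopic m/z agrees within `link_tol_ppm` (default 10), bridging up to
`max_gap` missing scans (default 1, covering single-scan dropouts at
envelope edges); traces shorter than `min_scans` (default 3) are dropped.
Feature m/z is the intensity-weighted mean of member envelopes; area is the
trapezoidal integral of the monoisotope trace over retention time. An MS/MS
scan links to a feature when its precursor falls within tolerance of *any*
isotope of the envelope (instruments routinely pick the +1 or +2 isotope)
and its rt is within the feature range padded by `rt_pad` (default
0.2 min); competing features resolve to the nearest monoisotopic m/z.

## Spectral processing and provenance

De-isotoping reuses the envelope machinery on the MS/MS peak list and
collapses each envelope to its monoisotopic peak with summed intensity,
writing the envelope charge into a per-peak annotation. Peaks already
carrying a charge annotation are excluded from later envelope formation;
this is what makes de-isotoping idempotent (without it, monoisotopic peaks
of unrelated fragments that happen to sit ~1 isotope spacing apart would
regroup on a second pass). Charge reduction consumes the annotations:
m/z → z·m/z − (z−1)·proton, exactly conserving each peak's neutral mass;
without annotations it is a logged no-op. Reduced peaks landing within
`merge_tol` (default 0.01 Th) of another peak merge, keeping the more
intense member's m/z.

A pipeline execution returns a ProcessingRecord — SHA-256 digest of the
input spectrum's content (peaks + precursor descriptor; scan id and rt are
excluded so the digest names spectral content), the ordered steps with
parameters, and the output digest. The record's own digest excludes the
timestamp, so re-search exports are byte-reproducible. Replay re-runs the
steps and verifies both digests. User steps register by name with the same
`f(spectrum, **params)` contract as the built-ins; no sandboxing is
attempted.

## Results store

The schema is a single SQLite table with worksheet-style canonical columns
("Peptide Sequence", "Variable Modifications", "Peptide Score", …). It is
declared canonical for this package, not claimed identical to any engine's
native export; importers map common header spellings onto it and pepXML
import takes top-ranked hits by default. Queries are restricted to single
SELECT statements and executed under `PRAGMA query_only`; shortcut
identifiers expand to quoted canonical columns outside string literals.
Completion returns keyword matches before column/shortcut matches, each
group alphabetical.

## Quantification

Impurity correction is a full linear solve of C·x = observed rather than
sequential subtraction — exact, symmetric, and validated by a
forward-multiply/solve round trip to 1e-9 relative error. The certificate
loader maps vendor −2/−1/+1/+2 percentage columns into C column-wise;
leakage beyond the panel edge is genuinely lost signal, so edge columns sum
below 1. Negative solutions (possible with inconsistent observed vectors)
are clamped to zero and flagged rather than propagated. Injection-time
normalization is defined as corrected = value × reference_time /
injection_time, i.e. intensities from longer accumulations are scaled down;
the convention is a package decision and is recorded on each QuantRow.
Reporter extraction takes the most intense peak per channel window
(default ±0.003 Th) — robust to satellite peaks near the nominal position.

## Notebook

Bundles are zip archives of one JSON document per entry plus a manifest of
SHA-256 digests — diffable, shareable, and verifiable offline. Tampered
entries load but are flagged, so a viewer can refuse them as evidence
without losing the rest of the notebook. Annotations anchor in data
coordinates (m/z or rt, intensity), not canvas pixels, and must lie inside
the item's data range; this keeps drawings meaningful under re-rendering at
any size. SVG export is generated directly from the data (hence
byte-deterministic and countable in tests); PNG/PDF render the same
geometry through matplotlib. NIST library export uses MSP text, the open
interchange form accepted by NIST search tools; PowerPoint export is
declined by design.

## Synthetic data: what it shows and what it does not

The generator plants peptides with Gaussian elution (default σ 0.08 min on
a 0.05 min MS1 interval, i.e. ~9 scans per feature above the 1% elution
cutoff), averagine envelopes of 4 isotopes, exact theoretical fragment
peaks, and optional chemical noise (uniform m/z, exponential intensity,
Gaussian ppm jitter on signal). The standard noisy condition used in tests
is 20 noise peaks per 100 Th per scan at one-tenth of the signal apex
intensity ("signal-to-noise 10") with 2 ppm jitter. All randomness flows
from a single integer seed; outputs are byte-identical across runs.

Passing tests therefore demonstrate correct grouping, linking, querying,
and bookkeeping under the package's own isotope and elution model. They do
not demonstrate robustness to co-eluting chimeric precursors, detector
saturation, profile-mode peak shapes, lock-mass drift, or retention-time
structure beyond Gaussians — all real phenomena the simulator deliberately
omits. Problem sizes in tests and the acceptance script (10-peptide runs,
~200 MS1 scans, 1000-row result fixtures, 100-matrix/500-peptide property
sweeps) were chosen as the smallest sizes at which the tested properties
are non-trivial.

## Numerical and format choices

- mzML is read and written with a minimal in-repo codec (lxml + base64,
  64-bit float arrays, no compression on write, zlib accepted on read);
  64-bit encoding keeps 1e-6 Th round trips honest. Scan ids are 1-based
  integers parsed from the native id string.
- XIC windows are closed intervals, tolerance either ppm or Th; closed
  windows make the brute-force oracle unambiguous.
- MGF dialect: TITLE = `<run>.<scan>.<scan>.<charge>`, six decimals on m/z,
  CHARGE omitted when unknown; processed exports append the processing-
  record digest to the TITLE so re-imported results re-link to the exact
  processed spectrum.
- All file outputs are written to a temporary name and atomically renamed.
- Ties anywhere (seed order, equidistant peaks, equal-distance scans)
  break toward lower m/z / lower scan id for determinism.
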