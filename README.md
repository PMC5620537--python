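# mzcanvas

Headless tools for the detective work of mass-spectrometry-based proteomics:
interrogating LC-MS/MS data at the level of individual spectra, testing
alternative hypotheses for peptide sequence and modification placement, and
keeping a verifiable provenance trail for every assignment decision.

Large-scale pipelines reduce an experiment to a list of peptides and
proteins; they are poor at the follow-up questions. Does this low-scoring
MS/MS spectrum improve after removing inhibitor-derived fragment ions and
collapsing isotope envelopes? Is the phosphate on S7 or T9? Which intense
MS1 features never received a sequence assignment at all? `mzcanvas` is a
library (with a thin CLI) for exactly those questions, working entirely from
open formats: mzML in, MGF/MSP/TSV/SVG out.

## What it does

- **spectra_io** — mzML run model with random access by scan id and
  retention time, LRU multi-run caching, extracted ion chromatograms (XIC),
  and a strict MGF writer for re-search export.
- **pepcalc** — theoretical peptide masses and fragment ions (b/y for
  CAD/HCD, c/z-dot for ETD) at any charge; modification repositioning and
  enumeration of all C(m, k) site isoforms for localization work; nearest-
  peak spectrum annotation with signed ppm errors.
- **feature_detect** — unbiased MS1 feature detection: per-scan isotope
  envelopes found greedily and scored against an averagine-predicted
  pattern (cosine ≥ 0.9), traced across retention time with gap tolerance,
  linked to the MS/MS scans sampled from them, and minable for features no
  search engine explained.
- **spec_process** — pluggable pre-processing pipeline (diagnostic-ion
  filtering, de-isotoping, charge reduction, user-registered steps) where
  every execution yields a ProcessingRecord: input digest, ordered steps and
  parameters, output digest. Replaying the record reproduces the output
  bit-for-bit.
- **results_store** — PSM results from Mascot/Comet/X!Tandem-style TSV/CSV
  or pepXML in a single SQLite table with worksheet-style column names,
  read-only SELECT queries, shortcut expansion (`varmods` →
  `"Variable Modifications"`), keyword/column autocompletion, and PSM → scan
  resolution through the run cache.
- **quantify** — reporter-ion extraction for iTRAQ4/8 and TMT6/10, reagent
  impurity correction by solving C·x = observed (clamp-and-flag for negative
  solutions), protein-input and ion-injection-time normalization, and
  trapezoidal XIC peak areas.
- **notebook** — self-contained evidence entries (peak lists, processed
  spectra with their records, chromatograms, result excerpts) with data-
  anchored annotations and attachments, bundled as a zip with SHA-256
  digests: tamper-evident, replayable, and renderable to SVG/PNG/PDF or MSP
  with no raw files present.
- **synth** — a deterministic synthetic LC-MS/MS generator (Gaussian
  elution, averagine envelopes, exact theoretical fragments, tunable noise)
  whose truth tables back every test in the repository.

## The core models

Fragment m/z values follow the standard monoisotopic arithmetic. For a
peptide of residues r₁…rₙ with positioned modification deltas, the b/y ions
at cleavage i are

    b_i = Σ_{j≤i} m(r_j) + mods(≤i),        y_i = Σ_{j>n−i} m(r_j) + mods(>n−i) + H₂O
    c_i = b_i + NH₃,                         z_i = y_i − NH₂   (z-dot, ETD)
    m/z = (neutral + z·m_p) / z,             m_p = 1.007276 Da

so that singly charged complements obey b_i + y_{n−i} = M + 2·m_p — an
identity the test suite checks exhaustively.

Isotope envelopes are modeled with the averagine approximation: the
expected heavy-isotope count of a peptide grows linearly with neutral mass
(λ ≈ 5.36·10⁻⁴ per Da), and relative isotope abundances follow a Poisson(λ)
distribution. Observed envelopes are scored by cosine similarity against
this prediction; detector and simulator share the same model.

Reporter impurity correction solves the square linear system C·x = observed,
where column j of C is reagent j's certified −2/−1/+1/+2 leakage profile.

## Worked example

Fragment table for a phosphopeptide (move the phosphate with
`reposition_mod` / `candidate_site_peptides` to compare site hypotheses):

```
$ mzcanvas pepcalc --seq LVNELTEFAK --mods "7:phospho" --series by --max-charge 1
# peptide LVNELTEFAK mass 1242.58972
ion     series  index   charge  mz
b1+     b       1       1       114.09134
b2+     b       2       1       213.15975
b3+     b       3       1       327.20268
...
```

The peptide's neutral mass (1242.58972 Da) includes the +79.96633 Da
phosphate; b7+ onward carry it (b6+ = 670.37702 is unshifted, b7+ =
879.38594 = b7 of the plain peptide + 79.96633 + proton arithmetic).

Simulate a run with known ground truth, then detect and assign features:

```
$ mzcanvas synth --out demo --seed 5 --n-peptides 4
run: demo/synthetic.mzML; 4 planted features; 4 fixture PSMs
$ mzcanvas features demo/synthetic.mzML --out demo/features.tsv --results demo/results.tsv
4 features written to demo/features.tsv
$ cat demo/features.tsv
mono_mz    charge  rt_start  rt_end  apex_rt  area        n_scans  ms2_scans  assigned
740.40136  2       1.8000    2.2000  2.0000   90145.015   9        42         1
523.25243  3       2.4000    2.8000  2.6000   103387.724  9        55         1
542.30092  2       3.0000    3.4000  3.2000   155168.604  9        68         1
581.63621  3       3.6000    4.0000  3.8000   78790.748   9        81         1
```

Each row is one isotopic cluster traced over retention time: its
monoisotopic m/z and charge, rt extent and apex, trapezoidal area of the
monoisotope trace, the number of MS1 scans it spans, the MS/MS scans
sampled from it, and whether any of those scans appear in the imported
results (here all four planted peptides were "identified" by the fixture,
so `assigned` = 1 throughout; unassigned features are the re-search
candidates).

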