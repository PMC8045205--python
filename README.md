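# cirtdose

Conversion of organ-at-risk dose constraints for carbon-ion radiotherapy
(CIRT) between fractionation schemes and RBE models, plus DVH-based
constraint-compliance evaluation of patient cohorts.

Dose constraints for the rectum in prostate CIRT are published for
16-fraction courses, in two incompatible RBE-weighted dose scales: the
microdosimetric kinetic model (MKM, used at NIRS) and the local effect
model (LEM, used at CNAO and other European-style centers). `cirtdose`
implements the machinery needed to carry these limits to shorter courses
(12, 8, 4 fractions) and to the LEM scale:

- **`cirtdose.lq`** — closed-form linear-quadratic (LQ) iso-effect
  conversion of total RBE-weighted doses between fractionation schemes
  (equal biologically effective dose at a configurable alpha/beta ratio;
  default 3.9 Gy for rectum).
- **`cirtdose.curve`** — the RBE-conversion model as a strictly monotone
  anchor-interpolated curve (monotone shape-preserving cubic by default)
  mapping MKM doses to LEM doses, with an exact inverse by bracketed
  root-finding.
- **`cirtdose.strategies`** — the two orderings of those operations
  (`MKM_LQ`: LQ first in MKM space, curve second; `LEM_LQ`: curve first,
  LQ second in LEM space), adaptation of LEM-native absolute-volume
  constraint sets via backward curve inversion, the relative-difference
  metric between the two strategies, and wide report tables.
- **`cirtdose.dvh`** — cumulative-DVH metrics (D_x%, D_xcc with D0% = max
  dose), per-patient compliance reports and cohort summaries
  (median/maximum/exceedance counts).
- **`cirtdose.synthetic`** — seeded generators for DVHs with prescribed
  metric values, patient cohorts with exact controlled numbers of
  constraint exceedances, and smooth monotone conversion curves.
- **`cirtdose.fixtures`** — the published 16-fraction constraint sets
  (NIRS MKM percent-volume, CNAO LEM absolute-volume, and the LEM
  percent-volume set derived from them) and conversion-curve fixtures,
  including clearly labelled *reconstructed* 12/8/4-fraction curves that
  reproduce the published MKM-LQ outputs by construction.

## CLI

```sh
# Convert the NIRS 16-fraction MKM set to LEM limits at 12/8/4 fractions
cirtdose convert-constraints --constraints nirs-16fx --strategy both \
    --schemes 12,8,4 --out out/

# Convert the CNAO absolute-volume LEM set
cirtdose convert-constraints --constraints cnao-16fx --strategy lem-lq \
    --schemes 12,8,4 --out out/

# Render both packaged tables in one go
cirtdose report --out report/

# Generate a seeded synthetic cohort (38 patients, 8 exceeding D20%,
# 4 of those also exceeding D10%) and score it
cirtdose simulate --seed 7 --n-patients 38 --exceed "D20%=8,D10%=4" --out sim/
cirtdose evaluate-dvh --constraints center-lem-16fx \
    --manifest sim/cohort/cohort_manifest.csv --out eval/
```

Constraint sets, curves, and DVHs can also be given as files; dialects are
plain CSV with `#`-comment metadata lines (see the `External Interfaces`
docstrings in each module). Every command is deterministic given its
arguments and seed; full-precision conversion provenance is embedded in the
JSON outputs, and doses are rounded (half-up, 2 decimals) only at render
time.

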