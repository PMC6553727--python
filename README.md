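# keratrace

Ray-traced total corneal refractive power (TCRP) and keratometry-formula
agreement analysis for eyes after myopic small-incision lenticule
extraction (SMILE).

## The problem

After myopic corneal refractive surgery, conventional keratometry is
systematically wrong: the simulated keratometry reading
`Km = (1.3375 − 1)/r1` converts only the anterior radius to diopters and
relies on a fixed anterior-to-posterior radius ratio (0.822) and corneal
thickness (500 μm) that surgery has invalidated. Clinicians therefore
compare candidate corneal-power measures against the **clinical history
method (CHM)** — the preoperative keratometry minus the surgically induced
refractive change at the corneal plane — before trusting them for IOL
power calculation.

`keratrace` reimplements that comparison as a fully testable pipeline. It
models the cornea as two coaxial conicoid surfaces, traces axis-parallel
rays through both surfaces with the exact vector form of Snell's law
(indices 1 / 1.376 / 1.336), and converts each exit ray into a per-ray
power

    P(h) = n_aqueous · sin U′ / h          (h in metres)

whose `h → 0` limit is the Gaussian thick-lens equivalent power
`P = P1 + P2 − (d/n) P1 P2`. Per-ray powers are aggregated on a **ring**
(single diameter) or over a **zone** (filled disc), centered on the
corneal **apex** or the **pupil** axis — the four TCRP variants reported
by Scheimpflug tomographers at diameters 1.0–8.0 mm. Alongside TCRP the
package evaluates the classical estimates

- true net power `TNP = 0.376/r1 − 0.040/r2`,
- equivalent keratometry reading `EKR = 0.376/r1 − 0.03165/r2`,
- the Haigis (`1.119·Km − 5.78`) and Shammas (`1.14·Km − 6.8`) regressions,
- the modified TCRP (4 mm zone TCRP + 0.70 D),

and compares each against CHM with repeated-measures ANOVA (Bonferroni
pairwise contrasts), Pearson correlation, and Bland–Altman bias with 95%
limits of agreement (bias ± 1.96·SD).

Because per-eye patient data are not distributable, a synthetic-cohort
generator reproduces the study conditions (preop Km 42.52 ± 1.30 D on
[39.80, 44.50], preop SE −4.91 ± 2.01 D, postop SE 0.20 ± 0.40 D, optical
zones 6.0–6.5 mm) and applies a simple lenticule-extraction reshape to the
anterior surface. See `docs/methods.md` for the model and its limits.

## Worked example

```python
from keratrace import (CohortConfig, generate_cohort, cohort_to_table, build_report,
                       CornealModel, ConicSurface, trace_power_at, gaussian_equivalent_power)

eye = CornealModel(anterior=ConicSurface(7.7, -0.25),
                   posterior=ConicSurface(6.4, -0.20, 0.5),
                   central_thickness=0.5)
print(f"paraxial power : {gaussian_equivalent_power(eye):.3f} D")
print(f"ray power @3mm : {trace_power_at(eye, 3.0):.3f} D")

table = cohort_to_table(generate_cohort(CohortConfig(n=40, seed=1)))
report = build_report(table, seed=1)
row = report.table2.set_index("method").loc["TCRP_apex_zone_4.0"]
print(f"TCRP apex/zone 4 mm: mean {row['mean']:.2f} D, bias vs CHM {row['bias']:+.2f} D, "
      f"LOA [{row['loa_low']:.2f}, {row['loa_high']:.2f}] D, r = {row['pearson_r']:.3f}")
```

prints

```
paraxial power : 42.692 D
ray power @3mm : 44.312 D
TCRP apex/zone 4 mm: mean 36.58 D, bias vs CHM -1.35 D, LOA [-1.83, -0.87] D, r = 0.994
```

The first two lines show the paraxial (thick-lens) power of a 7.7/6.4 mm
cornea and the higher power carried by a marginal ray at 3 mm (spherical
aberration of the prolate conicoid pair). The last line is one row of the
agreement table for a 40-eye synthetic cohort: the 4 mm zone TCRP sits
about 1.4 D below the CHM benchmark (ray-traced total power is genuinely
lower than a fictitious-index keratometry reading) while correlating with
it almost perfectly — which is exactly why a fixed additive conversion to
TCRP is attractive clinically.

## Command line

```sh
keratrace all --config run.yaml          # simulate -> analyze -> plots
keratrace simulate --seed 7              # cohort CSV only
keratrace analyze                        # table1.csv, table2.csv, report.json
```

Every output gets a JSON provenance sidecar (tool version, seed, config
hash). Measured cohorts can be imported from CSV, or from an XLSX export
through an explicit column mapping (`keratrace.io.read_xlsx_cohort`).

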