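# ironmr

Two-sample Mendelian randomization (MR) of systemic iron status on the risk of
amyotrophic lateral sclerosis (ALS), built as a tested, reusable Python package.
It is aimed at genetic epidemiologists who want a transparent, fully scripted
re-analysis: every number in the original study's result tables can be
recomputed from the two printed GWAS summary tables that ship with the package.

## The question and the method

Observational studies report higher iron status in people who develop ALS, but
cannot separate causation from reverse causation and confounding. MR sidesteps
both by using genetic variants as instruments: alleles are assigned at random
at conception and are not altered by disease.

Instruments are SNPs associated at genome-wide significance (p < 5×10⁻⁸) with
four biomarkers of iron status — serum iron, (log) ferritin, transferrin
saturation and transferrin — in the Genetics of Iron Status consortium
meta-analysis (N = 48,972 Europeans). Their ALS associations come from an
80,610-subject case-control meta-analysis (20,806 cases / 59,804 controls).
Both tables ship as fixtures (12 SNPs). Two instrument sets are used:

* **conservative** — the 3 SNPs significant for all four biomarkers whose
  signs describe a coherent shift in iron status (iron, ferritin and
  transferrin saturation moving together, transferrin opposite);
* **liberal** — per biomarker, every SNP significant for that biomarker
  (5 / 6 / 5 / 9 SNPs).

For each SNP *j* with exposure effect β_xj (per SD of biomarker) and outcome
effect β_yj (log-odds), the Wald ratio is β_yj/β_xj. The main estimate is the
inverse-variance-weighted (IVW) mean of the Wald ratios with weights
w_j = β_xj²/se_yj²; sensitivity analyses are MR-Egger regression (its
intercept estimates average directional pleiotropy), the weighted median, a
residual-sum-and-outlier simulation test, and leave-one-out re-estimation.
Instrument strength is R² = 2β²(1−EAF)EAF and F = R²(N−k−1)/((1−R²)k); power
uses the normal approximation
Φ(|ln OR|·√(N·R²·φ(1−φ)) − z₁₋α/₂) with φ the case fraction.

## Worked example

```python
from ironmr import (load_iron_table, load_als_fixture, conservative_set,
                    harmonize_set, ivw)

table = load_iron_table()
als = load_als_fixture()
for biomarker in table:
    instruments = harmonize_set(conservative_set(table, trait=biomarker), als)
    r = ivw(list(instruments.instruments))
    print(f"{biomarker:24s} OR {r.or_value:.3f} ({r.ci_low:.3f}-{r.ci_high:.3f}) p={r.pvalue:.3f}")
```

prints

```
iron                     OR 1.039 (0.955-1.131) p=0.374
ferritin                 OR 1.098 (0.896-1.346) p=0.366
transferrin_saturation   OR 1.031 (0.964-1.102) p=0.375
transferrin              OR 0.961 (0.859-1.076) p=0.493
```

— the odds ratio for ALS per SD increase in each biomarker, using the 3
conservative instruments. All four confidence intervals span 1.0: no evidence
that iron status affects ALS risk. The numbered scripts under `analysis/`
(`01_select_instruments.py` … `05_calibration.py`) run the complete study —
selection and strength, conservative IVW with the rs1800562-exclusion re-run,
the liberal four-method battery, the power table, and synthetic-data
calibration — and write their tables under `results/`.

A CLI mirrors the scripts: `ironmr run --mode liberal --methods
ivw,egger,wm,presso --out results/liberal`, `ironmr power`, `ironmr simulate`.

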