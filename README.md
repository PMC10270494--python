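# gutliver

Analysis of the gut–blood–liver axis from multi-compartment 16S rRNA
profiles in chronic liver disease, with paired liver transcriptomes.

Patients with cirrhosis and hepatocellular carcinoma (HCC) show a failing
gut barrier: DNA of fecal bacteria turns up in their blood and liver tissue.
`gutliver` is a Python library (plus a thin CLI) for quantifying that
process from genus-level 16S count tables collected in three compartments —
feces, blood, liver — across three disease groups — NAFLD, cirrhosis, HCC:

* **Diversity** — Shannon index H = −Σ p ln p, Pielou evenness J = H/ln S,
  pairwise Mann-Whitney group tests; Bray-Curtis distances with global and
  pairwise PERMANOVA (pseudo-F, R², seeded permutation p, exhaustive
  enumeration for small n).
* **Translocation scoring** — the *proportion of fecal bacteria* T of a
  blood/liver sample: the summed relative abundance of its disease group's
  *fecal core signature*, the genera at ≥ 0.1% relative abundance in ≥ 5% of
  that group's fecal samples. Contrasts vs a reference group (NAFLD),
  BH-adjusted per compartment.
* **Differential abundance** — a LefSe-style screen: rank-sum gate at
  α = 0.05, bootstrap Fisher-LDA effect size on the per-million scale,
  reporting taxa with |log10 LDA| ≥ 3.5 in at least one sample type.
* **Host–microbe association** — per-gene negative-binomial GLMs (log link,
  profile-ML dispersion, median-of-ratios offsets, Wald z = β1/SE):
  disease-group differential expression and a gene × genus grid against
  liver genus relative abundance, with joint Benjamini-Hochberg FDR at
  q < 0.05 and the ≥ 5-nonzero-samples genus filter.
* **Synthetic cohorts** — a seeded generator of three-compartment cohorts
  with known ground truth: Dirichlet-multinomial communities, blood/liver
  profiles mixed as (1 − π)·tissue background + π·own fecal profile with a
  group-specific translocation fraction π, and paired NB transcriptomes with
  planted gene–genus effects. Every downstream stage is testable against
  planted truth without any external data.

See `docs/methods.md` for the models, defaults and numerical choices.

## Worked example

```python
import gutliver as gl

config = gl.SimConfig(n_subjects_per_group={g: 12 for g in gl.GROUPS}, seed=3)
table, truth = gl.simulate_cohort(config)   # 108 samples x 100 taxa

report = gl.translocation_report(table)     # score blood + liver samples
print(report.samples.groupby(["compartment", "group"])["proportion"]
      .median().unstack().round(3))
print(report.contrasts[["compartment", "group", "p", "q"]])
```

prints

```
group          HCC  NAFLD  cirrhosis
compartment
blood        0.225  0.047      0.147
liver        0.197  0.023      0.142

  compartment      group             p         q
0       blood  cirrhosis  1.743179e-04  0.000174
1       blood        HCC  7.396023e-07  0.000001
2       liver  cirrhosis  2.958409e-06  0.000003
3       liver        HCC  7.396023e-07  0.000001
```

The generator planted translocation fractions π = 0.03 / 0.12 / 0.22 for
NAFLD / cirrhosis / HCC; the median fecal proportion T recovers that gradient
in both compartments (medians sit close to π plus the small shared-background
overlap), and both disease groups are significantly elevated over NAFLD after
BH adjustment — the analysis recovers a known ground truth end to end.

The `examples/` directory has one short script per capability
(`python examples/03_translocation.py` produces the output above, plus
signature sizes).

## Command line

```bash
gutliver simulate --subjects 10 --seed 7 --out run/        # simulate + all stages
gutliver all --feature-table ft.tsv --metadata meta.tsv \
             --taxonomy tax.tsv --gene-counts genes.tsv --out run/
gutliver translocate --tau-abund 0.001 --tau-prev 0.05 ...  # single stages
gutliver validate --feature-table ft.tsv --metadata meta.tsv
```

Inputs are TSV: a taxa-in-rows feature table, metadata with
`sample_id, subject_id, compartment, group`, a taxonomy table
(`d__...;g__...` lineages accepted), and an optional genes × samples count
matrix. Results are written as tidy TSV/JSON plus a deterministic
`manifest.json`; a rerun under the same config and seed is bitwise identical.

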