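# hsmap

Sex-specific genetic-map construction and QTL reanalysis for
heterogeneous-stock (HS) rat cohorts.

A genetic map assigns every physical position a genetic position in
centimorgans (cM), where 1 cM is one expected crossover per hundred meioses.
The rat's map was long based on ~90 meioses and ~2,300 markers; its modern
revision rests on 870 informative meioses from 528 HS rats — an outbred
population descended from eight inbred founder strains — genotyped at ~96,000
markers, yielding sub-0.02 cM resolution and, for the first time, separate
male and female maps (genome totals 1,589 and 1,826 cM; sex-averaged
1,708 cM over 2,619 Mb ≈ 0.66 cM/Mb by the per-chromosome-mean convention).
`hsmap` implements that entire construction as a reusable, tested pipeline,
for map builders and QTL mappers who need the machinery rather than the
archived genotypes:

* **simhs** — synthetic HS cohorts with fully known truth: founder
  haplotypes, per-gamete crossover positions (sex-specific Poisson process on
  the cM scale), genotyping errors, missingness, Mendelian-error-prone
  markers, and physically displaced ("errant") markers;
* **genoqc** — monomorphic removal, cohort Mendelian-error filtering
  (rate > 2% across trios), MAF > 0.05 / 10-kb window thinning;
* **mapestim** — parental-genotype calling, segregation-distortion
  filtering, minimum-recombination phasing of each parent, per-interval
  recombination fractions r = k/n converted to cM by Haldane's
  d = −50 ln(1−2r) (Kosambi selectable), assembled into cumulative
  male / female / averaged tracks;
* **mapclean** — the two-stage cleaning: LOESS residual filtering of markers
  whose genetic placement disagrees with their physical position
  (|residual| > 1 cM), then a monotone piecewise-cubic (PCHIP) bp→cM model
  whose derivative is the local recombination rate in cM/Mb;
* **mapresources** — cM for every kilobase of the assembly, cM annotation of
  arbitrary (SSLP-style) marker lists, and chromosome/genome summary tables;
* **qtlscan** — single-locus F2 interval mapping by multiple imputation
  (2-cM grid, LOD averaged as log₁₀ mean 10^LOD), permutation thresholds
  (0.05 significant / 0.63 suggestive), Bayes credible intervals, and
  old-map vs new-map peak-shift comparison (> 10 cM flags a re-localised
  QTL — 9 of 32 in the published comparison).

See `docs/methods.md` for the models, assumptions and numerical choices.

## Worked example

Run the pipeline end to end on a small simulated cohort (20 families, two
chromosomes with known male/female lengths 70/82 and 48/56 cM):

```python
from hsmap import RunConfig, run_pipeline

cfg = RunConfig(
    out_dir="demo", seed=7, n_families=20, offspring_per_family=6,
    marker_spacing_bp=300_000,
    chromosomes={"chr1": [120_000_000, 70.0, 82.0],
                 "chr2": [80_000_000, 48.0, 56.0]},
)
results = run_pipeline(cfg)
print(results["genome_summary"])
```

which prints (stage logs omitted):

```
{'n_markers': 533, 'cm_male': 93.9, 'cm_female': 136.5, 'cm_avg': 115.2,
 'mb': 200.0, 'rate_unweighted': 0.58, 'rate_weighted': 0.58,
 'resolution_cm': 0.216...}
```

320 meioses recovered genome totals of 93.9 / 136.5 cM against simulated
truths of 118 / 138 cM.  The female total is within 1%; the male total is
low because at this deliberately small scale two effects bite that vanish at
study scale: the Poisson sampling floor (~5% SD per total at 160 meioses per
sex) and truncation of chromosome-end regions where phase coverage is sparse
(see the limitations section of `docs/methods.md`).  At the real design —
870 meioses and ~2,000 markers per chromosome — recovery is within ~1%
(run `scripts/acceptance.py` below).  `demo/` now holds the cohort
(PED/MAP), crossover truth, raw and
cleaned map TSVs, the cleaning report, spline anchors, the per-kb cM table
and a chromosome summary, plus a manifest recording every stage, parameter
and seed.

The same stages are available as an umbrella command:

```sh
hsmap simulate --families 65 --strains 8 --seed 1 --out cohort/
hsmap qc --ped cohort/cohort.ped --map cohort/cohort.map --out qc/
hsmap estimate --ped qc/clean.ped --map qc/clean.map --seed 1 --out est/
hsmap clean --map est/genetic_map_raw.tsv --out clean/
hsmap scan --cross f2.csv --step 2 --perms 1000 --seed 1 --out scan/
```

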