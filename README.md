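# breedtrends

Dog breeds rise and collapse in popularity on timescales of a decade —
classic boom–bust fashion cycles in kennel-club puppy registrations (the
Irish setter climbed from ~2,500 AKC registrations in 1961 to over 60,000
in 1974, then fell back to ~3,000). Is that driven by *function* (breeds
with better temperament, health, or longevity becoming popular) or by
*fashion* (social copying, indifferent to breed qualities)?

`breedtrends` is a tested pipeline for that question. From a breed × year
registration count matrix N_b(t) it computes, per breed:

* **total popularity** P_b = Σ_t N_b(t) over the breed's observed span;
* **volatility** V_b = mean |N_b(t+1) − N_b(t)| over consecutive observed
  years (79 changes for a full 1926–2005 span);
* **boom–bust peak**: the registration maximum, bounded by the nearest
  years before/after at ≤ 10% of the peak value (breeds without both
  bounds have no peak; only the single highest peak is analyzed);
* **rates of increase/decrease** r⁺_b, r⁻_b: net registration change per
  year between each peak boundary and the peak.

These measures are correlated with breed-typical trait scores: the 14
C-BARQ behavior/temperament scales (averaged over dogs per breed, breeds
with < 20 dogs dropped), median longevity from survey and
veterinary-hospital sources, and per-breed inherited-disorder counts.
Because the variables are far from normal, inference is nonparametric:
two-sided permutation tests (default 50,000 permutations, add-one
convention) and paired percentile-bootstrap confidence intervals, with
Bonferroni and Benjamini–Yekutieli FDR adjustment per 14-comparison
panel. One-way ANOVAs (with η²) quantify breed variability in behavior,
and an exact-with-ties Wilcoxon signed-rank test compares the two
longevity sources. A synthetic-data module generates registration
matrices with planted peak geometry, per-dog questionnaire records, and
trait vectors with planted correlations, plus a Wright–Fisher neutral
copying model as a drift-only null — so every stage is validated against
known ground truth without the proprietary registry files.

## Worked example

Recover a planted Irish-setter-shaped boom–bust cycle:

```python
import breedtrends as bt

series, truth = bt.gen_peak_series(
    years=(1926, 2005), peak_height=60_000, t_peak=1974,
    rise_years=13, fall_years=12, baseline_frac=2_500 / 60_000, seed=0,
)
print(bt.detect_peak(series))     # (True, 1964, 1974, 1983)
print(bt.peak_rates(series, (1964, 1974, 1983)))
                                  # (5479.5, 6051.888888888889)
print(bt.total_popularity(series))  # 592257.0
print(bt.volatility(series))        # (1455.6962025316457, 79)
```

The peak detector finds the planted boundaries exactly: registrations
first dip to ≤ 10% of the 60,000-dog peak in 1964 (rising flank) and
1983 (falling flank), giving a rise rate of ~5,480 and a fall rate of
~6,052 registrations/year.

End-to-end on a full synthetic dataset (registrations + per-dog records
+ longevity + disorder counts, with a planted disorder–popularity
correlation of 0.5 and no behavior effects):

```bash
breedtrends simulate --preset traits --seed 1 --out ex/in
breedtrends run --config ex/cfg.yaml      # B: 5000, seed: 42
```

```
profiles: 80 rows
associations: 56 rows
health_associations: 7 rows
anova: 14 rows
longevity_comparison: 1 rows
```

`associations.csv` holds the 4 × 14 behavior screen; with no planted
behavior effect nothing survives adjustment (e.g. total vs trainability:
r = −0.022, permutation p = 0.857, BY-adjusted p = 1.0 at n = 69).
`health_associations.csv` recovers the planted health signal and leaves
the rest null:

```
   measure            trait  n      r  ci_low  ci_high  p_perm  p_by
     total      n_disorders 69  0.485   0.285    0.650   0.000 0.002
volatility      n_disorders 69  0.453   0.254    0.620   0.001 0.003
   rate_up      n_disorders 54  0.261   0.046    0.469   0.056 0.160
 rate_down      n_disorders 54  0.312   0.058    0.539   0.023 0.087
    change      n_disorders 69 -0.078  -0.294    0.258   0.528 1.000
     total longevity_survey 69 -0.099  -0.289    0.115   0.423 0.823
     total    longevity_vet 69 -0.073  -0.300    0.178   0.548 0.823
```

Breeds with more disorders are more "popular" here because that is what
was planted; the correlation, its bootstrap CI and the BY-adjusted
permutation p recover it at the planted strength. The longevity
comparison confirms the generated veterinary estimates sit below the
survey estimates (medians 7.2 vs 11.7 years, signed-rank p < 1e-15).

Real registry/questionnaire deposits, once downloaded, drop into the
same CSV formats (`breed,year,count`; `dog_id,breed,<14 scales>`);
`breedtrends verify --akc ... --cbarq ...` recomputes their descriptive
counts, and skips cleanly when the files are absent.

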