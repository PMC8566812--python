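# mrtools

Two-sample Mendelian randomization (MR) from GWAS summary statistics:
instrument selection, LD clumping, proxy substitution, allele
harmonization, the three standard causal estimators (fixed-effect IVW,
weighted median, MR-Egger), heterogeneity and leave-one-out sensitivity
analyses, and a summary-level simulator with known ground truth so the
whole pipeline is testable offline.

## What it computes

For each exposure → outcome pair, per-SNP Wald ratios `Y_k / X_k` are
combined by:

- **IVW** (primary): `beta = Σ X_k Y_k σ_Yk⁻² / Σ X_k² σ_Yk⁻²`,
  `se = sqrt(1 / Σ X_k² σ_Yk⁻²)` — fixed-effect, first-order weights
  (equivalently, weighted least squares of Y on X through the origin).
- **Weighted median**: interpolated median of the weighted empirical
  distribution of Wald ratios (weights `(X_k/σ_Yk)²`), SE by seeded
  parametric bootstrap; consistent when valid instruments carry more
  than half the weight.
- **MR-Egger**: weighted regression with a free intercept after
  orienting instruments to non-negative exposure effects; the intercept
  tests directional pleiotropy, the slope is the adjusted estimate
  (t(K−2) inference, multiplicative over-dispersion floored at 1).

Binary outcomes are handled on the log-OR scale; estimates are reported
as OR with normal-quantile (t for Egger) confidence intervals, and a
Bonferroni threshold `alpha / n_exposures` flags the primary IVW test.

## CLI

```sh
# full multi-exposure study from a YAML config
mr run --config study.yaml --out results/ --seed 17

# harmonize one exposure/outcome pair to a TSV
mr harmonize --exposure exp.tsv --outcome out.tsv --out harmonized.tsv

# emit a named synthetic scenario (exposure.tsv, outcome.tsv, truth.tsv)
mr simulate --scenario directional_inside_ok --out sim/
```

A study config looks like:

```yaml
outcome:
  name: ms
  path: outcome.tsv
  trait_type: binary
  effect_scale: odds_ratio   # OR column is log-transformed on read
exposures:
  - {name: fgf23, path: fgf23.tsv}
  - {name: gdf15, path: gdf15.tsv}
p_instrument: 5.0e-8   # strict p < threshold
clump_r2: 0.01         # strict r² > cutoff removes
clump_window: 1000000
proxy_r2: 0.8
palindromic_mode: keep # keep | drop | frequency
ld_pairs_path: ld.tsv      # optional TSV: snp_a, snp_b, r2
proxy_table_path: prox.tsv # optional TSV: snp, proxy, r2[, phase]
```

Column dialects are configurable per table (`column_map`), with named
presets `twosamplemr` (SNP, effect_allele, other_allele, beta, se, pval,
eaf) and `gwas_catalog`. Outputs are TSV tables (consolidated report,
per-exposure single-SNP / leave-one-out / audit tables) plus a
full-precision JSON; `--plots` adds scatter, forest and leave-one-out
figures derived from those tables.

## Package layout

- `mrtools.summary_io` — reading/validating/writing summary tables and reports
- `mrtools.harmonize` — instrument selection, clumping, proxies, allele alignment
- `mrtools.estimators` — Wald ratio, IVW, weighted median, MR-Egger
- `mrtools.sensitivity` — Cochran's Q, leave-one-out, single-SNP tables, outlier screen
- `mrtools.synthetic_data` — summary-level simulator and named scenario suite
- `mrtools.pipeline` / `mrtools.cli` — config-driven orchestration and the `mr` command
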