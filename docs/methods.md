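# Methods

## Scope and model

`adjacoex` studies the co-expression of physically adjacent genes on an
amplified chromosome arm through four mechanistic screens: copy-number
cis effects, positional co-expression clustering, bidirectional
promoters, and ceRNA (shared-miRNA) coupling. Every statistic in the
pipeline reduces to Pearson correlation, set algebra, or a
hypergeometric tail, so all quantities are defined on continuous
(log-scale) expression values; no count model is involved anywhere.

## Coordinate conventions

All intervals are 0-based half-open `[start, end)`. GFF3 input (1-based
inclusive) is converted once at the reading boundary. Interval length is
`end − start`, so a spacer bounded by 32207791 and 32207880 is 89 bp
with no off-by-one ambiguity. Genes are assigned to the cytoband
covering their **start** coordinate; a boundary-straddling gene
therefore has a deterministic, documented assignment. The TSS of a `+`
gene is its interval start and of a `−` gene its interval end, which is
what makes "adjacent 5' ends" well defined for divergent pairs under
half-open coordinates.

## Correlation engine

`pearson` pairwise-deletes missing values (never imputes), requires at
least 3 paired observations and non-constant vectors (constant input is
an error, not a silent r = 0), and takes its two-sided p-value from the
exact t transform `t = r·√((n−2)/(1−r²))` on n−2 df. Batch runs attach
Benjamini–Hochberg q-values. The cis screen defaults to the raw-p rule
(`r > 0.65`, `p ≤ 1e−4`) because that is the classical reporting
convention for this analysis; `use_bh=True` switches the flag to the
q-value. Genes present in only one matrix, or untestable rows, are
returned in an explicit exclusions table.

## Neighborhood analysis

The seed profile correlates every gene against one seed; the
significance threshold `r ≥ 0.6` is **inclusive**, and the seed itself is
excluded from its own significant set (so "86 significant genes" never
counts the seed). Band fractions are `significant-on-band /
annotated-on-band`; because raw fractions are incomparable across bands
of different size, each band also gets a one-sided hypergeometric
upper-tail p (population = all annotated genes, successes = band
members, draws = the significant set) with BH q across bands. Adjacency
clustering scans genes in coordinate order: a cluster is a maximal run
of significant genes in which each interruption is at most `max_gap`
consecutive non-significant genes (default 0; 1 is the documented
alternative for visibly interrupted runs), and clusters below
`min_size = 2` are dropped.

## Promoter pairs

Only coordinate-adjacent pairs are classified (an all-pairs scan adds
nothing for promoter sharing and is quadratic). Left strand `−` with
right strand `+` is divergent head-to-head; the intergenic interval is
`[left.end, right.start)`; overlapping pairs get distance 0, an overlap
flag, and are never called bidirectional. The bidirectional rule is
*strictly* less than `max_dist` (default 1000 bp). CpG islands use the
Gardiner-Garden–Frommer defaults (length ≥ 200 bp, GC ≥ 0.5,
observed/expected CpG = `N_CpG·L/(N_C·N_G)` ≥ 0.6) over a 100 bp
sliding window; qualifying windows are merged and each merged region is
re-checked against all three thresholds. Real bidirectional-promoter
islands can be shorter than 200 bp, so `cpg_min_len` is exposed (the
pipeline warns below 200 rather than failing). TATA presence is the
TATAWAW consensus on either strand. PWM scanning scores
`Σ log2((f+ε)/(0.25+ε))` in bits against a uniform background with
pseudocount ε = 0.01 (no background model is estimated from input);
the reverse strand is scored with the reverse-complemented matrix, and
any N in a window disqualifies it.

## Regulators and ceRNA

Venn partitioning assigns every element of the union of up to 8 named
sets to exactly one membership-signature cell. Shared-regulator
enrichment is the one-sided hypergeometric upper tail with the
enrichment universe defaulting to all genes in the expression matrix
(service-based tools use library-specific universes they do not
publish; an explicit universe is the reproducible choice). TF sign
classification splits at r ≥ 0 (activator-like) vs r < 0
(repressor-like) — a strict partition, with r = 0 counted as
activator-like. Shared-miRNA analysis intersects, per evidence source,
the miRNAs targeting *every* gene of the group, then unions across
sources keeping element lists. The ceRNA verdict requires
simultaneously: union of shared miRNAs ≥ `min_shared` (5), pair
expression r ≥ `r_pair_min` (0.6), and ≥ `min_support` (3) shared
miRNAs anti-correlated (r < 0, p < 0.05) with **both** genes. The
thresholds are deliberately permissive enough that a textbook ceRNA
configuration (tens of shared miRNAs, pair r ≈ 0.8) passes with margin,
and all are CLI-exposed. Raising any threshold can only turn verdicts
false (monotonicity, property-tested).

## Synthetic world

The generator emits a full input bundle with planted truth. Expression
follows a latent-factor linear-Gaussian model

```
expr(g,s) = μ + β_g·(cna(g,s) − 2) + Σ_b τ_b·f_b(s)·[g∈b]
          − Σ_m γ_m·m(s)·[g targeted by m] + ε,   ε ~ N(0, σ²)
```

with standard-normal latent factors per block (`f_b`) and per miRNA
(`m`, also emitted as the miRNA matrix). Defaults: 60 genes, 200
samples, 8 bands, two focal amplification segments (gene ranges 14–26
and 38–46; per-sample gain probability 0.5, gain +2 copies — a typical
arm-gain frequency), β = 0.5 inside segments with one cis-null gene per
segment (β = 0) for specificity checks, two co-expression blocks of 5
and 3 genes (τ = 1.5), one divergent pair at an 89 bp CpG-rich
TATA-less spacer, which is also the planted ceRNA pair coupled through
6 shared miRNAs (γ = 1), σ = 1, baseline 8. Non-planted intergenic gaps
are drawn above 1 kb so the planted pair is the only possible
bidirectional call. CpG-rich spacers are rejection-sampled until they
satisfy GC ≥ 0.5 and obs/exp ≥ 0.6 and contain no TATAWAW; all
randomness flows from `seed` through per-stage `default_rng` streams,
making bundles byte-identical for equal configs.

One consequence of this stated world is worth flagging: with β = 0.5
and σ = 1 the model-implied cis correlation is `β·sd(cna)/sd(expr)` ≈
0.45, *below* the 0.65 screen threshold, so the default fixture yields
zero cis-driven flags. The fixture therefore exercises the screen's
specificity (cis-null genes are essentially never flagged) and its
noise-free limit (σ = 0 gives r = 1 for every β ≠ 0 gene), not its
power at the default threshold.

What the generator does **not** emulate: count-level noise
(negative-binomial dispersion), miRNA titration kinetics (repression
enters linearly; ceRNA coupling appears only as marginal positive
covariance between co-targets), allele-specific copy number, tumor
purity, batch effects, and realistic gene-density/band-size variation.
A green recovery test therefore establishes that the algorithms detect
the planted linear-Gaussian signatures at realistic effect sizes — not
that real cohort data would behave as cleanly.

## Numerical choices

- Matrix TSVs are written with `%.17g`, and read back by exact strtod
  parsing, so write→read round trips are bit-exact (pandas'
  fast-path `to_numeric` parser is deliberately avoided).
- Hypergeometric tails come from `scipy.stats.hypergeom.sf(k−1, …)`;
  tests verify equality with exhaustive draw enumeration for all
  universes ≤ 12.
- BH q-values via `statsmodels` `multipletests(method="fdr_bh")`.
- Cluster/report tables use stable (merge) sorts so ties never reorder
  between runs.
- Degenerate inputs error loudly: constant vectors, < 3 shared samples,
  empty regulator sets, overlapping cytobands, unstranded genes in
  orientation calls, query genes outside the enrichment universe.

## Pipeline determinism and resume

Stages run in dependency order (io → correlate → neighborhood →
promoters → regulators → cerna); a failure halts the run, preserving
completed outputs and a report naming the failed stage. Re-running the
same config into the same directory is byte-identical. `--resume`
reloads the correlation screen from its TSVs when present; downstream
stages are cheap and recomputed deterministically, which preserves the
identical-downstream-results guarantee.

## Known limitations

- Identifier matching is case-sensitive exact string match; no alias or
  versioned-annotation resolution.
- Genome builds are not modelled; coordinates are build-agnostic
  integers supplied by the single input annotation (different public
  annotations place TSSs differently, and the package takes whichever
  one it is given).
- Only Pearson correlation is offered (no Spearman/partial); no
  permutation p-values in v1.
- The seed-profile stage is O(genes) per seed gene and is run for one
  seed at a time.
- miRNA family/arm identity is taken at face value: union counts are
  deduplicated by identifier string only.
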