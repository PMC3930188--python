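# Methods

## Model and procedure

The pipeline treats TF-target inference as a conditional-distribution
problem: if a TF regulates a probe, the probe's distribution differs across
strata of the TF's expression. Samples are ranked by the conditioning
variable and cut into K contiguous blocks of near-equal size ("1/10th
subgrouping", K = 10 by default, so each block holds roughly a decile).
When N mod K = r > 0, the r extra members go one each to the
highest-expression blocks — the analysis privileges the top decile, which
is also the stratum the survival screen dichotomizes at. Ties in the
conditioning variable are broken by stable input order, making every
downstream result deterministic for a fixed input ordering.

The dependence statistic is a Cramér–von-Mises-type functional of the gap
between the within-block and pooled empirical CDFs of the target,
normalized by 3/N so that subCID and CID lie in [0, 1) (the bound follows
from Σ_j (1 − j/N)² < N/3). CID is the block-size-weighted mean of the
subCID values; this decomposition is exact and tested to 1e-12. Because
only ranks enter, CID is invariant under strictly monotone transforms of
either variable. The statistic is deliberately a pluggable callable in the
permutation machinery: network membership is permutation-calibrated, so
any monotone rescaling of the statistic leaves calls unchanged.

Significance of CID is assessed by permuting the target against the fixed
subgrouping, p = (1 + #{perm ≥ obs})/(B + 1) with B = 999 by default.
Genome-wide runs share one permutation index matrix across probes (one
seed → one matrix): this is both faster and reproducible, and under the
null each probe's p-value remains marginally valid. Internally the engine
exploits the identity that only the quadratic term
Σ_k (1/n_k) Σ_{i,i'∈G_k} min(cg_i, cg_{i'}) (cg_i = #{j: y_j ≥ y_i})
varies under label permutation, reducing the cost per probe to O(B·N); the
suite verifies exact agreement with the direct statistic-permutation path,
ties included. A numba kernel accelerates the loop, with a pure-numpy
fallback.

The univariate network is the union rule: a probe is a member if the CID
permutation p or the Pearson-correlation t-test p is ≤ α = 0.05 (raw,
per probe — matching the screening convention of significance at the 0.05
level; Benjamini–Hochberg correction within each arm is available behind
`fdr_method="bh"` and is OFF by default). The bivariate run conditions on
the mean of the two TFs' rank percentiles — a simple symmetric score whose
top block is exactly "high in both TFs"; min-rank is a noted alternative
but not the default. Mechanism pools follow the significance pattern:
jointly non-significant probes are unpooled; otherwise M1 (both TFs
univariately significant), M2 (TF1 only), M3 (TF2 only), M4 (joint only).
The published description names the pools but does not print their
defining rule; this significance-pattern operationalization is this
package's, stated as such. U is the overlap of the two univariate networks
minus every mechanism-classified probe — subtracting all of M1–M4 (not M1
alone) is what makes the five pools pairwise disjoint, which the original
Venn layout presumes.

Prognostic screening dichotomizes each probe within each cohort at the
90th percentile by rank: the high group is the top round(N/10) samples
(minimum 1), ties broken by stable sample order with a warning. A
rank-based cut is deterministic under ties, at the cost of possibly
differing from a value-threshold cut on tied data. The two groups are
compared by the standard two-group log-rank test; calls are S/NS at raw
α = 0.05 per test. Feature typing reads the call triple in the fixed
cohort roles (91A, other-of-{90A,181A}, network cohort); probes
significant somewhere but NS in their network cohort fit none of the four
published patterns and are retained as "untyped" rather than silently
dropped or guessed into a type. The consensus signature is the exact
intersection of the two type-II sets. Kaplan–Meier estimation, the
log-rank test and Cox fits are delegated to lifelines (product-limit with
censored subjects at risk through tied event times; Efron ties in Cox
partial likelihood); independent hand oracles for all three live in the
test suite only. Cox fits that fail to converge (e.g. monotone
likelihood) are returned as flagged rows, never as silent estimates.

Descriptive stages use the field-standard tools: per-probe median
centering (idempotent, exact zero medians), complete-linkage agglomeration
on Euclidean distances via scipy (verified against an O(n³) brute-force
oracle for n ≤ 8), one-way fixed-effects ANOVA via scipy with per-level
means reported so the caller can read which clinical status carries the
highest TF mean. Patient subcohorts are extracted by clustering the
median-centered signature submatrix over samples and cutting the
dendrogram into n_groups (default 2) by merge height; the group with the
higher mean TF1+TF2 expression is labeled "high". The delineation of
subcohorts in the original heatmaps is not described beyond the figure;
this dendrogram-cut rule is a stated stand-in, not a fidelity claim.

## Synthetic cohort generator

The generator emulates the study conditions the analysis assumes, not any
real dataset's distributions. Composition defaults to the study's subtype
counts (Group IE 61, IIE 29, TN 48, ERBB2+ 29, ER−PR+HER− 5, ER−PR+HER+ 6,
ER−PR+HER? 3; 90 ER+ / 91 ER− / 181 total) and is exact for every seed.
TF1 (MYB-like) carries a +1.5 mean shift in ER+ tumors; TF2 (ARNT2-like)
is generated independent of TF1 and without an ER shift so that
planted-truth FDR scoring is meaningful — any TF2-network hit on a
TF1-only target would otherwise be an artifact of builder-induced
TF-TF correlation rather than a method error. Planted mechanisms: linear
(effect·z(TF1)), nonmonotone (effect·|z(TF1)|, near-zero Pearson by
symmetry), joint AND/OR gates on both TFs' rank percentiles, and
single-TF variants; non-planted probes are independent standard normals.
The documented benchmark plants 30 linear + 30 nonmonotone + 20 joint
targets among 920 nulls, effect 1.5, noise SD 1.0, at 1,000 target probes
(desk scale; full array scale is a config choice).

Survival is exponential proportional hazards — the simplest generator
consistent with validating the KM/log-rank/Cox stages (Weibull is a
possible config extension): event rate λ0·exp(β·score), where the score is
the standardized mean of the planted signature probes (default: the linear
targets). The protective program is modeled as ER+-enriched: the hazard
effect is attenuated by a factor `er_neg_activity` in ER− tumors, which is
what makes the planted probes land in feature type II (NS in 91A, S in 90A
and 181A). Censoring is an independent exponential whose rate is solved
numerically so the expected censored fraction matches `censor_rate`.

Defaults and why: λ0 = 0.012/month (baseline median ≈ 58 months, a
plausible follow-up scale), β = −2.2 per SD of signature score,
er_neg_activity = 0.10, censor_rate = 0.20. β and the attenuation were
fixed once by a design-stage power calculation: the binding constraint is
the 9-vs-81 top-decile log-rank inside the 90-sample ER+ cohort, and a
per-SD hazard ratio of e^−2.2 ≈ 0.11 — strong but within the range
reported for curated prognostic signatures — gives that test reliable
power while leaving the attenuated ER− cohort correctly null. Clinical
indices (grade and its three components, LVI, LNM/LYM, size, stage) are
drawn monotone in a latent aggressiveness score negatively coupled to TF1,
mirroring the qualitative claim that high TF1 accompanies early clinical
statuses without asserting any particular effect size.

What passing tests do and do not show: the generator's nulls are
independent Gaussians and its planted effects are homoscedastic and
cohort-stationary, so recovery results certify the machinery (calibration,
union logic, typing, consensus) under the stated conditions — they say
nothing about probe-level measurement error structure, batch effects, or
the effect sizes of real regulatory relationships, for which no published
values exist.

## Numerical choices and degenerate inputs

Missing expression values are a single `NA` sentinel; operations that
cannot tolerate them (networks, clustering) reject affected probes with a
warning rather than imputing. Constant targets have CID = 0 by definition
and permutation p = 1; constant vectors make Pearson undefined — flagged,
excluded from the GPCC arm, never a crash. Cohorts smaller than 2K cannot
be subgrouped (error advising a smaller K); cohorts under 10 samples
yield "unavailable" screening calls rather than silent NS. Permutation
p-value comparisons use a 1e-9 relative tolerance so exact ties (e.g.
constant targets) count as exceedances. The top-decile cut size is
computed as round(N − N·q) with halves rounding up. HER status "unknown"
is first-class and never blocks ER-based cohort assignment; the
ER−PR−HER? corner of the status grid gets its own explicit label rather
than being folded into TN or ERBB2+.

## Benchmark definition

The planted-edge recovery benchmark (reported by `scripts/acceptance.py`
and asserted in the acceptance suite) runs both TFs' univariate networks
on the 181A cohort at B = 999 with BH-corrected arms. With 920 null
probes, the raw union rule flags ≈ 1 − 0.95² ≈ 9.75% of nulls — calibrated
per arm, but ~70 false edges against ~90 true ones, i.e. an FDR near 0.45
no matter how well the statistic works; FDR-meaningful edge recovery is
therefore defined over the BH-corrected networks (sensitivity ≥ 0.8 at
FDR ≤ 0.15 under the documented conditions), while raw-α mode remains the
default everywhere else for fidelity to the screening convention. The
end-to-end consensus bound (≥ 70% of planted protective probes recovered)
is pooled over ten seeds; single-seed recovery fluctuates because all
signature probes share one survival realization per cohort.

## Known limitations

No directionality or causality claims; no genome-wide TF×TF pair scan
(only configured pairs); no probe-to-gene re-annotation, normalization
from raw scans, or pathway enrichment. The GEO series-matrix reader
parses the table and exposes characteristics lines as raw strings only.
Published real-data headline numbers (signature size 41, cohort network
counts, subcohort KM p-values) depend on the original accession and a
statistic variant printed only in earlier work; they ship as transcribed
fixtures for set queries and are never claimed as computed output.
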