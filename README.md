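# cidprognet

Supervised transcription-factor network inference with survival-based
prognostic signature screening, for bulk expression cohorts with
receptor-defined subtypes (the motivating system is infiltrating ductal
breast carcinoma profiled as log2 tumor/reference ratios, with ER/PR/HER
IHC status and follow-up survival per sample).

It is aimed at computational biologists who want to (a) infer which probes
a transcription factor (TF) regulates from co-expression structure that
plain correlation misses, (b) ask which of those network probes carry
prognostic information in which patient stratum, and (c) distill a
consensus prognostic signature — plus a synthetic cohort generator with
planted ground truth to benchmark every stage.

## The statistics at the core

**CID (coefficient of intrinsic dependence).** Samples are split into K
contiguous rank blocks G_1..G_K of the conditioning TF's expression (the
"1/10th subgrouping", K = 10). With F the pooled empirical CDF of a target
probe y and F_k the CDF inside block k (n_k members, N samples):

    subCID_k = (3/N) * Σ_j ( F_k(y_j) − F(y_j) )²        evaluated at all N observed y_j
    CID      = Σ_k (n_k/N) * subCID_k                     ∈ [0, 1)

CID is rank-based (invariant under monotone transforms) and sensitive to
*any* distributional shift across TF levels, monotone or not; the block
with the highest subCID localizes where the regulatory relationship is
strongest. Significance is calibrated by permutation of the target against
the fixed subgrouping, p = (1 + #{stat_perm ≥ stat_obs})/(B + 1), B = 999.

**CIDUGPCC.** A probe enters the univariate TF network if it is significant
by CID *or* by the Pearson correlation (GPCC) t-test — the union of a
shape-free arm and a linear arm.

**Two-TF mechanism pools.** For a TF pair, CID on blocks of a joint
conditioning score (mean of the two TFs' rank percentiles, so the top block
is "high in both") gives a multivariate network. Probes are partitioned
into pools: M1–M4 by which univariate arms accompany joint significance
(both / TF1 only / TF2 only / joint only), and U = the overlap of the two
univariate networks not claimed by any mechanism pool.

**Prognostic screening.** Every network probe is dichotomized at its 90th
expression percentile within each of three cohorts (91A = ER−, 90A = ER+,
181A = all) and the top-decile group's survival is compared by log-rank.
The S/NS call triple (91A, other, network cohort) types each probe:
(S,S,S) → I, (NS,S,S) → II, (S,NS,S) → III, (NS,NS,S) → IV. The consensus
signature is the intersection of the type-II sets of the 90A- and
181A-anchored networks; signature-defined patient subcohorts are extracted
by complete-linkage clustering and compared by Kaplan–Meier/log-rank, with
Cox proportional-hazards fits available for covariate adjustment.

## Worked example

```python
import warnings; warnings.simplefilter("ignore")
from cidprognet import benchmark_config
from cidprognet.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(synthetic=benchmark_config(seed=1), seed=1)
res = run_pipeline(cfg)
print("181A network probes:", len(res.full_networks["181A"]))
print("pool sizes (181A):  ", {k: len(v) for k, v in sorted(res.pools["181A"].items())})
print("consensus signature:", len(res.consensus), "probes")
planted = set(res.truth.signature_probes)
print("planted protective probes recovered:",
      f"{len(planted & set(res.consensus))}/{len(planted)}")
for cname, sub in res.subcohorts.items():
    print(f"subcohort KM ({cname}): log-rank p = {sub.p:.3g}")
```

prints

```
181A network probes: 108
pool sizes (181A):   {'M1': 15, 'M2': 39, 'M3': 4, 'M4': 36, 'U': 14}
consensus signature: 22 probes
planted protective probes recovered: 19/30
subcohort KM (90A): log-rank p = 3.63e-11
subcohort KM (181A): log-rank p = 2.4e-08
```

The synthetic benchmark plants 30 linear, 30 non-monotone and 20
two-TF-gated targets among 920 noise probes in a 181-sample cohort
(90 ER+ / 91 ER−); 30 linear targets additionally drive a protective
hazard in ER+ tumors. Here the pipeline's 181A network holds 108 probes
split across the mechanism pools, the type-II consensus recovers 19 of the
30 planted protective probes at this seed, and the signature-defined
patient subcohorts separate sharply in survival. A `cidprognet` CLI
(`run`, `synth`, `network`, `screen`, `anova`, `subcohorts`) wraps the same
calls for shell use.

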