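# decif

Prognostic classification of high-grade breast cancer by the joint
**ECM3 / interferon (IFN)** status of a tumor, and the tooling needed to
carry that classifier from genome-wide expression arrays down to a
12-gene qPCR assay.

A subset of breast cancers (~30–40%) coordinately over-expresses a panel
of structural extracellular-matrix genes; these **ECM3-positive** tumors
have a distinctive, ECM-rich microenvironment. A second axis summarizes
the interferon response as a 21-gene **IFN metagene**. Tumors that are
ECM3-positive *and* below the cohort median of the IFN metagene
(**dECIF = ECM3+/IFN−**) form the high-risk group: an immune-cold,
matrix-rich phenotype with markedly worse overall survival (hazard ratio
≈ 3 against all other tumors in the cohorts this method was developed on).

The package implements the full analysis as a tested pipeline:

- **`decif.biclustering`** — ECM3 calling by *large-average-submatrix*
  (LAS) biclustering over an ECM gene panel. A k×l submatrix of the
  row-standardized matrix with entry average τ is scored
  `S = −log Φ(−τ√(kl)) − log C(m,k) − log C(n,l)`; the search alternates
  size-adaptive gene/sample updates after a fixed-size warm-up, with an
  exhaustive mode for small matrices.
- **`decif.metagene`** — IFN metagene (mean of direction-signed z-scores)
  dichotomized at the cohort 50th percentile.
- **`decif.classifier`** — the four-level ECM3/IFN joint variable, the
  dichotomous dECIF variable, and application of reduced logistic
  signatures (`score = β₀ + Σ βg·z_g`, positive iff score ≥ cutoff).
- **`decif.reduction`** — reduction of a large signature to a few genes:
  direction-filtered Kruskal–Wallis screen → Spearman-CI redundancy
  pruning (strong pair: lower 95% confidence limit of r_s > 0.6) →
  Bonferroni selection → all-subset logistic regression scored by the
  c-statistic → optimal agreement cutoff → Cohen's kappa against the
  original calls.
- **`decif.survival`** — Kaplan–Meier curves, log-rank tests and Cox
  proportional-hazards models (Efron ties, Wald CIs) via lifelines.
- **`decif.stats`** — Cohen's kappa with CI and Landis–Koch labels,
  Fisher's exact test, Kruskal–Wallis (with an exact small-sample mode),
  Spearman correlation with Fisher-z CI, a CD3-complex PCA surrogate
  score, and percentage-marker dichotomizers.
- **`decif.qpcr`** — triplicate Cq aggregation with outlier rejection,
  calibrator-based inter-plate correction, ΔCq normalization against a
  housekeeping gene (RPLP1 by default), and cross-assay agreement.
- **`decif.simulate`** — seed-deterministic synthetic cohorts with a
  planted expression bicluster, a latent IFN factor, group-specific
  survival hazards and derived qPCR plates, so every stage can be scored
  against known truth.

Classification stages are also exposed as scikit-learn-style estimators
(`ECM3Classifier`, `IFNClassifier`, `ReducedSignatureClassifier`,
`SignatureReducer`) that support `get_params`/`clone` and compose with
sklearn tooling.

## Worked example

```python
import pandas as pd
from decif import (default_ecm_panel, default_ifn_panel, simulate_expression,
                   call_ecm3, metagene_score, dichotomize_ifn, assign_decif,
                   simulate_survival, cox_fit, reduce_signature)

ecm, ifn_panel = default_ecm_panel(), default_ifn_panel()
expr, truth = simulate_expression(n_samples=200, ecm_panel=ecm,
                                  ifn_panel=ifn_panel, delta=1.5, seed=3)

ecm3 = call_ecm3(expr, ecm, n_restarts=200, seed=1)[0][0]
ifn = dichotomize_ifn(metagene_score(expr, ifn_panel))
labels = assign_decif(ecm3, ifn)
print(labels["joint"].value_counts().to_dict())
# {'ECM3-/IFN+': 66, 'ECM3-/IFN-': 64, 'ECM3+/IFN-': 36, 'ECM3+/IFN+': 34}

clin = simulate_survival(labels["dichotomous"],
                         {"ECM3+/IFN-": 3.2, "other": 1.0}, seed=5)
res = cox_fit(clin, ["group"], {"group": "other"})[0]
print(f"dECIF HR {res.hr:.2f} (95% CI {res.ci_low:.2f}-{res.ci_high:.2f})")
# dECIF HR 2.25 (95% CI 1.47-3.43)

sig, trace = reduce_signature(expr, ecm, ecm3)
print(len(sig.genes), trace.agreement.kappa, trace.agreement.label)
# 4 0.9889746416758545 almost perfect
```

The joint counts show the four ECM3/IFN categories of the cohort; the Cox
fit flags the planted excess hazard of the 36 ECM3+/IFN− samples (the
point estimate sits below the planted 3.2 at this cohort size — the 95%
interval is wide at 36 high-risk samples); the reduction compresses the
40-gene ECM panel to a 4-gene logistic classifier that agrees with the
full LAS call at kappa 0.99 ("almost perfect").

A command-line front end mirrors the library
(`decif simulate|classify|reduce|survival|qpcr`); see `decif --help`.

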