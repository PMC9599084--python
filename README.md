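# cerna-icb

Analysis pipeline for circRNA/lncRNA dysregulation and the clinical
response to immune-checkpoint blockade (ICB) in bulk RNA-seq cohorts —
e.g. metastatic melanoma biopsies from anti-PD-1-treated patients.

circRNAs and lncRNAs can act as competing endogenous RNAs (ceRNAs):
by sponging miRNAs they de-repress the miRNAs' mRNA targets, which
predicts a *positive* ceRNA–mRNA expression correlation. This package
implements the full chain from raw multi-caller circRNA junction calls
to a prognostic ceRNA-signature risk score:

1. **Consensus circRNA detection** (`CircConsensus`). Back-splice
   junction (BSJ) calls from up to five callers (CIRI, CIRCexplorer2,
   DCC, STARchip, CIRIquant) are harmonized onto canonical 0-based
   half-open coordinates via per-caller offset profiles and filtered to
   a high-confidence set: ≥ 2 BSJ reads in ≥ 2 samples and detection by
   ≥ 3 callers. Cross-caller quantification is merged as the per-cell
   median.
2. **Circular-to-linear ratio** (`circular_linear_ratio`). For BSJ and
   forward-splice (FSJ) reads at one locus,
   `r = 2·bsj / (2·bsj + fsj)` ∈ [0, 1]; 1 means purely circular
   output, 0 purely linear.
3. **Differential expression** (`NBWaldDE`). Per-feature NB2 GLM
   (variance = μ + α·μ²) with a responder/non-responder contrast, size
   factors anchored to each sample's *total linear mapped reads*,
   Cox–Reid-adjusted dispersion estimation with empirical-Bayes
   moderation, Wald test, Benjamini–Hochberg adjustment, and
   significance at adjusted p < 0.1 and |log2FC| > 1.5.
4. **ceRNA network** (`CeRnaNetworkBuilder`). An edge links a DE ceRNA
   to a DE mRNA when they share a miRNA whose mRNA-side prediction is
   supported by ≥ 5 of 7 tools; edges are validated by the Pearson
   correlation of log2-normalized expression and, by default, only
   directly (positively) correlated edges are kept.
5. **Survival risk score** (`CoxRiskScore`). Each signature feature
   gets a univariate Cox coefficient (Newton–Raphson on the Efron
   partial likelihood); the patient risk score is
   `RS = Σᵢ expressionᵢ · coefficientᵢ`, patients split into high/low
   risk at the median score, and the groups are compared with
   Kaplan–Meier curves and the log-rank test (OS and PFS).

A seeded synthetic-data generator (`SimConfig`, `simulate_all`)
produces cohorts with planted caller dropout, NB effects, high-support
interaction triples and signature-linked hazards, plus an exhaustive
ground-truth table, so every stage is testable end to end.

## Worked example

```python
import pandas as pd
from cerna_icb import (SimConfig, simulate_all, CircConsensus, NBWaldDE,
                       CeRnaNetworkBuilder, CoxRiskScore,
                       estimate_size_factors, normalize_expression)

cfg = SimConfig(n_circ_loci=200, seed=7)   # 8 responders vs 4 non-responders
sim = simulate_all(cfg)
groups = sim.samples.set_index("sample_id")["response"]
sf = estimate_size_factors(
    sim.samples.set_index("sample_id")["total_linear_mapped_reads"])

cc = CircConsensus().fit(sim.calls, sample_ids=list(groups.index))
de_circ = NBWaldDE().fit(cc.matrix_, groups, size_factors=sf)
de_lnc = NBWaldDE().fit(sim.lnc_counts, groups, size_factors=sf)
de_mrna = NBWaldDE().fit(sim.mrna_counts, groups, size_factors=sf)

net = CeRnaNetworkBuilder().fit(
    sim.circ_mirna, sim.lnc_mirna, sim.mrna_mirna,
    de_circ.significant_ | de_lnc.significant_, de_mrna.significant_,
    cerna_expression=normalize_expression(
        pd.concat([cc.matrix_, sim.lnc_counts]), sf),
    mrna_expression=normalize_expression(sim.mrna_counts, sf))

signature = sorted(de_circ.significant_ | de_lnc.significant_)
expr = normalize_expression(
    pd.concat([cc.matrix_, sim.lnc_counts]), sf).loc[signature]
meta = sim.samples.set_index("sample_id")
model = CoxRiskScore().fit(expr, meta["os_time"], meta["os_event"])
ev = model.evaluate(meta["os_time"], meta["os_event"])
```

Printed summary of this run:

```
high-confidence circRNAs: 187 / 200 loci
DE circRNAs: 10 up / 7 down
DE lncRNAs:  17 up / 22 down
ceRNA network: 29 edges, 24 ceRNAs, 17 mRNAs
risk signature: 56 features; median OS low-risk 18.31 vs high-risk 1.64 months; log-rank p = 0.0067
```

Reading: of 200 simulated circRNA loci, 187 survive the
2-reads/2-samples/3-callers filter; the NB Wald test recovers the
planted two-group effects; the network keeps only positively
correlated ceRNA–mRNA pairs that share a high-support miRNA; and the
56-feature risk score separates overall survival of the high- and
low-risk halves by an order of magnitude in median survival.

The same flow is scriptable via the `cerna-icb` CLI
(`simulate`, `consensus`, `ratio`, `de`, `network`, `risk`, `run`,
`report`), with `run` driving all stages from one YAML config and
writing a content-hashed run manifest.

## Scope notes

The package consumes caller output tables; it does not run the circRNA
callers, align reads, or query interaction databases (interaction
tables are user-supplied inputs). Enrichment/upstream-regulator
analysis over proprietary knowledge bases is out of scope. See
`docs/methods.md` for the statistical model, defaults and limitations.
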