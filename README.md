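# dyam

Multimodal prediction of immunotherapy response in non-small cell lung
cancer (NSCLC), for computational oncology researchers and methods
developers: CT lesion radiomics with robustness filtering, PD-L1
immunohistochemistry (IHC) texture quantification, genomic feature encoding,
attention-based multiple-instance learning, and a masked dynamic-attention
fusion model with the matching evaluation protocol and attention-reweighting
analysis — all exercised on a synthetic multimodal cohort generator, so the
whole pipeline is testable without any clinical data.

## The model

A patient carries up to five feature blocks ("modalities"): CT lesion
texture at three sites (lung parenchyma, pleura, lymph node), PD-L1/IHC
texture plus the tumor proportion score (TPS), and genomics
(oncogenic-alteration bits + tumor mutational burden).  Blocks may be
absent — not every patient has segmentable disease or a PD-L1-positive
slide.  Each modality *m* has a logistic **risk head**
r_m = σ(w_m·x_m + b_m) and an **attention head** producing a logit t_m;
attention weights compete through a softmax over the modalities the patient
actually has (absent modalities are masked to zero attention before
normalization), and the overall score is the convex combination

    s = Σ_m a_m · r_m,   a = softmax over present modalities of t,
    Σ over present modalities of a_m = 1.

With exactly one modality present the softmax is a singleton, so the gate is
bypassed and s equals that modality's risk.  All heads train jointly
(full-batch Adam, balanced binary cross-entropy, learning rate 0.01, 125
steps, L2 10⁻³).  A fitted model can be interrogated per patient (partial
risks r̄, attention weights ā) and reweighted in closed form: scaling
modality k's attention by m gives

    a'_k = m·a_k / (1 + (m−1)·a_k),   a'_{i≠k} = a_i / (1 + (m−1)·a_k),

so "alpine" scans of AUC, hazard ratio and early-progression quartile ratio
versus m ∈ [10⁻², 10²] quantify each modality's contribution without
refitting.

Supporting machinery: a first-order + GLCM texture bank (25 co-occurrence
functionals, per-ROI in 3-D and per-pixel over 3×3 kernels in 2-D), a
segmentation-perturbation robustness filter (features kept when the
within-lesion perturbation variance is < 0.15 of the cohort variance),
H-DAB stain deconvolution, attention-pooled MIL over lesion bags, and the
evaluation protocol: merged ten-fold cross-validation, DeLong confidence
intervals, permutation nulls, 90/10 subsampling, Youden calibration,
Kaplan-Meier / log-rank and Cox hooks (via lifelines).

## Worked example

```python
import numpy as np
from dyam import CohortConfig, generate_cohort, DyAMClassifier, stack_cohort
from dyam.records import cohort_labels, cohort_survival
from dyam.evaluation import tenfold_cv, auc_delong, km_logrank
from dyam.attention import ReweightSpec, reweight_attention

cohort = generate_cohort(CohortConfig(n_patients=247, seed=0))
blocks = stack_cohort(cohort)          # five (n, d_m) blocks, NaN rows = absent
y = cohort_labels(cohort)

scores = tenfold_cv(blocks, y, DyAMClassifier(), seed=0, X_kind="blocks")
auc, (lo, hi), _ = auc_delong(scores, y)
print(f"merged 10-fold CV AUC: {auc:.2f} (95% CI {lo:.2f}-{hi:.2f})")

model = DyAMClassifier().fit(blocks, y)
out = model.explain(blocks)[0]
print(f"patient {cohort[0].patient_id}: score {out.overall_score:.2f}")
print("attention:", {k: round(v, 2) for k, v in out.attention.items()})

times, events = cohort_survival(cohort)
high_risk = scores < np.median(scores)
_, stat, p = km_logrank(times, events, high_risk.astype(int))
print(f"log-rank chi2 {stat:.1f}, p = {p:.1e}")

a = reweight_attention(np.array([0.5, 0.25, 0.25]), ReweightSpec(k=0, m=10.0))
print("reweighted attention at m=10:", a.round(3))
```

prints

```
merged 10-fold CV AUC: 0.55 (95% CI 0.46-0.63)
patient P0000: score 0.17
attention: {'ct_parenchymal': 0.9, 'ct_pleural': 0.0, 'ct_node': 0.0, 'ihc': 0.07, 'genomics': 0.03}
log-rank chi2 1.0, p = 3.2e-01
reweighted attention at m=10: [0.909 0.045 0.045]
```

Reading the output: at the real study's sample size (n = 247) and with
modality signals calibrated to that study's discriminative levels, the
honestly cross-validated AUC of the attention model is modest and its CI
wide — small cohorts are exactly where merged-CV evaluation matters.  The
per-patient readout shows the model placing 90% of this patient's attention
on their parenchymal CT block; the closed-form reweighting shows a modality
holding half the attention jumping to 0.91 when boosted ten-fold, the other
modalities shrinking by the factor 0.18.  Larger cohorts with per-patient
modality-relevance structure (see `CohortConfig.relevance_heterogeneity`)
are where the attention mechanism pays off; `gate=False` gives the
equal-weight averaging baseline.

A `dyam` console script exposes the pipeline stages
(`simulate`, `featurize-ct`, `featurize-ihc`, `featurize-genomics`,
`train`, `evaluate`, `attention-scan`); `dyam simulate --n 60 --seed 3
--outdir cohort/ --render` writes a full cohort directory (clinical and
feature TSVs, mutation tables, NIfTI volumes, TIFF slides, JSON manifest)
that the featurize commands consume.

## Layout

| Module | Contents |
|---|---|
| `dyam.synthetic` | cohort generator, lesion/slide/mutation renderers |
| `dyam.radiomics` | feature extraction, perturbation, robustness-z filter |
| `dyam.ihc` | stain deconvolution, per-pixel GLCM maps, IHC-A / IHC-G |
| `dyam.genomics` | alteration-bit encoding, TMB |
| `dyam.predictors` | elasticnet LR, attention-MIL (sklearn estimators) |
| `dyam.model` | `DyAMClassifier` — masked dynamic-attention fusion |
| `dyam.evaluation` | merged CV, DeLong, permutation, survival readouts |
| `dyam.attention` | closed-form reweighting, alpine scans |
| `dyam.io`, `dyam.cli` | cohort directories, model JSON, console script |

See `docs/methods.md` for the full account of the model, defaults, the
generator's assumptions and known limitations.
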