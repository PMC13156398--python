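# evidfuse

Belief-function (Dempster–Shafer) multimodal fusion of structured EHR
data and free-text clinical notes for binary ICU outcome prediction
(mortality, prolonged length of stay), with explicit per-prediction
uncertainty and a full accuracy + reliability evaluation panel.

## Who it is for

Clinical-ML researchers who want to fuse heterogeneous EHR modalities
*in evidence space* rather than by feature concatenation: each modality
produces a Dempster–Shafer mass function — belief per outcome class
plus an explicit ignorance term m(Ω) — and the modalities are pooled by
Dempster's rule, which accounts for the conflict between them.
Credentialed ICU datasets cannot be redistributed, so the package ships
a synthetic-cohort generator that emulates their statistical shape
(~12% positive prevalence, mixed numeric/binary structured features
with missingness, multiple note types with partially complementary
class signal) and makes every component testable offline.

## The model

For a frame of discernment Ω = {ω₁, …, ω_M} (here M = 2), evidence is a
mass function m with m(∅) = 0 and Σ_A m(A) = 1.  Two independent masses
combine by Dempster's rule

    (m₁ ⊕ m₂)(A) = Σ_{B∩C=A} m₁(B) m₂(C) / (1 − κ),
    κ = Σ_{B∩C=∅} m₁(B) m₂(C),

and decisions use Smets' pignistic transform p(ω) = Σ_{A∋ω} m(A)/|A|.

Per modality, an encoder (MLP or tabular ResNet for structured data; a
frozen embedding provider plus one trainable 128-unit layer for notes)
feeds a prototype evidential layer: each of H = 20 prototypes π_h emits
distance-discounted evidence

    s_h = β_h exp(−γ_h ‖x − π_h‖²),
    m_h({ω_c}) = u_h^(c) s_h,   m_h(Ω) = 1 − s_h,

and the H masses are pooled with Dempster's rule.  Modality masses are
then fused the same way, and the fused mass yields pignistic
probabilities plus a reported ignorance m(Ω).  Training minimizes the
augmented objective L = L_main + α·L_aux^struct + β·L_aux^text
(α = 2, β = 1), where L_main is class-weighted cross-entropy on the
pignistic probabilities and the auxiliary terms are weighted softmax
cross-entropies on per-modality heads.  Class weights are balanced
inverse frequency, w_c = N/(M·N_c).

Comparison fusion strategies (feature concatenation, mean, attention)
and three evidence partitionings (modalities / data types / data
sources) are included.

## Worked example

```bash
evidfuse simulate --seed 7 --out cohort --set cohort.n_patients=2000
# cohort: n=2000, prevalence=0.1135, missing=0.0500

evidfuse train --seed 7 --data cohort --out run
# test metrics (mean): precision=0.6667, recall=0.7391,
#   specificity=0.9520, npv=0.9656, bacc=0.8456, f1=0.7010,
#   auroc=0.9718, auprc=0.8477, brier=0.0491, nll=0.1814
```

`simulate` writes the canonical input files (`structured.csv` with a
`tags.json` sidecar mapping each column to its source and type,
`notes.jsonl`, `labels.csv`).  `train` fits the evidential fusion model
on a stratified 60/20/20 split (add `--cv` for 5-fold stratified
cross-validation with mean ± standard error per metric) and writes
`metrics.{csv,json}`, per-epoch `history.jsonl`, and `predictions.csv`
with one row per held-out patient: the pignistic positive probability,
the fused mass components (`m_pos`, `m_neg`, `m_omega` — the last being
the model's admitted ignorance for that patient), and the thresholded
label.  In the run above the fused model reaches AUROC 0.97 on held-out
patients while keeping Brier score 0.049, i.e. its probabilities are
well calibrated, and recall 0.74 at the 0.5 threshold despite the 11%
prevalence thanks to class weighting.

`evidfuse compare-fusion` trains the evidential, concatenation, mean
and attention strategies on identical folds and tabulates all ten
metrics per strategy; `evidfuse evaluate` recomputes the panel from any
predictions CSV.

The same pipeline is available as a library:

```python
from evidfuse import CohortSpec, FusionSpec, TrainConfig, generate, run_experiment
from evidfuse.encoders import StructuredEncoderConfig, TextEncoderConfig
from evidfuse.evidence import EMConfig

raw = generate(CohortSpec(n_patients=2000, seed=7))
result = run_experiment(raw, StructuredEncoderConfig(), TextEncoderConfig(),
                        EMConfig(), FusionSpec(), TrainConfig(seed=7))
print(result.report.summary()["auroc"])
```

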