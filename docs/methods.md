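# Methods

## Model

The classifier fuses K modality-specific pieces of evidence about a
binary outcome in the Dempster–Shafer sense.  Working in the restricted
family of mass functions whose focal sets are the M singletons and the
full frame Ω has two advantages: it is closed under Dempster's rule
(so combination stays O(M)), and the Ω mass is a direct, interpretable
ignorance report per prediction.  `belief` implements both this
restricted form and the general power-set form; the two are checked
against each other to 1e-10 on random inputs, and the power-set form
serves as the exact oracle everywhere the network's arithmetic is
tested.

Each modality bundle is encoder → evidential layer → (training-only)
auxiliary head.  The evidential layer holds H = 20 prototypes; a
feature vector activates prototype h with s_h = β_h·exp(−γ_h·d_h²)
(d_h Euclidean), the prototype emits the restricted mass
(u_h·s_h, 1 − s_h), and the H masses are pooled with Dempster's rule.
Constrained parameters are trained through smooth bijections — β_h by a
logistic map, γ_h by softplus, membership rows u_h by softmax — so the
optimizer sees an unconstrained problem.  All of it (prototypes
included) is learned jointly with the encoders — whether these
quantities should be learned or fixed is an open design point in
prototype evidential classifiers, and joint learning is this package's
choice.

Inside the layer the H-fold Dempster combination is evaluated in closed
form: with w_c = Π_h (m_h({ω_c}) + m_h(Ω)) and w_Ω = Π_h m_h(Ω), the
unnormalized combination is (w_c − w_Ω) per singleton and w_Ω on Ω,
normalized once at the end.  This is algebraically identical to a
per-step-normalized left fold (verified against the power-set oracle to
1e-16) and substantially cheaper inside the autodiff graph.  The
normalizer is clamped at 1e-12: Dempster's rule is undefined at total
conflict κ = 1, and the clamp keeps gradients finite even though
restricted masses with s_h < 1 can never reach it.  Eager (non-graph)
combination raises a total-conflict error naming κ instead.

Modality masses are fused by a per-step-normalized left fold of the
same rule; associativity (tested) makes the order irrelevant up to
float noise.  Decisions use the pignistic transform, which for
restricted masses is p(ω_c) = m({ω_c}) + m(Ω)/M; the positive class is
predicted at p ≥ 0.5 (config-exposed threshold).

## Training objective and protocol

L = L_main + α·L_aux^struct + β·L_aux^text with α = 2, β = 1.  L_main
is class-weighted cross-entropy on the pignistic probabilities (logs
clamped at 1e-12); each auxiliary term is a class-weighted softmax
cross-entropy on a single affine head over that bundle's encoder
features (structured-derived bundles weighted by α, note-derived by β —
for the finer partitionings this generalizes the two-modality form).
Class weights default to balanced inverse frequency,
w_c = N/(M·N_c) — the standard way to weight by relative class
frequencies — and are config-overridable.

Optimization: Adam at 1e-3 (optimizer and rate are this package's
defaults, config-exposed), mini-batches of 32, at most 150 epochs with
early stopping, stratified 60/20/20 holdout or 5-fold stratified CV
(fold test sets partition the data; the remainder is re-split so the
validation share matches the configured fraction).  Fold summaries
report mean ± SD/√folds.

Model selection monitors the validation **main** loss, not the
augmented objective.  This was a deliberate decision after diagnosis:
the structured auxiliary term (weight 2) keeps improving long after the
fused prediction stops, so an overall-loss monitor can select epochs
where one modality's memorized noise is already damaging the fused
output.  The deployment quantity is the fused prediction; selecting on
its loss made the model robust to an uninformative modality (see
below) without touching any other regime.  Training itself still
minimizes the full augmented objective.

## Numerical choices that mattered

Two failure modes of the joint optimization drove design choices:

1. **Feature drift kills distance kernels.**  The auxiliary losses
   reshape encoder features; with an unbounded feature space the
   features move away from the initialized prototypes, s_h underflows,
   the layer's output saturates at total ignorance and its gradient
   vanishes permanently.  Encoder outputs are therefore projected onto
   the √dim sphere (scaled L2 normalization, ε = 1e-6 so zero rows stay
   zero; `normalize_output` flag).  This bounds every distance the
   layer can see.

2. **Kernel width must respect the ambient space, not the initial
   scatter.**  Prototypes initialize at k-means centroids of the
   (random) initial encoder features with γ = 1/(mean pairwise
   prototype distance² + 2·dim).  The 2·dim term is the mean squared
   distance of two random points on the √dim sphere; without it γ is
   calibrated to the tight initial scatter and underflows as soon as
   features rotate elsewhere on the sphere (observed: s_h ~ 1e-5 and a
   permanently silent text modality).  β_h initializes at 0.5,
   memberships near-uniform with small seeded noise; γ, β, u are all
   learned, so resolution sharpens as prototypes settle.  A
   label-informed membership initialization was tried and rejected: it
   anchors the layer to the arbitrary geometry of untrained features
   and performs clearly worse.

Undefined metric cells (zero denominators, single-class test sets) are
reported as missing (NaN) and excluded from fold aggregates rather than
silently becoming zeros.

## Synthetic cohorts

`synthetic.generate` draws: Bernoulli labels at 12% prevalence; numeric
vitals/labs as class-conditional Gaussians (6 of 18 informative, mean
shift 0.5 SD by default); binary treatments/comorbidities as
class-conditional Bernoullis (4 of 12 informative, rate shift 0.18);
demographics (age, weight, a 3-level admission type) whose weak signal
scales with the same effect parameters so zero-effect specs carry no
signal anywhere; four note types whose class-informative tokens appear
with probability logistic(−2 + 1.5·y) among background tokens; MCAR
missingness at 8% on numeric/categorical cells.  A shared per-patient
severity latent, weighted by `modality_correlation` (0.3), correlates
the two modalities' noise and controls how complementary their signals
are.  Preset variants pin the benchmark regimes: `separable_spec`
(strong independent signal in both modalities), `noise_text_spec` /
`noise_struct_spec` (one modality pure noise).

What the generator does *not* emulate: real lab-value semantics and
units, informative missingness, temporal structure, clinical language
(notes are token soups; the hashing embedder only sees bags of tokens),
and inter-feature correlation beyond the single severity latent.
Passing tests therefore demonstrate that the machinery recovers known
signal structure under controlled conditions — not clinical validity on
real EHR data.

Preprocessing follows the contractual EHR rules: features with ≥50%
training-split missingness are dropped; categoricals are one-hot
encoded over training categories (binary-valued columns stay single
indicators); numerics are z-scored and median-imputed, categoricals
mode-imputed — every statistic fitted on the training split only
(leakage is unit-tested by poisoning held-out rows).  Four numeric
imputation strategies are available (mean, median, KNN with k = 5,
iterative with 10 rounds / tol 1e-3).  Notes are prefixed with their
type ("Nursing: …"), concatenated with newlines in the fixed order
Nursing, Nursing/Other, Physician, Radiology, tokenized (stub:
lowercase whitespace), and truncated/padded to exactly 512 tokens.
Prolonged length of stay is a stay strictly exceeding 7 days.
Missingness is MCAR by design — the minimal assumption, and it keeps
the imputation comparison interpretable.

## Text encoder contract

Note embeddings come from a frozen provider — any function from text to
a fixed-size vector — with one trainable 128-unit projection on top.
The shipped provider is a deterministic bag-of-hashed-tokens embedder
(blake2b buckets, L2-normalized, 256-dim, no downloads, no
randomness); a pre-trained language model plugs in through the same
contract, with pooling left provider-defined.  The stub's whitespace
tokenizer is a stand-in for real subword tokenizers; only the
512-token truncation/padding semantics are contractual.

## Problem sizes

End-to-end checks run on 5000-patient cohorts (the acceptance script
uses 3000) with up to 60 epochs and patience 10 — the scale at which
the synthetic benchmark's training curves flatten.  The full benchmark
(fused + ablations) completes in a few minutes on one CPU.

## Known limitations

* Binary outcomes only; multiclass frames are supported by the algebra
  but not by the training pipeline.
* No missing-modality handling: a sample lacking a bundle's input fails
  fast by design.
* Class weighting trades calibration for minority recall: weighted runs
  have visibly higher Brier/NLL than unweighted ones at matched AUROC.
* The attention baseline is the simplest faithful reading (per-bundle
  affine scorer, softmax over bundles); it is a comparison point, not a
  tuned competitor.
* The autodiff engine is deliberately minimal (float64, no
  broadcasting-free fast paths, no GPU); it is sized for cohorts of
  thousands, not millions.
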