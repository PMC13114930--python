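# mmib — information-bottleneck toolkit for multimodal biomedical data

Multimodal biomedical models (multi-omics integration, clinical + imaging
fusion, longitudinal disease tracking) are usually judged by task accuracy
alone, which says nothing about *how* predictive information is
distributed across data sources, how performance will degrade when a
modality is missing, whether a fused representation has silently collapsed
onto one input, or when a prediction should be deferred to a clinician.
`mmib` makes those questions measurable. It is aimed at computational
biologists and ML researchers working with tabular multimodal cohorts
(one numeric matrix per modality plus a categorical label, or long-format
longitudinal records).

## What it computes

**Variational multimodal information bottleneck (VMIB).** Per-modality MLP
encoders, concatenation fusion, a diagonal-Gaussian latent Z, and a
classifier head, trained on

    L = E[-log q(y|z)] + lambda * E[KL(q(z|x) || N(0, I))],

so that every trained model carries its own information-plane coordinates:
the KL term upper-bounds I(Z;X), and H(Y) − cross-entropy lower-bounds
I(Z;Y). `information_plane_sweep` traces the compression–prediction
trajectory across lambda.

**Mutual-information decomposition.** Classifier lower bounds
I(X;Y) ≥ H(Y) + E[log q(y|x)] per modality subset (stratified 5-fold CV,
shared folds), with pairwise interaction proxies

    S_ij = I(X_i, X_j; Y) − I(X_i; Y) − I(X_j; Y)   (synergy; R_ij = −S_ij)

and the missing-modality information loss Imiss(S) = max(0, MI(full) − MI(S)).

**Missing-modality robustness.** Modality-dropout training (keep-one rule)
and a forward-KL posterior-consistency penalty, with ablation grids that
pair each observed subset's AUC with its Imiss.

**Fusion-collapse diagnostics.** Per-modality predictive gaps
G̃_i = max(0, AUC(all) − AUC(ablate i)) and the balance index
B = H(G̃/ΣG̃)/ln M (1 = balanced reliance, 0 = collapse), plus adaptation
audits (scratch / linear probe / full / partial fine-tune) reporting
ΔAUC against the posterior-KL shift ΔKL.

**Uncertainty.** Predictive-entropy deferral curves with a random-deferral
baseline, held-out-class OOD detection, expected calibration error.

**Transfer entropy.** TE_{X→Y} = I(X_hist; Y_t | Y_hist) on longitudinal
records (classifier bounds for discrete targets, exact linear-Gaussian
residual-variance estimator for continuous ones), a closed-form oracle for
coupled AR(1) processes, subject-level sequential prediction ladders, and
stage-conditioned modality discriminability.

**Synthetic generators** with known information structure (exact discrete
joints, a Bernoulli-logistic interaction model, a latent-class multi-omics
emulator, a coupled AR longitudinal process) make every pipeline testable
without downloads. All quantities are in nats. See `docs/methods.md` for
estimators, defaults, and caveats.

## Worked example

```python
import numpy as np
from mmib import (
    LatentClassGenConfig, gen_latent_class, decompose_information,
    ProbeProtocol, VMIBConfig, train_vmib, evaluate_model, balance_index,
)

data = gen_latent_class(LatentClassGenConfig(n=2000, seed=0))  # m1 dominant
dec = decompose_information(
    data, protocol=ProbeProtocol(hidden_units=64, max_iter=200), seed=0
)
for subset in (("m1",), ("m3",), ("m1", "m2", "m3")):
    est = dec.mi(subset)
    print(f"I({'+'.join(subset)};Y) = {est.value:.3f} ± {est.std:.3f} nats "
          f"({dec.pct(subset):.1f}% of H(Y))")
print(f"S(m1,m2) = {dec.pairwise_synergy[('m1','m2')]:.3f} nats")

model = train_vmib(data, VMIBConfig(latent_dim=16, hidden_units=64,
                                    epochs=60, dropout_rate=0.1, seed=2))
print(f"test AUC = {evaluate_model(model, data)['auc']:.3f}")
```

prints

```
I(m1;Y) = 1.317 ± 0.032 nats (87.6% of H(Y))
I(m3;Y) = 0.731 ± 0.031 nats (48.6% of H(Y))
I(m1+m2+m3;Y) = 1.401 ± 0.022 nats (93.2% of H(Y))
S(m1,m2) = -1.186 nats
test AUC = 0.998
```

Reading: the dominant modality m1 alone captures ~88% of the label
entropy; m2 reads the same latent coordinates as m1, so their synergy
proxy is strongly negative (redundancy-dominated); fusing all three
modalities adds little over m1 — exactly the situation in which
missing-m1 robustness and fusion-collapse monitoring matter.

The same workflows are available from the shell:

```bash
mmib decompose --seed 0 --out out/ -o n=2000 -o probe_hidden=64
mmib sweep     --seed 0 --out out/ -o "lambda_grid=[0.0001,0.001,0.01,0.1,1.0]"
mmib temporal  --seed 0 --out out/
```

Each command writes CSV tables plus a `report.json` echoing the
configuration and every seed used.

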