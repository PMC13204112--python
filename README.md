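# mucocilia

Quantitative analysis of mucociliary recovery in chronic rhinosinusitis
transcriptomics: gene-set module scores, epithelial-cytokine interaction
scores, negative-binomial differential expression, and paired mixed-model
inference — plus a ground-truth synthetic cohort generator so every stage
can be validated without patient data.

## Who this is for

Eosinophilic chronic rhinosinusitis (ECRS) destroys mucociliary clearance:
type 2 cytokines (IL-4/IL-13) suppress the multiciliogenesis program and
planar cell polarity (PCP), while eosinophil extracellular traps thicken
the mucus. Studies of IL-4/13 blockade profile nasal tissue by bulk UMI
RNA-seq in four arms — healthy controls (`Ctrl`), non-eosinophilic CRS
(`nonECRS`), and paired pre-/post-treatment ECRS samples (`PreECRS`,
`PostECRS`) — and ask two questions: which transcriptional modules recover
after treatment, and does a patient's baseline mucosal cytokine tone
predict how much they recover? This package implements that analysis as a
tested, reusable pipeline for anyone running a comparable design.

## The statistics at its core

- **Module scores.** For a gene set S, the per-sample score is
  `(1/|S|) * sum_{g in S} log2(CPM_g + 1)`. Built-in sets: the
  multiciliogenesis master-regulator hierarchy (*TP73, MCIDAS, E2F4/5,
  CCNO, DEUP1, MYB, FOXJ1, FOXN4, RFX2/3*), core PCP (*CELSR1–3, FZD3/6,
  VANGL1–2, DVL1–3, PRICKLE1–4, ANKRD6*) and the CPLANE ciliary effectors
  (*FUZ, INTU, WDPCP*); the registry is user-extensible.
- **Cytokine interaction scores.** For a ligand L with receptor subunits
  R1..Rk: `expr(L) * mean(expr(R1..Rk))`, a per-sample proxy for signaling
  potential (TSLP→CRLF2+IL7R, IL-33→IL1RL1+IL1RAP, IL-25→IL17RA+IL17RB).
- **Differential expression.** DESeq2-style NB Wald stage: median-of-ratios
  size factors, method-of-moments dispersions shrunk toward a mean-dispersion
  trend, per-gene NB GLM with log link, Benjamini–Hochberg adjustment; DEGs
  at `padj < 0.05` and `|log2FC| > 1` (strict).
- **Mixed models.** `score ~ Group + (1 | PatientID)` by REML with
  Satterthwaite degrees of freedom; Tukey HSD over all pairwise marginal-mean
  contrasts (studentized-range reference); Nakagawa marginal/conditional R²
  with `Rm = sign(slope) * sqrt(R2_marginal)`; and the recovery model
  `score ~ condition + baseline_ix + condition:baseline_ix + (1 | PatientID)`,
  whose interaction term tests whether the pre-treatment cytokine interaction
  score predicts the Post − Pre change.

## Worked example

Simulate a treatment-responsive cohort (6/8/9 arms, known ground truth) and
run the core inference:

```python
import mucocilia as mc
from mucocilia.mixedmodels import fit_group_lmm, tukey_contrasts, fit_recovery_lmm
from mucocilia.pipeline import _baseline_ix

cm, meta, truth = mc.simulate_cohort(mc.effect_scenario(seed=1))
expr = mc.log2p1(mc.cpm(cm))
scores = mc.compute_all_scores(expr, mc.builtin_registry())

fit = fit_group_lmm(scores["cilia_master"], meta)
print(fit.fixed_effects[["estimate", "se"]].round(3))
print(tukey_contrasts(fit).table[["level_a", "level_b", "estimate", "p_tukey", "paired"]])

baseline = _baseline_ix(scores, meta, "IL33")
rec = fit_recovery_lmm(scores["cilia_master"], meta, baseline)
print(f"beta_interaction={rec.beta_interaction:.4f} p={rec.p_interaction:.4f} Rm={rec.rm:.3f}")
```

prints

```
          estimate     se
Ctrl         7.901  0.158
nonECRS      7.787  0.137
PreECRS      6.362  0.129
PostECRS     9.292  0.129
level_a  level_b  estimate  p_tukey  paired
   Ctrl  nonECRS    0.1134   0.9476   False
   Ctrl  PreECRS    1.5386   0.0000   False
   Ctrl PostECRS   -1.3912   0.0000   False
nonECRS  PreECRS    1.4253   0.0000   False
nonECRS PostECRS   -1.5046   0.0000   False
PreECRS PostECRS   -2.9299   0.0000    True
beta_interaction=0.0085  p_interaction=0.0284  Rm=0.966
```

The cilia-master score is suppressed before treatment (PreECRS below Ctrl
by 1.54 log2 units, Tukey p < 1e-4), overshoots after treatment (PostECRS
above Ctrl), and the within-patient Pre→Post contrast is flagged `paired`.
The recovery model finds a significant positive interaction: patients with
higher baseline IL-33 interaction scores recover more (here the generator's
coupling was γ = 0.015, estimated 0.0085 from n = 9 with a noisy baseline).

The same analysis runs from the shell:

```sh
mucocilia simulate --scenario effect --seed 1 --out cohort/
mucocilia all --config run.yaml        # counts/metadata paths + options
mucocilia score|de|lmm|recover ...     # individual stages
```

`run_pipeline` writes per-score contrast tables, six DE contrast tables with
a categorized DEG grid (up = ◯, down = ▲), association and recovery JSON
summaries, Z-score matrices per gene module, and a manifest with SHA-256
digests of every output; identical inputs and config reproduce every table
byte-for-byte.

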