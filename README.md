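# selhier — kinetic modelling of the selenoprotein mRNA hierarchy

Selenoproteins incorporate selenocysteine (Sec) at an in-frame UGA codon.
During translation the ribosome pauses there, and the outcome is a
competition: either a Sec-charged tRNA binds (recoding, productive
translation) or the UGA is read as a premature termination codon, which can
commit the transcript to nonsense-mediated decay (NMD).  Because the
aminoacylated tRNA-Sec pool grows with selenium supply, this competition
couples selenium status to mRNA abundance — but with very different
sensitivity between genes (the *selenoprotein hierarchy*): some mRNAs rise
250–350% from selenium-deficient to replete conditions, others barely move,
and a few (GPX2/SPS2-like) *decrease* by ~30%.

`selhier` implements, as a tested pipeline, the modelling study behind this
picture: deterministic kinetic models of selenoprotein translation, a
synthetic-data generator emulating an 11-gene Caco-2 selenite-titration qPCR
study, multistart calibration with BIC model selection, profile-likelihood
identifiability analysis, and prediction of UPF1-knockdown responses.

## Models

All abundances are in arbitrary units, time in hours.  Per transcript the
state chain is

```
        v_txn      k_init      k_el1        k_bind·s        k_sec        k_el2
   ∅ ────────▶ M ────────▶ R0 ────────▶ R1 ──────────▶ R2 ────────▶ R3 ────────▶ M
                                         │ k_nmd (NMD, → ∅)
                                         │ k_drop (drop-off, → M;  M2/M3)
```

with background decay `d_bg` on every state and segment elongation rates
`k_el1 = r_elong / codons(start→UGA)`, `k_el2 = r_elong / codons(UGA→stop)`.
At the paused state `R1`, release-factor binding (NMD commitment, `k_nmd`)
competes with tRNA-Sec binding (`k_bind · s`, where `s` is the tRNA-Sec
level, a saturating function of selenite dose with a basal term).

* **Model 1 (M1)** — the competition alone. Steady-state total mRNA is
  provably non-decreasing in `s`: M1 can only *raise* mRNA with selenium.
* **Model 1B** — all genes coupled through one finite tRNA-Sec pool
  (`R1 + tRNA → R2`, mass action; free + bound tRNA exactly conserved).
* **Model 2 (M2)** — adds ribosome drop-off at `R1` (plain termination that
  releases an intact mRNA). Still rising-only.
* **Model 3 (M3)** — every state carries a poly(A)-tail level
  (70, 60, …, 10 a.u.); each completed translation shortens the tail one
  step, drop-off preserves it, and completion at the critical level destroys
  the transcript.  With frequent drop-off this yields an *inverse* selenium
  response — the mechanism for GPX2/SPS2-like genes.

Fitting uses the normalized steady-state dose-response,
`χ² = Σ_c [(ŷ_c − y_c)/SE_c]²`, multistart optimization (log-uniform starts,
alternating differential evolution with trust-region least squares), and
`BIC = χ² + k·ln n` for model ranking.  Identifiability is assessed by
profile likelihood with the 95% threshold `χ²_min + 3.84`.

## Worked example

```bash
python analysis/01_generate_panel_and_dataset.py --seed 1
python analysis/02_hierarchy_statistics.py
python analysis/03_fit_and_compare_models.py --n-starts 8
python analysis/04_identifiability_profiles.py
python analysis/05_predict_upf1_knockdown.py
```

Step 01 samples an 11-gene panel whose *solved* dose-response ratios land in
their hierarchy-class windows, e.g.

```
gene     class        model ratio 40/0       window NMD target
GPX1     strong_up    M1         2.824   [2.5, 3.5]       True
SELK     flat         M1         1.006 [0.95, 1.05]      False
GPX2     inverse      M3         0.725  [0.6, 0.75]       True
```

Step 02 reproduces the descriptive findings on the simulated data: GPX2 and
SPS2 contribute *negatively* to the total selenium-driven rise, and mRNA
abundance does not set the hierarchy (`Spearman rho = -0.355, p = 0.285`).
Step 03 fits M1/M2/M3 per gene and prints the BIC ranking — the rising-only
models cover nine genes while the inverse-response genes need Model 3:

```
GPX2: best M3 (chi2=4.13, BIC=10.56)
SPS2: best M3 (chi2=0.53, BIC=6.97)
genes requiring the deadenylation model: GPX2, SPS2
```

Step 04 classifies each fitted rate (flat genes leave all competition rates
practically unidentifiable; the Sec-insertion rate is a structural gauge
freedom of normalized fits), and step 05 predicts UPF1-knockdown fold
changes, largest without added selenium and fading with the dose:

```
predicted fold change at 100% UPF1 KD, no added selenium:
  GPX1      13.17x
  SEPW1      9.54x
  ...
  SELK       1.01x
```

The same pipeline is available as a CLI (`selhier all --seed 1 --out
results/run`) or via `selhier.workflow.run_full_study`, which persists every
stage (dataset, fits, comparison table, profiles, KD predictions, Markdown
summary with figures) and is bit-reproducible from one master seed.

## Layout

```
src/selhier/      library: models, synthetic data, calibration, profiles,
                  knockdown, hierarchy statistics, workflow, CLI
analysis/         numbered narrative drivers over the library
scripts/          acceptance.py (headline quantities as JSON)
tests/            pytest suite (unit, property and acceptance tests)
docs/methods.md   modelling assumptions, parameter choices, limitations
```
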