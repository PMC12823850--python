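# bbnet

Analysis pipeline for binaural-beat (BB) EEG studies: spectral band power,
coherence-based brain graphs, graph-theory network metrics, digit-span
working-memory scoring, and the group-level statistics that tie them
together — plus a synthetic-data module that makes every stage testable
against closed-form ground truth.

## The problem

Binaural beats — the perceptual beat heard when each ear receives a pure
tone of slightly different frequency — are studied as a noninvasive way to
entrain cortical oscillations and modulate working memory. A typical study
design records 14-channel 10–20 EEG at 128 Hz in three states (**Pre-BB**,
**Du-BB**, **Post-BB**: before, during and after stimulation) for three
groups receiving α- (10 Hz), β- (14 Hz) or γ-band (30 Hz) beats, together
with a digit-span test before and after stimulation. `bbnet` implements the
full analysis such a study needs:

1. **Preprocessing** — detrending, 5th-order Butterworth band-pass
   (1–45 Hz, zero-phase by default), amplitude-threshold artifact rejection
   on 2-s epochs with a 10% rejection-rate warning.
2. **Spectral analysis** — Welch PSD (4-s Hann window, 2-s overlap,
   512-point FFT → 0.25 Hz bins at 128 Hz); relative power in
   θ (4–8), α (8–12), β (13–29) and γ (30–45 Hz), each normalized by total
   1–45 Hz power; magnitude-squared coherence

   C_ab(f) = |P_ab(f)|² / (P_aa(f) · P_bb(f)) ∈ [0, 1],

   averaged over each band's bins into a 14 × 14 coherence matrix.
3. **Network metrics** — edges where coherence exceeds 0.30, then per-node
   clustering coefficient CC_i = 2t_i / (k_i(k_i−1)), local efficiency
   (mean inverse shortest-path length within a node's neighborhood
   subgraph), in/out-degree, in/out-closeness (1/Σ path lengths over the
   reachable set) and unnormalized betweenness Σ σ_st(i)/σ_st.
4. **Behavior** — digit-span rounds of 4–8 digits, percent-correct round
   scores, the inclusive 60% advancement rule, session score and time.
5. **Statistics** — paired t-tests for state contrasts (Pre vs Du, Pre vs
   Post) with Benjamini–Hochberg FDR per test family; Cohen's d on the
   paired differences (>0.8 large, 0.4–0.8 medium, <0.4 small); Pearson
   power–behavior correlation maps; two-way group × state ANOVA with η²;
   a noncentral-t sample-size utility for paired designs.

The synthetic-data module generates all of this with known truth:
band-limited sources with an exactly flat in-band spectrum, pink-noise
background, controllable shared-variance fractions (hence analytic
coherence), group × state effects, digit-span sessions, and the dichotic
pure-tone stimulus itself.

## Worked example

Recover a known coherence, then a planted network effect:

```python
import numpy as np
from bbnet.synthetic_data import (StudyConfig, EffectSpec,
                                  generate_common_source_pair,
                                  estimate_pair_msc, theoretical_pair_msc)
from bbnet.pipeline import run_simulated_study, PipelineConfig

# Two channels driven by one 6 Hz source at per-bin SNR 1 on each channel:
# closed-form magnitude-squared coherence is 1·1/(2·2) = 0.25.
rec = generate_common_source_pair(f0=6.0, snr_a=1.0, snr_b=1.0,
                                  duration=300.0, seed=0)
print("closed-form MSC:", theoretical_pair_msc(1.0, 1.0))
print("Welch estimate :", round(estimate_pair_msc(rec, f0=6.0), 3))

# A two-group study in which only group A gains theta-band coherence
# after stimulation; the pipeline should flag A and clear B.
cfg = StudyConfig(n_per_group=20, groups=("A", "B"),
                  states=("Pre-BB", "Post-BB"), duration=120.0,
                  effect=EffectSpec("theta", coherence_delta=0.20),
                  effect_group="A", seed=7)
report = run_simulated_study(cfg, PipelineConfig(bands=("theta",)),
                             with_behavior=False)
g = report.contrasts_global
print(g[g.metric == "CC"][["group", "metric", "t", "p_adjusted",
                           "reject", "d", "size_label"]].round(4))
```

Output:

```
closed-form MSC: 0.25
Welch estimate : 0.241
group metric       t  p_adjusted  reject       d size_label
    A     CC 10.7360      0.0000    True  2.4007      large
    B     CC -0.1756      0.9648   False -0.0393      small
```

The Welch estimate lands within sampling error of the analytic coherence,
and the Pre-vs-Post contrast on global θ clustering coefficient is
FDR-significant with a large effect only in the group that actually received
the planted coherence increase.

The same analysis runs from the shell on a manifest-described study
(EDF or headered-CSV EEG plus a digit-span TSV):

```sh
bbnet simulate --config sim.json --out study/ --seed 1
bbnet run --manifest study/manifest.json --out report/
```

`report/` then holds long-format TSV tables (band power, node metrics,
FDR-corrected contrasts, correlation maps, ANOVA) and a JSON provenance
block (config hash, seed, versions).

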