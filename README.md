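# digitizer-lab

Quantitative characterization and predictive modeling of **recombinase-based
digitizer circuits** — gene circuits that convert a graded (analog) input into
a near-Boolean (digital) output by driving a site-specific recombinase (Flp)
that irreversibly flips a frt-STOP-frt reporter, with shRNA-mediated
titration of the recombinase transcript suppressing leaky activation.

The package is for synthetic biologists who characterize such circuits by
flow cytometry and want (i) standardized signal-quality metrics on
single-cell populations and (ii) a per-cell model that predicts how circuit
performance moves as the recombinase:shRNA component ratio, inducer level, or
input signal changes.

## What it computes

For an induced/uninduced pair of cell populations (calibrated MEFL
fluorescence, one row per cell):

- **Fold change** `FC = geomean(ON) / geomean(OFF)` — amplitude only.
- **AUC** — area under the empirical ROC curve built by sweeping a threshold
  over the combined fluorescence range (0.5 = indistinguishable, 1 = fully
  distinguishable); equals the tie-corrected Mann–Whitney statistic.
- **Extended SNR** in log10-fluorescence space,

  `SNR = 10 log10( Δμ² / (σ̄² + (P_Dud + P_Leaky) · Δμ²) )  [dB]`

  where `Δμ` is the distance between the ON and OFF modes of a two-component
  Gaussian mixture fit, `σ̄` the mean mode SD, and the *fail power* charges
  the misclassified subpopulations — `P_Dud` (OFF when it should be ON) and
  `P_Leaky` (ON when it should be OFF) — at full signal amplitude.
- **Δ-metrics** (output minus input across a circuit stage); positive ΔSNR
  means the circuit amplified the signal.

The per-cell model couples a transient-transfection platform (lognormal
plasmid uptake partitioned among co-delivered plasmids, Gaussian onset
delays, measurement noise) to the reduced circuit kinetics

```
m   = copies_flp · (a_f + (b_f − a_f) · Hill(dox))      inducible transcription
s   = topology-dependent shRNA flux
φ   = ½[(m − s − K_d) + sqrt((m − s − K_d)² + 4 K_d m)]  titration (QSS)
dF/dt = φ − δ_F F                                        recombinase activity
dr/dt = c F^h (1 − r)                                    recombined fraction
```

with stable fluorescent proteins accumulating from their drivers (OFP from
recombined reporter copies, IFP from the inducible promoter, CFP from a
constitutive marker used to gate the top 30% of transfected cells).
Three topologies are built in: no-shRNA, constant-shRNA and
feedforward-shRNA (inducer simultaneously activates the recombinase and
represses the shRNA). On top of the model sit dose-response fitting with
identifiability diagnostics (multistart landscapes, the b_f–K_d ridge and
the dimensionless "effective Kd" `eKd = K_d / (b_f · copies)`), ratio-grid
metric heatmaps, and transduction of measured input distributions into
predicted output distributions.

## Worked example

Simulate a balanced constant-shRNA digitizer (35 ng Flp : 5 ng shRNA),
induced with 225 nM doxycycline versus uninduced, gate to the top 30% of
CFP-expressing cells, and score the output channel:

```python
import digitizer_lab as dl
from digitizer_lab import Topology

p, plat, up = dl.ModelParams(), dl.PlatformParams(), dl.UptakeParams()
doses = dl.preset_doses(Topology.CONSTANT, "balanced")

induced = dl.simulate_population(5000, doses, dox=225.0,
                                 topology=Topology.CONSTANT,
                                 p=p, plat=plat, uptake=up, t=48.0, seed=1)
uninduced = dl.simulate_population(5000, doses, dox=0.0,
                                   topology=Topology.CONSTANT,
                                   p=p, plat=plat, uptake=up, t=48.0, seed=2)

gate = lambda pop: dl.gate_top_fraction(dl.filter_valid_events(pop), "cfp", 0.30)
ms = dl.metric_set(gate(induced), gate(uninduced), channel="ofp", seed=0)
print(f"FC  = {ms.fc:.1f}")
print(f"AUC = {ms.auc:.3f}")
print(f"SNR = {ms.snr.snr_db:.2f} dB "
      f"(delta_mu={ms.snr.delta_mu:.2f}, sigma_bar={ms.snr.sigma_bar:.2f}, "
      f"P_dud={ms.snr.p_dud:.2f}, P_leaky={ms.snr.p_leaky:.2f})")
```

prints

```
FC  = 680.8
AUC = 1.000
SNR = 2.91 dB (delta_mu=2.98, sigma_bar=0.31, P_dud=0.47, P_leaky=0.03)
```

i.e. induction raises the output geometric mean ~680-fold, the ON and OFF
populations are perfectly separable by threshold (AUC 1.0), and the SNR
decomposition shows a ~3 decade amplitude against a ~0.3 decade spread, with
the mixture fit charging part of the broad induced mode as a fail term —
exactly the fitting sensitivity that makes SNR the noisiest of the three
metrics.

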