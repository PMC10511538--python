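# meaburst

Analysis of spontaneous electrophysiological activity in dissociated
cortical networks on 60-electrode micro-electrode arrays (MEAs), aimed at
cultures grown either as a single uniform network (1N) or as four
interconnected sub-populations at the corners of the active area (4N).
The package is for electrophysiologists and modellers who want a tested,
scriptable version of the standard MEA analysis chain plus the
propagation-sequence statistics specific to modular cultures.

## What it computes

Given raw 10 kHz voltage traces or per-electrode spike ("peak") trains:

1. **Spike detection** — differential (peak-to-peak) threshold at 8× the
   noise SD with 2 ms spike lifetime and 1 ms refractory period, timed at
   the dominant extremum.
2. **Burst detection** — string method: runs of ≥5 spikes with every
   inter-spike interval ≤100 ms.
3. **Network bursts (NBs)** — burst events chained under a self-adaptive
   inter-burst-event-interval threshold; chains covering ≥20% of the
   recording electrodes become NBs.
4. **Firing statistics** — MFR, MBR, burst duration, IBI/SD_IBI/CV_IBI per
   electrode; NB rate, NB duration and inter-NB intervals per recording;
   electrodes below 0.1 spikes/s are discarded.
5. **Activation sequences** — the instantaneous firing rate
   (IFR, Gaussian kernel of width Δt = 100 ms) of each 13-electrode
   cluster; cluster *i* activates in NB *k* at

       t_start(i,k) = argmax_{t ∈ [t_start(k), t_end(k)]} IFR_i(t)

   and clusters ordered by activation time form the NB's activation
   sequence.
6. **Sequence statistics** — circular-path (CP) vs diagonal-path (DP)
   classification on the 2×2 cluster grid (P(CP) = 1/3 under random
   propagation), initiator frequency classes, Shannon diversity
   H = −Σ pᵢ ln pᵢ and equitability E = H/ln N against seeded Monte Carlo
   nulls, and the weighted occurrence W = L·O_L of series of L identical
   consecutive sequences.
7. **Dose–response** — basal-normalised MFR per concentration phase fitted
   with the four-parameter Hill curve
   `MFR(c) = top + (bottom − top)/(1 + 10^{HC(log IC50 − log c)})`
   to estimate IC50.

A synthetic-data module generates recordings with known ground truth
(rhythmic NBs, dominant initiators, adjacency-biased propagation, repeated
sequences, Hill-curve dose-response data) so every stage can be scored by
recovery.

## Worked example

```python
import meaburst as mb

layout = mb.build_4q_layout()                       # 4×13 + 7 electrodes
params = mb.SimulationParams(seed=11, duration=120.0)
spikes, truth = mb.simulate_recording(params, layout)
report = mb.run_pipeline(spikes, layout)

m = report["metrics"]
print(m["n_network_bursts"], len(truth))            # 55 55
print(round(m["per_electrode_median"]["mfr"], 2))   # 6.77 spikes/s
print(round(m["recording"]["nb_per_min"], 1))       # 27.5 NBs/min
s = report["stats"]
print(s["paths"])   # {'n_sequences_len3plus': 53, 'observed_cp': 44,
                    #  'expected_cp': 17.666666666666668}
print(round(s["diversity"]["E"], 3),
      round(s["diversity"]["E_expected"], 3))       # 0.855 0.961
```

All 55 simulated network bursts are detected.  The median electrode fires
at 6.77 spikes/s and NBs recur at 27.5/min.  Of the 53 sequences recruiting
at least 3 clusters, 44 follow circular paths versus 17.7 expected under
random propagation — the simulation's adjacency bias (0.75) is clearly
recovered — and the observed sequence diversity (E = 0.855) sits below its
length-matched Monte Carlo null (0.961), reflecting the dominant,
repetitive sequence types the generator plants.

The same pipeline runs from the shell:

```
meaburst simulate --seed 11 --duration 120 --out-dir sim/
meaburst run sim/spikes.tsv --out-dir out/        # writes report.json + TSVs
meaburst dose-response basal.tsv c1.tsv ... --concentrations "[0,0.3,1,3,10,30]"
```

Spike trains are exchanged as TSV (`electrode_id<TAB>spike_time_s`) with a
JSON sidecar carrying sampling rate, duration, assembly type and the
electrode→cluster map, so externally recorded peak trains can be analysed
unchanged.

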