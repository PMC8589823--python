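# surgact

Unsupervised surgical activity recognition for simulator trajectories,
combining three ingredients:

1. **Self-supervised progress regression.** A CNN-encoder → recurrent-
   decoder → MLP model is trained on video alone to predict the remaining
   surgery progress `y_t = 1 − t/τ` (sigmoid output, MAE loss). No manual
   labels are needed, yet solving the task forces the network to notice
   milestone events.
2. **Representation mining.** Internal activations — in particular GRU
   update-gate traces — are segmented with PELT (kernelized mean-change
   cost, penalty calibrated to ~10 change points per trajectory), units are
   ranked by their standardized mean shift at known events, and the best
   unit is discretized into a latched binary "diagnosis has ended"
   observable.
3. **Explicit-duration HSMM decoding.** Activities form the hidden states
   of a hidden semi-Markov model with categorical transitions (zero
   diagonal), shifted negative-binomial dwell times, and per-channel
   categorical emissions estimated by Dirichlet-MAP from a single annotated
   sequence. Exact explicit-duration Viterbi decodes the most probable
   activity segmentation; adding the mined indicator as one extra
   observable channel (the *UpdateGateHSMM*) is compared against sensors
   alone (the *SensorHSMM*) by per-activity mean IoU.

The intended users are surgical-data-science researchers who want a
fully testable, desk-scale implementation of this pipeline. Real
simulator recordings are rarely shareable, so the package ships a
synthetic-data generator that emulates their structure (six-activity task
graph of a hysteroscopic myomectomy, negative-binomial durations,
deliberately ambiguous sensor channels, toy video with a progress drift
and a "tool appears" cue at the end of the diagnosis); see
`docs/methods.md` for the model and the study conditions in detail.

## Worked example

```python
from surgact import GeneratorConfig, PipelineConfig, run_benchmark

cfg = PipelineConfig(generator=GeneratorConfig(n_trajectories=19, seed=0), seed=0)
res = run_benchmark(cfg)          # planted indicator channel
print(res.table.to_string(index=False))
```

prints

```
         model  frame_accuracy  miou:diagnosis  std:diagnosis  miou:handle chips  std:handle chips
    SensorHSMM        0.831815        0.837489       0.108451           0.681492          0.425055
UpdateGateHSMM        0.898535        1.000000       0.000000           0.721174          0.389549
```

One of the 19 simulated trials serves as the single annotated sequence;
the other 18 are decoded by both models. The sensor channels of
*diagnosis*, *position hysteroscope* and *handle chips* are identical by
construction, so the sensor-only model places the diagnosis boundary by
duration priors alone (mIoU 0.84) and sometimes lets ambiguous activities
swallow the final chip-handling segment (mIoU 0.68, large spread). The
model that also observes the diagnosis-ended indicator pins the boundary
exactly (mIoU 1.00), starts every decoding with a diagnosis, and recovers
chip handling more reliably (0.72) — the qualitative comparison the
pipeline exists to demonstrate.

The learned-feature pathway (train the progress regressor, extract
update-gate traces, build the indicator from the top unit) is
`run_benchmark(cfg, use_learned_indicator=True)`, or step by step from the
shell:

```bash
surgact run-all --seed 0 --out pipeline_out          # full chain, ~1 min
surgact run-all --planted-indicator --seed 0 --out fast_out
surgact run-stage simulate --seed 0 --out pipeline_out   # single stages
```

Each stage writes its artifacts plus a provenance record (config hash,
seed, input hashes) and is a no-op when re-run unchanged.

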