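# skelref

Constraint-based refinement of skeleton streams from depth-camera SDKs
(Kinect v2, Nuitrack, and compatible). Given per-frame 3-D joint estimates
with tracking states, `skelref`:

1. estimates stable per-bone **reference lengths** from an initialization
   window, pooling mirrored left/right bones (angle-confidence weighting
   followed by iterated deviation reweighting);
2. detects **untrusted joints** per frame (untracked state, bone-length
   deviation, implausible motion);
3. predicts joint positions with a combined **forward/backward second-order
   finite-difference** scheme (three frames on each side, hence a fixed
   0.1 s latency at 30 Hz) and scores consecutive prediction disagreements
   per joint (k-score, outlier flagging, 4-frame recovery limit);
4. refines each frame by a quasi-Newton **energy minimization**
   `E = λ1·E1 + λ2·E2` that anchors joints to observations/predictions (E1)
   and enforces bone-length constancy and left/right symmetry through shared
   per-class reference lengths (E2). Defaults: λ1 = 0.2, λ2 = 8.25, σ = 3.

A first-class synthetic-motion module generates ground-truth articulated
motion with exactly constant bone lengths and corrupts it with an SDK-like
noise model (angle-dependent, temporally correlated jitter; outlier runs;
tracking-state dropouts; left/right flips), so the whole pipeline is testable
offline.

## Data format

Sequences are JSON Lines, one frame per line:

```json
{"t": 0.033, "joints": [{"name": "Head", "p": [0.01, 0.80, 2.49], "state": "tracked"}, ...]}
```

States are `tracked | inferred | notTracked`. Positions are meters in a
right-handed camera frame, +Z along the optical axis. Two dialects are
built in — `kinect21` (Kinect v2 joint set without hand tips and thumbs) and
`nuitrack20` — and custom dialects load from a JSON file with `joints`,
`edges`, and `symmetry_pairs`.

## CLI

```sh
# synthesize a 600-frame sequence plus a corrupted copy and corruption log
skelref simulate --dialect kinect21 --frames 600 --seed 7 \
    --outlier-rate 0.02 --out truth.jsonl --noisy noisy.jsonl --log corruptions.csv

# refine it (per-frame energy log and trust report optional)
skelref refine --input noisy.jsonl --dialect kinect21 --output refined.jsonl \
    --lambda1 0.2 --lambda2 8.25 --theta 0.10 --theta-p 0.08 --init-frames 100 \
    --energy-log energy.csv --trust-log trust.csv

# before/after diagnostics (bone-length variance, prediction series, symmetry)
skelref evaluate --input noisy.jsonl --refined refined.jsonl \
    --truth truth.jsonl --log corruptions.csv --report report.json

# spreadsheet export
skelref export-csv --input refined.jsonl --out refined.csv
```

`refine` also accepts a YAML/JSON config file (`--config`) with the same
keys, and `--batch` for non-causal offline processing.

### A note on the anchor weights

The per-joint blend between observation and prediction is
`u = exp(−k²/2σ²)`, `w = 1 − u` with `k` the consecutive-disagreement count.
By default the *observation* keeps the weight `u` (clean joints stay on their
observations; joints flagged untracked or length-deviant are replaced by
their predictions). The opposite assignment — clean joints anchored to the
prediction — closes an extrapolation feedback loop whose characteristic
roots lie on the unit circle and lets noise excite sustained oscillations;
it remains available via `--no-swap-uw` / `EnergyConfig(swap_uw=False)`.

## Layout

| module | contents |
| --- | --- |
| `skelref.skeleton` | dialects, poses, tracking states, JSONL/CSV I/O |
| `skelref.reference` | reference bone-length estimation |
| `skelref.prediction` | forward/backward prediction, trust rules, k-scores |
| `skelref.refinement` | per-frame energy minimization, streaming pipeline |
| `skelref.synthetic` | ground-truth generator and corruption model |
| `skelref.evaluation` | variance / prediction-distance / symmetry metrics |
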