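# lagte — lagged transfer entropy for cardiorespiratory coupling

`lagte` measures **directed, time-scale-resolved information transfer**
between two physiological time series.  It was built for neonatal
cardiorespiratory analysis — the beat-indexed heart-period series (RR,
successive R-wave intervals) and the respiration amplitude resampled at
each heartbeat (RESP) — where the two control pathways operate on
different time scales: a fast, quickly vanishing respiration→RR route
(respiratory sinus arrhythmia, vagally mediated) and a slower, more
sustained RR→respiration route.  Plain transfer entropy compresses all of
that into one number; `lagte` resolves it across lags.

## The statistic

For stationary processes X (source) and Y (target), transfer entropy is
the information X's past carries about Y's present beyond Y's own past:

    TE_{X→Y} = H(y_n | y⁻) − H(y_n | x⁻, y⁻)   [nats]

The conditioning sets are built by **non-uniform embedding**: from the
candidate pool Ω = {X_{n−1},…,X_{n−10}, Y_{n−1},…,Y_{n−10}} a greedy
procedure accepts, round by round, the candidate with the largest
conditional-mutual-information gain, gated by a selection-corrected
permutation test; the first failure stops.  With the selected vector
V_k = [V_k^X, V_k^Y],

    TE_{X→Y} = H(y_n, V_k^Y) − H(V_k^Y) − H(y_n, V_k) + H(V_k),

estimated by nearest-neighbor statistics (Chebyshev metric, k = 10, all
four terms sharing the joint-space k-th-neighbor radius so their biases
cancel).  The **lagged** variant shifts the driven series back by
τ = 0…15 samples and re-runs everything per lag and direction, tracing
TE as a function of the interaction delay.  Significance per value comes
from 100 time-shift surrogates (source circularly shifted by 1–20
samples, TE recomputed under the observed conditioning vector,
95th-percentile threshold).  Scientific details and calibration notes:
`docs/methods.md`.

## Worked example

```python
import lagte

# coupled autoregressive pair: X is an AR(2) oscillator driving Y at
# delays 1, 2 and 5 (coefficients 0.5); Y feeds back weakly (0.07)
pair = lagte.simulate_coupled_ar(seed=1)          # N = 300

est, surr = lagte.surrogate_test(pair, "x->y", lag=0, seed=1)
print(f"TE x->y at lag 0: {est.value:.3f} nats")
print("selected candidates:",
      [(c.process, c.delay) for c in est.embedding.selected])
print(f"surrogate 95th percentile: {surr.threshold:.3f}")
print(f"significant: {surr.significant}")

rev = lagte.transfer_entropy(pair, "y->x", lag=0, seed=1)
print(f"TE y->x at lag 0: {rev.value:.3f} nats")
```

prints

```
TE x->y at lag 0: 0.704 nats
selected candidates: [('source', 2), ('target', 3), ('source', 1), ('source', 5)]
surrogate 95th percentile: 0.550
significant: True
TE y->x at lag 0: 0.034 nats
```

The embedding recovers the designed source delays (1, 2, 5); the forward
TE far exceeds its surrogate threshold while the reverse direction is
near zero.  `lagte.lag_profile(pair, seed=1)` computes the full 16-lag ×
2-direction grid, and `lagte.analysis.validation_experiment(...)`
replicates the whole study with its lag ANOVA and Bonferroni contrasts.

The same machinery runs on physiological records from the command line:

```bash
lagte simulate --kind physio --seed 1 --out rec/      # or your own files
lagte preprocess --peaks rec/rpeaks.txt --resp rec/resp.csv \
      --states rec/sleep_states.csv --out segments/
lagte profile --input segments/segment-0000.csv --seed 1 --out profile.csv
```

(`preprocess` applies the artifact rules — RR outside 0.3–0.667 s or
changing > 10 % against the previous accepted beat, breathing cycles
outside 0.5–2.5 s or changing > 40 % — and emits z-normalized 300-beat
segment pairs per sleep state.)

## Layout

| module | contents |
|---|---|
| `lagte.estimators` | k-NN entropy, shared-radius CMI, linear-Gaussian TE oracle |
| `lagte.embedding` | candidate set, gated greedy selection, selection frequencies |
| `lagte.transfer_entropy` | lag alignment, TE, time-shift surrogates, lag profiles |
| `lagte.simulate` | coupled-AR validation system, null pairs, synthetic physiology |
| `lagte.preprocess` | RR/RESP construction, artifact rules, segmentation, breathing rate |
| `lagte.analysis` | validation ANOVA, cohort-style ANCOVA, Sobel mediation |
| `lagte.config` / `lagte.io` / `lagte.cli` | configuration, text formats, CLI |
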