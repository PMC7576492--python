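# emgforce

Channel selection for high-density surface EMG (HD-sEMG) force estimation.

Estimating the force a muscle produces from its surface electromyogram is a
core problem in prosthetics control, rehabilitation and ergonomics.
High-density linear electrode arrays (here: three 8-contact arrays over the
long and short heads of the biceps brachii and the brachioradialis, sampled
at 2048 Hz during isometric elbow flexion) improve accuracy but produce
highly redundant, correlated channels.  `emgforce` implements
redundancy-aware channel selection together with the full estimation
pipeline, so that a small subset of channels can match — or beat — the
full array.

## Methods at a glance

**Power-correlation ratio (PCR).**  For channel *c* of muscle *m*, with
band power `PSD_{c,m}` (10–500 Hz Welch estimate) normalized per muscle,

    PSD̄_{c,m} = PSD_{c,m} / max_c(PSD_{c,m}),
    m_c  = (1/(N−1)) Σ_{r≠c} |r_{c,r}|        (mean |Pearson r|)
    PCR_c = PSD̄_{c,m} / m_c .

Channels with much spectral power and little correlation with their
neighbours rank highest; the top *k* per muscle are kept.

**PCA selection.**  Channels are alternatively ranked by their absolute
loadings on the leading principal components of either the linear-envelope
time courses (per muscle) or the FFT magnitude spectra of all 21
differential channels jointly (phase discarded).  With more than one
retained component, votes are weighted by explained-variance fraction.

**Fast orthogonal search (FOS).**  Force is modelled as a sparse expansion

    y(n) = Σ_{m=1..M} a_m p_m(n) + e(n)

over a pool of candidate basis functions built from the normalized EMG
linear envelopes LE and the elbow angle θ: constant, θ, LE, sin θ·LE,
cos θ·LE, cross-muscle products sin θ·LE_i·LE_j and cos θ·LE_i·LE_j, and
quadratic / saturating-square / square-root / logistic transforms of each
LE.  Greedy Gram–Schmidt selection adds, at each step, the candidate with
the greatest reduction of the residual mean squared error, and stops after
9 terms.  Accuracy is reported as

    %NMSE = 100 · Σ(F_meas − F_est)² / Σ F_meas² ,

evaluated on held-out trials (train on trial 1, test on trials 2–3 of each
subject × angle × posture condition).

Because no public accession exists for such recordings, the package ships a
seeded synthetic cohort generator with planted ground truth (three
informative + four redundant differential channels per muscle, a known
force-to-envelope law, and per-trial gain instability on the redundant
channels); every stage of the pipeline is tested against it.

## Worked example

```python
from emgforce import (preprocess_recording, select_pcr, pool_from_envelopes,
                      fos_fit, run_protocol)
from emgforce.synthetic import SyntheticSpec, generate_trial

spec = SyntheticSpec(seed=42)
trials = [generate_trial(spec, subject=1, angle=90.0, posture="neutral",
                         trial_idx=j) for j in (1, 2, 3)]

env = preprocess_recording(trials[0])      # differential, filtered, normalized
sel = select_pcr(env, k=3)                 # 3 of 7 channels per muscle
print(sel.selected)

pool, y = pool_from_envelopes(env, sel)    # candidate basis + target force
print(fos_fit(pool, y).summary())

print(run_protocol(trials, method="pcr", k=3)["nmse_pct"])
print(run_protocol(trials, method="all")["nmse_pct"])
```

prints (abridged):

```
{'biceps_long': [0, 1, 2], 'biceps_short': [0, 2, 1], 'brachioradialis': [0, 1, 2]}
Fast orthogonal search results
  terms selected : 9 (pool of 83)
  observations   : 18432
  training MSE   : 3.7277
 term                       basis      coef  mse_reduction
    4           LE[biceps_long:2] 18.729405    7652.647526
    2           LE[biceps_long:0] 20.277027      12.550040
   73 sqrt(LE[brachioradialis:2]) 39.735525       3.729466
 ...
0.0549
0.1016
```

The PCR index recovers the three planted informative channels of every
muscle; the force model built from those 9 channels (of 21) achieves a test
%NMSE of 0.055 versus 0.102 for the full 21-channel model — the redundant
channels' unstable gains hurt generalization, so discarding them halves
the error while cutting dimensionality by 57 %.

The same pipeline is available from the shell:

```sh
emgforce simulate --spec spec.yaml --out cohort/
emgforce preprocess --in cohort/sub01_ang090_neutral_t1.h5 --out env.h5
emgforce select --method pcr --k 3 --in env.h5 --out selection.json
emgforce fit --env env.h5 --selection selection.json --out model.json
emgforce evaluate --cohort cohort/ --methods pcr --k 3 --out report.csv
```

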