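# rqadetect

Automatic seizure detection from single-channel EEG by recurrence
quantification analysis (RQA), mutual-information feature selection and a
neural-network classifier.

Epileptic seizures show up in the EEG as an abrupt switch to rhythmic,
high-amplitude, synchronized activity — a change in the *dynamics* of the
signal rather than in any single spectral band.  `rqadetect` characterizes
each short window (1.475 s) of EEG by how its reconstructed phase-space
trajectory recurs: the scalar series u_1…u_N is delay-embedded as
x_t = (u_t, u_{t+τ}, …, u_{t+(m−1)τ}), the recurrence plot
R_ij = Θ(ε − ‖x_i − x_j‖) is thresholded at a fixed recurrence rate, and
twelve complexity measures are read off its point density, diagonal and
vertical line structures, recurrence times, and the associated recurrence
network:

> RR, DET, L, Lmax, ENTR, LAM, TT, Vmax, T1, T2, RPDE, Trans

Deterministic, rhythmic (ictal) windows give long diagonals (high DET,
Lmax) and a concentrated recurrence-period density (low RPDE); irregular
background activity gives the opposite.  A minimal-redundancy
maximal-relevance (mRMR) step, J(f) = I(f;c) − β Σ_{s∈S} I(f;s), picks the
five most informative, least redundant measures, which feed a two-layer
feed-forward network (20 hidden units) evaluated by twenty repeats of a
random 60/5/35 train/validation/test split over five clinical
classification cases (healthy vs interictal vs ictal and four two/three
class variants of the five-subset A–E recording layout).

A seeded synthetic-data module generates a five-subset surrogate dataset
(irregular broadband "healthy" activity, colored noise with spike
transients for "interictal", a quasi-periodic 3.5 Hz oscillation for
"ictal") so the entire pipeline runs and is tested with no external data;
a local directory of real recordings in the common one-integer-per-line
ASCII format can be substituted.

See `docs/methods.md` for definitions, conventions and limitations.

## Worked example

```python
from rqadetect import (CASES, EvalProtocol, SurrogateSpec, features_table,
                       gen_surrogate_subsets)
from rqadetect.pipeline import (MRMRSettings, PipelineConfig,
                                dataset_from_table, evaluate_case)

subsets = gen_surrogate_subsets(SurrogateSpec(n_segments=10, seed=0))
table = features_table(subsets)          # 800 blocks x 12 measures
ds = dataset_from_table(table, CASES["III"])   # healthy (A) vs ictal (E)

cfg = PipelineConfig(mrmr=MRMRSettings(k=5, scope="train"),
                     eval=EvalProtocol(n_repeats=5, seed=1))
report = evaluate_case(ds, "III", cfg)
print(f"{report.mean:.2f}% +/- {report.sd:.2f}%")
```

prints

```
100.00% +/- 0.00%
```

the mean and standard deviation of the test accuracy over five repeats,
with mRMR rerun inside each training split (no selection leakage).  The
`examples/` directory has one short script per capability — recurrence
measures of known dynamics, delay/dimension estimation, surrogate feature
tables, selection + classification — each printing the numbers it
computes and what they mean.

There is also a thin CLI over the same functions:

```bash
rqadetect generate --out data/ --n-segments 100 --seed 0
rqadetect features --data data/ --out features.csv
rqadetect select   --features features.csv --case I --k 5 --out sel.csv
rqadetect classify --features features.csv --case I --k 5 --out report.json
rqadetect run      --config pipeline.yaml
rqadetect plot-rp  --segment data/E/E000.txt --out rp.png
```

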