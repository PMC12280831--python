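# wellrec

A therapy-session recommender driven by pre/post well-being deltas, together
with the evaluation harness needed to judge whether its recommendations beat
a user's own choices — and a seeded synthetic cohort generator so the whole
pipeline can be validated end to end without access to any real patient data.

## The problem

Digital mental-health platforms offer large libraries of on-demand audio
psychotherapy sessions (mindfulness, CBT, music therapy, …).  Around each
session, three well-being measures can be collected:

* **OSL** — objective stress level in [0, 1] from facial biomarkers (arrives
  here as a number; estimating it is out of scope), lower is better;
* **SRS** — a 0–10 self-reported stress slider (faces at the quadrant
  midpoints 1.25 / 3.75 / 6.25 / 8.75), lower is better;
* **SRM** — self-reported mood in [0, 1], scored implicitly from the words a
  user taps on a 32-word mood board (each word scores −2…+2 by quadrant; a
  selection of k words with sentiment sum σ maps to (σ + 2k)/(4k)).

The recommender is deliberately *noncollaborative*: it uses only one user's
own history.  Its single assumption is that sessions that helped a user
before will keep helping that user.  For a training window of k sessions:

1. **ΔWM = WM_post − WM_pre** per session; oriented so larger = more
   beneficial (b = −ΔWM for stress measures, +ΔWM for mood).
2. Every session carries a payload of 3 mood words (from 36) and 3 intent
   words (from 24).  Each payload word of a training session gets a **raw
   word score** R equal to that session's oriented benefit.
3. **S = R × A × B × C**, where the guide scaler
   **A = 1 + W·(ḡ − ḡ_min)/(ḡ_max − ḡ_min)** up-weights words delivered by
   guides (narrators) that were historically efficacious *for this user*
   (W = 1 by default; B = C = 1).
4. **T = ΣS** per word; the 3 mood + 3 intent words with greatest T are the
   user's profile.
5. Every library session is ranked by its association with those six words
   (sum of max(T, 0) over shared payload words); the top 3 are the
   **algorithmically selected (AS)** sessions.

The harness evaluates AS sessions against the **user-selected (US)**
baseline (all sessions the user actually completed after the training
window): per-k efficacy differentials and their linear trend, a
within-subject ANOVA at k = 15 (for two conditions F = t² of the paired t),
10-fold 80%-subsample cross-validation, Pearson correlations among the three
deltas, and observed-vs-chance overlap of AS sessions with the user's own
choices under an exact hypergeometric null.

## Worked example

```bash
wellrec simulate --seed 7 --out demo
wellrec correlate --records demo/records.csv --library demo/library.csv --out demo/corr.csv
wellrec recommend --records demo/records.csv --library demo/library.csv \
    --measure osl --user u001 --k 15 --out demo/rec.json
```

The simulated cohort (67 users × 40 sessions, the shape of the real study)
reproduces the study's measurement structure — the two self-report deltas
correlate with each other while the objective delta stays independent:

```
       osl    srs    srm
osl  1.000  0.028 -0.052
srs  0.028  1.000 -0.497
srm -0.052 -0.497  1.000
```

(ΔSRS and ΔSRM correlate at −0.50: stress drops as mood rises within a
sitting; ΔOSL correlates with neither.)  For user `u001`, trained on their
first 15 sessions with objective stress data:

```
top mood  : ['calm', 'gloomy', 'anxious']
top intent: ['acceptance', 'resilience', 'compassion']
AS sessions: ['s031', 's058', 's027']
best scores: [('s031', 5.509), ('s058', 4.328), ('s027', 2.793)]
```

`s031` carries the word profile with the strongest accumulated evidence of
benefit for this user; the association score is the summed positive total
word score over payload words shared with the user's top six.

`wellrec run --seed 7 --out results/` executes the whole pipeline
(simulate → recommend → evaluate → overlap → correlate) and writes per-k
CSV tables, a stats JSON, and a checksum manifest; add `--plots` for PNG
figures of the efficacy curves and overlap bars.

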