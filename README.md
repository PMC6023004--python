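# emotionwear

Emotion recognition from wearable biosignals — photoplethysmography (PPG),
electrodermal activity (EDA) and fingertip skin temperature (SKT) — for
researchers in psychophysiology and affective computing who need a
transparent, fully testable alternative to black-box classifiers.

The pipeline implements the classical autonomic-specificity approach:

1. **Feature extraction.** Beats are detected in the raw PPG; interbeat
   intervals (IBI) are cubically interpolated onto the 100 Hz sample grid and
   summarized by centered rolling windows: HR = 60000/IBI(ms), SDNN (rolling
   std of IBI), SDSD and RMSSD (std and RMS of successive IBI differences),
   and LF/HF band integrals of the windowed IBI spectrum over 0.04–0.15 Hz
   and 0.15–0.40 Hz. EDA and SKT are zero-phase low-passed (2nd-order
   Butterworth, normalized cutoff 0.005) and summarized by rolling mean/std.
2. **Orienting-response (OR) validation.** An emotion is considered
   *elicited* only when a skin-conductance onset co-occurs with cardiac
   deceleration: the least-squares HR slope over the 2-s window starting 1 s
   before the EDA onset must be sufficiently negative. A positive slope of
   the same magnitude flags a *defensive* (aversive) response instead.
3. **ANS-specificity classification.** The 60-s mean levels of HR, EDA and
   SKT after each valid OR are compared against a relax-period baseline;
   the per-channel direction triple (↑/0/↓, with a deadband of 0.5 baseline
   standard deviations) is matched against per-emotion sign patterns:
   joy (+,+,+), disgust (+,+,−), fear (+,+,−). Fear/disgust share a
   signature and are reported as an explicit tie.
4. **Response–stimulus synchronisation.** OR events and emotion calls are
   aligned with the stimulus timeline (greedy earliest-match within a
   latency window); unmatched ORs are labelled non-specific.

A synthetic session generator with exact ground truth (scripted SCRs, HR
decelerations/shifts, SKT trends, baseline wander, per-channel noise) makes
the whole chain verifiable without human recordings.

## Worked example

```sh
emotionwear synth --preset iaps_520 --seed 2 --out demo/
emotionwear run --session demo/session.csv --timeline demo/timeline.yaml --out demo/out/
```

The preset renders a 760-s session: 3 min of relax, then 20 still pictures
(6 s each, 20-s blanks — a 520-s stimulus block) whose unpleasant half
scripts disgust episodes. The run log ends with

```
... emotionwear INFO 11 EDA onsets, 11 valid ORs
... emotionwear INFO alignment: 11/20 stimuli matched, 0 non-specific
```

and `demo/out/emotion_calls.csv` contains one call per valid OR:

```
t0,t1,hr_dir,eda_dir,skt_dir,emotions,score,truncated
181.09,241.09,1,1,1,joy,1.0,False
441.09,501.09,1,1,-1,disgust|fear,1.0,False
...
675.1,735.1,1,1,-1,disgust|fear,1.0,False
```

Reading: at 181.09 s (the first pleasant picture) all three channels rose —
a joy call; from 440.95 s on (the unpleasant block) HR and EDA rose while
fingertip temperature fell — the shared disgust/fear signature, reported as
a tie with match score 1.0. Eleven of twenty stimuli elicited a validated
OR; nine pleasant pictures scripted no response, so they are correctly
unmatched.

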