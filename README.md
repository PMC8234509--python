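# cescore

Automated small-bowel cleansing-quality assessment for capsule
endoscopy (CE).

A CE examination yields tens of thousands of small-bowel frames, and
their diagnostic value depends on how much mucosa is actually visible —
air bubbles, bile and debris can obscure most of it. Guidelines ask
that the adequacy of bowel preparation be stated in the CE report, but
visual grading of an entire video is subjective and impractical.
`cescore` implements an automated pipeline for this task, validated end
to end on synthetic frames with exact ground truth:

* **Per-frame scoring.** Every frame gets a cleansing score
  S ∈ {1,…,5} from the proportion of visible mucosa
  (S1 < 25 %, S2 25–50 %, S3 50–75 %, S4 75–90 %, S5 > 90 %), either by
  a transparent rule-based pixel classifier or by a small 5-class CNN
  with a softmax output: S ≜ argmaxᵢ P(Gᵢ). Inputs are three
  preprocessed channels — Rec. 601 gray, HSV saturation and CIELAB b* —
  in which bubbles, bile and debris are each separable from mucosa.
* **Case aggregation.** The final cleansing score of a case is the mean
  of its frame scores, (1/N) Σₙ Sₙ ∈ [1.0, 5.0].
* **Clinical grading.** The case is split into proximal/middle/distal
  thirds; each third gets a grade 1–4 from its fraction of frames with
  > 50 % invisible mucosa (<5 %, 5–15 %, 15–25 %, >25 %); the sum of
  the three grades maps to overall grade A (3–5), B (6–8) or C (9–12);
  A and B are clinically adequate.
* **Evaluation.** Top-1 accuracy, Cohen's kappa κ = (P₀ − Pₑ)/(1 − Pₑ)
  with under/over-estimation split, group comparison across grades, and
  an ROC of the final score for the adequacy decision with a Youden-
  index cut-off reported as the midpoint between straddling scores.
* **Synthetic data.** A generator renders mucosa-like frames occluded
  by bubbles/bile/debris with a *known* visible fraction per frame and
  a smooth cleanliness trajectory per case, so every stage above is
  testable without clinical data.

See `docs/methods.md` for the model details, conventions and
limitations.

## Worked example

```sh
cescore simulate --n-cases 1 --n-frames 30 --trajectory constant \
    --value 0.95 --seed 3 --out frames
cescore score --manifest frames/case_000/manifest.csv --rule-based \
    --out scores.csv
cescore grade --scores scores.csv --case-id case_000 --out report.json
```

prints

```
wrote frames/case_000
wrote scores.csv
case_000: final score 5.0, grade A (adequate)
```

Every frame of this well-prepped case (95 % mucosa visible) scores 5,
so the final cleansing score is 5.0; no segment has any frame with
> 50 % invisible mucosa, the segmental grades are (1, 1, 1), their sum
3 gives overall grade A — clinically adequate preparation. The same
flow with `--value 0.10` yields `final score 1.0, grade C
(inadequate)`: every frame scores 1, all three segments are grade 4.

The whole pipeline (simulate → score → grade → evaluate) runs as one
deterministic command:

```sh
cescore run --seed 7 --out out/
cat out/metrics.json   # frame-level top-1/kappa vs ground truth, ROC
```

The library mirrors the CLI one-to-one — `render_frame`,
`stack_channels`, `estimate_visible_fraction` / `train_classifier` /
`predict`, `final_score`, `grade_case`, `cohen_kappa`, `roc_analysis`,
`run_pipeline`.

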