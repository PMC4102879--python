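# prosocontrast

Do speakers use prosodic *phrasing* to mark the contrastive status of a
discourse referent — and do speakers with schizophrenia (SZ), whose
theory-of-mind (ToM) abilities are often impaired, fail to do so?

`prosocontrast` is a reusable, tested pipeline for the production side of
this question in French.  In French, a noun that contrasts with a
just-mentioned alternative tends to be parsed as its own Accentual Phrase
(AP), separately from the following adjective (`[les BONBONS][violets]`,
"2 APs"), whereas a *given* (repeated) noun is grouped with its adjective
into a single AP (`[les BONBONS violets]`, "1 AP").  The package takes
token-level acoustic annotations from a referential communication (map)
task — syllable durations and f0 landmarks for each elicited noun —
and runs the full analysis chain:

1. **Boundary detection** — a noun is classified `TWO_AP` when both
   AP-right-boundary cues hold on its last full syllable S2:
   a rising pitch accent, `f0(H) ≥ 1.10 · f0(L)` (the H maximum at least
   10% above the preceding early L minimum), and pre-boundary
   lengthening, `dur(S2) ≥ 1.10 · dur(S1)`.  Tokens with disfluencies or
   labeling errors are filtered out first.
2. **Scoring** — each participant gets a prosodic phrasing score on a
   0–20 scale: the proportion of tokens whose phrasing matches the
   condition-expected one (1 AP for given, 2 APs for contrastive),
   pooled over both conditions and scaled by 20.  The scale matches the
   hinting task's 0–20 ToM score, so the two are directly comparable.
3. **Models** — a mixed-effects logistic regression of the binary
   phrasing outcome (TWO_AP = 1),

   `phrasing ~ DiscourseStatus * Group + (1 | participant) + (1 | item)`,

   with crossed random intercepts, estimated by Laplace-approximate
   maximum likelihood (the same approximation as lme4's `glmer`, against
   which it is tested); linear mixed models on `log dur(S2)` and
   `log f0(H)` with the same structure; pooled two-sample t-tests (from
   raw vectors or printed group summaries); Spearman rank correlation of
   the phrasing score with the hinting score; and AIC comparison between
   random-effect structures.
4. **Synthetic data** — because no recordings ship with the package, a
   first-class generator produces the whole hierarchical design
   (2 groups × 2 conditions, crossed participant/item intercepts on the
   log-odds of TWO_AP, acoustics realised around the 10% thresholds, and
   hinting scores linked to each participant's phrasing propensity), so
   every stage of the pipeline is testable end to end.

Praat TextGrid + PitchTier files (long or short text format) can be
ingested directly; the canonical interchange format is a flat CSV, one
row per token.

## Worked example

Simulate the default study design (10 participants per group, 20 items)
and run every stage:

```sh
prosocontrast run --seed 11 --out out/
```

The run writes `tokens.csv`, `detection.csv`, `scores.csv`,
`report.json` and `report.md` under `out/` and prints the report.
Excerpts from this exact command:

```
## Token filtering

- tokens in: 400
- retained: 314 (78.50%)

## Phrasing by group and condition

| Group | Condition | 1 AP | 2 APs | % 1 AP | % 2 APs |
| --- | --- | --- | --- | --- | --- |
| HC | contrastive | 18 | 56 | 24.3 | 75.7 |
| HC | given | 56 | 22 | 71.8 | 28.2 |
| SZ | contrastive | 45 | 30 | 60.0 | 40.0 |
| SZ | given | 45 | 42 | 51.7 | 48.3 |
```

Healthy controls (HC) switch to two-AP phrasing under contrastive status
(75.7% vs 28.2%); the simulated SZ group barely does (40.0% vs 48.3%).
The mixed logit quantifies this as a strong positive discourse-status
effect that is cancelled by the interaction:

```
| Fixed effect                     | Estimate | Std. error | z      | p         |
| (Intercept)                      | -1.0870  | 0.4118     | -2.639 | 0.008306  |
| condition[contrastive]           | 2.4197   | 0.5014     | 4.826  | 1.391e-06 |
| group[SZ]                        | 1.0581   | 0.4977     | 2.126  | 0.0335    |
| condition[contrastive]:group[SZ] | -2.8546  | 0.5598     | -5.099 | 3.415e-07 |
```

and the phrasing score correlates with the ToM score within the SZ
group but not within HC:

```
- hinting: t(18) = -2.91, p = 0.009439 (SZ 15.20 ± 2.66, HC 18.00 ± 1.49)
- phrasing_vs_hinting_SZ: rho = 0.760 (n = 10, p = 0.0108)
- phrasing_vs_hinting_HC: rho = 0.383 (n = 10, p = 0.275)
```

The same stages are available individually (`prosocontrast simulate`,
`detect`, `score`, `fit`) and as library functions:

```python
from prosocontrast import phrasing_score, Phrasing

labels = [("given", Phrasing.ONE_AP)] * 3 + [("given", Phrasing.TWO_AP)] * 6 \
       + [("contrastive", Phrasing.TWO_AP)] * 6 + [("contrastive", Phrasing.ONE_AP)] * 3
phrasing_score("P29", "SZ", labels).phrasing_score   # -> 10.0
```

A participant who matches the expected phrasing on 3 of 9 given tokens
and 6 of 9 contrastive tokens scores 9/18 = 10 on the 0–20 scale.

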