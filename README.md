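# hgfbehav

Behavioral modeling of audio-visual associative learning in a volatile
environment.

In the task this package models, a low- (352 Hz) or high-pitch (576 Hz)
tone precedes the rotation of a pair of dots. A hidden contingency links
tone to rotation direction (clockwise CW / counterclockwise CCW), holds on
75% of unambiguous trials, and reverses every 16, 24 or 32 trials. On each
trial participants first *predict* the rotation and then *report* what they
perceived; interleaved ambiguous trials, in which the dots jump without
rotating, probe how strongly prior beliefs bias perception. Runs comprise
72 trials in 8-trial blocks of 6 expected / 1 unexpected / 1 ambiguous
trials; a session is 5 runs (360 trials).

The package provides, as a tested pipeline:

* **Task simulation** — schedule generation with the exact block/reversal
  statistics, and synthetic agents whose dual reports are sampled from the
  same likelihood the fitting machinery evaluates.
* **Contingency model** — a three-level Hierarchical Gaussian Filter (HGF)
  for binary inputs. Level 2 tracks the log-odds tendency μ₂ of the
  tone-rotation association; level 3 tracks its log-volatility μ₃. Each
  trial yields predictions (μ̂₂, π̂₂, μ̂₃, π̂₃), the conditional rotation
  probability μ_a = P(CW | tone), and precision-weighted prediction errors
  ε₂, ε₃.
* **Response models** — eight variants {0, A, P, S, AP, AS, PS, APS}
  toggling associative learning (A: μ_a weighted by a precision π_a),
  priming (P: the previous percept) and sensory memory (S: the previous
  ambiguous percept) as additive log-odds influences on the percept
  probability P(θ₁); predictions follow a noisy decision rule on μ_a.
* **Inversion** — per-run MAP estimation (BFGS with seeded restarts) with
  Laplace-approximated log model evidence.
* **Model selection / averaging** — random-effects Bayesian model
  selection with exceedance and protected exceedance probabilities
  (PXP = EP·(1−BOR) + BOR/K) and Bayesian model averaging of parameters.
* **Analysis** — behavioral scoring (prediction accuracy, ambiguous-trial
  congruency with the current contingency, perception accuracy), t tests
  and Cohen's d, Pearson correlations with Benjamini–Hochberg FDR control,
  parameter/model recovery studies, and export of the nine trial-wise
  parametric modulators (π̂₃, |μ̂₃|, π̂₂, |μ̂₂|, μ_a tone-locked; |ε₃|,
  |ε₂|, |δ_q|, P(θ₁) rotation-locked, with δ_q = P(θ₁) − y_perception)
  for event-related GLM use.

## Worked example

Simulate three associative-learning agents at the default study conditions
and score them:

```sh
$ hgfbehav simulate --seed 11 --subjects 3 --model A --out sim
wrote sim/sub-01_trials.tsv
wrote sim/sub-02_trials.tsv
wrote sim/sub-03_trials.tsv
$ hgfbehav stats sim/*.tsv
sim/sub-01_trials.tsv: prediction accuracy 0.769, ambiguous congruency 0.822, unambiguous perception 1.000
sim/sub-02_trials.tsv: prediction accuracy 0.750, ambiguous congruency 0.644, unambiguous perception 1.000
sim/sub-03_trials.tsv: prediction accuracy 0.714, ambiguous congruency 0.822, unambiguous perception 1.000
group prediction accuracy vs 0.5: t(2) = 15.02, p = 0.0044, d = 8.67
```

Each line gives the fraction of correct predictions, the fraction of
ambiguous trials perceived according to the current contingency (the prior
bias the task is designed to measure — well above the 0.5 chance level),
and perception accuracy on unambiguous trials. From Python, the belief
trajectories behind these reports are one call away:

```python
>>> from hgfbehav import HgfParams, filter_inputs, generate_run, schedule_inputs
>>> run = generate_run(seed=11)
>>> traj = filter_inputs(schedule_inputs(run), HgfParams(omega2=-0.72, omega3=-6.23))
>>> traj.to_frame()[["muhat2", "pihat2", "muhat3", "eps2"]].head(4).round(4)
   muhat2  pihat2  muhat3    eps2
0  0.0000  1.7043  0.0000  0.0000
1  0.0000  0.9315  0.0000  0.4232
2  0.4232  0.7526 -0.0092 -0.6093
3 -0.1861  0.6696 -0.0033  0.5956
```

Trial 1 here is ambiguous (no objective rotation, hence no update); the
following unambiguous trials move the association belief μ̂₂ by the
precision-weighted prediction error ε₂. `hgfbehav fit`, `hgfbehav bms`,
`hgfbehav bma`, `hgfbehav recover` and `hgfbehav export-modulators` chain
the remaining stages from the shell; the same functionality is available
programmatically (`invert`, `fit_subject`, `rfx_bms`, `bma`,
`analysis.run_recovery`, `analysis.export_modulators`).

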