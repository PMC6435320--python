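# vlpag

Analysis of ventrolateral periaqueductal gray (vlPAG) single-unit activity
during three-cue probabilistic fear discrimination — for systems
neuroscientists asking whether midbrain firing tracks *fear output* or
*threat probability*.

In the task, three 10 s auditory cues predict foot shock with probability
1.00 (danger), 0.375 (uncertainty) and 0.00 (safety); shock arrives 2 s
after cue offset on shocked trials (32 trials/session: 6 danger,
6 uncertainty-shock, 10 uncertainty-omission, 10 safety).  Fear output is
conditioned suppression of rewarded nose poking,

    suppression ratio = (baseline poke rate − cue poke rate)
                        / (baseline poke rate + cue poke rate)

computed over the whole cue (*total fear*) and per 1 s interval
(*interval fear*).  Because suppression scales nonlinearly with shock
probability (≈ 0.80 / 0.53 / 0.03 for the three cues), fear output and
threat probability are dissociable regressors.  The core statistic is a
trial-by-trial OLS per unit per interval,

    z_firing ~ 1 + interval_fear + total_fear + probability

whose beta coefficients say which signal captures the firing; sweeping the
uncertainty entry of the probability regressor over 0–1 in 0.125 steps
yields a threat-tuning curve whose peak locates the probability the
population is tuned to.

The package covers the full chain: session data model and plain-text I/O;
a synthetic session generator (Poisson pokes and inhomogeneous-Poisson
spike trains with onset / ramping / high-firing / nonresponsive profiles);
suppression measures; unit clustering (LFR/HFR) and cue-responsiveness
screening; peri-stimulus histograms and two Z-normalization schemes;
population statistics (sliding-window departure, firing-pattern shuffle
nulls, bias and chi-square tests, a nose-poke-cessation control);
regression sweeps, tuning curves, post-cue regression and beta-correlation
matrices; and a one-command pipeline with CSV/figure reports.  See
`docs/methods.md` for models, conventions and limitations.

## Worked example

The package ships the complete regression input for first-interval firing
of one recorded onset unit (32 trials).  Fitting it:

```sh
$ vlpag worked-example
beta(interval_fear) = 0.24  (p = 0.211)
beta(total_fear) = -0.14  (p = 0.779)
beta(probability) = 2.19  (p = 0.000124)
```

Neither fear measure explains this unit's trial-by-trial firing (betas
near zero, p > 0.2), while threat probability does (beta 2.19, p ≈ 1e-4):
the unit fires in proportion to the cue's shock probability, invariant of
the fear the animal expresses.  The same numbers come from the library:

```python
from vlpag import fit_worked_example
betas = fit_worked_example()
print(betas.table.round(4))
#                  beta      se       t       p
# constant      -0.8761  0.2435 -3.5983  0.0012
# interval_fear  0.2442  0.1906  1.2810  0.2107
# total_fear    -0.1372  0.4840 -0.2836  0.7788
# probability    2.1905  0.4922  4.4501  0.0001
```

An end-to-end synthetic run (simulate → suppression → classify →
normalize → population stats → regression → report):

```sh
vlpag run-all --seed 7 --out results/demo
```

writes `suppression.csv`, `labels.csv`, `betas.csv`, `tuning.csv`,
`beta_corr.csv`, pattern/departure/bias tables, figures and a
`report.json` carrying the config hash and seed; identical seeds produce
byte-identical tables.

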