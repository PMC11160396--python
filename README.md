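# skillfit

Learning-curve and diffusion-model analysis of skill acquisition with and
without instructions.

## The problem

When people learn arbitrary stimulus-response (SR) mappings ("if you see
the drum picture, press left"), being *instructed* the mapping up front
speeds early performance relative to discovering it by trial and error.
Whether that benefit persists into the automatic-execution phase — after
dozens of repetitions — is a substantive question in skill-acquisition
research.  Answering it requires (1) modelling the non-linear RT decline
over practice and (2) modelling asymptotic choice behaviour in a way that
is immune to speed-accuracy trade-offs.  `skillfit` implements that
two-stage pipeline for researchers analysing choice-RT practice data.

**Stage 1 — exponential law of practice.**  Per participant,

    RT(R) = RT0 + B e^(-alpha R)

with asymptote `RT0`, head start `B` (initial minus asymptotic RT) and
learning rate `alpha`; `R` counts prior presentations of the stimulus.
Each parameter may be tied or free across the instruction conditions
(feedback-only `F` vs instructed `I+F`); all 8 constraint models are fitted
by least squares with particle swarm optimisation and compared via
`BIC = k ln n + n ln(SSE/n)`.

**Stage 2 — diffusion decision model (DDM).**  The final repetitions of
each stimulus (the asymptotic window: last 10, or last 15 for the
longer online design) are fitted with the full DDM — drift `v`, boundary
separation `a`, non-decision time `t0`, between-trial variabilities `sv`,
`sz`, `st0`, unbiased start `a/2`, 5% uniform RT contaminants — by maximum
likelihood (`BIC = k ln n - 2 SLL`) under the matching constraint
hierarchy.  BIC weights, model-averaged parameters, group Bayes factors
and asymptote diagnostics (residual-learning LLR, QQ quantile tables)
complete the analysis.

A synthetic-data module generates both experiment designs and trial data
with the assumed statistical structure, so the whole pipeline is validated
by parameter recovery without any behavioural data.

## Worked example

```python
import skillfit as sf

# one synthetic participant: 8:1 mapping, 16 + 16 stimuli, 40 repetitions
trials = sf.simulate_experiment(experiment=1, mapping_ratio=8,
                                participants=1, seed=42)

# stage 1: learning-curve hierarchy
curve = sf.ExponentialLearningModel(trials)
comparison = curve.fit_hierarchy(seed=1, participant_id="sim000")
print(comparison.summary())

# stage 2: DDM on the last 10 repetitions
from skillfit.pipeline import select_asymptotic_window
asym = select_asymptotic_window(trials, last_k=10)
ddm = sf.DiffusionModel(asym)
fit = ddm.fit(sf.DDMModelSpec(), seed=2)   # the no-difference model
print(fit.summary())
```

prints:

```
Model comparison  participant=sim000  n=1280
          none  k= 3  BIC= -4650.044  w=0.8306
             B  k= 4  BIC= -4645.468  w=0.0843
           RT0  k= 4  BIC= -4644.025  w=0.0410
         alpha  k= 4  BIC= -4643.879  w=0.0381
         RT0+B  k= 5  BIC= -4638.398  w=0.0025
       B+alpha  k= 5  BIC= -4638.345  w=0.0024
     RT0+alpha  k= 5  BIC= -4636.881  w=0.0012
   RT0+B+alpha  k= 6  BIC= -4631.297  w=0.0001
DDM fit  spec=none  k=6  n=320
SLL = 281.0851   BIC = -527.5602
          v       a      t0      sv      sz     st0
F    5.0771  1.2046  0.3278  1.8921  0.0173  0.0837
I+F  5.0771  1.2046  0.3278  1.8921  0.0173  0.0837
```

The generator used identical parameters in both instruction conditions, and
the comparison recovers exactly that: the `none` model (no condition
differences, `k = 3`) carries 83% of the posterior model probability, and
the DDM estimates sit close to the generating values (v = 5, a = 1.2,
t0 = 0.33); under the `none` spec both conditions share one tied parameter
set.  On real data a high weight for the `B`-only model instead would
indicate instructions give a head start without changing the asymptote or
learning rate.

A command-line interface mirrors the stages
(`skillfit simulate | fit-curve | fit-ddm | compare | report | run`);
`skillfit run --config config.yaml` executes the full pipeline and writes
fit tables, weights, diagnostics and a reproducibility manifest.

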