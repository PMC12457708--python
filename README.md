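# matechoice

Do virgin females mate indiscriminately and become choosy only after
their first mating? `matechoice` is a pipeline for answering that
question with an isofemale-strain design in *Drosophila melanogaster*:
males from a panel of strains are presented to virgin (V+) and
previously-mated (V−) females, with (C+) or without (C−) male–male
competition, and the among-strain variance in male mating success — the
signature of female choosiness — is estimated within each context and
correlated across contexts. It is written for quantitative geneticists
and behavioural ecologists who want the full chain: a faithful simulator
of the blocked 20-strain experiment, the data-preparation rules that make
the four contexts comparable, the Bayesian hierarchical model for the
strain covariance structure, inbreeding-sensitive fitness and viability
decompositions, and the wing-morphometrics regressions.

## The model at its core

Male strain s carries a context-specific effect vector
a_s ~ MVN(0, diag(σ) R diag(σ)) over the four contexts
(V+C+, V−C+, V+C−, V−C−). Binary mating success follows a
Bernoulli-logit model,

    noncompetitive:  logit p = μ_k + a_{m,k} + b_{f,k}
    competitive:     logit p = μ_k + γ_color + a_{m,k}

with female-strain responsiveness effects b and a dye-color fixed effect.
σ_k measures how strongly success discriminates among male genotypes in
context k (choosiness); R_{jk} tells whether the same genotypes win
across contexts (e.g. R between the two noncompetitive contexts asks
whether virgin and non-virgin females make the same "choices").

To put all contexts on one scale, noncompetitive latency trials are
scored as success/failure at the 25th percentile per block × status
(censored at 120 min), matching the 25% success implied by sampling one
male from each four-male competition vial; that one-male-per-vial
sampling is repeated (default 100×) with the model refit per resample and
the posteriors pooled. Summaries are posterior modes with 95%
highest-density credible intervals. Fitness is the log-ratio
w = ln((wt+1)/(be+1)) against a brown-eyed competitor, decomposed by
linear mixed models (random M_strain, F_strain, M×F; fixed block and
cross); wing shape comes from a full Procrustes fit of nine landmarks
with 14 shape PCs and χ²(15)-based Mahalanobis outlier removal.

## Worked example

```python
import matechoice as mc

cfg = mc.SimConfig(seed=7)                      # the 5-block, 20-strain design
study = mc.simulate_study(cfg, seed=7)

nc_bin = mc.binarize_latency(study.noncompetitive)   # 25th-percentile scoring
vials = mc.mated_competitive(study.competitive)      # drop no-mating vials
resamples = mc.build_resample_sets(vials, n_resamples=5, seed=7)

spec = mc.ChoiceModelSpec(chains=2, iterations=2000, thin=5, seed=7)
pooled = mc.fit_resampled(nc_bin, resamples, spec)

for row in pooled.summarize(
    ["sd[V+C-]", "sd[V-C-]", "cor[V+C-,V-C-]"], force=True
).itertuples(index=False):
    print(f"{row.parameter:<16} mode {row.mode:5.2f}   "
          f"95% HDCI ({row.lower:5.2f}, {row.upper:5.2f})")

r = mc.strain_mean_correlation(
    nc_bin[nc_bin.context == "V+C-"], nc_bin[nc_bin.context == "V-C-"]
)
print(f"strain-mean correlation (virgin vs non-virgin, noncompetitive): {r:.2f}")
```

prints

```
sd[V+C-]         mode  0.21   95% HDCI ( 0.00,  0.34)
sd[V-C-]         mode  0.48   95% HDCI ( 0.27,  0.77)
cor[V+C-,V-C-]   mode  0.72   95% HDCI (-0.10,  0.99)
strain-mean correlation (virgin vs non-virgin, noncompetitive): 0.70
```

Read: both virgin and non-virgin females discriminate among male strains
(nonzero σ), and the correlation between their "choices" is high in this
realization (mode 0.72) though, with 20 strains, its credible interval is
wide — the strain-mean correlation (0.70) tells the same story more
crudely. This run was generated with male-strain SDs (0.27, 0.41, 0.32,
0.38) and a true noncompetitive cross-context correlation of 0.80, so the
fit is recovering planted structure; `study.params` holds the truth for
any such check. Short chains with pooled resamples are used here for
speed — production settings are 4 chains × 20,000 iterations, thin 10
(4,000 retained draws).

The same pipeline runs from the shell with a YAML config:

```sh
python -m matechoice all --config config.yaml --out run1
```

emitting the choice-model summary matrix (`table1_choice.csv`), the
fitness/viability decomposition (`table2_fitness.csv`), posterior draws,
wing traits and the morphology regressions, all byte-identical on rerun
with the same seed.

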