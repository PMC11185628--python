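# admixmate

Forward-in-time simulation of **ancestry-assortative mating** in admixed
populations, with explicit local-ancestry tract tracking and downstream
admixture dating.

Empirical studies of recently admixed human populations repeatedly find a
positive correlation in global ancestry proportion between spouses. That
*outcome* is compatible with very different *mechanisms* — individual
preference for ancestry-similar mates, or social-group barriers that are
only correlated with ancestry. `admixmate` is built for population
geneticists and statistical geneticists who want to ask which mechanisms
can produce an observed mate correlation, how that correlation behaves
over time, and how non-random mating distorts tract-length-based inference
of admixture timing.

## The models

A census of N diploid, hermaphroditic individuals is founded by a single
admixture pulse (fraction *m* from source 1). Each generation, N mating
events occur: parent 1 is drawn uniformly, parent 2 proportional to a
mate-choice weight ψᵢⱼ (no selfing), one child per event. Children inherit
the social group of parent 1. Five kernels are available, all calibrated by
a single strength α — the endogamy:exogamy odds at founding, so the
first-generation admixed-offspring fraction is A = 1/(1+α):

- **random** — ψ = 1
- **stationary preference** — ψᵢⱼ = exp(−ln(α)·|xᵢ−xⱼ|)
- **increasing preference** — ψᵢⱼ = exp(−(ln(α)·σ²ₓ(0)/σ²ₓ(t))·|xᵢ−xⱼ|),
  sharpening as the population homogenizes
- **broad preference** — Gaussian ψᵢⱼ ∝ exp(−(xᵢ−xⱼ)²/2σ²), σ² = 1/(2 ln α)
- **social group** — ψ = 1−1/(α+1) within group, 1/(α+1) between

Haplotypes are represented directly as source-labeled ancestry tracts;
meiosis draws Poisson crossovers on a uniform map (default: 22 human-sized
chromosomes, 2.88 Gb, r = 1e-8 /bp, so 1 cM = 1 Mb). Tract lengths feed the
standard exponential dating model, λ = (t+1)·m per Morgan, inverted as
t̂ = λ̂/m − 1.

## Worked example

Social-group model, α = 7, N = 2,000, twenty generations after an equal
(m = 0.5) pulse:

```python
from admixmate import SimConfig, run_simulation
from admixmate.dating import date_admixture

cfg = SimConfig(n=2000, generations=20, kind="social", alpha=7.0,
                seed=42, snapshot_generations=(20,))
res = run_simulation(cfg)
print(res.summary[["t", "r", "sigma2", "group_assoc"]].iloc[[0, 9, 19]].to_string(index=False))
fit = date_admixture(res.tract_lengths[20]["length_bp"].to_numpy(),
                     recomb_rate=cfg.recomb_rate, m=cfg.m)
print(f"t_hat = {fit.t_hat:.1f} (true 20), mean tract = {fit.mean_cM:.2f} cM, "
      f"tail excess = {fit.tail_excess_cM:+.2f} cM")
```

```
 t        r   sigma2  group_assoc
 1 0.728041 0.215998     0.864009
10 0.512646 0.022275     0.244760
20 0.407910 0.002104     0.066820
t_hat = 16.6 (true 20), mean tract = 11.38 cM, tail excess = +1.12 cM
```

Reading this: the mate correlation r(t) is *not* constant — it decays from
0.73 to 0.41 — yet a substantial correlation persists at t = 20 even though
the association between social group and ancestry (`group_assoc`) has
almost vanished (0.86 → 0.07): a purely social barrier keeps "recording"
itself in ancestry long after group and ancestry decouple. The preserved
long tracts make admixture look ~3.4 generations too recent (t̂ = 16.6),
with a positive tail excess over the fitted exponential.

The same machinery is available from the shell:

```sh
admixmate simulate --config run.yaml --out results/
admixmate date-admixture --tracts results/tracts_t20.bed --m 0.5
admixmate fixtures list
admixmate plot-hexbin --pairs results/pairs_t20.csv --out pairs.png
```

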