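# herbisim

An agent-based (individual-based) forward-time simulator of the **joint
evolution of plant herbivory defense and mating system**, with a
closed-form theory companion.

Plants defend against insect herbivores in two ways: *resistance* (traits
that prevent herbivory) and *tolerance* (traits that reduce the fitness
loss once damage occurs). Both are costly, so a population carrying both —
a *mixed defense strategy* — duplicates costs and should be unstable, yet
mixed strategies are common in nature. `herbisim` is built for theorists
and empiricists studying how the shape of cost/benefit accumulation
(multiplicative vs. additive, convex vs. concave) and the plant's mating
system (selfing vs. outcrossing, with its attendant inbreeding depression)
govern when mixed defense strategies and mixed mating systems persist.

## The model in brief

Individual plant fitness is the base fitness `w0` rescaled by a factor `F`
built from the costs of resistance (`RC = c_r r^l`), tolerance
(`TC = c_t t^l`), herbivory damage (`HD = c_h d^l`), the inducible
tolerance benefit (`TB = b_t d^l t^l`), and two inbreeding-depression
components — overdominance (`O1 = (h_i/H)^k` or `O2 = k(H − h_i)`) and
dominance (`D = (u_i s)^l`, with recessive lethality `I`):

```
multiplicative:  F = (1−RC)(1−TC)(1−HD+TB) · O1 · (1−D) · I
additive:        F = (1 − RC − TC − HD + TB − O2 − D) · I
```

Seed numbers are Poisson with mean `w0·F`. Resistance works through a
**gene-for-gene** interaction with coevolving herbivores: one resistance
allele at an uncountered gene protects fully, one matching anti-resistance
allele in the herbivore disarms it. Investments `r`, `t`, `a` are the
carried fraction of effect alleles at two unlinked diallelic genes per
trait; `h_i` and `u_i` derive from a 100-gene load genome with recessive
lethal mutations. Selfing is either *heritable* (probability = selfing
allele dosage) or *non-heritable* (a maternally transmitted all-or-nothing
tag). See `docs/methods.md` for the full specification.

## Worked example

```python
import herbisim as hs

# closed-form scenario analysis at the default parameters
pred = hs.scenario_predictions(hs.default_params())
print(pred.w_rs, pred.w_nrs, pred.t_opt, round(pred.f_r, 4), pred.favored)
# 0.9625 0.30625 0.75 0.3182 resistance

# simulate: multiplicative model, coevolving herbivores, no selfing
p = hs.default_params(K_plants=250, K_herbivores=250, generations=600, seed=11)
runs = hs.run_replicates(p)            # 3 replicates, streams split from seed
print(round(hs.persistence(runs, "resistance"), 3))   # 0.301
print(round(hs.persistence(runs, "tolerance"), 3))    # 0.045
print(hs.classify_outcome(runs).states["resistance"])  # 'polymorphic'
```

The scenario analysis says that with default costs, keeping a single
resistance allele (`w_RS = 1 − c_r/4 = 0.9625`) beats the best
tolerance-only strategy (`w_NRS ≈ 0.306` at tolerance investment
`t_h = 0.75`), so resistance is favored (`f_r < 1`). The simulation agrees
mechanistically: the resistance allele neither fixes nor disappears but
cycles around the single-allele optimum (persistence ≈ 0.30, i.e. about
one allele per plant), while costly tolerance is driven out
(persistence ≈ 0.05). The load genome equilibrates near the
lethal-recessive balance `2n√mu ≈ 9.9` alleles per individual.

The same engine runs from the shell:

```
herbisim theory                                   # scenario + load predictions
herbisim simulate --config my.toml --out runs/    # replicates -> CSVs
herbisim sweep --config my.toml --grid grid.toml --reps 3 --out sweep/
herbisim surface --axes "c_r=0:1:21,c_t=0:1:21" --out surface.csv
herbisim summarize --in sweep/ --out summary.csv
```

Configs are plain `key = value` files (e.g. `c_t = 0.9`); unspecified keys
take the documented defaults.

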