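# repdist

Monte Carlo machinery for measuring **how far a replication study is from
the original experiment**, in units of result reproducibility.

Replications in practice almost never repeat an original study exactly: the
measured variables, the model, the analysis, or the data design differ.
`repdist` formalizes a study as the ordered tuple (K, Spre, M, Spost, D) —
background knowledge, pre-data methods, generative model, post-data
methods, and data (structure Ds + values Dv) — and quantifies the gap
between two studies per component.  It is aimed at metascience researchers
and simulation-minded statisticians who want to compare study designs, plan
replications, or steer a sequence of planned modifications toward a
minimum viable experiment (MVE).

## The statistic

For a binary result r, the reproducibility rate of an experiment is

    phi = lim_{N->inf} (1/N) * sum_i I{R_i = r}

over exact replications (components fixed, data values redrawn), estimated
by the agreement fraction phi_hat over N simulated replicates.  Swapping
components between an original study and a replication yields a 2^4-cell
permutation grid (K is never permuted), and the distance with respect to a
component — say the model — is

    d(M_o, M') = | (1/8) sum_{grid, M=M_o} phi  -  (1/8) sum_{grid, M=M'} phi |,

the averages running over all permutations of the other three components.
Hybrid experiments that are not performable (the model demands a variable
the design never measured; a Bayesian analysis with no prior assignable to
some parameter) enter the averages with rate 0 by convention.  The result
is a four-coordinate distance vector (Spre, M, Spost, Ds) — deliberately
never collapsed to one number.

The bundled example contrasts two dugong growth studies: a linear model of
length on log-age and weight fit by OLS on a small biased sample, versus an
asymptotic growth model `y = alpha - beta3 * gamma^age` fit by vague-prior
MCMC on a large clean sample, with the shared binary result "does the
fitted study assign the same *certain to breed* status (mean length >
2.50 m at age 17 y, weight 250 kg) as the true model?".

## Worked example

```python
import numpy as np
import repdist as rd

# distances from the published 16-cell rate table of the dugong example
table = rd.published_rate_table()
d = rd.distance_vector(table)
for k, v in d.as_dict().items():
    print(f"d({k}) = {v:.3f}")

# estimate one cell's rate afresh: study 1's analysis on the clean n=100 design
s1, s2, res = rd.build_studies()
spec = rd.assemble(1, 1, 1, 2, original=s1, replication=s2)
rng = np.random.default_rng(np.random.SeedSequence(entropy=42, spawn_key=(2,)))
est = rd.estimate_rate(spec, res, 2000, rng)
print(f"phi_hat = {est.phi_hat:.3f} (mc_se = {est.mc_se:.4f}, n_valid = {est.n_valid})")
```

prints

```
d(spre) = 0.406
d(model) = 0.539
d(spost) = 0.036
d(dstruct) = 0.111
phi_hat = 0.999 (mc_se = 0.0009, n_valid = 2000)
```

Reading: the two studies are far apart in pre-data methods (0.406, driven
by the weight variable that study 2 never measures, which makes four grid
cells non-performable) and in model (0.539), but nearly interchangeable in
analysis method (0.036) — least squares and vague-prior Bayes behave alike
on these well-posed models — and surprisingly close in data structure
(0.111) despite study 1's small biased sample.  The freshly simulated cell
rate (phi_hat ≈ 0.999) says the OLS analysis on clean n=100 data almost
always reproduces the true breeding status.

The same pipeline is scriptable from the shell:

```
repdist dugong run --reps 10000 --bayes-reps 1000 --seed 42 --out out/
repdist distance --rates out/rates.csv
repdist estimate --study 1 --reps 1000 --seed 7
```

## Layout

| module | contents |
| --- | --- |
| `repdist.experiment` | experiment tuple, result spec, permutation engine |
| `repdist.growth` | dugong growth models, designs, dataset simulation |
| `repdist.estimators` | OLS, Levenberg-Marquardt NLS, Metropolis-within-Gibbs |
| `repdist.rates` | reproducibility-rate estimation and rate tables |
| `repdist.distance` | component-wise distance vectors |
| `repdist.mve` | planned-modification sequences, convergence heuristic |
| `repdist.dugong` | the bundled example and published reference rates |
| `repdist.io`, `repdist.cli` | CSV/YAML plumbing and the `repdist` CLI |
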