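# bpgrowth

Fitting and model selection for the **Bertalanffy–Pütter growth model**

```
dm/dt = p · m(t)^a − q · m(t)^b,        m(0) = m0,   0 ≤ a ≤ b,
```

which describes body mass `m` (grams) at age `t` (years) and unifies the
classical growth laws: the von Bertalanffy mass model `(a, b) = (2/3, 1)`,
the VBGF length model `(0, 1)`, West's model `(3/4, 1)`, logistic growth
`(1, 2)`, and — on the diagonal `a = b`, where the right-hand side passes to
its limit `p·m^a − q·ln(m)·m^a` — the (generalized) Gompertz model.  The
asymptotic mass is `m_max = (p/q)^(1/(b−a))`, or `exp(p/q)` on the diagonal.

The package is aimed at growth-curve analysis of size-at-age data as it
arises in fisheries science: given per-age-class average masses, it answers

* what the best-fitting parameters `(m0, p, q)` are for a *given* exponent
  pair, by constrained least squares on the class averages
  (`SSE_opt(a, b) = min over (m0, p, q) of SSE`, with `m0 > 10` g and
  `p > q > 0`);
* which exponent pair is *globally* optimal, via coarse-to-fine grid scans
  with warm starts and a multiplicative simulated-annealing refinement; and
* which exponent pairs are *defensible*, via the small-sample Akaike
  criterion `AICc = N·ln(SSE/N) + 2K + 2K(K+1)/(N−K−1)`, pairwise Akaike
  weights `w = e^(−Δ/2)/(1 + e^(−Δ/2))`, and the equivalent SSE-ratio
  threshold `SSE/SSE_best < (1/t − 1)^(2/N)` (1.757 for `N = 13`,
  `t = 2.5%`).

The bundled dataset is the 13-class average weight-at-age table for male
Walleye (*Sander vitreus*) from Lake Erie (20,166 fish), available as
`bpgrowth.walleye_table1()`.  A synthetic-data module generates raw
age–mass records around any known growth curve (lognormal individual
scatter with configurable coefficient of variation, class design cloned
from the Walleye table by default) for end-to-end recovery experiments.

## Worked example

```python
from bpgrowth import BertalanffyPutter, ExponentPair, walleye_table1

model = BertalanffyPutter(walleye_table1())
res = model.fit(ExponentPair(2/3, 1))          # classical von Bertalanffy pair
print(res.summary())
```

```
Bertalanffy-Putter growth fit
=============================
exponent pair     a = 0.666667, b = 1
method            local-simplex
converged         True
function evals    582
-----------------------------
m0 (g)            203.794
p                 11.2001
q                 0.859626
m_max (g)         2211.75
SSE (g^2)         23708.456616
N classes         13
AICc (K=4)        110.6123
```

The fit reads: a fitted initial mass of ~204 g at age 0 (the age-0 class
average is 192 g), an asymptotic mass of ~2212 g, and a sum of squared
errors of ~23,708 g² over the 13 class averages.  Scanning all exponent pairs
(`coarse_scan`, `scan_row`, `global_optimum`) lowers the SSE by ~9% to
~21,504 g² at a Gompertz-type optimum `a = b ≈ 0.685` — but model selection
keeps the classical pair: with the extra exponent penalized by AICc, the
`(2/3, 1)` model scores *better* than the refined optimum (it falls in the
"green" parsimony region), while the logistic pair `(1, 2)` is rejected
outright (its SSE ratio ~3.3 exceeds the 1.757 acceptability threshold).

The same machinery is scriptable from the shell:

```bash
bpgrowth fit --a 0.6667 --b 1 --table1 --out fit.csv
bpgrowth scan --step 0.1 --table1 --out scan.csv
bpgrowth anneal --start-a 0.7 --start-b 0.7 --steps 50000 --table1 --out best.csv
bpgrowth simulate --cv 0.25 --seed 1
```

All commands accept `--config config.yaml` (command line takes precedence)
and write the results schema `a,b,m0,p,q,SSR,m_max`.

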