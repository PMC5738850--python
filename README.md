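# gpasim

A deterministic genomic prediction accuracy simulator, packaged as a
Python library and CLI. It implements eight closed-form expressions for
the expected correlation `r` between true and predicted genomic breeding
values as a function of population-genetic design factors — training-set
size `N`, heritability `h2` (or genomic heritability `h2M`), number of
independent chromosome segments `Me`, effective population size `Ne`,
marker number `M`, and the marker-captured variance fraction `b` — plus
a two-training-population formula for predicting accuracy in a third
population. Alongside the formulas it ships:

- an estimator of the ridge-regression expectation term
  `E(||x' X' V^-1||^2)` from simulated genotype matrices
  (`V = X X' + lambda I`), which links marker data back to the `Me/N`
  term of the closed-form expressions;
- a parameter-sweep engine producing tidy accuracy-vs-factor tables
  (1D curves) and two-factor surfaces;
- CSV/JSON table serialization, png/svg/self-contained-html plots, and a
  `gpasim` command-line interface.

## Library overview

```python
import gpasim as g

g.daetwyler(n_train=1000, h2=0.5, me=500)        # 0.7071...
g.goddard2009(1000, 0.5, 500, ne=100)            # 0.7705...
g.goddard2011(1000, 0.5, 500, m_markers=500)     # b = M/(M+Me)
g.rabier(1000, 0.5, 500)
g.rabier_eterm(h2=0.5, eterm=0.5)
g.deloscampos(b=0.5, h2=0.64)
g.karaman(1000, h2_m=0.5, me=500)
g.wientjes(n_a=1000, n_b=1000, h2_a=0.5, h2_b=0.5, me_ac=500,
           me_bc=500, r_g_ac=0.8, r_g_bc=0.8, r_g_ab=0.6,
           b_ac=0.9, b_bc=0.9)

g.evaluate("daetwyler", {"n_train": 1000, "h2": 0.5, "me": 500})
g.list_formulas()                                # 8 registry entries

geno = g.simulate_genotypes(n_train=200, n_test=50, m_markers=1000, seed=1)
lam = g.default_ridge_lambda(m_markers=1000, h2=0.5)   # M (1-h2) / h2
est = g.estimate_eterm(geno, g.RidgeSpec(lam))         # <= 1 same-population
me_hat = g.me_from_eterm(est, n_train=200)

table = g.run_sweep(g.SweepSpec(
    formula_id="daetwyler", x_param="n_train", x_min=100, x_max=10_000,
    n_points=101, fixed={"h2": 0.5, "me": 1000.0}))
g.write_table(table, "curve.csv")
g.render(table, g.RenderSpec(kind="curve", output_path="curve.png"))
```

Validation is eager: every parameter is checked against its domain
(`h2` in (0, 1], strictly below 1 for the two `rabier` forms; `ne` > 0.5;
`me` > 0; correlations in [-1, 1]; counts positive integers) and errors
name the offending field.

## CLI

```sh
gpasim list-formulas
gpasim compute --formula daetwyler --param N=1000 --param h2=0.5 --param Me=500
gpasim sweep --formula daetwyler --x-param N --x-min 100 --x-max 10000 \
    --fixed h2=0.5 --fixed Me=1000 --out curve.csv --plot curve.png
gpasim surface --formula wientjes --x-param NA --x-min 100 --x-max 5000 \
    --y-param NB --y-min 100 --y-max 5000 \
    --fixed h2A=0.5 --fixed h2B=0.5 --fixed MeAC=500 --fixed MeBC=500 \
    --fixed rGAC=0.8 --fixed rGBC=0.8 --fixed rGAB=0.6 \
    --fixed bAC=0.9 --fixed bBC=0.9 --out surface.csv --plot surface.png
gpasim eterm --n-train 200 --n-test 50 --m 1000 --seed 1 --h2 0.5
```

Parameters accept either the conventional symbols (`N`, `h2`, `h2M`,
`Me`, `Ne`, `M`, `b`; `NA`, `NB`, `h2A`, `h2B`, `MeAC`, `MeBC`, `rGAC`,
`rGBC`, `rGAB`, `bAC`, `bBC`) or the canonical field names (`n_train`,
`me`, ...). Results go to stdout/files, diagnostics to stderr; exit
status is 0 on success, 1 on a domain/validation error, 2 on a usage
error.

Sweeps are also reproducible from flat `key = value` config files
(`#` starts a comment):

```
formula = daetwyler
x_param = n_train
x_min = 100
x_max = 10000
n_points = 101        # scale = linear | log
fixed.h2 = 0.5
fixed.me = 1000.0
```

Surface configs add `y_param`, `y_min`, `y_max` and use per-axis
`x_points`/`x_scale`/`y_points`/`y_scale`. Run them with
`gpasim sweep --config FILE --out ...` or `gpasim surface --config ...`.

## Notes on numerics

- The random-marker formula (`goddard2009`) is evaluated through a
  cancellation-free rearrangement: the log term via
  `2 ln((sqrt(a)+1)/(sqrt(a)-1))`, and the whole radicand via its power
  series in `1/alpha` when `alpha > 2`. Tests compare it against a
  50-digit evaluation of the published expression.
- The two-population formula is computed as the square root of the full
  scalar quadratic form `a' P^-1 a`, with a reciprocal-condition guard
  (1e-12) on the 2x2 solve.
- The expectation-term estimator uses a Cholesky solve of
  `V = X X' + lambda I`, never an explicit inverse; genotypes are
  centered by `2 p_j` with no variance standardization.
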