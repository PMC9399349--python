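# dmyest — daily milk yield estimation from single AM or PM milkings

In AM-PM milk-recording plans only one of a cow's two daily milkings is
weighed on each test day, alternating morning (AM) and evening (PM) across
test days. The daily milk yield (DMY) must then be estimated from that
single milking. `dmyest` implements the standard estimators side by side,
evaluates them by replicated cross-validation, and ships a synthetic
milking-record generator so the whole pipeline is testable without access
to restricted herd data. It is aimed at dairy-recording analysts and
quantitative geneticists who need reproducible correction factors and
honest out-of-sample accuracy numbers.

## Models

With `x` the measured single-session yield (kg), `t` its milking interval
(h), `d` days in milk, `d0 = 158` a reference DIM, and `j ∈ {AM, PM}`:

| Model | Form | DMY estimate |
|-------|------|--------------|
| M0 | doubling | `ŷ = 2x` |
| M1 | cell-mean ACF | `ŷ = Δ(class, month) + 2x` |
| M2A/B | ACF regression `z = α_j + βt + γ(d−d0)` on `z = y − 2x` | direct, or `Δ_j(k) = α̂_j + β̂·t̄_j(k)` per interval class |
| M3A/B | linear regression `y = α_j + βt + γ(d−d0) + bx` | direct, or via ACF with estimated `b̂ ≈ 1.75` |
| M4 | M3 plus `t²` and `(d−d0)²` | direct only |
| M5 | bulk proportions `Σx/Σy` per class, quadratic smoothing | `ŷ = F_j(k)·x`, `F = 1/(α̂ + β̂₁t̄ + β̂₂t̄²)` |
| M6 | per-class no-intercept regression, reciprocal-line smoothing | `ŷ = F_j(k)·x + γ̂_jk(d−d0)` |
| M7A/B | ratio regression `x/y = α_j + βt + γ(d−d0)` | direct `ŷ = x/denominator`, or `F = 1/(α̂_j + β̂t̄)` |
| M8A/B | exponential regression `y = x^b e^{α_j+βt+γ(d−d0)+ε}` | direct, or per-class `F = E(x)^{b̂−1}·ρ·e^{α̂_j+β̂t̄}` with lognormal correction `ρ` |

Accuracy is assessed by k-fold cross-validation replicated with fresh
random partitions, decomposing `MSE = Var + Bias²` across replicates and
reporting `R² = σ²/(σ² + MSE)`, which (unlike correlation) penalizes bias.

## Worked example

```python
from dmyest import (CVPlan, build_mic_grid, generate_dataset, get_profile,
                    render_table, run_crossval)

records = generate_dataset(get_profile("holstein", n_cows=3000,
                                       records_per_cow=2, seed=7))
grid = build_mic_grid()          # 1-h classes, midpoints at 6..20 h
report = run_crossval(records, ["M0", "M2B", "M8A"],
                      CVPlan(k=5, replicates=3, seed=7), grid)
print(render_table(report).to_string(index=False))
```

prints

```
model    Var  Bias2   MSE       Acc (SE)       Cor (SE)
   M0 0.0000  6.867 6.867 0.793 (0.0000) 0.891 (0.0000)
  M2B 0.0001  2.199 2.199 0.923 (0.0000) 0.961 (0.0000)
  M8A 0.0001  1.600 1.600 0.943 (0.0000) 0.969 (0.0000)
```

Read: doubling (M0) carries a large squared bias because AM intervals
average ~0.7 h longer than PM intervals, so `2x` over-/under-shoots
whenever the measured interval is not 12 h; the regression-based ACF
(M2B) removes most of that bias, and the exponential model (M8A) is both
the least biased and the most accurate — all with essentially zero
variance (high precision). The same ordering the models show on real
Holstein records.

The same pipeline is available from the shell:

```bash
dmyest simulate --profile holstein --n-cows 3000 --seed 7 --out runs/sim
dmyest crossval runs/sim/records.csv --models M0,M2B,M8A \
       --k 5 --replicates 3 --seed 7 --out runs/cv
dmyest factors runs/sim/records.csv --models M2B,M7B,M8B --out runs/factors
```

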