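# siakit

Solvent Interaction Analysis (SIA) of protein partitioning in aqueous
two-phase systems (ATPSs), for structural biochemists who use partition
behaviour as a probe of protein conformation and stability.

When two polymers such as dextran and Ficoll are mixed in water above
threshold concentrations, they form two immiscible aqueous phases with
subtly different solvent properties. A protein distributes between the
phases according to its solvent-exposed surface; its **partition
coefficient** K = [top]/[bottom] is therefore a numerical index of its 3D
structure. Measuring K in several ATPSs of different ionic composition and
comparing the resulting log-K vector with a reference protein's yields a
single **SIA signature distance** that is sensitive to point mutations,
misfolding and ligand binding:

    d_i0 = sqrt( Σ_j [ (log K_ij − log K_0j) / log K_0j ]² · s_j / s_max )

where *j* runs over the systems, s_j is the normalised standard deviation
attributed to system *j* and s_max the largest of them. The package covers
the full workflow:

* **partition** — K as the least-squares slope of top-phase vs bottom-phase
  signal over a dilution series, with replicate averaging and a 3%
  reproducibility check;
* **signature** — the distance above, with its ambiguous details (square
  root, choice of s_j) exposed as configuration;
* **regression** — OLS with the diagnostics quoted in partitioning studies
  (coefficients ± SE, N, r², residual SD, variance ratio F), a
  leave-one-out outlier scan, and re-runs of the six published
  structure–stability regressions for the two packaged mutant panels
  (staphylococcal nuclease A, 9 variants; T4 lysozyme, 6 variants);
* **sasa** — polar/apolar/total solvent-accessible surface area of PDB
  structures by the Shrake–Rupley probe-sphere method (probe radius 1.4 Å,
  deterministic golden-spiral quadrature);
* **synthetic** — generators for dilution series, mutant panels with
  planted cross-system and stability models, and toy structures with
  analytic reference areas.

## Worked example

```python
from siakit import *

# K from a (simulated) dilution series with planted K = 0.97
series = gen_dilution_series(true_k=0.97, n_points=6, rel_noise=0.01, seed=1)
est = estimate_k(series)
print(f"K = {est.k:.3f} ± {est.se:.3f} (n={est.n_points})")

# signature distances of the packaged nuclease panel, most perturbed first
panel = load_panel("nucleaseA")
for m, d in signature_table(panel.partition, "WT")[:3]:
    print(f"{m}: d = {d:.2f}")

# the cross-system log-K regression over both panels (minus outlier L37I)
rep = reproduce_equation(EquationId.E2)
print(f"n={rep.fit.n} r2={rep.fit.r2:.4f} "
      f"slope(Na2SO4 system) = {rep.fit.coef('K_atps2'):.3f}")
```

prints

```
K = 0.974 ± 0.006 (n=6)
L108I: d = 14.89
L108V: d = 10.01
L37I: d = 8.22
n=14 r2=0.9424 slope(Na2SO4 system) = 0.775
```

The fitted K recovers the planted 0.97 within its standard error. The
signature ranking flags the position-108 and L37I mutants as the least
wild-type-like partition profiles (the published signature column ranks
L37I first; recomputed distances depend on the documented s_j convention).
The cross-system regression reproduces the published r² = 0.9424 and
sulfate-system slope 0.78, confirming that log K in the buffer-only system
is a linear blend of the two salt systems' log K.

A command-line interface mirrors the library: `siakit reproduce` re-runs
all six published regressions and writes per-equation JSON plus a
side-by-side summary; `siakit signature`, `siakit fit`, `siakit sasa` and
`siakit simulate` dispatch to the corresponding modules (logs to stderr,
results to files).

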