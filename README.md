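# conefate

Quantitative analysis and multiscale stochastic modeling of cone
photoreceptor patterning along the dorsal-ventral (D-V) axis of the mouse
retina.

Mouse cones come in two subtypes defined by opsin expression: **S-only
cones** express short-wavelength (S) opsin at a high level regardless of
position, while **co-expression-competent (CEC) cones** express medium-
wavelength (M) opsin and/or S-opsin at graded, position-dependent levels.
Along the D-V axis the fraction of cones expressing S-opsin switches on
extremely sharply — a Hill transition

&nbsp;&nbsp;&nbsp;&nbsp; f(y) = base + amplitude · yⁿ / (Kⁿ + yⁿ)

with coefficient n ≈ 30 — while the M-opsin expressing fraction declines
gradually (n ≈ 2–3), and the S-only subtype rises from ~1% of cones
dorsally to ~20–30% ventrally. `conefate` provides both halves of the
study of this pattern:

1. **Analysis** — active-contour segmentation of two-channel
   immunofluorescence tiles into per-cone intensity measurements; cell
   classification, D-V expressing-fraction profiles and Hill-transition
   fits; retina alignment at the S transition midpoint; joint intensity
   distributions; HDBSCAN clustering of the (S, M) intensity manifolds; and
   transition statistics (CEC fraction and slope at the S midpoint).
2. **Model** — a hybrid multiscale simulation: thyroid hormone (T3)
   diffuses deterministically across a 5 × 1 mm strip with constant-
   concentration boundaries, 23,760 cones on a hexagonal lattice exchange
   T3 molecules stochastically with their microenvironment, and each cone
   runs an exact Gillespie simulation of a reaction network in which
   T3-bound receptor (Thrβ2*) represses the S-only fate choice, activates
   M-opsin expression and represses S-opsin expression in CEC cones.

A synthetic-retina generator with the measured statistical structure
(subtype fractions, Hill transitions, intensity gradients, log-normal
noise, hexagonal packing, image rendering) makes every stage testable with
no external data. All three data sources — synthetic, image-derived and
simulated — share one per-cell CSV schema.

## Worked example

```python
from conefate import (GeneratorParams, SimConfig, generate_cell_table,
                      cluster_cells, transition_stats, run_simulation)
from conefate.profiling import fit_s_fraction, fit_m_fraction

# synthetic mean retina: classify, profile, fit, cluster
table = generate_cell_table(GeneratorParams(seed=11))
fs, fm = fit_s_fraction(table), fit_m_fraction(table)
st, cl = transition_stats(table), cluster_cells(table)
print(f"S transition: n = {fs.n:.1f}, midpoint = {fs.midpoint_um:.0f} um")
print(f"M transition: n = {fm.n:.1f}")
print(f"clusters: {cl.n_clusters}")
print(f"CEC fraction at S midpoint: {st.cec_fraction_at_midpoint:.3f}")

# calibrated hybrid simulation of the full strip
sim = run_simulation(SimConfig(), seed=1)
df = sim.data
print(f"dorsal-mm S-only: {100*(df[df.y_um<1000].fate_truth=='S_ONLY').mean():.2f}%")
print(f"ventral-mm S-only: {100*(df[df.y_um>4000].fate_truth=='S_ONLY').mean():.2f}%")
```

prints

```
S transition: n = 27.8, midpoint = 3007 um
M transition: n = 2.8
clusters: 2
CEC fraction at S midpoint: 0.876
dorsal-mm S-only: 1.03%
ventral-mm S-only: 23.72%
```

The sharp S switch (n ≈ 28–30) against the gradual M decline (n ≈ 2.8),
the two intensity clusters (S-only vs CEC manifold), and the 1% → 24%
dorsal-to-ventral rise of the S-only fate are the package's headline
reproductions; the simulation derives all of them from a single linear T3
gradient read out by one receptor.

A command-line interface mirrors the library:

```bash
conefate generate --seed 1 --out cells.csv
conefate profile --cells cells.csv --out profile.csv
conefate simulate --seed 1 --out sim.csv            # add --knockout-thrb2 for the mutant
conefate pipeline --seed 1 --out-dir run/
```

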