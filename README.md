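# podosim

An individual cell-based (agent) model of mesenchymal stem cell (MSC)
expansion *in vitro*, with explicit force-generating podia.

MSC cultures grow to confluence within days, switching from fast-moving
fibroblastoid cells at low density to aligned, spindle-shaped cells at
high density.  `podosim` reproduces this spatio-temporal organisation
from single-cell mechanics: cells are elastic, compressible spheres on an
adhesive substrate; each carries a variable number of podia — cones that
elongate under a constant protrusion force `F_p` at the tip, build
harmonic traction `k·L` between tip and body, and are stochastically
generated and inactivated.  Contact guidance rotates overlapping podia
off neighbouring cells (and onto substrate microgrooves), producing
nematic alignment domains; density-dependent ramps down-regulate the
growth rate, the podium inactivation rate and the podium count as the
number of nearest neighbours rises, producing contact inhibition.

The package is aimed at computational biologists studying collective cell
behaviour, contact guidance by micro-structured substrates, and cell
culture optimisation.

## Model core

Per cell i the body energy is

    E_i = −(ε_cc Σ_j A_ij + ε_cs A_is)                adhesion
          + Σ_contacts (8/15) E* √R_eff δ^{5/2}       Hertz deformation
          + (K/2)(V_i − V_t,i)² / V_t,i               compression

with over-damped dynamics

    (γ_cs A_is + γ_v) v_i + γ_cc Σ_j A_ij (v_i − v_j) = −∂E/∂r_i + Σ_m k L_m p̂_m
    γ_R S̃_i Ṙ_i = −∂E/∂R_i,     γ_p v_tip,m = F_p·[active] − k L_m

Cells divide through a 5-phase cycle (target-volume growth in stochastic
increments, compression quiescence, pre-division podium retraction) once
the target volume doubles.  Orientation statistics use the consensus
podium axis and the nematic order parameter S(d) = ⟨cos 2Δφ⟩ (1 aligned,
0 disordered), averaged to S* below 50 µm separation.

Default parameters are the published table for this cell system (e.g.
`F_p = 2.5 nN`, `k = 0.1 nN/µm` → maximum podium length 25 µm,
`λ = 1440/d`, `r_ind = [2…0]/d`, `n_off = [3.5…2.5]`, growth
`[1200…0] µm³/d` ramping off between 4 and 5 neighbours).  See
`docs/methods.md` for every equation, gap-filling constant and numerical
choice.

## Worked example

```python
import podosim as ps

params = ps.load_parameters()          # published defaults
traj = ps.run(params, days=3.0, seed=11)
state = traj.final()
cells = state.cells()
print(len(cells), "cells")
print("mean population radius  %.1f um" % ps.mean_population_radius(cells))
print("mean podium length      %.1f um" % ps.mean_podium_length(cells))
print("order parameter S*      %.2f" % ps.order_parameter_star(cells))
```

prints (seed 11)

```
93 cells
mean population radius  156.8 um
mean podium length      21.7 um
order parameter S*      0.23
```

— after three simulated days a single seeded cell has grown into ~90
cells spread over ~150 µm; podia average ~22 µm (growing towards their
25 µm maximum), and local nematic alignment is already well above the
disordered value 0.

The same run from the shell, with snapshot CSVs and a metrics table:

```bash
podosim simulate --days 3 --seed 11 --out run/
podosim analyze run/snapshot_*.csv --out metrics.csv
podosim render run/snapshot_t003.000d.csv --out day3.png
```

Substrate micro-structures: `--substrate parallel` (stripes, default
8 µm grooves at 8 µm spacing) or `--substrate star` (the starlike
radial-groove plating unit that biases migration outward and increases
cell yield).

## Acceptance script

`scripts/acceptance.py` recomputes, from scratch with the package's own
sampler, the modal outgrowth angle between a newly generated podium and
its nearest existing podium on two-podia cells (5° histogram bins,
default parameters):

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The JSON maps each target id to the recomputed value and the sample size
used.
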