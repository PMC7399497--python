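# pdzscaffold

Tools for analysing the self-assembly of a tandem PDZ-domain scaffold:
crystallographic symmetry logic, oligomer construction with avidity
accounting, SAXS forward modelling and reduction, oligomer-mixture fitting,
and single-site isothermal titration calorimetry — with synthetic-data
generators so every stage is testable against known ground truth.

## The problem

PSD-95, the major scaffold protein of the postsynaptic density, clusters
ion channels through its first two PDZ domains ("PDZ1-2").  In solution at
postsynaptic-density-like concentrations, ligand-saturated PDZ1-2
oligomerizes.  The analysis implemented here interprets that
oligomerization as the population of a *scaffolding lattice*: a
body-centred cubic packing in the chiral space group I2₁3 (International
Tables no. 199, 24 general positions, cell edge |a| = 4·Δx ≈ 148 Å) in
which each monomer makes five interactions — two reciprocal
αB(PDZ2)–βD-βE(PDZ1) contacts (the twofold dimer), two directed
αA(PDZ2)–βB-βC(PDZ1) contacts (cyclic trimers around the threefolds), and
one PDZ1–PDZ1 contact.  Removing a monomer from the full lattice breaks
five interactions; from a dimer or tetramer only two — the avidity argument
for why large oligomers persist after dilution.

The package is aimed at structural biologists who want to reproduce,
stress-test or extend this style of analysis: symmetry-based oligomer
models fitted to SAXS curves as non-negative mixtures, with populations
p_k = f_k·n_k / Σ f_j·n_j, alongside the supporting curve reduction
(damage-aware frame merging, scaling, point-by-point extrapolation to
infinite dilution I(q,c) = P(q)(1 − β(q)c) → P(q)) and single-site ITC
(Wiseman c = N·M/K_d identifiability diagnostics).

## Worked example

```python
from pdzscaffold import scaffold, spacegroup
from pdzscaffold.mixture import Component, ComponentSet, fit_volume_fractions
from pdzscaffold.synthetic_data import (
    oligomer_component_curves, make_mixture_dataset, mixture_q_grid)

# 1. Which chiral cubic group fits the observed symmetry elements?
survivors = spacegroup.eliminate_space_groups(
    ["no_fourfold_axes", "threefold_axes_do_not_intersect",
     "has_pure_twofold_rotation"])
print([(r.it_number, r.symbol) for r in survivors])   # [(199, 'I2_1 3')]
print(len(spacegroup.general_positions(199)))         # 24

# 2. Avidity accounting in that lattice
print(scaffold.full_lattice_degree())                 # (2, 2, 1, 5)
dimer = scaffold.combinatorial_assembly("2e")
print(scaffold.dissociation_cost(dimer, 0))           # 2

# 3. Recover oligomer populations from a synthetic mixture curve
comps = oligomer_component_curves(q=mixture_q_grid())
truth = {"1e": 0.35, "2e": 0.20, "4e": 0.30, "24e": 0.15,
         "8e": 0, "12e": 0, "16e": 0, "20e": 0}
data, _ = make_mixture_dataset(comps, truth, noise_level=0.02, seed=11)
cset = ComponentSet([Component(n, comps[n], int(n[:-1])) for n in comps])
res = fit_volume_fractions(data, cset)
print(res.report(cset))
```

which prints

```
scale = 1.00716   reduced chi2 = 0.9526
        1e  f = 0.3495 +- 0.0231   population = 0.0634 +- 0.0041
        2e  f = 0.2142 +- 0.0185   population = 0.0777 +- 0.0063
        4e  f = 0.2868 +- 0.0159   population = 0.2080 +- 0.0096
        8e  f = 0.0000 +- 0.0000   population = 0.0000 +- 0.0000
       12e  f = 0.0000 +- 0.0000   population = 0.0000 +- 0.0000
       16e  f = 0.0000 +- 0.0000   population = 0.0000 +- 0.0000
       20e  f = 0.0000 +- 0.0000   population = 0.0000 +- 0.0000
       24e  f = 0.1495 +- 0.0028   population = 0.6509 +- 0.0101
```

The fitted volume fractions recover the generating values (0.35 / 0.20 /
0.30 / 0.15) within their uncertainties at 2% noise, and the population
column re-expresses them as the proportion of *monomers* living in each
oligomer — the 24-mer holds 65% of the protein despite being only 15% of
the particles, because each one contains 24 chains.

A command-line layer wraps the same functions, e.g.

```sh
pdzscaffold spacegroup ops --number 199
pdzscaffold scaffold build --ops 24e --cell 148 -o unit_cell.pdb
pdzscaffold itc simulate --kd 60 -o iso.txt && pdzscaffold itc fit --isotherm iso.txt
```

## Module map

| module | contents |
| --- | --- |
| `spacegroup` | exact operator tables for the 13 Sohncke cubic groups, elimination logic, axis angles, cubic cell |
| `structures` | coordinate sets, fixed-column PDB read/write (CRYST1 aware), radius of gyration, symmetry-image distances |
| `scaffold` | oligomer presets 1e…24e, interface graphs (combinatorial and geometric), dissociation costs, trimer-of-dimers grid search (a = 4Δx) |
| `saxs_model` | Debye forward scattering, Guinier, Kratky, regularized P(r) |
| `saxs_reduce` | damage-aware frame merging, high-q scaling, extrapolation to infinite dilution |
| `mixture` | NNLS volume-fraction fitting, reduced χ², population histograms |
| `itc` | single-site titration simulation and fitting, identifiability flag |
| `synthetic_data` | dumbbell monomers, component curves, dilution/frame series, titrations — all with JSON ground truth |

See `docs/methods.md` for the models, their assumptions and the numerical
conventions.

## Acceptance script

`scripts/acceptance.py` recomputes the package's headline quantities from
scratch — the space-group elimination result, the general-position count of
the scaffolding group, and the mean dissociation constant recovered from 50
simulated single-site titrations under the standard injection protocol —
and writes them to JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
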