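# caxport

Analysis pipeline for **Ca2+/phosphate co-transport by CAX-family H+/Ca2+
antiporters**.

Bacterial CAX antiporters such as YfkE export cytosolic Ca2+ in exchange
for H+. Beyond the slow H+/Ca2+ exchange mode, these transporters can run a
high-flux mode in which Ca2+ and inorganic phosphate (Pi, as mono-anionic
H2PO4-) are co-transported 1:1, with Pi acting as a "transport chaperon"
that accelerates Ca2+ efflux severalfold. Characterizing that mechanism
takes a heterogeneous toolchain - transport kinetics, binding calorimetry,
luminescence resonance energy transfer, structure surveys, restraint-based
modeling, and alchemical free-energy bookkeeping. `caxport` implements that
toolchain as a tested, reusable Python library with synthetic-data
generators standing in for the raw measurements, so every stage is runnable
and checkable offline.

## What is in the box

| module              | what it does |
|---------------------|--------------|
| `synthetic_data`    | scaffold with a planted Ca2+/H2PO4- site; labelled survey fixtures; simulated rates, uptake time courses, calorimetric isotherms, luminescence decays, Gaussian alchemical work - all seeded and with known ground truth |
| `site_survey`       | geometric screen of PDB/mmCIF structures for a shared Ca2+/phosphate site (resolution <= 3.0 A, ion-pair closest approach <= 3.2 A, 2 acidic + 1 His flanking, < 70% sequence redundancy) |
| `restraint_model`   | the ten-restraint binding-site ledger (flat-bottom Ca2+ coordination, phosphate placement targets, chelate planarity) and a simulated-annealing sampler producing restraint-satisfying side-chain/ion ensembles on a frozen backbone |
| `ensemble_analysis` | no-superposition pairwise RMSD, leader clustering at 0.6 A, cluster statistics, voxel occupancy maps with an 85% contour, OpenDX export |
| `protonation_fep`   | per-window exponential averaging (BAR optional), equilibration discard, bidirectional mean +- half-difference, protein-vs-solution protonation ddG, pKa-shift conversion (-1.364 kcal/mol per pH unit at 298 K) |
| `assay_analysis`    | Michaelis-Menten fits, fold-acceleration, 1:1 stoichiometry by through-origin regression with bootstrap CI, one-site calorimetry fits, luminescence lifetimes and Forster distances, phosphate speciation vs pH |

A `caxport` command-line tool wraps the library
(`simulate`, `survey`, `model`, `cluster`, `occupancy`, `fep`, `assays`).

## Worked example

Recover the Ca2+ transport Km from a synthetic triplicate initial-rate
experiment (true Km = 69 uM, Vmax = 4.2 umol/min/g, 5% multiplicative
noise), then build a restraint-satisfying model of the shared binding site
and count the Ca2+ coordination shell:

```python
import numpy as np
from caxport.synthetic_data import gen_initial_rates, build_scaffold
from caxport.assay_analysis import fit_michaelis_menten
from caxport.restraint_model import (build_default_restraints,
                                     sample_ensemble, coordination_count)

rates = gen_initial_rates(km=69.0, vmax=4.2,
                          conc_grid=np.geomspace(10, 1000, 8),
                          noise_cv=0.05, n_rep=3, seed=1)
fit = fit_michaelis_menten(rates)
print(f"Km = {fit.km:.1f} uM (95% CI {fit.km_ci95[0]:.1f}-{fit.km_ci95[1]:.1f})")

scaffold = build_scaffold()
models = sample_ensemble(scaffold, build_default_restraints(scaffold),
                         n_models=5, seed=3)
n, partners = coordination_count(models[0])
print(n, [p for p, _ in partners])
```

prints

```
Km = 73.4 uM (95% CI 67.9-79.4)
7 ['ASN69:OD1', 'GLY68:O', 'GLU72:OE2', 'GLU255:OE1', '2HP402:O1',
   'GLU255:OE2', 'GLU72:OE1']
```

The fitted Km brackets the generating value within its confidence interval,
and the restraint-satisfying model coordinates Ca2+ with exactly seven
oxygens - the four carboxylate oxygens of the two chelating glutamates, the
G68 backbone carbonyl, the N69 side-chain carbonyl, and one phosphate
oxygen - the coordination number the restraint ledger is designed to imply.

The same steps from the shell:

```sh
caxport simulate kinetics --km 69 --vmax 4.2 \
    --grid 10,27,72,193,374,518,746,1000 --seed 1 --out rates.csv
caxport assays mm --in rates.csv
caxport model sample --n 50 --seed 3 --out ensemble.pdb
caxport cluster ensemble.pdb --threshold 0.6
```

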