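# Methods

This note documents the models, algorithms and numerical choices behind
`caxport`, in the order the pipeline runs them.

## Synthetic binding-site scaffold

The scaffold stands in for the alpha-repeat region of an inward-facing
H+/Ca2+ antiporter (CAX family) with Ca2+ and mono-anionic phosphate
(H2PO4-) bound at a shared central site. It carries the nine site positions
G68, N69, E72, N99, N252, E255, H256, S278 and Q281 as rigid single-residue
fragments built from ideal internal coordinates (NeRF placement; chi
torsions are the only side-chain degrees of freedom), plus one Ca2+ ion and
one tetrahedral phosphate.

Residues are placed rigidly so that the wild-type scaffold satisfies the
full default restraint ledger *exactly*: both carboxylates chelate Ca2+
bi-dentately at 2.50 A per oxygen, the G68 backbone carbonyl and N69
side-chain carbonyl sit at 2.40 A, the nearest phosphate oxygen at 2.45 A,
and the phosphorus-to-residue distances hit their targets (3.9 / 4.5 /
4.5 A), as do the two polar-network distances (3.2 / 4.2 A). Orientation
parameters of the outward-pointing residue bodies were chosen once so that
all non-contact heavy-atom pairs stay >= 2.8 A apart. Fidelity to any
particular crystal structure's backbone is *not* claimed - only the
inter-residue geometry needed for the restraints to be satisfiable, so no
external coordinate download is ever required.

Construction is deterministic: the same spec yields bit-identical
coordinates.

## Survey engine

The survey applies four filters in a fixed order, annotating every
rejection with the first failing criterion:

1. resolution <= 3.0 A (from REMARK 2 / the mmCIF refinement category);
2. a co-bound site: minimum over (Ca atom, phosphate non-H atom) pairs of
   the inter-ion distance <= 3.2 A. "Minimum distance" is read as closest
   approach, so Ca-to-oxygen rather than Ca-to-phosphorus typically decides;
3. flanking motif: >= 2 acidic residues (Asp/Glu) and >= 1 His with a
   side-chain functional atom (carboxylate O, imidazole N) within 4.5 A of
   either ion. The 4.5 A cutoff is a package default (configurable) - it is
   the upper end of salt-bridge/H-bond second-shell distances;
4. greedy redundancy removal in ascending-resolution (then lexicographic
   id) order: a hit is dropped when its best chain-pair global sequence
   identity to any previously accepted hit is >= 70%.

Identity uses Needleman-Wunsch (match +1, mismatch 0, gap open -5, extend
-1) with the denominator excluding terminal-gap columns. The criterion is
coarse (70%), so the exact substitution matrix is immaterial; the scoring is
fixed and documented so results are reproducible. Phosphate entities are
recognized by a configurable het-code whitelist {PO4, 2HP, PI, H2P}.

Running against the full PDB is an external-data mode: the engine takes any
set of PDB/mmCIF files; the in-repo fixtures (two planted positives, four
single-fault decoys) exercise every criterion without downloads.

## Restraint ledger and ensemble sampler

The ten logical restraints expand to 14 scalar terms:

| id  | form                       | atoms                                   | target    |
|-----|----------------------------|------------------------------------------|-----------|
| r1  | flat-bottom, sigma 0.1 A   | Ca - {E72 Oe1, Oe2; E255 Oe1, Oe2}       | <= 2.6 A  |
| r2  | flat-bottom                | Ca - nearest phosphate O                 | <= 2.6 A  |
| r3  | flat-bottom                | Ca - G68 carbonyl O                      | <= 2.6 A  |
| r4  | flat-bottom                | Ca - N69 side-chain O                    | <= 2.6 A  |
| r5  | harmonic target, sigma 0.1 | P - H256 Nd1                             | 3.9 A     |
| r6  | harmonic target            | P - N252 Cg                              | 4.5 A     |
| r7  | harmonic target            | P - S278 Og (ledger alias for "Cg")      | 4.5 A     |
| r8  | harmonic target            | Q281 Oe1 - N69 Nd2                       | 3.2 A     |
| r9  | harmonic target            | N252 Cg - N99 Cg                         | 4.2 A     |
| r10 | dihedral, sigma 20 deg     | (Ca, Oe1, Oe2, Cd) for E72 and E255      | 0 deg     |

Flat-bottom terms cost 0 up to the target and ((d - t)/sigma)^2/2 beyond;
harmonic targets are two-sided (fixed distances read as targets, not
bounds); the dihedral uses the minimal angular difference. r5-r9 share the
0.1 A sigma of r1-r4 by default (configurable) since no separate value is
given anywhere. Serine has no Cg; the selector S278:CG resolves to Og
through an explicit alias table, as do the Nd/Od names of Asn vs His
(ND2/OD1 vs ND1).

The chelate-planarity dihedral is evaluated over the atom ordering
(Ca, Oe1, Oe2, Cd): in the standard torsion convention this ordering reads
0 deg for the in-plane bi-dentate pose (the ordering Ca-Cd-Oe1-Oe2 would
read 180 deg for the same geometry), so a 0-deg target expresses the
intended planarity.

Sampling is simulated annealing over 18 chi torsions, the Ca2+ position and
the rigid-body phosphate pose (24 degrees of freedom), backbone frozen.
Each restart perturbs the scaffold configuration (chi sd 12 deg, positions
sd 0.15 A), then cools geometrically from T = 10 to 0.01 score units over
200 steps with one Metropolis proposal per degree of freedom per step; move
sizes shrink with sqrt(T). The annealing score adds two auxiliary channels
to the restraint pseudo-energy:

* soft-sphere sterics: heavy atoms of different residues penalized below
  2.7 A (sigma 0.1 A), excluding restrained pairs and the Ca2+ ion;
* coordination-shell exclusion: O/N atoms that are not among the seven
  designated partners (and all but the nearest phosphate oxygen) are
  penalized within 3.2 A of Ca2+.

A model is accepted when every restraint *and* auxiliary term deviates by
at most 3 sigma. The exclusion channel is what turns the ledger's implied
coordination number of 7 into an exact property of every accepted model:
without it, a stray amide oxygen could drift into the 3.0 A shell while all
ten restraints remained satisfied. Restarts are independently seeded, so
the ensemble is a pure function of (scaffold, restraints, n, seed, budget);
if the restart budget (default 3n) is exhausted, a partial ensemble is
returned with an explicit warning.

## Ensemble analysis

RMSD is computed over all non-hydrogen atoms of N69, E72, N99, N252, E255,
H256, S278, Q281 plus the two ions, *without* superposition - all models
share the frozen backbone frame, so direct RMSD is well defined.
Clustering is leader-style in model-index order (a model joins the first
cluster whose founding model is within the 0.6 A threshold, else founds a
new one), which makes every stated invariant assertable: members within the
threshold of their representative, populations summing to n, determinism.

Occupancy grids count, per voxel, the fraction of models with at least one
selected atom center inside the voxel (no smoothing; contour semantics
"value >= level", default level 0.85, default spacing 0.5 A); grids export
to OpenDX. One consequence of honest flat-bottom sampling deserves note:
the feasible region the coordination restraints leave the Ca2+ ion is
roughly 1 A across, so at 0.5 A spacing no single voxel reaches 85%
occupancy. The tightness test therefore uses 2.0 A cells, which cover the
feasible region; with them the Ca2+ 85% contour is a single cell centred
within 1 A of the construction seed. Contours computed from much tighter
optimizer-driven ensembles would concentrate at finer spacings; those
depend on the sampler, not on the analysis code tested here.

## Protonation free-energy bookkeeping

Energies are kept in kT internally and converted to kcal/mol only at
reporting (R = 1.98720e-3 kcal/mol/K, default T = 298 K). The per-window
estimator is exponential averaging, dG = -ln<exp(-dU)>, computed by
log-sum-exp (stable to at least |dU| = 700 kT, which is tested). Bennett's
acceptance ratio is available behind a flag for variance reduction; it
pairs forward window i with reverse window n-1-i and solves the implicit
equation by bracketing. Equilibration discard masks the first
ceil(fraction * n) samples of each window; masked samples never reach an
estimator, and a window left with fewer than two samples is an error.

Direction totals are signed so both estimate the same physical free energy;
the reported value is their mean and the error bar the half-difference.
The protein-vs-solution cycle gives ddG = dG(protein) - dG(solution) with
errors in quadrature; negative ddG means protonation is favoured in the
protein, i.e. an upshifted apparent pKa, with

    pKa shift = -ddG / (RT ln 10)  =  +1 pH unit per -1.364 kcal/mol at 298 K.

The synthetic work generator draws Gaussian dU with mu = dG_w + sd^2/2, so
the analytic per-window ground truth is exact (Gaussian exponential-average
identity); the reverse direction is generated independently with negated
ground truth. Reference ddG values for the antiporter's titratable sites,
which require membrane-protein MD to compute, are shipped as an annotated
table only and are never asserted.

## Assay models

* **Kinetics**: v = Vmax S/(Km + S), nonlinear least squares with Km and
  Vmax log-parameterized (positivity by construction); initial guesses
  Vmax = max(v), Km = S at half-max. CIs use the t distribution on the
  log-scale standard errors. Non-convergence is flagged, never replaced.
* **Stoichiometry**: through-origin OLS slope sum(xy)/sum(x^2) of paired
  per-time-point rates, with a seeded 1000-resample bootstrap percentile CI.
* **ITC**: single-site isotherm with standard perfusion-cell dilution
  bookkeeping (cell volume 1.4 ml); bound fraction from the 1:1 quadratic;
  injection heat = change in cell heat content with displaced-volume
  correction plus a fitted constant offset standing in for dilution heats.
  Kd is log-parameterized; in the low-c regime (c = n M/Kd << 1, e.g. the
  millimolar phosphate titration) n is fixed at 1, the standard remedy for
  the n-dH degeneracy. The Wiseman c-value is reported and flagged outside
  [0.01, 1e4].
* **LRET**: single-exponential fit y = A exp(-t/tau) + baseline, then the
  Forster equation R = R0 [tau_DA/(tau_D - tau_DA)]^(1/6). R0 for a given
  donor/acceptor pair is a required user input.
* **Speciation**: mono-anion fraction f = 1/(1 + 10^(pH - pKa)), pKa 7.2
  (two-species Henderson-Hasselbalch approximation).
* **pH profile**: argmax over the measured Vmax values, no interpolation
  (the underlying experiment is a discrete pH series); ties and boundary
  maxima are flagged rather than resolved.

## Synthetic-data conditions and what they do (not) show

Generator defaults mirror the experimental conditions they emulate: Ca2+
kinetics Km 69 uM /
Vmax 4.2 (no phosphate) and 198.7 uM / 33.3 (+5 mM phosphate) on an
8-point log-spaced 10-1000 uM grid in triplicate with 5% multiplicative
noise; phosphate kinetics Km 4.9 mM / Vmax 0.097 on a 7-point 0.5-40 mM
grid; titrations of 25 x 10 ul injections into a 1.4 ml cell (10 mM
phosphate into 10 uM protein; Ca2+ into 5 uM protein) with 0.05 ucal
additive heat noise; millisecond-scale luminescence decays with 1%
amplitude noise; 40-window alchemical paths. Where no measured value pins a
condition (uptake amplitudes, ITC enthalpies, decay sampling), values typical
of the instrument class were fixed once: saturating uptake with a
0.15/min approach rate, dH = -8 kcal/mol (Ca2+) / -3 kcal/mol (phosphate),
200-point decays over five lifetimes.

The generators emulate noise structure (multiplicative CV on rates,
additive on heats and photon traces) and the coupling/control logic of the
assays (1:1 Pi:Ca flux in co-transport mode, zero transport with a
protonophore, with empty vesicles, or with Ca2+ chelated). They do not
emulate membrane voltage, vesicle leakage, baseline drift, titrant
impurities or correlated instrument noise - so passing round-trip tests
shows the estimators are correct and well-conditioned under these assay
designs, not that real traces of arbitrary quality would fit as well.

Reproduction scale: the ensemble-based checks run on 1-50 model ensembles
rather than thousands; cluster-population fractions are properties of
whichever sampler produced an ensemble, so the clustering code is checked
through its invariants (membership within threshold, population
conservation, determinism) rather than against any particular fractions.

## Known limitations

* The scaffold is an idealized construction, not a crystal structure;
  survey fixtures made from it are labelled synthetic.
* The annealer explores the basin around the restraint-feasible manifold it
  is seeded in; it is a restraint-satisfaction sampler, not a conformational
  search, and makes no ergodicity claim.
* The FEP module consumes energy-difference samples; it contains no MD
  engine, force field or dual-topology structure building.
* Through-origin stoichiometry assumes errors mainly in the Pi channel;
  with 5% CV on both channels the attenuation bias (~cv^2) is negligible
  but would matter at much higher noise.
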