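# saxsflex

SAXS ensemble optimization for multidomain proteins with flexible
hinges. The package implements the full analysis loop used to detect
interdomain flexibility from small-angle X-ray scattering:

1. **Topology** (`saxsflex.topology`) — declare a chain as rigid
   segments (Calpha bead templates, from PDB or generated toy rods) and
   flexible segments by inclusive residue ranges.
2. **Conformer pools** (`saxsflex.conformers`) — generate random
   clash-free conformers in which rigid segments move as units and
   flexible linkers are resampled as self-avoiding virtual-bond chains;
   per-conformer descriptors: Rg, Dmax, end-to-end distance, inter-arm
   angle and U/L/I shape class.
3. **Scattering** (`saxsflex.saxs`) — Debye-formula intensities (exact
   double sum and a histogram-accelerated mode), self-consistent Guinier
   fits, Kratky transforms, pair-distance histograms, and 3-column
   `.dat` curve I/O.
4. **Fitting** (`saxsflex.fitting`) — analytic least-squares scale and
   reduced chi-square of model curves against data with uncertainties.
5. **Ensemble selection** (`saxsflex.selection`) — genetic-algorithm
   selection of the size-50 sub-ensemble (multiset, repetition allowed)
   whose average curve best fits the data, plus pool-vs-selected
   distribution summaries with peak detection.
6. **Synthetic ground truth** (`saxsflex.synthetic`) — named scenarios
   (`L_shape`, `bimodal_UI`, `uniform_flexible`, `rigid_linear`) with
   declared inter-arm-angle distributions and calibrated noisy SAXS
   data, so the whole pipeline is testable offline.
7. **Pipeline** (`saxsflex.pipeline`, `saxsflex.cli`) — the three-model
   comparison (rigid linear-extended vs rigid-linker "linear" vs
   flexible "hinged") on one data curve, ranked by chi-square.

## Command line

Every subcommand takes `--seed`, `--config` (YAML, overridden by flags)
and `--out`, and logs its effective parameters:

```sh
# fabricate a ground-truth fixture (topology + truth pool + noisy data)
saxsflex simulate --scenario bimodal_UI --seed 1 --out fixture/

# full three-model comparison at desk scale
saxsflex compare --data fixture/data.dat --topology fixture/topology.yaml \
    --pool-size 1000 --ensemble-size 50 --seed 1 --out comparison/

# individual stages
saxsflex pool --topology fixture/topology.yaml --n 10000 --seed 1 --out pool/
saxsflex saxs --model arm.pdb --out arm.dat
saxsflex fit-rigid --model arm.pdb --data fixture/data.dat --out fit.json
saxsflex select --pool-dir pool/ --topology fixture/topology.yaml \
    --data fixture/data.dat --ensemble-size 50 --seed 1 --out selected/
saxsflex summarize --pool-dir pool/ --topology fixture/topology.yaml \
    --ensemble selected/ensemble_members.tsv --data fixture/data.dat --out summary/
```

Defaults follow the reference protocol (pool of 10,000 conformers,
selected ensembles of 50); scale `--pool-size` down to ~1,000 for quick
runs.

## Conventions

* q = 4 pi sin(theta) / lambda, in inverse Angstrom; default grid
  0–0.25 A^-1, 101 points.
* One bead per residue at the Calpha position, unit scattering weight by
  default; virtual bonds of 3.8 A.
* Reduced chi-square uses K-1 degrees of freedom (the fitted scale);
  configurable.
* All randomness flows through numpy `SeedSequence` spawning, so pools,
  GA runs and synthetic data are reproducible from a single seed.
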