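# ctmorph

Single-nucleus 3D quantification of chromosome territories (CTs) in
multichannel fluorescence z-stacks, built for the kind of question asked
about early embryos at zygotic genome activation: how large and how round is
each labelled chromosome or chromosome arm relative to its nucleus, how much
do neighbouring territories intermix, and in what fraction of nuclei are the
two parental homologs paired?

It is aimed at imaging groups who label whole chromosomes or arms with
Oligopaint-style FISH probes (plus a DNA counterstain and optionally an
immunofluorescence channel) and want an open, scriptable replacement for
closed-source blob/compartment analysis — with a built-in synthetic-data
simulator so the whole measurement chain can be validated against exact
ground truth.

## What it computes

* **Segmentation** — nuclei from the DNA channel (Otsu + watershed on the
  Euclidean distance transform, physical units, border handling), FISH
  signals per channel by per-nucleus thresholding with spot-level
  watershed splitting of fused spots.
* **Morphometrics** — volume (voxel count × voxel volume), volume
  normalized to the host nucleus V_CT / V_nuc, sphericity
  Ψ = π^⅓(6V)^⅔ / A from a marching-cubes surface mesh (Ψ = 1 for a
  sphere), territory overlap as 100·|A∩B|/|A| and 100·|A∩B|/|B|, and mean
  intensity with the k brightest nuclear bodies excluded.
* **Homolog pairing** — a nucleus is paired for a target when its two
  signals lie ≤ 0.8 µm apart in 3D or only one signal is present; arm ×
  centromere calls cross into six conformation classes; replicate
  aggregation reports mean ± SD across replicates with n ≥ 300 nuclei /
  ≥ 3 replicate reporting minimums.
* **Statistics** — two-sided Mann-Whitney U (exact for small samples),
  Fisher's two-tailed exact test, Levene's test (median-centred), and KDE
  bimodality detection with antimode location.
* **Simulation** — fields of non-overlapping ellipsoidal nuclei with
  per-channel territory/homolog placement at a configurable pairing
  fraction, Gaussian PSF, Poisson + read noise, and exact truth tables.

## Worked example

Simulate three replicates of a 40-nucleus field (FISH channel at pairing
fraction 0.8), run the full pipeline, and read the pairing summary:

```python
from ctmorph import protocols
from ctmorph.pipeline import run_pipeline
import pandas as pd

run_pipeline(protocols.demo_pipeline_config("demo_out", seed=1))
print(pd.read_csv("demo_out/pairing_summary.csv").to_string(index=False))
```

```
target  mean_percent_paired  sd_percent_paired  total_nuclei  n_replicates  reportable
  chr2            85.833333           5.204165           120             3        True
```

85.8% ± 5.2 of the 120 nuclei (3 replicates × 40) are called paired —
consistent with the generating fraction of 0.8 plus the merged/≤0.8 µm
placements the call counts as paired. `demo_out/` also contains per-nucleus
and per-signal tables, the paired-versus-unpaired combined normalized
volumes with their Mann-Whitney and Levene comparisons (`stats.csv`), label
TIFFs, and a JSON manifest; for this run all 40 nuclei per replicate are
recovered, matching the simulator truth counts recorded in the manifest.

The same stages are available from the shell:

```sh
ctmorph simulate --config sim.yaml --seed 1 --out sim_out/
ctmorph quantify --image stack.ome.tif --dna-channel dna --out q_out/
ctmorph pair --calls run_out/pairing_calls.csv --min-nuclei 300
ctmorph run --config pipeline.yaml --seed 1
```

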