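# woundsight

Quantification of exocytosis and endocytosis during plasma-membrane wound
repair, for cell biologists analyzing laser-ablation time-lapse movies.

When a cell's plasma membrane is wounded, a membrane-impermeable dye
(e.g. FM4-64) floods in until the wound reseals — typically within ~30 s.
Early-endosome exocytosis delivers membrane to the wound zone in the first
~10 s, and clathrin-mediated endocytosis later retrieves it at the same
sites, a sequence that regulates membrane tension during repair.
`woundsight` implements the measurements that establish this picture:

* **punctae detection** — per-frame spot detection (difference-of-Gaussians
  band-pass → noise-quantile threshold → connected components → size
  filter), with externally produced probability maps accepted as input;
* **concentric-ring quantification** — event counts per circle ROI around
  the wound (circle 1 nearest, circle 6 farthest, 20 µm diameter
  increments), normalized per ring to the pre-wound count (null baselines
  set to 1) and the ring area in µm² — the [ring × time] heatmap matrices;
* **resealing kinetics** — background-corrected dye-influx curves with a
  plateau-vs-linear classifier, the around-wound 20 µm ROI curve, wound
  delineation area fractions, and scrape-assay repair percentages;
* **spatial statistics** — object-based colocalization matrices and the
  nearest-neighbor exo→endo association series (k-d tree), with the far-ring
  control;
* **membrane biophysics** — the hole-energetics model
  `H(R) = 2E + 2πRλ − πR²σ` with critical radius `R_c = λ/σ`, hole-fate
  scans under tension reduction, and tether-force plateau extraction from
  optical-tweezers traces;
* **a synthetic-data generator** — movies, force traces and count tables
  with known ground truth, so the whole pipeline is testable without raw
  imaging data.

## The model at the core

A circular hole of radius `R` costs edge energy (line tension `λ`, in N)
and releases area energy (membrane tension `σ`, in N/m):

    H(R) = 2E + 2πRλ − πR²σ,      dH/dR = 0  at  R_c = λ/σ

`H` is concave, so `R_c` is an energy barrier: holes with `R < R_c` reseal
spontaneously, larger ones grow.  With standard values `λ ≈ 1 pN` and
`σ ≈ 1e−5 N/m`, `R_c = 100 nm`; lowering tension one order of magnitude
moves it to `1 µm` — which is why locally reduced membrane tension (via
exocytic membrane delivery and actin depolymerization) rescues the
resealing of micron-scale wounds.

## Worked example

Simulate a resealing wound movie, run the full chain, and read the results:

```bash
woundsight simulate movie --seed 4 --out sim
woundsight detect sim/movie.ome.tif --out punctae.csv
woundsight quantify punctae.csv sim/movie.ome.tif --out quant
woundsight nnassoc punctae.csv sim/movie.ome.tif --out nn
woundsight kinetics influx --movie sim/movie.ome.tif --out influx.csv
woundsight physics critical-radius --line-tension 1e-12 --tension 1e-5
woundsight physics scan --radius 1e-6 --factors 1,0.1,0.05
```

which prints, stage by stage:

```
wrote movie (102 frames) and ground truth to sim
65196 punctae over 102 frames → punctae.csv
count matrix [6 rings × 102 frames] → quant
nearest-neighbor series → nn
classification: resealed
{"R_c_m": 1e-07, "R_c_nm": 100.0}
{"1.0": "grow", "0.1": "critical", "0.05": "reseal"}
```

Reading the artifacts with pandas shows the planted biology recovered:

* `quant/count_matrix.csv` — mean normalized density in circle 1 during the
  exocytic window is 0.0023 µm⁻² versus 0.0003 µm⁻² in circle 6 (~8× inner-
  ring elevation, from the 5× burst planted near the wound);
* `nn/nn_reference.csv` — the circle-1-referenced normalized nearest-
  neighbor distance averages 1.015 before resealing and drops to 0.942
  afterwards: endocytosis concentrating at previous exocytic sites;
* `influx.csv` — the dye curve saturates and the verdict is `resealed`,
  matching the generator's ground truth;
* the physics lines print the 100 nm critical hole size at standard tension
  and show a 1 µm hole turning from growing to resealing as tension drops
  10–20×.

The same chain is available programmatically (`woundsight.generate_movie`,
`detect_punctae`, `count_matrix`, `nn_series`, `influx_curve`,
`critical_radius`, …) and as one reproducible run with a provenance
manifest: `woundsight run --config cfg.yaml --seed 7 --out run/`.

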