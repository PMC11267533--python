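# cspscreen

Analysis pipeline for protein-observed NMR fragment screening: from
assigned ¹⁵N-HSQC peak lists to triaged mixtures, deconvoluted hits,
apparent dissociation constants, and per-residue structure maps.

Fragment-based drug discovery against a protein target often starts with
a ¹⁵N-HSQC screen: fragments are delivered in mixtures (here, ten at a
time at a 4:1 fragment:protein molar ratio), and binding shows up as
chemical shift perturbations (CSPs) of backbone amide resonances.
`cspscreen` implements the downstream analysis for such a screen of a
membrane-bound target with an annotated functional surface (cationic
patch and catalytic site residues), and ships a ground-truthed synthetic
data generator so every stage can be validated end-to-end.

## The model

For each assigned amide, the perturbation between a reference and an
observed spectrum is the weighted combined shift

```
Δδ = sqrt( (Δδ_H)² + (α · Δδ_N)² ),   α = 0.14
```

Mixtures are triaged by counting interface-region resonances with
Δδ > 0.01 ppm; flagged mixtures are deconvoluted by retesting members
singly, and a fragment is called a hit when ≥ 7 of the 15 observable
functional resonances shift by more than 0.01 ppm.

Because screening concentrations (tens to hundreds of μM) are comparable
to the protein concentration, bound ligand depletes the free pool and the
hyperbolic isotherm is invalid. Titrations are fit with the exact 1:1
solution in total concentrations,

```
f_bound = ((P + L + Kd) − sqrt((P + L + Kd)² − 4·P·L)) / (2·P)
Δδ(L)   = Δδ_max · f_bound(P, L, Kd)
```

assuming fast exchange. Top-shifting resonances (CSP ≥ 1σ above the
profile mean at the highest titration point) are fit individually, fits
with R² < 0.85 are discarded, and the survivors are refit jointly with
one shared apparent K_d and per-residue Δδ_max; the K_d standard error
comes from the joint-fit covariance. Fragments are classified as hits
(K_d < 1 mM and structurally localized shifting), weak binders
(localized but K_d ≥ 1 mM), or nonspecific (delocalized).

## Worked example

Simulate a 100-fragment screen with three planted binders (K_d = 105 μM,
realistic peak noise), then run triage → deconvolution → titration:

```python
from cspscreen import run_pipeline

summary = run_pipeline({
    "mode": "simulate",
    "seed": 11,
    "outdir": "demo",
    "simulate": {"library_size": 100, "n_binders": 3, "mixture_size": 10},
})
```

which prints (via `summary.json`):

```json
{
  "hit_rate_percent": 3.0,
  "kd_uM": {
    "F0013": 115.14396309278686,
    "F0014": 92.84195262783321,
    "F0080": 115.87821504492344
  },
  "n_deconvoluted": 3,
  "n_flagged": 2,
  "n_mixtures": 10,
  "n_validated_hits": 3,
  "planted_binders": ["F0013", "F0014", "F0080"],
  "validated_hits": ["F0013", "F0014", "F0080"]
}
```

Two mixtures were flagged (two planted binders happen to share one
mixture), all three planted binders — and nothing else — passed the
7-of-15 deconvolution rule, and their fitted apparent K_d values scatter
around the planted 105 μM as expected at this noise level. The output
directory also holds `mixtures.csv` (triage tiers), `deconvolution.csv`,
`fits.csv` (K_d, stderr, classification per fragment) and `truth.csv`.

The same stages are exposed on the command line (`cspscreen simulate`,
`screen`, `deconvolute`, `titrate`, `map`, `report`, `run`), reading
Sparky-style `.list` peak lists, a `residue,category` annotation CSV and
a YAML config. `cspscreen map` additionally writes per-residue CSPs into
the B-factor column of a PDB copy (CSP × 1000) for structure coloring.

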