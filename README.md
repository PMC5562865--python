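# cntnmech

Single-molecule AFM force-spectroscopy analysis of multidomain adhesion
proteins, built around contactin-4 (CNTN4): a synthetic saw-tooth
curve generator with ground truth, the worm-like-chain (WLC) inference
pipeline that turns retraction traces into per-event unfolding lengths
and rupture forces, Gaussian-mixture population statistics with
detectors for the characteristic spectral signatures, and an
anisotropic-network-model (ANM) mechanical-stiffness module.

## The scientific problem

CNTN4's ectodomain is a chain of six immunoglobulin C2-type (IgC2)
modules followed by four fibronectin type III (FnIII) modules. Pulled
between an AFM tip and a substrate, the chain unfolds module by module,
producing a saw-tooth force-extension curve. Each rising branch follows
the Marko–Siggia worm-like chain,

    F(x) = (k_B T / L_p) · [ 1/(4(1 − x/L_c)²) − 1/4 + x/L_c ],

with persistence length `L_p ≈ 0.4 nm` and a contour length `L_c` that
grows by `ΔL` at every rupture. `ΔL` fingerprints the module that
unraveled: FnIII modules release ~31 nm, while each IgC2 module is
clamped by an internal disulfide bridge and releases only the residues
outside the Cys–Cys loop (~10 or ~17 nm depending on loop size).
Rupture forces are class-specific too (IgC2 weaker than FnIII). Pooled
over thousands of events, the ΔL histogram decomposes into three
Gaussian populations and the per-class force histograms into two each.
Secondary signatures carry extra structure: a 13–18 nm intermediate
("hump") inside an FnIII unfolding, an initial 23.1–24.4 nm partial
unfolding of FnIII₁, and a long ~20 pN plateau from the opening of the
horseshoe arrangement of the first four IgC2 modules.

The package is for researchers who need a tested, reproducible version
of this analysis chain — and a generator of realistic synthetic curves
with ground truth to validate it end to end.

## Worked example

```sh
cntnmech simulate --n 200 --seed 42 --out curves
cntnmech analyze  --in curves --out events.tsv
cntnmech mixture  --events events.tsv --out mixtures.tsv --dl-max 37.2
```

The run above printed:

```
INFO cntnmech: wrote 200 curves to curves
INFO cntnmech: analyzed 200 curves: 138 selected (>=4 peaks), 67 strong-attachment; events written to events.tsv (version=0.1.0)
INFO cntnmech: mixture parameters written to mixtures.tsv (method=histogram-LS seed=0 version=0.1.0)
```

and `mixtures.tsv` held:

```
population     component  mean     sd       weight    n
dL_nm          1          11.3471  2.65254  0.252508  886
dL_nm          2          18.2282  3.47365  0.334922  886
dL_nm          3          30.6104  2.67317  0.41257   886
Fmax_IgC2_pN   1          65.217   11.096   0.48777   508
Fmax_IgC2_pN   2          103.389  23.8851  0.51223   508
Fmax_FnIII_pN  1          85.3837  20.9445  0.640074  378
Fmax_FnIII_pN  2          162.069  35.5103  0.359926  378
```

Reading: of 200 synthetic pulls, 138 passed the ≥4-clear-maxima quality
filter and 67 were strong attachments (7–10 peaks, high detachment
force). The 886 recovered contour-length increments decompose into the
two clamped IgC2 populations (~11 and ~18 nm here; at this small sample
the component means scatter by 1–2 nm) and the full FnIII population
(30.6 nm). IgC2 modules rupture around 65/103 pN, FnIII around 85/162
pN. `cntnmech report` draws the corresponding histograms;
`cntnmech mechstiff` computes per-residue effective spring constants
from a Cα PDB.

The same chain is available as a library; see `cntnmech.simulate`,
`cntnmech.pipeline`, `cntnmech.population`, `cntnmech.mechstiff`.

## Data formats

Curves travel as plain TSV (`#`-prefixed `key = value` metadata, then
`separation_nm` / `force_pN` columns at 9 significant digits); events,
mixtures and stiffness tables are TSV as well. Native instrument
formats are not parsed — any converter that emits the curve dialect
plugs in upstream.
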