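# nsc-color

Species-independent color distances from spectral reflectance curves.

The package implements the **normalized segment classification (NSC)** color
model: the visible range is split into `n + 1` equal wavelength segments for a
viewer with `n` receptor types, each segment's share of total photon flux
gives a relative brightness, and a color locus is built from `n - 1`
chromatic opponent coordinates (for a trichromat, `Z1 = R - G`,
`Z2 = Y - B`) plus an achromatic coordinate `Zn = beta / beta_m` — brightness
relative to a perfect white reflector, in [0, 1]. Distances are Euclidean
with the achromatic term weighted by a free parameter `alpha` (`alpha = 1`:
proposed model; `alpha = 0`: the classic chromatic-only segment scheme).
Also included:

* Endler's segment classification (polar chroma/hue coordinates plus raw
  brightness `X3`) and its trigonometric chromatic distance;
* a chromatically **normalized** NSC variant (`2*(R-G)/(R+G)`, ...) with a
  guard against near-zero denominators;
* three comparator color-discrimination models on receptor excitations:
  color-opponent coding (city-block metric), the color hexagon, and
  receptor-noise-limited loci (species-dependent parameters, linear or
  log excitations), plus the rectangular-sensitivity approximation
  `E_S = B+G, E_M = G+Y, E_L = Y+R`;
* an evaluation harness rank-correlating (Spearman) model distances against
  behavioral proportion-correct data;
* a synthetic-spectra generator (sigmoid / bell / flat / step reflectances)
  so everything is testable offline.

Built-in plain-text data: the CIE D65 daylight table (energy units, with a
photon-unit conversion used by default, since segment brightness is a photon
flux) and the green-foliage reflectance + photon-unit D65 tables distributed
with the pavo R package (v2.4.0), used by the brightness-sum integration
targets.

## Library quick start

```python
import nsc

grid = nsc.WavelengthGrid(300, 700, 1)
d65 = nsc.builtin_illuminant("d65", grid=grid)
part = nsc.SegmentPartition(300, 700, n_receptors=3)

red = nsc.generate(nsc.SpectrumRecipe("sigmoid", center=600, width=15), grid)
gray = nsc.generate(nsc.SpectrumRecipe("flat", ceiling=0.5), grid)

locus_red = nsc.nsc_locus(nsc.radiance(red, d65), d65, part)
locus_gray = nsc.nsc_locus(nsc.radiance(gray, d65), d65, part)
print(nsc.nsc_distance(locus_red, locus_gray, nsc.DistanceSpec(alpha=1.0)))
```

## CLI

```sh
nsc fixtures --out demo/                      # write the synthetic suite
nsc loci --spectra spectra.csv --illuminant d65 --range 300:700 --n 3
nsc dist --spectra spectra.csv --alpha 1.0
nsc compare --excitations exc.csv --model hexagon
nsc evaluate --behavior beh.csv --spectra spectra.csv \
    --models nsc,nsc0,nscnorm,coc,hexagon
```

Spectra CSVs have a `wavelength` column (nm, uniform spacing) and one column
per spectrum. Behavioral CSVs: `pair,stimA,stimB,prop_correct` plus optional
precomputed `dist_<model>` columns. Shared options can live in a YAML config
(`--config`): keys `range`, `step`, `n_receptors`, `variant`, `alpha`,
`illuminant`.

## Conventions worth knowing

* Brightness is an **unweighted sum** over grid samples (no `dlambda`
  weighting), so Endler's `X3` depends on bin width; the NSC achromatic
  coordinate `beta/beta_m` does not.
* Segments are half-open `[lambda_{i-1}, lambda_i)`, final segment closed.
* Reflectance above 1 warns but proceeds (measured-spectrum artifacts);
  negative values and non-uniform wavelength spacing are errors.
* Resampling is linear interpolation and never extrapolates.
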