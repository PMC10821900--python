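# skinquant

Quantification of UVB-induced melanocyte epidermal migration from
two-channel fluorescence images of mouse skin, together with a synthetic
ground-truth image generator that makes every stage of the measurement
chain verifiable end to end.

## The problem

After UVB irradiation, melanocyte stem cells (McSCs) leave the hair-follicle
bulge and repopulate the interfollicular epidermis — the cellular basis of
repigmentation in depigmenting conditions such as vitiligo.  On whole-mount
skin imaged from the surface, the measurement is:

* **red channel** — hair follicles autofluoresce; counting them gives the
  denominator (~320 follicles per field, 20–25 fields per mouse, so each
  animal's rate rests on 6400–8000 follicles);
* **green channel** — nuclear H2B-GFP labels melanocyte nuclei as
  point-like signals, but the follicle autofluorescence bleeds through;
  after balancing the green channel with a scaled copy of the red channel,
  the surviving points are the migrated McSCs.

The per-mouse statistic is the pooled ratio

```
migration rate = number of McSCs / number of hair follicles
```

Sectioned-tissue readouts are also covered: positive-staining-area / DAPI-area
ratios (e.g. Ly6G, Cox-2), cells-per-image counts (e.g. CD3+ T cells,
epidermal melanocytes per frame), and object-based EdU–reporter
colocalization fractions.  Group comparisons use two-tailed Welch t, paired
t, or Mann–Whitney U, with SEM error reporting, plus per-mouse
normalization by an expression level (Cox-2 scheme) or by a littermate
control's rate.

Because no image data are deposited for the source experiments, the package
ships a generator (`skinquant.simulate`) that emulates this geometry with
exact ground truth — follicle centres, melanocyte positions, bleed
coefficient, painted mask areas — so detection, unmixing, counting and the
statistics layer are all validated against known answers.

## Worked example

```python
from skinquant import FieldParams, generate_wholemount, quantify_field

params = FieldParams(width_px=1024, height_px=1024, n_follicles=80,
                     mcsc_rate=0.2, bleed_alpha=0.30, seed=7)
field, truth = generate_wholemount(params)
q = quantify_field(field)
```

prints (via `python examples/02_bleed_correction_and_spot_counting.py`):

```
true bleed coefficient    : 0.300
estimated bleed coefficient: 0.302
true melanocytes          : 14
detected melanocytes      : 14
per-field migration rate  : 0.1750
```

The robust green-vs-red slope recovers the simulated 30% bleed-through to
three decimals, and after unmixing every Poisson-placed GFP nucleus is
found, giving the field's migration rate (14 melanocytes / 80 follicles).
The other scripts under `examples/` walk through follicle counting,
section area ratios and colocalization, and a two-group in-silico study
ending in a Welch test on per-mouse rates.

A thin CLI mirrors the library:

```bash
skinquant simulate mouse --seed 1 --out sim/
skinquant quantify wholemount --in sim/ --out results/
skinquant stats compare --counts results/per_mouse.csv --test welch_t --out results/
skinquant run --config study.yaml --seed 1 --out results/
```

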