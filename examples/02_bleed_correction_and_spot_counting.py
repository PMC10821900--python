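"""Estimate red->green bleed-through, unmix, and count GFP nuclei.

Hair-follicle autofluorescence leaks from the red into the green channel.
The pipeline fits the leak coefficient (a robust green-vs-red slope over
follicle pixels), subtracts the scaled red channel, and counts the
remaining point-like nuclear GFP signals — the migrated melanocytes.
"""

from skinquant import FieldParams, generate_wholemount, quantify_field

params = FieldParams(width_px=1024, height_px=1024, n_follicles=80,
                     mcsc_rate=0.2, bleed_alpha=0.30, seed=7)
field, truth = generate_wholemount(params)
q = quantify_field(field)

print(f"true bleed coefficient    : {truth.bleed_alpha:.3f}")
print(f"estimated bleed coefficient: {q.unmix.alpha:.3f}")
print(f"true melanocytes          : {truth.n_mcsc}")
print(f"detected melanocytes      : {q.record.n_mcsc}")
print(f"per-field migration rate  : {q.record.n_mcsc / q.record.n_follicles:.4f}")
# The estimated coefficient should sit within ~0.02 of the truth, and the
# detected spot count should match the Poisson-drawn truth: unmixing makes
# the dim nuclear points countable against follicle autofluorescence.
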