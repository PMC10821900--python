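"""Generate one default whole-mount field and count its hair follicles.

The red channel of a whole-mount skin field carries hair-follicle
autofluorescence; the follicle count is the denominator of the melanocyte
migration rate.  The default geometry places 320 follicles per
2048x2048 px field, matching the acquisition this pipeline models.
"""

from skinquant import FieldParams, detect_follicles, generate_wholemount

field, truth = generate_wholemount(FieldParams(seed=1))
det = detect_follicles(field.red)

print(f"true follicles placed : {truth.n_follicles}")
print(f"detected follicles    : {det.count}")
print(f"relative error        : {abs(det.count - truth.n_follicles) / truth.n_follicles:.2%}")
# A relative error of a few percent or less means the blob detector is
# recovering the per-field denominator the migration rate depends on.
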