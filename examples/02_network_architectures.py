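"""Build the two reconstruction networks and inspect their wiring.

The stage-1 completion network (10 rows) repairs a low-resolution
defective skull; the stage-2 enhancement network (14 rows) lifts the
repaired model back to full resolution using the original defective
volume. Parameter totals are a pure function of the layer spec — the
builds below print 8,269 and 11,741 regardless of grid size.
"""

from craniofill.nn.networks import (
    build_completion_network,
    build_enhancement_network,
    count_trainable_parameters,
)

completion = build_completion_network((128, 128, 96), seed=0)
print(f"completion network: {count_trainable_parameters(completion)} parameters")
for i, row in enumerate(completion.spec.layers, 1):
    print(f"  row {i:2d}: {row.kind:14s} channels={row.channels_out}"
          + (" (dilation 2)" if row.dilation == 2 else ""))
print(f"  skip summations: {completion.spec.skip_pairs}")
print(f"  projections: {completion.spec.projections}")
print("  output = sigmoid conv + input (existing bone is always kept)\n")

enhancement = build_enhancement_network((128, 128, 96), (512, 512, 384), seed=0)
print(f"enhancement network: {count_trainable_parameters(enhancement)} parameters")
for i, row in enumerate(enhancement.spec.layers, 1):
    shared = f" [shared with {row.shares_weights_with}]" if row.shares_weights_with else ""
    print(f"  row {i:2d}: {row.kind:14s} channels={row.channels_out}{shared}")
print("  the two input streams merge by summation at half resolution;")
print("  predictions are thresholded at 0.45 to recover binary bone")
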