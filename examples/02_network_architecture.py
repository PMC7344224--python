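"""Inspect the 2D U-Net architecture and its capacity dial.

Prints the layer table of the quarter-width network and the convolution
weight totals of both standard widths. The full-width model (base_filters
64) carries ~13.4 million convolution weights, the quarter-width one
(base_filters 16) ~0.84 million — a 16x ratio, i.e. every layer's filter
count divided by four.
"""

from cmrseg import UNetConfig, count_conv_weights, describe_unet

desc16 = describe_unet(UNetConfig(base_filters=16))
print(desc16.to_table())

for f in (64, 16):
    n = count_conv_weights(describe_unet(UNetConfig(base_filters=f)))
    print(f"base_filters={f:2d}: {n:>12,} conv weights  ({n/1e6:.2f} million)")
ratio = (count_conv_weights(describe_unet(UNetConfig(base_filters=64)))
         / count_conv_weights(describe_unet(UNetConfig(base_filters=16))))
print(f"width ratio 64/16 -> weight ratio {ratio:.3f} (~16: filters per layer x4)")
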