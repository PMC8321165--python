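"""Build the two segmentation networks and audit their parameter ledgers.

The U-Net is the classic encoder–decoder with skip connections (two biased
k×k convolutions per stage, 32→256 feature maps, dropout 10% after each
conv); E-Net is the compact bottleneck network with batch normalization.
The printed totals are what a deep-learning framework would report as
trainable / non-trainable parameters.
"""

from fibroseg import build_model, count_parameters

for kind in ("unet3", "unet5", "enet"):
    net = build_model(kind)
    pc = count_parameters(net)
    convs = sum(1 for e in net.ledger() if "conv" in e["kind"])
    print(f"{kind:>6}: {pc.trainable:>9,} trainable  {pc.non_trainable:>5,} "
          f"non-trainable  ({convs} convolution layers)")

print("\nThe E-Net non-trainable parameters are the batch-norm moving mean/variance;")
print("the U-Net has none because it uses no batch normalization.")
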