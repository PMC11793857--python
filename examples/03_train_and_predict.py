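"""Two-stage training at toy scale, then end-to-end prediction.

Stage 1 fits the dual-decoder segmentation module (region + contour
losses, alpha warm-down); stage 2 trains the clinical-staging heads under
the encoder fine-tuning (FT-E) setup with class-balanced cross-entropy.
Sized for a quick demonstration, not for accuracy: expect the printed
losses to fall but grades to be unreliable at this scale.
"""

from xcelunet.network import NetworkConfig
from xcelunet.preprocessing import build_dcls, build_dseg
from xcelunet.synthetic import generate_dataset
from xcelunet.training import (
    TrainConfig,
    predict,
    train_classification,
    train_segmentation,
)

net = NetworkConfig(seed=0)
phantoms = generate_dataset(6, seed=8, grid_shape=(32, 32, 32))

cfg1 = TrainConfig(seed=0, max_epochs=3, batch_size=2, network=net)
weights, rec1 = train_segmentation(build_dseg(phantoms[:5]), cfg1)
print(f"stage 1: {rec1.stopping_epoch} epochs, train loss "
      f"{rec1.train_losses[0]:.3f} -> {rec1.train_losses[-1]:.3f} "
      f"(region + contour loss, perfect prediction would reach 0)")

dcls = build_dcls(phantoms[:5], crop_edge=16)
cfg2 = TrainConfig(seed=0, max_epochs=3, batch_size=4, freeze_setup="FT-E",
                   network=net)
weights2, rec2 = train_classification(weights, dcls, cfg2)
print(f"stage 2 (FT-E): head warm-up on pooled features already fits this "
      f"tiny corpus, then {rec2.stopping_epoch} fine-tuning epochs keep the "
      f"classification loss at {rec2.train_losses[-1]:.3f}")

res = predict(weights2, phantoms[5].ct, net_cfg=net, crop_edge=16)
print(f"prediction status: {res.status}")
if res.conditions:
    print(f"predicted grades (os, js, hsa) = ({res.conditions.os_grade}, "
          f"{res.conditions.js_grade}, {res.conditions.hsa}); "
          f"truth = ({phantoms[5].truth.os_grade}, "
          f"{phantoms[5].truth.js_grade}, {phantoms[5].truth.hsa})")
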