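# gramnet

Tools for liver-CT image analysis built around two ideas:

1. **En–DeNet** — a UNet-shaped encoder–decoder that segments the liver (or
   its tumors) from 2-D slices, trained with a combined
   `BCE + 0.2 · (1 − DC)` loss, followed by binarization at 0.5 and
   connected-component fragment clearing.
2. **GraMNet** — *gradational modular network* construction for
   classification: small convolutional SubNets are added to a frozen
   existing network in series (the new SubNet consumes the network's final
   feature maps) or in parallel (both branches read the raw input and their
   feature maps are depth-concatenated), and **only the newest SubNet plus
   the classification head is trained at each stage**. This keeps the
   per-stage trainable parameter count near the size of one small SubNet
   no matter how large the assembled network grows.

Because the real CT collections (LiTS, 3DIRCADb01) cannot be redistributed,
the package ships a synthetic **phantom generator**: elliptical "livers" on
a darker background containing hypodense (darker) or hyperdense (brighter)
circular "tumors", with Gaussian noise and a benign/malignant label
(malignant ⇔ tumor present). Every pipeline — preprocessing, augmentation,
segmentation, staged classification, evaluation — runs end to end on these
phantoms at desk scale. Thin loaders for per-slice DICOM series and NIfTI
volume/mask pairs are included for real data.

## The model in brief

A SubNet is a stack of layer groups, each
`conv → batch-norm → ReLU → 2×2 max-pool`, i.e. per group
`x^l = g(W^l x^{l-1} + b^l)` with `g(x) = MaxPool(max(0, x))`. Five presets
A–E ship (A: 3×3 kernels with 8/16/32 filters; B and D: 3×3 with
64/128/256; C: 1×1 with 8/16/32; E: 1×3 / 3×1 / 1×3 with 64/128/256).
The assembled classifier grows through

```
A  →  A+B  →  (A+B)‖C  →  (A+B)‖C+D  →  ((A+B)‖C+D)‖E
```

freezing everything already trained before each extension. A series join
of an `L_A`-layer network with an `L_B`-layer SubNet has `L_A + L_B + 1`
layers, the `+1` being the single fully connected softmax head; a parallel
join places the head at `max(L_A, L_B) + 1`.

Segmentation and classification are scored with JSI, DC, ACC, PRE, REC,
SPE, F1 and AUC (JSI = |A∩B|/|A∪B|, DC = 2|A∩B|/(|A|+|B|)); HD95 is
available as an optional contour metric.

The neural-network layers themselves (im2col convolution, batch norm, max
pooling, Adam, explicit backprop) are implemented in numpy inside
`gramnet.nn` — no deep-learning framework is required, and the backward
passes are verified against finite differences in the test suite.

## Worked example

```python
import numpy as np
from gramnet.phantomgen import PhantomConfig, generate_phantom
from gramnet.gramnet_core import one_hot
from gramnet.gramnet_train import (CLASSES, StageTrainConfig,
                                   build_and_train_gramnet, predict_class)

cfg = PhantomConfig(image_size=32, tumor_radius=(0.06, 0.12), seed=17)
samples = [generate_phantom(cfg, i) for i in range(400)]
x = np.stack([s.image for s in samples])[..., None]
y = one_hot([s.label for s in samples], CLASSES)

graph, hists = build_and_train_gramnet(
    (x[:288], y[:288]), (x[288:320], y[288:320]),
    cfg=StageTrainConfig(epochs=16, batch_size=16, seed=0), seed=0)
for h in hists:
    print(f"{h.stage_name:18s} val_acc={h.final_val_accuracy:.3f} "
          f"trainable={h.trainable_parameters:>7d} of {h.total_parameters}")
labels, _ = predict_class(graph, x[320:])
print("test accuracy:", (labels == y[320:].argmax(1)).mean())
```

prints

```
A                  val_acc=1.000 trainable=   6066 of 6066
A+B                val_acc=1.000 trainable= 388930 of 394930
(A+B)||C           val_acc=1.000 trainable=   1394 of 395810
(A+B)||C+D         val_acc=1.000 trainable= 536386 of 931618
((A+B)||C+D)||E    val_acc=1.000 trainable= 125442 of 1056546
test accuracy: 1.0
```

Note the freezing at work: at stage 3 the million-parameter network trains
only the 1.4 k parameters of SubNet C and the head, yet validation
accuracy is retained, and by stage 5 only 11.9 % of the network is
trainable. Exact accuracies vary slightly with the seed.

The equivalent command-line workflow:

```sh
gramnet generate --n-train 2346 --n-test 392 --out data/
gramnet prep --manifest data/manifest.csv --out data/manifest.csv
gramnet train-cls --manifest data/manifest.csv --out run/
gramnet evaluate --model run/ --manifest data/manifest.csv
gramnet train-seg --manifest data/manifest.csv --out segrun/
gramnet predict-seg --model segrun/ --images data/ --out masks/
```

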