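# edgewalk

Edge-sensitive contour-tracing segmentation. A convolutional
first-edge-point predictor places the agent on the object boundary and
emits a low-resolution edge-probability map; a double deep Q-network
then traces the remaining boundary point by point inside a deterministic
Markov decision process, producing a closed contour and a filled binary
mask. Everything — including the neural networks and their
backpropagation — is implemented in NumPy, so the package runs on a
single CPU core with no deep-learning framework.

## Layout

| module | contents |
| --- | --- |
| `edgewalk.metrics` | masks, contours, polygon rasterization, IoU, APD, precision/recall/F, Sobel |
| `edgewalk.rewards` | the three immediate-reward terms (overlap sign, edge proximity, clustering penalty) and their toggles |
| `edgewalk.environment` | the MDP: 5-layer state patches, 8-direction skip moves, termination and skip-reduction schedule |
| `edgewalk.first_p_net` | reduced bottleneck-residual encoder producing the 1/8-scale probability map and first point |
| `edgewalk.dqn_agent` | Q-network, replay buffer, epsilon-greedy policy, double-Q targets, training loop |
| `edgewalk.synthetic` | ventricle-like phantom generator with exact ground-truth contours/masks |
| `edgewalk.cli` / `io` / `config` | command-line surface, Sunnybrook-dialect contour files, PNG masks, YAML configs |
| `edgewalk.nn` | minimal NumPy layers (conv, batch norm, residual blocks, bilinear resize) with manual backprop |

Two named profiles exist: `paper` (368 px images, 51 px states, replay
21,000, batch 256 — GPU-scale constants, not trained here) and `desk`
(96 px phantoms, 25 px states, replay 2,000 — trains in minutes on one
CPU core). Reward/geometry thresholds in the desk profile are rescaled
to the smaller image; the default `RewardConfig` keeps the original
constants (reward range [-1.5, 1.5]).

## CLI

```sh
# 1. generate a phantom dataset (images + contours + masks + manifest)
edgewalk simulate --out data/ --n 40 --seed 0

# 2. train the first-point predictor
edgewalk train-first --manifest data/manifest.tsv --out first.npz --profile desk --seed 0

# 3. train the tracing agent
edgewalk train-agent --manifest data/manifest.tsv --first-net first.npz \
    --out agent.npz --profile desk --seed 0 --updates 6000

# 4. segment an image (optionally score against ground truth)
edgewalk segment --image data/phantom_0000.png --first-net first.npz --agent agent.npz \
    --out-contour pred.txt --out-mask pred.png \
    --gt-contour data/phantom_0000_contour.txt --gt-mask data/phantom_0000_mask.png

# 5. tabulate metrics over aligned manifests
edgewalk evaluate --pred-manifest preds/manifest.tsv --gt-manifest data/manifest.tsv
```

Contour text files use the `x y` (column row) convention, one point per
line; in-memory coordinates are `(row, col)`. `--greedy` disables the
epsilon-greedy exploration at inference (the default keeps epsilon at
0.2, matching training).

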