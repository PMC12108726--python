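# avsmotion

An unsupervised artificial visual system (AVS) for motion direction
detection, modelled on early visual processing in the vertebrate retina and
cortex. Given two temporally adjacent images of a scene, the system reports
the global direction (one of eight, 45° apart) in which the object in the
scene moved by one pixel.

It is aimed at computational-neuroscience and biomimetic-vision work where
the question is not "what is the best optical-flow estimator" but "can a
population of direction-selective neurons *self-organize* into global motion
detectors from exposure alone, without labels".

## The model

**Local layer — direction-selective neurons (LMDNs).** Each pixel of an
H×W retinal grid hosts eight local motion detection neurons, one per
direction d ∈ {0,…,7} (direction 0 is rightward; each step rotates 45°
counterclockwise). A neuron combines three retinal cell signals at its pixel
(i, j):

- bipolar cell (temporal change): `BC = 1 iff |X(i,j,t) − X(i,j,t+1)| > L`
- horizontal cell (directional comparison):
  `HC = 1 iff |X(i,j,t) − X(i+α,j+β,t+1)| > L`, where (α, β) is the unit
  offset of the neuron's preferred direction
- ganglion cell (AND-NOT logic): `out = BC · ¬HC`

so the neuron fires exactly when its pixel changed *and* the pixel's old
content reappears one step along the preferred direction. A sigmoid-synapse
("soft") ganglion mode `S(x) = 1/(1+e^{−k(ωx−θ)})` is provided and
reproduces the same truth table at the default parameters.

**Identity encoding.** An activated neuron outputs an 8×2 index matrix whose
single nonzero row (its direction) holds `(a + row, a + col)` with offset
a = 16; the matrix is flattened and divided by `a + max(H, W) − 1` (47 for
32×32), giving a 16-vector with two nonzeros in [0, 1].

**Global layer — Gaussian mixture.** The 16-vectors of all H·W·8 neurons
(8192 for 32×32) are clustered, unsupervised, by an 8-component
full-covariance Gaussian mixture fitted with EM (from scratch: log-space
densities, Cholesky factorization, diagonal ridge 10⁻⁶, best of 10 random
restarts). Because each direction owns a dedicated dimension pair, a
direction-pure fit puts each component's mean mass on one pair — which is
how the component labels are calibrated to directions, deterministically,
after every training run.

**Readout.** For a frame pair, every activated neuron's vector is
hard-assigned to a mixture component (argmax responsibility); component
labels translate to directions; the global motion direction is the
direction with the most activated neurons.

## Worked example

```
$ avsmotion train --seed 0 --out model.npz
trained: cluster sizes [1024, 1024, 1024, 1024, 1024, 1024, 1024, 1024], purity 1.0,
label map [7, 5, 1, 2, 0, 3, 4, 6], 13 EM iterations -> model.npz

$ avsmotion simulate --size 64 --direction 1 --seed 5 --out stim
wrote stim_t.png and stim_t1.png

$ avsmotion detect --model model.npz --frames stim_t.png stim_t1.png
{
  "global_direction": 1,
  "angle_deg": 45.0,
  "n_activated": 123,
  "per_direction_counts": [17, 36, 19, 13, 8, 6, 8, 16],
  ...
}
```

Reading the output: training clustered the 8192 ideal index vectors into
eight components of exactly 1024 neurons each, every component containing a
single true direction (purity 1.0); the label map says e.g. component 0
collects the neurons preferring direction 7 (315°). The simulated stimulus
is a random 64-pixel object on a random background, shifted one pixel
toward the upper right (direction 1, 45°); detection activated 123 neurons,
36 of them in the 45° population — the maximum — so the system reports 45°.

The same workflow is available from Python:

```python
from avsmotion import MotionDirectionAVS
model = MotionDirectionAVS(random_state=0).fit()   # enumerates the ideal set
result = model.detect(pair)                        # pair: a FramePair
print(result.global_direction, result.per_direction_counts)
```

`MotionDirectionAVS` and the underlying `GaussianMixtureEM` follow
scikit-learn estimator conventions (`fit`, `predict`, `get_params`,
fitted attributes with trailing underscores).

Other subcommands: `evaluate` (object-size × noise-fraction accuracy grid,
written as CSV), `report` (summarize a model bundle), `plot` (2-D embedding
of the index vectors).

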