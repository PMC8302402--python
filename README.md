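# evoderm

Evolutionary blind enhancement of motion-blurred skin-lesion photographs,
with the evaluation statistics used to quantify the downstream diagnostic
benefit.

## The problem

Tele-dermatology pipelines in resource-poor settings depend on photographs
captured with hand-held devices; unpredictable relative motion of device
and patient convolves the image with a line-segment point-spread function
`h(l, θ)` (motion length `l` in pixels, angle `θ` in degrees), and the blur
parameters are unknown to the receiving site. `evoderm` restores such
images *blindly*: a genetic algorithm evolves seven-gene filter-parameter
chromosomes

```
(type, hsize, radius, sigma, alpha, length, theta)
```

— a motion-blur hypothesis `(length, theta)` that is inverted by
Wiener-form deconvolution, plus a secondary correction filter chosen by
`type` — and ranks every candidate restoration with the no-reference
Naturalness Image Quality Evaluator (NIQE), a Mahalanobis-type distance
between an image's natural-scene statistics and a pristine reference
model. Smaller NIQE = more natural. The GA minimizes

```
fitness(c) = NIQE( enhance(image, c) )
```

with elitism, single-point crossover at the boundary before the `length`
gene, and one mutant per generation drawn from the best 80% of the
population. A companion statistics module computes confusion matrices,
per-class/overall accuracies, and the paired t-test
`t = d̄ / (s/√n)` comparing classifier accuracy on blurred versus enhanced
images. Everything runs on seeded synthetic data — no dataset download.

## Worked example

```bash
# 1. make a synthetic lesion photograph and blur it with (length 19, theta 3)
evoderm simulate --kind lesion --seed 0 --out work/
evoderm blur --input work/lesion.png --length 19 --theta 3 --output work/blurred.png

# 2. score both images under the packaged pristine model
evoderm niqe --image work/lesion.png     # prints 3.2492
evoderm niqe --image work/blurred.png    # prints 26.3733

# 3. blind enhancement by genetic search
evoderm enhance --input work/blurred.png --generations 300 --pop 10 --seed 3 \
                --out work/enhanced.png --trajectory work/traj.csv
# prints:  best chromosome: [6.00, 11.00, 4.86, 0.78, 0.89, 18.27, 3.71]
#          best score: 3.3166

# 4. the paired t-test on the bundled seven-class case-study table
evoderm ttest
# prints:  d = 11.30, s = 8.13, n = 7, df = 6, t = 3.68, p(one-sided) = 0.0052
```

Reading the output: the blurred image scores 26.4 (far from natural
statistics), and after 300 generations the GA's best chromosome hypothesizes
a blur of 18.27 px at 3.71° — close to the true (19, 3°) — bringing the
enhanced image down to 3.3, essentially the pristine image's 3.2. The `ttest`
line is the paired analysis of per-class classifier accuracies under the
two image conditions: the mean matched difference of 11.30 percentage
points (SD 8.13, n = 7 classes) gives t = 3.68 with 6 degrees of freedom,
one-sided p ≈ 0.005, so enhancement significantly improves accuracy at the
0.05 level.

The same operations are available as a library:

```python
from evoderm import (LesionImageSpec, make_lesion_image, MotionBlurSpec,
                     make_motion_psf, apply_kernel, default_model, GAConfig, evolve)

image = make_lesion_image(LesionImageSpec(seed=0))
blurred = apply_kernel(image, make_motion_psf(MotionBlurSpec(19, 3)))
best, enhanced, trajectory = evolve(blurred, default_model(),
                                    GAConfig(generations=300, seed=3))
print(best.to_vector())   # [ 6.  13.  4.86  0.78  0.89  18.31  3.74]
```

## Package layout

| module | contents |
| --- | --- |
| `evoderm.blur_kernels` | motion PSF, eight-member parametric filter bank, convolution |
| `evoderm.niqe` | MSCN/AGGD features, pristine model fitting, NIQE score |
| `evoderm.enhancement` | Wiener-form deconvolution + secondary filter |
| `evoderm.ga_engine` | chromosomes, GA operators, `evolve` loop |
| `evoderm.eval_stats` | confusion matrices, accuracies, paired t-test, case-study tables |
| `evoderm.synthetic_data` | seeded lesion images, pristine corpora, label sets |
| `evoderm.cli` | `evoderm` command-line interface |

See `docs/methods.md` for the model details, parameter choices and known
limitations (in particular: blur *length* recovery is robust, blur *angle*
identifiability at this geometry is marginal).
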