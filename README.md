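# somtraj

Self-organizing-map based recognition of spatio-temporal motion trajectories,
built for monitoring coarse full-body therapeutic exercises recorded as
20-joint depth-sensor skeletons.

## How it works

1. **features** — each skeletal frame is moved into a subject-centred
   *body-plane* coordinate system anchored at the spine (X-Y = coronal plane)
   and summarised by a 71-dimensional vector: the 19 unit direction vectors of
   the kinematic-tree edges (3 × 19 components) plus 14 joint angles.  The
   features are invariant to the subject's position, facing direction and
   height.
2. **som** — a Kohonen map (default 10 × 10 neurons, η₀ = 0.1, 100 epochs,
   constant neighborhood width σ = 1.0, PCA-plane initialization) quantizes
   posture space.
3. **posture_map** — the trained map's U-matrix is segmented by
   marker-controlled watershed into catchment basins; shallow basins are
   merged into their lowest-saddle neighbors.  Each surviving basin is one
   *basic posture unit*.
4. **trajmap** — a recording becomes a per-frame basin sequence; adjacent
   repetitions are collapsed (1,1,8,8,3,8,1 → 1,8,3,8,1) and the sequence is
   rendered as a fixed-size gray *trajectory map* (visited basins shaded by
   first-appearance order, darker = earlier) with per-basin binary appearance
   strings.
5. **matching** — one template per exercise is distilled from several
   instances by an exact multi-sequence longest-common-subsequence, and
   unknown trajectory maps are classified by normalized image correlation
   against the template maps, with threshold rejection for unknown movements.
6. **synthetic_motion** — a seeded generator of multi-subject recordings of 12
   built-in exercises (key-pose interpolation with bone-length
   renormalization; speed, pause, rotation, noise and anthropometric
   perturbations) so the whole pipeline is trainable and testable without
   sensor data.

## CLI

```sh
# generate a synthetic dataset (JSON-Lines frames + manifest)
somtraj simulate --out data/train --subjects 5 --reps 10 --seed 1
somtraj simulate --out data/test --subjects 5 --reps 10 --seed 1 --subject-offset 100

# train the posture map and build templates
somtraj train --dataset data/train --out pmap.json --seed 1
somtraj templates --dataset data/train --posture-map pmap.json --out lib.json

# classify a labeled dataset (accuracy + confusion) or individual files
somtraj evaluate --dataset data/test --posture-map pmap.json --templates lib.json --out report
somtraj classify --posture-map pmap.json --templates lib.json --out cls data/test/*.jsonl
```

Robustness conditions are flags on `simulate`: `--speed 0.5` (half speed),
`--pause 0.5:12` (mid-exercise pause), `--rotation 45` (facing rotation).
Grid-size sweeps use `somtraj train --rows 6 --cols 6 ...`.

## Python API

```python
from somtraj.synthetic_motion import builtin_exercises, generate_dataset
from somtraj.pipeline import train_posture_map, build_library, evaluate
from somtraj.som import TrainingSchedule

records = generate_dataset(builtin_exercises(), n_subjects=5, reps=10, seed=1)
pmap = train_posture_map(records, 10, 10, TrainingSchedule(seed=1))
library = build_library(pmap, records, instances_per_label=5)
report = evaluate(pmap, library, records)
print(pmap.n_units, report.accuracy)
```
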