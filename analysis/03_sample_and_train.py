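#!/usr/bin/env python
"""Build the stratified training set and train the per-region forests.

250 points per 50 km grid cell are drawn over the study extent, labelled
per year from the (noisy) reference maps, filtered to crop classes with
usable features, and split 80/20 within the training years; the earliest
year is held back entirely as a hindcast test. One 500-tree random forest
is trained per region. Writes samples.csv and the models to scratch/run/
and the per-region class-frequency table to results/.
"""

import sys
from pathlib import Path

from cornsoy import io as csio
from cornsoy.pipeline import default_config, sample_stage, train_stage
from cornsoy.sampling import class_frequency_report

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
OUT = Path("scratch/run")

cfg = default_config(seed=SEED)
labels = {y: csio.read_labels(OUT / "labels" / f"{y}.tif") for y in cfg.years}
features = {y: csio.read_features(OUT / "features" / f"{y}.tif")[:2] for y in cfg.years}
partition = csio.read_partition(OUT / "partition.tif")

sample = sample_stage(cfg, labels, features, partition)
csio.write_samples(OUT / "samples.csv", sample)
models = train_stage(cfg, sample, partition)
for region, model in models.items():
    csio.write_model(OUT / "models" / f"region_{region}.joblib", model)

freq = class_frequency_report(sample)
Path("results").mkdir(exist_ok=True)
freq.to_csv("results/sample_class_frequencies.csv", index=False)

n_train = (sample["split"] == "train").sum()
print(f"{len(sample)} records ({n_train} train); {len(models)} regional models")
print(freq.round(1).to_string(index=False))
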