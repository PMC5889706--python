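"""Generate a synthetic mark-resight survey with known ground truth.

The generator reproduces the survey's structure — a line of baited camera
stations watched for daily occasions, a trap line that marks part of the
population, aggregate counts for unmarked animals, and telemetry on the
collared ones — so the estimator can be tested against known truth.
"""

from smrpva.synthetic import SimConfig, simulate_dataset

config = SimConfig(seed=1, N_true=10, buffer=500.0, trap_nights=12)
data, truth, space = simulate_dataset(config)

n_f = int(data.sex.sum())
print(f"true population: {truth.n} animals "
      f"({int(truth.sex.sum())} F / {int((1 - truth.sex).sum())} M)")
print(f"marked by trapping: {data.n_marked} ({n_f} F), "
      f"{int(data.ycap.sum())} total captures at {data.n_traps} traps")
print(f"camera survey: {data.n_cameras} stations x {data.n_occasions} occasions")
print(f"marked resightings: {int(data.ycam.sum())}")
print(f"unmarked sightings: {int(data.nU.sum())} "
      f"(counts only, no individual identity)")
print(f"telemetry: {sum(t.shape[0] for t in data.telemetry)} fixes on "
      f"{sum(t.shape[0] > 0 for t in data.telemetry)} collared animals")
# Unmarked sightings are deliberately sparse: territorial carnivores at
# low density yield few camera detections of never-trapped animals.
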