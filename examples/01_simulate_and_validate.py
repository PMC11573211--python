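"""Generate a synthetic multi-plate synovial-fluid SomaScan-style run.

Builds a 4-plate study with the standard plate design (83 participant wells,
pooled OA and injury replicates, 5 plasma calibrators, 3 plasma QC wells and
3 blanks per plate), validates it, and prints what was planted.
"""

from sfsomaqc import validate_dataset
from sfsomaqc.synthdata import SynthConfig, generate_dataset

config = SynthConfig(seed=1, n_plates=4)
dataset, truth = generate_dataset(config)

print(f"samples x SOMAmers: {dataset.rfu.shape}")
print(dataset.samples["role"].value_counts().to_string())
report = validate_dataset(dataset)
print(f"validation issues: {len(report.issues)} (dataset is "
      f"{'valid' if report.ok else 'INVALID'})")
print(f"planted bad samples: "
      f"{ {k: len(v) for k, v in truth.bad_samples.items()} }")
print(f"planted control/confounder/low-R2 SOMAmers: "
      f"{len(truth.control_somamers)}/"
      f"{len(truth.age_somamers) + len(truth.ft_somamers)}/"
      f"{len(truth.low_r2_somamers)}")
# The truth record is the oracle the QC pipeline is tested against: every
# planted effect above should be detected and removed downstream.
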