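"""Simulate a small multi-breed dataset and validate the input files.

Writes the three standard inputs (HapMap genotypes, ID/breed table,
per-breed geography), reads them back, and cross-checks consistency.
"""

import tempfile
from pathlib import Path

from breedkit import (
    SimulationConfig,
    read_breed_table,
    read_geo_table,
    read_hapmap,
    validate_dataset,
    write_fixture_suite,
)

outdir = Path(tempfile.mkdtemp()) / "demo"
config = SimulationConfig(n_breeds=4, n_per_breed=12, n_snps=500, fst=0.2, seed=11)
paths = write_fixture_suite(outdir, config)

G = read_hapmap(paths["genotypes"])
breeds = read_breed_table(paths["breeds"])
geo = read_geo_table(paths["geo"])
report = validate_dataset(G, breeds, geo)

print(f"genotypes: {G.n_individuals} individuals x {G.n_snps} SNPs")
print(f"per-breed counts: {report.breed_counts}")
print(f"unlabelled individuals: {report.genotyped_without_breed}")
print(f"blocking for training: {report.blocking_for_training}")
# Counts of 12 per breed and empty mismatch lists mean the three files
# agree and a classifier can be trained on every genotyped individual.
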