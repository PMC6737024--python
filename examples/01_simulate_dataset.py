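"""Generate a small ground-truthed allotetraploid scenario and write it out.

The scenario: a four-line pedigree (SL-1 x CDA -> CY2; SL-1-derived NY1;
NY1 x CY2 -> NY7), three population groups, one near-fixed interspecific
introgression tract and one swept region.
"""

from polyped import (
    IntrogressionEvent,
    SelectionTarget,
    SimulationConfig,
    simulate,
    write_dataset,
)

config = SimulationConfig(
    seed=7,
    chromosomes=[("A01", "A", 200_000), ("A02", "A", 200_000),
                 ("C01", "C", 200_000), ("C02", "C", 200_000)],
    group_sizes={"EU": 10, "AS_DH": 8, "AS_DL": 6},
    introgression_events=[
        IntrogressionEvent("CDA", "AS_DH", "A02", 50_000, 150_000, 0.95)
    ],
    selection_targets=[SelectionTarget("C02", 60_000, 140_000, "AS_DH")],
)
dataset = simulate(config)
paths = write_dataset(dataset, "example_dataset")

print(f"samples: {dataset.genotypes.n_samples}, sites: {dataset.genotypes.n_sites}")
print("genomes written:", [n for n in dataset.assemblies])
print("site classes:", dataset.truth.site_classes["site_class"].value_counts().to_dict())
print("introgression carriers:", dataset.truth.carriers[0])
print(f"files under example_dataset/: {len(paths)}")
# The truth BED/TSV files give exact IBD tracks, ancestry tracts and site
# classes, so every downstream stage can be scored against known answers.
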