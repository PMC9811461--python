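"""Build a starting configuration from a measured fed-state composition.

Loads the HV3 duodenal-fluid preset (concentrations in mM per molecule
class), converts them to integer molecule counts for a periodic cubic box,
and emits a randomized starting configuration as a GRO file.  A 12 nm box
is used here so the example runs in seconds; production boxes are 45 nm.
"""

from hifcolloids import (
    BoxSpec,
    build_random,
    load_presets,
    mm_to_count,
    species_counts,
    strip_glycerides,
    write_structure,
)

box = BoxSpec(12.0)
hv3 = load_presets()["HV3"]

print("HV3 fed-state composition (mM) and molecule counts in a 12 nm box:")
for cls, conc in hv3.concentrations.items():
    print(f"  {cls:13s} {conc:5.1f} mM  ->  {mm_to_count(conc, box):4d} molecules")

counts = species_counts(hv3, box)
print("\nPer-species counts (bile salts split equally, phospholipids 50/50):")
print(" ", counts)

config = build_random(hv3, box, seed=1, water_density=2.0)
write_structure(config, "hv3_random.gro")
print(f"\nwrote hv3_random.gro: {config.n_molecules} molecules, {config.n_beads} beads")

# the glyceride-free variant keeps everything else identical
noglyc = strip_glycerides(hv3)
print(
    "glyceride-free set: MAG/DAG/TAG ->",
    [noglyc.concentrations[g] for g in ("MAG", "DAG", "TAG")],
    "mM; bile salts still", noglyc.concentrations["bile_salt"], "mM",
)
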