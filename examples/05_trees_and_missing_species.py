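"""Extract island clades from a Newick tree and insert unsampled species.

Renders the five-clade surrogate dataset as an ultrametric tree with mainland
sisters, reads the colonization (stem) and branching ages back off the tree,
then grafts two unsampled extant species at random positions and re-extracts.
"""

from islandbd import MissingSpeciesAssignment, extract_island_clades, insert_missing_species
from islandbd.data import dataset_to_newick
from islandbd.fixtures import make_table1_fixture

ds = make_table1_fixture(seed=1)
newick, island_tips = dataset_to_newick(ds)
back = extract_island_clades(newick, island_tips, island_age=30.0, mainland_pool_M=1000)
print("extracted clades (stem age, size):")
for c in back.clades:
    print(f"  {c.name:9s} {c.colonization_age:6.2f} My  {c.n_species:3d} species")

assignments = [
    MissingSpeciesAssignment("sp_missing_1", "tip_branch", ("clade_1_sp3",)),
    MissingSpeciesAssignment("sp_missing_2", "within_clade", ("clade_2_sp1", "clade_2_sp9")),
]
trees = insert_missing_species(newick, assignments, n_replicates=3, seed=9)
labels = island_tips | {"sp_missing_1", "sp_missing_2"}
for i, t in enumerate(trees):
    ext = extract_island_clades(t, labels, island_age=30.0, mainland_pool_M=1000)
    print(f"replicate {i}: {ext.total_species} island species in {ext.n_clades} clades")
print(
    "\nEach replicate adds one age-0 tip per assignment at a random height\n"
    "(uniform along the tip branch, or uniform over the clade's branch length),\n"
    "keeping the tree ultrametric; all replicates have 67 island species."
)
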