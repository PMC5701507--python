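"""Screen a synthetic genome for chromosome-specific repeated target sites.

Plants one clustered and one scattered repeat family on chrT, screens both
chromosomes for 23-bp Cas9 sites (20-nt spacer + NGG PAM), and prints the
chromosome-specific catalog.  Each catalog row is a spacer whose exact
occurrences all lie on one chromosome — a single sgRNA against it cuts
that chromosome many times and nothing else.
"""

from karyocut import chromosome_specific_catalog
from karyocut.simulate import Decoy, FixtureConfig, PlantedFamily, make_genome

config = FixtureConfig(
    seed=7,
    chromosomes=(("chrT", 100_000), ("chrB", 60_000)),
    families=(
        PlantedFamily("clustered_fam", "chrT", 12, "clustered", span=8_000),
        PlantedFamily("scattered_fam", "chrT", 8, "scattered"),
    ),
    decoys=(Decoy("clustered_fam", 3, "chrB"),),  # near-match, must not confound
)
fixture = make_genome(config)

catalog = chromosome_specific_catalog(fixture.genome)
print("spacer                PAM   copies  home     span   distribution")
for fam in catalog:
    print(f"{fam.spacer}  {fam.pam_consensus()}       {fam.copy_number:>2}    "
          f"{fam.home_chromosome}  {fam.span:>6}   {fam.distribution}")
print()
print("Both planted families are recovered with their exact copy numbers;")
print("the 3-mismatch decoy on chrB does not break chromosome specificity,")
print("because specificity is judged on exact matches only.")
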