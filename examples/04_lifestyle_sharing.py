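"""Lifestyle partition of the packaged published SSP-cluster table.

Loads the packaged 49-species registry and the published table of SSP
clusters spanning three or more species, maps every member species to its
lifestyle group (ECM / white rot / brown rot / litter decayer / other), and
counts clusters per exact Venn region and per specificity class.
"""

from collections import Counter

from secretominer import compare, registry_io

registry = registry_io.load_species_registry()
clusters = registry_io.load_cluster_fixture(registry)
profiles = [compare.lifestyle_profile(c, registry) for c in clusters]

print(f"species in registry:  {len(registry)}")
print(f"clusters in table:    {len(clusters)}")

specificity = Counter(p.specificity for p in profiles)
print("cluster specificity:")
for label, count in specificity.most_common():
    print(f"  {label:<22} {count}")

no_pfam = [
    c for c, p in zip(clusters, profiles)
    if p.specificity == "ECM_only" and c.pfam_label == "None"
]
print(f"ECM-only clusters without a PFAM domain: {len(no_pfam)} "
      f"(ids {sorted(c.cluster_id for c in no_pfam)})")

print("Venn regions over the four lifestyle groups:")
for region, count in sorted(compare.venn_partition(profiles).items()):
    print(f"  {' + '.join(region):<45} {count}")
# 17 clusters contain only ectomycorrhizal species (6 of them without any
# PFAM domain — candidate symbiosis-specific effector families); 5 clusters
# are shared between ECM and saprotrophic fungi, 3 are saprotroph-only.
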