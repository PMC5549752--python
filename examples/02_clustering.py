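"""Cluster reads into OTUs at 97% identity and materialize a count table.

Three well-separated centroid sequences each spawn point-mutated reads
assigned to one sample's DNA or RNA fraction; the greedy length-sorted
clusterer recovers the three OTUs.
"""

from cloudotu import cluster_counts, greedy_cluster, pairwise_identity
from cloudotu.core import SampleFraction
from cloudotu.synth import generate_reads, random_centroids

centroids = random_centroids(3, 150, rng=4)
print("pairwise centroid identities (should be well below 0.97):")
for i in range(3):
    for j in range(i + 1, 3):
        ident = pairwise_identity(centroids[i][1], centroids[j][1])
        print(f"  {centroids[i][0]} vs {centroids[j][0]}: {ident:.2f}")

reads, truth = generate_reads(centroids, {c: 8 for c, _ in centroids}, divergence=0.005, seed=8)
clusters = greedy_cluster([(r.id, r.bases, 1) for r in reads], threshold=0.97)
print(f"\n{len(clusters)} OTUs from {len(reads)} reads:")
for c in clusters:
    true_origin = {truth[m] for m in c.member_ids}
    print(f"  centroid {c.centroid_id}: {c.size} reads, true origin {true_origin}")

# assign alternating reads to DNA/RNA and build the OTU table
read_map = {
    r.id: SampleFraction("cloud1", "DNA" if i % 2 == 0 else "RNA")
    for i, r in enumerate(reads)
}
table = cluster_counts(clusters, read_map)
print(f"\n{table}")
print(table.to_frame())
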