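"""KO differential abundance between functional station clusters.

Raw counts are aggregated to KO level and tested between every cluster pair
with the simplified negative-binomial Wald procedure; fold changes of
significant features are binned 0-2 / 2-4 / >4 log2 units.
"""

from oceanmg import biogeo, differential, profiles, synthetic

stations, catalog, counts, truth = synthetic.make_transect(seed=1)
filtered = profiles.filter_classified(counts, catalog)
profs = profiles.build_profiles(counts, catalog)
clusters = biogeo.optimal_k(biogeo.bray_curtis(profs["taxon"])).labels

ko_counts = profiles.aggregate_counts(filtered, catalog, "ko")
results, summary = differential.pairwise_cluster_enrichment(ko_counts, clusters)
for (a, b), res in results.items():
    enriched = (res["bin"] != "none").mean()
    print(f"clusters {a} vs {b}: {100 * enriched:.1f}% of "
          f"{len(res)} KOs enriched (|log2FC| >= 2, q <= 0.05)")
print("\nLow enrichment between clusters reflects the planted KO redundancy: "
      "every KO\nis carried by taxa of every thermal regime, so community "
      "function is stable\neven where taxonomic composition shifts.")
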