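"""Generate a synthetic ocean transect and look at its planted structure.

Builds the default 22-station latitudinal transect (50 taxa in three thermal
regimes, 40 KOs carried across all regimes, 8 gene variants per (taxon, KO)
pair) and prints the scale of the data set and the planted regime labels.
"""

from oceanmg import synthetic

stations, catalog, counts, truth = synthetic.make_transect(seed=1)

print(f"stations: {len(stations)}  (temperature "
      f"{stations.temperature.min():.1f}-{stations.temperature.max():.1f} degC)")
print(f"genes in catalog: {len(catalog)}")
print(f"reads per station: {int(counts.sum(axis=0).iloc[0])}")
print("\nplanted station regimes (0=cold, 1=temperate, 2=warm):")
print(truth.station_regimes(stations).to_string())
print("\nEach station's community is dominated by taxa of its thermal regime;"
      "\nthe analysis modules must recover this structure from counts alone.")
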