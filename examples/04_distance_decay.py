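"""Distance-decay contrasts: gene variants turn over much faster than taxa,
and KO (function) profiles barely at all."""

from oceanmg import biogeo, decay, profiles, synthetic

stations, catalog, counts, truth = synthetic.make_transect(seed=1)
profs = profiles.build_profiles(counts, catalog)
dissims = {lv: biogeo.bray_curtis(p) for lv, p in profs.items()}

fits = decay.fit_all(dissims, stations)
print(fits.round(4).to_string(index=False))
print("\nSlope ordering gene > taxon > KO (both predictors) is the planted "
      "signature:\nsub-species gene variants track temperature tightly while "
      "overall community\nfunction (KO) is redundant across the basin.")
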