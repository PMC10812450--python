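"""Load the transcribed study tables and aggregate compounds into the three
polyphenol-class responses.

Prints the per-class totals (µg/g dry extract) for a few harvest batches
and the per-area concentration extrema for two marker compounds.
"""

import numpy as np

from strawpoly import datamodel as dm

class_map = dm.load_class_map()
measurements = []
for name in ("table2_guariba.csv", "table3_valparaiso.csv"):
    measurements += dm.load_compound_table(dm.fixture_path(name), class_map)
conditions, ic50 = dm.load_conditions()

table = dm.aggregate_classes(measurements, class_map, ic50=ic50)
print("Class responses for three batches (µg/g dry extract):")
print(table.loc[["G05", "G14", "V06"]].round(1))

guariba = dm.summarize_extrema(measurements, conditions, group="Guariba")
valpa = dm.summarize_extrema(measurements, conditions, group="Valparaiso")
print("\nChlorogenic acid max, Guariba:   ", guariba.loc["Chlorogenic acid", "max"])
print("5-O-Feruloylquinic max, Valparaiso:", valpa.loc["5-O-Feruloylquinic acid", "max"])
print("\nABTS IC50 range (mg/mL):", np.nanmin(ic50["abts_ic50"]), "-",
      np.nanmax(ic50["abts_ic50"]))
# Lower IC50 = stronger radical scavenging; NaN rows are assays the study
# did not determine.
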