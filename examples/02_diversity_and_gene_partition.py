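"""Alpha diversity, evenness, shared/unique genes, category comparison.

Richness, Shannon, inverse Simpson, Pielou and Simpson evenness per sample;
Welch t tests between lakes; the shared/unique gene partition; and the
per-category relative-intensity comparison with significance stars.
"""
import fmen

catalog = fmen.generate_catalog(n_probes=3000, seed=1)
signals, _ = fmen.simulate_two_lake(
    catalog, fmen.SimulationConfig(n_probes=3000), seed=2)
normalized, _ = fmen.preprocess(signals)

alpha = fmen.alpha_diversity(normalized)
print("Group means (per index):")
print(alpha.group_stats.round(3))
print()
print("Welch t tests (HL vs RAL); positive t means higher in HL:")
print(alpha.tests.round(4))
print()

sets = fmen.group_detected_sets(normalized)
part = fmen.shared_unique_partition(sets["HL"], sets["RAL"])
print(f"Gene partition: {len(part.shared)} shared "
      f"({part.shared_pct:.1f}% of the union), "
      f"{len(part.unique_a)} unique to HL, {len(part.unique_b)} to RAL.")
print()

table = fmen.category_intensity_compare(normalized, catalog)
print("Category-level relative intensity (delta in percentage points):")
print(table.round(4).to_string())
print()
print("The planted effects (carbon/nitrogen up, sulfur/phosphorus down in "
      "HL) carry stars with the right sign; with 6 samples per lake an "
      "unplanted category occasionally reaches significance too.")
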