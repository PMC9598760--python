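"""Degree-preserving null ensemble and the full two-lake comparison report.

Runs the entire pipeline (preprocessing, diversity, community tests, per-lake
RMT networks, 50 rewired null replicates each) and prints the side-by-side
topology table.  z scores far above 2 mark the non-random small-world
signature: the empirical networks are far more clustered and far more spread
out than degree-matched random graphs.
"""
import warnings

import fmen

catalog = fmen.generate_catalog(n_probes=5000, seed=1)
signals, _ = fmen.simulate_two_lake(catalog, fmen.SimulationConfig(), seed=2)

analysis = fmen.AnalysisConfig(n_null=50)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    result = fmen.analyze_two_lakes(signals, catalog, analysis, seed=3)

print(result.report.side_by_side().round(3).to_string())
print()
for group, rep in result.report.reports.items():
    z = rep.null_summary.table["z"]
    print(f"{group}: St={rep.st} ({rep.st_method}); "
          f"z(HD)={z['harmonic_geodesic_distance']:.0f}, "
          f"z(avgCC)={z['avg_clustering']:.0f}, "
          f"z(Q)={z['modularity']:.0f} vs the rewired null.")
print()
print("The HL-like lake plants more, weaker correlated blocks, so across "
      "replicates its network tends to fragment more (longer harmonic "
      "geodesic distance) and cluster less than the RAL-like lake's; with "
      "6 samples per lake the direction holds in most, not all, datasets.")
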