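"""RMT-thresholded co-occurrence network for one lake.

Pearson correlations between the core element-cycling gene families, the
random-matrix-theory threshold scan (eigenvalue spacing statistics flip from
GOE to Poisson at the similarity threshold St), network construction, and
topology statistics.
"""
import fmen

catalog = fmen.generate_catalog(n_probes=5000, seed=1)
signals, _ = fmen.simulate_two_lake(catalog, fmen.SimulationConfig(), seed=2)
normalized, _ = fmen.preprocess(signals)

corr = fmen.correlation_matrix(
    normalized, "HL", families=fmen.CORE_NETWORK_FAMILIES, catalog=catalog)
print(f"{len(corr.genes)} core-family genes enter the HL correlation matrix.")

scan = fmen.rmt_threshold_scan(corr, on_no_transition="max_p")
trace = scan.trace.dropna()
print(f"Selected St = {scan.st} ({scan.method}); NNSD trace near the "
      "transition:")
print(trace[trace.threshold.between(scan.st - 0.03, scan.st + 0.02)]
      .round(4).to_string(index=False))
print()

network = fmen.build_network(corr, scan.st, catalog=catalog)
topo = fmen.topology_summary(network)
print(f"Network: n={topo.n_nodes} genes, L={topo.n_links} links "
      f"({100 * topo.negative_fraction:.1f}% negative), avgK={topo.avg_k:.3f}")
print(f"Harmonic geodesic distance HD={topo.harmonic_geodesic_distance:.3f}, "
      f"avgCC={topo.avg_clustering:.3f}, power-law R^2={topo.power_law_r2:.2f}")
print(f"Modularity Q={topo.modularity:.3f} over {topo.n_modules} modules.")
print()
print("Top-5 hub genes by connectivity:")
print(fmen.hub_genes(network, 5).to_string(index=False))
print()
print("Hubs come from the planted correlated blocks, which sit inside the "
      "core element-cycling families.")
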