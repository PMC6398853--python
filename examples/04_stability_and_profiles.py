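"""Full analysis: consensus, chain agreement, stability, cluster profiles.

Runs the end-to-end workflow on a simulated survey and prints the artifacts
a study report would use: per-chain agreement, per-cluster stability, and
each cluster's outcome (party-identification) enrichment relative to the
whole sample.
"""

from crpclust import GeneratorConfig, SamplerConfig, generate, run_analysis

gen = GeneratorConfig(
    n=120, scheme="explicit", weights=[0.45, 0.35, 0.2], separation=0.03, seed=5
)
data, truth = generate(gen)
cfg = SamplerConfig(burn_in=150, thinning=5, n_samples=80, n_chains=2, seed=5)
report = run_analysis(data, cfg)

print(f"consensus clusters (sizes): {report.cluster_sizes}")
print(f"chain disagreement: {report.disagreement_count} of {data.n} "
      f"({100 * report.disagreement_fraction:.1f}%)")
print("\nper-cluster stability (mean similarity of the cluster across draws):")
for row in report.stability.clusters:
    ts = "  n/a" if row.mean_transfer_similarity is None else f"{row.mean_transfer_similarity:5.2f}"
    print(f"  cluster {row.cluster} (n={row.size:3d}): TS {ts}  MS {row.mean_mirkin_similarity:5.2f}")

print("\noutcome enrichment vs whole sample (ratio > 1 = over-represented):")
for profile, ratios in zip(report.profiles, report.enrichment):
    top = max((c for c in ratios if ratios[c] is not None), key=lambda c: ratios[c])
    print(f"  cluster {profile.cluster}: most enriched outcome '{top}' "
          f"(x{ratios[top]:.2f}, {100 * profile.outcome_frequencies[top]:.1f}% "
          f"vs {100 * report.overall_profile.outcome_frequencies[top]:.1f}% overall)")

# Optional: render one cluster as a bar chart
# from crpclust.plotting import plot_cluster_profile
# plot_cluster_profile(report.profiles[0], "cluster0.png")
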