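"""Generate a synthetic pharmacovigilance world and inspect its structure.

A world bundles everything the pipeline consumes: a sparse drug-target
interaction matrix, a spontaneous-report count table whose excess reports
are driven by planted causal targets, a clinical-trial-style percentage
table, a noisy target-disease association table and ATC codes.
"""

import pvsignal as pv

config = pv.SyntheticConfig(seed=7)
world = pv.generate_world(config)

print(f"interactions: {world.interactions.n_drugs} drugs x "
      f"{world.interactions.n_targets} targets, "
      f"{world.interactions.nonzero_count()} nonzero scores")
print(f"reports:      {len(world.reports.drugs)} drugs x "
      f"{len(world.reports.socs)} SOCs, "
      f"{world.reports.grand_total} total reports")
print(f"planted SOCs: {list(config.planted_socs)}")
print(f"null SOCs:    {list(config.null_socs)}")
for soc, targets in world.truth.items():
    print(f"  {soc}: causal targets {targets}")
print(f"no-data target (absent from associations): {world.no_data_target}")

# Each planted SOC multiplies the Poisson report rate by relative_risk
# for every drug whose score with a causal target exceeds 0.4, so the
# report table carries a recoverable mechanistic signal.
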