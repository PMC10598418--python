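"""Generate a study-scale synthetic gillnet fleet and validate it.

Builds a season of lumpfish-fishery trips — 7 boats, 84 trips, 5-16 trossas
(gillnet tiers) per trip, 61 of them carrying a deterrent buoy — with
depth-dependent Poisson bird/mammal bycatch and overdispersed fish catch,
then runs the dataset validator.
"""

from trossa import FleetConfig, generate_fleet, validate_dataset, write_trossa_table

dataset, truth = generate_fleet(FleetConfig(seed=42))
report = validate_dataset(dataset)

print(f"trossas:            {len(dataset)}")
print(f"trips:              {report.n_trips}")
print(f"deterrent trossas:  {report.n_leb}")
print(f"total birds caught: {sum(r.total_birds for r in dataset.records)}")
print(f"expected (truth):   {truth.expected_birds.sum():.1f}")
print(f"total lumpfish:     {sum(r.lumpfish_count for r in dataset.records)}")
print(f"validation ok:      {report.ok} ({len(report.flags)} flags)")

write_trossa_table(dataset, "synthetic_fleet.csv")
print("wrote synthetic_fleet.csv")

# The observed bird total should sit within Poisson noise of the generator's
# analytic expectation; the validator confirms every record satisfies the
# effort/date/count invariants.
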