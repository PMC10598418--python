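"""Fleet-wide depth-restriction scenarios from published inputs.

Converts the 2014-2021 mean national lumpfish landings (5386.8 t, at 3 kg
per fish) into per-depth-bin fishing effort using the published depth-
specific catch rates, recovers unrounded bird bycatch rates from the per-bin
annual bycatch column, then closes the bins shallower than each candidate
restriction depth and redistributes their effort in equal absolute shares to
the remaining open bins.
"""

from trossa import (
    LandingsSeries,
    effort_from_landings,
    extrapolate_bycatch,
    rate_table_with_unrounded_birds,
    scenario_table,
    simulate_restriction,
)
from trossa.reference import MEAN_ANNUAL_LANDINGS_TONS, reference_rate_table

rates = reference_rate_table()
effort = effort_from_landings(MEAN_ANNUAL_LANDINGS_TONS, rates)
unrounded = rate_table_with_unrounded_birds(rates, MEAN_ANNUAL_LANDINGS_TONS)

per_bin, baseline = extrapolate_bycatch(effort, unrounded)
print(f"total fleet effort:        {effort.total:,.0f} standardised trossa-days")
print(f"baseline annual bycatch:   {baseline:,.0f} seabirds")
print()
print("restriction  catch (t)  birds/yr  d_catch  d_birds  d_mammals")
for depth in (10, 20, 30, 40, 50):
    r = simulate_restriction(effort, unrounded, depth)
    print(f"   >{depth} m     {r.projected_catch_tons:7.0f}   {r.projected_bird_bycatch:7.0f}"
          f"   {r.delta_catch:+6.1%}  {r.delta_birds:+6.1%}   {r.delta_mammals:+6.1%}")
print()
print("A >50 m restriction eliminates projected seabird bycatch while the")
print("annual catch stays near 5200-6000 t; mammal change is relative only,")
print("because trial-area mammal rates are not representative fleet-wide.")

# the same table over a landings series, with per-year min-max ranges
landings = LandingsSeries(tons={"low year": 4516.0, "high year": 7601.0})
print()
print(scenario_table(landings, rates, [20, 50]).round(1).to_string(index=False))
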