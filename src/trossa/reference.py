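"""Published summary statistics of the 2022 Icelandic lumpfish trial.

These are the printed depth-specific rates, landings proportions and annual
extrapolations reported for the Húnaflói Bay deterrent trial, together with
the national lumpfish landings summary for 2014–2021.  They let the scenario
engine (and the packaged demo) run without access to the raw trial database:
the rate table plus the landings series are sufficient inputs for the
fleet-wide extrapolation and the depth-restriction simulations.
"""

from __future__ import annotations

import numpy as np

from .rates import RateTable

#: Lower edges of the 10 m depth bins; the last bin is open (>50 m).
DEPTH_BIN_EDGES = np.array([0.0, 10.0, 20.0, 30.0, 40.0, 50.0])

#: Lumpfish catch rate (fish per standardised trossa-day) per depth bin.
FISH_CATCH_RATE = np.array([43.03, 36.13, 32.84, 33.51, 31.41, 39.76])

#: Seabird bycatch rate (birds per standardised trossa-day), printed at 2 d.p.
SEABIRD_BYCATCH_RATE = np.array([0.38, 0.19, 0.09, 0.05, 0.01, 0.00])

#: Marine-mammal bycatch rate (mammals per standardised trossa-day), 2 d.p.
MAMMAL_BYCATCH_RATE = np.array([0.00, 0.01, 0.01, 0.02, 0.02, 0.00])

#: Fraction of national annual lumpfish landings taken in each depth bin.
LANDINGS_PROPORTION = np.array([0.13, 0.34, 0.18, 0.13, 0.10, 0.12])

#: Average annual fish catch per bin, 2014–2021 (metric tons).
ANNUAL_FISH_CATCH_TONS = np.array([700.3, 1831.5, 969.6, 700.3, 538.7, 646.4])

#: Average annual seabird bycatch per bin, 2014–2021 (individuals).
ANNUAL_SEABIRD_BYCATCH = np.array([2067.0, 3204.0, 902.0, 329.0, 70.0, 0.0])

#: National annual lumpfish landings 2014–2021: mean and (min, max) tons.
MEAN_ANNUAL_LANDINGS_TONS = float(ANNUAL_FISH_CATCH_TONS.sum())  # 5386.8
LANDINGS_RANGE_TONS = (4516.0, 7601.0)
LANDINGS_YEARS = (2014, 2021)

#: Assumed mass of one gravid female lumpfish (kg), used to convert landings
#: tonnage into numbers of fish.
MEAN_FISH_WEIGHT_KG = 3.0

#: Reported bycatch totals by species across the whole trial (individuals);
#: used as the default multinomial species mix of the synthetic generator.
BIRD_SPECIES_TOTALS = {
    "common_eider": 151,
    "common_guillemot": 48,
    "black_guillemot": 29,
    "long_tailed_duck": 10,
    "great_cormorant": 7,
    "european_shag": 2,
    "atlantic_puffin": 1,
    "red_throated_diver": 1,
    "northern_fulmar": 1,
}

MAMMAL_SPECIES_TOTALS = {
    "harbour_porpoise": 10,
    "harbour_seal": 10,
    "grey_seal": 3,
    "harp_seal": 3,
    "bottlenose_dolphin": 2,
    "white_beaked_dolphin": 1,
}

#: Study scale: trips, trossas, deterrent-equipped trossas.
STUDY_N_BOATS = 7
STUDY_N_TRIPS = 84
STUDY_N_TROSSAS = 936
STUDY_N_LEB = 61

#: Trossa area summary (m²) across the trial.
TROSSA_AREA_RANGE = (993.2, 2837.7)
TROSSA_AREA_MEAN = 2000.0


def reference_rate_table() -> RateTable:
    """The published depth-specific rate table, with landings proportions.

    Bird rates are the printed 2-decimal values; the per-bin annual bycatch
    column is attached so that unrounded rates can be recovered downstream
    (see :func:`trossa.scenarios.unrounded_bird_rates`).
    """
    return RateTable(
        edges=DEPTH_BIN_EDGES.copy(),
        fish_rate=FISH_CATCH_RATE.copy(),
        bird_rate=SEABIRD_BYCATCH_RATE.copy(),
        mammal_rate=MAMMAL_BYCATCH_RATE.copy(),
        landings_proportion=LANDINGS_PROPORTION.copy(),
        annual_bird_bycatch=ANNUAL_SEABIRD_BYCATCH.copy(),
    )
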