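#!/usr/bin/env python
"""Basal operating point of the mitochondrial clearance network.

Computes the steady state of the default model at 0 mM D-alanine and
reports the quantities that anchor everything downstream: the steady H2O2
concentration (~3.3 nM at a 4 uM/s generation flux), the NADPH/NADP+ ratio
(~13.6) and the NADPH regeneration flux (~4.0 uM/s).  Writes the full
species vector to results/basal_state.csv.
"""

from pathlib import Path

import pandas as pd

from mitonadph.redox_network import Geometry, KineticParameters, SPECIES
from mitonadph.steady_state import MoietyTotals, basal_ratio, initialize_oxidized_species

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    params, geometry, totals = KineticParameters(), Geometry(), MoietyTotals()
    state = initialize_oxidized_species(totals, params, geometry)

    OUT.mkdir(exist_ok=True)
    pd.Series({n: getattr(state, n) for n in SPECIES}, name="concentration_uM").to_csv(
        OUT / "basal_state.csv"
    )

    print(f"basal H2O2:            {state.h2o2 * 1e3:8.3f} nM")
    print(f"basal NADPH:           {state.nadph:8.2f} uM")
    print(f"basal NADP+:           {state.nadp:8.3f} uM")
    print(f"basal NADPH/NADP+:     {basal_ratio(state):8.2f}")
    print(f"regeneration flux:     {params.k_gen_nadph * state.nadp:8.3f} uM/s")
    print(f"-> {OUT / 'basal_state.csv'}")


if __name__ == "__main__":
    main()
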