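"""Generate the synthetic WEE1-inhibition phosphoproteomics dataset.

Default scenario: 300 proteins, 200 CDK1/CDK2 substrates with planted
S/T-P-x-K/R flanks split between fast (K ~ 10 min) and slow (K ~ 60
min) Michaelis-Menten activation, 60 flat basophilic control
substrates, and 2,000 decoy sites (1,700 flat, 300 decreasing), over
a 0/20/40/60/90 min x 3 replicate design.
"""

import sys
from pathlib import Path

from phosdyn.synth import SimulationConfig, simulate, write_simulation

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parent.parent / "results" / "simdata"


def main() -> None:
    sim = simulate(SimulationConfig(), seed=SEED)
    write_simulation(sim, OUT)
    truth = sim.truth.sites
    print(f"simulated {sim.phospho.n_features} phosphosites x "
          f"{sim.phospho.n_samples} samples (seed {SEED})")
    print("kinetic classes:",
          truth["kinetic_class"].value_counts().to_dict())
    print("planted kinase sites:",
          sim.annotations["kinase"].value_counts().to_dict())
    print(f"outputs in {OUT}")


if __name__ == "__main__":
    main()
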