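"""Fit the bivariate threshold-linear animal model to the simulated data.

Fits white-striping liability paired with pHu on the population written by
01_simulate.py, using a reduced schedule (20,000 iterations, 4,000 burn-in,
thinning 10; the full analysis schedule is 100,000/20,000/20).  Also runs
the two intra-line refits.  Chains are written to results/chains/.
"""

import pathlib
import sys
import time

from wstripe.simulate import load_dataset
from wstripe.threshold_model import McmcConfig, ModelSpec, gibbs_run

ROOT = pathlib.Path(__file__).resolve().parents[1]
SIM = ROOT / "results" / "simulated_population"
OUT = ROOT / "results" / "chains"

SCHEDULE = dict(iterations=20_000, burnin=4_000, thin=10)


def main(seed: int = 1) -> None:
    if not (SIM / "phenotypes.csv").exists():
        print("no simulated population found - run 01_simulate.py first")
        return
    OUT.mkdir(parents=True, exist_ok=True)
    ped, pheno, truth = load_dataset(SIM)
    print(f"pedigree: {len(ped)} birds; generating truth: "
          f"G = {truth['true_G']}, thresholds = {truth['thresholds']}")

    for line, tag in ((None, "all"), ("pHu+", "pHu_plus"), ("pHu-", "pHu_minus")):
        spec = ModelSpec(trait1="WS", trait2="pHu", line=line)
        t0 = time.time()
        chain = gibbs_run(ped, pheno, spec, McmcConfig(seed=seed, **SCHEDULE))
        path = OUT / f"chain_WS_pHu_{tag}.csv"
        chain.to_csv(path)
        print(f"[{tag}] {chain.n_records} records, {len(chain)} retained draws "
              f"in {time.time() - t0:.0f}s -> {path}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
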