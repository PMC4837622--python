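"""Posterior summaries, scale conversion, convergence diagnostics.

Reads the chains written by 03_fit_threshold_model.py, reports heritability
and genetic-correlation estimates (posterior mean ± SD) with significance
flags, converts the liability-scale heritability to the observed scale at
the realized incidence (Dempster-Lerner), and runs the Heidelberger-Welch
test on every stored parameter.  Tables land in results/posterior/.
"""

import pathlib

import pandas as pd

from wstripe.posterior import dempster_lerner, heidelberger_welch, summarize
from wstripe.simulate import load_dataset

ROOT = pathlib.Path(__file__).resolve().parents[1]
CHAINS = ROOT / "results" / "chains"
OUT = ROOT / "results" / "posterior"


def main() -> None:
    paths = sorted(CHAINS.glob("chain_*.csv")) if CHAINS.exists() else []
    if not paths:
        print("no chains found - run 03_fit_threshold_model.py first")
        return
    OUT.mkdir(parents=True, exist_ok=True)

    for path in paths:
        draws = pd.read_csv(path)
        tag = path.stem.replace("chain_", "")
        summ = summarize(draws)
        summ.to_csv(OUT / f"summary_{tag}.csv", index=False)
        print(f"\n== {tag} ({len(draws)} draws) ==")
        print(summ.round(4).to_string(index=False))

        rows = []
        for col in draws.columns:
            if col == "iter":
                continue
            r = heidelberger_welch(draws[col].to_numpy())
            rows.append({"parameter": col,
                         "stationarity": r.stationarity_passed,
                         "halfwidth": r.halfwidth_passed,
                         "cvm_pvalue": round(r.cvm_pvalue, 4)})
        diag = pd.DataFrame(rows)
        diag.to_csv(OUT / f"heidelberger_welch_{tag}.csv", index=False)
        bad = diag[~diag.stationarity]
        print("Heidelberger-Welch stationarity failures:",
              bad.parameter.tolist() if len(bad) else "none")

        if tag.endswith("all"):
            h2 = float(summ.loc[summ.parameter == "h2_1", "mean"].iloc[0])
            _, pheno, _ = load_dataset(ROOT / "results" / "simulated_population")
            p = float((pheno["WS"] != "NORM").mean())
            print(f"liability-scale h2 = {h2:.2f} at incidence {p:.2f} -> "
                  f"observed-scale h2 = {dempster_lerner(h2, p):.2f} "
                  "(Dempster-Lerner)")


if __name__ == "__main__":
    main()
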