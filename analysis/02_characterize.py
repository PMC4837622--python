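"""Phenotypic characterization stage.

Two parts: (1) recompute the published overall white-striping incidences
from the per-line category counts (MOD 36.7%, SEV 14.0%, affected 50.7% of
1,349 scored birds); (2) run the same machinery on the simulated population
from 01_simulate.py — incidence by line and sex, chi-squared comparisons per
category, and the intra-line fixed-effects model with LSMeans and
Tukey-Kramer letters for pHu.  Tables land in results/characterization/.
"""

import pathlib

import pandas as pd

from wstripe.pheno import (
    chi_square_by_category,
    fit_ws_fixed_model,
    incidence_table,
    lsmeans_tukey,
)
from wstripe.simulate import load_dataset

ROOT = pathlib.Path(__file__).resolve().parents[1]
SIM = ROOT / "results" / "simulated_population"
OUT = ROOT / "results" / "characterization"

PER_LINE_COUNTS = {
    "pHu+": {"NORM": 234, "MOD": 289, "SEV": 162},
    "pHu-": {"NORM": 431, "MOD": 206, "SEV": 27},
}


def published_incidences() -> pd.DataFrame:
    rows = []
    for line, by_cat in PER_LINE_COUNTS.items():
        for cat, n in by_cat.items():
            rows += [{"id": f"{line}-{cat}-{i}", "WS": cat, "line": line}
                     for i in range(n)]
    return incidence_table(pd.DataFrame(rows), by=["line"])


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    inc_pub = published_incidences()
    inc_pub.to_csv(OUT / "incidence_published_counts.csv", index=False)
    overall = inc_pub.iloc[-1]
    print("published counts -> overall incidence: "
          f"MOD {overall['MOD_pct']:.1f}%  SEV {overall['SEV_pct']:.1f}%  "
          f"affected {overall['affected_pct']:.1f}%  (n = {int(overall['n'])})")

    if not (SIM / "phenotypes.csv").exists():
        print("no simulated population found - run 01_simulate.py first")
        return
    ped, pheno, _ = load_dataset(SIM)
    tab = pheno.merge(ped.table[["id", "line", "sex", "hatch", "generation"]], on="id")
    # characterization uses the last two generations of the selected lines,
    # mirroring a scoring campaign at generations 5-6
    tab = tab[tab["generation"].isin([5, 6])]

    inc = incidence_table(tab, by=["line", "sex"])
    inc.to_csv(OUT / "incidence_simulated.csv", index=False)
    print("\nsimulated incidence by line x sex:")
    print(inc.to_string(index=False))

    chi = chi_square_by_category(tab)
    chi.to_csv(OUT / "chi_square_simulated.csv", index=False)
    sig = chi[(chi.comparison == "overall") & (chi.p_value < 0.05)]
    print(f"\ncategories with unequal line x sex frequencies (p < 0.05): "
          f"{sig.category.tolist()}")

    fit = fit_ws_fixed_model(tab, "pHu")
    ls = lsmeans_tukey(fit)
    ls.to_csv(OUT / "lsmeans_pHu.csv", index=False)
    ls.attrs["pairwise"].to_csv(OUT / "lsmeans_pHu_pairwise.csv", index=False)
    print("\nLSMeans of pHu by WS within line (Tukey-Kramer letters):")
    print(ls.round(4).to_string(index=False))


if __name__ == "__main__":
    main()
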