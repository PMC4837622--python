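"""Phenotypic characterization of white striping.

Incidence tables by line × sex, chi-squared comparisons of category
frequencies between groups, and the intra-line fixed-effects model

    y = hatch + sex + line + WS(line) + e

with LSMeans (marginal means averaged uniformly over hatch and sex) and
Tukey–Kramer pairwise comparisons of the white-striping categories within
each line.  Drip loss should be entered log-transformed (``transform="log"``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from patsy import build_design_matrices

from .simulate import WS_CATEGORIES

__all__ = [
    "incidence_table",
    "chi_square_by_category",
    "fit_ws_fixed_model",
    "lsmeans_tukey",
    "flag_outliers",
    "WSFixedModel",
]

_WS_NUMERIC = {1: "NORM", 2: "MOD", 3: "SEV", "1": "NORM", "2": "MOD", "3": "SEV"}


def _normalize_ws(col: pd.Series) -> pd.Series:
    """Coerce a WS column to the ordered category labels NORM < MOD < SEV."""
    out = col.replace(_WS_NUMERIC)
    bad = out.dropna()[~out.dropna().isin(WS_CATEGORIES)]
    if len(bad):
        raise ValueError(f"unrecognized WS codes: {sorted(set(bad))}")
    return pd.Categorical(out, categories=list(WS_CATEGORIES), ordered=True)


def incidence_table(tab: pd.DataFrame, by: list[str] | None = None) -> pd.DataFrame:
    """Counts and percentages of each WS category, per group and overall.

    Parameters
    ----------
    tab : DataFrame with a ``WS`` column ({NORM, MOD, SEV} or {1,2,3}).
    by : grouping columns (e.g. ``["line", "sex"]``); ``None`` → overall only.

    The denominator of every percentage is the number of birds with a
    non-missing WS score in the group.  Empty groups are reported with count
    0 and NaN percentages, flagged in the ``empty`` column.
    """
    ws = _normalize_ws(tab["WS"])
    df = tab.assign(WS=ws)
    df = df[df["WS"].notna()]

    def one_group(g: pd.DataFrame, label: tuple) -> dict:
        n = len(g)
        row: dict = dict(zip(by or [], label if isinstance(label, tuple) else (label,)))
        row["n"] = n
        for cat in WS_CATEGORIES:
            cnt = int((g["WS"] == cat).sum())
            row[f"{cat}_n"] = cnt
            row[f"{cat}_pct"] = 100.0 * cnt / n if n else np.nan
        row["affected_pct"] = (
            row["MOD_pct"] + row["SEV_pct"] if n else np.nan
        )
        row["empty"] = n == 0
        return row

    rows = []
    if by:
        for label, g in df.groupby(by, observed=False, sort=True):
            rows.append(one_group(g, label))
    rows.append({**one_group(df, ()), **{c: "all" for c in (by or [])}})
    out = pd.DataFrame(rows)
    return out


def chi_square_by_category(
    tab: pd.DataFrame, groups: list[str] = ("line", "sex")
) -> pd.DataFrame:
    """Per-WS-category Pearson chi-squared comparisons across groups.

    For each category the g groups are compared on the 2×g table
    (in-category vs not); pairwise 2×2 subtables use the same uncorrected
    statistic.  Expected cells < 1 are flagged (``low_expected``), the
    statistic is still returned.
    """
    groups = list(groups)
    ws = _normalize_ws(tab["WS"])
    df = tab.assign(WS=ws)
    df = df[df["WS"].notna()]
    glabels = [
        lab if isinstance(lab, tuple) else (lab,)
        for lab in df.groupby(groups, observed=True).groups
    ]
    if len(glabels) < 2:
        raise ValueError("need at least two groups to compare")
    key = df[groups].apply(tuple, axis=1)
    rows = []
    for cat in WS_CATEGORIES:
        in_cat = (df["WS"] == cat).to_numpy()

        def table_for(labels):
            t = np.array(
                [
                    [
                        int((in_cat & (key == lab)).sum()),
                        int((~in_cat & (key == lab)).sum()),
                    ]
                    for lab in labels
                ]
            ).T  # 2 x g
            return t

        def run(labels, comparison):
            t = table_for(labels)
            if (t.sum(axis=1) == 0).any():
                # category absent everywhere (or universal): proportions are
                # identical across groups by construction
                chi2, p, dof = 0.0, 1.0, len(labels) - 1
                expected = np.zeros_like(t, dtype=float)
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    chi2, p, dof, expected = stats.chi2_contingency(t, correction=False)
            rows.append(
                {
                    "category": cat,
                    "comparison": comparison,
                    "statistic": float(chi2),
                    "df": int(dof),
                    "p_value": float(p),
                    "low_expected": bool((expected < 1).any()),
                }
            )

        run(glabels, "overall")
        for i in range(len(glabels)):
            for j in range(i + 1, len(glabels)):
                run(
                    [glabels[i], glabels[j]],
                    f"{'/'.join(map(str, glabels[i]))} vs {'/'.join(map(str, glabels[j]))}",
                )
    return pd.DataFrame(rows)


@dataclass
class WSFixedModel:
    """Fitted fixed-effects model with the metadata LSMeans needs."""

    result: object  # statsmodels RegressionResults
    trait: str
    data: pd.DataFrame
    hatch_levels: list
    sex_levels: list
    line_levels: list
    ws_levels: list


def fit_ws_fixed_model(
    tab: pd.DataFrame, trait: str, transform: str | None = None
) -> WSFixedModel:
    """Least-squares fit of  trait ~ hatch + sex + line + WS(line).

    ``tab`` must carry the trait, WS, hatch, sex and line columns (merge the
    pedigree metadata in first if needed).  ``transform="log"`` fits
    log(trait), the convention for drip loss.
    """
    df = tab.copy()
    df["WS"] = _normalize_ws(df["WS"]).astype(str)
    df = df[df["WS"].isin(WS_CATEGORIES)]
    df = df.dropna(subset=[trait])
    y = df[trait].astype(float)
    if transform == "log":
        if (y <= 0).any():
            raise ValueError(f"log transform requires positive {trait}")
        df["_y"] = np.log(y)
    elif transform is None:
        df["_y"] = y
    else:
        raise ValueError(f"unknown transform {transform!r}")
    for c in ("hatch", "sex", "line"):
        df[c] = df[c].astype(str)
    formula = "_y ~ C(hatch) + C(sex) + C(line) + C(line):C(WS)"
    model = smf.ols(formula, data=df)
    res = model.fit()
    # all-zero columns are empty line x WS cells: non-estimable, skipped by
    # LSMeans; any remaining deficiency is a genuine confounding error
    nonzero = ~np.all(model.exog == 0, axis=0)
    rank = np.linalg.matrix_rank(model.exog[:, nonzero])
    if rank < int(nonzero.sum()):
        names = np.asarray(model.exog_names)[nonzero]
        r = np.linalg.qr(model.exog[:, nonzero], mode="r")
        diag = np.abs(np.diag(r))
        aliased = [names[j] for j in np.where(diag < 1e-8 * diag.max())[0]]
        raise ValueError(f"rank-deficient design beyond the intended nesting: {aliased}")
    return WSFixedModel(
        result=res,
        trait=trait,
        data=df,
        hatch_levels=sorted(df["hatch"].unique()),
        sex_levels=sorted(df["sex"].unique()),
        line_levels=sorted(df["line"].unique()),
        ws_levels=[c for c in WS_CATEGORIES if c in set(df["WS"])],
    )


def _cell_contrast(fit: WSFixedModel, line: str, ws: str) -> np.ndarray:
    """Design row of the LSMean of cell (line, ws): uniform average over
    the hatch × sex grid."""
    grid = pd.DataFrame(
        [
            {"hatch": h, "sex": s, "line": line, "WS": ws}
            for h in fit.hatch_levels
            for s in fit.sex_levels
        ]
    )
    (X,) = build_design_matrices([fit.result.model.data.design_info], grid)
    return np.asarray(X).mean(axis=0)


def lsmeans_tukey(fit: WSFixedModel, alpha: float = 0.05) -> pd.DataFrame:
    """LSMeans ± SE of WS within line, with Tukey–Kramer letters.

    Marginal means average uniformly over hatch and sex; pairwise intra-line
    comparisons use the studentized-range (Tukey–Kramer, unequal n)
    adjustment at the given alpha, summarized as a compact letter display.
    """
    res = fit.result
    V = res.cov_params().to_numpy()
    beta = res.params.to_numpy()
    df_resid = res.df_resid
    rows = []
    pairwise_rows = []
    for line in fit.line_levels:
        cells = {}
        for ws in fit.ws_levels:
            if ((fit.data["line"] == line) & (fit.data["WS"] == ws)).sum() == 0:
                continue  # non-estimable cell, excluded from letters
            c = _cell_contrast(fit, line, ws)
            cells[ws] = c
        k = len(cells)
        names = list(cells)
        pmat = pd.DataFrame(np.ones((k, k)), index=names, columns=names)
        for i in range(k):
            for j in range(i + 1, k):
                d = cells[names[i]] - cells[names[j]]
                se = float(np.sqrt(d @ V @ d))
                q = abs(float(d @ beta)) / se * np.sqrt(2.0)
                p = float(stats.studentized_range.sf(q, k, df_resid)) if k > 1 else 1.0
                pmat.iloc[i, j] = pmat.iloc[j, i] = p
                pairwise_rows.append(
                    {
                        "line": line,
                        "WS_a": names[i],
                        "WS_b": names[j],
                        "estimate": float(d @ beta),
                        "se": se,
                        "p_tukey": p,
                    }
                )
        letters = _compact_letters(names, pmat, alpha)
        for ws in names:
            c = cells[ws]
            rows.append(
                {
                    "line": line,
                    "WS": ws,
                    "lsmean": float(c @ beta),
                    "se": float(np.sqrt(c @ V @ c)),
                    "letters": letters[ws],
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["pairwise"] = pd.DataFrame(pairwise_rows)
    return out


def _compact_letters(names: list, pmat: pd.DataFrame, alpha: float) -> dict:
    """Insert-and-absorb compact letter display from a pairwise p-value matrix."""
    groups: list[set] = [set(names)]
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if pmat.loc[a, b] < alpha:
                new_groups: list[set] = []
                for g in groups:
                    if a in g and b in g:
                        new_groups += [g - {a}, g - {b}]
                    else:
                        new_groups.append(g)
                # keep maximal sets only, deduplicated
                groups = []
                for g in new_groups:
                    if g and not any(g < h for h in new_groups) and g not in groups:
                        groups.append(g)
    groups.sort(key=lambda g: min(names.index(x) for x in g) if g else 0)
    out = {nm: "" for nm in names}
    for letter, g in zip("abcdefghijklmnopqrstuvwxyz", groups):
        for nm in names:
            if nm in g:
                out[nm] += letter
    return out


def flag_outliers(values: pd.Series, k: float = 5.0) -> pd.Series:
    """Optional robust outlier filter: |value − median| > k·MAD.

    Off by default everywhere; returns a boolean mask of flagged records so
    every removal can be logged by the caller.
    """
    v = values.astype(float)
    med = v.median()
    mad = (v - med).abs().median()
    if mad == 0:
        return pd.Series(False, index=values.index)
    return (v - med).abs() > k * mad * 1.4826
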