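"""Synthetic divergent-selection breeding scheme.

Emulates an experimental broiler population of two lines divergently selected
on breast-meat ultimate pH (pHu): a base generation of unrelated founders is
split into two pools, and in each subsequent generation the highest- (pHu+
line) or lowest- (pHu− line) phenotyped males and females are mated at random
to produce the next one.  Each bird carries a multivariate breeding value
(parent average + Mendelian-sampling deviation with covariance
0.5·(1 − (F_s + F_d)/2)·G) and a phenotype
μ + hatch + sex + maternal environment (body weight only) + breeding value +
residual.  The first trait may be a latent liability, thresholded into the
ordinal white-striping categories NORM < MOD < SEV.

Defaults mirror the study population this package models: ~10,700 birds over
a base plus 6 generations, 32 sires and 84 dams per line and generation,
3 hatches per generation (21 hatch levels), liability heritability 0.65 with
residual variance fixed at 1, thresholds placed so that ≈36.7% of birds are
MOD and ≈14% SEV, and a quantitative pHu trait with h² = 0.55, phenotypic
variance 0.02 and a genetic correlation of 0.21 with the liability.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .pedigree import UNKNOWN, KinshipCalculator, Pedigree, load_pedigree, write_pedigree

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_population",
    "write_dataset",
    "load_dataset",
]

WS_CATEGORIES = ("NORM", "MOD", "SEV")


def _default_G() -> np.ndarray:
    # liability h2 = 0.65 with sigma2_e = 1; pHu h2 = 0.55, sigma2_p = 0.02;
    # genetic correlation 0.21
    g1 = 0.65 / 0.35
    g2 = 0.55 * 0.02
    g12 = 0.21 * np.sqrt(g1 * g2)
    return np.array([[g1, g12], [g12, g2]])


def _default_R() -> np.ndarray:
    # liability residual fixed at 1; mild environmental correlation 0.1
    e2 = 0.45 * 0.02
    e12 = 0.10 * np.sqrt(1.0 * e2)
    return np.array([[1.0, e12], [e12, e2]])


def _default_thresholds() -> tuple[float, ...]:
    # with liability mean ~0.030 and SD sqrt(1 + 0.65/0.35) = 1.690 this puts
    # ~49.3% NORM, ~36.7% MOD, ~14% SEV
    return (0.0, 1.855)


@dataclass
class SimulationConfig:
    """Full parameterization of the synthetic breeding scheme."""

    n_generations: int = 6
    base_size: int = 1640
    sires_per_line: int = 32
    dams_per_line: int = 84
    offspring_per_dam: int = 9
    hatches_per_generation: int = 3
    trait_names: tuple = ("WS", "pHu")
    liability_trait: str | None = "WS"
    true_G: np.ndarray = field(default_factory=_default_G)
    true_R: np.ndarray = field(default_factory=_default_R)
    maternal_trait: str | None = None  # e.g. "BW"
    c2: float = 0.10  # maternal-environment fraction of phenotypic variance
    thresholds: tuple = field(default_factory=_default_thresholds)
    trait_means: tuple | None = None  # default: liability 0.030, others 0
    sex_effect_sd: float = 0.3  # in phenotypic-SD units, per trait
    hatch_effect_sd: float = 0.25  # in phenotypic-SD units, per trait
    selection_trait: str = "pHu"
    selection_direction: int = +1  # high line selects +, low line −
    selection_fraction: float | None = None  # None: take exactly the needed parents
    measured_generations: dict | None = None  # trait -> iterable of generations
    seed: int = 2016

    def __post_init__(self) -> None:
        self.true_G = np.asarray(self.true_G, dtype=float)
        self.true_R = np.asarray(self.true_R, dtype=float)
        t = len(self.trait_names)
        for name, M in (("true_G", self.true_G), ("true_R", self.true_R)):
            if M.shape != (t, t):
                raise ValueError(f"{name} must be {t}x{t} for traits {self.trait_names}")
            if not np.allclose(M, M.T):
                raise ValueError(f"{name} must be symmetric")
            if np.linalg.eigvalsh(M).min() < -1e-10:
                raise ValueError(f"{name} must be positive semi-definite")
        if self.liability_trait is not None:
            if self.liability_trait not in self.trait_names:
                raise ValueError("liability_trait must be one of trait_names")
            th = np.asarray(self.thresholds, dtype=float)
            if th.ndim != 1 or np.any(np.diff(th) <= 0):
                raise ValueError("thresholds must be strictly increasing")
        if self.selection_trait not in self.trait_names:
            raise ValueError("selection_trait must be one of trait_names")
        if self.selection_fraction is not None and not (0 < self.selection_fraction <= 1):
            raise ValueError("selection_fraction must be in (0, 1]")
        if self.maternal_trait is not None and self.maternal_trait not in self.trait_names:
            raise ValueError("maternal_trait must be one of trait_names")
        if not 0 <= self.c2 < 1:
            raise ValueError("c2 must be in [0, 1)")

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)

    def means(self) -> np.ndarray:
        if self.trait_means is not None:
            return np.asarray(self.trait_means, dtype=float)
        mu = np.zeros(self.n_traits)
        if self.liability_trait is not None:
            mu[self.trait_names.index(self.liability_trait)] = 0.030
        return mu

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["true_G"] = self.true_G.tolist()
        d["true_R"] = self.true_R.tolist()
        d["trait_names"] = list(self.trait_names)
        d["thresholds"] = list(self.thresholds)
        if d["measured_generations"] is not None:
            d["measured_generations"] = {
                k: list(v) for k, v in d["measured_generations"].items()
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for k in ("trait_names", "thresholds"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class SimulatedDataset:
    """A simulated population: pedigree, phenotypes, and the generating truth."""

    pedigree: Pedigree
    phenotypes: pd.DataFrame  # id, WS category, quantitative traits
    breeding_values: pd.DataFrame  # id + one column per trait (true values)
    liabilities: pd.DataFrame | None  # id, liability (when a liability trait exists)
    selection_audit: pd.DataFrame  # realized selection differentials
    config: SimulationConfig


def _mvn(rng, mean, cov, size):
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(cov.shape[0]))
    z = rng.standard_normal((size, cov.shape[0]))
    return np.asarray(mean) + z @ L.T


def simulate_population(cfg: SimulationConfig) -> SimulatedDataset:
    """Run the breeding scheme and return the full simulated dataset."""
    rng = np.random.default_rng(cfg.seed)
    t = cfg.n_traits
    G, R = cfg.true_G, cfg.true_R
    mu = cfg.means()
    sigma_p = np.sqrt(np.diag(G) + np.diag(R))
    sel_j = cfg.trait_names.index(cfg.selection_trait)
    lia_j = (
        cfg.trait_names.index(cfg.liability_trait)
        if cfg.liability_trait is not None
        else None
    )
    maternal_j = (
        cfg.trait_names.index(cfg.maternal_trait)
        if cfg.maternal_trait is not None
        else None
    )
    sigma2_c = 0.0
    if maternal_j is not None:
        sigma2_p_m = G[maternal_j, maternal_j] + R[maternal_j, maternal_j]
        # c2 is the maternal fraction of total phenotypic variance
        sigma2_c = cfg.c2 / (1.0 - cfg.c2) * sigma2_p_m

    # fixed-effect offsets, drawn once per config (recorded in the truth file)
    n_hatches = (cfg.n_generations + 1) * cfg.hatches_per_generation
    hatch_eff = rng.normal(0.0, cfg.hatch_effect_sd, size=(n_hatches, t)) * sigma_p
    sex_eff = rng.normal(0.0, cfg.sex_effect_sd, size=t) * sigma_p  # female − male

    # growing per-individual records
    sire_idx: list[int] = []
    dam_idx: list[int] = []
    line: list[str] = []
    sex: list[str] = []
    hatch: list[int] = []
    generation: list[int] = []
    bv = np.empty((0, t))
    phen = np.empty((0, t))
    kin = KinshipCalculator([], [])
    audit_rows: list[dict] = []

    def add_cohort(n, sires, dams, lab, gen, hatches):
        """Append n birds; sires/dams are index arrays (UNKNOWN for founders)."""
        nonlocal bv, phen
        start = len(sire_idx)
        sire_idx.extend(int(s) for s in sires)
        dam_idx.extend(int(d) for d in dams)
        kin.extend(sires, dams)
        line.extend([lab] * n)
        sx = np.where(rng.random(n) < 0.5, "M", "F")
        sex.extend(sx.tolist())
        hatch.extend(int(h) for h in hatches)
        generation.extend([gen] * n)
        # breeding values
        if np.all(np.asarray(sires) == UNKNOWN):
            a = _mvn(rng, np.zeros(t), G, n)
        else:
            Fs = np.array([kin.F(int(s)) for s in sires])
            Fd = np.array([kin.F(int(d)) for d in dams])
            pa = 0.5 * (bv[np.asarray(sires)] + bv[np.asarray(dams)])
            # Mendelian deviation: chol(G) draw scaled per individual
            scale = np.sqrt(0.5 * (1.0 - 0.5 * (Fs + Fd)))
            ms = _mvn(rng, np.zeros(t), G, n) * scale[:, None]
            a = pa + ms
        # maternal-environment draw: one per dam per generation
        c_contrib = np.zeros((n, t))
        if maternal_j is not None and sigma2_c > 0 and not np.all(
            np.asarray(dams) == UNKNOWN
        ):
            udams = np.unique(np.asarray(dams))
            cvals = {int(dd): rng.normal(0.0, np.sqrt(sigma2_c)) for dd in udams}
            c_contrib[:, maternal_j] = [cvals[int(dd)] for dd in dams]
        e = _mvn(rng, np.zeros(t), R, n)
        y = mu + hatch_eff[np.asarray(hatches, dtype=int)] + c_contrib + a + e
        y[sx == "F"] += sex_eff
        bv = np.vstack([bv, a])
        phen = np.vstack([phen, y])
        return np.arange(start, start + n)

    # --- base generation, split into two line pools -------------------------
    base_h = rng.integers(0, cfg.hatches_per_generation, size=cfg.base_size)
    base_rows = add_cohort(
        cfg.base_size,
        [UNKNOWN] * cfg.base_size,
        [UNKNOWN] * cfg.base_size,
        "base",
        0,
        base_h,
    )
    pool = rng.permutation(base_rows)
    cohorts = {"pHu+": pool[: cfg.base_size // 2], "pHu-": pool[cfg.base_size // 2 :]}

    # --- selected generations ----------------------------------------------
    for gen in range(1, cfg.n_generations + 1):
        for lab, direction in (("pHu+", +1), ("pHu-", -1)):
            direction *= cfg.selection_direction
            cand = cohorts[lab]
            sexes = np.asarray(sex, dtype=object)[cand]
            males = cand[sexes == "M"]
            females = cand[sexes == "F"]
            mcrit = phen[males, sel_j] * direction
            fcrit = phen[females, sel_j] * direction
            if len(males) < cfg.sires_per_line or len(females) < cfg.dams_per_line:
                raise ValueError(
                    f"generation {gen} line {lab}: not enough candidates to select"
                )
            if cfg.selection_fraction is None:
                sires = males[np.argsort(-mcrit)[: cfg.sires_per_line]]
                dams = females[np.argsort(-fcrit)[: cfg.dams_per_line]]
            else:
                km = max(cfg.sires_per_line, int(np.ceil(len(males) * cfg.selection_fraction)))
                kf = max(cfg.dams_per_line, int(np.ceil(len(females) * cfg.selection_fraction)))
                sires = rng.choice(
                    males[np.argsort(-mcrit)[:km]], cfg.sires_per_line, replace=False
                )
                dams = rng.choice(
                    females[np.argsort(-fcrit)[:kf]], cfg.dams_per_line, replace=False
                )
            audit_rows.append(
                {
                    "generation": gen,
                    "line": lab,
                    "candidates_mean": float(np.mean(phen[cand, sel_j])),
                    "sires_mean": float(np.mean(phen[sires, sel_j])),
                    "dams_mean": float(np.mean(phen[dams, sel_j])),
                    "differential": float(
                        0.5 * (np.mean(phen[sires, sel_j]) + np.mean(phen[dams, sel_j]))
                        - np.mean(phen[cand, sel_j])
                    ),
                }
            )
            # mating: dams shuffled round-robin over sires; one hatch per dam
            dams = rng.permutation(dams)
            dam_sire = sires[np.arange(len(dams)) % len(sires)]
            dam_hatch = (
                gen * cfg.hatches_per_generation
                + (np.arange(len(dams)) % cfg.hatches_per_generation)
            )
            n_off = len(dams) * cfg.offspring_per_dam
            off_d = np.repeat(dams, cfg.offspring_per_dam)
            off_s = np.repeat(dam_sire, cfg.offspring_per_dam)
            off_h = np.repeat(dam_hatch, cfg.offspring_per_dam)
            cohorts[lab] = add_cohort(n_off, off_s, off_d, lab, gen, off_h)

    # --- assemble tables ----------------------------------------------------
    n = len(sire_idx)
    ids = np.arange(1, n + 1)
    ped_df = pd.DataFrame(
        {
            "id": ids,
            "sire": np.where(np.asarray(sire_idx) == UNKNOWN, 0, np.asarray(sire_idx) + 1),
            "dam": np.where(np.asarray(dam_idx) == UNKNOWN, 0, np.asarray(dam_idx) + 1),
            "line": line,
            "sex": sex,
            "hatch": np.asarray(hatch) + 1,
            "generation": generation,
        }
    )
    ped = Pedigree.from_frame(ped_df)

    pheno = pd.DataFrame({"id": ids})
    lia_df = None
    for j, name in enumerate(cfg.trait_names):
        col = phen[:, j].copy()
        if j == lia_j:
            th = np.asarray(cfg.thresholds)
            cat = np.digitize(col, th)  # 0 below t1, 1 in [t1,t2), 2 >= t2
            pheno["WS"] = np.asarray(WS_CATEGORIES, dtype=object)[cat]
            lia_df = pd.DataFrame({"id": ids, "liability": col})
        else:
            pheno[name] = col
    # missingness masks by generation
    if cfg.measured_generations:
        gen_arr = np.asarray(generation)
        for trait, gens in cfg.measured_generations.items():
            colname = "WS" if trait == cfg.liability_trait else trait
            mask = ~np.isin(gen_arr, list(gens))
            pheno.loc[mask, colname] = np.nan if colname != "WS" else None

    bv_df = pd.DataFrame({"id": ids})
    for j, name in enumerate(cfg.trait_names):
        bv_df[name] = bv[:, j]

    return SimulatedDataset(
        pedigree=ped,
        phenotypes=pheno,
        breeding_values=bv_df,
        liabilities=lia_df,
        selection_audit=pd.DataFrame(audit_rows),
        config=cfg,
    )


def write_dataset(ds: SimulatedDataset, outdir) -> dict:
    """Write pedigree, phenotype and truth files; returns the path map."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "pedigree": os.path.join(outdir, "pedigree.csv"),
        "phenotypes": os.path.join(outdir, "phenotypes.csv"),
        "breeding_values": os.path.join(outdir, "breeding_values.csv"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    write_pedigree(ds.pedigree, paths["pedigree"])
    # phenotypes in original id order
    ds.phenotypes.to_csv(paths["phenotypes"], index=False)
    ds.breeding_values.to_csv(paths["breeding_values"], index=False)
    cfg = ds.config
    truth = {
        "seed": cfg.seed,
        "trait_names": list(cfg.trait_names),
        "true_G": cfg.true_G.tolist(),
        "true_R": cfg.true_R.tolist(),
        "thresholds": list(cfg.thresholds),
        "maternal_trait": cfg.maternal_trait,
        "c2": cfg.c2,
        "config": cfg.to_dict(),
        "selection_audit": ds.selection_audit.to_dict(orient="records"),
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1)
    return paths


def load_dataset(outdir):
    """Read back a written dataset: (Pedigree, phenotype frame, truth dict)."""
    ped = load_pedigree(os.path.join(outdir, "pedigree.csv"))
    pheno = pd.read_csv(os.path.join(outdir, "phenotypes.csv"))
    with open(os.path.join(outdir, "truth.json")) as fh:
        truth = json.load(fh)
    return ped, pheno, truth
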