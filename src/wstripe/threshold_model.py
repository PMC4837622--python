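"""Bivariate threshold–linear animal model fitted by Gibbs sampling.

The model for each trait is

    y = μ + hatch + sex + maternal environment (body weight only) + a + e

with breeding values a over the whole pedigree, Var(a) = A ⊗ G, and residual
blocks R per bird.  When trait 1 is the ordinal white-striping score its
record is a latent normal liability: category c is observed when the
liability falls between thresholds t_{c-1} and t_c.  Identifiability is fixed
by t_1 = 0 and σ²_e1 = 1 (documented in chain output); the free threshold and
the liabilities are sampled as ordinary Gibbs blocks.

Missing co-trait records are data-augmented each sweep from their residual
conditional and discarded, which realizes the analytic marginalization over
the unobserved trait; birds with no records contribute through A only.

Per iteration the sampler draws: liabilities → free threshold → fixed-effect
blocks → maternal-environment effects → breeding values (individual-wise
over the sparse A⁻¹ neighborhood) → G (inverse-Wishart on the
Mendelian-sampling cross-products) → σ²_c (scaled inverse chi-squared) → R
(conditional-regression decomposition when σ²_e1 is constrained, otherwise
inverse-Wishart).  Priors are flat for location effects and thresholds and
minimally informative for the (co)variances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import _kernels as K
from .pedigree import Pedigree, a_inverse, mendelian_sampling_variances
from .simulate import WS_CATEGORIES

__all__ = [
    "ModelSpec",
    "McmcConfig",
    "ChainStore",
    "MissingPlan",
    "gibbs_run",
    "solve_mme",
    "handle_missing",
    "draw_truncated_normal",
    "sample_threshold",
]

# minimally informative (co)variance priors
NU0_G_EXTRA = 1.0  # G ~ IW(dim + 1 + q, 0.1 I + S_a)
S0_G = 0.1
NU0_C, S0_C = 1.0, 0.1  # sigma2_c ~ scaled-inv-chi2
NU0_PSI, S0_PSI = 1.0, 0.1  # conditional residual variance, constrained R
S0_R = 0.1  # unconstrained R ~ IW(dim + 1 + n, 0.1 I + S_e)


class ModelError(ValueError):
    """Raised for inconsistent model inputs."""


@dataclass
class ModelSpec:
    """Trait pair and effect structure of one bivariate (or univariate) fit."""

    trait1: str = "WS"
    trait2: str | None = None
    ws_column: str = "WS"
    maternal_traits: tuple = ("BW",)
    fixed_effects: tuple = ("mu", "hatch", "sex")
    include_line_effect: bool = False
    line: str | None = None  # restrict records to one line (intra-line refit)

    @property
    def bivariate(self) -> bool:
        return self.trait2 is not None

    @property
    def threshold(self) -> bool:
        return self.trait1 == self.ws_column


@dataclass
class McmcConfig:
    """Chain schedule; the default is the full analysis schedule
    (100,000 iterations, 20,000 burn-in, thinning 20 → 4,000 retained)."""

    iterations: int = 100_000
    burnin: int = 20_000
    thin: int = 20
    seed: int = 0
    initial: dict | None = None  # optional "G", "R", "sigma2_c" start values
    fix_variances: bool = False  # hold (co)variances at start values (diagnostics)

    def __post_init__(self) -> None:
        if not (0 <= self.burnin < self.iterations):
            raise ValueError("burn-in must be shorter than the chain")
        if self.thin < 1:
            raise ValueError("thinning interval must be >= 1")

    @property
    def retained(self) -> int:
        return (self.iterations - self.burnin) // self.thin


@dataclass
class ChainStore:
    """Thinned post-burn-in draws plus chain provenance."""

    draws: pd.DataFrame
    seed: int
    spec: ModelSpec
    config: McmcConfig
    effect_means: dict
    n_records: int
    n_pedigree: int
    n_resampled: int = 0

    def __len__(self) -> int:
        return len(self.draws)

    def to_csv(self, path) -> None:
        self.draws.to_csv(path, index=False)

    @staticmethod
    def read_draws(path) -> pd.DataFrame:
        return pd.read_csv(path)


@dataclass
class MissingPlan:
    """How each record pattern enters the likelihood (augment-and-discard)."""

    n_both: int
    n_trait1_only: int
    n_trait2_only: int
    n_pedigree_only: int
    strategy: str = "augment"


def draw_truncated_normal(rng, mean, sd, lo=-np.inf, hi=np.inf, size=None):
    """Inverse-CDF truncated-normal draws (the liability-sampling primitive)."""
    lo = -K.INF if np.isneginf(lo) else float(lo)
    hi = K.INF if np.isposinf(hi) else float(hi)
    if size is None:
        return K.trunc_normal(float(mean), float(sd), lo, hi, float(rng.random()))
    u = rng.random(size)
    return np.array([K.trunc_normal(float(mean), float(sd), lo, hi, float(v)) for v in u])


def sample_threshold(rng, y1: np.ndarray, code1: np.ndarray) -> float:
    """Draw the free threshold t_2 uniformly on
    (max liability among MOD, min liability among SEV)."""
    mod = y1[code1 == 1]
    sev = y1[code1 == 2]
    if len(mod) == 0 or len(sev) == 0:
        raise ModelError("threshold unidentifiable: empty MOD or SEV category")
    lo = float(mod.max())
    hi = float(sev.min())
    return lo + rng.random() * (hi - lo)


def handle_missing(pheno: pd.DataFrame, spec: ModelSpec) -> MissingPlan:
    """Classify records by missingness pattern for the augmentation plan."""
    o1 = pheno[spec.trait1].notna() if spec.trait1 in pheno else pd.Series(False, index=pheno.index)
    if spec.bivariate:
        o2 = pheno[spec.trait2].notna() if spec.trait2 in pheno else pd.Series(False, index=pheno.index)
    else:
        o2 = pd.Series(False, index=pheno.index)
    return MissingPlan(
        n_both=int((o1 & o2).sum()),
        n_trait1_only=int((o1 & ~o2).sum()),
        n_trait2_only=int((~o1 & o2).sum()),
        n_pedigree_only=int((~o1 & ~o2).sum()),
    )


# --------------------------------------------------------------------------
# data preparation shared by the sampler and the dense MME oracle
# --------------------------------------------------------------------------


class _ModelData:
    def __init__(self, ped: Pedigree, pheno: pd.DataFrame, spec: ModelSpec):
        meta_cols = ["id", "line", "sex", "hatch", "dam"]
        df = pheno.merge(ped.table[meta_cols], on="id", how="inner", suffixes=("", "_ped"))
        if len(df) < len(pheno):
            missing = set(pheno["id"]) - set(ped.table["id"])
            raise ModelError(f"phenotyped birds absent from pedigree: {sorted(missing)[:5]}")
        if spec.line is not None:
            df = df[df["line"] == spec.line]
        obs1 = df[spec.trait1].notna().to_numpy()
        obs2 = (
            df[spec.trait2].notna().to_numpy()
            if spec.bivariate
            else np.zeros(len(df), dtype=bool)
        )
        keep = obs1 | obs2
        df = df[keep].reset_index(drop=True)
        if df["id"].duplicated().any():
            raise ModelError("multiple records per bird are not supported")
        self.df = df
        self.spec = spec
        self.n = len(df)
        if self.n == 0:
            raise ModelError("no phenotyped records after filtering")
        self.obs1 = obs1[keep]
        self.obs2 = obs2[keep] if spec.bivariate else np.zeros(self.n, dtype=bool)
        self.an_idx = ped.rows_of(df["id"])
        self.q = len(ped)
        self.rec_of = np.full(self.q, -1, dtype=np.int64)
        self.rec_of[self.an_idx] = np.arange(self.n)

        # trait 1: liability codes and starting values
        if spec.threshold:
            raw = df[spec.ws_column]
            cats = raw.replace({1: "NORM", 2: "MOD", 3: "SEV", "1": "NORM", "2": "MOD", "3": "SEV"})
            present = [c for c in WS_CATEGORIES if c in set(cats.dropna())]
            if len(present) < 2:
                raise ModelError("need at least two observed WS categories")
            for c in WS_CATEGORIES:
                if c not in present:
                    raise ModelError(
                        f"liability category {c} has zero observations; "
                        "its threshold is unidentifiable"
                    )
            self.m = len(present)
            cat_code = {c: i for i, c in enumerate(present)}
            self.code1 = np.array(
                [cat_code[c] if isinstance(c, str) and c in cat_code else K.FREE for c in cats],
                dtype=np.int64,
            )
            # start the free threshold at its probit-consistent position so the
            # slow-mixing threshold walk begins near the data, not at an
            # arbitrary point: with t1 = 0 and initial liability variance v0,
            # t2 ≈ sqrt(v0)·(z_{p0+p1} − z_{p0})
            obs_codes = self.code1[self.code1 >= 0]
            freqs = np.bincount(obs_codes, minlength=self.m) / len(obs_codes)
            v0 = 2.0  # initial total liability variance (sigma2_g 1 + sigma2_e 1)
            zcum = stats.norm.ppf(np.clip(np.cumsum(freqs)[:-1], 1e-6, 1 - 1e-6))
            thr_init = np.sqrt(v0) * (zcum - zcum[0])
            self.thr0 = thr_init
            # liabilities start at the conditional category means of N(mu0, v0)
            mu0 = -np.sqrt(v0) * zcum[0]
            bounds = np.concatenate([[-np.inf], thr_init, [np.inf]])
            mids = {}
            for c in range(self.m):
                lo = bounds[c] if np.isfinite(bounds[c]) else thr_init[0] - 1.0
                hi = bounds[c + 1] if np.isfinite(bounds[c + 1]) else thr_init[-1] + 1.0
                mids[c] = 0.5 * (lo + hi)
            self.y1 = np.array([mids.get(c, mu0) for c in self.code1], dtype=float)
            self.mu0_liability = mu0
        else:
            self.m = 0
            self.thr0 = np.zeros(0)
            vals = df[spec.trait1].to_numpy(dtype=float)
            self.code1 = np.where(self.obs1, K.FIXED, K.FREE).astype(np.int64)
            fill = np.nanmean(vals) if np.isnan(vals).any() else 0.0
            self.y1 = np.where(self.obs1, vals, fill).astype(float)

        if spec.bivariate:
            vals = df[spec.trait2].to_numpy(dtype=float)
            fill = vals[self.obs2].mean()
            self.y2 = np.where(self.obs2, vals, fill).astype(float)
        else:
            self.y2 = np.zeros(self.n)

        # fixed-effect factors per trait: (name, codes, nlev, first_free)
        self.factors: list[list[tuple]] = [[], []]
        ntraits = 2 if spec.bivariate else 1
        for t in range(ntraits):
            for name in spec.fixed_effects:
                if name == "mu":
                    self.factors[t].append(("mu", np.zeros(self.n, dtype=np.int64), 1, 0))
                elif name in ("hatch", "sex", "line"):
                    if name == "line" and not spec.include_line_effect:
                        continue
                    codes, levels = pd.factorize(df[name].astype(str), sort=True)
                    if len(levels) > 1:
                        self.factors[t].append((name, codes.astype(np.int64), len(levels), 1))
                else:
                    raise ModelError(f"unknown fixed effect {name!r}")
            if spec.include_line_effect and "line" not in [f[0] for f in self.factors[t]]:
                codes, levels = pd.factorize(df["line"].astype(str), sort=True)
                if len(levels) > 1:
                    self.factors[t].append(("line", codes.astype(np.int64), len(levels), 1))

        # maternal environment: which trait (if any) carries it
        self.maternal_t = -1
        traits = [spec.trait1] + ([spec.trait2] if spec.bivariate else [])
        for t, name in enumerate(traits):
            if name in spec.maternal_traits:
                self.maternal_t = t
        if self.maternal_t >= 0:
            dams = df["dam"].to_numpy()
            known = dams != 0
            codes = np.full(self.n, -1, dtype=np.int64)
            if known.any():
                codes[known], levels = pd.factorize(dams[known])
                self.n_dam = len(levels)
            else:
                self.n_dam = 0
            self.dam_codes = codes
        else:
            self.dam_codes = np.full(self.n, -1, dtype=np.int64)
            self.n_dam = 0

        self.trait_names = traits

    def variance_starts(self, initial: dict | None):
        """G, R, sigma2_c starting values (halved phenotypic variance)."""
        spec = self.spec
        dim = 2 if spec.bivariate else 1
        v1 = 1.0 if spec.threshold else max(float(np.var(self.y1[self.obs1])), 1e-8)
        G = np.eye(dim) * 0.5 * v1
        R = np.eye(dim) * (1.0 if spec.threshold else 0.5 * v1)
        if spec.bivariate:
            v2 = max(float(np.var(self.y2[self.obs2])), 1e-8)
            G[1, 1] = 0.5 * v2
            R[1, 1] = 0.5 * v2
        sigma2_c = 0.0
        if self.maternal_t >= 0:
            vm = G[self.maternal_t, self.maternal_t] * 2.0
            sigma2_c = 0.1 * vm
        if initial:
            if "G" in initial:
                G = np.atleast_2d(np.asarray(initial["G"], dtype=float)).copy()
            if "R" in initial:
                R = np.atleast_2d(np.asarray(initial["R"], dtype=float)).copy()
            if "sigma2_c" in initial:
                sigma2_c = float(initial["sigma2_c"])
        return G, R, sigma2_c


def _inv2(M: np.ndarray) -> np.ndarray:
    if M.shape == (1, 1):
        return np.array([[1.0 / M[0, 0]]])
    det = M[0, 0] * M[1, 1] - M[0, 1] * M[1, 0]
    if det <= 0:
        raise ModelError("non-positive-definite covariance encountered")
    return np.array([[M[1, 1], -M[0, 1]], [-M[1, 0], M[0, 0]]]) / det


# --------------------------------------------------------------------------
# the sampler
# --------------------------------------------------------------------------


def gibbs_run(
    ped: Pedigree, pheno: pd.DataFrame, spec: ModelSpec, cfg: McmcConfig
) -> ChainStore:
    """Run the Gibbs sampler and return the thinned post-burn-in chain."""
    data = _ModelData(ped, pheno, spec)
    rng = np.random.default_rng(cfg.seed)
    n, q = data.n, data.q
    bivar = spec.bivariate
    dim = 2 if bivar else 1

    Ainv = a_inverse(ped).matrix
    indptr, indices, avals = Ainv.indptr, Ainv.indices, Ainv.data
    dvec = mendelian_sampling_variances(ped)
    s_idx, d_idx = ped.sire_idx, ped.dam_idx

    G, R, sigma2_c = data.variance_starts(cfg.initial)
    if spec.threshold:
        R[0, 0] = 1.0
    thr = data.thr0.copy()
    y1, y2 = data.y1.copy(), data.y2.copy()
    a = np.zeros((q, 2))
    coefs = {
        (t, name): np.zeros(nlev)
        for t in range(dim)
        for (name, _, nlev, _) in data.factors[t]
    }
    if spec.threshold:
        key = (0, "mu")
        if key in coefs:
            coefs[key][0] = data.mu0_liability
    if not spec.threshold:
        # start the intercept at the trait mean so residuals begin centred
        for t, (yv, obs) in enumerate([(y1, data.obs1), (y2, data.obs2)][:dim]):
            key = (t, "mu")
            if key in coefs:
                coefs[key][0] = yv[obs].mean() if obs.any() else 0.0
    elif bivar:
        key = (1, "mu")
        if key in coefs and data.obs2.any():
            coefs[key][0] = y2[data.obs2].mean()
    c_eff = np.zeros(max(data.n_dam, 1))

    def predicted(t):
        m = np.zeros(n)
        for name, codes, nlev, _ in data.factors[t]:
            m += coefs[(t, name)][codes]
        if data.maternal_t == t:
            mask = data.dam_codes >= 0
            m[mask] += c_eff[data.dam_codes[mask]]
        m += a[data.an_idx, t]
        return m

    e1 = y1 - predicted(0)
    e2 = y2 - predicted(1) if bivar else np.zeros(n)

    # retained draws
    cols: dict[str, list] = {k: [] for k in (
        ["iter", "sigma2_g1", "sigma2_e1", "h2_1"]
        + (["sigma_g12", "sigma2_g2", "sigma_e12", "sigma2_e2", "h2_2", "rg"] if bivar else [])
        + (["sigma2_c"] if data.maternal_t >= 0 else [])
        + (["t2"] if spec.threshold and data.m == 3 else [])
    )}
    eff_sums = {k: np.zeros_like(v) for k, v in coefs.items()}
    a_sum = np.zeros((q, dim))
    c_sum = np.zeros_like(c_eff)
    n_post = 0
    n_resampled = 0
    known_s = s_idx >= 0
    known_d = d_idx >= 0

    for it in range(cfg.iterations):
        Rinv = _inv2(R)
        r00 = Rinv[0, 0]
        r01 = Rinv[0, 1] if bivar else 0.0
        r11 = Rinv[1, 1] if bivar else 0.0

        # (1) liabilities / trait-1 augmentation
        if spec.threshold or (~data.obs1).any():
            if bivar:
                b12 = R[0, 1] / R[1, 1]
                sd1c = float(np.sqrt(R[0, 0] - R[0, 1] ** 2 / R[1, 1]))
            else:
                b12, sd1c = 0.0, float(np.sqrt(R[0, 0]))
            K.sample_liabilities(y1, e1, e2, data.code1, thr, b12, sd1c, rng.random(n))

        # (2) free threshold
        if spec.threshold and data.m == 3:
            thr[1] = sample_threshold(rng, y1, data.code1)

        # (3) trait-2 augmentation
        if bivar and (~data.obs2).any():
            b21 = R[0, 1] / R[0, 0]
            sd2c = float(np.sqrt(R[1, 1] - R[0, 1] ** 2 / R[0, 0]))
            K.augment_trait2(y2, e2, e1, data.obs2, b21, sd2c, rng.standard_normal(n))

        # (4) fixed effects, blocked per factor
        for t in range(dim):
            for name, codes, nlev, first_free in data.factors[t]:
                K.update_factor(
                    codes, nlev, t, e1, e2, r00, r01, r11,
                    coefs[(t, name)], 0.0, rng.standard_normal(nlev), first_free,
                )

        # (5) maternal-environment effects
        if data.maternal_t >= 0 and data.n_dam > 0:
            K.update_factor(
                data.dam_codes, data.n_dam, data.maternal_t, e1, e2, r00, r01, r11,
                c_eff, 1.0 / max(sigma2_c, 1e-12), rng.standard_normal(data.n_dam), 0,
            )

        # (6) breeding values
        Ginv = _inv2(G)
        if bivar:
            K.update_breeding_bivariate(
                indptr, indices, avals, data.rec_of, e1, e2,
                r00, r01, r11, Ginv[0, 0], Ginv[0, 1], Ginv[1, 1],
                a, rng.standard_normal((q, 2)),
            )
        else:
            K.update_breeding_univariate(
                indptr, indices, avals, data.rec_of, e1,
                r00, Ginv[0, 0], a[:, 0], rng.standard_normal(q),
            )

        # (7) (co)variance components
        if not cfg.fix_variances:
            av = a[:, :dim]
            u = av.copy()
            u[known_s] -= 0.5 * av[s_idx[known_s]]
            u[known_d] -= 0.5 * av[d_idx[known_d]]
            Sa = (u / dvec[:, None]).T @ u
            for _attempt in range(20):
                Gp = stats.invwishart.rvs(
                    df=dim + NU0_G_EXTRA + q, scale=S0_G * np.eye(dim) + Sa, random_state=rng
                )
                Gp = np.atleast_2d(Gp)
                if np.all(np.linalg.eigvalsh(Gp) > 0):
                    G = 0.5 * (Gp + Gp.T)
                    break
                n_resampled += 1

            if data.maternal_t >= 0 and data.n_dam > 0:
                ssc = float(c_eff @ c_eff)
                sigma2_c = float(
                    stats.invgamma.rvs(
                        a=(NU0_C + data.n_dam) / 2.0,
                        scale=(NU0_C * S0_C + ssc) / 2.0,
                        random_state=rng,
                    )
                )

            if bivar:
                if spec.threshold:
                    # constrained: sigma2_e1 = 1; regress e2 on e1
                    s11 = float(e1 @ e1)
                    s12 = float(e1 @ e2)
                    s22 = float(e2 @ e2)
                    bhat = s12 / s11
                    sse = s22 - bhat * s12
                    psi = float(
                        stats.invgamma.rvs(
                            a=(NU0_PSI + n) / 2.0,
                            scale=(NU0_PSI * S0_PSI + max(sse, 1e-12)) / 2.0,
                            random_state=rng,
                        )
                    )
                    b = bhat + np.sqrt(psi / s11) * rng.standard_normal()
                    R = np.array([[1.0, b], [b, psi + b * b]])
                else:
                    Se = np.array([
                        [float(e1 @ e1), float(e1 @ e2)],
                        [float(e1 @ e2), float(e2 @ e2)],
                    ])
                    for _attempt in range(20):
                        Rp = stats.invwishart.rvs(
                            df=3 + n, scale=S0_R * np.eye(2) + Se, random_state=rng
                        )
                        if np.all(np.linalg.eigvalsh(Rp) > 0):
                            R = 0.5 * (Rp + Rp.T)
                            break
                        n_resampled += 1
            else:
                if spec.threshold:
                    pass  # R = [[1]] fixed
                else:
                    ss = float(e1 @ e1)
                    R = np.array([[
                        stats.invgamma.rvs(
                            a=(NU0_PSI + n) / 2.0,
                            scale=(NU0_PSI * S0_PSI + ss) / 2.0,
                            random_state=rng,
                        )
                    ]])

        # periodic residual refresh against float drift
        if (it + 1) % 1000 == 0:
            e1 = y1 - predicted(0)
            if bivar:
                e2 = y2 - predicted(1)

        # bookkeeping
        if it >= cfg.burnin:
            n_post += 1
            for k in coefs:
                eff_sums[k] += coefs[k]
            a_sum += a[:, :dim]
            c_sum += c_eff
            if (it + 1 - cfg.burnin) % cfg.thin == 0:
                cols["iter"].append(it + 1)
                cols["sigma2_g1"].append(G[0, 0])
                cols["sigma2_e1"].append(R[0, 0])
                den1 = G[0, 0] + R[0, 0] + (sigma2_c if data.maternal_t == 0 else 0.0)
                cols["h2_1"].append(G[0, 0] / den1)
                if bivar:
                    cols["sigma_g12"].append(G[0, 1])
                    cols["sigma2_g2"].append(G[1, 1])
                    cols["sigma_e12"].append(R[0, 1])
                    cols["sigma2_e2"].append(R[1, 1])
                    den2 = G[1, 1] + R[1, 1] + (sigma2_c if data.maternal_t == 1 else 0.0)
                    cols["h2_2"].append(G[1, 1] / den2)
                    cols["rg"].append(G[0, 1] / np.sqrt(G[0, 0] * G[1, 1]))
                if data.maternal_t >= 0:
                    cols["sigma2_c"].append(sigma2_c)
                if spec.threshold and data.m == 3:
                    cols["t2"].append(thr[1])

    effect_means = {f"{data.trait_names[t]}:{name}": eff_sums[(t, name)] / max(n_post, 1)
                    for (t, name) in eff_sums}
    effect_means["breeding_values"] = a_sum / max(n_post, 1)
    if data.maternal_t >= 0:
        effect_means["maternal"] = c_sum / max(n_post, 1)

    return ChainStore(
        draws=pd.DataFrame(cols),
        seed=cfg.seed,
        spec=spec,
        config=cfg,
        effect_means=effect_means,
        n_records=n,
        n_pedigree=q,
        n_resampled=n_resampled,
    )


# --------------------------------------------------------------------------
# dense mixed-model-equation oracle (small instances)
# --------------------------------------------------------------------------


def solve_mme(
    ped: Pedigree,
    pheno: pd.DataFrame,
    spec: ModelSpec,
    G: np.ndarray,
    R: np.ndarray,
    sigma2_c: float = 0.0,
) -> dict:
    """Posterior means of all location effects at fixed (co)variances.

    Builds the dense mixed-model equations
    [W'R⁻¹W + blockdiag(0, I/σ²_c, A⁻¹ ⊗ G⁻¹)] θ = W'R⁻¹y and solves them
    directly.  Requires fully observed continuous records (no liabilities) —
    this is the independent check for the Gibbs location conditionals, not a
    fitting path.
    """
    data = _ModelData(ped, pheno, spec)
    if spec.threshold:
        raise ModelError("MME oracle requires continuous traits")
    if not (data.obs1.all() and (not spec.bivariate or data.obs2.all())):
        raise ModelError("MME oracle requires complete records")
    n, q = data.n, data.q
    dim = 2 if spec.bivariate else 1
    G = np.atleast_2d(np.asarray(G, dtype=float))[:dim, :dim]
    R = np.atleast_2d(np.asarray(R, dtype=float))[:dim, :dim]
    Rinv = _inv2(R)
    Ginv = _inv2(G)

    # unknown layout: per trait fixed-effect free levels, maternal, a per trait
    blocks = []  # (label, trait, codes, nlev_free, offset)
    p = 0
    for t in range(dim):
        for name, codes, nlev, first_free in data.factors[t]:
            nfree = nlev - first_free
            blocks.append((f"{data.trait_names[t]}:{name}", t, codes, first_free, nlev, p))
            p += nfree
    mat_off = None
    if data.maternal_t >= 0 and data.n_dam > 0:
        mat_off = p
        p += data.n_dam
    a_off = p
    p += dim * q

    X = [np.zeros((n, p)) for _ in range(dim)]  # design of each trait's mean
    for label, t, codes, first_free, nlev, off in blocks:
        for lev in range(first_free, nlev):
            X[t][codes == lev, off + (lev - first_free)] = 1.0
    if mat_off is not None:
        mask = data.dam_codes >= 0
        X[data.maternal_t][np.where(mask)[0], mat_off + data.dam_codes[mask]] = 1.0
    for t in range(dim):
        X[t][np.arange(n), a_off + t * q + data.an_idx] = 1.0

    Y = [data.y1, data.y2][:dim]
    C = np.zeros((p, p))
    rhs = np.zeros(p)
    for t in range(dim):
        for s in range(dim):
            C += Rinv[t, s] * (X[t].T @ X[s])
            rhs += Rinv[t, s] * (X[t].T @ Y[s])
    Ad = a_inverse(ped).matrix.toarray()
    for t in range(dim):
        for s in range(dim):
            C[a_off + t * q:a_off + (t + 1) * q, a_off + s * q:a_off + (s + 1) * q] += (
                Ginv[t, s] * Ad
            )
    if mat_off is not None:
        C[mat_off:mat_off + data.n_dam, mat_off:mat_off + data.n_dam] += (
            np.eye(data.n_dam) / sigma2_c
        )
    theta = np.linalg.solve(C, rhs)

    out: dict = {}
    for label, t, codes, first_free, nlev, off in blocks:
        full = np.zeros(nlev)
        full[first_free:] = theta[off:off + (nlev - first_free)]
        out[label] = full
    if mat_off is not None:
        out["maternal"] = theta[mat_off:mat_off + data.n_dam]
    out["breeding_values"] = theta[a_off:].reshape(dim, q).T
    return out
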