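"""Numba kernels for the threshold–linear Gibbs sampler.

Hot loops only: truncated-normal liability draws, factor-block location
updates, and the individual-wise breeding-value sweep over the sparse A⁻¹
neighborhood.  All randomness comes in as pre-drawn arrays so a single seeded
numpy Generator in the driver controls the whole chain.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

INF = 1.0e30

# liability codes per record: -2 = fixed (observed quantitative trait 1),
# -1 = free (missing, plain normal draw), >= 0 = ordinal category index
FIXED = -2
FREE = -1


@njit(cache=True)
def ndtri(p: float) -> float:
    """Inverse standard-normal CDF, Wichura's AS 241 (double precision)."""
    q = p - 0.5
    if abs(q) <= 0.425:
        r = 0.180625 - q * q
        num = (((((((2.5090809287301226727e3 * r + 3.3430575583588128105e4) * r
                    + 6.7265770927008700853e4) * r + 4.5921953931549871457e4) * r
                  + 1.3731693765509461125e4) * r + 1.9715909503065514427e3) * r
                + 1.3314166789178437745e2) * r + 3.3871328727963666080e0)
        den = (((((((5.2264952788528545610e3 * r + 2.8729085735721942674e4) * r
                    + 3.9307895800092710610e4) * r + 2.1213794301586595867e4) * r
                  + 5.3941960214247511077e3) * r + 6.8718700749205790830e2) * r
                + 4.2313330701600911252e1) * r + 1.0)
        return q * num / den
    r = p if q < 0.0 else 1.0 - p
    if r <= 0.0:
        return -INF if q < 0.0 else INF
    r = math.sqrt(-math.log(r))
    if r <= 5.0:
        r = r - 1.6
        num = (((((((7.74545014278341407640e-4 * r + 2.27238449892691845833e-2) * r
                    + 2.41780725177450611770e-1) * r + 1.27045825245236838258e0) * r
                  + 3.64784832476320460504e0) * r + 5.76949722146069140550e0) * r
                + 4.63033784615654529590e0) * r + 1.42343711074968357734e0)
        den = (((((((1.05075007164441684324e-9 * r + 5.47593808499534494600e-4) * r
                    + 1.51986665636164571966e-2) * r + 1.48103976427480074590e-1) * r
                  + 6.89767334985100004550e-1) * r + 1.67638483018380384940e0) * r
                + 2.05319162663775882187e0) * r + 1.0)
    else:
        r = r - 5.0
        num = (((((((2.01033439929228813265e-7 * r + 2.71155556874348757815e-5) * r
                    + 1.24266094738807843860e-3) * r + 2.65321895265761230930e-2) * r
                  + 2.96560571828504891230e-1) * r + 1.78482653991729133580e0) * r
                + 5.46378491116411436990e0) * r + 6.65790464350110377720e0)
        den = (((((((2.04426310338993978564e-15 * r + 1.42151175831644588870e-7) * r
                    + 1.84631831751005468180e-5) * r + 7.86869131145613259100e-4) * r
                  + 1.48753612908506148525e-2) * r + 1.36929880922735805310e-1) * r
                + 5.99832206555887937690e-1) * r + 1.0)
    val = num / den
    return -val if q < 0.0 else val


@njit(cache=True)
def ndtr(x: float) -> float:
    return 0.5 * math.erfc(-x / math.sqrt(2.0))


@njit(cache=True)
def trunc_normal(mean: float, sd: float, lo: float, hi: float, u: float) -> float:
    """Inverse-CDF draw from N(mean, sd²) truncated to (lo, hi)."""
    plo = 0.0 if lo <= -INF else ndtr((lo - mean) / sd)
    phi = 1.0 if hi >= INF else ndtr((hi - mean) / sd)
    width = phi - plo
    if width < 1.0e-14:
        # interval mass numerically zero: pin just inside the nearer boundary
        if lo <= -INF:
            return hi - 1.0e-8 * sd
        if hi >= INF:
            return lo + 1.0e-8 * sd
        return 0.5 * (lo + hi)
    p = plo + u * width
    if p < 1.0e-15:
        p = 1.0e-15
    elif p > 1.0 - 1.0e-15:
        p = 1.0 - 1.0e-15
    x = mean + sd * ndtri(p)
    if x <= lo:
        x = lo + 1.0e-10 * max(sd, 1.0)
    elif x >= hi and hi < INF:
        x = hi - 1.0e-10 * max(sd, 1.0)
    return x


@njit(cache=True)
def sample_liabilities(y1, e1, e2, code1, thr, b12, sd1c, u):
    """Draw latent liabilities (and augment missing trait-1 records) in place.

    ``thr`` holds the full threshold vector (t_1 = 0 first); a record in
    category c lies in (thr[c-1], thr[c]) with ±inf at the ends.  ``b12`` is
    the residual regression of trait 1 on trait 2 (R12/R22) and ``sd1c`` the
    conditional residual SD; with no second trait pass b12 = 0, sd1c = 1.
    """
    n = y1.shape[0]
    m = thr.shape[0]
    for i in range(n):
        c = code1[i]
        if c == FIXED:
            continue
        m1 = y1[i] - e1[i]
        mean = m1 + b12 * e2[i]
        if c == FREE:
            lo = -INF
            hi = INF
        else:
            lo = -INF if c == 0 else thr[c - 1]
            hi = INF if c >= m else thr[c]
        draw = trunc_normal(mean, sd1c, lo, hi, u[i])
        y1[i] = draw
        e1[i] = draw - m1


@njit(cache=True)
def augment_trait2(y2, e2, e1, obs2, b21, sd2c, z):
    """Data-augment missing trait-2 records from their residual conditional."""
    n = y2.shape[0]
    for i in range(n):
        if obs2[i]:
            continue
        m2 = y2[i] - e2[i]
        draw = m2 + b21 * e1[i] + sd2c * z[i]
        y2[i] = draw
        e2[i] = draw - m2


@njit(cache=True)
def update_factor(codes, nlev, trait, e1, e2, r00, r01, r11,
                  coef, prior_prec, z, first_free):
    """Blocked Gibbs update of one factor's level coefficients (one trait).

    ``codes`` maps records to levels (-1 = not applicable); levels of one
    factor partition the records, so drawing them jointly from their scalar
    full conditionals is an exact block update.  ``first_free`` = 0 samples
    all levels, 1 keeps level 0 at its corner-constraint value.  ``r``
    entries are the 2×2 residual precision (r01 = 0, r00 = 1/σ²e for a
    univariate run).  Residuals are corrected in place.
    """
    P = np.full(nlev, prior_prec)
    r = np.zeros(nlev)
    n = codes.shape[0]
    if trait == 0:
        for i in range(n):
            c = codes[i]
            if c < 0:
                continue
            P[c] += r00
            r[c] += r00 * (e1[i] + coef[c]) + r01 * e2[i]
    else:
        for i in range(n):
            c = codes[i]
            if c < 0:
                continue
            P[c] += r11
            r[c] += r11 * (e2[i] + coef[c]) + r01 * e1[i]
    new = coef.copy()
    for l in range(first_free, nlev):
        if P[l] > prior_prec or prior_prec > 0.0:
            new[l] = r[l] / P[l] + z[l] / math.sqrt(P[l])
    if trait == 0:
        for i in range(n):
            c = codes[i]
            if c >= 0:
                e1[i] -= new[c] - coef[c]
    else:
        for i in range(n):
            c = codes[i]
            if c >= 0:
                e2[i] -= new[c] - coef[c]
    for l in range(nlev):
        coef[l] = new[l]


@njit(cache=True)
def update_breeding_bivariate(indptr, indices, data, rec_of, e1, e2,
                              r00, r01, r11, gi00, gi01, gi11, a, z):
    """Individual-wise Gibbs sweep over breeding values (two traits).

    For individual i the full conditional has precision
    A⁻¹_ii·G⁻¹ + Z_i'R⁻¹Z_i and mean term −G⁻¹ Σ_{j≠i} A⁻¹_ij a_j plus the
    data contribution; the sweep is sequential (Gauss–Seidel style), which
    preserves the stationary distribution.
    """
    q = a.shape[0]
    for i in range(q):
        s1 = 0.0
        s2 = 0.0
        aii = 0.0
        for ptr in range(indptr[i], indptr[i + 1]):
            j = indices[ptr]
            v = data[ptr]
            if j == i:
                aii = v
            else:
                s1 -= v * a[j, 0]
                s2 -= v * a[j, 1]
        p00 = aii * gi00
        p01 = aii * gi01
        p11 = aii * gi11
        r1 = gi00 * s1 + gi01 * s2
        r2 = gi01 * s1 + gi11 * s2
        rec = rec_of[i]
        if rec >= 0:
            f1 = e1[rec] + a[i, 0]
            f2 = e2[rec] + a[i, 1]
            r1 += r00 * f1 + r01 * f2
            r2 += r01 * f1 + r11 * f2
            p00 += r00
            p01 += r01
            p11 += r11
        # Cholesky of the 2x2 precision: P = L L'
        l00 = math.sqrt(p00)
        l10 = p01 / l00
        l11 = math.sqrt(p11 - l10 * l10)
        # mean = P^{-1} r  via two triangular solves
        w1 = r1 / l00
        w2 = (r2 - l10 * w1) / l11
        mu2 = w2 / l11
        mu1 = (w1 - l10 * mu2) / l00
        # sample: mean + L'^{-1} z
        d2 = z[i, 1] / l11
        d1 = (z[i, 0] - l10 * d2) / l00
        n1 = mu1 + d1
        n2 = mu2 + d2
        if rec >= 0:
            e1[rec] -= n1 - a[i, 0]
            e2[rec] -= n2 - a[i, 1]
        a[i, 0] = n1
        a[i, 1] = n2


@njit(cache=True)
def update_breeding_univariate(indptr, indices, data, rec_of, e1, r00, ginv, a, z):
    q = a.shape[0]
    for i in range(q):
        s1 = 0.0
        aii = 0.0
        for ptr in range(indptr[i], indptr[i + 1]):
            j = indices[ptr]
            if j == i:
                aii = data[ptr]
            else:
                s1 -= data[ptr] * a[j]
        p = aii * ginv
        r = ginv * s1
        rec = rec_of[i]
        if rec >= 0:
            r += r00 * (e1[rec] + a[i])
            p += r00
        mu = r / p
        n1 = mu + z[i] / math.sqrt(p)
        if rec >= 0:
            e1[rec] -= n1 - a[i]
        a[i] = n1
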