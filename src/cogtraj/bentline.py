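"""Bayesian bent-line regression with person-level random change points.

The model describes a longitudinal cognitive composite (a Z-scored score
observed at irregular ages) as a continuous piecewise-linear function of age
with a person-specific change point (CP): performance follows one slope up to
the CP and another after it, with the two segments meeting at the CP.

For participant ``i`` with visit ages ``a_ij`` and scores ``y_ij``::

    y_ij ~ Normal(f(a_ij; theta_i), sigma_resid)
    f(a; theta) = alpha1 + alpha2 * min(a - tau, 0) + alpha3 * max(a - tau, 0)

where ``theta_i = (alpha1_i, alpha2_i, alpha3_i, tau_i)`` are the score at
the CP, the pre-CP slope (Z/year), the post-CP slope (Z/year) and the CP age
(years).  Each person-level parameter is exchangeable across participants::

    alpha_k,i ~ Normal(mu_k, sd_k),   tau_i ~ Normal(mu_tau, sd_tau)

with weakly-informative hyperpriors (normal on the population means,
half-normal on the between-person SDs and the residual SD).  The CP is not
constrained to a participant's observation window, so CPs before the first or
after the last visit are admissible and are shrunk toward the population mean.

Posterior sampling uses a Metropolis-within-Gibbs scheme: the three linear
person parameters and the population means have conjugate Gaussian full
conditionals and are sampled in closed form; the change points and the scale
parameters are updated with adaptive random-walk Metropolis steps (adaptation
runs during warmup only, so the post-warmup chain is a valid Markov chain).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "PersonParams",
    "LongitudinalSeries",
    "PriorConfig",
    "BentLineModel",
    "bentline_mean",
    "fit_bablr",
    "extract_person_medians",
    "classify_cp_position",
    "convergence_report",
]

PARAM_NAMES = ("alpha1", "alpha2", "alpha3", "tau")
FIXED_NAMES = (
    "mu_alpha1",
    "mu_alpha2",
    "mu_alpha3",
    "mu_tau",
    "sd_alpha1",
    "sd_alpha2",
    "sd_alpha3",
    "sd_tau",
    "sigma_resid",
)

# accepted long-format column aliases: (participant, age, score)
_COLUMN_ALIASES = (
    ("participant_id", "visit_age_years", "pacc3_z"),
    ("participant_id", "age", "score"),
)


@dataclass(frozen=True)
class PersonParams:
    """Person-level bent-line parameters.

    alpha1: composite score at the change point [Z].
    alpha2: slope before the change point [Z/year].
    alpha3: slope after the change point [Z/year].
    tau: change-point age [years].
    """

    alpha1: float
    alpha2: float
    alpha3: float
    tau: float

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha1, self.alpha2, self.alpha3, self.tau])


@dataclass
class LongitudinalSeries:
    """One participant's (age, score) visit sequence."""

    participant_id: object
    ages: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.ages.ndim != 1 or self.ages.shape != self.scores.shape:
            raise ValueError("ages and scores must be 1-D and equally long")
        if self.ages.size < 3:
            raise ValueError(
                f"participant {self.participant_id!r}: at least 3 visits "
                f"required, got {self.ages.size}"
            )
        if not np.all(np.diff(self.ages) > 0):
            raise ValueError(
                f"participant {self.participant_id!r}: visit ages must be "
                "strictly increasing"
            )
        if not (np.all(np.isfinite(self.ages)) and np.all(np.isfinite(self.scores))):
            raise ValueError(
                f"participant {self.participant_id!r}: non-finite ages/scores"
            )

    @property
    def n_visits(self) -> int:
        return self.ages.size


@dataclass(frozen=True)
class PriorConfig:
    """Hyperprior settings.

    Population means are normal; ``mu_tau_loc=None`` anchors the CP-age mean
    prior at the sample mean visit age.  Between-person SDs and the residual
    SD carry half-normal priors with the given scales.
    """

    mu_loc: tuple = (0.0, 0.0, 0.0, None)
    mu_scale: tuple = (5.0, 5.0, 5.0, 15.0)
    sd_scale: tuple = (2.5, 2.5, 2.5, 10.0)
    resid_scale: float = 2.0


def _hinge_parts(d, smooth_width: float = 0.0):
    """Split age-minus-CP into pre/post parts; optional smooth transition.

    Returns (neg_part, pos_part) with neg + pos == d, pos >= 0, and both zero
    at d == 0.  With smooth_width == 0 these are exactly min(d, 0) and
    max(d, 0) (no smoothing at the knot).
    """
    d = np.asarray(d, dtype=float)
    if smooth_width > 0:
        w = smooth_width
        pos = 0.5 * (d + np.sqrt(d * d + w * w) - w)
        return d - pos, pos
    return np.minimum(d, 0.0), np.maximum(d, 0.0)


def bentline_mean(age, params, smooth_width: float = 0.0):
    """Expected composite score at ``age`` under bent-line parameters.

    ``params`` is a :class:`PersonParams` or a length-4 sequence
    (alpha1, alpha2, alpha3, tau).  Vectorized over ``age``.
    """
    if isinstance(params, PersonParams):
        a1, a2, a3, tau = params.alpha1, params.alpha2, params.alpha3, params.tau
    else:
        a1, a2, a3, tau = (float(v) for v in params)
    age_arr = np.asarray(age, dtype=float)
    if not np.all(np.isfinite(age_arr)) or not all(
        np.isfinite(v) for v in (a1, a2, a3, tau)
    ):
        raise ValueError("bentline_mean requires finite inputs")
    neg, pos = _hinge_parts(age_arr - tau, smooth_width)
    out = a1 + a2 * neg + a3 * pos
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------


def _as_series_list(X) -> list[LongitudinalSeries]:
    if isinstance(X, pd.DataFrame):
        cols = None
        for alias in _COLUMN_ALIASES:
            if all(c in X.columns for c in alias):
                cols = alias
                break
        if cols is None:
            raise ValueError(
                "long-format input needs columns "
                + " or ".join(str(a) for a in _COLUMN_ALIASES)
            )
        pid, age_c, score_c = cols
        out = []
        for key, grp in X.groupby(pid, sort=False):
            grp = grp.sort_values(age_c)
            out.append(
                LongitudinalSeries(key, grp[age_c].to_numpy(), grp[score_c].to_numpy())
            )
        return out
    series = list(X)
    if not all(isinstance(s, LongitudinalSeries) for s in series):
        raise TypeError("expected a DataFrame or a list of LongitudinalSeries")
    return series


def _pack(series: list[LongitudinalSeries]):
    n = len(series)
    if n == 0:
        raise ValueError("no participants to fit")
    jmax = max(s.n_visits for s in series)
    ages = np.zeros((n, jmax))
    y = np.zeros((n, jmax))
    mask = np.zeros((n, jmax), dtype=bool)
    for i, s in enumerate(series):
        m = s.n_visits
        ages[i, :m] = s.ages
        y[i, :m] = s.scores
        mask[i, :m] = True
    ids = [s.participant_id for s in series]
    return ids, ages, y, mask


# ---------------------------------------------------------------------------
# sampler
# ---------------------------------------------------------------------------


def _run_chain(
    ages: np.ndarray,
    y: np.ndarray,
    mask: np.ndarray,
    iterations: int,
    warmup: int,
    seed,
    prior_loc: np.ndarray,
    prior_scale: np.ndarray,
    sd_scale: np.ndarray,
    resid_scale: float,
    tau_support,
    smooth_width: float,
):
    rng = np.random.default_rng(seed)
    n, jmax = ages.shape
    maskf = mask.astype(float)
    m = maskf.sum(axis=1)
    n_obs = float(m.sum())

    # --- initialisation from per-person straight-line fits
    ma = (maskf * ages).sum(1) / m
    my = (maskf * y).sum(1) / m
    dx = (ages - ma[:, None]) * maskf
    dy = (y - my[:, None]) * maskf
    sxx = (dx * dx).sum(1)
    slope = (dx * dy).sum(1) / np.maximum(sxx, 1e-12)
    # chain starts are over-dispersed around the per-person line fits so
    # that split-R-hat can detect unexplored posterior mass
    tau = ma + rng.normal(0.0, 2.0, n)
    beta = np.column_stack(
        [my + slope * (tau - ma), slope, slope]
    ) + rng.normal(0.0, 0.02, (n, 3))
    mu = np.array(
        [beta[:, 0].mean(), slope.mean(), slope.mean(), tau.mean()]
    ) + rng.normal(0.0, 1.0, 4) * np.array([0.15, 0.02, 0.02, 2.0])
    sd_pop = np.maximum(
        [beta[:, 0].std(), slope.std(), slope.std(), max(tau.std(), 1.0)],
        [0.05, 0.01, 0.01, 0.5],
    ).astype(float) * np.exp(rng.normal(0.0, 0.3, 4))
    resid0 = dy - slope[:, None] * dx
    sigma = max(float(np.sqrt((resid0 * resid0).sum() / n_obs)), 0.05)

    log_step_tau = np.full(n, 0.0)  # log of per-person RW scale (years)
    log_scale_sd = np.full(5, np.log(0.3))  # 4 pop SDs + residual SD
    log_scale_shift = np.array([np.log(0.05), np.log(0.01), np.log(0.01), np.log(0.5)])
    log_scale_scale = np.full(4, np.log(0.3))

    def sse_for(tau_vec, beta_mat):
        neg, pos = _hinge_parts(ages - tau_vec[:, None], smooth_width)
        fit = beta_mat[:, 0, None] + beta_mat[:, 1, None] * neg + beta_mat[:, 2, None] * pos
        r = (y - fit) * maskf
        return (r * r).sum(1)

    n_keep = iterations - warmup
    fixed_draws = np.empty((n_keep, len(FIXED_NAMES)))
    person_draws = np.empty((n_keep, n, 4))
    accept_tau = 0.0
    rw_count = 0

    eye3 = np.eye(3)

    def design_sums(tau_vec):
        """Masked design cross-products for the 3 linear person parameters."""
        neg, pos = _hinge_parts(ages - tau_vec[:, None], smooth_width)
        neg *= maskf
        pos *= maskf
        xtx = np.empty((n, 3, 3))
        xtx[:, 0, 0] = m
        xtx[:, 0, 1] = xtx[:, 1, 0] = neg.sum(1)
        xtx[:, 0, 2] = xtx[:, 2, 0] = pos.sum(1)
        xtx[:, 1, 1] = (neg * neg).sum(1)
        xtx[:, 1, 2] = xtx[:, 2, 1] = (neg * pos).sum(1)
        xtx[:, 2, 2] = (pos * pos).sum(1)
        return neg, pos, xtx

    def marginal_ll(tau_vec, sig2, prior_prec3, log_det_s3):
        """Per-person log p(y_i | tau_i) with the linear block integrated out.

        Uses the Woodbury identity: the marginal covariance is
        sigma^2 I + X S X' with S = diag(between-person variances); its
        determinant and quadratic form reduce to the 3x3 matrix
        A = S^-1 + X'X / sigma^2.
        """
        neg, pos, xtx = design_sums(tau_vec)
        r = (y - (mu[0] + mu[1] * neg + mu[2] * pos)) * maskf
        rtr = (r * r).sum(1)
        xtr = np.stack([r.sum(1), (neg * r).sum(1), (pos * r).sum(1)], axis=1)
        a = xtx / sig2 + eye3 * prior_prec3
        chol = np.linalg.cholesky(a)
        logdet_a = 2.0 * np.log(
            np.diagonal(chol, axis1=1, axis2=2)
        ).sum(1)
        u = np.linalg.solve(a, xtr[..., None])[..., 0]
        quad = (xtr * u).sum(1)
        return -0.5 * (
            m * np.log(sig2) + logdet_a + log_det_s3 + rtr / sig2 - quad / sig2**2
        ), (neg, pos, xtx)

    cache = None
    for it in range(iterations):
        adapt = it < warmup
        sig2 = sigma * sigma
        prior_prec3 = 1.0 / (sd_pop[:3] ** 2)
        log_det_s3 = float(np.log(sd_pop[:3] ** 2).sum())

        # --- collapsed Gibbs draw of the three linear population means
        # (person-level parameters integrated out): with beta_i marginal,
        # y_i ~ N(X_i mu, sigma^2 I + X_i S X_i'), which is linear-Gaussian
        # in mu, so mu has an exact Gaussian full conditional.
        neg0, pos0, xtx0 = design_sums(tau)
        ym0 = y * maskf
        xty0 = np.stack([ym0.sum(1), (neg0 * ym0).sum(1), (pos0 * ym0).sum(1)], axis=1)
        a0 = xtx0 / sig2 + eye3 * prior_prec3
        ainv_xty = np.linalg.solve(a0, xty0[..., None])[..., 0]
        ainv_xtx = np.linalg.solve(a0, xtx0)
        xtmx = xtx0 / sig2 - np.einsum("nij,njk->nik", xtx0, ainv_xtx) / sig2**2
        xtmy = xty0 / sig2 - np.einsum("nij,nj->ni", xtx0, ainv_xty) / sig2**2
        post_prec = np.diag(1.0 / prior_scale[:3] ** 2) + xtmx.sum(0)
        post_b = prior_loc[:3] / prior_scale[:3] ** 2 + xtmy.sum(0)
        lmu = np.linalg.cholesky(post_prec)
        mu3_mean = np.linalg.solve(post_prec, post_b)
        mu[:3] = mu3_mean + np.linalg.solve(lmu.T, rng.standard_normal(3))

        # --- collapsed Metropolis updates of tau per person (linear
        # parameters integrated out, then redrawn conjugately).  Proposals
        # alternate between a per-person adaptive random walk and an
        # independence draw from the hierarchical prior; for the latter the
        # Hastings ratio reduces to the marginal-likelihood ratio, which
        # lets weakly-identified change points jump between modes.
        ll_cur, parts_cur = marginal_ll(tau, sig2, prior_prec3, log_det_s3)
        for sweep in range(3):
            independence = rng.random() < 0.25
            if independence:
                # widen every other independence proposal beyond the current
                # hierarchical prior so underestimated between-person spread
                # cannot lock the chain out of far change-point modes
                prop_sd = sd_pop[3] * (1.0 if rng.random() < 0.5 else 3.0)
                prop = mu[3] + prop_sd * rng.standard_normal(n)
            else:
                prop = tau + np.exp(log_step_tau) * rng.standard_normal(n)
            ll_prop, parts_prop = marginal_ll(prop, sig2, prior_prec3, log_det_s3)
            prior_cur = -0.5 * ((tau - mu[3]) / sd_pop[3]) ** 2
            prior_prop = -0.5 * ((prop - mu[3]) / sd_pop[3]) ** 2
            if independence:
                lp_cur = ll_cur + prior_cur + 0.5 * ((tau - mu[3]) / prop_sd) ** 2
                lp_prop = ll_prop + prior_prop + 0.5 * ((prop - mu[3]) / prop_sd) ** 2
            else:
                lp_cur = ll_cur + prior_cur
                lp_prop = ll_prop + prior_prop
            if tau_support is not None:
                lo, hi = tau_support
                lp_prop = np.where((prop < lo) | (prop > hi), -np.inf, lp_prop)
            acc = np.log(rng.random(n)) < lp_prop - lp_cur
            tau = np.where(acc, prop, tau)
            ll_cur = np.where(acc, ll_prop, ll_cur)
            accn = acc[:, None]
            parts_cur = (
                np.where(accn, parts_prop[0], parts_cur[0]),
                np.where(accn, parts_prop[1], parts_cur[1]),
                np.where(acc[:, None, None], parts_prop[2], parts_cur[2]),
            )
            if not independence:
                if adapt:
                    log_step_tau += 0.05 * (acc.astype(float) - 0.44)
                else:
                    accept_tau += acc.mean()
                    rw_count += 1

        # --- conjugate draw of (alpha1, alpha2, alpha3) given tau
        neg, pos, xtx = parts_cur
        ym = y * maskf
        xty = np.stack([ym.sum(1), (neg * y).sum(1), (pos * y).sum(1)], axis=1)
        prec = xtx / sig2 + eye3 * prior_prec3
        rhs = xty / sig2 + mu[:3] * prior_prec3
        chol = np.linalg.cholesky(prec)
        mean = np.linalg.solve(prec, rhs[..., None])[..., 0]
        z = rng.standard_normal((n, 3))
        beta = mean + np.linalg.solve(
            np.transpose(chol, (0, 2, 1)), z[..., None]
        )[..., 0]
        fit_mean = beta[:, 0, None] + beta[:, 1, None] * neg + beta[:, 2, None] * pos
        resid = (y - fit_mean) * maskf
        sse_cur = (resid * resid).sum(1)

        # --- joint translation moves: shift one whole random-effect
        # hierarchy and its population mean together.  These traverse the
        # ridge between person-level parameters and their population mean,
        # which plain alternation explores slowly.
        for k, g in ((0, maskf), (1, neg), (2, pos)):
            c = np.exp(log_scale_shift[k]) * rng.standard_normal()
            s1 = float((resid * g).sum())
            s2 = float((g * g).sum())
            dll = (2.0 * c * s1 - c * c * s2) / (2.0 * sig2)
            dpr = -(
                (mu[k] + c - prior_loc[k]) ** 2 - (mu[k] - prior_loc[k]) ** 2
            ) / (2.0 * prior_scale[k] ** 2)
            a = np.log(rng.random()) < dll + dpr
            if a:
                beta[:, k] += c
                mu[k] += c
                resid -= c * g
                sse_cur = (resid * resid).sum(1)
            if adapt:
                log_scale_shift[k] += 0.05 * (float(a) - 0.25)
        c = np.exp(log_scale_shift[3]) * rng.standard_normal()
        prop_tau = tau + c
        ok = True
        if tau_support is not None:
            lo, hi = tau_support
            ok = bool(np.all((prop_tau >= lo) & (prop_tau <= hi)))
        if ok:
            sse_new = sse_for(prop_tau, beta)
            dll = -(float(sse_new.sum()) - float(sse_cur.sum())) / (2.0 * sig2)
            dpr = -(
                (mu[3] + c - prior_loc[3]) ** 2 - (mu[3] - prior_loc[3]) ** 2
            ) / (2.0 * prior_scale[3] ** 2)
            a = np.log(rng.random()) < dll + dpr
            if a:
                tau = prop_tau
                mu[3] += c
                sse_cur = sse_new
        else:
            a = False
        if adapt:
            log_scale_shift[3] += 0.05 * (float(a) - 0.25)

        # --- non-centered scale moves: rescale a hierarchy about its mean
        # while proposing its between-person SD.  In the standardized
        # parameterization the move is a plain MH step on log SD with the
        # random effects held at fixed Z-scores, which removes the funnel
        # that pins the hierarchy when the SD approaches zero.
        for k, g in ((0, maskf), (1, neg), (2, pos)):
            eps = np.exp(log_scale_scale[k]) * rng.standard_normal()
            s_old = sd_pop[k]
            s_new = s_old * np.exp(eps)
            d = (s_new / s_old - 1.0) * (beta[:, k] - mu[k])
            rg = (resid * g).sum(1)
            gg = (g * g).sum(1)
            dll = (2.0 * float(d @ rg) - float((d * d) @ gg)) / (2.0 * sig2)
            dpr = (
                -0.5 * (s_new / sd_scale[k]) ** 2
                + np.log(s_new)
                + 0.5 * (s_old / sd_scale[k]) ** 2
                - np.log(s_old)
            )
            a = np.log(rng.random()) < dll + dpr
            if a:
                sd_pop[k] = s_new
                beta[:, k] += d
                resid -= d[:, None] * g
                sse_cur = (resid * resid).sum(1)
            if adapt:
                log_scale_scale[k] += 0.05 * (float(a) - 0.25)
        eps = np.exp(log_scale_scale[3]) * rng.standard_normal()
        s_old = sd_pop[3]
        s_new = s_old * np.exp(eps)
        tau_new = mu[3] + (s_new / s_old) * (tau - mu[3])
        ok = True
        if tau_support is not None:
            lo, hi = tau_support
            ok = bool(np.all((tau_new >= lo) & (tau_new <= hi)))
        a = False
        if ok:
            sse_new = sse_for(tau_new, beta)
            dll = -(float(sse_new.sum()) - float(sse_cur.sum())) / (2.0 * sig2)
            dpr = (
                -0.5 * (s_new / sd_scale[3]) ** 2
                + np.log(s_new)
                + 0.5 * (s_old / sd_scale[3]) ** 2
                - np.log(s_old)
            )
            a = np.log(rng.random()) < dll + dpr
            if a:
                sd_pop[3] = s_new
                tau = tau_new
                sse_cur = sse_new
        if adapt:
            log_scale_scale[3] += 0.05 * (float(a) - 0.25)

        # --- conjugate update of population means
        theta = np.column_stack([beta, tau])
        for k in range(4):
            post_prec = n / sd_pop[k] ** 2 + 1.0 / prior_scale[k] ** 2
            post_mean = (
                theta[:, k].sum() / sd_pop[k] ** 2
                + prior_loc[k] / prior_scale[k] ** 2
            ) / post_prec
            mu[k] = post_mean + rng.standard_normal() / np.sqrt(post_prec)

        # --- MH updates of between-person SDs (half-normal priors, log scale)
        for k in range(4):
            ssd = float(((theta[:, k] - mu[k]) ** 2).sum())
            ls = np.log(sd_pop[k])
            ls_p = ls + np.exp(log_scale_sd[k]) * rng.standard_normal()

            def logt(v, _ssd=ssd, _a=sd_scale[k]):
                s = np.exp(v)
                return -n * v - _ssd / (2.0 * s * s) - 0.5 * (s / _a) ** 2 + v

            a = np.log(rng.random()) < logt(ls_p) - logt(ls)
            if a:
                sd_pop[k] = np.exp(ls_p)
            if adapt:
                log_scale_sd[k] += 0.05 * (float(a) - 0.44)

        # --- MH update of the residual SD
        sse_tot = float(sse_cur.sum())
        ls = np.log(sigma)
        ls_p = ls + np.exp(log_scale_sd[4]) * rng.standard_normal()

        def logt_r(v):
            s = np.exp(v)
            return (
                -n_obs * v - sse_tot / (2.0 * s * s) - 0.5 * (s / resid_scale) ** 2 + v
            )

        a = np.log(rng.random()) < logt_r(ls_p) - logt_r(ls)
        if a:
            sigma = float(np.exp(ls_p))
        if adapt:
            log_scale_sd[4] += 0.05 * (float(a) - 0.44)

        if it >= warmup:
            j = it - warmup
            fixed_draws[j, :4] = mu
            fixed_draws[j, 4:8] = sd_pop
            fixed_draws[j, 8] = sigma
            person_draws[j] = theta

    return fixed_draws, person_draws, accept_tau / max(rw_count, 1)


class BentLineModel(BaseEstimator):
    """Hierarchical Bayesian bent-line (random change-point) model.

    Parameters
    ----------
    chains, iterations, warmup:
        MCMC geometry.  The default is 4 chains of 5000 iterations with the
        first half discarded as warmup; desk-scale analyses typically use
        ``chains=2, iterations=1500``.  ``warmup=None`` means half of
        ``iterations``.
    seed:
        Master seed; per-chain seeds are derived deterministically.
    priors:
        :class:`PriorConfig` hyperprior settings.
    smooth_width:
        Optional smooth-transition width (years) at the change point; the
        default 0 keeps the bend exact (piecewise max/min algebra).
    tau_support:
        Optional ``(low, high)`` hard support for change-point ages; by
        default the CP is only softly constrained by its hierarchical prior.
    rhat_threshold:
        Split-R-hat above which the fit is flagged as not converged.

    Fitted attributes
    -----------------
    person_params_ : DataFrame indexed by participant with posterior-median
        alpha1/alpha2/alpha3/tau.
    fixed_effects_ : DataFrame of population parameters (median, 90% credible
        interval, R-hat, bulk ESS).
    draws_ : dict with ``fixed`` (chains, draws, 9) and ``person``
        (chains, draws, n, 4) arrays.
    diagnostics_ : dict with max R-hat, min ESS and acceptance rates.
    converged_ : bool flag (max R-hat <= rhat_threshold).
    """

    def __init__(
        self,
        chains: int = 4,
        iterations: int = 5000,
        warmup: int | None = None,
        seed: int | None = None,
        priors: PriorConfig | None = None,
        smooth_width: float = 0.0,
        tau_support: tuple | None = None,
        rhat_threshold: float = 1.05,
    ):
        self.chains = chains
        self.iterations = iterations
        self.warmup = warmup
        self.seed = seed
        self.priors = priors
        self.smooth_width = smooth_width
        self.tau_support = tau_support
        self.rhat_threshold = rhat_threshold

    def fit(self, X, y=None):
        if self.chains < 2:
            raise ValueError("at least 2 chains are required")
        series = _as_series_list(X)
        ids, ages, yy, mask = _pack(series)
        warmup = self.iterations // 2 if self.warmup is None else self.warmup
        if not 0 < warmup < self.iterations:
            raise ValueError("warmup must lie strictly inside iterations")

        priors = self.priors or PriorConfig()
        prior_loc = np.array(
            [
                0.0 if v is None else float(v)
                for v in (
                    priors.mu_loc[0],
                    priors.mu_loc[1],
                    priors.mu_loc[2],
                    ages[mask].mean() if priors.mu_loc[3] is None else priors.mu_loc[3],
                )
            ]
        )
        prior_scale = np.asarray(priors.mu_scale, dtype=float)
        sd_scale = np.asarray(priors.sd_scale, dtype=float)

        seeds = np.random.SeedSequence(self.seed).spawn(self.chains)
        fixed, person, acc = [], [], []
        for cs in seeds:
            f, p, a = _run_chain(
                ages,
                yy,
                mask,
                self.iterations,
                warmup,
                cs,
                prior_loc,
                prior_scale,
                sd_scale,
                priors.resid_scale,
                self.tau_support,
                self.smooth_width,
            )
            fixed.append(f)
            person.append(p)
            acc.append(a)

        self.participants_ = ids
        self.n_warmup_ = warmup
        self.draws_ = {
            "fixed": np.stack(fixed),
            "person": np.stack(person),
            "fixed_names": FIXED_NAMES,
            "param_names": PARAM_NAMES,
        }
        self._summarize(float(np.mean(acc)))
        return self

    # -- summaries ---------------------------------------------------------

    def _summarize(self, accept_tau: float) -> None:
        import arviz as az

        fixed = self.draws_["fixed"]  # (C, D, 9)
        person = self.draws_["person"]  # (C, D, n, 4)

        med = np.median(fixed, axis=(0, 1))
        q5 = np.quantile(fixed, 0.05, axis=(0, 1))
        q95 = np.quantile(fixed, 0.95, axis=(0, 1))
        rhat = np.empty(fixed.shape[2])
        ess = np.empty(fixed.shape[2])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for k in range(fixed.shape[2]):
                rhat[k] = float(az.rhat(fixed[:, :, k]))
                ess[k] = float(az.ess(fixed[:, :, k]))
            prh = az.rhat(az.convert_to_dataset({"person": person}))["person"]
            prh = np.asarray(prh)  # (n_participants, 4)
            person_rhat = np.nanmax(prh, axis=0)
        self.fixed_effects_ = pd.DataFrame(
            {"median": med, "q5": q5, "q95": q95, "rhat": rhat, "ess_bulk": ess},
            index=list(FIXED_NAMES),
        )
        pm = np.median(person, axis=(0, 1))
        self.person_params_ = pd.DataFrame(
            pm, columns=list(PARAM_NAMES), index=pd.Index(self.participants_, name="participant_id")
        )
        max_rhat = float(np.nanmax([np.nanmax(rhat), np.nanmax(person_rhat)]))
        self.diagnostics_ = {
            "max_rhat": max_rhat,
            "max_rhat_fixed": float(np.nanmax(rhat)),
            "max_rhat_person": {
                PARAM_NAMES[k]: float(person_rhat[k]) for k in range(4)
            },
            "min_ess_fixed": float(np.nanmin(ess)),
            "accept_tau": accept_tau,
            "chains": int(self.draws_["fixed"].shape[0]),
            "draws_per_chain": int(self.draws_["fixed"].shape[1]),
        }
        self.converged_ = bool(max_rhat <= self.rhat_threshold)
        if not self.converged_:
            warnings.warn(
                f"bent-line fit may not have converged: max R-hat "
                f"{max_rhat:.3f} > {self.rhat_threshold}",
                RuntimeWarning,
            )

    def predict(self, X):
        """Posterior-median trajectory value for (participant, age) rows."""
        df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(X)
        pid_col = "participant_id"
        age_col = "visit_age_years" if "visit_age_years" in df.columns else "age"
        out = np.empty(len(df))
        for j, (pid, age) in enumerate(zip(df[pid_col], df[age_col])):
            p = self.person_params_.loc[pid]
            out[j] = bentline_mean(
                age, (p.alpha1, p.alpha2, p.alpha3, p.tau), self.smooth_width
            )
        return out


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------


def fit_bablr(
    series,
    chains: int = 4,
    iterations: int = 5000,
    warmup: int | None = None,
    seed: int | None = None,
    priors: PriorConfig | None = None,
    **kwargs,
) -> BentLineModel:
    """Fit the hierarchical bent-line model; returns the fitted estimator."""
    model = BentLineModel(
        chains=chains,
        iterations=iterations,
        warmup=warmup,
        seed=seed,
        priors=priors,
        **kwargs,
    )
    return model.fit(series)


def extract_person_medians(fit: BentLineModel) -> pd.DataFrame:
    """Element-wise posterior median of each person-level parameter."""
    draws = getattr(fit, "draws_", None)
    if draws is None or draws["person"].size == 0:
        raise ValueError("no retained draws to summarize")
    pm = np.median(draws["person"], axis=(0, 1))
    return pd.DataFrame(
        pm,
        columns=list(PARAM_NAMES),
        index=pd.Index(fit.participants_, name="participant_id"),
    )


def classify_cp_position(person_medians: pd.DataFrame, series) -> tuple[pd.Series, dict]:
    """Locate each posterior-median CP relative to the observation window.

    Returns (per-participant category Series, cohort proportion dict) with
    categories ``before_first_visit`` / ``observed`` / ``after_last_visit``;
    "observed" means first visit age <= tau <= last visit age.
    """
    slist = _as_series_list(series)
    windows = {s.participant_id: (s.ages[0], s.ages[-1]) for s in slist}
    cats = {}
    for pid, row in person_medians.iterrows():
        if pid not in windows:
            raise KeyError(f"participant {pid!r} missing from series")
        first, last = windows[pid]
        tau = row["tau"]
        if tau < first:
            cats[pid] = "before_first_visit"
        elif tau > last:
            cats[pid] = "after_last_visit"
        else:
            cats[pid] = "observed"
    out = pd.Series(cats, name="cp_position")
    n = len(out)
    props = {
        c: float((out == c).sum()) / n
        for c in ("before_first_visit", "observed", "after_last_visit")
    }
    return out, props


def convergence_report(fit: BentLineModel, rhat_threshold: float = 1.05) -> dict:
    """Pass/fail convergence summary from stored chain diagnostics."""
    draws = fit.draws_["fixed"]
    if draws.shape[0] < 2:
        return {"assessable": False, "reason": "R-hat undefined with one chain"}
    diag = fit.diagnostics_
    per_param = fit.fixed_effects_[["rhat", "ess_bulk"]].copy()
    per_param["pass"] = per_param["rhat"] <= rhat_threshold
    degenerate = bool(per_param["rhat"].isna().any())
    max_rhat = diag["max_rhat"]
    return {
        "assessable": True,
        "pass": bool(not degenerate and max_rhat <= rhat_threshold),
        "max_rhat": max_rhat,
        "min_ess": diag["min_ess_fixed"],
        "degenerate": degenerate,
        "threshold": rhat_threshold,
        "per_parameter": per_param,
    }
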