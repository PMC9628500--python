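"""Hierarchical robust regression, estimated marginal means and contrasts.

For each trial measure the model is a Bayesian hierarchical robust
regression

    y_itc = mu + beta_W * walk_i + beta_c + gamma_c * walk_i
            + u_i + w_{s(i)} + eps_itc,
    eps_itc ~ StudentT(nu, 0, sigma_{g(i)}),

with fixed effects for group (walking vs standing, reference standing),
condition (Gr, IC, IU, OC, OU, reference Gr) and their interaction, random
intercepts for participant (u) and counterbalance schedule (w), a
heavy-tailed Student likelihood against outliers, and a separate residual
scale per group (heterogeneous variances).  Priors are weakly informative:
Normal(0, 2.5 * sd(y)) on locations, half-Student-t(3, sd(y)) on scales and
a Gamma(2, 0.1) prior on the degrees of freedom (shifted to nu > 2).

Sampling expresses the Student likelihood as a normal scale mixture with
latent per-observation Gamma weights, which makes all location parameters
(fixed effects and random intercepts) jointly Gaussian given the weights:
each sweep draws them exactly from their full conditional, then updates
the variance components and degrees of freedom by Metropolis steps on the
log scale.  Convergence is assessed with split-Rhat and effective sample
size (arviz).  The two-group summary model uses an affine-invariant
ensemble sampler (emcee).

Estimated marginal means (EMMs) are per-draw cell means of group x
condition with random effects at their zero population mean; planned
pairwise contrasts are per-draw EMM differences summarized by median, SD,
equal-tailed 95% CI, the posterior probability PP of the first-minus-second
> 0 direction, and evidence ratios ER01 = PP/(1-PP), ER10 = (1-PP)/PP
(reported as "Inf" when no draw opposes the direction).  Table flags follow
the reporting convention bold: PP > 0.85 or < 0.15, star: PP > 0.95 or
< 0.05 (two-sided).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

import emcee

with warnings.catch_warnings():
    warnings.simplefilter("ignore", FutureWarning)
    import arviz as az

from .design import CONDITIONS

GROUP_REF = "standing"
COND_REF = "Gr"


@dataclass(frozen=True)
class ModelSpec:
    """Likelihood, priors and sampler settings."""

    likelihood: str = "student"          # "student" or "normal"
    group_scales: bool = True            # separate residual scale per group
    chains: int = 4
    iterations: int = 4000               # ensemble steps per chain
    warmup: int = 2000
    prior_scale_mult: float = 2.5        # location prior: N(0, mult * sd_y)
    scale_prior_df: float = 3.0          # half-t prior on scales
    nu_prior: tuple[float, float] = (2.0, 0.1)   # Gamma(shape, rate) on nu
    rhat_threshold: float = 1.01
    max_draws_per_chain: int = 2000
    nwalkers: int = 0                    # 0 = auto (>= 2.2 * ndim, even)

    def __post_init__(self) -> None:
        if self.chains < 1 or self.iterations < 2 or not \
                0 < self.warmup < self.iterations:
            raise ValueError("sampler settings must be positive with "
                             "warmup < iterations")
        if self.likelihood not in ("student", "normal"):
            raise ValueError(f"unknown likelihood {self.likelihood!r}")


#: scaled-down settings for simulation studies and test suites
SCALED_SPEC = ModelSpec(chains=2, iterations=1000, warmup=500)


@dataclass
class ContrastResult:
    """Posterior summary of one pairwise contrast (first minus second)."""

    label: str
    group: str
    median: float
    sd: float
    ci_low: float
    ci_high: float
    pp: float
    er01: float
    er10: float

    @property
    def bold(self) -> bool:
        return self.pp > 0.85 or self.pp < 0.15

    @property
    def star(self) -> bool:
        return self.pp > 0.95 or self.pp < 0.05


def evidence_ratios(pp: float) -> tuple[float, float]:
    """Posterior odds for and against a direction; inf at sample resolution."""
    if not 0.0 <= pp <= 1.0:
        raise ValueError("posterior probability must lie in [0, 1]")
    er01 = math.inf if pp == 1.0 else pp / (1.0 - pp)
    er10 = math.inf if pp == 0.0 else (1.0 - pp) / pp
    return er01, er10


def jeffreys_label(bf: float) -> str:
    """Evidence category of a Bayes factor (boundaries go to the lower bin).

    Bayes factors below 1 are labelled by their reciprocal's bin with the
    direction noted.
    """
    if not bf > 0:
        raise ValueError("Bayes factor must be positive")
    if bf < 1:
        return jeffreys_label(1.0 / bf) + " (reciprocal)"
    if bf <= 3:
        return "anecdotal"
    if bf <= 10:
        return "substantial"
    if bf <= 30:
        return "strong"
    if bf <= 100:
        return "very strong"
    return "decisive"


# ---------------------------------------------------------------------------
# model internals
# ---------------------------------------------------------------------------

@dataclass
class _ModelData:
    y: np.ndarray
    X: np.ndarray                  # (n_obs, n_fix)
    fix_names: list[str]
    part_idx: np.ndarray
    sched_idx: np.ndarray
    group_idx: np.ndarray          # 0 = standing, 1 = walking (residual scale)
    n_part: int
    n_sched: int
    n_groups: int
    sd_y: float
    mean_y: float
    conditions: list[str]
    groups: list[str]


def _build_design(table: pd.DataFrame, value_col: str = "value") -> _ModelData:
    req = {"participant", "group", "condition", "schedule", value_col}
    missing = req - set(table.columns)
    if missing:
        raise ValueError(f"trial table missing columns {sorted(missing)}")
    df = table.dropna(subset=[value_col]).reset_index(drop=True)
    if not np.isfinite(df[value_col]).all():
        raise ValueError("trial table contains non-finite values")
    groups = sorted(df["group"].unique(), key=lambda g: g != GROUP_REF)
    conds = [c for c in CONDITIONS if c in set(df["condition"])]
    if len(conds) < 2:
        raise ValueError("degenerate design: need at least 2 conditions")
    if len(groups) < 2:
        raise ValueError("degenerate design: need at least 2 groups")
    for g in groups:
        if df.loc[df.group == g, "participant"].nunique() < 2:
            raise ValueError(f"degenerate design: <2 participants in group {g}")

    walk = (df["group"] != GROUP_REF).to_numpy(float)
    cols = [np.ones(len(df)), walk]
    names = ["intercept", "group_walking"]
    for c in conds:
        if c == COND_REF:
            continue
        ind = (df["condition"] == c).to_numpy(float)
        cols.append(ind)
        names.append(f"cond_{c}")
        cols.append(ind * walk)
        names.append(f"walk:cond_{c}")
    X = np.column_stack(cols)

    parts = {p: i for i, p in enumerate(pd.unique(df["participant"]))}
    scheds = {s: i for i, s in enumerate(pd.unique(df["schedule"]))}
    y = df[value_col].to_numpy(float)
    return _ModelData(
        y=y, X=X, fix_names=names,
        part_idx=df["participant"].map(parts).to_numpy(),
        sched_idx=df["schedule"].map(scheds).to_numpy(),
        group_idx=walk.astype(int),
        n_part=len(parts), n_sched=len(scheds), n_groups=2,
        sd_y=float(y.std()) or 1.0, mean_y=float(y.mean()),
        conditions=conds, groups=groups)


def _half_t_logpdf(sigma: float, scale: float, df: float) -> float:
    return -(df + 1) / 2 * math.log1p((sigma / scale) ** 2 / df)


def _gibbs_chain(data: _ModelData, spec: ModelSpec, seed: int) -> dict:
    """One MCMC chain for the hierarchical robust model.

    The Student likelihood is expressed as a normal scale mixture with
    latent per-observation Gamma weights, so all location parameters
    (fixed effects + random intercepts) are drawn jointly and exactly from
    their multivariate-normal full conditional; the variance components and
    the degrees of freedom are updated by random-walk Metropolis steps on
    the log scale.
    """
    rng = np.random.default_rng(seed)
    y = data.y
    n = y.size
    p = data.X.shape[1]
    # combined design [X | Z_participant | Z_schedule]
    C = np.zeros((n, p + data.n_part + data.n_sched))
    C[:, :p] = data.X
    C[np.arange(n), p + data.part_idx] = 1.0
    C[np.arange(n), p + data.n_part + data.sched_idx] = 1.0
    q = C.shape[1]

    # prior on locations: N(prior_mean, prior_sd^2); random-effect slots get
    # their precision from the current sd_u / sd_w each sweep
    loc_scale = spec.prior_scale_mult * data.sd_y
    prior_mean = np.zeros(q)
    prior_mean[0] = data.mean_y
    fixed_prec = np.zeros(q)
    fixed_prec[:p] = 1.0 / loc_scale ** 2

    # state
    beta_uw, *_ = np.linalg.lstsq(C, y, rcond=None)
    resid = y - C @ beta_uw
    sigma = np.full(2, max(float(resid.std()), 1e-3 * data.sd_y))
    sd_u = max(0.5 * float(resid.std()), 1e-3 * data.sd_y)
    sd_w = 0.2 * data.sd_y
    nu = 10.0
    lam = np.ones(n)
    student = spec.likelihood == "student"
    gidx = data.group_idx if spec.group_scales else np.zeros(n, dtype=int)
    n_scales = 2 if spec.group_scales else 1

    keep = spec.iterations - spec.warmup
    out = {"beta": np.empty((keep, p)), "u": np.empty((keep, data.n_part)),
           "w": np.empty((keep, data.n_sched)), "sd_u": np.empty(keep),
           "sd_w": np.empty(keep), "sigma": np.empty((keep, 2)),
           "nu": np.empty(keep)}
    df_p = spec.scale_prior_df
    a_nu, b_nu = spec.nu_prior
    # RW-MH step sizes, adapted toward ~44% acceptance during warmup
    step_s, step_nu = 0.15, 0.3
    MH_TRIES = 3

    for it in range(spec.iterations):
        sig_obs = sigma[gidx]
        # --- latent Student weights ---------------------------------
        if student:
            z2 = (resid / sig_obs) ** 2
            lam = rng.gamma((nu + 1) / 2, 2.0 / (nu + z2))
            lam = np.clip(lam, 1e-10, None)
        # --- joint draw of beta, u, w -------------------------------
        wgt = lam / sig_obs ** 2
        Cw = C * wgt[:, None]
        A = C.T @ Cw
        prec = fixed_prec.copy()
        prec[p:p + data.n_part] = 1.0 / sd_u ** 2
        prec[p + data.n_part:] = 1.0 / sd_w ** 2
        A[np.diag_indices(q)] += prec
        b = Cw.T @ y + prec * prior_mean
        L = np.linalg.cholesky(A)
        mean = np.linalg.solve(A, b)
        theta = mean + np.linalg.solve(L.T, rng.standard_normal(q))
        resid = y - C @ theta
        # --- residual scales: collapsed RW Metropolis on log sigma,
        # with the latent weights integrated out (marginal likelihood is
        # Student for the robust model, normal otherwise); the weights are
        # redrawn from their full conditional at the top of the next sweep.
        acc_s = 0
        n_mh = 0

        def marg_loglik(r: np.ndarray, s_val: float) -> float:
            z2 = (r / s_val) ** 2
            if student:
                return float(r.size * (gammaln((nu + 1) / 2)
                                       - gammaln(nu / 2)
                                       - 0.5 * math.log(nu * math.pi)
                                       - math.log(s_val))
                             - (nu + 1) / 2 * np.log1p(z2 / nu).sum())
            return float(-r.size * (0.5 * math.log(2 * math.pi)
                                    + math.log(s_val)) - 0.5 * z2.sum())

        for g in range(n_scales):
            m = gidx == g
            if not m.any():
                continue
            r_g = resid[m]

            def logp_sig(s_val: float) -> float:
                return (marg_loglik(r_g, s_val)
                        + _half_t_logpdf(s_val, data.sd_y, df_p)
                        + math.log(s_val))
            for _ in range(MH_TRIES):
                cur = sigma[g]
                prop = cur * math.exp(step_s * rng.standard_normal())
                n_mh += 1
                if math.log(rng.random()) < logp_sig(prop) - logp_sig(cur):
                    sigma[g] = prop
                    acc_s += 1
        if not spec.group_scales:
            sigma[1] = sigma[0]
        # --- random-effect scales -----------------------------------
        for name in ("u", "w"):
            vals = theta[p:p + data.n_part] if name == "u" \
                else theta[p + data.n_part:]
            cur = sd_u if name == "u" else sd_w
            ss_v = float((vals ** 2).sum())
            k = vals.size

            def logp_sd(s_val: float) -> float:
                return (-k * math.log(s_val) - 0.5 * ss_v / s_val ** 2
                        + _half_t_logpdf(s_val, data.sd_y, df_p)
                        + math.log(s_val))
            for _ in range(MH_TRIES):
                prop = cur * math.exp(step_s * rng.standard_normal())
                n_mh += 1
                if math.log(rng.random()) < logp_sd(prop) - logp_sd(cur):
                    cur = prop
                    acc_s += 1
            if name == "u":
                sd_u = cur
            else:
                sd_w = cur
        # --- degrees of freedom: collapsed MH on log(nu - 2) --------
        if student:
            z2_all = (resid / sigma[gidx]) ** 2

            def logp_nu(nu_val: float) -> float:
                return (n * (gammaln((nu_val + 1) / 2) - gammaln(nu_val / 2)
                             - 0.5 * math.log(nu_val * math.pi))
                        - (nu_val + 1) / 2 * np.log1p(z2_all / nu_val).sum()
                        + a_nu * math.log(nu_val - 2) - b_nu * (nu_val - 2)
                        + math.log(nu_val - 2))
            acc_nu = 0
            for _ in range(MH_TRIES * 2):
                prop = 2.0 + (nu - 2.0) * math.exp(
                    step_nu * rng.standard_normal())
                if math.log(rng.random()) < logp_nu(prop) - logp_nu(nu):
                    nu = prop
                    acc_nu += 1
            if it < spec.warmup:
                rate_nu = acc_nu / (MH_TRIES * 2)
                step_nu = float(np.clip(
                    step_nu * math.exp(0.05 * (rate_nu - 0.44)), 0.02, 2.0))
        if it < spec.warmup and n_mh:
            rate_s = acc_s / n_mh
            step_s = float(np.clip(
                step_s * math.exp(0.05 * (rate_s - 0.44)), 0.02, 2.0))
        if it >= spec.warmup:
            j = it - spec.warmup
            out["beta"][j] = theta[:p]
            out["u"][j] = theta[p:p + data.n_part]
            out["w"][j] = theta[p + data.n_part:]
            out["sd_u"][j] = sd_u
            out["sd_w"][j] = sd_w
            out["sigma"][j] = sigma
            out["nu"][j] = nu
    if keep > spec.max_draws_per_chain:
        idx = np.linspace(0, keep - 1, spec.max_draws_per_chain).astype(int)
        out = {k: v[idx] for k, v in out.items()}
    return out


@dataclass
class Posterior:
    """Posterior draws (chain, draw, ...) plus metadata and diagnostics."""

    draws: dict
    data: _ModelData
    spec: ModelSpec
    diagnostics: dict = field(default_factory=dict)

    def flat(self, name: str) -> np.ndarray:
        d = self.draws[name]
        return d.reshape(-1, *d.shape[2:])

    def coef_draws(self, name: str) -> np.ndarray:
        if name not in self.data.fix_names:
            raise KeyError(f"unknown coefficient {name!r}; "
                           f"available: {self.data.fix_names}")
        return self.flat("beta")[:, self.data.fix_names.index(name)]

    # ---- estimated marginal means -------------------------------------

    def emmeans(self) -> dict:
        """Per-cell (group, condition) marginal-mean draws, random effects
        at their zero population mean."""
        beta = self.flat("beta")
        names = self.data.fix_names
        out: dict[tuple[str, str], np.ndarray] = {}
        for g in self.data.groups:
            walk = 0.0 if g == GROUP_REF else 1.0
            for c in self.data.conditions:
                x = np.zeros(len(names))
                x[names.index("intercept")] = 1.0
                x[names.index("group_walking")] = walk
                if c != COND_REF:
                    x[names.index(f"cond_{c}")] = 1.0
                    x[names.index(f"walk:cond_{c}")] = walk
                out[(g, c)] = beta @ x
        return out

    def contrast(self, pair: tuple[str, str], group: str) -> ContrastResult:
        """Pairwise EMM contrast ``pair[0] - pair[1]`` within ``group``."""
        emm = self.emmeans()
        for c in pair:
            if (group, c) not in emm:
                raise KeyError(f"no cell ({group}, {c}) in the fitted design")
        d = emm[(group, pair[0])] - emm[(group, pair[1])]
        return summarize_contrast(d, f"{pair[0]}–{pair[1]}", group)

    def directional_test(self, coefficient: str, direction: str = ">",
                         ) -> dict:
        """One-sided posterior test of a named coefficient's sign.

        Output columns match directional-hypothesis reporting: estimate,
        estimation error, one-sided 95% CI, evidence ratio, posterior
        probability, star flag.
        """
        d = self.coef_draws(coefficient)
        if direction not in (">", "<"):
            raise ValueError("direction must be '>' or '<'")
        pp = float((d > 0).mean()) if direction == ">" else float((d < 0).mean())
        er, _ = evidence_ratios(pp)
        lo, hi = np.percentile(d, [2.5, 97.5])
        return {"coefficient": coefficient, "direction": direction,
                "estimate": float(np.median(d)), "est_error": float(d.std()),
                "ci_low": float(lo), "ci_high": float(hi),
                "evidence_ratio": er, "post_prob": pp, "star": pp > 0.95}


def summarize_contrast(draws: np.ndarray, label: str, group: str,
                       ) -> ContrastResult:
    lo, hi = np.percentile(draws, [2.5, 97.5])
    pp = float((draws > 0).mean())
    er01, er10 = evidence_ratios(pp)
    return ContrastResult(label=label, group=group,
                          median=float(np.median(draws)),
                          sd=float(draws.std()),
                          ci_low=float(lo), ci_high=float(hi),
                          pp=pp, er01=er01, er10=er10)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_hierarchical(table: pd.DataFrame, spec: ModelSpec | None = None,
                     seed: int = 0, value_col: str = "value") -> Posterior:
    """Fit the hierarchical robust model to a tidy trial-measure table.

    ``table`` needs columns participant, group, condition, schedule and the
    value column.  The same (table, spec, seed) yields identical draws.
    Emits a ``RuntimeWarning`` if any monitored split-Rhat reaches the
    convergence threshold.
    """
    spec = spec or ModelSpec()
    data = _build_design(table, value_col)
    ss = np.random.SeedSequence(seed)
    chain_seeds = [int(s.generate_state(1)[0] % (2 ** 31 - 1))
                   for s in ss.spawn(spec.chains)]
    chains = [_gibbs_chain(data, spec, cs) for cs in chain_seeds]
    draws = {k: np.stack([c[k] for c in chains]) for k in chains[0]}
    diag = _diagnostics(draws, data, spec)
    if diag["max_rhat"] >= spec.rhat_threshold:
        warnings.warn(
            f"convergence: max Rhat {diag['max_rhat']:.3f} >= "
            f"{spec.rhat_threshold}", RuntimeWarning)
    return Posterior(draws=draws, data=data, spec=spec, diagnostics=diag)


def _diagnostics(draws: dict, data: _ModelData, spec: ModelSpec) -> dict:
    monitored = {
        **{f"beta_{n}": draws["beta"][:, :, i]
           for i, n in enumerate(data.fix_names)},
        "sd_u": draws["sd_u"], "sigma_standing": draws["sigma"][:, :, 0],
        "sigma_walking": draws["sigma"][:, :, -1], "nu": draws["nu"],
    }
    idata = az.from_dict(posterior={k: v for k, v in monitored.items()})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = az.rhat(idata)
        ess = az.ess(idata)
    rhats = {k: float(rhat[k].values) for k in monitored}
    esss = {k: float(ess[k].values) for k in monitored}
    return {"rhat": rhats, "ess": esss,
            "max_rhat": max(rhats.values()), "min_ess": min(esss.values())}


# ---------------------------------------------------------------------------
# group-level directional tests (per-participant scalars)
# ---------------------------------------------------------------------------

@dataclass
class GroupPosterior:
    """Posterior of the two-group robust location model."""

    beta_draws: np.ndarray        # draws of the walking-minus-standing effect
    mu_draws: np.ndarray
    diagnostics: dict

    def directional_test(self, direction: str = ">") -> dict:
        d = self.beta_draws
        if direction not in (">", "<"):
            raise ValueError("direction must be '>' or '<'")
        pp = float((d > 0).mean()) if direction == ">" else float((d < 0).mean())
        er, _ = evidence_ratios(pp)
        lo, hi = np.percentile(d, [2.5, 97.5])
        return {"coefficient": "group_walking", "direction": direction,
                "estimate": float(np.median(d)), "est_error": float(d.std()),
                "ci_low": float(lo), "ci_high": float(hi),
                "evidence_ratio": er, "post_prob": pp, "star": pp > 0.95}


def fit_group_model(values: np.ndarray, groups: np.ndarray,
                    spec: ModelSpec | None = None, seed: int = 0,
                    ) -> GroupPosterior:
    """Robust two-group location model for per-participant scalars.

    Same likelihood family as the hierarchical model (Student likelihood,
    separate residual scale per group) without random effects; used for the
    directional hypothesis tests of the walking-vs-standing effect on
    summary measures (SNR difference, SCL, ISCR, nSCR, presence).
    Parameters: location, group effect, two log-scales, log(nu - 2).
    """
    spec = spec or SCALED_SPEC
    y = np.asarray(values, float)
    g = np.asarray(groups)
    if y.size != g.size or y.size < 4:
        raise ValueError("need matching values/groups with >= 4 observations")
    walk = (g != GROUP_REF).astype(int)
    if walk.min() == walk.max():
        raise ValueError("degenerate design: only one group present")
    sd_y = float(y.std()) or 1.0
    mean_y = float(y.mean())

    def logp(theta: np.ndarray) -> np.ndarray:
        mu, beta = theta[:, 0], theta[:, 1]
        ls = theta[:, 2:4]
        nu = 2.0 + np.exp(theta[:, 4])
        pred = mu[:, None] + beta[:, None] * walk[None, :]
        ls_obs = ls[:, walk]
        z2 = ((y[None, :] - pred) * np.exp(-ls_obs)) ** 2
        if spec.likelihood == "student":
            lp = (y.size * (gammaln((nu + 1) / 2) - gammaln(nu / 2)
                            - 0.5 * np.log(nu * np.pi))
                  - ls_obs.sum(axis=1)
                  - ((nu[:, None] + 1) / 2
                     * np.log1p(z2 / nu[:, None])).sum(axis=1))
        else:
            lp = (-0.5 * y.size * np.log(2 * np.pi) - ls_obs.sum(axis=1)
                  - 0.5 * z2.sum(axis=1))
        loc = spec.prior_scale_mult * sd_y
        lp += -0.5 * ((mu - mean_y) ** 2 + beta ** 2) / loc ** 2
        dfp = spec.scale_prior_df
        for log_s in ls.T:
            sv = np.exp(log_s)
            lp += -(dfp + 1) / 2 * np.log1p((sv / sd_y) ** 2 / dfp) + log_s
        a, b = spec.nu_prior
        num2 = nu - 2.0
        lp += a * np.log(num2) - b * num2
        lp[~np.isfinite(lp)] = -np.inf
        return lp

    ndim, nwalkers = 5, 32
    ss = np.random.SeedSequence(seed)
    chains = []
    for sub in ss.spawn(spec.chains):
        rng = np.random.RandomState(int(sub.generate_state(1)[0] % (2 ** 31 - 1)))
        x0 = np.array([mean_y, 0.0, np.log(sd_y), np.log(sd_y), np.log(10.0)])
        p0 = x0[None, :] + 0.05 * np.array([sd_y, sd_y, 1, 1, 1])[None, :] \
            * rng.standard_normal((nwalkers, ndim))
        sampler = emcee.EnsembleSampler(nwalkers, ndim, logp, vectorize=True)
        sampler.random_state = rng.get_state()
        sampler.run_mcmc(p0, spec.iterations, progress=False,
                         skip_initial_state_check=True)
        chains.append(sampler.get_chain(discard=spec.warmup).reshape(-1, ndim))
    theta = np.stack(chains)
    idata = az.from_dict(posterior={"mu": theta[:, :, 0],
                                    "beta": theta[:, :, 1]})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = az.rhat(idata)
    diag = {"rhat": {k: float(rhat[k].values) for k in ("mu", "beta")}}
    return GroupPosterior(beta_draws=theta[:, :, 1].ravel(),
                          mu_draws=theta[:, :, 0].ravel(), diagnostics=diag)


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

#: the eight planned pairwise environment contrasts of the report tables
PLANNED_CONTRASTS = (
    ("Gr", "IC"), ("Gr", "IU"), ("Gr", "OC"), ("Gr", "OU"),
    ("OC", "OU"), ("IC", "IU"), ("OC", "IC"), ("OU", "IU"),
)


def planned_contrasts(post: Posterior) -> list[ContrastResult]:
    out = []
    for pair in PLANNED_CONTRASTS:
        if not set(pair) <= set(post.data.conditions):
            continue
        for g in post.data.groups:
            out.append(post.contrast(pair, g))
    return out


def _fmt_er(x: float) -> str:
    return "Inf" if math.isinf(x) else f"{x:.3f}"


def render_table(results: list[ContrastResult], markdown: bool = False,
                 ) -> pd.DataFrame | str:
    """Contrast table with the report column set and bold/star flags."""
    cols = ["Contrast", "Group", "Median", "SD", "95% CI", "PP",
            "ER01", "ER10", "Star"]
    rows = []
    for r in results:
        rows.append({
            "Contrast": r.label, "Group": r.group,
            "Median": round(r.median, 3), "SD": round(r.sd, 3),
            "95% CI": f"[{r.ci_low:.3f}, {r.ci_high:.3f}]",
            "PP": round(r.pp, 3), "ER01": _fmt_er(r.er01),
            "ER10": _fmt_er(r.er10), "Star": "*" if r.star else "",
        })
    df = pd.DataFrame(rows, columns=cols)
    if not markdown:
        return df
    lines = ["| " + " | ".join(cols) + " |",
             "|" + "|".join("---" for _ in cols) + "|"]
    for r, row in zip(results, df.to_dict("records")):
        cells = [str(row[c]) for c in cols]
        if r.bold:
            cells = [f"**{c}**" if c else c for c in cells]
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines)
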