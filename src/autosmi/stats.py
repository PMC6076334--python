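"""Maximum-likelihood statistics for single-molecule trajectories.

Implements the full estimation layer of the toolkit:

* per-molecule diffusion coefficients from 66-ms step displacements,
  ``D = dr^2 / (4 T)``;
* pooled mean square displacement curves, MSD(n*dt), averaged over tracks
  and overlapping start frames;
* confined-diffusion MLE of ``MSD(t) = (C^2/3)(1 - exp(-12 D t / C^2))``
  against per-cell MSD curves, under both a normal and a log-normal
  cell-to-cell error model with per-lag nuisance scales sigma_j (the
  log-normal density carries the -sigma^2/2 mean correction so its mean
  equals the model curve); the model with the larger log-likelihood is
  adopted;
* mixtures of diffusion states: the displacement density
  ``P(r) = sum_n C_n r / (2 D_n dt) exp(-r^2 / (4 D_n dt))`` fitted by EM,
  with the state count N = 1..4 chosen by the Akaike information criterion
  ``AIC = -2 logL + 2k`` (k = 2N - 1 free parameters);
* oligomer-size mixtures: first-frame spot intensities modeled as a
  mixture of Gaussians with mean ``n*mu`` and variance ``n*sigma^2`` for
  n = 1..10, mu and sigma shared across conditions;
* pharmacology: Hill dose-response ``MSD([L])`` giving (EC50, h) and the
  noncompetitive-inhibition surface ``MSD([L],[I])`` giving (EC50, IC50),
  both by MLE with per-condition normal or log-normal scales;
* residence times and 40-s time-course binning of every estimator.

Trajectories are passed as ``(T, 2)`` position arrays in micrometres;
conversion from pixels happens at this boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "MSDCurve", "ConfinedFit", "StateModel", "ClusterModel",
    "DoseFit", "InhibitionFit",
    "confined_msd", "hill_msd", "inhibition_msd",
    "step_diffusion", "msd", "step_displacements",
    "fit_confined", "fit_state_mixture", "select_states",
    "fit_cluster_sizes", "fit_dose_response", "fit_inhibition",
    "residence_time", "cell_success", "timecourse", "compare_conditions",
]

DEFAULT_DT = 0.033  # s, frame interval


# ---------------------------------------------------------------------------
# Model curves

def confined_msd(t, d, c):
    """Confined-diffusion MSD: plateau C^2/3, initial slope 4D."""
    t = np.asarray(t, dtype=float)
    return (c ** 2 / 3.0) * (1.0 - np.exp(-12.0 * d * t / c ** 2))


def hill_msd(lig, msd_max, msd_min, ec50, h):
    """Hill dose-response; [L] = 0 maps to the upper boundary MSD_max."""
    lig = np.asarray(lig, dtype=float)
    out = np.full(lig.shape, float(msd_max))
    pos = lig > 0
    ratio = (ec50 / lig[pos]) ** h
    out[pos] = msd_max - (msd_max - msd_min) / (1.0 + ratio)
    return out if out.ndim else float(out)


def inhibition_msd(lig, inh, msd_max, msd_min, ec50, ic50):
    """Noncompetitive inhibition surface; [L] = 0 maps to MSD_max."""
    lig = np.asarray(lig, dtype=float)
    inh = np.broadcast_to(np.asarray(inh, dtype=float), lig.shape)
    out = np.full(lig.shape, float(msd_max))
    pos = lig > 0
    denom = (1.0 + ec50 / lig[pos]) * (1.0 + inh[pos] / ic50)
    out[pos] = msd_max - (msd_max - msd_min) / denom
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Displacements / MSD

def step_displacements(trajectories, lag: int = 2) -> np.ndarray:
    """Pooled displacements r (um) over ``lag`` frames, overlapping windows."""
    out = []
    for pos in trajectories:
        pos = np.asarray(pos, dtype=float)
        if len(pos) <= lag:
            continue
        d = pos[lag:] - pos[:-lag]
        out.append(np.hypot(d[:, 0], d[:, 1]))
    return np.concatenate(out) if out else np.empty(0)


def step_diffusion(trajectories, dt: float = DEFAULT_DT, T: float = 0.066):
    """Per-molecule diffusion coefficients D = dr^2 / (4 T).

    The squared displacement over ``T`` (two frames by default) is averaged
    over overlapping windows within each track; tracks too short to supply
    one displacement are excluded.  Returns an array of per-molecule D
    values (um^2/s).
    """
    lag = int(round(T / dt))
    ds = []
    for pos in trajectories:
        pos = np.asarray(pos, dtype=float)
        if len(pos) <= lag:
            continue
        d = pos[lag:] - pos[:-lag]
        ds.append(np.mean(d[:, 0] ** 2 + d[:, 1] ** 2) / (4.0 * T))
    return np.asarray(ds)


@dataclass
class MSDCurve:
    """Per-cell MSD(n*dt) pooled over tracks and start frames."""

    lags: np.ndarray          # seconds
    values: np.ndarray        # um^2
    n_pairs: np.ndarray       # displacements contributing per lag
    cell_id: object = None


def msd(trajectories, dt: float = DEFAULT_DT, max_lag: int = 15,
        cell_id=None) -> MSDCurve:
    """Pooled MSD over all tracks i and all start frames m (overlapping)."""
    sums = np.zeros(max_lag)
    counts = np.zeros(max_lag, dtype=int)
    for pos in trajectories:
        pos = np.asarray(pos, dtype=float)
        t = len(pos)
        for n in range(1, min(max_lag, t - 1) + 1):
            d = pos[n:] - pos[:-n]
            sums[n - 1] += np.sum(d[:, 0] ** 2 + d[:, 1] ** 2)
            counts[n - 1] += len(d)
    valid = counts > 0
    values = np.full(max_lag, np.nan)
    values[valid] = sums[valid] / counts[valid]
    lags = dt * np.arange(1, max_lag + 1)
    return MSDCurve(lags=lags, values=values, n_pairs=counts, cell_id=cell_id)


# ---------------------------------------------------------------------------
# Profiled per-group nuisance scales (shared by the curve fits)

def _norm_profile(resid_sq_mean: float, n: int, scale: float):
    """Optimal sigma and per-group max log-likelihood term, normal model.

    Given the mean squared residual of a group of n points, the profiled
    sigma^2 equals that mean and the group's contribution to -logL is
    n*log(sigma) + n/2 (plus the global (n/2) log 2pi term added by the
    caller).  sigma is floored at a tiny fraction of the data scale so an
    exact fit through a single group cannot send the likelihood to
    infinity (degenerate-variance guard).
    """
    floor = (1e-8 * scale) ** 2
    sigma = np.sqrt(max(resid_sq_mean, floor))
    return sigma, n * np.log(sigma) + 0.5 * n


def _lognorm_profile(a: np.ndarray):
    """Optimal sigma for the mean-corrected log-normal group likelihood.

    a_i = log d_i - log M.  The group's -logL contribution (excluding the
    (n/2) log 2pi and the sum of log d_i, added by the caller) is minimized
    at sigma^2 = 2 (sqrt(1 + mean(a^2)) - 1), a root of the quadratic
    obtained from d/d(sigma^2) = 0.  sigma^2 is floored against the same
    degenerate-variance collapse as the normal profile.
    """
    n = len(a)
    s_bar = float(np.mean(a ** 2))
    u = 2.0 * (np.sqrt(1.0 + s_bar) - 1.0)
    u = max(u, 1e-16)
    sigma = np.sqrt(u)
    cost = (n / 2.0) * np.log(u) + np.sum((a + u / 2.0) ** 2) / (2.0 * u)
    return sigma, cost


def _grouped_loglik(d_groups, model_values, error_model: str):
    """Max log-likelihood over the nuisance scales, one scale per group.

    d_groups : list of 1-D arrays of per-cell observations.
    model_values : model prediction per group.
    Returns (logL, sigmas).
    """
    total = 0.0
    sigmas = []
    n_total = sum(len(g) for g in d_groups)
    scale = max(float(np.mean([np.mean(np.abs(g)) for g in d_groups])), 1e-300)
    for d, m in zip(d_groups, model_values):
        d = np.asarray(d, dtype=float)
        n = len(d)
        if error_model == "normal":
            sigma, cost = _norm_profile(float(np.mean((d - m) ** 2)), n, scale)
        elif error_model == "lognormal":
            if m <= 0 or np.any(d <= 0):
                return -np.inf, []
            a = np.log(d) - np.log(m)
            sigma, cost = _lognorm_profile(a)
            cost += float(np.sum(np.log(d)))
        else:
            raise ValueError(error_model)
        total -= cost
        sigmas.append(sigma)
    total -= 0.5 * n_total * np.log(2.0 * np.pi)
    return total, np.asarray(sigmas)


def _multistart_minimize(neg, x0_list, rng, n_random: int = 5, scale: float = 0.3):
    """Nelder-Mead from each start plus seeded random jitters; best wins."""
    starts = [np.asarray(x0, dtype=float) for x0 in x0_list]
    base = starts[0]
    for _ in range(n_random):
        starts.append(base + rng.normal(0.0, scale, size=base.shape))
    best = None
    for x0 in starts:
        res = minimize(neg, x0, method="Nelder-Mead",
                       options={"xatol": 1e-9, "fatol": 1e-10, "maxiter": 4000})
        if best is None or res.fun < best.fun:
            best = res
    return best


# ---------------------------------------------------------------------------
# Confined-diffusion fit

@dataclass
class ConfinedFit:
    d: float                 # um^2/s
    c: float                 # confinement side, um
    sigmas: np.ndarray       # per-lag nuisance scales of the adopted model
    logl_norm: float
    logl_log: float
    error_model: str         # adopted model ("normal" or "lognormal")
    params_norm: tuple = ()
    params_log: tuple = ()
    converged: bool = True


def fit_confined(per_cell_msd: np.ndarray, lags=None, seed: int = 0) -> ConfinedFit:
    """MLE of (D, C) from per-cell MSD curves.

    per_cell_msd : (N_cell, J) array, one row per cell, lags j = 1..J
        (default J = 15 at dt = 33 ms, i.e. times j/30 s).
    Both error models are maximized (per-lag sigma_j profiled in closed
    form); the model with the larger log-likelihood is adopted.
    """
    d_mat = np.asarray(per_cell_msd, dtype=float)
    if d_mat.ndim != 2 or d_mat.shape[0] < 2:
        raise ValueError("need a (N_cell >= 2, J) array of per-cell MSD values")
    n_cell, n_lag = d_mat.shape
    if lags is None:
        lags = DEFAULT_DT * np.arange(1, n_lag + 1)
    lags = np.asarray(lags, dtype=float)
    groups = [d_mat[:, j] for j in range(n_lag)]

    # moment starts: slope of the first lags gives D, the largest value the plateau
    mean_curve = np.nanmean(d_mat, axis=0)
    d0 = max(mean_curve[0] / (4.0 * lags[0]), 1e-6)
    c0 = max(np.sqrt(3.0 * np.nanmax(mean_curve)), 1e-4)
    rng = np.random.default_rng(seed)

    from scipy.optimize import least_squares

    def ls_resid(x):
        return confined_msd(lags, *np.exp(x)) - mean_curve

    try:
        ls = least_squares(ls_resid, [np.log(d0), np.log(c0)], max_nfev=2000)
        starts = [ls.x, [np.log(d0), np.log(c0)]]
    except Exception:
        starts = [[np.log(d0), np.log(c0)]]

    results = {}
    for model in ("normal", "lognormal"):
        def neg(x, model=model):
            d, c = np.exp(x)
            m = confined_msd(lags, d, c)
            ll, _ = _grouped_loglik(groups, m, model)
            return -ll

        best = _multistart_minimize(neg, starts, rng)
        d_hat, c_hat = np.exp(best.x)
        ll, sig = _grouped_loglik(groups, confined_msd(lags, d_hat, c_hat), model)
        results[model] = (d_hat, c_hat, ll, sig, best.success)

    adopted = "lognormal" if results["lognormal"][2] >= results["normal"][2] else "normal"
    d_hat, c_hat, _, sig, ok = results[adopted]
    return ConfinedFit(d=float(d_hat), c=float(c_hat), sigmas=sig,
                       logl_norm=float(results["normal"][2]),
                       logl_log=float(results["lognormal"][2]),
                       error_model=adopted,
                       params_norm=results["normal"][:2],
                       params_log=results["lognormal"][:2],
                       converged=bool(ok))


# ---------------------------------------------------------------------------
# Diffusion-state mixtures

@dataclass
class StateModel:
    n_states: int
    fractions: np.ndarray     # C_n, sum to 1, sorted by ascending D
    d_values: np.ndarray      # um^2/s, ascending
    logl: float
    aic: float
    k: int
    n_mol: int


def _mixture_logpdf(r2: np.ndarray, fractions, d_values, dt: float):
    lam = 1.0 / (4.0 * np.asarray(d_values) * dt)        # rate in r^2
    # p(r) = sum C_n * 2 lam r exp(-lam r^2); work with log-sum-exp
    log_comp = (np.log(np.asarray(fractions))[None, :]
                + np.log(2.0 * lam)[None, :]
                + 0.5 * np.log(r2)[:, None]
                - lam[None, :] * r2[:, None])
    mx = log_comp.max(axis=1, keepdims=True)
    return mx[:, 0] + np.log(np.exp(log_comp - mx).sum(axis=1))


def fit_state_mixture(displacements, n_states: int, dt: float = 0.066,
                      max_iter: int = 1000, tol: float = 1e-8,
                      seed: int = 0) -> StateModel:
    """EM fit of an N-state displacement mixture at time interval dt.

    In s = r^2 the model is a mixture of exponentials, so EM has closed-form
    updates: D_n = sum(gamma * r^2) / (4 dt sum(gamma)) and C_n = mean
    responsibility.  States whose D collapse together are merged with a
    warning.  AIC uses k = 2N - 1.
    """
    r = np.asarray(displacements, dtype=float)
    r = r[r > 0]
    if len(r) < n_states:
        raise ValueError("not enough displacements for the requested state count")
    if not 1 <= n_states <= 4:
        raise ValueError("n_states must be in 1..4")
    r2 = r ** 2
    mean_d = np.mean(r2) / (4.0 * dt)

    if n_states == 1:
        d_vals = np.array([mean_d])
        fracs = np.array([1.0])
    else:
        qs = np.quantile(r2, np.linspace(0.15, 0.85, n_states))
        d_vals = np.maximum(qs / (4.0 * dt), 1e-8)
        fracs = np.full(n_states, 1.0 / n_states)
        prev = -np.inf
        for _ in range(max_iter):
            lam = 1.0 / (4.0 * d_vals * dt)
            log_comp = (np.log(fracs)[None, :] + np.log(lam)[None, :]
                        - lam[None, :] * r2[:, None])
            mx = log_comp.max(axis=1, keepdims=True)
            w = np.exp(log_comp - mx)
            gamma = w / w.sum(axis=1, keepdims=True)
            nk = gamma.sum(axis=0)
            fracs = nk / len(r2)
            d_vals = np.maximum((gamma * r2[:, None]).sum(axis=0) / (4.0 * dt * nk),
                                1e-10)
            ll = float(np.sum(_mixture_logpdf(r2, fracs, d_vals, dt)))
            if abs(ll - prev) < tol * max(1.0, abs(ll)):
                break
            prev = ll

    # merge degenerate states
    order = np.argsort(d_vals)
    d_vals, fracs = d_vals[order], fracs[order]
    merged_d, merged_f = [d_vals[0]], [fracs[0]]
    for d_n, f_n in zip(d_vals[1:], fracs[1:]):
        if d_n / merged_d[-1] < 1.001:
            warnings.warn("two diffusion states converged; merged")
            merged_f[-1] += f_n
        else:
            merged_d.append(d_n)
            merged_f.append(f_n)
    d_vals = np.asarray(merged_d)
    fracs = np.asarray(merged_f)
    fracs = fracs / fracs.sum()
    n_eff = len(d_vals)

    ll = float(np.sum(_mixture_logpdf(r2, fracs, d_vals, dt)))
    k = 2 * n_eff - 1
    return StateModel(n_states=n_eff, fractions=fracs, d_values=d_vals,
                      logl=ll, aic=-2.0 * ll + 2.0 * k, k=k, n_mol=len(r2))


def select_states(displacements, dt: float = 0.066, max_states: int = 4,
                  seed: int = 0) -> StateModel:
    """Fit N = 1..max_states and return the smallest-AIC model."""
    models = [fit_state_mixture(displacements, n, dt=dt, seed=seed)
              for n in range(1, max_states + 1)]
    return min(models, key=lambda m: m.aic)


# ---------------------------------------------------------------------------
# Oligomer (cluster) size mixtures

@dataclass
class ClusterModel:
    mu: float                     # monomer mean intensity (a.u.)
    sigma: float                  # monomer intensity SD (a.u.)
    fractions: np.ndarray         # (n_conditions, N) C_n per condition
    logl: float
    n_max: int
    conditions: list = field(default_factory=list)

    @property
    def mean_sizes(self) -> np.ndarray:
        """Mean cluster size sum(n * C_n) per condition."""
        n = np.arange(1, self.n_max + 1)
        return self.fractions @ n


def fit_cluster_sizes(intensities_by_condition, n_max: int = 10,
                      max_iter: int = 2000, tol: float = 1e-10,
                      seed: int = 0) -> ClusterModel:
    """Shared-(mu, sigma) Gaussian mixture over n-mer intensities.

    ``intensities_by_condition`` is a list (or dict) of 1-D arrays of
    first-frame spot intensities, one per experimental condition.  The
    n-mer component is Normal(n*mu, n*sigma^2) for n = 1..n_max; mu and
    sigma are global across conditions, the fractions C_n are fitted per
    condition.  EM with closed-form updates.
    """
    if isinstance(intensities_by_condition, dict):
        conditions = list(intensities_by_condition)
        data = [np.asarray(intensities_by_condition[c], dtype=float)
                for c in conditions]
    else:
        data = [np.asarray(a, dtype=float) for a in intensities_by_condition]
        conditions = list(range(len(data)))
    for arr in data:
        if np.any(arr <= 0):
            raise ValueError("intensities must be > 0")
    pooled = np.concatenate(data)
    if len(pooled) < 100:
        warnings.warn("fewer than ~100 spots; cluster fractions will have wide CIs")

    ns = np.arange(1, n_max + 1)

    def run_em(mu, sigma):
        fracs = [np.full(n_max, 1.0 / n_max) for _ in data]
        prev = -np.inf
        for _ in range(max_iter):
            num_mu = den_mu = num_s2 = den_s2 = 0.0
            ll = 0.0
            gammas = []
            for idx, x in enumerate(data):
                log_comp = (np.log(np.maximum(fracs[idx], 1e-300))[None, :]
                            - 0.5 * np.log(2 * np.pi * ns)[None, :] - np.log(sigma)
                            - (x[:, None] - ns[None, :] * mu) ** 2
                            / (2.0 * ns[None, :] * sigma ** 2))
                mx = log_comp.max(axis=1, keepdims=True)
                w = np.exp(log_comp - mx)
                tot = w.sum(axis=1, keepdims=True)
                ll += float(np.sum(mx[:, 0] + np.log(tot[:, 0])))
                gamma = w / tot
                gammas.append(gamma)
                num_mu += float(np.sum(gamma * x[:, None]))
                den_mu += float(np.sum(gamma * ns[None, :]))
            mu = num_mu / den_mu
            for idx, x in enumerate(data):
                gamma = gammas[idx]
                fracs[idx] = gamma.mean(axis=0)
                num_s2 += float(np.sum(gamma * (x[:, None] - ns[None, :] * mu) ** 2
                                       / ns[None, :]))
                den_s2 += gamma.sum()
            sigma = np.sqrt(max(num_s2 / den_s2, 1e-12))
            if abs(ll - prev) < tol * max(1.0, abs(ll)):
                break
            prev = ll
        return mu, sigma, np.asarray(fracs), ll

    best = None
    for q in (30.0, 50.0):
        mu0 = float(np.percentile(pooled, q))
        fit = run_em(mu0, 0.25 * mu0)
        if best is None or fit[3] > best[3]:
            best = fit
    mu, sigma, fracs, ll = best
    fracs = fracs / fracs.sum(axis=1, keepdims=True)
    return ClusterModel(mu=float(mu), sigma=float(sigma), fractions=fracs,
                        logl=float(ll), n_max=n_max, conditions=conditions)


# ---------------------------------------------------------------------------
# Dose-response / inhibition

@dataclass
class DoseFit:
    msd_max: float
    msd_min: float
    ec50: float              # nM
    h: float
    sigmas: dict             # condition -> nuisance scale (adopted model)
    logl_norm: float
    logl_log: float
    error_model: str
    converged: bool = True


@dataclass
class InhibitionFit:
    msd_max: float
    msd_min: float
    ec50: float              # nM
    ic50: float              # nM
    sigmas: dict
    logl_norm: float
    logl_log: float
    error_model: str
    converged: bool = True


def _fit_curve_by_condition(table: pd.DataFrame, cond_cols, model_fn,
                            x0, unpack, seed: int = 0):
    """Shared machinery for the dose-response and inhibition fits."""
    conds, d_groups = [], []
    for key, sub in table.groupby(list(cond_cols))["msd"]:
        conds.append(key[0] if len(cond_cols) == 1 else key)
        d_groups.append(sub.to_numpy(dtype=float))
    cond_arr = np.asarray([c if isinstance(c, tuple) else (c,) for c in conds],
                          dtype=float)
    rng = np.random.default_rng(seed)

    # least-squares warm start on the condition means
    means = np.asarray([np.mean(g) for g in d_groups])

    def ls_resid(x):
        m = model_fn(cond_arr, *unpack(x))
        return np.where(np.isfinite(m), m - means, 1e6)

    from scipy.optimize import least_squares
    try:
        ls = least_squares(ls_resid, x0, max_nfev=2000)
        starts = [ls.x, x0]
    except Exception:
        starts = [x0]

    results = {}
    for model in ("normal", "lognormal"):
        def neg(x, model=model):
            params = unpack(x)
            m = model_fn(cond_arr, *params)
            if np.any(~np.isfinite(m)) or np.any(m <= 0):
                return np.inf
            ll, _ = _grouped_loglik(d_groups, m, model)
            return -ll

        best = _multistart_minimize(neg, starts, rng)
        params = unpack(best.x)
        ll, sig = _grouped_loglik(d_groups, model_fn(cond_arr, *params), model)
        results[model] = (params, ll, dict(zip(conds, sig)), best.success)

    adopted = "lognormal" if results["lognormal"][1] >= results["normal"][1] else "normal"
    return adopted, results


def fit_dose_response(table: pd.DataFrame, seed: int = 0) -> DoseFit:
    """MLE of (MSD_max, MSD_min, EC50, h) from per-cell MSD values.

    ``table`` needs columns ``ligand_nM`` and ``msd`` (um^2, one row per
    cell).  Per-condition sigma([L]) scales are profiled; both error models
    are fitted and the larger-log-likelihood one adopted.
    """
    if table["ligand_nM"].nunique() < 3:
        raise ValueError("need >= 3 ligand concentrations")
    means = table.groupby("ligand_nM")["msd"].mean()
    hi, lo = float(means.max()), float(means.min())
    if hi / max(lo, 1e-12) < 1.05:
        warnings.warn("dose-response data look flat; EC50 may be unidentifiable")
    pos_l = means.index[means.index > 0]
    ec0 = float(np.sqrt(pos_l.min() * pos_l.max())) if len(pos_l) else 1.0

    def model_fn(cond_arr, msd_max, msd_min, ec50, h):
        return hill_msd(cond_arr[:, 0], msd_max, msd_min, ec50, h)

    def unpack(x):
        msd_min = np.exp(x[0])
        msd_max = msd_min + np.exp(x[1])
        return msd_max, msd_min, np.exp(x[2]), np.exp(x[3])

    x0 = [np.log(max(lo, 1e-6)), np.log(max(hi - lo, 1e-6)), np.log(ec0), 0.0]
    adopted, results = _fit_curve_by_condition(table, ["ligand_nM"], model_fn,
                                               x0, unpack, seed=seed)
    (msd_max, msd_min, ec50, h), _, sig, ok = results[adopted]
    return DoseFit(msd_max=float(msd_max), msd_min=float(msd_min),
                   ec50=float(ec50), h=float(h), sigmas=sig,
                   logl_norm=float(results["normal"][1]),
                   logl_log=float(results["lognormal"][1]),
                   error_model=adopted, converged=bool(ok))


def fit_inhibition(table: pd.DataFrame, seed: int = 0) -> InhibitionFit:
    """MLE of (MSD_max, MSD_min, EC50, IC50) on a ligand x inhibitor grid.

    ``table`` needs columns ``ligand_nM``, ``inhibitor_nM`` and ``msd``.
    """
    if table["ligand_nM"].nunique() < 2 or table["inhibitor_nM"].nunique() < 2:
        raise ValueError("need >= 2 ligand and >= 2 inhibitor levels")
    means = table.groupby(["ligand_nM", "inhibitor_nM"])["msd"].mean()
    hi, lo = float(means.max()), float(means.min())
    lig = table["ligand_nM"].to_numpy()
    inh = table["inhibitor_nM"].to_numpy()
    ec0 = float(np.sqrt(lig[lig > 0].min() * lig.max()))
    ic0 = float(np.sqrt(max(inh[inh > 0].min(), 1e-3) * max(inh.max(), 1.0)))

    def model_fn(cond_arr, msd_max, msd_min, ec50, ic50):
        return inhibition_msd(cond_arr[:, 0], cond_arr[:, 1],
                              msd_max, msd_min, ec50, ic50)

    def unpack(x):
        msd_min = np.exp(x[0])
        msd_max = msd_min + np.exp(x[1])
        return msd_max, msd_min, np.exp(x[2]), np.exp(x[3])

    x0 = [np.log(max(lo, 1e-6)), np.log(max(hi - lo, 1e-6)),
          np.log(ec0), np.log(ic0)]
    adopted, results = _fit_curve_by_condition(
        table, ["ligand_nM", "inhibitor_nM"], model_fn, x0, unpack, seed=seed)
    (msd_max, msd_min, ec50, ic50), _, sig, ok = results[adopted]
    return InhibitionFit(msd_max=float(msd_max), msd_min=float(msd_min),
                         ec50=float(ec50), ic50=float(ic50), sigmas=sig,
                         logl_norm=float(results["normal"][1]),
                         logl_log=float(results["lognormal"][1]),
                         error_model=adopted, converged=bool(ok))


# ---------------------------------------------------------------------------
# Residence time / success filter / time course

def residence_time(trajectories, dt: float = DEFAULT_DT):
    """Mean trajectory duration (len-1)*dt in seconds, with its SE."""
    durations = np.asarray([(len(np.asarray(p)) - 1) * dt for p in trajectories])
    if len(durations) == 0:
        raise ValueError("need at least one trajectory")
    se = float(np.std(durations, ddof=1) / np.sqrt(len(durations))) \
        if len(durations) > 1 else 0.0
    return float(np.mean(durations)), se


def compare_conditions(values_a, values_b, alpha: float = 0.005):
    """Two-sided Welch test between per-cell distributions.

    Used to flag condition differences (e.g. before vs after stimulation)
    on per-cell summaries such as MSD(66 ms).  Returns ``(p_value,
    significant)`` with the significance flag at the given alpha.
    """
    from scipy.stats import ttest_ind

    res = ttest_ind(np.asarray(values_a, dtype=float),
                    np.asarray(values_b, dtype=float), equal_var=False)
    return float(res.pvalue), bool(res.pvalue < alpha)


def cell_success(trajectories, dt: float = DEFAULT_DT,
                 min_duration: float = 1.0) -> bool:
    """A cell's recording counts if any spot was tracked for >= 1 s."""
    return any((len(np.asarray(p)) - 1) * dt >= min_duration
               for p in trajectories)


def timecourse(trajectories, start_times, intensities=None,
               dt: float = DEFAULT_DT, bin_width: float = 40.0,
               stimulus_time: float = 0.0, n_states: int | None = None,
               cluster_n_max: int = 10) -> pd.DataFrame:
    """Re-estimate every summary statistic inside consecutive time bins.

    trajectories : list of (T, 2) um position arrays.
    start_times : per-trajectory start timestamp (s), monotone or not.
    intensities : optional per-trajectory first-frame intensity (a.u.).
    Bins of ``bin_width`` seconds are anchored so that a bin edge falls on
    ``stimulus_time``; bins entirely before it are flagged as baseline.
    Empty bins are omitted (with a note column in no rows).  Per bin the
    state fractions (AIC-selected unless ``n_states`` given), mean
    intensity, cluster fractions (monomer / dimer / larger) and residence
    time are recomputed.
    """
    start_times = np.asarray(start_times, dtype=float)
    if len(start_times) != len(trajectories):
        raise ValueError("start_times must match trajectories")
    t0 = np.floor((start_times.min() - stimulus_time) / bin_width) * bin_width \
        + stimulus_time
    edges = np.arange(t0, start_times.max() + bin_width, bin_width)
    rows = []
    for lo in edges:
        hi = lo + bin_width
        idx = np.nonzero((start_times >= lo) & (start_times < hi))[0]
        if len(idx) == 0:
            continue
        trs = [trajectories[i] for i in idx]
        row: dict = {"bin_start": lo, "bin_end": hi,
                     "baseline": hi <= stimulus_time, "n_tracks": len(idx)}
        r = step_displacements(trs)
        if len(r) >= 10:
            model = (select_states(r, dt=2 * dt) if n_states is None
                     else fit_state_mixture(r, n_states, dt=2 * dt))
            row["state_fractions"] = tuple(model.fractions)
            row["state_d_values"] = tuple(model.d_values)
        rt, rt_se = residence_time(trs, dt=dt)
        row["residence_time_s"] = rt
        row["residence_time_se"] = rt_se
        if intensities is not None:
            ints = np.asarray(intensities, dtype=float)[idx]
            row["mean_intensity"] = float(np.mean(ints))
            if len(ints) >= 30 and np.all(ints > 0):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    cm = fit_cluster_sizes([ints], n_max=cluster_n_max)
                fr = cm.fractions[0]
                row["monomer_fraction"] = float(fr[0])
                row["dimer_fraction"] = float(fr[1])
                row["oligomer_fraction"] = float(fr[2:].sum())
        rows.append(row)
    return pd.DataFrame(rows)
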