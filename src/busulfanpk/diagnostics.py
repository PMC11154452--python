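"""Model evaluation: residuals, npde, visual predictive check, bootstrap,
train/test split, covariate-stripped clearance and clearance-trend simulation.

All diagnostics are seed-reproducible and operate on a :class:`FitResult`
(or, for the simulation-only tools, directly on a population model).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import StudyDataset, Subject
from .popmodel import PopulationModel
from .saem import (
    FitResult,
    ModelSpec,
    SaemSettings,
    _phi_mean,
    _theta_coefs,
    fit_saem,
)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# simulation under a fitted model (reusing each subject's design)

def _simulate_predictions(fit: FitResult, n_sim: int,
                          rng: np.random.Generator,
                          with_noise: bool = True) -> np.ndarray:
    """(n_sim, n, mmax) float32 concentrations simulated under the fit."""
    fd = fit.data
    mu = _phi_mean(fd, _theta_coefs(fd, fit.theta))
    direct = fit.direct_values() | fit.comed_theta
    sds = np.array([math.sqrt(fit.omega2[c]) for c in fd.comps])
    out = np.empty((n_sim, fd.n, fd.mmax), dtype=np.float32)
    for s in range(n_sim):
        phi = mu + sds * rng.standard_normal(mu.shape)
        for _ in range(50):
            bad = np.where(~np.isfinite(fd.predict(phi, direct)).all(axis=1))[0]
            if bad.size == 0:
                break
            phi[bad] = mu[bad] + sds * rng.standard_normal((bad.size, len(fd.comps)))
        pred = fd.predict(phi, direct)
        if with_noise:
            pred = pred + fit.sigma * rng.standard_normal(pred.shape)
        out[s] = pred
    return out


# ---------------------------------------------------------------------------
# residual diagnostics

def icwres(fit: FitResult) -> pd.DataFrame:
    """Conditional individual weighted residuals, (obs - ipred) / sigma.

    Computed with the empirical Bayes parameter estimates; roughly symmetric
    about zero when the structural and error models are adequate.
    """
    fd = fit.data
    pred = fd.predict(fit.ebe_phi, fit.direct_values() | fit.comed_theta)
    rows = []
    for i in range(fd.n):
        m = fd.mask[i]
        for t, y, p in zip(fd.t_obs[i, m], fd.y[i, m], pred[i, m]):
            rows.append((fd.subject_ids[i], t, y, p, (y - p) / fit.sigma))
    return pd.DataFrame(rows, columns=["subject_id", "t", "obs", "ipred", "icwres"])


def npde(fit: FitResult, n_sim: int = 10000, seed: int = 0) -> pd.DataFrame:
    """Normalized prediction distribution errors.

    Monte-Carlo simulation of the fitted model over each subject's design,
    per-subject decorrelation with the simulated mean and covariance, then a
    rank-based probability integral transform mapped through the standard
    normal quantile function.  Under a correct model the npde are
    approximately N(0, 1).
    """
    if n_sim < 1000:
        log.warning("npde with n_sim=%d is noisy; >= 1000 recommended", n_sim)
    fd = fit.data
    rng = np.random.default_rng(seed)
    sims = _simulate_predictions(fit, n_sim, rng)
    rows = []
    for i in range(fd.n):
        m = fd.mask[i]
        y = fd.y[i, m]
        Y = sims[:, i, m].astype(np.float64)
        E = Y.mean(axis=0)
        C = np.cov(Y, rowvar=False)
        C = np.atleast_2d(C) + 1e-10 * np.eye(m.sum())
        L = np.linalg.cholesky(C)
        y_star = np.linalg.solve(L, y - E)
        sims_star = np.linalg.solve(L, (Y - E).T)  # (m_i, n_sim)
        pde = (sims_star < y_star[:, None]).mean(axis=1)
        pde = np.clip(pde, 1.0 / (2 * n_sim), 1.0 - 1.0 / (2 * n_sim))
        z = stats.norm.ppf(pde)
        for t, zz in zip(fd.t_obs[i, m], z):
            rows.append((fd.subject_ids[i], t, zz))
    return pd.DataFrame(rows, columns=["subject_id", "t", "npde"])


# ---------------------------------------------------------------------------
# visual predictive check

@dataclass
class VpcResult:
    """Observed vs simulated percentiles per (unbinned) sampling time point."""

    table: pd.DataFrame          # one row per time point
    n_sim: int
    flagged: list[float] = field(default_factory=list)  # points with n < 5


def vpc(fit: FitResult, n_sim: int = 1000, seed: int = 0,
        percentiles=(5.0, 50.0, 95.0)) -> VpcResult:
    """Visual predictive check without time binning.

    Simulation reuses each subject's dosing and sampling design; per time
    point the observed 5th/50th/95th percentiles are compared with the 95%
    confidence bands of the same percentiles across simulations.
    """
    fd = fit.data
    rng = np.random.default_rng(seed)
    sims = _simulate_predictions(fit, n_sim, rng)
    t_round = np.round(fd.t_obs, 6)
    rows = []
    flagged = []
    times = np.unique(t_round[fd.mask])
    for t in times:
        sel = (t_round == t) & fd.mask
        n_at = int(sel.sum())
        if n_at < 5:
            flagged.append(float(t))
        obs_p = np.percentile(fd.y[sel], percentiles)
        sim_vals = sims[:, sel]                      # (n_sim, n_at)
        sim_p = np.percentile(sim_vals, percentiles, axis=1)  # (3, n_sim)
        row = {"t": float(t), "n": n_at}
        for pi, pct in enumerate(percentiles):
            lo, hi = np.percentile(sim_p[pi], [2.5, 97.5])
            row[f"obs_p{pct:g}"] = float(obs_p[pi])
            row[f"sim_p{pct:g}"] = float(np.median(sim_p[pi]))
            row[f"sim_p{pct:g}_lo"] = float(lo)
            row[f"sim_p{pct:g}_hi"] = float(hi)
        rows.append(row)
    return VpcResult(table=pd.DataFrame(rows), n_sim=n_sim, flagged=flagged)


# ---------------------------------------------------------------------------
# bootstrap

@dataclass
class BootstrapResult:
    estimates: pd.DataFrame      # one row per converged replicate
    ci: pd.DataFrame             # per parameter: lower, upper (2.5/97.5%)
    n_requested: int
    n_converged: int


def bootstrap(ds: StudyDataset, spec: ModelSpec, n: int = 500,
              settings: SaemSettings | None = None,
              seed: int = 0) -> BootstrapResult:
    """Nonparametric bootstrap over subjects.

    Resampled datasets have the original size, with subjects possibly present
    multiple times.  Each replicate is refit with fixed starting values
    (ln V = 2.5, ln k = -1, ln kappa = ln(ln 2 / 24), others 0); 95% CIs are
    the 2.5 and 97.5 percentiles of the converged replicate estimates.
    """
    settings = settings or SaemSettings()
    rng = np.random.default_rng(seed)
    rows = []
    n_conv = 0
    for b in range(n):
        idx = rng.integers(0, len(ds.subjects), size=len(ds.subjects))
        subjects = []
        for pos, i in enumerate(idx):
            src = ds.subjects[i]
            subjects.append(Subject(
                subject_id=f"B{pos:03d}", covariates=src.covariates,
                doses=[type(d)(f"B{pos:03d}", d.t0, d.amount, d.duration,
                               d.dose_index) for d in src.doses],
                observations=[type(o)(f"B{pos:03d}", o.t, o.conc,
                                      o.dosing_interval)
                              for o in src.observations],
            ))
        bds = StudyDataset(subjects=subjects, provenance="bootstrap")
        rep_settings = SaemSettings(
            exploration=settings.exploration, smoothing=settings.smoothing,
            seed=int(rng.integers(0, 2**31 - 1)), perturb_starts=False)
        fit = fit_saem(bds, spec, rep_settings)
        if not fit.converged:
            log.warning("bootstrap replicate %d did not converge; excluded", b)
            continue
        n_conv += 1
        row = {"replicate": b, **fit.theta, "sigma": fit.sigma}
        row |= {f"omega2_{k}": v for k, v in fit.omega2.items()}
        rows.append(row)
    est = pd.DataFrame(rows)
    params = [c for c in est.columns if c != "replicate"]
    ci = pd.DataFrame({
        "lower": est[params].quantile(0.025),
        "upper": est[params].quantile(0.975),
    })
    return BootstrapResult(estimates=est, ci=ci, n_requested=n,
                           n_converged=n_conv)


# ---------------------------------------------------------------------------
# train/test split

def train_test_split(ds: StudyDataset, ratio: float = 0.75, seed: int = 0,
                     spec: ModelSpec | None = None,
                     settings: SaemSettings | None = None,
                     ) -> tuple[StudyDataset, StudyDataset, dict]:
    """Subject-level split, fit on the training set, SSR/n on both sets.

    The report carries the training fit plus the population-level sum of
    squared residuals divided by the number of concentrations for each set.
    A test/train SSR ratio above 2 is flagged as poor generalization.
    """
    if len(ds.subjects) < 8:
        raise ValueError("need at least 8 subjects for a meaningful split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ds.subjects))
    n_train = round(ratio * len(ds.subjects))
    train = StudyDataset([ds.subjects[i] for i in sorted(order[:n_train])],
                         provenance="train split")
    test = StudyDataset([ds.subjects[i] for i in sorted(order[n_train:])],
                        provenance="test split")
    report = {"n_train": len(train.subjects), "n_test": len(test.subjects)}
    if spec is not None:
        settings = settings or SaemSettings()
        fit = fit_saem(train, spec, settings)
        report["fit"] = fit

        def ssr_per_obs(dataset):
            from .saem import FitData
            fd = FitData(dataset, spec)
            mu = _phi_mean(fd, _theta_coefs(fd, fit.theta))
            pred = fd.predict(mu, fit.direct_values() | fit.comed_theta)
            resid = (fd.y - pred)[fd.mask]
            return float((resid**2).sum() / resid.size), pd.DataFrame({
                "obs": fd.y[fd.mask], "pred": pred[fd.mask]})

        report["ssr_train"], report["obs_pred_train"] = ssr_per_obs(train)
        report["ssr_test"], report["obs_pred_test"] = ssr_per_obs(test)
        ratio_ssr = report["ssr_test"] / max(report["ssr_train"], 1e-12)
        report["ssr_ratio"] = ratio_ssr
        report["flagged"] = bool(ratio_ssr > 2.0)
        if report["flagged"]:
            log.warning("test/train SSR ratio %.2f exceeds 2", ratio_ssr)
    return train, test, report


# ---------------------------------------------------------------------------
# covariate-stripped clearance

def covariate_stripped_cl(ds: StudyDataset, fit: FitResult,
                          drop: tuple[tuple[str, str], ...] = (
                              ("lk", "ALL"), ("lk", "dlnAlb")),
                          settings: SaemSettings | None = None,
                          ) -> tuple[pd.DataFrame, dict]:
    """Individual clearance as a multiple of its population prediction after
    refitting without selected covariates.

    Dropping e.g. the ALL and albumin effects on ln k and refitting lets the
    subject-level clearances re-absorb those effects; the ratio
    CL_subject / CL_population then visualizes them.  Returns the per-subject
    table plus a two-sided t-test (ALL vs rest) and the OLS slope of the
    ratio against serum albumin.
    """
    settings = settings or SaemSettings()
    spec = fit.spec
    for param, term in drop:
        if term not in spec.covariates.get(param, ()):
            raise ValueError(f"covariate {term!r} on {param!r} not in the model")
        spec = spec.without_covariate(param, term)
    refit = fit_saem(ds, spec, settings)
    fd = refit.data
    mu = _phi_mean(fd, _theta_coefs(fd, refit.theta))
    ip = refit.individual_parameters()
    cl_ind = ip["k"] * ip["V"]
    cl_pop = np.exp(mu[:, fd.icomp["lk"]]) * np.exp(mu[:, fd.icomp["lV"]])
    table = pd.DataFrame({
        "subject_id": fd.subject_ids,
        "cl_ratio": cl_ind / cl_pop,
        "ALL": fd.terms["ALL"].astype(bool),
        "albumin": [s.covariates.albumin for s in ds.subjects],
    })
    grp_all = table.loc[table["ALL"], "cl_ratio"]
    grp_rest = table.loc[~table["ALL"], "cl_ratio"]
    t_res = (stats.ttest_ind(grp_all, grp_rest)
             if len(grp_all) > 1 and len(grp_rest) > 1 else None)
    alb = table.dropna(subset=["albumin"])
    reg = (stats.linregress(alb["albumin"], alb["cl_ratio"])
           if len(alb) > 2 else None)
    info = {
        "all_vs_rest_t": None if t_res is None else float(t_res.statistic),
        "all_vs_rest_p": None if t_res is None else float(t_res.pvalue),
        "albumin_slope": None if reg is None else float(reg.slope),
        "albumin_slope_p": None if reg is None else float(reg.pvalue),
        "refit": refit,
    }
    return table, info


# ---------------------------------------------------------------------------
# dose linearity

def dose_linearity(nca_table: pd.DataFrame,
                   intervals=(3, 5, 7)) -> tuple[pd.DataFrame, dict]:
    """Dose-normalized AUC ratios of later intervals against the first.

    For every subject with a measured first interval and a measured interval
    m in ``intervals``, the ratio (AUC/dose)_m / (AUC/dose)_1 is regressed on
    the dose ratio dose_m/dose_1.  A slope compatible with zero indicates
    dose-linear kinetics.  Even-numbered measured intervals (evening starts)
    are excluded.
    """
    rows = []
    for sid, grp in nca_table.groupby("subject_id"):
        grp = grp.set_index("interval")
        if 1 not in grp.index:
            continue
        base = grp.loc[1]
        for m in intervals:
            if m not in grp.index or m % 2 == 0:
                continue
            r = grp.loc[m]
            rows.append({
                "subject_id": sid, "interval": m,
                "auc_dose_ratio": (r["auc"] / r["dose"]) / (base["auc"] / base["dose"]),
                "dose_ratio": r["dose"] / base["dose"],
            })
    table = pd.DataFrame(rows)
    regressions = {}
    for m in intervals:
        sub = table[table["interval"] == m] if len(table) else table
        if len(sub) < 3 or sub["dose_ratio"].nunique() < 2:
            regressions[m] = None
            continue
        reg = stats.linregress(sub["dose_ratio"], sub["auc_dose_ratio"])
        regressions[m] = {"slope": float(reg.slope), "p": float(reg.pvalue),
                          "n": int(len(sub))}
    return table, regressions


# ---------------------------------------------------------------------------
# population CL(t) trend simulation

@dataclass
class ClTrendResult:
    t: np.ndarray
    mean_curve: np.ndarray       # from the fixed effects
    mean_curve_hlh: np.ndarray   # fixed effects for the HLH/XLP group
    bands: dict[str, np.ndarray]  # "lo95", "lo80", "hi80", "hi95"


def simulate_cl_trend(pop: PopulationModel, n: int = 100_000,
                      horizon_h: float = 72.0, seed: int = 0,
                      n_times: int = 145) -> ClTrendResult:
    """Population distribution of the relative clearance trend CL(t)/CL(0).

    Draws the amplitude d_k from N(theta_dk, Omega_dk) and the rate kappa_k
    from N(kappa_hat, SE(kappa) * sqrt(N subjects)) -- the latter because no
    random effect is fitted on kappa, so its population spread is emulated by
    inflating the estimation uncertainty.  Non-positive kappa draws violate
    the model's invariant and are rejected and redrawn.  The ratio curve is
    ``1 + d_k (1 - exp(-kappa t))``; the solid reference curves use the fixed
    effects only (with and without the HLH/XLP shift).
    """
    if horizon_h <= 0:
        raise ValueError("horizon must be positive")
    rng = np.random.default_rng(seed)
    dk_mean = pop.theta["dk"]
    dk_sd = math.sqrt(pop.omega2.get("dk", 0.0))
    kappa_hat = math.exp(pop.theta["lkappa"])
    se_lkappa = pop.se.get("lkappa", 0.0)
    n_subj = pop.n_subjects or 1
    kappa_sd = se_lkappa * kappa_hat * math.sqrt(n_subj)
    dk = rng.normal(dk_mean, dk_sd, size=n)
    kappa = rng.normal(kappa_hat, kappa_sd, size=n)
    for _ in range(200):
        bad = kappa <= 0
        if not bad.any():
            break
        kappa[bad] = rng.normal(kappa_hat, kappa_sd, size=int(bad.sum()))
    t = np.linspace(0.0, horizon_h, n_times)
    curves = 1.0 + dk[:, None] * -np.expm1(-kappa[:, None] * t[None, :])
    lo95, lo80, hi80, hi95 = np.percentile(curves, [2.5, 10.0, 90.0, 97.5],
                                           axis=0)
    mean_curve = 1.0 + dk_mean * -np.expm1(-kappa_hat * t)
    dk_hlh = dk_mean + pop.theta.get("dk:HLHXLP", 0.0)
    mean_hlh = 1.0 + dk_hlh * -np.expm1(-kappa_hat * t)
    return ClTrendResult(t=t, mean_curve=mean_curve, mean_curve_hlh=mean_hlh,
                         bands={"lo95": lo95, "lo80": lo80,
                                "hi80": hi80, "hi95": hi95})
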