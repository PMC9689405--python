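"""Crossed random-effects variance components and repeatability coefficients.

The reliability model for a long-format measurement table is

    y_{p,r,k} = x_p' beta + a_p + b_r + c_{p,k} + eps_{p,r,k}

with crossed patient (a), reader (b) and occasion (c; the re-presented
radiograph, shared by all readers) random effects.  Because the random
effects are fully crossed, the fit is written directly on the mixed-model
equations rather than through a nested-grouping LMM API: with W = [X Z] and
G the random-effect covariance, the REML deviance reduces to

    -2 l_R = (n - p - q) log s2e + sum_c q_c log s2c + log|M| + y'P y

where M is the mixed-model-equations coefficient matrix.  The residual
variance is profiled out analytically, leaving a numerically cheap
optimization over the log variance ratios.

Repeatability coefficients follow the within-subject-SD convention:
RC = 2.77 * sqrt(within-subject variance), 2.77 being 1.96 * sqrt(2) — the
95% bound for the difference of two repeat measurements.

* same patient, same reader:      RC = 2.77 * sqrt(s2_residual)
* same patient, different reader: RC = 2.77 * sqrt(s2_residual + s2_reader)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "VarianceComponents",
    "RCResult",
    "ConvergenceError",
    "fit_variance_components",
    "repeatability_coefficients",
]

RC_FACTOR = 2.77  # 1.96 * sqrt(2), normal-quantile convention

_COMPONENTS = ("patient", "reader", "repeat")


class ConvergenceError(RuntimeError):
    """REML optimization failed; the message carries diagnostics."""


@dataclass
class VarianceComponents:
    """REML estimates for the crossed reliability model.

    Variances in squared measurement units.  ``ci`` maps component name
    (patient/reader/repeat/residual) to a 95% interval (Satterthwaite
    chi-square by default; lognormal Wald and profile likelihood are also
    available), or ``None`` when the component sits on the zero boundary
    (interval not estimable — reported the way variance-component software
    prints N/A).
    """

    constant: float
    var_patient: float
    var_reader: float
    var_repeat: float
    var_residual: float
    ci: dict = field(default_factory=dict)
    fixed_effects: dict = field(default_factory=dict)
    fixed_effects_se: dict = field(default_factory=dict)
    n_obs: int = 0
    restricted_loglik: float = math.nan
    converged: bool = False
    warnings: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "constant": self.constant,
            "var_patient": self.var_patient,
            "var_reader": self.var_reader,
            "var_repeat": self.var_repeat,
            "var_residual": self.var_residual,
        }


@dataclass(frozen=True)
class RCResult:
    """Repeatability (same reader) and reproducibility (different reader)."""

    rc_same_reader: float
    rc_different_reader: float

    def __post_init__(self):
        if self.rc_different_reader < self.rc_same_reader:
            raise ValueError("between-reader RC cannot be smaller than within-reader RC")


class _MMESolver:
    """Mixed-model-equations factorization for the crossed reliability model.

    Orders the unknowns as a small dense block (fixed effects + reader
    effects) followed by per-patient blocks (patient effect + that patient's
    occasion effects).  The patient part of the MME matrix is block diagonal
    with tiny blocks, so each evaluation is a batched small Cholesky plus a
    Schur complement on the dense block — orders of magnitude cheaper than
    factoring the full system, and exact.
    """

    def __init__(self, y, X, blocks, active):
        self.n, self.p = X.shape
        self.active = list(active)
        self.has_reader = "reader" in active
        self.has_repeat = "repeat" in active
        pat_codes, P = blocks["patient"]
        self.P = P
        rdr_codes, R = blocks["reader"]
        self.R = R if self.has_reader else 0
        self.f = self.p + self.R

        F = X if not self.has_reader else np.hstack([X, np.equal.outer(rdr_codes, np.arange(R)).astype(float)])
        self.FtF = F.T @ F
        self.Fty = F.T @ y
        self.yty = float(y @ y)

        if self.has_repeat:
            occ_codes, _ = blocks["repeat"]
            # occasion index within patient, contiguous
            occ_of_patient = {}
            occ_local = np.empty(self.n, dtype=int)
            K_p = np.zeros(P, dtype=int)
            for i in range(self.n):
                key = (pat_codes[i], occ_codes[i])
                if key not in occ_of_patient:
                    occ_of_patient[key] = K_p[pat_codes[i]]
                    K_p[pat_codes[i]] += 1
                occ_local[i] = occ_of_patient[key]
        else:
            K_p = np.zeros(P, dtype=int)
            occ_local = np.zeros(self.n, dtype=int)

        self.groups = []  # (patient_index_array, G (g,s,s), C (g,f,s), Uty (g,s))
        for K in np.unique(K_p):
            pats = np.nonzero(K_p == K)[0]
            s = 1 + (K if self.has_repeat else 0)
            g = pats.size
            G = np.zeros((g, s, s))
            C = np.zeros((g, self.f, s))
            Uty = np.zeros((g, s))
            pat_pos = {pp: i for i, pp in enumerate(pats)}
            for i in range(self.n):
                pp = pat_codes[i]
                if pp not in pat_pos:
                    continue
                gi = pat_pos[pp]
                colu = [0] + ([1 + occ_local[i]] if self.has_repeat else [])
                for a in colu:
                    Uty[gi, a] += y[i]
                    C[gi, :, a] += F[i]
                    for b in colu:
                        G[gi, a, b] += 1.0
            self.groups.append((pats, G, C, Uty))
        self.q_total = P + (int(K_p.sum()) if self.has_repeat else 0) + self.R
        self._last = None

    def factor(self, lam):
        """Return (logdet M, theta_dense, Q) at variance ratios ``lam``."""
        lam = np.asarray(lam, dtype=float)
        ratios = dict(zip(self.active, lam))
        inv_pat = 1.0 / ratios["patient"]
        inv_rep = 1.0 / ratios["repeat"] if self.has_repeat else 0.0

        S = self.FtF.copy()
        if self.has_reader:
            idx = np.arange(self.p, self.f)
            S[idx, idx] += 1.0 / ratios["reader"]
        rhs = self.Fty.copy()
        logdet_D = 0.0
        solves = []
        for pats, G, C, Uty in self.groups:
            s = G.shape[1]
            D = G.copy()
            D[:, 0, 0] += inv_pat
            if s > 1:
                k = np.arange(1, s)
                D[:, k, k] += inv_rep
            L = np.linalg.cholesky(D)
            logdet_D += 2.0 * float(np.sum(np.log(np.diagonal(L, axis1=1, axis2=2))))
            DinvCt = np.linalg.solve(D, np.transpose(C, (0, 2, 1)))  # (g, s, f)
            DinvUty = np.linalg.solve(D, Uty[:, :, None])[:, :, 0]  # (g, s)
            S -= np.einsum("gfs,gsh->fh", C, DinvCt)
            rhs -= np.einsum("gfs,gs->f", C, DinvUty)
            solves.append((D, C, Uty, DinvUty))
        try:
            Ls = np.linalg.cholesky(S)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - pathological input
            raise ConvergenceError(f"mixed-model equations not positive definite at ratios {lam}") from exc
        logdet_S = 2.0 * float(np.sum(np.log(np.diag(Ls))))
        theta_F = np.linalg.solve(Ls.T, np.linalg.solve(Ls, rhs))
        Q = self.yty - float(theta_F @ self.Fty)
        for D, C, Uty, DinvUty in solves:
            t = np.linalg.solve(D, (Uty - np.einsum("gfs,f->gs", C, theta_F))[:, :, None])[:, :, 0]
            Q -= float(np.einsum("gs,gs->", t, Uty))
        self._last = (S, theta_F)
        return logdet_D + logdet_S, theta_F, max(Q, 1e-300)

    def beta_cov_unscaled(self):
        """(M^{-1}) restricted to the fixed-effect block, at the last factor."""
        S, _ = self._last
        return np.linalg.inv(S)[: self.p, : self.p]


def _design(table: pd.DataFrame, metric, side, fixed):
    df = table
    if metric is not None:
        df = df[df["metric"] == metric]
    if side is not None:
        df = df[df["side"] == side]
    if df.empty:
        raise ValueError(f"no rows for metric={metric!r}, side={side!r}")
    df = df.reset_index(drop=True)
    y = df["value"].to_numpy(dtype=float)
    n = y.size

    cols = [np.ones(n)]
    names = ["constant"]
    for name in fixed:
        if name not in df.columns:
            raise ValueError(f"fixed covariate {name!r} not in table")
        cols.append(df[name].to_numpy(dtype=float))
        names.append(name)
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify aliased columns by incremental rank
        aliased, kept = [], np.ones(n)[:, None]
        for j in range(X.shape[1]):
            trial = np.column_stack([kept, X[:, j]])
            if np.linalg.matrix_rank(trial) == kept.shape[1]:
                aliased.append(names[j])
            else:
                kept = trial
        raise ValueError(f"rank-deficient fixed-effect design; aliased covariates: {aliased}")

    pat_codes, pat_levels = pd.factorize(df["patient_id"], sort=True)
    rdr_codes, rdr_levels = pd.factorize(df["reader_id"], sort=True)
    occ_codes, occ_levels = pd.factorize(
        pd.Series(list(zip(df["patient_id"], df["replicate"]))), sort=True
    )
    blocks = {
        "patient": (pat_codes, len(pat_levels)),
        "reader": (rdr_codes, len(rdr_levels)),
        "repeat": (occ_codes, len(occ_levels)),
    }
    return df, y, X, names, blocks


def fit_variance_components(
    table: pd.DataFrame,
    metric: str | None = None,
    side: str | None = None,
    fixed: tuple[str, ...] = (),
    max_iter: int = 200,
    ci_method: str = "satterthwaite",
) -> VarianceComponents:
    """REML fit of the crossed patient/reader/occasion model.

    ``table`` is a long-format measurement table (columns ``patient_id``,
    ``reader_id``, ``replicate``, ``value`` and optionally ``metric``/
    ``side`` and fixed covariates).  Components that the design cannot
    identify (a single reader; no repeated occasions) are fixed at zero with
    a warning rather than estimated.  Estimates at the zero boundary are
    reported as 0 with ``ci`` of ``None``.  ``ci_method`` selects the
    variance-component interval: ``"satterthwaite"`` (default), ``"wald"``
    (lognormal) or ``"profile"`` (profile likelihood).
    """
    df, y, X, fixed_names, blocks = _design(table, metric, side, fixed)
    n, p = X.shape
    warnings: list[str] = []

    if len(pd.unique(df["patient_id"])) < 2:
        raise ValueError("at least 2 patients are required")
    active = ["patient"]
    if blocks["reader"][1] >= 2:
        active.append("reader")
    else:
        warnings.append("single reader: reader variance fixed at 0")
    # the occasion effect is identifiable only if some patient has >1 occasion
    if blocks["repeat"][1] > blocks["patient"][1]:
        active.append("repeat")
    else:
        warnings.append("no repeated occasions: repeated-measure variance fixed at 0")

    q_sizes = [blocks[name][1] for name in active]
    solver = _MMESolver(y, X, blocks, active)
    n_check, p_check = solver.n, solver.p
    assert (n_check, p_check) == (n, p)

    def mme(lam: np.ndarray):
        return solver.factor(lam)

    def profiled_deviance(psi: np.ndarray) -> float:
        lam = np.exp(psi)
        logdet, _, Qval = mme(lam)
        s2e = Qval / (n - p)
        return (n - p) * math.log(s2e) + float(np.dot(q_sizes, psi)) + logdet + (n - p)

    psi0 = np.zeros(len(active))
    res = minimize(
        profiled_deviance,
        psi0,
        method="L-BFGS-B",
        bounds=[(-25.0, 25.0)] * len(active),
        options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-10},
    )
    psi = res.x
    # Newton polish with central differences for near machine-level optimum
    psi = _newton_polish(profiled_deviance, psi, bounds=(-25.0, 25.0))
    if not res.success and profiled_deviance(psi) > profiled_deviance(psi0):
        raise ConvergenceError(f"REML optimization failed: {res.message} (n={n}, components={active})")

    lam = np.exp(psi)
    logdet, theta, Qval = mme(lam)
    s2e = Qval / (n - p)
    variances = dict.fromkeys(_COMPONENTS, 0.0)
    boundary = set(_COMPONENTS) - set(active)
    for name, lam_c, psi_c in zip(active, lam, psi):
        if psi_c <= -10.0:  # variance ratio below ~5e-5: boundary estimate
            variances[name] = 0.0
            boundary.add(name)
        else:
            variances[name] = lam_c * s2e
    dev = profiled_deviance(psi)
    restricted_loglik = -0.5 * (dev + (n - p) * math.log(2 * math.pi))

    deviance_log, names, theta0 = _log_variance_deviance(active, boundary, variances, s2e, n, p, q_sizes, mme)
    se_log = _log_scale_se(names, theta0, deviance_log)
    if ci_method == "satterthwaite":
        ci = _satterthwaite_ci(names, theta0, se_log)
    elif ci_method == "wald":
        ci = _lognormal_wald_ci(names, theta0, se_log)
    elif ci_method == "profile":
        ci = _profile_ci(names, theta0, deviance_log, _lognormal_wald_ci(names, theta0, se_log))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    mme(lam)  # leave the solver factored at the optimum
    beta = theta[:p]
    beta_se = np.sqrt(np.clip(np.diag(solver.beta_cov_unscaled()) * s2e, 0.0, None))

    return VarianceComponents(
        constant=float(beta[0]),
        var_patient=float(variances["patient"]),
        var_reader=float(variances["reader"]),
        var_repeat=float(variances["repeat"]),
        var_residual=float(s2e),
        ci=ci,
        fixed_effects=dict(zip(fixed_names, map(float, beta))),
        fixed_effects_se=dict(zip(fixed_names, map(float, beta_se))),
        n_obs=n,
        restricted_loglik=float(restricted_loglik),
        converged=True,
        warnings=warnings,
    )


def _newton_polish(fun, x0: np.ndarray, bounds: tuple[float, float], iters: int = 6, h: float = 1e-4) -> np.ndarray:
    """Few damped Newton steps on a smooth scalar objective (finite diffs)."""
    x = x0.copy()
    k = x.size
    f0 = fun(x)
    for _ in range(iters):
        g = np.zeros(k)
        H = np.zeros((k, k))
        fx = fun(x)
        for i in range(k):
            ei = np.zeros(k)
            ei[i] = h
            fp, fm = fun(x + ei), fun(x - ei)
            g[i] = (fp - fm) / (2 * h)
            H[i, i] = (fp - 2 * fx + fm) / h**2
            for j in range(i + 1, k):
                ej = np.zeros(k)
                ej[j] = h
                H[i, j] = H[j, i] = (fun(x + ei + ej) - fun(x + ei - ej) - fun(x - ei + ej) + fun(x - ei - ej)) / (4 * h**2)
        try:
            evals = np.linalg.eigvalsh(H)
            if evals.min() <= 0:
                break
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        for damp in (1.0, 0.5, 0.25, 0.1):
            trial = np.clip(x - damp * step, bounds[0], bounds[1])
            if fun(trial) <= fx + 1e-12:
                x = trial
                break
        else:
            break
        if np.linalg.norm(damp * step) < 1e-10:
            break
    return x if fun(x) <= f0 else x0


_CHI2_1DF_95 = 3.841458820694124


def _log_variance_deviance(active, boundary, variances, s2e, n, p, q_sizes, mme):
    """Closure evaluating the unprofiled REML deviance in log-variance
    coordinates, plus the coordinate names and the optimum ``theta0``."""
    names = [c for c in active if c not in boundary] + ["residual"]
    theta0 = np.log(np.array([variances[c] for c in active if c not in boundary] + [s2e]))
    act_idx = [i for i, c in enumerate(active) if c not in boundary]
    qs = np.asarray(q_sizes, float)

    def deviance_log(th: np.ndarray) -> float:
        s2 = np.exp(th)
        s2e_ = s2[-1]
        lam = np.full(len(active), 1e-12)
        for pos, i in enumerate(act_idx):
            lam[i] = s2[pos] / s2e_
        logdet, _, Qval = mme(lam)
        return (n - p - qs.sum()) * math.log(s2e_) + float(np.dot(qs, np.log(lam * s2e_))) + logdet + Qval / s2e_

    return deviance_log, names, theta0


def _empty_ci() -> dict:
    ci: dict[str, tuple | None] = {c: None for c in _COMPONENTS}
    ci["residual"] = None
    return ci


def _log_scale_se(names, theta0, deviance_log):
    """SE of each log-variance from the observed REML information."""
    k = theta0.size
    h = 1e-4
    H = np.zeros((k, k))
    f0 = deviance_log(theta0)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h
        fp, fm = deviance_log(theta0 + ei), deviance_log(theta0 - ei)
        H[i, i] = (fp - 2 * f0 + fm) / h**2
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = h
            H[i, j] = H[j, i] = (
                deviance_log(theta0 + ei + ej)
                - deviance_log(theta0 + ei - ej)
                - deviance_log(theta0 - ei + ej)
                + deviance_log(theta0 - ei - ej)
            ) / (4 * h**2)
    try:
        cov = 2.0 * np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.zeros(k)
    return {name: float(s) for name, s in zip(names, se)}


def _lognormal_wald_ci(names, theta0, se_log):
    """95% CIs of the lognormal Wald form (symmetric on the log scale)."""
    ci = _empty_ci()
    for name, th in zip(names, theta0):
        s = se_log[name]
        if 0 < s < 10:
            ci[name] = (float(np.exp(th - 1.96 * s)), float(np.exp(th + 1.96 * s)))
    return ci


def _satterthwaite_ci(names, theta0, se_log, alpha: float = 0.05):
    """Satterthwaite chi-square CIs for the variance components.

    Matches each estimate to a scaled chi-square with effective df
    nu = 2 / SE_log^2 (equivalently 2 (sigma^2-hat)^2 / Var(sigma^2-hat)),
    giving intervals [nu v / chi2(1-a/2, nu), nu v / chi2(a/2, nu)].  For
    components with few levels these are much better calibrated than the
    symmetric-on-log-scale Wald form.
    """
    from scipy.stats import chi2

    ci = _empty_ci()
    for name, th in zip(names, theta0):
        s = se_log[name]
        if not 0 < s < 10:
            continue
        nu = 2.0 / s**2
        v = float(np.exp(th))
        lo_q = float(chi2.ppf(alpha / 2, nu))
        if lo_q <= 0:
            continue
        ci[name] = (nu * v / float(chi2.ppf(1 - alpha / 2, nu)), nu * v / lo_q)
    return ci


def _profile_ci(names, theta0, deviance_log, wald_ci):
    """Profile-likelihood 95% CIs on the log-variance scale.

    For each component, the bound solves profile(theta_j) = devmin + 3.84,
    re-minimizing the deviance over the remaining components at each trial
    value (Wald intervals seed the bracket).  A lower bound that never
    crosses before the variance is numerically zero is reported as 0.
    """
    k = theta0.size
    dev_min = deviance_log(theta0)
    target = dev_min + _CHI2_1DF_95
    ci = _empty_ci()

    for j, name in enumerate(names):
        warm = {"x": np.delete(theta0, j)}

        def profile(t, j=j, warm=warm):
            if k == 1:
                return deviance_log(np.array([t]))

            def obj(rest):
                return deviance_log(np.insert(rest, j, t))

            r = minimize(obj, warm["x"], method="Nelder-Mead", options={"fatol": 2e-3, "xatol": 2e-3, "maxfev": 150})
            warm["x"] = r.x
            return float(r.fun)

        se0 = 0.5
        if wald_ci.get(name):
            se0 = max((math.log(wald_ci[name][1]) - math.log(wald_ci[name][0])) / (2 * 1.96), 0.05)
        bounds = []
        for direction in (-1.0, 1.0):
            warm["x"] = np.delete(theta0, j)
            # bracket the crossing, starting just inside the Wald guess
            t_in, g_in = theta0[j], -_CHI2_1DF_95
            step = 1.4 * 1.96 * se0 * direction
            bound = None
            for _ in range(12):
                t_out = t_in + step
                g_out = profile(t_out) - target
                if g_out >= 0.0:
                    # secant refinement inside the bracket
                    lo_t, g_lo, hi_t, g_hi = t_in, g_in, t_out, g_out
                    for _ in range(8):
                        t_new = lo_t - g_lo * (hi_t - lo_t) / (g_hi - g_lo)
                        t_min, t_max = min(lo_t, hi_t), max(lo_t, hi_t)
                        t_new = min(max(t_new, t_min + 1e-6), t_max - 1e-6)
                        g_new = profile(t_new) - target
                        if abs(g_new) < 0.01 or abs(hi_t - lo_t) < 2e-3:
                            hi_t, g_hi = t_new, g_new
                            break
                        if g_new < 0:
                            lo_t, g_lo = t_new, g_new
                        else:
                            hi_t, g_hi = t_new, g_new
                    bound = hi_t if abs(g_hi) <= abs(g_lo) else lo_t
                    break
                t_in, g_in = t_out, g_out
                step *= 1.7
                if direction < 0 and t_in < theta0[j] - 30:
                    break
            if bound is None:
                bound = -math.inf if direction < 0 else math.inf
            bounds.append(bound)
        lo = 0.0 if math.isinf(bounds[0]) else float(np.exp(bounds[0]))
        hi = math.inf if math.isinf(bounds[1]) else float(np.exp(bounds[1]))
        ci[name] = (lo, hi)
    return ci


def repeatability_coefficients(vc, var_reader: float | None = None) -> RCResult:
    """Repeatability coefficients from variance components.

    Accepts a :class:`VarianceComponents` or a residual variance (with the
    reader variance as second argument).  RC(same reader) = 2.77 sqrt(s2e);
    RC(different reader) = 2.77 sqrt(s2e + s2reader).  Rounding, if any, is
    presentation-side only.
    """
    if isinstance(vc, VarianceComponents):
        var_residual = vc.var_residual
        var_reader = vc.var_reader
    else:
        var_residual = float(vc)
        var_reader = 0.0 if var_reader is None else float(var_reader)
    if var_residual < 0 or var_reader < 0:
        raise ValueError("variance components must be non-negative")
    return RCResult(
        rc_same_reader=RC_FACTOR * math.sqrt(var_residual),
        rc_different_reader=RC_FACTOR * math.sqrt(var_residual + var_reader),
    )
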