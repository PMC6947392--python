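"""Cohort statistics: contingency tables, one-way ANOVA on scores,
Kaplan-Meier estimation, log-rank testing, Cox proportional hazards with
Efron tie handling, bidirectional stepwise selection, and a global
Schoenfeld proportionality test.

All estimators are order-invariant and implemented natively (external
survival packages are used only as cross-checks in the test suite).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import FACTOR_LEVELS


def percent_round_half_up(count: int, total: int) -> float:
    """100*count/total rounded half-up to one decimal (integer arithmetic)."""
    if total <= 0:
        raise ValueError("total must be positive")
    return ((count * 2000 + total) // (2 * total)) / 10


# ---------------------------------------------------------------------------
# contingency analysis
# ---------------------------------------------------------------------------

@dataclass
class ContingencyResult:
    table: pd.DataFrame          # levels x outcome counts
    expected: pd.DataFrame       # expected counts under independence
    percentages: dict[str, float]  # per-level outcome rate, one decimal
    overall_percentage: float
    chi2: float
    p: float
    dof: int
    warnings: list[str] = field(default_factory=list)


def contingency_analysis(
    records: pd.DataFrame, factor: str, outcome: str = "event"
) -> ContingencyResult:
    """Pearson chi-square (no continuity correction) of factor x outcome.

    Levels with zero observations are dropped with a warning; expected
    counts below 5 raise a small-cell warning rather than switching tests.
    """
    table = pd.crosstab(records[factor], records[outcome])
    notes: list[str] = []
    if factor in FACTOR_LEVELS:
        declared = [lv for lv in FACTOR_LEVELS[factor] if lv in table.index]
        dropped = [lv for lv in FACTOR_LEVELS[factor] if lv not in table.index]
        if dropped:
            notes.append(f"levels with zero observations dropped: {dropped}")
        table = table.loc[declared]
    if table.shape[0] < 2:
        raise ValueError(f"factor {factor!r} has fewer than 2 observed levels")

    obs = table.to_numpy(dtype=float)
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row @ col / obs.sum()
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    dof = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(stats.chi2.sf(chi2, dof))
    if (expected < 5).any():
        notes.append("expected count < 5 in at least one cell")

    pos_col = 1 if 1 in table.columns else table.columns[-1]
    percentages = {
        str(lv): percent_round_half_up(int(table.loc[lv, pos_col]), int(row[i, 0]))
        for i, lv in enumerate(table.index)
    }
    overall = percent_round_half_up(int(table[pos_col].sum()), int(obs.sum()))
    return ContingencyResult(
        table=table,
        expected=pd.DataFrame(expected, index=table.index, columns=table.columns),
        percentages=percentages,
        overall_percentage=overall,
        chi2=chi2,
        p=p,
        dof=dof,
        warnings=notes,
    )


# ---------------------------------------------------------------------------
# one-way ANOVA
# ---------------------------------------------------------------------------

def anova_scores(groups: list[np.ndarray | list[float]]) -> tuple[float, float]:
    """One-way ANOVA over score groups: F = MS_between / MS_within."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 1 for a in arrays):
        raise ValueError("need >= 2 groups, each with >= 1 value")
    if not any(a.size >= 2 for a in arrays):
        raise ValueError("at least one group needs >= 2 values")
    all_vals = np.concatenate(arrays)
    grand = all_vals.mean()
    k = len(arrays)
    n = all_vals.size
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if ss_within == 0 and ss_between == 0:
        warnings.warn("ANOVA undefined: zero between- and within-group variance")
        return float("nan"), float("nan")
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / (n - k)
    f = ms_between / ms_within
    p = float(stats.f.sf(f, k - 1, n - k))
    return float(f), p


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

def km_estimate(times, events) -> pd.DataFrame:
    """Product-limit survival estimate.

    Returns one row per distinct observed time with columns ``time``,
    ``n_risk``, ``n_events``, ``n_censored`` and ``survival``. Deaths are
    processed before censorings at tied times (the censored subject is
    still at risk for the tied event).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size and (t <= 0).any():
        raise ValueError("times must be strictly positive")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    rows = []
    s = 1.0
    n_risk = t.size
    for ut in np.unique(t):
        at = t == ut
        d = int(e[at].sum())
        c = int(at.sum() - d)
        if d > 0:
            s *= 1.0 - d / n_risk
        rows.append((float(ut), int(n_risk), d, c, s))
        n_risk -= d + c
    return pd.DataFrame(rows, columns=["time", "n_risk", "n_events", "n_censored", "survival"])


# ---------------------------------------------------------------------------
# log-rank test
# ---------------------------------------------------------------------------

def logrank_test(times, events, group) -> tuple[float, float]:
    """Two-group log-rank: chi2 = (sum(O1-E1))^2 / V, p from chi2(df=1)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(group)
    labels = np.unique(g)
    if labels.size != 2:
        raise ValueError("log-rank requires exactly 2 groups")
    if e.sum() == 0:
        warnings.warn("log-rank undefined: no events")
        return float("nan"), float("nan")
    in1 = g == labels[1]
    o_minus_e = 0.0
    var = 0.0
    for ut in np.unique(t[e == 1]):
        at_risk = t >= ut
        n = int(at_risk.sum())
        n1 = int((at_risk & in1).sum())
        d = int(((t == ut) & (e == 1)).sum())
        d1 = int(((t == ut) & (e == 1) & in1).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        warnings.warn("log-rank undefined: zero variance")
        return float("nan"), float("nan")
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, 1))


# ---------------------------------------------------------------------------
# Cox proportional hazards (Efron ties)
# ---------------------------------------------------------------------------

@dataclass
class CoxTerm:
    name: str
    beta: float
    se: float
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p: float
    df: int = 1
    estimable: bool = True


@dataclass
class CoxFit:
    terms: list[CoxTerm]
    beta: np.ndarray
    cov: np.ndarray
    log_likelihood: float
    n: int
    n_events: int
    names: list[str]
    blocks: dict[str, list[int]]           # covariate/factor -> column indices
    converged: bool
    X: np.ndarray
    times: np.ndarray
    events: np.ndarray

    def block_wald(self, block: str) -> tuple[float, int, float]:
        """(chi2, df, p) Wald test that all coefficients of a block are 0."""
        idx = self.blocks[block]
        b = self.beta[idx]
        v = self.cov[np.ix_(idx, idx)]
        chi2 = float(b @ np.linalg.solve(v, b))
        df = len(idx)
        return chi2, df, float(stats.chi2.sf(chi2, df))


def encode_covariates(
    records: pd.DataFrame, covariates: list[str]
) -> tuple[np.ndarray, list[str], dict[str, list[int]]]:
    """Design matrix with treatment-coded factor blocks.

    Declared categorical factors become indicator columns for their
    non-reference observed levels (entering/leaving stepwise selection as a
    block); booleans become one 0/1 column; numeric columns pass through.
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    blocks: dict[str, list[int]] = {}
    for cov in covariates:
        if cov not in records.columns:
            raise KeyError(f"covariate {cov!r} not in records")
        series = records[cov]
        start = len(names)
        if cov in FACTOR_LEVELS:
            levels = [lv for lv in FACTOR_LEVELS[cov] if (series == lv).any()]
            for lv in levels[1:]:
                cols.append((series == lv).to_numpy(dtype=float))
                names.append(f"{cov}[{lv}]")
        elif series.dtype == bool or set(series.dropna().unique()) <= {0, 1, True, False}:
            cols.append(series.to_numpy(dtype=float))
            names.append(cov)
        else:
            cols.append(series.to_numpy(dtype=float))
            names.append(cov)
        blocks[cov] = list(range(start, len(names)))
        if start == len(names):
            raise ValueError(f"covariate {cov!r} has a single observed level")
    X = np.column_stack(cols) if cols else np.empty((len(records), 0))
    return X, names, blocks


def _efron_loglik(beta, X, times, events):
    """(log-likelihood, gradient, information) under Efron tie handling."""
    eta = X @ beta
    eta = eta - eta.max()  # guard exp overflow; cancels in ratios
    w = np.exp(eta)
    p = X.shape[1]
    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    order = np.argsort(-times, kind="stable")  # decreasing time
    Xs, ts, es, ws, etas = X[order], times[order], events[order], w[order], eta[order]
    s0 = 0.0
    s1 = np.zeros(p)
    s2 = np.zeros((p, p))
    i = 0
    n = len(ts)
    while i < n:
        j = i
        while j < n and ts[j] == ts[i]:
            j += 1
        chunk = slice(i, j)
        s0 += ws[chunk].sum()
        s1 += ws[chunk] @ Xs[chunk]
        s2 += (ws[chunk][:, None] * Xs[chunk]).T @ Xs[chunk]
        dmask = es[chunk] == 1
        d = int(dmask.sum())
        if d > 0:
            Xd = Xs[chunk][dmask]
            wd = ws[chunk][dmask]
            s0d = wd.sum()
            s1d = wd @ Xd
            s2d = (wd[:, None] * Xd).T @ Xd
            ll += etas[chunk][dmask].sum()
            grad += Xd.sum(axis=0)
            for l in range(d):
                f = l / d
                phi = s0 - f * s0d
                psi = s1 - f * s1d
                chi = s2 - f * s2d
                ll -= np.log(phi)
                grad -= psi / phi
                info += chi / phi - np.outer(psi, psi) / phi**2
        i = j
    return ll, grad, info


class CoxDivergenceError(RuntimeError):
    """Monotone partial likelihood (complete separation)."""


def cox_fit(
    records: pd.DataFrame,
    covariates: list[str],
    tol: float = 1e-9,
    max_iter: int = 50,
    beta_bound: float = 15.0,
) -> CoxFit:
    """Cox PH fit by Newton-Raphson on the Efron partial likelihood.

    A coefficient wandering beyond ``beta_bound`` in absolute value is
    reported as non-estimable (divergence under monotone likelihood)
    rather than returned as a fake finite estimate.
    """
    times = records["time_months"].to_numpy(dtype=float)
    events = records["event"].to_numpy(dtype=int)
    if events.sum() < 1:
        raise ValueError("Cox fit needs at least one event")
    X, names, blocks = encode_covariates(records, covariates)
    # center columns: improves conditioning, leaves beta unchanged
    Xc = X - X.mean(axis=0)
    p = X.shape[1]
    beta = np.zeros(p)
    ll, grad, info = _efron_loglik(beta, Xc, times, events)
    converged = False
    diverged = False
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, grad, rcond=None)[0]
        new_beta = beta + step
        new_ll, new_grad, new_info = _efron_loglik(new_beta, Xc, times, events)
        halvings = 0
        while new_ll < ll and halvings < 10:
            step /= 2
            new_beta = beta + step
            new_ll, new_grad, new_info = _efron_loglik(new_beta, Xc, times, events)
            halvings += 1
        delta = abs(new_ll - ll)
        beta, grad, info = new_beta, new_grad, new_info
        if np.any(np.abs(beta) > beta_bound):
            diverged = True
            ll = new_ll
            break
        if delta < tol * (abs(new_ll) + tol):
            ll = new_ll
            converged = True
            break
        ll = new_ll
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    terms = []
    for k, name in enumerate(names):
        estimable = not (diverged and abs(beta[k]) > beta_bound)
        b, s = float(beta[k]), float(se[k])
        z = b / s if s > 0 else np.nan
        terms.append(
            CoxTerm(
                name=name,
                beta=b if estimable else float("nan"),
                se=s if estimable else float("nan"),
                hazard_ratio=float(np.exp(b)) if estimable else float("nan"),
                ci_low=float(np.exp(b - 1.96 * s)) if estimable else float("nan"),
                ci_high=float(np.exp(b + 1.96 * s)) if estimable else float("nan"),
                p=float(2 * stats.norm.sf(abs(z))) if estimable else float("nan"),
                estimable=estimable,
            )
        )
    if diverged:
        warnings.warn(
            "Cox fit diverged (monotone partial likelihood); affected terms "
            "reported as non-estimable"
        )
    return CoxFit(
        terms=terms,
        beta=beta,
        cov=cov,
        log_likelihood=float(ll),
        n=len(records),
        n_events=int(events.sum()),
        names=names,
        blocks=blocks,
        converged=converged and not diverged,
        X=Xc,
        times=times,
        events=events,
    )


# ---------------------------------------------------------------------------
# Schoenfeld residuals / proportional-hazards test
# ---------------------------------------------------------------------------

def schoenfeld_residuals(fit: CoxFit) -> tuple[np.ndarray, np.ndarray]:
    """(event times, residual matrix) — one row per event, Efron weighting.

    Each event's residual is its covariate vector minus the (Efron-averaged)
    risk-set weighted mean at its event time.
    """
    X, times, events, beta = fit.X, fit.times, fit.events, fit.beta
    w = np.exp(X @ beta)
    ev_times = []
    resids = []
    for ut in np.unique(times[events == 1]):
        at_risk = times >= ut
        dmask = (times == ut) & (events == 1)
        d = int(dmask.sum())
        s0 = w[at_risk].sum()
        s1 = w[at_risk] @ X[at_risk]
        s0d = w[dmask].sum()
        s1d = w[dmask] @ X[dmask]
        xbar = np.mean(
            [(s1 - (l / d) * s1d) / (s0 - (l / d) * s0d) for l in range(d)], axis=0
        )
        for xi in X[dmask]:
            ev_times.append(ut)
            resids.append(xi - xbar)
    return np.asarray(ev_times), np.asarray(resids)


def schoenfeld_global_test(fit: CoxFit) -> float:
    """Global proportional-hazards score test (identity time transform).

    Regresses Schoenfeld residuals on event time; chi-square with df equal
    to the number of model terms. Returns NaN (flagged) when there are not
    more events than terms.
    """
    p = len(fit.names)
    if fit.n_events <= p:
        warnings.warn("Schoenfeld test undefined: not more events than terms")
        return float("nan")
    g, r = schoenfeld_residuals(fit)
    gt = g - g.mean()
    denom = float(gt @ gt)
    if denom == 0:
        warnings.warn("Schoenfeld test undefined: single event time")
        return float("nan")
    u = gt @ r  # p-vector
    chi2 = float(fit.n_events * (u @ fit.cov @ u) / denom)
    return float(stats.chi2.sf(chi2, p))


# ---------------------------------------------------------------------------
# stepwise selection
# ---------------------------------------------------------------------------

def stepwise_select(
    records: pd.DataFrame,
    candidate_covariates: list[str],
    p_enter: float = 0.05,
    p_remove: float = 0.05,
    prefilter_p: float = 0.25,
) -> tuple[CoxFit | None, list[dict]]:
    """Univariate screen at ``prefilter_p`` then bidirectional stepwise Cox.

    Factors enter and leave as blocks (Wald block test). Returns the final
    fit (None if nothing enters) and a full selection trace.
    """
    if not candidate_covariates:
        raise ValueError("no candidate covariates")
    trace: list[dict] = []
    screened: list[str] = []
    for cov in candidate_covariates:
        try:
            fit = cox_fit(records, [cov])
            _, _, p = fit.block_wald(cov)
        except (ValueError, KeyError) as exc:
            trace.append({"action": "screen-error", "factor": cov, "detail": str(exc)})
            continue
        trace.append({"action": "screen", "factor": cov, "p": p})
        if np.isfinite(p) and p < prefilter_p:
            screened.append(cov)

    model: list[str] = []
    seen: set[frozenset] = set()
    while True:
        changed = False
        # forward
        best_cov, best_p = None, np.inf
        for cov in screened:
            if cov in model:
                continue
            try:
                fit = cox_fit(records, model + [cov])
                _, _, p = fit.block_wald(cov)
            except (ValueError, np.linalg.LinAlgError):
                continue
            if np.isfinite(p) and p < best_p:
                best_cov, best_p = cov, p
        if best_cov is not None and best_p < p_enter:
            model.append(best_cov)
            trace.append({"action": "add", "factor": best_cov, "p": best_p})
            changed = True
        # backward
        if model:
            fit = cox_fit(records, model)
            worst_cov, worst_p = None, -np.inf
            for cov in model:
                _, _, p = fit.block_wald(cov)
                if np.isfinite(p) and p > worst_p:
                    worst_cov, worst_p = cov, p
            if worst_cov is not None and worst_p > p_remove:
                model.remove(worst_cov)
                trace.append({"action": "remove", "factor": worst_cov, "p": worst_p})
                changed = True
        key = frozenset(model)
        if key in seen and changed:
            trace.append({"action": "cycle-stop", "model": sorted(model)})
            break
        seen.add(key)
        if not changed:
            break

    final = cox_fit(records, model) if model else None
    trace.append({"action": "final", "model": sorted(model)})
    return final, trace
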