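"""Survival association of candidate genes.

Patients are stratified into altered vs normal groups by an expression
z-score threshold; group survival is summarized by the product-limit
(Kaplan-Meier) estimator

    S(t_j) = prod_{i<=j} (1 - d_i / n_i),

compared by the two-group log-rank test, and modeled by the Cox
proportional-hazards model h(t|X) = h0(t) exp(beta' X) whose hazard ratios
are HR = exp(beta).  The partial likelihood is maximized by Newton-Raphson
with step-halving; tied event times are handled by the Efron (default) or
Breslow approximation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .studies import ClinicalTable

log = logging.getLogger(__name__)

ALTERED = "altered"
NORMAL = "normal"
TIES_METHODS = ("efron", "breslow")


class ConvergenceError(RuntimeError):
    """Cox partial-likelihood maximization failed."""


class MonotoneLikelihoodError(ConvergenceError):
    """Monotone partial likelihood (typically perfect separation)."""


def stratify_by_alteration(zscores, z_threshold: float = 2.0) -> np.ndarray:
    """Label each patient 'altered' iff |z| >= z_threshold, else 'normal'."""
    if z_threshold <= 0:
        raise ValueError("z_threshold must be > 0")
    z = np.asarray(zscores, dtype=float)
    return np.where(np.abs(z) >= z_threshold, ALTERED, NORMAL)


# ---------------------------------------------------------------------------
# Product-limit estimator

@dataclass(eq=False)
class KMCurve:
    """Product-limit curve over the distinct event times."""

    times: np.ndarray       # distinct event times, ascending
    at_risk: np.ndarray     # n_j just before each event time
    events: np.ndarray      # d_j events at each time
    survival: np.ndarray    # S(t_j)

    def survival_at(self, t: float) -> float:
        """Step-function value S(t); 1 before the first event time."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.times, "n_at_risk": self.at_risk,
            "n_events": self.events, "survival": self.survival,
        })


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimate.

    At tied times deaths are processed before censorings: everyone with
    time >= t_j is at risk at t_j.  Censored-only times do not create steps.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("empty survival input")
    if t.size != e.size:
        raise ValueError("times and events lengths differ")
    if np.any(t < 0):
        raise ValueError("negative survival times")
    event_times = np.unique(t[e == 1])
    n_at_risk = np.array([(t >= tj).sum() for tj in event_times], dtype=int)
    d = np.array([((t == tj) & (e == 1)).sum() for tj in event_times], dtype=int)
    surv = np.cumprod(1.0 - d / n_at_risk) if event_times.size else np.array([])
    return KMCurve(event_times, n_at_risk, d, surv)


def write_km_curve(curve: KMCurve, path) -> None:
    curve.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Log-rank test

@dataclass(frozen=True)
class LogrankResult:
    statistic: float
    p: float
    observed_a: float
    expected_a: float


def logrank_test(times_a, events_a, times_b, events_b) -> LogrankResult:
    """Two-group log-rank test of H0: S_a(t) = S_b(t).

    At each distinct event time the observed events in group A are compared
    with their hypergeometric expectation; the chi-square statistic
    (sum(O-E))^2 / sum(V) is referred to 1 df.
    """
    ta, ea = np.asarray(times_a, float), np.asarray(events_a, int)
    tb, eb = np.asarray(times_b, float), np.asarray(events_b, int)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb])
    in_a = np.concatenate([np.ones(ta.size, bool), np.zeros(tb.size, bool)])
    event_times = np.unique(t[e == 1])
    O = E = V = 0.0
    for tj in event_times:
        at_risk = t >= tj
        n = at_risk.sum()
        n1 = (at_risk & in_a).sum()
        dead = (t == tj) & (e == 1)
        d = dead.sum()
        d1 = (dead & in_a).sum()
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if V == 0:
        return LogrankResult(0.0, 1.0, O, E)
    stat = (O - E) ** 2 / V
    return LogrankResult(float(stat), float(stats.chi2.sf(stat, 1)), float(O), float(E))


# ---------------------------------------------------------------------------
# Cox proportional hazards

@dataclass(eq=False)
class CoxFit:
    """Fitted Cox PH model; hazard ratios are exactly exp(beta)."""

    names: tuple
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    converged: bool
    ties: str
    n_patients: int
    n_events: int
    iterations: int

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def z(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.beta / self.se

    @property
    def p(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.z))

    def confint(self, level: float = 0.95) -> np.ndarray:
        q = stats.norm.ppf(0.5 + level / 2)
        return np.column_stack([self.beta - q * self.se, self.beta + q * self.se])

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"beta": self.beta, "HR": self.hr, "se": self.se, "z": self.z, "p": self.p},
            index=pd.Index(self.names, name="covariate"),
        )


def hazard_ratio(beta):
    """HR = exp(beta)."""
    return np.exp(beta)


def _cox_loglik_grad_info(X, times, events, beta, ties):
    """Log partial likelihood, score vector and observed information.

    Risk-set sums are reverse-cumulative over samples sorted by descending
    time; Efron's tie correction is applied per tied event time.
    """
    n, p = X.shape
    order = np.argsort(-times, kind="stable")
    t_s, e_s, X_s = times[order], events[order], X[order]
    eta = np.clip(X_s @ beta, -500, 500)
    w = np.exp(eta)
    cum0 = np.cumsum(w)
    cum1 = np.cumsum(w[:, None] * X_s, axis=0)
    cum2 = np.cumsum(w[:, None, None] * (X_s[:, :, None] * X_s[:, None, :]), axis=0)

    is_last = np.r_[t_s[1:] != t_s[:-1], True]
    end_idx = np.flatnonzero(is_last)                 # last row of each time group
    group_id = np.cumsum(np.r_[0, is_last[:-1]])
    d_g = np.bincount(group_id, weights=e_s.astype(float), minlength=end_idx.size)

    ev = d_g > 0
    S0 = cum0[end_idx]
    S1 = cum1[end_idx]
    S2 = cum2[end_idx]

    ll = float(eta[e_s == 1].sum())
    grad = X_s[e_s == 1].sum(axis=0).astype(float)
    info = np.zeros((p, p))

    # Breslow contribution for every event time (exact when d=1)
    dv, S0v, S1v, S2v = d_g[ev], S0[ev], S1[ev], S2[ev]
    ll -= float(np.sum(dv * np.log(S0v)))
    m = S1v / S0v[:, None]
    grad -= (dv[:, None] * m).sum(axis=0)
    info += np.einsum("g,gij->ij", dv, S2v / S0v[:, None, None])
    info -= np.einsum("g,gi,gj->ij", dv, m, m)

    if ties == "efron":
        tied = np.flatnonzero(ev & (d_g >= 2))
        for gi in tied:
            fail = (group_id == gi) & (e_s == 1)
            d = int(d_g[gi])
            wD = w[fail]
            XD = X_s[fail]
            S0D = wD.sum()
            S1D = (wD[:, None] * XD).sum(axis=0)
            S2D = np.einsum("k,ki,kj->ij", wD, XD, XD)
            # remove the Breslow block, add the Efron one
            ll += d * np.log(S0[gi])
            mg = S1[gi] / S0[gi]
            grad += d * mg
            info -= d * (S2[gi] / S0[gi] - np.outer(mg, mg))
            for l in range(d):
                f = l / d
                phi0 = S0[gi] - f * S0D
                phi1 = S1[gi] - f * S1D
                phi2 = S2[gi] - f * S2D
                ll -= np.log(phi0)
                ml = phi1 / phi0
                grad -= ml
                info += phi2 / phi0 - np.outer(ml, ml)
    return ll, grad, info


def cox_fit(X, times, events, ties: str = "efron", max_iter: int = 100,
            tol: float = 1e-8, names=None) -> CoxFit:
    """Maximize the Cox partial likelihood by Newton-Raphson.

    Convergence is declared when the score sup-norm falls below ``tol`` (or
    the step below 1e-10); the step is halved whenever the likelihood would
    decrease.  Standard errors come from the inverse observed information;
    Wald p-values are two-sided normal.
    """
    if ties not in TIES_METHODS:
        raise ValueError(f"ties must be one of {TIES_METHODS}, got {ties!r}")
    if isinstance(X, pd.DataFrame):
        names = tuple(X.columns) if names is None else tuple(names)
        X = X.to_numpy(dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and len(np.asarray(times)) == X.shape[1]:
        X = X.T
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    n, p = X.shape
    if names is None:
        names = tuple(f"x{r}" for r in range(p))
    if times.size != n or events.size != n:
        raise ValueError("X, times and events have inconsistent lengths")
    if events.sum() == 0:
        raise ValueError("no events in the data")
    if np.any(np.ptp(X, axis=0) == 0):
        const = [names[j] for j in np.flatnonzero(np.ptp(X, axis=0) == 0)]
        raise ValueError(f"constant covariate(s): {const}")

    beta = np.zeros(p)
    ll, grad, info = _cox_loglik_grad_info(X, times, events, beta, ties)
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError("singular information matrix") from exc
        scale = 1.0
        for _ in range(40):
            beta_new = beta + scale * step
            ll_new, grad_new, info_new = _cox_loglik_grad_info(X, times, events, beta_new, ties)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            scale /= 2.0
        else:
            break  # cannot improve: report flagged fit
        step_size = float(np.max(np.abs(scale * step)))
        beta, ll, grad, info = beta_new, ll_new, grad_new, info_new
        if np.max(np.abs(beta)) > 15:  # |HR| beyond e^15: monotone likelihood
            raise MonotoneLikelihoodError(
                "diverging coefficients: monotone partial likelihood (perfect separation?)"
            )
        if step_size < 1e-10:
            converged = bool(np.max(np.abs(grad)) < np.sqrt(tol))
            break
    if not converged and np.max(np.abs(grad)) < tol:
        converged = True
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        converged = False
    if not converged:
        warnings.warn("Cox fit did not converge; estimates are flagged", RuntimeWarning)
    return CoxFit(names, beta, se, float(ll), converged, ties, n, int(events.sum()),
                  iterations)


def cox_score_test(x, times, events) -> tuple[float, float]:
    """Score (Rao) test of beta=0 for a single covariate Cox model.

    With untied event times this equals the two-group log-rank chi-square.
    """
    X = np.asarray(x, dtype=float).reshape(-1, 1)
    _, grad, info = _cox_loglik_grad_info(
        X, np.asarray(times, float), np.asarray(events, int), np.zeros(1), "breslow"
    )
    stat = float(grad[0] ** 2 / info[0, 0])
    return stat, float(stats.chi2.sf(stat, 1))


# ---------------------------------------------------------------------------
# Cohorts and the gene screen

@dataclass(eq=False)
class SurvivalCohort:
    """Per-patient survival data with per-gene alteration status.

    ``status`` is patients x genes, boolean (True = altered); ``clinical``
    holds categorical factors as strings.
    """

    patient_ids: pd.Index
    time: np.ndarray
    event: np.ndarray
    status: pd.DataFrame
    clinical: pd.DataFrame
    expression_z: pd.DataFrame | None = None
    z_threshold: float = 2.0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        n = len(self.patient_ids)
        if self.time.size != n or self.event.size != n or len(self.status) != n:
            raise ValueError("cohort components have inconsistent lengths")
        if not np.isin(self.event, [0, 1]).all():
            raise ValueError("event indicator must be 0/1")

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    @property
    def genes(self) -> list[str]:
        return list(self.status.columns)

    @classmethod
    def from_clinical(cls, clinical: ClinicalTable, expression_z: pd.DataFrame,
                      z_threshold: float = 2.0) -> "SurvivalCohort":
        """Join a clinical table with a genes x patients z-score matrix.

        Patients absent from either side are dropped; alteration status is
        |z| >= z_threshold per gene.
        """
        z = expression_z.copy()
        z.index = z.index.astype(str).str.upper()
        z.columns = z.columns.astype(str)
        common = [p for p in clinical.patients if p in z.columns]
        if not common:
            raise ValueError("no patients shared between clinical table and z matrix")
        dropped = len(clinical.patients) - len(common)
        if dropped:
            log.warning("dropping %d patients without expression data", dropped)
        keep = clinical.patients.isin(common)
        zt = z[common].T.astype(float)
        status = pd.DataFrame(
            np.abs(zt.to_numpy()) >= z_threshold, index=zt.index, columns=zt.columns
        )
        return cls(
            patient_ids=pd.Index(common),
            time=clinical.time[keep],
            event=clinical.event[keep],
            status=status,
            clinical=clinical.factors.loc[common],
            expression_z=z[common],
            z_threshold=z_threshold,
        )


def dummy_encode(factors: pd.DataFrame) -> pd.DataFrame:
    """Dummy-encode categorical factors against the most frequent level.

    Factors with a single level are dropped with a warning.
    """
    cols = {}
    for name in factors.columns:
        col = factors[name].astype(str)
        counts = col.value_counts()
        if len(counts) < 2:
            warnings.warn(f"clinical factor {name!r} has a single level; dropped",
                          UserWarning)
            continue
        top = counts.max()
        ref = sorted(counts.index[counts == top])[0]
        for level in sorted(set(col.unique()) - {ref}):
            cols[f"{name}[{level}]"] = (col == level).astype(float)
    return pd.DataFrame(cols, index=factors.index)


SCREEN_COLUMNS = [
    "beta_uni", "hr_uni", "p_uni",
    "beta_multi", "hr_multi", "p_multi",
    "beta_comb", "hr_comb", "p_comb",
    "logrank_p", "logrank_selected", "flagged",
]


@dataclass(eq=False)
class ScreenReport:
    """Per-gene univariate / multivariate / combined Cox results."""

    table: pd.DataFrame
    km_curves: dict = field(default_factory=dict)
    alpha: float = 0.05
    warnings: list = field(default_factory=list)

    def flagged_genes(self) -> list[str]:
        return list(self.table.index[self.table["flagged"]])


def _safe_fit(X: pd.DataFrame, times, events, ties: str, messages: list):
    if X.shape[1] == 0:
        return None
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            fit = cox_fit(X, times, events, ties=ties)
        messages.extend(str(w.message) for w in caught)
        return fit
    except (ValueError, ConvergenceError) as exc:
        messages.append(f"cox fit on {list(X.columns)[:3]}...: {exc}")
        return None


def gene_survival_screen(cohort: SurvivalCohort, genes, clinical_factors=None,
                         alpha: float = 0.05, ties: str = "efron",
                         make_km: bool = True) -> ScreenReport:
    """Screen genes for survival association, mirroring a three-block report.

    Per gene: univariate Cox on alteration status; multivariate Cox on all
    screened genes jointly; combined Cox on the gene plus clinical dummies.
    A gene is flagged when its univariate Wald p <= alpha; the log-rank test
    (altered vs normal) selects genes for interpretation of the combined
    model and drives which Kaplan-Meier curves are emitted.
    """
    genes = [str(g).upper() for g in genes]
    messages: list[str] = []
    table = pd.DataFrame(index=pd.Index(genes, name="gene"),
                         columns=SCREEN_COLUMNS, dtype=object)
    if not genes:
        table = table.astype({c: float for c in SCREEN_COLUMNS[:10]})
        return ScreenReport(table, {}, alpha, messages)

    missing = [g for g in genes if g not in cohort.status.columns]
    if missing:
        messages.append(f"genes absent from cohort: {missing}")
    usable = [g for g in genes if g not in missing]

    times, events = cohort.time, cohort.event
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        clin = dummy_encode(
            cohort.clinical[list(clinical_factors)] if clinical_factors is not None
            else cohort.clinical
        )
    messages.extend(str(w.message) for w in caught)

    for c in SCREEN_COLUMNS[:10]:
        table[c] = np.nan
    table["logrank_selected"] = False
    table["flagged"] = False

    # univariate + log-rank
    km_curves: dict[str, dict] = {}
    for g in usable:
        x = cohort.status[g].astype(float)
        fit = _safe_fit(x.to_frame(g), times, events, ties, messages)
        if fit is not None and fit.converged:
            table.loc[g, ["beta_uni", "hr_uni", "p_uni"]] = (
                fit.beta[0], fit.hr[0], fit.p[0])
        alt = x.to_numpy() == 1
        if alt.any() and (~alt).any():
            lr = logrank_test(times[alt], events[alt], times[~alt], events[~alt])
            table.loc[g, "logrank_p"] = lr.p
            table.loc[g, "logrank_selected"] = bool(lr.p <= alpha)

    # multivariate: all screened genes jointly
    nonconst = [g for g in usable if cohort.status[g].astype(float).nunique() > 1]
    X_multi = cohort.status[nonconst].astype(float)
    fit = _safe_fit(X_multi, times, events, ties, messages)
    if fit is not None and fit.converged:
        for j, g in enumerate(nonconst):
            table.loc[g, ["beta_multi", "hr_multi", "p_multi"]] = (
                fit.beta[j], fit.hr[j], fit.p[j])

    # combined: one gene + clinical covariates
    for g in usable:
        X = pd.concat([cohort.status[g].astype(float).rename(g), clin], axis=1)
        fit = _safe_fit(X, times, events, ties, messages)
        if fit is not None and fit.converged:
            table.loc[g, ["beta_comb", "hr_comb", "p_comb"]] = (
                fit.beta[0], fit.hr[0], fit.p[0])

    table["flagged"] = table["p_uni"].astype(float) <= alpha
    table["flagged"] = table["flagged"].fillna(False)

    if make_km:
        for g in table.index[table["flagged"]]:
            alt = cohort.status[g].to_numpy()
            if alt.any() and (~alt).any():
                km_curves[g] = {
                    ALTERED: km_estimate(times[alt], events[alt]),
                    NORMAL: km_estimate(times[~alt], events[~alt]),
                }
    for c in SCREEN_COLUMNS[:10]:
        table[c] = table[c].astype(float)
    return ScreenReport(table, km_curves, alpha, messages)


def write_screen_report(report: ScreenReport, path) -> None:
    report.table.to_csv(path, sep="\t", float_format="%.6g")


def plot_km(curves: dict, path, title: str = "") -> None:
    """Step plot of altered vs normal survival curves (optional artifact)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for label, curve in curves.items():
        t = np.r_[0.0, curve.times]
        s = np.r_[1.0, curve.survival]
        ax.step(t, s, where="post", label=label)
    ax.set_xlabel("time (months)")
    ax.set_ylabel("S(t)")
    ax.set_ylim(0, 1.05)
    ax.legend()
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
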