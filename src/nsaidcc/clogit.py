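"""Conditional logistic regression for 1:M matched sets.

Each matched set contributes the Breslow conditional likelihood term

    exp(x_case . beta) / sum_{j in set} exp(x_j . beta),

which is exact here because every set has exactly one case (no ties to
handle).  The log likelihood

    l(beta) = sum_s [ x_{case,s} . beta - log sum_{j in s} exp(x_j . beta) ]

is concave; it is maximised by Newton-Raphson with step-halving from
beta = 0, using the analytic gradient and observed information.  Wald
intervals exp(beta +/- z * se) provide 95% CIs, and a protected backward
elimination removes candidate covariates (never the exposure terms or the
a-priori tier) one at a time, worst Wald p first, while p >= alpha_stay.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractError, EstimationError

SEPARATION_BOUND = 20.0


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (the table style: 0.5 rounds away from zero)."""
    x = float(x)
    if not np.isfinite(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# design container


@dataclass
class MatchedDesign:
    """Row-major design for matched sets, sorted by set.

    ``y`` marks the single case of each set; ``group`` holds contiguous set
    ids after sorting.
    """

    X: np.ndarray
    y: np.ndarray
    group: np.ndarray
    columns: list[str]

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.int64)
        self.group = np.asarray(self.group)
        order = np.argsort(self.group, kind="stable")
        self.X, self.y, self.group = self.X[order], self.y[order], self.group[order]
        cases = pd.Series(self.y, index=self.group).groupby(level=0).sum()
        if not (cases == 1).all():
            raise ContractError("every matched set must contain exactly one case")
        if len(self.group) == 0:
            self._starts = np.array([], dtype=np.int64)
        else:
            self._starts = np.flatnonzero(
                np.r_[True, self.group[1:] != self.group[:-1]])
        self._sizes = np.diff(np.r_[self._starts, len(self.group)])

    @property
    def n_sets(self) -> int:
        return len(self._starts)

    def set_sizes(self) -> np.ndarray:
        return self._sizes

    def select(self, columns: list[str]) -> "MatchedDesign":
        idx = [self.columns.index(c) for c in columns]
        return MatchedDesign(self.X[:, idx], self.y, self.group, list(columns))

    def drop_unmatched(self) -> tuple["MatchedDesign", int]:
        """Remove sets with no control (a single row)."""
        keep_sets = self._sizes > 1
        if keep_sets.all():
            return self, 0
        keep = np.repeat(keep_sets, self._sizes)
        return (MatchedDesign(self.X[keep], self.y[keep], self.group[keep],
                              list(self.columns)), int((~keep_sets).sum()))

    def informative_columns(self) -> np.ndarray:
        """Columns with within-set variation in at least one set."""
        s = self._starts
        ok = np.zeros(self.X.shape[1], dtype=bool)
        for j in range(self.X.shape[1]):
            mx = np.maximum.reduceat(self.X[:, j], s)
            mn = np.minimum.reduceat(self.X[:, j], s)
            ok[j] = bool(np.any(mx > mn))
        return ok


def design_from_frame(df: pd.DataFrame, columns: list[str],
                      set_col: str = "set_id", case_col: str = "is_case") -> MatchedDesign:
    return MatchedDesign(df[columns].to_numpy(np.float64),
                         df[case_col].to_numpy(np.int64),
                         df[set_col].to_numpy(), list(columns))


# ---------------------------------------------------------------------------
# likelihood


def conditional_loglik(design: MatchedDesign, beta, order: int = 0):
    """Breslow conditional log likelihood; optionally gradient and information.

    ``order`` 0 returns l; 1 returns (l, grad); 2 returns (l, grad, info)
    where info is the (positive semi-definite) observed information matrix.
    """
    beta = np.asarray(beta, dtype=np.float64)
    if not np.all(np.isfinite(beta)):
        raise ValueError("beta must be finite")
    X, y, s = design.X, design.y, design._starts
    gidx = np.repeat(np.arange(design.n_sets), design._sizes)
    eta = X @ beta
    m = np.maximum.reduceat(eta, s)
    w = np.exp(eta - m[gidx])
    S = np.add.reduceat(w, s)
    ll = float(eta[y == 1].sum() - (np.log(S) + m).sum())
    if order == 0:
        return ll
    P = w / S[gidx]
    grad = X[y == 1].sum(axis=0) - X.T @ P
    if order == 1:
        return ll, grad
    XP = X * P[:, None]
    B = np.add.reduceat(XP, s, axis=0)  # per-set weighted means of x
    info = X.T @ XP - B.T @ B
    return ll, grad, info


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FitResult:
    columns: list[str]
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    converged: bool
    n_sets_used: int
    n_sets_unmatched: int = 0
    dropped_columns: list[str] = field(default_factory=list)
    n_iter: int = 0

    def params(self) -> pd.Series:
        return pd.Series(self.beta, index=self.columns)

    def wald_p(self) -> pd.Series:
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(self.se > 0, self.beta / self.se, np.inf)
        return pd.Series(2 * stats.norm.sf(np.abs(z)), index=self.columns)

    def summary(self, level: float = 0.95) -> pd.DataFrame:
        rows = []
        for j, name in enumerate(self.columns):
            or_, lcl, ucl = wald_interval(self.beta[j], self.se[j], level)
            rows.append((name, self.beta[j], self.se[j], or_, lcl, ucl,
                         self.n_sets_used))
        df = pd.DataFrame(rows, columns=["term", "beta", "se", "or", "lcl",
                                         "ucl", "n_sets"])
        for name in self.dropped_columns:
            df.loc[len(df)] = (name, np.nan, np.nan, np.nan, np.nan, np.nan,
                               self.n_sets_used)
        return df


def fit_clogit(design: MatchedDesign, tol: float = 1e-8,
               max_iter: int = 50) -> FitResult:
    """Newton-Raphson with step-halving from beta = 0.

    Columns with no within-set variation are dropped (reported as
    not-estimable); unmatched sets are excluded with a count.  Separation is
    flagged (``converged=False``) when any |beta| exceeds 20.
    """
    design, n_unmatched = design.drop_unmatched()
    if design.n_sets == 0:
        raise EstimationError("no matched sets with at least one control")
    info_cols = design.informative_columns()
    dropped = [c for c, ok in zip(design.columns, info_cols) if not ok]
    kept = [c for c, ok in zip(design.columns, info_cols) if ok]
    if not kept:
        raise EstimationError("no informative covariate columns")
    d = design.select(kept)

    p = d.X.shape[1]
    beta = np.zeros(p)
    ll, grad, info = conditional_loglik(d, beta, order=2)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info + 1e-12 * np.eye(p), grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, grad, rcond=None)[0]
        # step-halving: insist on a non-decreasing log likelihood
        t = 1.0
        for _ in range(40):
            cand = beta + t * step
            ll_new = conditional_loglik(d, cand, order=0)
            if ll_new >= ll - 1e-12:
                break
            t /= 2.0
        beta = beta + t * step
        ll, grad, info = conditional_loglik(d, beta, order=2)
        if np.max(np.abs(beta)) > SEPARATION_BOUND:
            converged = False
            break
    else:
        it = max_iter
    if np.max(np.abs(beta)) > SEPARATION_BOUND:
        converged = False
    elif np.max(np.abs(grad)) < tol:
        converged = True

    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    return FitResult(columns=kept, beta=beta, se=se, loglik=ll,
                     converged=converged, n_sets_used=d.n_sets,
                     n_sets_unmatched=n_unmatched, dropped_columns=dropped,
                     n_iter=it)


# ---------------------------------------------------------------------------
# inference helpers


def wald_interval(beta_j: float, se_j: float, level: float = 0.95):
    """(OR, lcl, ucl) from a log-odds estimate and its standard error."""
    if not 0.0 < level < 1.0:
        raise ValueError("confidence level must lie strictly in (0, 1)")
    if se_j < 0:
        raise ValueError("standard error must be non-negative")
    z = stats.norm.ppf(0.5 + level / 2.0)
    with np.errstate(over="ignore"):  # separated columns: an infinite limit
        return (float(np.exp(beta_j)), float(np.exp(beta_j - z * se_j)),
                float(np.exp(beta_j + z * se_j)))


def point_estimate_from_ci(lcl: float, ucl: float, ndigits: int | None = 2) -> float:
    """Recover the Wald point estimate from its CI limits.

    A Wald interval is symmetric on the log scale, so the point estimate is
    the geometric mean of the limits.  QC utility for printed tables.
    """
    if lcl <= 0 or ucl <= 0:
        raise ValueError("interval limits must be positive")
    if lcl > ucl:
        raise ValueError("lower limit exceeds upper limit")
    est = float(np.exp((np.log(lcl) + np.log(ucl)) / 2.0))
    return round_half_up(est, ndigits) if ndigits is not None else est


# ---------------------------------------------------------------------------
# backward elimination


@dataclass
class EliminationTrace:
    removed: list[tuple[str, float]] = field(default_factory=list)
    retained: list[str] = field(default_factory=list)


def backward_eliminate(design: MatchedDesign, a_priori_columns: list[str],
                       candidate_columns: list[str], alpha_stay: float = 0.05,
                       **fit_kwargs) -> tuple[FitResult, EliminationTrace]:
    """Protected backward elimination on the candidate tier.

    Exposure columns are every design column outside the two tiers; they and
    the a-priori tier are never removed.  At each step the candidate with
    the largest Wald p >= ``alpha_stay`` leaves; candidates that are not
    estimable (no within-set variation) leave with p = NaN.
    """
    protected = [c for c in design.columns if c not in candidate_columns]
    bad = set(a_priori_columns) & set(candidate_columns)
    if bad:
        raise ContractError(f"columns in both tiers: {sorted(bad)}")
    candidates = [c for c in design.columns if c in candidate_columns]
    trace = EliminationTrace()
    while True:
        cols = protected + candidates
        fit = fit_clogit(design.select(cols), **fit_kwargs)
        dropped_cand = [c for c in fit.dropped_columns if c in candidates]
        if dropped_cand:
            for c in dropped_cand:
                trace.removed.append((c, float("nan")))
                candidates.remove(c)
            continue
        pvals = fit.wald_p()
        cand_p = pvals[[c for c in candidates if c in pvals.index]]
        if cand_p.empty or cand_p.max() < alpha_stay:
            trace.retained = cols
            return fit, trace
        worst = cand_p.idxmax()
        trace.removed.append((worst, float(cand_p[worst])))
        candidates.remove(worst)
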