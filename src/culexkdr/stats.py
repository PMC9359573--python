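"""Population and association statistics for kdr genotype surveys.

Covers: resistance-allele frequency from genotype counts with a binomial
standard error; assay concordance/accuracy; Fisher's exact test on r x c
tables by full enumeration (seeded Monte-Carlo fallback for large tables);
the proportional-odds (cumulative-logit) ordinal regression used to relate
genotype to species/region/land-use, fit by Newton-Raphson with Wald odds
ratios; and CDC bottle-bioassay metrics (knockdown-vs-time OLS, slope-equality
ANCOVA, 45-min resistance ratios, the 90%-at-120-min classification rule).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import expit, gammaln

GENOTYPE_ORDER = ("LL", "LF", "FF")  # ordinal outcome: susceptible .. resistant


# --- Allele frequency (resistance allele F at codon 1014) --------------------

@dataclass(frozen=True)
class AlleleFrequencyEstimate:
    """F_(FF,LF) = (2 N_FF + N_LF) / 2N with SE = sqrt(F(1-F)/2N)
    (binomial on the 2N sampled alleles)."""

    f: float
    se: float
    n_individuals: int

    def rounded(self, ndigits: int = 2) -> float:
        return round(self.f, ndigits)


def allele_frequency(n_ll: int, n_lf: int, n_ff: int) -> AlleleFrequencyEstimate:
    n = n_ll + n_lf + n_ff
    if n <= 0:
        raise ValueError("empty genotype count row")
    if min(n_ll, n_lf, n_ff) < 0:
        raise ValueError("negative genotype count")
    f = Fraction(2 * n_ff + n_lf, 2 * n)
    f_float = float(f)
    se = math.sqrt(f_float * (1.0 - f_float) / (2 * n))
    return AlleleFrequencyEstimate(f=f_float, se=se, n_individuals=n)


# --- Concordance -------------------------------------------------------------

@dataclass
class ConcordanceResult:
    n_total: int
    n_valid: int
    n_concordant: int
    percent: float
    confusion: pd.DataFrame  # rows = assay A, columns = assay B


def concordance(
    calls_a: dict[str, str],
    calls_b: dict[str, str],
    exclude: set[str] = frozenset({"EXCLUDED"}),
) -> ConcordanceResult:
    """Agreement between two call sets over shared specimen ids, after
    dropping specimens either assay excluded."""
    shared = sorted(set(calls_a) & set(calls_b))
    if not shared:
        raise ValueError("no shared specimen ids")
    valid = [s for s in shared if calls_a[s] not in exclude and calls_b[s] not in exclude]
    n_conc = sum(calls_a[s] == calls_b[s] for s in valid)
    labels = sorted({calls_a[s] for s in valid} | {calls_b[s] for s in valid})
    conf = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for s in valid:
        conf.loc[calls_a[s], calls_b[s]] += 1
    pct = 100.0 * n_conc / len(valid) if valid else float("nan")
    return ConcordanceResult(
        n_total=len(shared), n_valid=len(valid), n_concordant=n_conc,
        percent=pct, confusion=conf,
    )


# --- Fisher's exact test on r x c tables -------------------------------------

class EnumerationBudgetExceeded(RuntimeError):
    """Raised when exact enumeration would visit more tables than the budget;
    use fisher_exact_mc for a seeded Monte-Carlo p-value instead."""


def _drop_zero_margins(table: np.ndarray) -> np.ndarray:
    t = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    return t


def _log_pointprob(table: np.ndarray, lognum: float) -> float:
    return lognum - gammaln(table + 1).sum()


def fisher_exact_rxc(
    table, budget: int = 10**7, slack: float = 1e-12
) -> float:
    """Two-sided Fisher exact p for an r x c count table with fixed margins:
    the sum of probabilities of all margin-preserving tables whose point
    probability is at or below the observed one (classical "as or more
    extreme" rule). All-zero rows/columns are dropped first.
    """
    obs = np.asarray(table, dtype=int)
    if obs.ndim != 2 or (obs < 0).any():
        raise ValueError("table must be a 2-D nonnegative count array")
    obs = _drop_zero_margins(obs)
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        return 1.0  # no free cells: the observed table is the only table

    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    n = obs.sum()
    lognum = gammaln(rows + 1).sum() + gammaln(cols + 1).sum() - gammaln(n + 1)

    logp_obs = _log_pointprob(obs, lognum)
    cutoff = logp_obs + math.log1p(slack)

    r, c = obs.shape
    p_total = 0.0
    p_extreme = 0.0
    visited = 0

    work = np.zeros((r, c), dtype=int)
    colrem = cols.copy()

    def recurse(i: int, logfac_acc: float):
        nonlocal p_total, p_extreme, visited
        if i == r - 1:
            # last row forced by column margins
            if (colrem < 0).any():
                return
            visited += 1
            if visited > budget:
                raise EnumerationBudgetExceeded(
                    f"more than {budget} tables; use fisher_exact_mc"
                )
            logp = lognum - logfac_acc - gammaln(colrem + 1).sum()
            p = math.exp(logp)
            p_total += p
            if logp <= cutoff:
                p_extreme += p
            return
        fill_row(i, 0, rows[i], logfac_acc)

    def fill_row(i: int, j: int, rowrem: int, logfac_acc: float):
        if j == c - 1:
            if rowrem > colrem[j]:
                return
            work[i, j] = rowrem
            colrem[j] -= rowrem
            recurse(i + 1, logfac_acc + gammaln(rowrem + 1))
            colrem[j] += rowrem
            return
        hi = min(rowrem, colrem[j])
        for v in range(hi + 1):
            work[i, j] = v
            colrem[j] -= v
            fill_row(i, j + 1, rowrem - v, logfac_acc + gammaln(v + 1))
            colrem[j] += v

    recurse(0, 0.0)
    if not math.isclose(p_total, 1.0, rel_tol=1e-9):
        warnings.warn(f"enumeration total probability {p_total} != 1")
    return min(p_extreme, 1.0)


def fisher_exact_mc(
    table, n_resamples: int = 10**5, seed: int | None = None
) -> float:
    """Seeded Monte-Carlo Fisher p: sample margin-fixed tables and apply the
    same point-probability extremeness rule, with the +1 continuity
    correction (p can never be exactly 0)."""
    obs = _drop_zero_margins(np.asarray(table, dtype=int))
    rows, cols = obs.sum(axis=1), obs.sum(axis=0)
    n = obs.sum()
    lognum = gammaln(rows + 1).sum() + gammaln(cols + 1).sum() - gammaln(n + 1)
    logp_obs = _log_pointprob(obs, lognum)
    rng = np.random.default_rng(seed)
    dist = sps.random_table(rows, cols)
    samples = dist.rvs(n_resamples, random_state=rng)
    logps = lognum - gammaln(samples + 1).sum(axis=(1, 2))
    hits = int(np.sum(logps <= logp_obs + 1e-9))
    return (hits + 1) / (n_resamples + 1)


# --- Proportional-odds (cumulative logit) ordinal regression -----------------

@dataclass
class OrdinalFit:
    """Maximum-likelihood proportional-odds fit.

    Parameterisation follows the convention logit P(Y <= j | x) = alpha_j - x'beta,
    so beta > 0 shifts mass toward the resistant end of the outcome and
    exp(beta) is the odds ratio of being in a more resistant category.
    """

    cutpoints: np.ndarray
    coef: dict[str, float]
    cov: np.ndarray          # covariance of (cutpoints, coefs)
    se: dict[str, float]
    odds_ratios: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    p_values: dict[str, float]
    loglik: float
    converged: bool
    n_iter: int


def _po_loglik_grad(theta, X, counts):
    """Log-likelihood and analytic gradient for grouped ordinal data.

    X: (G, p) covariate rows; counts: (G, J) outcome counts per row.
    theta = [alpha_1..alpha_{J-1}, beta_1..beta_p].
    """
    G, J = counts.shape
    p = X.shape[1]
    alpha = theta[: J - 1]
    beta = theta[J - 1 :]
    eta = X @ beta  # (G,)

    # cumulative probs with 0 and 1 padding
    cum = np.empty((G, J + 1))
    cum[:, 0] = 0.0
    cum[:, -1] = 1.0
    cum[:, 1:J] = expit(alpha[None, :] - eta[:, None])
    pi = np.diff(cum, axis=1)
    pi = np.clip(pi, 1e-300, None)
    ll = float(np.sum(counts * np.log(pi)))

    # d cum_j / d alpha_k = delta_jk * s_j ; d cum_j / d beta = -x * s_j
    s = np.zeros((G, J + 1))
    s[:, 1:J] = cum[:, 1:J] * (1.0 - cum[:, 1:J])
    w = counts / pi  # (G, J)

    grad = np.zeros_like(theta)
    for j in range(J):
        coeff = w[:, j]
        # alpha parts: cum_{j+1} has alpha index j (if j < J-1), cum_j has j-1
        if j < J - 1:
            grad[j] += np.sum(coeff * s[:, j + 1])
        if j >= 1:
            grad[j - 1] -= np.sum(coeff * s[:, j])
        dbeta = -(s[:, j + 1] - s[:, j]) * coeff
        grad[J - 1 :] += X.T @ dbeta
    return ll, grad


def _numeric_hessian(theta, X, counts, h: float = 1e-6):
    k = theta.size
    H = np.zeros((k, k))
    for i in range(k):
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h
        tm[i] -= h
        _, gp = _po_loglik_grad(tp, X, counts)
        _, gm = _po_loglik_grad(tm, X, counts)
        H[i] = (gp - gm) / (2 * h)
    return (H + H.T) / 2.0


def fit_proportional_odds(
    X,
    counts,
    coef_names: list[str] | None = None,
    max_iter: int = 100,
    grad_tol: float = 1e-8,
    ll_tol: float = 1e-10,
    z: float = 1.959963984540054,
) -> OrdinalFit:
    """Fit logit P(Y<=j) = alpha_j - x'beta to grouped counts by Newton-Raphson.

    ``X`` is a (groups x p) design matrix (no intercept column: the cutpoints
    play that role); ``counts`` is (groups x J) with outcome categories
    ordered susceptible -> resistant. Wald CIs use the normal reference
    (the z default is the exact 97.5% point; 1.96 in reports).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    G, J = counts.shape
    p = X.shape[1]
    if X.shape[0] != G:
        raise ValueError("X and counts disagree on the number of groups")
    if J < 2:
        raise ValueError("need at least two outcome categories")
    if coef_names is None:
        coef_names = [f"x{i}" for i in range(p)]

    # init: pooled empirical cumulative logits, beta = 0
    pooled = counts.sum(axis=0)
    cum = np.cumsum(pooled)[:-1] / pooled.sum()
    cum = np.clip(cum, 1e-6, 1 - 1e-6)
    theta = np.concatenate([np.log(cum / (1 - cum)), np.zeros(p)])

    ll, grad = _po_loglik_grad(theta, X, counts)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        H = _numeric_hessian(theta, X, counts)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # Newton step (H is negative definite near the optimum)
        scale = 1.0
        for _ in range(30):
            cand = theta - scale * step
            ll_new, grad_new = _po_loglik_grad(cand, X, counts)
            if ll_new >= ll - 1e-12:
                break
            scale /= 2.0
        theta, ll_prev, ll, grad = cand, ll, ll_new, grad_new
        if np.max(np.abs(grad)) < grad_tol or abs(ll - ll_prev) < ll_tol * (abs(ll) + 1):
            converged = True
            break

    cutpoints = theta[: J - 1]
    beta = theta[J - 1 :]
    if not np.all(np.diff(cutpoints) > 0):
        converged = False
        warnings.warn("cutpoints not strictly ascending: fit is degenerate")
    if not converged:
        warnings.warn("proportional-odds fit did not converge")

    H = _numeric_hessian(theta, X, counts)
    cov = np.linalg.inv(-H)
    se_all = np.sqrt(np.clip(np.diag(cov), 0, None))
    se_beta = se_all[J - 1 :]

    coef = dict(zip(coef_names, beta))
    se = dict(zip(coef_names, se_beta))
    odds = {k: math.exp(v) for k, v in coef.items()}
    ci_lo = {k: math.exp(coef[k] - z * se[k]) for k in coef}
    ci_hi = {k: math.exp(coef[k] + z * se[k]) for k in coef}
    pvals = {
        k: 2.0 * (1.0 - sps.norm.cdf(abs(coef[k] / se[k]))) if se[k] > 0 else float("nan")
        for k in coef
    }
    return OrdinalFit(
        cutpoints=cutpoints, coef=coef, cov=cov, se=se,
        odds_ratios=odds, ci_low=ci_lo, ci_high=ci_hi, p_values=pvals,
        loglik=ll, converged=converged, n_iter=it,
    )


def fit_proportional_odds_counts(
    rows: dict[str, tuple[int, int, int]],
    reference: str,
    coef_prefix: str = "",
) -> OrdinalFit:
    """Convenience wrapper: one categorical covariate given as
    {level: (n_LL, n_LF, n_FF)} count rows with a named reference level.
    Dummy coding; coefficient names are ``coef_prefix + level``."""
    if reference not in rows:
        raise ValueError(f"reference level {reference!r} not among rows")
    others = [lvl for lvl in rows if lvl != reference]
    levels = [reference] + others
    X = np.zeros((len(levels), len(others)))
    for i, lvl in enumerate(levels[1:], start=1):
        X[i, i - 1] = 1.0
    counts = np.array([rows[lvl] for lvl in levels], dtype=float)
    return fit_proportional_odds(X, counts, coef_names=[coef_prefix + o for o in others])


# --- Bottle bioassay ---------------------------------------------------------

@dataclass
class BioassayResult:
    """Cumulative knockdown for one strain x insecticide, pooled over bottles.

    ``counts`` maps time (minutes) -> total knocked down; ``n_total`` is the
    number of mosquitoes across bottles.
    """

    strain: str
    insecticide: str
    n_total: int
    counts: dict[int, int] = field(default_factory=dict)

    def __post_init__(self):
        times = sorted(self.counts)
        vals = [self.counts[t] for t in times]
        if any(b < a for a, b in zip(vals, vals[1:])):
            raise ValueError("cumulative knockdown counts must be nondecreasing")
        if vals and vals[-1] > self.n_total:
            raise ValueError("knockdown count exceeds number of mosquitoes")

    def proportion(self, minute: int) -> float:
        return self.counts[minute] / self.n_total

    def percents(self) -> tuple[np.ndarray, np.ndarray]:
        times = np.array(sorted(self.counts), dtype=float)
        pct = np.array([100.0 * self.counts[int(t)] / self.n_total for t in times])
        return times, pct


@dataclass(frozen=True)
class RegressionLine:
    slope: float       # percent per minute
    intercept: float   # percent
    r_squared: float
    residual_ss: float


def knockdown_regression(times, percents) -> RegressionLine:
    """OLS of cumulative knockdown percent on time (minutes)."""
    x = np.asarray(times, dtype=float)
    y = np.asarray(percents, dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("need at least two distinct timepoints")
    res = sps.linregress(x, y)
    resid = y - (res.slope * x + res.intercept)
    return RegressionLine(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        residual_ss=float(np.sum(resid**2)),
    )


def ancova_slopes(x1, y1, x2, y2) -> tuple[float, tuple[int, int], float]:
    """Slope-equality ANCOVA for two groups sharing a predictor.

    Compares the full model (separate intercepts and slopes, 4 parameters)
    against the reduced model (separate intercepts, common slope):
    F = (SSE_reduced - SSE_full) / (SSE_full / (n - 4)) on (1, n-4) df.
    """
    x1, y1 = np.asarray(x1, float), np.asarray(y1, float)
    x2, y2 = np.asarray(x2, float), np.asarray(y2, float)
    n = x1.size + x2.size
    if n < 5 or np.unique(x1).size < 2 or np.unique(x2).size < 2:
        raise ValueError("degenerate ANCOVA design")

    def sse(x, y, slope=None):
        if slope is None:
            r = sps.linregress(x, y)
            return float(np.sum((y - (r.slope * x + r.intercept)) ** 2))
        a = np.mean(y) - slope * np.mean(x)
        return float(np.sum((y - (slope * x + a)) ** 2))

    sse_full = sse(x1, y1) + sse(x2, y2)
    # reduced: common slope, separate intercepts (pooled within-group OLS)
    xc1, xc2 = x1 - x1.mean(), x2 - x2.mean()
    yc1, yc2 = y1 - y1.mean(), y2 - y2.mean()
    common = float((xc1 @ yc1 + xc2 @ yc2) / (xc1 @ xc1 + xc2 @ xc2))
    sse_red = sse(x1, y1, common) + sse(x2, y2, common)

    df2 = n - 4
    if sse_full <= 0:  # noiseless inputs
        f = 0.0 if math.isclose(sse_red, sse_full, abs_tol=1e-18) else float("inf")
    else:
        f = (sse_red - sse_full) / (sse_full / df2)
        f = max(f, 0.0)
    p = float(sps.f.sf(f, 1, df2)) if math.isfinite(f) else 0.0
    return f, (1, df2), p


def resistance_ratio(
    reference: BioassayResult | float,
    test: BioassayResult | float,
    at_minute: int = 45,
) -> float:
    """Resistance ratio at a fixed time: susceptible-strain knockdown
    proportion over resistant(test)-strain knockdown proportion. A zero test
    proportion returns inf with a warning."""
    ref_p = reference.proportion(at_minute) if isinstance(reference, BioassayResult) else float(reference)
    test_p = test.proportion(at_minute) if isinstance(test, BioassayResult) else float(test)
    for name, v in (("reference", ref_p), ("test", test_p)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} proportion {v} outside [0, 1]")
    if test_p == 0.0:
        warnings.warn("test-strain knockdown proportion is 0: infinite resistance ratio")
        return float("inf")
    return ref_p / test_p


def classify_cdc_resistance(knockdown_at_120: float) -> str:
    """CDC bottle-bioassay rule: knockdown below 90% at 120 min flags the
    population as suspected resistant."""
    if not (0.0 <= knockdown_at_120 <= 1.0):
        raise ValueError("knockdown proportion must be in [0, 1]")
    return "resistant_suspected" if knockdown_at_120 < 0.90 else "susceptible"
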