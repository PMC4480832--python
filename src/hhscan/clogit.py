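"""Stratified (conditional) logistic regression with an exact likelihood.

Each stratum is one gene or intergenic region; the likelihood of the eQTL
flags is conditioned on the number of flagged SNPs per stratum, exactly as
in 1-to-many matched case-control designs. The conditional likelihood is
computed exactly: strata with a single case reduce to a per-stratum
softmax, and multi-case strata use the standard recursion over the
elementary-symmetric-type sums, so no Breslow-style approximation is made
at any stratum size.

Model terms follow the study's formula syntax: ``y ~ a + b:g + location``
where ``b:g`` (also written ``b×g``) fits one slope of the numeric
predictor ``b`` per level of the categorical ``g``. Because the stratifying
gene determines its category level, such interactions are the natural way
to let an effect vary by gene class while the stratum absorbs the class
main effect (which is not identifiable conditionally).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

logger = logging.getLogger(__name__)

SEPARATION_BOUND = 50.0
MAX_ITER = 50
REL_TOL = 1e-9


@dataclass(frozen=True)
class ModelSpec:
    """A conditional-logistic model: response, terms, stratum variable.

    Terms are column names; ``(a, b)`` tuples denote an interaction whose
    numeric member gets one slope per level of the categorical member.
    """

    response: str
    terms: tuple
    strata: str = "stratum"


def parse_formula(formula: str, strata: str = "stratum") -> ModelSpec:
    """Parse ``"eqtl ~ hh:go + ddaf + maf:go + location"`` into a ModelSpec.

    ``:``, ``*`` and ``×`` all denote the per-level-slope interaction.
    """
    lhs, _, rhs = formula.partition("~")
    if not rhs:
        raise ValueError(f"formula {formula!r} has no '~'")
    terms = []
    for raw in rhs.split("+"):
        raw = raw.strip()
        if not raw:
            continue
        parts = [p.strip() for p in re.split(r"[:*×]", raw)]
        if len(parts) == 1:
            terms.append(parts[0])
        elif len(parts) == 2:
            terms.append((parts[0], parts[1]))
        else:
            raise ValueError(f"cannot parse term {raw!r}")
    return ModelSpec(response=lhs.strip(), terms=tuple(terms), strata=strata)


# reference levels preferred per categorical variable, when present
_PREFERRED_REFERENCE = {"location": "intronic", "go": "OTHER", "group": "neither"}


@dataclass
class Design:
    """Expanded design matrix with stratum bookkeeping (rows sorted by stratum)."""

    X: np.ndarray
    names: list[str]
    y: np.ndarray
    strata: np.ndarray  # contiguous integer codes, sorted ascending
    starts: np.ndarray  # first row of each stratum
    counts: np.ndarray  # rows per stratum
    cases: np.ndarray  # cases per stratum
    dropped: list[str] = field(default_factory=list)
    index: pd.Index | None = None


def _reference_level(name: str, levels: Sequence[str]) -> str:
    pref = _PREFERRED_REFERENCE.get(name)
    if pref is not None and pref in levels:
        return pref
    return pd.Series(list(levels)).mode().iloc[0]


def build_design(df: pd.DataFrame, spec: ModelSpec) -> Design:
    """Expand a ModelSpec against a stratified dataset.

    Categorical main effects are dummy-coded against a reference level
    (intronic for location when present, else the most frequent level).
    A numeric x categorical interaction expands to one slope column per
    observed level; the reference-level slope is kept unless the numeric
    main effect is also in the model. Rows with missing predictor values
    are dropped (counted), as are strata left without both a case and a
    control; columns constant within every stratum are dropped with a
    warning since they are not identifiable conditionally.
    """
    for t in spec.terms:
        for col in (t if isinstance(t, tuple) else (t,)):
            if col not in df.columns:
                raise KeyError(f"model term references absent column {col!r}")
    if spec.response not in df.columns or spec.strata not in df.columns:
        raise KeyError("response or stratum column absent from dataset")

    main_numeric = {t for t in spec.terms if not isinstance(t, tuple)
                    and pd.api.types.is_numeric_dtype(df[t])}
    cols: list[np.ndarray] = []
    names: list[str] = []
    for t in spec.terms:
        if isinstance(t, tuple):
            a, b = t
            num, cat = (a, b) if pd.api.types.is_numeric_dtype(df[a]) else (b, a)
            levels = sorted(df[cat].astype(str).unique())
            drop_ref = num in main_numeric
            ref = _reference_level(cat, levels) if drop_ref else None
            x = df[num].to_numpy(dtype=float)
            for lev in levels:
                if lev == ref:
                    continue
                cols.append(np.where(df[cat].astype(str) == lev, x, 0.0))
                names.append(f"{num}:{cat}={lev}")
        elif pd.api.types.is_numeric_dtype(df[t]):
            cols.append(df[t].to_numpy(dtype=float))
            names.append(t)
        else:
            levels = sorted(df[t].astype(str).unique())
            ref = _reference_level(t, levels)
            for lev in levels:
                if lev == ref:
                    continue
                cols.append((df[t].astype(str) == lev).to_numpy(dtype=float))
                names.append(f"{t}={lev}")

    X = np.column_stack(cols) if cols else np.empty((len(df), 0))
    y = df[spec.response].to_numpy()
    y = y.astype(bool) if y.dtype != bool else y

    keep = ~np.isnan(X).any(axis=1)
    n_missing = int((~keep).sum())
    if n_missing:
        logger.info("dropping %d rows with missing predictor values", n_missing)
    X, y = X[keep], y[keep]
    strata_raw = df[spec.strata].to_numpy()[keep]
    idx = df.index[keep]

    codes, _ = pd.factorize(strata_raw, sort=False)
    order = np.argsort(codes, kind="stable")
    X, y, codes, idx = X[order], y[order], codes[order], idx[order]

    # keep only informative strata (>=1 case and >=1 control)
    counts = np.bincount(codes)
    cases = np.bincount(codes, weights=y.astype(float)).astype(int)
    ok = (cases > 0) & (cases < counts)
    keep_rows = ok[codes]
    if not keep_rows.all():
        logger.info("dropping %d strata without case/control contrast",
                    int((~ok).sum()))
    X, y, idx = X[keep_rows], y[keep_rows], idx[keep_rows]
    codes, _ = pd.factorize(codes[keep_rows], sort=True)
    counts = np.bincount(codes)
    cases = np.bincount(codes, weights=y.astype(float)).astype(int)
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])

    # drop columns constant within every stratum
    dropped: list[str] = []
    if X.shape[1]:
        first = X[starts]
        dev = np.abs(X - np.repeat(first, counts, axis=0)).max(axis=0)
        const = dev == 0
        if const.any():
            dropped = [n for n, c in zip(names, const) if c]
            logger.warning(
                "dropping %d column(s) constant within every stratum: %s",
                len(dropped), dropped,
            )
            X = X[:, ~const]
            names = [n for n, c in zip(names, const) if not c]
    if not names:
        raise ValueError("all model terms were dropped; nothing to fit")
    return Design(X=X, names=names, y=y, strata=codes, starts=starts,
                  counts=counts, cases=cases, dropped=dropped, index=idx)


# ---------------------------------------------------------------------------
# exact conditional likelihood


def _stratum_recursion(eta: np.ndarray, X: np.ndarray, k: int,
                       want_derivs: bool) -> tuple:
    """Exact denominator sum over case subsets of size k, with derivatives.

    Returns (log f_k, dlog, d2log) where f_k = sum over subsets S of size k
    of exp(sum_{i in S} eta_i), computed by the standard one-pass recursion;
    dlog/d2log are its log-gradient/Hessian contributions in beta space.
    """
    n, p = X.shape
    shift = eta.max()
    w = np.exp(eta - shift)
    f = np.zeros(k + 1)
    f[0] = 1.0
    if want_derivs:
        g = np.zeros((k + 1, p))
        h = np.zeros((k + 1, p, p))
        for i in range(n):
            xi = X[i]
            wi = w[i]
            xo = np.outer(xi, xi)
            for j in range(min(i + 1, k), 0, -1):
                h[j] += wi * (h[j - 1]
                              + np.outer(g[j - 1], xi) + np.outer(xi, g[j - 1])
                              + f[j - 1] * xo)
                g[j] += wi * (g[j - 1] + f[j - 1] * xi)
                f[j] += wi * f[j - 1]
        grad = g[k] / f[k]
        hess = h[k] / f[k] - np.outer(grad, grad)
        return np.log(f[k]) + k * shift, grad, hess
    for i in range(n):
        wi = w[i]
        for j in range(min(i + 1, k), 0, -1):
            f[j] += wi * f[j - 1]
    return np.log(f[k]) + k * shift, None, None


def _cll(beta: np.ndarray, d: Design, want_derivs: bool = True):
    """Exact conditional log-likelihood (and derivatives) at beta."""
    eta = d.X @ beta
    ll = float(eta[d.y].sum())
    grad = d.X[d.y].sum(axis=0) if want_derivs else None
    hess = np.zeros((len(beta), len(beta))) if want_derivs else None

    single = d.cases == 1
    if single.any():
        rows = np.repeat(single, d.counts)
        Xs, es = d.X[rows], eta[rows]
        starts = np.concatenate([[0], np.cumsum(d.counts[single])[:-1]])
        mx = np.maximum.reduceat(es, starts)
        grp = np.repeat(np.arange(single.sum()), d.counts[single])
        w = np.exp(es - mx[grp])
        denom = np.add.reduceat(w, starts)
        ll -= float(np.sum(np.log(denom) + mx))
        if want_derivs:
            P = w / denom[grp]
            PX = P[:, None] * Xs
            M = np.add.reduceat(PX, starts, axis=0)  # mu_g per stratum
            grad -= PX.sum(axis=0)
            hess -= Xs.T @ PX - M.T @ M

    for s in np.where(~single)[0]:
        sl = slice(d.starts[s], d.starts[s] + d.counts[s])
        logf, gr, he = _stratum_recursion(eta[sl], d.X[sl], int(d.cases[s]),
                                          want_derivs)
        ll -= logf
        if want_derivs:
            grad -= gr
            hess -= he
    return (ll, grad, hess) if want_derivs else ll


def conditional_loglik(beta, X, strata, case_flags) -> float:
    """Exact conditional log-likelihood of ``case_flags`` given per-stratum
    case counts, at coefficient vector ``beta``.

    Every stratum must contain at least one case and one control.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(case_flags).astype(bool)
    codes, _ = pd.factorize(np.asarray(strata), sort=False)
    order = np.argsort(codes, kind="stable")
    X, y, codes = X[order], y[order], codes[order]
    counts = np.bincount(codes)
    cases = np.bincount(codes, weights=y.astype(float)).astype(int)
    if np.any(cases == 0) or np.any(cases == counts):
        raise ValueError(
            "every stratum needs >=1 case and >=1 control "
            "(filter strata before computing the likelihood)"
        )
    d = Design(X=X, names=[f"x{i}" for i in range(X.shape[1])], y=y,
               strata=codes, starts=np.concatenate([[0], np.cumsum(counts)[:-1]]),
               counts=counts, cases=cases)
    return _cll(np.asarray(beta, dtype=float), d, want_derivs=False)


def null_loglik(counts: np.ndarray, cases: np.ndarray) -> float:
    """Closed form at beta = 0: -sum ln C(n_s, k_s)."""
    from scipy.special import gammaln

    n, k = np.asarray(counts, float), np.asarray(cases, float)
    return float(-np.sum(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)))


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FitResult:
    """One conditional-logistic fit: per-term effects and diagnostics."""

    params: pd.Series  # beta (log-odds per unit predictor)
    bse: pd.Series  # standard errors from inverse observed information
    llf: float
    llnull: float
    converged: bool
    message: str
    n_strata: int
    n_obs: int
    dropped: list[str]

    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.bse

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"beta": self.params, "se": self.bse, "z": self.zvalues}
        )


def fit(dataset: pd.DataFrame | Design, spec: ModelSpec | None = None,
        max_iter: int = MAX_ITER, tol: float = REL_TOL) -> FitResult:
    """Newton-type maximisation of the exact conditional likelihood.

    Non-convergence is reported through the ``converged`` flag and
    ``message`` (monotone-likelihood/separation is detected by a coefficient
    escaping +-50 with the likelihood still rising), never silently.
    """
    d = dataset if isinstance(dataset, Design) else build_design(dataset, spec)
    p = d.X.shape[1]
    beta = np.zeros(p)
    ll, grad, hess = _cll(beta, d)
    llnull = ll
    converged, message = False, "maximum iterations reached"
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(-hess, grad, rcond=None)[0]
        new_ll = -np.inf
        for _half in range(30):
            cand = beta + step
            new_ll, new_grad, new_hess = _cll(cand, d)
            if new_ll >= ll - 1e-12:
                break
            step = step / 2.0
        if not np.isfinite(new_ll) or new_ll < ll - 1e-8:
            message = "line search failed"
            break
        beta, delta = cand, new_ll - ll
        ll, grad, hess = new_ll, new_grad, new_hess
        if np.abs(beta).max() > SEPARATION_BOUND:
            message = "separation detected (coefficient diverging)"
            break
        if ll > -1e-8:
            # conditional likelihood numerically 1: every case set is
            # perfectly predicted, the textbook separation signature
            message = "separation detected (perfect prediction)"
            break
        if delta < tol * (abs(ll) + 1.0):
            converged, message = True, "converged"
            break

    cov = None
    try:
        cov = np.linalg.inv(-hess)
        se = np.sqrt(np.diag(cov))
        if not np.all(np.isfinite(se)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        if converged:
            converged, message = False, "singular information matrix"
    return FitResult(
        params=pd.Series(beta, index=d.names),
        bse=pd.Series(se, index=d.names),
        llf=ll,
        llnull=llnull,
        converged=converged,
        message=message,
        n_strata=len(d.counts),
        n_obs=len(d.y),
        dropped=list(d.dropped),
    )


def wald_contrast(beta1: float, se1: float, beta2: float, se2: float
                  ) -> tuple[float, float]:
    """z and two-tailed normal p for beta1 - beta2 with independent errors."""
    denom = np.hypot(se1, se2)
    if denom == 0:
        raise ValueError("both standard errors are zero; contrast undefined")
    z = (beta1 - beta2) / denom
    return float(z), float(2 * norm.sf(abs(z)))


def compare_group_effects(result: FitResult, term1: str, term2: str
                          ) -> tuple[float, float]:
    """Two-tailed test of equality of two fitted slopes (e.g. the score's
    effect in group 1 vs group 2)."""
    for t in (term1, term2):
        if t not in result.params.index or not np.isfinite(result.bse[t]):
            raise KeyError(f"slope {t!r} not estimated in this fit")
    return wald_contrast(result.params[term1], result.bse[term1],
                         result.params[term2], result.bse[term2])
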