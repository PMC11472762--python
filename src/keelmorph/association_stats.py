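"""Latent-normal correlation machinery and group comparisons.

Ordinal keel scores are modelled as discretisations of underlying
(approximately) normal variables: a score of j is observed when the
latent variable falls between thresholds tau_{j-1} and tau_j.  Under
that model the association between two ordinal variables is the
*polychoric* correlation, and between a continuous and an ordinal
variable the *polyserial* correlation.  Both are estimated here by
one-stage maximum likelihood over (rho, thresholds); standard errors
come from the inverse observed information.

Also provided: Pearson correlation with its large-sample standard
error sqrt((1 - r^2)/(n - 2)) for the longitudinal cross-age matrices,
and one-way ANOVA + Tukey HSD with a compact-letter display for
comparing the keel length:mid-depth ratio across damage-score groups.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import owens_t

log = logging.getLogger("keelmorph")

RHO_BOUNDARY = 0.9999
_TINY = 1e-300


@dataclass
class CorrelationEstimate:
    """A correlation with its standard error and estimation context."""

    rho: float
    se: float
    method: str  # polychoric | polyserial | pearson
    n: int
    thresholds_x: tuple = ()
    thresholds_y: tuple = ()
    at_boundary: bool = False
    converged: bool = True

    def __post_init__(self) -> None:
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError(f"|rho| must be <= 1, got {self.rho}")
        for th in (self.thresholds_x, self.thresholds_y):
            if len(th) > 1 and not np.all(np.diff(th) > 0):
                raise ValueError("thresholds must be strictly increasing")

    def __repr__(self) -> str:  # compact, Table-3 style
        return (f"{self.method}(rho={self.rho:+.3f} ± {self.se:.3f}, "
                f"n={self.n})")


# ---------------------------------------------------------------------------
# Bivariate normal CDF (Owen's T formulation; vectorised, abs err < 1e-7)

def bvn_cdf(h, k, rho: float):
    """P(X <= h, Y <= k) for standard bivariate normal with correlation rho.

    Uses the exact Owen's-T decomposition; accepts scalars or arrays in
    ``h``/``k`` (broadcast), and +-inf limits.
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    h, k = np.broadcast_arrays(h, k)
    rho = float(rho)
    if not -1.0 <= rho <= 1.0:
        raise ValueError("|rho| must be <= 1")
    if rho == 1.0:
        out = stats.norm.cdf(np.minimum(h, k))
        return out if out.ndim else float(out)
    if rho == -1.0:
        out = np.clip(stats.norm.cdf(h) + stats.norm.cdf(k) - 1.0, 0.0, 1.0)
        return out if out.ndim else float(out)
    if rho == 0.0:
        out = stats.norm.cdf(h) * stats.norm.cdf(k)
        return out if out.ndim else float(out)

    out = np.empty(h.shape, dtype=float)
    flat_h, flat_k, flat_o = h.ravel(), k.ravel(), out.ravel()

    # infinite limits reduce to univariate margins
    inf_mask = np.isinf(flat_h) | np.isinf(flat_k)
    if inf_mask.any():
        hh, kk = flat_h[inf_mask], flat_k[inf_mask]
        flat_o[inf_mask] = np.where(
            (hh == -np.inf) | (kk == -np.inf), 0.0,
            np.where(hh == np.inf, stats.norm.cdf(kk), stats.norm.cdf(hh)))

    fin = ~inf_mask
    hh, kk = flat_h[fin].copy(), flat_k[fin].copy()
    # Owen's-T decomposition is singular at exact zeros; the CDF is
    # continuous, so a 1e-13 nudge keeps full single-double accuracy.
    hh[hh == 0.0] = 1e-13
    kk[kk == 0.0] = 1e-13
    r1 = np.sqrt(1.0 - rho * rho)
    t_h = owens_t(hh, (kk - rho * hh) / (hh * r1))
    t_k = owens_t(kk, (hh - rho * kk) / (kk * r1))
    beta = np.where(hh * kk < 0, 0.5, 0.0)
    val = 0.5 * (stats.norm.cdf(hh) + stats.norm.cdf(kk)) - t_h - t_k - beta
    flat_o[fin] = np.clip(val, 0.0, 1.0)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Numerical helpers

def _num_hessian(f, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of scalar f at x."""
    x = np.asarray(x, dtype=float)
    p = x.size
    H = np.empty((p, p))
    f0 = f(x)
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = eps
            ej = np.zeros(p); ej[j] = eps
            if i == j:
                H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / eps**2
            else:
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej)
                    - f(x - ei + ej) + f(x - ei - ej)) / (4 * eps**2)
    return H


def _se_from_information(negloglik, params: np.ndarray, rho_index: int) -> float:
    """SE of rho from the inverse observed information; NaN on failure."""
    try:
        H = _num_hessian(negloglik, params)
        cov = np.linalg.inv(H)
        var = cov[rho_index, rho_index]
        return float(np.sqrt(var)) if var > 0 else float("nan")
    except np.linalg.LinAlgError:
        return float("nan")


def _ordinal_codes(v) -> tuple[np.ndarray, int]:
    """Map an ordinal vector to consecutive codes 0..K-1 preserving order."""
    v = np.asarray(v)
    cats = np.unique(v)
    codes = np.searchsorted(cats, v)
    return codes, len(cats)


def _margin_thresholds(codes: np.ndarray, k: int) -> np.ndarray:
    """Threshold start values from marginal cumulative proportions."""
    n = codes.size
    cum = np.cumsum(np.bincount(codes, minlength=k))[:-1] / n
    cum = np.clip(cum, 1.0 / (2 * n), 1 - 1.0 / (2 * n))
    return stats.norm.ppf(cum)


# ---------------------------------------------------------------------------
# Polychoric

def _cell_probs(rho: float, tx: np.ndarray, ty: np.ndarray) -> np.ndarray:
    ax = np.concatenate([[-np.inf], tx, [np.inf]])
    ay = np.concatenate([[-np.inf], ty, [np.inf]])
    H, K = np.meshgrid(ax, ay, indexing="ij")
    F = bvn_cdf(H, K, rho)
    return F[1:, 1:] - F[:-1, 1:] - F[1:, :-1] + F[:-1, :-1]


def polychoric(x, y, two_step: bool = False) -> CorrelationEstimate:
    """ML polychoric correlation between two ordinal vectors.

    One-stage ML jointly maximises the multinomial likelihood of the
    contingency table over (rho, thresholds_x, thresholds_y).  With
    ``two_step=True`` the thresholds are fixed at their marginal
    estimates and only rho is optimised (cross-check variant).
    """
    cx, kx = _ordinal_codes(x)
    cy, ky = _ordinal_codes(y)
    if cx.size != cy.size:
        raise ValueError("x and y must have equal length")
    n = cx.size
    if n < 10:
        raise ValueError("need at least 10 observations")
    if kx < 2 or ky < 2:
        raise ValueError("each margin needs at least 2 observed categories")
    table = np.zeros((kx, ky))
    np.add.at(table, (cx, cy), 1.0)

    tx0 = _margin_thresholds(cx, kx)
    ty0 = _margin_thresholds(cy, ky)

    # perfect concordance/discordance leaves no interior information
    def _loglik(rho, tx, ty):
        P = np.clip(_cell_probs(rho, tx, ty), _TINY, 1.0)
        return float(np.sum(table * np.log(P)))

    def _unpack(params):
        z = params[0]
        rho = np.tanh(z)
        tx = np.concatenate([[params[1]],
                             params[1] + np.cumsum(np.exp(params[2:1 + kx - 1]))]) \
            if kx > 2 else params[1:2]
        off = 1 + (kx - 1)
        ty = np.concatenate([[params[off]],
                             params[off] + np.cumsum(np.exp(params[off + 1:]))]) \
            if ky > 2 else params[off:off + 1]
        return rho, np.atleast_1d(tx), np.atleast_1d(ty)

    def _pack(rho, tx, ty):
        z = np.arctanh(np.clip(rho, -0.999, 0.999))
        px = [tx[0]] + list(np.log(np.maximum(np.diff(tx), 1e-6)))
        py = [ty[0]] + list(np.log(np.maximum(np.diff(ty), 1e-6)))
        return np.array([z] + px + py)

    if two_step:
        res = optimize.minimize_scalar(
            lambda z: -_loglik(np.tanh(z), tx0, ty0),
            bounds=(-6, 6), method="bounded")
        rho_hat = float(np.tanh(res.x))
        tx_hat, ty_hat = tx0, ty0
        converged = bool(res.success)
    else:
        x0 = _pack(0.0, tx0, ty0)
        res = optimize.minimize(
            lambda p: -_loglik(*_unpack(p)), x0, method="L-BFGS-B")
        rho_hat, tx_hat, ty_hat = _unpack(res.x)
        rho_hat = float(rho_hat)
        converged = bool(res.success)

    at_boundary = abs(rho_hat) >= RHO_BOUNDARY
    if at_boundary:
        rho_hat = float(np.sign(rho_hat) * RHO_BOUNDARY)
        se = float("nan")
    elif two_step:
        se = _se_from_information(
            lambda p: -_loglik(np.clip(p[0], -RHO_BOUNDARY, RHO_BOUNDARY),
                               tx0, ty0),
            np.array([rho_hat]), 0)
    else:
        def nll_natural(p):
            return -_loglik(np.clip(p[0], -RHO_BOUNDARY, RHO_BOUNDARY),
                            p[1:kx], p[kx:])

        nat = np.concatenate([[rho_hat], tx_hat, ty_hat])
        se = _se_from_information(nll_natural, nat, 0)
    return CorrelationEstimate(
        rho=rho_hat, se=se, method="polychoric", n=n,
        thresholds_x=tuple(tx_hat), thresholds_y=tuple(ty_hat),
        at_boundary=at_boundary, converged=converged)


# ---------------------------------------------------------------------------
# Polyserial

def polyserial(x, y) -> CorrelationEstimate:
    """ML polyserial correlation: continuous x, ordinal y.

    Latent model: the standardised x and the latent normal behind y are
    bivariate normal with correlation rho.  Joint ML over
    (rho, mu_x, sigma_x, thresholds_y); SE from observed information.
    """
    x = np.asarray(x, dtype=float)
    cy, ky = _ordinal_codes(y)
    if x.size != cy.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 observations")
    if ky < 2:
        raise ValueError("y needs at least 2 observed categories")
    if np.std(x) == 0:
        raise ValueError("x has zero variance")

    ty0 = _margin_thresholds(cy, ky)
    mu0, sd0 = float(np.mean(x)), float(np.std(x, ddof=1))

    def negloglik(params):
        rho = np.tanh(params[0])
        mu, logsd = params[1], params[2]
        sd = np.exp(logsd)
        t = params[3:] if ky > 2 else params[3:4]
        tau = np.concatenate([[-np.inf], np.atleast_1d(t), [np.inf]])
        if np.any(np.diff(tau[1:-1]) <= 0):
            return 1e12
        z = (x - mu) / sd
        r1 = np.sqrt(max(1.0 - rho * rho, 1e-12))
        upper = (tau[cy + 1] - rho * z) / r1
        lower = (tau[cy] - rho * z) / r1
        pcond = np.clip(stats.norm.cdf(upper) - stats.norm.cdf(lower),
                        _TINY, 1.0)
        return float(-(np.sum(stats.norm.logpdf(z)) - n * logsd
                       + np.sum(np.log(pcond))))

    x0 = np.concatenate([[0.0], [mu0], [np.log(sd0)], ty0])
    res = optimize.minimize(negloglik, x0, method="L-BFGS-B")
    rho_hat = float(np.tanh(res.x[0]))
    ty_hat = np.atleast_1d(res.x[3:])

    # SE in natural parameterisation (rho, mu, log sd, thresholds)
    def nll_nat(p):
        q = p.copy()
        q[0] = np.arctanh(np.clip(p[0], -0.999999, 0.999999))
        return negloglik(q)

    nat = res.x.copy()
    nat[0] = rho_hat
    se = _se_from_information(nll_nat, nat, 0)

    at_boundary = abs(rho_hat) >= RHO_BOUNDARY
    if at_boundary:
        rho_hat = float(np.sign(rho_hat) * RHO_BOUNDARY)
    return CorrelationEstimate(
        rho=rho_hat, se=se, method="polyserial", n=n,
        thresholds_y=tuple(ty_hat), at_boundary=at_boundary,
        converged=bool(res.success))


# ---------------------------------------------------------------------------
# Pearson with SE

def pearson_with_se(x, y) -> CorrelationEstimate:
    """Pearson r with large-sample SE sqrt((1 - r^2)/(n - 2))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    r = float(np.clip(r, -1.0, 1.0))
    se = float(np.sqrt(max(1.0 - r * r, 0.0) / (n - 2)))
    return CorrelationEstimate(rho=r, se=se, method="pearson", n=n)


# ---------------------------------------------------------------------------
# Tukey HSD + compact letter display

@dataclass
class TukeyGroups:
    """Per-group means with Tukey-HSD compact letters at alpha = 0.05."""

    groups: list
    means: dict
    n: dict
    letters: dict
    anova_f: float
    anova_p: float
    excluded: list = field(default_factory=list)


def _compact_letters(groups: list, not_different: set) -> dict:
    """Compact-letter display from the 'not significantly different' graph.

    Letters label the maximal cliques of the graph, so two groups share
    a letter iff no significant difference separates them.
    """
    gset = list(groups)
    idx = {g: i for i, g in enumerate(gset)}
    adj = [[False] * len(gset) for _ in gset]
    for a, b in not_different:
        adj[idx[a]][idx[b]] = adj[idx[b]][idx[a]] = True
    for i in range(len(gset)):
        adj[i][i] = True

    cliques = []
    m = len(gset)
    for mask in range(1, 1 << m):
        members = [i for i in range(m) if mask >> i & 1]
        if all(adj[i][j] for i, j in combinations(members, 2)):
            cliques.append(frozenset(members))
    maximal = [c for c in cliques
               if not any(c < other for other in cliques)]
    # label cliques in order of their smallest group mean position
    maximal.sort(key=lambda c: min(c))
    letters: dict = {g: "" for g in gset}
    for li, clique in enumerate(maximal):
        ch = chr(ord("a") + li)
        for i in sorted(clique):
            letters[gset[i]] += ch
    return letters


def group_means_tukey(values, groups, alpha: float = 0.05) -> TukeyGroups:
    """One-way ANOVA plus Tukey HSD with a compact-letter display.

    Groups with fewer than 2 observations are excluded with a warning.
    Two groups sharing a letter are not significantly different at the
    given alpha.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    mask = np.isfinite(values)
    values, groups = values[mask], groups[mask]
    uniq, counts = np.unique(groups, return_counts=True)
    excluded = [g for g, c in zip(uniq, counts) if c < 2]
    for g in excluded:
        warnings.warn(f"group {g!r} has < 2 observations; excluded from Tukey")
    keep = ~np.isin(groups, excluded)
    values, groups = values[keep], groups[keep]
    uniq = [g for g in uniq if g not in excluded]
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups with n >= 2")

    samples = [values[groups == g] for g in uniq]
    f_stat, p_val = stats.f_oneway(*samples)

    hsd = pairwise_tukeyhsd(values, groups, alpha=alpha)
    not_diff = set()
    for row in hsd.summary().data[1:]:
        g1, g2, reject = row[0], row[1], row[-1]
        if not reject:
            not_diff.add((g1, g2))
    # summary() may stringify group labels; map back
    label = {str(g): g for g in uniq}
    not_diff = {(label[str(a)], label[str(b)]) for a, b in not_diff}

    letters = _compact_letters(list(uniq), not_diff)
    return TukeyGroups(
        groups=list(uniq),
        means={g: float(np.mean(values[groups == g])) for g in uniq},
        n={g: int(np.sum(groups == g)) for g in uniq},
        letters=letters,
        anova_f=float(f_stat), anova_p=float(p_val),
        excluded=excluded)


# ---------------------------------------------------------------------------
# Longitudinal cross-age matrices

def longitudinal_matrix(
    wide: pd.DataFrame,
    timepoints: list[str] | None = None,
    min_pairs: int = 3,
) -> dict[str, pd.DataFrame]:
    """Pairwise-complete Pearson correlations across timepoints.

    ``wide`` has one row per bird and one column per timepoint for a
    single measurement variable.  Returns lower-triangular DataFrames
    ``{"rho", "se", "n"}``; cells with fewer than ``min_pairs``
    complete pairs are left missing.
    """
    cols = timepoints if timepoints is not None else list(wide.columns)
    rho = pd.DataFrame(np.nan, index=cols, columns=cols)
    se = pd.DataFrame(np.nan, index=cols, columns=cols)
    npair = pd.DataFrame(0, index=cols, columns=cols, dtype=int)
    for i, a in enumerate(cols):
        for b in cols[:i]:
            xa = wide[a].to_numpy(dtype=float)
            xb = wide[b].to_numpy(dtype=float)
            mask = np.isfinite(xa) & np.isfinite(xb)
            if mask.sum() < min_pairs:
                continue
            est = pearson_with_se(xa[mask], xb[mask])
            rho.loc[a, b] = est.rho
            se.loc[a, b] = est.se
            npair.loc[a, b] = est.n
    return {"rho": rho, "se": se, "n": npair}
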