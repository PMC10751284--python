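"""Per-word GLM with partial-F permutation inference.

Each word's (rank-transformed) rate is modeled across authors as

    frequency ~ intercept + sex + period + sex:period + translation + continent

and the joint contribution of the two sex terms is measured with a partial
F statistic comparing the full model against the nested model without them:

    F = [(RSS_nested - RSS_full) / p] / [RSS_full / (n - k)]

with p the number of dropped predictors, n the number of authors and k the
number of coefficients in the full model. Word frequency and historical
period are rank transformed. Significance comes from a permutation test
shuffling the author sex labels (the sex and sex-by-period columns are
rebuilt per shuffle; every other column stays fixed), a generalized Pareto
fit to the permutation tail refines small p-values below the resolution of
the shuffle count, and family-wise correction uses the permutation
distribution of the maximum F across words.

Coding conventions: sex is coded -0.5 (female) / +0.5 (male) and the period
rank transform is centered before forming the product, which decorrelates
the main and interaction columns; the partial F is invariant to any
full-rank recoding, but coefficient signs follow this convention (positive
sex coefficient = male-preferred).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .corpus import RateMatrix


# ---------------------------------------------------------------------------
# Design
# ---------------------------------------------------------------------------

@dataclass
class Design:
    """Design pieces for the per-word GLM.

    ``fixed`` holds intercept, centered period rank, translation code and
    drop-one geography dummies — the columns a sex-label shuffle leaves
    untouched. ``sex`` (+-0.5) and ``period`` (centered rank) generate the
    two permuted columns: sex and sex*period.
    """

    fixed: np.ndarray
    sex: np.ndarray
    period: np.ndarray
    fixed_names: list[str]

    @property
    def n(self) -> int:
        return self.fixed.shape[0]

    @property
    def k(self) -> int:
        """Coefficient count of the full model."""
        return self.fixed.shape[1] + 2

    def full_matrix(self, sex: np.ndarray | None = None) -> np.ndarray:
        s = self.sex if sex is None else sex
        return np.column_stack([self.fixed, s, s * self.period])

    @property
    def column_names(self) -> list[str]:
        return self.fixed_names + ["sex", "sex:period"]


def build_design(authors: pd.DataFrame, geography: str = "continent") -> Design:
    """Build the per-word design from the author table.

    ``geography`` selects the nuisance geography factor: ``"continent"``
    (default) or ``"country"`` (the alternative model).
    """
    if geography not in ("continent", "country"):
        raise ValueError(f"geography must be 'continent' or 'country', got {geography!r}")
    sexes = authors["sex"].to_numpy()
    if len(set(sexes)) < 2:
        raise ValueError("both sexes must be present")
    n = len(authors)
    sex = np.where(sexes == "male", 0.5, -0.5)
    period = stats.rankdata(authors["year_median"].to_numpy())
    period = (period - period.mean()) / n
    translated = authors["translated"].to_numpy()
    trans = np.where(np.isin(translated, ["translated", "1", "True", "true"]), 1.0, 0.0)
    geo = pd.get_dummies(authors[geography], drop_first=True, dtype=float)
    cols = [np.ones(n), period, trans] + [geo[c].to_numpy() for c in geo.columns]
    names = ["intercept", "period", "translated"] + [f"{geography}[{c}]" for c in geo.columns]
    # drop constant nuisance columns (e.g. nobody translated in a tiny corpus)
    keep = [i for i, c in enumerate(cols) if i == 0 or np.ptp(c) > 0]
    fixed = np.column_stack([cols[i] for i in keep])
    names = [names[i] for i in keep]
    design = Design(fixed=fixed, sex=sex, period=period, fixed_names=names)
    _check_full_rank(design.full_matrix(), design.column_names)
    return design


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        guilty = []
        for j in range(X.shape[1]):
            others = np.delete(X, j, axis=1)
            resid = X[:, j] - others @ np.linalg.lstsq(others, X[:, j], rcond=None)[0]
            if np.linalg.norm(resid) < 1e-8 * max(1.0, np.linalg.norm(X[:, j])):
                guilty.append(names[j])
        raise ValueError(f"design matrix is rank-deficient; collinear columns: {guilty}")


# ---------------------------------------------------------------------------
# Partial F
# ---------------------------------------------------------------------------

def partial_f(y: np.ndarray, full: np.ndarray, dropped: list[int] | np.ndarray) -> float:
    """Partial F for dropping columns ``dropped`` from the design ``full``.

    Both models are fit by least squares; F = [(RSS_n - RSS_f)/p] /
    [RSS_f/(n-k)].
    """
    y = np.asarray(y, dtype=float)
    full = np.asarray(full, dtype=float)
    dropped = list(dropped)
    n, k = full.shape
    if n <= k:
        raise ValueError(f"need n > k, got n={n}, k={k}")
    _check_full_rank(full, [f"col{j}" for j in range(k)])
    nested = np.delete(full, dropped, axis=1)
    rss_full = _rss(y, full)
    rss_nested = _rss(y, nested)
    p = len(dropped)
    return float(((rss_nested - rss_full) / p) / (rss_full / (n - k)))


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


# ---------------------------------------------------------------------------
# Permutation engine
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    """Observed and null partial-F statistics from a sex-label shuffle.

    ``f_obs[family]`` is the observed statistic per word and
    ``null[family]`` the (n_perm, n_words) null draws, for families
    ``"joint"`` (sex and sex:period dropped together, p=2), ``"sex"`` and
    ``"interaction"`` (single-term, p=1). All families share the same
    shuffle schedule, which is what makes the max-statistic FWE correction
    valid.
    """

    words: np.ndarray
    f_obs: dict[str, np.ndarray]
    null: dict[str, np.ndarray]
    coef: pd.DataFrame
    n: int
    k: int
    n_perm: int
    seed: int | None = None

    def p_perm(self, family: str = "joint") -> np.ndarray:
        """Empirical permutation p, (b+1)/(m+1) convention (the observed
        statistic counts as permutation zero, so p >= 1/(n_perm+1))."""
        exceed = (self.null[family] >= self.f_obs[family][None, :]).sum(axis=0)
        return (exceed + 1) / (self.n_perm + 1)


def _plane_projection(design: Design, sex: np.ndarray, q0: np.ndarray):
    """Orthonormal basis of the permuted sex/sex:period plane (residualized
    against the fixed columns) plus the unit directions testing each single
    term against the model containing the other."""
    x1 = sex - q0 @ (q0.T @ sex)
    x2 = sex * design.period
    x2 = x2 - q0 @ (q0.T @ x2)
    q, _ = np.linalg.qr(np.column_stack([x1, x2]))
    # coordinates of each raw column in the plane basis
    a1 = q.T @ x1
    a2 = q.T @ x2

    def unit_orth(a_target, a_other):
        # component of target orthogonal to other, inside the plane
        na = a_other / np.linalg.norm(a_other)
        u = a_target - (a_target @ na) * na
        return u / np.linalg.norm(u)

    u_sex = unit_orth(a1, a2)
    u_int = unit_orth(a2, a1)
    return q, u_sex, u_int


def permutation_test(
    matrix: RateMatrix,
    authors: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int | None = 0,
    geography: str = "continent",
    design: Design | None = None,
) -> PermutationResult:
    """Shuffle sex labels ``n_perm`` times and collect partial-F nulls.

    Per shuffle the sex and sex:period columns are rebuilt and the full
    regression recomputed for every word (exact under exchangeability of the
    labels); rank transforms of the word frequencies are computed once.
    """
    if design is None:
        design = build_design(authors, geography=geography)
    n, k = design.n, design.k
    if n <= k:
        raise ValueError(f"need more authors than coefficients (n={n}, k={k})")
    Y = stats.rankdata(matrix.rates, axis=0).astype(float)
    Y -= Y.mean(axis=0, keepdims=True)

    q0, _ = np.linalg.qr(design.fixed)
    rss0 = (Y**2).sum(axis=0) - ((q0.T @ Y) ** 2).sum(axis=0)  # RSS of nested model
    dof = n - k
    rng = np.random.default_rng(seed)

    f_obs: dict[str, np.ndarray] = {}
    null = {fam: np.empty((n_perm, matrix.n_words), dtype=np.float32)
            for fam in ("joint", "sex", "interaction")}

    for b in range(n_perm + 1):
        s = design.sex if b == 0 else design.sex[rng.permutation(n)]
        q, u_sex, u_int = _plane_projection(design, s, q0)
        G = q.T @ Y  # (2, W)
        d_joint = (G**2).sum(axis=0)
        d_sex = (u_sex @ G) ** 2
        d_int = (u_int @ G) ** 2
        rss_full = np.maximum(rss0 - d_joint, 1e-300)
        scale = dof / rss_full
        fj = (d_joint / 2) * scale
        fs = d_sex * scale
        fi = d_int * scale
        if b == 0:
            f_obs = {"joint": fj, "sex": fs, "interaction": fi}
        else:
            null["joint"][b - 1] = fj
            null["sex"][b - 1] = fs
            null["interaction"][b - 1] = fi

    X_full = design.full_matrix()
    beta, *_ = np.linalg.lstsq(X_full, Y, rcond=None)
    names = design.column_names
    coef = pd.DataFrame(
        {"coef_sex": beta[names.index("sex")], "coef_interaction": beta[names.index("sex:period")]},
        index=list(matrix.words),
    )
    return PermutationResult(
        words=np.asarray(matrix.words), f_obs=f_obs,
        null={fam: arr for fam, arr in null.items()},
        coef=coef, n=n, k=k, n_perm=n_perm, seed=seed,
    )


# ---------------------------------------------------------------------------
# Generalized Pareto tail refinement
# ---------------------------------------------------------------------------

def pareto_refine(
    null: np.ndarray,
    f_obs: float,
    tail_threshold: float = 0.10,
    tail_fraction: float = 0.10,
    gof_alpha: float = 0.05,
) -> float:
    """Refine an empirical permutation p-value with a generalized Pareto
    tail fit.

    If the empirical p exceeds ``tail_threshold`` it is returned unchanged.
    Otherwise exceedances over the (1 - tail_fraction) null quantile are fit
    with a maximum-likelihood generalized Pareto distribution; a
    Kolmogorov-Smirnov check guards the fit and the empirical p is returned
    (with a warning) if it fails. The refined p is
    ``tail_mass * GPD.sf(f_obs - threshold)``.
    """
    p_emp, null, u, exc = _tail_setup(null, f_obs, tail_threshold, tail_fraction)
    if exc is None:
        return p_emp
    return _gpd_tail_p(exc, u, np.asarray([f_obs]), len(null), p_emp=np.asarray([p_emp]),
                       gof_alpha=gof_alpha)[0]


def _tail_setup(null, f_obs, tail_threshold, tail_fraction):
    null = np.asarray(null, dtype=float)
    if null.size < 2 or np.ptp(null) == 0:
        raise ValueError("degenerate (constant) permutation null")
    m = null.size
    p_emp = ((null >= f_obs).sum() + 1) / (m + 1)
    if p_emp > tail_threshold:
        return float(p_emp), null, None, None
    u = np.quantile(null, 1 - tail_fraction)
    exc = null[null > u] - u
    if exc.size < 10 or np.ptp(exc) == 0:
        warnings.warn("too few distinct tail exceedances; keeping empirical p", stacklevel=2)
        return float(p_emp), null, None, None
    return float(p_emp), null, float(u), exc


def _gpd_tail_p(exc, u, f_obs_arr, m, p_emp, gof_alpha=0.05):
    try:
        c, loc, scale = stats.genpareto.fit(exc, floc=0.0)
    except Exception:  # pragma: no cover - scipy fit failure is rare
        warnings.warn("generalized Pareto fit failed; keeping empirical p", stacklevel=3)
        return p_emp
    ks = stats.kstest(exc, "genpareto", args=(c, 0.0, scale))
    if ks.pvalue < gof_alpha:
        warnings.warn(
            f"generalized Pareto tail fit rejected (KS p={ks.pvalue:.3g}); keeping empirical p",
            stacklevel=3,
        )
        return p_emp
    tail_mass = exc.size / m
    out = np.array(p_emp, dtype=float, copy=True)
    above = f_obs_arr > u
    refined = tail_mass * stats.genpareto.sf(f_obs_arr[above] - u, c, loc=0.0, scale=scale)
    # the analytic tail estimate refines, never inflates, the empirical p
    out[above] = np.maximum(np.minimum(refined, out[above]), np.finfo(float).tiny)
    return out


def refine_pvalues(
    null: np.ndarray,
    f_obs: np.ndarray,
    tail_threshold: float = 0.10,
    tail_fraction: float = 0.10,
    gof_alpha: float = 0.05,
) -> np.ndarray:
    """Vector version of :func:`pareto_refine`: one shared null sample (e.g.
    the max-F distribution), many observed statistics. The tail is fit once."""
    null = np.asarray(null, dtype=float)
    f_obs = np.atleast_1d(np.asarray(f_obs, dtype=float))
    if null.size < 2 or np.ptp(null) == 0:
        raise ValueError("degenerate (constant) permutation null")
    m = null.size
    p_emp = ((null[:, None] >= f_obs[None, :]).sum(axis=0) + 1) / (m + 1)
    need = p_emp <= tail_threshold
    if not need.any():
        return p_emp
    u = np.quantile(null, 1 - tail_fraction)
    exc = null[null > u] - u
    if exc.size < 10 or np.ptp(exc) == 0:
        warnings.warn("too few distinct tail exceedances; keeping empirical p", stacklevel=2)
        return p_emp
    refined = _gpd_tail_p(exc, u, f_obs, m, p_emp=p_emp, gof_alpha=gof_alpha)
    out = p_emp.copy()
    out[need] = np.minimum(refined[need], p_emp[need])
    return out


def fwe_correct(
    result: PermutationResult,
    family: str = "joint",
    **tail_kwargs,
) -> np.ndarray:
    """Family-wise corrected p-values from the max-F permutation distribution.

    The null of the maximum F across words (same shuffles for every word)
    gives, for each word, the probability under the complete null that *any*
    word beats its observed F — the max-statistic FWE correction. The tail
    is Pareto-refined like the per-word p-values.
    """
    null = result.null[family]
    max_null = null.max(axis=1)
    return refine_pvalues(max_null, result.f_obs[family], **tail_kwargs)


# ---------------------------------------------------------------------------
# High-level per-word table
# ---------------------------------------------------------------------------

def classify_direction(
    coef_sex: np.ndarray,
    p_fwc_sex: np.ndarray,
    p_fwc_interaction: np.ndarray,
    alpha: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Directionality and effect class per word.

    ``sex_sign`` follows the sign of the sex coefficient under the
    -0.5/+0.5 coding (positive = male-preferred; an exact zero ties to
    female-preferred with a warning). ``class`` reports which single-term
    family-wise p-values clear ``alpha``: main-effect, interaction, both, or
    none.
    """
    coef_sex = np.asarray(coef_sex, dtype=float)
    if np.any(coef_sex == 0):
        warnings.warn("zero sex coefficient; tie broken to female-preferred", stacklevel=2)
    sex_sign = np.where(coef_sex > 0, "male-preferred", "female-preferred")
    sig_sex = np.asarray(p_fwc_sex) < alpha
    sig_int = np.asarray(p_fwc_interaction) < alpha
    klass = np.full(len(coef_sex), "none", dtype=object)
    klass[sig_sex & ~sig_int] = "main-effect"
    klass[~sig_sex & sig_int] = "interaction"
    klass[sig_sex & sig_int] = "both"
    return sex_sign, klass


def run_word_tests(
    matrix: RateMatrix,
    authors: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int | None = 0,
    alpha: float = 0.05,
    geography: str = "continent",
    tail_threshold: float = 0.10,
    tail_fraction: float = 0.10,
) -> pd.DataFrame:
    """Full per-word inference: permutation F, Pareto-refined p, FWE p,
    directionality and class. Returns a tidy DataFrame (one row per word)."""
    res = permutation_test(matrix, authors, n_perm=n_perm, seed=seed, geography=geography)
    tail = dict(tail_threshold=tail_threshold, tail_fraction=tail_fraction)
    p_perm = res.p_perm("joint")
    p_pareto = np.array([
        pareto_refine(res.null["joint"][:, j], res.f_obs["joint"][j], **tail)
        for j in range(len(res.words))
    ])
    p_fwc = fwe_correct(res, "joint", **tail)
    p_fwc = np.maximum(p_fwc, p_pareto)  # max-statistic dominance, enforced
    p_fwc_sex = fwe_correct(res, "sex", **tail)
    p_fwc_int = fwe_correct(res, "interaction", **tail)
    sex_sign, klass = classify_direction(
        res.coef["coef_sex"].to_numpy(), p_fwc_sex, p_fwc_int, alpha=alpha
    )
    return pd.DataFrame(
        {
            "word": res.words,
            "F": res.f_obs["joint"],
            "p_perm": p_perm,
            "p_pareto": p_pareto,
            "p_fwc": p_fwc,
            "p_fwc_sex": p_fwc_sex,
            "p_fwc_interaction": p_fwc_int,
            "significant": p_fwc < alpha,
            "sex_sign": sex_sign,
            "class": klass,
            "coef_sex": res.coef["coef_sex"].to_numpy(),
            "coef_interaction": res.coef["coef_interaction"].to_numpy(),
        }
    )
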