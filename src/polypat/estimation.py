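"""Estimation of the degree of cross-fertilization (C) and the paternal
outcrossing success (P).

The C dataset joins, block-wise, all assigned seeds of a maternal genotype
into one binomial unit (cross vs self count). The P dataset is built at
(maternal genotype x paternal genotype x block[, year]) resolution after the
intra-genotype imputation: because self-fertilization and intra-genotype
cross-fertilization are indistinguishable at the markers, the diagonal count
of every maternal cell is set to the mean of the seven other donors' counts.
This inflates each cell's cross-fertilized total by 1/7 and fixes the
own-genotype share at exactly 1/8, so maternal genotype and block carry no
information about P by construction.

Models are binomial-logit GLMs fitted by IRLS (statsmodels backend).
Fractional imputed successes are retained and fitted as weighted logistic
responses (quasi-likelihood reading); rounding would bias the exact-1/8
construction. Sequential analyses of deviance, equal-weight LS means on the
logit scale, Wald z contrasts with Bonferroni correction, compact letter
displays and the Pearson C-P correlation follow.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .errors import DataError

logger = logging.getLogger("polypat")

Z_95 = 1.959963984540054  # normal 97.5% quantile: Wald intervals on the logit scale


def logit(p):
    return np.log(p / (1.0 - p))


def inv_logit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


# ---------------------------------------------------------------------------
# Datasets
# ---------------------------------------------------------------------------

def _full_grid(assignments, genotypes, blocks, years):
    if genotypes is None:
        genotypes = sorted(assignments["mother_genotype"].unique())
    if blocks is None:
        blocks = sorted(assignments["block"].unique())
    if years is None:
        years = sorted(assignments["year"].unique())
    return list(genotypes), list(blocks), list(years)


def build_c_dataset(
    assignments: pd.DataFrame,
    genotypes: Optional[Sequence[str]] = None,
    blocks: Optional[Sequence] = None,
    years: Optional[Sequence] = None,
) -> pd.DataFrame:
    """One binomial row per maternal genotype x block x year.

    ``n_cross`` counts inter-genotype seeds; ``n_self`` the remaining
    assigned seeds. Cells without assigned seeds are kept as (0, 0).
    """
    sub = assignments[assignments["status"] == "assigned"]
    genotypes, blocks, years = _full_grid(assignments, genotypes, blocks, years)
    inter = sub["father_genotype"] != sub["mother_genotype"]
    grouped = (
        pd.DataFrame(
            {
                "MG": sub["mother_genotype"],
                "block": sub["block"],
                "year": sub["year"],
                "n_cross": inter.astype(int),
                "n_assigned": 1,
            }
        )
        .groupby(["MG", "block", "year"])
        .sum()
    )
    idx = pd.MultiIndex.from_product(
        [genotypes, blocks, years], names=["MG", "block", "year"]
    )
    grouped = grouped.reindex(idx, fill_value=0).reset_index()
    grouped["n_self"] = grouped["n_assigned"] - grouped["n_cross"]
    return grouped[["MG", "block", "year", "n_cross", "n_self"]]


def pair_counts(
    assignments: pd.DataFrame,
    genotypes: Optional[Sequence[str]] = None,
    blocks: Optional[Sequence] = None,
    years: Optional[Sequence] = None,
) -> pd.DataFrame:
    """Raw counts of inter-genotype seeds per (MG, PG, block, year).

    Diagonal (MG == PG) entries are zero; :func:`impute_intra` fills them.
    """
    sub = assignments[assignments["status"] == "assigned"]
    genotypes, blocks, years = _full_grid(assignments, genotypes, blocks, years)
    inter = sub[sub["father_genotype"] != sub["mother_genotype"]]
    grouped = (
        pd.DataFrame(
            {
                "MG": inter["mother_genotype"],
                "PG": inter["father_genotype"],
                "block": inter["block"],
                "year": inter["year"],
                "seeds_sired": 1,
            }
        )
        .groupby(["MG", "PG", "block", "year"])
        .sum()
    )
    idx = pd.MultiIndex.from_product(
        [genotypes, genotypes, blocks, years], names=["MG", "PG", "block", "year"]
    )
    grouped = grouped.reindex(idx, fill_value=0).reset_index()
    grouped["seeds_sired"] = grouped["seeds_sired"].astype(float)
    return grouped


def impute_cell(off_diagonal: Sequence[float]) -> float:
    """Imputed intra-genotype count for one maternal cell: the mean of the
    other donors' counts. With the diagonal set to this mean, the cell total
    grows by a factor (k+1)/k and the diagonal share is exactly 1/(k+1) --
    1/8 for a polycross of eight genotypes."""
    off = np.asarray(off_diagonal, dtype=float)
    if off.size == 0:
        raise DataError("need at least one off-diagonal donor count")
    return float(off.mean())


def impute_intra(pair_table: pd.DataFrame) -> pd.DataFrame:
    """Set each diagonal entry to the mean of its cell's off-diagonal counts."""
    out = pair_table.copy()
    diag = out["MG"] == out["PG"]
    for (mg, block, year), cell in out.groupby(["MG", "block", "year"]):
        off = cell.loc[cell["PG"] != mg, "seeds_sired"]
        out.loc[diag & (out["MG"] == mg) & (out["block"] == block)
                & (out["year"] == year), "seeds_sired"] = impute_cell(off)
    return out


def build_p_dataset(imputed: pd.DataFrame) -> pd.DataFrame:
    """Pair-level binomial rows: (seeds sired by PG, other cross seeds of MG)."""
    totals = imputed.groupby(["MG", "block", "year"])["seeds_sired"].transform("sum")
    out = imputed.copy()
    out["n_cross"] = out["seeds_sired"]
    out["n_rest"] = totals - out["seeds_sired"]
    return out[["MG", "PG", "block", "year", "n_cross", "n_rest"]]


def donor_shares(imputed: pd.DataFrame) -> pd.DataFrame:
    """Each donor's share of a maternal cell's cross-fertilized seeds.

    Cells with a zero total get NA shares. By construction the eight shares
    of any cell sum to 1 and the diagonal share is exactly 1/8.
    """
    totals = imputed.groupby(["MG", "block", "year"])["seeds_sired"].transform("sum")
    out = imputed.copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        out["share"] = np.where(totals > 0, out["seeds_sired"] / totals, np.nan)
    return out


# ---------------------------------------------------------------------------
# Design matrices (treatment coding, sequential term entry)
# ---------------------------------------------------------------------------

def _parse_term(term: str):
    """'A' -> main; 'A:B' -> interaction; 'B(A)' -> B nested within A."""
    term = term.strip()
    if term.endswith(")") and "(" in term:
        inner, _, rest = term.partition("(")
        return ("nested", inner.strip(), rest[:-1].strip())
    if ":" in term:
        return ("interaction", *[f.strip() for f in term.split(":")])
    return ("main", term)


def _term_factors(term: str):
    parsed = _parse_term(term)
    return parsed[1:]


class DesignInfo:
    """Treatment-coded design matrices with stable factor levels.

    Levels are frozen from the fitting data so prediction grids reuse the
    same coding.
    """

    def __init__(self, data: pd.DataFrame, terms: Sequence[str]):
        self.terms = list(terms)
        self.factor_levels = {}
        for term in self.terms:
            for f in _term_factors(term):
                if f not in data.columns:
                    raise DataError(f"factor {f!r} not in dataset")
                if f not in self.factor_levels:
                    self.factor_levels[f] = sorted(data[f].unique().tolist())

    def _dummies(self, data, factor, drop_first=True):
        levels = self.factor_levels[factor]
        vals = data[factor].to_numpy()
        use = levels[1:] if drop_first else levels
        cols = [(vals == lv).astype(float) for lv in use]
        names = [f"{factor}[{lv}]" for lv in use]
        return cols, names

    def term_matrix(self, data: pd.DataFrame, term: str):
        parsed = _parse_term(term)
        if parsed[0] == "main":
            cols, names = self._dummies(data, parsed[1])
        elif parsed[0] == "interaction":
            factors = parsed[1:]
            parts = [self._dummies(data, f) for f in factors]
            cols, names = [], []
            for combo in itertools.product(*(range(len(p[0])) for p in parts)):
                col = np.ones(len(data))
                name = []
                for (pcols, pnames), k in zip(parts, combo):
                    col = col * pcols[k]
                    name.append(pnames[k])
                cols.append(col)
                names.append(":".join(name))
        else:  # nested: inner(outer) -> inner dummies within every outer level
            _, inner, outer = parsed
            outer_cols, outer_names = self._dummies(data, outer, drop_first=False)
            inner_cols, inner_names = self._dummies(data, inner)
            cols, names = [], []
            for ocol, oname in zip(outer_cols, outer_names):
                for icol, iname in zip(inner_cols, inner_names):
                    cols.append(ocol * icol)
                    names.append(f"{iname}({oname})")
        if not cols:
            return np.empty((len(data), 0)), []
        return np.column_stack(cols), names

    def matrix(self, data: pd.DataFrame):
        blocks = [np.ones((len(data), 1))]
        names = ["Intercept"]
        for term in self.terms:
            X, nm = self.term_matrix(data, term)
            blocks.append(X)
            names.extend(nm)
        return np.hstack(blocks), names

    def grid(self) -> pd.DataFrame:
        """Full Cartesian grid over every factor's levels."""
        factors = list(self.factor_levels)
        combos = itertools.product(*(self.factor_levels[f] for f in factors))
        return pd.DataFrame(combos, columns=factors)


# ---------------------------------------------------------------------------
# GLM fit
# ---------------------------------------------------------------------------

@dataclass
class GLMFit:
    terms: list
    design: DesignInfo
    param_names: list
    params: np.ndarray
    cov: np.ndarray
    deviance: float
    pearson_chi2: float
    df_resid: int
    df_model: int
    nobs: int
    converged: bool
    separated: list = field(default_factory=list)
    successes: str = "n_cross"
    failures: str = "n_self"

    @property
    def flagged(self) -> bool:
        return (not self.converged) or bool(self.separated)


def fit_binomial_glm(
    data: pd.DataFrame,
    terms: Sequence[str],
    successes: str = "n_cross",
    failures: str = "n_self",
    maxiter: int = 100,
    tol: float = 1e-10,
) -> GLMFit:
    """IRLS fit of a binomial-logit GLM with a two-column count response.

    Successes may be fractional (imputed diagonal counts): the response is
    treated as a weighted proportion with the binomial total as variance
    weight. Rows with a zero total contribute no information but keep their
    place in the layout (and the residual df), mirroring the design-based df
    accounting. Non-convergence and complete separation (unbounded logits)
    are flagged, not raised.
    """
    design = DesignInfo(data, terms)
    X, names = design.matrix(data)
    k = data[successes].to_numpy(dtype=float)
    f = data[failures].to_numpy(dtype=float)
    if (k < 0).any() or (f < 0).any():
        raise DataError("negative counts in binomial response")
    n = k + f
    y = np.divide(k, n, out=np.zeros_like(k), where=n > 0)

    model = sm.GLM(y, X, family=sm.families.Binomial(), var_weights=n)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = model.fit(maxiter=maxiter, tol=tol)
    converged = bool(getattr(res, "converged", True))

    params = np.asarray(res.params)
    cov = np.asarray(res.cov_params())
    separated = [nm for nm, b in zip(names, params) if abs(b) > 20]
    if separated:
        logger.warning("WARN separation: unbounded logit for %s", separated)
    if not converged:
        logger.warning("WARN convergence: IRLS did not converge in %d iters", maxiter)

    rank = int(np.linalg.matrix_rank(X))
    fit = GLMFit(
        terms=list(terms),
        design=design,
        param_names=names,
        params=params,
        cov=cov,
        deviance=float(res.deviance),
        pearson_chi2=float(res.pearson_chi2),
        df_resid=len(data) - rank,
        df_model=rank - 1,
        nobs=len(data),
        converged=converged,
        separated=separated,
        successes=successes,
        failures=failures,
    )
    return fit


def deviance_table(
    data: pd.DataFrame,
    terms: Sequence[str],
    successes: str = "n_cross",
    failures: str = "n_self",
) -> pd.DataFrame:
    """Sequential analysis of deviance (type-I), terms added in entry order.

    Each row reports the df consumed by the added term, the drop in deviance,
    and the likelihood-ratio chi-squared p value. The Null row carries
    nobs - 1 df and the null deviance; deviance changes plus the residual
    deviance add up to the null deviance exactly.
    """
    fits = [
        fit_binomial_glm(data, list(terms[:i]), successes, failures)
        for i in range(len(terms) + 1)
    ]
    rows = [("Null", fits[0].df_resid, np.nan, np.nan)]
    for i, term in enumerate(terms):
        prev, cur = fits[i], fits[i + 1]
        df = prev.df_resid - cur.df_resid
        dev = prev.deviance - cur.deviance
        p = scipy.stats.chi2.sf(dev, df) if df > 0 else np.nan
        rows.append((term, df, dev, p))
    rows.append(("Residual", fits[-1].df_resid, fits[-1].deviance, np.nan))
    table = pd.DataFrame(rows, columns=["term", "df", "deviance", "p_value"])
    table.loc[0, "deviance"] = fits[0].deviance
    return table


# ---------------------------------------------------------------------------
# LS means, contrasts, letters
# ---------------------------------------------------------------------------

def _lsmean_rows(fit: GLMFit, factor: str):
    if factor not in fit.design.factor_levels:
        raise DataError(f"factor {factor!r} not in the fitted model")
    grid = fit.design.grid()
    Xg, _ = fit.design.matrix(grid)
    levels = fit.design.factor_levels[factor]
    L = np.vstack(
        [Xg[(grid[factor] == lv).to_numpy()].mean(axis=0) for lv in levels]
    )
    return L, levels


def ls_means(fit: GLMFit, factor: str, conf_level: float = 0.95) -> pd.DataFrame:
    """Equal-weight marginal means of a factor on the logit scale.

    Levels of all other factors are averaged with equal weights; the CI uses
    the normal quantile on the logit scale and is back-transformed through
    the inverse logit.
    """
    L, levels = _lsmean_rows(fit, factor)
    est = L @ fit.params
    se = np.sqrt(np.einsum("ij,jk,ik->i", L, fit.cov, L))
    z = scipy.stats.norm.ppf(0.5 + conf_level / 2)
    lo, hi = est - z * se, est + z * se
    degenerate = np.abs(est) > 20
    if degenerate.any():
        logger.warning(
            "WARN lsmeans: degenerate CI for levels %s (infinite logit)",
            [lv for lv, d in zip(levels, degenerate) if d],
        )
    return pd.DataFrame(
        {
            "level": levels,
            "ls_mean_logit": est,
            "se": se,
            "ci_lo": lo,
            "ci_hi": hi,
            "backtransformed": inv_logit(est),
            "bt_lo": inv_logit(lo),
            "bt_hi": inv_logit(hi),
        }
    )


def contrasts(
    fit: GLMFit,
    L: np.ndarray,
    names: Sequence[str],
    correction: str = "bonferroni",
    family_size: Optional[int] = None,
) -> pd.DataFrame:
    """Wald z-tests of linear contrasts on the logit scale.

    ``family_size`` defaults to the number of contrast rows; the Bonferroni
    adjustment is min(1, m * p) over that declared family.
    """
    L = np.atleast_2d(np.asarray(L, dtype=float))
    if L.shape[1] != len(fit.params):
        raise DataError("contrast matrix width != number of coefficients")
    est = L @ fit.params
    var = np.einsum("ij,jk,ik->i", L, fit.cov, L)
    for i, v in enumerate(var):
        if not np.isfinite(v) or v < 0:
            raise DataError(f"contrast {names[i]!r} is not estimable")
    se = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, est / se, np.inf * np.sign(est))
    p = 2 * scipy.stats.norm.sf(np.abs(z))
    m = family_size if family_size is not None else len(p)
    if correction == "bonferroni":
        p_adj = np.minimum(1.0, m * p)
    elif correction in (None, "none"):
        p_adj = p
    else:
        raise DataError(f"unknown correction {correction!r}")
    logger.info("contrast family size m=%d (%s)", m, correction)
    return pd.DataFrame(
        {"contrast": list(names), "estimate": est, "se": se, "z": z,
         "p_value": p, "p_adj": p_adj}
    )


def pairwise_contrasts(
    fit: GLMFit,
    factor: str,
    correction: str = "bonferroni",
    family_size: Optional[int] = None,
    alpha: float = 0.05,
):
    """All pairwise LS-mean differences of a factor plus the significance
    matrix used for the compact letter display."""
    L, levels = _lsmean_rows(fit, factor)
    rows, names = [], []
    pairs = list(itertools.combinations(range(len(levels)), 2))
    for i, j in pairs:
        rows.append(L[i] - L[j])
        names.append(f"{levels[i]} - {levels[j]}")
    table = contrasts(fit, np.vstack(rows), names, correction, family_size)
    sig = np.zeros((len(levels), len(levels)), dtype=bool)
    for (i, j), p_adj in zip(pairs, table["p_adj"]):
        sig[i, j] = sig[j, i] = bool(p_adj < alpha)
    return table, levels, sig


def group_contrast(fit: GLMFit, factor: str, group_a, group_b) -> np.ndarray:
    """Contrast row: mean LS mean of group_a minus mean of group_b."""
    L, levels = _lsmean_rows(fit, factor)
    idx = {lv: i for i, lv in enumerate(levels)}
    row = np.zeros(L.shape[1])
    for lv in group_a:
        row += L[idx[lv]] / len(group_a)
    for lv in group_b:
        row -= L[idx[lv]] / len(group_b)
    return row


def compact_letter_display(levels: Sequence, sig: np.ndarray) -> dict:
    """Insert-and-absorb letters: two levels share a letter iff their
    difference is not significant."""
    n = len(levels)
    columns = [frozenset(range(n))]
    for i, j in itertools.combinations(range(n), 2):
        if not sig[i, j]:
            continue
        new_columns = []
        for col in columns:
            if i in col and j in col:
                new_columns.extend([col - {i}, col - {j}])
            else:
                new_columns.append(col)
        # absorb columns contained in another; dedupe
        new_columns = sorted(set(new_columns), key=lambda c: (-len(c), sorted(c)))
        kept = []
        for col in new_columns:
            if not any(col < other for other in new_columns if other != col):
                if col not in kept:
                    kept.append(col)
        columns = kept
    columns = sorted(columns, key=lambda c: sorted(c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {lv: "" for lv in levels}
    for letter, col in zip(alphabet, columns):
        for i in sorted(col):
            letters[levels[i]] += letter
    return letters


def estimate_p(fit: GLMFit, factor: str = "PG", alpha: float = 0.05) -> pd.DataFrame:
    """Per-donor paternal outcrossing success: back-transformed LS means over
    the maternal genotypes (and years), with significance letters."""
    means = ls_means(fit, factor)
    _, levels, sig = pairwise_contrasts(fit, factor, alpha=alpha)
    letters = compact_letter_display(levels, sig)
    means["letters"] = [letters[lv] for lv in means["level"]]
    return means


def estimate_c(fit: GLMFit, factor: str = "MG", alpha: float = 0.05) -> pd.DataFrame:
    """Per-genotype degree of cross-fertilization with significance letters."""
    means = ls_means(fit, factor)
    _, levels, sig = pairwise_contrasts(fit, factor, alpha=alpha)
    letters = compact_letter_display(levels, sig)
    means["letters"] = [letters[lv] for lv in means["level"]]
    return means


# ---------------------------------------------------------------------------
# Diagnostics and correlation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OverdispersionResult:
    deviance_ratio: float
    pearson_ratio: float
    flagged: bool


def overdispersion_check(fit: GLMFit, threshold: float = 1.5) -> OverdispersionResult:
    """Residual deviance / df and the Pearson analogue; ratios above the
    threshold are flagged in the log."""
    if fit.df_resid <= 0:
        return OverdispersionResult(np.nan, np.nan, False)
    dr = fit.deviance / fit.df_resid
    pr = fit.pearson_chi2 / fit.df_resid
    flagged = bool(max(dr, pr) > threshold)
    if flagged:
        logger.warning(
            "WARN overdispersion: deviance/df=%.3f pearson/df=%.3f", dr, pr
        )
    return OverdispersionResult(float(dr), float(pr), flagged)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int
    subset: str


def correlate_c_p(
    c_means: Union[Mapping, pd.Series],
    p_means: Union[Mapping, pd.Series],
    subset: Optional[Sequence[str]] = None,
    label: str = "all",
) -> CorrelationResult:
    """Pearson product-moment correlation between per-genotype C and P."""
    c_means = pd.Series(dict(c_means) if not isinstance(c_means, pd.Series) else c_means)
    p_means = pd.Series(dict(p_means) if not isinstance(p_means, pd.Series) else p_means)
    keys = [k for k in c_means.index if k in set(p_means.index)]
    if subset is not None:
        keys = [k for k in keys if k in set(subset)]
    x = c_means[keys].to_numpy(dtype=float)
    y = p_means[keys].to_numpy(dtype=float)
    if len(keys) < 3:
        raise DataError("need >=3 paired genotype values for a p-value")
    if np.std(x) == 0 or np.std(y) == 0:
        return CorrelationResult(np.nan, np.nan, len(keys), label)
    r, p = scipy.stats.pearsonr(x, y)
    return CorrelationResult(float(r), float(p), len(keys), label)
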