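"""Mixed-effects inference on the median-HDR summaries.

A linear mixed model with a participant random intercept is fitted to
the per-cell OxyHb summaries, with head position, within-block timing
(first/last), hemisphere and their two-way interactions as candidate
fixed effects.  Backward elimination removes the least significant
removable term (respecting marginality) until every retained term is
significant, and Tukey-adjusted pairwise contrasts compare the head
positions on estimated marginal means.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from patsy import build_design_matrices
from scipy.stats import studentized_range

__all__ = [
    "ModelSpec",
    "ModelResult",
    "fit_mixed",
    "term_pvalues",
    "backward_eliminate",
    "tukey_contrasts",
]

DEFAULT_FACTORS = ("position", "timing", "hemisphere")


@dataclass(frozen=True)
class ModelSpec:
    response: str = "oxyhb"
    factors: tuple[str, ...] = DEFAULT_FACTORS
    include_interactions: bool = True
    group: str = "participant"
    alpha: float = 0.05
    criterion: str = "wald"          # "wald" or "lrt"

    def candidate_terms(self) -> list[str]:
        terms = [f"C({f})" for f in self.factors]
        if self.include_interactions:
            terms += [f"C({a}):C({b})"
                      for a, b in itertools.combinations(self.factors, 2)]
        return terms


@dataclass
class ModelResult:
    retained_terms: list[str]
    params: pd.DataFrame                 # term, estimate, se, p
    elimination_path: list[dict]
    contrasts: pd.DataFrame | None
    fit_log: dict
    final_fit: object = field(repr=False, default=None)


def _formula(response: str, terms: list[str]) -> str:
    rhs = " + ".join(terms) if terms else "1"
    return f"{response} ~ {rhs}"


def fit_mixed(data: pd.DataFrame, terms: list[str],
              spec: ModelSpec = ModelSpec(), reml: bool = True):
    """REML fit of the random-intercept mixed model with the given terms.

    Term significance is assessed by Wald chi-square tests on each
    term's coefficient block (large-sample normal approximation; the
    approximate-df method is recorded in the fit log).
    """
    if data[spec.group].nunique() < 2:
        raise ValueError("need at least two participants")
    model = smf.mixedlm(_formula(spec.response, terms), data,
                        groups=data[spec.group])
    rank = np.linalg.matrix_rank(model.exog)
    if rank < model.exog.shape[1]:
        raise ValueError(
            f"singular fixed-effect design: rank {rank} < "
            f"{model.exog.shape[1]} columns for terms {terms}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=reml)
    return res


def term_pvalues(res, spec: ModelSpec = ModelSpec()) -> dict[str, float]:
    """Wald chi-square p-value per model term (intercept excluded)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = res.wald_test_terms(scalar=True).table
    return {term: float(p) for term, p in table["pvalue"].items()
            if term != "Intercept"}


def _lrt_pvalue(data: pd.DataFrame, terms: list[str], drop: str,
                spec: ModelSpec) -> float:
    from scipy.stats import chi2
    full = fit_mixed(data, terms, spec, reml=False)
    reduced = fit_mixed(data, [t for t in terms if t != drop], spec,
                        reml=False)
    lr = 2.0 * (full.llf - reduced.llf)
    df = full.k_fe - reduced.k_fe
    return float(chi2.sf(max(lr, 0.0), df))


def _removable(terms: list[str]) -> list[str]:
    """Terms not protected by marginality (no retained interaction
    contains them)."""
    out = []
    for t in terms:
        if ":" in t:
            out.append(t)
        else:
            if not any(":" in u and t in u.split(":") for u in terms):
                out.append(t)
    return out


def backward_eliminate(data: pd.DataFrame,
                       spec: ModelSpec = ModelSpec()) -> ModelResult:
    """Backward elimination over the candidate fixed effects.

    Starting from the full model, repeatedly drop the removable term
    with the largest p-value above alpha (interactions always eligible
    before the main effects they contain) and refit, until every
    removable term is significant or only the intercept remains.  The
    elimination is deterministic: no randomness enters the fitting.
    """
    terms = spec.candidate_terms()
    path: list[dict] = []
    res = fit_mixed(data, terms, spec)
    while terms:
        if spec.criterion == "lrt":
            pvals = {t: _lrt_pvalue(data, terms, t, spec)
                     for t in _removable(terms)}
        else:
            all_p = term_pvalues(res, spec)
            pvals = {t: all_p[t] for t in _removable(terms)}
        worst = max(pvals, key=pvals.get)
        if pvals[worst] <= spec.alpha:
            path.append({"action": "stop", "pvalues": pvals})
            break
        path.append({"action": "drop", "term": worst,
                     "p": pvals[worst], "pvalues": pvals})
        terms = [t for t in terms if t != worst]
        res = fit_mixed(data, terms, spec) if terms else fit_mixed(
            data, [], spec)
    if not terms:
        res = fit_mixed(data, [], spec)

    params = pd.DataFrame({
        "estimate": res.fe_params,
        "se": res.bse_fe,
        "p": res.pvalues[:len(res.fe_params)],
    })
    fit_log = {
        "method": "REML",
        "df_method": "large-sample Wald (normal approximation)",
        "criterion": spec.criterion,
        "alpha": spec.alpha,
        "n_obs": int(res.nobs),
        "n_groups": int(data[spec.group].nunique()),
        "random_intercept_var": float(np.asarray(res.cov_re)[0, 0]),
        "converged": bool(res.converged),
    }
    contrasts = None
    if "C(position)" in terms:
        contrasts = tukey_contrasts(res, data, terms, factor="position",
                                    spec=spec)
    return ModelResult(retained_terms=terms, params=params,
                       elimination_path=path, contrasts=contrasts,
                       fit_log=fit_log, final_fit=res)


def tukey_contrasts(res, data: pd.DataFrame, terms: list[str],
                    factor: str = "position",
                    spec: ModelSpec = ModelSpec()) -> pd.DataFrame:
    """All pairwise contrasts of a factor's estimated marginal means.

    Marginal means average the model predictions over a balanced grid of
    the other retained factors; the family-wise adjustment uses the
    studentized-range distribution with residual degrees of freedom
    (n_obs − n fixed-effect parameters).  For a two-level factor the
    adjustment reduces to the unadjusted two-sided t-test.
    """
    if f"C({factor})" not in terms:
        raise ValueError(
            f"factor '{factor}' is not retained in the final model; "
            "no contrasts available")
    design_info = res.model.data.design_info
    other = sorted({f for t in terms for f in t.replace("C(", "")
                    .replace(")", "").split(":")} - {factor})
    levels = sorted(data[factor].astype(str).unique())
    grids = {}
    for lev in levels:
        cols = {factor: [lev]}
        for f in other:
            cols[f] = sorted(data[f].astype(str).unique())
        grid = pd.DataFrame(
            [dict(zip(cols, vals)) for vals in itertools.product(
                *cols.values())])
        x = np.asarray(build_design_matrices([design_info], grid)[0])
        grids[lev] = x.mean(axis=0)

    k_fe = len(res.fe_params)
    cov = np.asarray(res.cov_params())[:k_fe, :k_fe]
    beta = np.asarray(res.fe_params)
    df = max(int(res.nobs) - k_fe, 1)
    k = len(levels)
    rows = []
    for a, b in itertools.combinations(levels, 2):
        c = grids[a] - grids[b]
        diff = float(c @ beta)
        se = float(np.sqrt(c @ cov @ c))
        q = abs(diff) / se * np.sqrt(2.0)
        p_adj = float(studentized_range.sf(q, k, df))
        rows.append({"contrast": f"{a} - {b}", "estimate": diff,
                     "se": se, "p_adj": min(max(p_adj, 0.0), 1.0)})
    return pd.DataFrame(rows)
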