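"""Marginal-model analysis of span records.

Span measurements are correlated within participants (each contributes many
trials) and their distributions are right-skewed, so the condition analysis
uses generalized estimating equations (GEE) with a gamma variance function,
the inverse link, an exchangeable working correlation, and cluster-robust
(sandwich) covariance — a population-average model of how the mean span
depends on tempo, expertise, condition, and note position.

Per-term hypothesis tests report the robust Wald chi-square statistic.  With
a modest number of clusters the chi-square reference for a multi-degree
Wald statistic is severely anticonservative, so p-values use the
Hotelling-type small-sample reference

    W (m - q) / (q (m - 1))  ~  F(q, m - q),

where m is the number of clusters and q the constraint degrees of freedom;
the asymptotic chi-square p-value is reported alongside.  The two references
agree as m grows.

Post hoc pairwise contrasts compare model predictions (estimated marginal
means back-transformed from the link scale) across the levels of one factor
at each level of another, with a multivariate-normal equicoordinate
("Tukey"-style single-step) multiplicity adjustment over each comparison
family.
"""

from __future__ import annotations

import itertools
import re
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import patsy
from scipy import stats as sps

import statsmodels.api as sm
import statsmodels.formula.api as smf

from .spans import EXCLUSION_NONE, SpanRecord

__all__ = [
    "GEEResult",
    "ContrastTable",
    "fit_gee",
    "model_selection_expertise",
    "posthoc_contrasts",
    "spearman_association",
    "records_to_frame",
    "DEFAULT_TERMS",
]

RESPONSE_COLUMNS = {"ets": "ets_beats", "saccade": "saccade_beats"}

DEFAULT_TERMS: Tuple[str, ...] = (
    "C(tempo_bpm)",
    "C(condition)*C(note_factor)",
)


def records_to_frame(records: Union[Sequence[SpanRecord], pd.DataFrame]) -> pd.DataFrame:
    """Span records as a DataFrame with a stable column order."""
    if isinstance(records, pd.DataFrame):
        return records
    cols = [
        "participant_id", "trial_id", "note_id", "condition", "note_factor",
        "tempo_bpm", "ets_beats", "saccade_beats", "fix_onset_beats",
        "fix_beat_pos", "expertise", "excluded", "ehs_lag_s", "fps_beats",
    ]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records], columns=cols)


@dataclass
class GEEResult:
    """Fitted marginal model with per-term Wald tests.

    ``wald_table`` is indexed by model term with columns ``df`` (constraint
    degrees of freedom), ``chi2`` (robust Wald statistic), ``p``
    (small-sample F reference), and ``p_asymptotic`` (chi-square reference).
    """

    formula: str
    response: str
    wald_table: pd.DataFrame
    params: pd.Series
    bse: pd.Series
    working_correlation: float
    dispersion: float
    n_obs: int
    n_clusters: int
    cluster_var: str
    family: str = "Gamma"
    link: str = "inverse_power"
    cov_struct: str = "exchangeable"
    result: object = field(default=None, repr=False)
    data: pd.DataFrame = field(default=None, repr=False)

    def term_p(self, term: str) -> float:
        return float(self.wald_table.loc[term, "p"])

    def term_chi2(self, term: str) -> float:
        return float(self.wald_table.loc[term, "chi2"])


def _small_sample_p(w: float, q: int, m: int) -> float:
    """Hotelling-type F reference for a q-df sandwich Wald statistic
    estimated from m clusters; falls back to chi-square when m <= q."""
    if m > q:
        return float(sps.f.sf(w * (m - q) / (q * (m - 1)), q, m - q))
    return float(sps.chi2.sf(w, q))


def fit_gee(
    records: Union[Sequence[SpanRecord], pd.DataFrame],
    response: str = "ets",
    terms: Sequence[str] = DEFAULT_TERMS,
    cluster: str = "participant_id",
    *,
    drop_excluded: bool = True,
    maxiter: int = 60,
    tol: float = 1e-6,
) -> GEEResult:
    """Fit the gamma/inverse-link/exchangeable GEE to span records.

    ``response`` is ``"ets"`` or ``"saccade"`` (or directly a column name).
    Excluded records are dropped, as are records whose response is
    undefined.  Raises if any remaining response is non-positive (gamma
    variance requires a positive mean response) or if fewer than two
    clusters remain.
    """
    df = records_to_frame(records).copy()
    col = RESPONSE_COLUMNS.get(response, response)
    if col not in df.columns:
        raise ValueError(f"unknown response {response!r}")
    if drop_excluded and "excluded" in df.columns:
        df = df[df["excluded"] == EXCLUSION_NONE]
    df = df[df[col].notna()]
    bad = df.index[df[col] <= 0]
    if len(bad):
        raise ValueError(
            f"non-positive {col} in rows {list(bad[:10])}"
            + ("..." if len(bad) > 10 else "")
            + "; gamma GEE needs a strictly positive response"
        )
    n_clusters = df[cluster].nunique()
    if n_clusters < 2:
        raise ValueError("GEE needs at least two clusters")
    formula = f"{col} ~ " + " + ".join(terms)
    family = sm.families.Gamma(link=sm.families.links.InversePower())
    with warnings.catch_warnings():
        # the inverse link is the canonical gamma link; statsmodels warns
        # that it does not map onto the positive half-line, which is handled
        # by the positivity check above
        warnings.filterwarnings("ignore", category=sm.tools.sm_exceptions.DomainWarning)
        model = smf.gee(
            formula,
            groups=cluster,
            data=df,
            family=family,
            cov_struct=sm.cov_struct.Exchangeable(),
        )
        if float(np.var(df[col])) == 0.0:
            # zero-dispersion boundary: a constant response solves the
            # estimating equations exactly at the link-transformed constant,
            # with no sampling variability left to estimate
            names = list(model.exog_names)
            icpt = names.index("Intercept") if "Intercept" in names else 0
            beta = np.zeros(model.exog.shape[1])
            beta[icpt] = family.link(float(df[col].iloc[0]))
            params = pd.Series(beta, index=names)
            wt = pd.DataFrame(
                {"df": [1] * len(names), "chi2": np.nan, "p": np.nan,
                 "p_asymptotic": np.nan},
                index=names,
            )
            return GEEResult(
                formula=formula, response=col, wald_table=wt, params=params,
                bse=pd.Series(0.0, index=names), working_correlation=0.0,
                dispersion=0.0, n_obs=len(df), n_clusters=int(n_clusters),
                cluster_var=cluster, result=None, data=df,
            )
        res = model.fit(maxiter=maxiter, ctol=tol)
    if not np.all(np.isfinite(res.params)):
        raise RuntimeError(
            f"GEE did not converge for {formula!r}; parameter trace contains "
            f"non-finite values after {maxiter} iterations"
        )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore")
        wt = res.wald_test_terms(scalar=True).table
    wt = wt.rename(columns={"statistic": "chi2", "df_constraint": "df", "pvalue": "p_asymptotic"})
    wt["df"] = wt["df"].astype(int)
    wt["p"] = [
        _small_sample_p(w, q, n_clusters) for w, q in zip(wt["chi2"], wt["df"])
    ]
    wt = wt[["df", "chi2", "p", "p_asymptotic"]]
    # Pearson-moment dispersion of the gamma variance function
    mu = np.asarray(res.fittedvalues)
    y = np.asarray(df[col])
    dof = max(len(y) - len(res.params), 1)
    dispersion = float(np.sum(((y - mu) / mu) ** 2) / dof)
    return GEEResult(
        formula=formula,
        response=col,
        wald_table=wt,
        params=res.params,
        bse=res.bse,
        working_correlation=float(np.atleast_1d(model.cov_struct.dep_params)[0]),
        dispersion=dispersion,
        n_obs=len(df),
        n_clusters=int(n_clusters),
        cluster_var=cluster,
        result=res,
        data=df,
    )


def model_selection_expertise(
    records: Union[Sequence[SpanRecord], pd.DataFrame],
    full_terms: Sequence[str],
    response: str = "ets",
    cluster: str = "participant_id",
    alpha: float = 0.05,
    expertise_var: str = "expertise",
) -> Tuple[GEEResult, GEEResult, List[str]]:
    """Drop non-significant expertise interactions and refit once.

    Fits the full model, removes every interaction term involving the
    expertise variable whose Wald p >= ``alpha``, refits, and returns
    ``(full_fit, reduced_fit, dropped_terms)``.  Main effects are never
    dropped; with no expertise interactions supplied this is the identity.
    """
    full = fit_gee(records, response=response, terms=full_terms, cluster=cluster)
    # decide on the expanded per-term names (a supplied a*b term expands)
    drop_names = [
        name
        for name in full.wald_table.index
        if ":" in name
        and expertise_var.lower() in name.lower()
        and full.wald_table.loc[name, "p"] >= alpha
    ]
    if not drop_names:
        return full, full, []
    reduced_terms = [
        name for name in full.wald_table.index
        if name != "Intercept" and name not in drop_names
    ]
    reduced = fit_gee(records, response=response, terms=reduced_terms, cluster=cluster)
    return full, reduced, drop_names


@dataclass
class ContrastTable:
    """Pairwise contrasts of model predictions on the response scale."""

    within: str
    across: str
    table: pd.DataFrame  # columns: within level, pair, estimate, se, z, p, p_adj


def _grid_variables(fit: GEEResult) -> Dict[str, list]:
    """Variables entering the model formula and the values to predict at:
    all observed levels for factors, the mean for plain numeric covariates."""
    rhs = fit.formula.split("~", 1)[1]
    out: Dict[str, list] = {}
    for colname in fit.data.columns:
        if not re.search(rf"\b{re.escape(colname)}\b", rhs):
            continue
        col = fit.data[colname]
        as_factor = f"C({colname}" in rhs or col.dtype == object or isinstance(
            col.dtype, pd.CategoricalDtype
        )
        if as_factor:
            out[colname] = sorted(col.unique().tolist())
        else:
            out[colname] = [float(col.mean())]
    return out


def posthoc_contrasts(
    fit: GEEResult,
    within: str,
    across: str,
    adjust: str = "mvt",
) -> ContrastTable:
    """Pairwise differences of predictions across ``across`` levels at each
    ``within`` level.

    Estimated marginal means are formed on the link scale by averaging the
    design rows over the levels of the remaining factors (equal weights) and
    back-transforming; differences are therefore on the response scale.
    Standard errors come from the delta method with the fit's robust
    covariance.  ``adjust="mvt"`` applies the single-step equicoordinate
    multivariate-normal adjustment over each ``within`` level's family of
    pairwise contrasts (identity for a single pair); ``adjust="none"``
    reports unadjusted two-sided normal p-values.
    """
    gridvars = _grid_variables(fit)
    for v in (within, across):
        if v not in gridvars:
            raise ValueError(f"factor {v!r} not in the fitted model")
    res = fit.result
    design_info = res.model.data.design_info
    keys = list(gridvars)
    grid = pd.DataFrame(
        [dict(zip(keys, vals)) for vals in itertools.product(*gridvars.values())]
    )
    (X,) = patsy.build_design_matrices([design_info], grid, return_type="matrix")
    X = np.asarray(X)
    beta = np.asarray(res.params)
    V = np.asarray(res.cov_params())
    link = res.model.family.link

    def emm_row(w_level, a_level) -> np.ndarray:
        mask = (grid[within] == w_level) & (grid[across] == a_level)
        return X[np.asarray(mask)].mean(axis=0)

    rows = []
    for w_level in gridvars[within]:
        pairs = list(itertools.combinations(gridvars[across], 2))
        ests, grads = [], []
        for a1, a2 in pairs:
            x1, x2 = emm_row(w_level, a1), emm_row(w_level, a2)
            eta1, eta2 = float(x1 @ beta), float(x2 @ beta)
            mu1, mu2 = float(link.inverse(eta1)), float(link.inverse(eta2))
            g = link.inverse_deriv(eta1) * x1 - link.inverse_deriv(eta2) * x2
            ests.append(mu1 - mu2)
            grads.append(np.asarray(g, dtype=float))
        G = np.vstack(grads)
        C = G @ V @ G.T
        se = np.sqrt(np.clip(np.diag(C), 1e-300, None))
        z = np.asarray(ests) / se
        p_un = 2.0 * sps.norm.sf(np.abs(z))
        if adjust == "none" or len(pairs) == 1:
            p_adj = p_un.copy()
        else:
            d = np.sqrt(np.diag(C))
            R = C / np.outer(d, d)
            R = (R + R.T) / 2.0
            mvn = sps.multivariate_normal(mean=np.zeros(len(pairs)), cov=R, allow_singular=True)
            p_adj = np.array(
                [
                    1.0
                    - mvn.cdf(
                        np.full(len(pairs), abs(zi)),
                        lower_limit=np.full(len(pairs), -abs(zi)),
                    )
                    for zi in z
                ]
            )
            p_adj = np.clip(p_adj, 0.0, 1.0)
        for (a1, a2), est, s, zi, pu, pa in zip(pairs, ests, se, z, p_un, p_adj):
            rows.append(
                {
                    within: w_level,
                    "pair": f"{a1} - {a2}",
                    "estimate": est,
                    "se": s,
                    "z": zi,
                    "p_unadj": pu,
                    "p_adj": pa,
                }
            )
    return ContrastTable(within=within, across=across, table=pd.DataFrame(rows))


def spearman_association(ets: Sequence[float], sacc: Sequence[float]) -> Tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) between paired ETS
    and incoming-saccade measurements."""
    ets = np.asarray(ets, dtype=float)
    sacc = np.asarray(sacc, dtype=float)
    if ets.shape != sacc.shape:
        raise ValueError(f"length mismatch: {ets.shape} vs {sacc.shape}")
    if ets.size < 3:
        raise ValueError("need at least 3 pairs")
    rho, p = sps.spearmanr(ets, sacc)
    return float(rho), float(p)
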