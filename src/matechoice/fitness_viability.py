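"""Log-ratio fitness/viability scores and their variance decomposition.

Competitive fitness of a wild-type focal fly against a brown-eyed standard
is scored as w = ln((wt + 1) / (be + 1)), where wt and be are the counts
of wild-type and brown-eyed offspring; egg-to-adult viability uses the
same statistic with wt -> adults and be -> eggs that failed to reach the
imago stage.  Zero-egg vials are uninformative and zero-adult vials may
just reflect no mating, so both are removed before analysis.

Each trait is decomposed with a Gaussian linear mixed model: random
male-strain, female-strain and male-by-female interaction intercepts,
fixed categorical block and cross (within- versus between-strain) effects.
The cross fixed effect separates inbreeding depression from other
compatibility-type effects.  Variances come from REML; each random term is
tested by a 1-df likelihood-ratio test on ML refits (a variance estimated
at zero reports statistic 0, p 1 -- no boundary mixture correction, though
one is available); fixed terms get type-II Wald chi-square tests under
sum-to-zero coding; and cross levels get estimated marginal means that
average over block levels with equal weights, random effects at zero.
Model residuals beyond 2 IQR in absolute value are removed once and the
model refit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import patsy
from scipy import stats

import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM

__all__ = [
    "fitness_score",
    "viability_score",
    "add_fitness_scores",
    "add_viability_scores",
    "filter_viability",
    "VarianceDecomposition",
    "fit_cross_lmm",
    "residual_outlier_filter",
    "marginal_means",
    "lrt_boundary_mixture_p",
    "analyze_trait",
]

_RANDOM_TERMS = ("f_strain", "m_strain", "mf")


def fitness_score(wt, be):
    """w = ln((wt + 1) / (be + 1)); strictly increasing in wt, decreasing
    in be, and antisymmetric under swapping the counts."""
    wt = np.asarray(wt)
    be = np.asarray(be)
    if (wt < 0).any() or (be < 0).any():
        raise ValueError("offspring counts must be non-negative")
    out = np.log((wt + 1.0) / (be + 1.0))
    return float(out) if out.ndim == 0 else out


def viability_score(eggs, adults):
    """Same log-ratio with adults as successes and dead eggs as failures."""
    eggs = np.asarray(eggs)
    adults = np.asarray(adults)
    if (eggs < 0).any() or (adults < 0).any():
        raise ValueError("counts must be non-negative")
    if (adults > eggs).any():
        raise ValueError("adults cannot exceed eggs")
    out = np.log((adults + 1.0) / (eggs - adults + 1.0))
    return float(out) if out.ndim == 0 else out


def add_fitness_scores(records: pd.DataFrame) -> pd.DataFrame:
    out = records.copy()
    out["w"] = fitness_score(out["wt"].to_numpy(), out["be"].to_numpy())
    return out


def add_viability_scores(records: pd.DataFrame) -> pd.DataFrame:
    out = records.copy()
    out["w"] = viability_score(out["eggs"].to_numpy(), out["adults"].to_numpy())
    return out


def filter_viability(records: pd.DataFrame) -> tuple[pd.DataFrame, int, int]:
    """Drop zero-egg vials, then zero-adult vials; report both counts."""
    n_zero_egg = int((records["eggs"] == 0).sum())
    kept = records.loc[records["eggs"] > 0]
    n_zero_adult = int((kept["adults"] == 0).sum())
    kept = kept.loc[kept["adults"] > 0].reset_index(drop=True)
    return kept, n_zero_egg, n_zero_adult


# ---------------------------------------------------------------------------
# mixed model


@dataclass
class VarianceDecomposition:
    """REML variance components with LRT/Wald tests and marginal means."""

    response: str
    variances: dict[str, float]  # f_strain, m_strain, mf, residual
    fixed_effects: pd.Series
    lrt: pd.DataFrame  # term, statistic, df, p
    wald: pd.DataFrame  # term, df, chi2, p
    emm: pd.DataFrame  # level, mean, se (cross factor)
    n_obs: int
    result: object  # fitted statsmodels MixedLMResults (REML)

    def report(self) -> pd.DataFrame:
        """Long-format report: one row per effect, variances x100."""
        rows = []
        for _, r in self.wald.iterrows():
            rows.append(
                {
                    "effect": f"{r['term']} (fixed)", "level": "", "emm (se)": "",
                    "variance_x100": "", "df": int(r["df"]),
                    "chi2": round(r["chi2"], 2), "p": r["p"],
                }
            )
            if r["term"] == "cross":
                for _, e in self.emm.iterrows():
                    rows.append(
                        {
                            "effect": "", "level": e["level"],
                            "emm (se)": f"{e['mean']:.2f} ({e['se']:.2f})",
                            "variance_x100": "", "df": "", "chi2": "", "p": "",
                        }
                    )
        for _, r in self.lrt.iterrows():
            rows.append(
                {
                    "effect": f"{r['term']} (random)", "level": "", "emm (se)": "",
                    "variance_x100": round(100 * self.variances[r["term"]], 2),
                    "df": int(r["df"]), "chi2": round(r["statistic"], 2),
                    "p": r["p"],
                }
            )
        rows.append(
            {
                "effect": "Residual", "level": "", "emm (se)": "",
                "variance_x100": round(100 * self.variances["residual"], 2),
                "df": "", "chi2": "", "p": "",
            }
        )
        return pd.DataFrame(rows)


def _prep_frame(scores: pd.DataFrame, response: str) -> pd.DataFrame:
    for col in ("block", "m_strain", "f_strain", "cross", response):
        if col not in scores.columns:
            raise ValueError(f"missing column {col!r}")
    df = scores.reset_index(drop=True).copy()
    df["mf"] = df["m_strain"].astype(str) + ":" + df["f_strain"].astype(str)
    return df


def _fixed_formula(df: pd.DataFrame, response: str) -> str:
    terms = []
    if df["block"].nunique() > 1:
        terms.append("C(block, Sum)")
    if df["cross"].nunique() > 1:
        terms.append("C(cross, Sum)")
    rhs = " + ".join(terms) if terms else "1"
    return f"{response} ~ {rhs}"


class _OLSAsMixed:
    """OLS result dressed in the mixed-model interface (no random terms).

    REML on a model with no random structure is exactly OLS with the
    residual variance on n - p denominators.
    """

    def __init__(self, res, reml: bool):
        self._res = res
        self.fe_params = res.params
        self.vcomp = np.empty(0)
        n, p = res.nobs, len(res.params)
        rss = float(res.ssr)
        self.scale = rss / (n - p) if reml else rss / n
        self.llf = float(res.llf)  # ML Gaussian log-likelihood
        if reml:  # REML log-likelihood of the fixed-only model
            sigma2 = rss / (n - p)
            X = res.model.exog
            _, logdet = np.linalg.slogdet(X.T @ X / sigma2)
            self.llf = float(
                -0.5 * (n - p) * (np.log(2 * np.pi * sigma2) + 1) - 0.5 * logdet
            )
        self.resid = res.resid
        self.model = res.model
        self.model.exog_vc = type("vc", (), {"names": []})()

    def cov_params(self):
        return self._res.cov_params()


def _fit_mixed(
    df: pd.DataFrame,
    response: str,
    random_terms: tuple[str, ...],
    reml: bool,
):
    formula = _fixed_formula(df, response)
    vcf = {t: f"0 + C({t})" for t in random_terms}
    if not vcf:
        res = sm.OLS.from_formula(formula, data=df).fit()
        return _OLSAsMixed(res, reml)
    model = MixedLM.from_formula(
        formula, groups=np.ones(len(df)), vc_formula=vcf, data=df
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=reml, method=["lbfgs", "cg"], maxiter=2000)
    return res


def fit_cross_lmm(
    scores: pd.DataFrame,
    response: str = "w",
    random_terms: tuple[str, ...] = _RANDOM_TERMS,
) -> VarianceDecomposition:
    """Decompose a trait with the block + cross mixed model.

    Requires at least two strains and both cross levels.  Variance
    estimates are REML (non-negative by construction); LRTs refit by ML
    with each random term dropped in turn; Wald chi-squares test each
    fixed term with the others retained (type II under sum coding).
    """
    df = _prep_frame(scores, response)
    if df["m_strain"].nunique() < 2 or df["cross"].nunique() < 2:
        raise ValueError("need >= 2 strains and both cross levels")
    res = _fit_mixed(df, response, random_terms, reml=True)

    variances = {
        t: float(v) for t, v in zip(res.model.exog_vc.names, res.vcomp)
    }
    variances["residual"] = float(res.scale)

    # likelihood-ratio tests per random term (ML refits)
    full_ml = _fit_mixed(df, response, random_terms, reml=False)
    lrt_rows = []
    for t in random_terms:
        reduced = tuple(u for u in random_terms if u != t)
        red_ml = _fit_mixed(df, response, reduced, reml=False)
        stat = max(0.0, 2.0 * (full_ml.llf - red_ml.llf))
        if variances.get(t, 0.0) < 1e-8:
            stat = 0.0
        p = float(stats.chi2.sf(stat, 1)) if stat > 0 else 1.0
        lrt_rows.append({"term": t, "statistic": stat, "df": 1, "p": p})
    lrt = pd.DataFrame(lrt_rows)

    # type-II Wald chi-square per fixed term
    fe = res.fe_params
    cov = np.asarray(res.cov_params())[: len(fe), : len(fe)]
    wald_rows = []
    for term in ("block", "cross"):
        cols = [
            i for i, name in enumerate(fe.index) if f"C({term}, Sum)" in name
        ]
        if not cols:
            continue
        b = fe.to_numpy()[cols]
        V = cov[np.ix_(cols, cols)]
        chi2 = float(b @ np.linalg.solve(V, b))
        wald_rows.append(
            {
                "term": term,
                "df": len(cols),
                "chi2": chi2,
                "p": float(stats.chi2.sf(chi2, len(cols))),
            }
        )
    wald = pd.DataFrame(wald_rows)

    emm = marginal_means(res, "cross")
    return VarianceDecomposition(
        response=response,
        variances=variances,
        fixed_effects=fe,
        lrt=lrt,
        wald=wald,
        emm=emm,
        n_obs=len(df),
        result=res,
    )


def marginal_means(result, factor: str) -> pd.DataFrame:
    """Estimated marginal means per level of a fixed factor.

    Predictions on a grid of all fixed-factor level combinations, averaged
    with equal weights over the other factors' levels, random effects at
    zero; SEs by the delta method on the fixed-effect covariance.
    """
    frame = result.model.data.frame
    design_info = result.model.data.design_info
    factors = [f for f in ("block", "cross") if f in frame.columns
               and any(f"C({f}, Sum)" in n for n in result.fe_params.index)]
    if factor not in frame.columns:
        raise ValueError(f"unknown factor {factor!r}")
    levels = sorted(frame[factor].unique())
    others = [f for f in factors if f != factor]
    fe = result.fe_params.to_numpy()
    cov = np.asarray(result.cov_params())[: len(fe), : len(fe)]
    rows = []
    for lev in levels:
        grid = {factor: [lev]}
        for o in others:
            grid[o] = sorted(frame[o].unique())
        gdf = pd.DataFrame(
            [
                {factor: lev, **dict(zip(others, combo))}
                for combo in _product([grid[o] for o in others])
            ]
        )
        if gdf.empty:
            gdf = pd.DataFrame({factor: [lev]})
        Xg = np.asarray(patsy.dmatrix(design_info, gdf))
        L = Xg.mean(axis=0)
        mean = float(L @ fe)
        se = float(np.sqrt(L @ cov @ L))
        rows.append({"level": lev, "mean": mean, "se": se})
    return pd.DataFrame(rows)


def _product(list_of_lists):
    if not list_of_lists:
        return [()]
    out = [()]
    for lst in list_of_lists:
        out = [t + (v,) for t in out for v in lst]
    return out


def residual_outlier_filter(
    scores: pd.DataFrame, result, k: float = 2.0
) -> tuple[pd.DataFrame, int]:
    """Drop rows whose model residual exceeds k x IQR in absolute value.

    A single pass anchored at zero (|residual| > k * IQR of the residual
    distribution); the caller refits on the kept rows.
    """
    resid = np.asarray(result.resid)
    if len(resid) != len(scores):
        raise ValueError("model residuals do not match the score table")
    iqr = float(np.subtract(*np.percentile(resid, [75, 25])))
    keep = np.abs(resid) <= k * iqr
    return scores.loc[keep].reset_index(drop=True), int((~keep).sum())


def lrt_boundary_mixture_p(stat: float) -> float:
    """Optional 50:50 chi2(0)/chi2(1) boundary-corrected p-value."""
    if stat <= 0:
        return 1.0
    return float(0.5 * stats.chi2.sf(stat, 1))


def analyze_trait(
    scores: pd.DataFrame,
    response: str = "w",
    outlier_k: float = 2.0,
) -> tuple[VarianceDecomposition, int]:
    """Fit, remove >k IQR residual outliers once, and refit.

    Returns the refit decomposition and the number of removed rows.
    """
    first = fit_cross_lmm(scores, response)
    kept, n_removed = residual_outlier_filter(scores, first.result, k=outlier_k)
    if n_removed == 0:
        return first, 0
    return fit_cross_lmm(kept, response), n_removed
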