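"""Behaviour and fitness model fitting with AIC model selection.

Behavioural traits (log home range, mean daytime depth, DVM) are analysed
with Gaussian linear mixed models carrying a fish-ID random intercept to
absorb among-individual variance; candidate fixed-effect structures are
compared by AIC with all models fitted by maximum likelihood (ML, not
REML) so that AICs are comparable across fixed-effect structures.
Fitness (relative longevity S) is analysed with the Lande-Arnold linear
regression of relative fitness on traits, whose coefficients estimate
selection gradients.

Factor coding is treatment contrasts with the ancestral arrangement, the
female sex and the feeding season as reference levels, so a term like
``LG07_inv:season`` is the extra effect of being homozygous-inverted at
LG07 during the spawning season.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_REGIONS = ("LG01", "LG02", "LG07", "LG12")


def _base_term_value(df: pd.DataFrame, term: str) -> np.ndarray:
    if term == "intercept":
        return np.ones(len(df))
    if term == "season":
        return (df["season"] == "spawning").to_numpy(float)
    if term == "length":
        return df["length_cm"].to_numpy(float)
    if term == "sex_male":
        return (df["sex"] == "M").to_numpy(float)
    if term.startswith("class_"):
        return (df["genotype_class"] == term.split("_", 1)[1]).to_numpy(float)
    for region in _REGIONS:
        for state in ("het", "inv"):
            if term == f"{region}_{state}":
                return (df[region] == state).to_numpy(float)
    raise ValueError(f"unknown design term {term!r}")


def build_design(df: pd.DataFrame, terms: list[str]) -> tuple[np.ndarray, list[str]]:
    """Design matrix for a term list; ``A:season`` denotes an interaction.

    Terms use treatment coding with reference levels feeding / ancestral /
    female; the shared grammar ties the simulator and the fitting code to
    the same parameterisation.
    """
    cols, names = [], []
    for t in terms:
        if ":" in t:
            a, b = t.split(":")
            v = _base_term_value(df, a) * _base_term_value(df, b)
        else:
            v = _base_term_value(df, t)
        cols.append(v)
        names.append(t)
    return np.column_stack(cols), names


def expand_terms(terms: list[str]) -> list[str]:
    """Expand factor shorthand: 'LG07' -> het+inv dummies, 'S*LG07' -> both
    main-effect dummies plus their season interactions."""
    out: list[str] = []
    for t in terms:
        inter = t.startswith("S*")
        base = t[2:] if inter else t
        if base in _REGIONS:
            expanded = [f"{base}_het", f"{base}_inv"]
        elif base == "class":
            expanded = ["class_TVEf"]
        else:
            expanded = [base]
        for e in expanded:
            if e not in out:
                out.append(e)
            if inter:
                out.append(f"{e}:season")
        if inter and "season" not in out:
            out.insert(0, "season")
    return out


@dataclass
class ModelSpec:
    """A fixed-effect structure for one response.

    ``terms`` are design terms per :func:`build_design` (the intercept is
    implicit); ``random_intercept`` adds a fish-ID random intercept.
    """

    response: str
    terms: list[str] = field(default_factory=list)
    random_intercept: bool = True
    label: str = ""

    @property
    def design_terms(self) -> list[str]:
        return ["intercept"] + [t for t in self.terms if t != "intercept"]


@dataclass
class FitResult:
    spec: ModelSpec
    params: pd.Series
    se: pd.Series
    pvalues: pd.Series
    aic: float
    llf: float
    n_params: int
    sigma2_id: float
    sigma2_res: float
    icc: float
    marginal_r2: float
    n_obs: int
    converged: bool
    singular: bool = False
    r_squared: float | None = None  # OLS only


def fit_trait_lmm(data: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Fit a Gaussian LMM (fish-ID random intercept) by maximum likelihood.

    Rows with a missing response are dropped.  AIC = -2 log L + 2 k with
    k = fixed effects + random-intercept variance + residual variance.
    A singular (near-zero) among-fish variance is reported via the
    ``singular`` flag, not silenced.
    """
    import statsmodels.api as sm
    import warnings

    df = data.dropna(subset=[spec.response]).reset_index(drop=True)
    y = df[spec.response].to_numpy(float)
    X, names = build_design(df, spec.design_terms)
    dead = [t for j, t in enumerate(names) if t != "intercept" and X[:, j].std() == 0]
    if dead:
        raise ValueError(f"design columns without variation (unobserved levels): {dead}")

    if not spec.random_intercept:
        res = sm.OLS(y, X).fit()
        k = X.shape[1] + 1
        resid_var = float(res.scale)
        fixed_var = float(np.var(res.fittedvalues))
        return FitResult(
            spec=spec,
            params=pd.Series(res.params, index=names),
            se=pd.Series(res.bse, index=names),
            pvalues=pd.Series(res.pvalues, index=names),
            aic=float(res.aic),
            llf=float(res.llf),
            n_params=k,
            sigma2_id=0.0,
            sigma2_res=resid_var,
            icc=0.0,
            marginal_r2=fixed_var / (fixed_var + resid_var),
            n_obs=len(y),
            converged=True,
            r_squared=float(res.rsquared),
        )

    groups = df["fish_id"].to_numpy()
    model = sm.MixedLM(y, X, groups=groups)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=False)
        except np.linalg.LinAlgError:
            res = model.fit(reml=False, method="powell", maxiter=500)
        if not res.converged:
            res = model.fit(reml=False, method="powell", maxiter=500)

    sigma2_res = float(res.scale)
    sigma2_id = float(np.asarray(res.cov_re)[0, 0])
    k = X.shape[1] + 2
    aic = -2.0 * float(res.llf) + 2.0 * k
    fixed_var = float(np.var(X @ res.fe_params))
    total = fixed_var + sigma2_id + sigma2_res
    return FitResult(
        spec=spec,
        params=pd.Series(np.asarray(res.fe_params), index=names),
        se=pd.Series(np.asarray(res.bse_fe), index=names),
        pvalues=pd.Series(np.asarray(res.pvalues)[: len(names)], index=names),
        aic=aic,
        llf=float(res.llf),
        n_params=k,
        sigma2_id=sigma2_id,
        sigma2_res=sigma2_res,
        icc=sigma2_id / (sigma2_id + sigma2_res),
        marginal_r2=fixed_var / total,
        n_obs=len(y),
        converged=bool(res.converged),
        singular=sigma2_id < 1e-8 * sigma2_res,
    )


def variance_partition(fit: FitResult) -> tuple[float, float]:
    """(ICC, marginal R²) of a mixed fit.

    ICC = sigma2_id / (sigma2_id + sigma2_res); marginal R² is the variance
    of the fixed-effect predictions over the total model variance
    (Nakagawa-style).
    """
    return fit.icc, fit.marginal_r2


def select_by_aic(labels: list[str], aics: list[float], n_params: list[int] | None = None):
    """Pick the minimum-AIC candidate; ties go to fewer parameters.

    Works on precomputed AIC columns as well as freshly fitted ones.
    Returns (selected label, ranked DataFrame).
    """
    df = pd.DataFrame({"label": labels, "aic": aics})
    df["n_params"] = n_params if n_params is not None else range(len(labels))
    ranked = df.sort_values(["aic", "n_params"], kind="mergesort").reset_index(drop=True)
    return ranked.loc[0, "label"], ranked


def aic_select(
    candidates: list[ModelSpec], data: pd.DataFrame
) -> tuple[FitResult, list[FitResult]]:
    """Fit all candidate specs by ML on identical rows and rank by AIC.

    All candidates must address the same response; rows with any NA among
    the union of needed columns are dropped once so every model sees the
    same data.  Returns (selected fit, fits ranked by AIC).
    """
    if len(candidates) < 2:
        raise ValueError("need >= 2 candidate models")
    responses = {c.response for c in candidates}
    if len(responses) != 1:
        raise ValueError("candidates must share a response")
    needed = {candidates[0].response, "fish_id"}
    for c in candidates:
        for t in c.design_terms:
            for part in t.split(":"):
                if part == "intercept":
                    continue
                elif part == "season":
                    needed.add("season")
                elif part == "length":
                    needed.add("length_cm")
                elif part == "sex_male":
                    needed.add("sex")
                elif part.startswith("class_"):
                    needed.add("genotype_class")
                else:
                    for r in _REGIONS:
                        if part.startswith(r):
                            needed.add(r)
    cols = [c for c in needed if c in data.columns]
    df = data.dropna(subset=cols).reset_index(drop=True)

    fits = [fit_trait_lmm(df, c) for c in candidates]
    order = np.lexsort(([f.n_params for f in fits], [f.aic for f in fits]))
    ranked = [fits[i] for i in order]
    return ranked[0], ranked


def two_step_ladder(
    response: str,
    data: pd.DataFrame,
    inversion_terms: list[str],
    size_sex_options: list[list[str]],
    inversion_options: list[list[str]],
    random_intercept: bool = True,
) -> tuple[FitResult, dict]:
    """Two-step AIC ladder.

    Step 1 chooses the body-size/sex structure while keeping all inversion
    terms of interest; step 2 keeps the winning size/sex structure and
    chooses the inversion structure.  Option lists use the
    :func:`expand_terms` shorthand (e.g. ``["S*LG07", "S*L"]``).
    """
    step1 = [
        ModelSpec(
            response=response,
            terms=expand_terms(inversion_terms + opt),
            random_intercept=random_intercept,
            label=" + ".join(inversion_terms + opt),
        )
        for opt in size_sex_options
    ]
    best1, ranked1 = aic_select(step1, data)
    chosen_size_sex = size_sex_options[step1.index(best1.spec)]

    step2 = [
        ModelSpec(
            response=response,
            terms=expand_terms(opt + chosen_size_sex),
            random_intercept=random_intercept,
            label=" + ".join(opt + chosen_size_sex),
        )
        for opt in inversion_options
    ]
    best2, ranked2 = aic_select(step2, data)
    return best2, {"step1": ranked1, "step2": ranked2, "size_sex": chosen_size_sex}


def fit_selection_model(data: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Lande-Arnold linear selection regression by OLS.

    The response is relative longevity S (mean 1 over included fish);
    coefficients are selection differentials on the fitted scale.  Rank
    deficiency is reported through near-zero degrees of freedom / NaN SEs
    rather than silenced.
    """
    spec = ModelSpec(
        response=spec.response,
        terms=spec.terms,
        random_intercept=False,
        label=spec.label,
    )
    return fit_trait_lmm(data, spec)
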