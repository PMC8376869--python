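"""GLM screens of season, host group and MHC effects on parasite load.

Fixed-effect approximation of the study design: sampling year enters as
a fixed factor instead of a random intercept, and overdispersed counts
use a negative-binomial family instead of Poisson observation-level
random effects.  Model choice per response follows the prevalence rule
(taxa at <= 30% prevalence are modeled as presence/absence, otherwise as
abundance), predictors are restricted to alleles/supertypes carried by
more than 7 individuals of the analyzed group, and each full model is
reduced by backward stepwise selection on AICc: a removal is accepted
when the reduced model's AICc is lower or within 2 of the larger model,
the simpler model being preferred; a likelihood-ratio p-value per
removal is reported as a supplementary, non-binding criterion.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import GenotypeTable, ParasiteMatrix

FAMILIES = ("poisson", "negbin", "bernoulli")


def choose_response_form(prevalence: float, strict_lt: bool = False) -> str:
    """'prevalence' for rare taxa, 'abundance' otherwise (30% rule)."""
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError("prevalence must lie in [0, 1]")
    rare = prevalence < 0.30 if strict_lt else prevalence <= 0.30
    return "prevalence" if rare else "abundance"


def eligible_predictors(presence: pd.DataFrame, min_carriers: int = 7
                        ) -> list[str]:
    """Presence columns carried by strictly more than ``min_carriers``
    individuals of the (already subset) group."""
    carriers = presence.sum(axis=0)
    return [c for c in presence.columns if carriers[c] > min_carriers]


@dataclass
class FitSummary:
    formula: str
    family: str
    params: pd.Series
    pvalues: pd.Series
    llf: float
    k: int
    n: int
    aicc: float
    converged: bool
    flags: list = field(default_factory=list)


def _aicc(llf: float, k: int, n: int) -> float:
    if n - k - 1 <= 0:
        return np.inf
    return -2.0 * llf + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def fit_glm(data: pd.DataFrame, formula: str, family: str) -> FitSummary:
    """Fit one GLM; NB dispersion is estimated by ML.

    Bernoulli fits showing separation (huge coefficients) are flagged
    and refit with a small L2 penalty on the linear predictor.
    """
    if family not in FAMILIES:
        raise ValueError(f"family must be one of {FAMILIES}")
    flags: list[str] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if family == "poisson":
            res = smf.glm(formula, data, family=sm.families.Poisson()).fit()
            converged = res.converged
        elif family == "bernoulli":
            res = smf.glm(formula, data, family=sm.families.Binomial()).fit()
            converged = res.converged
            if np.abs(res.params).max() > 15:
                flags.append("separation")
                res = smf.glm(formula, data,
                              family=sm.families.Binomial()
                              ).fit_regularized(alpha=1e-3, L1_wt=0.0)
                mu = np.clip(res.predict(data), 1e-9, 1 - 1e-9)
                y = res.model.endog
                llf = float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))
                k = len(res.params)
                n = len(y)
                return FitSummary(formula, family, res.params,
                                  pd.Series(np.nan, index=res.params.index),
                                  llf, k, n, _aicc(llf, k, n), True, flags)
        else:
            try:
                res = smf.negativebinomial(formula, data).fit(
                    method="bfgs", maxiter=200, disp=0)
                converged = bool(res.mle_retvals.get("converged", True))
            except Exception:
                res = smf.glm(formula, data, family=sm.families.Poisson()).fit()
                converged = res.converged
                flags.append("nb_fallback_poisson")
        llf = float(res.llf)
        params = res.params.copy()
        pvalues = res.pvalues.copy()
        k = len(params)
        n = int(res.nobs)
    if not converged:
        flags.append("not_converged")
    return FitSummary(formula, family, params, pvalues, llf, k, n,
                      _aicc(llf, k, n), converged, flags)


def _formula(response: str, terms: list[str]) -> str:
    rhs = " + ".join(terms) if terms else "1"
    return f"Q('{response}') ~ {rhs}"


def _main_effects_of(term: str) -> set[str]:
    return set(term.split(":")) if ":" in term else set()


def _removable(terms: list[str]) -> list[str]:
    """Interactions are removed before the main effects they contain."""
    locked = set()
    for t in terms:
        locked |= _main_effects_of(t)
    return [t for t in terms if t not in locked]


def backward_stepwise(data: pd.DataFrame, response: str, terms: list[str],
                      family: str, delta: float = 2.0):
    """AICc backward stepwise selection.

    Returns (final FitSummary, retained terms, trace DataFrame).  Each
    accepted removal records the AICc change and a supplementary
    likelihood-ratio p for the dropped term.
    """
    current_terms = list(terms)
    current = fit_glm(data, _formula(response, current_terms), family)
    trace = []
    while current_terms:
        candidates = []
        for term in _removable(current_terms):
            reduced_terms = [t for t in current_terms if t != term]
            fit = fit_glm(data, _formula(response, reduced_terms), family)
            lr = max(0.0, 2.0 * (current.llf - fit.llf))
            df = max(1, current.k - fit.k)
            p_lr = float(stats.chi2.sf(lr, df))
            candidates.append((fit.aicc, -p_lr, term, fit, p_lr))
        if not candidates:
            break
        candidates.sort(key=lambda c: (c[0], c[1], c[2]))
        best_aicc, _, term, fit, p_lr = candidates[0]
        if best_aicc <= current.aicc + delta:
            trace.append({"removed": term, "aicc_before": current.aicc,
                          "aicc_after": best_aicc, "p_lr": p_lr})
            current_terms = [t for t in current_terms if t != term]
            current = fit
        else:
            break
    return current, current_terms, pd.DataFrame(trace)


# ---------------------------------------------------------------------------
# model series

_ECTO = {"Monogenea", "Crustacea"}


def _assemble_data(genotypes: GenotypeTable, parasites: ParasiteMatrix,
                   predictors: pd.DataFrame | None = None) -> pd.DataFrame:
    idx = [i for i in genotypes.individuals
           if i in parasites.abundance.index]
    df = genotypes.ind_meta.loc[idx, ["group", "season", "year"]].copy()
    df["year"] = df["year"].astype(str)
    ab = parasites.abundance.loc[idx]
    df["total_abundance"] = ab.sum(axis=1)
    df["total_richness"] = (ab > 0).sum(axis=1)
    if parasites.taxon_meta is not None:
        grp_ab = parasites.group_abundance().loc[idx]
        for g in grp_ab.columns:
            df[f"{g}_abundance"] = grp_ab[g]
        ecto = [t for t in parasites.taxa
                if parasites.taxon_meta.loc[t, "taxon_group"] in _ECTO]
        df["ectoparasite_abundance"] = ab[ecto].sum(axis=1)
        df["endoparasite_abundance"] = ab.drop(columns=ecto).sum(axis=1)
    for taxon in parasites.taxa:
        df[taxon] = ab[taxon]
    df["DAB_t"] = genotypes.counts_per_individual().loc[idx]
    df["DAB1_t"] = genotypes.counts_per_individual("DAB1").loc[idx]
    df["DAB3_t"] = genotypes.counts_per_individual("DAB3").loc[idx]
    if predictors is not None:
        for c in predictors.columns:
            df[_safe_name(c)] = predictors.loc[idx, c].values
    return df


def _safe_name(name: str) -> str:
    return re.sub(r"\W", "_", name)


def _response_spec(df: pd.DataFrame, col: str, kind: str,
                   strict_lt: bool = False):
    """(column, family) after applying the 30% prevalence rule to taxa."""
    if kind == "richness":
        return col, "poisson"
    prev = float((df[col] > 0).mean())
    if choose_response_form(prev, strict_lt) == "prevalence":
        df[col + "_prev"] = (df[col] > 0).astype(int)
        return col + "_prev", "bernoulli"
    return col, "negbin"


def run_model_series(genotypes: GenotypeTable, parasites: ParasiteMatrix,
                     series: str = "counts", group: str | None = None,
                     supertypes: pd.DataFrame | None = None,
                     season_subset: str | None = None,
                     min_carriers: int = 7, strict_lt: bool = False,
                     responses: list[str] | None = None) -> pd.DataFrame:
    """One table of final models per response, mirroring the study layout.

    ``series``: 'counts' (season + group + allele numbers), 'counts-split'
    (DAB1_t/DAB3_t instead of DAB_t), 'alleles-by-group' or
    'supertypes-by-group' (season + presence predictors within one group).
    """
    if series in ("alleles-by-group", "supertypes-by-group") and group is None:
        raise ValueError(f"series {series} requires a host group")
    pred = None
    if series == "supertypes-by-group":
        if supertypes is None:
            raise ValueError("supertype assignment required")
        kept = supertypes[supertypes["kept"]]
        pres = {}
        for st in sorted(kept["supertype"].unique()):
            members = [a for a in kept.index[kept["supertype"] == st]
                       if a in genotypes.presence.columns]
            pres[f"ST_{st}"] = (genotypes.presence[members].sum(axis=1) > 0
                                ).astype(int)
        pred = pd.DataFrame(pres)
    elif series == "alleles-by-group":
        pred = genotypes.presence

    df = _assemble_data(genotypes, parasites, pred)
    if group is not None:
        df = df[df["group"] == group]
    if season_subset is not None:
        df = df[df["season"] == season_subset]

    response_specs = [("total_richness", "richness"),
                      ("total_abundance", "count")]
    response_specs += [(c, "count") for c in df.columns
                       if c.endswith("_abundance") and c != "total_abundance"]
    response_specs += [(t, "count") for t in parasites.taxa]
    if responses is not None:
        response_specs = [(c, k) for c, k in response_specs if c in responses]

    if series in ("counts", "counts-split"):
        base = ["season", "group", "year"]
        if series == "counts":
            base += ["DAB_t", "DAB_t:group"]
        else:
            base += ["DAB1_t", "DAB3_t", "DAB1_t:group", "DAB3_t:group"]
    else:
        base = ["season"]
        predictors = eligible_predictors(
            df[[_safe_name(c) for c in (pred.columns if pred is not None
                                        else [])]], min_carriers)
        base += predictors
    base = [t for t in base
            if all(df[p].nunique() > 1 for p in _main_effects_of(t) or [t]
                   if p in df.columns)]

    rows = []
    for col, kind in response_specs:
        if df[col].nunique() <= 1:
            rows.append({"response": col, "note": "zero variance, skipped"})
            continue
        resp, family = _response_spec(df, col, kind, strict_lt)
        fit, retained, trace = backward_stepwise(df, resp, base, family)
        for term in (retained or ["(intercept only)"]):
            entry = {"response": col, "form": family, "term": term,
                     "aicc": fit.aicc, "note": ";".join(fit.flags)}
            if term in ("(intercept only)",):
                rows.append(entry)
                continue
            match = [p for p in fit.params.index
                     if term.split(":")[0].split("[")[0] in p]
            if match:
                entry["coef"] = float(fit.params[match[0]])
                entry["sign"] = "+" if entry["coef"] > 0 else "-"
                entry["p"] = float(fit.pvalues[match[0]])
            rows.append(entry)
    out = pd.DataFrame(rows)
    if "p" in out.columns:
        mask = out["p"].notna()
        if mask.any():
            out.loc[mask, "p_bh"] = multipletests(
                out.loc[mask, "p"], method="fdr_bh")[1]
    return out
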