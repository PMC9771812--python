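"""Binomial-logit GLMs of cluster composition.

Cluster counts ``N_c`` out of sample totals ``N`` are modelled as
``N_c ~ Binomial(p_c, N)`` with ``logit(p_c) = beta X`` where the design
carries cluster indicators, sample covariates (site, signature, sort
fraction, region) and their cluster interactions. Enrichment is reported as
log2 odds ratios with Bonferroni-corrected Wald p-values, mirroring the
dot-plot convention (colour = log2 OR, size = -log10 adjusted p).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from patsy import dmatrix

from tmeco.core_tables import ClusterCountTable

LN2 = float(np.log(2.0))

#: absolute coefficient beyond which an estimate is treated as separated
SEPARATION_LIMIT = 15.0


@dataclass
class ModelSpec:
    """Which covariates and cluster interactions enter the model.

    ``covariates`` are sample metadata columns; ``interactions`` are
    covariates whose cluster interactions are reported. ``three_way`` adds the
    cluster x site x signature term. Reference levels default to the
    alphabetically first level unless overridden in ``reference_levels``.
    """

    covariates: tuple[str, ...] = ("site", "signature")
    interactions: tuple[str, ...] = ("site", "signature")
    three_way: bool = False
    exclude_sites: tuple[str, ...] = ()
    reference_levels: dict = field(default_factory=dict)
    scale: str | None = None  # None (binomial) or "X2" (quasi-binomial)
    ridge: float = 0.0

    def __post_init__(self) -> None:
        unknown = set(self.interactions) - set(self.covariates)
        if unknown:
            raise ValueError(f"interactions over covariates not in the model: {sorted(unknown)}")
        if self.three_way and not {"site", "signature"} <= set(self.covariates):
            raise ValueError("three-way term requires site and signature covariates")


def _treat(col: str, data: pd.DataFrame, spec: ModelSpec) -> str:
    ref = spec.reference_levels.get(col, sorted(data[col].astype(str).unique())[0])
    return f"C({col}, Treatment(reference={ref!r}))"


def build_design(
    table: ClusterCountTable, spec: ModelSpec
) -> tuple[pd.DataFrame, np.ndarray, str]:
    """Long-form data, design matrix and formula for the composition GLM.

    Returns ``(long, X, formula)`` where ``long`` has one row per
    (sample, cluster) with the response encoded as the cluster proportion
    ``prop = N_c / N`` and binomial weight ``n_total``, and ``X`` is the
    treatment-coded design matrix.
    """
    long = table.to_long()
    if spec.exclude_sites:
        if "site" not in long.columns:
            raise ValueError("exclude_sites given but no 'site' metadata present")
        long = long[~long["site"].isin(spec.exclude_sites)].copy()
    missing = [c for c in spec.covariates if c not in long.columns]
    if missing:
        raise ValueError(f"covariates missing from sample metadata: {missing}")
    for col in ("cluster", *spec.covariates):
        levels = long[col].astype(str).unique()
        if len(levels) < 2:
            raise ValueError(f"covariate {col!r} has a single level: {levels[0]!r}")
    if (long["n_total"] <= 0).any():
        bad = long.loc[long["n_total"] <= 0, "sample_id"].unique()
        raise ValueError(f"samples with zero total cells: {list(bad)}")
    long["prop"] = long["n_c"] / long["n_total"]

    cl = _treat("cluster", long, spec)
    terms = [cl]
    for cov in spec.covariates:
        terms.append(_treat(cov, long, spec))
    for cov in spec.interactions:
        terms.append(f"{cl}:{_treat(cov, long, spec)}")
    if spec.three_way:
        terms.append(f"{cl}:{_treat('site', long, spec)}:{_treat('signature', long, spec)}")
    formula = " + ".join(terms)
    X = dmatrix(formula, long, return_type="dataframe")
    return long, X, formula


@dataclass
class CompositionFit:
    """A fitted composition GLM with bookkeeping for reporting."""

    result: object
    long: pd.DataFrame
    design: pd.DataFrame
    formula: str
    spec: ModelSpec
    separated: tuple[str, ...] = ()

    @property
    def params(self) -> pd.Series:
        return self.result.params

    @property
    def converged(self) -> bool:
        return bool(getattr(self.result, "converged", True))


def fit_composition_glm(table: ClusterCountTable, spec: ModelSpec | None = None) -> CompositionFit:
    """Maximum-likelihood binomial-logit fit of cluster composition.

    Coefficients with an absolute estimate above :data:`SEPARATION_LIMIT` or a
    non-finite standard error are flagged as separated and later excluded from
    the enrichment report. ``spec.ridge`` adds a small L2 penalty for
    robustness against separation; ``spec.scale='X2'`` estimates a
    quasi-binomial overdispersion scale used in the Wald tests.
    """
    spec = spec or ModelSpec()
    long, X, formula = build_design(table, spec)
    family = sm.families.Binomial()
    model = sm.GLM(long["prop"], X, family=family, var_weights=long["n_total"])
    if spec.ridge > 0:
        alpha = np.full(X.shape[1], spec.ridge)
        alpha[0] = 0.0
        result = model.fit_regularized(alpha=alpha, L1_wt=0.0)
        # refit unpenalized covariance around the ridge solution is out of
        # scope; regularized results carry point estimates only
    else:
        result = model.fit(scale=spec.scale, maxiter=200)
        if not result.converged:
            raise RuntimeError(
                f"composition GLM did not converge in {result.fit_history['iteration']} iterations"
            )
    params = result.params
    bse = getattr(result, "bse", pd.Series(np.nan, index=params.index))
    separated = tuple(
        name
        for name in params.index
        if abs(params[name]) > SEPARATION_LIMIT or not np.isfinite(bse[name])
    )
    return CompositionFit(
        result=result, long=long, design=X, formula=formula, spec=spec, separated=separated
    )


def _parse_term(name: str) -> tuple[str, str] | None:
    """Map a patsy interaction column name to (cluster level, covariate level)."""
    parts = name.split(":")
    if len(parts) < 2:
        return None
    levels = []
    for part in parts:
        if "[T." not in part:
            return None
        levels.append(part.split("[T.", 1)[1].rstrip("]"))
    return levels[0], ":".join(levels[1:])


def enrichment_report(fit: CompositionFit) -> pd.DataFrame:
    """Per (cluster, covariate level) enrichment table.

    Each row corresponds to one cluster interaction term. For a two-way term
    the reported ``estimate`` is the cluster's log odds ratio between the
    covariate level and its reference level — the covariate main effect plus
    the cluster interaction, i.e. the change in ``logit p_c`` attributable to
    the level, which is what the enrichment/depletion dot plots colour. For a
    three-way term the raw coefficient (the site x signature modulation for
    that cluster) is reported. Columns: natural-log ``estimate``, ``se``,
    ``log2_or``, raw and Bonferroni-adjusted Wald p-values (family = number
    of reported rows) and ``neg_log10_p_adj``. Separated coefficients are
    excluded.
    """
    if not fit.converged:
        raise RuntimeError("cannot report from an unconverged fit")
    params = fit.result.params
    columns = list(params.index)
    rows = []
    for name in columns:
        parsed = _parse_term(name)
        if parsed is None or name in fit.separated:
            continue
        cluster, level = parsed
        contrast = np.zeros(len(columns))
        contrast[columns.index(name)] = 1.0
        main = name.split(":", 1)[1]
        if ":" not in main and main in columns:  # two-way: add the level main effect
            contrast[columns.index(main)] = 1.0
        test = fit.result.t_test(contrast)
        estimate = float(np.squeeze(test.effect))
        rows.append(
            {
                "cluster": cluster,
                "level": level,
                "estimate": estimate,
                "se": float(np.squeeze(test.sd)),
                "log2_or": estimate / LN2,
                "p_raw": float(np.squeeze(test.pvalue)),
                "n_samples": fit.long["sample_id"].nunique(),
            }
        )
    report = pd.DataFrame(rows)
    if report.empty:
        return report
    family = len(report)
    report["p_adj"] = np.minimum(1.0, report["p_raw"] * family)
    with np.errstate(divide="ignore"):
        report["neg_log10_p_adj"] = -np.log10(report["p_adj"])
    report.attrs["family_size"] = family
    report.attrs["formula"] = fit.formula
    return report
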