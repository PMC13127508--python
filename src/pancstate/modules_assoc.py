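"""Gene-module association with TF activity, and the clone genotype model.

Module scores (secretory acinar, UPR/ER stress, IFN/inflam, ductal core,
duct CFTRhi, duct MUC5B, ...) are regressed on residualized TF activity
with technical and design covariates, globally across all cells and
stratified within each exocrine subtype; BH FDR is computed jointly over
the whole module x stratum table.

The clone experiment models rank-based inverse-normal-transformed
expression against additive risk-allele dose with a random intercept per
edited clone (REML), falling back to OLS when the clone variance estimate
is zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import N_GENES_DETECTED
from .hurdle import bh_fdr, build_design

#: covariates for the global module models (subtype added when present)
MODULE_COVARIATES = (
    "donor",
    "context",
    N_GENES_DETECTED,
    "pct_mito",
    "pct_ribo",
    "contamination",
)

GLOBAL_STRATUM = "global"


@dataclass
class ModuleAssociation:
    module: str
    stratum: str
    coefficient: float
    se: float
    p: float
    n_cells: int
    status: str = "ok"
    fdr: float = np.nan


def fit_module_association(
    scores: np.ndarray,
    activity: np.ndarray,
    meta: pd.DataFrame,
    module: str = "module",
    stratum: str | None = None,
    covariates: tuple[str, ...] = MODULE_COVARIATES,
    include_subtype: bool = True,
) -> ModuleAssociation:
    """OLS of module scores on activity + covariates, optionally per subtype.

    When ``stratum`` names a subtype, cells are filtered to it first and
    the subtype covariate is dropped from the design.  Strata too small for
    the design return a status-flagged missing result rather than raising.
    """
    import statsmodels.api as sm

    scores = np.asarray(scores, dtype=float)
    activity = np.asarray(activity, dtype=float)
    mask = np.ones(len(scores), dtype=bool)
    label = GLOBAL_STRATUM
    use_subtype = include_subtype and "subtype" in meta.columns
    if stratum is not None:
        if "subtype" not in meta.columns:
            raise ValueError("stratified fit requires a 'subtype' metadata column")
        mask = (meta["subtype"] == stratum).to_numpy()
        label = stratum
        use_subtype = False

    cov_cols = list(covariates)
    if use_subtype:
        cov_cols = ["subtype"] + cov_cols
    missing = [c for c in cov_cols if c not in meta.columns]
    if missing:
        raise ValueError(f"fit_module_association: missing covariates {missing}")

    sub_meta = meta.loc[meta.index[mask], cov_cols]
    y = scores[mask]
    a = activity[mask]
    n = int(mask.sum())

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            X, names = build_design(a, sub_meta)
        except Exception:
            return ModuleAssociation(module, label, np.nan, np.nan, np.nan, n, "design_error")
    if n <= X.shape[1] + 1:
        return ModuleAssociation(module, label, np.nan, np.nan, np.nan, n, "too_few_cells")

    res = sm.OLS(y, X).fit()
    coef = float(res.params[1])
    se = float(res.bse[1])
    p = float(res.pvalues[1])
    return ModuleAssociation(module, label, coef, se, max(p, np.finfo(float).tiny), n)


class ModuleAssociationModel:
    """Fit every module globally and within each subtype stratum.

    ``fit()`` returns :class:`ModuleAssociationResults` whose frame carries
    one row per module x stratum with a jointly BH-adjusted FDR column.
    """

    def __init__(
        self,
        module_scores: pd.DataFrame,
        activity: np.ndarray,
        meta: pd.DataFrame,
        stratify: bool = True,
        covariates: tuple[str, ...] = MODULE_COVARIATES,
    ):
        if len(module_scores) != len(meta):
            raise ValueError("module scores and metadata are misaligned")
        self.module_scores = module_scores
        self.activity = np.asarray(activity, dtype=float)
        self.meta = meta
        self.stratify = stratify and "subtype" in meta.columns
        self.covariates = covariates

    def fit(self) -> "ModuleAssociationResults":
        strata: list[str | None] = [None]
        if self.stratify:
            strata += sorted(pd.unique(self.meta["subtype"]).tolist())
        rows: list[ModuleAssociation] = []
        for module in self.module_scores.columns:
            scores = self.module_scores[module].to_numpy(dtype=float)
            for stratum in strata:
                rows.append(
                    fit_module_association(
                        scores,
                        self.activity,
                        self.meta,
                        module=module,
                        stratum=stratum,
                        covariates=self.covariates,
                    )
                )
        return ModuleAssociationResults(rows)


class ModuleAssociationResults:
    def __init__(self, rows: list[ModuleAssociation]):
        frame = pd.DataFrame(
            {
                "module": [r.module for r in rows],
                "stratum": [r.stratum for r in rows],
                "coefficient": [r.coefficient for r in rows],
                "se": [r.se for r in rows],
                "p": [r.p for r in rows],
                "n_cells": [r.n_cells for r in rows],
                "status": [r.status for r in rows],
            }
        )
        frame["fdr"] = bh_fdr(frame["p"].to_numpy())
        self.frame = frame

    def summary(self, alpha: float = 0.05) -> str:
        f = self.frame
        lines = [
            "Module-activity associations",
            "============================",
            f"models fit:      {len(f)}",
            f"strata:          {f['stratum'].nunique()}",
            f"FDR < {alpha:g}:      {(f['fdr'] < alpha).sum()}",
        ]
        ok = f[f["status"] == "ok"]
        for _, row in ok[ok["stratum"] == GLOBAL_STRATUM].iterrows():
            star = "*" if row["fdr"] < alpha else " "
            lines.append(
                f"  {row['module']:<18s} beta={row['coefficient']:+.4f} "
                f"p={row['p']:.3g}{star}"
            )
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.8g")


# ----------------------------------------------------------------------
def int_transform(x: np.ndarray, offset: float = 0.375) -> np.ndarray:
    """Rank-based inverse normal transform (Blom offset 3/8; ties mid-ranked).

    y_i = Phi^-1((rank_i - offset) / (n - 2*offset + 1)).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("int_transform: need at least 2 values")
    if not np.all(np.isfinite(x)):
        raise ValueError("int_transform: non-finite values")
    ranks = stats.rankdata(x, method="average")
    quantiles = (ranks - offset) / (x.size - 2 * offset + 1)
    return stats.norm.ppf(quantiles)


class GenotypeDoseModel:
    """Additive genotype-dose model for INT expression with clone grouping.

    Data: one row per measurement with columns ``clone`` (categorical),
    ``dose`` (risk-allele count 0/1/2) and ``expression`` (already on the
    INT scale).  ``fit()`` runs a REML random-intercept model
    (expression ~ dose, random intercept per clone); when the clone
    variance estimate collapses to zero the OLS fit is returned instead.
    """

    def __init__(self, data: pd.DataFrame):
        required = {"clone", "dose", "expression"}
        if not required <= set(data.columns):
            raise ValueError(f"GenotypeDoseModel: data needs columns {sorted(required)}")
        doses = set(np.unique(data["dose"]))
        if not doses <= {0, 1, 2}:
            raise ValueError("GenotypeDoseModel: doses must be in {0, 1, 2}")
        if len(doses) < 2:
            raise ValueError("GenotypeDoseModel: need at least 2 distinct dose levels")
        if data["clone"].nunique() < 2:
            raise ValueError("GenotypeDoseModel: need at least 2 clones")
        self.data = data.reset_index(drop=True)

    def fit(self) -> "GenotypeDoseResults":
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        d = self.data
        method = "reml_random_intercept"
        beta = p = np.nan
        clone_var = np.nan
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                md = smf.mixedlm("expression ~ dose", d, groups=d["clone"])
                res = md.fit(reml=True)
            beta = float(res.params["dose"])
            p = float(res.pvalues["dose"])
            clone_var = float(res.cov_re.iloc[0, 0])
            if not np.isfinite(p) or clone_var < 1e-10:
                raise RuntimeError("degenerate random-effect fit")
        except Exception:
            X = np.column_stack([np.ones(len(d)), d["dose"].to_numpy(dtype=float)])
            ols = sm.OLS(d["expression"].to_numpy(dtype=float), X).fit()
            beta = float(ols.params[1])
            p = float(ols.pvalues[1])
            clone_var = 0.0
            method = "ols_fallback"
        return GenotypeDoseResults(beta=beta, p=p, clone_var=clone_var, method=method,
                                   n_obs=len(d), n_clones=d["clone"].nunique())


@dataclass
class GenotypeDoseResults:
    beta: float
    p: float
    clone_var: float
    method: str
    n_obs: int
    n_clones: int

    def summary(self) -> str:
        return "\n".join(
            [
                "Genotype-dose association (INT expression)",
                "==========================================",
                f"observations:   {self.n_obs} ({self.n_clones} clones)",
                f"dose effect:    {self.beta:+.4f}",
                f"p-value:        {self.p:.3g}",
                f"clone variance: {self.clone_var:.4f}",
                f"method:         {self.method}",
            ]
        )


def fit_genotype_association(data: pd.DataFrame) -> tuple[float, float]:
    """Functional wrapper: returns (dose coefficient, p-value)."""
    res = GenotypeDoseModel(data).fit()
    return res.beta, res.p
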