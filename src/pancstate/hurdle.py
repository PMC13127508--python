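"""Two-part hurdle association between TF activity and per-gene expression.

For each gene, expression across cells is split into a binary detection
indicator (expression > 0) and a continuous level among detected cells.
Detection is modeled by logistic regression on activity plus covariates;
the continuous level by OLS on the same design restricted to detected
cells.  Per-component evidence (signed z from the two-sided p-value and
the coefficient's sign) is combined Stouffer-style with configurable
weights (equal for the exocrine arm, 2:1 detection:continuous for the
tumor arm), and an overall p-value comes from Fisher's method.  BH FDRs
are computed per component and for the combination.

The statsmodels-style surface is :class:`HurdleModel` (built from an
:class:`AnnotatedMatrix` plus an activity vector) whose ``fit()`` returns
:class:`HurdleResults` with a results frame, ``summary()`` and RNK export.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import AnnotatedMatrix, N_GENES_DETECTED

#: covariate presets for the two analysis arms
EXOCRINE_COVARIATES = ("subtype", "donor", "context", N_GENES_DETECTED)
TUMOR_COVARIATES = ("cluster", "sample", N_GENES_DETECTED)

STATUS_OK = "ok"
STATUS_TOO_FEW = "too_few_positive"
STATUS_FIT_ERROR = "fit_error"
STATUS_DEGENERATE = "degenerate_detection"

RESULT_COLUMNS = [
    "gene",
    "n_pos",
    "logOR_det",
    "OR_det",
    "p_det",
    "z_det",
    "beta_cont",
    "p_cont",
    "z_cont",
    "z_combined",
    "p_combined",
    "FDR_det",
    "FDR_cont",
    "FDR_comb",
    "status",
]


def build_design(
    activity: np.ndarray, covariates: pd.DataFrame | None
) -> tuple[np.ndarray, list[str]]:
    """Design matrix: intercept, activity, then expanded covariates.

    Categorical (non-numeric) covariate columns expand to indicator columns
    with the first level as reference.  Numeric adjustment covariates are
    z-scaled (the activity term is passed through untouched, so its
    coefficient keeps its scale); collinear columns other than the activity
    term are dropped with a warning.
    """
    n = len(activity)
    blocks = [np.ones((n, 1)), np.asarray(activity, dtype=float).reshape(-1, 1)]
    names = ["const", "activity"]
    if covariates is not None and covariates.shape[1] > 0:
        for col in covariates.columns:
            v = covariates[col]
            if pd.api.types.is_numeric_dtype(v):
                x = np.asarray(v, dtype=float)
                if x.std() > 0:
                    x = (x - x.mean()) / x.std()
                blocks.append(x.reshape(-1, 1))
                names.append(col)
            else:
                dummies = pd.get_dummies(v, prefix=col, drop_first=True, dtype=float)
                blocks.append(dummies.to_numpy())
                names.extend(dummies.columns.tolist())
    X = np.hstack(blocks)
    X, names = _drop_collinear(X, names, protected={"const", "activity"})
    return X, names


def _drop_collinear(
    X: np.ndarray, names: list[str], protected: set[str]
) -> tuple[np.ndarray, list[str]]:
    keep = list(range(X.shape[1]))
    # constant non-intercept columns first, then rank-deficiency by greedy QR
    for j in range(X.shape[1] - 1, -1, -1):
        if names[j] not in protected and np.ptp(X[:, j]) == 0:
            keep.remove(j)
    Xk = X[:, keep]
    if np.linalg.matrix_rank(Xk) < Xk.shape[1]:
        kept: list[int] = []
        for j in keep:
            trial = kept + [j]
            if np.linalg.matrix_rank(X[:, trial]) == len(trial):
                kept.append(j)
            elif names[j] in protected:
                raise ValueError(f"design column {names[j]!r} is collinear")
            else:
                warnings.warn(f"dropping collinear design column {names[j]!r}")
        keep = kept
    dropped = set(range(X.shape[1])) - set(keep)
    if dropped:
        for j in sorted(dropped):
            if names[j] not in protected and np.ptp(X[:, j]) == 0:
                warnings.warn(f"dropping constant design column {names[j]!r}")
    return X[:, keep], [names[j] for j in keep]


def _logit_fit(X: np.ndarray, y: np.ndarray):
    """Maximum-likelihood logistic fit; returns (coef, se) for column 1."""
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y, X)
        res = model.fit(disp=0, maxiter=50, method="newton")
        if not res.mle_retvals.get("converged", True):
            raise RuntimeError("logistic fit did not converge")
        # guard against separation: unbounded coefficients
        if not np.all(np.isfinite(res.bse)) or np.any(np.abs(res.params) > 50):
            raise RuntimeError("logistic fit degenerate (possible separation)")
    return float(res.params[1]), float(res.bse[1])


def _ols_fit(X: np.ndarray, y: np.ndarray):
    """OLS fit; returns (coef, se, df_resid) for column 1."""
    import statsmodels.api as sm

    res = sm.OLS(y, X).fit()
    return float(res.params[1]), float(res.bse[1]), float(res.df_resid)


@dataclass
class HurdleResult:
    """Per-gene hurdle statistics (one row of the results frame)."""

    gene: str
    n_pos: int
    status: str
    logOR_det: float = np.nan
    p_det: float = np.nan
    z_det: float = np.nan
    beta_cont: float = np.nan
    p_cont: float = np.nan
    z_cont: float = np.nan
    z_combined: float = np.nan
    p_combined: float = np.nan

    @property
    def OR_det(self) -> float:
        return float(np.exp(self.logOR_det))


def fit_hurdle_gene(
    expr: np.ndarray,
    activity: np.ndarray,
    covariates: pd.DataFrame | None = None,
    min_pos: int = 25,
    weights: tuple[float, float] = (1.0, 1.0),
    clip: float = 10.0,
) -> HurdleResult:
    """Fit the two-part hurdle model for one gene.

    Genes with fewer than ``min_pos`` expressing cells get status
    ``too_few_positive`` and no statistics.  All-detected genes get status
    ``degenerate_detection`` (detection component missing) with the
    continuous part still fit.
    """
    expr = np.asarray(expr, dtype=float)
    activity = np.asarray(activity, dtype=float)
    det = (expr > 0).astype(float)
    n_pos = int(det.sum())
    gene = ""

    if n_pos < min_pos:
        return HurdleResult(gene=gene, n_pos=n_pos, status=STATUS_TOO_FEW)

    status = STATUS_OK
    logOR = p_det = z_det = np.nan
    if det.all():
        status = STATUS_DEGENERATE
    else:
        try:
            X, _ = build_design(activity, covariates)
            coef, se = _logit_fit(X, det)
            logOR = coef
            z_raw = coef / se
            p_det = float(2 * stats.norm.sf(abs(z_raw)))
            p_det = max(p_det, np.finfo(float).tiny)
            z_det = float(np.sign(coef) if coef != 0 else 0.0) * float(
                stats.norm.isf(p_det / 2)
            )
        except Exception:
            status = STATUS_FIT_ERROR

    beta = p_cont = z_cont = np.nan
    pos_mask = det > 0
    try:
        sub_cov = covariates.loc[covariates.index[pos_mask]] if covariates is not None else None
        Xc, _ = build_design(activity[pos_mask], sub_cov)
        coef, se, df = _ols_fit(Xc, expr[pos_mask])
        beta = coef
        t_raw = coef / se
        p_cont = float(2 * stats.t.sf(abs(t_raw), df))
        p_cont = max(p_cont, np.finfo(float).tiny)
        z_cont = float(np.sign(coef) if coef != 0 else 0.0) * float(
            stats.norm.isf(p_cont / 2)
        )
    except Exception:
        if status == STATUS_OK:
            status = STATUS_FIT_ERROR

    result = HurdleResult(
        gene=gene,
        n_pos=n_pos,
        status=status,
        logOR_det=logOR,
        p_det=p_det,
        z_det=z_det,
        beta_cont=beta,
        p_cont=p_cont,
        z_cont=z_cont,
    )
    if status in (STATUS_OK, STATUS_DEGENERATE):
        zc, pc = combine_evidence(
            p_det=None if np.isnan(p_det) else p_det,
            sign_det=float(np.sign(z_det)) if not np.isnan(z_det) else 1.0,
            p_cont=None if np.isnan(p_cont) else p_cont,
            sign_cont=float(np.sign(z_cont)) if not np.isnan(z_cont) else 1.0,
            weights=weights,
            clip=clip,
        )
        result.z_combined = zc
        result.p_combined = pc
    return result


def combine_evidence(
    p_det: float | None,
    sign_det: float,
    p_cont: float | None,
    sign_cont: float,
    weights: tuple[float, float] = (1.0, 1.0),
    clip: float = 10.0,
) -> tuple[float, float]:
    """Weighted signed-z (Stouffer) and Fisher combination of two components.

    z_i = sign_i * Phi^-1(1 - p_i / 2), clipped to +/- clip;
    z_combined = (w_det z_det + w_cont z_cont) / sqrt(w_det^2 + w_cont^2);
    p_combined = chi-square(4 df) survival at -2 (ln p_det + ln p_cont).
    A single available component passes through as-is; both missing returns
    (nan, nan).
    """
    w_det, w_cont = weights
    if w_det <= 0 or w_cont <= 0:
        raise ValueError("combine_evidence: weights must be positive")

    def to_z(p: float, sign: float) -> float:
        if not (0 < p <= 1):
            raise ValueError(f"combine_evidence: p-value {p} outside (0, 1]")
        if sign not in (-1.0, 0.0, 1.0):
            sign = float(np.sign(sign))
        z = float(stats.norm.isf(p / 2))
        return float(np.clip(sign * z, -clip, clip))

    have_det = p_det is not None and not (isinstance(p_det, float) and np.isnan(p_det))
    have_cont = p_cont is not None and not (isinstance(p_cont, float) and np.isnan(p_cont))
    if not have_det and not have_cont:
        return np.nan, np.nan
    if have_det and not have_cont:
        return to_z(p_det, sign_det), float(p_det)
    if have_cont and not have_det:
        return to_z(p_cont, sign_cont), float(p_cont)

    z_det = to_z(p_det, sign_det)
    z_cont = to_z(p_cont, sign_cont)
    z_combined = (w_det * z_det + w_cont * z_cont) / np.sqrt(w_det**2 + w_cont**2)
    fisher_x = -2.0 * (np.log(p_det) + np.log(p_cont))
    p_combined = float(stats.chi2.sf(fisher_x, df=4))
    p_combined = max(p_combined, np.finfo(float).tiny)
    return float(z_combined), p_combined


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaN entries pass through."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.sum() == 0:
        return out
    vals = p[mask]
    if np.any((vals <= 0) | (vals > 1)):
        raise ValueError("bh_fdr: p-values outside (0, 1]")
    out[mask] = multipletests(vals, method="fdr_bh")[1]
    return out


def export_rank_file(results: pd.DataFrame, path, clip: float = 10.0) -> None:
    """Write a two-column RNK file (gene, clipped z_combined) sorted descending."""
    frame = results[results["status"].isin([STATUS_OK, STATUS_DEGENERATE])]
    frame = frame.dropna(subset=["z_combined"])
    if frame["gene"].duplicated().any():
        raise ValueError("export_rank_file: duplicate gene symbols")
    z = frame["z_combined"].clip(-clip, clip)
    ordered = pd.DataFrame({"gene": frame["gene"], "z": z}).sort_values(
        "z", ascending=False, kind="stable"
    )
    ordered.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


def read_rank_file(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=["gene", "z"])


class HurdleModel:
    """Per-gene hurdle association of expression with an activity score.

    Parameters
    ----------
    m
        Log-normalized :class:`AnnotatedMatrix`.
    activity
        Per-cell activity vector aligned with ``m`` (typically residualized
        TF activity).
    covariates
        Metadata column names used as adjustment covariates; categorical
        columns expand to fixed-effect indicators.  Presets:
        :data:`EXOCRINE_COVARIATES`, :data:`TUMOR_COVARIATES`.
    genes
        Optional subset of gene symbols to fit (default: all).
    """

    def __init__(
        self,
        m: AnnotatedMatrix,
        activity: np.ndarray,
        covariates: tuple[str, ...] = EXOCRINE_COVARIATES,
        genes: list[str] | None = None,
        min_pos: int = 25,
        weights: tuple[float, float] = (1.0, 1.0),
        clip: float = 10.0,
    ):
        if m.lognorm is None:
            raise ValueError("HurdleModel: log-normalized layer required")
        self.m = m
        self.activity = np.asarray(activity, dtype=float)
        if len(self.activity) != m.n_cells:
            raise ValueError("HurdleModel: activity length mismatch")
        missing = [c for c in covariates if c not in m.cell_meta.columns]
        if missing:
            raise ValueError(f"HurdleModel: missing covariate columns {missing}")
        self.covariates = m.cell_meta.loc[:, list(covariates)]
        self.genes = list(genes) if genes is not None else list(m.genes)
        self.min_pos = min_pos
        self.weights = weights
        self.clip = clip

    def fit(self) -> "HurdleResults":
        gene_pos = self.m.genes.get_indexer(self.genes)
        if np.any(gene_pos < 0):
            raise KeyError("HurdleModel: unknown gene symbols requested")
        rows = []
        for g, j in zip(self.genes, gene_pos):
            res = fit_hurdle_gene(
                self.m.lognorm[:, j],
                self.activity,
                self.covariates,
                min_pos=self.min_pos,
                weights=self.weights,
                clip=self.clip,
            )
            res.gene = g
            rows.append(res)
        return HurdleResults(rows, weights=self.weights, clip=self.clip)


class HurdleResults:
    """Fitted hurdle-model results across genes, with FDRs and export."""

    def __init__(self, rows: list[HurdleResult], weights=(1.0, 1.0), clip=10.0):
        self.rows = rows
        self.weights = weights
        self.clip = clip
        self.frame = self._build_frame()

    def _build_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            recs.append(
                {
                    "gene": r.gene,
                    "n_pos": r.n_pos,
                    "logOR_det": r.logOR_det,
                    "OR_det": np.exp(r.logOR_det),
                    "p_det": r.p_det,
                    "z_det": r.z_det,
                    "beta_cont": r.beta_cont,
                    "p_cont": r.p_cont,
                    "z_cont": r.z_cont,
                    "z_combined": r.z_combined,
                    "p_combined": r.p_combined,
                    "status": r.status,
                }
            )
        frame = pd.DataFrame(recs)
        if len(frame):
            frame["FDR_det"] = bh_fdr(frame["p_det"].to_numpy())
            frame["FDR_cont"] = bh_fdr(frame["p_cont"].to_numpy())
            frame["FDR_comb"] = bh_fdr(frame["p_combined"].to_numpy())
            frame = frame[
                ["gene", "n_pos", "logOR_det", "OR_det", "p_det", "z_det",
                 "beta_cont", "p_cont", "z_cont", "z_combined", "p_combined",
                 "FDR_det", "FDR_cont", "FDR_comb", "status"]
            ]
        return frame

    def summary(self, alpha: float = 0.05) -> str:
        f = self.frame
        ok = f[f["status"] == STATUS_OK]
        lines = [
            "Hurdle association results",
            "==========================",
            f"genes fit:          {len(f)}",
            f"status ok:          {len(ok)}",
            f"too few positive:   {(f['status'] == STATUS_TOO_FEW).sum()}",
            f"degenerate det.:    {(f['status'] == STATUS_DEGENERATE).sum()}",
            f"fit errors:         {(f['status'] == STATUS_FIT_ERROR).sum()}",
            f"weights (det:cont): {self.weights[0]:g}:{self.weights[1]:g}",
            f"FDR_comb < {alpha:g}:    {(ok['FDR_comb'] < alpha).sum()}",
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.8g")

    def export_rank_file(self, path) -> None:
        export_rank_file(self.frame, path, clip=self.clip)
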