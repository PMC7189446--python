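"""Loop-conditioned coregulation: partner log2-fold-change regressions.

Differentially expressed (DE) gene pairs joined by conserved loops are fit
by ordinary least squares with the first gene's log2(fold change) as
predictor and the second gene's as response.  Stratified variants repeat the
fit per distance quartile or per loop-strength (Z) quartile combination
across two conditions, mirroring the published analysis design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["RegressionResult", "select_de_pairs", "regress_pair_logfc", "stratified_regression"]


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    f_pvalue: float
    n_pairs: int
    stratum: str = ""


def select_de_pairs(
    pairs: pd.DataFrame,
    de_table: pd.DataFrame | None = None,
    p_max: float = 0.01,
    require_conserved: bool = True,
) -> pd.DataFrame:
    """Keep pairs whose both genes are DE and whose loop is conserved.

    ``de_table`` (gene_id, log2fc, pvalue) overrides any per-pair DE columns;
    without it the pair table must carry ``de_pvalue1/2`` and ``log2fc1/2``.
    Conservation requires a finite ``z_other`` column (strength in the other
    condition), as produced by conserved-loop matching; pairs lacking a
    log2FC are dropped (counted in ``result.attrs["n_dropped_missing_fc"]``).
    """
    work = pairs.copy()
    if de_table is not None:
        de = de_table.set_index("gene_id")
        for tag in ("1", "2"):
            work[f"de_pvalue{tag}"] = de["pvalue"].reindex(work[f"gene{tag}"]).to_numpy()
            work[f"log2fc{tag}"] = de["log2fc"].reindex(work[f"gene{tag}"]).to_numpy()
    for col in ("de_pvalue1", "de_pvalue2", "log2fc1", "log2fc2"):
        if col not in work.columns:
            raise ValueError(f"pair table lacks column {col!r}")
    keep = (work["de_pvalue1"] < p_max) & (work["de_pvalue2"] < p_max)
    if require_conserved:
        if "z_other" in work.columns:
            keep &= np.isfinite(work["z_other"].to_numpy(dtype=float))
        elif "z_root" in work.columns:
            keep &= np.isfinite(work["z_root"].to_numpy(dtype=float))
    have_fc = np.isfinite(work["log2fc1"].to_numpy(dtype=float)) & np.isfinite(
        work["log2fc2"].to_numpy(dtype=float)
    )
    out = work[keep & have_fc].reset_index(drop=True)
    out.attrs["n_dropped_missing_fc"] = int((keep & ~have_fc).sum())
    return out


def regress_pair_logfc(pairs: pd.DataFrame, stratum: str = "") -> RegressionResult:
    """OLS of log2fc2 on log2fc1: slope, intercept, R^2, F-test p (1, n-2 df)."""
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 pairs for a fit, have {len(pairs)}")
    x = pairs["log2fc1"].to_numpy(dtype=float)
    y = pairs["log2fc2"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in predictor log2fc1")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        f_pvalue=float(model.f_pvalue),
        n_pairs=len(pairs),
        stratum=stratum,
    )


def _quartile(x: np.ndarray, n: int) -> np.ndarray:
    breaks = np.quantile(x, np.arange(1, n) / n)
    return np.searchsorted(breaks, x, side="left")


def stratified_regression(
    pairs: pd.DataFrame,
    strat: str = "strength",
    n_quantiles: int = 4,
    z_cols: tuple[str, str] = ("z", "z_other"),
) -> pd.DataFrame:
    """Repeat the pair regression per stratum.

    ``strat='distance'``: quartiles of the pair distance (n_quantiles fits).
    ``strat='strength'``: quantiles of loop Z in each of two conditions
    (columns ``z_cols``), giving an n x n grid of fits.  Cells with fewer
    than 3 pairs are reported with NaN statistics.  Returns a tidy frame with
    stratum labels, n, slope, intercept, r_squared, f_pvalue.
    """
    rows = []
    if strat == "distance":
        d = pairs["distance"].to_numpy(dtype=float)
        labels = _quartile(d, n_quantiles)
        for qd in range(n_quantiles):
            sub = pairs[labels == qd]
            rec = {"stratum": f"distance_q{qd + 1}", "n": len(sub)}
            rows.append(_fit_row(rec, sub))
    elif strat == "strength":
        za = pairs[z_cols[0]].to_numpy(dtype=float)
        zb = pairs[z_cols[1]].to_numpy(dtype=float)
        qa = _quartile(za, n_quantiles)
        qb = _quartile(zb, n_quantiles)
        for i in range(n_quantiles):
            for j in range(n_quantiles):
                sub = pairs[(qa == i) & (qb == j)]
                rec = {
                    "stratum": f"zA_q{i + 1}:zB_q{j + 1}",
                    "qa": i + 1,
                    "qb": j + 1,
                    "n": len(sub),
                }
                rows.append(_fit_row(rec, sub))
    else:
        raise ValueError(f"unknown stratification {strat!r}")
    return pd.DataFrame(rows)


def _fit_row(rec: dict, sub: pd.DataFrame) -> dict:
    if len(sub) >= 3 and np.ptp(sub["log2fc1"].to_numpy(dtype=float)) > 0:
        fit = regress_pair_logfc(sub)
        rec.update(
            slope=fit.slope, intercept=fit.intercept,
            r_squared=fit.r_squared, f_pvalue=fit.f_pvalue,
        )
    else:
        rec.update(slope=np.nan, intercept=np.nan, r_squared=np.nan, f_pvalue=np.nan)
    return rec
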