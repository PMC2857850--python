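"""Model comparison and prediction-accuracy reporting.

Produces the standard comparison layout: one row per fitted covariance
model with its AIC, free identity-variance component (residual or
polygenic, depending on the residual mode), fitted range parameter, and
Pearson correlations of the GEBVs with (a) the stage-1 fitted values of
the phenotyped individuals and (b) the true breeding values of the
unphenotyped (validation) individuals when a TBV table is supplied.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .growth import Stage1Result
from .model import GenomicBLUPResults

__all__ = ["pearson", "comparison_table", "render_report"]


def pearson(a, b) -> float:
    """Product-moment correlation; NaN when either series has zero variance."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1-d arrays of equal length")
    if len(a) < 3:
        raise ValueError("need at least 3 observations")
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def _identity_variance_label(res: GenomicBLUPResults) -> tuple[str, float | None]:
    vc = res.varcomp
    if vc.sigma2_e is not None:
        return "residual_variance", vc.sigma2_e
    return "polygenic_variance", vc.sigma2_v


def comparison_table(
    fits: dict[str, GenomicBLUPResults],
    stage1: Stage1Result | pd.Series,
    tbv: pd.Series | None = None,
    *,
    validation_ids=None,
    tbv_all_individuals: bool = False,
) -> pd.DataFrame:
    """One comparison row per fitted model.

    GEBV-TBV correlations are computed over the unphenotyped validation
    individuals (the prediction target) unless ``tbv_all_individuals``;
    GEBV-fitted correlations over the phenotyped set.  All fits must share
    the same training individuals.
    """
    if not fits:
        raise ValueError("no fitted models supplied")
    fitted = stage1.predictions if isinstance(stage1, Stage1Result) else stage1
    rows = []
    ref_ids = None
    for name, res in fits.items():
        ids = list(res.model.ids)
        if ref_ids is None:
            ref_ids = ids
        elif ids != ref_ids:
            raise ValueError(f"fit {name!r} was made on a different individual set")
        gebv_train = res.gebv
        common = [i for i in ids if i in fitted.index]
        corr_fitted = (
            pearson(gebv_train.loc[common], fitted.loc[common]) if len(common) >= 3 else np.nan
        )
        corr_tbv = np.nan
        if tbv is not None:
            if tbv_all_individuals:
                table = res.gebv_table()
                eval_ids = [i for i in table.index if i in tbv.index]
                corr_tbv = pearson(table.loc[eval_ids, "gebv"], tbv.loc[eval_ids])
            else:
                pred = res.predict(ids=validation_ids) if validation_ids is not None else res.predict()
                eval_ids = [i for i in pred.index if i in tbv.index]
                if len(eval_ids) >= 3:
                    corr_tbv = pearson(pred.loc[eval_ids], tbv.loc[eval_ids])
        label, ident = _identity_variance_label(res)
        rows.append(
            {
                "model": name,
                "aic": res.aic,
                label: ident,
                "theta": res.theta,
                "corr_fitted": corr_fitted,
                "corr_tbv": corr_tbv,
            }
        )
    table = pd.DataFrame(rows).set_index("model")
    table["aic_rank"] = table["aic"].rank(method="min").astype(int)
    return table


def render_report(table: pd.DataFrame) -> str:
    """Human-readable text report of a comparison table."""
    lines = [
        "Genotypic covariance model comparison",
        "(smaller AIC preferred; corr_tbv computed on unphenotyped individuals)",
        "",
        table.to_string(float_format=lambda v: f"{v:.4f}"),
        "",
        f"AIC-best model: {table['aic'].idxmin()}",
    ]
    return "\n".join(lines)
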