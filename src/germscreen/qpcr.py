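"""Relative qPCR quantification and germline-vs-soma attribution.

Ct values are normalized to the reference gene gpd-1 (GAPDH) per
biological replicate (technical replicates averaged first), fold
changes are 2**(-ddCt) against the vehicle arm with an unpaired
two-tailed t-test on per-replicate dCt values, and the glp-1
temperature design attributes changes to the germline: worms grown at
15C carry a germline (soma + germline expression), worms shifted to
25C do not (soma only), so an effect significant at 15C but not at
25C is germline specific.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simkit import REFERENCE_GENE

__all__ = [
    "delta_ct", "relative_expression", "germline_attribution",
    "attribution_report", "ExpressionResult",
]

CT_COLUMNS = ["gene", "condition", "temp_c", "bio_rep", "tech_rep", "ct"]


@dataclass(frozen=True)
class ExpressionResult:
    """Fold change of one gene in one condition arm vs vehicle."""

    gene: str
    fold: float
    p_value: float
    n_treated: int
    n_vehicle: int
    unbalanced_tech: bool = False


def delta_ct(records: pd.DataFrame,
             reference_gene: str = REFERENCE_GENE) -> pd.DataFrame:
    """Reference-normalized dCt per (condition, temp, bio_rep, gene).

    Technical replicates are averaged first; then
    dCt = mean Ct(target) - mean Ct(reference) within each biological
    replicate of each sample.  A sample missing the reference gene is
    an error; unbalanced technical replication is tolerated (mean of
    the available wells) and flagged.
    """
    missing = [c for c in CT_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"Ct table missing column(s): {', '.join(missing)}")
    if records.empty:
        raise ValueError("empty Ct table")
    tech = (records.groupby(["condition", "temp_c", "bio_rep", "gene"])
            .agg(mean_ct=("ct", "mean"), n_tech=("ct", "size"))
            .reset_index())
    out_rows = []
    for (cond, temp, rep), sub in tech.groupby(["condition", "temp_c",
                                                "bio_rep"]):
        ref = sub.loc[sub.gene == reference_gene, "mean_ct"]
        if ref.empty:
            raise ValueError(
                f"sample ({cond!r}, {temp}C, rep {rep}) lacks the reference "
                f"gene {reference_gene!r}")
        ref_ct = float(ref.iloc[0])
        unbalanced = sub["n_tech"].nunique() > 1
        for row in sub.itertuples(index=False):
            if row.gene == reference_gene:
                continue
            out_rows.append({
                "condition": cond, "temp_c": temp, "bio_rep": rep,
                "gene": row.gene, "delta_ct": row.mean_ct - ref_ct,
                "unbalanced_tech": unbalanced,
            })
    return pd.DataFrame(out_rows)


def relative_expression(treated_dct: pd.DataFrame | np.ndarray,
                        vehicle_dct: pd.DataFrame | np.ndarray,
                        gene: str | None = None) -> ExpressionResult:
    """Fold change 2**(-ddCt) and unpaired two-tailed t-test.

    Inputs are either per-biological-replicate dCt arrays for one gene
    or :func:`delta_ct` frames (then ``gene`` selects the rows).
    ddCt = mean dCt(treated) - mean dCt(vehicle); amplification
    efficiency is fixed at 2.
    """
    def extract(d):
        if isinstance(d, pd.DataFrame):
            sub = d if gene is None else d[d.gene == gene]
            if sub.empty:
                raise ValueError(f"no dCt rows for gene {gene!r}")
            flag = bool(sub.get("unbalanced_tech", pd.Series(False)).any())
            return sub["delta_ct"].to_numpy(dtype=float), flag
        return np.asarray(d, dtype=float), False

    t_vals, t_flag = extract(treated_dct)
    v_vals, v_flag = extract(vehicle_dct)
    if len(t_vals) < 2 or len(v_vals) < 2:
        raise ValueError("need >= 2 biological replicates per arm for the "
                         "t-test")
    ddct = t_vals.mean() - v_vals.mean()
    fold = 2.0 ** (-ddct)
    if np.allclose(t_vals, t_vals.mean()) and np.allclose(v_vals,
                                                          v_vals.mean()):
        p = 1.0 if np.isclose(ddct, 0.0) else 0.0
    else:
        p = float(stats.ttest_ind(t_vals, v_vals).pvalue)
    return ExpressionResult(gene=gene or "", fold=fold, p_value=p,
                            n_treated=len(t_vals), n_vehicle=len(v_vals),
                            unbalanced_tech=t_flag or v_flag)


def germline_attribution(result_15c: tuple[float, float],
                         result_25c: tuple[float, float],
                         alpha: float = 0.05) -> str:
    """Attribute an expression change to the germline or the soma.

    Each argument is a (fold, p) pair from one temperature arm.
    ``germline_specific``: significant at 15C (soma + germline) but
    not at 25C (soma only).  ``somatic``: significant at 25C.
    ``none`` otherwise.
    """
    for res in (result_15c, result_25c):
        if res is None or len(res) != 2:
            raise ValueError("both temperature arms are required")
    _, p15 = result_15c
    _, p25 = result_25c
    if p25 < alpha:
        return "somatic"
    if p15 < alpha:
        return "germline_specific"
    return "none"


def attribution_report(ct_table: pd.DataFrame, vehicle: str = "DMSO",
                       alpha: float = 0.05,
                       reference_gene: str = REFERENCE_GENE) -> pd.DataFrame:
    """Full per-gene, per-condition report over both temperature arms.

    ``ct_table`` is a tidy Ct table covering both 15C and 25C arms for
    the vehicle and at least one chemical condition.  Returns one row
    per (condition, gene) with fold and p at each temperature and the
    attribution label.
    """
    dct = delta_ct(ct_table, reference_gene=reference_gene)
    temps = sorted(ct_table["temp_c"].unique())
    if not {15, 25} <= {int(t) for t in temps}:
        raise ValueError("attribution needs both 15C and 25C arms")
    conditions = [c for c in dct["condition"].unique() if c != vehicle]
    genes = sorted(dct["gene"].unique())
    rows = []
    for cond in conditions:
        for g in genes:
            per_temp: dict[int, ExpressionResult] = {}
            for t in (15, 25):
                treated = dct[(dct.condition == cond) & (dct.temp_c == t)]
                veh = dct[(dct.condition == vehicle) & (dct.temp_c == t)]
                per_temp[t] = relative_expression(treated, veh, gene=g)
            label = germline_attribution(
                (per_temp[15].fold, per_temp[15].p_value),
                (per_temp[25].fold, per_temp[25].p_value), alpha=alpha)
            rows.append({
                "condition": cond, "gene": g,
                "fold_15c": per_temp[15].fold, "p_15c": per_temp[15].p_value,
                "fold_25c": per_temp[25].fold, "p_25c": per_temp[25].p_value,
                "attribution": label,
            })
    return pd.DataFrame(rows)
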