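"""Plate-phenotype and germline-cytology statistics.

Implements the nonparametric tests used throughout the follow-up
analyses — an exact two-tailed Mann-Whitney test with mid-rank tie
handling (full enumeration of the permutation null for small samples,
tie-corrected normal approximation otherwise) and the two-sided
Fisher exact test by the probability-mass method — plus lethality
fractions, RAD-51 zone-profile comparisons, corpse analysis with its
p53/cep-1 dependence call, and diakinesis DAPI-body tallies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .simkit import DIAKINESIS_CLASSES, GermlineProfile

__all__ = [
    "TestResult", "lethality_fractions", "mann_whitney_two_tailed",
    "fisher_exact_two_sided", "zone_assign", "zone_profile_compare",
    "corpse_analysis", "diakinesis_tally", "significance_stars",
]

#: full enumeration is used while C(n1+n2, n1) does not exceed this
EXACT_ENUMERATION_LIMIT = 10 ** 6
#: relative slack when comparing hypergeometric table probabilities
FISHER_RELATIVE_SLACK = 1e-7


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test.

    ``statistic`` is the Mann-Whitney U of the first sample or the
    observed 2x2 table probability; ``method`` records whether the
    exact null or a normal approximation was used.
    """

    statistic: float
    p_value: float
    method: str  # "exact" | "normal_approx"
    n1: int
    n2: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0 + 1e-12:
            raise ValueError("p-value outside [0, 1]")


def significance_stars(p: float) -> str:
    """Star annotation at the conventional 0.05 / 0.01 / 0.001 levels."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


# ---------------------------------------------------------------------------
# plate phenotypes

def lethality_fractions(eggs: int, hatched: int,
                        adults: int) -> tuple[float, float]:
    """Embryonic and larval lethality fractions from nested counts.

    ``emb = (eggs - hatched)/eggs``; ``larval = (hatched - adults)/
    hatched``.  Undefined denominators yield NaN (a mother laying no
    eggs has no embryonic lethality; with no hatchlings the larval
    fraction is undefined).
    """
    if not 0 <= adults <= hatched <= eggs:
        raise ValueError("counts must be nested: adults <= hatched <= eggs")
    emb = (eggs - hatched) / eggs if eggs > 0 else math.nan
    larv = (hatched - adults) / hatched if hatched > 0 else math.nan
    return emb, larv


# ---------------------------------------------------------------------------
# Mann-Whitney

def _u_statistic(ranks_x: np.ndarray, n1: int) -> float:
    return float(ranks_x.sum() - n1 * (n1 + 1) / 2.0)


def mann_whitney_two_tailed(x: Sequence[float],
                            y: Sequence[float]) -> TestResult:
    """Two-tailed Mann-Whitney test with mid-rank tie handling.

    For small samples (C(n1+n2, n1) <= 10^6 arrangements) the exact
    permutation null is enumerated: two-tailed p is the probability,
    under random relabeling, of a U at least as far from its null mean
    n1*n2/2 as observed.  Larger samples use the tie-corrected normal
    approximation (with continuity correction).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # mid-ranks for ties
    u_obs = _u_statistic(ranks[:n1], n1)
    if math.comb(n1 + n2, n1) <= EXACT_ENUMERATION_LIMIT:
        mean_u = n1 * n2 / 2.0
        dev_obs = abs(u_obs - mean_u) - 1e-12
        n_extreme = 0
        n_total = 0
        for idx in combinations(range(n1 + n2), n1):
            u = _u_statistic(ranks[list(idx)], n1)
            n_total += 1
            if abs(u - mean_u) >= dev_obs:
                n_extreme += 1
        return TestResult(statistic=u_obs, p_value=n_extreme / n_total,
                          method="exact", n1=n1, n2=n2)
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="asymptotic")
    return TestResult(statistic=float(res.statistic),
                      p_value=float(res.pvalue),
                      method="normal_approx", n1=n1, n2=n2)


# ---------------------------------------------------------------------------
# Fisher exact

def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> TestResult:
    """Two-sided Fisher exact test on the 2x2 table [[a, b], [c, d]].

    Probability-mass method: with margins fixed, p is the sum of
    hypergeometric probabilities of every table whose probability does
    not exceed the observed table's (within 1e-7 relative slack).
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("table entries must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    row1, col1 = a + b, a + c
    if n == 0:
        return TestResult(statistic=1.0, p_value=1.0, method="exact",
                          n1=row1, n2=c + d)
    rv = stats.hypergeom(n, row1, col1)
    k_min = max(0, col1 - (c + d))
    k_max = min(row1, col1)
    ks = np.arange(k_min, k_max + 1)
    pmf = rv.pmf(ks)
    p_obs = float(rv.pmf(a))
    p = float(pmf[pmf <= p_obs * (1.0 + FISHER_RELATIVE_SLACK)].sum())
    return TestResult(statistic=p_obs, p_value=min(p, 1.0), method="exact",
                      n1=row1, n2=c + d)


# ---------------------------------------------------------------------------
# germline zones

def zone_assign(position: float) -> int:
    """Zone (1..7) of a normalized gonad-axis coordinate in [0, 1).

    The distal tip is 0; the seven zones are equal half-open bins.
    """
    if not 0.0 <= position < 1.0:
        raise ValueError("position must lie in [0, 1)")
    return int(7 * position) + 1


def _pooled_zone_counts(profiles: Iterable[GermlineProfile],
                        zone: int) -> np.ndarray:
    parts = []
    for i, p in enumerate(profiles):
        v = np.asarray(p.zone_foci[zone])
        if v.size == 0:
            raise ValueError(f"gonad {i} has an empty focus vector in "
                             f"zone {zone + 1}")
        parts.append(v)
    return np.concatenate(parts)


def zone_profile_compare(exposed: Sequence[GermlineProfile],
                         vehicle: Sequence[GermlineProfile]) -> pd.DataFrame:
    """Per-zone RAD-51 focus comparison between two arms.

    Nucleus-level counts are pooled across gonads within each arm;
    each zone is compared by the two-tailed Mann-Whitney test.
    Returns one row per zone with means +/- SEM and the test result.
    """
    rows = []
    for z in range(7):
        e = _pooled_zone_counts(exposed, z)
        v = _pooled_zone_counts(vehicle, z)
        res = mann_whitney_two_tailed(e, v)
        rows.append({
            "zone": z + 1,
            "mean_exposed": e.mean(), "sem_exposed": stats.sem(e),
            "mean_vehicle": v.mean(), "sem_vehicle": stats.sem(v),
            "n_exposed": len(e), "n_vehicle": len(v),
            "statistic": res.statistic, "p_value": res.p_value,
            "method": res.method,
            "stars": significance_stars(res.p_value),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# germ-cell corpses

def corpse_analysis(counts: pd.DataFrame, vehicle: str = "DMSO",
                    alpha: float = 0.05,
                    cep1_null_genotype: str = "cep-1",
                    ) -> tuple[pd.DataFrame, dict[str, str]]:
    """Corpse-count statistics by condition x genotype, with the
    p53/cep-1 dependence call.

    ``counts`` must carry columns ``condition, genotype, count`` (one
    row per gonad).  Each condition is compared against the vehicle of
    its own genotype (fold of means, two-tailed Mann-Whitney).  A
    condition whose corpse increase is significant in the
    cep-1-functional background but not in the cep-1 null is labelled
    ``cep-1-dependent``; significant in both, ``cep-1-independent``;
    not significant in the functional background, ``none``.  The call
    needs both genotype arms: when the cep-1 null background is absent
    entirely no call is attempted (empty label mapping); when it is
    present, a condition missing either arm is an error.
    """
    required = {"condition", "genotype", "count"}
    if not required <= set(counts.columns):
        raise ValueError(f"counts must carry columns {sorted(required)}")
    groups = {(c, g): sub["count"].to_numpy(dtype=float)
              for (c, g), sub in counts.groupby(["condition", "genotype"])}
    genotypes = sorted(counts["genotype"].unique())
    rows = []
    signif: dict[tuple[str, str], bool] = {}
    for (cond, gen), vals in groups.items():
        if (vehicle, gen) not in groups:
            raise ValueError(f"no vehicle ({vehicle!r}) arm for genotype "
                             f"{gen!r}")
        veh = groups[(vehicle, gen)]
        fold = vals.mean() / veh.mean() if veh.mean() > 0 else math.nan
        if cond == vehicle:
            res = TestResult(statistic=len(vals) * len(veh) / 2.0,
                             p_value=1.0, method="exact",
                             n1=len(vals), n2=len(veh))
        else:
            res = mann_whitney_two_tailed(vals, veh)
        signif[(cond, gen)] = res.p_value < alpha
        rows.append({"condition": cond, "genotype": gen,
                     "n_gonads": len(vals), "mean_corpses": vals.mean(),
                     "sem_corpses": stats.sem(vals) if len(vals) > 1 else 0.0,
                     "fold_vs_vehicle": fold, "p_value": res.p_value,
                     "method": res.method,
                     "stars": significance_stars(res.p_value)})
    table = pd.DataFrame(rows).sort_values(
        ["genotype", "condition"]).reset_index(drop=True)

    labels: dict[str, str] = {}
    func_genotypes = [g for g in genotypes if g != cep1_null_genotype]
    if cep1_null_genotype not in genotypes or not func_genotypes:
        return table, labels
    for cond in counts["condition"].unique():
        if cond == vehicle:
            continue
        func = func_genotypes[0]
        if (cond, func) not in signif or (cond, cep1_null_genotype) not in signif:
            raise ValueError(f"condition {cond!r} missing a genotype arm for "
                             "the dependence call")
        sig_func = signif[(cond, func)]
        sig_null = signif[(cond, cep1_null_genotype)]
        if sig_func and not sig_null:
            labels[cond] = "cep-1-dependent"
        elif sig_func and sig_null:
            labels[cond] = "cep-1-independent"
        else:
            labels[cond] = "none"
    return table, labels


# ---------------------------------------------------------------------------
# diakinesis

def diakinesis_tally(records: Sequence[tuple[int, str]]) -> dict:
    """Tally diakinesis oocyte records (DAPI-body count, defect class).

    Returns per-class counts and percentages, the DAPI-body count
    histogram and its mode, and the number of oocytes scored.
    """
    if not records:
        raise ValueError("no diakinesis records")
    n = len(records)
    class_counts = {c: 0 for c in DIAKINESIS_CLASSES}
    body_hist: dict[int, int] = {}
    for n_bodies, cls in records:
        if cls not in class_counts:
            raise ValueError(f"unknown defect class {cls!r}")
        class_counts[cls] += 1
        body_hist[int(n_bodies)] = body_hist.get(int(n_bodies), 0) + 1
    percent = {c: 100.0 * k / n for c, k in class_counts.items()}
    modal = max(sorted(body_hist), key=body_hist.get)
    return {"n": n, "counts": class_counts, "percent": percent,
            "dapi_body_histogram": dict(sorted(body_hist.items())),
            "modal_dapi_bodies": modal}
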