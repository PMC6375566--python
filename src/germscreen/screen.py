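"""Well scoring, fold-increase aggregation, testing, ranking and hit calling.

The screen readout for a well is the fraction of gated adults whose
GFP peak height clears the calibrated threshold (worms carrying at
least one male-destined, GFP+ embryo).  Per biological replicate the
fold increase over the matched vehicle (0.1% DMSO) well is computed,
replicates are averaged, chemical-vs-vehicle fractions are compared by
a paired two-tailed t-test, and chemicals are ranked; a chemical is a
hit when its mean fold exceeds the benchmark chemical's (BPA).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gating import ADULT_NEG, ADULT_POS

__all__ = [
    "WellResult", "ScreenSummary",
    "score_well", "fold_change", "summarize_chemical", "call_hits",
    "summaries_to_frame",
]


class WellFailedError(ValueError):
    """A well produced no gated adults and cannot be scored."""


@dataclass(frozen=True)
class WellResult:
    """GFP+ readout of one well (one chemical, one biological replicate)."""

    chemical: str
    replicate: int
    n_adults: int
    n_gfp_pos: int

    def __post_init__(self) -> None:
        if self.n_adults <= 0:
            raise ValueError("n_adults must be > 0")
        if not 0 <= self.n_gfp_pos <= self.n_adults:
            raise ValueError("n_gfp_pos must be in [0, n_adults]")

    @property
    def fraction(self) -> float:
        return self.n_gfp_pos / self.n_adults


@dataclass
class ScreenSummary:
    """Aggregated per-chemical screen result."""

    chemical: str
    folds: list[float]
    mean_fold: float
    sem_fold: float
    p_value: float
    rank: int | None = None
    hit: bool | None = None
    category: str | None = None


def score_well(classes: pd.Series | list[str], chemical: str,
               replicate: int) -> WellResult:
    """Score one well from per-event classifications.

    The readout is positives / gated adults; a well with zero gated
    adults has failed (clog, mis-dispense) and raises
    :class:`WellFailedError`.
    """
    arr = np.asarray(classes)
    n_pos = int(np.sum(arr == ADULT_POS))
    n_adults = n_pos + int(np.sum(arr == ADULT_NEG))
    if n_adults == 0:
        raise WellFailedError(
            f"well {chemical!r} rep {replicate}: no gated adults")
    return WellResult(chemical=chemical, replicate=replicate,
                      n_adults=n_adults, n_gfp_pos=n_pos)


def fold_change(chem_well: WellResult, vehicle_well: WellResult) -> float:
    """Per-replicate fold increase of the GFP+ fraction over vehicle.

    A continuity constant eps = 1/(2 * n_adults_vehicle) keeps the fold
    bounded when the vehicle fraction is zero; at screening depth
    (300+ adults/well) its bias is negligible.
    """
    if chem_well.replicate != vehicle_well.replicate:
        raise ValueError(
            f"mismatched replicate ids: {chem_well.replicate} vs "
            f"{vehicle_well.replicate}")
    eps = 1.0 / (2.0 * vehicle_well.n_adults)
    return (chem_well.fraction + eps) / (vehicle_well.fraction + eps)


def _paired_t_p(x: np.ndarray, y: np.ndarray) -> float:
    """Paired two-tailed t-test p; all-zero differences give p = 1."""
    d = x - y
    if np.allclose(d, 0.0):
        return 1.0
    if np.std(d, ddof=1) == 0.0:
        # constant non-zero shift: t is infinite, p -> 0
        return 0.0
    t = stats.ttest_rel(x, y)
    return float(t.pvalue)


def summarize_chemical(chem_wells: list[WellResult],
                       vehicle_wells: list[WellResult]) -> ScreenSummary:
    """Aggregate matched chemical/vehicle wells into a ScreenSummary.

    Wells are paired by biological-replicate id.  Per-replicate folds
    are averaged arithmetically (mean +/- SEM) and the p-value comes
    from a paired two-tailed t-test of the chemical vs vehicle GFP+
    fractions.
    """
    if len(chem_wells) < 2:
        raise ValueError("need >= 2 replicates for the paired t-test")
    veh_by_rep = {w.replicate: w for w in vehicle_wells}
    missing = [w.replicate for w in chem_wells if w.replicate not in veh_by_rep]
    if missing:
        raise ValueError(f"no matched vehicle well for replicate(s) {missing}")
    chems = sorted(chem_wells, key=lambda w: w.replicate)
    vehs = [veh_by_rep[w.replicate] for w in chems]
    folds = [fold_change(c, v) for c, v in zip(chems, vehs)]
    mean_fold = float(np.mean(folds))
    sem_fold = (float(np.std(folds, ddof=1) / np.sqrt(len(folds)))
                if len(folds) > 1 else 0.0)
    p = _paired_t_p(np.array([c.fraction for c in chems]),
                    np.array([v.fraction for v in vehs]))
    return ScreenSummary(chemical=chems[0].chemical, folds=folds,
                         mean_fold=mean_fold, sem_fold=sem_fold, p_value=p)


def call_hits(summaries: list[ScreenSummary],
              benchmark: str = "BPA") -> list[ScreenSummary]:
    """Rank chemicals by mean fold and flag hits above the benchmark.

    A chemical is a hit iff its mean fold strictly exceeds the
    benchmark chemical's mean fold.  Rank 1 is the largest mean fold;
    ties are broken alphabetically.  Returns the summaries sorted by
    rank; the input objects are annotated in place.
    """
    by_name = {s.chemical: s for s in summaries}
    if benchmark not in by_name:
        raise ValueError(f"benchmark chemical {benchmark!r} not among "
                         "summaries")
    bench_fold = by_name[benchmark].mean_fold
    ordered = sorted(summaries, key=lambda s: (-s.mean_fold, s.chemical))
    for i, s in enumerate(ordered, start=1):
        s.rank = i
        s.hit = s.mean_fold > bench_fold
    return ordered


def summaries_to_frame(summaries: list[ScreenSummary]) -> pd.DataFrame:
    """Tidy per-chemical results table (one row per chemical)."""
    rows = []
    for s in summaries:
        row = {"chemical": s.chemical, "category": s.category,
               "mean_fold": s.mean_fold, "sem_fold": s.sem_fold,
               "p_value": s.p_value, "rank": s.rank, "hit": s.hit}
        for i, f in enumerate(s.folds, start=1):
            row[f"fold_rep{i}"] = f
        rows.append(row)
    return pd.DataFrame(rows)
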