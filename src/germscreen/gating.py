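"""Adult-gate and GFP-threshold calibration for sorter event streams.

The screen only scores gravid adults.  The adult gate is fit on a
stage-labeled calibration run (adults vs L4 and younger); the GFP+
threshold is fit by contrasting the same reporter strain with and
without the him-8 mutation — nearly every gravid him-8 adult carries
at least one GFP+ (male-destined) embryo, while the self-fertilizing
strain essentially never does.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AdultGate", "GfpThreshold", "UnusableCalibrationError",
    "fit_adult_gate", "fit_gfp_threshold", "classify",
    "save_calibration", "load_calibration",
]

#: classification labels
OUT_OF_GATE = "out_of_gate"
ADULT_NEG = "adult_gfp_neg"
ADULT_POS = "adult_gfp_pos"

#: maximum tolerated fraction of labeled L4 events inside the gate
MAX_L4_CONTAMINATION = 0.01
#: ToF percentile span of the adult population used for the raw gate
GATE_PERCENTILES = (0.5, 99.5)
#: adult capture below this after enforcing the L4 criterion means the
#: two stages are not separable at that criterion
MIN_ADULT_CAPTURE = 0.95

MIN_LABELED = 50


class UnusableCalibrationError(ValueError):
    """Calibration runs cannot be separated well enough to use."""


@dataclass(frozen=True)
class AdultGate:
    """ToF window capturing the adult population.

    ``adult_capture`` and ``l4_contamination`` record the achieved
    rates on the calibration data; ``separable`` is False when the 1%
    L4-contamination criterion could not be met.
    """

    tof_min: float
    tof_max: float
    adult_capture: float
    l4_contamination: float
    separable: bool = True

    def __post_init__(self) -> None:
        if not self.tof_min < self.tof_max:
            raise ValueError("tof_min must be < tof_max")


@dataclass(frozen=True)
class GfpThreshold:
    """GFP peak-height cut; events strictly above ``tau`` are positive.

    ``fpr_neg``: fraction of negative-strain gated adults above tau.
    ``fnr_pos``: fraction of positive-strain gated adults at or below
    tau.
    """

    tau: float
    fpr_neg: float
    fnr_pos: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.fpr_neg <= 1.0 and 0.0 <= self.fnr_pos <= 1.0):
            raise ValueError("rates must be in [0, 1]")


def fit_adult_gate(labeled_events: pd.DataFrame) -> AdultGate:
    """Fit the adult ToF gate from a stage-labeled calibration run.

    The raw gate spans the [0.5th, 99.5th] ToF percentiles of labeled
    adults; its lower bound is then raised just enough that at most 1%
    of labeled L4 events fall inside.  If enforcing that criterion
    costs too much adult capture (below ``MIN_ADULT_CAPTURE``) the two
    stages are inseparable at the 1% criterion: the gate is still
    returned, with ``separable=False`` and the achieved rates.
    """
    if "true_stage" not in labeled_events.columns:
        raise ValueError("labeled_events must carry a 'true_stage' column")
    adults = labeled_events.loc[labeled_events.true_stage == "adult",
                                "tof"].to_numpy()
    l4 = labeled_events.loc[labeled_events.true_stage == "L4",
                            "tof"].to_numpy()
    if len(adults) < MIN_LABELED:
        raise ValueError(f"need >= {MIN_LABELED} labeled adult events, "
                         f"got {len(adults)}")
    if len(l4) < MIN_LABELED:
        raise ValueError(f"need >= {MIN_LABELED} labeled L4 events, "
                         f"got {len(l4)}")
    tof_min, tof_max = np.percentile(adults, GATE_PERCENTILES)

    def l4_contam(lo: float) -> float:
        return float(np.mean((l4 >= lo) & (l4 <= tof_max)))

    separable = True
    if l4_contam(tof_min) > MAX_L4_CONTAMINATION:
        # smallest raise of tof_min meeting the criterion: just above
        # the in-gate L4 value leaving <=1% of all L4 inside
        in_gate = np.sort(l4[(l4 >= tof_min) & (l4 <= tof_max)])
        allowed = int(np.floor(MAX_L4_CONTAMINATION * len(l4)))
        # keep the top `allowed` in-gate L4 values; cut just above the rest
        cut_idx = len(in_gate) - allowed
        candidate = np.nextafter(in_gate[cut_idx - 1], np.inf)
        if candidate >= tof_max:
            separable = False
        else:
            tof_min = candidate
    capture = float(np.mean((adults >= tof_min) & (adults <= tof_max)))
    if capture < MIN_ADULT_CAPTURE:
        separable = False
    return AdultGate(tof_min=float(tof_min), tof_max=float(tof_max),
                     adult_capture=capture,
                     l4_contamination=l4_contam(tof_min),
                     separable=separable)


def _threshold_candidates(values: np.ndarray) -> np.ndarray:
    """Midpoints between adjacent sorted unique values plus extremes."""
    u = np.unique(values)
    mids = (u[:-1] + u[1:]) / 2.0 if len(u) > 1 else np.empty(0)
    lo = u[0] - 1.0
    hi = u[-1] + 1.0
    return np.concatenate(([lo], mids, [hi]))


def fit_gfp_threshold(neg_run: pd.DataFrame | np.ndarray,
                      pos_run: pd.DataFrame | np.ndarray,
                      max_objective: float = 0.8) -> GfpThreshold:
    """Fit the GFP+ threshold from the two calibration strains.

    ``neg_run`` holds gated adults of the plain reporter strain
    (treated as all-negative), ``pos_run`` those of the him-8 reporter
    strain (treated as all-positive; the ~0.4% of him-8 adults
    genuinely carrying zero GFP+ embryos are accepted as label noise).
    tau minimizes fpr + fnr over all midpoint candidates, ties broken
    toward the larger tau.  Runs drawn from one distribution leave the
    best achievable fpr + fnr near 1 (finite samples dip somewhat
    below); a best objective at or above ``max_objective`` raises
    :class:`UnusableCalibrationError`.
    """
    neg = np.asarray(neg_run["gfp_peak"] if hasattr(neg_run, "columns")
                     else neg_run, dtype=float)
    pos = np.asarray(pos_run["gfp_peak"] if hasattr(pos_run, "columns")
                     else pos_run, dtype=float)
    if len(neg) == 0 or len(pos) == 0:
        raise ValueError("both calibration runs must be non-empty")
    cands = _threshold_candidates(np.concatenate([neg, pos]))
    # fpr(t) = mean(neg > t); fnr(t) = mean(pos <= t)
    fpr = (neg[None, :] > cands[:, None]).mean(axis=1)
    fnr = (pos[None, :] <= cands[:, None]).mean(axis=1)
    obj = fpr + fnr
    best = obj.min()
    if best >= max_objective:
        raise UnusableCalibrationError(
            f"calibration strains indistinguishable (min fpr+fnr = {best:.3f})")
    # ties toward the larger tau
    idx = np.flatnonzero(np.isclose(obj, best, rtol=0, atol=1e-12))[-1]
    return GfpThreshold(tau=float(cands[idx]), fpr_neg=float(fpr[idx]),
                        fnr_pos=float(fnr[idx]))


def classify(events: pd.DataFrame, gate: AdultGate,
             thr: GfpThreshold) -> pd.Series:
    """Classify each event as out_of_gate / adult_gfp_neg / adult_gfp_pos.

    In-gate iff ToF lies in [tof_min, tof_max]; positive iff GFP peak
    height is strictly above tau (an event exactly at tau is negative).
    Order-preserving and order-invariant.
    """
    tof = events["tof"].to_numpy()
    gfp = events["gfp_peak"].to_numpy()
    in_gate = (tof >= gate.tof_min) & (tof <= gate.tof_max)
    pos = in_gate & (gfp > thr.tau)
    out = np.where(~in_gate, OUT_OF_GATE, np.where(pos, ADULT_POS, ADULT_NEG))
    return pd.Series(out, index=events.index, name="event_class")


# ---------------------------------------------------------------------------
# serialization: small key-value calibration files reusable across runs

def save_calibration(path: str | Path, gate: AdultGate, thr: GfpThreshold,
                     extra: dict[str, str] | None = None) -> None:
    lines = [
        f"tof_min={gate.tof_min!r}", f"tof_max={gate.tof_max!r}",
        f"adult_capture={gate.adult_capture!r}",
        f"l4_contamination={gate.l4_contamination!r}",
        f"separable={int(gate.separable)}",
        f"tau={thr.tau!r}", f"fpr_neg={thr.fpr_neg!r}",
        f"fnr_pos={thr.fnr_pos!r}",
    ]
    for k, v in (extra or {}).items():
        lines.append(f"{k}={v}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_calibration(path: str | Path) -> tuple[AdultGate, GfpThreshold]:
    kv: dict[str, str] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        k, _, v = line.partition("=")
        kv[k.strip()] = v.strip()
    try:
        gate = AdultGate(tof_min=float(kv["tof_min"]),
                         tof_max=float(kv["tof_max"]),
                         adult_capture=float(kv["adult_capture"]),
                         l4_contamination=float(kv["l4_contamination"]),
                         separable=bool(int(kv["separable"])))
        thr = GfpThreshold(tau=float(kv["tau"]),
                           fpr_neg=float(kv["fpr_neg"]),
                           fnr_pos=float(kv["fnr_pos"]))
    except KeyError as exc:
        raise ValueError(f"calibration file missing key {exc.args[0]!r}")
    return gate, thr
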