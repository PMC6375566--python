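"""Generative simulator of worm broods, sorter events, germline cytology and qPCR.

This module is the single source of all synthetic inputs for the
screening pipeline.  It encodes the biological structure the analysis
assumes:

* strain genetics — the baseline X-nondisjunction rate (male-destined,
  X0 embryo probability), cuticle permeability, p53/``cep-1`` status,
  meiotic double-strand-break (DSB) formation (``spo-11``), DSB-repair
  turnover (``rad-54``), and the temperature-sensitive germline-less
  design (``glp-1``);
* dose-response — every exposure endpoint follows a Hill curve on the
  permeability-adjusted external dose;
* large-object cytometry physics — stage-specific time-of-flight
  (ToF) lognormals, in-utero embryo loads, and a GFP peak height that
  is autofluorescence plus a per-embryo brightness contribution;
* germline cytology — per-zone RAD-51 focus counts along the distal-
  proximal axis, apoptotic corpse counts, diakinesis DAPI-body
  records and categorical gonad defects;
* qPCR — per-gene Ct values with germline/soma expression components
  switched by growth temperature.

All randomness flows through a single :class:`numpy.random.Generator`
so that every output is bit-for-bit reproducible given (seed,
parameters, version).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StrainParams",
    "DoseResponseParams",
    "ExposureParams",
    "GermlineProfile",
    "hill_effect",
    "simulate_brood",
    "simulate_biosort_run",
    "simulate_germline",
    "simulate_qpcr",
    "STAGES",
    "PANEL_GENES",
    "REFERENCE_GENE",
]

# ---------------------------------------------------------------------------
# parameter containers

ZERO_DR_FIELDS = ("ndj", "brood", "emb_lethality", "larval_lethality",
                  "apoptosis", "dsb")


@dataclass(frozen=True)
class DoseResponseParams:
    """Hill-curve parameters for one endpoint.

    ``effect(d) = emax * d**n / (ec50**n + d**n)``; zero at dose 0,
    monotone non-decreasing, saturating at ``emax``.  ``ec50 = 0`` is
    treated as a step at 0+ (full effect at any positive dose).
    """

    ec50: float = 1.0  # umol/L
    hill_n: float = 1.0
    emax: float = 0.0

    def __post_init__(self) -> None:
        if self.hill_n <= 0:
            raise ValueError("hill_n must be > 0")
        if self.ec50 < 0:
            raise ValueError("ec50 must be >= 0")


def hill_effect(dose: float, params: DoseResponseParams) -> float:
    """Evaluate the Hill dose-response curve at ``dose`` (umol/L)."""
    if dose < 0:
        raise ValueError("dose must be >= 0")
    if dose == 0:
        return 0.0
    if params.ec50 == 0:
        return params.emax
    r = (dose / params.ec50) ** params.hill_n
    return params.emax * r / (1.0 + r)


@dataclass(frozen=True)
class StrainParams:
    """Genetic background of the simulated worms.

    ``p_male`` is the baseline probability that a self-progeny embryo
    is male-destined (X0).  Self-fertilizing wild-type hermaphrodites
    produce <0.2% males; the him-8 calibration strain produces 36.7%.
    ``permeability`` multiplies the effective dose (>=1; the cuticle
    collagen mutation of the screening strain is folded in here).
    """

    name: str
    p_male: float = 0.001
    permeability: float = 1.0
    cep1_functional: bool = True
    spo11_active: bool = True
    rad54_functional: bool = True
    glp1_ts: bool = False  # temperature-sensitive germline-less design

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_male <= 1.0:
            raise ValueError("p_male must be in [0, 1]")
        if self.permeability < 1.0:
            raise ValueError("permeability must be >= 1")

    def germline_present_at(self, temp_c: float) -> bool:
        """Whether adults grown at ``temp_c`` carry a germline."""
        if self.glp1_ts:
            return temp_c < 20.0
        return True


@dataclass(frozen=True)
class ExposureParams:
    """One chemical exposure: identity, dose and per-endpoint Hill curves.

    ``gene_effects`` maps gene name to a pair of Hill curves whose
    ``emax`` values are the saturating log2 fold changes in the
    germline and the soma respectively.  ``diakinesis_probs`` are the
    categorical probabilities of (normal, fragments, bridges, frayed)
    oocyte classes at this exposure; ``gonad_defect_probs`` the
    Bernoulli probabilities of (gap, aggregate, lz_like) pachytene
    defects.
    """

    chemical: str
    dose: float  # umol/L
    solvent: str = "DMSO"
    ndj: DoseResponseParams = DoseResponseParams()
    brood: DoseResponseParams = DoseResponseParams()
    emb_lethality: DoseResponseParams = DoseResponseParams()
    larval_lethality: DoseResponseParams = DoseResponseParams()
    apoptosis: DoseResponseParams = DoseResponseParams()
    dsb: DoseResponseParams = DoseResponseParams()
    gene_effects: Mapping[str, tuple[DoseResponseParams, DoseResponseParams]] = \
        field(default_factory=dict)
    diakinesis_probs: tuple[float, float, float, float] = (0.95, 0.02, 0.015, 0.015)
    gonad_defect_probs: tuple[float, float, float] = (0.109, 0.073, 0.055)

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError("dose must be >= 0")
        if abs(sum(self.diakinesis_probs) - 1.0) > 1e-9:
            raise ValueError("diakinesis_probs must sum to 1")

    def at_dose(self, dose: float) -> "ExposureParams":
        return replace(self, dose=dose)

    def effect(self, endpoint: str, strain: StrainParams) -> float:
        """Hill effect of this exposure for ``endpoint`` on ``strain``."""
        dr: DoseResponseParams = getattr(self, endpoint)
        return hill_effect(self.dose * strain.permeability, dr)


@dataclass
class GermlineProfile:
    """Cytology of one gonad arm.

    ``zone_foci`` holds, for each of the seven equal zones along the
    distal-proximal axis, the per-nucleus RAD-51 focus counts.
    ``diakinesis`` records the last (-1, -2) oocytes as
    (DAPI-body count, defect class) pairs.
    """

    zone_foci: list[np.ndarray]
    corpse_count: int
    diakinesis: list[tuple[int, str]]
    gonad_defects: dict[str, bool]


# ---------------------------------------------------------------------------
# documented preset constants (study conditions)

#: mean brood size (eggs laid per unexposed mother over the scoring window)
MU_BROOD = 250.0
#: baseline embryonic / larval death probabilities
BASE_EMB_LETHALITY = 0.01
BASE_LARVAL_LETHALITY = 0.01
#: mean number of in-utero embryos per gravid adult
MU_EMBRYOS = 12.0
#: GFP peak-height units contributed per male-destined (GFP+) embryo
GFP_PER_EMBRYO = 30.0
#: lognormal autofluorescence of the worm body (gut granules etc.)
AUTOFLUOR_MEDIAN = 5.0
AUTOFLUOR_SIGMA = 0.5

STAGES = ("debris", "L1", "L2", "L3", "L4", "adult")
#: stage-specific ToF lognormal medians (a.u.) and log-scale sigmas;
#: adults are the largest objects, well separated from L4
TOF_MEDIAN = {"debris": 25.0, "L1": 45.0, "L2": 90.0, "L3": 160.0,
              "L4": 250.0, "adult": 700.0}
TOF_SIGMA = {"debris": 0.35, "L1": 0.2, "L2": 0.2, "L3": 0.2,
             "L4": 0.2, "adult": 0.18}

#: physiological germ-cell corpse rate (cep-1 independent)
LAMBDA_PHYS = 1.2
#: small cep-1-dependent corpse-rate elevation attributable to the
#: DMSO vehicle itself
LAMBDA_DMSO = 0.6

#: per-zone RAD-51 focus rate baseline (z1..z7): low in the mitotic tip,
#: rising from meiotic entry, peaking mid-pachytene (z5), falling by z7
ZONE_BASELINE = np.array([0.2, 0.25, 0.8, 2.0, 3.2, 2.4, 1.0])
#: residual mitotic-background rate in meiotic zones when spo-11 is depleted
MITOTIC_BACKGROUND = 0.05
#: per-zone break-formation increments (z3..z7); with rad-54 lost, repair
#: is blocked and rates accumulate as the running sum of these
RAD54_INCREMENTS = np.array([0.8, 1.2, 1.2, 0.8, 0.5])
#: nuclei scored per zone (z1..z7), matching reported scoring depth
NUCLEI_PER_ZONE = (80, 93, 97, 86, 59, 56, 58)
#: diakinesis oocytes scored per gonad (-1 and -2)
OOCYTES_PER_GONAD = 2

DIAKINESIS_CLASSES = ("normal", "fragments", "bridges", "frayed")
GONAD_DEFECTS = ("gap", "aggregate", "lz_like")

#: qPCR: per-gene baseline Ct at reference expression, and noise scales
REFERENCE_GENE = "gpd-1"
PANEL_GENES = (
    "spo-11", "mre-11", "rad-50", "rad-51", "rad-54", "brc-1", "msh-4",
    "msh-5", "chk-1", "chk-2", "cep-1", "hus-1", "mrt-2", "atl-1", "prmt-5",
)
BASE_CT = {REFERENCE_GENE: 16.0}
BASE_CT.update({g: 22.0 + 0.5 * i for i, g in enumerate(PANEL_GENES)})


def _rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _check_prob(p: float, what: str) -> float:
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"composed {what} probability {p!r} outside [0, 1]; "
                         "check strain/exposure presets")
    return p


# ---------------------------------------------------------------------------
# simulators

def simulate_brood(strain: StrainParams, exposure: ExposureParams,
                   n_mothers: int,
                   rng: np.random.Generator | int | None = None) -> pd.DataFrame:
    """Simulate per-mother brood records.

    Eggs are Poisson with mean ``MU_BROOD * (1 - brood effect)``; each
    egg independently dies as an embryo with the baseline-plus-effect
    probability, each hatchling likewise as a larva, and each surviving
    adult is male with probability ``p_male + ndj effect``.

    Returns a DataFrame with columns ``mother, eggs, hatched, adults,
    males`` satisfying males <= adults <= hatched <= eggs row-wise.
    """
    if n_mothers < 1:
        raise ValueError("n_mothers must be >= 1")
    rng = _rng(rng)
    mu = MU_BROOD * (1.0 - _check_prob(exposure.effect("brood", strain),
                                       "brood-reduction"))
    p_emb = _check_prob(
        BASE_EMB_LETHALITY + exposure.effect("emb_lethality", strain),
        "embryonic-lethality")
    p_larv = _check_prob(
        BASE_LARVAL_LETHALITY + exposure.effect("larval_lethality", strain),
        "larval-lethality")
    p_male = _check_prob(strain.p_male + exposure.effect("ndj", strain),
                         "male")
    eggs = rng.poisson(mu, size=n_mothers)
    hatched = rng.binomial(eggs, 1.0 - p_emb)
    adults = rng.binomial(hatched, 1.0 - p_larv)
    males = rng.binomial(adults, p_male)
    return pd.DataFrame({
        "mother": np.arange(n_mothers),
        "eggs": eggs, "hatched": hatched, "adults": adults, "males": males,
    })


DEFAULT_COMPOSITION = {"debris": 0.15, "L1": 0.02, "L2": 0.02, "L3": 0.03,
                       "L4": 0.08, "adult": 0.70}


def simulate_biosort_run(strain: StrainParams, exposure: ExposureParams,
                         composition: Mapping[str, float] | None = None,
                         n_events: int = 1000,
                         rng: np.random.Generator | int | None = None,
                         ) -> pd.DataFrame:
    """Simulate a large-object cytometer run.

    Each event draws a true stage from ``composition``, a ToF from the
    stage-specific lognormal, and — for adults — an in-utero embryo
    load Poisson(``MU_EMBRYOS``) thinned binomially to GFP+ embryos at
    the effective male-destined probability.  The recorded GFP peak
    height is lognormal autofluorescence plus ``GFP_PER_EMBRYO`` per
    GFP+ embryo.

    Returns a DataFrame with columns ``tof, gfp_peak, true_stage,
    n_embryos, n_gfp_embryos``.
    """
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    comp = dict(DEFAULT_COMPOSITION if composition is None else composition)
    unknown = set(comp) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s) in composition: {sorted(unknown)}")
    weights = np.array([comp.get(s, 0.0) for s in STAGES], dtype=float)
    if abs(weights.sum() - 1.0) > 1e-6:
        raise ValueError("composition weights must sum to 1")
    rng = _rng(rng)
    p_male = _check_prob(strain.p_male + exposure.effect("ndj", strain),
                         "male")
    stage_idx = rng.choice(len(STAGES), size=n_events, p=weights)
    medians = np.array([TOF_MEDIAN[s] for s in STAGES])
    sigmas = np.array([TOF_SIGMA[s] for s in STAGES])
    tof = np.exp(rng.normal(np.log(medians[stage_idx]), sigmas[stage_idx]))
    is_adult = stage_idx == STAGES.index("adult")
    n_embryos = np.where(is_adult, rng.poisson(MU_EMBRYOS, size=n_events), 0)
    n_gfp = rng.binomial(n_embryos, p_male)
    autofluor = np.exp(rng.normal(np.log(AUTOFLUOR_MEDIAN), AUTOFLUOR_SIGMA,
                                  size=n_events))
    gfp_peak = autofluor + GFP_PER_EMBRYO * n_gfp
    return pd.DataFrame({
        "tof": tof,
        "gfp_peak": gfp_peak,
        "true_stage": [STAGES[i] for i in stage_idx],
        "n_embryos": n_embryos,
        "n_gfp_embryos": n_gfp,
    })


def zone_rates(strain: StrainParams, exposure: ExposureParams) -> np.ndarray:
    """Expected RAD-51 foci per nucleus for zones z1..z7.

    The exposure's DSB multiplier (1 + Hill effect) scales meiotic
    zones (z3..z7) only; mitotic-tip rates are exposure independent.
    With spo-11 inactive the meiotic zones collapse to mitotic
    background; with rad-54 lost, breaks are trapped unrepaired and
    meiotic-zone rates become the running sum of formation increments
    (non-decreasing z3 -> z7).
    """
    rates = ZONE_BASELINE.copy()
    mult = 1.0 + exposure.effect("dsb", strain)
    if not strain.spo11_active:
        rates[2:] = MITOTIC_BACKGROUND
        return rates
    if strain.rad54_functional:
        rates[2:] = ZONE_BASELINE[2:] * mult
    else:
        rates[2:] = np.cumsum(RAD54_INCREMENTS * mult)
    return rates


def corpse_rate(strain: StrainParams, exposure: ExposureParams) -> float:
    """Expected germ-cell corpse count per gonad.

    Physiological apoptosis is cep-1 independent; the DMSO-vehicle
    elevation and the damage-induced term both require functional
    p53/cep-1.
    """
    lam = LAMBDA_PHYS
    if strain.cep1_functional:
        if exposure.solvent == "DMSO":
            lam += LAMBDA_DMSO
        lam += exposure.effect("apoptosis", strain)
    return lam


def simulate_germline(strain: StrainParams, exposure: ExposureParams,
                      n_gonads: int,
                      rng: np.random.Generator | int | None = None,
                      ) -> list[GermlineProfile]:
    """Simulate germline cytology for ``n_gonads`` gonad arms."""
    if n_gonads < 1:
        raise ValueError("n_gonads must be >= 1")
    rng = _rng(rng)
    rates = zone_rates(strain, exposure)
    lam_corpse = corpse_rate(strain, exposure)
    dia_p = np.asarray(exposure.diakinesis_probs)
    defect_p = np.asarray(exposure.gonad_defect_probs)
    profiles = []
    for _ in range(n_gonads):
        foci = [rng.poisson(rates[z], size=NUCLEI_PER_ZONE[z])
                for z in range(7)]
        corpses = int(rng.poisson(lam_corpse))
        diakinesis = []
        for _ in range(OOCYTES_PER_GONAD):
            if not strain.spo11_active:
                # no meiotic breaks -> no crossovers -> 12 univalents
                diakinesis.append((12, "normal"))
                continue
            cls = DIAKINESIS_CLASSES[rng.choice(4, p=dia_p)]
            if cls == "fragments":
                n_bodies = 6 + int(rng.integers(1, 7))
            else:
                n_bodies = 6
            diakinesis.append((n_bodies, cls))
        defects = {d: bool(rng.random() < defect_p[i])
                   for i, d in enumerate(GONAD_DEFECTS)}
        profiles.append(GermlineProfile(foci, corpses, diakinesis, defects))
    return profiles


def simulate_qpcr(strain: StrainParams, exposure: ExposureParams,
                  temp_c: float, genes: Sequence[str],
                  n_bio: int = 3, n_tech: int = 3,
                  rng: np.random.Generator | int | None = None,
                  sigma_ct: float = 0.2, sigma_sample: float = 0.5,
                  ) -> pd.DataFrame:
    """Simulate a qPCR Ct table for one condition at one temperature.

    The true log2 expression change of a gene is its somatic component
    plus its germline component when the strain carries a germline at
    ``temp_c`` (glp-1 design: germline at 15C, none at 25C).  Each
    (condition, biological replicate) sample carries a shared Ct offset
    of scale ``sigma_sample`` (RNA input/plate effect, cancelling in
    reference normalization); each well adds Gaussian noise
    ``sigma_ct``.  The reference gene is unaffected by exposure.

    Returns a tidy DataFrame with columns
    ``gene, condition, temp_c, bio_rep, tech_rep, ct``.
    """
    if n_tech < 1:
        raise ValueError("n_tech must be >= 1")
    if REFERENCE_GENE not in genes:
        raise ValueError(f"reference gene {REFERENCE_GENE!r} must be included")
    unknown = [g for g in genes if g not in BASE_CT]
    if unknown:
        raise ValueError(f"unknown gene(s): {', '.join(unknown)}")
    rng = _rng(rng)
    germline = strain.germline_present_at(temp_c)
    eff_dose = exposure.dose * strain.permeability
    rows = []
    for b in range(n_bio):
        sample_offset = rng.normal(0.0, sigma_sample) if sigma_sample else 0.0
        for g in genes:
            lfc = 0.0
            if g != REFERENCE_GENE and g in exposure.gene_effects:
                germ_dr, soma_dr = exposure.gene_effects[g]
                lfc = hill_effect(eff_dose, soma_dr)
                if germline:
                    lfc += hill_effect(eff_dose, germ_dr)
            true_ct = BASE_CT[g] - lfc + sample_offset
            for t in range(n_tech):
                noise = rng.normal(0.0, sigma_ct) if sigma_ct else 0.0
                rows.append((g, exposure.chemical, temp_c, b, t,
                             true_ct + noise))
    return pd.DataFrame(rows, columns=["gene", "condition", "temp_c",
                                       "bio_rep", "tech_rep", "ct"])
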