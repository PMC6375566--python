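"""Named study-condition presets: strains, chemicals and exposures.

Strain presets carry the published baseline male frequencies (<0.2%
for the self-fertilizing screening strain, 36.7% for the him-8
calibration strain).  Chemical exposure presets anchor each Hill curve
to the reported dose series: significant embryonic lethality from
100 uM for DBP and permethrin and from 10 uM for TCMTB; ~50% brood
reduction at 500 uM DBP/permethrin and at 100-500 uM TCMTB; 2- to
3-fold corpse increases at the follow-up doses (100 uM DBP/permethrin,
10 uM TCMTB); germline-specific chk-1 upregulation for all three
chemicals plus DBP-specific spo-11/prmt-5 up- and mre-11
down-regulation.
"""

from __future__ import annotations

from dataclasses import replace

from .chemlib import ChemicalRecord, molecular_weight, parse_formula
from .simkit import DoseResponseParams, ExposureParams, StrainParams

__all__ = [
    "STRAINS", "CHEMICALS", "EXPOSURES", "vehicle_exposure",
    "get_strain", "get_exposure", "exposure_with_ndj", "STUDY_DOSES",
]

# ---------------------------------------------------------------------------
# strains

STRAINS: dict[str, StrainParams] = {
    # Pxol-1::gfp; col-121 screening strain (cuticle permeability folded
    # into effective dose; default multiplier 1)
    "screen": StrainParams(name="screen", p_male=0.001),
    "wild-type": StrainParams(name="wild-type", p_male=0.001),
    # him-8: high incidence of males via X nondisjunction
    "him-8": StrainParams(name="him-8", p_male=0.367),
    # p53 ortholog null: no damage-induced germ-cell apoptosis
    "cep-1": StrainParams(name="cep-1", p_male=0.001, cep1_functional=False),
    # repair factor loss traps RAD-51 at breaks (total DSB counting)
    "rad-54": StrainParams(name="rad-54", p_male=0.001, rad54_functional=False),
    # RNAi depletion of the meiotic DSB-forming enzyme
    "spo-11-depleted": StrainParams(name="spo-11-depleted", p_male=0.001,
                                    spo11_active=False),
    # temperature-sensitive germline-less design: germline at 15C only
    "glp-1": StrainParams(name="glp-1", p_male=0.001, glp1_ts=True),
}


def get_strain(name: str) -> StrainParams:
    try:
        return STRAINS[name]
    except KeyError:
        raise KeyError(f"unknown strain preset {name!r}; "
                       f"available: {', '.join(sorted(STRAINS))}") from None


# ---------------------------------------------------------------------------
# chemicals (formulas from standard references)

def _chem(name: str, category: str, formula: str, dose: float,
          solvent: str = "DMSO") -> ChemicalRecord:
    return ChemicalRecord(name=name, category=category, formula=formula,
                          molar_mass=molecular_weight(parse_formula(formula)),
                          screen_dose=dose, solvent=solvent)


CHEMICALS: dict[str, ChemicalRecord] = {
    "DMSO": _chem("DMSO", "vehicle", "C2H6OS", 0.0),
    "DBP": _chem("DBP", "phthalate", "C16H22O4", 100.0),
    "permethrin": _chem("permethrin", "pesticide", "C21H20Cl2O3", 100.0),
    "TCMTB": _chem("TCMTB", "pesticide", "C9H6N2S3", 10.0),
    "BPA": _chem("BPA", "plasticizer", "C15H16O2", 100.0),
}

#: follow-up study doses (umol/L) per chemical
STUDY_DOSES = {"DBP": 100.0, "permethrin": 100.0, "TCMTB": 10.0,
               "BPA": 100.0, "DMSO": 0.0}

# ---------------------------------------------------------------------------
# exposures

_DR = DoseResponseParams

# brood ec50 chosen so the Hill curve passes exactly through a 50%
# reduction at the anchoring dose: ec50 = d50 / 5**(1/3) with emax 0.6, n 3
_BROOD_D500 = _DR(ec50=500 / 5 ** (1 / 3), hill_n=3, emax=0.6)
_BROOD_D100 = _DR(ec50=100 / 5 ** (1 / 3), hill_n=3, emax=0.6)


def _gene_fx(ec50: float, **lfc: tuple[float, float]):
    """Map gene -> (germline, soma) Hill curves saturating at the given
    log2 fold changes."""
    return {g: (_DR(ec50=ec50, hill_n=2, emax=germ),
                _DR(ec50=ec50, hill_n=2, emax=soma))
            for g, (germ, soma) in lfc.items()}


EXPOSURES: dict[str, ExposureParams] = {
    "DMSO": ExposureParams(chemical="DMSO", dose=0.0),
    "DBP": ExposureParams(
        chemical="DBP", dose=100.0,
        ndj=_DR(ec50=120, hill_n=1.5, emax=0.08),
        brood=_BROOD_D500,
        emb_lethality=_DR(ec50=150, hill_n=2, emax=0.35),
        larval_lethality=_DR(ec50=900, hill_n=3, emax=0.15),
        apoptosis=_DR(ec50=30, hill_n=2, emax=3.6),
        dsb=_DR(ec50=40, hill_n=2, emax=1.5),
        gene_effects=_gene_fx(30, **{
            "chk-1": (0.8, 0.0), "spo-11": (1.0, 0.0),
            "mre-11": (-0.8, 0.0), "prmt-5": (0.9, 0.0)}),
        diakinesis_probs=(0.70, 0.12, 0.08, 0.10),
        gonad_defect_probs=(0.302, 0.208, 0.245),
    ),
    "permethrin": ExposureParams(
        chemical="permethrin", dose=100.0,
        ndj=_DR(ec50=130, hill_n=1.5, emax=0.07),
        brood=_BROOD_D500,
        emb_lethality=_DR(ec50=160, hill_n=2, emax=0.32),
        larval_lethality=_DR(ec50=900, hill_n=3, emax=0.15),
        apoptosis=_DR(ec50=32, hill_n=2, emax=3.2),
        dsb=_DR(ec50=45, hill_n=2, emax=1.4),
        gene_effects=_gene_fx(32, **{"chk-1": (0.8, 0.0)}),
        diakinesis_probs=(0.72, 0.10, 0.08, 0.10),
        gonad_defect_probs=(0.15, 0.217, 0.478),
    ),
    "TCMTB": ExposureParams(
        chemical="TCMTB", dose=10.0,
        ndj=_DR(ec50=12, hill_n=1.5, emax=0.09),
        brood=_BROOD_D100,
        emb_lethality=_DR(ec50=15, hill_n=2, emax=0.35),
        larval_lethality=_DR(ec50=450, hill_n=3, emax=0.25),
        apoptosis=_DR(ec50=3, hill_n=2, emax=3.4),
        dsb=_DR(ec50=4, hill_n=2, emax=1.5),
        gene_effects=_gene_fx(3, **{"chk-1": (0.8, 0.0)}),
        diakinesis_probs=(0.68, 0.13, 0.09, 0.10),
        gonad_defect_probs=(0.18, 0.333, 0.317),
    ),
    # benchmark endocrine disruptor: a real but modest nondisjunction
    # effect, below the three follow-up chemicals at their study doses
    "BPA": ExposureParams(
        chemical="BPA", dose=100.0,
        ndj=_DR(ec50=150, hill_n=1.5, emax=0.02),
        emb_lethality=_DR(ec50=400, hill_n=2, emax=0.1),
        apoptosis=_DR(ec50=80, hill_n=2, emax=1.0),
    ),
}


def vehicle_exposure() -> ExposureParams:
    """The 0.1% DMSO vehicle arm (zero effect on every endpoint)."""
    return EXPOSURES["DMSO"]


def get_exposure(name: str, dose: float | None = None) -> ExposureParams:
    """Fetch an exposure preset, optionally re-dosed."""
    try:
        exp = EXPOSURES[name]
    except KeyError:
        raise KeyError(f"unknown exposure preset {name!r}; "
                       f"available: {', '.join(sorted(EXPOSURES))}") from None
    return exp if dose is None else exp.at_dose(dose)


def exposure_with_ndj(name: str, delta_p: float,
                      dose: float = 100.0) -> ExposureParams:
    """A minimal exposure whose nondisjunction increment at ``dose`` is
    exactly ``delta_p`` (used for pipeline-recovery experiments)."""
    return ExposureParams(chemical=name, dose=dose,
                          ndj=DoseResponseParams(ec50=0.0, hill_n=1.0,
                                                 emax=delta_p))
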