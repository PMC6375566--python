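"""End-to-end orchestration: simulate -> calibrate -> screen ->
phenostats -> qpcr -> report.

Each stage reads and writes comma-delimited UTF-8 tables under the
configured output directory, so every stage is re-runnable from files
alone.  Stage failures raise :class:`StageError` carrying the exit
code contract (2 config, 3 data validation, 4 statistical stage).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import cytostats, gating, qpcr, screen, simkit
from .io import (RunConfig, file_digest, load_screen_folds, params_digest,
                 read_table, summaries_from_fold_table, write_table)
from .presets import EXPOSURES, get_exposure, get_strain, vehicle_exposure
from .screen import summaries_to_frame

__all__ = ["StageError", "run_pipeline", "SCENARIOS", "STAGES",
           "profiles_from_foci_table"]

log = logging.getLogger("germscreen")

EXIT_CONFIG = 2
EXIT_DATA = 3
EXIT_STATS = 4

SCENARIOS: dict[str, dict] = {
    "paper-default": {
        "chemicals": ["BPA", "DBP", "permethrin", "TCMTB"],
        "qpcr_chemicals": ["DBP", "permethrin", "TCMTB"],
    },
    "smoke": {
        "chemicals": ["DBP"],
        "qpcr_chemicals": ["DBP"],
    },
}

STAGES = ("simulate", "calibrate", "screen", "phenostats", "qpcr", "report")

VEHICLE = "DMSO"

#: calibration-run composition: staged mixture including debris
CALIBRATION_COMPOSITION = {"debris": 0.1, "L1": 0.05, "L2": 0.05,
                           "L3": 0.1, "L4": 0.2, "adult": 0.5}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and exit code."""

    def __init__(self, stage: str, exit_code: int, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage
        self.exit_code = exit_code


def _scenario(cfg: RunConfig) -> dict:
    try:
        return SCENARIOS[cfg.scenario]
    except KeyError:
        raise StageError("simulate", EXIT_CONFIG,
                         f"unknown scenario {cfg.scenario!r}; available: "
                         f"{', '.join(sorted(SCENARIOS))}")


def _out(cfg: RunConfig) -> Path:
    p = Path(cfg.out_dir)
    p.mkdir(parents=True, exist_ok=True)
    return p


# ---------------------------------------------------------------------------
# simulate

def stage_simulate(cfg: RunConfig) -> None:
    sc = _scenario(cfg)
    out = _out(cfg)
    rng = np.random.default_rng(cfg.seed)
    meta = {"scenario": cfg.scenario, "n_events": cfg.n_events,
            "n_gonads": cfg.n_gonads, "n_mothers": cfg.n_mothers}
    chems = sc["chemicals"]
    conditions = [VEHICLE] + chems
    strain = get_strain("screen")

    # calibration runs (stage-labeled; negative and him-8 positive strain)
    for tag, strain_name, n in (("neg", "screen", 4000),
                                ("pos", "him-8", 2000)):
        ev = simkit.simulate_biosort_run(
            get_strain(strain_name), vehicle_exposure(),
            CALIBRATION_COMPOSITION, n, rng)
        write_table(ev, out / f"events_calibration_{tag}.csv",
                    seed=cfg.seed, params={**meta, "run": tag})

    # screen wells
    events_dir = out / "events"
    for chem in conditions:
        exposure = get_exposure(chem)
        for rep in range(1, cfg.n_replicates + 1):
            ev = simkit.simulate_biosort_run(strain, exposure,
                                             n_events=cfg.n_events, rng=rng)
            write_table(ev, events_dir / f"events_{chem}_rep{rep}.csv",
                        seed=cfg.seed,
                        params={**meta, "chemical": chem, "rep": rep})

    # plate phenotypes
    brood_frames = []
    for chem in conditions:
        b = simkit.simulate_brood(strain, get_exposure(chem),
                                  cfg.n_mothers, rng)
        b.insert(0, "condition", chem)
        brood_frames.append(b)
    write_table(pd.concat(brood_frames, ignore_index=True),
                out / "brood.csv", seed=cfg.seed, params=meta)

    # germline cytology: corpses in both cep-1 backgrounds, foci and
    # diakinesis in the screening background
    corpse_rows, foci_rows, dia_rows = [], [], []
    for chem in conditions:
        exposure = get_exposure(chem)
        for genotype in ("screen", "cep-1"):
            profiles = simkit.simulate_germline(get_strain(genotype),
                                                exposure, cfg.n_gonads, rng)
            for i, p in enumerate(profiles):
                corpse_rows.append((chem, genotype, i, p.corpse_count))
                if genotype != "screen":
                    continue
                for z in range(7):
                    for j, f in enumerate(p.zone_foci[z]):
                        foci_rows.append((chem, i, z + 1, j, int(f)))
                for k, (nb, cls) in enumerate(p.diakinesis):
                    dia_rows.append((chem, i, k, nb, cls))
    write_table(pd.DataFrame(corpse_rows, columns=["condition", "genotype",
                                                   "gonad", "count"]),
                out / "corpses.csv", seed=cfg.seed, params=meta)
    write_table(pd.DataFrame(foci_rows, columns=["condition", "gonad",
                                                 "zone", "nucleus", "foci"]),
                out / "foci.csv", seed=cfg.seed, params=meta)
    write_table(pd.DataFrame(dia_rows, columns=["condition", "gonad",
                                                "oocyte", "n_bodies",
                                                "defect_class"]),
                out / "diakinesis.csv", seed=cfg.seed, params=meta)

    # qPCR in the glp-1 temperature design
    glp1 = get_strain("glp-1")
    genes = [simkit.REFERENCE_GENE, *simkit.PANEL_GENES]
    ct_frames = []
    for temp, n_bio in ((15, 3), (25, 4)):
        for chem in [VEHICLE] + sc["qpcr_chemicals"]:
            ct_frames.append(simkit.simulate_qpcr(
                glp1, get_exposure(chem), temp, genes, n_bio=n_bio, rng=rng))
    write_table(pd.concat(ct_frames, ignore_index=True), out / "ct.csv",
                seed=cfg.seed, params=meta)
    log.info("simulate: wrote inputs for scenario %r under %s (seed %d, "
             "params %s)", cfg.scenario, out, cfg.seed, params_digest(meta))


# ---------------------------------------------------------------------------
# calibrate

def stage_calibrate(cfg: RunConfig) -> None:
    out = _out(cfg)
    neg_path = out / "events_calibration_neg.csv"
    pos_path = out / "events_calibration_pos.csv"
    for p in (neg_path, pos_path):
        if not p.exists():
            raise StageError("calibrate", EXIT_DATA,
                             f"calibration run {p.name} not found; run the "
                             "simulate stage first")
    neg = read_table(neg_path)
    pos = read_table(pos_path)
    try:
        gate = gating.fit_adult_gate(neg)
        neg_adults = neg[(neg.tof >= gate.tof_min) & (neg.tof <= gate.tof_max)]
        pos_adults = pos[(pos.tof >= gate.tof_min) & (pos.tof <= gate.tof_max)]
        thr = gating.fit_gfp_threshold(neg_adults, pos_adults)
    except (ValueError, gating.UnusableCalibrationError) as exc:
        raise StageError("calibrate", EXIT_STATS, str(exc))
    cal_path = Path(cfg.calibration_file or out / "calibration.txt")
    gating.save_calibration(cal_path, gate, thr, extra={
        "neg_digest": file_digest(neg_path),
        "pos_digest": file_digest(pos_path),
        "seed": str(cfg.seed),
    })
    log.info("calibrate: gate [%.1f, %.1f] (capture %.3f, L4 %.4f), "
             "tau %.2f (fpr %.4f, fnr %.4f) -> %s", gate.tof_min,
             gate.tof_max, gate.adult_capture, gate.l4_contamination,
             thr.tau, thr.fpr_neg, thr.fnr_pos, cal_path)


# ---------------------------------------------------------------------------
# screen

def _well_from_file(path: Path, gate, thr, chem: str,
                    rep: int) -> screen.WellResult:
    events = read_table(path)
    classes = gating.classify(events, gate, thr)
    return screen.score_well(classes, chem, rep)


def stage_screen(cfg: RunConfig) -> None:
    out = _out(cfg)
    cal_path = Path(cfg.calibration_file or out / "calibration.txt")
    if not cal_path.exists():
        raise StageError("screen", EXIT_CONFIG,
                         f"calibration file {cal_path} not found; the "
                         "gating stage (calibrate) must run first")
    gate, thr = gating.load_calibration(cal_path)
    events_dir = out / "events"
    files = sorted(events_dir.glob("events_*_rep*.csv"))
    if not files:
        raise StageError("screen", EXIT_DATA,
                         f"no event tables under {events_dir}")
    wells: dict[str, list[screen.WellResult]] = {}
    for f in files:
        stem = f.stem[len("events_"):]
        chem, _, rep_part = stem.rpartition("_rep")
        try:
            rep = int(rep_part)
        except ValueError:
            raise StageError("screen", EXIT_DATA,
                             f"cannot parse replicate id from {f.name}")
        try:
            wells.setdefault(chem, []).append(
                _well_from_file(f, gate, thr, chem, rep))
        except screen.WellFailedError as exc:
            raise StageError("screen", EXIT_DATA, str(exc))
    if VEHICLE not in wells:
        raise StageError("screen", EXIT_DATA,
                         f"no vehicle ({VEHICLE!r}) wells found")
    try:
        summaries = [screen.summarize_chemical(w, wells[VEHICLE])
                     for chem, w in wells.items() if chem != VEHICLE]
        if cfg.benchmark in wells:
            ranked = screen.call_hits(summaries, benchmark=cfg.benchmark)
        else:
            ranked = sorted(summaries,
                            key=lambda s: (-s.mean_fold, s.chemical))
            for i, s in enumerate(ranked, 1):
                s.rank = i
    except ValueError as exc:
        raise StageError("screen", EXIT_STATS, str(exc))
    write_table(summaries_to_frame(ranked), out / "summary.csv",
                seed=cfg.seed)
    log.info("screen: scored %d chemicals, %d hits above %r",
             len(ranked), sum(bool(s.hit) for s in ranked), cfg.benchmark)


# ---------------------------------------------------------------------------
# phenostats

def profiles_from_foci_table(df: pd.DataFrame) -> list[simkit.GermlineProfile]:
    """Rebuild per-gonad zone-focus profiles from a tidy foci table
    (columns gonad, zone, foci)."""
    profiles = []
    for _, sub in df.groupby("gonad"):
        foci = [sub.loc[sub.zone == z + 1, "foci"].to_numpy()
                for z in range(7)]
        profiles.append(simkit.GermlineProfile(foci, 0, [], {}))
    return profiles


def stage_phenostats(cfg: RunConfig) -> None:
    out = _out(cfg)
    for name in ("brood.csv", "corpses.csv", "foci.csv", "diakinesis.csv"):
        if not (out / name).exists():
            raise StageError("phenostats", EXIT_DATA,
                             f"{name} not found under {out}; run simulate")
    try:
        # plate phenotypes
        brood = read_table(out / "brood.csv")
        rows = []
        veh = brood[brood.condition == VEHICLE]
        for cond, sub in brood.groupby("condition"):
            emb, larv = zip(*(cytostats.lethality_fractions(e, h, a)
                              for e, h, a in zip(sub.eggs, sub.hatched,
                                                 sub.adults)))
            emb, larv = np.array(emb), np.array(larv)
            row = {"condition": cond, "n_mothers": len(sub),
                   "mean_brood": sub.eggs.mean(),
                   "sem_brood": sub.eggs.sem(),
                   "emb_lethality": np.nanmean(emb),
                   "larval_lethality": np.nanmean(larv)}
            if cond != VEHICLE:
                veh_emb = ((veh.eggs - veh.hatched) / veh.eggs).to_numpy()
                row["p_brood"] = cytostats.mann_whitney_two_tailed(
                    sub.eggs, veh.eggs).p_value
                row["p_emb"] = cytostats.mann_whitney_two_tailed(
                    emb[~np.isnan(emb)], veh_emb[~np.isnan(veh_emb)]).p_value
            rows.append(row)
        write_table(pd.DataFrame(rows), out / "plate_phenotypes.csv",
                    seed=cfg.seed)

        # corpses
        corpses = read_table(out / "corpses.csv")
        table, labels = cytostats.corpse_analysis(corpses, vehicle=VEHICLE,
                                                  alpha=cfg.alpha)
        table["cep1_dependence"] = table.condition.map(labels).fillna("")
        write_table(table, out / "corpse_stats.csv", seed=cfg.seed)

        # zone profiles
        foci = read_table(out / "foci.csv")
        veh_profiles = profiles_from_foci_table(
            foci[foci.condition == VEHICLE])
        zone_frames = []
        for cond in foci.condition.unique():
            if cond == VEHICLE:
                continue
            zp = cytostats.zone_profile_compare(
                profiles_from_foci_table(foci[foci.condition == cond]),
                veh_profiles)
            zp.insert(0, "condition", cond)
            zone_frames.append(zp)
        if zone_frames:
            write_table(pd.concat(zone_frames, ignore_index=True),
                        out / "zone_profiles.csv", seed=cfg.seed)

        # diakinesis
        dia = read_table(out / "diakinesis.csv")
        dia_rows = []
        for cond, sub in dia.groupby("condition"):
            tally = cytostats.diakinesis_tally(
                list(zip(sub.n_bodies, sub.defect_class)))
            dia_rows.append({"condition": cond, "n_oocytes": tally["n"],
                             "modal_dapi_bodies": tally["modal_dapi_bodies"],
                             **{f"pct_{c}": v
                                for c, v in tally["percent"].items()}})
        write_table(pd.DataFrame(dia_rows), out / "diakinesis_summary.csv",
                    seed=cfg.seed)
    except StageError:
        raise
    except ValueError as exc:
        raise StageError("phenostats", EXIT_STATS, str(exc))
    log.info("phenostats: wrote plate_phenotypes, corpse_stats, "
             "zone_profiles, diakinesis_summary")


# ---------------------------------------------------------------------------
# qpcr

def stage_qpcr(cfg: RunConfig) -> None:
    out = _out(cfg)
    ct_path = out / "ct.csv"
    if not ct_path.exists():
        raise StageError("qpcr", EXIT_DATA,
                         f"{ct_path.name} not found under {out}; run simulate")
    try:
        report = qpcr.attribution_report(read_table(ct_path), vehicle=VEHICLE,
                                         alpha=cfg.alpha)
    except ValueError as exc:
        raise StageError("qpcr", EXIT_STATS, str(exc))
    write_table(report, out / "qpcr_report.csv", seed=cfg.seed)
    log.info("qpcr: %d germline-specific calls of %d gene x condition pairs",
             int((report.attribution == "germline_specific").sum()),
             len(report))


# ---------------------------------------------------------------------------
# report

def stage_report(cfg: RunConfig) -> None:
    out = _out(cfg)
    bundle: dict = {"config": asdict(cfg), "inputs": {}}
    for name in ("summary.csv", "plate_phenotypes.csv", "corpse_stats.csv",
                 "diakinesis_summary.csv", "qpcr_report.csv"):
        p = out / name
        if p.exists():
            bundle["inputs"][name] = file_digest(p)
    summary_path = out / "summary.csv"
    if summary_path.exists():
        df = read_table(summary_path)
        if "hit" in df.columns:
            bundle["n_hits"] = int((df.hit == True).sum())  # noqa: E712
        bundle["chemicals"] = df.chemical.tolist()
    qpcr_path = out / "qpcr_report.csv"
    if qpcr_path.exists():
        df = read_table(qpcr_path)
        bundle["germline_specific"] = (
            df[df.attribution == "germline_specific"]
            [["condition", "gene"]].to_dict("records"))
    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(bundle, fh, indent=2)
    log.info("report: wrote report.json")


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "calibrate": stage_calibrate,
    "screen": stage_screen,
    "phenostats": stage_phenostats,
    "qpcr": stage_qpcr,
    "report": stage_report,
}


def run_pipeline(cfg: RunConfig,
                 stages: tuple[str, ...] = STAGES) -> None:
    """Execute the requested stages in dependency order."""
    order = [s for s in STAGES if s in stages]
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise StageError("pipeline", EXIT_CONFIG,
                         f"unknown stage(s): {', '.join(sorted(unknown))}")
    for s in order:
        log.info("running stage %s", s)
        _STAGE_FUNCS[s](cfg)
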