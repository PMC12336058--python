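"""End-to-end analysis flows composing the preprocessing, laterality and
reliability modules, on files or on in-memory synthetic cohorts."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import (config_hash, load_preprocess_config, read_cohort_csv,
                 read_recording_csv, read_schedule_csv, write_cohort_csv,
                 write_json, write_recording_csv, write_schedule_csv)
from .laterality import BLD, LLD, compute_li
from .preprocess import PreprocessConfig, preprocess_session
from .reliability import (PairedLISet, bland_altman, cohens_kappa,
                          cutoff_sweep, icc_a1, percent_agreement)
from .simulate import RetestCohortConfig, generate_retest_cohort

__all__ = [
    "run_session", "analyze_session", "cohort_from_simulation",
    "reliability_report", "run_reliability", "simulate_to_dir",
]

logger = logging.getLogger(__name__)


def analyze_session(rec, sched, cfg: PreprocessConfig | None = None,
                    ci_method: str = "t", manual_exclusions=()):
    """Preprocess one recording and compute its laterality result.

    Returns ``(LateralityResult, qc_summary)``.
    """
    cfg = cfg or PreprocessConfig()
    es = preprocess_session(rec, sched, cfg, manual_exclusions)
    qc = es.qc_summary()
    logger.info("session QC: %s", qc)
    return compute_li(es, cfg, ci_method=ci_method), qc


def run_session(recording_path, schedule_path, config_path=None,
                ci_method: str = "t"):
    """File-level session analysis: read, preprocess, classify."""
    cfg = load_preprocess_config(config_path)
    rec = read_recording_csv(recording_path)
    sched = read_schedule_csv(schedule_path)
    result, qc = analyze_session(rec, sched, cfg, ci_method=ci_method)
    report = result.to_dict()
    report["qc"] = qc
    report["provenance"] = {"config_hash": config_hash(cfg),
                            "package_version": __version__,
                            "recording": str(recording_path)}
    return result, report


def cohort_from_simulation(cohort, cfg: PreprocessConfig | None = None,
                           ci_method: str = "t") -> PairedLISet:
    """Run the full pipeline on a simulated retest cohort and assemble the
    per-subject paired LI set (first two sessions per subject)."""
    cfg = cfg or PreprocessConfig()
    ids, li1, li2, lab1, lab2 = [], [], [], [], []
    for subj in cohort:
        if len(subj.sessions) < 2:
            logger.warning("subject %s has fewer than 2 sessions; dropped",
                           subj.subject_id)
            continue
        results = []
        for rec, sched, _truth in subj.sessions[:2]:
            res, _ = analyze_session(rec, sched, cfg, ci_method=ci_method)
            results.append(res)
        ids.append(subj.subject_id)
        li1.append(results[0].li)
        li2.append(results[1].li)
        lab1.append(results[0].label)
        lab2.append(results[1].label)
    subgroup = ["initial-" + l if l in (BLD, LLD) else "other" for l in lab1]
    return PairedLISet(np.array(ids), np.array(li1), np.array(li2),
                       np.array(lab1, dtype=object),
                       np.array(lab2, dtype=object),
                       np.array(subgroup, dtype=object))


def reliability_report(pairs: PairedLISet, cutoffs=None) -> dict:
    """The full test-retest battery on a paired LI set.

    Whole-group ICC(A,1), Cohen's kappa and Bland-Altman; subgroup ICCs
    and percentage agreements for subjects initially classified BLD or
    LLD; sign-consistency counts; and the fixed-cutoff sweep table.
    """
    report: dict = {"n_subjects": pairs.n}
    icc = icc_a1(pairs.li_s1, pairs.li_s2)
    report["icc"] = {"icc": icc.icc, "f": icc.f, "df1": icc.df1,
                     "df2": icc.df2, "p": icc.p}
    kap = cohens_kappa(pairs.label_s1, pairs.label_s2)
    report["kappa"] = {"kappa": kap.kappa, "z": kap.z, "p": kap.p,
                       "contingency": kap.contingency.tolist(),
                       "categories": list(kap.categories)}
    ba = bland_altman(pairs.li_s1, pairs.li_s2)
    report["bland_altman"] = {"mean_diff": ba.mean_diff, "sd_diff": ba.sd_diff,
                              "loa_low": ba.loa_low, "loa_high": ba.loa_high}
    frac_all, pct_all = percent_agreement(pairs.label_s1, pairs.label_s2)
    report["agreement"] = {"all": {"fraction": frac_all, "percent": pct_all,
                                   "n": pairs.n}}
    for initial in (BLD, LLD):
        mask = pairs.label_s1 == initial
        entry: dict = {"n": int(mask.sum())}
        if mask.sum() >= 1:
            frac, pct = percent_agreement(pairs.label_s1, pairs.label_s2, mask)
            entry.update(fraction=frac, percent=pct)
        if mask.sum() >= 3:
            sub_icc = icc_a1(pairs.li_s1[mask], pairs.li_s2[mask])
            entry["icc"] = {"icc": sub_icc.icc, "f": sub_icc.f,
                            "df1": sub_icc.df1, "df2": sub_icc.df2,
                            "p": sub_icc.p}
        report["agreement"][f"initial_{initial}"] = entry
    sign1 = np.sign(pairs.li_s1)
    sign2 = np.sign(pairs.li_s2)
    consistent = int((sign1 == sign2).sum())
    report["sign"] = {"consistent": consistent,
                      "changed": pairs.n - consistent,
                      "fraction_consistent": consistent / pairs.n}
    sweep = cutoff_sweep(pairs.li_s1, pairs.li_s2, cutoffs)
    report["cutoff_sweep"] = sweep.to_dict(orient="records")
    return report


def run_reliability(cohort_path, cutoffs=None) -> dict:
    """File-level reliability analysis on a cohort CSV."""
    pairs = read_cohort_csv(cohort_path)
    report = reliability_report(pairs, cutoffs)
    report["provenance"] = {"cohort": str(cohort_path),
                            "package_version": __version__}
    return report


def simulate_to_dir(cfg: RetestCohortConfig, out_dir) -> dict:
    """Write a complete synthetic cohort to disk.

    Per subject and session: a recording CSV and a schedule CSV; plus one
    truth-ledger JSON for the whole cohort.  Byte-identical across reruns
    with the same config and seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = generate_retest_cohort(cfg)
    ledger = {"seed": cfg.seed, "n_subjects": cfg.n_subjects,
              "state_sd": cfg.state_sd, "subjects": []}
    for subj in cohort:
        entry = {"subject_id": subj.subject_id, "trait_li": subj.trait_li,
                 "sessions": []}
        for s, (rec, sched, truth) in enumerate(subj.sessions, start=1):
            rec_path = out / f"{subj.subject_id}_ses-{s}_recording.csv"
            sched_path = out / f"{subj.subject_id}_ses-{s}_schedule.csv"
            write_recording_csv(rec, rec_path)
            write_schedule_csv(sched, sched_path)
            entry["sessions"].append({
                "session": s, "recording": rec_path.name,
                "schedule": sched_path.name,
                "state_offset": truth.state_offset,
                "expected_li": truth.expected_li,
                "artifacts": [list(a) for a in truth.artifacts],
            })
        ledger["subjects"].append(entry)
    write_json(ledger, out / "truth_ledger.json")
    return ledger
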