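"""End-to-end orchestration: simulate -> measure -> quantify -> analyze.

The CLI wraps these functions; they are equally usable from Python, which is
how the test-suite and the reproduction script drive the pipeline.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from aaquant import __version__
from aaquant.cross_section import (
    MeasureConfig, QC_OK, measure_tree, measurements_to_frame,
)
from aaquant.phantom import (
    CohortData, CohortParams, PhantomVolume, generate_cohort,
)
from aaquant.quantify import (
    Thresholds, classify, compute_ratios, count_aa_pairs, ratio_summary,
)
from aaquant.stats import (
    LMMResult, ModelSpec, ROCResult, RESPONSES, SpecificationError,
    compute_icc, fit_lmm, group_tests, lrt_select, roc_threshold,
)
from aaquant.tree_model import read_tree, write_tree, label_tree

logger = logging.getLogger(__name__)

MEASUREMENT_COLUMNS = [
    "subject_id", "branch_id", "lobe", "generation", "segmental_generation",
    "volume_state", "inner_diameter_mm", "outer_diameter_mm",
    "wall_thickness_mm", "artery_diameter_mm", "qc_status",
]


def simulate_to_dir(out_dir, params_cf: Optional[CohortParams] = None,
                    params_control: Optional[CohortParams] = None,
                    n_per_cohort: Optional[int] = None, seed: int = 0,
                    write_volumes: bool = True) -> CohortData:
    """Simulate both cohorts and write volumes/trees/truth/metadata to disk."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(params_cf, params_control, n_per_cohort,
                             rng_seed=seed, rasterize_volumes=write_volumes)
    for (sid, state), tree in cohort.trees.items():
        write_tree(tree, out / f"{sid}_{state}.tree.json")
    if write_volumes:
        for (sid, state), vol in cohort.volumes.items():
            vol.save_nifti(out / f"{sid}_{state}.nii.gz")
    cohort.ground_truth.to_csv(out / "ground_truth.csv", index=False)
    subjects = pd.DataFrame([vars(s) for s in cohort.subjects])
    subjects.to_csv(out / "subjects.csv", index=False)
    with open(out / "metadata.json", "w") as fh:
        json.dump({"seed": seed, "package_version": __version__,
                   "n_volumes": len(cohort.volumes),
                   "n_trees": len(cohort.trees)}, fh, indent=1)
    return cohort


def measure_cohort(cohort: CohortData,
                   config: Optional[MeasureConfig] = None,
                   positions: Sequence[float] = (0.5,)) -> pd.DataFrame:
    """Measure every branch of every volume; one session per position.

    Multiple positions yield repeated measurements of each branch at
    jittered centreline locations (column ``session``), the substrate for
    intra-observer-style ICC analysis.
    """
    config = config or MeasureConfig()
    frames = []
    subj_info = {s.subject_id: s for s in cohort.subjects}
    for (sid, state), vol in sorted(cohort.volumes.items()):
        tree = cohort.trees[(sid, state)]
        labels = label_tree(tree)
        for si, pos in enumerate(positions):
            cfg = MeasureConfig(**{**vars(config), "position": pos})
            df = measurements_to_frame(
                measure_tree(vol, tree, labels, sid, state, cfg))
            df["session"] = si + 1
            df["position"] = pos
            s = subj_info[sid]
            df["disease_status"] = s.disease_status
            df["age_years"] = s.age_years
            df["height_cm"] = s.height_cm
            df["gender"] = s.gender
            frames.append(df)
    return pd.concat(frames, ignore_index=True)


def measure_directory(volume_dir, tree_dir=None,
                      config: Optional[MeasureConfig] = None,
                      positions: Sequence[float] = (0.5,),
                      subjects_csv=None) -> tuple[pd.DataFrame, List[str]]:
    """Measure all ``<subject>_<state>.nii.gz`` + matching tree files.

    Unreadable inputs skip that subject and are reported in the failure
    list; the batch never aborts.
    """
    config = config or MeasureConfig()
    volume_dir = Path(volume_dir)
    tree_dir = Path(tree_dir) if tree_dir is not None else volume_dir
    covars = None
    sub_csv = Path(subjects_csv) if subjects_csv else volume_dir / "subjects.csv"
    if sub_csv.exists():
        covars = pd.read_csv(sub_csv).drop_duplicates("subject_id") \
            .set_index("subject_id")
    frames, failures = [], []
    paths = sorted(itertools.chain(volume_dir.glob("*.nii.gz"),
                                   volume_dir.glob("*.nii"),
                                   volume_dir.glob("*.mha"),
                                   volume_dir.glob("*.mhd")))
    for vol_path in paths:
        stem = vol_path.name
        for ext in (".nii.gz", ".nii", ".mha", ".mhd"):
            if stem.endswith(ext):
                stem = stem[: -len(ext)]
                break
        try:
            sid, state = stem.rsplit("_", 1)
            vol = PhantomVolume.load(vol_path)
            tree = read_tree(tree_dir / f"{stem}.tree.json")
            labels = label_tree(tree)
        except Exception as exc:  # noqa: BLE001 - per-subject isolation
            logger.error("skipping %s: %s", vol_path.name, exc)
            failures.append(f"{vol_path.name}: {exc}")
            continue
        for si, pos in enumerate(positions):
            cfg = MeasureConfig(**{**vars(config), "position": pos})
            df = measurements_to_frame(
                measure_tree(vol, tree, labels, sid, state, cfg))
            df["session"] = si + 1
            df["position"] = pos
            if covars is not None and sid in covars.index:
                for c in ("disease_status", "age_years", "height_cm", "gender"):
                    if c in covars.columns:
                        df[c] = covars.loc[sid, c]
            frames.append(df)
    if not frames:
        return pd.DataFrame(columns=MEASUREMENT_COLUMNS), failures
    return pd.concat(frames, ignore_index=True), failures


@dataclass
class AnalysisResult:
    """Bundle of everything the analysis stage produces."""

    ratios: pd.DataFrame
    counts: pd.DataFrame
    counts_by_generation: pd.DataFrame
    ratio_summaries: pd.DataFrame
    lmm: Dict[str, LMMResult] = field(default_factory=dict)
    lmm_by_generation: Optional[pd.DataFrame] = None
    lrt: Dict[str, Dict] = field(default_factory=dict)
    roc: Dict[str, ROCResult] = field(default_factory=dict)
    icc: Dict[str, Dict] = field(default_factory=dict)
    tests: Dict[str, Dict] = field(default_factory=dict)
    notes: List[str] = field(default_factory=list)
    report: str = ""


def _check_schema(df: pd.DataFrame) -> None:
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise SpecificationError(
            f"measurement table is missing required columns: {missing}")


def analyze_measurements(measurements: pd.DataFrame,
                         thresholds: Optional[Thresholds] = None,
                         use_peripheral_cuts: bool = False,
                         seed: int = 0, n_boot: int = 500,
                         fit_models: bool = True) -> AnalysisResult:
    """Quantify + model a measurement (or ground-truth) table.

    Runs ratio computation and classification, AA-pair counting, the four
    mixed-effects ratio models (disease status + volume state, subject and
    lobe random effects) with a likelihood-ratio test for the disease term,
    per-generation disease contrasts, ROC threshold finding on inspiratory
    data, the nonparametric test battery, and, when a ``session`` column
    with replicates is present, hierarchical ICCs per dimension.
    """
    _check_schema(measurements)
    df = measurements.copy()
    if "session" in df.columns:
        primary = df[df["session"] == df["session"].min()].copy()
    else:
        primary = df
    ratios = classify(compute_ratios(primary), thresholds, use_peripheral_cuts)

    have_cohort = "disease_status" in ratios.columns and \
        ratios["disease_status"].nunique() > 1
    count_keys = ["volume_state"]
    if "disease_status" in ratios.columns:
        count_keys = ["disease_status", "volume_state"]
    res = AnalysisResult(
        ratios=ratios,
        counts=count_aa_pairs(ratios, count_keys),
        counts_by_generation=count_aa_pairs(
            ratios.dropna(subset=["segmental_generation"]),
            count_keys + ["segmental_generation"]),
        ratio_summaries=ratio_summary(
            ratios, count_keys + ["segmental_generation"]),
    )

    ok = ratios[ratios["qc_status"] == QC_OK]
    rng = np.random.default_rng(seed)

    if fit_models and have_cohort and ok["subject_id"].nunique() >= 4:
        for resp in RESPONSES:
            try:
                spec = ModelSpec(response=resp)
                res.lmm[resp] = fit_lmm(ok, spec)
                full = fit_lmm(ok, spec, reml=False)
                reduced = fit_lmm(ok, ModelSpec(response=resp,
                                                fixed=("volume_state",)),
                                  reml=False)
                stat, dof, p = lrt_select(full, reduced)
                res.lrt[resp] = {"statistic": stat, "df": dof, "p": p,
                                 "dropped": "disease_status"}
            except (SpecificationError, np.linalg.LinAlgError) as exc:
                res.notes.append(f"LMM for {resp} not fitted: {exc}")
        res.lmm_by_generation = _per_generation_contrasts(ok)
    elif fit_models and not have_cohort:
        res.notes.append("single cohort: mixed-model contrasts skipped")

    insp = ok[ok["volume_state"] == "inspiration"]
    if have_cohort and insp["disease_status"].nunique() > 1:
        labels = (insp["disease_status"] == "CF").to_numpy()
        for resp in ("AinA", "AoutA"):
            res.roc[resp] = roc_threshold(
                insp[resp].to_numpy(), labels,
                subjects=insp["subject_id"].to_numpy(),
                n_boot=n_boot, rng=rng)
        peri = insp[insp["segmental_generation"].astype(float) >= 4]
        if peri["disease_status"].nunique() > 1 and len(peri) >= 20:
            for resp in ("AinA", "AoutA"):
                res.roc[f"{resp}_peripheral"] = roc_threshold(
                    peri[resp].to_numpy(),
                    (peri["disease_status"] == "CF").to_numpy(),
                    subjects=peri["subject_id"].to_numpy(),
                    n_boot=n_boot, rng=rng)

    if "disease_status" in ratios.columns:
        per_subject = count_aa_pairs(
            ratios, ["subject_id", "disease_status", "volume_state"])
        for c in ("age_years", "height_cm"):
            if c in ratios.columns:
                per_subject = per_subject.merge(
                    ratios[["subject_id", c]].drop_duplicates("subject_id"),
                    on="subject_id")
        try:
            res.tests = group_tests(per_subject)
        except SpecificationError as exc:
            res.notes.append(f"group tests skipped: {exc}")

    if "session" in df.columns and df["session"].nunique() >= 2:
        rep = df[df["qc_status"] == QC_OK].copy()
        rep["target"] = rep["subject_id"] + "/" + rep["volume_state"] + \
            "/" + rep["branch_id"]
        rep["segmental_generation"] = pd.to_numeric(
            rep["segmental_generation"], errors="coerce").astype(float)
        for dim in ("inner_diameter_mm", "outer_diameter_mm",
                    "wall_thickness_mm", "artery_diameter_mm"):
            sub = rep.dropna(subset=[dim, "segmental_generation"])
            sub = sub[sub.groupby("target")["session"].transform("nunique") >= 2]
            if sub.empty:
                continue
            try:
                icc = compute_icc(sub, value_col=dim, target_col="target",
                                  subject_col="subject_id",
                                  generation_col="segmental_generation")
                res.icc[dim] = {"icc": icc.icc, "band": icc.band,
                                **{f"var_{k}": v
                                   for k, v in icc.var_components.items()}}
            except SpecificationError as exc:
                res.notes.append(f"ICC for {dim} skipped: {exc}")

    res.report = render_report(res)
    return res


def _per_generation_contrasts(ok: pd.DataFrame) -> pd.DataFrame:
    """Disease contrast (CF - control) per segmental generation, from a
    mixed model fitted within each generation stratum (inspiration only)."""
    rows = []
    insp = ok[ok["volume_state"] == "inspiration"]
    gens = sorted(insp["segmental_generation"].dropna().unique())
    for g in gens:
        sub = insp[insp["segmental_generation"] == g]
        if sub["disease_status"].nunique() < 2 or sub["subject_id"].nunique() < 4:
            continue
        for resp in RESPONSES:
            try:
                fit = fit_lmm(sub, ModelSpec(response=resp, fixed=("disease_status",)))
            except (SpecificationError, np.linalg.LinAlgError):
                continue
            term = [t for t in fit.params.index if "disease_status" in t]
            if not term:
                continue
            est = float(fit.params[term[0]])
            # patsy codes control as the reference when levels sort CF first;
            # report the CF - control contrast regardless of coding
            if "control" in term[0]:
                est = -est
            rows.append({"segmental_generation": float(g), "response": resp,
                         "cf_minus_control": est,
                         "se": float(fit.bse[term[0]]),
                         "p": float(fit.pvalues[term[0]]),
                         "n": fit.n_obs})
    return pd.DataFrame(rows)


def render_report(res: AnalysisResult) -> str:
    """Human-readable text report of counts, contrasts, cuts and agreement."""
    lines = ["airway-artery quantification report", "=" * 36, ""]
    lines.append("Visible AA-pairs (qc ok) per cohort and volume state:")
    lines.append(res.counts.to_string(index=False))
    lines.append("")
    if not res.counts_by_generation.empty:
        lines.append("Visible AA-pairs per segmental generation:")
        lines.append(res.counts_by_generation.to_string(index=False))
        lines.append("")
    if res.lmm:
        lines.append("Mixed-effects models (REML; subject intercept + lobe "
                     "component):")
        for resp, fit in res.lmm.items():
            lines.append(f"-- {fit.formula}  "
                         f"[var subj {fit.var_subject:.4g}, lobe "
                         f"{fit.var_lobe:.4g}, resid {fit.var_residual:.4g}]"
                         + ("  (singular fit)" if fit.singular else ""))
            lines.append(fit.summary_frame().to_string())
            if resp in res.lrt:
                t = res.lrt[resp]
                lines.append(f"   LRT drop {t['dropped']}: chi2={t['statistic']:.2f}, "
                             f"df={t['df']}, p={t['p']:.3g}")
        lines.append("")
    if res.lmm_by_generation is not None and not res.lmm_by_generation.empty:
        lines.append("Disease contrast (CF - control) per segmental generation, "
                     "inspiration:")
        lines.append(res.lmm_by_generation.to_string(index=False))
        lines.append("")
    if res.roc:
        lines.append("ROC cut-offs for bronchiectasis (CF vs control, "
                     "inspiration):")
        for name, r in res.roc.items():
            lines.append(
                f"  {name}: AUC {r.auc:.3f} (95% CI {r.auc_ci[0]:.3f}-"
                f"{r.auc_ci[1]:.3f}), threshold {r.threshold:.3f} "
                f"(sens {r.sensitivity:.2f}, spec {r.specificity:.2f})")
        lines.append("")
    if res.tests:
        lines.append("Nonparametric tests on per-subject visible-pair counts:")
        for name, t in res.tests.items():
            parts = ", ".join(f"{k}={v:.4g}" for k, v in t.items())
            lines.append(f"  {name}: {parts}")
        lines.append("")
    if res.icc:
        lines.append("Repeated-measurement ICC per dimension:")
        for dim, d in res.icc.items():
            lines.append(f"  {dim}: ICC {d['icc']:.3f} ({d['band']})")
        lines.append("")
    lines.append("Note: p-values are reported raw (no multiple-testing "
                 "correction).")
    for note in res.notes:
        lines.append(f"note: {note}")
    return "\n".join(lines) + "\n"


def write_analysis(res: AnalysisResult, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    res.ratios.to_csv(out / "ratios.csv", index=False)
    res.counts.to_csv(out / "counts.csv", index=False)
    res.counts_by_generation.to_csv(out / "counts_by_generation.csv", index=False)
    if not res.ratio_summaries.empty:
        res.ratio_summaries.to_csv(out / "ratio_summaries.csv", index=False)
    if res.lmm:
        frames = []
        for resp, fit in res.lmm.items():
            f = fit.summary_frame().reset_index(names="term")
            f.insert(0, "response", resp)
            f["var_subject"] = fit.var_subject
            f["var_lobe"] = fit.var_lobe
            f["var_residual"] = fit.var_residual
            f["singular"] = fit.singular
            frames.append(f)
        pd.concat(frames, ignore_index=True).to_csv(out / "lmm_effects.csv",
                                                    index=False)
    if res.lmm_by_generation is not None and not res.lmm_by_generation.empty:
        res.lmm_by_generation.to_csv(out / "lmm_by_generation.csv", index=False)
    blob = {
        "lrt": res.lrt,
        "roc": {k: vars(v) for k, v in res.roc.items()},
        "icc": res.icc,
        "tests": res.tests,
        "notes": res.notes,
    }
    with open(out / "models.json", "w") as fh:
        json.dump(blob, fh, indent=1, default=float)
    with open(out / "report.txt", "w") as fh:
        fh.write(res.report)
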