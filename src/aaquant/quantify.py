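"""AA-ratios, bronchiectasis / wall-thickening classification, and counts.

The four dimensionless ratios per airway-artery pair:

* ``AinA``      = inner airway diameter / artery diameter
* ``AoutA``     = outer airway diameter / artery diameter
* ``AWTA``      = wall thickness / artery diameter (= AoutA - AinA)
* ``AWTratio``  = wall thickness / outer diameter  (= 1 - AinA / AoutA)

Bronchiectasis (BE) is flagged when an AA-ratio exceeds its cut-off; airway
wall thickening (AWT) when the wall occupies more than 20% of the outer
diameter or more than 33% of the artery diameter. All cuts are strict
inequalities: boundary equality is negative.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from aaquant.cross_section import QC_OK

RATIO_COLUMNS = ("AinA", "AoutA", "AWTA", "AWTratio")
FLAG_COLUMNS = ("be_by_AoutA", "be_by_AinA", "awt_by_wall20", "awt_by_artery33")


class DataIntegrityError(ValueError):
    """A qc-ok row carries impossible diameters."""


@dataclass
class Thresholds:
    """Ratio cut-offs for BE and AWT classification.

    Defaults are the ROC-optimal paediatric cuts (0.5 inner, 1.11 outer;
    0.56/1.17 for peripheral airways, segmental generation >= 4), the
    classical adult AA cut of 1, and the 20%-of-outer / 33%-of-artery wall
    conventions.
    """

    be_AinA_cut: float = 0.5
    be_AoutA_cut: float = 1.11
    be_AinA_cut_peripheral: float = 0.56
    be_AoutA_cut_peripheral: float = 1.17
    adult_AA_cut: float = 1.0
    awt_wall_fraction_cut: float = 0.20
    awt_artery_fraction_cut: float = 0.33

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")


def compute_ratios(measurements: pd.DataFrame) -> pd.DataFrame:
    """Add the four AA-ratio columns to a measurement table.

    Excluded rows (``qc_status != ok``) pass through with NaN ratios so that
    visibility itself remains analysable; qc-ok rows must have positive
    artery and outer > inner > 0.
    """
    df = measurements.copy()
    ok = df["qc_status"] == QC_OK
    bad = ok & (
        ~(df["artery_diameter_mm"] > 0)
        | ~(df["outer_diameter_mm"] > df["inner_diameter_mm"])
        | ~(df["inner_diameter_mm"] > 0)
    )
    if bad.any():
        ids = df.loc[bad, "branch_id"].tolist()[:5]
        raise DataIntegrityError(
            f"{int(bad.sum())} qc-ok rows with non-positive artery or "
            f"inconsistent diameters (e.g. branches {ids})"
        )
    for col in RATIO_COLUMNS:
        df[col] = np.nan
    artery = df.loc[ok, "artery_diameter_mm"]
    inner = df.loc[ok, "inner_diameter_mm"]
    outer = df.loc[ok, "outer_diameter_mm"]
    wall = df.loc[ok, "wall_thickness_mm"]
    df.loc[ok, "AinA"] = inner / artery
    df.loc[ok, "AoutA"] = outer / artery
    df.loc[ok, "AWTA"] = wall / artery
    df.loc[ok, "AWTratio"] = wall / outer
    return df


def classify(ratios: pd.DataFrame, thresholds: Optional[Thresholds] = None,
             use_peripheral_cuts: bool = False) -> pd.DataFrame:
    """Flag bronchiectasis and wall thickening per row (strict cuts).

    With ``use_peripheral_cuts``, peripheral airways (segmental generation
    >= 4) are judged against the dedicated peripheral BE cuts.
    """
    t = thresholds or Thresholds()
    df = ratios.copy()
    if "is_peripheral" in df.columns:
        peripheral = df["is_peripheral"].astype(bool)
    else:
        sg = pd.to_numeric(df.get("segmental_generation"), errors="coerce")
        peripheral = (sg >= 4).fillna(False)
    if use_peripheral_cuts:
        in_cut = np.where(peripheral, t.be_AinA_cut_peripheral, t.be_AinA_cut)
        out_cut = np.where(peripheral, t.be_AoutA_cut_peripheral, t.be_AoutA_cut)
    else:
        in_cut = np.full(len(df), t.be_AinA_cut)
        out_cut = np.full(len(df), t.be_AoutA_cut)
    df["be_by_AinA"] = df["AinA"] > in_cut
    df["be_by_AoutA"] = df["AoutA"] > out_cut
    df["awt_by_wall20"] = df["AWTratio"] > t.awt_wall_fraction_cut
    df["awt_by_artery33"] = df["AWTA"] > t.awt_artery_fraction_cut
    for col in FLAG_COLUMNS:   # excluded rows carry no classification
        df.loc[df["qc_status"] != QC_OK, col] = False
    return df


def count_aa_pairs(records: pd.DataFrame,
                   group_by: Sequence[str] = ("disease_status", "volume_state"),
                   ) -> pd.DataFrame:
    """Visible (qc-ok) AA-pair counts per group, with per-subject means.

    Returns one row per group with ``n_ok``, ``n_subjects``,
    ``mean_per_subject`` and one ``n_<qc_status>`` column per exclusion
    reason — exclusions are reported, never silently dropped, since the
    number of visible AA-pairs is itself an outcome.
    """
    group_by = list(group_by)
    if records.empty:
        return pd.DataFrame(columns=group_by + ["n_ok", "n_subjects",
                                                "mean_per_subject"])
    df = records.copy()
    rows = []
    for keys, grp in df.groupby(group_by, dropna=False, observed=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        ok = grp[grp["qc_status"] == QC_OK]
        n_subj = grp["subject_id"].nunique()
        row = dict(zip(group_by, keys))
        row["n_ok"] = len(ok)
        row["n_subjects"] = n_subj
        per_subject = ok.groupby("subject_id").size()
        # subjects with zero visible pairs still count in the mean
        row["mean_per_subject"] = (
            per_subject.reindex(grp["subject_id"].unique(), fill_value=0).mean()
            if n_subj else np.nan
        )
        for status, n in grp.loc[grp["qc_status"] != QC_OK, "qc_status"] \
                .value_counts().items():
            row[f"n_{status}"] = int(n)
        rows.append(row)
    out = pd.DataFrame(rows)
    for c in out.columns:
        if c.startswith("n_excluded"):
            out[c] = out[c].fillna(0).astype(int)
    return out


def ratio_summary(ratios: pd.DataFrame,
                  group_by: Sequence[str] = ("disease_status", "volume_state",
                                             "segmental_generation"),
                  ) -> pd.DataFrame:
    """Median (IQR) of each ratio per group, qc-ok rows only."""
    ok = ratios[ratios["qc_status"] == QC_OK]
    if ok.empty:
        return pd.DataFrame()
    rows = []
    for keys, grp in ok.groupby(list(group_by), dropna=True, observed=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        row = dict(zip(group_by, keys))
        row["n"] = len(grp)
        for r in RATIO_COLUMNS:
            row[f"{r}_median"] = grp[r].median()
            row[f"{r}_q25"] = grp[r].quantile(0.25)
            row[f"{r}_q75"] = grp[r].quantile(0.75)
        rows.append(row)
    return pd.DataFrame(rows)
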