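"""Suppressor-screen colony scoring (synthetic genetic array plates).

Colony sizes on a treated (HU) and a control (rich-medium) plate are each
normalized to the median colony size of their plate; a mutant's score is
its normalized treated size divided by its normalized control size, and
suppressors are called at score strictly greater than a fold-change
threshold (default 1.5).  Strains whose normalized size is 0 in either
condition are removed after normalization, before scoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd


@dataclass
class ColonyPlate:
    """One arrayed plate of colony sizes.

    ``wells`` has columns row, column, strain_id, size (arbitrary area
    units, >= 0).  (row, column) must be unique on the plate.
    """

    plate_id: str
    condition: str  # "control" or "treated"
    wells: pd.DataFrame

    def __post_init__(self):
        required = {"row", "column", "strain_id", "size"}
        missing = required - set(self.wells.columns)
        if missing:
            raise ValueError(f"plate {self.plate_id}: missing columns {sorted(missing)}")
        if self.condition not in ("control", "treated"):
            raise ValueError(f"condition must be control or treated, got {self.condition!r}")
        if self.wells.duplicated(["row", "column"]).any():
            raise ValueError(f"plate {self.plate_id}: duplicate (row, column)")
        if (self.wells["size"] < 0).any():
            raise ValueError(f"plate {self.plate_id}: negative colony size")


def normalize_plate(plate: ColonyPlate, include_zeros: bool = True) -> pd.Series:
    """Colony sizes divided by the plate median, indexed by strain.

    The median is taken over all wells, zero colonies included (they are
    removed downstream, after normalization); set ``include_zeros=False``
    to take it over growing colonies only.
    """
    sizes = plate.wells["size"].astype(float)
    med = float(sizes.median() if include_zeros else sizes[sizes > 0].median())
    if not med or pd.isna(med):
        raise ValueError(f"plate {plate.plate_id}: plate median is 0")
    out = pd.Series(sizes.to_numpy() / med, index=plate.wells["strain_id"].to_numpy())
    if out.index.duplicated().any():
        raise ValueError(f"plate {plate.plate_id}: strain appears in multiple wells")
    return out


def suppressor_scores(
    control_plates: list[ColonyPlate] | ColonyPlate,
    treated_plates: list[ColonyPlate] | ColonyPlate,
    fc_threshold: float = 1.5,
    include_zeros_in_median: bool = True,
) -> pd.DataFrame:
    """Score every strain as normalized treated size / normalized control size.

    Replicate plates of the same condition are averaged per strain.  Strains
    present in only one condition are dropped with a warning; strains with a
    zero normalized size in either condition are removed.  The result is
    sorted by descending score (waterfall order) with columns
    ``norm_control``, ``norm_treated``, ``score``, ``called``; a call means
    score strictly greater than ``fc_threshold``.
    """
    if isinstance(control_plates, ColonyPlate):
        control_plates = [control_plates]
    if isinstance(treated_plates, ColonyPlate):
        treated_plates = [treated_plates]
    for plate, cond in [(p, "control") for p in control_plates] + [
        (p, "treated") for p in treated_plates
    ]:
        if plate.condition != cond:
            raise ValueError(f"plate {plate.plate_id} has condition {plate.condition}, expected {cond}")

    def combined(plates: list[ColonyPlate]) -> pd.Series:
        per_plate = [normalize_plate(p, include_zeros_in_median) for p in plates]
        return pd.concat(per_plate).groupby(level=0).mean()

    ctrl = combined(control_plates)
    trt = combined(treated_plates)
    only_one = set(ctrl.index) ^ set(trt.index)
    if only_one:
        warnings.warn(
            f"{len(only_one)} strain(s) present in one condition only; dropped",
            stacklevel=2,
        )
    common = ctrl.index.intersection(trt.index)
    df = pd.DataFrame({"norm_control": ctrl.loc[common], "norm_treated": trt.loc[common]})
    df = df[(df["norm_control"] > 0) & (df["norm_treated"] > 0)]
    df["score"] = df["norm_treated"] / df["norm_control"]
    df["called"] = df["score"] > fc_threshold
    df.index.name = "strain_id"
    return df.sort_values("score", ascending=False)


def read_plates_tsv(path: str | Path) -> list[ColonyPlate]:
    """Load plates from a TSV with columns plate_id, condition, row,
    column, strain_id, size."""
    df = pd.read_csv(path, sep="\t", dtype={"plate_id": str, "condition": str, "strain_id": str})
    plates = []
    for (pid, cond), grp in df.groupby(["plate_id", "condition"], sort=False):
        plates.append(ColonyPlate(pid, cond, grp.reset_index(drop=True)))
    return plates


def write_waterfall_tsv(scores: pd.DataFrame, path: str | Path) -> None:
    scores.to_csv(path, sep="\t")
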