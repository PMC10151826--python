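"""Bench-assay quantification: climbing index, CAFE intake, comparative-Ct
fold changes with replicate-CV exclusion, and per-reference normalization.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ClimbingTrial",
    "CafeReading",
    "CafeResult",
    "climbing_index",
    "cafe_consumption",
    "ddct_fold_change",
    "normalize_per_reference",
]


@dataclass(frozen=True)
class ClimbingTrial:
    """Fly counts per terminal chamber of a six-chamber counter-current run.

    n0 = flies that failed the first trial; n1..n5 = flies whose last
    successful climb was trial 1..5.
    """

    n0: int
    n1: int
    n2: int
    n3: int
    n4: int
    n5: int

    @property
    def counts(self) -> tuple[int, ...]:
        return (self.n0, self.n1, self.n2, self.n3, self.n4, self.n5)


def climbing_index(trial: ClimbingTrial | Sequence[int]) -> float:
    """Weighted-average climbing score over the six terminal chambers.

        index = (0*n0 + 1*n1 + 2*n2 + 3*n3 + 4*n4 + 5*n5) / (5 * (n0+...+n5))

    Ranges from 0 (every fly failed the first trial) to 1 (every fly passed
    all five trials); invariant to uniform scaling of the counts.
    """
    counts = trial.counts if isinstance(trial, ClimbingTrial) else tuple(trial)
    if len(counts) != 6:
        raise ValueError(f"expected six chamber counts n0..n5, got {len(counts)}")
    if any(c < 0 for c in counts):
        raise ValueError("chamber counts must be non-negative")
    total = sum(counts)
    if total == 0:
        raise ValueError("no flies counted: all chamber counts are zero")
    return sum(i * c for i, c in enumerate(counts)) / (5.0 * total)


@dataclass(frozen=True)
class CafeReading:
    """One vial's capillary feeder measurements.

    displacements_mm: liquid-level drop per capillary (NaN = capillary lost);
    mm_per_ul: calibration from the 1-ul graduation marks;
    n_flies: flies in the vial; duration_h: feeding period.
    """

    displacements_mm: tuple[float, ...]
    mm_per_ul: float
    n_flies: int
    duration_h: float = 19.0
    evaporation_mm: float = 0.0


@dataclass(frozen=True)
class CafeResult:
    total_ul: float
    per_fly_ul: float
    per_fly_per_hour_ul: float
    n_capillaries: int


def cafe_consumption(reading: CafeReading) -> CafeResult:
    """Food intake from capillary displacement.

        consumed (ul) = sum over capillaries of (displacement_mm - evaporation_mm)
                        / mm_per_ul
        per fly       = consumed / n_flies

    Missing (NaN) capillaries are skipped with a warning and the total is
    computed over the recorded ones.  An optional blank-vial evaporation
    displacement can be subtracted per capillary (default 0: no evaporation
    control).
    """
    if reading.mm_per_ul <= 0:
        raise ValueError("mm_per_ul calibration must be positive")
    if reading.n_flies < 1:
        raise ValueError("n_flies must be >= 1")
    if reading.duration_h <= 0:
        raise ValueError("duration_h must be positive")
    disp = np.asarray(reading.displacements_mm, dtype=float)
    recorded = disp[~np.isnan(disp)]
    if len(recorded) < len(disp):
        warnings.warn(
            f"{len(disp) - len(recorded)} capillary reading(s) missing; "
            "computing over the recorded ones",
            stacklevel=2,
        )
    if len(recorded) == 0:
        raise ValueError("no recorded capillary displacements")
    if (recorded < 0).any():
        raise ValueError("negative capillary displacement: data-entry error")
    corrected = np.maximum(recorded - reading.evaporation_mm, 0.0)
    total_ul = float(corrected.sum() / reading.mm_per_ul)
    per_fly = total_ul / reading.n_flies
    return CafeResult(
        total_ul=total_ul,
        per_fly_ul=per_fly,
        per_fly_per_hour_ul=per_fly / reading.duration_h,
        n_capillaries=len(recorded),
    )


def ddct_fold_change(
    plate: pd.DataFrame,
    reference_gene: str = "rp49",
    control_group: str = "control",
    cv_threshold: float = 3.0,
    calibrator_sample: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Comparative-Ct relative expression with technical-replicate CV filter.

    ``plate`` is long format with columns sample_id, group, gene, ct (one
    row per technical replicate).  Any (sample, gene) whose replicate CV
    (SD/mean of raw Ct, in percent) exceeds ``cv_threshold`` is excluded and
    listed.  Then, per sample and target gene:

        dCt  = mean Ct(target) - mean Ct(reference_gene)
        ddCt = dCt - baseline
        fold = 2 ** (-ddCt)

    The baseline is the control group's mean dCt per gene, or a single
    calibrator sample's dCt when ``calibrator_sample`` is given.

    Returns (results, excluded); results has columns sample_id, group, gene,
    dct, ddct, fold_change.
    """
    required = {"sample_id", "group", "gene", "ct"}
    missing = required - set(plate.columns)
    if missing:
        raise ValueError(f"plate table lacks columns {sorted(missing)}")
    if (plate["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")

    stats = (
        plate.groupby(["sample_id", "group", "gene"], sort=False)["ct"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    if (stats["count"] < 2).any():
        bad = stats.loc[stats["count"] < 2, ["sample_id", "gene"]]
        raise ValueError(f"need >= 2 technical replicates per (sample, gene): {bad.values.tolist()}")
    stats["cv_pct"] = stats["std"] / stats["mean"] * 100.0
    excluded = stats.loc[stats["cv_pct"] > cv_threshold].copy()
    excluded["reason"] = "cv_above_threshold"
    kept = stats.loc[stats["cv_pct"] <= cv_threshold]

    ref = kept.loc[kept["gene"] == reference_gene, ["sample_id", "mean"]].rename(
        columns={"mean": "ct_reference"}
    )
    targets = kept.loc[kept["gene"] != reference_gene].merge(ref, on="sample_id", how="inner")
    if targets.empty:
        raise ValueError("no (sample, target gene) pairs with a usable reference gene")
    targets["dct"] = targets["mean"] - targets["ct_reference"]

    rows = []
    for gene, sub in targets.groupby("gene", sort=False):
        if calibrator_sample is not None:
            base_rows = sub.loc[sub["sample_id"] == calibrator_sample, "dct"]
            if base_rows.empty:
                raise ValueError(f"calibrator sample {calibrator_sample!r} missing for {gene}")
            baseline = float(base_rows.iloc[0])
        else:
            controls = sub.loc[sub["group"] == control_group, "dct"]
            if controls.empty:
                raise ValueError(
                    f"control group {control_group!r} empty for {gene} after exclusions"
                )
            baseline = float(controls.mean())
        out = sub[["sample_id", "group", "gene", "dct"]].copy()
        out["ddct"] = out["dct"] - baseline
        out["fold_change"] = 2.0 ** (-out["ddct"])
        rows.append(out)
    results = pd.concat(rows, ignore_index=True)
    excluded = excluded[["sample_id", "group", "gene", "cv_pct", "reason"]].reset_index(drop=True)
    return results, excluded


def normalize_per_reference(values, reference) -> np.ndarray:
    """Elementwise ratio of readouts to a positive per-sample reference."""
    v = np.asarray(values, dtype=float)
    r = np.asarray(reference, dtype=float)
    if v.shape != r.shape:
        raise ValueError(f"shape mismatch: values {v.shape}, reference {r.shape}")
    if (r <= 0).any():
        raise ValueError("reference values must all be positive")
    return v / r
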