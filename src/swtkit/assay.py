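"""Plate-reader fluorescence analysis for SWT characterization.

Normalization and fold change follow the standard in-vitro transcription
readout: every batch includes a no-template control whose fluorescence (the
background) is subtracted from each measurement,

    normalized fluorescence = fluorescence - background,

and a construct's fold change is the ratio of its background-subtracted ON
signal (cognate trigger present) to its background-subtracted OFF signal,

    fold change = NF_ON / NF_OFF.

Significance between conditions uses Welch's unequal-variance t-test.  The
module also provides a seeded synthetic plate generator (multiplicative
Gaussian replicate noise around programmed condition means) used as the test
fixture; it emulates replicate scatter, not instrument physics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AssayError",
    "UndefinedFoldChangeError",
    "PLATE_COLUMNS",
    "validate_plate",
    "normalize_fluorescence",
    "background_level",
    "fold_change",
    "FoldChangeResult",
    "welch_t_test",
    "orthogonality_table",
    "SimSpec",
    "simulate_plate",
]

PLATE_COLUMNS = ["well", "construct", "condition", "replicate", "rfu", "timepoint_min"]
CONDITIONS = {"ON", "OFF", "BACKGROUND"}

DEFAULT_TIMEPOINT_MIN = 120.0  # endpoint read, 2 h after reaction start


class AssayError(ValueError):
    """Malformed plate data or degenerate statistics input."""


class UndefinedFoldChangeError(AssayError):
    """The background-subtracted OFF signal is <= 0, so the ON/OFF ratio is
    undefined (reported rather than clamped, which would fabricate dynamic
    range)."""


def validate_plate(plate: pd.DataFrame) -> pd.DataFrame:
    """Check the plate table schema and invariants; returns the frame."""
    missing = [c for c in PLATE_COLUMNS if c not in plate.columns]
    if missing:
        raise AssayError(f"plate table is missing columns {missing}")
    bad = set(plate["condition"]) - CONDITIONS
    if bad:
        raise AssayError(f"unknown conditions {sorted(bad)}")
    if not np.isfinite(plate["rfu"]).all():
        raise AssayError("RFU values must be finite")
    if not (plate["condition"] == "BACKGROUND").any():
        raise AssayError("each batch needs at least one BACKGROUND row")
    return plate


def normalize_fluorescence(raw, background):
    """Background-subtracted fluorescence (may be negative, with a warning)."""
    out = np.asarray(raw, dtype=float) - np.asarray(background, dtype=float)
    if np.any(out < 0):
        warnings.warn(
            "normalized fluorescence below zero: signal under the no-template "
            "background", stacklevel=2)
    return out if out.ndim else float(out)


def background_level(
    plate: pd.DataFrame, timepoint_min: float | None = DEFAULT_TIMEPOINT_MIN
) -> float:
    """Batch background: the mean RFU of the BACKGROUND rows (at the chosen
    endpoint when time-course rows are present)."""
    rows = plate[plate["condition"] == "BACKGROUND"]
    if timepoint_min is not None and rows["timepoint_min"].nunique() > 1:
        rows = rows[rows["timepoint_min"] == timepoint_min]
    if rows.empty:
        raise AssayError("no BACKGROUND rows at the requested timepoint")
    return float(rows["rfu"].mean())


@dataclass(frozen=True)
class FoldChangeResult:
    construct: str
    normalized_on: float
    normalized_off: float
    fold_change: float
    replicate_on: tuple[float, ...]
    replicate_off: tuple[float, ...]
    replicate_ratios: tuple[float, ...] | None
    welch_t: float | None
    welch_df: float | None
    welch_p: float | None


def welch_t_test(group_a, group_b) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test: (t, Welch-Satterthwaite df,
    two-sided p)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise AssayError("Welch's t-test needs >= 2 values per group")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, float(len(a) + len(b) - 2), 1.0
        raise AssayError("both groups have zero variance but unequal means")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def fold_change(
    on_rows: pd.DataFrame,
    off_rows: pd.DataFrame,
    background_rows: pd.DataFrame,
    *,
    construct: str = "",
    method: str = "ratio_of_means",
    timepoint_min: float | None = DEFAULT_TIMEPOINT_MIN,
) -> FoldChangeResult:
    """ON/OFF fold change for one construct.

    ``ratio_of_means`` (default) divides the background-subtracted replicate
    means; ``mean_of_ratios`` averages per-replicate ratios instead (exposed
    because published fold changes do not always say which was used).
    Replicate-level values are retained for dispersion; Welch's t compares
    the normalized ON and OFF replicates when both groups have >= 2 values.
    """
    def endpoint(rows: pd.DataFrame) -> pd.DataFrame:
        if timepoint_min is not None and rows["timepoint_min"].nunique() > 1:
            rows = rows[rows["timepoint_min"] == timepoint_min]
        return rows

    on_rows, off_rows = endpoint(on_rows), endpoint(off_rows)
    if on_rows.empty or off_rows.empty or background_rows.empty:
        raise AssayError("ON, OFF and BACKGROUND groups must be non-empty")
    bg = float(endpoint(background_rows)["rfu"].mean())
    on = on_rows["rfu"].to_numpy(dtype=float) - bg
    off = off_rows["rfu"].to_numpy(dtype=float) - bg

    norm_on, norm_off = float(np.mean(on)), float(np.mean(off))
    if norm_off <= 0:
        raise UndefinedFoldChangeError(
            f"{construct or 'construct'}: normalized OFF mean is "
            f"{norm_off:.3f} <= 0; the fold change is undefined")
    if method == "ratio_of_means":
        fc = norm_on / norm_off
    elif method == "mean_of_ratios":
        if len(on) != len(off):
            raise AssayError("mean_of_ratios needs paired ON/OFF replicates")
        if np.any(off <= 0):
            raise UndefinedFoldChangeError(
                f"{construct or 'construct'}: an OFF replicate is <= 0 after "
                f"background subtraction")
        fc = float(np.mean(on / off))
    else:
        raise AssayError(f"unknown method {method!r}")

    ratios = tuple(on / off) if (len(on) == len(off) and np.all(off > 0)) else None
    t = df = p = None
    if len(on) >= 2 and len(off) >= 2 and (np.var(on, ddof=1) or np.var(off, ddof=1)):
        t, df, p = welch_t_test(on, off)
    return FoldChangeResult(
        construct=construct,
        normalized_on=norm_on,
        normalized_off=norm_off,
        fold_change=float(fc),
        replicate_on=tuple(on),
        replicate_off=tuple(off),
        replicate_ratios=ratios,
        welch_t=t, welch_df=df, welch_p=p,
    )


def orthogonality_table(
    plate: pd.DataFrame,
    mapping: pd.DataFrame,
    *,
    method: str = "ratio_of_means",
    timepoint_min: float | None = DEFAULT_TIMEPOINT_MIN,
) -> pd.DataFrame:
    """Fold-change matrix over SWT x trigger combinations.

    ``mapping`` columns: ``swt``, ``trigger``, ``construct`` — the plate
    construct measuring that combination (its ON rows).  The OFF state for
    each switch is the no-trigger condition: OFF rows of the same construct
    when present, else OFF rows of any construct mapping that switch.
    Missing combinations stay NaN (explicitly empty, never 0).
    """
    validate_plate(plate)
    for col in ("swt", "trigger", "construct"):
        if col not in mapping.columns:
            raise AssayError(f"mapping is missing column {col!r}")
    bg_rows = plate[plate["condition"] == "BACKGROUND"]
    swts = list(dict.fromkeys(mapping["swt"]))
    trigs = list(dict.fromkeys(mapping["trigger"]))
    out = pd.DataFrame(np.nan, index=swts, columns=trigs, dtype=float)
    for rec in mapping.itertuples(index=False):
        on = plate[(plate["construct"] == rec.construct)
                   & (plate["condition"] == "ON")]
        off = plate[(plate["construct"] == rec.construct)
                    & (plate["condition"] == "OFF")]
        if off.empty:
            sibling = mapping[mapping["swt"] == rec.swt]["construct"]
            off = plate[plate["construct"].isin(sibling)
                        & (plate["condition"] == "OFF")]
        if on.empty or off.empty:
            continue
        res = fold_change(
            on, off, bg_rows, construct=rec.construct,
            method=method, timepoint_min=timepoint_min)
        out.loc[rec.swt, rec.trigger] = res.fold_change
    return out


@dataclass(frozen=True)
class SimSpec:
    """Programmed truth for a synthetic plate: per-construct raw ON/OFF mean
    RFU (background included), the background mean, a replicate coefficient
    of variation, replicate count and seed."""

    construct_means: dict[str, tuple[float, float]]  # name -> (ON, OFF) RFU
    background_mean: float = 300.0
    cv: float = 0.05
    replicates: int = 3
    seed: int = 0
    timepoint_min: float = DEFAULT_TIMEPOINT_MIN

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise AssayError("coefficient of variation must be >= 0")
        if self.replicates < 1:
            raise AssayError("at least one replicate is required")
        for name, (on, off) in self.construct_means.items():
            if min(on, off) <= self.background_mean:
                raise AssayError(
                    f"{name}: programmed means must exceed the background")

    def programmed_fold(self, name: str) -> float:
        on, off = self.construct_means[name]
        return (on - self.background_mean) / (off - self.background_mean)


def simulate_plate(spec: SimSpec) -> pd.DataFrame:
    """Draw a synthetic plate table: rfu = condition mean * (1 + cv * z) with
    z ~ N(0, 1), deterministic per seed.  BACKGROUND rows are drawn around the
    background mean the same way."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    well = 0

    def emit(construct: str, condition: str, mean: float) -> None:
        nonlocal well
        for rep in range(spec.replicates):
            noise = rng.standard_normal() if spec.cv > 0 else 0.0
            rows.append({
                "well": f"W{well:03d}",
                "construct": construct,
                "condition": condition,
                "replicate": rep + 1,
                "rfu": mean * (1.0 + spec.cv * noise),
                "timepoint_min": spec.timepoint_min,
            })
            well += 1

    for name in spec.construct_means:
        on, off = spec.construct_means[name]
        emit(name, "ON", on)
        emit(name, "OFF", off)
    emit("no_template", "BACKGROUND", spec.background_mean)
    return validate_plate(pd.DataFrame(rows, columns=PLATE_COLUMNS))
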