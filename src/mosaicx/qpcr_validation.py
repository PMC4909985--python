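"""qPCR validation: standard curves, X copy ratios and 3-SD calling.

Each target assay is duplexed with the autosomal RNase P reference.  Ct
values interpolate concentrations via per-assay standard curves; the
target/reference ratio times two gives the diploid-equivalent X copy
number in that region, and the mean over the twelve target assays gives
the overall X signal ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .probe_model import MosaicXWarning

#: Number of target assays averaged into the overall X ratio.
N_TARGET_ASSAYS = 12

PLATE_CSV_COLUMNS = (
    "plate_id", "assay_id", "sample_id", "role", "dilution_log10",
    "replicate", "ct",
)

QPCR_CALLS = ("gain", "normal", "loss")

#: Array call vocabulary mapped onto the qPCR vocabulary.
_ARRAY_TO_QPCR = {"gain": "gain", "loss": "loss", "copy-neutral": "normal"}


@dataclass(frozen=True)
class StandardCurve:
    """Least-squares line of Ct on log10(concentration) for one assay."""

    assay_id: str
    slope: float
    intercept: float
    efficiency: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError("standard curve slope must be negative")
        if not (0.0 < self.efficiency <= 1.2):
            raise ValueError("efficiency must lie in (0, 1.2]")

    def concentration(self, ct: float) -> float:
        """Interpolate template concentration from a Ct value."""
        return float(10.0 ** ((ct - self.intercept) / self.slope))


@dataclass(frozen=True)
class QpcrAssayResult:
    """Per-assay and overall X copy ratios for one sample."""

    sample_id: str
    ratios: dict[str, float]
    mean_ratio: float
    call: str | None = None

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.ratios.values()):
            raise ValueError("copy ratios must be positive")


def fit_standard_curve(
    dilution_concentrations: Sequence[float],
    ct_values: Sequence[float],
    assay_id: str = "assay",
) -> StandardCurve:
    """Fit a standard curve from a dilution series (>= 4 points)."""
    conc = np.asarray(dilution_concentrations, dtype=float)
    ct = np.asarray(ct_values, dtype=float)
    if len(conc) != len(ct):
        raise ValueError("concentrations and Ct values must have equal length")
    if len(conc) < 4:
        raise ValueError(f"need >= 4 dilution points, got {len(conc)}")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    res = stats.linregress(np.log10(conc), ct)
    if res.slope >= 0:
        raise ValueError(
            f"assay {assay_id}: non-negative standard-curve slope "
            f"({res.slope:.3f}); invalid curve"
        )
    efficiency = 10.0 ** (-1.0 / res.slope) - 1.0
    return StandardCurve(
        assay_id=assay_id,
        slope=float(res.slope),
        intercept=float(res.intercept),
        efficiency=float(efficiency),
        r_squared=float(res.rvalue**2),
    )


def x_copy_ratio(
    sample_cts: Mapping[str, Sequence[float]],
    curves: Mapping[str, StandardCurve],
    reference_assay: str,
    reference_cts: Mapping[str, Sequence[float]] | Sequence[float],
    sample_id: str = "sample",
    n_target_assays: int = N_TARGET_ASSAYS,
) -> QpcrAssayResult:
    """Overall X copy ratio from triplicate Cts over the target assays.

    ``sample_cts`` maps target assay -> replicate Cts; ``reference_cts``
    is either the shared reference replicate Cts or a per-assay mapping.
    Triplicates are summarized by their median (robust to single-well
    dropout); a replicate range above 1 Ct draws a warning.
    """
    targets = sorted(a for a in curves if a != reference_assay)
    if len(targets) != n_target_assays:
        raise ValueError(
            f"expected {n_target_assays} target assay curves, got {len(targets)}"
        )
    missing = [a for a in targets if a not in sample_cts]
    if missing:
        raise ValueError(f"sample {sample_id}: missing assays {missing}")
    if reference_assay not in curves:
        raise ValueError(f"no standard curve for reference assay {reference_assay}")

    def median_ct(assay: str, cts: Sequence[float]) -> float:
        arr = np.asarray(cts, dtype=float)
        arr = arr[np.isfinite(arr)]
        if arr.size == 0:
            raise ValueError(f"sample {sample_id}: no Ct values for assay {assay}")
        if arr.size > 1 and (arr.max() - arr.min()) > 1.0:
            warnings.warn(
                f"sample {sample_id} assay {assay}: triplicate Ct range "
                f"{arr.max() - arr.min():.2f} > 1; median still used",
                MosaicXWarning,
                stacklevel=3,
            )
        return float(np.median(arr))

    ref_curve = curves[reference_assay]
    ratios: dict[str, float] = {}
    for assay in targets:
        target_conc = curves[assay].concentration(
            median_ct(assay, sample_cts[assay])
        )
        if isinstance(reference_cts, Mapping):
            ref_ct = median_ct(reference_assay, reference_cts[assay])
        else:
            ref_ct = median_ct(reference_assay, reference_cts)
        ref_conc = ref_curve.concentration(ref_ct)
        ratios[assay] = 2.0 * target_conc / ref_conc
    return QpcrAssayResult(
        sample_id=sample_id,
        ratios=ratios,
        mean_ratio=float(np.mean(list(ratios.values()))),
    )


def call_qpcr_state(
    mean_ratio: float, control_mean: float, control_sd: float
) -> str:
    """3-SD rule: gain above mean + 3 sd, loss below mean - 3 sd."""
    if control_sd <= 0:
        raise ValueError("control_sd must be positive")
    if mean_ratio > control_mean + 3.0 * control_sd:
        return "gain"
    if mean_ratio < control_mean - 3.0 * control_sd:
        return "loss"
    return "normal"


def concordance(
    array_calls: Mapping[str, str],
    qpcr_calls: Mapping[str, str],
) -> dict:
    """Per-array-class and overall agreement between array and qPCR calls.

    Array ``copy-neutral`` maps to qPCR ``normal``.  Every sample must be
    present in both mappings.
    """
    if not array_calls:
        raise ValueError("no paired calls supplied")
    unpaired = set(array_calls) ^ set(qpcr_calls)
    if unpaired:
        raise ValueError(f"unpaired samples: {sorted(unpaired)[:10]}")
    per_class: dict[str, dict] = {}
    agree_total = 0
    for sid, acall in array_calls.items():
        if acall not in _ARRAY_TO_QPCR:
            raise ValueError(f"unknown array call {acall!r} for sample {sid}")
        expected = _ARRAY_TO_QPCR[acall]
        hit = qpcr_calls[sid] == expected
        rec = per_class.setdefault(acall, {"n": 0, "agree": 0})
        rec["n"] += 1
        rec["agree"] += int(hit)
        agree_total += int(hit)
    for rec in per_class.values():
        rec["rate"] = rec["agree"] / rec["n"]
    return {
        "per_class": per_class,
        "overall": agree_total / len(array_calls),
        "n": len(array_calls),
    }


# ---------------------------------------------------------------------------
# Plate-table processing
# ---------------------------------------------------------------------------

def read_plate_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = set(PLATE_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def analyze_plate(
    plate: pd.DataFrame,
    reference_assay: str = "RNaseP",
    n_target_assays: int = N_TARGET_ASSAYS,
) -> dict[str, QpcrAssayResult]:
    """Fit per-assay curves from a plate's standards and quantify samples.

    Standards (role ``standard``) supply the dilution series per assay;
    rows with role ``sample`` are quantified.  Curves are fit per plate.
    """
    results: dict[str, QpcrAssayResult] = {}
    for plate_id, pl in plate.groupby("plate_id"):
        std = pl[pl["role"] == "standard"]
        curves: dict[str, StandardCurve] = {}
        for assay, grp in std.groupby("assay_id"):
            # all replicate wells enter the regression
            curves[str(assay)] = fit_standard_curve(
                10.0 ** grp["dilution_log10"].to_numpy(float),
                grp["ct"].to_numpy(float),
                assay_id=str(assay),
            )
        samp = pl[pl["role"] == "sample"]
        for sid, grp in samp.groupby("sample_id"):
            cts = {
                str(a): g["ct"].to_numpy(float)
                for a, g in grp.groupby("assay_id")
            }
            ref_cts = cts.pop(reference_assay, None)
            if ref_cts is None:
                raise ValueError(
                    f"plate {plate_id} sample {sid}: missing reference assay "
                    f"{reference_assay}"
                )
            results[str(sid)] = x_copy_ratio(
                cts, curves, reference_assay, ref_cts,
                sample_id=str(sid), n_target_assays=n_target_assays,
            )
    return results
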