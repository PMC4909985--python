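"""Phasing of mosaic X events to the inactive (Xi) or active (Xa) homolog.

Female X promoter probes that are differentially methylated between the
sexes (methylated on Xi, unmethylated on Xa and on the male X) report which
homolog an event involves: beta values above the female control expectation
indicate extra Xi copies, below indicate Xi loss.

The expected beta under an event follows copy bookkeeping.  With ``f`` the
mosaic cell fraction and the duplicated homolog retaining its methylation
state, the methylated-copy fraction ``m`` is::

    loss of Xi:           (1 - f) / (2 - f)
    loss of Xa:           1 / (2 - f)
    gain of Xi:           (1 + f) / (2 + f)
    gain of Xa:           1 / (2 + f)
    copy-neutral, Xi->Xa substrate (Xi replaced Xa):  (1 + f) / 2
    copy-neutral, Xa->Xi substrate (Xa replaced Xi):  (1 - f) / 2

scaled by ``beta0 / 0.5`` so that ``f = 0`` returns the normal female mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort_stats import two_sided_binomial
from .event_caller import MosaicCall

logger = logging.getLogger(__name__)

HOMOLOGS = ("Xi", "Xa")

#: Minimum number of distinct promoter regions spanned for a call.
MIN_PROMOTERS = 5

#: |mean z| below this is indeterminate (guards noise-dominated calls).
Z_CALL_THRESHOLD = 0.5

_INTERPRETATION = {
    ("loss", "Xi"): "loss of Xi",
    ("loss", "Xa"): "loss of Xa",
    ("gain", "Xi"): "gain of Xi",
    ("gain", "Xa"): "gain of Xa",
    ("copy-neutral", "Xi"): "Xi replaced Xa",
    ("copy-neutral", "Xa"): "Xa replaced Xi",
}

REFERENCE_COLUMNS = (
    "position", "promoter_region_id", "mean_beta_women", "sd_beta_women",
    "mean_beta_men", "sd_beta_men", "passed_filter",
)


@dataclass(frozen=True)
class MethylationReference:
    """Per-probe control beta statistics and the differential probe filter.

    ``table`` is indexed by probe_id with columns
    :data:`REFERENCE_COLUMNS`; positions are 0-based.
    """

    table: pd.DataFrame
    n_control_women: int
    n_control_men: int

    def __post_init__(self) -> None:
        missing = set(REFERENCE_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"reference table missing columns {sorted(missing)}")

    @property
    def passing(self) -> pd.DataFrame:
        return self.table[self.table["passed_filter"]]


@dataclass(frozen=True)
class PhasingResult:
    """Xi/Xa assignment of one event from promoter methylation z-scores."""

    sample_id: str
    start_bp: int
    end_bp: int
    state: str
    n_probes: int
    n_promoters: int
    mean_z: float
    direction: str  # increase | decrease | none
    homolog_call: str  # Xi | Xa | indeterminate
    interpretation: str


def select_reference_probes(
    control_betas_women: pd.DataFrame,
    control_betas_men: pd.DataFrame,
    annotation: pd.DataFrame,
    min_controls: int = 20,
) -> MethylationReference:
    """Build the differentially methylated promoter-probe reference set.

    A probe passes when 0.35 <= mean_w <= 0.5 and sd_w < 0.09 in control
    women, and mean_m < 0.15 and sd_m < 0.05 in control men (means
    inclusive, SDs strict).

    ``control_betas_*`` are probes x samples; ``annotation`` requires
    columns probe_id, pos, promoter_region_id (pos 1-based on disk
    convention is the caller's concern; this function treats it as given).
    """
    for col in ("probe_id", "pos", "promoter_region_id"):
        if col not in annotation.columns:
            raise ValueError(f"annotation is missing required column {col!r}")
    n_w = control_betas_women.shape[1]
    n_m = control_betas_men.shape[1]
    if n_w < min_controls or n_m < min_controls:
        raise ValueError(
            f"need >= {min_controls} controls per sex, got {n_w} women / {n_m} men"
        )
    ann = annotation.set_index("probe_id")
    probes = ann.index.intersection(control_betas_women.index).intersection(
        control_betas_men.index
    )
    w = control_betas_women.loc[probes]
    m = control_betas_men.loc[probes]
    mean_w, sd_w = w.mean(axis=1), w.std(axis=1, ddof=1)
    mean_m, sd_m = m.mean(axis=1), m.std(axis=1, ddof=1)
    passed = (
        (mean_w >= 0.35) & (mean_w <= 0.5) & (sd_w < 0.09)
        & (mean_m < 0.15) & (sd_m < 0.05)
    )
    table = pd.DataFrame(
        {
            "position": ann.loc[probes, "pos"].astype(int),
            "promoter_region_id": ann.loc[probes, "promoter_region_id"],
            "mean_beta_women": mean_w,
            "sd_beta_women": sd_w,
            "mean_beta_men": mean_m,
            "sd_beta_men": sd_m,
            "passed_filter": passed,
        }
    )
    return MethylationReference(
        table=table, n_control_women=n_w, n_control_men=n_m
    )


def expected_beta(state: str, homolog: str, f: float, beta0: float) -> float:
    """Expected carrier beta for an event of the given type and homolog."""
    if not (0.0 <= f <= 1.0):
        raise ValueError("fraction must lie in [0, 1]")
    if not (0.0 < beta0 < 1.0):
        raise ValueError("beta0 must lie in (0, 1)")
    if homolog not in HOMOLOGS:
        raise ValueError(f"unknown homolog {homolog!r}")
    if state == "loss":
        m = (1.0 - f) / (2.0 - f) if homolog == "Xi" else 1.0 / (2.0 - f)
    elif state == "gain":
        m = (1.0 + f) / (2.0 + f) if homolog == "Xi" else 1.0 / (2.0 + f)
    elif state == "copy-neutral":
        # homolog denotes the duplicated (replacing) homolog
        m = (1.0 + f) / 2.0 if homolog == "Xi" else (1.0 - f) / 2.0
    else:
        raise ValueError(f"unknown state {state!r}")
    return m * beta0 / 0.5


def phase_event(
    carrier_betas: pd.Series,
    reference: MethylationReference,
    call: MosaicCall,
    min_promoters: int = MIN_PROMOTERS,
    z_threshold: float = Z_CALL_THRESHOLD,
) -> PhasingResult:
    """Assign an event to Xi or Xa from promoter-probe z-scores.

    z-scores use the female control statistics only.  The call is
    indeterminate when fewer than ``min_promoters`` promoter regions are
    spanned or |mean z| is below ``z_threshold``.
    """
    ref = reference.passing
    in_event = (ref["position"] >= call.start_bp) & (ref["position"] < call.end_bp)
    probes = ref.index[in_event].intersection(carrier_betas.dropna().index)
    sub = ref.loc[probes]
    n_probes = len(probes)
    n_promoters = int(sub["promoter_region_id"].nunique())
    if n_probes == 0:
        logger.info(
            "sample %s event %d-%d: no passing probes in event",
            call.sample_id, call.start_bp, call.end_bp,
        )
        return PhasingResult(
            sample_id=call.sample_id, start_bp=call.start_bp, end_bp=call.end_bp,
            state=call.state, n_probes=0, n_promoters=0, mean_z=float("nan"),
            direction="none", homolog_call="indeterminate",
            interpretation="no differentially methylated probes in event",
        )
    z = (carrier_betas.loc[probes] - sub["mean_beta_women"]) / sub["sd_beta_women"]
    mean_z = float(z.mean())
    direction = "increase" if mean_z > 0 else "decrease"
    if n_promoters < min_promoters or abs(mean_z) < z_threshold:
        homolog = "indeterminate"
        interpretation = (
            f"indeterminate ({n_promoters} promoters, mean z {mean_z:.2f})"
        )
    else:
        if call.state == "loss":
            homolog = "Xi" if mean_z < 0 else "Xa"
        elif call.state == "gain":
            homolog = "Xi" if mean_z > 0 else "Xa"
        else:  # copy-neutral: sign says which homolog was duplicated
            homolog = "Xi" if mean_z > 0 else "Xa"
        interpretation = _INTERPRETATION[(call.state, homolog)]
    return PhasingResult(
        sample_id=call.sample_id, start_bp=call.start_bp, end_bp=call.end_bp,
        state=call.state, n_probes=n_probes, n_promoters=n_promoters,
        mean_z=mean_z, direction=direction, homolog_call=homolog,
        interpretation=interpretation,
    )


def xi_preference_test(results: list[PhasingResult]) -> float:
    """Two-sided exact binomial test of preferential Xi involvement.

    ``results`` must be loss/gain phasings with determinate homolog calls;
    copy-neutral events carry no net dosage change and are excluded by the
    caller.  Returns the tail-doubled p-value at p0 = 0.5.
    """
    usable = [r for r in results if r.state in ("loss", "gain")]
    if any(r.homolog_call == "indeterminate" for r in usable):
        raise ValueError("all results must have a determinate homolog call")
    n = len(usable)
    if n == 0:
        raise ValueError("no loss/gain phasing results supplied")
    k = sum(1 for r in usable if r.homolog_call == "Xi")
    return two_sided_binomial(k, n, 0.5)


def write_reference_tsv(path, reference: MethylationReference) -> None:
    df = reference.table.copy()
    df.insert(0, "probe_id", df.index)
    df["position"] = df["position"].astype(int) + 1  # 1-based on disk
    df.to_csv(path, sep="\t", index=False)
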