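"""Typing, quantification and location classification of candidate segments.

Candidate segments from BAF segmentation are typed by the band structure of
a Gaussian mixture fit (2-4 components), assigned a copy state from the
batch-adjusted LRR shift, quantified as a mosaic cell fraction, and placed
into a chromosomal location class.  Constitutional whole-chromosome
aneuploidies (XO / trisomy X) are screened out of the mosaic tallies.

Cell-fraction closed forms follow from allele/copy bookkeeping for a
mixture of a fraction ``f`` of altered cells with ``1 - f`` diploid cells:

* copy-neutral: het BAF = 0.5 +/- f/2            => f = 2 db
* loss:         het BAF deviation = (f/2)/(2-f)  => f = 4 db / (1 + 2 db)
* gain:         het BAF deviation = (f/2)/(2+f)  => f = 4 db / (1 - 2 db)

and the ideal LRR dosage responses log2((2-f)/2) (loss) and log2((2+f)/2)
(gain).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import GaussianMixture

from .probe_model import (
    ClusterBatch,
    MosaicXWarning,
    ProbeMap,
    SampleIntensities,
    adjust_lrr,
    mirrored_baf,
    select_informative,
)
from .segmentation import Segment, cbs_segment, filter_segments

logger = logging.getLogger(__name__)

STATES = ("loss", "gain", "copy-neutral")
LOCATIONS = ("interstitial", "spans centromere", "telomeric p", "telomeric q", "whole")

#: Component standard-deviation floor for the BAF mixture (prevents
#: degenerate spikes on clipped homozygote bands).
SD_FLOOR = 0.005

#: Detection ceiling for BAF-based fraction estimates.
FRACTION_CEILING = 0.88


class SegmentRejected(Exception):
    """A candidate segment failed model-based typing (with diagnostic)."""


@dataclass(frozen=True)
class GmmFit:
    """Best BAF band mixture for a segment."""

    k: int
    means: tuple[float, ...]
    sds: tuple[float, ...]
    weights: tuple[float, ...]
    bic: float
    delta_b_hat: float

    def __post_init__(self) -> None:
        if self.k not in (2, 3, 4):
            raise ValueError("k must be 2, 3 or 4")
        if abs(sum(self.weights) - 1.0) > 1e-6:
            raise ValueError("weights must sum to 1")
        if list(self.means) != sorted(self.means):
            raise ValueError("means must be sorted ascending")
        if self.delta_b_hat < 0:
            raise ValueError("delta_b_hat must be >= 0")


@dataclass(frozen=True)
class MosaicCall:
    """A detected mosaic event (bp bounds 0-based half-open)."""

    sample_id: str
    start_bp: int
    end_bp: int
    n_probes: int
    state: str
    location: str
    delta_b: float
    delta_lrr: float
    fraction: float
    whole_flag: bool
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}")
        if self.location not in LOCATIONS:
            raise ValueError(f"unknown location {self.location!r}")
        if not (0.0 <= self.fraction <= 1.0):
            raise ValueError("fraction must lie in [0, 1]")


@dataclass
class CallerParams:
    """Tunable parameters of the per-sample calling pipeline."""

    alpha: float = 0.01
    n_perm: int = 1000
    min_markers: int = 50
    merge_tol: float = 0.005
    min_size_bp: int = 2_000_000
    min_delta_b: float = 0.03
    end_tol_bp: int = 1_000_000
    min_segment_baf_values: int = 50
    use_genotype: bool | None = None
    baf_window: tuple[float, float] = (0.10, 0.90)
    seed: int | None = None


def fit_baf_mixture(
    values: np.ndarray,
    seed: int | None = None,
    delta_init: float | None = None,
) -> GmmFit:
    """Fit 2-, 3- and 4-component Gaussian mixtures to segment BAF values.

    Fixed initializations anchor the homozygote bands at 0.05/0.95, the
    undisplaced het band at 0.5, and the split het bands at
    ``0.5 -/+ delta_init``.  The best model is chosen by minimum BIC with
    ties (delta BIC < 2) resolved toward smaller k.  ``delta_b_hat`` is
    half the separation of the two central components when k = 4, else 0.

    Candidate fits must respect the band semantics: the central components
    of a k = 3 or k = 4 model must lie inside (0.06, 0.94).  Without this
    check, extra components refit the clipped homozygote pile-ups at 0/1
    (component means ~0.03/0.97) on segments with no het band at all,
    which is a better density but not a band structure.  The window still
    admits the highest-fraction detectable events (f = 0.88 copy-neutral
    puts het bands at 0.06/0.94).
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 50:
        raise ValueError(f"need >= 50 BAF values, got {len(x)}")
    if delta_init is None:
        delta_init = max(float(np.mean(np.maximum(x, 1 - x))) - 0.5, 0.05)
    delta_init = float(np.clip(delta_init, 0.02, 0.45))
    inits = {
        2: [0.05, 0.95],
        3: [0.05, 0.5, 0.95],
        4: [0.05, 0.5 - delta_init, 0.5 + delta_init, 0.95],
    }
    fits: dict[int, GmmFit] = {}
    X = x.reshape(-1, 1)
    for k, means0 in inits.items():
        gm = GaussianMixture(
            n_components=k,
            covariance_type="diag",
            means_init=np.array(means0).reshape(-1, 1),
            weights_init=np.full(k, 1.0 / k),
            reg_covar=SD_FLOOR**2,
            max_iter=200,
            n_init=1,
            random_state=seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            gm.fit(X)
        if not gm.converged_:
            continue
        order = np.argsort(gm.means_.ravel())
        means = gm.means_.ravel()[order]
        sds = np.sqrt(gm.covariances_.ravel()[order])
        weights = gm.weights_[order]
        central = means[1:-1]
        if k > 2 and (central.min() <= 0.06 or central.max() >= 0.94):
            continue  # hom-band refit, not a het-band structure
        delta_hat = float((means[2] - means[1]) / 2) if k == 4 else 0.0
        fits[k] = GmmFit(
            k=k,
            means=tuple(float(m) for m in means),
            sds=tuple(float(s) for s in sds),
            weights=tuple(float(w) for w in weights),
            bic=float(gm.bic(X)),
            delta_b_hat=max(delta_hat, 0.0),
        )
    if not fits:
        raise SegmentRejected("no mixture model converged on segment BAF values")
    best_bic = min(f.bic for f in fits.values())
    for k in sorted(fits):  # smallest k within the BIC tie window wins
        if fits[k].bic <= best_bic + 2.0:
            return fits[k]
    raise AssertionError("unreachable")


def classify_copy_state(delta_lrr: float, whole_flag: bool) -> str:
    """Copy state from the mean adjusted LRR shift of the segment.

    Whole-chromosome events use thresholds +/-0.01; partial events use the
    more conservative +/-0.05 (greater LRR variation over fewer probes).
    Boundary values are copy-neutral.
    """
    if not np.isfinite(delta_lrr):
        raise ValueError("delta_lrr must be finite")
    thr = 0.01 if whole_flag else 0.05
    if delta_lrr > thr:
        return "gain"
    if delta_lrr < -thr:
        return "loss"
    return "copy-neutral"


def estimate_mosaic_fraction(delta_b: float, state: str) -> float:
    """Mosaic cell fraction from the het-band BAF deviation and copy state."""
    if delta_b < 0:
        raise ValueError("delta_b must be >= 0")
    if state not in STATES:
        raise ValueError(f"unknown state {state!r}")
    if state == "copy-neutral":
        f = 2.0 * delta_b
    elif state == "loss":
        f = 4.0 * delta_b / (1.0 + 2.0 * delta_b)
    else:  # gain
        if delta_b > 1.0 / 6.0:
            warnings.warn(
                f"gain delta_b={delta_b:.3f} exceeds the pure-trisomic limit "
                "1/6; fraction capped at 1",
                MosaicXWarning,
                stacklevel=2,
            )
            return 1.0
        f = 4.0 * delta_b / (1.0 - 2.0 * delta_b)
    return float(np.clip(f, 0.0, 1.0))


def _lrr_fraction(delta_lrr: float, state: str) -> float:
    """Cell fraction implied by the ideal LRR dosage response."""
    if state == "loss":
        f = 2.0 - 2.0 ** (delta_lrr + 1.0)
    elif state == "gain":
        f = 2.0 ** (delta_lrr + 1.0) - 2.0
    else:
        raise ValueError("LRR carries no fraction information for copy-neutral")
    return float(np.clip(f, 0.0, 1.0))


def classify_location(
    start_bp: int,
    end_bp: int,
    pmap: ProbeMap,
    end_tol_bp: int = 1_000_000,
) -> str:
    """Mutually exclusive location class for an event interval.

    Terminality is judged against the first/last assayed probe with
    tolerance ``end_tol_bp``.  Precedence: whole > telomeric p/q > spans
    centromere > interstitial.
    """
    if not (0 <= start_bp < end_bp <= pmap.chrom_length):
        raise ValueError(
            f"bounds [{start_bp}, {end_bp}) outside chromosome of length "
            f"{pmap.chrom_length}"
        )
    p_terminal = start_bp <= pmap.first_probe_bp + end_tol_bp
    q_terminal = end_bp >= pmap.last_probe_bp + 1 - end_tol_bp
    if p_terminal and q_terminal:
        return "whole"
    if p_terminal:
        return "telomeric p"
    if q_terminal:
        return "telomeric q"
    cs, ce = pmap.centromere
    if start_bp < cs and end_bp > ce:
        return "spans centromere"
    return "interstitial"


def screen_constitutional(
    calls: list[MosaicCall],
    fraction_threshold: float = 0.95,
) -> tuple[list[MosaicCall], list[MosaicCall]]:
    """Separate constitutional whole-X aneuploidies from mosaic calls.

    Whole-chromosome dosage events at fraction >= ``fraction_threshold``
    are flagged XO (loss) or trisomy X (gain) and returned separately;
    copy-neutral and partial events are always retained.
    """
    retained: list[MosaicCall] = []
    flagged: list[MosaicCall] = []
    for c in calls:
        if (
            c.location == "whole"
            and c.fraction >= fraction_threshold
            and c.state in ("loss", "gain")
        ):
            label = "XO" if c.state == "loss" else "trisomy_X"
            flagged.append(
                MosaicCall(**{**c.__dict__, "flags": c.flags + (label,)})
            )
        else:
            retained.append(c)
    return retained, flagged


def call_events(
    sample: SampleIntensities,
    pmap: ProbeMap,
    batch: ClusterBatch,
    params: CallerParams | None = None,
) -> tuple[list[MosaicCall], list[MosaicCall]]:
    """Run the full per-sample calling pipeline.

    Returns ``(calls, constitutional)`` with calls sorted by start
    position.  Segments whose best mixture lacks a split het band are
    rejected unless k = 2 with a corroborating LRR shift, in which case a
    high-fraction event is called with its fraction taken from the LRR
    dosage response.
    """
    params = params or CallerParams()
    sample.validate_against(pmap)
    informative = select_informative(
        sample, pmap, use_genotype=params.use_genotype, baf_window=params.baf_window
    )
    if informative.size == 0:
        return [], []
    mbaf = mirrored_baf(sample.baf[informative])
    positions = pmap.positions[informative]
    segments = cbs_segment(
        mbaf,
        positions,
        alpha=params.alpha,
        n_perm=params.n_perm,
        min_markers=params.min_markers,
        seed=params.seed,
        merge_tol=params.merge_tol,
    )
    candidates = filter_segments(
        segments, min_size_bp=params.min_size_bp, min_delta_b=params.min_delta_b
    )
    adj = adjust_lrr(sample, batch)

    calls: list[MosaicCall] = []
    for seg in candidates:
        in_seg = (pmap.positions >= seg.start_bp) & (pmap.positions < seg.end_bp)
        seg_baf = sample.baf[in_seg & np.isfinite(sample.baf)]
        seg_lrr = adj[in_seg & np.isfinite(adj)]
        if len(seg_baf) < params.min_segment_baf_values or seg_lrr.size == 0:
            logger.info(
                "sample %s: segment %d-%d rejected (too few probe values)",
                sample.sample_id, seg.start_bp, seg.end_bp,
            )
            continue
        delta_lrr = float(np.mean(seg_lrr))
        location = classify_location(
            seg.start_bp, seg.end_bp, pmap, end_tol_bp=params.end_tol_bp
        )
        whole_flag = location == "whole"
        state = classify_copy_state(delta_lrr, whole_flag)
        try:
            fit = fit_baf_mixture(seg_baf, seed=params.seed, delta_init=seg.delta_b)
        except SegmentRejected as exc:
            logger.info(
                "sample %s: segment %d-%d rejected (%s)",
                sample.sample_id, seg.start_bp, seg.end_bp, exc,
            )
            continue
        flags: tuple[str, ...] = ()
        if fit.k == 4:
            delta_b = fit.delta_b_hat
            fraction = estimate_mosaic_fraction(delta_b, state)
        elif fit.k == 2:
            # no het band at all: requires LRR corroboration, else it is a
            # genotyping artifact (e.g. a run of homozygosity)
            if state == "copy-neutral":
                logger.info(
                    "sample %s: k=2 segment %d-%d without LRR support rejected",
                    sample.sample_id, seg.start_bp, seg.end_bp,
                )
                continue
            delta_b = seg.delta_b
            fraction = _lrr_fraction(delta_lrr, state)
            flags = ("no_het_band",)
        else:  # k == 3: undisplaced het band contradicts the candidate
            logger.info(
                "sample %s: k=3 segment %d-%d rejected (no split het band)",
                sample.sample_id, seg.start_bp, seg.end_bp,
            )
            continue
        calls.append(
            MosaicCall(
                sample_id=sample.sample_id,
                start_bp=seg.start_bp,
                end_bp=seg.end_bp,
                n_probes=int(np.sum(in_seg)),
                state=state,
                location=location,
                delta_b=float(delta_b),
                delta_lrr=delta_lrr,
                fraction=float(fraction),
                whole_flag=whole_flag,
                flags=flags,
            )
        )
    calls.sort(key=lambda c: c.start_bp)
    return screen_constitutional(calls)


# ---------------------------------------------------------------------------
# BED-like output
# ---------------------------------------------------------------------------

BED_COLUMNS = (
    "chrom", "start", "end", "sample_id", "state", "location",
    "delta_b", "delta_lrr", "fraction", "n_probes", "flags",
)


def write_calls_bed(path, calls: list[MosaicCall], chrom: str,
                    header_lines=()) -> None:
    """Write calls to a BED-like TSV (0-based half-open coordinates)."""
    with open(path, "w") as fh:
        fh.write("# coordinates: 0-based, half-open\n")
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("\t".join(BED_COLUMNS) + "\n")
        for c in sorted(calls, key=lambda c: (c.sample_id, c.start_bp)):
            flags = ",".join(c.flags) if c.flags else "."
            fh.write(
                f"{chrom}\t{c.start_bp}\t{c.end_bp}\t{c.sample_id}\t{c.state}\t"
                f"{c.location}\t{c.delta_b:.4f}\t{c.delta_lrr:.4f}\t"
                f"{c.fraction:.4f}\t{c.n_probes}\t{flags}\n"
            )
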