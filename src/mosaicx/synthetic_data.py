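"""Synthetic cohorts with known ground truth for every pipeline stage.

Generates SNP-array BAF/LRR vectors, methylation beta matrices and qPCR
plate tables whose statistical structure matches the detection, phasing
and validation models, so the whole pipeline is testable offline.

Determinism: every draw derives from the master seed through
``np.random.SeedSequence(master_seed, spawn_key=(domain, index))`` where
``domain`` is a fixed small integer per generator and ``index`` the
entity index, so per-sample generation is reproducible and order-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .methylation_phasing import expected_beta
from .probe_model import ClusterBatch, ProbeMap, SampleIntensities

# hg18 / NCBI36 X-chromosome geometry (1-based lengths, stored 0-based).
HG18_X_LENGTH = 154_913_754
HG18_X_CENTROMERE = (58_500_000, 61_700_000)
HG18_X_PARS = ((0, 2_709_520), (154_584_237, 154_913_754))

_DOMAIN_MAP = 0
_DOMAIN_SAMPLE = 1
_DOMAIN_COHORT = 2
_DOMAIN_METH = 3
_DOMAIN_QPCR = 4

STATE_WEIGHTS = {"loss": 59, "copy-neutral": 43, "gain": 22}


def _rng(master_seed: int, domain: int, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=master_seed, spawn_key=(domain, index))
    )


@dataclass(frozen=True)
class EventSpec:
    """Ground-truth mosaic event (bp bounds 0-based half-open)."""

    state: str
    homolog: str
    start_bp: int
    end_bp: int
    fraction: float

    def __post_init__(self) -> None:
        if self.state not in ("loss", "gain", "copy-neutral"):
            raise ValueError(f"unknown state {self.state!r}")
        if self.homolog not in ("Xi", "Xa"):
            raise ValueError(f"unknown homolog {self.homolog!r}")
        if not (0.01 <= self.fraction <= 1.0):
            raise ValueError("fraction must lie in [0.01, 1]")
        if self.start_bp >= self.end_bp:
            raise ValueError("start_bp must be < end_bp")


@dataclass
class SimulationConfig:
    """All knobs of the synthetic generators (seed mandatory)."""

    seed: int
    n_women: int = 500
    n_probes: int = 1500
    chrom_length: int = HG18_X_LENGTH
    centromere: tuple[int, int] = HG18_X_CENTROMERE
    par_regions: tuple[tuple[int, int], ...] = HG18_X_PARS
    exclude_par: bool = True
    het_rate: float = 0.30
    nc_rate: float = 0.01
    baf_noise_sd: float = 0.03
    lrr_noise_sd: float = 0.15
    lrr_compression: float = 1.0
    batch_baselines: Mapping[str, float] = field(
        default_factory=lambda: {"batch0": 0.0}
    )
    batch_male_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"batch0": 0.0}
    )
    # carrier model: logit(p) = prevalence_intercept + log_or_per_year * age
    prevalence_intercept: float = -8.5763
    log_or_per_year: float = float(np.log(1.04))
    age_mean: float = 62.0
    age_sd: float = 10.0
    age_range: tuple[float, float] = (30.0, 92.0)
    multi_event_share: float = 0.15
    fraction_range: tuple[float, float] = (0.06, 0.88)
    whole_chrom_share: float = 0.484
    xi_share: float = 0.80
    interstitial_size_range: tuple[int, int] = (4_000_000, 40_000_000)
    # methylation
    n_promoters: int = 60
    probes_per_promoter: int = 4
    decoy_fraction: float = 0.3
    n_control_women: int = 50
    n_control_men: int = 50
    # qPCR
    n_qpcr_assays: int = 12
    qpcr_efficiency: float = 1.0
    ct_noise_sd: float = 0.1
    n_dilutions: int = 6
    qpcr_reference_assay: str = "RNaseP"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a master seed is mandatory")
        for name in ("baf_noise_sd", "lrr_noise_sd", "ct_noise_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0.0 <= self.multi_event_share <= 1.0):
            raise ValueError("multi_event_share must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Allele/dosage response of the array
# ---------------------------------------------------------------------------

def delta_b_for(state: str, f: float) -> float:
    """Het-band BAF displacement implied by an event (forward model)."""
    if state == "copy-neutral":
        return f / 2.0
    if state == "loss":
        return (f / 2.0) / (2.0 - f)
    if state == "gain":
        return (f / 2.0) / (2.0 + f)
    raise ValueError(f"unknown state {state!r}")


def lrr_shift_for(state: str, f: float, compression: float = 1.0) -> float:
    """Ideal LRR dosage response of an event."""
    if state == "loss":
        return compression * float(np.log2((2.0 - f) / 2.0))
    if state == "gain":
        return compression * float(np.log2((2.0 + f) / 2.0))
    if state == "copy-neutral":
        return 0.0
    raise ValueError(f"unknown state {state!r}")


# ---------------------------------------------------------------------------
# Probe map and per-sample intensities
# ---------------------------------------------------------------------------

def make_probe_map(n_probes: int, config: SimulationConfig) -> ProbeMap:
    """Uniform random probe positions over the (non-PAR) chromosome."""
    if n_probes < 100:
        raise ValueError("need at least 100 probes")
    rng = _rng(config.seed, _DOMAIN_MAP)
    positions: set[int] = set()
    while len(positions) < n_probes:
        draw = rng.integers(0, config.chrom_length,
                            size=2 * (n_probes - len(positions)))
        if config.exclude_par:
            for s, e in config.par_regions:
                draw = draw[(draw < s) | (draw >= e)]
        positions.update(int(p) for p in draw)
    pool = np.fromiter(positions, dtype=np.int64)
    pos = np.sort(rng.choice(pool, size=n_probes, replace=False))
    return ProbeMap(
        probe_ids=tuple(f"rsX{i:06d}" for i in range(n_probes)),
        positions=pos,
        chromosome="X",
        chrom_length=config.chrom_length,
        centromere=config.centromere,
        par_regions=config.par_regions,
    )


def simulate_sample(
    events: Sequence[EventSpec],
    pmap: ProbeMap,
    batch: ClusterBatch,
    config: SimulationConfig,
    seed_index: int = 0,
    sample_id: str = "S0",
) -> SampleIntensities:
    """Per-probe BAF/LRR/genotype vector with the given planted events."""
    ev = sorted(events, key=lambda e: e.start_bp)
    for e1, e2 in zip(ev, ev[1:]):
        if e2.start_bp < e1.end_bp:
            raise ValueError("events must be non-overlapping")
    rng = _rng(config.seed, _DOMAIN_SAMPLE, seed_index)
    n = pmap.n_probes
    u = rng.random(n)
    genotype = np.where(u < config.het_rate, "AB",
                        np.where(u < config.het_rate + (1 - config.het_rate) / 2,
                                 "AA", "BB")).astype("U2")
    nc = rng.random(n) < config.nc_rate

    baf_mean = np.where(genotype == "AB", 0.5,
                        np.where(genotype == "AA", 0.0, 1.0))
    lrr_mean = np.full(n, batch.lrr_baseline)
    for e in ev:
        inside = (pmap.positions >= e.start_bp) & (pmap.positions < e.end_bp)
        het = inside & (genotype == "AB")
        db = delta_b_for(e.state, e.fraction)
        sign = np.where(rng.random(n) < 0.5, 1.0, -1.0)
        baf_mean = np.where(het, 0.5 + sign * db, baf_mean)
        lrr_mean = np.where(
            inside,
            batch.lrr_baseline
            + lrr_shift_for(e.state, e.fraction, config.lrr_compression),
            lrr_mean,
        )
    baf = np.clip(baf_mean + rng.normal(0, config.baf_noise_sd, n), 0.0, 1.0)
    lrr = lrr_mean + rng.normal(0, config.lrr_noise_sd, n)
    genotype[nc] = "NC"
    return SampleIntensities(
        sample_id=sample_id, baf=baf, lrr=lrr, genotype=genotype,
        batch_id=batch.batch_id,
    )


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

def _draw_events(
    rng: np.random.Generator, config: SimulationConfig
) -> list[EventSpec]:
    n_events = 1
    if rng.random() < config.multi_event_share:
        n_events = 2
    states = list(STATE_WEIGHTS)
    weights = np.array(list(STATE_WEIGHTS.values()), dtype=float)
    weights /= weights.sum()
    events: list[EventSpec] = []
    attempts = 0
    while len(events) < n_events and attempts < 50:
        attempts += 1
        state = str(rng.choice(states, p=weights))
        homolog = "Xi" if rng.random() < config.xi_share else "Xa"
        f = float(rng.uniform(*config.fraction_range))
        # multi-event carriers necessarily hold partial events
        if n_events == 1 and rng.random() < config.whole_chrom_share:
            start, end = 0, config.chrom_length
        else:
            size = int(rng.integers(*config.interstitial_size_range))
            start = int(rng.integers(3_000_000, config.chrom_length - size - 1))
            end = start + size
        if any(not (end <= e.start_bp or start >= e.end_bp) for e in events):
            continue
        if any(e.start_bp == 0 and e.end_bp == config.chrom_length
               for e in events):
            continue
        events.append(EventSpec(state, homolog, start, end, f))
    return events


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, Callable[[int], SampleIntensities], pd.DataFrame]:
    """Draw a cohort with age-dependent carrier status and ground truth.

    Returns ``(cohort, sample_factory, truth)``.  ``sample_factory(i)``
    materializes the intensity vectors for woman ``i`` on demand (the
    probe map is shared and obtained from :func:`make_probe_map`), so
    large cohorts can be simulated without holding every array in memory.
    """
    rng = _rng(config.seed, _DOMAIN_COHORT)
    n = config.n_women
    ages = np.clip(
        rng.normal(config.age_mean, config.age_sd, n), *config.age_range
    )
    logit = config.prevalence_intercept + config.log_or_per_year * ages
    p_carrier = 1.0 / (1.0 + np.exp(-logit))
    carrier = rng.random(n) < p_carrier

    batch_ids = list(config.batch_baselines)
    batches = {
        b: ClusterBatch(
            batch_id=b,
            lrr_baseline=config.batch_baselines[b],
            male_fraction=config.batch_male_fractions.get(b, 0.0),
        )
        for b in batch_ids
    }
    assigned = rng.choice(batch_ids, size=n)

    sample_ids = [f"W{i:06d}" for i in range(n)]
    truth_rows = []
    events_by_index: dict[int, list[EventSpec]] = {}
    for i in np.flatnonzero(carrier):
        evs = _draw_events(_rng(config.seed, _DOMAIN_COHORT, int(i) + 1), config)
        events_by_index[int(i)] = evs
        for e in evs:
            truth_rows.append(
                (sample_ids[i], e.state, e.homolog, e.start_bp, e.end_bp,
                 e.fraction)
            )

    anc = rng.dirichlet((20.0, 1.0, 1.0), size=n)
    cohort = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "age": ages,
            "case_status": np.where(rng.random(n) < 0.5, "case", "control"),
            "dna_source": np.where(rng.random(n) < 0.95, "blood", "buccal"),
            "study_id": rng.choice(["study1", "study2", "study3"], size=n),
            "ancestry_eur": anc[:, 0],
            "ancestry_afr": anc[:, 1],
            "ancestry_asn": anc[:, 2],
            "batch_id": assigned,
            "has_x_event": carrier,
            "has_autosomal_event": rng.random(n) < 0.01,
            "x_event_count": [
                len(events_by_index.get(i, [])) for i in range(n)
            ],
            "mean_fraction": [
                float(np.mean([e.fraction for e in events_by_index[i]]))
                if i in events_by_index else np.nan
                for i in range(n)
            ],
        }
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["sample_id", "state", "homolog", "start", "end", "fraction"],
    )
    pmap = make_probe_map(config.n_probes, config)

    def sample_factory(i: int) -> SampleIntensities:
        return simulate_sample(
            events_by_index.get(i, []),
            pmap,
            batches[str(assigned[i])],
            config,
            seed_index=i,
            sample_id=sample_ids[i],
        )

    sample_factory.probe_map = pmap  # type: ignore[attr-defined]
    sample_factory.batches = batches  # type: ignore[attr-defined]
    return cohort, sample_factory, truth


# ---------------------------------------------------------------------------
# Methylation
# ---------------------------------------------------------------------------

def simulate_methylation(
    config: SimulationConfig,
    carriers: Mapping[str, Sequence[EventSpec]],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Control and carrier beta matrices plus the probe annotation.

    Returns ``(betas_women, betas_men, betas_carriers, annotation)``.
    Probe means for non-decoy probes are drawn inside the differential
    filter box with a safety margin so the empirical filter recovers
    exactly the probes generated inside the box; decoys are drawn clearly
    outside it.
    """
    rng = _rng(config.seed, _DOMAIN_METH)
    n_probes = config.n_promoters * config.probes_per_promoter
    # promoters spread over the chromosome; probes clustered within 2 kb
    promoter_pos = np.sort(
        rng.integers(3_000_000, config.chrom_length - 3_000_000,
                     size=config.n_promoters)
    )
    positions = np.concatenate(
        [p + rng.integers(0, 2000, size=config.probes_per_promoter)
         for p in promoter_pos]
    )
    promoter_ids = np.repeat(
        [f"prom{j:04d}" for j in range(config.n_promoters)],
        config.probes_per_promoter,
    )
    probe_ids = [f"cg{j:07d}" for j in range(n_probes)]

    decoy = rng.random(n_probes) < config.decoy_fraction
    mean_w = np.where(
        decoy,
        np.where(rng.random(n_probes) < 0.5,
                 rng.uniform(0.05, 0.30, n_probes),
                 rng.uniform(0.56, 0.85, n_probes)),
        rng.uniform(0.37, 0.48, n_probes),
    )
    sd_w = np.where(decoy, rng.uniform(0.02, 0.06, n_probes),
                    rng.uniform(0.02, 0.055, n_probes))
    mean_m = np.where(decoy, rng.uniform(0.20, 0.40, n_probes),
                      rng.uniform(0.03, 0.12, n_probes))
    sd_m = rng.uniform(0.01, 0.035, n_probes)

    def control_matrix(mean, sd, n_samples, prefix):
        mat = np.clip(
            mean[:, None] + rng.normal(0, 1, (n_probes, n_samples)) * sd[:, None],
            0.0, 1.0,
        )
        return pd.DataFrame(
            mat, index=probe_ids,
            columns=[f"{prefix}{j:04d}" for j in range(n_samples)],
        )

    betas_w = control_matrix(mean_w, sd_w, config.n_control_women, "CW")
    betas_m = control_matrix(mean_m, sd_m, config.n_control_men, "CM")

    carrier_cols = {}
    for sid, events in carriers.items():
        beta = mean_w + rng.normal(0, 1, n_probes) * sd_w
        for e in events:
            inside = (positions >= e.start_bp) & (positions < e.end_bp)
            exp = np.array([
                expected_beta(e.state, e.homolog, e.fraction, m)
                for m in mean_w[inside]
            ])
            beta[inside] = exp + rng.normal(0, 1, int(inside.sum())) * sd_w[inside]
        carrier_cols[sid] = np.clip(beta, 0.0, 1.0)
    betas_c = pd.DataFrame(carrier_cols, index=probe_ids)

    annotation = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "chrom": "X",
            "pos": positions,
            "promoter_region_id": promoter_ids,
            "in_filter_box": ~decoy,
        }
    )
    return betas_w, betas_m, betas_c, annotation


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

def simulate_qpcr(
    sample_ratios: Mapping[str, float],
    config: SimulationConfig,
    plate_id: str = "plate1",
) -> pd.DataFrame:
    """Plate table (standards + triplicate sample wells) for known ratios.

    Standards cover ``n_dilutions`` ten-fold-spaced concentrations for
    every assay including the reference; sample target concentration is
    ``ratio / 2`` times the reference concentration.
    """
    for sid, r in sample_ratios.items():
        if r <= 0:
            raise ValueError(f"sample {sid}: ratio must be positive")
    rng = _rng(config.seed, _DOMAIN_QPCR)
    slope = -1.0 / np.log10(1.0 + config.qpcr_efficiency)
    assays = [f"XA{j:02d}" for j in range(1, config.n_qpcr_assays + 1)]
    assays.append(config.qpcr_reference_assay)
    intercepts = {a: float(rng.uniform(19.0, 23.0)) for a in assays}

    rows = []
    dilutions = np.arange(config.n_dilutions, dtype=float) - 2.0  # log10 conc
    for assay in assays:
        for d in dilutions:
            for rep in range(1, 4):
                ct = (intercepts[assay] + slope * d
                      + rng.normal(0, config.ct_noise_sd))
                rows.append((plate_id, assay, "STD", "standard", d, rep, ct))
    for sid, ratio in sample_ratios.items():
        ref_conc = 1.0
        target_conc = ratio / 2.0 * ref_conc
        for assay in assays:
            if assay == config.qpcr_reference_assay:
                # reference is duplexed in every target well: one Ct per
                # replicate of every target assay
                n_rep = 3 * config.n_qpcr_assays
                conc = ref_conc
            else:
                n_rep = 3
                conc = target_conc
            for rep in range(1, n_rep + 1):
                ct = (intercepts[assay] + slope * np.log10(conc)
                      + rng.normal(0, config.ct_noise_sd))
                rows.append((plate_id, assay, sid, "sample", np.nan, rep, ct))
    return pd.DataFrame(
        rows,
        columns=["plate_id", "assay_id", "sample_id", "role",
                 "dilution_log10", "replicate", "ct"],
    )
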