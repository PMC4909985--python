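"""Probe maps, per-sample intensity vectors and batch LRR baselines.

Coordinate convention: all in-memory positions and intervals are 0-based,
half-open.  File readers and writers convert from/to the 1-based inclusive
convention used in the tab-separated interchange formats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

GENOTYPES = ("AA", "AB", "BB", "NC")

#: Columns of the per-probe interchange TSV, in order.
PROBE_TSV_COLUMNS = ("sample_id", "probe_id", "chrom", "pos", "genotype", "baf", "lrr")


class MosaicXWarning(UserWarning):
    """Base warning for non-fatal pipeline diagnostics."""


@dataclass(frozen=True)
class ProbeMap:
    """Chromosome geometry plus the ordered assayed probe positions.

    Parameters
    ----------
    probe_ids
        Opaque probe identifiers, one per assayed position.
    positions
        0-based probe positions, strictly increasing.
    chromosome
        Chromosome label (e.g. ``"X"``).
    chrom_length
        Chromosome length in base pairs.
    centromere
        ``(start, end)`` of the centromere, 0-based half-open.
    par_regions
        Pseudoautosomal intervals, 0-based half-open, non-overlapping.
    """

    probe_ids: tuple[str, ...]
    positions: np.ndarray
    chromosome: str
    chrom_length: int
    centromere: tuple[int, int]
    par_regions: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=np.int64)
        object.__setattr__(self, "positions", pos)
        if len(self.probe_ids) != len(pos):
            raise ValueError("probe_ids and positions must have equal length")
        if len(pos) and not np.all(np.diff(pos) > 0):
            raise ValueError("probe positions must be strictly increasing")
        if len(pos) and (pos[0] < 0 or pos[-1] >= self.chrom_length):
            raise ValueError("probe positions outside [0, chrom_length)")
        cs, ce = self.centromere
        if not (0 <= cs < ce <= self.chrom_length):
            raise ValueError("centromere interval must lie inside the chromosome")
        pars = sorted(self.par_regions)
        for (s, e) in pars:
            if not (0 <= s < e <= self.chrom_length):
                raise ValueError(f"PAR interval ({s}, {e}) outside chromosome")
        for (_, e1), (s2, _) in zip(pars, pars[1:]):
            if s2 < e1:
                raise ValueError("PAR intervals overlap")

    @property
    def n_probes(self) -> int:
        return len(self.positions)

    @property
    def par_mask(self) -> np.ndarray:
        """Boolean mask of probes falling inside any PAR interval."""
        mask = np.zeros(self.n_probes, dtype=bool)
        for s, e in self.par_regions:
            mask |= (self.positions >= s) & (self.positions < e)
        return mask

    @property
    def first_probe_bp(self) -> int:
        return int(self.positions[0])

    @property
    def last_probe_bp(self) -> int:
        return int(self.positions[-1])


@dataclass
class SampleIntensities:
    """One woman's per-probe BAF/LRR/genotype vectors on a :class:`ProbeMap`.

    Missing BAF or LRR values are NaN; they are carried through explicitly
    and never silently dropped.
    """

    sample_id: str
    baf: np.ndarray
    lrr: np.ndarray
    genotype: np.ndarray
    batch_id: str = "batch0"

    def __post_init__(self) -> None:
        self.baf = np.asarray(self.baf, dtype=float)
        self.lrr = np.asarray(self.lrr, dtype=float)
        self.genotype = np.asarray(self.genotype, dtype="U2")
        n = len(self.baf)
        if len(self.lrr) != n or len(self.genotype) != n:
            raise ValueError("baf, lrr and genotype must have equal length")
        finite = self.baf[np.isfinite(self.baf)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("BAF values must lie in [0, 1]")
        bad = set(np.unique(self.genotype)) - set(GENOTYPES)
        if bad:
            raise ValueError(f"unknown genotype codes: {sorted(bad)}")

    @property
    def n_probes(self) -> int:
        return len(self.baf)

    def validate_against(self, pmap: ProbeMap) -> None:
        if self.n_probes != pmap.n_probes:
            raise ValueError(
                f"sample {self.sample_id}: {self.n_probes} probes, "
                f"map has {pmap.n_probes}"
            )


@dataclass(frozen=True)
class ClusterBatch:
    """Expected female X LRR offset for one genotyping cluster batch."""

    batch_id: str
    lrr_baseline: float
    male_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.lrr_baseline):
            raise ValueError("lrr_baseline must be finite")
        if not (0.0 <= self.male_fraction <= 1.0):
            raise ValueError("male_fraction must lie in [0, 1]")


def mirrored_baf(baf):
    """Fold BAF onto [0.5, 1]: ``mBAF = max(b, 1 - b)``.

    Accepts scalars or arrays; NaN (missing) passes through.
    """
    b = np.asarray(baf, dtype=float)
    finite = b[np.isfinite(b)]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise ValueError("BAF out of range [0, 1]")
    out = np.maximum(b, 1.0 - b)
    if np.isscalar(baf) or np.ndim(baf) == 0:
        return float(out)
    return out


def select_informative(
    sample: SampleIntensities,
    pmap: ProbeMap,
    use_genotype: bool | None = None,
    baf_window: tuple[float, float] = (0.10, 0.90),
) -> np.ndarray:
    """Indices of probes usable for BAF segmentation, in map order.

    Heterozygous probes are taken from genotype calls (``AB``) when calls
    exist; otherwise probes with BAF strictly inside ``baf_window`` are
    used.  PAR probes and missing BAF are always excluded.
    """
    sample.validate_against(pmap)
    has_calls = bool(np.any(sample.genotype != "NC"))
    if use_genotype is None:
        use_genotype = has_calls
    if use_genotype and not has_calls:
        raise ValueError(f"sample {sample.sample_id}: no genotype calls present")

    ok = np.isfinite(sample.baf) & ~pmap.par_mask
    if use_genotype:
        ok &= sample.genotype == "AB"
    else:
        lo, hi = baf_window
        ok &= (sample.baf > lo) & (sample.baf < hi)
    idx = np.flatnonzero(ok)
    if idx.size == 0:
        warnings.warn(
            f"sample {sample.sample_id}: no informative probes on "
            f"{pmap.chromosome}; segmentation will be skipped",
            MosaicXWarning,
            stacklevel=2,
        )
    return idx


def estimate_batch_baseline(
    samples: Sequence[SampleIntensities],
    batch_id: str,
    min_controls: int = 20,
    male_fraction: float = 0.0,
) -> ClusterBatch:
    """Batch LRR baseline: median over controls of per-sample median LRR.

    ``samples`` must be female control samples from the named batch.
    """
    if len(samples) < min_controls:
        raise ValueError(
            f"batch {batch_id}: {len(samples)} female controls, "
            f"need at least {min_controls}"
        )
    medians = []
    for s in samples:
        finite = s.lrr[np.isfinite(s.lrr)]
        if finite.size:
            medians.append(np.median(finite))
    if not medians:
        raise ValueError(f"batch {batch_id}: all control LRR values missing")
    return ClusterBatch(
        batch_id=batch_id,
        lrr_baseline=float(np.median(medians)),
        male_fraction=male_fraction,
    )


def adjust_lrr(sample: SampleIntensities, batch: ClusterBatch) -> np.ndarray:
    """Subtract the batch baseline from the LRR vector (NaN stays NaN)."""
    if sample.batch_id != batch.batch_id:
        raise ValueError(
            f"sample {sample.sample_id} belongs to batch {sample.batch_id}, "
            f"not {batch.batch_id}"
        )
    return sample.lrr - batch.lrr_baseline


# ---------------------------------------------------------------------------
# Interchange I/O (1-based inclusive on disk)
# ---------------------------------------------------------------------------

def read_probe_tsv(path: str | Path) -> dict[str, SampleIntensities]:
    """Read the per-probe interchange TSV into per-sample intensity vectors.

    Columns (header required): sample_id, probe_id, chrom, pos, genotype,
    baf, lrr.  '.' denotes missing.  Probes must appear in identical order
    for every sample.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing_cols = set(PROBE_TSV_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"{path}: missing columns {sorted(missing_cols)}")
    df["baf"] = pd.to_numeric(df["baf"].replace(".", np.nan))
    df["lrr"] = pd.to_numeric(df["lrr"].replace(".", np.nan))
    df["genotype"] = df["genotype"].replace(".", "NC")
    batches = {}
    if "batch_id" in df.columns:
        batches = df.groupby("sample_id")["batch_id"].first().to_dict()
    out: dict[str, SampleIntensities] = {}
    probe_order: list[str] | None = None
    for sid, grp in df.groupby("sample_id", sort=False):
        ids = grp["probe_id"].tolist()
        if probe_order is None:
            probe_order = ids
        elif ids != probe_order:
            raise ValueError(f"{path}: probe order differs for sample {sid}")
        out[str(sid)] = SampleIntensities(
            sample_id=str(sid),
            baf=grp["baf"].to_numpy(float),
            lrr=grp["lrr"].to_numpy(float),
            genotype=grp["genotype"].to_numpy(),
            batch_id=str(batches.get(sid, "batch0")),
        )
    return out


def write_probe_tsv(
    path: str | Path,
    samples: Iterable[SampleIntensities],
    pmap: ProbeMap,
    header_lines: Sequence[str] = (),
) -> None:
    """Write samples to the interchange TSV (positions converted to 1-based)."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("\t".join(PROBE_TSV_COLUMNS) + "\tbatch_id\n")
        pos1 = pmap.positions + 1
        for s in samples:
            s.validate_against(pmap)
            for i in range(pmap.n_probes):
                baf = "." if not np.isfinite(s.baf[i]) else f"{s.baf[i]:.4f}"
                lrr = "." if not np.isfinite(s.lrr[i]) else f"{s.lrr[i]:.4f}"
                fh.write(
                    f"{s.sample_id}\t{pmap.probe_ids[i]}\t{pmap.chromosome}\t"
                    f"{pos1[i]}\t{s.genotype[i]}\t{baf}\t{lrr}\t{s.batch_id}\n"
                )


def probe_map_from_sidecar(
    path: str | Path,
    chromosome: str,
    chrom_length: int,
    centromere: tuple[int, int],
    par_regions: Sequence[tuple[int, int]] = (),
) -> ProbeMap:
    """Build a ProbeMap from a (probe_id, chrom, pos) sidecar TSV.

    Geometry arguments are 1-based inclusive, as in the run config, and
    are converted to the internal 0-based half-open convention.
    """
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str, "pos": int})
    for col in ("probe_id", "chrom", "pos"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col}")
    df = df[df["chrom"] == chromosome]
    df = df.sort_values("pos")
    return ProbeMap(
        probe_ids=tuple(df["probe_id"]),
        positions=df["pos"].to_numpy(np.int64) - 1,
        chromosome=chromosome,
        chrom_length=chrom_length,
        centromere=(centromere[0] - 1, centromere[1]),
        par_regions=tuple((s - 1, e) for s, e in par_regions),
    )


def write_probe_map_sidecar(path: str | Path, pmap: ProbeMap) -> None:
    with open(path, "w") as fh:
        fh.write("probe_id\tchrom\tpos\n")
        for pid, pos in zip(pmap.probe_ids, pmap.positions):
            fh.write(f"{pid}\t{pmap.chromosome}\t{pos + 1}\n")
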