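"""Core domain types for SNP-array based preimplantation genetic testing.

Coordinates are 1-based inclusive throughout (GRCh37 convention, matching the
printed HBA locus ``16:222846-227521``). Genotypes use the Illumina AB
abstraction (``AA``/``AB``/``BB``/``NC``); ``baf`` is the B-allele fraction and
``lrr`` the log2 R ratio (0 at two copies). Missing BAF/LRR are ``NaN`` and are
excluded from numeric summaries, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ALLOWED_CHROMOSOMES",
    "GENOTYPES",
    "AlphaPgtError",
    "FormatError",
    "IntegrityError",
    "DomainError",
    "GenomeInterval",
    "SnpPanel",
    "SampleArray",
    "FamilyConfig",
    "RegionPartition",
    "compute_call_rate",
    "partition_region",
    "HBA_LOCUS",
]

ALLOWED_CHROMOSOMES = tuple(str(c) for c in range(1, 23)) + ("X", "Y")
GENOTYPES = ("AA", "AB", "BB", "NC")

#: number of B alleles in each diploid genotype call; NC maps to -1
GTYPE_B_DOSE = {"AA": 0, "AB": 1, "BB": 2, "NC": -1}


class AlphaPgtError(Exception):
    """Base class for all package errors."""


class FormatError(AlphaPgtError):
    """A file does not conform to the expected dialect."""


class IntegrityError(AlphaPgtError):
    """Input data violate an internal-consistency requirement."""


class DomainError(AlphaPgtError):
    """An operation was invoked outside its domain of validity."""


def normalize_chromosome(chrom: object) -> str:
    """Map 'chr16', 16, '16' etc. onto the canonical label set 1-22, X, Y."""
    label = str(chrom).strip()
    if label.lower().startswith("chr"):
        label = label[3:]
    if label not in ALLOWED_CHROMOSOMES:
        raise DomainError(f"unknown chromosome label: {chrom!r}")
    return label


@dataclass(frozen=True)
class GenomeInterval:
    """A closed genomic interval [start, end], 1-based, on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chromosome(self.chrom))
        if self.start < 1:
            raise DomainError(f"interval start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise DomainError(
                f"interval end {self.end} precedes start {self.start}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, position: int) -> bool:
        return (
            normalize_chromosome(chrom) == self.chrom
            and self.start <= position <= self.end
        )

    def contains_positions(self, positions: np.ndarray) -> np.ndarray:
        """Vectorised membership test for positions on this interval's chromosome."""
        return (positions >= self.start) & (positions <= self.end)


#: HBA1 + HBA2 locus on 16p13.3, GRCh37.
HBA_LOCUS = GenomeInterval("16", 222_846, 227_521)


class SnpPanel:
    """An ordered SNP panel: unique ids with chromosome and position.

    Wraps a DataFrame with columns ``snp_id``, ``chrom``, ``pos``, sorted by
    (chromosome, position). Genotype tables are stored row-aligned to a panel.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"snp_id", "chrom", "pos"}
        missing = required - set(table.columns)
        if missing:
            raise FormatError(f"panel table missing columns: {sorted(missing)}")
        df = table.loc[:, ["snp_id", "chrom", "pos"]].copy()
        df["snp_id"] = df["snp_id"].astype(str)
        df["chrom"] = df["chrom"].map(normalize_chromosome)
        df["pos"] = df["pos"].astype(np.int64)
        if (df["pos"] < 1).any():
            raise DomainError("SNP positions must be >= 1")
        if df["snp_id"].duplicated().any():
            dup = df.loc[df["snp_id"].duplicated(), "snp_id"].iloc[0]
            raise IntegrityError(f"duplicate SNP id in panel: {dup}")
        df = df.sort_values(
            ["chrom", "pos"],
            key=lambda s: s.map(ALLOWED_CHROMOSOMES.index) if s.name == "chrom" else s,
            kind="stable",
        ).reset_index(drop=True)
        self.table = df
        self._index = pd.Index(df["snp_id"])
        self._chrom_masks: dict[str, np.ndarray] = {}

    def __len__(self) -> int:
        return len(self.table)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SnpPanel):
            return NotImplemented
        return self.table.equals(other.table)

    @property
    def snp_ids(self) -> np.ndarray:
        return self.table["snp_id"].to_numpy()

    @property
    def chroms(self) -> np.ndarray:
        return self.table["chrom"].to_numpy()

    @property
    def positions(self) -> np.ndarray:
        return self.table["pos"].to_numpy()

    def chromosome_mask(self, chrom: str) -> np.ndarray:
        chrom = normalize_chromosome(chrom)
        if chrom not in self._chrom_masks:
            self._chrom_masks[chrom] = self.chroms == chrom
        return self._chrom_masks[chrom]

    def interval_mask(self, interval: GenomeInterval) -> np.ndarray:
        return self.chromosome_mask(interval.chrom) & interval.contains_positions(
            self.positions
        )

    def indexer(self, snp_ids: Iterable[str]) -> np.ndarray:
        idx = self._index.get_indexer(list(snp_ids))
        if (idx < 0).any():
            raise IntegrityError("SNP id not present in panel")
        return idx


@dataclass
class SampleArray:
    """One sample's genotypes over a panel, row-aligned with ``panel.table``.

    ``data`` has columns ``gtype`` (AA/AB/BB/NC), ``baf`` and ``lrr``
    (float, NaN = missing), one row per panel SNP in panel order.
    """

    sample_id: str
    role: str  # father | mother | embryo
    panel: SnpPanel
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.role not in ("father", "mother", "embryo"):
            raise DomainError(f"unknown sample role: {self.role!r}")
        required = {"gtype", "baf", "lrr"}
        if not required <= set(self.data.columns):
            raise FormatError(f"sample data must have columns {sorted(required)}")
        if len(self.data) != len(self.panel):
            raise IntegrityError(
                f"sample {self.sample_id}: {len(self.data)} records for a "
                f"{len(self.panel)}-SNP panel"
            )
        bad = ~self.data["gtype"].isin(GENOTYPES)
        if bad.any():
            raise FormatError(
                f"sample {self.sample_id}: invalid genotype "
                f"{self.data.loc[bad, 'gtype'].iloc[0]!r}"
            )
        baf = self.data["baf"].to_numpy(float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(baf, initial=0.0) < 0 or np.nanmax(baf, initial=0.0) > 1:
                raise DomainError(f"sample {self.sample_id}: BAF outside [0, 1]")

    def _cached(self, attr: str, column: str, dtype=None) -> np.ndarray:
        cached = getattr(self, attr, None)
        if cached is None:
            col = self.data[column]
            cached = col.to_numpy(dtype) if dtype else col.to_numpy()
            object.__setattr__(self, attr, cached)
        return cached

    @property
    def gtypes(self) -> np.ndarray:
        return self._cached("_gtypes", "gtype")

    @property
    def baf(self) -> np.ndarray:
        return self._cached("_baf", "baf", float)

    @property
    def lrr(self) -> np.ndarray:
        return self._cached("_lrr", "lrr", float)

    @property
    def b_dose(self) -> np.ndarray:
        """Per-SNP B-allele count of the called genotype; -1 for NC.

        Cached on first access; sample data are treated as immutable once
        constructed.
        """
        cached = getattr(self, "_b_dose", None)
        if cached is None:
            cached = self.data["gtype"].map(GTYPE_B_DOSE).to_numpy(np.int8)
            object.__setattr__(self, "_b_dose", cached)
        return cached

    @property
    def call_rate(self) -> float:
        return compute_call_rate(self)


def compute_call_rate(sample: SampleArray) -> float:
    """Fraction of panel SNPs with a non-NC genotype call.

    A whole-genome-amplification quality metric: single-cell material with
    degraded amplification shows depressed call rates (e.g. 0.88 vs a good
    sample's 0.95+).
    """
    n = len(sample.data)
    if n == 0:
        raise DomainError("call rate undefined for a sample with no records")
    return float((sample.gtypes != "NC").sum()) / n


@dataclass
class FamilyConfig:
    """Pedigree roles plus target-locus geometry for one carrier x carrier family."""

    family_id: str
    father_id: str
    mother_id: str
    embryo_ids: Sequence[str] = field(default_factory=list)
    locus: GenomeInterval = HBA_LOCUS
    flank_bp: int = 2_000_000
    deletion: GenomeInterval | None = None
    genome_build: str = "GRCh37"

    def __post_init__(self) -> None:
        if self.flank_bp < 0:
            raise DomainError("flank_bp must be non-negative")
        if self.deletion is None:
            self.deletion = self.locus
        d, l = self.deletion, self.locus
        if d.chrom != l.chrom or d.start > l.start or d.end < l.end:
            raise DomainError("deletion interval must contain the locus interval")

    def with_embryos(self, embryo_ids: Sequence[str]) -> "FamilyConfig":
        return replace(self, embryo_ids=list(embryo_ids))


@dataclass(frozen=True)
class RegionPartition:
    """The locus and its two flanks: 5' upstream (telomeric, lower coordinates),
    the gene interval itself, and 3' downstream (centromeric, higher coordinates).

    Either flank may be ``None`` when empty (zero flank, or upstream clipped
    away entirely at the p-arm terminus).
    """

    upstream_5p: GenomeInterval | None
    in_gene: GenomeInterval
    downstream_3p: GenomeInterval | None

    FLANK_LABELS = ("upstream_5p", "in_gene", "downstream_3p")

    def label_positions(self, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """Per-SNP flank label; empty string for SNPs outside the partition."""
        labels = np.full(len(pos), "", dtype=object)
        for name in self.FLANK_LABELS:
            iv = getattr(self, name)
            if iv is None:
                continue
            m = (chrom == iv.chrom) & (pos >= iv.start) & (pos <= iv.end)
            labels[m] = name
        return labels


def partition_region(config: FamilyConfig) -> RegionPartition:
    """Split the flanked target region into 5' flank / gene / 3' flank.

    The upstream flank is clipped at position 1: for HBA on 16p13.3 the gene
    sits < 0.3 Mb from the p-arm terminus, so a 2-Mb upstream flank collapses
    to [1, locus.start - 1]. The three intervals tile
    [max(1, start - flank), end + flank] with no gaps or overlaps.
    """
    locus = config.locus
    flank = config.flank_bp
    upstream = None
    if flank > 0 and locus.start > 1:
        upstream = GenomeInterval(
            locus.chrom, max(1, locus.start - flank), locus.start - 1
        )
    downstream = (
        GenomeInterval(locus.chrom, locus.end + 1, locus.end + flank)
        if flank > 0
        else None
    )
    return RegionPartition(upstream_5p=upstream, in_gene=locus, downstream_3p=downstream)
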