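"""Readers and writers for SNP genotype tables, Gap-PCR peak files and
family configurations.

The SNP table dialect follows GenomeStudio "Final Report" conventions: a
tab-separated file with one row per SNP per sample and header columns
``Sample ID``, ``SNP Name``, ``Chr``, ``Position``, ``GType``,
``B Allele Freq``, ``Log R Ratio``. The column mapping is configurable for
other exports of the same shape. Unparseable BAF/LRR fields become missing
values rather than errors; a missing mandatory column or a duplicated
(sample, SNP) row is an error.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .model import (
    FamilyConfig,
    FormatError,
    GenomeInterval,
    IntegrityError,
    SampleArray,
    SnpPanel,
    normalize_chromosome,
)

__all__ = [
    "DEFAULT_SNP_COLUMNS",
    "read_snp_table",
    "write_snp_table",
    "read_peaks_csv",
    "write_peaks_csv",
    "load_family_config",
    "dump_family_config",
]

#: logical field -> GenomeStudio Final Report column name
DEFAULT_SNP_COLUMNS: Mapping[str, str] = {
    "sample": "Sample ID",
    "snp": "SNP Name",
    "chrom": "Chr",
    "pos": "Position",
    "gtype": "GType",
    "baf": "B Allele Freq",
    "lrr": "Log R Ratio",
}

_FLOAT_FMT = "%.6f"


def read_snp_table(
    path: str | Path,
    panel: SnpPanel | None = None,
    columns: Mapping[str, str] | None = None,
    roles: Mapping[str, str] | None = None,
) -> dict[str, SampleArray]:
    """Read a final-report-style TSV into one :class:`SampleArray` per sample.

    Parameters
    ----------
    path
        Tab-separated file with a header naming at least the mapped columns.
    panel
        Panel to validate and align records against. When omitted, the panel
        is inferred from the file (each sample must then cover all SNPs seen).
    columns
        Override of :data:`DEFAULT_SNP_COLUMNS` (logical name -> header name).
    roles
        Optional sample_id -> role map; unlisted samples default to "embryo".
    """
    colmap = dict(DEFAULT_SNP_COLUMNS)
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for logical in ("sample", "snp", "chrom", "pos", "gtype", "baf", "lrr"):
        if colmap[logical] not in df.columns:
            raise FormatError(
                f"SNP table {path} is missing mandatory column "
                f"{colmap[logical]!r}"
            )
    df = df.rename(columns={v: k for k, v in colmap.items()})
    if df.duplicated(subset=["sample", "snp"]).any():
        row = df[df.duplicated(subset=["sample", "snp"])].iloc[0]
        raise IntegrityError(
            f"duplicate row for sample {row['sample']!r}, SNP {row['snp']!r}"
        )
    df["baf"] = pd.to_numeric(df["baf"], errors="coerce")
    df["lrr"] = pd.to_numeric(df["lrr"], errors="coerce")
    gtype = df["gtype"].str.upper().str.strip()
    gtype = gtype.where(gtype.isin(["AA", "AB", "BB"]), "NC")
    df["gtype"] = gtype

    if panel is None:
        first = df.drop_duplicates(subset="snp")
        panel = SnpPanel(
            first.rename(columns={"snp": "snp_id"})[["snp_id", "chrom", "pos"]]
        )
    samples: dict[str, SampleArray] = {}
    for sample_id, grp in df.groupby("sample", sort=True):
        idx = panel.indexer(grp["snp"])
        data = pd.DataFrame(
            {
                "gtype": np.full(len(panel), "NC", dtype=object),
                "baf": np.full(len(panel), np.nan),
                "lrr": np.full(len(panel), np.nan),
            }
        )
        if len(grp) != len(panel):
            raise IntegrityError(
                f"sample {sample_id!r} has {len(grp)} records for a "
                f"{len(panel)}-SNP panel"
            )
        data.loc[idx, "gtype"] = grp["gtype"].to_numpy()
        data.loc[idx, "baf"] = grp["baf"].to_numpy()
        data.loc[idx, "lrr"] = grp["lrr"].to_numpy()
        role = (roles or {}).get(str(sample_id), "embryo")
        samples[str(sample_id)] = SampleArray(
            sample_id=str(sample_id), role=role, panel=panel, data=data
        )
    return samples


def write_snp_table(
    samples: Sequence[SampleArray] | Mapping[str, SampleArray],
    path: str | Path,
    columns: Mapping[str, str] | None = None,
) -> Path:
    """Write samples to a final-report-style TSV (inverse of :func:`read_snp_table`).

    All samples must share one panel; genotypes round-trip exactly and
    BAF/LRR to 6 decimals.
    """
    if isinstance(samples, Mapping):
        samples = list(samples.values())
    colmap = dict(DEFAULT_SNP_COLUMNS)
    if columns:
        colmap.update(columns)
    path = Path(path)
    if samples:
        panel = samples[0].panel
        for s in samples[1:]:
            if s.panel is not panel and s.panel != panel:
                raise IntegrityError("samples do not share one panel")
    frames = []
    for s in samples:
        frames.append(
            pd.DataFrame(
                {
                    colmap["sample"]: s.sample_id,
                    colmap["snp"]: s.panel.snp_ids,
                    colmap["chrom"]: s.panel.chroms,
                    colmap["pos"]: s.panel.positions,
                    colmap["gtype"]: s.gtypes,
                    colmap["baf"]: s.baf,
                    colmap["lrr"]: s.lrr,
                }
            )
        )
    header = [
        colmap[k] for k in ("sample", "snp", "chrom", "pos", "gtype", "baf", "lrr")
    ]
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=header)
    out.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT, na_rep="")
    return path


def read_peaks_csv(path: str | Path) -> dict[str, list["PcrPeak"]]:
    """Read fluorescent Gap-PCR peaks (CSV: sample, size_bp, dye, height)."""
    from .gap_pcr import PcrPeak

    df = pd.read_csv(path, dtype={"sample": str, "dye": str})
    for col in ("sample", "size_bp", "height"):
        if col not in df.columns:
            raise FormatError(f"peaks file {path} is missing column {col!r}")
    peaks: dict[str, list[PcrPeak]] = {}
    for _, row in df.iterrows():
        dye = row.get("dye")
        dye = None if pd.isna(dye) or dye == "" else str(dye)
        peaks.setdefault(str(row["sample"]), []).append(
            PcrPeak(size_bp=int(row["size_bp"]), dye=dye, height=float(row["height"]))
        )
    return peaks


def write_peaks_csv(peaks: Mapping[str, Sequence["PcrPeak"]], path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {
            "sample": sample,
            "size_bp": p.size_bp,
            "dye": p.dye or "",
            "height": p.height,
        }
        for sample, plist in peaks.items()
        for p in plist
    ]
    pd.DataFrame(rows, columns=["sample", "size_bp", "dye", "height"]).to_csv(
        path, index=False
    )
    return path


def _interval_from_mapping(chrom: str, m: Mapping) -> GenomeInterval:
    return GenomeInterval(normalize_chromosome(m.get("chrom", chrom)), int(m["start"]), int(m["end"]))


def load_family_config(path: str | Path) -> FamilyConfig:
    """Load a family configuration from YAML or JSON.

    Keys: ``family_id``, ``father``, ``mother``, ``embryos``, ``locus``
    {chrom, start, end}, ``flank_bp``, ``deletion`` {start, end}, ``build``.
    """
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    try:
        locus_raw = raw.get("locus")
        kwargs = dict(
            family_id=str(raw["family_id"]),
            father_id=str(raw["father"]),
            mother_id=str(raw["mother"]),
            embryo_ids=[str(e) for e in raw.get("embryos", [])],
        )
    except KeyError as exc:
        raise FormatError(f"family config {path} is missing key {exc}") from exc
    if locus_raw:
        kwargs["locus"] = _interval_from_mapping("16", locus_raw)
    if "flank_bp" in raw:
        kwargs["flank_bp"] = int(raw["flank_bp"])
    if raw.get("deletion"):
        chrom = kwargs.get("locus", FamilyConfig.__dataclass_fields__["locus"].default).chrom
        kwargs["deletion"] = _interval_from_mapping(chrom, raw["deletion"])
    if "build" in raw:
        kwargs["genome_build"] = str(raw["build"])
    return FamilyConfig(**kwargs)


def dump_family_config(config: FamilyConfig, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "family_id": config.family_id,
        "father": config.father_id,
        "mother": config.mother_id,
        "embryos": list(config.embryo_ids),
        "locus": {
            "chrom": config.locus.chrom,
            "start": config.locus.start,
            "end": config.locus.end,
        },
        "flank_bp": config.flank_bp,
        "deletion": {
            "chrom": config.deletion.chrom,
            "start": config.deletion.start,
            "end": config.deletion.end,
        },
        "build": config.genome_build,
    }
    if path.suffix == ".json":
        path.write_text(json.dumps(payload, indent=2))
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
    return path
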