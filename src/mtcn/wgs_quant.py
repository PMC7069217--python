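"""Coverage-ratio mtDNA copy number from sequencing depth.

Relative copy number is the flag-filtered mean depth over mtDNA divided by
the mean depth over an autosomal reference region, inverse-normal
transformed across the cohort.  Depth can be ingested from per-base TSV
tables or accumulated from SAM text records.

Coordinates are 1-based inclusive at every interface, matching SAM/VCF
convention.  The minimal depth accumulator counts a read at every position
of its aligned reference span (no CIGAR gap handling) — a documented
limitation of the text-record path; the pysam path uses the reference span
reported by the alignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .qpcr_quant import inverse_normal_transform

__all__ = [
    "SAM_FLAGS",
    "DEFAULT_EXCLUDE_FLAGS",
    "ReadRecord",
    "DepthProfile",
    "build_exclusion_mask",
    "filter_records",
    "read_sam_records",
    "depth_from_records",
    "read_depth_tsv",
    "write_depth_tsv",
    "region_mean_depth",
    "coverage_cn",
    "cohort_normalize",
]

#: SAM flag bits by name.  Values are distinct powers of two.
SAM_FLAGS: dict[str, int] = {
    "read_unmapped": 0x4,
    "mate_unmapped": 0x8,
    "not_primary_alignment": 0x100,
    "fails_quality_checks": 0x200,
    "duplicate": 0x400,
    "supplementary_alignment": 0x800,
}

#: The six exclusion flags combined: decimal 3852.
DEFAULT_EXCLUDE_FLAGS = tuple(SAM_FLAGS)


@dataclass(frozen=True)
class ReadRecord:
    """Minimal alignment record: reference, 1-based start, flag, span."""

    rname: str
    pos: int
    flag: int
    span: int

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError("position must be >= 1")
        if self.flag < 0:
            raise ValueError("flag must be >= 0")
        if self.span < 0:
            raise ValueError("span must be >= 0")


@dataclass
class DepthProfile:
    """Per-position depth over a 1-based inclusive region."""

    rname: str
    start: int
    end: int
    depths: np.ndarray

    def __post_init__(self):
        self.depths = np.asarray(self.depths)
        if self.start < 1 or self.end < self.start:
            raise ValueError("invalid region")
        if len(self.depths) != self.end - self.start + 1:
            raise ValueError("depth vector length does not match region")
        if (self.depths < 0).any():
            raise ValueError("negative depth")

    def __len__(self) -> int:
        return self.end - self.start + 1


def build_exclusion_mask(flag_names) -> int:
    """Bitwise-OR the named SAM flags into one exclusion mask.

    The six standard exclusion flags (read unmapped, mate unmapped, not
    primary, fails QC, duplicate, supplementary) combine to 3852.
    """
    mask = 0
    for name in flag_names:
        if name not in SAM_FLAGS:
            raise ValueError(
                f"unknown SAM flag {name!r}; known: {sorted(SAM_FLAGS)}"
            )
        mask |= SAM_FLAGS[name]
    return mask


def filter_records(records, mask: int):
    """Keep exactly the records with (flag AND mask) == 0, order preserved."""
    if mask < 0:
        raise ValueError("mask must be >= 0")
    return [r for r in records if (r.flag & mask) == 0]


def read_sam_records(path) -> list[ReadRecord]:
    """Read a SAM text file into minimal :class:`ReadRecord` objects.

    Unmapped records (no reference span) get span 0 and position clamped
    to 1 so they survive construction; flag filtering removes them.
    """
    import pysam

    records = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam.fetch(until_eof=True):
            if aln.reference_id < 0 or aln.reference_start is None:
                records.append(ReadRecord("*", 1, aln.flag, 0))
                continue
            start = aln.reference_start + 1  # pysam is 0-based
            end = aln.reference_end if aln.reference_end else aln.reference_start + 1
            records.append(
                ReadRecord(aln.reference_name, start, aln.flag, end - aln.reference_start)
            )
    return records


def depth_from_records(records, rname: str, start: int, end: int) -> DepthProfile:
    """Accumulate per-position depth from records over [start, end].

    Each record contributes 1 to every position of its aligned span that
    overlaps the region.
    """
    if end < start:
        raise ValueError("empty region")
    depths = np.zeros(end - start + 1, dtype=np.int64)
    for r in records:
        if r.rname != rname or r.span == 0:
            continue
        lo = max(r.pos, start)
        hi = min(r.pos + r.span - 1, end)
        if lo <= hi:
            depths[lo - start : hi - start + 1] += 1
    return DepthProfile(rname, start, end, depths)


def read_depth_tsv(path) -> dict[str, DepthProfile]:
    """Read a per-base depth TSV (chrom, pos 1-based, depth) into one
    profile per chromosome.  Positions absent from the table have depth 0;
    each profile spans position 1..max(pos) for its chromosome.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "pos", "depth"],
                     comment="#", dtype={"chrom": str})
    profiles = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        end = int(sub["pos"].max())
        depths = np.zeros(end, dtype=np.int64)
        depths[sub["pos"].to_numpy(dtype=int) - 1] = sub["depth"].to_numpy(dtype=int)
        profiles[chrom] = DepthProfile(chrom, 1, end, depths)
    return profiles


def write_depth_tsv(profiles, path) -> None:
    """Write profiles as a (chrom, pos, depth) TSV, zero-depth rows omitted."""
    frames = []
    for p in profiles if not isinstance(profiles, dict) else profiles.values():
        pos = np.nonzero(p.depths)[0] + p.start
        frames.append(pd.DataFrame(
            {"chrom": p.rname, "pos": pos, "depth": p.depths[pos - p.start]}
        ))
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["chrom", "pos", "depth"])
    out.to_csv(path, sep="\t", header=False, index=False)


def region_mean_depth(profile: DepthProfile, start: int | None = None,
                      end: int | None = None) -> float:
    """Arithmetic mean depth over [start, end] (defaults: whole profile).

    Positions of the region with no coverage contribute 0.
    """
    start = profile.start if start is None else start
    end = profile.end if end is None else end
    if end < start:
        raise ValueError("empty region")
    if start < profile.start or end > profile.end:
        raise ValueError("region outside profile bounds")
    return float(profile.depths[start - profile.start : end - profile.start + 1].mean())


def coverage_cn(mt_mean: float, nuc_mean: float) -> float:
    """Raw copy-number ratio: mean mtDNA depth / mean nuclear depth."""
    if nuc_mean <= 0:
        raise ValueError("nuclear mean depth must be > 0; sample unusable")
    return mt_mean / nuc_mean


def cohort_normalize(ratios) -> np.ndarray:
    """Inverse-normal transform of raw coverage ratios across a cohort."""
    return inverse_normal_transform(np.asarray(ratios, dtype=float))


def coverage_table(
    depth_by_sample: dict[str, dict[str, DepthProfile]],
    mt_name: str = "MT",
    nuc_name: str = "NUC",
) -> pd.DataFrame:
    """Build the per-sample coverage table (mt mean, nuclear mean, ratio,
    normalized score) from per-sample depth profiles keyed by chromosome."""
    rows = []
    for sid, profiles in depth_by_sample.items():
        if mt_name not in profiles or nuc_name not in profiles:
            raise ValueError(f"sample {sid}: missing {mt_name} or {nuc_name} profile")
        mt = region_mean_depth(profiles[mt_name])
        nuc = region_mean_depth(profiles[nuc_name])
        rows.append({"sample_id": sid, "mt_mean": mt, "nuc_mean": nuc,
                     "ratio": coverage_cn(mt, nuc)})
    df = pd.DataFrame(rows)
    if len(df) >= 2 and df["ratio"].nunique() > 1:
        df["cn_normalized"] = cohort_normalize(df["ratio"].to_numpy())
    else:
        df["cn_normalized"] = np.nan
    return df


def _depth_dir_or_file(path) -> dict[str, dict[str, DepthProfile]]:
    """Load depth TSVs: a directory of per-sample ``<sample>.tsv`` files,
    or one 4-column (sample_id, chrom, pos, depth) TSV."""
    path = Path(path)
    if path.is_dir():
        return {p.stem: read_depth_tsv(p) for p in sorted(path.glob("*.tsv"))}
    probe = pd.read_csv(path, sep="\t", header=None, nrows=1)
    if probe.shape[1] == 4:
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["sample_id", "chrom", "pos", "depth"],
                         dtype={"sample_id": str, "chrom": str})
        out: dict[str, dict[str, DepthProfile]] = {}
        for sid, sub in df.groupby("sample_id", sort=False):
            profiles = {}
            for chrom, csub in sub.groupby("chrom", sort=False):
                end = int(csub["pos"].max())
                depths = np.zeros(end, dtype=np.int64)
                depths[csub["pos"].to_numpy(dtype=int) - 1] = csub["depth"].to_numpy(dtype=int)
                profiles[chrom] = DepthProfile(chrom, 1, end, depths)
            out[sid] = profiles
        return out
    return {"sample": read_depth_tsv(path)}
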