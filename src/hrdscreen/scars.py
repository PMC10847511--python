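"""Genomic scar scores: TAI, LST, genomic LOH and their sum (the HRD score).

The three components quantify the chromosomal footprint of homologous
recombination deficiency on an allele-specific copy-number profile:

* **LOH** — number of loss-of-heterozygosity segments (minor allele copy
  number 0, total copy number >= 1) longer than ``loh_min_len`` that do not
  span an entire chromosome.
* **TAI** — number of allelically imbalanced segments (major != minor copy
  number) of length >= ``tai_min_len`` that reach a chromosome end (within
  ``telomere_tolerance``) without extending into the centromere interval.
* **LST** — after removing segments shorter than ``lst_smooth_len`` from each
  chromosome arm and fusing same-state neighbours whose gap is at most
  ``lst_smooth_len``, the number of state transitions between adjacent
  segments that are each >= ``lst_min_seg`` long and separated by at most
  ``lst_smooth_len``. A segment's state is its (total_cn, minor_cn) pair;
  segments crossing the centromere contribute their clipped p- and q-arm
  parts separately.

The HRD score is the plain sum TAI + LST + LOH; no dichotomisation at a
clinical cutoff is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import pandas as pd

from .genome import AlleleSpecificSegment, ChromosomeArmTable, SegmentProfile


@dataclass(frozen=True)
class ScarConfig:
    """Length constants (bp) for the three scar components."""

    loh_min_len: int = 15_000_000
    tai_min_len: int = 11_000_000
    lst_min_seg: int = 10_000_000
    lst_smooth_len: int = 3_000_000
    telomere_tolerance: int = 0

    @classmethod
    def from_mapping(cls, mapping: dict | None) -> "ScarConfig":
        if not mapping:
            return cls()
        return cls(**{k: int(v) for k, v in mapping.items()})


@dataclass(frozen=True)
class ScarResult:
    sample_id: str
    tai: int
    lst: int
    loh: int

    @property
    def hrd_score(self) -> int:
        return self.tai + self.lst + self.loh


def _spans_whole_chromosome(
    seg: AlleleSpecificSegment, chrom_length: int, tol: int
) -> bool:
    return seg.start <= 1 + tol and seg.end >= chrom_length - tol


def _touches_telomere(seg: AlleleSpecificSegment, chrom_length: int, tol: int) -> bool:
    return seg.start <= 1 + tol or seg.end >= chrom_length - tol


def _crosses_centromere(seg: AlleleSpecificSegment, cen: tuple[int, int]) -> bool:
    cen_start, cen_end = cen
    return seg.start < cen_end and seg.end > cen_start


def compute_loh(
    profile: SegmentProfile,
    arms: ChromosomeArmTable,
    min_len: int = 15_000_000,
    telomere_tolerance: int = 0,
) -> int:
    """Count LOH segments: b_cn = 0, total_cn >= 1, length > ``min_len``,
    excluding segments spanning a whole chromosome."""
    count = 0
    for seg in profile.segments:
        if seg.b_cn != 0 or seg.total_cn < 1 or seg.length <= min_len:
            continue
        if _spans_whole_chromosome(seg, arms.length(seg.chromosome), telomere_tolerance):
            continue
        count += 1
    return count


def compute_tai(
    profile: SegmentProfile,
    arms: ChromosomeArmTable,
    min_len: int = 11_000_000,
    telomere_tolerance: int = 0,
) -> int:
    """Count telomeric allelic-imbalance segments: imbalanced, length >=
    ``min_len``, reaching a chromosome end, not extending into the
    centromere interval."""
    count = 0
    for seg in profile.segments:
        if not seg.imbalanced or seg.length < min_len:
            continue
        if not _touches_telomere(seg, arms.length(seg.chromosome), telomere_tolerance):
            continue
        if _crosses_centromere(seg, arms.centromere(seg.chromosome)):
            continue
        count += 1
    return count


def _clip_to_arm(
    segments: Iterable[AlleleSpecificSegment], arm_start: int, arm_end: int
) -> list[AlleleSpecificSegment]:
    clipped = []
    for seg in segments:
        start, end = max(seg.start, arm_start), min(seg.end, arm_end)
        if start <= end:
            clipped.append(replace(seg, start=start, end=end))
    return clipped


def _fuse_same_state(
    segments: list[AlleleSpecificSegment], max_gap: int
) -> list[AlleleSpecificSegment]:
    fused: list[AlleleSpecificSegment] = []
    for seg in segments:
        if (
            fused
            and fused[-1].state == seg.state
            and seg.start - fused[-1].end - 1 <= max_gap
        ):
            fused[-1] = replace(fused[-1], end=seg.end)
        else:
            fused.append(seg)
    return fused


def compute_lst(
    profile: SegmentProfile,
    arms: ChromosomeArmTable,
    min_seg: int = 10_000_000,
    smooth_len: int = 3_000_000,
) -> int:
    """Count large-scale state transitions, genome-wide, one arm at a time."""
    count = 0
    for chrom in arms.chromosomes:
        chrom_segs = profile.chromosome_segments(chrom)
        if not chrom_segs:
            continue
        for _, arm_start, arm_end in arms.arm_intervals(chrom):
            segs = _clip_to_arm(chrom_segs, arm_start, arm_end)
            segs = [s for s in segs if s.length >= smooth_len]
            segs = _fuse_same_state(segs, smooth_len)
            for left, right in zip(segs, segs[1:]):
                gap = right.start - left.end - 1
                if (
                    gap <= smooth_len
                    and left.state != right.state
                    and left.length >= min_seg
                    and right.length >= min_seg
                ):
                    count += 1
    return count


def compute_hrd_score(
    profile: SegmentProfile,
    arms: ChromosomeArmTable,
    config: ScarConfig | None = None,
) -> ScarResult:
    """TAI + LST + LOH under the supplied constants."""
    cfg = config or ScarConfig()
    return ScarResult(
        sample_id=profile.sample_id,
        tai=compute_tai(profile, arms, cfg.tai_min_len, cfg.telomere_tolerance),
        lst=compute_lst(profile, arms, cfg.lst_min_seg, cfg.lst_smooth_len),
        loh=compute_loh(profile, arms, cfg.loh_min_len, cfg.telomere_tolerance),
    )


def score_cohort(
    profiles: Iterable[SegmentProfile],
    arms: ChromosomeArmTable,
    config: ScarConfig | None = None,
) -> pd.DataFrame:
    """Per-sample scar table with columns sample_id, TAI, LST, LOH, HRD_score."""
    rows = []
    for profile in profiles:
        res = compute_hrd_score(profile, arms, config)
        rows.append(
            {
                "sample_id": res.sample_id,
                "TAI": res.tai,
                "LST": res.lst,
                "LOH": res.loh,
                "HRD_score": res.hrd_score,
            }
        )
    return pd.DataFrame(rows, columns=["sample_id", "TAI", "LST", "LOH", "HRD_score"])
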