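"""Per-tumor 96-class mutation context spectra from somatic SNV calls.

Converts somatic single-nucleotide variants into counts over the 96
pyrimidine-normalized trinucleotide substitution classes, restricted to the
capture (panel) region.  Purine-reference SNVs are reverse-complemented into
their pyrimidine class, the field-standard normalization.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .catalog import CANONICAL_CLASSES, CLASS_INDEX, class_label

logger = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
PURINES = frozenset("AG")


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))


@dataclass(frozen=True)
class SomaticVariant:
    """One somatic call.  ``pos`` is 1-based (VCF convention)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    depth: int | None = None
    vaf: float | None = None

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        if self.vaf is not None and not (0.0 <= self.vaf <= 1.0):
            raise ValueError(f"VAF {self.vaf} outside [0,1] at {self.chrom}:{self.pos}")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1 and self.ref in "ACGT" and self.alt in "ACGT"


@dataclass(frozen=True)
class ContextSpectrum:
    """Counts per substitution class; ``n_snv`` is their total."""

    counts: np.ndarray  # shape (96,), non-negative integers

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (96,):
            raise ValueError("spectrum must have exactly 96 classes")
        if (c < 0).any() or not np.allclose(c, np.round(c)):
            raise ValueError("spectrum counts must be non-negative integers")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @property
    def n_snv(self) -> int:
        return int(self.counts.sum())

    def as_series(self):
        import pandas as pd

        return pd.Series(self.counts, index=list(CANONICAL_CLASSES), name="count")

    def __add__(self, other: "ContextSpectrum") -> "ContextSpectrum":
        return ContextSpectrum(self.counts + other.counts)

    @classmethod
    def zeros(cls) -> "ContextSpectrum":
        return cls(np.zeros(96, dtype=np.int64))

    @classmethod
    def from_mapping(cls, counts: Mapping[str, int]) -> "ContextSpectrum":
        arr = np.zeros(96, dtype=np.int64)
        for label, n in counts.items():
            arr[CLASS_INDEX[label]] = n
        return cls(arr)


class ReferenceMismatchError(ValueError):
    """A variant's REF allele disagrees with the reference FASTA base."""


@dataclass
class CaptureRegion:
    """BED intervals (0-based half-open) with point-membership queries.

    All 1-based-VCF to 0-based-BED conversion is funnelled through
    :meth:`contains` to keep the off-by-one logic in one place.
    """

    intervals: dict[str, list[tuple[int, int]]]

    @classmethod
    def from_bed(cls, path: str | Path) -> "CaptureRegion":
        intervals: dict[str, list[tuple[int, int]]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                intervals.setdefault(chrom, []).append((start, end))
        for chrom in intervals:
            intervals[chrom] = sorted(intervals[chrom])
        return cls(intervals)

    @classmethod
    def from_intervals(cls, intervals: Iterable[tuple[str, int, int]]) -> "CaptureRegion":
        d: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            d.setdefault(chrom, []).append((int(start), int(end)))
        for chrom in d:
            d[chrom] = sorted(d[chrom])
        return cls(d)

    def contains(self, chrom: str, pos_1based: int) -> bool:
        ivs = self.intervals.get(chrom)
        if not ivs:
            return False
        p = pos_1based - 1  # 0-based point
        i = bisect_right(ivs, (p, float("inf"))) - 1
        return i >= 0 and ivs[i][0] <= p < ivs[i][1]

    def total_bases(self) -> int:
        return sum(e - s for ivs in self.intervals.values() for s, e in ivs)


def _fetch_triplet(reference, chrom: str, pos: int) -> str | None:
    """Reference bases at pos-1..pos+1 (1-based), or None near contig edges."""
    if pos < 2:
        return None
    seq = str(reference[chrom][pos - 2 : pos + 1]).upper()
    if len(seq) < 3:
        return None
    return seq


def count_contexts(
    variants: Sequence[SomaticVariant],
    reference,
    capture: CaptureRegion | None = None,
) -> ContextSpectrum:
    """Count SNVs into the 96 pyrimidine-normalized classes.

    Parameters
    ----------
    variants : sequence of SomaticVariant
    reference : pyfaidx.Fasta (or any mapping of contig -> sliceable sequence)
    capture : optional panel region; SNVs outside it are not counted.

    Non-SNVs and SNVs with ambiguous (N) flanking bases are excluded with a
    logged count.  A REF allele disagreeing with the FASTA base raises
    :class:`ReferenceMismatchError` — it signals a genome-build mismatch.
    """
    counts = np.zeros(96, dtype=np.int64)
    n_non_snv = n_outside = n_ambiguous = 0
    for v in variants:
        if not v.is_snv:
            n_non_snv += 1
            continue
        if capture is not None and not capture.contains(v.chrom, v.pos):
            n_outside += 1
            continue
        triplet = _fetch_triplet(reference, v.chrom, v.pos)
        if triplet is None or "N" in triplet:
            n_ambiguous += 1
            continue
        if triplet[1] != v.ref:
            raise ReferenceMismatchError(
                f"{v.chrom}:{v.pos} REF={v.ref} but reference FASTA has {triplet[1]}"
            )
        ref, alt = v.ref, v.alt
        if ref in PURINES:
            triplet = revcomp(triplet)
            ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
        label = class_label(triplet[0], ref, alt, triplet[2])
        counts[CLASS_INDEX[label]] += 1
    if n_non_snv or n_outside or n_ambiguous:
        logger.info(
            "count_contexts excluded %d non-SNV, %d off-capture, %d ambiguous-flank calls",
            n_non_snv, n_outside, n_ambiguous,
        )
    return ContextSpectrum(counts)


def filter_calls(
    variants: Sequence[SomaticVariant],
    min_depth: int = 25,
    min_vaf: float = 0.10,
    permit_unannotated: bool = False,
) -> list[SomaticVariant]:
    """Apply the depth/VAF call filter.

    Variants lacking depth or VAF annotations pass only when
    ``permit_unannotated`` is set; otherwise they are dropped with a logged
    count.
    """
    if min_depth < 0 or min_vaf < 0:
        raise ValueError("filter thresholds must be non-negative")
    kept: list[SomaticVariant] = []
    n_unannotated = 0
    for v in variants:
        unannotated = (min_depth > 0 and v.depth is None) or (min_vaf > 0 and v.vaf is None)
        if unannotated:
            n_unannotated += 1
            if permit_unannotated:
                kept.append(v)
            continue
        if v.depth is not None and v.depth < min_depth:
            continue
        if v.vaf is not None and v.vaf < min_vaf:
            continue
        kept.append(v)
    if n_unannotated:
        logger.info(
            "filter_calls: %d calls lacked depth/VAF annotations (%s)",
            n_unannotated, "kept" if permit_unannotated else "excluded",
        )
    return kept


def read_somatic_vcf(path: str | Path, sample: str | int | None = None) -> list[SomaticVariant]:
    """Read somatic calls from a VCF (v4.2, plain or bgzipped) via cyvcf2.

    Multi-allelic records are split; each ALT becomes its own variant.  Depth
    is taken from FORMAT/DP (falling back to the AD sum, then INFO/DP) and the
    VAF from FORMAT/AD when present, else from FORMAT/AF or INFO/AF; calls
    without usable annotations carry ``depth=None`` / ``vaf=None``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_idx: int | None
    if sample is None:
        sample_idx = 0 if vcf.samples else None
    elif isinstance(sample, int):
        sample_idx = sample
    else:
        sample_idx = vcf.samples.index(sample)

    out: list[SomaticVariant] = []
    for rec in vcf:
        for alt_i, alt in enumerate(rec.ALT):
            depth = None
            vaf = None
            if sample_idx is not None:
                try:
                    ad = rec.format("AD")
                except KeyError:
                    ad = None
                if ad is not None:
                    row = ad[sample_idx]
                    total = int(np.sum(row[row >= 0]))
                    alt_reads = int(row[alt_i + 1]) if len(row) > alt_i + 1 else 0
                    if total > 0:
                        depth = total
                        vaf = alt_reads / total
                try:
                    dp = rec.format("DP")
                except KeyError:
                    dp = None
                if dp is not None and depth is None:
                    d = int(dp[sample_idx][0])
                    if d >= 0:
                        depth = d
                if vaf is None:
                    try:
                        af = rec.format("AF")
                    except KeyError:
                        af = None
                    if af is not None:
                        a = float(af[sample_idx][alt_i if af.shape[1] > alt_i else 0])
                        if a >= 0:
                            vaf = a
            if depth is None and rec.INFO.get("DP") is not None:
                depth = int(rec.INFO["DP"])
            if vaf is None and rec.INFO.get("AF") is not None:
                info_af = rec.INFO["AF"]
                vaf = float(info_af[alt_i] if isinstance(info_af, tuple) else info_af)
            out.append(SomaticVariant(rec.CHROM, rec.POS, rec.REF, str(alt), depth=depth, vaf=vaf))
    return out
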