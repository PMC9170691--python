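"""Loss-of-heterozygosity detection across MUTYH from paired calls.

A germline-heterozygous site whose tumor VAF has shifted to (near-)homozygosity
supports allelic loss.  LOH over the gene is called when enough supporting
sites overlap or flank the gene interval with no still-heterozygous site
between them.  The VAF bands and support requirements are a configurable
reconstruction of the standard paired-sample approach.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .spectrum import SomaticVariant

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LohConfig:
    """VAF bands and support requirements.

    A site is informative when the germline VAF lies in ``[het_lo, het_hi]``
    at depth >= ``min_depth``; it supports loss when the tumor VAF is
    >= ``hom_hi`` or <= ``hom_lo``.  ``near_gene_window`` (bp) bounds the
    flanking region reported around the gene.
    """

    het_lo: float = 0.3
    het_hi: float = 0.7
    hom_lo: float = 0.1
    hom_hi: float = 0.9
    min_depth: int = 25
    min_support: int = 2
    near_gene_window: int = 100_000


@dataclass(frozen=True)
class GeneInterval:
    chrom: str
    start: int  # 0-based half-open
    end: int


@dataclass(frozen=True)
class LohCall:
    has_loh: bool
    informative_sites: int
    supporting_sites: int
    region: tuple[str, int, int] | None  # supporting run (contig, start, end), 1-based inclusive
    near_gene_sites: int

    def __post_init__(self) -> None:
        if self.supporting_sites > self.informative_sites:
            raise ValueError("supporting sites cannot exceed informative sites")


def _orient(vaf: float) -> float:
    """Fold VAF so ref/alt orientation is irrelevant (v and 1-v equivalent)."""
    return min(vaf, 1.0 - vaf)


def detect_loh(
    germline: list[SomaticVariant],
    somatic: list[SomaticVariant],
    gene: GeneInterval,
    config: LohConfig | None = None,
) -> LohCall:
    """Call LOH over ``gene`` from paired germline/tumor variants with VAFs.

    Sites are matched on (chrom, pos, ref, alt).  The supporting run is the
    maximal block of consecutive informative sites around the gene that all
    shifted to homozygosity; a still-heterozygous informative site inside the
    block contradicts and truncates it.
    """
    config = config or LohConfig()
    tumor_at = {(v.chrom, v.pos, v.ref, v.alt): v for v in somatic}
    sites: list[tuple[int, bool]] = []  # (pos, supporting) for informative sites on gene contig
    n_informative = 0
    for g in germline:
        key = (g.chrom, g.pos, g.ref, g.alt)
        t = tumor_at.get(key)
        if t is None or g.vaf is None or t.vaf is None:
            continue
        if g.depth is not None and g.depth < config.min_depth:
            continue
        # folded VAFs make informative/supporting status invariant to ref/alt
        # orientation (v and 1-v are the same site read the other way)
        if _orient(g.vaf) < max(config.het_lo, 1.0 - config.het_hi):
            continue
        n_informative += 1
        supporting = _orient(t.vaf) <= min(config.hom_lo, 1.0 - config.hom_hi)
        if g.chrom == gene.chrom:
            sites.append((g.pos, supporting))
    if n_informative == 0:
        logger.warning("no shared informative sites between germline and tumor call sets")
        return LohCall(False, 0, 0, None, 0)

    sites.sort()
    n_supporting = sum(1 for _, s in sites if s)

    # maximal contradiction-free run of supporting sites containing/flanking the gene
    best_run: list[int] = []
    run: list[int] = []
    for pos, supporting in sites:
        if supporting:
            run.append(pos)
        else:
            if _run_touches_gene(run, gene) and len(run) > len(best_run):
                best_run = run
            run = []
    if _run_touches_gene(run, gene) and len(run) > len(best_run):
        best_run = run

    has_loh = len(best_run) >= config.min_support
    region = (gene.chrom, best_run[0], best_run[-1]) if best_run else None
    near = sum(
        1
        for pos, s in sites
        if s and (gene.start - config.near_gene_window) < pos <= (gene.end + config.near_gene_window)
    )
    return LohCall(has_loh, n_informative, n_supporting, region, near)


def _run_touches_gene(run: list[int], gene: GeneInterval) -> bool:
    """A run counts when it overlaps the gene or straddles/flanks it."""
    if not run:
        return False
    lo, hi = run[0], run[-1]
    return hi > gene.start and lo <= gene.end or any(gene.start < p <= gene.end for p in run) or (
        lo <= gene.start and hi > gene.end
    )
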