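"""Germline/somatic MUTYH variant grading, tumor categorization, and
VUS-reclassification evidence.

Variants are graded pathogenic (ClinVar pathogenic / likely pathogenic),
potentially pathogenic (ClinVar VUS or conflicting, or absent from ClinVar
with an in-silico score above threshold: CADD > 20.0 or REVEL > 0.6), or not
retained.  Tumors are then assigned to one of five mutually exclusive groups
based on carried alleles; for tumors in the potential-biallelic group the
signature classifier's verdict is turned into per-VUS reclassification
evidence.

Phase cannot be resolved from panel data: two heterozygous variants are
treated as trans (biallelic candidates), and reports carry the cis caveat.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

from .classifier import MutyhCall

CIS_CAVEAT = (
    "two heterozygous variants are assumed in trans; the possibility that "
    "they lie on the same allele (cis) cannot be excluded from panel data"
)


class ClinVarClass(str, Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    VUS = "vus"
    CONFLICTING = "conflicting"
    BENIGN = "benign"
    ABSENT = "absent"


class Grade(str, Enum):
    PATHOGENIC = "pathogenic"
    POTENTIALLY_PATHOGENIC = "potentially_pathogenic"
    NOT_RETAINED = "not_retained"


class MutyhCategory(str, Enum):
    POSITIVE = "positive"
    MONOALLELIC = "monoallelic"
    NEGATIVE = "negative"
    POTENTIAL_BIALLELIC = "potential_biallelic"
    UNCERTAIN = "uncertain"


class Evidence(str, Enum):
    SUPPORTS_PATHOGENIC = "supports_pathogenic"
    SUPPORTS_BENIGN = "supports_benign"
    NONE = "none"


@dataclass(frozen=True)
class VariantAnnotation:
    """One annotated MUTYH variant (transcript NM_001128425.1)."""

    hgvs_c: str
    hgvs_p: str | None = None
    clinvar: ClinVarClass = ClinVarClass.ABSENT
    cadd: float | None = None
    revel: float | None = None
    gnomad_af: float | None = None
    zygosity: str = "het"  # het | hom
    origin: str = "germline"  # germline | somatic

    def __post_init__(self) -> None:
        if self.revel is not None and not (0.0 <= self.revel <= 1.0):
            raise ValueError(f"REVEL {self.revel} outside [0,1] for {self.hgvs_c}")
        if self.zygosity not in ("het", "hom"):
            raise ValueError(f"zygosity must be het or hom, got {self.zygosity!r}")
        if self.origin not in ("germline", "somatic"):
            raise ValueError(f"origin must be germline or somatic, got {self.origin!r}")

    @property
    def name(self) -> str:
        return f"{self.hgvs_c} {self.hgvs_p}" if self.hgvs_p else self.hgvs_c


@dataclass(frozen=True)
class GradedVariant:
    variant: VariantAnnotation
    grade: Grade

    @property
    def alleles(self) -> int:
        return 2 if self.variant.zygosity == "hom" else 1


CADD_THRESHOLD = 20.0
REVEL_THRESHOLD = 0.6


def grade_variant(
    v: VariantAnnotation,
    cadd_threshold: float = CADD_THRESHOLD,
    revel_threshold: float = REVEL_THRESHOLD,
) -> GradedVariant:
    """Grade one variant from its ClinVar class and in-silico scores."""
    if v.clinvar in (ClinVarClass.PATHOGENIC, ClinVarClass.LIKELY_PATHOGENIC):
        g = Grade.PATHOGENIC
    elif v.clinvar in (ClinVarClass.VUS, ClinVarClass.CONFLICTING):
        g = Grade.POTENTIALLY_PATHOGENIC
    elif v.clinvar is ClinVarClass.ABSENT and (
        (v.cadd is not None and v.cadd > cadd_threshold)
        or (v.revel is not None and v.revel > revel_threshold)
    ):
        g = Grade.POTENTIALLY_PATHOGENIC
    else:
        g = Grade.NOT_RETAINED
    return GradedVariant(v, g)


def categorize(
    germline: Sequence[GradedVariant],
    somatic: Sequence[GradedVariant] = (),
) -> MutyhCategory:
    """Assign one of the five study categories from graded variants.

    Order-independent in the inputs.  Positivity (two pathogenic alleles)
    requires germline carriership; any other combination of two or more
    retained alleles is a potential biallelic.
    """
    for v in somatic:
        if v.variant.origin != "somatic":
            raise ValueError(f"somatic list contains {v.variant.origin} variant {v.variant.name}")
    for v in germline:
        if v.variant.origin != "germline":
            raise ValueError(f"germline list contains {v.variant.origin} variant {v.variant.name}")

    germ_retained = [v for v in germline if v.grade is not Grade.NOT_RETAINED]
    som_retained = [v for v in somatic if v.grade is not Grade.NOT_RETAINED]
    germ_path_alleles = sum(v.alleles for v in germ_retained if v.grade is Grade.PATHOGENIC)
    total_alleles = sum(v.alleles for v in germ_retained) + sum(v.alleles for v in som_retained)

    if germ_path_alleles >= 2:
        return MutyhCategory.POSITIVE
    if total_alleles == 0:
        return MutyhCategory.NEGATIVE
    if total_alleles >= 2:
        return MutyhCategory.POTENTIAL_BIALLELIC
    # exactly one retained allele
    only = (germ_retained + som_retained)[0]
    if only.variant.origin == "germline" and only.grade is Grade.PATHOGENIC:
        return MutyhCategory.MONOALLELIC
    return MutyhCategory.UNCERTAIN


@dataclass(frozen=True)
class VusEvidence:
    variant: VariantAnnotation
    evidence: Evidence
    unresolvable: bool = False  # among >=2 VUS only one may be the pathogenic allele
    note: str = ""


def reclassification_evidence(
    category: MutyhCategory,
    call: MutyhCall,
    variants: Sequence[GradedVariant],
) -> list[VusEvidence]:
    """Per-VUS reclassification evidence for a potential-biallelic tumor.

    A positive signature call alongside exactly one VUS (and a pathogenic
    allele) supports pathogenicity of that VUS; with two or more VUS the
    support is flagged unresolvable among them.  A negative call supports a
    benign classification only when backed by adequate evidence — a
    reconstruction error already below the error threshold or an adjusted
    mutation count reaching the count threshold — otherwise no evidence is
    emitted.
    """
    if category is not MutyhCategory.POTENTIAL_BIALLELIC:
        raise ValueError("reclassification evidence applies to potential-biallelic tumors only")
    vus = [v for v in variants if v.grade is Grade.POTENTIALLY_PATHOGENIC]
    has_pathogenic = any(v.grade is Grade.PATHOGENIC for v in variants)
    out: list[VusEvidence] = []
    if call.positive:
        if has_pathogenic and len(vus) == 1:
            out.append(VusEvidence(vus[0].variant, Evidence.SUPPORTS_PATHOGENIC, note=CIS_CAVEAT))
        elif len(vus) >= 2:
            for v in vus:
                out.append(
                    VusEvidence(
                        v.variant,
                        Evidence.SUPPORTS_PATHOGENIC,
                        unresolvable=True,
                        note="one of these VUS is likely pathogenic; which one cannot "
                        "be resolved from this tumor. " + CIS_CAVEAT,
                    )
                )
        else:
            out.extend(VusEvidence(v.variant, Evidence.NONE) for v in vus)
    else:
        adequate = (call.error_pct < 39.0) or (call.adjusted_snv >= 9.0)
        ev = Evidence.SUPPORTS_BENIGN if adequate else Evidence.NONE
        note = "" if adequate else "negative call lacks adequate evidence (high error and low count)"
        out.extend(VusEvidence(v.variant, ev, note=note) for v in vus)
    return out
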