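"""Somatic-landscape statistics: TMB and hypermutation classes, Fisher
enrichment, exact binomial tests and confidence intervals, summary-statistic
t-tests, per-mutation SBS18/36 relative likelihood, and the two-hotspot rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .catalog import BER_SIGNATURES, CLASS_INDEX, SignatureCatalog
from .refit import ExposureSolution

logger = logging.getLogger(__name__)

HYPERMUTATED_TMB = 10.0  # mutations/Mb, strict
ULTRA_TMB = 100.0

#: The two somatic hotspot mutations enriched in biallelic MUTYH carriers,
#: both in C>A contexts characteristic of SBS18/SBS36.
HOTSPOTS = {("KRAS", "p.G12C"), ("PIK3CA", "p.Q546K")}


@dataclass(frozen=True)
class TumorMetrics:
    """Mutational burden (SNVs + indels per Mb) and hypermutation class."""

    tmb: float
    hyper_class: str  # normal | hypermutated | ultra
    msi_status: str | None = None  # externally supplied MSS/MSI flag


def tmb(n_snv: int, n_indel: int, capture_mb: float, msi_status: str | None = None) -> TumorMetrics:
    """Tumor mutational burden with strict >10 / >100 per-Mb class thresholds."""
    if capture_mb <= 0:
        raise ValueError("capture_mb must be positive")
    burden = (n_snv + n_indel) / capture_mb
    if burden > ULTRA_TMB:
        cls = "ultra"
    elif burden > HYPERMUTATED_TMB:
        cls = "hypermutated"
    else:
        cls = "normal"
    return TumorMetrics(tmb=burden, hyper_class=cls, msi_status=msi_status)


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 carrier/feature table: a,b = carriers with/without the feature,
    c,d = non-carriers with/without."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if (self.a + self.b) == 0 or (self.c + self.d) == 0 or (self.a + self.c) == 0 or (self.b + self.d) == 0:
            raise ValueError("all margins must be positive for exact testing")


def fisher_enrichment(t: ContingencyTable) -> float:
    """Two-sided Fisher's exact p-value (hypergeometric, sum of probabilities
    no larger than the observed table's)."""
    return float(stats.fisher_exact([[t.a, t.b], [t.c, t.d]], alternative="two-sided")[1])


def hypermutation_binomial(k: int, n: int, baseline: float) -> float:
    """One-sided (greater) exact binomial tail P(X >= k | n, baseline)."""
    if not (0 <= k <= n):
        raise ValueError("need 0 <= k <= n")
    if not (0 < baseline < 1):
        raise ValueError("baseline must be in (0,1)")
    return float(stats.binomtest(k, n, baseline, alternative="greater").pvalue)


def clopper_pearson(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact (Beta-quantile) binomial confidence interval, in percent.

    For k = n the lower bound is (alpha/2)^(1/n) and the upper bound 100%.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if not (0 <= k <= n):
        raise ValueError("need 0 <= k <= n")
    alpha = 1.0 - conf
    lo = stats.beta.ppf(alpha / 2, k, n - k + 1) if k > 0 else 0.0
    hi = stats.beta.ppf(1 - alpha / 2, k + 1, n - k) if k < n else 1.0
    return float(lo) * 100.0, float(hi) * 100.0


def summary_ttest(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float]:
    """Two-sided pooled-variance two-sample t-test from summary statistics."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    res = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=True, alternative="two-sided"
    )
    return float(res.statistic), float(res.pvalue)


def relative_likelihood(
    mutation_class: str,
    solution: ExposureSolution,
    catalog: SignatureCatalog,
    targets: Iterable[str] = BER_SIGNATURES,
) -> float:
    """Posterior probability that a mutation in the given context arose from
    the target signatures, given refitted exposures.

    ``sum_{s in targets} e_s M[c,s] / sum_s e_s M[c,s]``; defined as 0 (with
    a warning) when the context is impossible under every active signature.
    """
    targets = set(targets)
    row = CLASS_INDEX[mutation_class]
    num = den = 0.0
    for name, e in solution.exposures.items():
        mass = e * float(catalog.profiles.iloc[row][name])
        den += mass
        if name in targets:
            num += mass
    if den == 0.0:
        logger.warning(
            "context %s has zero mass under all active signatures; relative likelihood set to 0",
            mutation_class,
        )
        return 0.0
    return num / den


def mean_relative_likelihood(
    mutation_classes: Sequence[str],
    solution: ExposureSolution,
    catalog: SignatureCatalog,
    targets: Iterable[str] = BER_SIGNATURES,
) -> float:
    """Cohort aggregation: mean relative likelihood over mutations."""
    if not mutation_classes:
        raise ValueError("need at least one mutation")
    vals = [relative_likelihood(c, solution, catalog, targets) for c in mutation_classes]
    return float(np.mean(vals))


def hotspot_rule(annotated_variants: Iterable[Mapping[str, str]]) -> bool:
    """True iff KRAS p.G12C or PIK3CA p.Q546K is present.

    Each variant is a mapping with at least ``gene`` and ``hgvs_p`` keys.
    """
    for v in annotated_variants:
        if (v.get("gene"), v.get("hgvs_p")) in HOTSPOTS:
            return True
    return False
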