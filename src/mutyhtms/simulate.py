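"""Seeded synthetic tumors, cohorts, catalogs and toy sequence bundles.

Everything here emulates the statistical structure the classifier assumes:
96-context spectra drawn from exposure mixtures at panel-scale mutation
counts (single digits to tens of SNVs), a small fraction of biallelic-like
tumors with dominant SBS18/36-like exposure, monoallelic/sporadic tumors
without it, and binomial panel down-sampling.  All randomness flows through
numpy Generators seeded explicitly; nothing reads global random state.

The 14-signature catalog produced by :func:`synthetic_catalog` is SYNTHETIC:
profiles are constructed deterministically to mimic the qualitative shape of
the published colorectal signature set (two similar C>A-dominated
base-excision-repair columns named SBS18/SBS36, a CpG C>T column, APOBEC-like
columns, flat background columns) — it is not the COSMIC catalog.  Supply a
real COSMIC v3.x TSV through :func:`mutyhtms.catalog.load_catalog` for real
data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .catalog import (
    BASES,
    CANONICAL_CLASSES,
    DEFAULT_CRC_SIGNATURES,
    SignatureCatalog,
)
from .interpretation import ClinVarClass, VariantAnnotation
from .spectrum import COMPLEMENT, ContextSpectrum, SomaticVariant, revcomp

_CATALOG_SEED = 20_220_606  # fixed: the catalog is a deterministic constant


def _profile_from_mask(rng: np.random.Generator, mask: np.ndarray, focus: float) -> np.ndarray:
    """Profile with `focus` of its mass spread (log-normally) over `mask`."""
    p = np.full(96, (1.0 - focus) / 96.0)
    w = rng.lognormal(0.0, 1.0, size=int(mask.sum()))
    p[mask] += focus * w / w.sum()
    return p / p.sum()


def _class_mask(substitution: str | None = None, three_prime: str | None = None) -> np.ndarray:
    mask = np.zeros(96, dtype=bool)
    for i, label in enumerate(CANONICAL_CLASSES):
        five, rest = label[0], label[2:]
        sub, three = rest[:3], rest[-1]
        if substitution is not None and sub != substitution:
            continue
        if three_prime is not None and three != three_prime:
            continue
        mask[i] = True
    return mask


def synthetic_catalog(names: Sequence[str] = DEFAULT_CRC_SIGNATURES) -> SignatureCatalog:
    """Deterministic synthetic stand-in for the reduced CRC signature set.

    SBS18 and SBS36 are C>A dominated and similar to each other (cosine
    similarity in the high 0.8s) but differ in specific flank contexts;
    SBS1 is CpG C>T; SBS2/SBS13 are APOBEC-like; remaining columns are
    smooth pseudo-random profiles.  Identical output on every call.
    """
    rng = np.random.default_rng(_CATALOG_SEED)
    ca = _class_mask("C>A")
    profiles: dict[str, np.ndarray] = {}

    w18 = _profile_from_mask(rng, ca, focus=0.92)
    # perturb the C>A emphasis to get a similar-but-distinct second BER column
    perturb = _profile_from_mask(rng, ca, focus=0.92)
    w36 = 0.65 * w18 + 0.35 * perturb
    profiles["SBS18"] = w18
    profiles["SBS36"] = w36 / w36.sum()
    profiles["SBS1"] = _profile_from_mask(rng, _class_mask("C>T", three_prime="G"), focus=0.9)
    profiles["SBS2"] = _profile_from_mask(rng, _class_mask("C>T"), focus=0.85)
    profiles["SBS13"] = _profile_from_mask(rng, _class_mask("C>G"), focus=0.85)
    for name in names:
        if name not in profiles:
            profiles[name] = _profile_from_mask(rng, np.ones(96, dtype=bool), focus=0.7)

    df = pd.DataFrame(
        {n: profiles[n] for n in names}, index=list(CANONICAL_CLASSES)
    )
    return SignatureCatalog(df)


def simulate_tumor(
    exposures: np.ndarray | dict[str, float],
    n_snv: int,
    catalog: SignatureCatalog,
    seed: int | np.random.Generator = 0,
) -> ContextSpectrum:
    """Draw ``counts ~ multinomial(n_snv, catalog . exposures)``."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if isinstance(exposures, dict):
        e = np.array([exposures.get(n, 0.0) for n in catalog.names])
    else:
        e = np.asarray(exposures, dtype=float)
    if (e < 0).any() or abs(e.sum() - 1.0) > 1e-9:
        raise ValueError("exposures must lie on the probability simplex")
    if n_snv < 0:
        raise ValueError("n_snv must be non-negative")
    p = catalog.matrix @ e
    return ContextSpectrum(rng.multinomial(int(n_snv), p / p.sum()))


def thin_spectrum(
    spectrum: ContextSpectrum, fraction: float, seed: int | np.random.Generator = 0
) -> ContextSpectrum:
    """Binomial down-sampling: each mutation kept independently with ``fraction``.

    Emulates intersecting exome-scale calls with a small capture panel.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1.0:
        return spectrum
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return ContextSpectrum(rng.binomial(spectrum.counts, fraction))


# --- germline variant vocabulary: real MUTYH HGVS names with annotations as
# --- printed in the study's potential-biallelic table, used as fixtures so the
# --- interpretation stage sees realistic inputs
PATHOGENIC_VOCAB = (
    VariantAnnotation("c.536A>G", "p.Y179C", ClinVarClass.PATHOGENIC, cadd=24.7, revel=0.963, gnomad_af=0.001),
    VariantAnnotation("c.1187G>A", "p.G396D", ClinVarClass.PATHOGENIC, cadd=29.4, revel=0.551, gnomad_af=0.003),
)
VUS_VOCAB = (
    VariantAnnotation("c.1141G>T", "p.G381W", ClinVarClass.VUS, cadd=23.8, revel=0.521),
    VariantAnnotation("c.1276C>T", "p.R426C", ClinVarClass.VUS, cadd=22.9, revel=0.615, gnomad_af=0.001),
    VariantAnnotation("c.912C>G", "p.S304R", ClinVarClass.VUS, cadd=12.8, revel=0.229, gnomad_af=3e-5),
    VariantAnnotation("c.925C>T", "p.R309C", ClinVarClass.VUS, cadd=13.9, revel=0.592, gnomad_af=5.4e-4),
)


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a synthetic cohort.

    Biallelic-like tumors draw their combined SBS18/36 exposure weight from
    U[0.55, 0.95] and mutation counts uniformly from 9..32; sporadic (and
    monoallelic) tumors draw the weight from U[0, 0.25] and counts from 1..12,
    the low-count regime where panel false positives arise.
    """

    n_tumors: int = 100
    fraction_biallelic: float = 0.1
    fraction_monoallelic: float = 0.0
    biallelic_weight: tuple[float, float] = (0.55, 0.95)
    sporadic_weight: tuple[float, float] = (0.0, 0.25)
    biallelic_snv: tuple[int, int] = (9, 32)
    sporadic_snv: tuple[int, int] = (1, 12)
    panel_mb: float = 1.34
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.fraction_biallelic <= 1) or not (0 <= self.fraction_monoallelic <= 1):
            raise ValueError("class fractions must lie in [0,1]")
        if self.fraction_biallelic + self.fraction_monoallelic > 1:
            raise ValueError("class fractions must sum to at most 1")
        if self.biallelic_snv[0] < 1 or self.sporadic_snv[0] < 1:
            raise ValueError("every simulated tumor needs at least one SNV (inclusion rule)")


@dataclass(frozen=True)
class TumorDossier:
    """One synthetic tumor with its ground truth."""

    tumor_id: str
    spectrum: ContextSpectrum
    panel_mb: float
    germline_variants: tuple[VariantAnnotation, ...]
    truth_class: str  # biallelic | monoallelic | sporadic
    true_exposures: dict[str, float]

    @property
    def true_sbs18_36(self) -> float:
        return 100.0 * (self.true_exposures.get("SBS18", 0.0) + self.true_exposures.get("SBS36", 0.0))


def _draw_exposures(
    rng: np.random.Generator, catalog: SignatureCatalog, weight_range: tuple[float, float]
) -> dict[str, float]:
    names = catalog.names
    w = rng.uniform(*weight_range)
    r = rng.uniform()
    e = {n: 0.0 for n in names}
    e["SBS18"] = w * r
    e["SBS36"] = w * (1.0 - r)
    others = [n for n in names if n not in ("SBS18", "SBS36")]
    rest = rng.dirichlet(np.ones(len(others))) * (1.0 - w)
    for n, v in zip(others, rest):
        e[n] = float(v)
    return e


def simulate_cohort(
    config: CohortConfig, catalog: SignatureCatalog | None = None
) -> list[TumorDossier]:
    """Generate a labelled cohort; byte-identical for the same config."""
    catalog = catalog or synthetic_catalog()
    rng = np.random.default_rng(config.seed)
    dossiers: list[TumorDossier] = []
    for i in range(config.n_tumors):
        u = rng.uniform()
        if u < config.fraction_biallelic:
            cls = "biallelic"
        elif u < config.fraction_biallelic + config.fraction_monoallelic:
            cls = "monoallelic"
        else:
            cls = "sporadic"
        if cls == "biallelic":
            exposures = _draw_exposures(rng, catalog, config.biallelic_weight)
            n_snv = int(rng.integers(config.biallelic_snv[0], config.biallelic_snv[1] + 1))
            if rng.uniform() < 0.5:
                germ = (replace(PATHOGENIC_VOCAB[int(rng.integers(2))], zygosity="hom"),)
            else:
                germ = PATHOGENIC_VOCAB
        else:
            exposures = _draw_exposures(rng, catalog, config.sporadic_weight)
            n_snv = int(rng.integers(config.sporadic_snv[0], config.sporadic_snv[1] + 1))
            germ = (PATHOGENIC_VOCAB[int(rng.integers(2))],) if cls == "monoallelic" else ()
        spectrum = simulate_tumor(exposures, n_snv, catalog, rng)
        dossiers.append(
            TumorDossier(
                tumor_id=f"S{i:04d}",
                spectrum=spectrum,
                panel_mb=config.panel_mb,
                germline_variants=germ,
                truth_class=cls,
                true_exposures=exposures,
            )
        )
    return dossiers


def cohort_manifest(dossiers: Sequence[TumorDossier]) -> pd.DataFrame:
    """Tabular view of a cohort: one row per tumor with truth labels."""
    return pd.DataFrame(
        {
            "tumor_id": [d.tumor_id for d in dossiers],
            "truth_class": [d.truth_class for d in dossiers],
            "n_snv": [d.spectrum.n_snv for d in dossiers],
            "panel_mb": [d.panel_mb for d in dossiers],
            "true_sbs18_36_pct": [round(d.true_sbs18_36, 1) for d in dossiers],
            "germline_variants": [";".join(v.name for v in d.germline_variants) for d in dossiers],
        }
    )


# --- toy sequence bundle: FASTA + BED + VCF that round-trip exactly ---------

TOY_CONTIG = "toy1"


def write_toy_reference(path: str | Path, length: int = 60_000, seed: int = 1) -> Path:
    """Write a random single-contig FASTA (with .fai) long enough that every
    trinucleotide context occurs many times."""
    rng = np.random.default_rng(seed)
    seq = "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f">{TOY_CONTIG}\n")
        for i in range(0, length, 60):
            fh.write(seq[i : i + 60] + "\n")
    import pyfaidx

    pyfaidx.Faidx(str(path))  # build the .fai index
    return path


def spectrum_to_variants(spectrum: ContextSpectrum, reference, seed: int = 0) -> list[SomaticVariant]:
    """Place each counted mutation at a toy-reference position whose context
    matches its class (forward or reverse-complement strand), so that
    re-counting the emitted variants reproduces the spectrum exactly."""
    rng = np.random.default_rng(seed)
    seq = str(reference[TOY_CONTIG][:]).upper()
    index: dict[str, list[int]] = {}
    for i in range(1, len(seq) - 1):
        index.setdefault(seq[i - 1 : i + 2], []).append(i + 1)  # 1-based center
    used: set[int] = set()
    variants: list[SomaticVariant] = []
    for label, count in zip(CANONICAL_CLASSES, spectrum.counts):
        if count == 0:
            continue
        five, ref, alt, three = label[0], label[2], label[4], label[6]
        fwd = five + ref + three
        rev = revcomp(fwd)
        candidates = [(p, ref, alt) for p in index.get(fwd, ())] + [
            (p, COMPLEMENT[ref], COMPLEMENT[alt]) for p in index.get(rev, ())
        ]
        candidates = [c for c in candidates if c[0] not in used]
        if len(candidates) < count:
            raise ValueError(f"toy reference too short to place {count} x {label}")
        picks = rng.choice(len(candidates), size=int(count), replace=False)
        for j in picks:
            pos, r, a = candidates[int(j)]
            used.add(pos)
            variants.append(SomaticVariant(TOY_CONTIG, pos, r, a, depth=100, vaf=0.5))
    return sorted(variants, key=lambda v: v.pos)


def write_vcf(variants: Sequence[SomaticVariant], path: str | Path, contig_length: int = 60_000) -> Path:
    """Write plain VCF v4.2 with a single TUMOR sample carrying AD/DP."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={TOY_CONTIG},length={contig_length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR\n")
        for v in variants:
            depth = v.depth if v.depth is not None else 100
            vaf = v.vaf if v.vaf is not None else 0.5
            alt_reads = int(round(depth * vaf))
            ref_reads = depth - alt_reads
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\t"
                f"GT:AD:DP\t0/1:{ref_reads},{alt_reads}:{depth}\n"
            )
    return path


def write_bed(path: str | Path, intervals: Sequence[tuple[str, int, int]] | None = None) -> Path:
    path = Path(path)
    intervals = intervals or [(TOY_CONTIG, 0, 60_000)]
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")
    return path
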