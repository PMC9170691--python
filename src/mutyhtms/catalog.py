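"""Single-base-substitution signature catalogs in the COSMIC tab-separated format.

A signature catalog is a 96 x k matrix of probability profiles: for each
signature, the probability that a mutation attributed to it falls in each of
the 96 pyrimidine-normalized trinucleotide substitution classes.  This module
owns the canonical class ordering, catalog I/O, validation and subsetting.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

PYRIMIDINES = ("C", "T")
BASES = ("A", "C", "G", "T")
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: Tolerance band inside which a signature column is renormalized to sum 1.
COLUMN_SUM_BAND = (0.999, 1.001)

#: Default reduced signature set used for colorectal-cancer refitting.  The
#: classifier logic depends only on SBS18 and SBS36 being present; the rest of
#: this list is an editable placeholder for the CRC signatures active in
#: whole-genome colorectal tumors and can be overridden in configuration.
DEFAULT_CRC_SIGNATURES = (
    "SBS1", "SBS2", "SBS3", "SBS5", "SBS8", "SBS13", "SBS15",
    "SBS17a", "SBS17b", "SBS18", "SBS28", "SBS30", "SBS36", "SBS44",
)

BER_SIGNATURES = ("SBS18", "SBS36")


class CatalogFormatError(ValueError):
    """Raised when a signature file violates the COSMIC TSV contract."""


def canonical_classes() -> list[str]:
    """The 96 substitution classes in canonical order.

    Substitution-major (C>A, C>G, C>T, T>A, T>C, T>G) with 5'/3' flanks
    iterated lexicographically (A, C, G, T), e.g. ``A[C>A]A`` first.
    """
    out = []
    for sub in SUBSTITUTIONS:
        ref, alt = sub.split(">")
        for five in BASES:
            for three in BASES:
                out.append(f"{five}[{ref}>{alt}]{three}")
    return out


CANONICAL_CLASSES: tuple[str, ...] = tuple(canonical_classes())
CLASS_INDEX = {c: i for i, c in enumerate(CANONICAL_CLASSES)}


def class_label(five: str, ref: str, alt: str, three: str) -> str:
    """Render a substitution class as its canonical ``X[R>A]Y`` text form."""
    label = f"{five}[{ref}>{alt}]{three}"
    if label not in CLASS_INDEX:
        raise ValueError(f"not a valid pyrimidine-normalized class: {label}")
    return label


@dataclass(frozen=True)
class SignatureCatalog:
    """Ordered set of SBS signature probability profiles.

    Attributes
    ----------
    profiles : pandas.DataFrame
        96 rows indexed by canonical class labels, one column per signature.
        Every column is non-negative and sums to 1.
    """

    profiles: pd.DataFrame

    def __post_init__(self) -> None:
        p = self.profiles
        if list(p.index) != list(CANONICAL_CLASSES):
            raise CatalogFormatError("profiles must be indexed by the 96 canonical classes in order")
        if (p.values < 0).any():
            bad = p.columns[(p.values < 0).any(axis=0)][0]
            raise CatalogFormatError(f"negative entry in signature column {bad!r}")
        sums = p.sum(axis=0).values
        if not np.allclose(sums, 1.0, atol=1e-6):
            bad = p.columns[np.argmax(np.abs(sums - 1.0))]
            raise CatalogFormatError(f"signature column {bad!r} sums to {sums.max():.6f}, not 1")

    @property
    def names(self) -> list[str]:
        return list(self.profiles.columns)

    @property
    def matrix(self) -> np.ndarray:
        """Profiles as a (96, k) float array in canonical row order."""
        return self.profiles.to_numpy(dtype=float)

    def __len__(self) -> int:
        return self.profiles.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.profiles[name].to_numpy(dtype=float)


def _validate_rows(index: pd.Index, path: object) -> None:
    seen = set(index)
    dupes = index[index.duplicated()].tolist()
    if dupes:
        raise CatalogFormatError(f"{path}: duplicate context row(s) {dupes}")
    missing = [c for c in CANONICAL_CLASSES if c not in seen]
    if missing:
        raise CatalogFormatError(f"{path}: missing context row(s) {missing}")
    extra = [c for c in index if c not in CLASS_INDEX]
    if extra:
        raise CatalogFormatError(f"{path}: unrecognized context row(s) {extra}")


def load_catalog(path: str | Path) -> SignatureCatalog:
    """Load a COSMIC-format signature TSV.

    The first column holds ``X[R>A]Y`` context labels (any row order); each
    remaining column is one signature.  Rows are re-ordered to the canonical
    order and columns renormalized when their sum lies within
    ``COLUMN_SUM_BAND``; columns outside the band are rejected.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 1:
        raise CatalogFormatError(f"{path}: no signature columns found")
    df.index = df.index.astype(str)
    _validate_rows(df.index, path)
    df = df.loc[list(CANONICAL_CLASSES)]
    for col in df.columns:
        vals = df[col].to_numpy(dtype=float)
        if (vals < 0).any():
            row = df.index[int(np.argmax(vals < 0))]
            raise CatalogFormatError(f"{path}: negative entry for {row!r} in column {col!r}")
        s = vals.sum()
        if not (COLUMN_SUM_BAND[0] <= s <= COLUMN_SUM_BAND[1]):
            raise CatalogFormatError(
                f"{path}: column {col!r} sums to {s:.6f}, outside {COLUMN_SUM_BAND}"
            )
        if abs(s - 1.0) > 1e-9:  # keep renormalization idempotent at bit level
            vals = vals / s
        df[col] = vals
    return SignatureCatalog(df)


def write_catalog(catalog: SignatureCatalog, path: str | Path) -> None:
    """Write a catalog back to the canonical COSMIC TSV dialect."""
    out = catalog.profiles.copy()
    out.index.name = "Type"
    # default shortest-repr float formatting parses back to the same double,
    # keeping load -> write -> load bit-identical
    out.to_csv(path, sep="\t")


def reduce_catalog(catalog: SignatureCatalog, keep: Sequence[str]) -> SignatureCatalog:
    """Subset a catalog to ``keep`` (in the requested order), profiles unchanged."""
    keep = list(keep)
    if not keep:
        raise ValueError("cannot reduce to an empty signature set (refit basis would be empty)")
    unknown = [k for k in keep if k not in catalog.profiles.columns]
    if unknown:
        raise KeyError(
            f"unknown signature(s) {unknown}; available: {catalog.names}"
        )
    return SignatureCatalog(catalog.profiles[keep].copy())


def cosine_similarity_columns(catalog: SignatureCatalog, a: str, b: str) -> float:
    """Cosine similarity between two signature columns."""
    x, y = catalog.column(a), catalog.column(b)
    return float(x @ y / (np.linalg.norm(x) * np.linalg.norm(y)))
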