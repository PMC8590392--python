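"""Core domain containers shared across the pipeline.

Variants are biallelic SNPs with per-sample alternate-allele dosages
(0, 1, 2, or missing).  Positions are 1-based, following VCF convention;
any interval arithmetic elsewhere uses 0-based half-open coordinates and
converts at the boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

#: sentinel for a missing diploid dosage
MISSING: int = -1

_BASES = frozenset("ACGT")

CONSEQUENCE_CLASSES = (
    "missense",
    "synonymous",
    "intronic",
    "3'UTR",
    "5'UTR",
    "intergenic",
    "other",
)


def chromosome_sort_key(chrom: str) -> tuple[int, int | str]:
    """Sort key giving natural order 1..22 first, then others lexicographically.

    A leading ``chr`` prefix is ignored for ordering (but preserved on the
    record).  Non-autosomal labels sort after the autosomes.
    """
    label = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if re.fullmatch(r"\d+", label):
        return (0, int(label))
    return (1, label)


def is_autosome(chrom: str) -> bool:
    label = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return bool(re.fullmatch(r"\d+", label))


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic SNP with per-sample alt-allele dosages.

    ``genotypes`` holds one entry per panel sample, in panel order, each in
    {0, 1, 2} or :data:`MISSING`.
    """

    chrom: str
    pos: int
    rsid: str | None
    ref: str
    alt: str
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt alleles are identical ({self.ref})")
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError(
                f"not a SNP: ref={self.ref!r} alt={self.alt!r} at {self.chrom}:{self.pos}"
            )
        geno = np.asarray(self.genotypes, dtype=np.int8)
        bad = ~np.isin(geno, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"invalid dosage values at {self.chrom}:{self.pos}")
        object.__setattr__(self, "genotypes", geno)

    @property
    def key(self) -> str:
        """Preferred variant key: rsid when present, else chrom:pos:ref:alt."""
        if self.rsid:
            return self.rsid
        return self.coordinate_key

    @property
    def coordinate_key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    def sort_key(self) -> tuple:
        return (*chromosome_sort_key(self.chrom), self.pos, self.ref, self.alt)


class SamplePanel:
    """Sample → population (and optional super-population) mapping."""

    def __init__(
        self,
        entries: Mapping[str, tuple[str, str | None]] | Iterable[tuple[str, str, str | None]],
    ) -> None:
        if isinstance(entries, Mapping):
            items = [(s, p, sp) for s, (p, sp) in entries.items()]
        else:
            items = [(s, p, sp) for s, p, sp in entries]
        seen: dict[str, tuple[str, str | None]] = {}
        for sample, pop, super_pop in items:
            if sample in seen:
                raise ValueError(f"duplicate sample id in panel: {sample}")
            if not pop:
                raise ValueError(f"empty population label for sample {sample}")
            seen[sample] = (pop, super_pop)
        if not seen:
            raise ValueError("panel is empty")
        self._entries = seen
        self.samples: list[str] = list(seen)
        self._index = {s: i for i, s in enumerate(self.samples)}

    def __len__(self) -> int:
        return len(self.samples)

    def __contains__(self, sample: str) -> bool:
        return sample in self._entries

    def population_of(self, sample: str) -> str:
        return self._entries[sample][0]

    def super_population_of(self, sample: str) -> str | None:
        return self._entries[sample][1]

    @property
    def populations(self) -> list[str]:
        """Distinct population labels, in first-appearance order."""
        out: list[str] = []
        for pop, _ in self._entries.values():
            if pop not in out:
                out.append(pop)
        return out

    def sample_indices(self, population: str) -> np.ndarray:
        """Indices (into panel sample order) of the samples in *population*."""
        idx = [i for i, s in enumerate(self.samples) if self._entries[s][0] == population]
        if not idx:
            raise KeyError(f"unknown population label: {population}")
        return np.asarray(idx, dtype=np.intp)

    def items(self):
        return self._entries.items()


@dataclass(frozen=True)
class ReferenceFrequency:
    """Alt-allele frequency and allele number for one (variant, population)."""

    frequency: float
    allele_number: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.frequency <= 1.0:
            raise ValueError(f"frequency {self.frequency} outside [0, 1]")
        if self.allele_number <= 0:
            raise ValueError(f"allele number must be positive, got {self.allele_number}")


class ReferenceFrequencySet:
    """Per-variant, per-population reference allele frequencies.

    Variants are keyed on rsid when available, else on chrom:pos:ref:alt;
    lookups accept either key for variants registered with both.
    """

    def __init__(self) -> None:
        self._data: dict[str, dict[str, ReferenceFrequency]] = {}
        self._alias: dict[str, str] = {}

    def add(
        self,
        key: str,
        population: str,
        frequency: float,
        allele_number: int,
        *,
        alias: str | None = None,
    ) -> None:
        entry = ReferenceFrequency(frequency, allele_number)
        self._data.setdefault(key, {})[population] = entry
        if alias:
            self._alias[alias] = key

    def _resolve(self, key: str) -> str | None:
        if key in self._data:
            return key
        return self._alias.get(key)

    def __contains__(self, key: str) -> bool:
        return self._resolve(key) is not None

    def lookup(self, key: str, population: str) -> ReferenceFrequency | None:
        resolved = self._resolve(key)
        if resolved is None:
            return None
        return self._data[resolved].get(population)

    def populations_for(self, key: str) -> list[str]:
        resolved = self._resolve(key)
        if resolved is None:
            return []
        return list(self._data[resolved])

    @property
    def populations(self) -> list[str]:
        out: list[str] = []
        for pops in self._data.values():
            for p in pops:
                if p not in out:
                    out.append(p)
        return out

    def __len__(self) -> int:
        return len(self._data)


@dataclass(frozen=True)
class Annotation:
    """Functional annotation for one variant."""

    gene: str
    consequence: str
    cadd: float | None
    pharmgkb: bool

    def __post_init__(self) -> None:
        if self.cadd is not None and self.cadd < 0:
            raise ValueError(f"CADD score must be non-negative, got {self.cadd}")
        if self.consequence not in CONSEQUENCE_CLASSES:
            raise ValueError(f"unknown consequence class: {self.consequence}")


class AnnotationTable:
    """rsid → gene / consequence / CADD / pharmacogene-membership table."""

    def __init__(self, entries: Mapping[str, Annotation] | None = None) -> None:
        self._entries: dict[str, Annotation] = dict(entries or {})

    def add(self, rsid: str, annotation: Annotation) -> None:
        if rsid in self._entries:
            raise ValueError(f"duplicate rsid in annotation table: {rsid}")
        self._entries[rsid] = annotation

    def get(self, rsid: str) -> Annotation | None:
        return self._entries.get(rsid)

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def items(self):
        return self._entries.items()
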