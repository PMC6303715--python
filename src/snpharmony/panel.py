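"""Core containers for multi-dataset SNP genotype panels.

A :class:`GenotypePanel` holds diploid biallelic genotypes as a dosage matrix
(individuals x loci) counting copies of the *designated* allele — the first
allele of each locus' ``allele_pair``.  Missing genotypes use the dedicated
sentinel :data:`MISSING`, never dosage 0.  Swapping which allele is designated
maps every dosage g -> 2 - g; the designation is carried explicitly so this
never happens silently.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

#: Sentinel dosage for a missing genotype call.
MISSING: int = -1

BASES: tuple[str, ...] = ("A", "C", "G", "T")
COMPLEMENT: dict[str, str] = {"A": "T", "T": "A", "C": "G", "G": "C"}

# A/T and C/G polymorphisms equal their own reverse complement, so the
# sequenced strand cannot be recovered from allele identities alone.
_AMBIGUOUS_PAIRS = (frozenset("AT"), frozenset("CG"))


class PanelError(ValueError):
    """Invalid panel structure, alleles, or inconsistent metadata."""


@dataclass(frozen=True)
class LocusDef:
    """A biallelic locus: identifier, ordered allele pair, provenance."""

    locus_id: str
    allele_pair: tuple[str, str]
    linkage_group: str | None = None
    source_panels: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        a, b = self.allele_pair
        if a not in BASES or b not in BASES:
            raise PanelError(
                f"locus {self.locus_id!r}: alleles must be one of {BASES}, "
                f"got {self.allele_pair!r}"
            )
        if a == b:
            raise PanelError(f"locus {self.locus_id!r}: alleles must be distinct")

    @property
    def is_ambiguous(self) -> bool:
        """True iff the unordered allele pair is {A,T} or {C,G}."""
        return frozenset(self.allele_pair) in _AMBIGUOUS_PAIRS

    def complemented(self) -> "LocusDef":
        """Same locus read on the opposite strand (alleles complemented)."""
        a, b = self.allele_pair
        return LocusDef(
            self.locus_id,
            (COMPLEMENT[a], COMPLEMENT[b]),
            self.linkage_group,
            self.source_panels,
        )

    def with_swapped_designation(self) -> "LocusDef":
        a, b = self.allele_pair
        return LocusDef(self.locus_id, (b, a), self.linkage_group, self.source_panels)


@dataclass(frozen=True)
class SampleUnit:
    """One sampling location within one dataset of origin."""

    location_code: str
    dataset: str
    n_individuals: int
    latitude: float | None = None
    longitude: float | None = None

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise PanelError(
                f"sample {self.location_code}/{self.dataset}: n_individuals >= 1 required"
            )


class GenotypePanel:
    """Loci, samples, individuals and the dosage matrix of one dataset.

    Parameters
    ----------
    loci
        Locus definitions, unique ``locus_id`` each.
    samples
        One :class:`SampleUnit` per (location_code, dataset) present.
    individuals
        ``(individual_id, location_code)`` in matrix row order.
    dosages
        ``(n_individuals, n_loci)`` integer matrix over {0, 1, 2, MISSING}.
    """

    def __init__(
        self,
        loci: Sequence[LocusDef],
        samples: Sequence[SampleUnit],
        individuals: Sequence[tuple[str, str]],
        dosages: np.ndarray,
    ) -> None:
        self.loci = list(loci)
        self.samples = list(samples)
        self.individuals = [tuple(ind) for ind in individuals]
        self.dosages = np.asarray(dosages, dtype=np.int8)
        self._locus_idx: dict[str, int] = {
            l.locus_id: i for i, l in enumerate(self.loci)
        }
        self._sample_idx: dict[tuple[str, str], SampleUnit] = {
            (s.location_code, s.dataset): s for s in self.samples
        }
        self.validate()

    # ------------------------------------------------------------------ checks
    def validate(self) -> None:
        if len(self._locus_idx) != len(self.loci):
            raise PanelError("duplicate locus_id within panel")
        if len(self._sample_idx) != len(self.samples):
            raise PanelError("duplicate (location_code, dataset) sample")
        if self.dosages.shape != (len(self.individuals), len(self.loci)):
            raise PanelError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.loci)} loci"
            )
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise PanelError("dosages must be in {0, 1, 2, MISSING}")
        known_locations = {s.location_code for s in self.samples}
        for ind_id, loc in self.individuals:
            if loc not in known_locations:
                raise PanelError(
                    f"individual {ind_id!r} at location {loc!r} has no SampleUnit"
                )
        ids = [i for i, _ in self.individuals]
        if len(set(ids)) != len(ids):
            raise PanelError("duplicate individual_id within panel")

    # --------------------------------------------------------------- accessors
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_ids(self) -> list[str]:
        return [l.locus_id for l in self.loci]

    @property
    def datasets(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            if s.dataset not in seen:
                seen.append(s.dataset)
        return seen

    def locus_index(self, locus_id: str) -> int:
        try:
            return self._locus_idx[locus_id]
        except KeyError:
            raise PanelError(f"unknown locus {locus_id!r}") from None

    def locus(self, locus_id: str) -> LocusDef:
        return self.loci[self.locus_index(locus_id)]

    def dataset_of_location(self, location_code: str) -> str:
        for s in self.samples:
            if s.location_code == location_code:
                return s.dataset
        raise PanelError(f"unknown location {location_code!r}")

    def rows_for(
        self, location_code: str | None = None, dataset: str | None = None
    ) -> np.ndarray:
        """Row indices of individuals filtered by location and/or dataset."""
        loc_to_ds = {s.location_code: s.dataset for s in self.samples}
        keep = []
        for i, (_, loc) in enumerate(self.individuals):
            if location_code is not None and loc != location_code:
                continue
            if dataset is not None and loc_to_ds[loc] != dataset:
                continue
            keep.append(i)
        return np.asarray(keep, dtype=np.intp)

    def allele_frequency(
        self, location_code: str, locus_id: str
    ) -> tuple[float, int]:
        """Frequency of the designated allele among non-missing calls.

        Returns ``(freq, n_called)``; ``freq`` is NaN when no calls exist
        (an undefined-frequency signal, not an exception).
        """
        rows = self.rows_for(location_code)
        if rows.size == 0:
            raise PanelError(f"unknown location {location_code!r}")
        col = self.dosages[rows, self.locus_index(locus_id)]
        called = col[col != MISSING]
        n = int(called.size)
        if n == 0:
            return float("nan"), 0
        return float(called.sum()) / (2.0 * n), n

    def genotype_counts(
        self, location_code: str, locus_id: str
    ) -> tuple[int, int, int]:
        """(hom designated, het, hom other) counts at one location/locus."""
        rows = self.rows_for(location_code)
        col = self.dosages[rows, self.locus_index(locus_id)]
        return (
            int((col == 2).sum()),
            int((col == 1).sum()),
            int((col == 0).sum()),
        )

    def counts_by_location(self) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
        """Per location: (hom-designated, het, hom-other) arrays over all loci."""
        out = {}
        for s in self.samples:
            rows = self.rows_for(s.location_code)
            sub = self.dosages[rows, :]
            out[s.location_code] = (
                (sub == 2).sum(axis=0),
                (sub == 1).sum(axis=0),
                (sub == 0).sum(axis=0),
            )
        return out

    @property
    def locations(self) -> list[str]:
        return [s.location_code for s in self.samples]

    # -------------------------------------------------------------- transforms
    def copy(self) -> "GenotypePanel":
        return GenotypePanel(
            list(self.loci),
            list(self.samples),
            list(self.individuals),
            self.dosages.copy(),
        )

    def swap_designation(self, locus_id: str) -> None:
        """Swap which allele is designated: dosages g -> 2 - g, pair reversed.

        An involution; allele identities are unchanged.
        """
        j = self.locus_index(locus_id)
        col = self.dosages[:, j]
        mask = col != MISSING
        col[mask] = 2 - col[mask]
        self.loci[j] = self.loci[j].with_swapped_designation()
        self._locus_idx = {l.locus_id: i for i, l in enumerate(self.loci)}

    def apply_strand_flip(self, locus_id: str, rows: np.ndarray | None = None) -> None:
        """Re-read a locus on the opposite strand for the given rows.

        Alleles are complemented and dosages mapped g -> 2 - g for the
        affected rows (all rows when ``rows`` is None).  For ambiguous loci
        the complemented pair is letter-identical to the original reversed
        pair, which is exactly why flips there are undetectable from allele
        identities.
        """
        j = self.locus_index(locus_id)
        if rows is None:
            rows = np.arange(self.n_individuals)
        col = self.dosages[rows, j]
        mask = col != MISSING
        col[mask] = 2 - col[mask]
        self.dosages[rows, j] = col
        a, b = self.loci[j].allele_pair
        self.loci[j] = LocusDef(
            locus_id,
            (COMPLEMENT[b], COMPLEMENT[a]),
            self.loci[j].linkage_group,
            self.loci[j].source_panels,
        )

    def subset_loci(self, locus_ids: Sequence[str]) -> "GenotypePanel":
        idx = [self.locus_index(l) for l in locus_ids]
        return GenotypePanel(
            [self.loci[i] for i in idx],
            list(self.samples),
            list(self.individuals),
            self.dosages[:, idx].copy(),
        )

    def canonicalized(self) -> "GenotypePanel":
        """Designation normalized to the lower allele code (A<C<G<T) first."""
        p = self.copy()
        order = {b: i for i, b in enumerate(BASES)}
        for locus in list(p.loci):
            a, b = locus.allele_pair
            if order[a] > order[b]:
                p.swap_designation(locus.locus_id)
        return p

    # ---------------------------------------------------------------- equality
    def equals(self, other: "GenotypePanel", up_to_designation: bool = False) -> bool:
        a, b = (self, other)
        if up_to_designation:
            a, b = a.canonicalized(), b.canonicalized()
        return (
            [(l.locus_id, l.allele_pair) for l in a.loci]
            == [(l.locus_id, l.allele_pair) for l in b.loci]
            and a.samples == b.samples
            and a.individuals == b.individuals
            and np.array_equal(a.dosages, b.dosages)
        )


@dataclass
class DistanceMatrix:
    """Pairwise distances (km) between sampling locations."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise PanelError("distance matrix labels must be unique")
        if self.values.shape != (n, n):
            raise PanelError("distance matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise PanelError("distance matrix must be symmetric")
        if np.abs(np.diag(self.values)).max(initial=0.0) > 1e-9:
            raise PanelError("distance matrix diagonal must be zero")
        if (self.values < -1e-9).any():
            raise PanelError("distances must be nonnegative")

    def subset(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(tuple(labels), self.values[np.ix_(idx, idx)])

    def lookup(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])


def merge_panels(
    panels: Sequence[GenotypePanel], locus_ids: Sequence[str]
) -> GenotypePanel:
    """Concatenate individuals of several aligned panels over shared loci.

    All panels must carry identical (locus_id, allele_pair) designations for
    every requested locus — i.e. run after intersection/alignment.
    """
    ref = panels[0]
    loci = []
    for lid in locus_ids:
        defs = [p.locus(lid) for p in panels]
        pairs = {d.allele_pair for d in defs}
        if len(pairs) != 1:
            raise PanelError(f"locus {lid!r}: panels disagree on allele designation")
        sources = frozenset().union(*(d.source_panels for d in defs))
        if not sources:
            sources = frozenset(ds for p in panels for ds in p.datasets)
        d0 = defs[0]
        loci.append(LocusDef(lid, d0.allele_pair, d0.linkage_group, sources))

    samples: list[SampleUnit] = []
    individuals: list[tuple[str, str]] = []
    blocks = []
    for p in panels:
        samples.extend(p.samples)
        individuals.extend(p.individuals)
        idx = [p.locus_index(l) for l in locus_ids]
        blocks.append(p.dosages[:, idx])
    dosages = np.vstack(blocks) if blocks else np.zeros((0, len(loci)), dtype=np.int8)
    return GenotypePanel(loci, samples, individuals, dosages)
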