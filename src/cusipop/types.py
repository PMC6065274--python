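"""Core in-memory containers shared by every analysis stage.

A :class:`GenotypeMatrix` stores diploid, unphased allele calls for a set of
individuals at a set of loci.  Allele codes are dense non-negative integers
(recoded to ``0..k-1`` per locus on ingestion); a fully missing genotype is
stored as the pair ``(-1, -1)``.  Half-called genotypes are never stored --
readers coerce them to missing before construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: sentinel for a missing allele inside ``calls``
MISSING = -1


class ValidationError(ValueError):
    """A container violated one of its structural invariants."""


class ParseError(ValueError):
    """An input file could not be interpreted in its declared format."""


@dataclass
class GenotypeMatrix:
    """Individuals x loci diploid genotype calls.

    Parameters
    ----------
    individual_ids:
        Ordered unique identifiers, one per row of ``calls``.
    locus_ids:
        Ordered unique identifiers, one per column of ``calls``.
    calls:
        ``(n_individuals, n_loci, 2)`` integer array of allele codes; a
        missing genotype is ``(-1, -1)``.  Within a genotype the allele pair
        is unordered.
    locus_positions:
        Optional per-locus ``(chromosome, 1-based position)`` tuples, keyed
        by locus id.
    """

    individual_ids: list[str]
    locus_ids: list[str]
    calls: np.ndarray
    locus_positions: dict[str, tuple[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int32)
        if self.calls.ndim != 3 or self.calls.shape[2] != 2:
            raise ValidationError(
                f"calls must have shape (n, L, 2); got {self.calls.shape}"
            )
        n, L = self.calls.shape[:2]
        if len(self.individual_ids) != n or len(self.locus_ids) != L:
            raise ValidationError("id lists do not match calls shape")
        if len(set(self.individual_ids)) != n:
            raise ValidationError("duplicate individual ids")
        if len(set(self.locus_ids)) != L:
            raise ValidationError("duplicate locus ids")
        half = (self.calls == MISSING).sum(axis=2) == 1
        if half.any():
            raise ValidationError("half-missing genotype present; coerce before construction")

    # -- basic geometry -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    def missing_mask(self) -> np.ndarray:
        """Boolean ``(n, L)`` array, True where the genotype is missing."""
        return self.calls[:, :, 0] == MISSING

    def n_alleles(self) -> np.ndarray:
        """Number of distinct observed alleles per locus (0 for all-missing)."""
        out = np.zeros(self.n_loci, dtype=int)
        for j in range(self.n_loci):
            obs = self.calls[:, j, :]
            obs = obs[obs != MISSING]
            out[j] = 0 if obs.size == 0 else int(obs.max()) + 1
        return out

    def recode_dense(self) -> "GenotypeMatrix":
        """Return a copy with allele codes remapped to ``0..k-1`` per locus.

        Observed allele codes are ranked; rank order is preserved so VCF
        REF=0 stays 0 whenever 0 is observed.
        """
        calls = self.calls.copy()
        for j in range(self.n_loci):
            col = calls[:, j, :]
            obs = np.unique(col[col != MISSING])
            if obs.size == 0:
                continue
            lut = {int(a): i for i, a in enumerate(obs)}
            keep = col != MISSING
            col[keep] = np.vectorize(lut.get, otypes=[np.int32])(col[keep])
        return GenotypeMatrix(
            list(self.individual_ids), list(self.locus_ids), calls,
            dict(self.locus_positions),
        )

    def dosage(self) -> np.ndarray:
        """Counts of allele 1 per genotype for biallelic data.

        Returns a float ``(n, L)`` array with values 0/1/2 and ``nan`` for
        missing.  Raises if any locus carries more than two alleles.
        """
        if (self.n_alleles() > 2).any():
            raise ValidationError("dosage() requires biallelic loci")
        d = self.calls.sum(axis=2).astype(float)
        d[self.missing_mask()] = np.nan
        return d

    def subset_loci(self, keep: np.ndarray | list[int]) -> "GenotypeMatrix":
        keep = np.asarray(keep, dtype=np.intp)
        ids = [self.locus_ids[i] for i in keep]
        pos = {i: self.locus_positions[i] for i in ids if i in self.locus_positions}
        return GenotypeMatrix(list(self.individual_ids), ids, self.calls[:, keep, :], pos)

    def subset_individuals(self, keep: np.ndarray | list[int]) -> "GenotypeMatrix":
        keep = np.asarray(keep, dtype=np.intp)
        ids = [self.individual_ids[i] for i in keep]
        return GenotypeMatrix(ids, list(self.locus_ids), self.calls[keep, :, :],
                              dict(self.locus_positions))


@dataclass
class PopulationMap:
    """Mapping from individual id to population label."""

    assignments: dict[str, str]

    def populations(self) -> list[str]:
        """Distinct labels in first-appearance order."""
        seen: dict[str, None] = {}
        for p in self.assignments.values():
            seen.setdefault(p, None)
        return list(seen)

    def members(self, population: str) -> list[str]:
        return [i for i, p in self.assignments.items() if p == population]

    def labels_for(self, matrix: GenotypeMatrix) -> np.ndarray:
        """Per-row population labels aligned to ``matrix.individual_ids``."""
        missing = [i for i in matrix.individual_ids if i not in self.assignments]
        if missing:
            raise ValidationError(f"individuals absent from population map: {missing}")
        return np.array([self.assignments[i] for i in matrix.individual_ids])

    def validate_against(self, matrix: GenotypeMatrix) -> None:
        self.labels_for(matrix)
        if not self.assignments:
            raise ValidationError("population map is empty")
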