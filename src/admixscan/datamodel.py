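"""Core in-memory containers for the pipeline.

Genotypes are stored as alt-allele dosage codes {0, 1, 2} with ``-1`` for
missing; phase is discarded (no downstream analysis here is phase-aware).
Locus coordinates are 1-based internally; BED files are 0-based half-open at
the boundary, with the conversion centralized in :func:`bed_to_pos` /
:func:`pos_to_bed`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = -1

#: columns every locus table must carry, in order
LOCUS_COLUMNS = ("chrom", "pos", "ref", "alt")

LOCATION_CLASSES = ("genic", "upstream5kb", "downstream5kb", "intergenic", "unassigned")


def bed_to_pos(start: int) -> int:
    """0-based half-open BED start -> 1-based position of the first base."""
    return start + 1


def pos_to_bed(pos: int) -> int:
    """1-based position -> 0-based half-open BED start covering it."""
    return pos - 1


def _as_locus_frame(loci: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in LOCUS_COLUMNS if c not in loci.columns]
    if missing:
        raise ValueError(f"locus table missing columns: {missing}")
    return loci.reset_index(drop=True)


@dataclass
class GenotypeMatrix:
    """Samples x biallelic-loci genotype matrix.

    Parameters
    ----------
    sample_ids
        Ordered sample identifiers (unique).
    loci
        DataFrame with at least ``chrom, pos, ref, alt``; optionally
        ``site_quality`` (RMS mapping quality as provided by the caller,
        never computed here) and ``location_class``.
    G
        ``(n_samples, n_loci)`` int8 array of alt-allele dosages, -1 missing.
    D
        Optional per-genotype sequencing depth, same shape, non-negative.
    chrom_lengths
        Optional mapping chromosome -> length in bp (used for windowing).
    """

    sample_ids: list[str]
    loci: pd.DataFrame
    G: np.ndarray
    D: np.ndarray | None = None
    chrom_lengths: dict[str, int] | None = None
    sample_platform: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        self.loci = _as_locus_frame(self.loci)
        self.G = np.asarray(self.G, dtype=np.int8)
        if self.G.shape != (len(self.sample_ids), len(self.loci)):
            raise ValueError(
                f"G shape {self.G.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.loci)} loci"
            )
        if not np.isin(self.G, (MISSING, 0, 1, 2)).all():
            raise ValueError("genotype codes must be in {-1, 0, 1, 2}")
        if self.D is not None:
            self.D = np.asarray(self.D)
            if self.D.shape != self.G.shape:
                raise ValueError("depth matrix shape differs from genotype matrix")
            if (self.D < 0).any():
                raise ValueError("negative depths")
        self._check_loci_sorted()

    def _check_loci_sorted(self) -> None:
        if len(self.loci) < 2:
            return
        key = pd.MultiIndex.from_frame(self.loci[["chrom", "pos"]])
        if key.duplicated().any():
            dup = self.loci.loc[key.duplicated(), ["chrom", "pos"]].iloc[0]
            raise ValueError(f"duplicate locus at {dup.chrom}:{dup.pos}")
        chrom = self.loci["chrom"].to_numpy()
        pos = self.loci["pos"].to_numpy()
        same = chrom[1:] == chrom[:-1]
        if (pos[1:][same] <= pos[:-1][same]).any():
            raise ValueError("loci must be strictly sorted by (chrom, pos)")
        # chromosomes must appear in contiguous blocks
        first = pd.unique(chrom)
        seen = set()
        prev = None
        for c in chrom:
            if c != prev and c in seen:
                raise ValueError("loci of one chromosome must be contiguous")
            seen.add(c)
            prev = c
        del first

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def called(self) -> np.ndarray:
        """Boolean mask of non-missing genotypes."""
        return self.G != MISSING

    def sample_indices(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        unknown = [s for s in ids if s not in lookup]
        if unknown:
            raise KeyError(f"unknown samples: {unknown}")
        return np.array([lookup[s] for s in ids], dtype=int)

    # -- subsetting ------------------------------------------------------
    def take_samples(self, ids) -> "GenotypeMatrix":
        idx = self.sample_indices(ids)
        return replace(
            self,
            sample_ids=[self.sample_ids[i] for i in idx],
            G=self.G[idx].copy(),
            D=None if self.D is None else self.D[idx].copy(),
            sample_platform={
                s: self.sample_platform[s] for s in ids if s in self.sample_platform
            },
        )

    def take_loci(self, mask) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return replace(
            self,
            loci=self.loci.iloc[idx].reset_index(drop=True),
            G=self.G[:, idx].copy(),
            D=None if self.D is None else self.D[:, idx].copy(),
        )

    def copy(self) -> "GenotypeMatrix":
        return replace(
            self,
            loci=self.loci.copy(),
            G=self.G.copy(),
            D=None if self.D is None else self.D.copy(),
        )

    def locus_key(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_frame(self.loci[list(LOCUS_COLUMNS)])


@dataclass
class PopulationMap:
    """Sample -> population assignment, with an optional subgroup label."""

    table: pd.DataFrame  # columns: sample, population[, subgroup]

    def __post_init__(self) -> None:
        if not {"sample", "population"}.issubset(self.table.columns):
            raise ValueError("population map needs 'sample' and 'population' columns")
        if self.table["sample"].duplicated().any():
            dup = self.table.loc[self.table["sample"].duplicated(), "sample"].tolist()
            raise ValueError(f"samples assigned more than once: {dup}")
        self.table = self.table.reset_index(drop=True)

    @classmethod
    def from_dict(cls, mapping: dict[str, str]) -> "PopulationMap":
        return cls(
            pd.DataFrame(
                {"sample": list(mapping), "population": list(mapping.values())}
            )
        )

    @property
    def populations(self) -> list[str]:
        return list(pd.unique(self.table["population"]))

    def samples_in(self, population: str) -> list[str]:
        sel = self.table.loc[self.table["population"] == population, "sample"]
        return sel.tolist()

    def indices_in(self, gm: GenotypeMatrix, population: str) -> np.ndarray:
        samples = self.samples_in(population)
        if not samples:
            raise KeyError(f"population {population!r} not in map")
        present = [s for s in samples if s in gm.sample_ids]
        if not present:
            raise KeyError(
                f"population {population!r} has no samples in the matrix"
            )
        return gm.sample_indices(present)

    def restrict_to(self, gm: GenotypeMatrix) -> "PopulationMap":
        """Keep only the samples present in the matrix."""
        keep = self.table["sample"].isin(gm.sample_ids)
        return PopulationMap(self.table.loc[keep].reset_index(drop=True))

    def validate_against(self, gm: GenotypeMatrix) -> None:
        mapped = set(self.table["sample"])
        missing = [s for s in gm.sample_ids if s not in mapped]
        if missing:
            raise ValueError(f"samples absent from population map: {missing}")


@dataclass
class GeneAnnotation:
    """Gene intervals, 0-based half-open (BED convention), with strand."""

    table: pd.DataFrame  # columns: chrom, start, end, name, strand

    def __post_init__(self) -> None:
        need = {"chrom", "start", "end", "name"}
        if not need.issubset(self.table.columns):
            raise ValueError(f"gene annotation needs columns {sorted(need)}")
        if "strand" not in self.table.columns:
            self.table = self.table.assign(strand="+")
        if (self.table["end"] <= self.table["start"]).any():
            raise ValueError("gene intervals must satisfy start < end")
        self.table = self.table.sort_values(["chrom", "start"]).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)
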