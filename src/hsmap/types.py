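"""Core containers shared by the pipeline stages.

Coordinates are 1-based inclusive base pairs throughout.  Genotypes are stored
as allele-B dosages (``0``, ``1``, ``2``; ``-1`` = missing call), with the
allele pair of each marker recorded on the :class:`MarkerPanel`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = -1

MALE = "male"
FEMALE = "female"
SEXES = (MALE, FEMALE)

#: genetic-map tracks carried by :class:`GeneticMap` / map models
TRACKS = ("male", "female", "avg")


class HsmapError(Exception):
    """Base class for validation errors raised by hsmap."""


@dataclass(frozen=True)
class MarkerPanel:
    """An ordered panel of biallelic markers with physical positions.

    Markers must be grouped by chromosome and strictly increasing in
    ``position_bp`` within each chromosome; marker ids are unique genome-wide.
    """

    marker_id: np.ndarray
    chromosome: np.ndarray
    position_bp: np.ndarray
    alleles: np.ndarray  # (n, 2) allele symbols

    def __post_init__(self):
        object.__setattr__(self, "marker_id", np.asarray(self.marker_id, dtype=object))
        object.__setattr__(self, "chromosome", np.asarray(self.chromosome, dtype=object))
        object.__setattr__(self, "position_bp", np.asarray(self.position_bp, dtype=np.int64))
        object.__setattr__(self, "alleles", np.asarray(self.alleles, dtype=object))
        if len({self.marker_id.shape[0], self.chromosome.shape[0], self.position_bp.shape[0], self.alleles.shape[0]}) != 1:
            raise HsmapError("panel fields must have equal length")
        if len(np.unique(self.marker_id)) != self.n_markers:
            raise HsmapError("marker ids must be unique genome-wide")
        if np.any(self.position_bp < 1):
            raise HsmapError("positions are 1-based and must be >= 1")
        for chrom in self.chromosomes:
            sl = self.chrom_slice(chrom)
            pos = self.position_bp[sl]
            if np.any(np.diff(pos) <= 0):
                raise HsmapError(f"marker positions not strictly increasing on {chrom}")

    @property
    def n_markers(self) -> int:
        return int(self.marker_id.shape[0])

    @property
    def chromosomes(self) -> list:
        """Chromosome labels in first-appearance order."""
        seen, out = set(), []
        for c in self.chromosome:
            if c not in seen:
                seen.add(c)
                out.append(c)
        return out

    def chrom_slice(self, chrom) -> slice:
        idx = np.nonzero(self.chromosome == chrom)[0]
        if idx.size == 0:
            return slice(0, 0)
        lo, hi = int(idx[0]), int(idx[-1]) + 1
        if hi - lo != idx.size:
            raise HsmapError(f"markers of chromosome {chrom} are not contiguous")
        return slice(lo, hi)

    def subset(self, indices) -> "MarkerPanel":
        indices = np.asarray(indices)
        if indices.dtype == bool:
            indices = np.nonzero(indices)[0]
        return MarkerPanel(
            self.marker_id[indices],
            self.chromosome[indices],
            self.position_bp[indices],
            self.alleles[indices],
        )

    def index_of(self, marker_ids: Iterable) -> np.ndarray:
        lookup = {m: i for i, m in enumerate(self.marker_id)}
        return np.array([lookup[m] for m in marker_ids], dtype=np.int64)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": self.marker_id,
                "chromosome": self.chromosome,
                "position_bp": self.position_bp,
                "allele_a": self.alleles[:, 0],
                "allele_b": self.alleles[:, 1],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MarkerPanel":
        alleles = np.column_stack([df["allele_a"].to_numpy(object), df["allele_b"].to_numpy(object)])
        return cls(
            df["marker_id"].to_numpy(object),
            df["chromosome"].to_numpy(object),
            df["position_bp"].to_numpy(np.int64),
            alleles,
        )


@dataclass
class Pedigree:
    """Individuals with parent links, sex, family and generation.

    Founders have neither parent; non-founders have both.  Sires are male and
    dams female.  ``generation`` increases from founders to final offspring.
    """

    table: pd.DataFrame  # individual_id, sire_id, dam_id, sex, family_id, generation

    REQUIRED = ("individual_id", "sire_id", "dam_id", "sex", "family_id", "generation")

    def __post_init__(self):
        df = self.table
        for col in self.REQUIRED:
            if col not in df.columns:
                raise HsmapError(f"pedigree missing column {col}")
        if df["individual_id"].duplicated().any():
            raise HsmapError("duplicate individual ids in pedigree")
        has_sire = df["sire_id"].notna()
        has_dam = df["dam_id"].notna()
        if (has_sire != has_dam).any():
            raise HsmapError("individuals must have both parents or neither")
        if not df["sex"].isin(SEXES).all():
            raise HsmapError("sex must be 'male' or 'female'")
        gen = dict(zip(df["individual_id"], df["generation"]))
        sex = dict(zip(df["individual_id"], df["sex"]))
        for _, row in df.loc[has_sire].iterrows():
            for pid, want in ((row["sire_id"], MALE), (row["dam_id"], FEMALE)):
                if pid not in gen:
                    raise HsmapError(f"unknown parent {pid!r}")
                if gen[pid] >= row["generation"]:
                    raise HsmapError("parents must precede offspring in generation")
                if sex[pid] != want:
                    raise HsmapError(f"parent {pid!r} has wrong sex for its role")

    @property
    def individuals(self) -> list:
        return list(self.table["individual_id"])

    @property
    def founders(self) -> list:
        return list(self.table.loc[self.table["sire_id"].isna(), "individual_id"])

    def final_generation(self) -> int:
        return int(self.table["generation"].max())

    def n_informative_meioses(self, genotyped: set | None = None) -> int:
        """Two meioses per final-generation offspring with both parents genotyped."""
        df = self.table
        last = df["generation"] == self.final_generation()
        sub = df.loc[last & df["sire_id"].notna()]
        if genotyped is not None:
            ok = (
                sub["individual_id"].isin(genotyped)
                & sub["sire_id"].isin(genotyped)
                & sub["dam_id"].isin(genotyped)
            )
            sub = sub.loc[ok]
        return 2 * len(sub)

    def trios(self) -> pd.DataFrame:
        """All (offspring, sire, dam) rows, any generation."""
        df = self.table
        sub = df.loc[df["sire_id"].notna(), ["individual_id", "sire_id", "dam_id", "family_id"]]
        return sub.reset_index(drop=True)


@dataclass
class GenotypeTable:
    """Diploid genotype calls for a set of individuals on a marker panel.

    ``dosage[i, m]`` counts copies of the marker's B allele (-1 = missing).
    Column order follows the panel.
    """

    individuals: list
    panel: MarkerPanel
    dosage: np.ndarray  # int8 (n_individuals, n_markers)

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.individuals), self.panel.n_markers):
            raise HsmapError("dosage shape does not match individuals x panel")
        self._row = {ind: i for i, ind in enumerate(self.individuals)}

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def row(self, individual) -> np.ndarray:
        return self.dosage[self._row[individual]]

    def row_index(self, individuals: Iterable) -> np.ndarray:
        return np.array([self._row[i] for i in individuals], dtype=np.int64)

    def has(self, individual) -> bool:
        return individual in self._row

    def subset_markers(self, indices) -> "GenotypeTable":
        indices = np.asarray(indices)
        if indices.dtype == bool:
            indices = np.nonzero(indices)[0]
        return GenotypeTable(list(self.individuals), self.panel.subset(indices), self.dosage[:, indices])

    def reorder_to(self, panel: MarkerPanel) -> "GenotypeTable":
        """Re-key columns to another panel holding the same marker ids."""
        perm = {m: i for i, m in enumerate(self.panel.marker_id)}
        idx = np.array([perm[m] for m in panel.marker_id], dtype=np.int64)
        return GenotypeTable(list(self.individuals), panel, self.dosage[:, idx])

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per marker over non-missing calls (NaN if none)."""
        d = self.dosage.astype(np.float64)
        d[d < 0] = np.nan
        with np.errstate(invalid="ignore"):
            p = np.nanmean(d, axis=0) / 2.0
        return np.minimum(p, 1.0 - p)


class TrueRecombinationMap:
    """Ground-truth sex-specific bp -> cM maps used by the gamete simulator.

    Each chromosome and sex holds a piecewise-linear anchor list
    ``(position_bp, cM)`` with ``cM`` starting at 0 and non-decreasing.
    """

    def __init__(self, anchors: Mapping[tuple, tuple]):
        # anchors: (chrom, sex) -> (bp array, cm array)
        self.anchors = {}
        for (chrom, sex), (bp, cm) in anchors.items():
            bp = np.asarray(bp, dtype=np.float64)
            cm = np.asarray(cm, dtype=np.float64)
            if bp.size < 2 or cm[0] != 0 or np.any(np.diff(cm) < 0) or np.any(np.diff(bp) <= 0):
                raise HsmapError(f"invalid anchors for {chrom}/{sex}")
            self.anchors[(chrom, sex)] = (bp, cm)
        chroms = {c for c, _ in self.anchors}
        for c in chroms:
            for sex in SEXES:
                if (c, sex) not in self.anchors:
                    raise HsmapError(f"map missing {sex} anchors for {c}")
        self._chroms = sorted(chroms, key=lambda c: min(i for i, k in enumerate(self.anchors) if k[0] == c))

    @classmethod
    def from_lengths(
        cls,
        lengths_bp: Mapping,
        lengths_cm: Mapping,
    ) -> "TrueRecombinationMap":
        """Uniform-rate maps from physical lengths and per-sex genetic lengths.

        ``lengths_cm`` maps chromosome -> (male cM, female cM).
        """
        anchors = {}
        for chrom, L in lengths_bp.items():
            male, female = lengths_cm[chrom]
            for sex, total in ((MALE, male), (FEMALE, female)):
                anchors[(chrom, sex)] = (np.array([1.0, float(L)]), np.array([0.0, float(total)]))
        return cls(anchors)

    @property
    def chromosomes(self) -> list:
        return list(self._chroms)

    def total_cm(self, chrom, sex) -> float:
        return float(self.anchors[(chrom, sex)][1][-1])

    def cm_at(self, chrom, sex, bp) -> np.ndarray:
        b, c = self.anchors[(chrom, sex)]
        return np.interp(np.asarray(bp, dtype=np.float64), b, c)

    def bp_at(self, chrom, sex, cm) -> np.ndarray:
        b, c = self.anchors[(chrom, sex)]
        # invert the monotone piecewise-linear map; flat stretches map to their start
        return np.interp(np.asarray(cm, dtype=np.float64), c, b)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom in self.chromosomes:
            bm, cm_m = self.anchors[(chrom, MALE)]
            bf, cf = self.anchors[(chrom, FEMALE)]
            bp = np.union1d(bm, bf)
            rows.append(
                pd.DataFrame(
                    {
                        "chromosome": chrom,
                        "position_bp": bp.astype(np.int64),
                        "cm_male": np.interp(bp, bm, cm_m),
                        "cm_female": np.interp(bp, bf, cf),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


@dataclass
class CohortTruth:
    """Ground truth recorded by the cohort simulator.

    ``crossovers`` maps ``(individual_id, parent_role, chromosome)`` (role
    ``"sire"`` or ``"dam"``) to the bp positions of crossovers in the gamete
    that parent transmitted.  ``error_calls``/``missing_calls`` are
    ``(row, marker)`` index pairs into the genotype table.
    """

    crossovers: dict
    error_calls: np.ndarray
    missing_calls: np.ndarray
    founder_strains: dict = field(default_factory=dict)
    displaced_markers: list = field(default_factory=list)

    def crossover_count(self, individual, role) -> int:
        return sum(
            len(v) for (ind, r, _), v in self.crossovers.items() if ind == individual and r == role
        )


class GeneticMap:
    """Estimated per-marker genetic map with male/female/averaged cM tracks.

    Backed by a data frame with columns ``chromosome, marker_id, position_bp,
    cm_male, cm_female, cm_avg`` plus an optional ``offset_cm`` column holding
    the per-marker placement-discordance diagnostic (0 for concordant
    markers).  The *observed* genetic position of a marker on a track is
    ``cM + offset``; cleaned maps have zero offsets.
    """

    COLUMNS = ("chromosome", "marker_id", "position_bp", "cm_male", "cm_female", "cm_avg")

    def __init__(self, frame: pd.DataFrame, validate_monotone: bool = False):
        for col in self.COLUMNS:
            if col not in frame.columns:
                raise HsmapError(f"genetic map missing column {col}")
        frame = frame.reset_index(drop=True).copy()
        if "offset_cm" not in frame.columns:
            frame["offset_cm"] = 0.0
        self.frame = frame
        if validate_monotone:
            bad = self.monotonicity_violations()
            if bad:
                raise HsmapError(
                    "cM decreases at markers: " + ", ".join(str(m) for m in bad[:10])
                )

    @property
    def chromosomes(self) -> list:
        seen, out = set(), []
        for c in self.frame["chromosome"]:
            if c not in seen:
                seen.add(c)
                out.append(c)
        return out

    def chrom(self, chrom) -> pd.DataFrame:
        return self.frame.loc[self.frame["chromosome"] == chrom]

    def track(self, track: str) -> str:
        if track not in TRACKS:
            raise HsmapError(f"unknown track {track!r}")
        return f"cm_{track}"

    def observed(self, track: str) -> np.ndarray:
        """Per-marker observed genetic position: track cM plus placement offset."""
        return self.frame[self.track(track)].to_numpy(float) + self.frame["offset_cm"].to_numpy(float)

    def total_cm(self, track: str) -> float:
        col = self.track(track)
        return float(sum(self.chrom(c)[col].iloc[-1] for c in self.chromosomes))

    def chrom_total_cm(self, chrom, track: str) -> float:
        return float(self.chrom(chrom)[self.track(track)].iloc[-1])

    def monotonicity_violations(self) -> list:
        bad = []
        for c in self.chromosomes:
            sub = self.chrom(c)
            for col in ("cm_male", "cm_female", "cm_avg"):
                d = np.diff(sub[col].to_numpy(float))
                bad.extend(sub["marker_id"].to_numpy(object)[1:][d < -1e-9])
        return list(dict.fromkeys(bad))

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other) -> bool:
        return isinstance(other, GeneticMap) and self.frame.equals(other.frame)
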