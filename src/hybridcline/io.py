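"""Genotype and metadata containers plus text-file interchange.

The central container is :class:`GenotypeMatrix`: individuals x loci diploid
genotypes for co-dominant markers (multi-allelic SSRs or bi-allelic SNPs),
stored as an ``(n, L, 2)`` integer array of allele codes with ``-9`` marking
missing data.  Genotypes travel as STRUCTURE-format text files (one- or
two-row dialects) and population metadata as CSV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -9

#: columns a metadata table must provide (distance_km is derived when absent)
META_REQUIRED = ("population", "latitude", "longitude", "elevation_m")


class ParseError(ValueError):
    """Malformed genotype or metadata file."""


@dataclass
class GenotypeMatrix:
    """Diploid genotypes for ``n`` individuals at ``L`` co-dominant loci.

    Parameters
    ----------
    ids
        Individual labels, length ``n``.
    pops
        Population label per individual, length ``n``.
    loci
        Locus names, length ``L``.
    geno
        ``(n, L, 2)`` integer allele codes; ``-9`` marks a missing genotype
        (both copies must be missing together).
    marker_class
        ``"SSR"`` or ``"SNP"`` per locus.
    """

    ids: list[str]
    pops: np.ndarray
    loci: list[str]
    geno: np.ndarray
    marker_class: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.pops = np.asarray(self.pops, dtype=object)
        self.geno = np.asarray(self.geno)
        if self.geno.ndim != 3 or self.geno.shape[2] != 2:
            raise ValueError("geno must have shape (n, L, 2)")
        n, L, _ = self.geno.shape
        if len(self.ids) != n or len(self.pops) != n:
            raise ValueError("ids/pops length does not match genotype rows")
        if len(self.loci) != L:
            raise ValueError("loci length does not match genotype columns")
        if not self.marker_class:
            self.marker_class = ["SNP" if self._is_biallelic(j) else "SSR"
                                 for j in range(L)]
        if len(self.marker_class) != L:
            raise ValueError("marker_class length does not match loci")
        miss = self.geno == MISSING
        if np.any(miss[:, :, 0] != miss[:, :, 1]):
            raise ValueError("single missing allele copy: both copies of a "
                             "genotype must be missing together")
        if np.any((self.geno < 0) & ~miss):
            raise ValueError("allele codes must be non-negative or -9")

    # -- basic properties ---------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.geno.shape[0]

    @property
    def n_loci(self) -> int:
        return self.geno.shape[1]

    def _is_biallelic(self, locus: int) -> bool:
        col = self.geno[:, locus, :]
        return len(np.unique(col[col != MISSING])) <= 2

    def missing_mask(self) -> np.ndarray:
        """Boolean ``(n, L)`` mask of missing genotypes."""
        return self.geno[:, :, 0] == MISSING

    # -- selection ----------------------------------------------------------
    def subset(self, *, individuals=None, pops=None, loci=None) -> "GenotypeMatrix":
        """Restrict to given individual indices, population labels and/or loci."""
        rows = np.arange(self.n_individuals)
        if pops is not None:
            keep = set(np.atleast_1d(pops))
            rows = rows[[p in keep for p in self.pops]]
        if individuals is not None:
            rows = np.asarray(individuals)
        if loci is None:
            cols = np.arange(self.n_loci)
        elif len(loci) and isinstance(loci[0], str):
            cols = np.array([self.loci.index(l) for l in loci])
        else:
            cols = np.asarray(loci)
        return GenotypeMatrix(
            ids=[self.ids[i] for i in rows],
            pops=self.pops[rows],
            loci=[self.loci[j] for j in cols],
            geno=self.geno[np.ix_(rows, cols)],
            marker_class=[self.marker_class[j] for j in cols],
        )

    # -- allele bookkeeping -------------------------------------------------
    def allele_counts(self, locus: int, rows=None) -> dict[int, int]:
        """Counts of each allele code at ``locus`` over non-missing copies."""
        g = self.geno[:, locus, :] if rows is None else self.geno[rows, locus, :]
        g = g[g != MISSING]
        codes, counts = np.unique(g, return_counts=True)
        return dict(zip(codes.tolist(), counts.tolist()))

    def allele_freqs(self, locus: int, rows=None) -> dict[int, float]:
        counts = self.allele_counts(locus, rows)
        total = sum(counts.values())
        if total == 0:
            return {}
        return {a: c / total for a, c in counts.items()}

    def pop_rows(self, pop) -> np.ndarray:
        return np.where(self.pops == pop)[0]


# ---------------------------------------------------------------------------
# STRUCTURE-format genotype files
# ---------------------------------------------------------------------------

def read_structure_file(path, dialect: str = "two-row",
                        marker_class: str | None = None) -> GenotypeMatrix:
    """Read a STRUCTURE-format genotype text file.

    Two dialects are supported. *two-row*: each individual occupies two
    consecutive rows (``label pop a1 a2 ... aL``), one allele copy per row.
    *one-row*: one row per individual with two adjacent columns per locus.
    Missing alleles are coded ``-9``.
    """
    path = Path(path)
    rows: list[tuple[int, list[str]]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if tokens:
                rows.append((lineno, tokens))
    if not rows:
        raise ParseError(f"{path}: empty genotype file")

    width = len(rows[0][1])
    for lineno, tokens in rows:
        if len(tokens) != width:
            raise ParseError(f"{path}:{lineno}: ragged row "
                             f"({len(tokens)} fields, expected {width})")

    def _alleles(tokens, lineno):
        out = []
        for t in tokens:
            try:
                out.append(int(t))
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer allele "
                                 f"code {t!r}") from None
        return out

    ids, pops, geno = [], [], []
    if dialect == "two-row":
        if len(rows) % 2:
            raise ParseError(f"{path}: odd row count for two-row dialect")
        n_loci = width - 2
        for (ln1, r1), (ln2, r2) in zip(rows[::2], rows[1::2]):
            if r1[0] != r2[0]:
                raise ParseError(f"{path}:{ln2}: row pair labels differ "
                                 f"({r1[0]!r} vs {r2[0]!r})")
            ids.append(r1[0])
            pops.append(r1[1])
            a = _alleles(r1[2:], ln1)
            b = _alleles(r2[2:], ln2)
            geno.append(np.stack([a, b], axis=1))
    elif dialect == "one-row":
        if (width - 2) % 2:
            raise ParseError(f"{path}: odd number of allele columns for "
                             "one-row dialect")
        n_loci = (width - 2) // 2
        for lineno, r in rows:
            ids.append(r[0])
            pops.append(r[1])
            a = _alleles(r[2:], lineno)
            geno.append(np.asarray(a).reshape(n_loci, 2))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    loci = [f"L{j + 1}" for j in range(n_loci)]
    gm = GenotypeMatrix(ids=ids, pops=np.array(pops, dtype=object), loci=loci,
                        geno=np.stack(geno, axis=0),
                        marker_class=[marker_class] * n_loci if marker_class else [])
    return gm


def write_structure_file(gm: GenotypeMatrix, path, dialect: str = "two-row") -> None:
    """Write ``gm`` as a STRUCTURE-format text file (see reader for dialects)."""
    path = Path(path)
    with open(path, "w") as fh:
        for i in range(gm.n_individuals):
            label, pop = gm.ids[i], gm.pops[i]
            if dialect == "two-row":
                for copy in (0, 1):
                    alleles = " ".join(str(int(a)) for a in gm.geno[i, :, copy])
                    fh.write(f"{label} {pop} {alleles}\n")
            elif dialect == "one-row":
                alleles = " ".join(str(int(a)) for a in gm.geno[i].ravel())
                fh.write(f"{label} {pop} {alleles}\n")
            else:
                raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Population metadata
# ---------------------------------------------------------------------------

def _haversine_km(lat1, lon1, lat2, lon2):
    r = 6371.0
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlmb = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlmb / 2) ** 2
    return 2 * r * math.asin(math.sqrt(a))


def read_meta_csv(path) -> pd.DataFrame:
    """Read a per-population metadata CSV.

    Required columns: population, latitude, longitude, elevation_m.  When a
    ``distance_km`` column is absent, transect distances are derived as
    great-circle distance from the northernmost population (anchored at 0,
    increasing southward).
    """
    meta = pd.read_csv(path)
    missing = [c for c in META_REQUIRED if c not in meta.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    dups = meta["population"][meta["population"].duplicated()].tolist()
    if dups:
        raise ParseError(f"{path}: duplicate population codes {dups}")
    if "distance_km" not in meta.columns:
        north = meta.loc[meta["latitude"].idxmax()]
        meta = meta.copy()
        meta["distance_km"] = [
            _haversine_km(north["latitude"], north["longitude"], la, lo)
            for la, lo in zip(meta["latitude"], meta["longitude"])
        ]
    if (meta["distance_km"] < 0).any():
        raise ParseError(f"{path}: negative transect distances")
    return meta


def write_meta_csv(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, index=False)
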