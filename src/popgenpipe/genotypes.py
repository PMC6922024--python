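"""Core genotype containers shared by every analysis stage.

Genotypes are stored as a samples x SNPs dosage matrix counting copies of
``allele_b`` at each locus (0, 1, 2) with :data:`MISSING` (= -1) for no-calls.
The SNP map is a :class:`pandas.DataFrame` with one row per locus, sorted by
(chromosome, position); coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Dosage code for a missing genotype call.
MISSING: int = -1

#: Columns required in the SNP map frame.
SNP_COLUMNS = ("id", "chrom", "pos", "allele_a", "allele_b")


class GenotypeError(ValueError):
    """Raised on malformed or inconsistent genotype data."""


def snp_table(
    ids: Sequence[str],
    chrom: Sequence[int],
    pos: Sequence[int],
    allele_a: Sequence[str],
    allele_b: Sequence[str],
) -> pd.DataFrame:
    """Assemble a SNP map frame with the canonical column set and dtypes."""
    df = pd.DataFrame(
        {
            "id": np.asarray(ids, dtype=object),
            "chrom": np.asarray(chrom, dtype=np.int64),
            "pos": np.asarray(pos, dtype=np.int64),
            "allele_a": np.asarray(allele_a, dtype=object),
            "allele_b": np.asarray(allele_b, dtype=object),
        }
    )
    df.reset_index(drop=True, inplace=True)
    return df


@dataclass
class GenotypeMatrix:
    """Diploid biallelic genotype panel with sample metadata and SNP map.

    Parameters
    ----------
    sample_ids :
        Unique sample identifiers, one per matrix row.
    populations :
        Population label per sample (PLINK family ID).
    snps :
        SNP map frame with columns ``id, chrom, pos, allele_a, allele_b``.
    dosage :
        ``(n_samples, n_snps)`` int8 array counting ``allele_b`` copies;
        ``MISSING`` marks no-calls.
    """

    sample_ids: np.ndarray
    populations: np.ndarray
    snps: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.populations = np.asarray(self.populations, dtype=object)
        self.dosage = np.asarray(self.dosage)
        if self.dosage.dtype != np.int8:
            self.dosage = self.dosage.astype(np.int8)
        self.snps = self.snps.reset_index(drop=True)
        self.validate()

    # -- invariants ------------------------------------------------------

    def validate(self) -> None:
        """Check structural invariants; raise :class:`GenotypeError` on failure."""
        n, m = self.dosage.shape
        if len(self.sample_ids) != n:
            raise GenotypeError(
                f"sample_ids length {len(self.sample_ids)} != dosage rows {n}"
            )
        if len(self.populations) != n:
            raise GenotypeError("populations length does not match sample count")
        if len(self.snps) != m:
            raise GenotypeError(f"snp table length {len(self.snps)} != dosage cols {m}")
        missing_cols = [c for c in SNP_COLUMNS if c not in self.snps.columns]
        if missing_cols:
            raise GenotypeError(f"snp table missing columns {missing_cols}")
        if len(set(self.sample_ids)) != n:
            raise GenotypeError("duplicate sample ids")
        if self.snps["id"].duplicated().any():
            dups = self.snps.loc[self.snps["id"].duplicated(), "id"].tolist()[:5]
            raise GenotypeError(f"duplicate SNP ids, e.g. {dups}")
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise GenotypeError(
                f"invalid dosage code {self.dosage[i, j]} at sample "
                f"{self.sample_ids[i]!r}, snp {self.snps['id'].iloc[j]!r}"
            )
        if m and (self.snps["pos"].to_numpy() < 1).any():
            raise GenotypeError("positions must be >= 1 (1-based)")

    # -- basic properties ------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    @property
    def population_labels(self) -> list[str]:
        """Distinct population labels in order of first appearance."""
        return list(dict.fromkeys(self.populations))

    def is_sorted(self) -> bool:
        """True if SNPs are sorted by (chromosome, position)."""
        c = self.snps["chrom"].to_numpy()
        p = self.snps["pos"].to_numpy()
        if len(c) < 2:
            return True
        key = c.astype(np.int64) * (p.max() + 1) + p
        return bool(np.all(np.diff(key) >= 0))

    # -- views / subsets -------------------------------------------------

    def take_samples(self, index: Iterable[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(list(index), dtype=np.int64)
        return GenotypeMatrix(
            self.sample_ids[idx],
            self.populations[idx],
            self.snps.copy(),
            self.dosage[idx, :].copy(),
        )

    def take_snps(self, index: Iterable[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(list(index), dtype=np.int64)
        return GenotypeMatrix(
            self.sample_ids.copy(),
            self.populations.copy(),
            self.snps.iloc[idx],
            self.dosage[:, idx].copy(),
        )

    def for_population(self, label: str) -> "GenotypeMatrix":
        """Subset to the samples carrying population ``label``."""
        mask = self.populations == label
        if not mask.any():
            raise KeyError(f"population label {label!r} not present")
        return self.take_samples(np.flatnonzero(mask))

    def sort_snps(self) -> "GenotypeMatrix":
        order = np.lexsort(
            (self.snps["pos"].to_numpy(), self.snps["chrom"].to_numpy())
        )
        return self.take_snps(order)

    # -- per-locus statistics -------------------------------------------

    def called_mask(self) -> np.ndarray:
        """Boolean (samples x SNPs) mask of non-missing calls."""
        return self.dosage != MISSING

    def allele_b_freq(self) -> np.ndarray:
        """Frequency of ``allele_b`` per locus over non-missing calls (NaN if none)."""
        called = self.called_mask()
        n = called.sum(axis=0)
        tot = np.where(called, self.dosage, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, tot / (2.0 * n), np.nan)

    def maf(self) -> np.ndarray:
        p = self.allele_b_freq()
        return np.minimum(p, 1.0 - p)

    def snp_call_rate(self) -> np.ndarray:
        return self.called_mask().mean(axis=0)

    def sample_missing_rate(self) -> np.ndarray:
        return 1.0 - self.called_mask().mean(axis=1)

    # -- comparisons -----------------------------------------------------

    def equals(self, other: "GenotypeMatrix", harmonize_alleles: bool = False) -> bool:
        """Exact content equality; optionally modulo allele-label swaps.

        With ``harmonize_alleles`` a locus coded (A,B) in ``self`` and (B,A)
        in ``other`` compares equal after flipping the other's dosages 0<->2.
        """
        if (
            not np.array_equal(self.sample_ids, other.sample_ids)
            or not np.array_equal(self.populations, other.populations)
            or self.dosage.shape != other.dosage.shape
        ):
            return False
        s, o = self.snps, other.snps
        for col in ("id", "chrom", "pos"):
            if not np.array_equal(s[col].to_numpy(), o[col].to_numpy()):
                return False
        sa = s["allele_a"].to_numpy(dtype=object)
        sb = s["allele_b"].to_numpy(dtype=object)
        oa = o["allele_a"].to_numpy(dtype=object)
        ob = o["allele_b"].to_numpy(dtype=object)
        if not harmonize_alleles:
            if not ((sa == oa) & (sb == ob)).all():
                return False
            return np.array_equal(self.dosage, other.dosage)

        # '0' marks an allele unseen in the data (e.g. lost to drift before a
        # PED write); treat it as compatible with anything
        def _compat(x, y):
            return (x == y) | (x == "0") | (y == "0")

        same = _compat(sa, oa) & _compat(sb, ob)
        swapped = _compat(sa, ob) & _compat(sb, oa) & ~same
        if not (same | swapped).all():
            return False
        od = other.dosage.copy()
        flip = np.flatnonzero(swapped & ~same)
        for j in flip:
            col = od[:, j]
            called = col != MISSING
            od[called, j] = 2 - col[called]
        return np.array_equal(self.dosage, od)


@dataclass
class RelationshipMatrix:
    """Symmetric realized-relationship (UAR/GRM) matrix over samples."""

    sample_ids: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise GenotypeError("relationship matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise GenotypeError("relationship matrix is not symmetric")

    def off_diagonal_pairs(self, threshold: float) -> list[tuple[int, int, float]]:
        """All unordered (i, j, value) pairs with value > threshold."""
        iu, ju = np.triu_indices(len(self.sample_ids), k=1)
        vals = self.values[iu, ju]
        keep = vals > threshold
        return list(zip(iu[keep].tolist(), ju[keep].tolist(), vals[keep].tolist()))


def concatenate_samples(a: GenotypeMatrix, b: GenotypeMatrix) -> GenotypeMatrix:
    """Stack two panels that share an identical SNP map."""
    if not a.snps[["id", "chrom", "pos"]].equals(b.snps[["id", "chrom", "pos"]]):
        raise GenotypeError("panels do not share an identical SNP map")
    dup = set(a.sample_ids) & set(b.sample_ids)
    if dup:
        raise GenotypeError(f"duplicate sample ids across panels: {sorted(dup)[:5]}")
    return GenotypeMatrix(
        np.concatenate([a.sample_ids, b.sample_ids]),
        np.concatenate([a.populations, b.populations]),
        a.snps.copy(),
        np.vstack([a.dosage, b.dosage]),
    )
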