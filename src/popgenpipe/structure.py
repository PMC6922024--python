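"""Between-population structure: Weir-Cockerham FST, IBS/MDS, PCA, exporters."""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeError, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class FstMatrix:
    """Symmetric pairwise multilocus theta matrix over populations."""

    populations: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.populations)
        if self.values.shape != (k, k):
            raise ValueError("matrix shape does not match population count")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.populations, columns=self.populations)

    def get(self, a: str, b: str) -> float:
        return float(self.to_frame().loc[a, b])


@dataclass
class Ordination:
    """Low-dimensional sample embedding with per-axis explained fractions."""

    sample_ids: np.ndarray
    coordinates: np.ndarray
    explained_fraction: np.ndarray

    def to_frame(self, populations: np.ndarray | None = None) -> pd.DataFrame:
        k = self.coordinates.shape[1]
        df = pd.DataFrame(
            self.coordinates, columns=[f"axis{i + 1}" for i in range(k)]
        )
        df.insert(0, "sample_id", self.sample_ids)
        if populations is not None:
            df.insert(1, "population", populations)
        return df


# ---------------------------------------------------------------------------
# FST
# ---------------------------------------------------------------------------


def _wc_components(
    n: np.ndarray, p: np.ndarray, h: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir & Cockerham (1984) per-locus variance components a, b, c.

    Arrays are populations x loci: ``n`` sample sizes (diploid counts),
    ``p`` allele frequencies, ``h`` observed heterozygote frequencies.
    """
    r = n.shape[0]
    nbar = n.mean(axis=0)
    nc = (r * nbar - (n**2).sum(axis=0) / (r * nbar)) / (r - 1)
    pbar = (n * p).sum(axis=0) / (r * nbar)
    s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n * h).sum(axis=0) / (r * nbar)
    a = (nbar / nc) * (
        s2
        - (1.0 / (nbar - 1.0))
        * (pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1.0 - pbar)
        - ((r - 1.0) / r) * s2
        - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
    )
    c = hbar / 2.0
    return a, b, c


def pairwise_fst(g: GenotypeMatrix, pop_a: str, pop_b: str) -> float:
    """Multilocus Weir-Cockerham theta between two populations.

    Per-locus components a, b, c are combined as ratio of sums,
    ``theta = sum(a) / sum(a + b + c)``; loci monomorphic across both
    populations (or with <2 calls in either) are excluded. Negative
    per-locus components are retained.
    """
    stats = []
    for pop in (pop_a, pop_b):
        d = g.dosage[g.populations == pop, :]
        if d.shape[0] == 0:
            raise KeyError(f"population label {pop!r} not present")
        called = d != MISSING
        nloc = called.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(called, d, 0).sum(axis=0) / (2.0 * nloc)
            h = (d == 1).sum(axis=0) / nloc
        stats.append((nloc, p, h))
    n = np.vstack([s[0] for s in stats])
    p = np.vstack([s[1] for s in stats])
    h = np.vstack([s[2] for s in stats])
    usable = (n >= 2).all(axis=0)
    poly = ~np.all(p == p[0:1, :], axis=0) | ((p[0] > 0) & (p[0] < 1))
    keep = usable & poly & ~np.isnan(p).any(axis=0)
    if not keep.any():
        raise GenotypeError(
            f"no usable loci for FST between {pop_a!r} and {pop_b!r}"
        )
    a, b, c = _wc_components(n[:, keep], p[:, keep], h[:, keep])
    denom = (a + b + c).sum()
    if denom == 0:
        raise GenotypeError(f"zero FST denominator for {pop_a!r} vs {pop_b!r}")
    return float(a.sum() / denom)


def fst_matrix(g: GenotypeMatrix) -> FstMatrix:
    """All unordered population pairs via :func:`pairwise_fst`."""
    pops = g.population_labels
    if len(pops) < 2:
        raise GenotypeError("need >=2 populations for an FST matrix")
    k = len(pops)
    vals = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            try:
                theta = pairwise_fst(g, pops[i], pops[j])
            except GenotypeError as e:
                raise GenotypeError(f"pair ({pops[i]}, {pops[j]}): {e}") from e
            vals[i, j] = vals[j, i] = theta
    return FstMatrix(pops, vals)


# ---------------------------------------------------------------------------
# IBS / MDS / PCA
# ---------------------------------------------------------------------------


def ibs_distance_matrix(g: GenotypeMatrix) -> pd.DataFrame:
    """Pairwise identity-by-state distance: 1 - shared alleles / (2 * loci).

    Loci with a missing call in either sample are skipped for that pair. For
    dosages the per-locus shared allele count is ``2 - |x - y|``, so the
    distance is ``mean(|x - y|) / 2`` over comparable loci.
    """
    if g.n_samples < 2:
        raise GenotypeError("need >=2 samples")
    x = g.dosage.astype(float)
    called = (g.dosage != MISSING).astype(float)
    x0 = np.where(g.dosage != MISSING, x, 0.0)
    # |x-y| summed over shared loci via (x-y)^2 trick is wrong for dosage 0/2;
    # use three matrix products on indicator matrices instead
    inds = [(g.dosage == v).astype(float) for v in (0, 1, 2)]
    absdiff = np.zeros((g.n_samples, g.n_samples))
    for vi, iv in enumerate(inds):
        for vj, jv in enumerate(inds):
            if vi == vj:
                continue
            absdiff += abs(vi - vj) * (iv @ jv.T)
    n_shared = called @ called.T
    if (n_shared[np.triu_indices(g.n_samples, 1)] == 0).any():
        iu, ju = np.triu_indices(g.n_samples, 1)
        bad = np.flatnonzero(n_shared[iu, ju] == 0)[0]
        raise GenotypeError(
            f"no comparable loci between samples {g.sample_ids[iu[bad]]!r} "
            f"and {g.sample_ids[ju[bad]]!r}"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = absdiff / (2.0 * n_shared)
    np.fill_diagonal(dist, 0.0)
    return pd.DataFrame(dist, index=g.sample_ids, columns=g.sample_ids)


def classical_mds(d: pd.DataFrame | np.ndarray, k: int = 2) -> Ordination:
    """Torgerson MDS: double-centre ``-d^2/2``, eigendecompose, scale by sqrt(eig).

    Explained fraction per axis = eigenvalue / sum of positive eigenvalues.
    ``k`` is reduced (with a warning) if fewer positive eigenvalues exist.
    """
    if isinstance(d, pd.DataFrame):
        ids = np.asarray(d.index, dtype=object)
        dm = d.to_numpy(dtype=float)
    else:
        dm = np.asarray(d, dtype=float)
        ids = np.array([f"s{i}" for i in range(dm.shape[0])], dtype=object)
    if not np.allclose(dm, dm.T) or not np.allclose(np.diag(dm), 0.0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    n = dm.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dm**2) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-12 * max(evals.max(), 1.0)
    n_pos = int(pos.sum())
    if k > n_pos:
        logger.warning("classical_mds: reducing k from %d to %d positive axes", k, n_pos)
        k = n_pos
    coords = evecs[:, :k] * np.sqrt(evals[:k])
    explained = evals[:k] / evals[pos].sum()
    return Ordination(ids, coords, explained)


def pca(g: GenotypeMatrix, k: int = 10, scaling: str = "patterson") -> Ordination:
    """Genotype PCA with mean imputation and optional Patterson scaling.

    Loci are centred by ``2p``; ``patterson`` scaling divides by
    ``sqrt(p(1-p))`` (monomorphic loci excluded), ``unit`` leaves columns
    unscaled. Missing dosages are mean-imputed per locus before the SVD.
    """
    if scaling not in ("patterson", "unit"):
        raise ValueError(f"unknown scaling {scaling!r}")
    p = g.allele_b_freq()
    keep = ~np.isnan(p)
    if scaling == "patterson":
        keep &= (p > 0) & (p < 1)
    x = g.dosage[:, keep].astype(float)
    pk = p[keep]
    x = np.where(g.dosage[:, keep] == MISSING, 2.0 * pk, x)
    x -= 2.0 * pk
    if scaling == "patterson":
        x /= np.sqrt(pk * (1.0 - pk))
    k = min(k, min(x.shape) - 1) if min(x.shape) > 1 else 1
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    coords = u[:, :k] * s[:k]
    explained = (s**2)[:k] / (s**2).sum()
    return Ordination(g.sample_ids.copy(), coords, explained)


# ---------------------------------------------------------------------------
# exporters
# ---------------------------------------------------------------------------


def _sanitize_labels(labels: list[str]) -> tuple[list[str], dict[str, str]]:
    mapping = {}
    out = []
    for lab in labels:
        clean = re.sub(r"\s+", "_", lab)
        mapping[clean] = lab
        out.append(clean)
    return out, mapping


def write_phylip(fst: FstMatrix, path: str | Path) -> None:
    """Square PHYLIP distance matrix (strict 10-char name field)."""
    labels, mapping = _sanitize_labels(fst.populations)
    with open(path, "w") as fh:
        fh.write(f"{len(labels)}\n")
        for lab, row in zip(labels, fst.values):
            fh.write(f"{lab[:10]:<10}" + " ".join(f"{v:.6f}" for v in row) + "\n")
    if any(k != v for k, v in mapping.items()):
        with open(str(path) + ".labels", "w") as fh:
            for k, v in mapping.items():
                fh.write(f"{k}\t{v}\n")


def read_phylip(path: str | Path) -> FstMatrix:
    with open(path) as fh:
        n = int(fh.readline().split()[0])
        labels, rows = [], []
        for _ in range(n):
            parts = fh.readline().split()
            labels.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    return FstMatrix(labels, np.array(rows))


def write_nexus(fst: FstMatrix, path: str | Path) -> None:
    """NEXUS Distances block (SplitsTree input)."""
    labels, _ = _sanitize_labels(fst.populations)
    n = len(labels)
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN Taxa;\n")
        fh.write(f"DIMENSIONS ntax={n};\nTAXLABELS\n")
        for i, lab in enumerate(labels, 1):
            fh.write(f"[{i}] '{lab}'\n")
        fh.write(";\nEND;\n\nBEGIN Distances;\n")
        fh.write(f"DIMENSIONS ntax={n};\n")
        fh.write("FORMAT labels=left diagonal triangle=both;\nMATRIX\n")
        for lab, row in zip(labels, fst.values):
            fh.write(f"'{lab}'\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")
        fh.write(";\nEND;\n")


def read_nexus(path: str | Path) -> FstMatrix:
    labels, rows = [], []
    in_matrix = False
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if s.upper() == "MATRIX":
                in_matrix = True
                continue
            if in_matrix:
                if s == ";":
                    break
                parts = s.split("\t")
                labels.append(parts[0].strip("'"))
                rows.append([float(v) for v in parts[1:]])
    return FstMatrix(labels, np.array(rows))


def write_treemix(g: GenotypeMatrix, path: str | Path) -> None:
    """TreeMix allele-count table, gzip text: one ``countA,countB`` per pop."""
    pops = g.population_labels
    labels, _ = _sanitize_labels(pops)
    counts = {}
    for pop in pops:
        d = g.dosage[g.populations == pop, :]
        called = d != MISSING
        nb = np.where(called, d, 0).sum(axis=0)
        na = 2 * called.sum(axis=0) - nb
        counts[pop] = (na, nb)
    with gzip.open(path, "wt") as fh:
        fh.write(" ".join(labels) + "\n")
        for j in range(g.n_snps):
            fh.write(
                " ".join(f"{counts[p][0][j]},{counts[p][1][j]}" for p in pops) + "\n"
            )


def export_external(
    obj: "FstMatrix | GenotypeMatrix", format: str, path_prefix: str | Path
) -> list[Path]:
    """Dispatch exporter: phylip | nexus | admixture_ped | treemix_freq."""
    from . import genotype_io

    stem = Path(path_prefix)
    stem.parent.mkdir(parents=True, exist_ok=True)
    if format == "phylip":
        out = stem.with_suffix(".phy")
        write_phylip(obj, out)
        return [out]
    if format == "nexus":
        out = stem.with_suffix(".nex")
        write_nexus(obj, out)
        return [out]
    if format == "admixture_ped":
        genotype_io.write_plink(obj, stem, format="ped")
        return [stem.with_suffix(".ped"), stem.with_suffix(".map")]
    if format == "treemix_freq":
        out = Path(str(stem) + ".treemix.gz")
        write_treemix(obj, out)
        return [out]
    raise ValueError(f"unknown export format {format!r}")
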