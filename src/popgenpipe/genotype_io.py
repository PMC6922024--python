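"""PLINK-format I/O, panel merging, QC filtering, and relatedness pruning.

Supports the two PLINK 1.x dialects: text PED/MAP and binary BED/BIM/FAM
(variant-major BED, magic ``0x6c 0x1b 0x01``). Dosage counts copies of
``allele_b``, which maps onto the BIM A2 column; BED two-bit codes are
``00`` hom-A1, ``01`` missing, ``10`` het, ``11`` hom-A2.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import (
    MISSING,
    GenotypeError,
    GenotypeMatrix,
    RelationshipMatrix,
    snp_table,
)

logger = logging.getLogger(__name__)
if not logger.handlers:  # default: per-step counts on stderr
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(name)s: %(message)s"))
    logger.addHandler(_h)

_BED_MAGIC = bytes([0x6C, 0x1B])
_BED_VARIANT_MAJOR = 0x01

#: BED 2-bit code -> dosage of allele_b (A2). 01 is the missing code.
_BED_CODE_TO_DOSAGE = np.array([0, MISSING, 1, 2], dtype=np.int8)
_DOSAGE_TO_BED_CODE = {0: 0, MISSING: 1, 1: 2, 2: 3}


class PlinkFormatError(GenotypeError):
    """Malformed or mutually inconsistent PLINK files."""


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------


def read_plink(path_prefix: str | Path, format: str | None = None) -> GenotypeMatrix:
    """Read a PLINK fileset given its path stem.

    Parameters
    ----------
    path_prefix :
        Path without extension; ``<stem>.ped/.map`` or ``<stem>.bed/.bim/.fam``.
    format :
        ``"ped"`` or ``"bed"``; autodetected from existing files when omitted.

    The population label of each sample is taken from the family-ID column.
    """
    stem = Path(path_prefix)
    if format is None:
        if stem.with_suffix(".bed").exists():
            format = "bed"
        elif stem.with_suffix(".ped").exists():
            format = "ped"
        else:
            raise FileNotFoundError(f"no .ped or .bed file at stem {stem}")
    if format == "ped":
        return _read_ped(stem)
    if format == "bed":
        return _read_bed(stem)
    raise ValueError(f"unknown format {format!r}; expected 'ped' or 'bed'")


def _read_map(path: Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) not in (3, 4):
                raise PlinkFormatError(f"{path}:{ln}: expected 3-4 columns")
            chrom, snp_id = parts[0], parts[1]
            pos = parts[-1]
            rows.append((_parse_chrom(chrom, path, ln), snp_id, int(pos)))
    return pd.DataFrame(rows, columns=["chrom", "id", "pos"])


def _parse_chrom(token: str, path: Path, ln: int) -> int:
    named = {"X": 27, "Y": 28, "XY": 29, "MT": 30, "M": 30}
    if token in named:
        return named[token]
    try:
        return int(token)
    except ValueError:
        raise PlinkFormatError(f"{path}:{ln}: unrecognized chromosome {token!r}")


def _read_ped(stem: Path) -> GenotypeMatrix:
    map_df = _read_map(stem.with_suffix(".map"))
    m = len(map_df)
    sample_ids: list[str] = []
    pops: list[str] = []
    allele_rows: list[np.ndarray] = []
    with open(stem.with_suffix(".ped")) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise PlinkFormatError(
                    f"{stem}.ped:{ln}: expected {6 + 2 * m} fields for {m} "
                    f"mapped SNPs, got {len(parts)}"
                )
            pops.append(parts[0])
            sample_ids.append(parts[1])
            allele_rows.append(np.array(parts[6:], dtype=object).reshape(m, 2))
    if not allele_rows:
        raise PlinkFormatError(f"{stem}.ped: no samples")
    alleles = np.stack(allele_rows)  # (n, m, 2)

    # Determine the two observed alleles per locus; counted allele (allele_b)
    # is the minor one, ties broken by lexicographic order (PLINK A1=minor).
    n = len(sample_ids)
    dosage = np.full((n, m), MISSING, dtype=np.int8)
    a_codes: list[str] = []
    b_codes: list[str] = []
    for j in range(m):
        col = alleles[:, j, :]
        called = (col[:, 0] != "0") & (col[:, 1] != "0")
        half_called = (col[:, 0] != "0") != (col[:, 1] != "0")
        if half_called.any():
            raise PlinkFormatError(
                f"{stem}.ped: half-missing genotype at locus "
                f"{map_df['id'].iloc[j]!r}"
            )
        obs, counts = np.unique(col[called], return_counts=True)
        obs = [o for o in obs]
        if len(obs) > 2:
            raise PlinkFormatError(
                f"{stem}.ped: >2 alleles {obs} at locus {map_df['id'].iloc[j]!r}"
            )
        tally = dict(zip(obs, counts))
        if len(obs) == 0:
            a, b = "0", "0"
        elif len(obs) == 1:
            a, b = obs[0], "0"
        else:
            # minor allele = fewer copies; tie -> lexicographically larger
            # becomes allele_b so behaviour is deterministic
            o0, o1 = sorted(obs)
            b, a = (o0, o1) if tally[o0] < tally[o1] else (o1, o0)
        a_codes.append(a)
        b_codes.append(b)
        if b != "0":
            dosage[called, j] = (col[called] == b).sum(axis=1)
        else:
            dosage[called, j] = 0
    order_snps = map_df  # keep file order; caller may sort
    snps = snp_table(order_snps["id"], order_snps["chrom"], order_snps["pos"], a_codes, b_codes)
    return GenotypeMatrix(np.array(sample_ids), np.array(pops), snps, dosage)


def _read_fam(path: Path) -> tuple[np.ndarray, np.ndarray]:
    fam = pd.read_csv(path, sep=r"\s+", header=None, dtype=str)
    if fam.shape[1] < 2:
        raise PlinkFormatError(f"{path}: expected >=2 columns")
    return fam[1].to_numpy(dtype=object), fam[0].to_numpy(dtype=object)


def _read_bim(path: Path) -> pd.DataFrame:
    bim = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        dtype={"id": str, "a1": str, "a2": str},
    )
    if bim.isna().any().any():
        raise PlinkFormatError(f"{path}: expected 6 columns")
    return bim


def _read_bed(stem: Path) -> GenotypeMatrix:
    sample_ids, pops = _read_fam(stem.with_suffix(".fam"))
    bim = _read_bim(stem.with_suffix(".bim"))
    n, m = len(sample_ids), len(bim)
    raw = Path(stem.with_suffix(".bed")).read_bytes()
    if len(raw) < 3 or raw[:2] != _BED_MAGIC:
        raise PlinkFormatError(f"{stem}.bed: missing BED magic bytes 0x6c 0x1b")
    if raw[2] != _BED_VARIANT_MAJOR:
        raise PlinkFormatError(f"{stem}.bed: not variant-major (mode {raw[2]:#x})")
    bytes_per_snp = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if len(body) != bytes_per_snp * m:
        raise PlinkFormatError(
            f"{stem}.bed: size {len(body)} bytes does not match "
            f"{n} samples x {m} SNPs"
        )
    body = body.reshape(m, bytes_per_snp)
    # unpack 2-bit codes, little-endian within byte
    codes = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (body >> (2 * k)) & 0b11
    dosage = _BED_CODE_TO_DOSAGE[codes[:, :n]].T.copy()
    chrom = np.array([_parse_chrom(str(c), stem, i) for i, c in enumerate(bim["chrom"])])
    snps = snp_table(bim["id"], chrom, bim["pos"], bim["a1"], bim["a2"])
    return GenotypeMatrix(sample_ids, pops, snps, dosage)


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------


def write_plink(g: GenotypeMatrix, path_prefix: str | Path, format: str = "ped") -> None:
    """Write ``g`` as ``<stem>.ped/.map`` or ``<stem>.bed/.bim/.fam``."""
    stem = Path(path_prefix)
    stem.parent.mkdir(parents=True, exist_ok=True)
    if format == "ped":
        _write_ped(g, stem)
    elif format == "bed":
        _write_bed(g, stem)
    else:
        raise ValueError(f"unknown format {format!r}")


def _map_lines(g: GenotypeMatrix):
    for rec in g.snps.itertuples(index=False):
        yield f"{rec.chrom}\t{rec.id}\t0\t{rec.pos}\n"


def _write_ped(g: GenotypeMatrix, stem: Path) -> None:
    with open(stem.with_suffix(".map"), "w") as fh:
        fh.writelines(_map_lines(g))
    aa = g.snps["allele_a"].to_numpy(dtype=object)
    bb = g.snps["allele_b"].to_numpy(dtype=object)
    with open(stem.with_suffix(".ped"), "w") as fh:
        for i in range(g.n_samples):
            fields = [
                str(g.populations[i]), str(g.sample_ids[i]), "0", "0", "0", "-9",
            ]
            row = g.dosage[i]
            for j in range(g.n_snps):
                d = row[j]
                if d == MISSING:
                    fields += ["0", "0"]
                elif d == 0:
                    fields += [aa[j], aa[j]]
                elif d == 1:
                    fields += [aa[j], bb[j]]
                else:
                    fields += [bb[j], bb[j]]
            fh.write(" ".join(fields) + "\n")


def _write_bed(g: GenotypeMatrix, stem: Path) -> None:
    with open(stem.with_suffix(".fam"), "w") as fh:
        for i in range(g.n_samples):
            fh.write(f"{g.populations[i]} {g.sample_ids[i]} 0 0 0 -9\n")
    with open(stem.with_suffix(".bim"), "w") as fh:
        for rec in g.snps.itertuples(index=False):
            fh.write(
                f"{rec.chrom}\t{rec.id}\t0\t{rec.pos}\t{rec.allele_a}\t{rec.allele_b}\n"
            )
    n, m = g.n_samples, g.n_snps
    bytes_per_snp = (n + 3) // 4
    codes = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    code_lut = np.zeros(4, dtype=np.uint8)
    for dos, code in _DOSAGE_TO_BED_CODE.items():
        code_lut[dos % 4] = code  # MISSING=-1 -> index 3
    codes[:, :n] = code_lut[g.dosage.T % 4]
    codes[:, n:] = 0
    body = np.zeros((m, bytes_per_snp), dtype=np.uint8)
    for k in range(4):
        body |= codes[:, k::4] << (2 * k)
    with open(stem.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC + bytes([_BED_VARIANT_MAJOR]))
        fh.write(body.tobytes())


# ---------------------------------------------------------------------------
# panel intersection
# ---------------------------------------------------------------------------


def intersect_panels(a: GenotypeMatrix, b: GenotypeMatrix) -> GenotypeMatrix:
    """Merge two panels on their shared SNP ids, concatenating samples.

    Alleles are harmonized so the merged dosage counts the same allele in
    both inputs: a locus coded (A,B) in ``a`` and (B,A) in ``b`` flips the
    ``b`` dosages 0<->2. Loci whose allele pairs cannot be reconciled
    (including strand-ambiguous swaps) are dropped and logged.
    """
    dup = set(a.sample_ids) & set(b.sample_ids)
    if dup:
        raise GenotypeError(f"duplicate sample ids across panels: {sorted(dup)[:5]}")
    ids_a = {s: i for i, s in enumerate(a.snps["id"])}
    shared = [s for s in b.snps["id"] if s in ids_a]
    if not shared:
        raise GenotypeError("zero overlapping SNPs between panels")
    idx_b = {s: i for i, s in enumerate(b.snps["id"])}
    ja = np.array([ids_a[s] for s in shared])
    jb = np.array([idx_b[s] for s in shared])

    aa_a = a.snps["allele_a"].to_numpy(dtype=object)[ja]
    ab_a = a.snps["allele_b"].to_numpy(dtype=object)[ja]
    aa_b = b.snps["allele_a"].to_numpy(dtype=object)[jb]
    ab_b = b.snps["allele_b"].to_numpy(dtype=object)[jb]
    # monomorphic loci may carry a '0' placeholder for the unseen allele
    def _compat(x, y):
        return (x == y) | (x == "0") | (y == "0")

    same = _compat(aa_a, aa_b) & _compat(ab_a, ab_b)
    swapped = _compat(aa_a, ab_b) & _compat(ab_a, aa_b) & ~same
    keep = same | swapped
    if (~keep).any():
        dropped = [shared[k] for k in np.flatnonzero(~keep)]
        logger.warning(
            "intersect_panels: dropped %d loci with irreconcilable alleles: %s%s",
            len(dropped), dropped[:5], "..." if len(dropped) > 5 else "",
        )
    ja, jb = ja[keep], jb[keep]
    same, swapped = same[keep], swapped[keep]
    aa_b, ab_b = aa_b[keep], ab_b[keep]
    if ja.size == 0:
        raise GenotypeError("zero overlapping SNPs after allele harmonization")

    dos_a = a.dosage[:, ja]
    dos_b = b.dosage[:, jb].copy()
    for j in np.flatnonzero(swapped):
        col = dos_b[:, j]
        called = col != MISSING
        dos_b[called, j] = 2 - col[called]
    snps = a.snps.iloc[ja].copy()
    # fill any '0' placeholder alleles from the other panel's codes
    fa = snps["allele_a"].to_numpy(dtype=object)
    fb = snps["allele_b"].to_numpy(dtype=object)
    other_a = np.where(swapped, ab_b, aa_b)
    other_b = np.where(swapped, aa_b, ab_b)
    snps["allele_a"] = np.where(fa == "0", other_a, fa)
    snps["allele_b"] = np.where(fb == "0", other_b, fb)
    merged = GenotypeMatrix(
        np.concatenate([a.sample_ids, b.sample_ids]),
        np.concatenate([a.populations, b.populations]),
        snps,
        np.vstack([dos_a, dos_b]),
    )
    logger.info(
        "intersect_panels: %d shared loci, %d samples", merged.n_snps, merged.n_samples
    )
    return merged


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


@dataclass
class QCConfig:
    """Thresholds for the fixed-order QC filter chain."""

    snp_call_rate_min: float = 0.90
    sample_missing_max: float = 0.10
    maf_min: float = 0.05
    autosomes_only: bool = True
    n_autosomes: int = 26

    def __post_init__(self) -> None:
        for name in ("snp_call_rate_min", "sample_missing_max", "maf_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")


@dataclass
class QCReport:
    """Per-step removal counts from :func:`apply_qc`."""

    n_samples_in: int = 0
    n_snps_in: int = 0
    samples_removed_missing: int = 0
    snps_removed_nonautosomal: int = 0
    snps_removed_call_rate: int = 0
    snps_removed_maf: int = 0
    n_samples_out: int = 0
    n_snps_out: int = 0
    removed_sample_ids: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    def to_frame(self) -> pd.DataFrame:
        d = asdict(self)
        d.pop("removed_sample_ids")
        return pd.DataFrame(
            {"step": list(d.keys()), "count": list(d.values())}
        )


def apply_qc(g: GenotypeMatrix, cfg: QCConfig | None = None) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the QC filter chain in fixed order and report per-step counts.

    Order: (1) samples with missing rate > ``sample_missing_max``;
    (2) non-autosomal SNPs; (3) SNPs with call rate < ``snp_call_rate_min``;
    (4) SNPs with MAF < ``maf_min`` computed on the retained samples,
    non-missing calls only.
    """
    if cfg is None:
        cfg = QCConfig()
    if g.n_samples == 0 or g.n_snps == 0:
        raise GenotypeError("empty genotype matrix")
    rep = QCReport(n_samples_in=g.n_samples, n_snps_in=g.n_snps)

    # 1. samples
    miss = g.sample_missing_rate()
    keep_s = miss <= cfg.sample_missing_max
    rep.samples_removed_missing = int((~keep_s).sum())
    rep.removed_sample_ids = [str(s) for s in g.sample_ids[~keep_s]]
    if not keep_s.any():
        raise GenotypeError("empty after QC: all samples exceeded missing-rate cap")
    g = g.take_samples(np.flatnonzero(keep_s))

    # 2. autosomes
    if cfg.autosomes_only:
        chrom = g.snps["chrom"].to_numpy()
        keep = (chrom >= 1) & (chrom <= cfg.n_autosomes)
        rep.snps_removed_nonautosomal = int((~keep).sum())
        g = g.take_snps(np.flatnonzero(keep))

    # 3. call rate
    if g.n_snps:
        keep = g.snp_call_rate() >= cfg.snp_call_rate_min
        rep.snps_removed_call_rate = int((~keep).sum())
        g = g.take_snps(np.flatnonzero(keep))

    # 4. MAF on retained samples
    if g.n_snps:
        maf = g.maf()
        keep = np.nan_to_num(maf, nan=-1.0) >= cfg.maf_min
        rep.snps_removed_maf = int((~keep).sum())
        g = g.take_snps(np.flatnonzero(keep))

    if g.n_snps == 0:
        raise GenotypeError("empty after QC: no SNPs survived the filters")
    rep.n_samples_out, rep.n_snps_out = g.n_samples, g.n_snps
    logger.info(
        "apply_qc: samples %d->%d, snps %d->%d (nonauto %d, call-rate %d, maf %d)",
        rep.n_samples_in, rep.n_samples_out, rep.n_snps_in, rep.n_snps_out,
        rep.snps_removed_nonautosomal, rep.snps_removed_call_rate,
        rep.snps_removed_maf,
    )
    return g, rep


# ---------------------------------------------------------------------------
# relatedness
# ---------------------------------------------------------------------------


def compute_uar(g: GenotypeMatrix) -> RelationshipMatrix:
    """Unified additive relationship (UAR) matrix from SNP dosages.

    Off-diagonal: ``A_jk = mean_i (x_ij - 2p_i)(x_ik - 2p_i) / (2p_i(1-p_i))``.
    Diagonal (same-individual form):
    ``A_jj = 1 + mean_i (x^2 - (1+2p)x + 2p^2) / (2p(1-p))``.
    Missing genotypes are excluded pairwise; each pair's mean runs over the
    SNPs called in both individuals.
    """
    p = g.allele_b_freq()
    mono = np.isnan(p) | (p <= 0.0) | (p >= 1.0)
    if mono.any():
        raise GenotypeError(
            f"{int(mono.sum())} monomorphic/uncalled SNPs present; apply QC "
            "(MAF filter) before compute_uar"
        )
    x = g.dosage.astype(float)
    called = g.called_mask()
    denom = 2.0 * p * (1.0 - p)
    w = np.where(called, (x - 2.0 * p), 0.0) / np.sqrt(denom)
    v = called.astype(float)
    num = w @ w.T
    cnt = v @ v.T
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(cnt > 0, num / cnt, np.nan)
    # diagonal: 1 + mean of (x^2 - (1+2p)x + 2p^2) / (2p(1-p))
    diag_terms = np.where(called, x * x - (1.0 + 2.0 * p) * x + 2.0 * p * p, 0.0) / denom
    n_called = called.sum(axis=1)
    diag = 1.0 + diag_terms.sum(axis=1) / n_called
    np.fill_diagonal(a, diag)
    return RelationshipMatrix(g.sample_ids.copy(), a)


def prune_related(
    g: GenotypeMatrix,
    r: RelationshipMatrix,
    threshold: float = 0.35,
) -> GenotypeMatrix:
    """Greedily drop samples until no off-diagonal relationship exceeds ``threshold``.

    While any pair exceeds the threshold, removes the sample in the most
    above-threshold pairs; ties go to the larger mean relatedness among its
    flagged pairs, then to input order. Removed ids are logged.
    """
    if not np.array_equal(r.sample_ids, g.sample_ids):
        raise GenotypeError("relationship matrix does not match genotype samples")
    n = g.n_samples
    vals = r.values.copy()
    active = np.ones(n, dtype=bool)
    removed: list[int] = []
    while True:
        mask = np.outer(active, active)
        np.fill_diagonal(mask, False)
        over = (vals > threshold) & mask
        if not over.any():
            break
        deg = over.sum(axis=1)
        top = deg.max()
        cand = np.flatnonzero(deg == top)
        if len(cand) > 1:
            mean_rel = np.array(
                [vals[i][over[i]].mean() for i in cand]
            )
            cand = cand[mean_rel == mean_rel.max()]
        drop = int(cand[0])
        active[drop] = False
        removed.append(drop)
    if removed:
        logger.info(
            "prune_related: removed %d samples above %.2f: %s",
            len(removed), threshold, [str(g.sample_ids[i]) for i in removed],
        )
    return g.take_samples(np.flatnonzero(active))
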