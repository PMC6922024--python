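"""Consecutive-run (window-free) ROH detection and genomic inbreeding F_ROH.

A run of homozygosity is a maximal stretch of consecutive SNPs on one
chromosome of one individual containing at most ``max_het`` heterozygous and
``max_missing`` missing calls, bounded by homozygous SNPs, with at least
``min_snps`` SNPs and a physical span of at least ``min_length_bp``. Maximal
means no qualifying run strictly contains it; overlapping maximal candidates
(which share a het/missing allowance) are resolved by a greedy left-to-right
scan, ties broken toward the longer run. Run length is the distance between
the terminal SNPs (``end_bp - start_bp``), with no flanking extension.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

#: Autosomal genome length used as the default F_ROH denominator (bp).
DEFAULT_GENOME_LENGTH_BP: float = 2.44e9

#: Half-open ROH length classes in Mb: [1,2), [2,4), [4,8), [8,16), [16, inf).
LENGTH_CLASS_EDGES_MB = (1.0, 2.0, 4.0, 8.0, 16.0, math.inf)
LENGTH_CLASS_LABELS = ("1-2Mb", "2-4Mb", "4-8Mb", "8-16Mb", ">16Mb")


@dataclass
class RohParams:
    """Detection thresholds for the consecutive-runs method."""

    min_length_bp: int = 1_000_000
    max_het: int = 1
    max_missing: int = 1
    min_snps: int = 2
    alpha_fp: float = 0.05

    def __post_init__(self) -> None:
        if self.min_length_bp <= 0:
            raise ValueError("min_length_bp must be positive")
        if self.max_het < 0 or self.max_missing < 0:
            raise ValueError("max_het/max_missing must be >= 0")
        if self.min_snps < 2:
            raise ValueError("min_snps must be >= 2")


@dataclass(frozen=True)
class RohSegment:
    """One homozygous run on one chromosome of one individual."""

    sample_id: str
    chromosome: int
    start_bp: int
    end_bp: int
    n_snps: int
    n_het: int
    n_missing: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


def min_snp_threshold(
    n_snps_per_individual: int,
    n_individuals: int,
    alpha_fp: float = 0.05,
    mean_het: float | None = None,
) -> int:
    """Minimum SNP count for a run to be unlikely by chance.

    ``l = ceil( ln(alpha / (n_s * n_i)) / ln(1 - het) )`` — the expected
    number of chance runs of length l across all individuals and SNP
    starting points is held below ``alpha_fp``.
    """
    if n_snps_per_individual <= 0 or n_individuals <= 0:
        raise ValueError("counts must be positive")
    if mean_het is None or not (0.0 < mean_het < 1.0):
        raise ValueError("mean_het must lie strictly between 0 and 1")
    l = math.log(alpha_fp / (n_snps_per_individual * n_individuals)) / math.log(
        1.0 - mean_het
    )
    return int(math.ceil(l))


def mean_heterozygosity(g: GenotypeMatrix) -> float:
    """Mean fraction of heterozygous calls across all SNPs and individuals."""
    called = g.called_mask()
    return float((g.dosage == 1).sum() / called.sum())


def _candidate_runs(
    dos: np.ndarray, max_het: int, max_missing: int
) -> list[tuple[int, int, int, int]]:
    """Maximal (start, end, n_het, n_missing) index runs on one chromosome.

    Runs start and end on homozygous SNPs. Uses a two-pointer sweep over
    homozygous start positions; the furthest reachable end is monotone in the
    start, so a candidate is maximal iff it reaches strictly further than
    every earlier start.
    """
    m = len(dos)
    is_het = dos == 1
    is_miss = dos == MISSING
    is_hom = ~is_het & ~is_miss
    het_cum = np.concatenate([[0], np.cumsum(is_het)])
    miss_cum = np.concatenate([[0], np.cumsum(is_miss)])
    hom_idx = np.flatnonzero(is_hom)
    if hom_idx.size == 0:
        return []

    def counts(a: int, b: int) -> tuple[int, int]:
        return int(het_cum[b + 1] - het_cum[a]), int(miss_cum[b + 1] - miss_cum[a])

    out: list[tuple[int, int, int, int]] = []
    r = 0  # furthest end index (exclusive bound handled via pointer)
    best_end = -1
    r_ptr = 0
    for a in hom_idx:
        if r_ptr < a:
            r_ptr = int(a)
        # advance r_ptr while the window [a, r_ptr+1] stays within allowances
        while r_ptr + 1 < m:
            h, mi = counts(a, r_ptr + 1)
            if h > max_het or mi > max_missing:
                break
            r_ptr += 1
        # retreat to the last homozygous SNP in [a, r_ptr]
        b = r_ptr
        while b >= a and not is_hom[b]:
            b -= 1
        if b < a:
            continue
        if b > best_end:
            h, mi = counts(a, b)
            out.append((int(a), int(b), h, mi))
            best_end = b
    return out


def detect_roh(g: GenotypeMatrix, params: RohParams) -> list[RohSegment]:
    """Detect ROH for every individual with the consecutive-runs method.

    Returns segments sorted by (sample order, chromosome, start). Requires a
    position-sorted SNP map; runs never cross chromosome boundaries.
    """
    if g.n_snps == 0:
        return []
    if not g.is_sorted():
        raise ValueError("SNP map must be sorted by (chromosome, position)")
    chroms = g.snps["chrom"].to_numpy()
    pos = g.snps["pos"].to_numpy()
    segments: list[RohSegment] = []
    for i in range(g.n_samples):
        row = g.dosage[i]
        for ch in np.unique(chroms):
            sel = chroms == ch
            cpos = pos[sel]
            cdos = row[sel]
            cands = [
                (a, b, h, mi)
                for a, b, h, mi in _candidate_runs(
                    cdos, params.max_het, params.max_missing
                )
                if (b - a + 1) >= params.min_snps
                and (cpos[b] - cpos[a]) >= params.min_length_bp
            ]
            # greedy left-to-right over overlapping candidates; candidates are
            # mutually non-nested so starts and ends are both increasing
            last_end = -1
            for a, b, h, mi in cands:
                if a <= last_end:
                    continue
                segments.append(
                    RohSegment(
                        sample_id=str(g.sample_ids[i]),
                        chromosome=int(ch),
                        start_bp=int(cpos[a]),
                        end_bp=int(cpos[b]),
                        n_snps=int(b - a + 1),
                        n_het=h,
                        n_missing=mi,
                    )
                )
                last_end = b
    return segments


def segments_frame(segments: list[RohSegment]) -> pd.DataFrame:
    """Tabulate segments (one row each) for TSV export."""
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in segments],
            "chromosome": [s.chromosome for s in segments],
            "start_bp": [s.start_bp for s in segments],
            "end_bp": [s.end_bp for s in segments],
            "n_snps": [s.n_snps for s in segments],
            "n_het": [s.n_het for s in segments],
            "n_missing": [s.n_missing for s in segments],
            "length_bp": [s.length_bp for s in segments],
        }
    )


def classify_roh(
    segments: list[RohSegment],
    sample_populations: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Count segments per length class, optionally per population.

    Classes are half-open in Mb: [1,2), [2,4), [4,8), [8,16), [16, inf).
    Returns one row per group with counts, percentages, and the total.
    """
    lengths_mb = np.array([s.length_bp for s in segments], dtype=float) / 1e6
    if len(lengths_mb) and lengths_mb.min() < LENGTH_CLASS_EDGES_MB[0]:
        raise ValueError("segment shorter than 1 Mb violates the length floor")
    if sample_populations is None:
        groups = {"all": np.ones(len(segments), dtype=bool)}
    else:
        labels = np.array([sample_populations[s.sample_id] for s in segments])
        groups = {
            lab: labels == lab for lab in dict.fromkeys(labels)
        }
    rows = []
    edges = np.array(LENGTH_CLASS_EDGES_MB)
    for lab, mask in groups.items():
        lens = lengths_mb[mask]
        counts, _ = np.histogram(lens, bins=edges)
        total = int(counts.sum())
        row: dict[str, object] = {"population": lab, "total": total}
        for name, c in zip(LENGTH_CLASS_LABELS, counts):
            row[f"n_{name}"] = int(c)
            row[f"pct_{name}"] = 100.0 * c / total if total else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def froh(
    segments: list[RohSegment],
    min_length_bp: float = 1e6,
    genome_length_bp: float = DEFAULT_GENOME_LENGTH_BP,
    sample_ids: list[str] | None = None,
) -> pd.Series:
    """Per-individual F_ROH: summed length of segments >= floor / genome length.

    ``sample_ids`` fixes the output index (individuals without qualifying
    segments get 0); defaults to the samples present in ``segments``.
    """
    if genome_length_bp <= 0:
        raise ValueError("genome_length_bp must be positive")
    if sample_ids is None:
        sample_ids = list(dict.fromkeys(s.sample_id for s in segments))
    totals = {sid: 0.0 for sid in sample_ids}
    for s in segments:
        if s.length_bp >= min_length_bp and s.sample_id in totals:
            totals[s.sample_id] += s.length_bp
    return pd.Series(
        {sid: totals[sid] / genome_length_bp for sid in sample_ids},
        name=f"froh_{int(min_length_bp / 1e6)}Mb",
    )


def roh_summary(
    segments: list[RohSegment],
    g: GenotypeMatrix,
    genome_length_bp: float = DEFAULT_GENOME_LENGTH_BP,
    froh_floors_mb: tuple[float, ...] = (1.0, 5.0, 10.0),
) -> pd.DataFrame:
    """Per-population ROH summary: count/length stats and F_ROH at each floor."""
    pops = {str(s): str(p) for s, p in zip(g.sample_ids, g.populations)}
    seg_by_sample: dict[str, list[RohSegment]] = {str(s): [] for s in g.sample_ids}
    for s in segments:
        seg_by_sample.setdefault(s.sample_id, []).append(s)
    rows = []
    for pop in g.population_labels:
        sids = [str(s) for s in g.sample_ids[g.populations == pop]]
        per_n = np.array([len(seg_by_sample[s]) for s in sids], dtype=float)
        per_len = np.array(
            [sum(x.length_bp for x in seg_by_sample[s]) / 1e6 for s in sids]
        )
        row: dict[str, object] = {
            "population": pop,
            "n": len(sids),
            "roh_total": int(per_n.sum()),
            "roh_number_mean": per_n.mean() if len(sids) else np.nan,
            "roh_number_min": per_n.min() if len(sids) else np.nan,
            "roh_number_max": per_n.max() if len(sids) else np.nan,
            "roh_length_mb_mean": per_len.mean() if len(sids) else np.nan,
            "roh_length_mb_min": per_len.min() if len(sids) else np.nan,
            "roh_length_mb_max": per_len.max() if len(sids) else np.nan,
        }
        for floor in froh_floors_mb:
            f = froh(
                segments,
                min_length_bp=floor * 1e6,
                genome_length_bp=genome_length_bp,
                sample_ids=sids,
            )
            key = f"froh_{floor:g}Mb"
            row[f"{key}_mean"] = float(f.mean())
            row[f"{key}_min"] = float(f.min())
            row[f"{key}_max"] = float(f.max())
        rows.append(row)
    return pd.DataFrame(rows)


def plot_roh_classes(class_table: pd.DataFrame, path: str) -> None:
    """Stacked per-population length-class distribution bar chart."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    bottoms = np.zeros(len(class_table))
    for name in LENGTH_CLASS_LABELS:
        vals = class_table[f"pct_{name}"].to_numpy()
        ax.bar(class_table["population"], vals, bottom=bottoms, label=name)
        bottoms += vals
    ax2 = ax.twinx()
    ax2.plot(
        class_table["population"], class_table["total"], "o", color="purple"
    )
    ax2.set_ylabel("total ROH count")
    ax.set_ylabel("% of segments")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
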