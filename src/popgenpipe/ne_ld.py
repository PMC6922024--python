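"""Historical effective population size from distance-binned LD.

The chain is explicit and configurable: squared Pearson correlation of
dosages (unphased, Rogers-Huff style) per same-chromosome SNP pair, physical
distance bins, sample-size correction ``r2 - 1/(beta*n)``, a physical->genetic
mapping (linear or Sved-Feldman adjusted), and the inversion
``Ne(t) = (1/(4c)) * (1/r2_adj - alpha)`` with ``t = 1/(2c)`` generations ago.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

#: Default mutation adjustment in the Ne inversion.
DEFAULT_ALPHA_MUT: float = 2.2

#: Default uniform map density, Morgans per Mb (1 cM/Mb).
DEFAULT_RATE_M_PER_MB: float = 0.01

_R2_FLOOR = 1e-6


@dataclass
class LdBin:
    """Mean r-squared of SNP pairs in one physical-distance bin."""

    d_min_bp: float
    d_max_bp: float
    d_rep_bp: float
    c: float
    n_pairs: int
    mean_r2: float
    mean_r2_adj: float | None = None
    flagged: bool = False


@dataclass
class NeTrajectory:
    """(t generations ago, Ne) points plus the configuration that produced them."""

    points: list[tuple[float, float]]
    alpha_mut: float
    mapping: str
    n_samples: int
    phased: bool
    dropped: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=["t_generations", "Ne"])


def map_distance_to_c(
    d_bp: float | np.ndarray,
    mapping: str = "linear",
    rate_M_per_Mb: float = DEFAULT_RATE_M_PER_MB,
) -> float | np.ndarray:
    """Physical distance (bp) to recombination rate c in Morgans.

    ``linear``: c = (d/1e6) * rate. ``sved_feldman``: c = d_lin/(1 + 2*d_lin)
    applied to the linear map. Both capped just below 0.5.
    """
    scalar = np.isscalar(d_bp)
    d = np.asarray(d_bp, dtype=float)
    if (d <= 0).any():
        raise ValueError("distances must be positive")
    c_lin = d / 1e6 * rate_M_per_Mb
    if mapping == "linear":
        c = c_lin
    elif mapping == "sved_feldman":
        c = c_lin / (1.0 + 2.0 * c_lin)
    else:
        raise ValueError(f"unknown mapping {mapping!r}")
    c = np.minimum(c, 0.5 - 1e-12)
    return float(c) if scalar else c


def c_to_distance(
    c: float, mapping: str = "linear", rate_M_per_Mb: float = DEFAULT_RATE_M_PER_MB
) -> float:
    """Inverse of :func:`map_distance_to_c` (c below the 0.5 cap)."""
    if not 0.0 < c < 0.5:
        raise ValueError("c must lie in (0, 0.5)")
    if mapping == "linear":
        c_lin = c
    elif mapping == "sved_feldman":
        c_lin = c / (1.0 - 2.0 * c)
    else:
        raise ValueError(f"unknown mapping {mapping!r}")
    return c_lin * 1e6 / rate_M_per_Mb


def bins_for_generations(
    t_targets: np.ndarray | list[float],
    mapping: str = "linear",
    rate_M_per_Mb: float = DEFAULT_RATE_M_PER_MB,
) -> tuple[np.ndarray, np.ndarray]:
    """Distance-bin edges whose representative distances hit the target t values.

    For each target t, the representative distance satisfies t = 1/(2c) under
    the chosen mapping; edges are geometric midpoints between neighbours, so
    the geometric bin centre is the representative itself.

    Returns (edges, representative distances), distances in bp ascending.
    """
    t = np.sort(np.asarray(t_targets, dtype=float))[::-1]  # big t = short d
    if (t <= 1.0).any():
        raise ValueError("t targets must exceed 1 generation")
    reps = np.array([c_to_distance(1.0 / (2.0 * ti), mapping, rate_M_per_Mb) for ti in t])
    if len(reps) == 1:
        edges = np.array([reps[0] / 1.5, reps[0] * 1.5])
        return edges, reps
    inner = np.sqrt(reps[:-1] * reps[1:])
    first = reps[0] * reps[0] / inner[0]
    last = reps[-1] * reps[-1] / inner[-1]
    edges = np.concatenate([[first], inner, [last]])
    return edges, reps


def _pairwise_r2_chrom(
    dos: np.ndarray, valid_snp: np.ndarray
) -> np.ndarray:
    """All-pairs r^2 matrix for one chromosome, pairwise-complete over samples.

    ``dos`` is samples x SNPs with MISSING for no-calls; ``valid_snp`` marks
    loci eligible for pairing. Entries for invalid loci or undefined pairs
    are NaN. Uses mask matrix products, so missing data stay exact.
    """
    x = dos.astype(float)
    called = dos != MISSING
    x0 = np.where(called, x, 0.0)
    m = called.astype(float)
    n = m.T @ m  # pairwise complete counts
    sx = x0.T @ m
    sy = m.T @ x0
    sxy = x0.T @ x0
    sxx = (x0 * x0).T @ m
    syy = m.T @ (x0 * x0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / n
        vx = sxx - sx * sx / n
        vy = syy - sy * sy / n
        r2 = (cov * cov) / (vx * vy)
    bad = (n < 2) | (vx <= 0) | (vy <= 0)
    r2[bad] = np.nan
    r2[~valid_snp, :] = np.nan
    r2[:, ~valid_snp] = np.nan
    return r2


def pairwise_r2_binned(
    g: GenotypeMatrix,
    population: str | None = None,
    bin_edges_bp: np.ndarray | list[float] | None = None,
    max_dist_bp: float | None = None,
    min_maf: float = 0.05,
    min_pairs: int = 50,
    mapping: str = "linear",
    rate_M_per_Mb: float = DEFAULT_RATE_M_PER_MB,
) -> list[LdBin]:
    """Mean r^2 of same-chromosome SNP pairs per physical-distance bin.

    Pairs are formed within ``max_dist_bp`` (default: the largest bin edge);
    loci below ``min_maf`` within the population are excluded, as are pairs
    involving a zero-variance locus. Bins with fewer than ``min_pairs`` pairs
    are flagged and later excluded from the trajectory.
    """
    sub = g.for_population(population) if population is not None else g
    if sub.n_samples < 2:
        raise ValueError("need >=2 samples for LD")
    if not sub.is_sorted():
        sub = sub.sort_snps()
    if bin_edges_bp is None:
        bin_edges_bp, _ = bins_for_generations(
            np.geomspace(4, 120, 12), mapping, rate_M_per_Mb
        )
    edges = np.asarray(bin_edges_bp, dtype=float)
    if max_dist_bp is None:
        max_dist_bp = float(edges.max())
    maf = sub.maf()
    valid = np.nan_to_num(maf, nan=-1.0) >= min_maf

    nb = len(edges) - 1
    sums = np.zeros(nb)
    cnts = np.zeros(nb, dtype=np.int64)
    chroms = sub.snps["chrom"].to_numpy()
    pos = sub.snps["pos"].to_numpy().astype(float)
    for ch in np.unique(chroms):
        sel = chroms == ch
        if sel.sum() < 2:
            continue
        r2 = _pairwise_r2_chrom(sub.dosage[:, sel], valid[sel])
        cpos = pos[sel]
        dist = np.abs(cpos[:, None] - cpos[None, :])
        iu = np.triu_indices(len(cpos), k=1)
        d = dist[iu]
        v = r2[iu]
        ok = (~np.isnan(v)) & (d <= max_dist_bp) & (d > 0)
        which = np.digitize(d[ok], edges) - 1
        inside = (which >= 0) & (which < nb)
        np.add.at(sums, which[inside], v[ok][inside])
        np.add.at(cnts, which[inside], 1)

    bins: list[LdBin] = []
    for k in range(nb):
        rep = float(np.sqrt(edges[k] * edges[k + 1]))
        c = float(map_distance_to_c(rep, mapping, rate_M_per_Mb))
        mean_r2 = float(sums[k] / cnts[k]) if cnts[k] else float("nan")
        bins.append(
            LdBin(
                d_min_bp=float(edges[k]),
                d_max_bp=float(edges[k + 1]),
                d_rep_bp=rep,
                c=c,
                n_pairs=int(cnts[k]),
                mean_r2=mean_r2,
                flagged=cnts[k] < min_pairs,
            )
        )
    n_flag = sum(b.flagged for b in bins)
    if n_flag:
        logger.warning("pairwise_r2_binned: %d bins below min_pairs=%d", n_flag, min_pairs)
    return bins


def correct_r2(mean_r2: float, n: int, phased: bool = False) -> float:
    """Sample-size-corrected r^2: subtract 1/(beta*n), beta=1 unphased, 2 phased.

    Floored at a small positive epsilon with a warning.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    beta = 2.0 if phased else 1.0
    adj = mean_r2 - 1.0 / (beta * n)
    if adj <= _R2_FLOOR:
        warnings.warn(
            f"corrected r2 {adj:.3g} at or below floor; point unreliable",
            stacklevel=2,
        )
        return _R2_FLOOR
    return adj


def ne_trajectory(
    bins: list[LdBin],
    alpha_mut: float = DEFAULT_ALPHA_MUT,
    n: int | None = None,
    phased: bool = False,
    mapping: str = "linear",
) -> NeTrajectory:
    """Invert binned LD to an Ne trajectory.

    Per bin: ``Ne = (1/(4c)) * (1/r2_adj - alpha)`` at ``t = 1/(2c)``.
    Bins flagged for low pair counts, with undefined means, or yielding
    non-positive Ne are dropped (with a warning). ``n`` triggers the
    sample-size correction when ``mean_r2_adj`` is not already set.
    """
    points = []
    dropped = 0
    for b in bins:
        if b.flagged or np.isnan(b.mean_r2):
            dropped += 1
            continue
        if b.mean_r2_adj is None:
            if n is None:
                raise ValueError("provide n for the sample-size correction")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                b.mean_r2_adj = correct_r2(b.mean_r2, n, phased)
        ne = (1.0 / (4.0 * b.c)) * (1.0 / b.mean_r2_adj - alpha_mut)
        t = 1.0 / (2.0 * b.c)
        if ne <= 0:
            dropped += 1
            continue
        points.append((t, ne))
    if not points:
        raise ValueError("all LD bins dropped; no Ne trajectory")
    if dropped:
        logger.warning("ne_trajectory: dropped %d of %d bins", dropped, len(bins))
    points.sort(key=lambda p: p[0])
    return NeTrajectory(
        points=points,
        alpha_mut=alpha_mut,
        mapping=mapping,
        n_samples=n if n is not None else -1,
        phased=phased,
        dropped=dropped,
    )


def ne_at_generation(
    traj: NeTrajectory, t_target: float, tolerance_factor: float = 2.0
) -> tuple[float, float]:
    """Ne at the trajectory point nearest ``t_target``.

    Returns ``(Ne, achieved_t)``; warns if the nearest point is further than
    ``tolerance_factor`` times (or under 1/factor of) the target.
    """
    if not traj.points:
        raise ValueError("empty trajectory")
    ts = np.array([p[0] for p in traj.points])
    k = int(np.argmin(np.abs(np.log(ts / t_target))))
    t, ne = traj.points[k]
    ratio = max(t / t_target, t_target / t)
    if ratio > tolerance_factor:
        warnings.warn(
            f"nearest trajectory point t={t:.1f} is {ratio:.1f}x away from "
            f"target t={t_target}",
            stacklevel=2,
        )
    return ne, t


def trajectory_table(bins: list[LdBin], traj: NeTrajectory) -> pd.DataFrame:
    """Join bin diagnostics with trajectory points for TSV export."""
    rows = []
    pts = dict((round(t, 9), ne) for t, ne in traj.points)
    for b in bins:
        t = 1.0 / (2.0 * b.c)
        rows.append(
            {
                "t_generations": t,
                "c_morgans": b.c,
                "d_rep_bp": b.d_rep_bp,
                "n_pairs": b.n_pairs,
                "mean_r2": b.mean_r2,
                "mean_r2_adj": b.mean_r2_adj,
                "Ne": pts.get(round(t, 9), np.nan),
                "flagged": b.flagged,
            }
        )
    return pd.DataFrame(rows).sort_values("t_generations").reset_index(drop=True)
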