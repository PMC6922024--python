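"""Within-population diversity: Ho, unbiased He, rarefied allelic richness, Fis."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotypes import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class DiversitySummary:
    population: str
    n: int
    Ho: float
    He_u: float
    Ar: float
    Fis: float
    Fis_CI: tuple[float, float]


def _pop_dosage(g: GenotypeMatrix, population: str) -> np.ndarray:
    mask = g.populations == population
    if not mask.any():
        raise KeyError(f"population label {population!r} not present")
    return g.dosage[mask, :]


def observed_heterozygosity(
    g: GenotypeMatrix, population: str
) -> tuple[np.ndarray, float]:
    """Per-locus and mean observed heterozygosity within one population.

    Per locus: fraction of non-missing genotypes that are heterozygous.
    The mean runs over loci with at least one non-missing call.
    """
    d = _pop_dosage(g, population)
    called = d != MISSING
    n = called.sum(axis=0)
    het = (d == 1).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = np.where(n > 0, het / n, np.nan)
    return ho, float(np.nanmean(ho))


def unbiased_expected_heterozygosity(
    g: GenotypeMatrix, population: str
) -> tuple[np.ndarray, float]:
    """Nei's unbiased expected heterozygosity per locus and its mean.

    ``He_u = (2n / (2n - 1)) * (1 - sum_i p_i^2)`` with n the non-missing
    diploid count at the locus. Loci with n < 2 are skipped (NaN) and logged.
    """
    d = _pop_dosage(g, population)
    called = d != MISSING
    n = called.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called, d, 0).sum(axis=0) / (2.0 * n)
        raw = 1.0 - p**2 - (1.0 - p) ** 2
        he = np.where(n >= 2, (2.0 * n / (2.0 * n - 1.0)) * raw, np.nan)
    n_skipped = int((n < 2).sum())
    if n_skipped:
        logger.warning(
            "unbiased_expected_heterozygosity(%s): skipped %d loci with <2 calls",
            population, n_skipped,
        )
    return he, float(np.nanmean(he))


def _log_comb(n: np.ndarray, k: float) -> np.ndarray:
    """log C(n, k) elementwise; -inf where n < k."""
    n = np.asarray(n, dtype=float)
    out = gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)
    return np.where(n >= k, out, -np.inf)


def rarefied_allelic_richness(
    g: GenotypeMatrix,
    populations: list[str] | None = None,
    g_rarefy: int | str = "auto",
) -> dict[str, float]:
    """Rarefied allelic richness per population (biallelic loci).

    Per locus ``Ar = sum_a [1 - C(2N - N_a, g) / C(2N, g)]`` where N is the
    population's non-missing diploid count at the locus and ``N_a`` the copies
    of allele a; the population value is the mean over loci. ``g_rarefy="auto"``
    uses the smallest ``2N`` over populations and loci.
    """
    if populations is None:
        populations = g.population_labels
    counts = {}
    for pop in populations:
        d = _pop_dosage(g, pop)
        called = d != MISSING
        n2 = 2 * called.sum(axis=0)  # genes per locus
        nb = np.where(called, d, 0).sum(axis=0)  # allele_b copies
        counts[pop] = (n2, nb)
    if g_rarefy == "auto":
        g_val = int(min(int(c[0].min()) for c in counts.values()))
    else:
        g_val = int(g_rarefy)
    if g_val < 2:
        raise ValueError(f"g_rarefy={g_val} < 2")
    out = {}
    for pop, (n2, nb) in counts.items():
        if (n2 < g_val).any():
            raise ValueError(
                f"g_rarefy={g_val} exceeds gene count at "
                f"{int((n2 < g_val).sum())} loci in population {pop!r}"
            )
        na = n2 - nb
        log_tot = _log_comb(n2, g_val)
        ar = np.zeros(len(n2), dtype=float)
        for copies in (na, nb):
            with np.errstate(invalid="ignore"):
                term = 1.0 - np.exp(_log_comb(n2 - copies, g_val) - log_tot)
            ar += np.where(copies > 0, term, 0.0)
        out[pop] = float(np.mean(ar))
    return out


def inbreeding_fis(
    g: GenotypeMatrix,
    population: str,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """Multilocus Fis = 1 - mean(Ho)/mean(He_u), with a percentile bootstrap CI.

    The CI resamples loci with replacement ``n_boot`` times (95% percentile
    interval, seeded). Raises if mean He_u is zero.
    """
    ho, _ = observed_heterozygosity(g, population)
    he, _ = unbiased_expected_heterozygosity(g, population)
    ok = ~np.isnan(ho) & ~np.isnan(he)
    ho, he = ho[ok], he[ok]
    if ho.size < 2:
        raise ValueError("need >=2 loci with defined Ho and He_u")
    mean_he = he.mean()
    if mean_he == 0.0:
        raise ZeroDivisionError("mean He_u is zero; Fis undefined")
    fis = 1.0 - ho.mean() / mean_he
    rng = np.random.default_rng(seed)
    L = ho.size
    idx = rng.integers(0, L, size=(n_boot, L))
    ho_b = ho[idx].mean(axis=1)
    he_b = he[idx].mean(axis=1)
    valid = he_b > 0
    boots = 1.0 - ho_b[valid] / he_b[valid]
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return float(fis), (float(lo), float(hi))


def diversity_table(
    g: GenotypeMatrix,
    g_rarefy: int | str = "auto",
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-population summary table: n, Ar, Ho, He(u), Fis and its 95% CI."""
    ar = rarefied_allelic_richness(g, g_rarefy=g_rarefy)
    rows = []
    for pop in g.population_labels:
        _, ho = observed_heterozygosity(g, pop)
        _, he = unbiased_expected_heterozygosity(g, pop)
        fis, ci = inbreeding_fis(g, pop, n_boot=n_boot, seed=seed)
        rows.append(
            DiversitySummary(
                population=pop,
                n=int((g.populations == pop).sum()),
                Ho=ho,
                He_u=he,
                Ar=ar[pop],
                Fis=fis,
                Fis_CI=ci,
            )
        )
    return pd.DataFrame(
        {
            "population": [r.population for r in rows],
            "n": [r.n for r in rows],
            "Ar": [r.Ar for r in rows],
            "Ho": [r.Ho for r in rows],
            "He_u": [r.He_u for r in rows],
            "Fis": [r.Fis for r in rows],
            "Fis_CI_low": [r.Fis_CI[0] for r in rows],
            "Fis_CI_high": [r.Fis_CI[1] for r in rows],
        }
    )
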