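"""Genotype simulators with recorded ground truth.

The primary engine is discrete-generation Wright-Fisher gene dropping on a
linear genetic map (1 cM/Mb) with Poisson crossovers. Founder haplotypes
carry unique marker ids that are inherited through meiosis, so true
identity-by-descent (autozygous) tracts are read directly off the dropped
chromosomes. Populations drift independently from a shared ancestral
allele-frequency pool (star divergence); optional pedigree loops grafted
onto the final generation create known recent inbreeding.

A coalescent generator backed by msprime is provided as an independent
cross-validation source for LD-based Ne recovery, where mutation-drift
equilibrium matters and forward burn-in would be costly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, snp_table

#: Uniform genetic map density: Morgans per bp (1 cM/Mb).
MORGANS_PER_BP: float = 1e-8

_PEDIGREE_F = {"selfing-proxy": 0.5, "full-sib": 0.25, "half-sib": 0.125}


@dataclass
class PopulationSpec:
    """One population: label, final sample size, and its Ne history.

    ``ne_trajectory`` lists (generation_span, Ne) segments oldest-first; the
    population drifts for the summed span after splitting from the ancestral
    pool.
    """

    label: str
    sample_size: int
    ne_trajectory: list[tuple[int, int]]

    @property
    def split_time(self) -> int:
        return int(sum(span for span, _ in self.ne_trajectory))

    @property
    def final_ne(self) -> int:
        return int(self.ne_trajectory[-1][1])


@dataclass
class PedigreeLoop:
    """A recent-inbreeding mating loop grafted onto one population."""

    kind: str  # selfing-proxy | full-sib | half-sib
    count: int = 1
    population: str | None = None  # default: first population
    include_parents: bool = False  # also sample the loop's sib pair

    def __post_init__(self) -> None:
        if self.kind not in _PEDIGREE_F:
            raise ValueError(f"unknown mating type {self.kind!r}")


@dataclass
class SimConfig:
    n_chromosomes: int = 26
    snps_per_chromosome: int = 200
    chromosome_length_bp: int = 100_000_000
    populations: list[PopulationSpec] = field(default_factory=list)
    pedigree_loops: list[PedigreeLoop] = field(default_factory=list)
    missing_rate: float = 0.0
    maf_floor: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.n_chromosomes < 1 or self.snps_per_chromosome < 1:
            raise ValueError("counts must be positive")
        for pop in self.populations:
            if pop.sample_size <= 0:
                raise ValueError(f"{pop.label}: sample_size must be positive")
            if pop.sample_size > 2 * pop.final_ne:
                raise ValueError(
                    f"{pop.label}: sample_size {pop.sample_size} exceeds "
                    f"2*Ne ({2 * pop.final_ne})"
                )


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated panel."""

    pedigree_f: dict[str, float]
    ne_by_generation: dict[str, list[tuple[int, int]]]
    expected_branch_fst: dict[str, float]
    expected_pairwise_fst: dict[str, float]
    ibd_tracts: dict[str, list[tuple[int, int, int]]]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    def tracts_frame(self) -> pd.DataFrame:
        rows = [
            (sid, ch, a, b)
            for sid, tracts in self.ibd_tracts.items()
            for ch, a, b in tracts
        ]
        return pd.DataFrame(rows, columns=["sample_id", "chromosome", "start_bp", "end_bp"])


def expected_drift_fst(N: int, t: int) -> float:
    """Expected per-branch fixation after t generations of drift at size N:
    ``1 - (1 - 1/(2N))^t``."""
    if N < 1 or t < 0:
        raise ValueError("need N >= 1 and t >= 0")
    return 1.0 - (1.0 - 1.0 / (2.0 * N)) ** t


# ---------------------------------------------------------------------------
# gene dropping machinery
# ---------------------------------------------------------------------------


class _Genome:
    """SNP coordinates and per-chromosome genetic lengths."""

    def __init__(self, cfg: SimConfig, rng: np.random.Generator):
        self.chrom = np.repeat(
            np.arange(1, cfg.n_chromosomes + 1), cfg.snps_per_chromosome
        )
        pos = []
        for _ in range(cfg.n_chromosomes):
            # rejection-sample distinct positions (cheap: few k out of ~1e8)
            want = cfg.snps_per_chromosome
            p = np.unique(rng.integers(1, cfg.chromosome_length_bp + 1, size=2 * want))
            while len(p) < want:
                extra = rng.integers(1, cfg.chromosome_length_bp + 1, size=want)
                p = np.unique(np.concatenate([p, extra]))
            p = np.sort(rng.choice(p, size=want, replace=False))
            pos.append(p)
        self.pos = np.concatenate(pos)
        self.n_snps = len(self.pos)
        self.slices = [
            slice(i * cfg.snps_per_chromosome, (i + 1) * cfg.snps_per_chromosome)
            for i in range(cfg.n_chromosomes)
        ]
        self.gen_pos = [self.pos[sl].astype(float) * MORGANS_PER_BP for sl in self.slices]
        self.gen_len = [float(cfg.chromosome_length_bp) * MORGANS_PER_BP] * cfg.n_chromosomes


def _drop_gametes(
    al: np.ndarray,
    ids: np.ndarray,
    parents: np.ndarray,
    genome: _Genome,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Produce one recombinant gamete per entry of ``parents``.

    ``al``/``ids`` are (2*N_parents, S) haplotype arrays (individual j owns
    rows 2j, 2j+1). Crossovers are Poisson on the genetic map; the starting
    haplotype of each chromosome is chosen uniformly.
    """
    G = len(parents)
    S = al.shape[1]
    out_al = np.empty((G, S), dtype=al.dtype)
    out_ids = np.empty((G, S), dtype=ids.dtype)
    hapA = 2 * parents
    hapB = hapA + 1
    for sl, gpos, L in zip(genome.slices, genome.gen_pos, genome.gen_len):
        starts = rng.integers(0, 2, size=G)
        n_x = rng.poisson(L, size=G)
        parity = np.repeat(starts[:, None], len(gpos), axis=1).astype(np.int8)
        for gidx in np.flatnonzero(n_x):
            xs = np.sort(rng.uniform(0.0, L, size=n_x[gidx]))
            parity[gidx] = (starts[gidx] + np.searchsorted(xs, gpos)) % 2
        use_b = parity == 1
        out_al[:, sl] = np.where(use_b, al[hapB][:, sl], al[hapA][:, sl])
        out_ids[:, sl] = np.where(use_b, ids[hapB][:, sl], ids[hapA][:, sl])
    return out_al, out_ids


def _wf_generation(
    al: np.ndarray,
    ids: np.ndarray,
    n_offspring: int,
    genome: _Genome,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One Wright-Fisher generation: random (monoecious) mating."""
    n_par = al.shape[0] // 2
    parents = rng.integers(0, n_par, size=2 * n_offspring)
    return _drop_gametes(al, ids, parents, genome, rng)


def _mate(state, jf: int, jm: int, genome, rng):
    """One offspring of individuals jf x jm; returns its two haplotype rows."""
    al, ids = state
    g_al, g_ids = _drop_gametes(al, ids, np.array([jf, jm]), genome, rng)
    return g_al, g_ids


def _ibd_tracts(
    ids: np.ndarray, genome: _Genome
) -> list[tuple[int, int, int]]:
    """Merge per-SNP autozygosity (hap ids equal) into (chrom, start, end) runs."""
    hapA, hapB = ids
    tracts = []
    for ci, sl in enumerate(genome.slices, start=1):
        eq = hapA[sl] == hapB[sl]
        pos = genome.pos[sl]
        j = 0
        m = len(eq)
        while j < m:
            if eq[j]:
                k = j
                while k + 1 < m and eq[k + 1]:
                    k += 1
                tracts.append((ci, int(pos[j]), int(pos[k])))
                j = k + 1
            else:
                j += 1
    return tracts


def simulate_panel(cfg: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Simulate a multi-population panel with recorded truth. Seeded and
    deterministic: the same config yields byte-identical output."""
    if not cfg.populations:
        raise ValueError("config lists no populations")
    rng = np.random.default_rng(cfg.seed)
    genome = _Genome(cfg, rng)
    S = genome.n_snps

    # ancestral counted-allele frequencies: uniform MAF in [maf_floor, 0.5],
    # random orientation
    maf = rng.uniform(cfg.maf_floor, 0.5, size=S)
    flip = rng.random(S) < 0.5
    p_anc = np.where(flip, 1.0 - maf, maf)

    sample_ids: list[str] = []
    pops_out: list[str] = []
    dosage_rows: list[np.ndarray] = []
    truth = SimTruth(
        pedigree_f={},
        ne_by_generation={},
        expected_branch_fst={},
        expected_pairwise_fst={},
        ibd_tracts={},
    )
    next_id = 0

    loops_by_pop: dict[str, list[PedigreeLoop]] = {}
    for loop in cfg.pedigree_loops:
        lab = loop.population or cfg.populations[0].label
        loops_by_pop.setdefault(lab, []).append(loop)

    for spec in cfg.populations:
        ne0 = spec.ne_trajectory[0][1]
        al = (rng.random((2 * ne0, S)) < p_anc).astype(np.int8)
        # one marker id per founder haplotype: equality of ids at a site
        # means descent from the same founder chromosome there
        ids = np.repeat(
            np.arange(next_id, next_id + 2 * ne0, dtype=np.int32)[:, None], S, axis=1
        )
        next_id += 2 * ne0

        gens = []
        drift_f = 1.0
        for span, ne in spec.ne_trajectory:
            for _ in range(int(span)):
                al, ids = _wf_generation(al, ids, int(ne), genome, rng)
                drift_f *= 1.0 - 1.0 / (2.0 * ne)
            gens.append((int(span), int(ne)))
        truth.ne_by_generation[spec.label] = gens
        truth.expected_branch_fst[spec.label] = 1.0 - drift_f

        n_final = al.shape[0] // 2
        chosen = rng.choice(n_final, size=spec.sample_size, replace=False)
        members: list[tuple[str, np.ndarray, np.ndarray, float]] = []
        for k, j in enumerate(chosen):
            sid = f"{spec.label}_{k:03d}"
            members.append((sid, al[2 * j : 2 * j + 2], ids[2 * j : 2 * j + 2], 0.0))

        for loop in loops_by_pop.get(spec.label, []):
            for rep in range(loop.count):
                founders = rng.choice(n_final, size=3, replace=False)
                state = (al, ids)
                if loop.kind == "selfing-proxy":
                    o_al, o_ids = _mate(state, founders[0], founders[0], genome, rng)
                elif loop.kind == "full-sib":
                    c1 = _mate(state, founders[0], founders[1], genome, rng)
                    c2 = _mate(state, founders[0], founders[1], genome, rng)
                    fam_al = np.vstack([c1[0], c2[0]])
                    fam_ids = np.vstack([c1[1], c2[1]])
                    o_al, o_ids = _mate((fam_al, fam_ids), 0, 1, genome, rng)
                else:  # half-sib: shared sire, two dams
                    c1 = _mate(state, founders[0], founders[1], genome, rng)
                    c2 = _mate(state, founders[0], founders[2], genome, rng)
                    fam_al = np.vstack([c1[0], c2[0]])
                    fam_ids = np.vstack([c1[1], c2[1]])
                    o_al, o_ids = _mate((fam_al, fam_ids), 0, 1, genome, rng)
                sid = f"{spec.label}_loop{loop.kind.replace('-', '')}_{rep:02d}"
                if loop.include_parents and loop.kind != "selfing-proxy":
                    members.append((f"{sid}_p1", fam_al[:2], fam_ids[:2], 0.0))
                    members.append((f"{sid}_p2", fam_al[2:], fam_ids[2:], 0.0))
                members.append((sid, o_al, o_ids, _PEDIGREE_F[loop.kind]))

        for sid, m_al, m_ids, f_ped in members:
            sample_ids.append(sid)
            pops_out.append(spec.label)
            dosage_rows.append(m_al.sum(axis=0).astype(np.int8))
            truth.pedigree_f[sid] = f_ped
            truth.ibd_tracts[sid] = _ibd_tracts(m_ids, genome)

    labels = [s.label for s in cfg.populations]
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            fi = truth.expected_branch_fst[labels[i]]
            fj = truth.expected_branch_fst[labels[j]]
            truth.expected_pairwise_fst[f"{labels[i]}|{labels[j]}"] = 0.5 * (fi + fj)

    dosage = np.vstack(dosage_rows)
    if cfg.missing_rate > 0:
        mask = rng.random(dosage.shape) < cfg.missing_rate
        dosage[mask] = MISSING

    snps = snp_table(
        [f"snp{c}_{p}" for c, p in zip(genome.chrom, genome.pos)],
        genome.chrom,
        genome.pos,
        ["A"] * S,
        ["G"] * S,
    )
    g = GenotypeMatrix(np.array(sample_ids), np.array(pops_out), snps, dosage)
    return g, truth


# ---------------------------------------------------------------------------
# shaped integration fixture
# ---------------------------------------------------------------------------


def five_breed_panel(seed: int = 0, snps_per_chromosome: int = 1470) -> tuple[GenotypeMatrix, SimTruth]:
    """A five-population panel shaped like a small multi-breed array study.

    Populations of sizes (31, 31, 30, 13, 24) on 26 autosomes (~38k SNPs by
    default), divergence tuned so pairwise FST spans roughly 0.01-0.07, and
    one population (POP4) carrying elevated recent inbreeding through
    pedigree loops.
    """
    cfg = SimConfig(
        n_chromosomes=26,
        snps_per_chromosome=snps_per_chromosome,
        chromosome_length_bp=100_000_000,
        populations=[
            PopulationSpec("POP1", 31, [(4, 180)]),
            PopulationSpec("POP2", 31, [(8, 180)]),
            PopulationSpec("POP3", 30, [(12, 180)]),
            PopulationSpec("POP4", 7, [(16, 120)]),
            PopulationSpec("POP5", 24, [(20, 180)]),
        ],
        pedigree_loops=[
            PedigreeLoop("half-sib", count=4, population="POP4"),
            PedigreeLoop("full-sib", count=2, population="POP4"),
        ],
        missing_rate=0.01,
        maf_floor=0.08,
        seed=seed,
    )
    return simulate_panel(cfg)


# ---------------------------------------------------------------------------
# coalescent generator (independent oracle for LD-based Ne)
# ---------------------------------------------------------------------------


def coalescent_panel(
    n_samples: int,
    ne_history: list[tuple[float, float]],
    n_chromosomes: int = 10,
    chromosome_length_bp: int = 20_000_000,
    mutation_rate: float = 1e-7,
    recombination_rate: float = MORGANS_PER_BP,
    maf_min: float = 0.05,
    max_snps_per_chromosome: int | None = None,
    seed: int = 1,
    label: str = "POP",
) -> GenotypeMatrix:
    """Single-population panel from the coalescent at a piecewise-constant Ne.

    ``ne_history`` lists (time_generations_ago, Ne) with the first entry at
    time 0 (the present). Chromosomes are simulated independently; sites are
    biallelic, filtered at ``maf_min`` and optionally thinned to a maximum
    count per chromosome.
    """
    import msprime

    if not ne_history or ne_history[0][0] != 0:
        raise ValueError("ne_history must start at time 0")
    demography = msprime.Demography()
    demography.add_population(name="P0", initial_size=ne_history[0][1])
    for t, ne in ne_history[1:]:
        demography.add_population_parameters_change(time=t, initial_size=ne, population="P0")

    rng = np.random.default_rng(seed)
    chroms, positions, rows = [], [], []
    for ci in range(1, n_chromosomes + 1):
        ts = msprime.sim_ancestry(
            samples=n_samples,
            demography=demography,
            sequence_length=chromosome_length_bp,
            recombination_rate=recombination_rate,
            random_seed=int(rng.integers(1, 2**31)),
        )
        ts = msprime.sim_mutations(
            ts,
            rate=mutation_rate,
            model=msprime.BinaryMutationModel(),
            random_seed=int(rng.integers(1, 2**31)),
        )
        gm = ts.genotype_matrix()  # sites x haplotypes, alleles 0/1
        gm = np.minimum(gm, 1)
        dos = gm[:, 0::2] + gm[:, 1::2]  # sites x diploids
        pos = ts.sites_position.astype(np.int64) + 1
        freq = dos.sum(axis=1) / (2.0 * dos.shape[1])
        keep = np.minimum(freq, 1 - freq) >= maf_min
        # drop duplicate integer positions
        pos_k = pos[keep]
        uniq = np.concatenate([[True], np.diff(pos_k) > 0])
        dos_k = dos[keep][uniq]
        pos_k = pos_k[uniq]
        if max_snps_per_chromosome and len(pos_k) > max_snps_per_chromosome:
            sel = np.sort(
                rng.choice(len(pos_k), size=max_snps_per_chromosome, replace=False)
            )
            dos_k, pos_k = dos_k[sel], pos_k[sel]
        chroms.append(np.full(len(pos_k), ci))
        positions.append(pos_k)
        rows.append(dos_k.T)  # diploids x sites

    chrom = np.concatenate(chroms)
    pos = np.concatenate(positions)
    dosage = np.hstack(rows).astype(np.int8)
    snps = snp_table(
        [f"c{c}_{p}" for c, p in zip(chrom, pos)],
        chrom,
        pos,
        ["A"] * len(pos),
        ["G"] * len(pos),
    )
    ids = np.array([f"{label}_{i:03d}" for i in range(n_samples)], dtype=object)
    return GenotypeMatrix(ids, np.full(n_samples, label, dtype=object), snps, dosage)
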