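"""End-to-end orchestration: QC -> diversity -> ROH -> Ne -> structure.

Every run writes a machine-readable JSON manifest recording parameters,
seeds, and stepwise sample/SNP counts, so identical inputs and config give
byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import diversity, genotype_io, ne_ld, roh, structure
from .genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    input_prefix: str = ""
    input_format: str | None = None  # ped | bed | None = autodetect
    out_dir: str = "popgenpipe_out"
    # QC
    snp_call_rate_min: float = 0.90
    sample_missing_max: float = 0.10
    maf_min: float = 0.05
    autosomes_only: bool = True
    n_autosomes: int = 26
    relatedness_threshold: float = 0.35
    prune_relatives: bool = True
    # ROH
    roh_min_length_bp: int = 1_000_000
    roh_max_het: int = 1
    roh_max_missing: int = 1
    roh_min_snps: int | None = None  # None -> compute l from alpha_fp
    roh_alpha_fp: float = 0.05
    genome_length_bp: float = roh.DEFAULT_GENOME_LENGTH_BP
    # Ne
    ne_alpha_mut: float = ne_ld.DEFAULT_ALPHA_MUT
    ne_mapping: str = "sved_feldman"
    ne_t_targets: tuple[float, ...] = (5.0, 8.0, 13.0, 20.0, 32.0, 50.0, 80.0, 125.0)
    ne_min_maf: float = 0.05
    ne_min_pairs: int = 50
    # bootstrap / rng
    n_boot: int = 1000
    seed: int = 1

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Parse a plain ``key = value`` config file (# comments allowed)."""
        kwargs = {}
        fields = {f: t for f, t in cls.__annotations__.items()}
        for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{ln}: expected 'key = value'")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in fields:
                raise ValueError(f"{path}:{ln}: unknown key {key!r}")
            kwargs[key] = _coerce(key, val)
        return cls(**kwargs)


def _coerce(key: str, val: str):
    if val.lower() in ("true", "false"):
        return val.lower() == "true"
    if val.lower() in ("none", ""):
        return None
    if key == "ne_t_targets":
        return tuple(float(v) for v in val.replace(",", " ").split())
    for cast in (int, float):
        try:
            return cast(val)
        except ValueError:
            pass
    return val


def _write_tsv(df: pd.DataFrame, path: Path, meta: dict) -> None:
    with open(path, "w") as fh:
        for k in sorted(meta):
            fh.write(f"# {k}={meta[k]}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def run_pipeline(
    cfg: PipelineConfig, g: GenotypeMatrix | None = None
) -> dict:
    """Run every stage and write the report bundle under ``cfg.out_dir``.

    ``g`` may be passed directly (e.g. a simulated panel) instead of reading
    ``cfg.input_prefix``. Returns the manifest dict. On a stage failure the
    manifest written so far is preserved next to the partial outputs.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(cfg), "stages": {}}
    meta = {"seed": cfg.seed}
    stage = "genotype_io"
    try:
        if g is None:
            g = genotype_io.read_plink(cfg.input_prefix, cfg.input_format)
        qc_cfg = genotype_io.QCConfig(
            snp_call_rate_min=cfg.snp_call_rate_min,
            sample_missing_max=cfg.sample_missing_max,
            maf_min=cfg.maf_min,
            autosomes_only=cfg.autosomes_only,
            n_autosomes=cfg.n_autosomes,
        )
        g, qc_rep = genotype_io.apply_qc(g, qc_cfg)
        (out / "qc_report.json").write_text(qc_rep.to_json())
        _write_tsv(qc_rep.to_frame(), out / "qc_report.tsv", meta)
        if cfg.prune_relatives:
            uar = genotype_io.compute_uar(g)
            n_before = g.n_samples
            g = genotype_io.prune_related(g, uar, cfg.relatedness_threshold)
            manifest["stages"]["relatedness"] = {
                "removed": n_before - g.n_samples,
                "threshold": cfg.relatedness_threshold,
            }
        manifest["stages"]["genotype_io"] = {
            "qc": {k: v for k, v in asdict(qc_rep).items() if k != "removed_sample_ids"},
            "n_samples": g.n_samples,
            "n_snps": g.n_snps,
        }

        stage = "diversity"
        div = diversity.diversity_table(g, n_boot=cfg.n_boot, seed=cfg.seed)
        _write_tsv(div, out / "diversity.tsv", meta)
        manifest["stages"]["diversity"] = {"populations": len(div)}

        stage = "roh"
        if cfg.roh_min_snps is None:
            l_thresh = roh.min_snp_threshold(
                g.n_snps, g.n_samples, cfg.roh_alpha_fp, roh.mean_heterozygosity(g)
            )
        else:
            l_thresh = cfg.roh_min_snps
        params = roh.RohParams(
            min_length_bp=cfg.roh_min_length_bp,
            max_het=cfg.roh_max_het,
            max_missing=cfg.roh_max_missing,
            min_snps=max(2, l_thresh),
            alpha_fp=cfg.roh_alpha_fp,
        )
        segs = roh.detect_roh(g, params)
        _write_tsv(roh.segments_frame(segs), out / "roh_segments.tsv", meta)
        pops_map = {str(s): str(p) for s, p in zip(g.sample_ids, g.populations)}
        classes = roh.classify_roh(segs, pops_map)
        _write_tsv(classes, out / "roh_classes.tsv", meta)
        summary = roh.roh_summary(segs, g, genome_length_bp=cfg.genome_length_bp)
        _write_tsv(summary, out / "roh_summary.tsv", meta)
        manifest["stages"]["roh"] = {"min_snps": params.min_snps, "n_segments": len(segs)}

        stage = "ne_ld"
        edges, _ = ne_ld.bins_for_generations(cfg.ne_t_targets, cfg.ne_mapping)
        ne_rows = []
        for pop in g.population_labels:
            n_pop = int((g.populations == pop).sum())
            bins = ne_ld.pairwise_r2_binned(
                g,
                pop,
                bin_edges_bp=edges,
                min_maf=cfg.ne_min_maf,
                min_pairs=cfg.ne_min_pairs,
                mapping=cfg.ne_mapping,
            )
            try:
                traj = ne_ld.ne_trajectory(
                    bins, cfg.ne_alpha_mut, n=n_pop, mapping=cfg.ne_mapping
                )
            except ValueError as e:
                logger.warning("ne_ld(%s): %s", pop, e)
                continue
            _write_tsv(
                ne_ld.trajectory_table(bins, traj),
                out / f"ne_trajectory_{pop}.tsv",
                meta,
            )
            ne5, t5 = ne_ld.ne_at_generation(traj, 5.0)
            ne50, t50 = ne_ld.ne_at_generation(traj, 50.0)
            ne_rows.append(
                {"population": pop, "n": n_pop, "Ne_5": ne5, "t_5": t5,
                 "Ne_50": ne50, "t_50": t50}
            )
        ne_df = pd.DataFrame(ne_rows)
        _write_tsv(ne_df, out / "ne_summary.tsv", meta)
        manifest["stages"]["ne_ld"] = {"populations": len(ne_rows)}

        stage = "structure"
        if len(g.population_labels) >= 2:
            fst = structure.fst_matrix(g)
            _write_tsv(
                fst.to_frame().reset_index(names="population"),
                out / "fst_matrix.tsv",
                meta,
            )
            structure.write_phylip(fst, out / "fst_matrix.phy")
            structure.write_nexus(fst, out / "fst_matrix.nex")
            manifest["stages"]["structure"] = {"populations": len(fst.populations)}
        ibs = structure.ibs_distance_matrix(g)
        mds = structure.classical_mds(ibs, k=3)
        df = mds.to_frame(g.populations)
        for i, f in enumerate(mds.explained_fraction, 1):
            df[f"explained{i}"] = f
        _write_tsv(df, out / "mds.tsv", meta)
        pc = structure.pca(g, k=min(10, g.n_samples - 1))
        df = pc.to_frame(g.populations)
        for i, f in enumerate(pc.explained_fraction, 1):
            df[f"explained{i}"] = f
        _write_tsv(df, out / "pca.tsv", meta)
        structure.export_external(g, "treemix_freq", out / "panel")

        manifest["ok"] = True
    except Exception as e:
        manifest["ok"] = False
        manifest["failed_stage"] = stage
        manifest["error"] = str(e)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def validate_against_reference(
    bundle_dir: str | Path, reference: str | Path
) -> pd.DataFrame:
    """Compare a report bundle against a reference expectations table.

    The reference TSV has columns ``statistic, population, expected,
    tolerance``. Supported statistics: diversity columns (``Ho``, ``He_u``,
    ``Ar``, ``Fis``), ROH summary columns (e.g. ``froh_1Mb_mean``,
    ``roh_total``), Ne summary columns (``Ne_5``, ``Ne_50``), and
    ``fst:<popA>:<popB>``. Returns one pass/fail row per reference line.
    """
    bundle = Path(bundle_dir)
    ref = pd.read_csv(reference, sep="\t", comment="#")
    required = {"statistic", "population", "expected", "tolerance"}
    if not required <= set(ref.columns):
        raise ValueError(f"reference needs columns {sorted(required)}")

    tables = {}

    def load(name):
        if name not in tables:
            tables[name] = pd.read_csv(bundle / name, sep="\t", comment="#")
        return tables[name]

    rows = []
    for rec in ref.itertuples(index=False):
        stat = str(rec.statistic)
        if stat.startswith("fst:"):
            _, a, b = stat.split(":")
            fst = load("fst_matrix.tsv").set_index("population")
            value = float(fst.loc[a, b])
        else:
            for fname in ("diversity.tsv", "roh_summary.tsv", "ne_summary.tsv"):
                tab = load(fname)
                if stat in tab.columns:
                    sel = tab[tab["population"] == rec.population]
                    if sel.empty:
                        raise KeyError(f"population {rec.population!r} not in {fname}")
                    value = float(sel[stat].iloc[0])
                    break
            else:
                raise KeyError(f"unknown statistic {stat!r}")
        ok = abs(value - float(rec.expected)) <= float(rec.tolerance)
        rows.append(
            {
                "statistic": stat,
                "population": rec.population,
                "expected": float(rec.expected),
                "computed": value,
                "tolerance": float(rec.tolerance),
                "pass": bool(ok),
            }
        )
    return pd.DataFrame(rows)
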