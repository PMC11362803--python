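"""End-to-end orchestration of the consensus docking workflow.

load -> pool top-k -> pairwise RMSD -> hierarchical clustering ->
Kelley penalty -> consensus selection -> interface map of the final
model -> alanine scan, with every stage's artefacts written under one
output directory.  All stages are deterministic given (inputs, config);
only the synthetic generator takes a seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import __version__
from .alascan import AlaScanResult, alanine_scan
from .config import RunConfig
from .consensus import (
    hierarchical_cluster,
    kelley_profile,
    pool_top_k,
    select_consensus,
)
from .errors import CondockError
from .geometry import rmsd_matrix
from .interface import contact_table, interface_map, residue_list
from .pose_synth import (
    SyntheticSpec,
    generate_ensemble,
    make_sidechain_complex,
    write_ensemble,
)
from .structmodel import Pose, load_ensemble, merge_structures, write_pdb

logger = logging.getLogger(__name__)


@dataclass
class RunReport:
    """Summary of one consensus run; every number is recomputable from
    the persisted artefacts."""

    engines: list[str]
    poses_per_engine: dict[str, int]
    pooled_count: int
    chosen_k: int
    cluster_sizes: dict[int, int]
    top_cluster: int
    representative: str
    n_interface_contacts: int
    n_interface_residues_receptor: int
    n_interface_residues_ligand: int
    wt_affinity: float
    top_scan_hits: list[dict]
    config_fingerprint: str
    version: str = __version__

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)


def _fingerprint(config: RunConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _penalty_plot(profile, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(profile.levels, profile.penalty, marker="o", ms=3, lw=1)
    best = profile.best_k
    ax.axvline(best, color="crimson", ls="--", lw=1, label=f"minimum at k = {best}")
    ax.set_xlabel("number of clusters k")
    ax.set_ylabel("Kelley penalty")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _scan_plot(result: AlaScanResult, path: Path) -> None:
    df = result.to_frame()
    if df.empty:
        return
    labels = [f"{r.chain}:{r.res_seq}{r.i_code} {r.res_name}" for r in df.itertuples()]
    fig, ax = plt.subplots(figsize=(max(4, 0.35 * len(labels)), 4))
    ax.bar(range(len(labels)), df["delta_affinity"], color="steelblue")
    ax.axhline(0.0, color="black", lw=0.8)
    ax.set_xticks(range(len(labels)))
    ax.set_xticklabels(labels, rotation=90, fontsize=7)
    ax.set_ylabel(r"$\Delta$affinity (positive = weaker binding)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_consensus(ensemble_dir: str | Path, config: RunConfig,
                  out_dir: str | Path) -> RunReport:
    """Execute the full consensus workflow and write all artefacts.

    On a stage failure, already-written partial artefacts are retained
    and a FAILED marker naming the stage is left in the output
    directory before the error propagates.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "effective_config.yaml")
    stage = "load"
    try:
        logger.info("stage load: reading ensemble from %s", ensemble_dir)
        ensemble = load_ensemble(ensemble_dir, config.layout)
        per_engine: dict[str, int] = {}
        for p in ensemble:
            per_engine[p.engine] = per_engine.get(p.engine, 0) + 1
        logger.info("stage load: %d poses in, engines=%s", len(ensemble), per_engine)

        stage = "pool"
        pooled = pool_top_k(ensemble, config.top_k)
        logger.info("stage pool: %d poses out (top_k=%d)", len(pooled), config.top_k)

        stage = "rmsd"
        matrix = rmsd_matrix(pooled, mode=config.rmsd_mode)
        matrix.to_csv(out / "rmsd_matrix.csv")

        stage = "cluster"
        dendrogram = hierarchical_cluster(matrix, linkage=config.linkage)

        stage = "kelley"
        profile = kelley_profile(dendrogram, matrix, norm_min=config.kelley_norm_min)
        profile.to_frame().to_csv(out / "kelley_profile.csv", index=False,
                                  float_format="%.6f")
        _penalty_plot(profile, out / "penalty_plot.png")

        stage = "select"
        result = select_consensus(profile, dendrogram, matrix)
        result.to_frame(pooled).to_csv(out / "partition.csv", index=False)
        logger.info("stage select: k=%d, top cluster %d (size %d), representative %s",
                    result.chosen_k, result.top_cluster,
                    result.cluster_sizes[result.top_cluster], result.representative)
        final = next(p for p in pooled if p.pose_id == result.representative)
        write_pdb(merge_structures(final.receptor, final.ligand, final.pose_id),
                  out / "representative.pdb")

        stage = "interface"
        imap = interface_map(final, cutoff=config.interface_cutoff)
        contact_table(imap).to_csv(out / "interface_contacts.csv", index=False)
        (out / "interface_residues.txt").write_text(
            "\n".join(["# receptor"]
                      + residue_list(imap.interface_residues_receptor)
                      + ["# ligand"]
                      + residue_list(imap.interface_residues_ligand)) + "\n")

        stage = "alascan"
        scan = alanine_scan(final, side=config.scan_side,
                            cutoff=config.interface_cutoff,
                            params=config.energy_params)
        scan.to_frame().to_csv(out / "alascan.csv", index=False,
                               float_format="%.9f")
        _scan_plot(scan, out / "alascan_plot.png")

        report = RunReport(
            engines=list(config.engines),
            poses_per_engine=per_engine,
            pooled_count=len(pooled),
            chosen_k=result.chosen_k,
            cluster_sizes=result.cluster_sizes,
            top_cluster=result.top_cluster,
            representative=result.representative,
            n_interface_contacts=len(imap.contacts),
            n_interface_residues_receptor=len(imap.interface_residues_receptor),
            n_interface_residues_ligand=len(imap.interface_residues_ligand),
            wt_affinity=scan.wt_affinity,
            top_scan_hits=[
                {"residue": f"{r.residue[0]}:{r.residue[1]}{r.residue[2]}",
                 "res_name": r.res_name, "delta_affinity": r.delta_affinity}
                for r in scan.rows[:5]
            ],
            config_fingerprint=_fingerprint(config),
        )
        report.to_json(out / "report.json")
        return report
    except (CondockError, OSError) as exc:
        (out / "FAILED").write_text(f"stage {stage}: {exc}\n")
        logger.error("pipeline failed at stage %r: %s", stage, exc)
        raise


def run_synth(spec: SyntheticSpec, out_dir: str | Path,
              n_res_receptor: int = 20, n_res_ligand: int = 10,
              with_sidechains: bool = True) -> None:
    """Generate and write a synthetic ensemble + truth file."""
    if with_sidechains:
        complex_ = make_sidechain_complex(n_res_receptor, n_res_ligand, spec.seed)
    else:
        from .pose_synth import make_toy_complex

        complex_ = make_toy_complex(n_res_receptor, n_res_ligand, spec.seed)
    poses, truth = generate_ensemble(spec, complex_)
    write_ensemble(poses, truth, out_dir)
    logger.info("wrote %d poses (%d engines) to %s", len(poses), spec.n_engines, out_dir)


def run_alascan(complex_pdb: str | Path, receptor_chain: str, ligand_chain: str,
                cutoff: float = 5.0, params=None, side: str = "both",
                out_dir: Optional[str | Path] = None) -> AlaScanResult:
    """Standalone alanine scan of a two-chain complex PDB."""
    from .structmodel import read_pdb, split_chains

    full = read_pdb(complex_pdb, chain_filter={receptor_chain, ligand_chain})
    pose = Pose(
        pose_id=Path(complex_pdb).stem,
        receptor=split_chains(full, {receptor_chain}, "receptor"),
        ligand=split_chains(full, {ligand_chain}, "ligand"),
        engine="user", rank=1,
    )
    result = alanine_scan(pose, side=side, cutoff=cutoff, params=params)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.to_frame().to_csv(out / "alascan.csv", index=False, float_format="%.9f")
        _scan_plot(result, out / "alascan_plot.png")
    return result
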