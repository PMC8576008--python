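"""Structure-file I/O, pipeline orchestration and report tables.

The pipeline runs the analyses in their natural order -- build model,
synthesize (or load) a trajectory, profile hydroxymethyl conformers,
detect and summarize hydrogen bonds, evaluate the energy tables -- and
writes one CSV per report plus a JSON run manifest (config hash, input
checksums, per-stage row counts and timings).  Identical config + inputs
+ seed reproduce byte-identical CSVs; the manifest's timestamps are the
only non-deterministic output.

Structure files are fixed-column PDB (MODEL/ENDMDL framing for
trajectories).  Chain identifiers cycle through a 62-symbol alphabet;
on reading, chains are re-partitioned wherever the residue numbering
restarts, so models with >62 chains round-trip their chain partition.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from . import crystal, conformers, hbonds, energetics, synth

__all__ = [
    "read_structure",
    "read_trajectory",
    "write_structure",
    "write_trajectory",
    "write_tables",
    "PipelineConfig",
    "RunManifest",
    "run_pipeline",
]

logger = logging.getLogger("cellufacet")

#: fixed float format for deterministic CSV output
CSV_FLOAT_FORMAT = "%.6g"


class PipelineError(RuntimeError):
    pass


# --------------------------------------------------------------------------
# Structure I/O
# --------------------------------------------------------------------------

def _annotate_chain_index(atoms) -> None:
    """Partition atoms into chains: a new chain starts when the PDB chain
    id changes or the residue numbering restarts (res_id decreases)."""
    n = atoms.array_length()
    chain_index = np.zeros(n, dtype=int)
    current = 0
    for i in range(1, n):
        new_chain = atoms.chain_id[i] != atoms.chain_id[i - 1] or (
            atoms.res_id[i] < atoms.res_id[i - 1]
        )
        if new_chain:
            current += 1
        chain_index[i] = current
    atoms.set_annotation("chain_index", chain_index)


def _fix_elements(atoms) -> None:
    blank = atoms.element == ""
    if np.any(blank):
        logger.warning(
            "element column missing for %d atoms; inferring from atom names",
            int(blank.sum()),
        )
        inferred = np.array([n.strip("0123456789")[:1] for n in atoms.atom_name])
        atoms.element = np.where(blank, inferred, atoms.element)


def read_structure(path) -> struc.AtomArray:
    """Read a single-model PDB; adds the ``chain_index`` annotation."""
    pdb = PDBFile.read(str(path))
    atoms = pdb.get_structure(model=1)
    _fix_elements(atoms)
    _annotate_chain_index(atoms)
    return atoms


def read_trajectory(path) -> struc.AtomArrayStack:
    """Read a multi-model PDB as a trajectory (frames = MODEL records)."""
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure()
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    _fix_elements(stack)
    _annotate_chain_index(stack)
    return stack


def _with_pdb_chain_ids(atoms):
    out = atoms.copy()
    if "chain_index" in atoms.get_annotation_categories():
        out.chain_id = np.array(
            [crystal.chain_id_label(ci) for ci in atoms.chain_index]
        )
    return out


def write_structure(model, path) -> None:
    """Write a model (NanocrystalModel or AtomArray) as PDB."""
    atoms = model.atoms if isinstance(model, crystal.NanocrystalModel) else model
    pdb = PDBFile()
    pdb.set_structure(_with_pdb_chain_ids(atoms))
    pdb.write(str(path))


def write_trajectory(stack: struc.AtomArrayStack, path) -> None:
    """Write a trajectory as multi-model PDB (MODEL/ENDMDL framing)."""
    pdb = PDBFile()
    pdb.set_structure(_with_pdb_chain_ids(stack))
    pdb.write(str(path))


def write_tables(tables: dict[str, pd.DataFrame], out_dir) -> dict[str, int]:
    """Write named DataFrames as CSV; returns per-table row counts.

    Refuses NaN in numeric columns (silent NaN propagation is an error),
    except columns explicitly allowed to be absent.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts = {}
    for name, df in tables.items():
        numeric = df.select_dtypes(include=[np.number])
        if numeric.isna().any().any():
            bad = numeric.columns[numeric.isna().any()].tolist()
            raise PipelineError(f"NaN in table {name!r}, columns {bad}")
        df.to_csv(out_dir / f"{name}.csv", index=False, float_format=CSV_FLOAT_FORMAT)
        counts[name] = len(df)
    return counts


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Declarative description of one pipeline run."""

    size: int = 6
    dp: int = 12
    facet: str = "O"
    n_frames: int = 50
    seed: int = 0
    equilibration_cut: float = 0.5
    hb_scope: str = "terminal"            # terminal | all
    max_oo_distance: float = 3.5
    min_dha_angle: float = 140.0
    persistence_threshold: float = 0.60
    mixtures: dict = field(default_factory=lambda: {"default": (0.6, 0.3, 0.1)})
    jitter_sigma: float = 0.05
    sigma_omega: float = 15.0
    trajectory_path: str | None = None    # analyse this instead of synthesizing
    densities_path: str | None = None     # default: bundled reference table
    energies_path: str | None = None      # default: bundled reference table
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        if path.suffix in (".toml", ".tml"):
            import tomllib

            data = tomllib.loads(path.read_text())
        elif path.suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(path.read_text())
        else:
            raise PipelineError(f"unsupported config format: {path.suffix}")
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


@dataclass
class RunManifest:
    tool_version: str
    config_hash: str
    input_checksums: dict
    row_counts: dict
    stage_seconds: dict
    timestamp: float

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


# --------------------------------------------------------------------------
# Orchestration
# --------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig, out_dir) -> RunManifest:
    """Run build -> trajectory -> conformers -> hydrogen bonds ->
    energetics, writing all report CSVs and the run manifest to
    ``out_dir``.  A stage failure aborts the run; outputs written so far
    are moved under ``failed/``."""
    from . import __version__

    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    checksums = {}
    for attr in ("trajectory_path", "densities_path", "energies_path"):
        p = getattr(config, attr)
        if p is not None:
            if not Path(p).exists():
                raise PipelineError(f"{attr} does not exist: {p}")
            checksums[attr] = _sha256(Path(p))

    row_counts: dict[str, int] = {}
    stage_seconds: dict[str, float] = {}
    stage = "build"
    try:
        t0 = time.perf_counter()
        model = crystal.assemble_nanocrystal(config.size, config.dp, config.facet)
        write_structure(model, out_dir / f"{model.name}.pdb")
        report = crystal.facet_coplanarity_check(model)
        row_counts["model_atoms"] = model.atoms.array_length()
        row_counts["model_chains"] = model.n_chains
        row_counts["model_residues"] = model.n_residues
        stage_seconds[stage] = round(time.perf_counter() - t0, 3)
        logger.info(
            "built %s: %d chains, coplanarity %.3f A / %.2f deg",
            model.name, model.n_chains, report.max_deviation, report.normal_angle_deg,
        )

        stage = "trajectory"
        t0 = time.perf_counter()
        if config.trajectory_path is not None:
            traj = read_trajectory(config.trajectory_path)
        else:
            syn_cfg = synth.SyntheticTrajectoryConfig(
                n_frames=config.n_frames,
                seed=config.seed,
                jitter_sigma=config.jitter_sigma,
                sigma_omega=config.sigma_omega,
                mixtures=config.mixtures,
            )
            traj, truth = synth.generate_trajectory(model, syn_cfg)
            (out_dir / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
        row_counts["frames"] = traj.stack_depth()
        stage_seconds[stage] = round(time.perf_counter() - t0, 3)

        stage = "conformers"
        t0 = time.perf_counter()
        torsions = conformers.torsion_table(traj, model)
        profile, histogram = conformers.conformer_profile(
            traj, model, equilibration_cut=config.equilibration_cut
        )
        stage_seconds[stage] = round(time.perf_counter() - t0, 3)

        stage = "hbonds"
        t0 = time.perf_counter()
        criteria = hbonds.HBondCriteria(
            max_oo_distance=config.max_oo_distance,
            min_dha_angle=config.min_dha_angle,
        )
        records = hbonds.detect_hbonds_trajectory(
            traj, criteria, scope=config.hb_scope, model=model
        )
        hb_summary = hbonds.fraction_summary(records)
        hb_summary["persistent"] = hb_summary.mean_fraction > config.persistence_threshold
        stage_seconds[stage] = round(time.perf_counter() - t0, 3)

        stage = "energetics"
        t0 = time.perf_counter()
        densities = (
            pd.read_csv(config.densities_path)
            if config.densities_path
            else energetics.load_reference_densities()
        )
        density_rep = energetics.density_report(densities)
        ledger = (
            pd.read_csv(config.energies_path)
            if config.energies_path
            else energetics.load_reference_sheet_energies()
        )
        shifts, extrema = energetics.solvent_shift(ledger)
        shifts["de_bind_family_sum_vacuum"] = shifts.model.map(
            energetics.bind_family_sums(ledger, "vacuum")
        )
        stage_seconds[stage] = round(time.perf_counter() - t0, 3)

        stage = "report"
        t0 = time.perf_counter()
        counts = write_tables(
            {
                "torsions": torsions,
                "conformer_profile": profile,
                "omega_histogram": histogram,
                "hbond_records": records,
                "hbond_summary": hb_summary,
                "hb_strength_report": density_rep,
                "sheet_energy_report": shifts,
            },
            out_dir,
        )
        (out_dir / "solvent_shift_extrema.json").write_text(
            json.dumps(extrema, indent=2, sort_keys=True)
        )
        row_counts.update(counts)
        stage_seconds[stage] = round(time.perf_counter() - t0, 3)
    except Exception:
        failed = out_dir / "failed"
        failed.mkdir(exist_ok=True)
        for item in out_dir.iterdir():
            if item.is_file():
                item.rename(failed / item.name)
        logger.exception("pipeline stage %r failed; partial outputs under %s", stage, failed)
        raise

    manifest = RunManifest(
        tool_version=__version__,
        config_hash=config.config_hash(),
        input_checksums=checksums,
        row_counts=row_counts,
        stage_seconds=stage_seconds,
        timestamp=time.time(),
    )
    manifest.write(out_dir / "manifest.json")
    return manifest
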