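"""End-to-end driver: load -> bounds -> restraints -> per-structure
[metrize -> embed 4D -> anneal 4D -> project -> anneal 3D -> minimize] -> rank.

Every structure is driven by its own child seed spawned from the master seed,
so runs are deterministic and embarrassingly parallel with results that do
not depend on the worker count.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import anneal as _anneal
from .anneal import AnnealSchedule, minimize, project_to_3d, run_annealing
from .embed import Conformer, embed_4d, metrize
from .energy import ForceConstants, PseudoEnergy
from .molgraph import (
    ChiralRestraint,
    MoleculeGraph,
    ReferenceGeometry,
    holonomic_bounds,
    load_structure,
    reference_chiral_volumes,
    signed_volume,
    smooth_bounds,
)
from .rank import EnsembleReport, rank_ensemble
from .restraints import RestraintSet, parse_noe_table, parse_rdc_tables


@dataclass
class RunConfig:
    """Full configuration of a floating-chirality run (published defaults)."""

    structure: str | None = None          # SDF path (or use in-memory inputs)
    noe_table: str | None = None
    rdc_tables: list[str] = field(default_factory=list)
    n_structures: int = 1000
    fixed_centers: list[int] = field(default_factory=list)
    fixed_methylenes: list[int] = field(default_factory=list)
    force_constants: ForceConstants = field(default_factory=ForceConstants)
    schedule: AnnealSchedule = field(default_factory=AnnealSchedule)
    schedule_3d: AnnealSchedule | None = None
    master_seed: int = 0
    output_dir: str | None = None
    use_noe: bool = True
    use_rdc: bool = True
    noe_half_width: float = 0.10
    minimize_tol: float = 1e-3
    minimize_max_steps: int = 3000
    k_w: float = _anneal.DEFAULT_KW
    n_metrize: int | None = None          # default 4N sampled pairs
    n_workers: int = 1

    def validate(self) -> None:
        if self.use_rdc and self.structure and not self.rdc_tables:
            if not self.use_noe or not self.noe_table:
                raise ValueError(
                    "no restraint source: enable NOEs with a table and/or "
                    "provide RDC tables"
                )
        if not self.use_noe and not self.use_rdc:
            raise ValueError("at least one restraint source must be enabled")


@dataclass
class RunResult:
    report: EnsembleReport
    conformers: list[Conformer]
    graph: MoleculeGraph
    config: RunConfig
    metadata: dict


def _child_seeds(master_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


def generate_structure(
    bounds,
    model: PseudoEnergy,
    seed: int,
    schedule: AnnealSchedule,
    schedule_3d: AnnealSchedule | None = None,
    fix_restraint: ChiralRestraint | None = None,
    k_w: float = _anneal.DEFAULT_KW,
    minimize_tol: float = 1e-3,
    minimize_max_steps: int = 3000,
    n_metrize: int | None = None,
    stop_after: str = "minimized",
) -> Conformer:
    """One full structure: metrize, embed 4D, anneal 4D, project, anneal 3D,
    minimize.  ``stop_after`` may name an earlier stage for diagnostics."""
    dmat = metrize(bounds, seed, n_sample=n_metrize)
    conf = embed_4d(dmat)
    conf.seed = seed
    if stop_after == "embedded4d":
        return conf
    conf = run_annealing(conf, "4d", schedule, model, seed + 1, k_w=k_w)
    if conf.failed or stop_after == "annealed4d":
        return conf
    # the 4D stage concludes with a gradient minimization under a stiffening
    # compression potential (homotopy in k_w, with the 3D-subspace terms
    # ramping in alongside), quenching the 4th dimension so the projection
    # that follows is essentially lossless
    for kw_quench, w3_quench in ((5.0 * k_w, 0.1), (50.0 * k_w, 0.5),
                                 (500.0 * k_w, 1.0)):
        conf = minimize(conf,
                        _anneal.Compressed4D(model, k_w=kw_quench, w3=w3_quench),
                        tol=minimize_tol,
                        max_steps=max(200, minimize_max_steps // 4),
                        stage_out=None)
    conf = project_to_3d(conf, fix_restraint=fix_restraint)
    if stop_after == "projected3d":
        return conf
    sched3 = schedule_3d or schedule
    conf = run_annealing(conf, "3d", sched3, model, seed + 2)
    if conf.failed or stop_after == "annealed3d":
        return conf
    return minimize(conf, model, tol=minimize_tol, max_steps=minimize_max_steps)


def _prepare(config: RunConfig):
    graph, ref = load_structure(config.structure)
    restraints = RestraintSet()
    if config.use_noe and config.noe_table:
        restraints.noes = parse_noe_table(config.noe_table, graph,
                                          half_width=config.noe_half_width)
    if config.use_rdc:
        if config.rdc_tables:
            restraints.rdcs = parse_rdc_tables(config.rdc_tables, graph)
        elif not restraints.noes:
            raise ValueError("use_rdc is on but no RDC tables were given")
    restraints.chirals = reference_chiral_volumes(
        graph, ref, fixed_centers=config.fixed_centers,
        allow_multiple_fixed=len(config.fixed_centers) > 1,
    )
    if config.fixed_methylenes:
        restraints.chirals = restraints.chirals + fix_methylenes(
            graph, ref, config.fixed_methylenes
        )
    restraints.validate(graph)
    bounds = smooth_bounds(holonomic_bounds(graph, ref))
    return graph, ref, restraints, bounds


def run(
    config: RunConfig,
    graph: MoleculeGraph | None = None,
    bounds=None,
    restraints: RestraintSet | None = None,
    reference=None,
) -> RunResult:
    """Execute a full run from a config (file inputs) or in-memory objects.

    Writes the ranked CSV/JSON/XYZ artifacts into ``config.output_dir`` when
    set.  ``reference`` optionally names the true configuration class for the
    report diagnostics.
    """
    config.validate()
    if graph is None:
        graph, _ref, restraints, bounds = _prepare(config)

    model = PseudoEnergy(bounds, restraints, config.force_constants)
    model.set_torsions(graph.planar_groups)
    fix_restraint = next(
        (c for c in restraints.chirals if c.kind == "fixed_stereocenter"), None
    )
    fixed_centers = [c.center for c in restraints.chirals
                     if c.kind == "fixed_stereocenter"]

    seeds = _child_seeds(config.master_seed, config.n_structures)
    args = dict(
        schedule=config.schedule, schedule_3d=config.schedule_3d,
        fix_restraint=fix_restraint, k_w=config.k_w,
        minimize_tol=config.minimize_tol,
        minimize_max_steps=config.minimize_max_steps,
        n_metrize=config.n_metrize,
    )
    if config.n_workers > 1:
        from joblib import Parallel, delayed

        confs = Parallel(n_jobs=config.n_workers)(
            delayed(generate_structure)(bounds, model, s, **args) for s in seeds
        )
    else:
        confs = [generate_structure(bounds, model, s, **args) for s in seeds]

    report = rank_ensemble(confs, graph, reference=reference,
                           fixed_centers=fixed_centers)
    metadata = {
        "n_structures": config.n_structures,
        "master_seed": config.master_seed,
        "force_constants": dataclasses.asdict(config.force_constants),
        "schedule": dataclasses.asdict(config.schedule),
        "kb": _anneal.KB,
        "time_per_fs": _anneal.TIME_PER_FS,
        "k_w": config.k_w,
        "fixed_centers": fixed_centers,
        "n_media": restraints.n_media,
        "n_noes": len(restraints.noes),
        "n_rdcs": len(restraints.rdcs),
        "n_failed": report.n_failed,
    }
    result = RunResult(report=report, conformers=confs, graph=graph,
                       config=config, metadata=metadata)
    if config.output_dir:
        write_artifacts(result, config.output_dir)
    return result


def fix_methylenes(
    graph: MoleculeGraph, ref: ReferenceGeometry, centers: list[int]
) -> list[ChiralRestraint]:
    """Fixed chiral-volume restraints for prochiral CH2 centers whose
    diastereotopic assignment is known (e.g. from 3J_HH / HMBC data)."""
    out = []
    for c in centers:
        if c not in graph.prochiral_centers:
            raise ValueError(
                f"atom {c} is not a prochiral CH2 center; only prochiral "
                "centers can be fixed through the methylene path"
            )
        quad = tuple(graph.neighbors(c))
        out.append(
            ChiralRestraint(
                center=c, substituents=quad,
                target_volume=signed_volume(ref.coordinates, quad),
                kind="fixed_stereocenter",
            )
        )
    return out


def toggle_methylene_fix(config: RunConfig, assignments: list[int]) -> RunConfig:
    """Return a config with the named prochiral centers converted to fixed
    chiral restraints (reduces the number of floating centers)."""
    if not assignments:
        return config
    if config.structure:
        graph, _ = load_structure(config.structure)
        for c in assignments:
            if c not in graph.prochiral_centers:
                raise ValueError(f"atom {c} is not a prochiral CH2 center")
    return replace(config, fixed_methylenes=list(config.fixed_methylenes) + list(assignments))


# ---------------------------------------------------------------------------
# Artifacts
# ---------------------------------------------------------------------------

def write_artifacts(result: RunResult, outdir: str) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.report.to_csv(out / "ranked.csv")
    result.report.to_json(out / "report.json")
    with open(out / "run_metadata.json", "w") as fh:
        json.dump(result.metadata, fh, indent=1)
    write_ranked_xyz(result, out / "ranked.xyz")
    with open(out / "structures.jsonl", "w") as fh:
        for s in result.report.structures:
            fh.write(json.dumps({
                "rank": s.rank, "seed": s.seed, "e_total": s.e_total,
                **s.breakdown, "fingerprint": str(s.fp),
            }) + "\n")


def write_ranked_xyz(result: RunResult, path, max_structures: int | None = None) -> None:
    """Multi-frame XYZ of ranked (minimized, non-failed) structures."""
    by_seed = {c.seed: c for c in result.conformers if not c.failed}
    elements = result.graph.elements
    lines = []
    for s in result.report.structures[:max_structures]:
        conf = by_seed[s.seed]
        lines.append(str(len(elements)))
        lines.append(f"rank={s.rank} seed={s.seed} e_total={s.e_total:.6f} fp={s.fp}")
        for el, xyz in zip(elements, conf.coords[:, :3]):
            lines.append(f"{el} {xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_ranked_sdf(result: RunResult, path, max_structures: int | None = None) -> None:
    """Multi-record SDF of ranked structures (requires the loaded RDKit mol)."""
    from rdkit import Chem

    mol0 = result.graph.mol
    if mol0 is None:
        raise ValueError("graph carries no RDKit molecule; use write_ranked_xyz")
    by_seed = {c.seed: c for c in result.conformers if not c.failed}
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    for s in result.report.structures[:max_structures]:
        conf = by_seed[s.seed]
        mol = Chem.Mol(mol0)
        mol.RemoveAllConformers()
        cc = Chem.Conformer(mol.GetNumAtoms())
        for i, xyz in enumerate(conf.coords[:, :3]):
            cc.SetAtomPosition(i, tuple(float(v) for v in xyz))
        mol.AddConformer(cc)
        mol.SetProp("_Name", f"rank_{s.rank}")
        mol.SetProp("e_total", f"{s.e_total:.6f}")
        mol.SetProp("fingerprint", str(s.fp))
        writer.write(mol)
    writer.close()
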