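"""Pipeline orchestration, configuration, serialization, and fixtures.

The numerical experiment runs in five stages: (1) enumerate and classify
the spanning trees of the scaffold, (2) select one or two classes by their
(MLD, N_p) index, (3) fix the energy parameters, (4) build the assembly
networks, and (5) integrate the coupled master equations and extract
observables.  ``run_pipeline`` executes the stages in order and writes all
artifacts; given the same configuration the outputs are byte-identical
(the ODE path has no stochastic component).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .energetics import EnergyParams
from .kinetics import KineticsParams, Trajectory, integrate
from .network import AssemblyNetwork, build_network
from .observables import delay_time, selectivity
from .polyhedra import get_polyhedron
from .treelib import TreeLibrary, build_library, dodecahedron_library

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "generate_fixtures"]


@dataclass(frozen=True)
class RunConfig:
    """Flat run configuration.

    ``tree_classes`` holds one or two (MLD, N_p) selectors; two selectors
    run a packaging competition.  ``mu0`` may be the string "equilibrium".
    ``class_ids`` optionally pins the exact library member per selector.
    """

    polyhedron: str = "dodecahedron"
    tree_classes: tuple[tuple[int, int], ...] = ((9, 8), (19, 2))
    class_ids: tuple[int | None, ...] | None = None
    e0: float = 4.0
    eps1: float = -0.5
    mu0: float | str = -4.0
    c0: float = 1.0
    d_ratio: float = 0.5
    lam: float = 1.0
    t_end: float = 1e6
    n_times: int = 400
    selection_rule: str = "barrier"

    def __post_init__(self):
        if not 1 <= len(self.tree_classes) <= 2:
            raise ValueError("one or two tree classes required")
        if self.e0 <= 0 or self.c0 <= 0 or self.d_ratio <= 0 or self.t_end <= 0:
            raise ValueError("e0, c0, D and t_end must be positive")
        if self.mu0 == "equilibrium":
            from .energetics import equilibrium_mu0

            object.__setattr__(self, "mu0", equilibrium_mu0(self.eps1))

    @property
    def energy_params(self) -> EnergyParams:
        return EnergyParams(e0=self.e0, eps1=self.eps1, mu0=self.mu0)

    @property
    def kinetics_params(self) -> KineticsParams:
        return KineticsParams(c0=self.c0, d_ratio=self.d_ratio, lam=self.lam)

    def to_dict(self) -> dict:
        return {
            "polyhedron": self.polyhedron,
            "tree_classes": [list(tc) for tc in self.tree_classes],
            "class_ids": list(self.class_ids) if self.class_ids else None,
            "e0": self.e0,
            "eps1": self.eps1,
            "mu0": self.mu0,
            "c0": self.c0,
            "d_ratio": self.d_ratio,
            "lambda": self.lam,
            "t_end": self.t_end,
            "n_times": self.n_times,
            "selection_rule": self.selection_rule,
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Read a flat ``key = value`` config file (# comments allowed)."""
        kv: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            kv[key.strip()] = val.strip()
        classes = tuple(
            tuple(int(x) for x in part.split(","))
            for part in kv.get("tree_classes", "9,8;19,2").split(";")
        )
        mu0: float | str = kv.get("mu0", "-4.0")
        if mu0 != "equilibrium":
            mu0 = float(mu0)
        return cls(
            polyhedron=kv.get("polyhedron", "dodecahedron"),
            tree_classes=classes,  # type: ignore[arg-type]
            e0=float(kv.get("e0", 4.0)),
            eps1=float(kv.get("eps1", -0.5)),
            mu0=mu0,
            c0=float(kv.get("c0", 1.0)),
            d_ratio=float(kv.get("d_ratio", 0.5)),
            lam=float(kv.get("lambda", 1.0)),
            t_end=float(kv.get("t_end", 1e6)),
            n_times=int(kv.get("n_times", 400)),
            selection_rule=kv.get("selection_rule", "barrier"),
        )


@dataclass
class PipelineResult:
    config: RunConfig
    library: TreeLibrary
    networks: list[AssemblyNetwork]
    trajectory: Trajectory
    observables: dict = field(default_factory=dict)


def _library_for(name: str) -> TreeLibrary:
    if name == "dodecahedron":
        return dodecahedron_library()
    return build_library(get_polyhedron(name))


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Execute the five-stage pipeline; optionally write all artifacts."""
    stage = "enumerate/classify"
    try:
        graph = get_polyhedron(config.polyhedron)
        library = _library_for(config.polyhedron)

        stage = "select tree classes"
        eparams = config.energy_params
        ids = config.class_ids or (None,) * len(config.tree_classes)
        classes = [
            library.select(
                m, w, rule=config.selection_rule, class_id=cid, energy_params=eparams
            )
            for (m, w), cid in zip(config.tree_classes, ids)
        ]

        stage = "assembly networks"
        networks = [build_network(c, graph, eparams) for c in classes]

        stage = "master equation"
        traj = integrate(
            networks,
            config.kinetics_params,
            config.t_end,
            e0=config.e0,
            n_times=config.n_times,
        )

        stage = "observables"
        obs: dict = {
            "barriers": [net.profile.barrier for net in networks],
            "multiplicities": [net.multiplicities for net in networks],
        }
        p1 = traj.packaged_fraction(0)
        try:
            dt = delay_time(traj.times, p1)
            obs["delay_time"] = dt.t_d
            obs["t_star"] = dt.t_star
        except ValueError:
            obs["delay_time"] = None
        if traj.n_species == 2:
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sel = selectivity(traj)
            obs["selectivity"] = sel.s
            obs["t_max"] = sel.t_max
            obs["peak_yield"] = float(np.max(p1))
        else:
            obs["final_yield"] = float(p1[-1])
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    result = PipelineResult(
        config=config,
        library=library,
        networks=networks,
        trajectory=traj,
        observables=obs,
    )
    if outdir is not None:
        write_result(result, Path(outdir))
    return result


# --------------------------------------------------------------------------
# serialization


def _header(config: RunConfig) -> dict:
    return {"version": __version__, "config_hash": config.config_hash()}


def write_result(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    (outdir / "config.json").write_text(
        json.dumps({**_header(cfg), "config": cfg.to_dict()}, sort_keys=True, indent=1)
    )
    # selected classes
    recs = [
        {**_header(cfg), **net.to_dict()} for net in result.networks
    ]
    (outdir / "networks.json").write_text(json.dumps(recs, sort_keys=True))
    # trajectory as CSV: time, species, n, i, P plus c_f
    traj = result.trajectory
    frames = []
    for s in range(traj.n_species):
        net = traj.networks[s]
        k = 0
        for n, m in enumerate(net.level_sizes):
            for i in range(m):
                frames.append(
                    pd.DataFrame(
                        {
                            "time": traj.times,
                            "species": s,
                            "n": n,
                            "i": i + 1,
                            "P": traj.node_probs[s][k],
                        }
                    )
                )
                k += 1
    df = pd.concat(frames, ignore_index=True)
    cf = pd.DataFrame({"time": traj.times, "c_f": traj.c_f})
    df = df.merge(cf, on="time")
    df.to_csv(outdir / "trajectory.csv", index=False, float_format="%.10g")
    # summary with the packaged-fraction series
    summary = {
        **_header(cfg),
        "observables": result.observables,
        "times": [float(t) for t in traj.times],
        "p_complete": [
            [float(x) for x in traj.packaged_fraction(s)]
            for s in range(traj.n_species)
        ],
        "c_f": [float(x) for x in traj.c_f],
    }
    (outdir / "summary.json").write_text(json.dumps(summary, sort_keys=True))


def write_library(library: TreeLibrary, path: Path, config_note: str = "") -> None:
    head = json.dumps(
        {"version": __version__, "polyhedron": library.graph.name, "note": config_note},
        sort_keys=True,
    )
    path.write_text("# " + head + "\n" + library.to_jsonl())


# --------------------------------------------------------------------------
# fixtures


def toy_three_level_network() -> AssemblyNetwork:
    """Hand-checkable 3-level ladder used as a kinetics oracle.

    Levels 0/1/2 with multiplicities (1, 2, 1), energies (0, 1, -0.5) in E0
    units, and full bipartite adjacency.  Small enough that the stationary
    state of the clamped master equation can be written down analytically.
    """
    graph = get_polyhedron("tetrahedron")  # placeholder scaffold; unused
    return AssemblyNetwork(
        graph=graph,
        tree=0,
        params=EnergyParams(e0=2.0, eps1=-0.5, mu0=0.0),
        e_min=np.array([0.0, 1.0, -0.5]),
        levels=[[()], [(0,), (1,)], [(0, 1)]],
        adjacency=[[[0, 1]], [[0], [0]]],
        stabilizer=[0],
    )


def generate_fixtures(outdir: str | Path) -> dict[str, Path]:
    """Write the fixture polyhedra, their spanning-tree libraries, and the
    toy kinetics network to ``outdir``; returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name in ("tetrahedron", "cube"):
        graph = get_polyhedron(name)
        p = outdir / f"{name}.json"
        p.write_text(graph.to_json(indent=1))
        written[name] = p
        lib = build_library(graph)
        lp = outdir / f"{name}_trees.jsonl"
        write_library(lib, lp, config_note="full spanning-tree library")
        written[f"{name}_trees"] = lp
    toy = toy_three_level_network()
    tp = outdir / "toy_network.json"
    tp.write_text(json.dumps(toy.to_dict(), sort_keys=True, indent=1))
    written["toy_network"] = tp
    return written
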