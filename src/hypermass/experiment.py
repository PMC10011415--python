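"""Config-driven experiment runner.

The library's functions are its interface; this module adds a thin,
reproducible layer for scripted experiments: a validated
:class:`ExperimentConfig` maps deterministically (given its seed) to a
bundle of plain-text results plus a manifest echoing the fully resolved
configuration and package version.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from hypermass import generators, qs as qsmod
from hypermass.blobchain import (
    BlobChainParams,
    chain_summary,
    stationary_pi,
)
from hypermass.gillespie import simulate
from hypermass.hypergraph import (
    DynamicsParameters,
    Hypergraph,
    constant_modulation,
    load_hypergraph,
    log2_modulation,
)
from hypermass.meanfield import branch_continuation

__all__ = ["ExperimentConfig", "run_experiment"]

_MODULATIONS = {"log2": log2_modulation, "const": constant_modulation}
_METHODS = ("gillespie", "qs", "sweep", "ode", "blob-exact")


@dataclass
class ExperimentConfig:
    """Validated description of one experiment.

    ``structure`` describes the hypergraph source: ``{"kind": "file",
    "path": ..., "format": ...}`` or ``{"kind": "hyperblob", "n": ...,
    "k": ...}`` or ``{"kind": "communities", "n": ..., "m_in": [...],
    "m_out": ..., "mu": ...}``; ``blob-exact`` runs need no structure.
    ``dynamics`` holds ``lam``, ``delta``, ``theta_star`` and the
    modulation name (``log2`` or ``const``).  ``options`` are
    method-specific keyword arguments.
    """

    method: str
    seed: int
    out_dir: str
    structure: dict = field(default_factory=dict)
    dynamics: dict = field(default_factory=dict)
    options: dict = field(default_factory=dict)

    def validate(self) -> list[str]:
        problems = []
        if self.method not in _METHODS:
            problems.append(f"method must be one of {_METHODS}, got {self.method!r}")
        if self.method != "blob-exact" and "kind" not in self.structure:
            problems.append("structure.kind is required")
        mod = self.dynamics.get("modulation", "log2")
        if mod not in _MODULATIONS:
            problems.append(f"dynamics.modulation must be one of {sorted(_MODULATIONS)}")
        if not isinstance(self.seed, (int, np.integer)):
            problems.append("seed must be an integer")
        return problems


def _build_structure(cfg: ExperimentConfig) -> Hypergraph:
    s = dict(cfg.structure)
    kind = s.pop("kind")
    if kind == "file":
        return load_hypergraph(s["path"], format=s.get("format", "edge-list"))
    if kind == "hyperblob":
        return generators.make_hyperblob(s["n"], s["k"], seed=cfg.seed)
    if kind == "communities":
        conf = generators.CommunityConfig(
            node_count=s["n"],
            m_in=tuple(s["m_in"]),
            m_out=s.get("m_out", 0),
            mu=s.get("mu", 8.0),
        )
        return generators.make_community_hypergraph(conf, seed=cfg.seed)
    raise ValueError(f"unknown structure kind: {kind!r}")


def _params(cfg: ExperimentConfig) -> DynamicsParameters:
    d = cfg.dynamics
    return DynamicsParameters(
        lam=float(d.get("lam", 0.0)),
        delta=float(d.get("delta", 1.0)),
        theta_star=float(d.get("theta_star", 0.5)),
        modulation=_MODULATIONS[d.get("modulation", "log2")],
    )


def _write_tsv(path: Path, header: list[str], rows) -> None:
    lines = ["\t".join(header)]
    for row in rows:
        lines.append("\t".join(f"{v:.12g}" if isinstance(v, float) else str(v) for v in row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def run_experiment(config: ExperimentConfig) -> dict:
    """Run the configured experiment; returns a summary dict and writes
    the result bundle (manifest, TSV/JSON outputs) under ``out_dir``."""
    problems = config.validate()
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result: dict = {}
    method = config.method

    if method == "blob-exact":
        o = config.options
        p = BlobChainParams(
            N=int(o["n"]),
            lam_k=float(o["lam_k"]),
            lam_star=float(o["lam_star"]),
            delta=float(o.get("delta", 1.0)),
            theta_star=o.get("theta_star"),
            theta=o.get("theta"),
            qs=True,
        )
        dist = stationary_pi(p)
        summ = chain_summary(dist, p)
        _write_tsv(
            out / "pi.tsv",
            ["n", "pi"],
            [(n, float(v)) for n, v in enumerate(dist.pi)],
        )
        (out / "summary.json").write_text(json.dumps(summ, indent=2), encoding="utf-8")
        result = summ
    else:
        H = _build_structure(config)
        params = _params(config)
        o = dict(config.options)
        if method == "gillespie":
            traj = simulate(
                H,
                params,
                init=o.get("init", 1.0),
                t_max=float(o.get("t_max", 100.0)),
                seed=config.seed,
            )
            _write_tsv(
                out / "events.tsv",
                ["time", "kind"],
                [(float(t), int(k)) for t, k in zip(traj.times, traj.kinds)],
            )
            result = {
                "n_events": int(traj.n_events),
                "t_end": float(traj.t_end),
                "absorbed": bool(traj.absorbed),
                "final_active": int(traj.final_state().sum()),
            }
        elif method == "qs":
            qs_cfg = qsmod.QSConfig(**o.pop("qs", {}))
            dist = qsmod.run_qs(H, params, qs_cfg, o.get("init", 1.0), seed=config.seed)
            rho, chi = qsmod.summary(dist)
            _write_tsv(
                out / "distribution.tsv",
                ["n", "probability"],
                [(n, float(v)) for n, v in enumerate(dist.probabilities())],
            )
            result = {"rho": rho, "chi": chi, "peaks": qsmod.peaks(dist)}
            (out / "summary.json").write_text(json.dumps(result, indent=2), encoding="utf-8")
        elif method == "sweep":
            qs_cfg = qsmod.QSConfig(**o.pop("qs", {}))
            diagram = qsmod.lambda_sweep(
                H,
                params,
                o["lambdas"],
                seeding=o.get("seeding", [1.0]),
                qs=qs_cfg,
                replicas=int(o.get("replicas", 1)),
                seed=config.seed,
            )
            _write_tsv(
                out / "diagram.tsv",
                ["lam", "branch", "rho", "chi"],
                [
                    (float(r["lam"]), int(r["branch"]), float(r["rho"]), float(r["chi"]))
                    for r in diagram.records
                ],
            )
            result = {"n_records": len(diagram.records)}
        elif method == "ode":
            seed_state = np.asarray(o.get("seed_state", np.ones(H.node_count)), dtype=float)
            traces = branch_continuation(
                H,
                params,
                o["lambdas"],
                seed_state,
                directions=tuple(o.get("directions", ("up", "down"))),
                seed_lambda=o.get("seed_lambda"),
            )
            rows = []
            for b, tr in enumerate(traces):
                for lam, rho in zip(tr.lambdas, tr.rhos):
                    rows.append((float(lam), b, float(rho)))
            _write_tsv(out / "trace.tsv", ["lam", "branch", "rho"], rows)
            result = {"n_traces": len(traces)}

    from hypermass import __version__

    manifest = {
        "package": "hypermass",
        "version": __version__,
        "config": asdict(config),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    return result
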