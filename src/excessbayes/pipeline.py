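"""End-to-end pipeline: simulate (or load a fixture) → relation → lattice →
logic report, with every intermediate written to disk.

A pipeline run is described by one JSON document: either a ``fixture``
(no simulation; the relation is constructed directly) or a ``simulation``
(Bayesian warm-up plus optional excess phase).  Reruns with identical
config and seed produce byte-identical artifacts.
"""

from __future__ import annotations

import json
import time
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, model_validator

from . import __version__
from .excess import run_excess_phase, threshold_relation
from .io import (
    hasse_dot,
    write_heatmap_csv,
    write_lattice_json,
    write_matrix_csv,
    write_prob_csv,
)
from .lattice import enumerate_lattice, reduce_relation
from .logic import FiniteLattice, classify
from .relation import FixtureSpec, make_fixture, write_relation_csv
from .simulate import SimulationConfig, heatmap_bins

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")

    def record(self) -> dict:
        return {"stage": self.stage, "error": str(self.cause)}


class PipelineConfig(BaseModel):
    """Either a fixture relation or a simulation, followed by the lattice
    and logic stages."""

    fixture: Optional[FixtureSpec] = None
    simulation: Optional[SimulationConfig] = None
    reduce: bool = False
    guard: int = 1 << 16

    @model_validator(mode="after")
    def _one_source(self) -> "PipelineConfig":
        if (self.fixture is None) == (self.simulation is None):
            raise ValueError("exactly one of fixture/simulation is required")
        return self


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute all stages, writing artifacts into ``out_dir``.

    Returns the report dictionary.  Any stage error aborts with
    :class:`PipelineError` naming the stage; no lattice artifacts are
    written in that case.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict = {}
    meta: dict = {
        "version": __version__,
        "config": json.loads(config.model_dump_json()),
    }

    t0 = time.perf_counter()
    try:
        if config.fixture is not None:
            rel = make_fixture(config.fixture)
        else:
            sim = config.simulation
            if sim.excess_steps > 0:
                state, rel = run_excess_phase(sim)
            else:
                from .simulate import run_bayesian_phase

                state = run_bayesian_phase(sim)
                rel = threshold_relation(
                    state.joint, sim.relation_threshold, inclusive=True
                )
            write_matrix_csv(state.joint, out / "final_joint.csv")
            write_heatmap_csv(
                heatmap_bins(state.joint, sim.heatmap_edges), out / "final_heatmap.csv"
            )
            write_prob_csv(state.prior, out / "final_hypothesis_marginal.csv")
            write_prob_csv(
                state.data_marginal(sim.smoothing), out / "final_data_marginal.csv"
            )
            for snap in state.history:
                if snap.phase == "excess":
                    write_matrix_csv(
                        snap.joint, out / f"excess_joint_t{snap.t:04d}.csv"
                    )
            meta["steps"] = state.t
            meta["seed"] = sim.seed
    except Exception as exc:  # noqa: BLE001 — stage boundary
        raise PipelineError("simulate", exc) from exc
    timings["simulate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    try:
        write_relation_csv(rel, out / "relation.csv")
        if config.reduce:
            rel, log = reduce_relation(rel)
            meta["reduction_log"] = [list(item) for item in log]
            write_relation_csv(rel, out / "relation_reduced.csv")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("relation", exc) from exc
    timings["relation"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    try:
        lat = enumerate_lattice(rel, config.guard)
        write_lattice_json(lat, out / "lattice.json")
        (out / "hasse.dot").write_text(hasse_dot(lat))
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("lattice", exc) from exc
    timings["lattice"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    try:
        report = classify(FiniteLattice.from_rough(lat))
        doc = report.to_dict()
        with open(out / "report.json", "w") as fh:
            json.dump(doc, fh, indent=1)
            fh.write("\n")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("logic", exc) from exc
    timings["logic"] = time.perf_counter() - t0

    meta["timings"] = timings
    with open(out / "metadata.json", "w") as fh:
        json.dump(meta, fh, indent=1)
        fh.write("\n")
    return doc
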