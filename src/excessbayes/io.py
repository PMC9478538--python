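"""Serialization of the package's artifacts to plain-text formats.

Probability tables go to CSV (12 significant digits), lattices to a JSON
document with deterministic element order, and Hasse diagrams to DOT.
"""

from __future__ import annotations

import csv
import json

import numpy as np

from .lattice import RoughLattice, hasse_covers
from .probability import JointMatrix, LikelihoodMatrix, ProbVector
from .simulate import HeatmapGrid

__all__ = [
    "write_matrix_csv",
    "write_prob_csv",
    "read_prob_csv",
    "write_heatmap_csv",
    "lattice_to_json",
    "lattice_from_json_dict",
    "write_lattice_json",
    "hasse_dot",
]

_FMT = "{:.12g}"


def write_matrix_csv(mat: JointMatrix | LikelihoodMatrix, path) -> None:
    """Joint or likelihood table: header ``P,h1,...``; one row per datum."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["P", *mat.hyp_labels])
        for i, d in enumerate(mat.data_labels):
            w.writerow([d, *(_FMT.format(x) for x in mat.entries[i])])


def write_prob_csv(p: ProbVector, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        for label, value in zip(p.labels, p.values):
            w.writerow([label, _FMT.format(value)])


def read_prob_csv(path) -> ProbVector:
    labels, values = [], []
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row:
                continue
            labels.append(row[0])
            values.append(float(row[1]))
    return ProbVector(tuple(labels), np.array(values))


def write_heatmap_csv(grid: HeatmapGrid, path) -> None:
    """Heatmap grid with bin names as cell values."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["bin", *grid.hyp_labels])
        for i, d in enumerate(grid.data_labels):
            w.writerow([d, *grid.bins[i]])


def lattice_to_json(lat: RoughLattice) -> dict:
    """Deterministic JSON form: elements sorted by (size, label positions);
    covers as index pairs [i, j] with element i covered by element j."""
    order = {e: i for i, e in enumerate(lat.elements)}
    pos = {d: i for i, d in enumerate(lat.universe)}
    covers = sorted(
        [order[a], order[b]] for a, b in hasse_covers(lat)
    )
    return {
        "universe": list(lat.universe),
        "elements": [sorted(e, key=pos.__getitem__) for e in lat.elements],
        "covers": covers,
        "bottom": order[lat.bottom],
        "top": order[lat.top],
    }


def write_lattice_json(lat: RoughLattice, path) -> None:
    with open(path, "w") as fh:
        json.dump(lattice_to_json(lat), fh, indent=1)
        fh.write("\n")


def lattice_from_json_dict(doc: dict):
    """Rebuild (elements, covers, universe) from the JSON form; used by the
    CLI's check/hasse subcommands."""
    universe = tuple(doc["universe"])
    elements = [frozenset(e) for e in doc["elements"]]
    covers = [(int(i), int(j)) for i, j in doc["covers"]]
    return universe, elements, covers


def hasse_dot(lat: RoughLattice) -> str:
    """DOT digraph of the Hasse diagram, one node per element, one edge per
    cover, bottom at the minimum rank."""
    doc = lattice_to_json(lat)
    lines = ["digraph hasse {", "  rankdir=BT;"]
    for i, e in enumerate(doc["elements"]):
        label = "{" + ",".join(e) + "}"
        lines.append(f'  n{i} [label="{label}"];')
    for i, j in doc["covers"]:
        lines.append(f"  n{i} -> n{j};")
    lines.append(f'  {{rank=min; n{doc["bottom"]};}}')
    lines.append(f'  {{rank=max; n{doc["top"]};}}')
    lines.append("}")
    return "\n".join(lines) + "\n"
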