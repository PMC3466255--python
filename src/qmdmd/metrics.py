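"""Named active-site geometry observables and ensemble statistics.

Metrics are role-based so the same specification applies to synthetic toy
sites and, given real input, to actual residues: a selector is a
(role, atom_name) pair that must resolve to exactly one atom.  Ensemble
tables render "mean (sd)" in the conventional active-site-table style
(2 decimals for Å, none for degrees).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_io import MolecularSystem


@dataclass(frozen=True)
class MetricSpec:
    label: str
    kind: str                      # "distance" | "angle"
    selectors: tuple               # 2 or 3 (role, atom_name) pairs

    def __post_init__(self):
        need = {"distance": 2, "angle": 3}.get(self.kind)
        if need is None:
            raise ValueError(f"unknown metric kind {self.kind!r}")
        if len(self.selectors) != need:
            raise ValueError(f"{self.label}: {self.kind} needs {need} selectors, "
                             f"got {len(self.selectors)}")


@dataclass
class EnsembleStat:
    label: str
    mean: float
    sd: float
    n: int
    units: str
    outliers: list = field(default_factory=list)

    def __post_init__(self):
        if self.sd < 0 or self.n < 1:
            raise ValueError("sd must be >= 0 and n >= 1")

    def render(self) -> str:
        if self.units == "degrees":
            return f"{self.mean:.0f} ({self.sd:.0f})"
        return f"{self.mean:.2f} ({self.sd:.2f})"


def resolve_selector(system: MolecularSystem, selector) -> int:
    role, name = selector
    matches = system.find_atoms(name, role=role)
    if not matches:
        raise KeyError(f"selector ({role!r}, {name!r}) resolves to no atom")
    if len(matches) > 1:
        raise KeyError(f"selector ({role!r}, {name!r}) is ambiguous: "
                       f"atoms {matches}")
    return matches[0]


def measure(structure: MolecularSystem, spec: MetricSpec,
            positions: np.ndarray | None = None) -> float:
    """Distance (Å) or interior angle at the middle atom (degrees)."""
    ids = [resolve_selector(structure, s) for s in spec.selectors]
    pos = structure.positions if positions is None else np.asarray(positions)
    if spec.kind == "distance":
        return float(np.linalg.norm(pos[ids[0]] - pos[ids[1]]))
    u = pos[ids[0]] - pos[ids[1]]
    v = pos[ids[2]] - pos[ids[1]]
    c = float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def ensemble_table(snapshots, specs, system: MolecularSystem | None = None):
    """Per-spec mean and sample SD over an ensemble of structures.

    ``snapshots`` is either a list of MolecularSystems, or an array of
    position frames with ``system`` supplying the annotation.  Returns
    (stats, DataFrame); values with |value − mean| > 4·sd are annotated as
    outliers, never removed.
    """
    if system is None:
        frames = [(s, None) for s in snapshots]
    else:
        frames = [(system, np.asarray(p)) for p in snapshots]
    if not frames:
        raise ValueError("at least one snapshot required")
    stats = []
    for spec in specs:
        vals = np.array([measure(s, spec, positions=p) for s, p in frames])
        n = len(vals)
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if n > 1 else 0.0
        outliers = ([int(i) for i in np.nonzero(np.abs(vals - mean) > 4 * sd)[0]]
                    if sd > 0 else [])
        units = "degrees" if spec.kind == "angle" else "Å"
        stats.append(EnsembleStat(spec.label, mean, sd, n, units, outliers))
    df = pd.DataFrame({
        "metric": [s.label for s in stats],
        "mean (sd)": [s.render() for s in stats],
        "n": [s.n for s in stats],
        "units": [s.units for s in stats],
        "outlier_note": [f"snapshots {s.outliers}" if s.outliers else ""
                         for s in stats],
    })
    return stats, df


def compare_variants(tables: dict[str, list[EnsembleStat]],
                     reference: str) -> pd.DataFrame:
    """Side-by-side variant table with longer/shorter/equal flags vs reference."""
    if reference not in tables:
        raise KeyError(f"reference variant {reference!r} missing")
    ref = {s.label: s for s in tables[reference]}
    labels = [s.label for s in tables[reference]]
    for name, stats in tables.items():
        got = [s.label for s in stats]
        if got != labels:
            raise ValueError(f"variant {name!r} metrics {got} do not match "
                             f"reference metrics {labels}")
    rows = []
    for label in labels:
        row = {"metric": label}
        for name, stats in tables.items():
            s = next(x for x in stats if x.label == label)
            row[name] = s.render()
            if name != reference:
                delta = s.mean - ref[label].mean
                row[f"{name} vs {reference}"] = (
                    "longer" if delta > 1e-9 else
                    "shorter" if delta < -1e-9 else "equal")
        rows.append(row)
    return pd.DataFrame(rows)


def default_metric_specs(include_substrate=True, include_water=True,
                         include_donor=True) -> list[MetricSpec]:
    """The stock active-site metric set (metal–ligand distances, donor
    alignment, H-bond distances) expressed as role-based selectors."""
    M = ("metal", "M")
    specs = [
        MetricSpec("Metal – O1(Arm1)", "distance", (M, ("site_residues", "OD1"))),
        MetricSpec("Metal – O2(Arm1)", "distance", (M, ("site_residues", "OD2"))),
        MetricSpec("Metal – O(Arm2)", "distance", (M, ("site_residues", "OE1"))),
        MetricSpec("Metal – O1(Arm3)", "distance", (M, ("site_residues", "OG1"))),
    ]
    if include_water:
        specs += [
            MetricSpec("Metal – O(water)", "distance", (M, ("water", "OW"))),
            MetricSpec("O(Arm1) – O(water)", "distance",
                       (("site_residues", "OD1"), ("water", "OW"))),
            MetricSpec("O(Glu) – O(water)", "distance",
                       (("site_residues", "OZ1"), ("water", "OW"))),
        ]
    if include_substrate:
        specs += [
            MetricSpec("Metal – O1(Sub)", "distance", (M, ("substrate", "O1"))),
            MetricSpec("Metal – O2(Sub)", "distance", (M, ("substrate", "O2"))),
        ]
    if include_substrate and include_donor:
        specs += [
            MetricSpec("O2(Sub) – C(Don)", "distance",
                       (("substrate", "O2"), ("cofactor", "CM"))),
            MetricSpec("O2(Sub) – S(Don)", "distance",
                       (("substrate", "O2"), ("cofactor", "S"))),
            MetricSpec("O2(Sub)-C(Don)-S(Don)", "angle",
                       (("substrate", "O2"), ("cofactor", "CM"),
                        ("cofactor", "S"))),
        ]
    return specs
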