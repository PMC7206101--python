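"""Spot-map layouts for the multiplexed sensing membrane.

A vertical flow assay (VFA) sensing membrane carries a square lattice of
immunoreaction spots. Each spot is dispensed with a *spotting condition* —
a capture protein plus buffer recipe — and conditions are replicated many
times across the grid. Because the vertical flow rate varies radially
across the membrane, a condition concentrated near the center (or the rim)
would see a systematically different flow environment than the others. The
generator here therefore distributes the replicates of every condition so
that no condition's mean radial distance from the grid centroid deviates
from the all-spot mean by more than a configurable tolerance.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "SpottingCondition",
    "SpotMap",
    "default_conditions",
    "generate_spot_map",
    "radial_balance_score",
    "read_spot_map",
    "write_spot_map",
]


@dataclass(frozen=True)
class SpottingCondition:
    """One capture-protein/buffer recipe replicated over the grid."""

    name: str
    capture_protein: str = ""
    reagent_cost_per_spot: float = 0.0
    replicates_requested: int = 1

    def __post_init__(self) -> None:
        if self.replicates_requested < 1:
            raise ValueError(
                f"condition {self.name!r}: replicates_requested must be >= 1"
            )
        if self.reagent_cost_per_spot < 0:
            raise ValueError(
                f"condition {self.name!r}: reagent_cost_per_spot must be >= 0"
            )


def default_conditions() -> list[SpottingCondition]:
    """The default seven-condition panel for a 9x9 (81-spot) membrane.

    Near-even replicate split 12,12,12,12,11,11,11. Per-spot reagent costs
    are placeholders proportional to a plausible capture-protein expense and
    are fully configurable through the layout file.
    """
    spec = [
        ("Ab", "capture antibody", 0.040, 12),
        ("Ag", "CRP antigen", 0.036, 12),
        ("Ag-low", "CRP antigen (low concentration)", 0.012, 12),
        ("Mix1", "Ab/Ag mixture 1", 0.038, 12),
        ("Mix2", "Ab/Ag mixture 2", 0.038, 11),
        ("SecondaryAb", "secondary antibody", 0.030, 11),
        ("Control", "BSA control", 0.006, 11),
    ]
    return [
        SpottingCondition(name, protein, cost, reps)
        for name, protein, cost, reps in spec
    ]


@dataclass
class SpotMap:
    """Assignment of spotting conditions to lattice positions.

    Coordinates are 0-based (row, col), row-major; the physical position of
    a spot is ``(col * periodicity, row * periodicity)`` millimetres from
    the top-left spot, and radii are measured from the grid centroid.
    """

    grid_rows: int
    grid_cols: int
    periodicity_mm: float
    conditions: list[SpottingCondition]
    assignment: dict[tuple[int, int], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- basic accessors -------------------------------------------------
    @property
    def n_spots(self) -> int:
        return self.grid_rows * self.grid_cols

    @property
    def condition_names(self) -> list[str]:
        return [c.name for c in self.conditions]

    def condition(self, name: str) -> SpottingCondition:
        for c in self.conditions:
            if c.name == name:
                return c
        raise KeyError(name)

    def spots(self) -> list[tuple[int, int]]:
        """All lattice cells in row-major order."""
        return sorted(self.assignment)

    def spots_of(self, name: str) -> list[tuple[int, int]]:
        return [rc for rc in sorted(self.assignment) if self.assignment[rc] == name]

    def condition_of(self, row: int, col: int) -> str:
        return self.assignment[(row, col)]

    def replicate_index(self, row: int, col: int) -> int:
        """0-based replicate index p of a spot within its condition."""
        return self.spots_of(self.assignment[(row, col)]).index((row, col))

    # -- geometry --------------------------------------------------------
    @property
    def centroid(self) -> tuple[float, float]:
        return ((self.grid_rows - 1) / 2.0, (self.grid_cols - 1) / 2.0)

    def radius(self, row: int, col: int) -> float:
        """Distance of a cell from the grid centroid, in lattice units."""
        r0, c0 = self.centroid
        return math.hypot(row - r0, col - c0)

    def radii(self) -> dict[tuple[int, int], float]:
        return {rc: self.radius(*rc) for rc in self.spots()}

    def position_mm(self, row: int, col: int) -> tuple[float, float]:
        """(x, y) position in mm from the top-left spot."""
        return (col * self.periodicity_mm, row * self.periodicity_mm)

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        names = self.condition_names
        if len(set(names)) != len(names):
            raise ValueError("condition names must be unique within a layout")
        if self.assignment:
            expected = {
                (r, c)
                for r in range(self.grid_rows)
                for c in range(self.grid_cols)
            }
            missing = expected - set(self.assignment)
            extra = set(self.assignment) - expected
            if missing:
                raise ValueError(
                    f"unassigned grid cells: {sorted(missing)[:5]}"
                    + ("..." if len(missing) > 5 else "")
                )
            if extra:
                raise ValueError(f"assignments outside the grid: {sorted(extra)[:5]}")
            unknown = {n for n in self.assignment.values() if n not in names}
            if unknown:
                raise ValueError(f"unknown condition name(s): {sorted(unknown)}")
            counts = {n: 0 for n in names}
            for n in self.assignment.values():
                counts[n] += 1
            for c in self.conditions:
                if counts[c.name] != c.replicates_requested:
                    raise ValueError(
                        f"condition {c.name!r} has {counts[c.name]} spots, "
                        f"requested {c.replicates_requested}"
                    )


def radial_balance_score(spot_map: SpotMap) -> dict[str, float]:
    """Relative deviation of each condition's mean radius from the global mean.

    Returns ``|mean_r(condition) - mean_r(all)| / mean_r(all)`` per condition
    (0 when the global mean radius is 0, e.g. a single-spot grid).
    """
    radii = spot_map.radii()
    global_mean = float(np.mean(list(radii.values())))
    scores: dict[str, float] = {}
    for c in spot_map.conditions:
        rs = [radii[rc] for rc in spot_map.spots_of(c.name)]
        if global_mean == 0.0:
            scores[c.name] = 0.0
        else:
            scores[c.name] = abs(float(np.mean(rs)) - global_mean) / global_mean
    return scores


def _max_imbalance(
    radii: np.ndarray, labels: np.ndarray, counts: np.ndarray
) -> float:
    global_mean = radii.mean()
    if global_mean == 0.0:
        return 0.0
    sums = np.bincount(labels, weights=radii, minlength=len(counts))
    return float(np.max(np.abs(sums / counts - global_mean)) / global_mean)


def generate_spot_map(
    grid_rows: int,
    grid_cols: int,
    periodicity: float,
    conditions: list[SpottingCondition],
    seed: int = 0,
    tolerance: float = 0.10,
    max_swaps: int = 10_000,
    max_restarts: int = 20,
) -> SpotMap:
    """Assign conditions to the grid with radially balanced replicates.

    Randomized initial assignment followed by swap-based local search that
    minimizes the maximum per-condition relative radial deviation. Among
    equally improving swaps the lowest (row, col) lexicographic pair wins,
    so the result is deterministic for a fixed seed.

    Raises ``ValueError`` if replicate counts do not sum to the grid size,
    or if no restart achieves the tolerance (the error reports the best
    imbalance reached).
    """
    total = sum(c.replicates_requested for c in conditions)
    n_cells = grid_rows * grid_cols
    if total != n_cells:
        raise ValueError(
            f"replicates sum to {total} but the grid has {n_cells} cells "
            f"(deficit {n_cells - total})"
        )
    names = [c.name for c in conditions]
    if len(set(names)) != len(names):
        raise ValueError("condition names must be unique")

    cells = [(r, c) for r in range(grid_rows) for c in range(grid_cols)]
    r0, c0 = (grid_rows - 1) / 2.0, (grid_cols - 1) / 2.0
    radii = np.array([math.hypot(r - r0, c - c0) for r, c in cells])
    base_labels = np.concatenate(
        [np.full(c.replicates_requested, i) for i, c in enumerate(conditions)]
    )
    counts = np.array([c.replicates_requested for c in conditions], dtype=float)

    rng = np.random.default_rng(seed)
    best_labels, best_score = None, np.inf
    for _ in range(max_restarts):
        labels = rng.permutation(base_labels)
        score = _max_imbalance(radii, labels, counts)
        swaps = 0
        improved = True
        while score > tolerance and improved and swaps < max_swaps:
            improved = False
            # best-improvement scan over all cross-condition swap pairs
            best_pair, best_new = None, score
            for i in range(len(cells)):
                for j in range(i + 1, len(cells)):
                    if labels[i] == labels[j]:
                        continue
                    labels[i], labels[j] = labels[j], labels[i]
                    new = _max_imbalance(radii, labels, counts)
                    labels[i], labels[j] = labels[j], labels[i]
                    if new < best_new - 1e-15:
                        best_new, best_pair = new, (i, j)
            if best_pair is not None:
                i, j = best_pair
                labels[i], labels[j] = labels[j], labels[i]
                score = best_new
                swaps += 1
                improved = True
        if score < best_score:
            best_score, best_labels = score, labels.copy()
        if best_score <= tolerance:
            break

    if best_score > tolerance:
        raise ValueError(
            f"could not balance layout to tolerance {tolerance:.3f}; "
            f"best achieved imbalance {best_score:.3f}"
        )
    assignment = {cells[i]: names[int(best_labels[i])] for i in range(len(cells))}
    return SpotMap(grid_rows, grid_cols, periodicity, list(conditions), assignment)


# ---------------------------------------------------------------------------
# serialization


def write_spot_map(spot_map: SpotMap, path: str | Path) -> None:
    """Write a layout as JSON (``.json``) or CSV (anything else)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        doc = {
            "grid_rows": spot_map.grid_rows,
            "grid_cols": spot_map.grid_cols,
            "periodicity_mm": spot_map.periodicity_mm,
            "conditions": [
                {
                    "name": c.name,
                    "capture_protein": c.capture_protein,
                    "cost_per_spot": c.reagent_cost_per_spot,
                    "replicates": c.replicates_requested,
                }
                for c in spot_map.conditions
            ],
            "assignment": [
                [r, c, spot_map.assignment[(r, c)]] for r, c in spot_map.spots()
            ],
        }
        path.write_text(json.dumps(doc, indent=1))
    else:
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["row", "col", "condition"])
            for r, c in spot_map.spots():
                writer.writerow([r, c, spot_map.assignment[(r, c)]])


def read_spot_map(
    path: str | Path,
    conditions: list[SpottingCondition] | None = None,
    periodicity_mm: float = 1.3,
) -> SpotMap:
    """Read a layout written by :func:`write_spot_map`.

    For the CSV dialect (which carries no condition metadata), ``conditions``
    may supply costs/proteins; otherwise conditions are reconstructed from
    the observed assignment counts.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        doc = json.loads(path.read_text())
        conds = [
            SpottingCondition(
                d["name"],
                d.get("capture_protein", ""),
                float(d.get("cost_per_spot", 0.0)),
                int(d["replicates"]),
            )
            for d in doc["conditions"]
        ]
        known = {c.name for c in conds}
        assignment: dict[tuple[int, int], str] = {}
        for r, c, name in doc["assignment"]:
            if name not in known:
                raise ValueError(f"assignment uses unknown condition {name!r}")
            if (r, c) in assignment:
                raise ValueError(f"duplicate assignment for cell ({r}, {c})")
            assignment[(int(r), int(c))] = name
        return SpotMap(
            int(doc["grid_rows"]),
            int(doc["grid_cols"]),
            float(doc["periodicity_mm"]),
            conds,
            assignment,
        )

    assignment = {}
    with path.open() as fh:
        reader = csv.DictReader(fh)
        for rec in reader:
            rc = (int(rec["row"]), int(rec["col"]))
            if rc in assignment:
                raise ValueError(f"duplicate assignment for cell {rc}")
            assignment[rc] = rec["condition"]
    if not assignment:
        raise ValueError("empty spot-map CSV")
    rows = 1 + max(r for r, _ in assignment)
    cols = 1 + max(c for _, c in assignment)
    missing = [
        (r, c)
        for r in range(rows)
        for c in range(cols)
        if (r, c) not in assignment
    ]
    if missing:
        raise ValueError(f"missing grid cell(s): {missing[:5]}")
    if conditions is None:
        counts: dict[str, int] = {}
        for name in assignment.values():
            counts[name] = counts.get(name, 0) + 1
        conditions = [
            SpottingCondition(name, replicates_requested=n)
            for name, n in sorted(counts.items())
        ]
    else:
        known = {c.name for c in conditions}
        unknown = {n for n in assignment.values() if n not in known}
        if unknown:
            raise ValueError(f"assignment uses unknown condition(s): {sorted(unknown)}")
    return SpotMap(rows, cols, periodicity_mm, list(conditions), assignment)
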