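"""Cost-function-driven spot and condition selection under cross-validation.

Phase 1 (spot selection): every physical spot receives a cost

    j_{m,p} = sum_{n=1}^{N_train} |s'_{m,n,p} - sbar'_{m,n}| / sbar'_{m,n},

the normalized distance of that spot from the mean of its like-condition
spots, accumulated over the training tests. High-cost spots are the ones
that disagree with their replicates — edge spots in poorly wetted regions,
dispense errors, contaminated positions. Spots are eliminated one per
iteration in descending cost order (never removing a condition's last
spot), and at each subset size a k-fold cross-validation of the
quantification network records MSLE and R^2; the operating subset is the
approximate minimum of the (smoothed) MSLE curve.

Phase 2 (condition selection): starting from the surviving spots, whole
spotting conditions are greedily eliminated — at each round the condition
whose removal gives the lowest cross-validated MSLE is dropped — producing
a ranking of the sensing channels and the final condition subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .image_processing import SignalTable
from .spot_map import SpotMap

__all__ = [
    "TrainingSet",
    "CostMap",
    "EliminationTrace",
    "spot_cost_map",
    "heatmap_matrix",
    "stratified_folds",
    "eliminate_spots_cv",
    "select_spot_subset",
    "eliminate_conditions_cv",
]

ACUTE_THRESHOLD_MG_L = 10.0


@dataclass
class TrainingSet:
    """QC-passing tests arranged as arrays for vectorized selection."""

    net_signals: np.ndarray  # (N, n_spots) background-subtracted signals
    spots: list[tuple[int, int]]  # column order, row-major
    spot_conditions: np.ndarray  # condition name per spot column
    concentration: np.ndarray  # (N,) ground truth, mg/L
    rid: np.ndarray
    fid: np.ndarray
    sample_id: np.ndarray
    test_id: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.concentration < 0):
            raise ValueError("concentrations must be >= 0")
        if self.net_signals.shape != (len(self.concentration), len(self.spots)):
            raise ValueError("net_signals shape inconsistent with spots/tests")

    @property
    def n_train(self) -> int:
        return len(self.concentration)

    @property
    def acute(self) -> np.ndarray:
        """Acute-inflammation flag: truth above the hsCRP range."""
        return self.concentration > ACUTE_THRESHOLD_MG_L

    @property
    def condition_names(self) -> list[str]:
        return sorted(str(c) for c in set(self.spot_conditions))

    @classmethod
    def from_tests(cls, tests: list[SignalTable], spot_map: SpotMap) -> "TrainingSet":
        tests = [t for t in tests if t.qc_pass]
        if not tests:
            raise ValueError("no QC-passing tests")
        spots = spot_map.spots()
        conds = np.array([spot_map.assignment[rc] for rc in spots])
        rows = []
        for t in tests:
            net = t.net()
            try:
                rows.append(net.loc[list(spots)].to_numpy())
            except KeyError as exc:
                raise ValueError(
                    f"test {t.test_id!r} is missing map spots"
                ) from exc
        return cls(
            net_signals=np.asarray(rows, dtype=float),
            spots=spots,
            spot_conditions=conds,
            concentration=np.array([t.truth_mg_l for t in tests], dtype=float),
            rid=np.array([t.rid for t in tests]),
            fid=np.array([t.fid for t in tests]),
            sample_id=np.array([t.sample_id for t in tests]),
            test_id=np.array([t.test_id for t in tests]),
        )

    @classmethod
    def from_cohort(cls, cohort) -> "TrainingSet":
        return cls.from_tests(cohort.tests, cohort.spot_map)

    def subset_tests(self, mask: np.ndarray) -> "TrainingSet":
        return TrainingSet(
            self.net_signals[mask],
            self.spots,
            self.spot_conditions,
            self.concentration[mask],
            self.rid[mask],
            self.fid[mask],
            self.sample_id[mask],
            self.test_id[mask],
        )

    def normalized(self, spot_idx: np.ndarray | None = None) -> np.ndarray:
        """Per-test normalized signals s' over the given spot columns."""
        cols = (
            np.arange(len(self.spots)) if spot_idx is None else np.asarray(spot_idx)
        )
        net = self.net_signals[:, cols]
        denom = net.sum(axis=1, keepdims=True)
        if np.any(denom <= 0):
            bad = np.where(denom[:, 0] <= 0)[0]
            raise ValueError(
                f"non-positive normalization denominator for test(s) "
                f"{self.test_id[bad][:5]}"
            )
        return net / denom

    def spot_indices(self, spots: list[tuple[int, int]]) -> np.ndarray:
        lookup = {rc: i for i, rc in enumerate(self.spots)}
        return np.array([lookup[tuple(rc)] for rc in spots])

    def condition_features(
        self, spots: list[tuple[int, int]] | None = None,
        conditions: list[str] | None = None,
    ) -> tuple[np.ndarray, list[str]]:
        """x_m features: condition means of s' renormalized over ``spots``.

        ``spots`` is the normalization pool (the membrane's spot subset);
        every spot in it enters the Eq.-style denominator. ``conditions``
        selects which per-condition means become model inputs and never
        changes the denominator, so dropping an input channel does not
        rescale the surviving features.
        """
        idx = (
            np.arange(len(self.spots))
            if spots is None
            else self.spot_indices(spots)
        )
        conds_of_idx = self.spot_conditions[idx]
        keep = (
            sorted(str(c) for c in set(conds_of_idx))
            if conditions is None
            else list(conditions)
        )
        missing = [c for c in keep if c not in set(conds_of_idx)]
        if missing:
            raise ValueError(f"condition(s) {missing} have no spots in the pool")
        s_norm = self.normalized(idx)
        X = np.column_stack(
            [s_norm[:, conds_of_idx == c].mean(axis=1) for c in keep]
        )
        return X, keep


@dataclass
class CostMap:
    """Per-spot cost j_{m,p} over the membrane grid."""

    values: pd.Series  # index (row, col), value j
    conditions: pd.Series  # index (row, col), condition name
    n_skipped_terms: int = 0  # (m, n) terms with zero like-spot mean

    def __post_init__(self) -> None:
        if (self.values < 0).any():
            raise ValueError("costs must be >= 0")

    def argmax_spot(self, among: list[tuple[int, int]] | None = None) -> tuple[int, int]:
        vals = self.values if among is None else self.values.loc[list(among)]
        top = vals.max()
        # lexicographic tie-break for determinism
        winners = sorted(vals.index[vals == top])
        return tuple(winners[0])


def spot_cost_map(training: TrainingSet) -> CostMap:
    """Accumulated normalized deviation of each spot from its like-spot mean.

    Training tests with a zero like-spot mean for some condition contribute
    no term for that condition's spots; the count of skipped terms is
    recorded on the returned map.
    """
    s_norm = training.normalized()
    conds = training.spot_conditions
    names = sorted(set(conds))
    j = np.zeros(s_norm.shape[1])
    skipped = 0
    for name in names:
        cols = conds == name
        mean_mn = s_norm[:, cols].mean(axis=1, keepdims=True)  # (N, 1)
        ok = (mean_mn[:, 0] != 0)
        skipped += int((~ok).sum()) * int(cols.sum())
        dev = np.abs(s_norm[np.ix_(ok, cols)] - mean_mn[ok]) / mean_mn[ok]
        j[cols] = dev.sum(axis=0)
    idx = pd.MultiIndex.from_tuples(training.spots, names=["row", "col"])
    return CostMap(
        values=pd.Series(j, index=idx, name="j"),
        conditions=pd.Series(conds, index=idx, name="condition"),
        n_skipped_terms=skipped,
    )


def heatmap_matrix(
    cost_map: CostMap,
    grid_rows: int,
    grid_cols: int,
    upsample: int = 1,
) -> np.ndarray:
    """Place j values on the grid; optionally bilinearly upsampled raster."""
    mat = np.full((grid_rows, grid_cols), np.nan)
    for (r, c), v in cost_map.values.items():
        mat[r, c] = v
    if np.isnan(mat).any():
        missing = [tuple(rc) for rc in np.argwhere(np.isnan(mat))]
        raise ValueError(f"missing spot(s) in cost map: {missing[:5]}")
    if upsample > 1:
        mat = ndimage.zoom(mat, upsample, order=1)
    return mat


# ---------------------------------------------------------------------------
# cross-validation machinery


def stratified_folds(
    concentration: np.ndarray,
    fid: np.ndarray,
    k: int,
    seed: int,
) -> np.ndarray:
    """Fold labels stratified by concentration quintile and FID.

    Within each (quintile, FID) cell, tests are dealt round-robin to folds
    in seeded random order, so folds partition the set and are balanced in
    both concentration and fabrication batch.
    """
    n = len(concentration)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of tests ({n})")
    rng = np.random.default_rng(seed)
    q = np.searchsorted(
        np.quantile(concentration, [0.2, 0.4, 0.6, 0.8]), concentration
    )
    folds = np.empty(n, dtype=int)
    start = 0
    for cell in sorted(set(zip(q.tolist(), fid.tolist()))):
        idx = np.where((q == cell[0]) & (fid == cell[1]))[0]
        idx = rng.permutation(idx)
        folds[idx] = (np.arange(len(idx)) + start) % k
        start += len(idx)
    return folds


def _cv_quantifier_score(
    training: TrainingSet,
    spots: list[tuple[int, int]],
    conditions: list[str],
    network_config,
    folds: np.ndarray,
) -> tuple[float, float]:
    """Pooled k-fold CV MSLE and R^2 of the quantifier on hsCRP-range tests."""
    from .inference import encode_batches, msle, train_quantifier_arrays

    X_cond, _ = training.condition_features(spots, conditions)
    B = encode_batches(training.rid, training.fid)
    hs = ~training.acute
    y = training.concentration
    preds = np.full(len(y), np.nan)
    for f in sorted(set(folds.tolist())):
        tr = hs & (folds != f)
        va = hs & (folds == f)
        if not va.any() or not tr.any():
            continue
        mu = X_cond[tr].mean(axis=0)
        sd = X_cond[tr].std(axis=0)
        sd[sd == 0] = 1.0
        Xtr = np.column_stack([(X_cond[tr] - mu) / sd, B[tr]])
        Xva = np.column_stack([(X_cond[va] - mu) / sd, B[va]])
        model = train_quantifier_arrays(Xtr, y[tr], network_config)
        preds[va] = np.maximum(np.expm1(model.decision_function(Xva)), 0.0)
    mask = hs & np.isfinite(preds)
    m = msle(y[mask], preds[mask])
    r = np.corrcoef(preds[mask], y[mask])[0, 1]
    return float(m), float(r**2) if np.isfinite(r) else 0.0


@dataclass
class EliminationIteration:
    members: list  # surviving spots (phase 1) or conditions (phase 2)
    msle: float
    r2: float
    removed: object = None  # what was removed to reach this subset


@dataclass
class EliminationTrace:
    iterations: list[EliminationIteration] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.iterations)

    def sizes(self) -> list[int]:
        return [len(it.members) for it in self.iterations]

    def msle_curve(self) -> np.ndarray:
        return np.array([it.msle for it in self.iterations])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": np.arange(len(self.iterations)),
                "subset_size": self.sizes(),
                "msle": self.msle_curve(),
                "r2": [it.r2 for it in self.iterations],
                "removed": [it.removed for it in self.iterations],
                "members": [
                    ";".join(map(str, it.members)) for it in self.iterations
                ],
            }
        )


def eliminate_spots_cv(
    training: TrainingSet,
    network_config=None,
    k: int = 5,
    seed: int = 0,
    track_metrics: bool = True,
) -> EliminationTrace:
    """Iteratively drop the highest-cost surviving spot, tracking CV error.

    The trace starts with the full spot set and ends when exactly one spot
    per condition survives; a condition's last spot is never removed. Fold
    assignment is fixed across iterations so the MSLE curve is comparable.
    With ``track_metrics=False`` the CV networks are skipped (NaN metrics),
    which makes the elimination order itself cheap to compute.
    """
    from .inference import NetworkConfig

    cost = spot_cost_map(training)
    conditions = training.condition_names
    folds = stratified_folds(training.concentration, training.fid, k, seed)
    if network_config is None:
        network_config = NetworkConfig(hidden=(32,), dropout=0.1, epochs=200,
                                       patience=20, seed=seed)

    surviving = list(training.spots)
    trace = EliminationTrace()

    def record(removed):
        if track_metrics:
            m, r2 = _cv_quantifier_score(
                training, surviving, conditions, network_config, folds
            )
        else:
            m, r2 = np.nan, np.nan
        trace.iterations.append(
            EliminationIteration(list(surviving), m, r2, removed)
        )

    record(None)
    while len(surviving) > len(conditions):
        counts: dict[str, int] = {}
        for rc in surviving:
            counts[cost.conditions.loc[rc]] = counts.get(cost.conditions.loc[rc], 0) + 1
        removable = [rc for rc in surviving if counts[cost.conditions.loc[rc]] > 1]
        victim = cost.argmax_spot(removable)
        surviving.remove(victim)
        record(victim)
    return trace


def select_spot_subset(
    trace: EliminationTrace, window: int = 5
) -> list[tuple[int, int]]:
    """Subset at the approximate minimum of the smoothed CV MSLE curve.

    A centered moving average (default window 5) suppresses the run-to-run
    noise of network training; ties go to the larger subset.
    """
    if not len(trace):
        raise ValueError("empty elimination trace")
    curve = trace.msle_curve()
    if np.all(np.isnan(curve)):
        raise ValueError("trace has no CV metrics; rerun with track_metrics=True")
    smooth = (
        pd.Series(curve).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )
    best = int(np.nanargmin(smooth))  # earliest index = largest subset on ties
    return list(trace.iterations[best].members)


def eliminate_conditions_cv(
    training: TrainingSet,
    spot_subset: list[tuple[int, int]],
    network_config=None,
    k: int = 5,
    seed: int = 0,
) -> tuple[EliminationTrace, list[str], list[str]]:
    """Greedy condition elimination over the selected spots.

    At each round every surviving condition's removal is scored by k-fold
    CV MSLE and the best removal is made permanent, down to one condition.
    Returns ``(trace, elimination_order, best_subset)`` where the trace's
    first entry is the full condition set and the best subset minimizes the
    recorded MSLE curve (ties to the larger subset).
    """
    from .inference import NetworkConfig

    if network_config is None:
        network_config = NetworkConfig(hidden=(32,), dropout=0.1, epochs=200,
                                       patience=20, seed=seed)
    idx = training.spot_indices(spot_subset)
    conditions = sorted(str(c) for c in set(training.spot_conditions[idx]))
    if len(conditions) < 2:
        raise ValueError("condition elimination needs >= 2 conditions")
    folds = stratified_folds(training.concentration, training.fid, k, seed)

    def score(conds: list[str]) -> tuple[float, float]:
        return _cv_quantifier_score(
            training, spot_subset, conds, network_config, folds
        )

    surviving = list(conditions)
    trace = EliminationTrace()
    m, r2 = score(surviving)
    trace.iterations.append(EliminationIteration(list(surviving), m, r2, None))
    order: list[str] = []
    while len(surviving) > 1:
        best_cond, best_m, best_r2 = None, np.inf, np.nan
        for cond in surviving:  # stable order: deterministic tie-break
            remaining = [c for c in surviving if c != cond]
            m, r2 = score(remaining)
            if m < best_m:
                best_cond, best_m, best_r2 = cond, m, r2
        surviving.remove(best_cond)
        order.append(best_cond)
        trace.iterations.append(
            EliminationIteration(list(surviving), best_m, best_r2, best_cond)
        )
    curve = trace.msle_curve()
    best_idx = int(np.nanargmin(curve))
    best_subset = list(trace.iterations[best_idx].members)
    return trace, order, best_subset
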