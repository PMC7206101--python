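"""Clinical-style evaluation: partitioning, precision/agreement metrics,
hook-effect ablations and reagent-cost accounting.

Risk strata follow the standard hsCRP cardiovascular cutoffs — low risk
below 1 mg/L, intermediate 1-3 mg/L, high 3-10 mg/L — with concentrations
above 10 mg/L flagged as acute inflammation. Precision is summarized as
the percent coefficient of variation (%CV = 100 * SD/mean, sample SD) over
replicate tests of each sample, averaged unweighted over samples; accuracy
as the least-squares line and squared Pearson correlation of predictions
against reference values; and agreement as Bland-Altman mean difference
with +/- 1 SD limits.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RiskStratum",
    "RISK_STRATA",
    "stratify_risk",
    "partition_train_test",
    "replicate_cv",
    "regression_metrics",
    "bland_altman",
    "cost_summary",
    "percent_reduction",
    "ablation_hook_effect",
    "EvaluationReport",
    "evaluate_predictions",
]


@dataclass(frozen=True)
class RiskStratum:
    label: str
    lower: float  # inclusive
    upper: float  # exclusive (inf for acute)


RISK_STRATA = (
    RiskStratum("low", 0.0, 1.0),
    RiskStratum("intermediate", 1.0, 3.0),
    RiskStratum("high", 3.0, 10.0),
    RiskStratum("acute", 10.0, math.inf),
)


def stratify_risk(concentration: float) -> RiskStratum:
    """Map a concentration (mg/L) to its CVD risk stratum.

    Boundaries are left-closed on the upper category: 1.0 -> intermediate,
    3.0 -> high, and anything strictly above 10 -> acute (10.0 itself is
    the top of the hsCRP range).
    """
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    if concentration <= 10.0:
        for s in RISK_STRATA[:3]:
            if s.lower <= concentration < s.upper:
                return s
        return RISK_STRATA[2]  # exactly 10.0
    return RISK_STRATA[3]


# ---------------------------------------------------------------------------
# partitioning


def partition_train_test(
    cohort,
    test_fraction: float,
    seed: int = 0,
    n_bins: int = 10,
) -> tuple[list, list]:
    """Split tests into train/test keeping replicates of a sample together.

    Test samples are drawn per (risk stratum, FID) cell so that the test
    set is spread linearly over the concentration range and proportionally
    over fabrication batches; within a cell, samples are taken at evenly
    spaced ranks of the sorted concentrations (seeded phase). Returns
    ``(train_tests, test_tests)`` lists of SignalTables.
    """
    if not (0.0 <= test_fraction <= 1.0):
        raise ValueError("test_fraction must be in [0, 1]")
    tests = [t for t in cohort.tests if t.qc_pass]
    samples: dict[str, dict] = {}
    for t in tests:
        rec = samples.setdefault(
            t.sample_id, {"truth": t.truth_mg_l, "fid": t.fid, "tests": []}
        )
        rec["tests"].append(t)
    rng = np.random.default_rng(seed)

    test_ids: set[str] = set()
    cells: dict[tuple, list[str]] = {}
    for sid, rec in samples.items():
        stratum = stratify_risk(rec["truth"]).label
        cells.setdefault((stratum, rec["fid"]), []).append(sid)
    for key in sorted(cells):
        sids = sorted(cells[key], key=lambda s: (samples[s]["truth"], s))
        quota = int(round(test_fraction * len(sids)))
        if quota == 0 and test_fraction > 0 and len(sids) >= 1 / max(test_fraction, 1e-9):
            warnings.warn(f"stratum cell {key} too small for its quota")
        if quota == 0:
            continue
        # evenly spaced ranks with a random phase: linear coverage of the range
        phase = rng.uniform(0, 1)
        picks = ((np.arange(quota) + phase) * len(sids) / quota).astype(int)
        picks = np.clip(picks, 0, len(sids) - 1)
        test_ids.update(sids[i] for i in sorted(set(picks.tolist())))

    train = [t for t in tests if t.sample_id not in test_ids]
    test = [t for t in tests if t.sample_id in test_ids]
    return train, test


# ---------------------------------------------------------------------------
# precision and agreement


def replicate_cv(predictions: pd.DataFrame, eps: float = 1e-9) -> pd.DataFrame:
    """Per-sample %CV of replicate predicted concentrations.

    ``predictions`` needs columns sample_id, concentration, truth_mg_L.
    Uses the n-1 sample SD; samples with fewer than 2 quantified replicates
    or near-zero mean are excluded (with a warning for the latter). Stratum
    is assigned from ground truth.
    """
    rows = []
    for sid, grp in predictions.groupby("sample_id"):
        vals = grp["concentration"].to_numpy(dtype=float)
        if len(vals) < 2:
            continue
        mean = vals.mean()
        if mean <= eps:
            warnings.warn(f"sample {sid}: mean prediction ~0, excluded from %CV")
            continue
        sd = vals.std(ddof=1)
        truth = float(grp["truth_mg_L"].iloc[0])
        rows.append(
            {
                "sample_id": sid,
                "n": len(vals),
                "mean": mean,
                "sd": sd,
                "cv_percent": 100.0 * sd / mean,
                "truth_mg_L": truth,
                "stratum": stratify_risk(truth).label,
            }
        )
    return pd.DataFrame(rows)


def regression_metrics(pred, truth) -> dict[str, float]:
    """R^2 (squared Pearson), slope and intercept of pred vs truth (OLS)."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if len(pred) < 3:
        raise ValueError("need at least 3 pairs")
    if np.var(truth) == 0:
        raise ValueError("zero variance in reference values")
    slope, intercept = np.polyfit(truth, pred, 1)
    r = np.corrcoef(truth, pred)[0, 1]
    return {"r2": float(r**2), "slope": float(slope), "intercept": float(intercept)}


def bland_altman(pred, truth) -> dict:
    """Bland-Altman agreement: mean difference and +/- SD limits.

    Differences are pred - truth; limits are reported at 1 SD (with the
    conventional 1.96 SD limits included as well). Returns the per-point
    (mean, difference) table for plotting.
    """
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if len(pred) < 2:
        raise ValueError("need at least 2 pairs")
    diff = pred - truth
    mean_diff = float(diff.mean())
    sd_diff = float(diff.std(ddof=1))
    table = pd.DataFrame({"mean": (pred + truth) / 2.0, "difference": diff})
    return {
        "mean_difference": mean_diff,
        "sd_difference": sd_diff,
        "limits_1sd": (mean_diff - sd_diff, mean_diff + sd_diff),
        "limits_196sd": (mean_diff - 1.96 * sd_diff, mean_diff + 1.96 * sd_diff),
        "table": table,
    }


# ---------------------------------------------------------------------------
# cost accounting


def percent_reduction(full_cost: float, selected_cost: float) -> dict[str, float]:
    """Reagent-cost reduction, truncated to whole percent and at full precision.

    The headline figure is floored (62.8% prints as 62%), with the exact
    value alongside.
    """
    if full_cost <= 0:
        raise ValueError("full cost must be > 0")
    exact = 100.0 * (full_cost - selected_cost) / full_cost
    return {"exact_percent": exact, "truncated_percent": float(math.floor(exact))}


def cost_summary(
    spot_map,
    selected_spots,
    per_spot_costs: dict | None = None,
) -> dict[str, float]:
    """Reagent cost per test for the full map vs the selected spot subset.

    Costs default to each condition's ``reagent_cost_per_spot``; an explicit
    ``{(row, col): cost}`` mapping overrides them.
    """
    def cost_of(rc):
        if per_spot_costs is not None:
            return float(per_spot_costs[tuple(rc)])
        return float(spot_map.condition(spot_map.assignment[tuple(rc)])
                     .reagent_cost_per_spot)

    full = sum(cost_of(rc) for rc in spot_map.spots())
    selected = sum(cost_of(rc) for rc in selected_spots)
    if any(cost_of(rc) < 0 for rc in spot_map.spots()):
        raise ValueError("costs must be >= 0")
    red = percent_reduction(full, selected)
    return {
        "cost_full": full,
        "cost_selected": selected,
        "reduction_exact_percent": red["exact_percent"],
        "reduction_truncated_percent": red["truncated_percent"],
    }


# ---------------------------------------------------------------------------
# ablations


def ablation_hook_effect(
    training,
    acute_tests: list,
    condition_subsets: dict[str, list[str]],
    spot_subset=None,
    classifier_config=None,
    quantifier_config=None,
    seed: int = 0,
) -> pd.DataFrame:
    """Retrain on restricted condition sets and probe acute-sample routing.

    For each named condition subset a fresh classifier + quantifier pair is
    trained using only those channels, then applied to the acute tests.
    With hook-affected channels only (e.g. Ab + SecondaryAb) the classifier
    cannot distinguish acute samples from hsCRP-range ones, so some acute
    tests get falsely routed to quantification with low reported values;
    including the monotone competitive Ag channel restores routing. Returns
    one row per (subset, acute test) with the routing and any quantified
    value.
    """
    from .inference import predict, train_model_bundle

    rows = []
    for name, conds in condition_subsets.items():
        if not conds:
            raise ValueError(f"condition subset {name!r} is empty")
        bundle = train_model_bundle(
            training,
            spot_subset=spot_subset,
            conditions=list(conds),
            classifier_config=classifier_config,
            quantifier_config=quantifier_config,
            seed=seed,
        )
        quant_all = None
        for t in acute_tests:
            res = predict(bundle, t)
            # what the quantifier alone would report, bypassing the router
            X = bundle.preprocessing.transform_test(t, t.rid, t.fid)
            raw_quant = float(
                max(np.expm1(bundle.quantifier.decision_function(X)[0]), 0.0)
            )
            rows.append(
                {
                    "subset": name,
                    "test_id": t.test_id,
                    "truth_mg_L": t.truth_mg_l,
                    "mode": res.mode,
                    "confidence": res.confidence,
                    "reported_mg_L": res.concentration,
                    "quantifier_only_mg_L": raw_quant,
                    "falsely_quantified_low": res.mode == "quantified"
                    and (res.concentration or 0.0) < 10.0,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# report


@dataclass
class EvaluationReport:
    n_quantified: int
    n_acute_truth: int
    overall_cv_percent: float
    stratum_cv_percent: dict[str, float]
    r2: float
    slope: float
    intercept: float
    msle: float
    bland_altman_mean: float
    bland_altman_sd: float
    classification_accuracy: float
    confusion: dict[str, int]
    n_per_stratum: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "n_quantified": self.n_quantified,
            "n_acute_truth": self.n_acute_truth,
            "overall_cv_percent": self.overall_cv_percent,
            "stratum_cv_percent": self.stratum_cv_percent,
            "r2": self.r2,
            "slope": self.slope,
            "intercept": self.intercept,
            "msle": self.msle,
            "bland_altman_mean": self.bland_altman_mean,
            "bland_altman_sd": self.bland_altman_sd,
            "classification_accuracy": self.classification_accuracy,
            "confusion": self.confusion,
            "n_per_stratum": self.n_per_stratum,
        }


def evaluate_predictions(predictions: pd.DataFrame) -> EvaluationReport:
    """Summarize routed predictions against ground truth.

    ``predictions`` columns: test_id, sample_id, truth_mg_L, mode,
    concentration (NaN for acute-routed tests). Quantification metrics use
    tests with truth in the hsCRP range that were routed to quantification;
    classification counts compare routing against truth > 10 mg/L.
    """
    from .inference import msle as _msle

    truth_acute = predictions["truth_mg_L"] > 10.0
    routed_acute = predictions["mode"] == "acute"
    confusion = {
        "true_acute": int((truth_acute & routed_acute).sum()),
        "false_hs": int((truth_acute & ~routed_acute).sum()),
        "false_acute": int((~truth_acute & routed_acute).sum()),
        "true_hs": int((~truth_acute & ~routed_acute).sum()),
    }
    accuracy = (confusion["true_acute"] + confusion["true_hs"]) / len(predictions)

    q = predictions[~truth_acute & ~routed_acute].copy()
    metrics = regression_metrics(q["concentration"], q["truth_mg_L"])
    ba = bland_altman(q["concentration"], q["truth_mg_L"])
    cv_table = replicate_cv(q)
    stratum_cv = (
        cv_table.groupby("stratum")["cv_percent"].mean().to_dict()
        if len(cv_table)
        else {}
    )
    n_per_stratum = (
        q["truth_mg_L"].map(lambda c: stratify_risk(c).label).value_counts().to_dict()
    )
    return EvaluationReport(
        n_quantified=len(q),
        n_acute_truth=int(truth_acute.sum()),
        overall_cv_percent=float(cv_table["cv_percent"].mean())
        if len(cv_table)
        else float("nan"),
        stratum_cv_percent={k: float(v) for k, v in stratum_cv.items()},
        r2=metrics["r2"],
        slope=metrics["slope"],
        intercept=metrics["intercept"],
        msle=_msle(q["truth_mg_L"], q["concentration"]),
        bland_altman_mean=ba["mean_difference"],
        bland_altman_sd=ba["sd_difference"],
        classification_accuracy=float(accuracy),
        confusion=confusion,
        n_per_stratum={k: int(v) for k, v in n_per_stratum.items()},
    )
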