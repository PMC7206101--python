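"""Synthetic VFA cohorts: dose-response, batch effects, noise, rendering.

Emulates the phenomenology of a multiplexed CRP vertical flow assay so the
whole analysis chain can be exercised without clinical data:

* **Sandwich channel (Ab)** — capture antibody spots. Signal follows a
  Langmuir binding term multiplied by a prozone-inhibition term,
  ``A * c/(K_a + c) * 1/(1 + c/K_h)``: it rises over the hsCRP range and
  *falls* at acute concentrations (the hook / prozone effect), which is the
  failure mode the multiplexed design exists to mitigate.
* **Competitive channel (Ag)** — immobilized antigen competing with sample
  CRP for conjugate: ``A / (1 + c/K_c)``, strictly decreasing, hence
  monotone and unambiguous at acute concentrations.
* **Mix channels** — weighted sums of the two mechanisms (co-spotted
  reagents).
* **Controls** — constant (SecondaryAb binds conjugate regardless of
  analyte; BSA control carries only background).

On top of the per-condition response the simulator applies multiplicative
reagent-batch (RID) and fabrication-batch (FID) gains, a radial flow-rate
bias across the grid (edge spots see attenuated signal), per-spot
multiplicative lognormal noise at a configured CV, and an additive noisy
background. Replicate tests of one sample share the true concentration but
draw independent noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .image_processing import MembraneImage, SignalTable
from .spot_map import SpotMap

__all__ = [
    "DoseResponseModel",
    "BatchEffectModel",
    "NoiseModel",
    "ImageParams",
    "CohortDesign",
    "SyntheticCohort",
    "default_dose_models",
    "condition_response",
    "simulate_membrane_signals",
    "render_membrane_image",
    "simulate_cohort",
]

_SHAPES = ("sandwich_hook", "competitive_decreasing", "constant_control",
           "background", "mixture")


@dataclass
class DoseResponseModel:
    """Expected relative signal of one spotting condition vs concentration."""

    condition: str
    shape: str
    amplitude: float = 1.0  # A, absorbance-like units
    k_a: float = 2.0  # mg/L, half-saturation of the sandwich binding term
    k_h: float = 150.0  # mg/L, prozone (hook) inhibition constant
    k_c: float = 20.0  # mg/L, competitive displacement constant
    components: tuple["DoseResponseModel", ...] = ()
    weights: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.shape not in _SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        for name, val in (("k_a", self.k_a), ("k_h", self.k_h), ("k_c", self.k_c)):
            if val <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.shape == "mixture" and len(self.components) != len(self.weights):
            raise ValueError("mixture needs one weight per component")


def condition_response(model: DoseResponseModel, concentration) -> np.ndarray | float:
    """Noiseless expected signal at the given concentration(s), mg/L."""
    c = np.asarray(concentration, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    if model.shape == "sandwich_hook":
        out = model.amplitude * (c / (model.k_a + c)) / (1.0 + c / model.k_h)
    elif model.shape == "competitive_decreasing":
        out = model.amplitude / (1.0 + c / model.k_c)
    elif model.shape == "constant_control":
        out = np.full_like(c, model.amplitude)
    elif model.shape == "background":
        out = np.zeros_like(c)
    else:  # mixture
        out = np.zeros_like(c)
        for w, comp in zip(model.weights, model.components):
            out = out + w * np.asarray(condition_response(comp, c))
    return out if out.ndim else float(out)


def default_dose_models() -> dict[str, DoseResponseModel]:
    """Dose-response panel matching the default seven-condition layout.

    The hook peak of the Ab channel, at sqrt(K_a * K_h) ~ 17 mg/L, sits
    between the hsCRP range (0-10 mg/L) and the acute spikes, so acute
    samples fold back onto hsCRP-range signal levels on that channel alone.
    """
    ab = DoseResponseModel("Ab", "sandwich_hook", amplitude=1.0)
    ag = DoseResponseModel("Ag", "competitive_decreasing", amplitude=0.8)
    return {
        "Ab": ab,
        "Ag": ag,
        "Ag-low": DoseResponseModel(
            "Ag-low", "competitive_decreasing", amplitude=0.8 / 3
        ),
        "Mix1": DoseResponseModel(
            "Mix1", "mixture", components=(ab, ag), weights=(0.5, 0.5)
        ),
        "Mix2": DoseResponseModel(
            "Mix2", "mixture", components=(ab, ag), weights=(0.65, 0.35)
        ),
        "SecondaryAb": DoseResponseModel(
            "SecondaryAb", "constant_control", amplitude=0.9
        ),
        "Control": DoseResponseModel("Control", "constant_control", amplitude=0.15),
    }


@dataclass
class BatchEffectModel:
    """Multiplicative batch gains and the radial flow bias.

    ``radial_alpha`` attenuates edge spots: the noiseless signal is divided
    by ``1 + alpha * (r / r_max)^2`` where ``r`` is the spot's distance from
    the grid centroid. Edge spots therefore carry both lower signal and (via
    the fixed additive background noise) the most relative variation,
    matching the empirical pattern that rim spots are least reliable.
    """

    rid_gains: dict[int, float] = field(default_factory=lambda: {1: 1.00, 2: 1.08})
    fid_gains: dict[int, float] = field(
        default_factory=lambda: {1: 1.00, 2: 0.93, 3: 1.05}
    )
    radial_alpha: float = 0.30

    def __post_init__(self) -> None:
        if any(g <= 0 for g in self.rid_gains.values()):
            raise ValueError("RID gains must be > 0")
        if any(g <= 0 for g in self.fid_gains.values()):
            raise ValueError("FID gains must be > 0")


@dataclass
class NoiseModel:
    """Per-spot multiplicative noise plus additive background.

    ``cv`` is the coefficient of variation of a unit-mean lognormal factor
    applied per spot (default 0.10, i.e. 10% replicate scatter, the scale
    of replicate variation a well-behaved paper membrane shows).
    """

    cv: float = 0.10
    background_level: float = 0.08
    background_sd: float = 0.01

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.background_level < 0:
            raise ValueError("background level must be >= 0")


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    if cv == 0:
        return np.ones(n)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=n)


def simulate_membrane_signals(
    spot_map: SpotMap,
    concentration: float,
    rid: int,
    fid: int,
    dose_models: Mapping[str, DoseResponseModel],
    batch_model: BatchEffectModel | None = None,
    noise_model: NoiseModel | None = None,
    seed: int | np.random.Generator = 0,
    noise_spots: Iterable[tuple[int, int]] = (),
    noise_spot_cv: float = 1.0,
    **table_meta,
) -> SignalTable:
    """Simulate one membrane's per-spot raw signals and backgrounds.

    Raw signal per spot:
    ``s = response * g_RID * g_FID / (1 + alpha (r/r_max)^2) * eta + b``
    with ``eta`` unit-mean lognormal at the configured CV and ``b`` the
    recorded additive background. Spots listed in ``noise_spots`` carry no
    dose information: their response is a unit-mean lognormal draw at
    ``noise_spot_cv`` (default 100% CV) around the condition's typical
    intensity (its dose-response averaged over the hsCRP range) — the
    signature of an unstable or contaminated dispense, used to probe the
    robustness of spot selection.
    """
    batch_model = batch_model or BatchEffectModel()
    noise_model = noise_model or NoiseModel()
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    missing = [
        n for n in spot_map.condition_names if n not in dose_models
    ]
    if missing:
        raise KeyError(f"no dose model for condition(s) {missing}")
    if rid not in batch_model.rid_gains:
        raise KeyError(f"RID {rid} not in batch model gains")
    if fid not in batch_model.fid_gains:
        raise KeyError(f"FID {fid} not in batch model gains")

    spots = spot_map.spots()
    noise_set = set(map(tuple, noise_spots))
    radii = np.array([spot_map.radius(r, c) for r, c in spots])
    r_max = radii.max() if radii.max() > 0 else 1.0
    radial = 1.0 / (1.0 + batch_model.radial_alpha * (radii / r_max) ** 2)
    gain = batch_model.rid_gains[rid] * batch_model.fid_gains[fid]

    resp = np.array(
        [
            float(condition_response(dose_models[spot_map.assignment[rc]],
                                     concentration))
            for rc in spots
        ]
    )
    if noise_set:
        is_noise = np.array([rc in noise_set for rc in spots])
        grid = np.logspace(-1, 1, 25)  # hsCRP range, log-spaced
        scale = np.array(
            [
                max(
                    float(
                        np.mean(
                            condition_response(
                                dose_models[spot_map.assignment[rc]], grid
                            )
                        )
                    ),
                    1e-3,
                )
                for rc in spots
            ]
        )
        resp[is_noise] = scale[is_noise] * _lognormal_factors(
            rng, noise_spot_cv, int(is_noise.sum())
        )

    eta = _lognormal_factors(rng, noise_model.cv, len(spots))
    b = noise_model.background_level + rng.normal(
        0, noise_model.background_sd, len(spots)
    )
    s_raw = resp * gain * radial * eta + b

    data = pd.DataFrame(
        {
            "row": [r for r, _ in spots],
            "col": [c for _, c in spots],
            "condition": [spot_map.assignment[rc] for rc in spots],
            "replicate": [spot_map.replicate_index(r, c) for r, c in spots],
            "s_raw": s_raw,
            "b": b,
        }
    )
    return SignalTable(data, rid=rid, fid=fid, **table_meta)


# ---------------------------------------------------------------------------
# rendering


@dataclass
class ImageParams:
    """Rasterization parameters for synthetic membrane images."""

    px_per_mm: float = 20.0
    spot_radius_mm: float = 0.52  # printed spot; sampling disks stay interior
    rotation_deg: float = 0.0
    offset_px: tuple[float, float] = (0.0, 0.0)  # (dy, dx)
    membrane_texture_sd: float = 0.0  # additive Gaussian texture, intensity units
    margin_mm: float = 2.0
    edge_sigma_px: float = 0.0  # Gaussian spot edge; 0 = anti-aliased hard disk


def render_membrane_image(
    signal_table: SignalTable,
    spot_map: SpotMap,
    image_params: ImageParams | None = None,
    seed: int | np.random.Generator = 0,
) -> MembraneImage:
    """Rasterize a simulated membrane in absorbance-like polarity.

    The membrane base level is the test's mean recorded background; each
    spot is a filled disk of amplitude ``s - b`` above it (2x supersampled
    for sub-pixel edge coverage), so disk-mean extraction recovers ``s - b``
    up to texture noise and quantization. Ground-truth lattice geometry is
    stored in the image metadata for segmentation oracles.
    """
    p = image_params or ImageParams()
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    period_px = spot_map.periodicity_mm * p.px_per_mm
    extent_r = (spot_map.grid_rows - 1) * period_px
    extent_c = (spot_map.grid_cols - 1) * period_px
    margin = p.margin_mm * p.px_per_mm
    # half-diagonal bound accommodates any rotation
    half_diag = 0.5 * np.hypot(extent_r, extent_c)
    h = int(np.ceil(2 * (half_diag + margin)))
    w = h
    max_off = max(abs(p.offset_px[0]), abs(p.offset_px[1]))
    if half_diag + max_off + p.spot_radius_mm * p.px_per_mm >= h / 2:
        raise ValueError("rotated/offset grid exceeds the image bounds")

    center = ((h - 1) / 2.0, (w - 1) / 2.0)
    r0, c0 = spot_map.centroid
    th = np.deg2rad(p.rotation_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])

    base = float(signal_table.data["b"].mean())
    img = np.full((h, w), base)
    if p.membrane_texture_sd > 0:
        img += rng.normal(0, p.membrane_texture_sd, (h, w))

    spot_r_px = p.spot_radius_mm * p.px_per_mm
    net = signal_table.data.set_index(["row", "col"])
    centers = []
    ss = 2  # supersampling factor for edge coverage
    for r, c in spot_map.spots():
        rel = np.array([r - r0, c - c0]) * period_px
        cy, cx = rot @ rel + np.array(center) + np.array(p.offset_px)
        centers.append((cy, cx))
        amp = float(net.loc[(r, c), "s_raw"] - net.loc[(r, c), "b"])
        win = int(np.ceil(spot_r_px + 3 * p.edge_sigma_px)) + 2
        y0, y1 = max(0, int(cy) - win), min(h, int(cy) + win + 1)
        x0, x1 = max(0, int(cx) - win), min(w, int(cx) + win + 1)
        if p.edge_sigma_px > 0:
            yy, xx = np.mgrid[y0:y1, x0:x1]
            dist = np.hypot(yy - cy, xx - cx)
            cov = 1.0 / (1.0 + np.exp((dist - spot_r_px) / p.edge_sigma_px))
        else:
            # 2x supersampled hard-disk coverage
            yy, xx = np.mgrid[y0 * ss : y1 * ss, x0 * ss : x1 * ss]
            dist = np.hypot((yy + 0.5) / ss - 0.5 - cy, (xx + 0.5) / ss - 0.5 - cx)
            inside = (dist <= spot_r_px).astype(float)
            cov = inside.reshape(y1 - y0, ss, x1 - x0, ss).mean(axis=(1, 3))
        img[y0:y1, x0:x1] += amp * cov

    meta = {
        "test_id": signal_table.test_id,
        "sample_id": signal_table.sample_id,
        "replicate": signal_table.replicate,
        "rid": signal_table.rid,
        "fid": signal_table.fid,
        "truth_mg_l": signal_table.truth_mg_l,
        "true_centers": np.array(centers),
        "true_rotation_deg": p.rotation_deg,
        "true_offset_px": tuple(p.offset_px),
        "period_px": period_px,
        "spot_radius_px": spot_r_px,
        "base_level": base,
    }
    return MembraneImage(img, p.px_per_mm, meta)


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class CohortDesign:
    """Study design: sample counts, ranges and batch sets.

    Defaults mirror a realistic clinical campaign: 85 hsCRP-range samples
    measured in triplicate over [0.1, 10] mg/L (log-uniform), plus acute
    samples in triplicate — one clinical outlier at 83.6 mg/L and three
    spiked serum samples at each of 200, 500 and 1000 mg/L — fabricated
    over 2 reagent batches and 3 fabrication batches.
    """

    n_hs_samples: int = 85
    concentration_range: tuple[float, float] = (0.1, 10.0)
    replicates: int = 3
    acute_concentrations: tuple[float, ...] = (
        83.6,
        200.0, 200.0, 200.0,
        500.0, 500.0, 500.0,
        1000.0, 1000.0, 1000.0,
    )
    rids: tuple[int, ...] = (1, 2)
    fids: tuple[int, ...] = (1, 2, 3)

    def __post_init__(self) -> None:
        if self.n_hs_samples < 1 or self.replicates < 1:
            raise ValueError("design counts must be >= 1")
        if not self.rids or not self.fids:
            raise ValueError("design needs at least one RID and one FID")


@dataclass
class SyntheticCohort:
    """A simulated study: one SignalTable per test plus a tidy long table."""

    tests: list[SignalTable]
    spot_map: SpotMap
    design: CohortDesign
    seed: int

    def table(self) -> pd.DataFrame:
        """Long-format table, one row per spot per test."""
        frames = []
        for t in self.tests:
            d = t.data.rename(columns={"replicate": "p"})
            d.insert(0, "test_id", t.test_id)
            d.insert(1, "sample_id", t.sample_id)
            d.insert(2, "replicate", t.replicate)
            d.insert(3, "rid", t.rid)
            d.insert(4, "fid", t.fid)
            d["truth_mg_L"] = t.truth_mg_l
            frames.append(d)
        return pd.concat(frames, ignore_index=True)

    def samples(self) -> pd.DataFrame:
        recs = {}
        for t in self.tests:
            recs.setdefault(
                t.sample_id, {"sample_id": t.sample_id, "truth_mg_L": t.truth_mg_l,
                              "n_tests": 0}
            )["n_tests"] += 1
        return pd.DataFrame(list(recs.values()))


def simulate_cohort(
    design: CohortDesign,
    spot_map: SpotMap,
    dose_models: Mapping[str, DoseResponseModel] | None = None,
    batch_model: BatchEffectModel | None = None,
    noise_model: NoiseModel | None = None,
    seed: int = 0,
    noise_spots: Iterable[tuple[int, int]] = (),
) -> SyntheticCohort:
    """Simulate a full cohort of VFA tests.

    hsCRP-range sample concentrations are drawn log-uniform over the design
    range; acute samples sit at the listed concentrations. Replicates share
    the sample concentration but draw independent noise. RID/FID are
    assigned round-robin over samples so every batch pairing is populated.
    """
    dose_models = dose_models or default_dose_models()
    batch_model = batch_model or BatchEffectModel()
    noise_model = noise_model or NoiseModel()
    rng = np.random.default_rng(seed)

    lo, hi = design.concentration_range
    concs = np.exp(rng.uniform(np.log(lo), np.log(hi), design.n_hs_samples))
    sample_specs = [(f"S{i:03d}", float(c), False) for i, c in enumerate(concs)]
    sample_specs += [
        (f"A{i:03d}", float(c), True)
        for i, c in enumerate(design.acute_concentrations)
    ]

    tests: list[SignalTable] = []
    for s_idx, (sid, conc, _acute) in enumerate(sample_specs):
        rid = design.rids[s_idx % len(design.rids)]
        fid = design.fids[s_idx % len(design.fids)]
        for rep in range(design.replicates):
            t = simulate_membrane_signals(
                spot_map,
                conc,
                rid,
                fid,
                dose_models,
                batch_model,
                noise_model,
                seed=rng,
                noise_spots=noise_spots,
                test_id=f"{sid}-r{rep}",
                sample_id=sid,
                replicate=rep,
                truth_mg_l=conc,
            )
            tests.append(t)
    return SyntheticCohort(tests, spot_map, design, seed)
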