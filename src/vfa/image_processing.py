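"""Spot-grid segmentation and signal extraction for VFA membrane images.

Pipeline per test: detect the spot lattice in the membrane image (template
cross-correlation over an offset x rotation search grid), average pixels in
a disk per spot (raw signal ``s``), average an annulus of bare blocked
membrane around it (local background ``b``), then normalize every
background-subtracted signal to the membrane total,

    s'_{m,p} = (s_{m,p} - b_{m,p}) / sum_{m,p} (s_{m,p} - b_{m,p}),

which cancels sensor-to-sensor scale variation (pipetting, fabrication and
illumination differences). Per-condition averages

    x_m = (1/P_m) sum_p s'_{m,p}

are the features handed to the inference networks. Intensity polarity is
absorbance-like throughout: larger values mean more bound gold-nanoparticle
conjugate. Photographic images (bright membrane, dark spots) are inverted
on load.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import match_template

from .spot_map import SpotMap

__all__ = [
    "MembraneImage",
    "LatticeFit",
    "SignalTable",
    "GridSearchParams",
    "ExtractionRadii",
    "QCThresholds",
    "detect_spot_grid",
    "extract_spot_signals",
    "normalize_signals",
    "condition_averages",
    "qc_check",
]


@dataclass
class MembraneImage:
    """Single-channel membrane image in absorbance-like polarity."""

    pixels: np.ndarray  # 2-D float array, larger = more signal
    px_per_mm: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("MembraneImage expects a 2-D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite intensities")
        if self.px_per_mm <= 0:
            raise ValueError("px_per_mm must be positive")

    @classmethod
    def from_photo(
        cls,
        array: np.ndarray,
        px_per_mm: float,
        channel: str = "green",
        metadata: dict | None = None,
    ) -> "MembraneImage":
        """Build from a photographic capture (bright membrane, dark spots).

        RGB input is reduced to ``channel`` ("red"/"green"/"blue", the green
        channel having the strongest contrast for gold-nanoparticle color,
        or "luminance"), then inverted so larger values mean more binding.
        """
        arr = np.asarray(array, dtype=float)
        if arr.ndim == 3:
            idx = {"red": 0, "green": 1, "blue": 2}
            if channel in idx:
                arr = arr[..., idx[channel]]
            elif channel == "luminance":
                arr = arr @ np.array([0.2126, 0.7152, 0.0722])
            else:
                raise ValueError(f"unknown channel {channel!r}")
        return cls(arr.max() - arr, px_per_mm, metadata or {})


@dataclass
class LatticeFit:
    """Recovered lattice geometry of the spot grid."""

    offset_px: tuple[float, float]  # (dy, dx) of the lattice centroid
    rotation_deg: float
    periodicity_px: float
    centers: np.ndarray  # (n_spots, 2) array of (row_px, col_px)
    residual: float  # 1 - mean template correlation at the centers
    success: bool

    def __post_init__(self) -> None:
        if self.residual < 0:
            self.residual = 0.0


@dataclass
class SignalTable:
    """Per-spot raw/background/normalized signals for one VFA test.

    ``data`` columns: row, col, condition, replicate, s_raw, b. Normalized
    signals and condition averages are computed on demand so the same table
    supports full-grid and selected-subset normalization.
    """

    data: pd.DataFrame
    test_id: str = ""
    sample_id: str = ""
    replicate: int = 0
    rid: int = 1
    fid: int = 1
    truth_mg_l: float | None = None
    qc_pass: bool = True
    qc_reasons: list[str] = field(default_factory=list)

    REQUIRED = ("row", "col", "condition", "s_raw", "b")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"SignalTable missing column(s) {missing}")
        if "replicate" not in self.data.columns:
            self.data = self.data.copy()
            self.data["replicate"] = (
                self.data.groupby("condition").cumcount().to_numpy()
            )

    def net(self, spots: Sequence[tuple[int, int]] | None = None) -> pd.Series:
        """Background-subtracted signals s - b, optionally on a spot subset."""
        d = self._subset(spots)
        return pd.Series(
            (d["s_raw"] - d["b"]).to_numpy(),
            index=pd.MultiIndex.from_frame(d[["row", "col"]]),
            name="net",
        )

    def normalized(
        self, spots: Sequence[tuple[int, int]] | None = None, eps: float | None = None
    ) -> pd.Series:
        d = self._subset(spots)
        return normalize_signals(
            d["s_raw"].to_numpy(),
            d["b"].to_numpy(),
            eps=eps,
            index=pd.MultiIndex.from_frame(d[["row", "col"]]),
        )

    def condition_averages(
        self, spots: Sequence[tuple[int, int]] | None = None
    ) -> pd.Series:
        d = self._subset(spots)
        s_norm = self.normalized(spots)
        return condition_averages(s_norm, d["condition"].to_numpy())

    def _subset(self, spots: Sequence[tuple[int, int]] | None) -> pd.DataFrame:
        if spots is None:
            return self.data
        keys = set(map(tuple, spots))
        mask = [
            (r, c) in keys
            for r, c in zip(self.data["row"], self.data["col"])
        ]
        d = self.data[mask]
        if len(d) != len(keys):
            found = {(r, c) for r, c in zip(d["row"], d["col"])}
            raise KeyError(f"spots not in table: {sorted(keys - found)[:5]}")
        return d


def normalize_signals(
    s_raw: np.ndarray,
    b: np.ndarray,
    eps: float | None = None,
    index: pd.Index | None = None,
) -> pd.Series:
    """Normalize background-subtracted signals to the membrane total.

    Raises ``ValueError`` (the caller converts this into a QC failure) when
    the denominator falls below ``eps`` — the signature of abnormal
    non-specific binding or conjugate loss. ``eps`` defaults to 1e-6 of the
    mean background.
    """
    s_raw = np.asarray(s_raw, dtype=float)
    b = np.asarray(b, dtype=float)
    net = s_raw - b
    if eps is None:
        eps = 1e-6 * max(float(np.mean(np.abs(b))), 1e-30)
    denom = float(net.sum())
    if not np.isfinite(denom) or denom <= eps:
        raise ValueError(
            "abnormal non-specific binding / low signal: "
            f"total net signal {denom:.3g} <= {eps:.3g}"
        )
    return pd.Series(net / denom, index=index, name="s_norm")


def condition_averages(
    s_norm: pd.Series | np.ndarray, conditions: np.ndarray
) -> pd.Series:
    """Mean normalized signal x_m per condition over the provided spots."""
    vals = np.asarray(s_norm, dtype=float)
    conditions = np.asarray(conditions)
    if len(vals) == 0:
        raise ValueError("no spots provided")
    df = pd.DataFrame({"condition": conditions, "s_norm": vals})
    out = df.groupby("condition", sort=True)["s_norm"].mean()
    out.name = "x_m"
    return out


# ---------------------------------------------------------------------------
# lattice detection


@dataclass
class GridSearchParams:
    """Search grid for the lattice registration."""

    rotation_max_deg: float = 5.0
    rotation_step_deg: float = 0.25
    offset_max_px: float | None = None  # default: one lattice period
    offset_step_px: float = 1.0
    # template disk matches the printed spot extent (~1 mm at 1.3 mm pitch)
    # so the correlation peak is unique rather than flat-topped
    spot_radius_frac: float = 0.40
    min_correlation: float = 0.20  # mean per-spot NCC below this = failed fit


def _lattice_centers(
    spot_map: SpotMap, period_px: float, center: tuple[float, float],
    rotation_deg: float, offset: tuple[float, float],
) -> np.ndarray:
    """Spot centers (row_px, col_px) for given lattice parameters."""
    r0, c0 = spot_map.centroid
    rel = np.array([(r - r0, c - c0) for r, c in spot_map.spots()]) * period_px
    th = np.deg2rad(rotation_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    return rel @ rot.T + np.array(center) + np.array(offset)


def _parabolic_step(y_minus: float, y0: float, y_plus: float) -> float:
    denom = y_minus - 2 * y0 + y_plus
    if denom >= -1e-12:  # not a local max
        return 0.0
    return float(np.clip(0.5 * (y_minus - y_plus) / denom, -1, 1))


def detect_spot_grid(
    image: MembraneImage,
    spot_map: SpotMap,
    search: GridSearchParams | None = None,
) -> LatticeFit:
    """Register the spot lattice by normalized template cross-correlation.

    A disk template is cross-correlated with the image once (FFT-backed
    normalized cross-correlation); the lattice offset and rotation are then
    found by maximizing the mean correlation sampled at the predicted spot
    centers over a bounded search grid, refined by parabolic interpolation.
    A failed fit (peak mean correlation below threshold) is reported via
    ``success=False`` rather than an exception, so QC can flag the test.
    """
    search = search or GridSearchParams()
    period_px = spot_map.periodicity_mm * image.px_per_mm
    h, w = image.pixels.shape
    extent_r = (spot_map.grid_rows - 1) * period_px
    extent_c = (spot_map.grid_cols - 1) * period_px
    if extent_r >= h or extent_c >= w:
        raise ValueError("image smaller than the expected lattice extent")

    spot_r = max(2, int(round(search.spot_radius_frac * period_px)))
    yy, xx = np.mgrid[-spot_r : spot_r + 1, -spot_r : spot_r + 1]
    template = (yy**2 + xx**2 <= spot_r**2).astype(float)
    ncc = match_template(image.pixels, template, pad_input=True, mode="mean")

    center = ((h - 1) / 2.0, (w - 1) / 2.0)
    off_max = search.offset_max_px if search.offset_max_px is not None else period_px
    offs = np.arange(-off_max, off_max + 1e-9, search.offset_step_px)
    rots = np.arange(
        -search.rotation_max_deg,
        search.rotation_max_deg + 1e-9,
        search.rotation_step_deg,
    )

    n_off = len(offs)
    scores = np.empty((len(rots), n_off, n_off))
    grid_dy, grid_dx = np.meshgrid(offs, offs, indexing="ij")
    for i, rot in enumerate(rots):
        base = _lattice_centers(spot_map, period_px, center, rot, (0.0, 0.0))
        # points: (n_off*n_off, n_spots, 2)
        pts_r = base[None, :, 0] + grid_dy.ravel()[:, None]
        pts_c = base[None, :, 1] + grid_dx.ravel()[:, None]
        vals = ndimage.map_coordinates(
            ncc, [pts_r.ravel(), pts_c.ravel()], order=1, mode="constant", cval=-1.0
        ).reshape(n_off * n_off, -1)
        scores[i] = vals.mean(axis=1).reshape(n_off, n_off)

    i, j, k = np.unravel_index(np.argmax(scores), scores.shape)
    best = float(scores[i, j, k])

    def neighbor(axis: int, delta: int) -> float:
        idx = [i, j, k]
        idx[axis] += delta
        if 0 <= idx[axis] < scores.shape[axis]:
            return float(scores[tuple(idx)])
        return -np.inf

    rot = rots[i]
    dy, dx = offs[j], offs[k]
    sub = [0.0, 0.0, 0.0]
    for axis, (lo, hi) in enumerate(
        [(neighbor(0, -1), neighbor(0, 1)),
         (neighbor(1, -1), neighbor(1, 1)),
         (neighbor(2, -1), neighbor(2, 1))]
    ):
        if np.isfinite(lo) and np.isfinite(hi):
            sub[axis] = _parabolic_step(lo, best, hi)
    rot += sub[0] * search.rotation_step_deg
    dy += sub[1] * search.offset_step_px
    dx += sub[2] * search.offset_step_px

    centers = _lattice_centers(spot_map, period_px, center, rot, (dy, dx))
    refined = float(
        ndimage.map_coordinates(
            ncc, [centers[:, 0], centers[:, 1]], order=1, mode="constant", cval=-1.0
        ).mean()
    )
    peak = max(best, refined)
    return LatticeFit(
        offset_px=(float(dy), float(dx)),
        rotation_deg=float(rot),
        periodicity_px=float(period_px),
        centers=centers,
        residual=1.0 - peak,
        success=bool(peak >= search.min_correlation),
    )


# ---------------------------------------------------------------------------
# signal extraction


@dataclass
class ExtractionRadii:
    """Disk/annulus radii as fractions of the lattice periodicity.

    Defaults keep the background annulus on bare blocked membrane without
    touching neighbouring spots at the standard 1.3 mm pitch. The sampling
    disk sits strictly inside a printed ~1 mm spot so rim pixels do not
    dilute the average; ``exclusion_r`` masks annulus pixels lying within a
    neighbouring spot's printed extent.
    """

    spot_r: float = 0.35
    bg_inner: float = 0.55
    bg_outer: float = 0.75
    exclusion_r: float = 0.45


def extract_spot_signals(
    image: MembraneImage,
    lattice: LatticeFit,
    spot_map: SpotMap,
    radii: ExtractionRadii | None = None,
) -> SignalTable:
    """Average each spot disk (s) and its local background annulus (b).

    Annulus pixels lying within a spot radius of any *other* spot center are
    excluded; an annulus left empty (image border, dense packing) is widened
    once to 1.5x the outer radius, after which the spot is QC-failed (NaN).
    """
    if not lattice.success:
        raise ValueError("cannot extract from a failed lattice fit")
    radii = radii or ExtractionRadii()
    p = lattice.periodicity_px
    spot_r = radii.spot_r * p
    bg_in, bg_out = radii.bg_inner * p, radii.bg_outer * p
    excl_r = radii.exclusion_r * p
    img = image.pixels
    h, w = img.shape
    centers = lattice.centers
    spots = spot_map.spots()

    rows_out = []
    for idx, (r, c) in enumerate(spots):
        cy, cx = centers[idx]
        win = int(np.ceil(bg_out * 1.5)) + 1
        y0, y1 = max(0, int(cy) - win), min(h, int(cy) + win + 1)
        x0, x1 = max(0, int(cx) - win), min(w, int(cx) + win + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dist = np.hypot(yy - cy, xx - cx)
        disk = dist <= spot_r
        s_val = float(img[y0:y1, x0:x1][disk].mean()) if disk.any() else np.nan

        # distance to the nearest *other* spot center, for exclusion
        others = np.delete(centers, idx, axis=0)
        d_other = np.min(
            np.hypot(yy[..., None] - others[None, None, :, 0],
                     xx[..., None] - others[None, None, :, 1]),
            axis=-1,
        )
        ann = (dist >= bg_in) & (dist <= bg_out) & (d_other > excl_r)
        if not ann.any():
            ann = (dist >= bg_in) & (dist <= bg_out * 1.5) & (d_other > excl_r)
        b_val = float(img[y0:y1, x0:x1][ann].mean()) if ann.any() else np.nan
        rows_out.append(
            {
                "row": r,
                "col": c,
                "condition": spot_map.assignment[(r, c)],
                "replicate": spot_map.replicate_index(r, c),
                "s_raw": s_val,
                "b": b_val,
            }
        )
    meta = image.metadata
    return SignalTable(
        pd.DataFrame(rows_out),
        test_id=str(meta.get("test_id", "")),
        sample_id=str(meta.get("sample_id", "")),
        replicate=int(meta.get("replicate", 0)),
        rid=int(meta.get("rid", 1)),
        fid=int(meta.get("fid", 1)),
        truth_mg_l=meta.get("truth_mg_l"),
    )


# ---------------------------------------------------------------------------
# QC


@dataclass
class QCThresholds:
    max_residual: float = 0.8  # 1 - mean NCC; above this = misalignment
    low_signal_frac: float = 0.05  # total net below this x expected = low signal

    # absolute floor for the total net signal; the relative criterion above
    # needs an expected scale which synthetic cohorts provide via metadata
    min_total_net: float = 1e-6


def qc_check(
    lattice: LatticeFit | None,
    signals: SignalTable | None,
    thresholds: QCThresholds | None = None,
    expected_total_net: float | None = None,
) -> tuple[bool, list[str]]:
    """Flag misaligned, low-signal or corrupt tests. Never raises.

    Mirrors the exclusions applied to real cohorts: fabrication misalignment
    (lattice fit failure or high residual), abnormally high non-specific
    binding (conjugate sequestered, leaving little specific signal on the
    membrane), and non-finite extracted values.
    """
    thresholds = thresholds or QCThresholds()
    reasons: list[str] = []
    if lattice is None or not lattice.success:
        reasons.append("misalignment: lattice fit failed")
    elif lattice.residual > thresholds.max_residual:
        reasons.append(
            f"misalignment: fit residual {lattice.residual:.3f} > "
            f"{thresholds.max_residual:.3f}"
        )
    if signals is not None:
        net = (signals.data["s_raw"] - signals.data["b"]).to_numpy(dtype=float)
        if not np.all(np.isfinite(net)):
            reasons.append("non-finite spot signal(s)")
        else:
            total = float(net.sum())
            floor = thresholds.min_total_net
            if expected_total_net is not None:
                floor = max(floor, thresholds.low_signal_frac * expected_total_net)
            if total < floor:
                reasons.append(
                    f"low signal / abnormal non-specific binding: total net "
                    f"{total:.3g} < {floor:.3g}"
                )
    elif lattice is not None and lattice.success:
        reasons.append("no signals extracted")
    return (len(reasons) == 0, reasons)
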