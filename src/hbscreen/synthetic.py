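"""Seeded synthetic haemoglobin-electrophoresis strip generator.

No public image set of Ponceau-stained Hb electrophoresis strips exists,
so this module renders them: up to eight patient lanes side by side on a
pink background, each lane carrying one to three dark-red bands at the
characteristic migration positions (HbA fastest and furthest from the
application point, then HbF, then HbA2 closest to it).  The relative
integrated darkness of each band encodes that variant's share of total
haemoglobin, which is what separates a normal lane (HbA2 below 3.5 % of
total stain) from a beta-thalassaemia-trait lane (HbA2 elevated, up to
about 7 %).

Nuisance structure emulated: additive Gaussian pixel noise, a linear
illumination gradient along the migration axis, lateral lane jitter, and
— with configurable probability — adjacent lanes whose stain regions
touch, the failure mode the two-scale erosion step downstream exists to
repair.  Every render is bit-reproducible from ``(spec, seed)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .core import LABELS, LaneBox, StripImage
from .errors import InvalidSpecError, IOFailure

# Migration positions as fractions of lane length from the application
# point (top).  HbA migrates fastest, HbA2 slowest.
BAND_CENTER_FRAC = {"HbA": 0.72, "HbF": 0.52, "HbA2": 0.32}
BAND_WIDTH_FRAC = {"HbA": 0.030, "HbF": 0.025, "HbA2": 0.020}

#: HbA2 share of total stain at or above this fraction marks
#: beta-thalassaemia trait.
HBA2_CUTOFF = 0.035

# Rendering constants: Ponceau-pink background, dark-red stain, and the
# gain converting a stain fraction into integrated darkness.  The gain is
# large enough that a dominant HbA band saturates (clips at darkness 1),
# as heavily stained bands do on real strips.
BACKGROUND_RGB = np.array([247.0, 214.0, 220.0])
BAND_RGB = np.array([135.0, 22.0, 58.0])
STAIN_GAIN = 60.0
_EDGE_ROLL_PX = 2.0  # cosine roll-off at the stain window edges


@dataclass(frozen=True)
class BandSpec:
    """One haemoglobin band within a lane."""

    variant: str  # "HbA" | "HbF" | "HbA2"
    center_frac: float  # distance from application point / lane length
    intensity_frac: float  # share of the lane's total stain
    width_frac: float  # band thickness / lane length

    def __post_init__(self) -> None:
        if self.variant not in BAND_CENTER_FRAC:
            raise InvalidSpecError(f"unknown variant {self.variant!r}")
        if not (0.0 < self.center_frac < 1.0):
            raise InvalidSpecError("center_frac must be in (0, 1)")
        if not (0.0 <= self.intensity_frac <= 1.0):
            raise InvalidSpecError("intensity_frac must be in [0, 1]")
        if not (0.0 < self.width_frac < 0.5):
            raise InvalidSpecError("width_frac must be in (0, 0.5)")


def make_band(variant: str, intensity_frac: float) -> BandSpec:
    """Band at the variant's canonical migration position."""
    return BandSpec(
        variant=variant,
        center_frac=BAND_CENTER_FRAC[variant],
        intensity_frac=intensity_frac,
        width_frac=BAND_WIDTH_FRAC[variant],
    )


@dataclass(frozen=True)
class LaneSpec:
    """One patient lane: class label, its bands and lateral jitter."""

    label: str  # "normal" | "thalassaemia"
    bands: tuple[BandSpec, ...]
    jitter_px: float = 0.0

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise InvalidSpecError(f"unknown label {self.label!r}")
        object.__setattr__(self, "bands", tuple(self.bands))
        total = sum(b.intensity_frac for b in self.bands)
        if total > 1.0 + 1e-9:
            raise InvalidSpecError(f"band intensities sum to {total} > 1")
        # Migration order: HbA furthest from the application point,
        # HbA2 closest.
        pos = {b.variant: b.center_frac for b in self.bands}
        order = [pos.get(v) for v in ("HbA", "HbF", "HbA2")]
        present = [p for p in order if p is not None]
        if any(a <= b for a, b in zip(present, present[1:])):
            raise InvalidSpecError(
                "migration order violated: need "
                "center_frac(HbA) > center_frac(HbF) > center_frac(HbA2)"
            )
        a2 = self.hba2_fraction
        if self.label == "normal" and a2 >= HBA2_CUTOFF:
            raise InvalidSpecError(f"normal lane with HbA2 fraction {a2}")
        if self.label == "thalassaemia" and a2 < HBA2_CUTOFF:
            raise InvalidSpecError(
                f"thalassaemia lane with HbA2 fraction {a2}"
            )

    @property
    def hba2_fraction(self) -> float:
        return sum(
            b.intensity_frac for b in self.bands if b.variant == "HbA2"
        )


@dataclass(frozen=True)
class LanePopulation:
    """Class-conditional sampling ranges for lane composition.

    Defaults follow clinical ranges: normal adults carry roughly 2–3.5 %
    HbA2 and negligible HbF; beta-thalassaemia trait raises HbA2 to
    3.5–7 %, sometimes with a mildly elevated HbF band.
    """

    hba2_normal: tuple[float, float] = (0.015, 0.030)
    hba2_thal: tuple[float, float] = (0.040, 0.070)
    hbf_prob_thal: float = 0.35
    hbf_range: tuple[float, float] = (0.03, 0.12)
    jitter_max_px: float = 3.0


DEFAULT_POPULATION = LanePopulation()

#: Extreme class separation (HbA2 ~1 % vs ~7 %, no HbF confounder) used
#: by the scaled end-to-end classification surrogate.
WELL_SEPARATED_POPULATION = LanePopulation(
    hba2_normal=(0.008, 0.012),
    hba2_thal=(0.065, 0.075),
    hbf_prob_thal=0.0,
)


@dataclass(frozen=True)
class StripSpec:
    """Geometry and nuisance parameters of one rendered strip.

    ``height_px`` is the migration axis (rows); ``width_px`` spans the
    ``n_lanes`` side-by-side lanes.  ``noise_sd`` is the additive
    Gaussian noise standard deviation in 8-bit grayscale units;
    ``illumination_slope`` is grayscale units per pixel row;
    ``merge_prob`` is the per-adjacent-pair probability that the two
    stain regions are pushed together until they touch.
    """

    height_px: int = 1280
    width_px: int = 320
    n_lanes: int = 8
    noise_sd: float = 3.0
    illumination_slope: float = 0.015
    merge_prob: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height_px <= 0 or self.width_px <= 0:
            raise InvalidSpecError("strip dimensions must be positive")
        if self.n_lanes < 1:
            raise InvalidSpecError("n_lanes must be >= 1")
        if not (0.0 <= self.merge_prob <= 1.0):
            raise InvalidSpecError("merge_prob must be in [0, 1]")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be >= 0")


#: Low-nuisance strip used by the scaled end-to-end surrogate.
def clean_strip_spec(seed: int = 0, **overrides) -> StripSpec:
    params = dict(noise_sd=1.0, illumination_slope=0.0, merge_prob=0.0)
    params.update(overrides)
    return StripSpec(seed=seed, **params)


@dataclass
class GroundTruth:
    """Per-lane boxes, labels and band rows consistent with the render."""

    lane_boxes: list[LaneBox]
    labels: list[str]
    band_centers: list[list[int]]

    def __post_init__(self) -> None:
        n = len(self.lane_boxes)
        if not (len(self.labels) == len(self.band_centers) == n):
            raise InvalidSpecError("ground-truth field lengths differ")


def sample_lane_spec(
    label: str,
    rng: np.random.Generator,
    population: LanePopulation = DEFAULT_POPULATION,
) -> LaneSpec:
    """Draw a lane composition for the given class."""
    if label == "normal":
        hba2 = rng.uniform(*population.hba2_normal)
        hbf = 0.0
    elif label == "thalassaemia":
        hba2 = rng.uniform(*population.hba2_thal)
        hbf = (
            rng.uniform(*population.hbf_range)
            if rng.random() < population.hbf_prob_thal
            else 0.0
        )
    else:
        raise InvalidSpecError(f"unknown label {label!r}")
    bands = [make_band("HbA", 1.0 - hba2 - hbf)]
    if hbf > 0:
        bands.append(make_band("HbF", hbf))
    bands.append(make_band("HbA2", hba2))
    jitter = float(
        rng.uniform(-population.jitter_max_px, population.jitter_max_px)
    )
    return LaneSpec(label=label, bands=tuple(bands), jitter_px=jitter)


def _stain_window(
    width: int, center: float, half: float
) -> np.ndarray:
    """Flat-top lateral stain profile with a short cosine roll-off."""
    cols = np.arange(width, dtype=float)
    d = np.abs(cols - center)
    w = np.zeros(width)
    inner = half - _EDGE_ROLL_PX
    w[d <= inner] = 1.0
    roll = (d > inner) & (d <= half)
    w[roll] = 0.5 * (1.0 + np.cos(np.pi * (d[roll] - inner) / _EDGE_ROLL_PX))
    return w


def render_strip(
    spec: StripSpec,
    lanes: list[LaneSpec] | None = None,
    population: LanePopulation = DEFAULT_POPULATION,
    labels: list[str] | None = None,
) -> tuple[StripImage, GroundTruth]:
    """Render one strip and its exactly consistent ground truth.

    If ``lanes`` is omitted, lane compositions are drawn from
    ``population``; class labels default to an even coin flip unless
    ``labels`` pins them.  All randomness comes from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height_px, spec.width_px
    n = spec.n_lanes

    if lanes is None:
        if labels is None:
            labels = [
                LABELS[int(rng.random() < 0.5)] for _ in range(n)
            ]
        if len(labels) != n:
            raise InvalidSpecError(
                f"{len(labels)} labels for {n} lanes"
            )
        lanes = [sample_lane_spec(lb, rng, population) for lb in labels]
    elif len(lanes) != n:
        raise InvalidSpecError(f"{len(lanes)} lane specs for {n} lanes")

    lane_w = w / n
    half = 0.30 * lane_w
    centers = np.array(
        [(i + 0.5) * lane_w + lanes[i].jitter_px for i in range(n)]
    )

    # Occasionally pull an adjacent pair together until only a 1–3 px
    # gap remains, then connect their dominant bands with a thin stain
    # bleed — the merged-lane failure mode the two-scale erosion step
    # downstream exists to repair.
    merged = [False] * n
    merged_pairs: list[int] = []
    for i in range(n - 1):
        if merged[i] or merged[i + 1]:
            continue
        if rng.random() < spec.merge_prob:
            target_gap = float(rng.integers(1, 4))
            gap = (centers[i + 1] - centers[i]) - 2 * half
            shift = (gap - target_gap) / 2.0
            if shift > 0:
                centers[i] += shift
                centers[i + 1] -= shift
                merged[i] = merged[i + 1] = True
                merged_pairs.append(i)

    darkness = np.zeros((h, w))
    rows = np.arange(h, dtype=float)[:, None]
    band_centers: list[list[int]] = []
    for i, lane in enumerate(lanes):
        window = _stain_window(w, centers[i], half)[None, :]
        profile = np.zeros((h, 1))
        rows_i: list[int] = []
        for band in lane.bands:
            c = round(band.center_frac * (h - 1))
            sigma = band.width_frac * h / 2.355  # FWHM convention
            amp = STAIN_GAIN * band.intensity_frac / (
                sigma * np.sqrt(2.0 * np.pi)
            )
            profile += amp * np.exp(-((rows - c) ** 2) / (2 * sigma**2))
            rows_i.append(c)
        darkness += np.clip(profile, 0.0, 1.0) * window
        band_centers.append(rows_i)

    # Stain bleed between merged lanes: a ~5-row-tall bar at the HbA
    # band rows spanning the inter-lane gap.  Tall bands survive a
    # radius-3 opening; this thin bridge does not.
    for i in merged_pairs:
        c_row = round(BAND_CENTER_FRAC["HbA"] * (h - 1))
        r0, r1 = max(0, c_row - 2), min(h, c_row + 3)
        c0 = int(np.floor(centers[i] + half - _EDGE_ROLL_PX - 1))
        c1 = int(np.ceil(centers[i + 1] - half + _EDGE_ROLL_PX + 1))
        c0, c1 = max(0, c0), min(w, c1)
        if c1 > c0:
            darkness[r0:r1, c0:c1] = np.maximum(
                darkness[r0:r1, c0:c1], 0.5
            )
    darkness = np.clip(darkness, 0.0, 1.0)

    img = (
        BACKGROUND_RGB[None, None, :]
        + darkness[:, :, None] * (BAND_RGB - BACKGROUND_RGB)[None, None, :]
    )
    if spec.illumination_slope != 0.0:
        img += (spec.illumination_slope * (rows - h / 2.0))[:, :, None]
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    # Ground-truth boxes span the stain window's column extent and the
    # full strip height; merged pairs are split at the overlap midpoint
    # so boxes stay pairwise disjoint.
    edges = [
        [max(0.0, c - half), min(float(w), c + half)] for c in centers
    ]
    for i in range(n - 1):
        if edges[i][1] > edges[i + 1][0]:
            mid = (edges[i][1] + edges[i + 1][0]) / 2.0
            edges[i][1] = mid
            edges[i + 1][0] = mid
    boxes = [
        LaneBox(0, h, int(np.floor(c0)), int(np.ceil(c1)))
        for c0, c1 in edges
    ]
    gt = GroundTruth(
        lane_boxes=boxes,
        labels=[lane.label for lane in lanes],
        band_centers=band_centers,
    )
    strip = StripImage(pixels, meta={"spec": spec, "n_lanes": n})
    return strip, gt


MANIFEST_COLUMNS = [
    "strip_path",
    "lane_index",
    "row0",
    "row1",
    "col0",
    "col1",
    "label",
]


def _derive_seed(seed: int, index: int) -> int:
    return (seed * 1_000_003 + index * 7919 + 1) % (2**31 - 1)


def generate_dataset(
    n_strips: int,
    class_balance: float,
    spec: StripSpec,
    out_dir: str | Path,
    population: LanePopulation = DEFAULT_POPULATION,
) -> pd.DataFrame:
    """Render ``n_strips`` strips to ``out_dir`` with a lane manifest.

    ``class_balance`` is the requested thalassaemia fraction over all
    lanes; the realised count is its nearest integer, so the balance is
    met within one lane.  Returns the manifest (also written to
    ``out_dir/manifest.csv``) with one row per lane.
    """
    from .io import write_image  # local import to avoid a cycle

    if n_strips < 1:
        raise InvalidSpecError("n_strips must be >= 1")
    if not (0.0 <= class_balance <= 1.0):
        raise InvalidSpecError("class_balance must be in [0, 1]")
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover - depends on filesystem
        raise IOFailure(f"cannot create output dir {out}: {exc}") from exc

    total = n_strips * spec.n_lanes
    n_thal = int(round(class_balance * total))
    labels = np.array(
        ["thalassaemia"] * n_thal + ["normal"] * (total - n_thal)
    )
    np.random.default_rng(_derive_seed(spec.seed, 0xBA1A)).shuffle(labels)

    rows = []
    for i in range(n_strips):
        strip_spec = replace(spec, seed=_derive_seed(spec.seed, i))
        chunk = list(labels[i * spec.n_lanes : (i + 1) * spec.n_lanes])
        strip, gt = render_strip(strip_spec, population=population,
                                 labels=chunk)
        name = f"strip_{i:04d}.png"
        write_image(strip.pixels, out / name)
        for k, (box, label) in enumerate(zip(gt.lane_boxes, gt.labels)):
            rows.append(
                {
                    "strip_path": name,
                    "lane_index": k,
                    "row0": box.row0,
                    "row1": box.row1,
                    "col0": box.col0,
                    "col1": box.col1,
                    "label": label,
                }
            )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def strip_spec_from_dict(cfg: dict) -> StripSpec:
    """Build a :class:`StripSpec` from a parsed YAML/JSON mapping,
    rejecting unknown keys."""
    allowed = {f.name for f in fields(StripSpec)}
    unknown = set(cfg) - allowed
    if unknown:
        raise InvalidSpecError(f"unknown StripSpec keys: {sorted(unknown)}")
    return StripSpec(**cfg)


def strip_spec_from_file(path: str | Path) -> StripSpec:
    path = Path(path)
    text = path.read_text()
    if path.suffix in {".yaml", ".yml"}:
        import yaml

        cfg = yaml.safe_load(text)
    else:
        cfg = json.loads(text)
    return strip_spec_from_dict(cfg)
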