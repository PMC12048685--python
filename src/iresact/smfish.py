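"""Single-molecule FISH spot calling and 5' UTR isoform classification.

Each diffraction-limited punctum is one mRNA molecule. Two probe sets are
imaged per section: a CDS probe hybridizing to all transcript isoforms and
an IRES probe hybridizing only to the long 5' UTR isoform. A CDS spot whose
pixel mask partially overlaps an IRES spot is therefore called a long-isoform
molecule; a CDS spot with no IRES overlap is a short-isoform molecule. Puncta
counts from all images of one embryo are pooled before forming the isoform
proportion, and region summaries average the per-embryo proportions.

Spot calling uses local intensity thresholding: a pixel is foreground when it
exceeds the local median by ``k`` local MADs (median absolute deviations),
both computed in a square sliding window; 8-connected foreground components
within configured area bounds become spots. Image coordinates are (row, col),
0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

__all__ = [
    "ImageStack",
    "Spot",
    "DetectionParams",
    "IsoformCallTable",
    "RegionSummary",
    "detect_spots",
    "classify_colocalization",
    "negcontrol_qc",
    "pool_and_summarize",
    "analyze_stack",
]

CHANNEL_ROLES = ("CDS", "IRES", "NEG", "NUC")


@dataclass
class ImageStack:
    """Registered 2D channel images keyed by probe role.

    Roles: ``CDS`` (all-isoform probe), ``IRES`` (long-isoform probe),
    ``NEG`` (negative-control probes, background QC), ``NUC`` (nuclear
    stain). All channels must share dimensions and contain finite,
    nonnegative intensities.
    """

    channels: dict[str, np.ndarray]
    pixel_size: float | None = None  # µm per pixel, if known
    region_label: str = ""
    embryo_id: str = ""

    def __post_init__(self) -> None:
        shape = None
        for role, img in self.channels.items():
            arr = np.asarray(img, dtype=float)
            if arr.ndim != 2:
                raise ValueError(f"channel {role!r} must be 2D, got shape {arr.shape}")
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ValueError(f"channel {role!r} must be finite and nonnegative")
            if shape is None:
                shape = arr.shape
            elif arr.shape != shape:
                raise ValueError("all channels must share identical dimensions")
            self.channels[role] = arr

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass(frozen=True)
class Spot:
    """One detected punctum: pixel mask, centroid and background-subtracted intensity."""

    channel: str
    mask: frozenset[tuple[int, int]]
    centroid: tuple[float, float]
    intensity: float
    area: int


@dataclass(frozen=True)
class DetectionParams:
    """Local-threshold spot-detection parameters.

    window: odd side length (px) of the square window for the local median
    and MAD. k: threshold in local MADs above the local median. min_area /
    max_area: accepted component size in pixels (the ceiling rejects merged
    blobs and large autofluorescent debris).
    """

    window: int = 15
    k: float = 5.0
    min_area: int = 2
    max_area: int = 200

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if self.min_area < 1:
            raise ValueError("min_area must be >= 1")
        if self.max_area < self.min_area:
            raise ValueError("max_area must be >= min_area")


def detect_spots(
    image: ImageStack, role: str, params: DetectionParams | None = None
) -> list[Spot]:
    """Call puncta on one channel by local median/MAD thresholding.

    A pixel is foreground when intensity > local median + k * local MAD
    (window statistics with symmetric boundary reflection); 8-connected
    foreground components within [min_area, max_area] become spots. Each
    spot's centroid is the intensity-weighted mean pixel position and its
    intensity is the summed local-background-subtracted signal, both using
    the positive part of (intensity - local median). Deterministic for fixed
    inputs.
    """
    params = params or DetectionParams()
    if role not in image.channels:
        raise KeyError(f"channel {role!r} not present in image stack")
    img = image.channels[role]
    if params.window > min(img.shape):
        raise ValueError(
            f"window {params.window} larger than image {img.shape}"
        )
    local_median = ndimage.median_filter(img, size=params.window, mode="reflect")
    local_mad = ndimage.median_filter(
        np.abs(img - local_median), size=params.window, mode="reflect"
    )
    foreground = img > local_median + params.k * local_mad
    labels = measure.label(foreground, connectivity=2)  # 8-connectivity
    excess = np.clip(img - local_median, 0.0, None)

    spots: list[Spot] = []
    for region in measure.regionprops(labels, intensity_image=excess):
        if not (params.min_area <= region.area <= params.max_area):
            continue
        coords = frozenset((int(r), int(c)) for r, c in region.coords)
        weights = excess[tuple(np.asarray(region.coords).T)]
        total = float(weights.sum())
        if total > 0:
            rows = np.asarray([r for r, _ in region.coords], dtype=float)
            cols = np.asarray([c for _, c in region.coords], dtype=float)
            centroid = (
                float((rows * weights).sum() / total),
                float((cols * weights).sum() / total),
            )
        else:
            centroid = tuple(map(float, region.centroid))
        spots.append(
            Spot(
                channel=role,
                mask=coords,
                centroid=centroid,
                intensity=total,
                area=int(region.area),
            )
        )
    spots.sort(key=lambda s: min(s.mask))
    return spots


@dataclass
class IsoformCallTable:
    """Per-image isoform calls from CDS/IRES colocalization.

    ``n_colocalized`` CDS spots overlap an IRES spot (long 5' UTR isoform),
    ``n_cds_only`` do not (short isoform). ``n_ires_only`` counts IRES spots
    with no CDS partner — a QC channel expected near zero, since every
    long-isoform molecule also carries the CDS target. Conservation:
    n_colocalized + n_cds_only equals the number of detected CDS spots.
    """

    n_colocalized: int
    n_cds_only: int
    n_ires_only: int
    n_neg_spots: int = 0
    embryo_id: str = ""
    region_label: str = ""

    @property
    def n_cds(self) -> int:
        return self.n_colocalized + self.n_cds_only


def classify_colocalization(
    cds_spots: list[Spot],
    ires_spots: list[Spot],
    min_overlap_px: int = 1,
    embryo_id: str = "",
    region_label: str = "",
) -> IsoformCallTable:
    """Classify CDS spots as long (IRES overlap) or short (CDS-only) isoform.

    A CDS spot is long iff its mask shares at least ``min_overlap_px`` pixels
    with the union of all IRES masks; it is counted once no matter how many
    IRES spots it touches, while one IRES spot may support several CDS spots.
    The result is invariant to the ordering of either spot list.
    """
    ires_union: set[tuple[int, int]] = set()
    for spot in ires_spots:
        ires_union |= spot.mask
    n_coloc = sum(
        1 for spot in cds_spots if len(spot.mask & ires_union) >= min_overlap_px
    )
    cds_union: set[tuple[int, int]] = set()
    for spot in cds_spots:
        cds_union |= spot.mask
    n_ires_only = sum(
        1 for spot in ires_spots if len(spot.mask & cds_union) < min_overlap_px
    )
    return IsoformCallTable(
        n_colocalized=n_coloc,
        n_cds_only=len(cds_spots) - n_coloc,
        n_ires_only=n_ires_only,
        embryo_id=embryo_id,
        region_label=region_label,
    )


def negcontrol_qc(
    image: ImageStack,
    params: DetectionParams | None = None,
    max_density_fraction: float = 0.1,
) -> dict:
    """Negative-control probe QC: spot density on NEG vs CDS channel.

    Runs the same detector on the negative-control channel and flags the
    image FAIL when NEG spot density (spots per megapixel) exceeds
    ``max_density_fraction`` of the CDS-channel density. Returns a verdict
    dict; missing NEG channel yields verdict ``not assessed``.
    """
    if "NEG" not in image.channels:
        return {"verdict": "not assessed", "reason": "NEG channel missing"}
    params = params or DetectionParams()
    mpx = image.shape[0] * image.shape[1] / 1e6
    neg_density = len(detect_spots(image, "NEG", params)) / mpx
    cds_density = (
        len(detect_spots(image, "CDS", params)) / mpx
        if "CDS" in image.channels
        else float("nan")
    )
    if np.isnan(cds_density) or cds_density == 0:
        verdict = "PASS" if neg_density == 0 else "FAIL"
    else:
        verdict = "PASS" if neg_density <= max_density_fraction * cds_density else "FAIL"
    return {
        "verdict": verdict,
        "neg_density_per_mpx": neg_density,
        "cds_density_per_mpx": cds_density,
    }


@dataclass
class RegionSummary:
    """Long-isoform proportion per embryo and its mean ± SD across embryos."""

    region_label: str
    proportions: dict[str, float] = field(default_factory=dict)  # embryo -> long fraction
    excluded_embryos: list[str] = field(default_factory=list)

    @property
    def n_embryos(self) -> int:
        return len(self.proportions)

    @property
    def mean(self) -> float:
        if not self.proportions:
            return float("nan")
        return float(np.mean(list(self.proportions.values())))

    @property
    def sd(self) -> float:
        vals = list(self.proportions.values())
        if len(vals) < 2:
            return float("nan") if not vals else 0.0
        return float(np.std(vals, ddof=1))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"region": self.region_label, "embryo": e, "long_fraction": p}
                for e, p in sorted(self.proportions.items())
            ]
        )


def pool_and_summarize(
    tables: list[IsoformCallTable], region_label: str | None = None
) -> RegionSummary:
    """Pool per-image counts within each embryo, then summarize across embryos.

    Per embryo the long-isoform proportion is the pooled ratio
    sum(n_colocalized) / sum(n_colocalized + n_cds_only) over its images —
    counts are pooled first, not averaged per image, so images contribute in
    proportion to their molecule counts. Embryos with zero CDS spots have an
    undefined proportion and are excluded with a flag.
    """
    if region_label is None:
        labels = {t.region_label for t in tables}
        region_label = labels.pop() if len(labels) == 1 else "mixed"
    pooled: dict[str, tuple[int, int]] = {}
    for t in tables:
        coloc, total = pooled.get(t.embryo_id, (0, 0))
        pooled[t.embryo_id] = (coloc + t.n_colocalized, total + t.n_cds)
    summary = RegionSummary(region_label=region_label)
    for embryo, (coloc, total) in pooled.items():
        if total == 0:
            summary.excluded_embryos.append(embryo)
        else:
            summary.proportions[embryo] = coloc / total
    return summary


def analyze_stack(
    image: ImageStack,
    params: DetectionParams | None = None,
    min_overlap_px: int = 1,
) -> IsoformCallTable:
    """Detect CDS and IRES spots on one stack and classify colocalization."""
    params = params or DetectionParams()
    cds = detect_spots(image, "CDS", params)
    ires = detect_spots(image, "IRES", params)
    table = classify_colocalization(
        cds,
        ires,
        min_overlap_px=min_overlap_px,
        embryo_id=image.embryo_id,
        region_label=image.region_label,
    )
    if "NEG" in image.channels:
        table.n_neg_spots = len(detect_spots(image, "NEG", params))
    return table
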