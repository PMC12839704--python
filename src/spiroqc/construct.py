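"""Build the graphical construct fed to the classifier.

The construct is assembled from a report page in two stages. First the
curves are isolated: post-bronchodilator tones (red/maroon/pink) are
masked to white, the page is converted to grayscale, only the bottom half
(where the plots live) is kept, the crop is binarized and inverted so
curve strokes are white on black, components smaller than 1000 px are
discarded, a morphological closing fills stroke gaps left by the mask,
and the two largest connected regions — the volume-time and flow-volume
curves — are cropped and stacked into a 700 × 500 panel (volume-time on
top). Second, a 200-column frame is appended on the right to form a
700 × 700 square whose three equal sections encode sex, age and BMI as
constant grays: each variable is min-max normalized to [0, 1] (age over
[10, 84] years, BMI over [15, 54] kg/m², sex man→0 / woman→1) and
multiplied by 255. The square is finally resized to the 224 × 224
three-channel input expected by standard convolutional backbones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from PIL import Image
from skimage import color as skcolor
from skimage import measure, morphology
from skimage.filters import threshold_otsu
from skimage.transform import resize as sk_resize

from .errors import InvalidParameterError, NoCurvesFoundError, StageError
from .ingest import Demographics, ReportPage

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizationSpec",
    "ConstructConfig",
    "RegionBox",
    "CurvePanel",
    "GraphicalConstruct",
    "mask_post_bd_colors",
    "extract_curve_regions",
    "compose_panel",
    "encode_demographics_frame",
    "finalize",
    "build_construct",
]

PANEL_SHAPE = (700, 500)  # rows, cols
FRAMED_SIDE = 700
INPUT_SIDE = 224
_SUBPANEL = (350, 500)  # each curve's sub-panel, rows × cols


@dataclass(frozen=True)
class NormalizationSpec:
    """Min-max bounds used to encode demographics as grays."""

    age_min: float = 10.0
    age_max: float = 84.0
    bmi_min: float = 15.0
    bmi_max: float = 54.0

    def __post_init__(self):
        if not (self.age_min < self.age_max and self.bmi_min < self.bmi_max):
            raise InvalidParameterError("normalization bounds must satisfy min < max")


@dataclass(frozen=True)
class ConstructConfig:
    """Tunables of the curve-extraction stage.

    ``min_area`` is the strict noise filter: components with area
    *strictly less than* this many pixels are discarded. ``hue_tol_deg``,
    ``sat_min`` and ``val_min`` define the red-family mask (hue within the
    tolerance of 0°/360°, covering maroon and pink). ``vt_position`` says
    which of the two surviving regions is the volume-time curve.
    """

    min_area: int = 1000
    closing_size: int = 5
    hue_tol_deg: float = 20.0
    sat_min: float = 0.20
    val_min: float = 0.20
    vt_position: str = "left"  # or "right"


@dataclass(frozen=True)
class RegionBox:
    """Half-open bounding box of a connected foreground region."""

    top: int
    left: int
    bottom: int
    right: int
    area: int

    def __post_init__(self):
        if not (self.bottom > self.top and self.right > self.left and self.area >= 1):
            raise InvalidParameterError(f"degenerate region box {self}")


@dataclass
class CurvePanel:
    """700 × 500 binary panel: volume-time curve above, flow-volume below."""

    image: np.ndarray  # uint8 {0, 255}
    #: per-curve placement (scale, panel_row_offset, panel_col_offset)
    placements: tuple = ()


@dataclass
class GraphicalConstruct:
    """The assembled network input plus inspectable intermediates."""

    panel: CurvePanel
    framed: np.ndarray  # (700, 700) uint8
    network_input: np.ndarray  # (224, 224, 3) uint8
    demographics: Demographics | None = None
    frame_grays: tuple[int, int, int] | None = None  # sex, age, bmi
    #: per-region page→panel mapping info, set by build_construct
    region_maps: list = field(default_factory=list)
    intermediates: dict = field(default_factory=dict)

    def map_page_box(self, box: tuple[int, int, int, int]):
        """Map a page-pixel box into 224 × 224 network-input coordinates.

        The box is assigned to the extracted curve region containing its
        center; returns None when it falls outside both regions.
        """
        if not self.region_maps:
            return None
        cr = (box[0] + box[2]) / 2, (box[1] + box[3]) / 2
        chosen = None
        for rm in self.region_maps:
            t, l, b, r = rm["page_box"]
            if t <= cr[0] < b and l <= cr[1] < r:
                chosen = rm
                break
        if chosen is None:  # fall back to nearest region center
            chosen = min(
                self.region_maps,
                key=lambda rm: (
                    ((rm["page_box"][0] + rm["page_box"][2]) / 2 - cr[0]) ** 2
                    + ((rm["page_box"][1] + rm["page_box"][3]) / 2 - cr[1]) ** 2
                ),
            )
        t, l, _, _ = chosen["page_box"]
        s, row_off, col_off = chosen["scale"], chosen["row_off"], chosen["col_off"]
        f = INPUT_SIDE / FRAMED_SIDE
        out = (
            ((box[0] - t) * s + row_off) * f,
            ((box[1] - l) * s + col_off) * f,
            ((box[2] - t) * s + row_off) * f,
            ((box[3] - l) * s + col_off) * f,
        )
        return tuple(int(np.clip(v, 0, INPUT_SIDE)) for v in out)


# --- stage 1: curve isolation -------------------------------------------------


def mask_post_bd_colors(
    page: ReportPage, config: ConstructConfig | None = None
) -> ReportPage:
    """White out red-family pixels (the post-bronchodilator curve).

    A pixel is red-family when its hue lies within ``hue_tol_deg`` of red
    and both saturation and value exceed their thresholds — this covers
    pure red, maroon (dark red) and pink (desaturated red) while leaving
    the blue curves and black text untouched.
    """
    config = config or ConstructConfig()
    hsv = skcolor.rgb2hsv(page.pixels)
    h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    tol = config.hue_tol_deg / 360.0
    red_family = ((h <= tol) | (h >= 1.0 - tol)) & (s >= config.sat_min) & (
        v >= config.val_min
    )
    out = page.pixels.copy()
    out[red_family] = 255
    return ReportPage(out, dpi=page.dpi, source_path=page.source_path)


def _to_gray(rgb: np.ndarray) -> np.ndarray:
    # fixed luma convention; any convention works since Otsu follows
    return rgb @ np.array([0.299, 0.587, 0.114])


def binarize_bottom_half(
    page: ReportPage, config: ConstructConfig | None = None
) -> np.ndarray:
    """Bottom half of the page as a boolean image, curves = True."""
    config = config or ConstructConfig()
    gray = _to_gray(page.pixels.astype(float))
    bottom = gray[gray.shape[0] // 2 :, :]
    if bottom.max() == bottom.min():
        raise NoCurvesFoundError("bottom half of the page is blank")
    thr = threshold_otsu(bottom)
    return bottom < thr  # invert: dark strokes become foreground


def _label_regions(binary: np.ndarray, config: ConstructConfig):
    """Filter, close and label a binary image; return labels + sorted regions."""
    # strict filter: discard area < min_area, i.e. remove area ≤ min_area - 1
    kept = morphology.remove_small_objects(binary, max_size=config.min_area - 1)
    closed = morphology.closing(
        kept, footprint=np.ones((config.closing_size, config.closing_size), bool)
    )
    labels = measure.label(closed, connectivity=2)
    regions = measure.regionprops(labels)
    # area descending; ties resolved toward the leftmost-topmost box
    regions.sort(key=lambda r: (-r.area, r.bbox[1], r.bbox[0]))
    if len(regions) >= 3 and regions[1].area == regions[2].area:
        logger.info("area tie between 2nd and 3rd regions; keeping leftmost-topmost")
    return labels, regions


def extract_curve_regions(
    page: ReportPage, config: ConstructConfig | None = None
):
    """Isolate the two curve regions from a (masked) report page.

    Returns ``(vt, fv)``, each a ``(RegionBox, crop)`` pair where the box
    is in bottom-half coordinates and the crop is the region's own binary
    mask. The two largest surviving components are assigned to
    volume-time / flow-volume by horizontal position per the layout
    convention.
    """
    config = config or ConstructConfig()
    binary = binarize_bottom_half(page, config)
    labels, regions = _label_regions(binary, config)
    if len(regions) < 2:
        raise NoCurvesFoundError(
            f"found {len(regions)} curve region(s) ≥ {config.min_area} px; need 2"
        )
    picked = regions[:2]

    out = []
    for r in picked:
        t, l, b, rr = r.bbox
        crop = labels[t:b, l:rr] == r.label
        out.append((RegionBox(t, l, b, rr, int(r.area)), crop))
    # horizontal order: leftmost is vt under the default layout
    out.sort(key=lambda pair: pair[0].left)
    if config.vt_position == "right":
        out = out[::-1]
    return out[0], out[1]


def _fit_crop(crop: np.ndarray, sub_rows: int, sub_cols: int):
    """Scale a binary crop to fit (sub_rows, sub_cols), preserving aspect."""
    h, w = crop.shape
    s = min(sub_rows / h, sub_cols / w)
    nh, nw = max(1, int(round(h * s))), max(1, int(round(w * s)))
    img = Image.fromarray((crop.astype(np.uint8)) * 255)
    resized = np.asarray(img.resize((nw, nh), Image.BILINEAR)) >= 128
    return resized, s, (sub_rows - nh) // 2, (sub_cols - nw) // 2


def compose_panel(vt_crop: np.ndarray, fv_crop: np.ndarray) -> CurvePanel:
    """Stack the two curve crops into the 700 × 500 panel.

    Each crop is scaled (aspect preserved) to fit a 350 × 500 sub-panel
    and centered: volume-time in rows [0, 350), flow-volume in [350, 700).
    """
    panel = np.zeros(PANEL_SHAPE, dtype=np.uint8)
    placements = []
    for base, crop in ((0, vt_crop), (_SUBPANEL[0], fv_crop)):
        crop = np.asarray(crop, dtype=bool)
        if crop.size == 0 or not crop.any():
            raise InvalidParameterError("empty curve crop")
        fitted, s, ro, co = _fit_crop(crop, *_SUBPANEL)
        panel[base + ro : base + ro + fitted.shape[0], co : co + fitted.shape[1]][
            fitted
        ] = 255
        placements.append((s, base + ro, co))
    return CurvePanel(image=panel, placements=tuple(placements))


# --- stage 2: demographic frame and network input -----------------------------

# three equal sections of the 700-row frame (700 is not divisible by 3;
# the first section absorbs the extra row): sex, age, BMI top to bottom
FRAME_SECTIONS = ((0, 234), (234, 467), (467, 700))


def _normalize(x: float, lo: float, hi: float) -> float:
    v = (x - lo) / (hi - lo)
    if not 0.0 <= v <= 1.0:
        logger.warning("demographic value %s outside [%s, %s]; clamped", x, lo, hi)
    return float(np.clip(v, 0.0, 1.0))


def _gray(v: float) -> int:
    return int(np.floor(v * 255 + 0.5))  # round half up


def frame_grays(demo: Demographics, spec: NormalizationSpec) -> tuple[int, int, int]:
    """Grayscale values (sex, age, bmi) for the demographic frame."""
    return (
        _gray(0.0 if demo.sex == "man" else 1.0),
        _gray(_normalize(demo.age, spec.age_min, spec.age_max)),
        _gray(_normalize(demo.bmi, spec.bmi_min, spec.bmi_max)),
    )


def encode_demographics_frame(
    panel: CurvePanel,
    demo: Demographics,
    spec: NormalizationSpec | None = None,
) -> np.ndarray:
    """Append the demographic frame, producing the 700 × 700 grayscale square."""
    spec = spec or NormalizationSpec()
    framed = np.zeros((FRAMED_SIDE, FRAMED_SIDE), dtype=np.uint8)
    framed[:, : PANEL_SHAPE[1]] = panel.image
    for (r0, r1), g in zip(FRAME_SECTIONS, frame_grays(demo, spec)):
        framed[r0:r1, PANEL_SHAPE[1] :] = g
    return framed


def finalize(framed: np.ndarray) -> np.ndarray:
    """Resize the framed square to the 224 × 224 × 3 network input.

    Bilinear with anti-aliasing, values kept on the [0, 255] scale, the
    single gray channel replicated to three identical channels
    (network-side standardization is the model's concern).
    """
    small = sk_resize(
        framed.astype(float),
        (INPUT_SIDE, INPUT_SIDE),
        order=1,
        anti_aliasing=True,
        preserve_range=True,
    )
    small = np.rint(np.clip(small, 0, 255)).astype(np.uint8)
    return np.repeat(small[..., None], 3, axis=2)


def build_construct(
    page: ReportPage,
    demo: Demographics,
    spec: NormalizationSpec | None = None,
    config: ConstructConfig | None = None,
) -> GraphicalConstruct:
    """Run the full pipeline: mask → extract → compose → encode → finalize.

    Stage failures are re-raised as :class:`StageError` naming the stage;
    all intermediates stay retrievable on the returned object.
    """
    spec = spec or NormalizationSpec()
    config = config or ConstructConfig()

    def stage(name: str, fn: Callable):
        try:
            return fn()
        except StageError:
            raise
        except Exception as exc:
            raise StageError(name, exc) from exc

    masked = stage("mask", lambda: mask_post_bd_colors(page, config))
    (vt_box, vt_crop), (fv_box, fv_crop) = stage(
        "extract", lambda: extract_curve_regions(masked, config)
    )
    panel = stage("compose", lambda: compose_panel(vt_crop, fv_crop))
    framed = stage("encode", lambda: encode_demographics_frame(panel, demo, spec))
    net_input = stage("finalize", lambda: finalize(framed))

    half = page.height // 2
    region_maps = [
        {
            "page_box": (box.top + half, box.left, box.bottom + half, box.right),
            "scale": pl[0],
            "row_off": pl[1],
            "col_off": pl[2],
        }
        for box, pl in zip((vt_box, fv_box), panel.placements)
    ]
    return GraphicalConstruct(
        panel=panel,
        framed=framed,
        network_input=net_input,
        demographics=demo,
        frame_grays=frame_grays(demo, spec),
        region_maps=region_maps,
        intermediates={
            "masked": masked,
            "vt_box": vt_box,
            "fv_box": fv_box,
            "vt_crop": vt_crop,
            "fv_crop": fv_crop,
        },
    )
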