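"""Report loading: first-page rasterization and demographic parsing.

A spirometry report arrives either as a raster image (PNG/JPEG) or as a
PDF whose pages are full-page images (the kind this package's simulator
writes). Only the first page carries the curves and demographics, so only
that page is kept. Demographics (sex, age, BMI) are parsed from labeled
text lines — either the report's own text block or a sidecar CSV.
"""

from __future__ import annotations

import csv
import io
import re
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import MissingFieldError, ReportFormatError

__all__ = [
    "ReportPage",
    "Demographics",
    "rasterize_first_page",
    "parse_demographics",
    "read_sidecar",
]


@dataclass
class ReportPage:
    """First page of a report as an RGB raster.

    Pixels are row-major with a top-left origin and 0-based indexing;
    boxes elsewhere in the package are half-open (top, left, bottom, right).
    """

    pixels: np.ndarray  # (H, W, 3) uint8
    dpi: float = 150.0
    source_path: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ReportFormatError(
                f"page must be an RGB raster, got shape {self.pixels.shape}"
            )

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class Demographics:
    """Patient fields encoded into the graphical construct."""

    sex: str  # "man" or "woman"
    age: float  # years
    bmi: float  # kg/m^2

    def __post_init__(self):
        if self.sex not in ("man", "woman"):
            raise ReportFormatError(f"sex must be 'man' or 'woman', got {self.sex!r}")
        if not (np.isfinite(self.age) and self.age > 0):
            raise ReportFormatError(f"age must be finite and positive, got {self.age}")
        if not (np.isfinite(self.bmi) and self.bmi > 0):
            raise ReportFormatError(f"bmi must be finite and positive, got {self.bmi}")


_MIN_PAGE_SIDE = 200


def _validate_page(page: ReportPage) -> ReportPage:
    if page.height < _MIN_PAGE_SIDE or page.width < _MIN_PAGE_SIDE:
        raise ReportFormatError(
            f"page too small ({page.height}x{page.width}); need ≥ {_MIN_PAGE_SIDE} px per side"
        )
    return page


def rasterize_first_page(path: str | Path, dpi: float = 150.0) -> ReportPage:
    """Load a report file and return its first page as an RGB raster.

    Raster inputs (PNG/JPEG/TIFF) are passed through unchanged, with
    grayscale promoted to three identical channels. PDF inputs must be
    image-based (one full-page embedded image per page, as produced by
    Pillow and by most scan-to-PDF tools); the first page's image is
    extracted and decoded. Vector-drawn PDFs are not supported because no
    rasterizer is bundled.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix == ".pdf":
        img = _first_pdf_image(path.read_bytes())
    else:
        try:
            img = Image.open(path)
            img.load()
        except Exception as exc:  # unreadable / not an image
            raise ReportFormatError(f"cannot read report image {path}: {exc}") from exc
    if img.mode != "RGB":
        img = img.convert("RGB")
    return _validate_page(ReportPage(np.asarray(img), dpi=dpi, source_path=str(path)))


# --- minimal image-only PDF reader -------------------------------------------
#
# Handles the narrow case of PDFs whose page content is a single embedded
# image XObject (DCTDecode = JPEG, or FlateDecode raw RGB/gray). Pillow
# writes exactly this structure, one image per page, in page order.

_STREAM_RE = re.compile(rb"<<(.*?)>>\s*stream\r?\n", re.S)


def _first_pdf_image(data: bytes) -> Image.Image:
    if not data.startswith(b"%PDF"):
        raise ReportFormatError("not a PDF file")
    for m in _STREAM_RE.finditer(data):
        header = m.group(1)
        if b"/Image" not in header:
            continue
        start = m.end()
        end = data.find(b"endstream", start)
        if end < 0:
            continue
        stream = data[start:end].rstrip(b"\r\n")
        if b"/DCTDecode" in header:
            return Image.open(io.BytesIO(stream))
        if b"/FlateDecode" in header:
            raw = zlib.decompress(stream)
            w = int(re.search(rb"/Width\s+(\d+)", header).group(1))
            h = int(re.search(rb"/Height\s+(\d+)", header).group(1))
            mode = "RGB" if b"/DeviceRGB" in header else "L"
            return Image.frombytes(mode, (w, h), raw)
        raise ReportFormatError("unsupported PDF image filter")
    raise ReportFormatError(
        "no embedded page image found; vector PDFs are not supported"
    )


# --- demographic text grammar -------------------------------------------------

_SEX_TOKENS = {
    "man": "man",
    "male": "man",
    "m": "man",
    "hombre": "man",
    "woman": "woman",
    "female": "woman",
    "f": "woman",
    "mujer": "woman",
}

# label synonyms, extensible via parse_demographics(labels=...)
_DEFAULT_LABELS = {
    "sex": ("sex", "gender", "sexo"),
    "age": ("age", "edad"),
    "bmi": ("bmi", "imc"),
}

_NUM_RE = re.compile(r"[-+]?\d+(?:[.,]\d+)?")


def parse_demographics(
    page_or_text, labels: dict[str, tuple[str, ...]] | None = None
) -> Demographics:
    """Parse sex/age/BMI from labeled report text lines.

    Accepts a plain string, or any object exposing the report's text block
    as a ``text_block`` attribute (e.g. a simulated report). Values are
    read after a ``:`` separator; decimal commas and trailing unit
    suffixes (``years``, ``kg/m2``) are tolerated. Raises
    :class:`MissingFieldError` naming the first absent field.
    """
    if isinstance(page_or_text, str):
        text = page_or_text
    elif hasattr(page_or_text, "text_block"):
        text = page_or_text.text_block
    else:
        raise MissingFieldError("sex")  # raster pages carry no text layer
    labels = labels or _DEFAULT_LABELS

    found: dict[str, str] = {}
    for line in re.split(r"[\n/;]+", text):
        if ":" not in line:
            continue
        key, _, value = line.partition(":")
        key = key.strip().lower()
        for field, synonyms in labels.items():
            if key in synonyms and field not in found:
                found[field] = value.strip()

    for field in ("sex", "age", "bmi"):
        if field not in found:
            raise MissingFieldError(field)

    sex_token = re.split(r"[\s(]", found["sex"].strip().lower())[0]
    if sex_token not in _SEX_TOKENS:
        raise ReportFormatError(f"unrecognized sex token {found['sex']!r}")

    def _number(raw: str, field: str) -> float:
        m = _NUM_RE.search(raw)
        if not m:
            raise ReportFormatError(f"cannot parse {field} from {raw!r}")
        return float(m.group(0).replace(",", "."))

    return Demographics(
        sex=_SEX_TOKENS[sex_token],
        age=_number(found["age"], "age"),
        bmi=_number(found["bmi"], "bmi"),
    )


def read_sidecar(csv_path: str | Path, report_path: str | Path) -> Demographics:
    """Look up demographics for ``report_path`` in a sidecar CSV.

    The CSV has columns ``path,sex,age,bmi``; ``path`` is matched on the
    file name so manifests survive directory moves.
    """
    name = Path(report_path).name
    with open(csv_path, newline="") as fh:
        for row in csv.DictReader(fh):
            if Path(row["path"]).name == name:
                return Demographics(
                    sex=_SEX_TOKENS[row["sex"].strip().lower()],
                    age=float(str(row["age"]).replace(",", ".")),
                    bmi=float(str(row["bmi"]).replace(",", ".")),
                )
    raise MissingFieldError("sex")
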