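"""Synthetic forced-expiration maneuvers and rendered report pages.

Real spirometry reports from clinical spirometers are not redistributable,
so this module generates labeled stand-ins end to end: a parametric
forced-expiration flow profile, optional maneuver artifacts that make the
test unacceptable (cough, early termination, submaximal effort, extra
breath), and a rendered report page with the volume-time and flow-volume
curves in the bottom half plus a demographics text block in the top half —
the layout the downstream image-construction stage expects.

The clean profile is a quarter-sine rise to peak flow followed by an
exponential decay,

    f(t) = PEF·sin(π t / (2 t_rise))          for t ≤ t_rise
    f(t) = PEF·exp(−(t − t_rise)/τ)           for t > t_rise,

rescaled so the exhaled volume (the time integral of flow) equals the
requested FVC. Two clinically meaningful knobs (PEF, FVC) control the
curve and every derived quantity has a closed form, which keeps the
generator checkable by quadrature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw, ImageFont
from scipy.integrate import cumulative_trapezoid

from .errors import InvalidParameterError, LayoutError
from .ingest import Demographics, ReportPage

__all__ = [
    "ARTIFACT_TYPES",
    "ManeuverParams",
    "Maneuver",
    "ReportLayout",
    "SyntheticReport",
    "simulate_maneuver",
    "inject_artifact",
    "render_report",
    "generate_reports",
    "generate_dataset",
]

ARTIFACT_TYPES = ("cough", "early_termination", "submaximal", "extra_breath")

#: sampling step for all simulated series, seconds
DT = 0.005


@dataclass(frozen=True)
class ManeuverParams:
    """Parameters of one simulated maneuver.

    fvc        forced vital capacity, liters
    pef        peak expiratory flow, L/s
    rise_time  time to peak flow, seconds
    decay_tau  exponential decay constant of the effort, seconds
    duration   exhalation length, seconds (≥ 6·decay_tau so the
               exponential tail is effectively complete)
    artifact   "none" or one of :data:`ARTIFACT_TYPES`
    artifact_params  artifact-specific scalars; missing keys take
               documented defaults drawn from ``seed``
    """

    fvc: float = 4.0
    pef: float = 8.0
    rise_time: float = 0.1
    decay_tau: float = 0.6
    duration: float = 6.0
    artifact: str = "none"
    artifact_params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        for name in ("fvc", "pef", "rise_time", "decay_tau", "duration"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be > 0")
        if self.duration < 6 * self.decay_tau:
            raise InvalidParameterError("duration must be ≥ 6·decay_tau")
        if self.artifact != "none" and self.artifact not in ARTIFACT_TYPES:
            raise InvalidParameterError(f"unknown artifact {self.artifact!r}")


@dataclass
class Maneuver:
    """A sampled maneuver: flow and cumulative exhaled volume over time."""

    time: np.ndarray  # seconds, uniform grid from 0
    flow: np.ndarray  # L/s
    volume: np.ndarray  # liters, cumulative quadrature of flow
    label: str  # "acceptable" | "unacceptable"
    artifact: str = "none"
    #: time interval (t0, t1) containing the injected perturbation, or None
    artifact_interval: tuple[float, float] | None = None


def simulate_maneuver(params: ManeuverParams) -> Maneuver:
    """Simulate a clean forced expiration from the parametric profile."""
    t = np.arange(0.0, params.duration + DT / 2, DT)
    rise = params.rise_time
    f = np.where(
        t <= rise,
        params.pef * np.sin(np.pi * t / (2 * rise)),
        params.pef * np.exp(-(t - rise) / params.decay_tau),
    )
    vol = cumulative_trapezoid(f, t, initial=0.0)
    scale = params.fvc / vol[-1]
    return Maneuver(time=t, flow=f * scale, volume=vol * scale, label="acceptable")


def inject_artifact(m: Maneuver, params: ManeuverParams) -> Maneuver:
    """Perturb a clean maneuver with the artifact named in ``params``.

    Defaults for unspecified artifact scalars are drawn reproducibly from
    ``params.seed``:

    - ``cough``: two opposite-sign Gaussian flow lobes (amplitude
      ``amplitude`` or ``amplitude_scale``·peak-flow, default 0.5·peak)
      centered at ``onset`` (default uniform in the last third of the
      exhalation), half-width ``width`` (default 0.08 s); the perturbation
      is exactly zero outside onset ± 3·width.
    - ``early_termination``: series truncated where volume reaches
      ``truncation_fraction``·FVC (default uniform in [0.5, 0.85]).
    - ``submaximal``: flow scaled by ``scale`` (default 0.7) and its peak
      flattened at ``flatten``·max (default 0.85).
    - ``extra_breath``: a negative-flow half-sine of ``breath_duration``
      (default 0.4 s) and amplitude ``amplitude_scale``·peak (default 0.3)
      inserted at ``onset``, after which exhalation resumes.
    """
    art = params.artifact
    if art == "none":
        raise InvalidParameterError("inject_artifact requires artifact != 'none'")
    if m.artifact != "none":
        raise InvalidParameterError("maneuver already carries an artifact")
    ap = params.artifact_params
    rng = np.random.default_rng(params.seed)
    t, flow = m.time, m.flow.copy()
    t_end = float(t[-1])
    peak = float(m.flow.max())

    if art == "cough":
        onset = float(ap.get("onset", rng.uniform(2 / 3 * t_end, 0.9 * t_end)))
        width = float(ap.get("width", 0.08))
        amp = float(ap.get("amplitude", ap.get("amplitude_scale", 0.5) * peak))
        sd = width / 2
        pert = amp * np.exp(-((t - (onset - width)) ** 2) / (2 * sd**2))
        pert -= amp * np.exp(-((t - (onset + width)) ** 2) / (2 * sd**2))
        inside = (t >= onset - 3 * width) & (t <= onset + 3 * width)
        pert[~inside] = 0.0
        flow = flow + pert
        interval = (onset - 3 * width, onset + 3 * width)
    elif art == "early_termination":
        frac = float(ap.get("truncation_fraction", rng.uniform(0.5, 0.85)))
        if not 0 < frac < 0.9:
            raise InvalidParameterError("truncation_fraction must be in (0, 0.9)")
        stop = int(np.searchsorted(m.volume, frac * m.volume[-1]))
        t, flow = t[: stop + 1], flow[: stop + 1]
        interval = (max(0.0, t[-1] - 0.3), float(t[-1]))
    elif art == "submaximal":
        scale = float(ap.get("scale", 0.7))
        if not 0 < scale < 0.8:
            raise InvalidParameterError("submaximal scale must be in (0, 0.8)")
        flow = flow * scale
        flow = np.minimum(flow, ap.get("flatten", 0.85) * flow.max())
        interval = (0.0, t_end)
    elif art == "extra_breath":
        onset = float(ap.get("onset", rng.uniform(0.3 * t_end, 0.6 * t_end)))
        dur = float(ap.get("breath_duration", 0.4))
        amp = float(ap.get("amplitude", ap.get("amplitude_scale", 0.3) * peak))
        n_ins = max(2, int(round(dur / DT)))
        lobe = -amp * np.sin(np.pi * np.arange(n_ins) / (n_ins - 1))
        i0 = int(np.searchsorted(t, onset))
        flow = np.concatenate([flow[:i0], lobe, flow[i0:]])
        t = np.arange(flow.size) * DT
        interval = (onset, onset + dur)
    else:  # pragma: no cover - guarded by ManeuverParams
        raise InvalidParameterError(art)

    vol = cumulative_trapezoid(flow, t, initial=0.0)
    return Maneuver(
        time=t,
        flow=flow,
        volume=vol,
        label="unacceptable",
        artifact=art,
        artifact_interval=interval,
    )


# --- report rendering ---------------------------------------------------------


@dataclass(frozen=True)
class ReportLayout:
    """Page geometry of the rendered synthetic report.

    Boxes are half-open (top, left, bottom, right) pixel intervals; both
    plot boxes must sit entirely in the bottom half of the page, with the
    volume-time plot to the left of the flow-volume plot.
    """

    page_width: int = 1000
    page_height: int = 1400
    dpi: float = 150.0
    vt_box: tuple[int, int, int, int] = (760, 70, 1340, 470)
    fv_box: tuple[int, int, int, int] = (760, 530, 1340, 930)
    text_origin: tuple[int, int] = (60, 60)
    line_height: int = 30
    stroke_width: int = 4
    pre_bd_color: tuple[int, int, int] = (0, 0, 255)
    post_bd_color: tuple[int, int, int] = (255, 0, 0)  # pink/maroon variants ok

    def __post_init__(self):
        half = self.page_height / 2
        for name, box in (("vt_box", self.vt_box), ("fv_box", self.fv_box)):
            top, left, bottom, right = box
            if top < half:
                raise LayoutError(f"{name} must lie in the bottom half of the page")
            if not (0 <= left < right <= self.page_width and bottom <= self.page_height):
                raise LayoutError(f"{name} outside the page")


@dataclass
class SyntheticReport:
    """A rendered report page with its ground truth attached."""

    page: ReportPage
    demographics: Demographics
    label: str
    artifact: str
    #: pixel box (top, left, bottom, right) of the rendered artifact, or None
    artifact_annotation: tuple[int, int, int, int] | None
    text_block: str
    layout: ReportLayout


def _to_pixels(box, xs, ys, xlim, ylim):
    """Map data points to (col, row) pixel coordinates inside ``box``."""
    top, left, bottom, right = box
    x0, x1 = xlim
    y0, y1 = ylim
    cols = left + (np.asarray(xs) - x0) / (x1 - x0) * (right - 1 - left)
    rows = bottom - 1 - (np.asarray(ys) - y0) / (y1 - y0) * (bottom - 1 - top)
    return np.column_stack([cols, rows])


def render_report(
    m: Maneuver,
    demo: Demographics,
    include_post_bd: bool = False,
    layout: ReportLayout | None = None,
    seed: int = 0,
) -> SyntheticReport:
    """Render a maneuver and demographics as a report page.

    The pre-bronchodilator curves are drawn in blue; when
    ``include_post_bd`` is set, a slightly weaker copy of the maneuver is
    drawn underneath in the layout's post-bronchodilator color (red by
    default) to emulate superimposed post-bronchodilator curves. The
    artifact's time interval, if any, is mapped to a pixel bounding box on
    the plot where it is visible.
    """
    layout = layout or ReportLayout()
    img = Image.new("RGB", (layout.page_width, layout.page_height), "white")
    draw = ImageDraw.Draw(img)

    # demographics text block (top half)
    try:
        font = ImageFont.load_default(size=22)
    except TypeError:  # older Pillow
        font = ImageFont.load_default()
    text_block = (
        "Spirometry Report\n"
        f"Sex: {demo.sex.capitalize()}\n"
        f"Age: {demo.age:g} years\n"
        f"BMI: {demo.bmi:g} kg/m2"
    )
    x0, y0 = layout.text_origin
    for i, line in enumerate(text_block.split("\n")):
        draw.text((x0, y0 + i * layout.line_height), line, fill="black", font=font)

    # axis limits from the pre-BD maneuver (shared by the post-BD overlay)
    t_lim = (0.0, float(m.time[-1]) * 1.05 + 1e-9)
    v_lim = (0.0, float(m.volume.max()) * 1.05 + 1e-9)
    f_lim = (min(float(m.flow.min()), 0.0) * 1.05 - 1e-9, float(m.flow.max()) * 1.05)

    def _draw_curves(mv: Maneuver, color):
        vt = _to_pixels(layout.vt_box, mv.time, mv.volume, t_lim, v_lim)
        fv = _to_pixels(layout.fv_box, mv.volume, mv.flow, v_lim, f_lim)
        for pts in (vt, fv):
            draw.line(
                [tuple(p) for p in pts], fill=color,
                width=layout.stroke_width, joint="curve",
            )

    if include_post_bd:
        rng = np.random.default_rng(seed)
        post = Maneuver(
            time=m.time,
            flow=m.flow * rng.uniform(0.85, 0.95),
            volume=m.volume * rng.uniform(0.85, 0.95),
            label=m.label,
        )
        _draw_curves(post, layout.post_bd_color)
    _draw_curves(m, layout.pre_bd_color)  # blue on top, as on real reports

    annotation = None
    if m.artifact_interval is not None:
        t0, t1 = m.artifact_interval
        sel = (m.time >= t0) & (m.time <= t1)
        if sel.any():
            if m.artifact == "early_termination":
                pts = _to_pixels(
                    layout.vt_box, m.time[sel], m.volume[sel], t_lim, v_lim
                )
            else:
                pts = _to_pixels(
                    layout.fv_box, m.volume[sel], m.flow[sel], v_lim, f_lim
                )
            pad = layout.stroke_width + 4
            annotation = (
                int(pts[:, 1].min()) - pad,
                int(pts[:, 0].min()) - pad,
                int(pts[:, 1].max()) + pad + 1,
                int(pts[:, 0].max()) + pad + 1,
            )

    page = ReportPage(np.asarray(img), dpi=layout.dpi)
    return SyntheticReport(
        page=page,
        demographics=demo,
        label=m.label,
        artifact=m.artifact,
        artifact_annotation=annotation,
        text_block=text_block,
        layout=layout,
    )


# --- dataset generation -------------------------------------------------------


def generate_reports(
    n: int,
    unacceptable_fraction: float = 0.3553,
    seed: int = 0,
    post_bd_prob: float = 0.3,
    layout: ReportLayout | None = None,
    artifact_types: Sequence[str] = ARTIFACT_TYPES,
    artifact_overrides: dict | None = None,
) -> Iterator[SyntheticReport]:
    """Yield ``n`` labeled synthetic reports.

    ``round(n · unacceptable_fraction)`` reports carry an artifact drawn
    uniformly from ``artifact_types`` (the default 35/65 split mirrors the
    class imbalance typical of spirometry training-course data).
    Demographics are uniform over the encoder's bounds — age in [10, 84]
    years, BMI in [15, 54] kg/m², sex fair Bernoulli — with no claim of
    population realism. Fully reproducible given ``seed``.
    """
    if n < 2:
        raise InvalidParameterError("n must be ≥ 2")
    if not 0 < unacceptable_fraction < 1:
        raise InvalidParameterError("unacceptable_fraction must be in (0, 1)")
    n_unacc = int(round(n * unacceptable_fraction))
    if n_unacc in (0, n):
        warnings.warn("degenerate class split: all reports share one label")

    rng = np.random.default_rng(seed)
    child_seeds = np.random.SeedSequence(seed).generate_state(2 * n) % (2**31)
    labels = np.array([1] * n_unacc + [0] * (n - n_unacc))
    rng.shuffle(labels)

    for i in range(n):
        params = ManeuverParams(
            fvc=rng.uniform(2.5, 5.5),
            pef=rng.uniform(5.0, 10.0),
            rise_time=rng.uniform(0.08, 0.15),
            decay_tau=(tau := rng.uniform(0.5, 0.9)),
            duration=max(6.0, 6 * tau),
            artifact=(
                str(rng.choice(list(artifact_types))) if labels[i] else "none"
            ),
            artifact_params=dict(artifact_overrides or {}),
            seed=int(child_seeds[2 * i]),
        )
        demo = Demographics(
            sex="woman" if rng.random() < 0.5 else "man",
            age=float(rng.integers(10, 85)),
            bmi=round(rng.uniform(15.0, 54.0), 1),
        )
        m = simulate_maneuver(params)
        if params.artifact != "none":
            m = inject_artifact(m, params)
        yield render_report(
            m,
            demo,
            include_post_bd=bool(rng.random() < post_bd_prob),
            layout=layout,
            seed=int(child_seeds[2 * i + 1]),
        )


def generate_dataset(
    out_dir: str | Path,
    n: int,
    unacceptable_fraction: float = 0.3553,
    seed: int = 0,
    post_bd_prob: float = 0.3,
    layout: ReportLayout | None = None,
    save_pdf: bool = False,
) -> pd.DataFrame:
    """Write ``n`` synthetic reports as PNGs plus a manifest CSV.

    The manifest (``manifest.csv`` in ``out_dir``) has columns
    ``path,label,sex,age,bmi,artifact`` and is byte-identical across runs
    with the same arguments. Returns the manifest as a DataFrame.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, report in enumerate(
        generate_reports(n, unacceptable_fraction, seed, post_bd_prob, layout)
    ):
        name = f"report_{i:04d}.png"
        img = Image.fromarray(report.page.pixels)
        img.save(out_dir / name)
        if save_pdf:
            img.save(out_dir / f"report_{i:04d}.pdf")
        rows.append(
            {
                "path": name,
                "label": report.label,
                "sex": report.demographics.sex,
                "age": report.demographics.age,
                "bmi": report.demographics.bmi,
                "artifact": report.artifact,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
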