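"""Synthetic fluorescence movies with known ground truth.

Emulates the statistical structure of confocal time-lapse data of fission
yeast expressing a GFP-tagged patch marker: elliptical cells with uniform
cytoplasmic autofluorescence on an unevenly illuminated (2-D Gaussian)
field, diffraction-limited endocytic patches whose molecule count follows a
triangular assembly/disassembly profile, photobleaching as a
double-exponential decay applied to everything fluorescent, and
Poisson-Gaussian camera noise on top of a constant offset.

Every renderer returns the image stack together with a :class:`GroundTruth`
record of all inputs, so downstream stages (correction, calibration,
tracking, alignment, rate fitting) can be validated against exact truth.
Absolute ADU scales are arbitrary — only ratios carry meaning — but the
defaults are chosen so signal-to-noise resembles the real acquisitions:
cytoplasm ≈ 100 ADU per pixel in the Z-sum against a 100 ADU offset and
2 ADU read noise, with patches of several thousand ADU integrated density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .core import MovieStack
from .errors import GenerationError, InvalidSpecError
from .photobleach import BleachModel

__all__ = [
    "SceneSpec",
    "CellSpec",
    "PatchSpec",
    "GroundTruth",
    "make_illumination_field",
    "render_calibration_stack",
    "render_patch_movie",
    "make_reference_images",
    "simulate_od_series",
    "triangular_trace",
    "place_cells",
    "place_patches",
]


# ----------------------------------------------------------------------
# specs
# ----------------------------------------------------------------------
@dataclass
class SceneSpec:
    """Acquisition geometry, illumination and camera model for one scene.

    ``illum_sigma`` may be left ``None``, in which case it is derived from
    ``illum_min_fraction`` so that the farthest corner of the frame sits at
    exactly that fraction of the peak illumination.  ``illum_min_fraction=1``
    means flat illumination.  The camera converts expected photon counts to
    ADU with gain ``photon_gain``; shot noise, read noise and the offset are
    each switchable off (``shot_noise=False``, ``read_noise_sd=0``,
    ``camera_offset=0``).
    """

    image_shape: tuple = (512, 512)  # (Y, X) pixels
    n_z: int = 6
    n_frames: int = 60
    frame_interval: float = 1.0  # s
    z_spacing: float = 0.6  # um
    illum_center: Optional[tuple] = None  # (y, x); default = frame center
    illum_sigma: Optional[float] = None  # px
    illum_min_fraction: float = 0.6
    camera_offset: float = 100.0  # ADU
    read_noise_sd: float = 2.0  # ADU
    photon_gain: float = 1.0  # ADU / photon
    shot_noise: bool = True
    cell_edge_sigma: float = 1.5  # px, optical blur of the cell boundary
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_z < 1 or self.n_frames < 1:
            raise InvalidSpecError("n_z and n_frames must be >= 1")
        if self.frame_interval <= 0:
            raise InvalidSpecError("frame_interval must be positive")
        if not 0 < self.illum_min_fraction <= 1:
            raise InvalidSpecError("illum_min_fraction must be in (0, 1]")
        if self.illum_sigma is not None and self.illum_sigma <= 0:
            raise InvalidSpecError("illum_sigma must be positive")
        if self.photon_gain <= 0:
            raise InvalidSpecError("photon_gain must be positive")
        if self.illum_center is None:
            self.illum_center = ((self.image_shape[0] - 1) / 2, (self.image_shape[1] - 1) / 2)

    @property
    def resolved_sigma(self) -> float:
        """Illumination sigma in pixels; ``inf`` for a flat field."""
        if self.illum_sigma is not None:
            return float(self.illum_sigma)
        if self.illum_min_fraction >= 1.0:
            return math.inf
        cy, cx = self.illum_center
        corners = [(0, 0), (0, self.image_shape[1] - 1),
                   (self.image_shape[0] - 1, 0),
                   (self.image_shape[0] - 1, self.image_shape[1] - 1)]
        d = max(math.hypot(y - cy, x - cx) for y, x in corners)
        return d / math.sqrt(2.0 * math.log(1.0 / self.illum_min_fraction))

    @classmethod
    def calibration(cls, **kw) -> "SceneSpec":
        """Single-time-point Z-stack geometry used for calibration imaging."""
        kw.setdefault("n_z", 21)
        kw.setdefault("n_frames", 1)
        return cls(**kw)


@dataclass
class CellSpec:
    """One elliptical cell with uniform cytoplasmic fluorescence.

    The expected background-corrected total fluorescence of the cell is
    ``autofluorescence_total + tagged_molecules * brightness_per_molecule``
    (ADU, summed over the footprint and all Z-sections, before illumination
    falloff and noise).
    """

    center: tuple  # (y, x) px
    axes: tuple = (18.0, 10.0)  # (semi-major, semi-minor) px
    orientation: float = 0.0  # radians
    autofluorescence_total: float = 0.0  # ADU
    tagged_molecules: float = 0.0
    brightness_per_molecule: float = 10.0  # ADU / molecule

    def __post_init__(self):
        if self.axes[0] <= 0 or self.axes[1] <= 0:
            raise InvalidSpecError("cell axes must be positive")
        if self.tagged_molecules < 0:
            raise InvalidSpecError("tagged_molecules must be >= 0")

    @property
    def total_fluorescence(self) -> float:
        return self.autofluorescence_total + self.tagged_molecules * self.brightness_per_molecule

    def footprint(self, shape) -> tuple:
        """Boolean mask of the ellipse within its bounding box.

        Returns ``(rows, cols, mask)`` slices into an image of ``shape``.
        Raises if the bounding box leaves the frame.
        """
        cy, cx = self.center
        a, b = self.axes
        r = max(a, b)
        y0, y1 = int(math.floor(cy - r)), int(math.ceil(cy + r)) + 1
        x0, x1 = int(math.floor(cx - r)), int(math.ceil(cx + r)) + 1
        if y0 < 0 or x0 < 0 or y1 > shape[0] or x1 > shape[1]:
            raise GenerationError(f"cell at {self.center} does not fit inside the frame")
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dy, dx = yy - cy, xx - cx
        c, s = math.cos(self.orientation), math.sin(self.orientation)
        u = (dx * c + dy * s) / a
        v = (-dx * s + dy * c) / b
        return slice(y0, y1), slice(x0, x1), (u * u + v * v) <= 1.0


@dataclass
class PatchSpec:
    """One endocytic patch with a triangular molecule-count profile.

    The number of tagged molecules rises linearly at ``assembly_rate`` from
    ``appear_time`` to ``peak_molecules``, then falls at
    ``disassembly_rate`` back to zero; it is zero outside that span.  The
    patch is rendered as an isotropic 2-D Gaussian spot of ``psf_sigma``
    whose centroid performs a Gaussian random walk of per-frame step SD
    ``motion_sd``.
    """

    cell_index: int
    appear_time: float  # s
    assembly_rate: float  # molecules / s
    peak_molecules: float
    disassembly_rate: float  # molecules / s
    motion_sd: float = 0.15  # px / frame
    psf_sigma: float = 1.5  # px
    position: Optional[tuple] = None  # (y, x); drawn inside the cell if None

    def __post_init__(self):
        if self.assembly_rate <= 0 or self.disassembly_rate <= 0 or self.peak_molecules <= 0:
            raise InvalidSpecError("rates and peak_molecules must be positive")

    @property
    def rise_duration(self) -> float:
        return self.peak_molecules / self.assembly_rate

    @property
    def fall_duration(self) -> float:
        return self.peak_molecules / self.disassembly_rate

    @property
    def end_time(self) -> float:
        return self.appear_time + self.rise_duration + self.fall_duration

    def molecules(self, t) -> np.ndarray:
        return triangular_trace(
            t, self.appear_time, self.assembly_rate, self.peak_molecules, self.disassembly_rate
        )


def triangular_trace(t, appear_time, assembly_rate, peak, disassembly_rate):
    """Piecewise-linear rise/fall molecule count, zero outside the event."""
    t = np.asarray(t, dtype=float)
    t_peak = appear_time + peak / assembly_rate
    t_end = t_peak + peak / disassembly_rate
    rise = assembly_rate * (t - appear_time)
    fall = peak - disassembly_rate * (t - t_peak)
    out = np.where(t < t_peak, rise, fall)
    out = np.where((t < appear_time) | (t > t_end), 0.0, out)
    return np.clip(out, 0.0, peak)


@dataclass
class GroundTruth:
    """Everything the generator knew: per-cell and per-patch truth tables.

    ``cells``:   cell_id, y, x, tagged_molecules, autofluorescence_total, ...
    ``patches``: patch_id, cell_index, appear_time, assembly_rate, ...
    ``traces``:  patch_id, frame, time, molecules, y, x (per-frame truth)
    ``bleach``:  a1, k1, a2, k2 of the applied decay
    ``calibration_slope``: ADU per molecule used for rendering
    """

    cells: pd.DataFrame
    patches: Optional[pd.DataFrame] = None
    traces: Optional[pd.DataFrame] = None
    bleach: Optional[dict] = None
    calibration_slope: float = float("nan")

    def to_csv(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.cells.to_csv(directory / "cells.csv", index=False)
        if self.patches is not None:
            self.patches.to_csv(directory / "patches.csv", index=False)
        if self.traces is not None:
            self.traces.to_csv(directory / "traces.csv", index=False)
        extra = {"calibration_slope": [self.calibration_slope]}
        if self.bleach is not None:
            extra.update({k: [v] for k, v in self.bleach.items()})
        pd.DataFrame(extra).to_csv(directory / "scene.csv", index=False)

    @classmethod
    def from_csv(cls, directory) -> "GroundTruth":
        directory = Path(directory)
        cells = pd.read_csv(directory / "cells.csv")
        patches = traces = None
        if (directory / "patches.csv").exists():
            patches = pd.read_csv(directory / "patches.csv")
        if (directory / "traces.csv").exists():
            traces = pd.read_csv(directory / "traces.csv")
        scene = pd.read_csv(directory / "scene.csv").iloc[0].to_dict()
        slope = scene.pop("calibration_slope", float("nan"))
        bleach = scene if scene else None
        return cls(cells=cells, patches=patches, traces=traces,
                   bleach=bleach, calibration_slope=slope)


# ----------------------------------------------------------------------
# rendering
# ----------------------------------------------------------------------
def make_illumination_field(spec: SceneSpec) -> np.ndarray:
    """Multiplicative illumination field: isotropic 2-D Gaussian, peak 1.

    The field equals 1 at ``illum_center`` and ``exp(-d^2 / (2 sigma^2))``
    at distance ``d``; an infinite sigma (flat limit) gives all ones.
    """
    sigma = spec.resolved_sigma
    y, x = spec.image_shape
    if not math.isfinite(sigma):
        return np.ones((y, x))
    cy, cx = spec.illum_center
    yy, xx = np.mgrid[0:y, 0:x]
    d2 = (yy - cy) ** 2 + (xx - cx) ** 2
    return np.exp(-d2 / (2.0 * sigma**2))


def _cytoplasm_image(spec: SceneSpec, cells: Sequence[CellSpec]) -> np.ndarray:
    """Z-summed noiseless cell signal (before illumination), checking overlap.

    The hard-edged ellipse is blurred by ``cell_edge_sigma`` to mimic the
    optical spread of the cell boundary; the blur conserves each cell's
    total fluorescence (cells sit away from the frame border).
    """
    img = np.zeros(spec.image_shape)
    occupancy = np.zeros(spec.image_shape, dtype=bool)
    for cell in cells:
        rows, cols, mask = cell.footprint(spec.image_shape)
        if (occupancy[rows, cols] & mask).any():
            raise GenerationError("cell ellipses overlap; calibration assumes separable cells")
        occupancy[rows, cols] |= mask
        area = mask.sum()
        img[rows, cols] += mask * (cell.total_fluorescence / area)
    if spec.cell_edge_sigma > 0:
        img = gaussian_filter(img, spec.cell_edge_sigma)
    return img


def _add_camera_noise(signal: np.ndarray, spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Poisson shot noise + Gaussian read noise + constant offset, in ADU."""
    out = signal
    if spec.shot_noise:
        photons = np.clip(signal, 0, None) / spec.photon_gain
        out = rng.poisson(photons).astype(float) * spec.photon_gain
    out = out + spec.camera_offset
    if spec.read_noise_sd > 0:
        out = out + rng.normal(0.0, spec.read_noise_sd, size=out.shape)
    return out


def _z_weights(n_z: int) -> np.ndarray:
    """How a diffraction-limited spot distributes over the Z-sections.

    A Gaussian axial profile centered on the stack (SD one section),
    normalized to sum 1 so integrated intensity is conserved.
    """
    z = np.arange(n_z, dtype=float)
    w = np.exp(-0.5 * (z - (n_z - 1) / 2) ** 2)
    return w / w.sum()


def render_calibration_stack(spec: SceneSpec, cells: Sequence[CellSpec]):
    """Render a single-time-point Z-stack of well-separated cells.

    Cell fluorescence is spread uniformly over the footprint and equally
    across the Z-sections, then multiplied by the local illumination factor
    and passed through the camera noise model.

    Returns ``(MovieStack with n_frames=1, GroundTruth)``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    illum = make_illumination_field(spec)
    signal2d = _cytoplasm_image(spec, cells) * illum
    per_z = signal2d / spec.n_z
    data = np.empty((1, spec.n_z, *spec.image_shape))
    for z in range(spec.n_z):
        data[0, z] = _add_camera_noise(per_z, spec, rng)
    gt = GroundTruth(
        cells=_cells_table(cells),
        calibration_slope=cells[0].brightness_per_molecule if cells else float("nan"),
    )
    stack = MovieStack(data, frame_interval=spec.frame_interval, z_spacing=spec.z_spacing,
                       meta={"kind": "calibration"})
    return stack, gt


def render_patch_movie(
    spec: SceneSpec,
    cells: Sequence[CellSpec],
    patches: Sequence[PatchSpec],
    bleach: Optional[BleachModel] = None,
):
    """Render a time-lapse movie of cells containing endocytic patches.

    Per frame, each patch contributes ``molecules(t) * brightness * decay(t)
    * illumination`` as a 2-D Gaussian spot (kernel normalized to sum 1, so
    integrated intensity is exactly conserved), distributed over Z; the
    cytoplasmic autofluorescence bleaches by the same factor.

    Returns ``(MovieStack, GroundTruth)`` where the ground truth includes
    the exact per-frame molecule counts and centroids of every patch.
    """
    if bleach is None:
        bleach = BleachModel.identity()
    rng = np.random.default_rng(spec.rng_seed)
    for p in patches:
        if not 0 <= p.cell_index < len(cells):
            raise InvalidSpecError(f"patch references nonexistent cell {p.cell_index}")

    illum = make_illumination_field(spec)
    cyto2d = _cytoplasm_image(spec, cells) * illum
    times = np.arange(spec.n_frames) * spec.frame_interval
    decay = bleach.decay(times)
    zw = _z_weights(spec.n_z)

    # patch positions: fixed start (inside the host cell) + random walk
    starts = []
    for p in patches:
        if p.position is not None:
            starts.append(np.asarray(p.position, dtype=float))
        else:
            cell = cells[p.cell_index]
            r = 0.5 * min(cell.axes)
            ang = rng.uniform(0, 2 * math.pi)
            rad = r * math.sqrt(rng.uniform())
            starts.append(np.asarray(cell.center) + rad * np.array([math.sin(ang), math.cos(ang)]))
    walks = []
    for p, s in zip(patches, starts):
        steps = rng.normal(0.0, p.motion_sd, size=(spec.n_frames, 2)) if p.motion_sd > 0 \
            else np.zeros((spec.n_frames, 2))
        walks.append(s + np.cumsum(steps, axis=0) - steps[0])

    brightness = cells[patches[0].cell_index].brightness_per_molecule if patches else (
        cells[0].brightness_per_molecule if cells else float("nan"))

    data = np.empty((spec.n_frames, spec.n_z, *spec.image_shape))
    trace_rows = []
    for f in range(spec.n_frames):
        frame2d = cyto2d * decay[f]
        for pid, (p, walk) in enumerate(zip(patches, walks)):
            n_mol = float(p.molecules(times[f]))
            y0, x0 = walk[f]
            trace_rows.append(
                {"patch_id": pid, "frame": f, "time": times[f],
                 "molecules": n_mol, "y": y0, "x": x0}
            )
            if n_mol <= 0:
                continue
            bpm = cells[p.cell_index].brightness_per_molecule
            total = n_mol * bpm * decay[f] * _bilinear(illum, y0, x0)
            _add_spot(frame2d, y0, x0, p.psf_sigma, total, spec.image_shape)
        per_z = frame2d[None, :, :] * zw[:, None, None]
        for z in range(spec.n_z):
            data[f, z] = _add_camera_noise(per_z[z], spec, rng)

    gt = GroundTruth(
        cells=_cells_table(cells),
        patches=pd.DataFrame(
            [{"patch_id": i, "cell_index": p.cell_index, "appear_time": p.appear_time,
              "assembly_rate": p.assembly_rate, "peak_molecules": p.peak_molecules,
              "disassembly_rate": p.disassembly_rate, "y0": s[0], "x0": s[1]}
             for i, (p, s) in enumerate(zip(patches, starts))]
        ),
        traces=pd.DataFrame(trace_rows),
        bleach={"a1": bleach.a1, "k1": bleach.k1, "a2": bleach.a2, "k2": bleach.k2},
        calibration_slope=brightness,
    )
    stack = MovieStack(data, frame_interval=spec.frame_interval, z_spacing=spec.z_spacing,
                       meta={"kind": "movie"})
    return stack, gt


def _bilinear(img: np.ndarray, y: float, x: float) -> float:
    """Bilinear sample of a 2-D array at a sub-pixel position (clamped)."""
    y = min(max(y, 0.0), img.shape[0] - 1.0)
    x = min(max(x, 0.0), img.shape[1] - 1.0)
    y0, x0 = int(y), int(x)
    y1, x1 = min(y0 + 1, img.shape[0] - 1), min(x0 + 1, img.shape[1] - 1)
    fy, fx = y - y0, x - x0
    return float(
        img[y0, x0] * (1 - fy) * (1 - fx) + img[y0, x1] * (1 - fy) * fx
        + img[y1, x0] * fy * (1 - fx) + img[y1, x1] * fy * fx
    )


def _add_spot(img: np.ndarray, y0: float, x0: float, sigma: float, total: float, shape):
    """Add a 2-D Gaussian spot of integrated intensity ``total`` in place."""
    r = int(math.ceil(4 * sigma))
    ya, yb = max(int(y0) - r, 0), min(int(y0) + r + 1, shape[0])
    xa, xb = max(int(x0) - r, 0), min(int(x0) + r + 1, shape[1])
    yy, xx = np.mgrid[ya:yb, xa:xb]
    kern = np.exp(-((yy - y0) ** 2 + (xx - x0) ** 2) / (2.0 * sigma**2))
    ksum = kern.sum()
    if ksum > 0:
        img[ya:yb, xa:xb] += kern * (total / ksum)


def _cells_table(cells: Sequence[CellSpec]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"cell_id": i, "y": c.center[0], "x": c.center[1],
          "semi_major": c.axes[0], "semi_minor": c.axes[1],
          "orientation": c.orientation,
          "tagged_molecules": c.tagged_molecules,
          "autofluorescence_total": c.autofluorescence_total,
          "brightness_per_molecule": c.brightness_per_molecule}
         for i, c in enumerate(cells)]
    )


def make_reference_images(spec: SceneSpec, flat_amplitude: float = 1000.0,
                          noise: bool = False, seed: Optional[int] = None):
    """Dark-frame and flat-field reference images matching a scene.

    The dark frame is the camera offset; the flat field is the illumination
    Gaussian scaled to ``flat_amplitude`` plus the offset.  With
    ``noise=True`` both carry read noise (references are normally averages
    of many exposures, so noise defaults to off).
    """
    illum = make_illumination_field(spec)
    dark = np.full(spec.image_shape, spec.camera_offset)
    flat = flat_amplitude * illum + spec.camera_offset
    if noise:
        rng = np.random.default_rng(spec.rng_seed if seed is None else seed)
        dark = dark + rng.normal(0, spec.read_noise_sd, spec.image_shape)
        flat = flat + rng.normal(0, spec.read_noise_sd, spec.image_shape)
    return dark, flat


# ----------------------------------------------------------------------
# scene layout helpers
# ----------------------------------------------------------------------
def place_cells(
    spec: SceneSpec,
    n_cells: int,
    rng: np.random.Generator,
    axes: tuple = (18.0, 10.0),
    autofluorescence_per_pixel: float = 60.0,
    tagged_molecules: float = 0.0,
    brightness_per_molecule: float = 10.0,
) -> list:
    """Place non-overlapping cells on a jittered grid.

    ``autofluorescence_per_pixel`` is the approximate Z-summed cytoplasmic
    brightness in ADU per footprint pixel; the per-cell total scales with
    the ellipse area so cells of different sizes look equally bright.
    """
    margin = max(axes) + 4
    pitch = 2 * max(axes) + 14  # keeps dilated measurement regions separate
    ys = np.arange(margin, spec.image_shape[0] - margin, pitch)
    xs = np.arange(margin, spec.image_shape[1] - margin, pitch)
    sites = [(y, x) for y in ys for x in xs]
    if len(sites) < n_cells:
        raise GenerationError(
            f"cannot place {n_cells} non-overlapping cells in {spec.image_shape}"
        )
    rng.shuffle(sites)
    area = math.pi * axes[0] * axes[1]
    cells = []
    for y, x in sites[:n_cells]:
        jitter = rng.uniform(-2, 2, size=2)
        cells.append(
            CellSpec(
                center=(float(y + jitter[0]), float(x + jitter[1])),
                axes=axes,
                orientation=float(rng.uniform(0, math.pi)),
                autofluorescence_total=autofluorescence_per_pixel * area,
                tagged_molecules=tagged_molecules,
                brightness_per_molecule=brightness_per_molecule,
            )
        )
    return cells


def place_patches(
    spec: SceneSpec,
    cells: Sequence[CellSpec],
    n_patches: int,
    rng: np.random.Generator,
    assembly_rate: float = 50.0,
    peak_molecules: float = 500.0,
    disassembly_rate: float = 40.0,
    motion_sd: float = 0.15,
    psf_sigma: float = 1.5,
    min_separation: float = 12.0,
    time_margin: float = 2.0,
) -> list:
    """Assign complete (fully visible) patches to cells, one per cell site.

    Appear times are drawn so each triangular profile starts and ends at
    least ``time_margin`` seconds inside the movie; positions keep at least
    ``min_separation`` pixels between patches so tracks never overlap.
    """
    duration = (spec.n_frames - 1) * spec.frame_interval
    lifetime = peak_molecules / assembly_rate + peak_molecules / disassembly_rate
    latest = duration - time_margin - lifetime
    if latest < time_margin:
        raise GenerationError("patch lifetime does not fit inside the movie")
    positions: list = []
    patches = []
    order = list(range(len(cells))) * ((n_patches // max(len(cells), 1)) + 1)
    for i in range(n_patches):
        ci = order[i]
        cell = cells[ci]
        for _ in range(200):
            r = 0.6 * min(cell.axes)
            ang = rng.uniform(0, 2 * math.pi)
            rad = r * math.sqrt(rng.uniform())
            pos = (cell.center[0] + rad * math.sin(ang), cell.center[1] + rad * math.cos(ang))
            if all(math.hypot(pos[0] - q[0], pos[1] - q[1]) >= min_separation for q in positions):
                break
        else:
            raise GenerationError("could not place patches with the requested separation")
        positions.append(pos)
        patches.append(
            PatchSpec(
                cell_index=ci,
                appear_time=float(rng.uniform(time_margin, latest)),
                assembly_rate=assembly_rate,
                peak_molecules=peak_molecules,
                disassembly_rate=disassembly_rate,
                motion_sd=motion_sd,
                psf_sigma=psf_sigma,
                position=pos,
            )
        )
    return patches


# ----------------------------------------------------------------------
# growth curves
# ----------------------------------------------------------------------
def simulate_od_series(
    rate: float,
    od0: float,
    times,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential liquid-culture growth: ``OD(t) = od0 * 2**(rate * t)``.

    ``rate`` is in doublings per hour and ``times`` in hours.  Noise is
    multiplicative lognormal: ``noise_sd`` is the SD of ln(OD), i.e. the
    coefficient of variation of the measurement.
    """
    if rate < 0:
        raise InvalidSpecError("rate must be >= 0")
    if od0 <= 0:
        raise InvalidSpecError("od0 must be positive")
    times = np.asarray(times, dtype=float)
    od = od0 * np.power(2.0, rate * times)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        od = od * np.exp(rng.normal(0.0, noise_sd, size=od.shape))
    return pd.DataFrame({"time": times, "od": od})
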