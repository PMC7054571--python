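"""Deterministic generator of supratemporal-plane-like folded surface patches.

Real white/pial surfaces of the auditory cortex are not redistributable, so
the test bed builds small synthetic patches that reproduce the features the
pipeline depends on: 1–3 oblique transverse ridges (single HG, common-stem
duplication, full posterior duplication morphotypes), a curvature field
with the FreeSurfer sign convention, a four-ROI Destrieux-style
parcellation (HG, HS, PT, posterior lateral sulcus), optional thin-strip
artifacts and optional atlas-style labelling-error injections.

Geometry: a regular (nx × ny) grid over an (Lx × Ly) mm extent, x running
medial (0) → lateral (Lx), y posterior (−Ly/2) → anterior (+Ly/2), with a
height field that is the pointwise maximum of Gaussian ridge profiles,
Gaussian-smoothed to remove crease artifacts, plus smoothed vertical
jitter.  The pial surface is the white surface offset along vertex normals
by the thickness field.  Curvature is computed with the same discrete
operator the pipeline uses, so fixtures and real data are interchangeable;
the analytic height-field curvature is kept as an internal cross-check.

Labelling errors are injected into the parcellation only — they are atlas
errors, not surface errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import gaussian_filter

from . import mesh
from .errors import ParameterError
from .pipeline import DEFAULT_ROI_NAMES
from .types import CorticalParcellation, TriangleSurface, VertexScalarField

ROI_COLORS = ((220, 20, 20), (20, 220, 20), (20, 20, 220), (220, 220, 20))

#: height-field smoothing (mm) applied after combining ridge components
SMOOTH_MM = 1.0
#: correlation length (mm) of the vertical jitter
NOISE_SMOOTH_MM = 2.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Generation parameters for one synthetic hemisphere patch.

    Defaults describe a realistic supratemporal plane at ~0.5 mm vertex
    spacing: a 60 × 45 mm patch, ridges of 6 mm amplitude and 4 mm Gaussian
    width running mediolaterally at 15° obliquity, cortical thickness
    2.5 ± 0.3 mm, and 0.05 mm of smooth vertical jitter.
    """

    morphotype: str = "single"            # {single, csd, fpd}
    grid: tuple[int, int] = (120, 90)     # (nx, ny) vertices
    extent: tuple[float, float] = (60.0, 45.0)  # (mm, mm)
    ridge_amplitude: float = 6.0          # mm
    ridge_width: float = 4.0              # Gaussian sigma, mm
    ridge_obliquity: float = 15.0         # degrees
    ridge1_y: float = 7.0                 # anterior ridge axis offset, mm
    ridge2_y: float = -7.0                # posterior ridge axis offset, mm
    sulcus_intermedius_span: float = 0.4  # csd: fraction split from lateral end
    thin_strip: tuple[int, str] | None = None   # (width_vertices, "posterior")
    exclude_medial_hg: bool = False
    spill_into_sulcus: bool = False
    split_csd_to_pt: bool = False
    thickness_mean: float = 2.5           # mm
    thickness_sd: float = 0.3             # mm
    noise_sd: float = 0.05                # mm vertical jitter
    hemisphere: str = "left"
    roi_names: tuple[str, str, str, str] = DEFAULT_ROI_NAMES
    medial_error_extent: float = 0.2      # fraction of Lx moved by exclude_medial_hg
    seed: int = 0

    def validate(self) -> None:
        if self.morphotype not in ("single", "csd", "fpd"):
            raise ParameterError(f"unknown morphotype {self.morphotype!r}")
        if self.grid[0] < 20 or self.grid[1] < 20:
            raise ParameterError("grid must be at least 20×20")
        if self.morphotype == "csd" and not 0 < self.sulcus_intermedius_span < 1:
            raise ParameterError(
                "csd sulcus_intermedius_span must lie strictly in (0, 1), "
                f"got {self.sulcus_intermedius_span}"
            )
        for name, val in (
            ("extent", min(self.extent)),
            ("ridge_amplitude", self.ridge_amplitude),
            ("ridge_width", self.ridge_width),
            ("thickness_mean", self.thickness_mean),
        ):
            if val <= 0:
                raise ParameterError(f"{name} must be positive, got {val}")
        if self.thickness_sd < 0 or self.noise_sd < 0:
            raise ParameterError("thickness_sd and noise_sd must be ≥ 0")
        if self.thin_strip is not None and self.thin_strip[0] < 1:
            raise ParameterError("thin_strip width must be ≥ 1 vertex")


@dataclass
class GroundTruth:
    """Generator-side truth for scoring a segmentation.

    gyrus_id: 0 = sulcal/flat, 1 = anterior gyrus (incl. the common stem),
    2 = posterior gyrus/duplication.  ``true_hg`` is gyrus 1, plus gyrus 2
    for the csd morphotype (duplications sharing a common stem belong to
    HG; fully separated posterior duplications do not).
    """

    gyrus_id: np.ndarray
    true_hg: np.ndarray
    crest: dict[int, np.ndarray]
    analytic_mean_curv: np.ndarray
    boundary: np.ndarray
    injected: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class SyntheticSubject:
    """Everything the pipeline consumes for one synthetic hemisphere."""

    white: TriangleSurface
    pial: TriangleSurface
    curv: VertexScalarField
    thickness: VertexScalarField
    parc: CorticalParcellation
    truth: GroundTruth
    spec: SyntheticSpec


def _grid_faces(nx: int, ny: int) -> np.ndarray:
    """Two CCW triangles per cell; normals point +z for a flat sheet."""
    iy, ix = np.meshgrid(np.arange(ny - 1), np.arange(nx - 1), indexing="ij")
    v = (iy * nx + ix).ravel()
    t1 = np.stack([v, v + 1, v + nx], axis=1)
    t2 = np.stack([v + 1, v + nx + 1, v + nx], axis=1)
    return np.concatenate([t1, t2]).astype(np.int64)


def _smoothed_noise(shape, rng: np.random.Generator, sd: float,
                    smooth_px: float) -> np.ndarray:
    if sd <= 0:
        return np.zeros(shape)
    raw = rng.standard_normal(shape)
    sm = gaussian_filter(raw, smooth_px, mode="nearest")
    s = sm.std()
    return sm * (sd / s) if s > 0 else np.zeros(shape)


def _analytic_mean_curvature(height: np.ndarray, dx: float, dy: float) -> np.ndarray:
    """FreeSurfer-signed mean curvature of the graph z = h(x, y)."""
    hy, hx = np.gradient(height, dy, dx)
    hyy, hyx = np.gradient(hy, dy, dx)
    _hxy, hxx = np.gradient(hx, dy, dx)
    num = (1 + hx**2) * hyy - 2 * hx * hy * hyx + (1 + hy**2) * hxx
    den = 2 * (1 + hx**2 + hy**2) ** 1.5
    return num / den  # hxx+hyy < 0 at a convex crest → negative, as required


def generate_subject(spec: SyntheticSpec) -> SyntheticSubject:
    """Generate one synthetic hemisphere patch with ground truth.

    Bit-identical output for identical specs (all randomness flows from
    ``spec.seed``).
    """
    spec.validate()
    nx, ny = spec.grid
    lx, ly = spec.extent
    dx, dy = lx / (nx - 1), ly / (ny - 1)
    rng = np.random.default_rng(spec.seed)

    xs = np.linspace(0.0, lx, nx)
    ys = np.linspace(-ly / 2, ly / 2, ny)
    Y, X = np.meshgrid(ys, xs, indexing="ij")   # (ny, nx) grids

    theta = np.deg2rad(spec.ridge_obliquity)
    slope, cos_t = np.tan(theta), np.cos(theta)
    amp, sigma = spec.ridge_amplitude, spec.ridge_width

    def axis_y(y0: float) -> np.ndarray:
        return y0 + slope * (X - lx / 2)

    # perpendicular signed distance to each ridge axis (positive = anterior)
    d1 = (Y - axis_y(spec.ridge1_y)) * cos_t
    two_ridges = spec.morphotype in ("csd", "fpd")
    d2 = (Y - axis_y(spec.ridge2_y)) * cos_t if two_ridges else None

    components = [amp * np.exp(-(d1**2) / (2 * sigma**2))]
    if two_ridges:
        components.append(amp * np.exp(-(d2**2) / (2 * sigma**2)))

    stem_x = None
    if spec.morphotype == "csd":
        # connector ridge running anteroposteriorly at the centre of the
        # medial (1 − span) stretch: keeps the two transverse ridges
        # curvature-connected through a negative-mean-curvature saddle
        stem_end = (1 - spec.sulcus_intermedius_span) * lx
        stem_x = stem_end / 2
        between = np.clip(Y - axis_y(spec.ridge1_y), 0, None) + \
            np.clip(axis_y(spec.ridge2_y) - Y, 0, None)
        taper = np.exp(-(between**2) / (2 * sigma**2))
        components.append(
            amp * np.exp(-((X - stem_x) ** 2) / (2 * sigma**2)) * taper
        )

    smooth_px = SMOOTH_MM / dx
    strip_x = None
    if spec.thin_strip is not None:
        width_v, _edge = spec.thin_strip
        sigma_target = max(0.4 * width_v * dx, 0.3)
        sigma_pre = np.sqrt(max(sigma_target**2 - SMOOTH_MM**2, 0.04))
        strip_amp = 2.0 * sigma_target / sigma_pre
        strip_x = 0.8 * lx
        below = Y < axis_y(spec.ridge1_y)
        components.append(
            np.where(below, strip_amp *
                     np.exp(-((X - strip_x) ** 2) / (2 * sigma_pre**2)), 0.0)
        )

    height = np.maximum.reduce(components)
    height = gaussian_filter(height, smooth_px, mode="nearest")
    height = height + _smoothed_noise(height.shape, rng, spec.noise_sd,
                                      NOISE_SMOOTH_MM / dx)

    coords = np.column_stack([X.ravel(), Y.ravel(), height.ravel()])
    faces = _grid_faces(nx, ny)
    white = TriangleSurface(coords=coords, faces=faces,
                            hemisphere=spec.hemisphere, surface_kind="white")

    # thickness field: smooth spatial variation around the mean, clipped > 0
    th = spec.thickness_mean + _smoothed_noise(
        height.shape, rng, spec.thickness_sd, NOISE_SMOOTH_MM / dx)
    th = np.clip(th, 0.2, None).ravel()
    thickness = VertexScalarField(values=th, kind="thickness")

    normals = mesh.vertex_normals(white)
    pial = TriangleSurface(coords=coords + normals * th[:, None], faces=faces,
                           hemisphere=spec.hemisphere, surface_kind="pial")

    curv_field, _ = mesh.discrete_curvatures(white)
    curv = VertexScalarField(values=curv_field.values, kind="mean_curvature")

    sigma_eff = np.sqrt(sigma**2 + SMOOTH_MM**2)
    band = 0.95 * sigma_eff           # truth band: inside the inflection line
    roi_band = 1.5 * sigma            # coarser atlas-style ROI band
    hs_width = 4.0
    lat_fis_x = 5.0

    gyrus_id = np.zeros(height.shape, dtype=np.int64)
    gyrus_id[np.abs(d1) <= band] = 1
    if two_ridges:
        gyrus_id[np.abs(d2) <= band] = 2
    stem_mask = np.zeros(height.shape, dtype=bool)
    if spec.morphotype == "csd":
        stem_mask = (
            (np.abs(X - stem_x) <= band)
            & (Y <= axis_y(spec.ridge1_y))
            & (Y >= axis_y(spec.ridge2_y))
        )
        gyrus_id[stem_mask & (gyrus_id == 0)] = 1

    # ---- parcellation (ids 0..3 = HG, HS, PT, posterior lateral sulcus)
    HG, HS, PT, LF = 0, 1, 2, 3
    roi = np.full(height.shape, -1, dtype=np.int64)
    if spec.morphotype == "single":
        roi[(d1 < -roi_band) & (d1 >= -roi_band - hs_width)] = HS
        roi[d1 < -roi_band - hs_width] = PT
        roi[np.abs(d1) <= roi_band] = HG
    elif spec.morphotype == "csd":
        roi[(d2 < -roi_band) & (d2 >= -roi_band - hs_width)] = HS
        roi[d2 < -roi_band - hs_width] = PT
        between = (d1 < -roi_band) & (d2 > roi_band)
        stem_end = (1 - spec.sulcus_intermedius_span) * lx
        roi[between & (X > stem_end)] = HS      # sulcus intermedius
        roi[between & (X <= stem_end)] = HG     # common stem territory
        roi[np.abs(d1) <= roi_band] = HG
        roi[np.abs(d2) <= roi_band] = HG
    else:  # fpd: posterior duplication correctly ascribed to PT
        roi[(d1 < -roi_band) & (d2 > roi_band)] = HS
        roi[d2 < -roi_band - hs_width] = PT
        roi[(d2 < -roi_band) & (d2 >= -roi_band - hs_width)] = PT
        roi[np.abs(d2) <= roi_band] = PT
        roi[np.abs(d1) <= roi_band] = HG
    roi[(X <= lat_fis_x) & (roi != HG)] = LF

    injected: dict[str, np.ndarray] = {}
    if spec.spill_into_sulcus:
        # atlas gyrus label spilling over into the adjacent sulcus
        spill = (d1 < -roi_band) & (d1 >= -1.2 * roi_band)
        injected["spilled_sulcus"] = np.flatnonzero(spill.ravel())
        roi[spill] = HG
    if spec.exclude_medial_hg:
        # the most medial portion of HG erroneously excluded from the
        # gyrus ROI and swallowed by the lateral-sulcus label
        moved = (roi == HG) & (X <= spec.medial_error_extent * lx)
        injected["excluded_medial"] = np.flatnonzero(moved.ravel())
        roi[moved] = LF
    if spec.split_csd_to_pt:
        if spec.morphotype != "csd":
            raise ParameterError("split_csd_to_pt requires the csd morphotype")
        moved = (np.abs(d2) <= roi_band) & (np.abs(d1) > roi_band) & ~stem_mask
        injected["csd_to_pt"] = np.flatnonzero(moved.ravel())
        roi[moved] = PT

    roi_table = {
        rid: (name, ROI_COLORS[rid])
        for rid, name in enumerate(spec.roi_names)
    }
    parc = CorticalParcellation(vertex_roi=roi.ravel(), roi_table=roi_table)

    gid = gyrus_id.ravel()
    true_ids = (1, 2) if spec.morphotype == "csd" else (1,)
    true_hg = np.flatnonzero(np.isin(gid, true_ids))
    boundary = mesh.boundary_vertices(white)
    # crest = rows nearest each ridge axis; the open-boundary ring is
    # excluded (the discrete curvature operator is undefined there)
    crest: dict[int, np.ndarray] = {}
    crest[1] = np.setdiff1d(
        np.flatnonzero((np.abs(d1) <= 0.6 * dy).ravel()), boundary)
    if two_ridges:
        crest[2] = np.setdiff1d(
            np.flatnonzero((np.abs(d2) <= 0.6 * dy).ravel()), boundary)

    truth = GroundTruth(
        gyrus_id=gid,
        true_hg=true_hg,
        crest=crest,
        analytic_mean_curv=_analytic_mean_curvature(height, dx, dy).ravel(),
        boundary=boundary,
        injected=injected,
    )
    return SyntheticSubject(white=white, pial=pial, curv=curv,
                            thickness=thickness, parc=parc, truth=truth,
                            spec=spec)


def write_subject_dir(subject: SyntheticSubject, out_dir) -> None:
    """Write a FreeSurfer-like subject directory (surf/, label/).

    Emits ``?h.white``, ``?h.pial``, ``?h.curv``, ``?h.thickness``,
    ``?h.aparc.a2009s.annot`` and the ground-truth HG label, all readable
    by the package's own readers (and by standard FreeSurfer tooling).
    """
    from pathlib import Path
    from . import io as fsio
    from .types import SurfaceLabel

    out = Path(out_dir)
    surf, label = out / "surf", out / "label"
    surf.mkdir(parents=True, exist_ok=True)
    label.mkdir(parents=True, exist_ok=True)
    h = "lh" if subject.white.hemisphere == "left" else "rh"
    fsio.write_surface(subject.white, surf / f"{h}.white")
    fsio.write_surface(subject.pial, surf / f"{h}.pial")
    fsio.write_scalar_field(subject.curv, surf / f"{h}.curv")
    fsio.write_scalar_field(subject.thickness, surf / f"{h}.thickness")
    fsio.write_annotation(subject.parc, label / f"{h}.aparc.a2009s.annot")
    truth_label = SurfaceLabel.from_vertices(
        subject.truth.true_hg, subject.white, name="true_HG")
    fsio.write_label(truth_label, label / f"{h}.true_HG.label")


def spec_to_dict(spec: SyntheticSpec) -> dict:
    d = asdict(spec)
    d["grid"] = list(d["grid"])
    d["extent"] = list(d["extent"])
    d["roi_names"] = list(d["roi_names"])
    if d["thin_strip"] is not None:
        d["thin_strip"] = list(d["thin_strip"])
    return d


def spec_from_dict(d: dict) -> SyntheticSpec:
    d = dict(d)
    for key in ("grid", "extent", "roi_names", "thin_strip"):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    spec = SyntheticSpec(**d)
    spec.validate()
    return spec
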