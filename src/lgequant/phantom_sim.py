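"""Synthetic short-axis LV phantom generator with parametric scar.

The phantom emulates the post-contrast appearance of a left ventricle with a
focal fibrosis stria: a circular annulus of nulled (dark) myocardium, a
bright blood pool, two papillary-muscle cylinders inside the cavity, and an
optional hyperenhanced scar sector placed intramurally or subepicardially in
the inferolateral wall.  Partial volume at the scar border is modelled as a
linear intensity ramp over a configurable width, which is what makes low
n-SD thresholds overcount relative to planimetry — the central phenomenon
the quantification methods disagree on.

Angular convention: 0 deg at the anterior wall, increasing clockwise in the
standard short-axis orientation; the inferolateral wall sits near 240 deg.

Ground truth is derived from the *noiseless* geometry: a voxel is scar iff
its noiseless scar weight exceeds 0.5, so the truth planimetry cuts the
partial-volume ramp at its midpoint.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .image_model import (
    LABEL_BACKGROUND,
    LABEL_BLOOD,
    LABEL_MYOCARDIUM,
    LABEL_PAPILLARY,
    LABEL_SCAR,
    GeometryError,
    LabelMap,
    MassResult,
    SliceStack,
    mass_of,
    myocardium_mask,
    write_labelmap,
    write_volume,
)

__all__ = [
    "PhantomSpec",
    "PhantomSubject",
    "CohortSpec",
    "generate_phantom",
    "generate_cohort",
    "save_subject",
]

WALL_POSITIONS = ("intramural", "subepicardial", "subendocardial")


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameterization of one synthetic subject.

    ``endo_radius_mm``/``epi_radius_mm`` may be scalars (same on all slices)
    or per-slice sequences.  ``scar_transmurality`` is the radial fraction of
    the wall occupied by scar; ``scar_wall_position`` selects where that
    radial span sits.  ``edge_softness_px`` is the width (pixels) of the
    linear partial-volume ramp at the scar border.
    """

    n_slices: int = 8
    rows: int = 96
    cols: int = 96
    pixel_spacing_mm: float = 1.0
    slice_thickness_mm: float = 8.0
    slice_gap_mm: float = 0.0
    endo_radius_mm: float | tuple[float, ...] = 20.0
    epi_radius_mm: float | tuple[float, ...] = 30.0
    scar_present: bool = True
    scar_slices: tuple[int, ...] = (2, 3, 4)
    scar_center_angle_deg: float = 240.0
    scar_angular_extent_deg: float = 60.0
    scar_transmurality: float = 0.5
    scar_wall_position: str = "intramural"
    edge_softness_px: float = 1.0
    intensity_myo: float = 50.0
    intensity_blood: float = 150.0
    intensity_scar: float = 180.0
    noise_sigma: float = 10.0
    noise_model: str = "gaussian"
    papillary: bool = True
    seed: int = 0

    def endo_radii(self) -> np.ndarray:
        return self._per_slice(self.endo_radius_mm)

    def epi_radii(self) -> np.ndarray:
        return self._per_slice(self.epi_radius_mm)

    def _per_slice(self, value) -> np.ndarray:
        arr = np.atleast_1d(np.asarray(value, dtype=float))
        if arr.size == 1:
            arr = np.full(self.n_slices, arr[0])
        if arr.size != self.n_slices:
            raise GeometryError(
                f"per-slice radius list has length {arr.size}, expected {self.n_slices}"
            )
        return arr

    def validate(self) -> None:
        if self.n_slices < 1 or self.rows < 8 or self.cols < 8:
            raise GeometryError("grid too small: need n_slices >= 1 and rows, cols >= 8")
        for name, v in (
            ("pixel_spacing_mm", self.pixel_spacing_mm),
            ("slice_thickness_mm", self.slice_thickness_mm),
        ):
            if v <= 0:
                raise GeometryError(f"{name} must be > 0, got {v}")
        if self.slice_gap_mm < 0:
            raise GeometryError(f"slice_gap_mm must be >= 0, got {self.slice_gap_mm}")
        endo, epi = self.endo_radii(), self.epi_radii()
        if np.any(endo <= 0):
            raise GeometryError("endo_radius_mm must be > 0 on every slice")
        if np.any(epi <= endo):
            raise GeometryError("epi_radius_mm must exceed endo_radius_mm on every slice")
        if self.scar_present:
            if not 0 < self.scar_transmurality <= 1:
                raise GeometryError(
                    f"scar_transmurality must be in (0, 1], got {self.scar_transmurality}"
                )
            if not 0 < self.scar_angular_extent_deg < 360:
                raise GeometryError(
                    f"scar_angular_extent_deg must be in (0, 360), got {self.scar_angular_extent_deg}"
                )
            if self.scar_wall_position not in WALL_POSITIONS:
                raise GeometryError(
                    f"scar_wall_position must be one of {WALL_POSITIONS}, got {self.scar_wall_position!r}"
                )
            bad = [s for s in self.scar_slices if not 0 <= s < self.n_slices]
            if bad:
                raise GeometryError(
                    f"scar_slices {bad} outside [0, {self.n_slices})"
                )
        if self.noise_sigma < 0:
            raise GeometryError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        if self.noise_model not in ("gaussian", "rician"):
            raise GeometryError(f"noise_model must be gaussian or rician, got {self.noise_model!r}")
        if self.edge_softness_px < 0:
            raise GeometryError(f"edge_softness_px must be >= 0, got {self.edge_softness_px}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scar_slices"] = list(self.scar_slices)
        for k in ("endo_radius_mm", "epi_radius_mm"):
            if isinstance(d[k], tuple):
                d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        if "scar_slices" in d:
            d["scar_slices"] = tuple(d["scar_slices"])
        for k in ("endo_radius_mm", "epi_radius_mm"):
            if k in d and isinstance(d[k], list):
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class PhantomSubject:
    """A generated subject: image, ground-truth labels and true masses."""

    image: SliceStack
    truth: LabelMap
    spec: PhantomSpec
    true_scar_mass_g: float
    true_myo_mass_g: float
    true_scar_percent: float


def _scar_weight_slice(
    r_mm: np.ndarray,
    theta_deg: np.ndarray,
    endo: float,
    epi: float,
    spec: PhantomSpec,
) -> np.ndarray:
    """Noiseless scar membership weight in [0, 1] for one slice.

    The weight is a linear ramp of the (approximate) signed distance to the
    annulus-sector scar region, with the 0.5 level on the nominal boundary.
    """
    wall = epi - endo
    half_span = 0.5 * spec.scar_transmurality * wall
    if spec.scar_wall_position == "intramural":
        mid = 0.5 * (endo + epi)
        r_in, r_out = mid - half_span, mid + half_span
    elif spec.scar_wall_position == "subepicardial":
        r_in, r_out = epi - 2 * half_span, epi
    else:  # subendocardial
        r_in, r_out = endo, endo + 2 * half_span

    px = spec.pixel_spacing_mm
    # signed distances in pixels (negative inside)
    d_radial = np.maximum(r_in - r_mm, r_mm - r_out) / px
    dtheta = np.abs((theta_deg - spec.scar_center_angle_deg + 180.0) % 360.0 - 180.0)
    d_arc = np.deg2rad(dtheta - 0.5 * spec.scar_angular_extent_deg) * r_mm / px
    d = np.maximum(d_radial, d_arc)

    e = spec.edge_softness_px
    if e == 0:
        return (d < 0).astype(np.float64)
    return np.clip(0.5 - d / e, 0.0, 1.0)


def generate_phantom(spec: PhantomSpec) -> PhantomSubject:
    """Render one phantom subject from its spec, deterministically.

    The noiseless intensity of pure-myocardium voxels is ``intensity_myo``;
    scar-core voxels are ``intensity_scar``; border voxels interpolate
    linearly over ``edge_softness_px``.  Noise is then added per
    ``noise_model`` using ``spec.seed``.  Truth labels come from the
    noiseless geometry (scar iff weight > 0.5).
    """
    spec.validate()
    endo, epi = spec.endo_radii(), spec.epi_radii()

    rows, cols = spec.rows, spec.cols
    rc = (np.arange(rows) - (rows - 1) / 2.0) * spec.pixel_spacing_mm
    cc = (np.arange(cols) - (cols - 1) / 2.0) * spec.pixel_spacing_mm
    dy, dx = np.meshgrid(rc, cc, indexing="ij")  # dy: down, dx: right
    r_mm = np.hypot(dx, dy)
    # 0 deg anterior (up), clockwise positive
    theta_deg = np.degrees(np.arctan2(dx, -dy)) % 360.0

    noiseless = np.zeros((spec.n_slices, rows, cols))
    labels = np.zeros((spec.n_slices, rows, cols), dtype=np.int16)

    for s in range(spec.n_slices):
        blood = r_mm < endo[s]
        myo = (r_mm >= endo[s]) & (r_mm < epi[s])
        labels[s][blood] = LABEL_BLOOD
        labels[s][myo] = LABEL_MYOCARDIUM
        noiseless[s][blood] = spec.intensity_blood
        noiseless[s][myo] = spec.intensity_myo

        if spec.papillary:
            # two myocardium-intensity cylinders inside the blood pool
            pap_r = 0.16 * endo[s]
            for ang in (120.0, 300.0):
                a = np.deg2rad(ang)
                py, px_ = -0.55 * endo[s] * np.cos(a), 0.55 * endo[s] * np.sin(a)
                pap = np.hypot(dx - px_, dy - py) < pap_r
                pap &= blood
                labels[s][pap] = LABEL_PAPILLARY
                noiseless[s][pap] = spec.intensity_myo

        if spec.scar_present and s in spec.scar_slices:
            w = _scar_weight_slice(r_mm, theta_deg, endo[s], epi[s], spec)
            w = np.where(myo, w, 0.0)
            noiseless[s] += w * (spec.intensity_scar - spec.intensity_myo)
            labels[s][w > 0.5] = LABEL_SCAR

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sigma == 0:
        image = noiseless.copy()
    elif spec.noise_model == "gaussian":
        image = noiseless + spec.noise_sigma * rng.standard_normal(noiseless.shape)
        np.clip(image, 0.0, None, out=image)
    else:  # rician: magnitude of complex signal with iid gaussian channels
        n1 = spec.noise_sigma * rng.standard_normal(noiseless.shape)
        n2 = spec.noise_sigma * rng.standard_normal(noiseless.shape)
        image = np.hypot(noiseless + n1, n2)

    geom = dict(
        pixel_spacing_mm=spec.pixel_spacing_mm,
        slice_thickness_mm=spec.slice_thickness_mm,
        slice_gap_mm=spec.slice_gap_mm,
    )
    stack = SliceStack(image, **geom)
    truth = LabelMap(labels, **geom)

    scar_mass = mass_of(LabelMap(labels == LABEL_SCAR, **geom))
    myo_mass = mass_of(myocardium_mask(truth))
    percent = 100.0 * scar_mass.mass_g / myo_mass.mass_g if myo_mass.mass_g > 0 else 0.0
    return PhantomSubject(
        image=stack,
        truth=truth,
        spec=spec,
        true_scar_mass_g=scar_mass.mass_g,
        true_myo_mass_g=myo_mass.mass_g,
        true_scar_percent=percent,
    )


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Distributional description of a synthetic study cohort.

    Range fields are ``(low, high)`` bounds of uniform draws.  Defaults are
    calibrated so that the scar-positive subjects carry a small fibrosis
    burden (a few percent of LV mass) with soft borders and a hyperenhanced
    core 11-14 remote-SDs above nulled myocardium, the regime in which the
    n-SD family and FWHM disagree the way they do on focal-fibrosis LGE.
    """

    n_subjects: int = 66
    lge_prevalence: float = 41.0 / 66.0
    n_slices: int = 8
    rows: int = 96
    cols: int = 96
    pixel_spacing_mm: float = 1.0
    slice_thickness_mm: float = 8.0
    endo_radius_mm_range: tuple[float, float] = (18.0, 22.0)
    wall_thickness_mm_range: tuple[float, float] = (9.0, 12.0)
    scar_extent_deg_range: tuple[float, float] = (40.0, 70.0)
    transmurality_range: tuple[float, float] = (0.35, 0.60)
    scar_center_angle_deg_range: tuple[float, float] = (215.0, 265.0)
    n_scar_slices_range: tuple[int, int] = (2, 3)
    scar_contrast_sd_range: tuple[float, float] = (11.0, 14.0)
    noise_sigma_range: tuple[float, float] = (8.0, 12.0)
    edge_softness_px_range: tuple[float, float] = (0.8, 1.5)
    intensity_myo: float = 50.0
    intensity_blood: float = 150.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise GeometryError(f"n_subjects must be >= 1, got {self.n_subjects}")
        if not 0.0 <= self.lge_prevalence <= 1.0:
            raise GeometryError(f"lge_prevalence must be in [0, 1], got {self.lge_prevalence}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
        return cls(**d)


def subject_seed(cohort_seed: int, index: int) -> int:
    """Stable per-subject seed derived from the cohort seed."""
    return int(np.random.SeedSequence([cohort_seed, index]).generate_state(1)[0] % (2**31))


def generate_cohort(cspec: CohortSpec) -> list[PhantomSubject]:
    """Generate a deterministic cohort of phantom subjects.

    Exactly ``round(n_subjects x lge_prevalence)`` subjects carry scar; the
    positive indices are a deterministic permutation of the cohort seed, so
    positives and negatives interleave as in an enrolment sequence.
    """
    cspec.validate()
    n_pos = int(round(cspec.n_subjects * cspec.lge_prevalence))
    assign_rng = np.random.default_rng(np.random.SeedSequence([cspec.seed, 0xA551]))
    positive = set(assign_rng.permutation(cspec.n_subjects)[:n_pos].tolist())

    subjects = []
    for i in range(cspec.n_subjects):
        rng = np.random.default_rng(np.random.SeedSequence([cspec.seed, 1, i]))
        u = lambda lo_hi: float(rng.uniform(*lo_hi))
        endo = u(cspec.endo_radius_mm_range)
        epi = endo + u(cspec.wall_thickness_mm_range)
        sigma = u(cspec.noise_sigma_range)
        n_scar = int(rng.integers(cspec.n_scar_slices_range[0], cspec.n_scar_slices_range[1] + 1))
        # basal-mid placement: start in the upper half of the stack (base first)
        max_start = max(1, cspec.n_slices // 2)
        start = int(rng.integers(1, max_start + 1))
        scar_slices = tuple(range(start, min(start + n_scar, cspec.n_slices)))
        spec = PhantomSpec(
            n_slices=cspec.n_slices,
            rows=cspec.rows,
            cols=cspec.cols,
            pixel_spacing_mm=cspec.pixel_spacing_mm,
            slice_thickness_mm=cspec.slice_thickness_mm,
            endo_radius_mm=endo,
            epi_radius_mm=epi,
            scar_present=i in positive,
            scar_slices=scar_slices,
            scar_center_angle_deg=u(cspec.scar_center_angle_deg_range),
            scar_angular_extent_deg=u(cspec.scar_extent_deg_range),
            scar_transmurality=u(cspec.transmurality_range),
            scar_wall_position="intramural" if rng.random() < 0.5 else "subepicardial",
            edge_softness_px=u(cspec.edge_softness_px_range),
            intensity_myo=cspec.intensity_myo,
            intensity_blood=cspec.intensity_blood,
            intensity_scar=cspec.intensity_myo + u(cspec.scar_contrast_sd_range) * sigma,
            noise_sigma=sigma,
            seed=subject_seed(cspec.seed, i),
        )
        subjects.append(generate_phantom(spec))
    return subjects


def save_subject(subject: PhantomSubject, out_dir: str | Path, stem: str = "subject") -> None:
    """Write image + truth as NIfTI-1 and the spec as JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_volume(subject.image, out / f"{stem}_image.nii.gz")
    write_labelmap(subject.truth, out / f"{stem}_truth.nii.gz")
    (out / f"{stem}_spec.json").write_text(json.dumps(subject.spec.to_dict(), indent=2))
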