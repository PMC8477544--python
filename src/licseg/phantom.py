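"""Seeded synthetic multi-echo abdominal phantoms with known ground truth.

Each phantom is a single trans-axial slice emulating the acquisition the
pipeline targets — 256 x 256 matrix, 20 echoes from 1.07 to 16.27 ms in
0.80 ms steps, 1.6 x 3.1 mm in-plane — and the anatomy its stages depend on:

* an elliptical body with a bright subcutaneous fat rim;
* a liver crescent on the patient-right (image-left) side with a prescribed
  LIC; intrahepatic vessels as thin low-LIC tubes;
* a posterior midline spine disk (low signal);
* the aorta (patient-left) and IVC (patient-right) as small disks with high
  S0 and near-zero R2*, so they are the brightest first-echo objects by
  construction and the max-centroid vessel-detection rule is satisfiable;
* optionally a confounder organ on the patient-left whose LIC equals the
  liver's exactly — the scenario plain intensity clustering cannot separate
  and the landmark rejection is designed to fix;
* optionally "severe-overload" artifacts: low-signal patches inside a heavily
  iron-loaded liver (one elongated band through the liver plus random
  blotches), reproducing the failure mode where the liver clusters into
  fragments and the output degrades to grade III.

Signal synthesis is the forward offset model S(TE) = S0 exp(-R2* TE) + C per
tissue, with R2* derived from the assigned LIC by the inverse calibration,
plus Rician noise.  Everything is determined by ``PhantomSpec.seed``.

Realism limits: tissues are piecewise constant (no texture), there is no
motion, field inhomogeneity or partial-volume effect, and geometry is a fixed
stylised layout — adequate for exercising the pipeline's decision logic, not
for claiming performance on patient data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

from .core import BinaryMask, ValidationError, disk_footprint
from .relaxometry import DEFAULT_ECHO_TIMES_MS, MultiEchoStack, r2star_from_lic

# tissue labels
AIR, BODY, FAT, LIVER, SPINE, AORTA, IVC, CONFOUNDER, IH_VESSEL = range(9)

ARTIFACT_MODES = ("none", "severe-overload-patches")


@dataclass
class PhantomSpec:
    image_size: tuple[int, int] = (256, 256)
    echo_times_ms: np.ndarray = field(default_factory=lambda: DEFAULT_ECHO_TIMES_MS.copy())
    pixel_spacing_mm: tuple[float, float] = (1.6, 3.1)
    liver_lic_mg_g: float = 10.0
    background_lic_mg_g: float = 1.0
    vessel_s0_scale: float = 1.8
    noise_sigma: float = 15.0
    confounder_enabled: bool = False
    confounder_touches_liver: bool = True
    intrahepatic_vessels: int = 2
    artifact_mode: str = "none"
    gt_clinical_erosion_px: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.liver_lic_mg_g < 0.202:
            raise ValidationError("liver LIC must be >= 0.202 mg/g dw")
        if self.background_lic_mg_g < 0.202:
            raise ValidationError("background LIC must be >= 0.202 mg/g dw")
        if not self.vessel_s0_scale > 1:
            raise ValidationError("vessel_s0_scale must be > 1")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        if self.artifact_mode not in ARTIFACT_MODES:
            raise ValidationError(f"artifact_mode must be one of {ARTIFACT_MODES}")


@dataclass
class PhantomTruth:
    label_map: np.ndarray
    entire_liver: BinaryMask
    clinical_liver: BinaryMask
    aorta_rc: tuple[float, float]
    ivc_rc: tuple[float, float]
    true_r2star: np.ndarray
    true_params: dict[int, tuple[float, float, float]]  # label -> (S0, R2* s^-1, C)


def add_rician_noise(signal, sigma: float, rng: np.random.Generator):
    """Magnitude-MRI noise: sqrt((s + e1)^2 + e2^2), e ~ N(0, sigma^2)."""
    s = np.asarray(signal, dtype=float)
    if sigma < 0:
        raise ValidationError("sigma must be >= 0")
    if sigma == 0:
        return s.copy()
    e1 = rng.normal(0.0, sigma, s.shape)
    e2 = rng.normal(0.0, sigma, s.shape)
    return np.sqrt((s + e1) ** 2 + e2**2)


def _tissue_params(spec: PhantomSpec) -> dict[int, tuple[float, float, float]]:
    """Per-tissue (S0, R2* in s^-1, C).  Vessels: high S0, near-zero decay."""
    liver_r2 = float(r2star_from_lic(spec.liver_lic_mg_g))
    bg_r2 = float(r2star_from_lic(spec.background_lic_mg_g))
    vessel_s0 = 800.0 * spec.vessel_s0_scale
    return {
        AIR: (0.0, 0.0, 4.0),
        BODY: (600.0, bg_r2, 25.0),
        FAT: (900.0, 45.0, 30.0),
        LIVER: (800.0, liver_r2, 25.0),
        SPINE: (150.0, 120.0, 15.0),
        AORTA: (vessel_s0, 5.0, 30.0),
        IVC: (vessel_s0, 5.0, 30.0),
        CONFOUNDER: (750.0, liver_r2, 25.0),
        IH_VESSEL: (1100.0, 10.0, 25.0),
    }


def _ellipse_mask(shape, center_rc, semi_rc, rotation=0.0) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    rr, cc = draw_ellipse(center_rc[0], center_rc[1], semi_rc[0], semi_rc[1], shape=shape, rotation=rotation)
    m[rr, cc] = True
    return m


def _severe_patches(liver: np.ndarray, rng: np.random.Generator, h: int) -> np.ndarray:
    """Low-signal artifact patches: one band through the liver + blotches."""
    patches = np.zeros_like(liver)
    rows, cols = np.nonzero(liver)
    cr, cc = rows.mean(), cols.mean()
    theta = rng.uniform(0.0, np.pi)
    nr, nc = np.cos(theta), np.sin(theta)
    rr, cc_all = np.nonzero(liver)
    dist = (rr - cr) * nr + (cc_all - cc) * nc
    band = np.zeros_like(liver)
    band[rr, cc_all] = np.abs(dist) <= 0.022 * h  # splits the crescent
    patches |= band

    n_blobs = 2 + int(rng.integers(0, 4))  # total patches >= 3
    idx = rng.integers(0, rows.size, size=n_blobs)
    for k in range(n_blobs):
        r0, c0 = rows[idx[k]], cols[idx[k]]
        semi = rng.uniform(0.03, 0.07, size=2) * h
        patches |= _ellipse_mask(liver.shape, (r0, c0), semi, rotation=rng.uniform(0, np.pi))
    return patches & liver


def generate_phantom(spec: PhantomSpec) -> tuple[MultiEchoStack, PhantomTruth]:
    """Render one phantom slice and its ground truth."""
    h, w = spec.image_size
    if h < 32 or w < 32:
        raise ValidationError("phantom must be at least 32 x 32")
    rng = np.random.default_rng(spec.seed)
    shape = (h, w)

    body_outer = _ellipse_mask(shape, (0.50 * h, 0.50 * w), (0.33 * h, 0.43 * w))
    body_inner = _ellipse_mask(shape, (0.50 * h, 0.50 * w), (0.31 * h, 0.40 * w))
    fat_rim = body_outer & ~body_inner

    liver = _ellipse_mask(shape, (0.45 * h, 0.33 * w), (0.227 * h, 0.203 * w))
    bite = _ellipse_mask(shape, (0.47 * h, 0.215 * w), (0.117 * h, 0.102 * w))
    liver = (liver & ~bite) & body_inner
    # the liver capsule is smooth: remove spurs sharper than the capsule scale
    liver = ndimage.binary_opening(liver, structure=disk_footprint(max(int(0.027 * h), 2)))
    if not liver.any():
        raise ValidationError("geometrically impossible spec: liver outside body")

    spine = np.zeros(shape, dtype=bool)
    rr, cc = draw_disk((0.76 * h, 0.50 * w), max(0.05 * h, 2.0), shape=shape)
    spine[rr, cc] = True
    spine &= body_inner

    vessel_r = max(0.02 * h, 2.0)
    aorta_rc = (0.617 * h, 0.57 * w)
    ivc_rc = (0.617 * h, 0.43 * w)
    aorta = np.zeros(shape, dtype=bool)
    rr, cc = draw_disk(aorta_rc, vessel_r, shape=shape)
    aorta[rr, cc] = True
    ivc = np.zeros(shape, dtype=bool)
    rr, cc = draw_disk(ivc_rc, vessel_r, shape=shape)
    ivc[rr, cc] = True

    confounder = np.zeros(shape, dtype=bool)
    if spec.confounder_enabled:
        col = 0.664 * w if spec.confounder_touches_liver else 0.744 * w
        confounder = _ellipse_mask(shape, (0.37 * h, col), (0.11 * h, 0.176 * w)) & body_inner

    ih_vessels = np.zeros(shape, dtype=bool)
    if spec.intrahepatic_vessels > 0:
        interior = ndimage.binary_erosion(liver, structure=disk_footprint(max(int(0.03 * h), 3)))
        irows, icols = np.nonzero(interior)
        if irows.size:
            idx = rng.integers(0, irows.size, size=spec.intrahepatic_vessels)
            for k in range(spec.intrahepatic_vessels):
                r0, c0 = irows[idx[k]], icols[idx[k]]
                semi = (max(0.06 * h, 4.0), max(0.008 * h, 1.5))
                tube = _ellipse_mask(shape, (r0, c0), semi, rotation=rng.uniform(0, np.pi))
                ih_vessels |= tube & interior

    label = np.full(shape, AIR, dtype=np.int8)
    label[body_outer] = BODY
    label[fat_rim] = FAT
    label[spine] = SPINE
    label[liver] = LIVER
    label[confounder & (label == BODY)] = CONFOUNDER
    label[ih_vessels] = IH_VESSEL
    label[aorta] = AORTA
    label[ivc] = IVC

    params = _tissue_params(spec)
    s0_map = np.zeros(shape)
    r2_map = np.zeros(shape)
    c_map = np.zeros(shape)
    for lbl, (s0, r2, c) in params.items():
        sel = label == lbl
        s0_map[sel] = s0
        r2_map[sel] = r2
        c_map[sel] = c

    if spec.artifact_mode == "severe-overload-patches":
        patches = _severe_patches(label == LIVER, rng, h)
        s0_map[patches] = 60.0
        r2_map[patches] = 50.0
        c_map[patches] = 10.0

    te = np.asarray(spec.echo_times_ms, dtype=float)
    clean = s0_map[..., None] * np.exp(-(r2_map[..., None] / 1e3) * te) + c_map[..., None]
    data = add_rician_noise(clean, spec.noise_sigma, rng)

    stack = MultiEchoStack(data=data, echo_times_ms=te, pixel_spacing_mm=spec.pixel_spacing_mm)

    entire = (label == LIVER) | (label == IH_VESSEL)
    clinical = entire
    if spec.gt_clinical_erosion_px > 0:
        clinical = ndimage.binary_erosion(
            entire, structure=disk_footprint(spec.gt_clinical_erosion_px), border_value=0
        )
    truth = PhantomTruth(
        label_map=label,
        entire_liver=BinaryMask(entire, spec.pixel_spacing_mm),
        clinical_liver=BinaryMask(clinical, spec.pixel_spacing_mm),
        aorta_rc=aorta_rc,
        ivc_rc=ivc_rc,
        true_r2star=r2_map,
        true_params=params,
    )
    return stack, truth


PRESETS = {
    "standard": {},
    "confounder": {"confounder_enabled": True},
    "severe-overload": {"liver_lic_mg_g": 35.0, "artifact_mode": "severe-overload-patches"},
}


def spec_for_preset(preset: str, seed: int = 0, **overrides) -> PhantomSpec:
    if preset not in PRESETS:
        raise ValidationError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    kw = dict(PRESETS[preset])
    kw.update(overrides)
    return PhantomSpec(seed=seed, **kw)


def generate_cohort(
    n: int,
    spec_ranges: dict | None = None,
    seed: int = 0,
    base_spec: PhantomSpec | None = None,
) -> tuple[list[tuple[MultiEchoStack, PhantomTruth]], list[dict]]:
    """Generate ``n`` phantoms with per-case specs sampled from ranges.

    ``spec_ranges`` maps PhantomSpec field names to either a (lo, hi) tuple
    (uniform draw) or a list of choices.  Returns the cases and a manifest of
    the per-case spec fields; fully determined by ``seed``.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if base_spec is None:
        base_spec = PhantomSpec()
    master = np.random.default_rng(seed)
    case_seeds = master.integers(0, 2**31 - 1, size=n)
    cases = []
    manifest = []
    for i in range(n):
        rng = np.random.default_rng(case_seeds[i])
        overrides: dict = {"seed": int(case_seeds[i])}
        for name, rng_spec in (spec_ranges or {}).items():
            if isinstance(rng_spec, (list, tuple)) and len(rng_spec) == 2 and all(
                isinstance(v, (int, float)) and not isinstance(v, bool) for v in rng_spec
            ):
                overrides[name] = float(rng.uniform(rng_spec[0], rng_spec[1]))
            else:
                overrides[name] = rng_spec[int(rng.integers(0, len(rng_spec)))]
        spec = replace(base_spec, **overrides)
        cases.append(generate_phantom(spec))
        row = {
            "case": i,
            "seed": spec.seed,
            "liver_lic_mg_g": spec.liver_lic_mg_g,
            "noise_sigma": spec.noise_sigma,
            "confounder_enabled": spec.confounder_enabled,
            "artifact_mode": spec.artifact_mode,
        }
        manifest.append(row)
    return cases, manifest
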