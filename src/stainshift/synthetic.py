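"""Paired-batch synthetic H&E cohort generator.

Emulates the situation where each patient contributes two slides cut from
the same tissue block ("adjacent recuts") but stained in two different
sessions: the tissue content — modelled as per-stain concentration fields —
is identical between the two renderings, while the optical stain signature
(stain matrix, stain intensity, noise) differs per batch.  A binary
metastasis outcome (Met+/Met-) is planted with a tunable effect size that
can be carried either by nuclear chromatin texture (morphology) or by
hematoxylin uptake (color), the latter serving as a deliberately
stain-confounded negative control.

Rendering follows the Beer-Lambert law: with stain matrix ``W`` (3x2 unit
optical-density columns, hematoxylin first), per-pixel concentrations
``c`` and per-stain intensity scales ``s``,

    I_ch = I0_ch * exp(-[W @ (s * c)]_ch + eps),   eps ~ N(0, noise_sd)

quantized to 8 bits.  Optical densities use the natural logarithm with a
per-channel white level I0 = 255 throughout the package.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from ._rng import child_seed, rng_from

# Published H&E optical-density directions (RGB order, unit-normalized below).
HEMATOXYLIN_OD = np.array([0.65, 0.70, 0.29])
EOSIN_OD = np.array([0.07, 0.99, 0.11])

# Concentration-field constants.  Nuclear hematoxylin sits well above the
# faint cytoplasmic uptake so nuclei dominate the hematoxylin channel.
NUCLEAR_H_CONC = 0.85
CYTO_H_BASE = 0.06  # strict upper bound of cytoplasmic hematoxylin


def _unit_columns(w: np.ndarray) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    return w / np.linalg.norm(w, axis=0, keepdims=True)


@dataclass(frozen=True)
class StainProfile:
    """A staining session's optical signature.

    stain_matrix : (3, 2) non-negative unit OD columns, hematoxylin first.
    intensity_scale : per-stain positive multipliers on concentrations;
        a darker (more basophilic) batch has a larger hematoxylin scale.
    illumination_I0 : per-channel white level (8-bit scale).
    noise_sd : additive Gaussian noise on optical density.
    """

    stain_matrix: np.ndarray
    intensity_scale: np.ndarray
    illumination_I0: np.ndarray = None  # type: ignore[assignment]
    noise_sd: float = 0.0
    name: str = ""
    # within-batch slide-to-slide staining variability (a batch is prepared
    # in one session, but individual slides still take up stain unevenly)
    slide_rotation_sd: float = 2.0
    slide_intensity_log_sd: float = 0.06

    def __post_init__(self):
        w = np.asarray(self.stain_matrix, dtype=float)
        if w.shape != (3, 2):
            raise ValueError("stain_matrix must be 3x2")
        if np.any(w < 0):
            raise ValueError("stain_matrix entries must be non-negative")
        if not np.allclose(np.linalg.norm(w, axis=0), 1.0, atol=1e-6):
            raise ValueError("stain_matrix columns must have unit norm")
        s = np.asarray(self.intensity_scale, dtype=float)
        if s.shape != (2,) or np.any(s <= 0):
            raise ValueError("intensity_scale must be 2 positive values")
        i0 = self.illumination_I0
        i0 = np.full(3, 255.0) if i0 is None else np.asarray(i0, dtype=float)
        if np.any(i0 <= 0) or np.any(i0 > 255):
            raise ValueError("illumination_I0 must be in (0, 255]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        object.__setattr__(self, "stain_matrix", w)
        object.__setattr__(self, "intensity_scale", s)
        object.__setattr__(self, "illumination_I0", i0)

    def fingerprint(self) -> int:
        """Stable integer identity of the optical parameters."""
        payload = np.concatenate(
            [
                self.stain_matrix.ravel(),
                self.intensity_scale,
                self.illumination_I0,
                [self.noise_sd],
            ]
        )
        return zlib.crc32(np.round(payload, 9).tobytes())


@dataclass(frozen=True)
class TissuePhenotype:
    """Per-patient tissue-architecture parameters.

    ``chromatin_texture_amp`` is the dimensionless amplitude of
    intra-nuclear hematoxylin texture; the planted morphology signal
    shifts it between outcome classes.  ``hematoxylin_level`` is a
    patient-level stain-uptake multiplier (slide-to-slide nuisance, and
    the carrier of the color-borne signal variant).
    """

    nuclear_density: float  # expected nuclei per tissue pixel
    nuclear_radius_mean: float  # pixels
    nuclear_radius_sd: float
    chromatin_texture_amp: float
    stroma_fraction: float
    tissue_coverage: float
    hematoxylin_level: float = 1.0

    def __post_init__(self):
        for f in (
            "nuclear_density",
            "nuclear_radius_mean",
            "nuclear_radius_sd",
            "chromatin_texture_amp",
            "hematoxylin_level",
        ):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be non-negative")
        for f in ("stroma_fraction", "tissue_coverage"):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{f} must be in [0, 1]")


@dataclass(frozen=True)
class VirtualPatient:
    patient_id: int
    label: int  # 1 = Met+, 0 = Met-
    phenotype: TissuePhenotype
    tissue_seed: int

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


@dataclass(frozen=True)
class SlidePair:
    """Two batch renderings of one patient's tissue."""

    patient: VirtualPatient
    conc_fields: np.ndarray  # (2, H, W): hematoxylin, eosin
    slide_A: np.ndarray  # (H, W, 3) uint8
    slide_B: np.ndarray
    batch_A: str = "A"
    batch_B: str = "B"


# ---------------------------------------------------------------------------
# stain profiles


def rotate_stain_matrix(w: np.ndarray, degrees: float) -> np.ndarray:
    """Rotate both stain columns by ``degrees`` within their shared plane.

    Entries are clipped to stay non-negative and columns re-normalized,
    mimicking a hue drift of the staining session.
    """
    w = _unit_columns(w)
    u1 = w[:, 0]
    v = w[:, 1] - (w[:, 1] @ u1) * u1
    u2 = v / np.linalg.norm(v)
    th = np.deg2rad(degrees)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    out = np.empty_like(w)
    for j in range(2):
        coords = np.array([w[:, j] @ u1, w[:, j] @ u2])
        a, b = rot @ coords
        col = a * u1 + b * u2 + (w[:, j] - coords[0] * u1 - coords[1] * u2)
        out[:, j] = np.clip(col, 0.0, None)
    return _unit_columns(out)


def default_profiles(
    rotation_deg: float = 10.0,
    intensity_ratio: float = 0.8,
    noise_sd: float = 0.02,
) -> tuple[StainProfile, StainProfile]:
    """The two default staining sessions.

    Batch A uses the published H&E stain vectors at full intensity (the
    darker, more basophilic batch); batch B uses A's matrix rotated by
    ``rotation_deg`` in OD space with intensities scaled by
    ``intensity_ratio`` (the lighter batch).
    """
    w_a = _unit_columns(np.stack([HEMATOXYLIN_OD, EOSIN_OD], axis=1))
    profile_a = StainProfile(w_a, np.array([1.0, 1.0]), noise_sd=noise_sd, name="A")
    w_b = rotate_stain_matrix(w_a, rotation_deg)
    profile_b = StainProfile(
        w_b,
        np.array([intensity_ratio, intensity_ratio]),
        noise_sd=noise_sd,
        name="B",
    )
    return profile_a, profile_b


# ---------------------------------------------------------------------------
# cohort sampling


def sample_cohort(
    n_patients: int,
    met_fraction: float,
    effect_size: float,
    seed: int,
    signal_channel: str = "morphology",
) -> list[VirtualPatient]:
    """Draw a cohort with exactly ``round(n_patients * met_fraction)`` Met+.

    Met+ phenotypes are shifted by ``effect_size`` relative to Met- on the
    chosen signal channel: ``morphology`` adds it to the chromatin-texture
    amplitude; ``color`` multiplies hematoxylin uptake by (1 + effect).
    With ``effect_size == 0`` the two classes follow an identical
    generating law.
    """
    if not isinstance(n_patients, (int, np.integer)) or n_patients < 2:
        raise ValueError("n_patients must be an integer >= 2")
    if not 0.0 <= met_fraction <= 1.0:
        raise ValueError("met_fraction must be in [0, 1]")
    if effect_size < 0:
        raise ValueError("effect_size must be non-negative")
    if signal_channel not in ("morphology", "color"):
        raise ValueError("signal_channel must be 'morphology' or 'color'")

    n_pos = int(round(n_patients * met_fraction))
    label_rng = rng_from(seed, "labels")
    labels = np.zeros(n_patients, dtype=int)
    labels[label_rng.permutation(n_patients)[:n_pos]] = 1

    patients = []
    for pid in range(n_patients):
        rng = rng_from(seed, "phenotype", pid)
        # nuisance heterogeneity is sampled identically for both classes
        density = max(float(rng.normal(8e-4, 1e-4)), 1e-5)
        radius_mean = float(np.clip(rng.normal(6.0, 0.4), 4.0, 9.0))
        texture = abs(float(rng.normal(0.25, 0.05)))
        stroma = float(rng.uniform(0.35, 0.65))
        coverage = float(rng.uniform(0.55, 0.80))
        h_level = float(rng.lognormal(0.0, 0.10))
        if labels[pid] == 1:
            if signal_channel == "morphology":
                texture += effect_size
            else:
                h_level *= 1.0 + effect_size
        phenotype = TissuePhenotype(
            nuclear_density=density,
            nuclear_radius_mean=radius_mean,
            nuclear_radius_sd=1.0,
            chromatin_texture_amp=texture,
            stroma_fraction=stroma,
            tissue_coverage=coverage,
            hematoxylin_level=h_level,
        )
        patients.append(
            VirtualPatient(
                patient_id=pid,
                label=int(labels[pid]),
                phenotype=phenotype,
                tissue_seed=child_seed(seed, "tissue", pid),
            )
        )
    return patients


# ---------------------------------------------------------------------------
# concentration-field synthesis


def _smooth_field(rng, shape, sigma, down=4) -> np.ndarray:
    """Smooth Gaussian random field, computed on a coarse grid for speed."""
    coarse = (max(shape[0] // down, 8), max(shape[1] // down, 8))
    g = ndimage.gaussian_filter(rng.standard_normal(coarse), sigma=sigma / down)
    g = ndimage.zoom(g, (shape[0] / coarse[0], shape[1] / coarse[1]), order=1)
    return g[: shape[0], : shape[1]]


def _smooth_unit_field(rng, shape, sigma) -> np.ndarray:
    g = _smooth_field(rng, shape, sigma)
    lo, hi = g.min(), g.max()
    return (g - lo) / max(hi - lo, 1e-12)


def synthesize_concentration_fields(
    patient: VirtualPatient,
    height: int,
    width: int,
    overlap_tolerance: float = 0.8,
) -> np.ndarray:
    """Procedural tissue for one patient: (2, H, W) concentration maps.

    Channel 0 (hematoxylin) is carried by disk-shaped nuclei with
    class-dependent intra-nuclear texture plus a faint cytoplasmic
    baseline; channel 1 (eosin) by stroma/cytoplasm.  A background margin
    and region carry zero concentration.  Fully determined by
    ``patient.tissue_seed``.

    Nuclei are placed by a Poisson process on the tissue support; a
    candidate position overlapping an accepted nucleus closer than
    ``overlap_tolerance`` times the sum of radii is re-drawn (a few
    retries, then accepted), so the nucleus count stays Poisson while
    overlaps remain rare.
    """
    if height < 64 or width < 64:
        raise ValueError("height and width must be >= 64")
    ph = patient.phenotype
    rng = np.random.default_rng(patient.tissue_seed)
    shape = (height, width)
    margin = max(8, min(shape) // 32)

    # tissue support: thresholded smooth field, margin forced to background;
    # the interior quantile compensates for the margin so total coverage
    # matches tissue_coverage.
    g = _smooth_field(rng, shape, sigma=min(shape) / 8, down=8)
    interior = np.zeros(shape, dtype=bool)
    interior[margin:-margin, margin:-margin] = True
    interior_frac = interior.mean()
    target = min(ph.tissue_coverage / interior_frac, 0.97)
    if target > 0:
        thr = np.quantile(g[interior], 1.0 - target)
        tissue = (g >= thr) & interior
    else:
        tissue = np.zeros(shape, dtype=bool)

    # eosin: stroma/cytoplasm, smoothly textured, positive across tissue
    s_field = _smooth_unit_field(rng, shape, sigma=6.0)
    eosin = tissue * (0.12 + 0.55 * ph.stroma_fraction * (0.4 + 0.6 * s_field))

    # hematoxylin: faint cytoplasmic uptake strictly below CYTO_H_BASE,
    # restricted to the cellular part of the tissue — acellular stroma
    # (collagen) takes up essentially no hematoxylin
    c_field = _smooth_unit_field(rng, shape, sigma=6.0)
    cellular = np.clip((c_field - 0.30) / 0.15, 0.0, 1.0)
    hema = tissue * cellular * (CYTO_H_BASE * (0.5 + 0.4 * c_field)) * ph.hematoxylin_level

    # chromatin texture field, standardized, sub-nuclear correlation length
    t_field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=1.5)
    t_field /= max(t_field.std(), 1e-12)

    n_tissue = int(tissue.sum())
    n_nuclei = rng.poisson(ph.nuclear_density * n_tissue) if n_tissue else 0
    if n_nuclei:
        safe_r = ph.nuclear_radius_mean + 2 * ph.nuclear_radius_sd + 1
        dist = ndimage.distance_transform_edt(tissue)
        cand = np.flatnonzero(dist.ravel() > safe_r)
        if cand.size == 0:
            cand = np.flatnonzero(tissue.ravel())
        if cand.size:
            centers: list[tuple[float, float, float]] = []
            cell = max(2.0 * ph.nuclear_radius_mean, 4.0)
            grid: dict[tuple[int, int], list[int]] = {}
            for _ in range(n_nuclei):
                r_i = max(float(rng.normal(ph.nuclear_radius_mean, ph.nuclear_radius_sd)), 2.0)
                pos = None
                for _try in range(6):
                    flat = int(cand[rng.integers(cand.size)])
                    cy, cx = divmod(flat, width)
                    gy, gx = int(cy // cell), int(cx // cell)
                    ok = True
                    for ny in (gy - 1, gy, gy + 1):
                        for nx in (gx - 1, gx, gx + 1):
                            for k in grid.get((ny, nx), ()):
                                oy, ox, orad = centers[k]
                                min_sep = overlap_tolerance * (r_i + orad)
                                if (cy - oy) ** 2 + (cx - ox) ** 2 < min_sep**2:
                                    ok = False
                                    break
                            if not ok:
                                break
                        if not ok:
                            break
                    if ok:
                        pos = (cy, cx)
                        break
                if pos is None:  # overcrowded: accept the last candidate
                    pos = (cy, cx)
                centers.append((pos[0], pos[1], r_i))
                key = (int(pos[0] // cell), int(pos[1] // cell))
                grid.setdefault(key, []).append(len(centers) - 1)

            amp = ph.chromatin_texture_amp
            base = NUCLEAR_H_CONC * ph.hematoxylin_level
            for cy, cx, r_i in centers:
                ir = int(np.ceil(r_i))
                y0, y1 = max(int(cy) - ir, 0), min(int(cy) + ir + 1, height)
                x0, x1 = max(int(cx) - ir, 0), min(int(cx) + ir + 1, width)
                yy, xx = np.ogrid[y0:y1, x0:x1]
                disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_i**2
                val = base * np.clip(1.0 + amp * t_field[y0:y1, x0:x1], 0.1, None)
                patch = hema[y0:y1, x0:x1]
                patch[disk] = np.maximum(patch[disk], val[disk])
                # nuclei displace cytoplasm/stroma: eosin drops inside them
                epatch = eosin[y0:y1, x0:x1]
                epatch[disk] *= 0.12

    return np.stack([hema, eosin]).astype(np.float64)


# ---------------------------------------------------------------------------
# rendering


def render_rgb(conc_fields: np.ndarray, profile: StainProfile, seed: int) -> np.ndarray:
    """Beer-Lambert rendering of concentration maps under one profile."""
    c = np.asarray(conc_fields, dtype=float)
    if c.ndim != 3 or c.shape[0] != 2:
        raise ValueError("conc_fields must have shape (2, H, W)")
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    scaled = profile.intensity_scale[:, None, None] * c
    od = np.tensordot(profile.stain_matrix, scaled, axes=1)  # (3, H, W)
    if profile.noise_sd > 0:
        od = od + np.random.default_rng(seed).normal(0.0, profile.noise_sd, od.shape)
    i0 = profile.illumination_I0[:, None, None]
    img = np.rint(i0 * np.exp(-od))
    img = np.clip(img, 0.0, i0)
    return img.transpose(1, 2, 0).astype(np.uint8)


def slide_profile(profile: StainProfile, seed: int, patient_id: int) -> StainProfile:
    """The per-slide realization of a batch's staining session.

    Draws a small stain-matrix rotation and per-stain intensity jitter
    around the batch profile; seeded by the profile's optical fingerprint
    (not its batch slot), so two identical profiles realize identically
    and swapping profiles swaps slides exactly.
    """
    if profile.slide_rotation_sd == 0 and profile.slide_intensity_log_sd == 0:
        return profile
    rng = rng_from(seed, "slide-stain", patient_id, profile.fingerprint())
    w = rotate_stain_matrix(
        profile.stain_matrix, float(rng.normal(0.0, profile.slide_rotation_sd))
    )
    scale = profile.intensity_scale * rng.lognormal(
        0.0, profile.slide_intensity_log_sd, size=2
    )
    return StainProfile(
        w,
        scale,
        profile.illumination_I0,
        profile.noise_sd,
        profile.name,
        slide_rotation_sd=0.0,
        slide_intensity_log_sd=0.0,
    )


def make_batch_pair(
    patient: VirtualPatient,
    profile_A: StainProfile,
    profile_B: StainProfile,
    height: int,
    width: int,
    seed: int,
) -> SlidePair:
    """Render the two batch slides from one shared tissue synthesis.

    The per-slide noise stream is derived from the profile's optical
    fingerprint (not its batch slot), so swapping the two profiles swaps
    the rendered slides exactly.
    """
    conc = synthesize_concentration_fields(patient, height, width)
    seed_a = child_seed(seed, "render", patient.patient_id, profile_A.fingerprint())
    seed_b = child_seed(seed, "render", patient.patient_id, profile_B.fingerprint())
    real_a = slide_profile(profile_A, seed, patient.patient_id)
    real_b = slide_profile(profile_B, seed, patient.patient_id)
    return SlidePair(
        patient=patient,
        conc_fields=conc,
        slide_A=render_rgb(conc, real_a, seed_a),
        slide_B=render_rgb(conc, real_b, seed_b),
    )


class SyntheticSlideStore:
    """Lazily rendered, cached slide access keyed by (patient_id, batch)."""

    def __init__(
        self,
        patients: list[VirtualPatient],
        profile_A: StainProfile,
        profile_B: StainProfile,
        height: int = 768,
        width: int = 768,
        seed: int = 0,
    ):
        self.patients = {p.patient_id: p for p in patients}
        self.profiles = {"A": profile_A, "B": profile_B}
        self.height, self.width, self.seed = height, width, seed
        self._conc_cache: dict[int, np.ndarray] = {}
        self._slide_cache: dict[tuple[int, str], np.ndarray] = {}

    def slide(self, patient_id: int, batch: str) -> np.ndarray:
        key = (patient_id, batch)
        if key not in self._slide_cache:
            patient = self.patients[patient_id]
            if patient_id not in self._conc_cache:
                self._conc_cache[patient_id] = synthesize_concentration_fields(
                    patient, self.height, self.width
                )
            profile = self.profiles[batch]
            render_seed = child_seed(
                self.seed, "render", patient_id, profile.fingerprint()
            )
            realized = slide_profile(profile, self.seed, patient_id)
            self._slide_cache[key] = render_rgb(
                self._conc_cache[patient_id], realized, render_seed
            )
            if all((patient_id, b) in self._slide_cache for b in self.profiles):
                self._conc_cache.pop(patient_id, None)
        return self._slide_cache[key]

    def drop_caches(self) -> None:
        self._conc_cache.clear()
        self._slide_cache.clear()


def shifted_phenotype(phenotype: TissuePhenotype, **updates) -> TissuePhenotype:
    """Convenience copy-with-updates for experiment variants."""
    return replace(phenotype, **updates)
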