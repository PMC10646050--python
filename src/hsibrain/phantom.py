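"""Synthetic intraoperative hyperspectral scene generator.

The phantom emulates the statistical structure of in-vivo brain captures so
that every pipeline stage can be exercised and validated without clinical
data: 826 bands over 400-1000 nm, class-dependent reflectance driven by
oxy-/deoxy-haemoglobin absorbance, tumour/vessel/background spatial layout,
radial illumination falloff, sensor noise, and white/dark reference frames
consistent with the forward model so that radiometric calibration inverts it
exactly at zero noise.

Optical model (per pixel)::

    A(lambda) = h * [c_HbO2 * eps_HbO2(lambda) + c_dHb * eps_dHb(lambda)]
                + baseline(lambda)
    R(lambda) = 10 ** (-A(lambda))
    raw       = R * (WI - DI) * falloff + DI + N(0, noise_sd)

where h is a smooth per-pixel heterogeneity field (tissue is not optically
uniform) and class boundaries are blurred by a small point-spread kernel so
boundary pixels contain genuine partial-volume mixtures — the ambiguity the
spatial-spectral stage exists to resolve.

The extinction curves are SYNTHETIC: Gaussian-peak approximations placing
the oxyhaemoglobin peaks near 542/576 nm and the deoxyhaemoglobin peaks near
555 and 760 nm. Only the relative shapes matter to the pipeline; units are
arbitrary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import (
    BG,
    BV,
    NT,
    TT,
    HSCube,
    LabelMap,
    ReferenceFrames,
    default_wavelengths,
)


def _gauss(wl: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - mu) / sigma) ** 2)


def hemoglobin_extinction(wavelengths: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic HbO2 / deoxyHb extinction shapes (arbitrary units).

    Gaussian-peak stand-in for the tabulated compendium curves: HbO2 shows
    the Soret tail and the 542/576 nm double peak with low NIR absorbance;
    deoxyHb shows a single 555 nm visible peak plus the characteristic
    760 nm NIR peak.
    """
    wl = np.asarray(wavelengths, dtype=float)
    eps_hbo2 = (
        0.60 * _gauss(wl, 415, 25)
        + 1.00 * _gauss(wl, 542, 18)
        + 1.05 * _gauss(wl, 576, 12)
        + 0.12 * _gauss(wl, 930, 90)
        + 0.02
    )
    eps_dhb = (
        0.50 * _gauss(wl, 430, 30)
        + 1.25 * _gauss(wl, 555, 28)
        + 0.45 * _gauss(wl, 760, 32)
        + 0.05
    )
    return eps_hbo2, eps_dhb


@dataclass
class ClassOptics:
    """Chromophore concentrations and scattering baseline of one class.

    ``baseline_a0``/``baseline_tilt`` define a wavelength-decreasing
    absorbance floor a0 + tilt * (1 - (lambda-400)/600 ).
    """

    c_hbo2: float
    c_dhb: float
    baseline_a0: float
    baseline_tilt: float

    def absorbance(self, wavelengths: np.ndarray) -> np.ndarray:
        return self.chromophore_absorbance(wavelengths) + self.baseline(wavelengths)

    def chromophore_absorbance(self, wavelengths: np.ndarray) -> np.ndarray:
        eps_o, eps_d = hemoglobin_extinction(wavelengths)
        return self.c_hbo2 * eps_o + self.c_dhb * eps_d

    def baseline(self, wavelengths: np.ndarray) -> np.ndarray:
        wl = np.asarray(wavelengths, dtype=float)
        t = (wl - 400.0) / 600.0
        return self.baseline_a0 + self.baseline_tilt * (1.0 - t)


# Default class optics. NT: moderately perfused, essentially oxygenated.
# TT: comparable total haemoglobin but markedly deoxygenated (visible 760 nm
# deoxyHb dip). BV: strongest absorbance overall. BG (sterile drapes,
# instruments): chromophore-free dark ramp.
DEFAULT_OPTICS: dict[int, ClassOptics] = {
    NT: ClassOptics(c_hbo2=0.45, c_dhb=0.02, baseline_a0=0.12, baseline_tilt=0.25),
    TT: ClassOptics(c_hbo2=0.55, c_dhb=0.50, baseline_a0=0.15, baseline_tilt=0.25),
    BV: ClassOptics(c_hbo2=1.60, c_dhb=0.90, baseline_a0=0.20, baseline_tilt=0.20),
    BG: ClassOptics(c_hbo2=0.0, c_dhb=0.0, baseline_a0=0.55, baseline_tilt=0.55),
}


def class_reflectance(
    class_code: int,
    wavelengths: np.ndarray | None = None,
    optics: dict[int, ClassOptics] | None = None,
) -> np.ndarray:
    """Noise-free reflectance spectrum of one class under the default model."""
    wl = default_wavelengths() if wavelengths is None else np.asarray(wavelengths)
    optics = optics or DEFAULT_OPTICS
    if class_code not in optics:
        raise ValueError(f"unknown class code {class_code}")
    return 10.0 ** (-optics[class_code].absorbance(wl))


@dataclass
class PhantomConfig:
    """Scene geometry, optics and sensor model of the default phantom."""

    rows: int = 160
    cols: int = 160
    seed: int = 0
    # layout
    bg_margin: int = 14
    tumour_centre: tuple[float, float] = (0.42, 0.56)  # fractional (row, col)
    tumour_radii: tuple[float, float] = (26.0, 19.0)  # pixels
    tumour_angle: float = 0.4  # radians
    vessel_width: float = 8.0  # pixels (~1 mm at the camera's 128.7 um pitch)
    # optics / sensor
    optics: dict[int, ClassOptics] = field(
        default_factory=lambda: dict(DEFAULT_OPTICS)
    )
    noise_sd: float = 0.02
    falloff_strength: float = 0.25
    white_level: float = 1.0
    dark_level: float = 0.05
    hetero_sd: float = 0.15  # relative chromophore heterogeneity
    hetero_corr: float = 6.0  # correlation length of the field, pixels
    pv_sigma: float = 1.2  # boundary partial-volume blur, pixels
    label_purity: float = 0.9  # min class abundance for a pixel to be labelled

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if min(self.rows, self.cols) < 4 * self.bg_margin:
            raise ValueError("geometry too small for the background margin")


@dataclass
class PhantomTruth:
    """Everything the generator knows about the scene it produced.

    ``labels`` follows the clinical high-confidence labelling convention:
    boundary pixels that are partial-volume mixtures (dominant class
    abundance below ``label_purity``) stay unlabelled, exactly as an
    operator labels only pixels clearly belonging to one class.
    ``regions`` keeps the full dense layout partition for segmentation
    experiments.
    """

    labels: LabelMap
    class_spectra: dict[int, np.ndarray]  # noise-free reflectance per class
    regions: np.ndarray  # dense layout partition used by segmentation tests


def _layout(cfg: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """Class-code layout raster: BG frame, NT field, TT blob, two vessels."""
    rr, cc = np.meshgrid(
        np.arange(cfg.rows, dtype=float),
        np.arange(cfg.cols, dtype=float),
        indexing="ij",
    )
    labels = np.full((cfg.rows, cfg.cols), NT, dtype=np.int64)
    m = cfg.bg_margin
    labels[:m, :] = BG
    labels[-m:, :] = BG
    labels[:, :m] = BG
    labels[:, -m:] = BG

    # two vessel curves: quadratic Beziers across the exposed tissue
    interior = np.s_[m : cfg.rows - m, m : cfg.cols - m]
    h, wdt = cfg.rows - 2 * m, cfg.cols - 2 * m
    curves = [
        ((0.15, 0.0), (0.45, 0.65), (0.95, 0.85)),
        ((0.85, 0.05), (0.55, 0.45), (0.05, 0.95)),
    ]
    vessel_mask = np.zeros_like(labels, dtype=bool)
    ts = np.linspace(0, 1, 400)
    for (p0, p1, p2) in curves:
        pts = (
            np.outer((1 - ts) ** 2, p0)
            + np.outer(2 * (1 - ts) * ts, p1)
            + np.outer(ts**2, p2)
        )
        pr = m + pts[:, 0] * (h - 1)
        pc = m + pts[:, 1] * (wdt - 1)
        for r0, c0 in zip(pr, pc):
            d2 = (rr - r0) ** 2 + (cc - c0) ** 2
            vessel_mask |= d2 <= (cfg.vessel_width / 2) ** 2
    vessel_mask[labels == BG] = False
    labels[vessel_mask] = BV

    # tumour ellipse on top of everything but BG
    r0 = cfg.tumour_centre[0] * cfg.rows
    c0 = cfg.tumour_centre[1] * cfg.cols
    ca, sa = np.cos(cfg.tumour_angle), np.sin(cfg.tumour_angle)
    u = (rr - r0) * ca + (cc - c0) * sa
    v = -(rr - r0) * sa + (cc - c0) * ca
    ellipse = (u / cfg.tumour_radii[0]) ** 2 + (v / cfg.tumour_radii[1]) ** 2 <= 1
    ellipse &= labels != BG
    labels[ellipse] = TT
    return labels


def _smooth_field(
    shape: tuple[int, int], sd: float, corr: float, rng: np.random.Generator
) -> np.ndarray:
    """Zero-mean smooth Gaussian field with pointwise std ``sd``."""
    if sd <= 0:
        return np.zeros(shape)
    noise = rng.standard_normal(shape)
    smooth = gaussian_filter(noise, sigma=corr)
    s = smooth.std()
    return smooth * (sd / s) if s > 0 else np.zeros(shape)


def generate_scene(
    cfg: PhantomConfig | None = None,
) -> tuple[HSCube, ReferenceFrames, PhantomTruth]:
    """Generate one raw capture with its references and ground truth.

    Deterministic per ``cfg.seed``: the same configuration reproduces a
    bit-identical scene.
    """
    cfg = cfg or PhantomConfig()
    rng = np.random.default_rng(cfg.seed)
    wl = default_wavelengths()
    labels = _layout(cfg, rng)

    codes = (NT, TT, BV, BG)
    chromo = np.stack(
        [cfg.optics[c].chromophore_absorbance(wl) for c in codes]
    ).astype(np.float32)
    base = np.stack([cfg.optics[c].baseline(wl) for c in codes]).astype(np.float32)

    # partial-volume abundances: blurred one-hot layout, renormalized
    onehot = np.stack([(labels == c).astype(np.float32) for c in codes], axis=-1)
    if cfg.pv_sigma > 0:
        for j in range(len(codes)):
            onehot[:, :, j] = gaussian_filter(onehot[:, :, j], sigma=cfg.pv_sigma)
        onehot /= onehot.sum(axis=-1, keepdims=True)

    hetero = 1.0 + _smooth_field(
        (cfg.rows, cfg.cols), cfg.hetero_sd, cfg.hetero_corr, rng
    )
    hetero = np.clip(hetero, 0.2, None).astype(np.float32)

    shape2 = (cfg.rows * cfg.cols, len(codes))
    a_chromo = (onehot.reshape(shape2) @ chromo).reshape(
        cfg.rows, cfg.cols, len(wl)
    )
    a_base = (onehot.reshape(shape2) @ base).reshape(cfg.rows, cfg.cols, len(wl))
    absorb = hetero[:, :, None] * a_chromo
    absorb += a_base
    # R = 10^-A, computed as exp(-ln10 A) in float32 for speed
    reflectance = np.exp(absorb * np.float32(-np.log(10.0)), dtype=np.float32)

    white = np.full(reflectance.shape, cfg.white_level, dtype=np.float32)
    dark = np.full(reflectance.shape, cfg.dark_level, dtype=np.float32)

    rr, cc = np.meshgrid(
        np.arange(cfg.rows, dtype=float),
        np.arange(cfg.cols, dtype=float),
        indexing="ij",
    )
    d2 = ((rr - cfg.rows / 2) / (cfg.rows / 2)) ** 2 + (
        (cc - cfg.cols / 2) / (cfg.cols / 2)
    ) ** 2
    falloff = (1.0 - cfg.falloff_strength * d2 / 2.0).astype(np.float32)

    raw = reflectance * (white - dark) * falloff[:, :, None] + dark
    if cfg.noise_sd > 0:
        noise = rng.standard_normal(raw.shape, dtype=np.float32)
        noise *= np.float32(cfg.noise_sd)
        raw += noise

    cube = HSCube(
        data=raw.astype(np.float32),
        wavelengths=wl,
        stage="raw",
        patient_id="Op-synth",
        capture_id="C1",
    )
    # high-confidence ground truth: partial-volume boundary pixels are
    # mixtures of classes and stay unlabelled
    purity = onehot.max(axis=-1)
    sparse = np.where(purity >= cfg.label_purity, labels, 0)
    truth = PhantomTruth(
        labels=LabelMap(sparse),
        class_spectra={c: class_reflectance(c, wl, cfg.optics) for c in codes},
        regions=labels.copy(),
    )
    # the white tile sees the same illumination field as the tissue, so the
    # reference pair absorbs the falloff and calibration divides it out;
    # references are noise-free (averaged over many lines in practice)
    white_ref = (white - dark) * falloff[:, :, None] + dark
    refs = ReferenceFrames(white=white_ref, dark=dark)
    return cube, refs, truth


def generate_blob_scene(
    rows: int = 160,
    cols: int = 160,
    n_blobs: int = 24,
    noise_sd: float = 0.01,
    seed: int = 0,
) -> tuple[HSCube, ReferenceFrames, np.ndarray]:
    """Tile the scene into ``n_blobs`` spectrally distinct rectangular regions.

    A fixture for segmentation-recovery experiments: each tile gets its own
    chromophore mixture so the true partition is known. Returns the raw
    cube, its references and the region map (1..n_blobs).
    """
    rng = np.random.default_rng(seed)
    wl = default_wavelengths()
    # near-square tiling
    n_r = int(np.floor(np.sqrt(n_blobs)))
    while n_blobs % n_r:
        n_r -= 1
    n_c = n_blobs // n_r
    regions = np.zeros((rows, cols), dtype=np.int64)
    r_edges = np.linspace(0, rows, n_r + 1).astype(int)
    c_edges = np.linspace(0, cols, n_c + 1).astype(int)

    # distinct optics per tile: grid over concentrations, alternating tilt
    c_hbo2 = np.linspace(0.15, 1.9, n_c)
    c_dhb = np.linspace(0.05, 1.3, n_r)
    reflectance = np.zeros((rows, cols, len(wl)), dtype=np.float32)
    k = 0
    for i in range(n_r):
        for j in range(n_c):
            k += 1
            sl = np.s_[r_edges[i] : r_edges[i + 1], c_edges[j] : c_edges[j + 1]]
            regions[sl] = k
            optic = ClassOptics(
                c_hbo2=float(c_hbo2[j]),
                c_dhb=float(c_dhb[i]),
                baseline_a0=0.12 + 0.08 * ((i + j) % 2),
                baseline_tilt=0.15 + 0.12 * ((i * n_c + j) % 3),
            )
            reflectance[sl] = 10.0 ** (-optic.absorbance(wl)).astype(np.float32)

    white_level, dark_level = 1.0, 0.05
    white = np.full(reflectance.shape, white_level, dtype=np.float32)
    dark = np.full(reflectance.shape, dark_level, dtype=np.float32)
    raw = reflectance * (white - dark) + dark
    if noise_sd > 0:
        noise = rng.standard_normal(raw.shape, dtype=np.float32)
        noise *= np.float32(noise_sd)
        raw += noise
    cube = HSCube(
        data=raw.astype(np.float32),
        wavelengths=wl,
        stage="raw",
        patient_id="Op-blobs",
        capture_id="C1",
    )
    return cube, ReferenceFrames(white=white, dark=dark), regions
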