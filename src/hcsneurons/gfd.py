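"""Generic shape and texture descriptors for whole-frame phenotyping.

Seven descriptor families complement the neuromorphology descriptor:

* shape, computed on the binary segmentation mask — Zernike, Legendre and
  Tchebichef orthogonal moments (orders 2/4/8/16) and the polar
  ("generic") Fourier transform magnitude spectrum (5 angular x 12 radial
  frequencies);
* texture, computed on the grayscale image — Haralick co-occurrence
  statistics (18 measures, 8 gray bins, distances 1–5, four directions,
  aggregated as mean + range over directions -> 180 values), a Gabor
  filter bank (6 orientations x 5 octave-spaced scales, mean + sd of the
  response magnitude -> 60 values), and Daubechies-4 wavelet sub-band
  energies over a 10-level decomposition (-> 30 values).

Feature-vector lengths depend only on the configuration, never on image
content: Zernike 4/9/25/81, Legendre & Tchebichef 9/25/81/289, generic
Fourier 60, Haralick 180, Gabor 60, wavelet 30.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt
from numpy.polynomial import legendre as npleg
from scipy.signal import fftconvolve
from skimage.feature import graycomatrix
from skimage.filters import gabor_kernel

__all__ = [
    "GFDConfig",
    "GFDVector",
    "zernike_features",
    "legendre_features",
    "tchebichef_features",
    "generic_fourier_features",
    "haralick_features",
    "gabor_features",
    "daubechies4_features",
    "extract_gfd",
    "HARALICK_STATS",
    "glcm_statistics",
    "discrete_tchebichef_polynomials",
    "pad_to_pow2",
]


@dataclass
class GFDConfig:
    """Descriptor-bank configuration (defaults are the reference settings)."""

    moment_orders: tuple[int, ...] = (2, 4, 8, 16)
    gf_angles: int = 5
    gf_frequencies: int = 12
    glcm_bins: int = 8
    glcm_distances: tuple[int, ...] = (1, 2, 3, 4, 5)
    glcm_angles: tuple[float, ...] = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)
    gabor_orientations: int = 6
    gabor_scales: int = 5
    wavelet: str = "db4"
    wavelet_levels: int = 10


@dataclass
class GFDVector:
    descriptor_name: str
    values: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.values)


def _mask_polar(mask: np.ndarray):
    """Centroid-anchored polar coordinates of mask pixels, radius-normalized."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask: shape descriptor undefined (no centroid)")
    rr, cc = np.nonzero(mask)
    cy, cx = rr.mean(), cc.mean()
    dy, dx = rr - cy, cc - cx
    radius = np.hypot(dy, dx)
    rmax = radius.max()
    if rmax == 0:
        rmax = 1.0
    return radius / rmax, np.arctan2(dy, dx)


# ---------------------------------------------------------------------------
# Zernike moments


def _zernike_radial(n: int, m: int, rho: np.ndarray) -> np.ndarray:
    out = np.zeros_like(rho)
    for s in range((n - m) // 2 + 1):
        c = (
            (-1) ** s
            * math.factorial(n - s)
            / (
                math.factorial(s)
                * math.factorial((n + m) // 2 - s)
                * math.factorial((n - m) // 2 - s)
            )
        )
        out += c * rho ** (n - 2 * s)
    return out


def zernike_features(mask: np.ndarray, order: int = 8) -> GFDVector:
    """Zernike moment magnitudes |Z_nm| up to ``order``.

    Moments are taken on the unit disk centred at the mask centroid and
    scaled to enclose the mask, so the magnitudes are invariant to
    translation and (up to rasterization) to rotation.  Count is
    (order/2 + 1)^2: 4, 9, 25 or 81 for orders 2, 4, 8, 16.
    """
    if order % 2 != 0:
        raise ValueError("moment order must be even")
    rho, theta = _mask_polar(mask)
    inside = rho <= 1.0
    rho, theta = rho[inside], theta[inside]
    values, names = [], []
    for n in range(order + 1):
        for m in range(n % 2, n + 1, 2):
            radial = _zernike_radial(n, m, rho)
            z = (n + 1) / math.pi * np.sum(radial * np.exp(-1j * m * theta))
            values.append(abs(z) / max(len(rho), 1))
            names.append(f"zern_n{n}_m{m}")
    return GFDVector("zernike", np.asarray(values), names)


# ---------------------------------------------------------------------------
# Legendre moments


def legendre_features(mask: np.ndarray, order: int = 8) -> GFDVector:
    """Legendre moments lambda_pq, p,q <= order, on the [-1,1]^2 image domain.

    lambda_pq = (2p+1)(2q+1)/(M N) * sum f(i,j) P_p(y_i) P_q(x_j); count
    is (order+1)^2.  For an all-ones image lambda_00 = 1 (the analytic
    integral of the constant image under this normalization).
    """
    mask = np.asarray(mask, dtype=float)
    if mask.sum() == 0:
        raise ValueError("empty mask: shape descriptor undefined")
    M, N = mask.shape
    y = np.linspace(-1.0, 1.0, M)
    x = np.linspace(-1.0, 1.0, N)
    eye = np.eye(order + 1)
    Py = np.stack([npleg.legval(y, eye[p]) for p in range(order + 1)])  # (order+1, M)
    Px = np.stack([npleg.legval(x, eye[q]) for q in range(order + 1)])
    lam = Py @ mask @ Px.T
    norm = np.outer(2 * np.arange(order + 1) + 1, 2 * np.arange(order + 1) + 1) / (M * N)
    lam = lam * norm
    names = [f"leg_p{p}_q{q}" for p in range(order + 1) for q in range(order + 1)]
    return GFDVector("legendre", lam.ravel(), names)


# ---------------------------------------------------------------------------
# Tchebichef moments


def discrete_tchebichef_polynomials(order: int, N: int) -> np.ndarray:
    """Orthonormal discrete Chebyshev polynomials t_0..t_order on {0..N-1}.

    Built with the standard three-term recurrence; rows are orthonormal:
    sum_x t_p(x) t_q(x) = delta_pq.
    """
    if order >= N:
        raise ValueError("order must be < signal length")
    x = np.arange(N, dtype=float)
    T = np.zeros((order + 1, N))
    T[0] = 1.0 / math.sqrt(N)
    if order >= 1:
        T[1] = (2 * x + 1 - N) * math.sqrt(3.0 / (N * (N**2 - 1)))
    for n in range(2, order + 1):
        a1 = (2.0 / n) * math.sqrt((4 * n**2 - 1) / (N**2 - n**2))
        a2 = ((1 - N) / n) * math.sqrt((4 * n**2 - 1) / (N**2 - n**2))
        a3 = ((n - 1.0) / n) * math.sqrt((2 * n + 1) / (2 * n - 3.0)) * math.sqrt(
            (N**2 - (n - 1) ** 2) / (N**2 - n**2)
        )
        T[n] = (a1 * x + a2) * T[n - 1] - a3 * T[n - 2]
    return T


def tchebichef_features(mask: np.ndarray, order: int = 8) -> GFDVector:
    """Discrete Tchebichef moments T_pq, p,q <= order; count (order+1)^2."""
    mask = np.asarray(mask, dtype=float)
    if mask.sum() == 0:
        raise ValueError("empty mask: shape descriptor undefined")
    M, N = mask.shape
    Ty = discrete_tchebichef_polynomials(order, M)
    Tx = discrete_tchebichef_polynomials(order, N)
    T = Ty @ mask @ Tx.T
    names = [f"tcheb_p{p}_q{q}" for p in range(order + 1) for q in range(order + 1)]
    return GFDVector("tchebichef", T.ravel(), names)


# ---------------------------------------------------------------------------
# Generic (polar) Fourier descriptor


def generic_fourier_features(
    mask: np.ndarray, angular: int = 5, radial: int = 12
) -> GFDVector:
    """Polar Fourier magnitude spectrum about the centroid, DC-normalized.

    |PF(m, n)| for radial frequencies m = 0..radial-1 and angular
    frequencies n = 0..angular-1, each divided by |PF(0, 0)| (so the DC
    entry is exactly 1); length ``angular * radial`` = 60 by default.
    """
    rho, theta = _mask_polar(mask)
    values, names = [], []
    dc = abs(np.sum(np.exp(-2j * math.pi * 0 * rho)))  # = number of pixels
    if dc == 0:
        raise ValueError("empty mask")
    for m in range(radial):
        for n in range(angular):
            pf = np.sum(np.exp(-1j * (2 * math.pi * m * rho + n * theta)))
            values.append(abs(pf) / dc)
            names.append(f"gfour_r{m}_a{n}")
    return GFDVector("generic_fourier", np.asarray(values), names)


# ---------------------------------------------------------------------------
# Haralick texture statistics

HARALICK_STATS = [
    "asm",
    "contrast",
    "correlation",
    "variance",
    "idm",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",
    "imc2",
    "autocorrelation",
    "dissimilarity",
    "cluster_shade",
    "cluster_prominence",
    "max_probability",
]


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def glcm_statistics(P: np.ndarray) -> dict[str, float]:
    """The 18 co-occurrence statistics of one normalized symmetric GLCM.

    Haralick's 13 classic measures (angular second moment, contrast,
    correlation, variance, inverse difference moment, sum average/
    variance/entropy, entropy, difference variance/entropy and both
    information measures of correlation) plus five common extensions
    (autocorrelation, dissimilarity, cluster shade, cluster prominence,
    maximum probability).  Degenerate single-bin matrices follow the
    point-mass limits: contrast 0, ASM 1, correlation reported as 0.
    """
    L = P.shape[0]
    i = np.arange(L)
    I, J = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float(np.sum(i * px))
    mu_y = float(np.sum(i * py))
    sd_x = math.sqrt(max(np.sum((i - mu_x) ** 2 * px), 0.0))
    sd_y = math.sqrt(max(np.sum((i - mu_y) ** 2 * py), 0.0))

    # p_{x+y}(k), k = 0..2L-2 and p_{x-y}(k), k = 0..L-1
    p_sum = np.zeros(2 * L - 1)
    np.add.at(p_sum, (I + J).ravel(), P.ravel())
    p_diff = np.zeros(L)
    np.add.at(p_diff, np.abs(I - J).ravel(), P.ravel())

    asm = float(np.sum(P**2))
    contrast = float(np.sum((I - J) ** 2 * P))
    if sd_x > 0 and sd_y > 0:
        correlation = float((np.sum(I * J * P) - mu_x * mu_y) / (sd_x * sd_y))
    else:
        correlation = 0.0
    variance = float(np.sum((I - mu_x) ** 2 * P))
    idm = float(np.sum(P / (1.0 + (I - J) ** 2)))
    k_sum = np.arange(2 * L - 1)
    sum_avg = float(np.sum(k_sum * p_sum))
    sum_var = float(np.sum((k_sum - sum_avg) ** 2 * p_sum))
    sum_ent = _entropy(p_sum)
    entropy = _entropy(P.ravel())
    k_diff = np.arange(L)
    diff_avg = float(np.sum(k_diff * p_diff))
    diff_var = float(np.sum((k_diff - diff_avg) ** 2 * p_diff))
    diff_ent = _entropy(p_diff)

    hx = _entropy(px)
    hy = _entropy(py)
    pxy = np.outer(px, py)
    nz = (P > 0) | (pxy > 0)
    with np.errstate(divide="ignore"):
        logpxy = np.where(pxy > 0, np.log2(np.where(pxy > 0, pxy, 1.0)), 0.0)
    hxy1 = float(-np.sum(P[nz] * logpxy[nz]))
    hxy2 = float(-np.sum(pxy[pxy > 0] * np.log2(pxy[pxy > 0])))
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    arg = 1.0 - math.exp(-2.0 * (hxy2 - entropy))
    imc2 = math.sqrt(max(arg, 0.0))

    autocorr = float(np.sum(I * J * P))
    dissim = float(np.sum(np.abs(I - J) * P))
    shade = float(np.sum((I + J - mu_x - mu_y) ** 3 * P))
    prom = float(np.sum((I + J - mu_x - mu_y) ** 4 * P))
    maxp = float(P.max())

    return dict(
        zip(
            HARALICK_STATS,
            [
                asm,
                contrast,
                correlation,
                variance,
                idm,
                sum_avg,
                sum_var,
                sum_ent,
                entropy,
                diff_var,
                diff_ent,
                imc1,
                imc2,
                autocorr,
                dissim,
                shade,
                prom,
                maxp,
            ],
        )
    )


def quantize_gray(image: np.ndarray, bins: int = 8) -> np.ndarray:
    """Uniform quantization to ``bins`` levels over the per-image min-max."""
    image = np.asarray(image, dtype=float)
    lo, hi = image.min(), image.max()
    if hi == lo:
        return np.zeros(image.shape, dtype=np.uint8)
    q = np.floor((image - lo) / (hi - lo) * bins).astype(np.int64)
    return np.clip(q, 0, bins - 1).astype(np.uint8)


def haralick_features(image: np.ndarray, config: GFDConfig | None = None) -> GFDVector:
    """180 Haralick features: 18 statistics x (mean, range) x 5 distances.

    The image is quantized to 8 bins; for each pixel distance 1..5 the
    four directional symmetric normalized GLCMs (0, 45, 90, 135 degrees)
    are built and each statistic is summarized by its mean and range over
    the four directions.
    """
    config = config or GFDConfig()
    q = quantize_gray(image, config.glcm_bins)
    values, names = [], []
    for d in config.glcm_distances:
        glcms = graycomatrix(
            q,
            distances=[d],
            angles=list(config.glcm_angles),
            levels=config.glcm_bins,
            symmetric=True,
            normed=True,
        )
        per_angle = []
        for a in range(glcms.shape[3]):
            P = glcms[:, :, 0, a]
            total = P.sum()
            if total > 0:
                P = P / total
            per_angle.append(glcm_statistics(P))
        for stat in HARALICK_STATS:
            vals = np.array([pa[stat] for pa in per_angle])
            values.extend([vals.mean(), vals.max() - vals.min()])
            names.extend([f"har_d{d}_{stat}_mean", f"har_d{d}_{stat}_range"])
    return GFDVector("haralick", np.asarray(values), names)


# ---------------------------------------------------------------------------
# Gabor filter bank


def _gabor_bank(orientations: int, scales: int, f_max: float = 0.4):
    bank = []
    for s in range(scales):
        freq = f_max / (2**s)  # octave-spaced scales
        for o in range(orientations):
            theta = o * math.pi / orientations
            bank.append((s, o, gabor_kernel(freq, theta=theta, bandwidth=1.0)))
    return bank


def _pad_symmetric(image: np.ndarray, pr: int, pc: int) -> np.ndarray:
    """Symmetric padding in steps (np.pad caps one reflection at the array size)."""
    out = image
    while pr > 0 or pc > 0:
        sr = min(pr, out.shape[0])
        sc = min(pc, out.shape[1])
        out = np.pad(out, ((sr, sr), (sc, sc)), mode="symmetric")
        pr -= sr
        pc -= sc
    return out


def gabor_features(image: np.ndarray, config: GFDConfig | None = None) -> GFDVector:
    """Mean and standard deviation of |image * Gabor| for a 6x5 bank (60 values).

    The image is reflect-padded by the kernel half-size before each
    convolution so a flat image yields a flat response (sd exactly the
    interior value, no boundary artifacts).
    """
    config = config or GFDConfig()
    image = np.asarray(image, dtype=float)
    values, names = [], []
    for s, o, kernel in _gabor_bank(config.gabor_orientations, config.gabor_scales):
        pr, pc = kernel.shape[0] // 2, kernel.shape[1] // 2
        padded = _pad_symmetric(image, pr, pc)
        resp = fftconvolve(padded, kernel, mode="same")
        mag = np.abs(resp[pr : pr + image.shape[0], pc : pc + image.shape[1]])
        values.extend([mag.mean(), mag.std()])
        names.extend([f"gabor_s{s}_o{o}_mean", f"gabor_s{s}_o{o}_sd"])
    return GFDVector("gabor", np.asarray(values), names)


# ---------------------------------------------------------------------------
# Daubechies wavelet energies


def pad_to_pow2(image: np.ndarray, min_size: int = 1024) -> np.ndarray:
    """Pad by iterated reflection to a square power-of-two of >= min_size.

    A power-of-two side halves cleanly at every decomposition level, so a
    10-level periodized transform is exactly orthonormal on the result.
    """
    image = np.asarray(image, dtype=float)
    target = max(min_size, 2 ** int(math.ceil(math.log2(max(image.shape)))))
    out = image
    while out.shape[0] < target or out.shape[1] < target:
        pr = min(out.shape[0], target - out.shape[0])
        pc = min(out.shape[1], target - out.shape[1])
        out = np.pad(out, ((0, pr), (0, pc)), mode="symmetric")
    return out


def daubechies4_features(image: np.ndarray, config: GFDConfig | None = None) -> GFDVector:
    """Mean detail-sub-band energies of a 10-level Daubechies wavelet transform.

    The image is reflection-padded to a power-of-two square and decomposed
    with the periodized orthonormal transform; for each level the mean
    squared coefficient of the horizontal, vertical and diagonal detail
    bands is recorded (3 x 10 = 30 values, coarsest level first).
    """
    config = config or GFDConfig()
    levels = config.wavelet_levels
    padded = pad_to_pow2(image, min_size=2**levels)
    if padded.shape[0] < 2**levels:
        raise ValueError("image too small for the requested decomposition depth")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # level > conventional max
        coeffs = pywt.wavedec2(padded, config.wavelet, mode="periodization", level=levels)
    values, names = [], []
    for lev, details in enumerate(coeffs[1:], start=1):
        for band, arr in zip(("h", "v", "d"), details):
            values.append(float(np.mean(np.asarray(arr) ** 2)))
            names.append(f"db4_L{lev}_{band}_energy")
    return GFDVector("daubechies4", np.asarray(values), names)


# ---------------------------------------------------------------------------
# dispatcher


def extract_gfd(
    image: np.ndarray, mask: np.ndarray, config: GFDConfig | None = None
) -> dict[str, GFDVector]:
    """Compute every descriptor family for one image.

    Shape families read the binary ``mask``; texture families read the
    grayscale ``image``.  If the mask is empty the shape descriptors are
    undefined and omitted with a warning; texture descriptors are still
    computed.
    """
    config = config or GFDConfig()
    if np.asarray(image).shape != np.asarray(mask).shape:
        raise ValueError("image and mask must share a shape")
    out: dict[str, GFDVector] = {}
    mask_ok = bool(np.asarray(mask, dtype=bool).any())
    if mask_ok:
        for name, fn in (
            ("zernike", zernike_features),
            ("legendre", legendre_features),
            ("tchebichef", tchebichef_features),
        ):
            vals, names = [], []
            for order in config.moment_orders:
                v = fn(mask, order)
                vals.append(v.values)
                names.extend(f"{n}_o{order}" for n in v.feature_names)
            out[name] = GFDVector(name, np.concatenate(vals), names)
        out["generic_fourier"] = generic_fourier_features(
            mask, config.gf_angles, config.gf_frequencies
        )
    else:
        warnings.warn("empty mask: shape descriptors undefined, skipped", stacklevel=2)
    out["haralick"] = haralick_features(image, config)
    out["gabor"] = gabor_features(image, config)
    out["daubechies4"] = daubechies4_features(image, config)
    return out
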