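"""Structural-colour optics and spectrum-to-sRGB colorimetry.

A phage-bundle photonic film reflects a narrow band of wavelengths set by
first-order Bragg reflection at normal incidence,

    lambda_peak = 2 * n_eff * d * (1 + s),

where ``d`` is the unswollen bundle period, ``n_eff`` the effective
refractive index of the film and ``s`` the fractional swelling induced by
analyte uptake.  The reflected spectrum is modelled as a Gaussian peak on a
flat baseline and rendered to an 8-bit sRGB triple through the CIE 1931 2°
colour-matching functions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

VISIBLE_MIN_NM = 380.0
VISIBLE_MAX_NM = 780.0

# CIE 1931 2-degree standard observer colour-matching functions, tabulated
# at 10 nm from 380 to 780 nm (x̄, ȳ, z̄).
CIE_WAVELENGTHS_NM = np.arange(380.0, 781.0, 10.0)

CIE_XYZ_CMF = np.array([
    [0.001368, 0.000039, 0.006450],
    [0.004243, 0.000120, 0.020050],
    [0.014310, 0.000396, 0.067850],
    [0.043510, 0.001210, 0.207400],
    [0.134380, 0.004000, 0.645600],
    [0.283900, 0.011600, 1.385600],
    [0.348280, 0.023000, 1.747060],
    [0.336200, 0.038000, 1.772110],
    [0.290800, 0.060000, 1.669200],
    [0.195360, 0.090980, 1.287640],
    [0.095640, 0.139020, 0.812950],
    [0.032010, 0.208020, 0.465180],
    [0.004900, 0.323000, 0.272000],
    [0.009300, 0.503000, 0.158200],
    [0.063270, 0.710000, 0.078250],
    [0.165500, 0.862000, 0.042160],
    [0.290400, 0.954000, 0.020300],
    [0.433450, 0.994950, 0.008750],
    [0.594500, 0.995000, 0.003900],
    [0.762100, 0.952000, 0.002100],
    [0.916300, 0.870000, 0.001650],
    [1.026300, 0.757000, 0.001100],
    [1.062200, 0.631000, 0.000800],
    [1.002600, 0.503000, 0.000340],
    [0.854450, 0.381000, 0.000190],
    [0.642400, 0.265000, 0.000050],
    [0.447900, 0.175000, 0.000020],
    [0.283500, 0.107000, 0.000000],
    [0.164900, 0.061000, 0.000000],
    [0.087400, 0.032000, 0.000000],
    [0.046770, 0.017000, 0.000000],
    [0.022700, 0.008210, 0.000000],
    [0.011359, 0.004102, 0.000000],
    [0.005790, 0.002091, 0.000000],
    [0.002899, 0.001047, 0.000000],
    [0.001440, 0.000520, 0.000000],
    [0.000690, 0.000249, 0.000000],
    [0.000332, 0.000120, 0.000000],
    [0.000166, 0.000060, 0.000000],
    [0.000083, 0.000030, 0.000000],
    [0.000042, 0.000015, 0.000000],
])

# Standard sRGB (D65 white point) XYZ -> linear RGB matrix (IEC 61966-2-1).
XYZ_TO_LINEAR_SRGB = np.array([
    [3.2406, -1.5372, -0.4986],
    [-0.9689, 1.8758, 0.0415],
    [0.0557, -0.2040, 1.0570],
])

# Default spectral-peak shape used when the swelling model does not override it.
DEFAULT_PEAK_WIDTH_NM = 30.0
DEFAULT_PEAK_AMPLITUDE = 0.9
DEFAULT_PEAK_BASELINE = 0.05


class InvalidParameterError(ValueError):
    """Raised for physically meaningless optical parameters."""


@dataclass(frozen=True)
class SpectralPeak:
    """A Gaussian reflectance peak on a flat baseline.

    Attributes
    ----------
    center_nm : float
        Peak wavelength, clamped into the visible range [380, 780] nm.
    width_nm : float
        Full width at half maximum in nm; must be positive.
    amplitude : float
        Peak reflectance in [0, 1].
    baseline : float
        Flat baseline reflectance, 0 <= baseline <= amplitude.
    """

    center_nm: float
    width_nm: float = DEFAULT_PEAK_WIDTH_NM
    amplitude: float = DEFAULT_PEAK_AMPLITUDE
    baseline: float = DEFAULT_PEAK_BASELINE

    def __post_init__(self) -> None:
        if not (VISIBLE_MIN_NM <= self.center_nm <= VISIBLE_MAX_NM):
            raise InvalidParameterError(
                f"center_nm {self.center_nm} outside [{VISIBLE_MIN_NM}, {VISIBLE_MAX_NM}]"
            )
        if self.width_nm <= 0:
            raise InvalidParameterError(f"width_nm must be positive, got {self.width_nm}")
        if not (0.0 <= self.baseline <= self.amplitude <= 1.0):
            raise InvalidParameterError(
                f"need 0 <= baseline <= amplitude <= 1, got "
                f"baseline={self.baseline}, amplitude={self.amplitude}"
            )

    def reflectance(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        """Evaluate the spectrum at the given wavelengths (nm)."""
        lam = np.asarray(wavelengths_nm, dtype=float)
        # FWHM parameterisation: exp(-4 ln2 ((lam-c)/w)^2)
        arg = -4.0 * np.log(2.0) * ((lam - self.center_nm) / self.width_nm) ** 2
        return self.baseline + (self.amplitude - self.baseline) * np.exp(arg)


def bragg_peak_center_nm(
    period_nm: float, n_eff: float, swelling_fraction: float
) -> float:
    """Unclamped first-order normal-incidence Bragg wavelength in nm."""
    if period_nm <= 0:
        raise InvalidParameterError(f"period_nm must be positive, got {period_nm}")
    if n_eff < 1.0:
        raise InvalidParameterError(f"n_eff must be >= 1, got {n_eff}")
    if swelling_fraction < 0:
        raise InvalidParameterError(
            f"swelling_fraction must be >= 0, got {swelling_fraction}"
        )
    return 2.0 * n_eff * period_nm * (1.0 + swelling_fraction)


def bragg_peak(
    period_nm: float,
    n_eff: float,
    swelling_fraction: float,
    *,
    width_nm: float = DEFAULT_PEAK_WIDTH_NM,
    amplitude: float = DEFAULT_PEAK_AMPLITUDE,
    baseline: float = DEFAULT_PEAK_BASELINE,
) -> SpectralPeak:
    """Reflectance peak of a swollen photonic film.

    The centre wavelength is ``2 * n_eff * period_nm * (1 + swelling_fraction)``
    clamped to the visible range; width/amplitude/baseline come from the
    configuration defaults unless overridden.
    """
    center = bragg_peak_center_nm(period_nm, n_eff, swelling_fraction)
    center = min(max(center, VISIBLE_MIN_NM), VISIBLE_MAX_NM)
    return SpectralPeak(
        center_nm=center, width_nm=width_nm, amplitude=amplitude, baseline=baseline
    )


def spectrum_to_xyz(
    peak: SpectralPeak, wavelengths_nm: np.ndarray | None = None,
    cmf: np.ndarray | None = None,
) -> np.ndarray:
    """Integrate a reflectance spectrum against the CIE 1931 2° observer.

    The stimulus is the reflectance spectrum itself (equal-energy
    illumination); XYZ is normalised so a flat unit spectrum has Y = 1.
    """
    if wavelengths_nm is None:
        wavelengths_nm = CIE_WAVELENGTHS_NM
    if cmf is None:
        cmf = CIE_XYZ_CMF
    refl = peak.reflectance(wavelengths_nm)
    xyz = refl @ cmf
    return xyz / cmf[:, 1].sum()


def _linear_to_srgb_gamma(channel: np.ndarray) -> np.ndarray:
    c = np.clip(channel, 0.0, None)
    return np.where(c <= 0.0031308, 12.92 * c, 1.055 * np.power(c, 1.0 / 2.4) - 0.055)


def spectrum_to_rgb8(peak: SpectralPeak) -> tuple[tuple[int, int, int], bool]:
    """Render a spectral peak to an 8-bit sRGB triple.

    Returns ``((r, g, b), gamut_clipped)`` where the flag is True when any
    linear-RGB channel fell outside [0, 1] before clipping.  Deterministic
    for a fixed input.
    """
    xyz = spectrum_to_xyz(peak)
    linear = XYZ_TO_LINEAR_SRGB @ xyz
    clipped = bool(np.any(linear < 0.0) or np.any(linear > 1.0))
    linear = np.clip(linear, 0.0, 1.0)
    srgb = _linear_to_srgb_gamma(linear)
    rgb8 = np.clip(np.round(srgb * 255.0), 0, 255).astype(int)
    return (int(rgb8[0]), int(rgb8[1]), int(rgb8[2])), clipped
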