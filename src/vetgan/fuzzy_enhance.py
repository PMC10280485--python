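"""Mamdani fuzzy-inference brightness correction and PSNR evaluation.

The enhancement stage treats pixel intensity as a linguistic variable.
Five input terms (Very Dark ... Very Bright) tile the 8-bit universe
[0, 255]; single-antecedent IF-THEN rules map each term to an output term
on a signed adjustment universe [-delta_max, +delta_max]; Mamdani
inference (min implication, max aggregation, centroid defuzzification)
turns a crisp intensity into a crisp brightness delta.

The default rule base is deliberately asymmetric::

    Very Dark   -> Slightly Dark
    Dark        -> Very Dark
    Medium      -> Slightly Bright
    Bright      -> Slightly Bright
    Very Bright -> No Change

i.e. dark pixels are pushed darker and mid/bright pixels brighter,
stretching contrast, while already-saturated pixels are left alone.

Because the input universe has only 256 values, inference is evaluated
once per intensity into a lookup table (LUT). LUT deltas are quantized to
integers: the images are 8-bit, so an integer delta reproduces the
per-pixel float pipeline exactly after the mandatory rounding, and it
makes the "Very Bright -> No Change" rule hold exactly on the Very Bright
plateau.

PSNR (dB) between an original and an enhanced image is
``10 log10(G^2 / MSE)`` with ``G`` the maximum intensity (255). The mean
squared error is taken over all pixels and channels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from skimage import color as _skcolor
from skimage import exposure as _skexposure

__all__ = [
    "MembershipFunction",
    "gaussian_mf",
    "trapezoid_mf",
    "FISConfig",
    "default_fis_config",
    "fuzzify",
    "evaluate_rules",
    "defuzzify",
    "build_lut",
    "enhance_image",
    "psnr",
    "clahe_reference",
    "hist_eq_reference",
]


# ---------------------------------------------------------------------------
# Membership functions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MembershipFunction:
    """A gaussian or trapezoidal membership function for one linguistic term.

    ``shape`` is "gaussian" with ``params = (mean, sigma)`` or "trapezoid"
    with ``params = (a, b, c, d)`` (membership rises on [a, b], is 1 on
    [b, c], falls on [c, d]). Triangles are degenerate trapezoids (b == c).
    """

    label: str
    shape: Literal["gaussian", "trapezoid"]
    params: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.shape == "gaussian":
            if len(self.params) != 2:
                raise ValueError("gaussian MF needs (mean, sigma)")
            if self.params[1] <= 0:
                raise ValueError("gaussian sigma must be > 0")
        elif self.shape == "trapezoid":
            if len(self.params) != 4:
                raise ValueError("trapezoid MF needs (a, b, c, d)")
            a, b, c, d = self.params
            if not (a <= b <= c <= d):
                raise ValueError("trapezoid requires a <= b <= c <= d")
        else:
            raise ValueError(f"unknown MF shape {self.shape!r}")

    def __call__(self, x: float | np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.shape == "gaussian":
            mean, sigma = self.params
            return np.exp(-0.5 * ((x - mean) / sigma) ** 2)
        a, b, c, d = self.params
        out = np.zeros_like(x, dtype=float)
        if b > a:
            rising = (x > a) & (x < b)
            out = np.where(rising, (x - a) / (b - a), out)
        if d > c:
            falling = (x > c) & (x < d)
            out = np.where(falling, (d - x) / (d - c), out)
        out = np.where((x >= b) & (x <= c), 1.0, out)
        return out


def gaussian_mf(label: str, mean: float, sigma: float) -> MembershipFunction:
    return MembershipFunction(label, "gaussian", (float(mean), float(sigma)))


def trapezoid_mf(label: str, a: float, b: float, c: float, d: float) -> MembershipFunction:
    return MembershipFunction(label, "trapezoid", (float(a), float(b), float(c), float(d)))


# ---------------------------------------------------------------------------
# FIS configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FISConfig:
    """Input/output membership functions, rule base and inference settings.

    ``rules`` are single-antecedent pairs ``(input_term, output_term)``.
    Implication is min, aggregation over rules is max, and defuzzification
    is the centroid of the aggregated output set — the textbook Mamdani
    operators. ``delta_max`` bounds the output universe.
    """

    input_mfs: tuple[MembershipFunction, ...]
    output_mfs: tuple[MembershipFunction, ...]
    rules: tuple[tuple[str, str], ...]
    delta_max: float = 64.0
    channel_mode: Literal["luminance", "per_channel"] = "luminance"
    resolution: int = 2049  #: grid points used for the centroid integral

    def __post_init__(self) -> None:
        in_terms = {mf.label for mf in self.input_mfs}
        out_terms = {mf.label for mf in self.output_mfs}
        for antecedent, consequent in self.rules:
            if antecedent not in in_terms:
                raise ValueError(f"rule references unknown input term {antecedent!r}")
            if consequent not in out_terms:
                raise ValueError(f"rule references unknown output term {consequent!r}")

    @property
    def input_terms(self) -> tuple[str, ...]:
        return tuple(mf.label for mf in self.input_mfs)

    @property
    def output_terms(self) -> tuple[str, ...]:
        return tuple(mf.label for mf in self.output_mfs)

    def to_dict(self) -> dict:
        """Plain-data form for YAML/JSON config files."""
        def mf_dict(mf: MembershipFunction) -> dict:
            return {"label": mf.label, "shape": mf.shape, "params": list(mf.params)}

        return {
            "input_mfs": [mf_dict(mf) for mf in self.input_mfs],
            "output_mfs": [mf_dict(mf) for mf in self.output_mfs],
            "rules": [list(rule) for rule in self.rules],
            "delta_max": self.delta_max,
            "channel_mode": self.channel_mode,
            "resolution": self.resolution,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "FISConfig":
        def mf(d: dict) -> MembershipFunction:
            return MembershipFunction(d["label"], d["shape"], tuple(d["params"]))

        return cls(
            input_mfs=tuple(mf(d) for d in data["input_mfs"]),
            output_mfs=tuple(mf(d) for d in data["output_mfs"]),
            rules=tuple((a, b) for a, b in data["rules"]),
            delta_max=float(data.get("delta_max", 64.0)),
            channel_mode=data.get("channel_mode", "luminance"),
            resolution=int(data.get("resolution", 2049)),
        )


#: default rule base: contrast stretch with a dead zone at saturation
DEFAULT_RULES: tuple[tuple[str, str], ...] = (
    ("Very Dark", "Slightly Dark"),
    ("Dark", "Very Dark"),
    ("Medium", "Slightly Bright"),
    ("Bright", "Slightly Bright"),
    ("Very Bright", "No Change"),
)


def default_fis_config(
    delta_max: float = 64.0,
    channel_mode: Literal["luminance", "per_channel"] = "luminance",
) -> FISConfig:
    """The default five-term brightness-correction FIS.

    Shoulder terms are trapezoids (so the extremes have genuine plateaus),
    interior terms gaussians. Bright uses a tighter sigma (16 vs. 25 for
    Dark/Medium) so that its tail has died off on the Very Bright plateau
    [223, 255]; otherwise the No-Change rule could never actually yield a
    zero adjustment for saturated pixels.
    """
    input_mfs = (
        trapezoid_mf("Very Dark", 0, 0, 32, 64),
        gaussian_mf("Dark", 80, 25),
        gaussian_mf("Medium", 128, 25),
        gaussian_mf("Bright", 176, 16),
        trapezoid_mf("Very Bright", 191, 223, 255, 255),
    )
    h = delta_max / 4.0  # half-width of each output triangle
    output_mfs = (
        trapezoid_mf("Very Dark", -3 * h - h, -3 * h, -3 * h, -3 * h + h),
        trapezoid_mf("Slightly Dark", -h - h, -h, -h, 0),
        trapezoid_mf("No Change", -h, 0, 0, h),
        trapezoid_mf("Slightly Bright", 0, h, h, h + h),
        trapezoid_mf("Very Bright", 3 * h - h, 3 * h, 3 * h, 3 * h + h),
    )
    return FISConfig(
        input_mfs=input_mfs,
        output_mfs=output_mfs,
        rules=DEFAULT_RULES,
        delta_max=delta_max,
        channel_mode=channel_mode,
    )


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

def fuzzify(intensity: float, input_mfs: Sequence[MembershipFunction]) -> np.ndarray:
    """Membership degree of ``intensity`` in every input term."""
    if not 0 <= intensity <= 255:
        raise ValueError(f"intensity {intensity} outside [0, 255]")
    return np.array([float(mf(intensity)) for mf in input_mfs])


def evaluate_rules(
    memberships: np.ndarray,
    rules: Sequence[tuple[str, str]],
    input_terms: Sequence[str],
    output_terms: Sequence[str],
) -> np.ndarray:
    """Activation of each output term under max aggregation.

    With single-antecedent rules, min implication reduces each rule's firing
    strength to the antecedent degree; terms fired by several rules keep the
    maximum.
    """
    degree = dict(zip(input_terms, np.asarray(memberships, dtype=float)))
    activations = dict.fromkeys(output_terms, 0.0)
    for antecedent, consequent in rules:
        if antecedent not in degree:
            raise ValueError(f"rule references unknown input term {antecedent!r}")
        if consequent not in activations:
            raise ValueError(f"rule references unknown output term {consequent!r}")
        activations[consequent] = max(activations[consequent], degree[antecedent])
    return np.array([activations[t] for t in output_terms])


def defuzzify(
    activations: np.ndarray,
    output_mfs: Sequence[MembershipFunction],
    delta_max: float = 64.0,
    resolution: int = 2049,
) -> float:
    """Centroid of the clipped, max-aggregated output fuzzy set.

    Each output MF is clipped (min) at its activation, the clipped sets are
    aggregated pointwise by max over a dense grid on
    ``[-delta_max, +delta_max]``, and the centroid of the aggregate is
    returned. When nothing fires the aggregate has zero area and the delta
    is defined as 0 (no change).
    """
    activations = np.asarray(activations, dtype=float)
    grid = np.linspace(-delta_max, delta_max, resolution)
    agg = np.zeros_like(grid)
    for act, mf in zip(activations, output_mfs):
        if act > 0.0:
            agg = np.maximum(agg, np.minimum(act, mf(grid)))
    area = agg.sum()
    if area == 0.0:
        return 0.0
    return float((agg * grid).sum() / area)


def build_lut(fis: FISConfig) -> np.ndarray:
    """Evaluate the full inference chain for all 256 intensities.

    Returns an int16 table of signed deltas: ``table[i]`` is the rounded
    centroid delta for input intensity ``i``. Integer quantization is
    lossless for 8-bit images (pixel updates round anyway).
    """
    deltas = np.empty(256, dtype=np.int16)
    for i in range(256):
        m = fuzzify(float(i), fis.input_mfs)
        a = evaluate_rules(m, fis.rules, fis.input_terms, fis.output_terms)
        d = defuzzify(a, fis.output_mfs, fis.delta_max, fis.resolution)
        deltas[i] = int(round(d))
    return deltas


def enhance_image(
    pixels: np.ndarray,
    fis: FISConfig | None = None,
    lut: np.ndarray | None = None,
) -> np.ndarray:
    """Apply the FIS brightness correction to an 8-bit RGB image.

    In ``luminance`` mode the value channel of an HSV decomposition is
    shifted by the LUT delta and the image recomposed, preserving hue; in
    ``per_channel`` mode every channel is shifted independently. Outputs
    are clipped to [0, 255].
    """
    if fis is None:
        fis = default_fis_config()
    if lut is None:
        lut = build_lut(fis)
    pixels = np.asarray(pixels)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 image, got shape {pixels.shape}")
    pixels = pixels.astype(np.uint8)

    if fis.channel_mode == "per_channel":
        shifted = pixels.astype(np.int32) + lut[pixels]
        return np.clip(shifted, 0, 255).astype(np.uint8)

    hsv = _skcolor.rgb2hsv(pixels)
    v8 = np.clip(np.round(hsv[..., 2] * 255.0), 0, 255).astype(np.uint8)
    v_new = np.clip(v8.astype(np.int32) + lut[v8], 0, 255)
    hsv[..., 2] = v_new / 255.0
    rgb = _skcolor.hsv2rgb(hsv)
    return np.clip(np.round(rgb * 255.0), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# Quality evaluation
# ---------------------------------------------------------------------------

def psnr(original: np.ndarray, enhanced: np.ndarray, g: float = 255.0) -> float:
    """Peak signal-to-noise ratio in decibels; ``inf`` for identical images.

    ``10 log10(g^2 / MSE)`` with the MSE averaged over every pixel and
    channel. Symmetric in its two arguments.
    """
    if g <= 0:
        raise ValueError("maximum intensity g must be > 0")
    original = np.asarray(original, dtype=np.float64)
    enhanced = np.asarray(enhanced, dtype=np.float64)
    if original.shape != enhanced.shape:
        raise ValueError(
            f"image shapes differ: {original.shape} vs {enhanced.shape}"
        )
    mse = np.mean((original - enhanced) ** 2)
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(g * g / mse)


def clahe_reference(pixels: np.ndarray, clip_limit: float = 0.01) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization (comparator)."""
    eq = _skexposure.equalize_adapthist(np.asarray(pixels, dtype=np.uint8), clip_limit=clip_limit)
    return np.clip(np.round(eq * 255.0), 0, 255).astype(np.uint8)


def hist_eq_reference(pixels: np.ndarray) -> np.ndarray:
    """Classic histogram equalization, per channel (comparator)."""
    pixels = np.asarray(pixels, dtype=np.uint8)
    eq = np.stack(
        [_skexposure.equalize_hist(pixels[..., c]) for c in range(pixels.shape[2])],
        axis=-1,
    )
    return np.clip(np.round(eq * 255.0), 0, 255).astype(np.uint8)
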