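"""Synthetic B-mode speckle phantoms with a controllable disease-severity knob.

The scene is a stack of horizontal tissue bands (cavity, myocardium,
pericardium on a dark background).  Per-pixel speckle is Rayleigh-
distributed amplitude, independent across pixels; each layer's pixel value
is its effective mean plus the centered Rayleigh fluctuation.  Severity
``theta`` couples to two mechanisms, each of which can be switched off:

* pericardial attenuation — the effective pericardial mean falls to
  ``mu_peri * (1 - attenuation_alpha * theta)``;
* myocardial heterogeneity — the myocardial speckle fluctuation is scaled
  by ``sqrt(1 + heterogeneity_beta * theta)``.

Identical (spec, seed) always yields a bit-identical frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from echostruct.imaging_io import EchoFrame, RegionOfInterest

RAYLEIGH_MEAN_FACTOR = math.sqrt(math.pi / 2.0)

_LAYERS = ("background", "cavity", "myocardium", "pericardium")


@dataclass(frozen=True)
class PhantomSpec:
    height: int = 256
    width: int = 256
    #: half-open row bands (start, stop) for the three tissue layers;
    #: remaining rows are background
    cavity_band: tuple = (40, 110)
    myo_band: tuple = (110, 180)
    peri_band: tuple = (180, 220)
    mu_background: float = 8.0
    mu_cavity: float = 20.0
    mu_myo: float = 90.0
    mu_peri: float = 200.0
    #: per-layer Rayleigh scale of the speckle fluctuation
    speckle_scale: dict = field(
        default_factory=lambda: {
            "background": 5.0,
            "cavity": 12.0,
            "myocardium": 35.0,
            "pericardium": 25.0,
        }
    )
    severity: float = 0.0
    attenuation_alpha: float = 0.4
    heterogeneity_beta: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.severity <= 1.0:
            raise ValueError(f"severity must lie in [0, 1], got {self.severity}")
        if not 0.0 <= self.attenuation_alpha < 1.0:
            raise ValueError("attenuation_alpha must lie in [0, 1)")
        if self.heterogeneity_beta < 0:
            raise ValueError("heterogeneity_beta must be non-negative")
        if not 0 < self.mu_cavity < self.mu_myo < self.mu_peri <= 255:
            raise ValueError("echogenicity ordering mu_cavity < mu_myo < mu_peri <= 255 violated")
        bands = [self.cavity_band, self.myo_band, self.peri_band]
        prev_stop = 0
        for lo, hi in bands:
            if lo < prev_stop or hi <= lo or hi > self.height:
                raise ValueError("tissue bands must be disjoint, ordered, and inside the frame")
            prev_stop = hi

    def effective_mu_peri(self) -> float:
        return self.mu_peri * (1.0 - self.attenuation_alpha * self.severity)

    def with_severity(self, theta: float, seed: int | None = None) -> "PhantomSpec":
        kwargs = {"severity": theta}
        if seed is not None:
            kwargs["seed"] = seed
        return replace(self, **kwargs)


@dataclass(frozen=True)
class GainTransform:
    """Multiplicative gain + additive offset with 8-bit clipping."""

    gain: float = 1.0
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError(f"gain must be positive, got {self.gain}")


def _band_rows(spec: PhantomSpec, layer: str) -> tuple:
    return {
        "cavity": spec.cavity_band,
        "myocardium": spec.myo_band,
        "pericardium": spec.peri_band,
    }[layer]


def _inset_rectangle(label: str, band: tuple, width: int, margin: int = 4) -> RegionOfInterest:
    r0, r1 = band[0] + margin, band[1] - 1 - margin
    c0, c1 = width // 4, 3 * width // 4
    return RegionOfInterest(label=label, vertices=[(r0, c0), (r0, c1), (r1, c1), (r1, c0)])


def generate_phantom(spec: PhantomSpec) -> tuple:
    """Render the phantom; returns (frame, myocardial ROI, pericardial ROI).

    Each pixel is ``round(clip(mu_layer_eff + (R - E[R]) * v_layer))`` with
    ``R ~ Rayleigh(scale_layer)``; ``v_layer`` is 1 except for the myocardium
    where it is ``sqrt(1 + heterogeneity_beta * severity)``.
    """
    rng = np.random.default_rng(spec.seed)
    img = np.empty((spec.height, spec.width), dtype=np.float64)

    mu = {
        "background": spec.mu_background,
        "cavity": spec.mu_cavity,
        "myocardium": spec.mu_myo,
        "pericardium": spec.effective_mu_peri(),
    }
    var_mult = {layer: 1.0 for layer in _LAYERS}
    var_mult["myocardium"] = math.sqrt(1.0 + spec.heterogeneity_beta * spec.severity)

    layer_of_row = np.full(spec.height, "background", dtype=object)
    for layer in ("cavity", "myocardium", "pericardium"):
        lo, hi = _band_rows(spec, layer)
        layer_of_row[lo:hi] = layer

    # draw row-blocks per layer in a fixed order so the stream is reproducible
    for layer in _LAYERS:
        rows = np.flatnonzero(layer_of_row == layer)
        if rows.size == 0:
            continue
        scale = float(spec.speckle_scale.get(layer, 0.0))
        if scale > 0:
            r = rng.rayleigh(scale, size=(rows.size, spec.width))
            fluct = (r - scale * RAYLEIGH_MEAN_FACTOR) * var_mult[layer]
        else:
            fluct = np.zeros((rows.size, spec.width))
        img[rows, :] = mu[layer] + fluct

    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    frame = EchoFrame(
        pixels=pixels,
        source_id=f"phantom(seed={spec.seed},theta={spec.severity:g})",
    )
    myo_roi = _inset_rectangle("myocardial", spec.myo_band, spec.width)
    peri_roi = _inset_rectangle("pericardial", spec.peri_band, spec.width)
    return frame, myo_roi, peri_roi


def apply_gain(frame: EchoFrame, transform: GainTransform) -> EchoFrame:
    """pixel <- round(clip(gain*pixel + offset, 0, 255))."""
    out = np.clip(
        np.rint(transform.gain * frame.pixels.astype(np.float64) + transform.offset), 0, 255
    ).astype(np.uint8)
    return EchoFrame(pixels=out, frame_index=frame.frame_index, source_id=frame.source_id)


def jitter_roi(
    roi: RegionOfInterest,
    max_shift_px: int,
    seed: int,
    frame: EchoFrame | None = None,
) -> RegionOfInterest:
    """Rigidly translate an ROI by a random integer offset in
    [-max_shift, +max_shift]^2, simulating reader placement variability."""
    if max_shift_px < 0:
        raise ValueError("max_shift_px must be non-negative")
    rng = np.random.default_rng(seed)
    drow, dcol = rng.integers(-max_shift_px, max_shift_px + 1, size=2)
    shifted = roi.translated(float(drow), float(dcol))
    if frame is not None:
        verts = np.asarray(shifted.vertices)
        if (
            verts[:, 0].min() < 0
            or verts[:, 1].min() < 0
            or verts[:, 0].max() > frame.height - 1
            or verts[:, 1].max() > frame.width - 1
        ):
            raise ValueError("jittered ROI falls outside the frame")
    return shifted
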