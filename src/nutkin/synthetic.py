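"""Synthetic apical-track generation.

Analytic parametric curves emulating the pattern classes reported for
nutating organs — circles, ellipses, lines, and epi-/hypo-trochoids
(the latter built as a sum of two rotating vectors with rates omega1 and
omega2) — with optional additive Gaussian position noise.  These stand
in for experimental tip-tracking data in tests of the inversion
pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ApicalTrack

__all__ = ["SyntheticTrackSpec", "generate_track", "add_position_noise"]

PATTERNS = ("circle", "ellipse", "epitrochoid", "hypotrochoid", "line")


@dataclass(frozen=True)
class SyntheticTrackSpec:
    """Recipe for a synthetic tip trajectory.

    ``omega`` is the (slow) angular rate in rad/s; trochoids add a second
    vector at ``rate_ratio * omega`` (sign flipped for the hypotrochoid)
    whose radius is ``radius2``.  ``noise_sd`` is the Gaussian position
    noise standard deviation as a fraction of the track scale.  Duration
    defaults to 5 slow periods (must cover at least 3).
    """

    pattern: str = "circle"
    radius: float = 5.0  # mm (semi-major axis for the ellipse)
    radius2: float = 1.0  # mm, second rotating vector (trochoids)
    eccentric: float = 0.6  # semi-minor/major ratio for the ellipse
    omega: float = 4.6e-4  # rad/s
    rate_ratio: float = 6.0  # |omega2 / omega1| for trochoids
    n_periods: float = 5.0
    sampling_dt: float = 60.0  # s
    noise_sd: float = 0.0  # fraction of track scale
    seed: int = 0

    def __post_init__(self):
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}; one of {PATTERNS}")
        if self.n_periods < 3:
            raise ValueError("duration must cover at least 3 slow periods")
        if self.radius <= 0 or self.sampling_dt <= 0 or self.omega == 0:
            raise ValueError("radius, sampling_dt and omega must be positive")


def generate_track(spec: SyntheticTrackSpec) -> ApicalTrack:
    """Sample the analytic pattern and add seeded position noise."""
    period = 2.0 * np.pi / abs(spec.omega)
    t = np.arange(0.0, spec.n_periods * period, spec.sampling_dt)
    w = spec.omega
    if spec.pattern == "circle":
        x = spec.radius * np.cos(w * t)
        y = spec.radius * np.sin(w * t)
    elif spec.pattern == "ellipse":
        x = spec.radius * np.cos(w * t)
        y = spec.eccentric * spec.radius * np.sin(w * t)
    elif spec.pattern == "line":
        x = spec.radius * np.cos(w * t)
        y = np.zeros_like(t)
    else:
        sign = 1.0 if spec.pattern == "epitrochoid" else -1.0
        w2 = sign * spec.rate_ratio * w
        x = spec.radius * np.cos(w * t) + spec.radius2 * np.cos(w2 * t)
        y = spec.radius * np.sin(w * t) + spec.radius2 * np.sin(w2 * t)
    track = ApicalTrack(t, x, y)
    if spec.noise_sd > 0:
        track = add_position_noise(track, spec.noise_sd, spec.seed)
    return track


def add_position_noise(
    track: ApicalTrack, noise_sd: float, seed: int
) -> ApicalTrack:
    """Additive isotropic Gaussian noise, sd = ``noise_sd`` x track scale.

    The scale is the maximum radial excursion about the track centroid.
    """
    rng = np.random.default_rng(seed)
    cx, cy = track.x.mean(), track.y.mean()
    scale = float(np.hypot(track.x - cx, track.y - cy).max())
    sd = noise_sd * scale
    return ApicalTrack(
        track.times,
        track.x + rng.normal(0.0, sd, track.x.shape),
        track.y + rng.normal(0.0, sd, track.y.shape),
    )
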