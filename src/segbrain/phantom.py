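"""Synthetic skull-stripped brain phantoms with exact tissue labels.

Every slice is a nested-ellipse caricature of a T1-weighted, skull-stripped
axial brain section: a dark background, a thin outer band of CSF, a cortical
band of gray matter, a white-matter interior, and optionally a few small
ventricle-like CSF ellipses inside the white matter.  Intensities follow the
T1 ordering CSF < GM < WM, corrupted by a smooth multiplicative bias field
and additive Gaussian noise, so the images exercise exactly the nuisances a
tissue-segmentation network must be robust to while the ground-truth label
map stays exact by construction.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_data import write_image_png, write_label_png

BACKGROUND, CSF, GM, WM = 0, 1, 2, 3
CLASS_NAMES = ("background", "CSF", "GM", "WM")
N_CLASSES = 4

DEFAULT_MEANS = {CSF: 0.20, GM: 0.50, WM: 0.80}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and noise parameters of a synthetic brain slice.

    Parameters
    ----------
    height, width : int
        Canvas size in pixels; each must be divisible by 4 so that two
        2x down/up-sampling stages invert cleanly.
    mean_intensity : dict
        Noise-free intensity per tissue class on a [0, 1] scale
        (background is fixed at 0).  Must satisfy CSF < GM < WM.
    noise_sigma : float
        Standard deviation of the additive Gaussian noise.
    bias_amplitude : float
        Relative amplitude of the smooth multiplicative bias field; the
        field spans [1 - amplitude, 1 + amplitude].
    rim_fractions : (float, float)
        Thickness of the CSF and GM bands as fractions of the brain radius.
    n_ventricles : int
        Number of small CSF ellipses placed inside the white matter.
    jitter : float
        Relative randomization of ellipse centers, axes and orientation.
    seed : int
        Default seed used when no explicit RNG is supplied.
    """

    height: int = 96
    width: int = 96
    mean_intensity: dict = field(default_factory=lambda: dict(DEFAULT_MEANS))
    noise_sigma: float = 0.03
    bias_amplitude: float = 0.10
    rim_fractions: tuple = (0.10, 0.28)
    n_ventricles: int = 2
    jitter: float = 0.10
    seed: int = 0

    def validate(self) -> None:
        if self.height % 4 != 0 or self.width % 4 != 0:
            raise ValueError(
                f"phantom dimensions must be divisible by 4 (two 2x poolings "
                f"must invert cleanly); got {self.height}x{self.width}"
            )
        m = self.mean_intensity
        if not (m[CSF] < m[GM] < m[WM]):
            raise ValueError(
                "mean intensities must be T1-ordered CSF < GM < WM, got "
                f"CSF={m[CSF]}, GM={m[GM]}, WM={m[WM]}"
            )
        if self.noise_sigma < 0 or self.bias_amplitude < 0:
            raise ValueError("noise_sigma and bias_amplitude must be >= 0")
        if self.n_ventricles < 0:
            raise ValueError("n_ventricles must be >= 0")


@dataclass
class PhantomPair:
    """A synthetic intensity slice with its exact label map."""

    image: np.ndarray  # (H, W) float64 in [0, 1]
    labels: np.ndarray  # (H, W) uint8 in {0, 1, 2, 3}
    geometry: dict = field(default_factory=dict)


def _elliptic_radius(h, w, center, axes, theta):
    """Normalized elliptic radius of every pixel: rho <= 1 is inside."""
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    dy, dx = yy - center[0], xx - center[1]
    ct, st = np.cos(theta), np.sin(theta)
    u = ct * dx + st * dy
    v = -st * dx + ct * dy
    return np.sqrt((u / axes[1]) ** 2 + (v / axes[0]) ** 2)


def generate_phantom(spec: PhantomSpec, rng: np.random.Generator | None = None) -> PhantomPair:
    """Generate one phantom slice; deterministic given (spec, rng state)."""
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(spec.seed)

    h, w = spec.height, spec.width
    jit = spec.jitter

    def jittered(x, scale=1.0):
        return x * (1.0 + scale * jit * rng.uniform(-1.0, 1.0))

    # Brain ellipse: slightly taller than wide, roughly centered.
    base_r = 0.42 * min(h, w)
    center = (h / 2.0 + base_r * 0.1 * jit * rng.uniform(-1, 1),
              w / 2.0 + base_r * 0.1 * jit * rng.uniform(-1, 1))
    axes = (jittered(1.05 * base_r), jittered(0.88 * base_r))
    theta = jit * rng.uniform(-0.35, 0.35)

    rho = _elliptic_radius(h, w, center, axes, theta)
    f_csf, f_gm = spec.rim_fractions
    labels = np.full((h, w), BACKGROUND, dtype=np.uint8)
    labels[rho <= 1.0] = CSF
    labels[rho <= 1.0 - f_csf] = GM
    labels[rho <= 1.0 - f_csf - f_gm] = WM

    # Ventricles: small CSF ellipses strictly inside the WM core (rho < 0.45).
    ventricles = []
    for k in range(spec.n_ventricles):
        side = -1.0 if k % 2 == 0 else 1.0
        vy = center[0] - 0.12 * axes[0] + 0.05 * jit * axes[0] * rng.uniform(-1, 1)
        vx = center[1] + side * (0.16 + 0.04 * jit * rng.uniform(-1, 1)) * axes[1]
        vaxes = (jittered(0.16 * axes[0], 0.5), jittered(0.07 * axes[1], 0.5))
        vtheta = theta + side * (0.35 + 0.2 * jit * rng.uniform(-1, 1))
        vrho = _elliptic_radius(h, w, (vy, vx), vaxes, vtheta)
        inside = (vrho <= 1.0) & (labels == WM)
        labels[inside] = CSF
        ventricles.append({"center": [vy, vx], "axes": list(vaxes), "theta": vtheta})

    # Intensity model: class mean x bias field + noise, clipped to [0, 1].
    means = np.zeros(N_CLASSES)
    for c, v in spec.mean_intensity.items():
        means[c] = v
    image = means[labels]

    bias_center = (center[0] + 0.5 * axes[0] * rng.uniform(-1, 1),
                   center[1] + 0.5 * axes[1] * rng.uniform(-1, 1))
    if spec.bias_amplitude > 0:
        yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
        sig = 0.6 * min(h, w)
        bump = np.exp(-((yy - bias_center[0]) ** 2 + (xx - bias_center[1]) ** 2) / (2 * sig**2))
        bump = (bump - bump.min()) / max(bump.max() - bump.min(), 1e-12)
        bias = 1.0 - spec.bias_amplitude + 2.0 * spec.bias_amplitude * bump
        image = image * bias

    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, size=image.shape)
        image = np.clip(image, 0.0, 1.0)

    geometry = {
        "center": list(center),
        "axes": list(axes),
        "theta": float(theta),
        "ventricles": ventricles,
    }
    return PhantomPair(image=image, labels=labels, geometry=geometry)


def generate_dataset(
    n: int,
    spec: PhantomSpec,
    seed: int,
    split_fraction: float = 0.8,
    out_dir: str | Path | None = None,
) -> tuple[list[PhantomPair], list[PhantomPair]]:
    """Generate ``n`` phantoms and split them into disjoint train/test sets.

    Per-item seeds are ``seed + index``, so any subset is reproducible from
    the master seed alone.  When ``out_dir`` is given, images (16-bit PNG),
    labels (8-bit PNG) and a sidecar JSON with the spec and per-item
    geometry are written there.
    """
    if n < 2:
        raise ValueError("need at least 2 phantoms to form a train/test split")
    n_train = int(round(n * split_fraction))
    if n_train <= 0 or n_train >= n:
        raise ValueError(
            f"split_fraction={split_fraction} leaves an empty partition for n={n}"
        )

    pairs = [generate_phantom(spec, np.random.default_rng(seed + i)) for i in range(n)]
    train, test = pairs[:n_train], pairs[n_train:]

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        sidecar = {
            "spec": {**dataclasses.asdict(spec),
                     "mean_intensity": {str(k): v for k, v in spec.mean_intensity.items()}},
            "seed": seed,
            "split_fraction": split_fraction,
            "items": [],
        }
        for i, pair in enumerate(pairs):
            stem = f"phantom_{i:04d}"
            write_image_png(out_dir / f"{stem}_image.png", pair.image)
            write_label_png(out_dir / f"{stem}_labels.png", pair.labels)
            sidecar["items"].append({
                "id": stem,
                "split": "train" if i < n_train else "test",
                "item_seed": seed + i,
                "geometry": pair.geometry,
            })
        (out_dir / "dataset.json").write_text(json.dumps(sidecar, indent=2))

    return train, test
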