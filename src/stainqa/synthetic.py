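"""Seeded synthetic paired autofluorescence / stain image generator.

Emulates the paired (AF, H&E-like) patches used to train and assess staining
transforms: a ground-truth scene of non-overlapping nucleus disks over a
smooth cytoplasm field is rendered twice — once as a 1-channel AF-like image
(nuclei bright, DAPI-style) and once as a 3-channel stain-like image through a
Beer-Lambert optical-density model with haematoxylin/eosin stain vectors.
Controllable degradation operators reproduce characteristic failure modes of
poor staining models: missing nuclei (realistic hallucination), blur, colour
shift and additive noise (unrealistic artefacts).

Everything is driven by explicit integer seeds and regenerates bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage
from skimage import color as skcolor

from .images import Domain, ImageFOV, write_image

# Standard haematoxylin / eosin optical-density directions, unit-normalized.
_H = np.array([0.65, 0.70, 0.29])
_E = np.array([0.07, 0.99, 0.11])
HAEMATOXYLIN = _H / np.linalg.norm(_H)
EOSIN = _E / np.linalg.norm(_E)

MAX_PLACEMENT_ATTEMPTS = 1000


@dataclass(frozen=True)
class SceneParams:
    """Scene sampling parameters (pixels)."""

    size: int = 64
    n_nuclei: tuple[int, int] = (6, 14)     # inclusive range; (k, k) fixes k
    radius_range: tuple[float, float] = (2.0, 4.0)
    cytoplasm_smoothness: float = 8.0       # Gaussian sigma of the field

    def __post_init__(self):
        if self.size < 16:
            raise ValueError("size must be >= 16 px")
        lo, hi = self.radius_range
        if lo <= 0 or hi < lo:
            raise ValueError("radius range must be positive and ordered")
        if hi > self.size / 2:
            raise ValueError("radius range exceeds half the image size")
        if self.n_nuclei[0] < 0 or self.n_nuclei[1] < self.n_nuclei[0]:
            raise ValueError("nucleus-count range must be ordered and >= 0")


@dataclass(frozen=True)
class RenderParams:
    """Rendering parameters for the paired AF / stain images."""

    stain_vector_h: tuple[float, float, float] = tuple(HAEMATOXYLIN)
    stain_vector_e: tuple[float, float, float] = tuple(EOSIN)
    od_nuclei: float = 1.0        # haematoxylin optical density on nuclei
    od_cytoplasm: float = 0.8     # eosin optical density scale on cytoplasm
    af_background: float = 0.15
    af_nuclei_gain: float = 0.6
    af_cytoplasm_gain: float = 0.25
    af_noise_std: float = 0.02

    def vectors(self) -> tuple[np.ndarray, np.ndarray]:
        v_h = np.asarray(self.stain_vector_h, float)
        v_e = np.asarray(self.stain_vector_e, float)
        v_h = v_h / np.linalg.norm(v_h)
        v_e = v_e / np.linalg.norm(v_e)
        if np.isclose(abs(np.dot(v_h, v_e)), 1.0, atol=1e-9):
            raise ValueError("degenerate stain vectors: directions are parallel")
        return v_h, v_e


@dataclass(frozen=True)
class GroundTruthScene:
    """Scene description: nucleus disks plus a smooth cytoplasm field.

    ``nuclei`` holds (row_center, col_center, radius) triples; disks lie fully
    inside the bounds and are pairwise non-overlapping.  ``n_requested``
    records how many nuclei were asked for, so a placement shortfall (the
    rejection sampler giving up) is visible in the ground truth.
    """

    width: int
    height: int
    nuclei: tuple[tuple[float, float, float], ...]
    cytoplasm_field: np.ndarray
    seed: int
    n_requested: int = -1

    def nuclei_mask(self) -> np.ndarray:
        """Rasterize the nucleus disks: pixel inside iff centre distance <= r."""
        mask = np.zeros((self.height, self.width), dtype=bool)
        if not self.nuclei:
            return mask
        rr, cc = np.mgrid[0:self.height, 0:self.width]
        for r0, c0, rad in self.nuclei:
            mask |= (rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2
        return mask


@dataclass(frozen=True)
class PairedSample:
    """A rendered (AF, stain) pair, optionally with its generating scene."""

    af: ImageFOV
    stain: ImageFOV
    scene: GroundTruthScene | None = None

    def __post_init__(self):
        if (self.af.height, self.af.width) != (self.stain.height, self.stain.width):
            raise ValueError("af and stain must have identical height/width")


@dataclass(frozen=True)
class DegradationSpec:
    """One degradation operator emulating a staining-model failure mode.

    ``kind``: nuclei_dropout (severity = per-nucleus removal probability),
    gaussian_blur (severity = sigma in px), colour_shift (severity = hue
    offset in [0,1] turns), additive_noise (severity = Gaussian std), or
    compose (apply ``parts`` in order).
    """

    kind: str
    severity: float = 0.0
    seed: int = 0
    parts: tuple["DegradationSpec", ...] = ()

    _KINDS = ("nuclei_dropout", "gaussian_blur", "colour_shift",
              "additive_noise", "compose")

    def __post_init__(self):
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown degradation kind: {self.kind}")
        if self.severity < 0:
            raise ValueError("severity must be >= 0")
        if self.kind == "nuclei_dropout" and not (0 <= self.severity <= 1):
            raise ValueError("nuclei_dropout severity must lie in [0, 1]")
        if self.kind == "compose" and not self.parts:
            raise ValueError("compose requires at least one part")


def sample_scene(params: SceneParams, seed: int) -> GroundTruthScene:
    """Draw a random scene: rejection-sample non-overlapping nucleus disks.

    Placement retries up to 1000 attempts per nucleus; if space runs out the
    scene is returned with fewer nuclei and ``n_requested`` records the
    shortfall.
    """
    rng = np.random.default_rng(seed)
    size = params.size
    lo, hi = params.n_nuclei
    n_req = int(rng.integers(lo, hi + 1)) if hi > lo else lo

    placed: list[tuple[float, float, float]] = []
    for _ in range(n_req):
        for _attempt in range(MAX_PLACEMENT_ATTEMPTS):
            rad = float(rng.uniform(*params.radius_range))
            r0 = float(rng.uniform(rad, size - rad))
            c0 = float(rng.uniform(rad, size - rad))
            ok = all((r0 - r1) ** 2 + (c0 - c1) ** 2 > (rad + rad1) ** 2
                     for r1, c1, rad1 in placed)
            if ok:
                placed.append((r0, c0, rad))
                break
        # else: give up on this nucleus; shortfall visible via n_requested

    field_raw = rng.normal(size=(size, size))
    field = ndimage.gaussian_filter(field_raw, params.cytoplasm_smoothness)
    fmin, fmax = field.min(), field.max()
    if fmax > fmin:
        field = (field - fmin) / (fmax - fmin)
    else:
        field = np.zeros_like(field)
    return GroundTruthScene(width=size, height=size, nuclei=tuple(placed),
                            cytoplasm_field=field, seed=seed,
                            n_requested=n_req)


def render_pair(scene: GroundTruthScene,
                params: RenderParams = RenderParams(),
                noise_seed: int | None = None) -> PairedSample:
    """Render a scene into a paired (AF, stain) sample.

    Stain: Beer-Lambert transmission ``exp(-(mask * d_H * v_H
    + cytoplasm * d_E * v_E))`` per RGB channel, clipped to [0, 1].
    AF: affine combination of the nuclei mask and cytoplasm field plus seeded
    Gaussian noise, clipped to [0, 1].
    """
    v_h, v_e = params.vectors()
    mask = scene.nuclei_mask().astype(float)
    cyto = scene.cytoplasm_field
    od = (mask[..., None] * params.od_nuclei * v_h
          + cyto[..., None] * params.od_cytoplasm * v_e)
    stain = np.clip(np.exp(-od), 0.0, 1.0)

    rng = np.random.default_rng(scene.seed if noise_seed is None else noise_seed)
    af = (params.af_background
          + params.af_nuclei_gain * mask
          + params.af_cytoplasm_gain * cyto
          + rng.normal(0.0, params.af_noise_std, size=mask.shape))
    af = np.clip(af, 0.0, 1.0)
    return PairedSample(
        af=ImageFOV(af, Domain.AF, {"scene_seed": scene.seed}),
        stain=ImageFOV(stain, Domain.STAIN, {"scene_seed": scene.seed}),
        scene=scene,
    )


def dropout_keep_mask(n_nuclei: int, severity: float, seed: int) -> np.ndarray:
    """Boolean keep-mask used by nuclei_dropout: independent Bernoulli draws."""
    rng = np.random.default_rng(seed)
    return rng.random(n_nuclei) >= severity


def apply_degradation(stain: ImageFOV, scene: GroundTruthScene | None,
                      spec: DegradationSpec,
                      render_params: RenderParams = RenderParams()) -> ImageFOV:
    """Apply one degradation operator to a stain-domain image.

    ``severity == 0`` is the identity for every kind.  ``nuclei_dropout``
    re-renders the stain image from the scene with each nucleus independently
    removed with probability ``severity`` (it therefore requires the scene);
    the other kinds act pixel-wise on the given image.  Output stays in [0,1].
    """
    if stain.domain is not Domain.STAIN:
        raise ValueError("degradations apply to STAIN-domain images")
    if spec.kind == "compose":
        out = stain
        for part in spec.parts:
            out = apply_degradation(out, scene, part, render_params)
        return out
    if spec.severity == 0.0:
        return ImageFOV(stain.pixels.copy(), Domain.STAIN, dict(stain.meta))

    meta = dict(stain.meta)
    meta["degradation"] = f"{spec.kind}:{spec.severity}"
    if spec.kind == "nuclei_dropout":
        if scene is None:
            raise ValueError("nuclei_dropout requires the ground-truth scene")
        keep = dropout_keep_mask(len(scene.nuclei), spec.severity, spec.seed)
        kept = tuple(n for n, k in zip(scene.nuclei, keep) if k)
        reduced = replace(scene, nuclei=kept)
        rendered = render_pair(reduced, render_params).stain
        return ImageFOV(rendered.pixels, Domain.STAIN, meta)
    if spec.kind == "gaussian_blur":
        out = np.stack([ndimage.gaussian_filter(stain.pixels[..., c],
                                                spec.severity)
                        for c in range(3)], axis=-1)
        return ImageFOV(np.clip(out, 0, 1), Domain.STAIN, meta)
    if spec.kind == "colour_shift":
        hsv = skcolor.rgb2hsv(np.clip(stain.pixels, 0, 1))
        hsv[..., 0] = (hsv[..., 0] + spec.severity) % 1.0
        return ImageFOV(np.clip(skcolor.hsv2rgb(hsv), 0, 1), Domain.STAIN, meta)
    if spec.kind == "additive_noise":
        rng = np.random.default_rng(spec.seed)
        out = stain.pixels + rng.normal(0.0, spec.severity,
                                        size=stain.pixels.shape)
        return ImageFOV(np.clip(out, 0, 1), Domain.STAIN, meta)
    raise AssertionError(f"unreachable kind {spec.kind}")


@dataclass(frozen=True)
class FixtureConfig:
    """Configuration for a paired-image dataset written to disk."""

    n_train: int = 9
    n_val: int = 1
    n_test: int = 5
    size: int = 64
    seed: int = 0
    scene_params: SceneParams | None = None
    render_params: RenderParams = RenderParams()
    degradations: tuple[DegradationSpec, ...] = ()

    def __post_init__(self):
        if min(self.n_train, self.n_val, self.n_test) < 1:
            raise ValueError("all split counts must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FixtureConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        degr = tuple(DegradationSpec(**d) for d in raw.pop("degradations", []))
        scene = raw.pop("scene_params", None)
        sp = SceneParams(**scene) if scene else None
        rp = RenderParams(**raw.pop("render_params", {}))
        return cls(scene_params=sp, render_params=rp, degradations=degr, **raw)


def generate_samples(n: int, params: SceneParams, seed: int,
                     render_params: RenderParams = RenderParams()
                     ) -> list[PairedSample]:
    """Render ``n`` paired samples with per-sample scene seeds derived from
    ``seed`` (scene i uses seed ``seed * 100000 + i``)."""
    return [render_pair(sample_scene(params, seed * 100000 + i), render_params)
            for i in range(n)]


def build_fixture(config: FixtureConfig, out_dir: str | Path) -> Path:
    """Write a paired-image dataset plus a CSV manifest to ``out_dir``.

    The train/validation split assignment is a seeded shuffle of the first
    ``n_train + n_val`` samples; test samples follow.  Degradations from the
    config are applied cyclically to the stain images of the *test* split and
    recorded in the manifest's label column (clean otherwise).  Running twice
    with the same config yields byte-identical manifests.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory not writable: {out_dir}") from exc

    sp = config.scene_params or SceneParams(size=config.size)
    n_total = config.n_train + config.n_val + config.n_test
    samples = generate_samples(n_total, sp, config.seed, config.render_params)

    rng = np.random.default_rng(config.seed)
    trainval = rng.permutation(config.n_train + config.n_val)
    split = np.empty(n_total, dtype=object)
    split[trainval[:config.n_train]] = "train"
    split[trainval[config.n_train:]] = "val"
    split[config.n_train + config.n_val:] = "test"

    rows = []
    for i, sample in enumerate(samples):
        stain = sample.stain
        label = "clean"
        if split[i] == "test" and config.degradations:
            k = (i - config.n_train - config.n_val) % (len(config.degradations) + 1)
            if k > 0:
                spec = config.degradations[k - 1]
                spec = replace(spec, seed=spec.seed + i)
                stain = apply_degradation(stain, sample.scene, spec,
                                          config.render_params)
                label = spec.kind
        path_af = out_dir / f"{i:05d}_af.png"
        path_stain = out_dir / f"{i:05d}_stain.png"
        write_image(path_af, sample.af)
        write_image(path_stain, stain)
        rows.append({
            "path_af": path_af.name, "path_stain": path_stain.name,
            "split": split[i], "seed": sample.scene.seed, "label": label,
        })
    manifest = pd.DataFrame(rows)
    manifest_path = out_dir / "manifest.csv"
    manifest.to_csv(manifest_path, index=False, lineterminator="\n")
    return manifest_path
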