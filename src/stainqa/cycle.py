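"""Iterative forward/backward cycle inference between image domains.

A fixed, trusted pair of transforms (the best AF->STAIN and STAIN->AF
checkpoints, always distinct from the model under scrutiny) is iterated from
a starting image to build an alternating sequence of 2T frames.  Errors in
the image under test perturb the cycle away from the transforms' fixed point,
so inference uncertainty accumulates along the sequence — the signature the
downstream classifier consumes.

Two sequence conventions are supported:

* VS-start — a measured AF image ``x0`` and the image under test ``y0`` are
  both available: ``x_{t+1} = G_vaf(y_t)``, ``y_t = G_vs(x_t)``, frames
  ordered ``(x0, y0, x1, y1, ...)``;
* HS-start — no AF measurement exists (e.g. scrutinizing a real stained
  slide): the AF sequence is shifted one step back with ``x_t = G_vaf(y_t)``,
  ``y_{t+1} = G_vs(x_t)``, frames ordered ``(y0, x0, ..., y_{T-1}, x_{T-1})``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .images import Domain, ImageFOV, write_image
from .metrics import mse, pcc, psnr
from .staining import ssim as _ssim


class CycleMode(str, enum.Enum):
    VS_START = "VS_START"
    HS_START = "HS_START"


@dataclass
class CycleSequence:
    """The alternating 2T-frame sequence produced by cycle inference."""

    mode: CycleMode
    T: int
    frames: list[ImageFOV]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.frames) != 2 * self.T:
            raise ValueError(f"expected {2 * self.T} frames, got {len(self.frames)}")
        first = (Domain.AF if self.mode is CycleMode.VS_START else Domain.STAIN)
        for i, frame in enumerate(self.frames):
            expect = first if i % 2 == 0 else (
                Domain.STAIN if first is Domain.AF else Domain.AF)
            if frame.domain is not expect:
                raise ValueError(f"frame {i} has domain {frame.domain}, "
                                 f"expected {expect}")
        h, w = self.frames[0].height, self.frames[0].width
        if any((f.height, f.width) != (h, w) for f in self.frames):
            raise ValueError("all frames must share the same height/width")

    def stain_frames(self) -> list[ImageFOV]:
        offset = 1 if self.mode is CycleMode.VS_START else 0
        return self.frames[offset::2]

    def af_frames(self) -> list[ImageFOV]:
        offset = 0 if self.mode is CycleMode.VS_START else 1
        return self.frames[offset::2]

    def dump(self, out_dir: str | Path, fmt: str = "png") -> list[Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for t, frame in enumerate(self.frames):
            p = out_dir / f"frame_{t}_{frame.domain.value.lower()}.{fmt}"
            paths.append(write_image(p, frame.clipped()))
        return paths


def _check_directions(g_vs, g_vaf) -> None:
    from .staining import Direction
    if getattr(g_vs, "direction", None) is not None:
        if Direction(g_vs.direction) is not Direction.AF_TO_STAIN:
            raise ValueError("g_vs must map AF -> STAIN")
    if getattr(g_vaf, "direction", None) is not None:
        if Direction(g_vaf.direction) is not Direction.STAIN_TO_AF:
            raise ValueError("g_vaf must map STAIN -> AF")


def _apply(model, image: ImageFOV, domain: Domain) -> ImageFOV:
    out = model(image)
    pixels = out.pixels if isinstance(out, ImageFOV) else np.asarray(out)
    return ImageFOV(np.clip(pixels, 0.0, 1.0), domain)


def run_cycle_vs_start(x0: ImageFOV, y0: ImageFOV, g_vs, g_vaf,
                       T: int) -> CycleSequence:
    """Cycle from a measured AF image and a stain image under test.

    Uses ``2T - 2`` transform calls; ``T = 1`` returns ``(x0, y0)`` verbatim.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if x0.domain is not Domain.AF or y0.domain is not Domain.STAIN:
        raise ValueError("x0 must be AF and y0 must be STAIN")
    if (x0.height, x0.width) != (y0.height, y0.width):
        raise ValueError("x0 and y0 must have the same height/width")
    _check_directions(g_vs, g_vaf)

    xs = [x0]
    ys = [y0]
    for t in range(T - 1):
        xs.append(_apply(g_vaf, ys[t], Domain.AF))
        ys.append(_apply(g_vs, xs[t + 1], Domain.STAIN))
    frames: list[ImageFOV] = []
    for xt, yt in zip(xs, ys):
        frames.extend([xt, yt])
    return CycleSequence(
        mode=CycleMode.VS_START, T=T, frames=frames,
        provenance={"g_vs": getattr(g_vs, "model_id", repr(g_vs)),
                    "g_vaf": getattr(g_vaf, "model_id", repr(g_vaf))},
    )


def run_cycle_hs_start(y0: ImageFOV, g_vs, g_vaf, T: int) -> CycleSequence:
    """Cycle from a stain image alone (no AF measurement available).

    The backward transform substitutes the missing AF measurement, so the
    sequence takes ``2T - 1`` transform calls (T backward + T-1 forward).
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if y0.domain is not Domain.STAIN:
        raise ValueError("y0 must be a STAIN image")
    _check_directions(g_vs, g_vaf)

    ys = [y0]
    xs = [_apply(g_vaf, y0, Domain.AF)]
    for t in range(T - 1):
        ys.append(_apply(g_vs, xs[t], Domain.STAIN))
        xs.append(_apply(g_vaf, ys[t + 1], Domain.AF))
    frames: list[ImageFOV] = []
    for yt, xt in zip(ys, xs):
        frames.extend([yt, xt])
    return CycleSequence(
        mode=CycleMode.HS_START, T=T, frames=frames,
        provenance={"g_vs": getattr(g_vs, "model_id", repr(g_vs)),
                    "g_vaf": getattr(g_vaf, "model_id", repr(g_vaf))},
    )


_METRICS = {
    "mse": mse,
    "pcc": pcc,
    "psnr": psnr,
    "ssim": lambda a, b: _ssim(a, b),
}


def cycle_divergence_profile(seq: CycleSequence, metric: str = "mse"
                             ) -> list[float]:
    """Metric between each stain frame ``y_t`` and ``y_0`` for t = 0..T-1.

    The first entry is the metric's identity value (0 for mse, 1 for pcc and
    ssim, +inf for psnr); a growing profile indicates accumulated inference
    error.
    """
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}; "
                         f"choose from {sorted(_METRICS)}")
    fn = _METRICS[metric]
    stains = seq.stain_frames()
    y0 = stains[0].pixels
    return [float(fn(y.pixels, y0)) for y in stains]
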