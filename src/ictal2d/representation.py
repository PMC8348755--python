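"""2D image representation of feature maps.

Scale x time scalograms are rendered as filled-contour images; channel x
frequency maps are rendered one pixel per cell. Both pass through a fixed
perceptually-uniform colormap to produce the 3-channel rasters the network
consumes, after per-image min-max scaling (so images are invariant to
positive affine transforms of the feature values).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
from PIL import Image

from .eeg_io import NONSEIZURE, SEIZURE
from .features import FeatureMap

DEFAULT_COLORMAP = "viridis"
N_CONTOUR_LEVELS = 10

#: Per-channel normalization constants of networks pretrained on the
#: standard large natural-image corpus; matching them is what makes
#: transfer-learned backbones usable on these images.
IMAGENET_MEAN = (0.485, 0.456, 0.406)
IMAGENET_STD = (0.229, 0.224, 0.225)

AUGMENT_OPS = ("flip_h", "flip_v", "rot90", "rot180", "rot270")


@dataclass
class RepresentationImage:
    """A 3-channel uint8 raster derived from a feature map."""

    pixels: np.ndarray  # H x W x 3, uint8
    source_axes: dict = field(default_factory=dict)
    label: str = NONSEIZURE

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(
                f"image must be H x W x 3, got shape {self.pixels.shape}"
            )
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must be at least 1 x 1")
        if self.pixels.dtype != np.uint8:
            self.pixels = np.clip(self.pixels, 0, 255).astype(np.uint8)
        if self.label not in (SEIZURE, NONSEIZURE):
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape


@dataclass
class NetInput:
    """A normalized 3 x R x R tensor ready for the network."""

    tensor: np.ndarray
    R: int

    def __post_init__(self) -> None:
        self.tensor = np.asarray(self.tensor, dtype=np.float32)
        if self.tensor.shape != (3, self.R, self.R):
            raise ValueError(
                f"tensor shape {self.tensor.shape} != (3, {self.R}, {self.R})"
            )


def _colormap(name: str):
    import matplotlib

    return matplotlib.colormaps[name]


def _minmax(values: np.ndarray) -> np.ndarray:
    lo, hi = float(values.min()), float(values.max())
    if hi <= lo:
        return np.full(values.shape, 0.5)
    return (values - lo) / (hi - lo)


def render_scalogram_image(
    fm: FeatureMap,
    out_res: int = 224,
    colormap: str = DEFAULT_COLORMAP,
    label: str = NONSEIZURE,
) -> RepresentationImage:
    """Render a scale x time scalogram as a filled-contour image.

    Values are min-max scaled per image and contoured at 10 equally spaced
    levels, time on the horizontal axis and scale on the vertical axis,
    rasterized at out_res x out_res with no axes or margins. A constant map
    renders as a uniform image.
    """
    if fm.row_axis != "scale":
        raise ValueError(
            f"render_scalogram_image expects row_axis='scale', got "
            f"{fm.row_axis!r}; use render_matrix_image for channel maps"
        )
    if out_res < 1:
        raise ValueError("out_res must be positive")
    cmap = _colormap(colormap)
    norm = _minmax(fm.values)
    if norm.min() == norm.max():
        rgba = np.asarray(cmap(0.5))
        pixels = np.tile(
            np.round(rgba[:3] * 255).astype(np.uint8), (out_res, out_res, 1)
        )
        return RepresentationImage(pixels=pixels,
                                   source_axes=_axes_meta(fm), label=label)

    from matplotlib.backends.backend_agg import FigureCanvasAgg
    from matplotlib.figure import Figure

    fig = Figure(figsize=(1, 1), dpi=out_res)
    canvas = FigureCanvasAgg(fig)
    ax = fig.add_axes((0, 0, 1, 1))
    ax.set_axis_off()
    levels = np.linspace(0.0, 1.0, N_CONTOUR_LEVELS + 1)
    ax.contourf(norm, levels=levels, cmap=cmap, origin="lower")
    canvas.draw()
    buf = np.asarray(canvas.buffer_rgba())[:, :, :3].copy()
    return RepresentationImage(pixels=buf, source_axes=_axes_meta(fm),
                               label=label)


def render_matrix_image(
    fm: FeatureMap,
    colormap: str = DEFAULT_COLORMAP,
    label: str = NONSEIZURE,
) -> RepresentationImage:
    """Render a channel x frequency map one pixel per cell.

    Intensities are per-image min-max scaled and passed through the
    colormap; a 23 x 23 map yields a 23 x 23 x 3 image, a 23 x 46 map a
    23 x 46 x 3 image.
    """
    if fm.row_axis != "channel":
        raise ValueError(
            f"render_matrix_image expects row_axis='channel', got "
            f"{fm.row_axis!r}; use render_scalogram_image for scalograms"
        )
    cmap = _colormap(colormap)
    rgba = cmap(_minmax(fm.values))
    pixels = np.round(rgba[:, :, :3] * 255).astype(np.uint8)
    return RepresentationImage(pixels=pixels, source_axes=_axes_meta(fm),
                               label=label)


def augment(
    img: RepresentationImage, ops: set[str] | frozenset[str] | list[str]
) -> list[RepresentationImage]:
    """Return the original image plus one flipped/rotated copy per op.

    Labels are preserved. Ops are applied in a fixed order for
    reproducibility.
    """
    transforms = {
        "flip_h": lambda p: p[:, ::-1, :],
        "flip_v": lambda p: p[::-1, :, :],
        "rot90": lambda p: np.rot90(p, k=1, axes=(0, 1)),
        "rot180": lambda p: np.rot90(p, k=2, axes=(0, 1)),
        "rot270": lambda p: np.rot90(p, k=3, axes=(0, 1)),
    }
    unknown = set(ops) - set(transforms)
    if unknown:
        raise ValueError(
            f"unknown augmentation ops {sorted(unknown)}; "
            f"valid ops are {sorted(transforms)}"
        )
    out = [img]
    for op in (o for o in AUGMENT_OPS if o in set(ops)):
        out.append(
            RepresentationImage(
                pixels=np.ascontiguousarray(transforms[op](img.pixels)),
                source_axes=dict(img.source_axes),
                label=img.label,
            )
        )
    return out


def to_net_input(
    img: RepresentationImage,
    R: int,
    mean: tuple[float, float, float] = IMAGENET_MEAN,
    std: tuple[float, float, float] = IMAGENET_STD,
) -> NetInput:
    """Bilinearly resize to R x R, scale to [0, 1], standardize per channel."""
    if R < 1:
        raise ValueError("resolution must be positive")
    pil = Image.fromarray(img.pixels)
    if pil.size != (R, R):
        pil = pil.resize((R, R), resample=Image.BILINEAR)
    arr = np.asarray(pil, dtype=np.float32) / 255.0  # R x R x 3
    arr = (arr - np.asarray(mean, dtype=np.float32)) / np.asarray(
        std, dtype=np.float32
    )
    return NetInput(tensor=arr.transpose(2, 0, 1), R=R)


def save_image(img: RepresentationImage, path: str | os.PathLike) -> None:
    """Write the image as PNG with a JSON sidecar (label, source axes)."""
    Image.fromarray(img.pixels).save(path, format="PNG")
    with open(f"{os.fspath(path)}.json", "w") as fh:
        json.dump({"label": img.label, "source_axes": img.source_axes}, fh)


def load_image(path: str | os.PathLike) -> RepresentationImage:
    pixels = np.asarray(Image.open(path).convert("RGB"))
    meta_path = f"{os.fspath(path)}.json"
    label, axes = NONSEIZURE, {}
    if os.path.exists(meta_path):
        with open(meta_path) as fh:
            meta = json.load(fh)
        label, axes = meta.get("label", NONSEIZURE), meta.get("source_axes", {})
    return RepresentationImage(pixels=pixels, source_axes=axes, label=label)


def _axes_meta(fm: FeatureMap) -> dict:
    return {
        "row_axis": fm.row_axis,
        "col_axis": fm.col_axis,
        "row_labels": [float(v) for v in fm.row_labels],
        "col_labels": [float(v) for v in fm.col_labels],
    }
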