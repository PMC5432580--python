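"""Photo preparation: chroma-key masking and downsampling bookkeeping.

Structure-from-motion reconstruction works best when everything outside the
subject is masked out.  With a chroma-key (green-screen) backdrop a binary
mask can be generated per photo automatically: background pixels (0) are
those close to the key color in a luminance-separated chroma plane, the
object is 1.  The downsampling-rate arithmetic normalizes reduced image
counts/resolutions against the reference acquisition of 56 photos at 24
megapixels.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Optional

import numpy as np
import scipy.ndimage as ndi
from skimage.color import rgb2hsv
from skimage.filters import threshold_otsu
from skimage.transform import resize


def _chroma_distance(photo: np.ndarray, key_color) -> np.ndarray:
    """Distance to the key color in the hue/saturation disc.

    Hue and saturation are luminance-insensitive, so shadows and lighting
    gradients on the green screen stay close to the key.
    """
    img = np.asarray(photo, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] < 3:
        raise ValueError("photo must be RGB")
    if img.max() > 1.0:
        img = img / 255.0
    key = np.asarray(key_color, dtype=np.float64).reshape(1, 1, 3)
    if key.max() > 1.0:
        key = key / 255.0
    hsv = rgb2hsv(img[..., :3])
    khsv = rgb2hsv(key)[0, 0]
    ang = 2 * np.pi * hsv[..., 0]
    kang = 2 * np.pi * khsv[0]
    x = hsv[..., 1] * np.cos(ang) - khsv[1] * np.cos(kang)
    y = hsv[..., 1] * np.sin(ang) - khsv[1] * np.sin(kang)
    return np.sqrt(x ** 2 + y ** 2)


def _valley_threshold(dist: np.ndarray) -> float:
    """Valley between the two main modes of the chroma-distance histogram;
    falls back to Otsu when the histogram is not clearly bimodal."""
    hist, edges = np.histogram(dist.ravel(), bins=128)
    smooth = ndi.gaussian_filter1d(hist.astype(np.float64), sigma=2.5)
    peaks = [i for i in range(1, 127)
             if smooth[i] >= smooth[i - 1] and smooth[i] >= smooth[i + 1]]
    peaks = sorted(peaks, key=lambda i: -smooth[i])[:2]
    if len(peaks) == 2:
        lo, hi = sorted(peaks)
        valley = lo + int(np.argmin(smooth[lo:hi + 1]))
        return float((edges[valley] + edges[valley + 1]) / 2.0)
    return float(threshold_otsu(dist))


def chroma_mask(photo: np.ndarray, key_color=(0, 190, 70),
                threshold: Optional[float] = None) -> np.ndarray:
    """Binary object mask from a chroma-key photo: 0 = background (within
    ``threshold`` of the key color in the chroma plane), 1 = object.

    The threshold defaults to the valley of the bimodal chroma-distance
    histogram.  The largest connected foreground component is kept and its
    holes filled.  If no key-colored region is found in auto mode the photo
    is returned fully foreground with a warning.
    """
    dist = _chroma_distance(photo, key_color)
    if threshold is None:
        if dist.min() > 0.25:  # nothing near the key color at all
            warnings.warn("no key-colored background found; returning "
                          "full-foreground mask")
            return np.ones(dist.shape, dtype=np.uint8)
        thr = _valley_threshold(dist)
    else:
        thr = float(threshold)
    fg = dist > thr
    if fg.any():
        lab, n = ndi.label(fg)
        if n > 1:
            sizes = ndi.sum(fg, lab, index=np.arange(1, n + 1))
            fg = lab == (1 + int(np.argmax(sizes)))
        fg = ndi.binary_fill_holes(fg)
    return fg.astype(np.uint8)


def save_mask(mask: np.ndarray, path) -> Path:
    """Write a mask as single-channel PNG, 0 = background, 255 = object."""
    import imageio.v3 as iio

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, (np.asarray(mask) > 0).astype(np.uint8) * 255)
    return path


def downsampling_rate(n_images: int, megapixels: float,
                      n_ref: int = 56, mp_ref: float = 24.0) -> float:
    """Normalized downsampling rate in [0, 1].

    rate = 1 - (n_images * megapixels) / (n_ref * mp_ref): 0 means full
    information (the reference acquisition), 1 no information.
    """
    if n_images <= 0 or megapixels <= 0 or n_ref <= 0 or mp_ref <= 0:
        raise ValueError("arguments must be positive")
    rate = 1.0 - (n_images * megapixels) / (n_ref * mp_ref)
    if rate < -1e-12:
        raise ValueError("more pixel information than the reference; "
                         "rate would be negative")
    return max(0.0, rate)


def downsample_image(photo: np.ndarray, target_mp: float) -> np.ndarray:
    """Aspect-ratio-preserving resampling to ``target_mp`` megapixels
    (within 1%).  Upsampling is refused."""
    img = np.asarray(photo)
    h, w = img.shape[:2]
    src_mp = h * w / 1e6
    if target_mp > src_mp * (1 + 1e-9):
        raise ValueError(f"target {target_mp} MP exceeds source {src_mp:.2f} MP")
    if abs(target_mp - src_mp) / src_mp < 1e-9:
        return img.copy()
    scale = np.sqrt(target_mp * 1e6 / (h * w))
    nh, nw = max(1, round(h * scale)), max(1, round(w * scale))
    out = resize(img, (nh, nw) + img.shape[2:], anti_aliasing=True,
                 preserve_range=True)
    return out.astype(img.dtype)
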