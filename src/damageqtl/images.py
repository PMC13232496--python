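"""Image-based quantification of insect feeding damage on plants.

Two complementary methods are provided for photographs taken against a
uniform lightbox background:

* **DTR** (supervised RGB thresholding): every plant pixel is classified as
  green, yellow (chlorotic) or necrotic tissue by fixed inequalities on its
  normalised R, G, B values.
* **DQU** (unsupervised colour quantisation): plant pixels are clustered by
  the median-cut algorithm into up to three colour subgroups, and each
  cluster is then mapped to a tissue class.

Both reduce an image to tissue-class pixel counts, from which the damage
fraction ``(yellow + necrotic) / (yellow + necrotic + green)`` is computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError

logger = logging.getLogger(__name__)

__all__ = [
    "RGBImage",
    "TissueCounts",
    "QuantizationResult",
    "GREEN",
    "YELLOW",
    "NECROTIC",
    "UNCLASSIFIED",
    "DEFAULT_CLASS_PROTOTYPES",
    "load_image",
    "mask_background",
    "classify_pixels_dtr",
    "median_cut_quantize",
    "assign_clusters_to_classes",
    "damage_score",
    "batch_quantify",
    "EmptyMaskError",
    "DamageUndefinedError",
]

# tissue-class label codes (order also breaks prototype-distance ties)
GREEN, YELLOW, NECROTIC, UNCLASSIFIED = 0, 1, 2, 3
_CLASS_NAMES = {GREEN: "green", YELLOW: "yellow", NECROTIC: "necrotic"}

#: RGB prototypes used when a cluster centroid satisfies none of the
#: threshold rules; chosen as typical healthy-green, chlorotic-yellow and
#: necrotic-brown leaf colours. Override via ``assign_clusters_to_classes``.
DEFAULT_CLASS_PROTOTYPES: Mapping[int, tuple[float, float, float]] = {
    GREEN: (58 / 255, 159 / 255, 70 / 255),
    YELLOW: (197 / 255, 140 / 255, 102 / 255),
    NECROTIC: (121 / 255, 89 / 255, 8 / 255),
}


class EmptyMaskError(ValueError):
    """Raised when background removal leaves no plant pixels."""


class DamageUndefinedError(ValueError):
    """Raised when an image has no classified tissue pixels."""


@dataclass
class RGBImage:
    """An RGB image with channels normalised to [0, 1].

    Parameters
    ----------
    pixels : ndarray, shape (H, W, 3)
        Channel values in [0, 1].
    mask : ndarray of bool, shape (H, W), optional
        True where the pixel belongs to the plant (foreground).
    source_path : str
        Origin of the image, for reporting.
    bit_depth : int
        Integer depth of the original file (8 for standard PNG/JPEG).
    """

    pixels: np.ndarray
    mask: np.ndarray | None = None
    source_path: str = ""
    bit_depth: int = 8

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must have shape (H, W, 3)")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("channel values must lie in [0, 1]")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.pixels.shape[:2]:
                raise ValueError(
                    f"mask shape {self.mask.shape} does not match image "
                    f"shape {self.pixels.shape[:2]}"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def masked_pixels(self) -> np.ndarray:
        """Plant pixels as an (N, 3) array; requires a mask."""
        if self.mask is None:
            raise ValueError("image has no plant mask")
        return self.pixels[self.mask]


@dataclass
class TissueCounts:
    """Pixel counts per tissue class for one image."""

    green: int = 0
    yellow: int = 0
    necrotic: int = 0
    unclassified: int = 0

    def __post_init__(self) -> None:
        for name in ("green", "yellow", "necrotic", "unclassified"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} count must be >= 0")

    @property
    def total(self) -> int:
        return self.green + self.yellow + self.necrotic + self.unclassified

    @property
    def classified(self) -> int:
        return self.green + self.yellow + self.necrotic


@dataclass
class QuantizationResult:
    """Outcome of median-cut colour quantisation on the plant pixels.

    ``labels`` has the full image shape with -1 outside the mask;
    ``class_of_cluster`` is filled by :func:`assign_clusters_to_classes`.
    """

    centroids: np.ndarray  # (k, 3)
    labels: np.ndarray  # (H, W) int, -1 outside mask
    cluster_sizes: np.ndarray  # (k,)
    class_of_cluster: dict[int, int] = field(default_factory=dict)


def load_image(path: str | Path, mask_path: str | Path | None = None) -> RGBImage:
    """Read a PNG or JPEG image and normalise channels to [0, 1].

    A mask image, if given, is interpreted as foreground where non-zero.
    """
    path = Path(path)
    with Image.open(path) as im:
        im = im.convert("RGB")
        arr = np.asarray(im, dtype=float)
    bit_depth = 8
    pixels = arr / (2**bit_depth - 1)
    mask = None
    if mask_path is not None:
        with Image.open(mask_path) as mim:
            mask = np.asarray(mim.convert("L")) > 0
        if mask.shape != pixels.shape[:2]:
            raise ValueError(
                f"mask shape {mask.shape} does not match image shape "
                f"{pixels.shape[:2]} for {path}"
            )
    return RGBImage(pixels=pixels, mask=mask, source_path=str(path), bit_depth=bit_depth)


def mask_background(
    img: RGBImage,
    background_color: Sequence[float],
    tol: float = 2 / 255,
) -> RGBImage:
    """Build a plant mask by excluding near-background pixels.

    A pixel is background when all three channels lie within ``tol`` of
    ``background_color``. Suitable for lightbox images with a uniform
    backdrop.
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    bg = np.asarray(background_color, dtype=float)
    if bg.shape != (3,):
        raise ValueError("background_color must be an RGB triple")
    is_bg = np.all(np.abs(img.pixels - bg) <= tol, axis=2)
    mask = ~is_bg
    if not mask.any():
        raise EmptyMaskError(
            "background removal left no plant pixels "
            f"(background={bg.tolist()}, tol={tol})"
        )
    return RGBImage(
        pixels=img.pixels,
        mask=mask,
        source_path=img.source_path,
        bit_depth=img.bit_depth,
    )


# --- supervised thresholding (DTR) -------------------------------------------

def _dtr_green(r: np.ndarray, g: np.ndarray, b: np.ndarray) -> np.ndarray:
    return (r < 0.9 * g) & (b < 0.9 * g) & (2 * g > (20 / 255) * (b + r))


def _dtr_yellow(r: np.ndarray, g: np.ndarray, b: np.ndarray) -> np.ndarray:
    return (
        (90 / 255 < r) & (r < 241 / 255)
        & (97 / 255 < g) & (g < 216 / 255)
        & (18 / 255 < b) & (b < 165 / 255)
    )


def _dtr_necrotic(r: np.ndarray, g: np.ndarray, b: np.ndarray) -> np.ndarray:
    return (
        (27 / 255 < r) & (r < 225 / 255)
        & (56 / 255 < g) & (g < 213 / 255)
        & (0 < b) & (b < 53 / 255)
    )


def classify_pixels_dtr(img: RGBImage) -> tuple[TissueCounts, np.ndarray]:
    """Classify plant pixels into tissue classes by fixed RGB thresholds.

    Each masked pixel receives exactly one label; the rules are evaluated in
    the precedence order green, yellow, necrotic (the yellow and necrotic
    boxes overlap, so order matters) with all inequalities strict. Pixels
    matching no rule are labelled unclassified.

    Returns
    -------
    counts : TissueCounts
    labels : ndarray, shape (H, W)
        Label codes; -1 outside the plant mask.
    """
    if img.mask is None:
        raise ValueError(
            "image has no plant mask; supply one or call mask_background first"
        )
    r, g, b = img.pixels[..., 0], img.pixels[..., 1], img.pixels[..., 2]
    labels = np.full(img.shape, -1, dtype=np.int8)
    m = img.mask
    lab = np.full(m.sum(), UNCLASSIFIED, dtype=np.int8)
    rm, gm, bm = r[m], g[m], b[m]
    is_green = _dtr_green(rm, gm, bm)
    is_yellow = ~is_green & _dtr_yellow(rm, gm, bm)
    is_necro = ~is_green & ~is_yellow & _dtr_necrotic(rm, gm, bm)
    lab[is_green] = GREEN
    lab[is_yellow] = YELLOW
    lab[is_necro] = NECROTIC
    labels[m] = lab
    counts = TissueCounts(
        green=int(is_green.sum()),
        yellow=int(is_yellow.sum()),
        necrotic=int(is_necro.sum()),
        unclassified=int((lab == UNCLASSIFIED).sum()),
    )
    return counts, labels


# --- unsupervised colour quantisation (DQU) -----------------------------------

def median_cut_quantize(img: RGBImage, n_clusters: int = 3) -> QuantizationResult:
    """Median-cut colour quantisation of the plant pixels.

    Starting from one box holding all masked pixels, the box whose widest
    channel range is largest is repeatedly split at the median of that
    channel until ``n_clusters`` boxes exist or no box is splittable.
    Deterministic tie-breaks: among boxes with equal widest range the one
    with more pixels is split, then the lower box index; pixels whose value
    equals the median go to the lower box. Each cluster centroid is the mean
    colour of its box.
    """
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    if img.mask is None:
        raise ValueError("image has no plant mask")
    pix = img.masked_pixels()
    if pix.shape[0] == 0:
        raise EmptyMaskError("plant mask is empty")

    boxes: list[np.ndarray] = [np.arange(pix.shape[0])]
    while len(boxes) < n_clusters:
        best_key = None
        best_i = -1
        for i, idx in enumerate(boxes):
            sub = pix[idx]
            ranges = sub.max(axis=0) - sub.min(axis=0)
            widest = float(ranges.max())
            if widest <= 0:
                continue  # single colour: unsplittable
            key = (widest, len(idx), -i)
            if best_key is None or key > best_key:
                best_key, best_i = key, i
        if best_key is None:
            break
        idx = boxes[best_i]
        sub = pix[idx]
        ranges = sub.max(axis=0) - sub.min(axis=0)
        ch = int(np.argmax(ranges))  # ties -> lowest channel index
        vals = sub[:, ch]
        med = np.median(vals)
        lower = vals <= med
        if lower.all():  # median equals the max; keep the upper box non-empty
            lower = vals < med
        boxes[best_i] = idx[lower]
        boxes.insert(best_i + 1, idx[~lower])

    centroids = np.array([pix[idx].mean(axis=0) for idx in boxes])
    sizes = np.array([len(idx) for idx in boxes])
    flat_labels = np.empty(pix.shape[0], dtype=np.int32)
    for k, idx in enumerate(boxes):
        flat_labels[idx] = k
    labels = np.full(img.shape, -1, dtype=np.int32)
    labels[img.mask] = flat_labels
    return QuantizationResult(centroids=centroids, labels=labels, cluster_sizes=sizes)


def assign_clusters_to_classes(
    q: QuantizationResult,
    prototypes: Mapping[int, tuple[float, float, float]] = DEFAULT_CLASS_PROTOTYPES,
) -> TissueCounts:
    """Map quantisation clusters to tissue classes and aggregate counts.

    Each centroid is first classified by the DTR threshold rules (same
    precedence as :func:`classify_pixels_dtr`). A centroid matching no rule
    is assigned to the nearest class prototype by Euclidean RGB distance,
    with ties broken by the fixed class order green < yellow < necrotic.
    Every cluster receives a class, so the unclassified count is zero.
    """
    counts = {GREEN: 0, YELLOW: 0, NECROTIC: 0}
    proto_classes = sorted(prototypes)  # green < yellow < necrotic
    proto_colors = np.array([prototypes[c] for c in proto_classes], dtype=float)
    q.class_of_cluster = {}
    for k, (centroid, size) in enumerate(zip(q.centroids, q.cluster_sizes)):
        r, g, b = centroid
        if _dtr_green(r, g, b):
            cls = GREEN
        elif _dtr_yellow(r, g, b):
            cls = YELLOW
        elif _dtr_necrotic(r, g, b):
            cls = NECROTIC
        else:
            d2 = ((proto_colors - centroid) ** 2).sum(axis=1)
            cls = proto_classes[int(np.argmin(d2))]  # argmin ties -> first
        q.class_of_cluster[k] = cls
        counts[cls] += int(size)
    return TissueCounts(
        green=counts[GREEN], yellow=counts[YELLOW], necrotic=counts[NECROTIC],
        unclassified=0,
    )


def damage_score(counts: TissueCounts) -> float:
    """Damage fraction ``(yellow + necrotic) / (yellow + necrotic + green)``.

    Unclassified pixels are excluded from the denominator.
    """
    denom = counts.classified
    if denom <= 0:
        raise DamageUndefinedError("no classified tissue pixels: damage undefined")
    return (counts.yellow + counts.necrotic) / denom


# --- batch processing ----------------------------------------------------------

_IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg"}


def _quantify_one(img: RGBImage, method: str) -> list[dict]:
    rows = []
    if method in ("dtr", "both"):
        counts, _ = classify_pixels_dtr(img)
        rows.append(("dtr", counts))
    if method in ("dqu", "both"):
        q = median_cut_quantize(img, n_clusters=3)
        counts = assign_clusters_to_classes(q)
        rows.append(("dqu", counts))
    out = []
    for meth, counts in rows:
        try:
            dmg = damage_score(counts)
        except DamageUndefinedError:
            dmg = np.nan
        out.append(
            dict(
                method=meth,
                n_green=counts.green,
                n_yellow=counts.yellow,
                n_necrotic=counts.necrotic,
                n_unclassified=counts.unclassified,
                damage=dmg,
            )
        )
    return out


def batch_quantify(
    image_dir: str | Path,
    method: str = "both",
    mask_dir: str | Path | None = None,
    background_color: Sequence[float] | None = None,
    tol: float = 2 / 255,
) -> pd.DataFrame:
    """Quantify damage for every image in a directory.

    Masks are looked up in ``mask_dir`` by stem (``<stem>.png``); otherwise a
    uniform-background rule (``background_color``, ``tol``) builds the mask.
    Unreadable or maskless images are logged and skipped, never fatal.

    Returns a table with one row per image and method:
    image_id, method, n_green, n_yellow, n_necrotic, n_unclassified, damage.
    """
    if method not in ("dtr", "dqu", "both"):
        raise ValueError("method must be 'dtr', 'dqu' or 'both'")
    image_dir = Path(image_dir)
    paths = sorted(p for p in image_dir.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES)
    if mask_dir is not None:
        mask_dir = Path(mask_dir)
        paths = [p for p in paths if not (p.parent == mask_dir and "mask" in p.stem)]
    if not paths:
        raise ValueError(f"no decodable images found in {image_dir}")
    rows = []
    n_skipped = 0
    for p in paths:
        try:
            mask_path = None
            if mask_dir is not None:
                cand = mask_dir / f"{p.stem}_mask.png"
                if not cand.exists():
                    cand = mask_dir / f"{p.stem}.png"
                if cand.exists() and cand != p:
                    mask_path = cand
            img = load_image(p, mask_path)
            if img.mask is None:
                if background_color is None:
                    raise ValueError("no mask found and no background rule configured")
                img = mask_background(img, background_color, tol)
            for rec in _quantify_one(img, method):
                rec["image_id"] = p.stem
                rows.append(rec)
        except (OSError, UnidentifiedImageError, ValueError) as exc:
            n_skipped += 1
            logger.warning("skipping %s: %s", p.name, exc)
    if n_skipped:
        logger.info("batch_quantify: %d image(s) skipped", n_skipped)
    cols = ["image_id", "method", "n_green", "n_yellow", "n_necrotic",
            "n_unclassified", "damage"]
    return pd.DataFrame(rows, columns=cols)
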