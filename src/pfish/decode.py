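"""Decoding of multi-round bit-image stacks into guide-spot tables.

The decoding chain mirrors a standard MERFISH-style readout: per-round
registration against fiducials, flat-field correction by a per-channel
background image, band-pass spot enhancement, z max-projection, threshold
binarization with morphological QC (area 7–450 px, eccentricity ≤ 0.8),
assembly of per-candidate bit vectors within a 5-pixel radius, single-error
codebook matching, an intensity-based two-cluster QC filter, and a
blank-normalized misidentification-rate estimate.

Coordinates are 0-based ``(x right, y down)`` with the half-open pixel
convention; centroids are intensity-unweighted component centroids.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure
from skimage.filters import gaussian
from skimage.registration import phase_cross_correlation
from sklearn.cluster import KMeans

from .codebook import Codebook

__all__ = [
    "PreprocessParams",
    "ErrorRateReport",
    "DecodeError",
    "register_rounds",
    "preprocess_bit_image",
    "detect_spots",
    "assemble_and_decode",
    "qc_filter_spots",
    "estimate_error_rate",
    "decode_field",
]

SPOT_MIN_AREA = 7
SPOT_MAX_AREA = 450
SPOT_MAX_ECCENTRICITY = 0.8

SPOT_COLUMNS = [
    "x",
    "y",
    "bits",
    "identity",
    "is_blank",
    "mean_intensity",
    "std_intensity",
    "area",
    "eccentricity",
    "qc_pass",
]


class DecodeError(ValueError):
    pass


@dataclass
class PreprocessParams:
    """Tunable knobs of the spot-image preprocessing.

    ``enhance_sigma`` / ``background_sigma`` are Gaussian standard
    deviations in pixels (band-pass: enhance minus broad blur).  The
    binarization ``threshold`` is absolute intensity in the preprocessed
    image; when ``None`` it defaults to mean + 3 std of that image.
    """

    enhance_sigma: float = 2.0
    background_sigma: float = 12.0
    n_z: int = 7
    threshold: float | None = None
    radius: float = 5.0

    def __post_init__(self) -> None:
        if self.enhance_sigma >= self.background_sigma:
            raise DecodeError("enhance_sigma must be smaller than background_sigma")
        if self.radius < 1:
            raise DecodeError("assembly radius must be at least 1 pixel")


@dataclass
class ErrorRateReport:
    """Blank-normalized misidentification rate.

    ``rate_percent = 100 × (n_blank / B) / ((n_total − n_blank) / R)``:
    blank calls per blank barcode relative to real calls per real barcode,
    so that the rate is insensitive to the codebook's blank fraction.
    """

    n_total: int
    n_blank: int
    n_targeting_barcodes: int  # R
    n_blank_barcodes: int  # B
    rate_percent: float

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)


def register_rounds(
    images: list[np.ndarray], fiducials: list[np.ndarray]
) -> tuple[list[tuple[int, int]], list[np.ndarray]]:
    """Estimate per-round integer translations against round 0 and shift.

    Offsets come from the cross-correlation peak of each round's fiducial
    image with the first round's.  Returns ``(offsets, shifted_images)``
    where ``offsets[r] = (dy, dx)`` is the displacement of round r relative
    to round 0 and the shifted images have it removed.
    """
    if len(images) != len(fiducials):
        raise DecodeError("need one fiducial image per round")
    ref = np.asarray(fiducials[0], dtype=float)
    offsets: list[tuple[int, int]] = []
    shifted: list[np.ndarray] = []
    for img, fid in zip(images, fiducials):
        fid = np.asarray(fid, dtype=float)
        if fid.shape != ref.shape:
            raise DecodeError("fiducial images must share dimensions")
        if fid.std() == 0 or ref.std() == 0:
            raise DecodeError("registration error: featureless fiducial image")
        shift, _, _ = phase_cross_correlation(ref, fid, upsample_factor=1)
        dy, dx = int(round(shift[0])), int(round(shift[1]))
        offsets.append((-dy, -dx))  # displacement of this round w.r.t. round 0
        shifted.append(np.roll(np.asarray(img, dtype=float), (dy, dx), axis=(0, 1)))
    return offsets, shifted


def preprocess_bit_image(
    raw: np.ndarray, background: np.ndarray, params: PreprocessParams | None = None
) -> np.ndarray:
    """Flat-field, band-pass enhance and z max-project one bit image.

    ``raw`` is a ``(n_z, H, W)`` stack (a 2D image is treated as a single
    plane).  Order of operations: divide by the channel background, Gaussian
    enhance (σ = ``enhance_sigma``), subtract the broad Gaussian blur
    (σ = ``background_sigma``) of the divided image, max-project over z,
    clip at zero.
    """
    params = params or PreprocessParams()
    raw = np.asarray(raw, dtype=float)
    background = np.asarray(background, dtype=float)
    if np.any(background <= 0):
        raise DecodeError("background image must be strictly positive")
    if raw.ndim == 2:
        raw = raw[None, :, :]
    if raw.shape[-2:] != background.shape:
        raise DecodeError("raw and background dimensions disagree")
    flat = raw / background[None, :, :]
    planes = []
    for z in range(flat.shape[0]):
        enhanced = gaussian(flat[z], sigma=params.enhance_sigma, preserve_range=True)
        broad = gaussian(flat[z], sigma=params.background_sigma, preserve_range=True)
        planes.append(enhanced - broad)
    out = np.max(planes, axis=0)
    return np.clip(out, 0.0, None)


def detect_spots(
    image: np.ndarray, threshold: float | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Threshold, label (8-connectivity) and morphologically filter spots.

    Components with area < 7 px, area > 450 px or eccentricity > 0.8 are
    removed.  Returns a table (x, y, area, eccentricity) of retained objects
    and the binary mask of their pixels.
    """
    image = np.asarray(image, dtype=float)
    if threshold is None:
        threshold = float(image.mean() + 3.0 * image.std())
    if threshold <= 0:
        raise DecodeError("binarization threshold must be positive")
    binary = image > threshold
    labels = measure.label(binary, connectivity=2)
    keep_mask = np.zeros_like(binary)
    rows = []
    for prop in measure.regionprops(labels):
        if prop.area < SPOT_MIN_AREA or prop.area > SPOT_MAX_AREA:
            continue
        if prop.eccentricity > SPOT_MAX_ECCENTRICITY:
            continue
        cy, cx = prop.centroid
        rows.append({"x": cx, "y": cy, "area": int(prop.area),
                     "eccentricity": float(prop.eccentricity)})
        keep_mask[labels == prop.label] = True
    df = pd.DataFrame(rows, columns=["x", "y", "area", "eccentricity"])
    return df, keep_mask


def assemble_and_decode(
    bit_masks: list[np.ndarray],
    bit_objects: list[pd.DataFrame],
    images: list[np.ndarray],
    codebook: Codebook,
    radius: float = 5.0,
) -> pd.DataFrame:
    """Assemble per-candidate bit vectors and match them to the codebook.

    Candidate centroids are the connected components of the logical OR of
    all retained per-bit masks.  Bit ``b`` of a candidate is "on" iff some
    retained object in bit image ``b`` has its centroid within ``radius``
    pixels of the candidate centroid.  Per-bit intensities are sampled at
    the candidate centroid from the preprocessed images; the reported mean
    and standard deviation are taken across the on-bits.
    """
    L = codebook.n_bits
    if len(bit_masks) != L or len(bit_objects) != L or len(images) != L:
        raise DecodeError(
            f"codebook expects {L} bit images, got "
            f"{len(bit_masks)}/{len(bit_objects)}/{len(images)}"
        )
    shapes = {m.shape for m in bit_masks}
    if len(shapes) != 1:
        raise DecodeError("bit images must share dimensions")

    union = np.zeros(bit_masks[0].shape, dtype=bool)
    for m in bit_masks:
        union |= m.astype(bool)
    labels = measure.label(union, connectivity=2)
    props = measure.regionprops(labels)

    centroids = [np.asarray(df[["x", "y"]], dtype=float) for df in bit_objects]
    blank_ids = codebook.blank_identities

    rows = []
    for prop in props:
        cy, cx = prop.centroid
        bits = np.zeros(L, dtype=np.uint8)
        for b in range(L):
            pts = centroids[b]
            if pts.shape[0] == 0:
                continue
            d2 = (pts[:, 0] - cx) ** 2 + (pts[:, 1] - cy) ** 2
            if np.any(d2 <= radius**2):
                bits[b] = 1
        identity = codebook.match_bitvector(bits)
        iy, ix = int(np.floor(cy)), int(np.floor(cx))
        per_bit = np.array([float(images[b][iy, ix]) for b in range(L)])
        on = bits.astype(bool)
        mean_int = float(per_bit[on].mean()) if on.any() else 0.0
        std_int = float(per_bit[on].std()) if on.any() else 0.0
        rows.append(
            {
                "x": cx,
                "y": cy,
                "bits": "".join(map(str, bits)),
                "identity": identity,
                "is_blank": identity in blank_ids if identity else False,
                "mean_intensity": mean_int,
                "std_intensity": std_int,
                "area": int(prop.area),
                "eccentricity": float(prop.eccentricity),
                "qc_pass": True,
            }
        )
    return pd.DataFrame(rows, columns=SPOT_COLUMNS)


def qc_filter_spots(spots: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Flag the misidentification-enriched intensity cloud.

    Matched spots are split into 2 clusters by k-means on z-scored
    (mean on-bit intensity, std across on-bits); the cluster with the
    higher blank fraction — or, on a tie, the dimmer one — has
    ``qc_pass`` set to False.  With no decoded blanks or a degenerate
    feature cloud all spots pass (with a warning).
    """
    spots = spots.copy()
    matched = spots["identity"].notna()
    if matched.sum() < 2:
        warnings.warn("degenerate QC: fewer than 2 matched spots, all pass")
        return spots
    feats = spots.loc[matched, ["mean_intensity", "std_intensity"]].to_numpy(float)
    if not spots.loc[matched, "is_blank"].any():
        warnings.warn("no blank spots decoded: QC filter has no anchor, all pass")
        return spots
    std = feats.std(axis=0)
    if np.all(std == 0):
        warnings.warn("degenerate QC: identical spot features, all pass")
        return spots
    z = (feats - feats.mean(axis=0)) / np.where(std == 0, 1.0, std)
    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(z)
    assign = km.labels_
    blank = spots.loc[matched, "is_blank"].to_numpy()
    frac = np.array([blank[assign == k].mean() for k in (0, 1)])
    if frac[0] == frac[1]:
        mean_int = feats[:, 0]
        means = np.array([mean_int[assign == k].mean() for k in (0, 1)])
        reject = int(np.argmin(means))
    else:
        reject = int(np.argmax(frac))
    qc = spots["qc_pass"].to_numpy(bool)
    qc[np.flatnonzero(matched.to_numpy())[assign == reject]] = False
    spots["qc_pass"] = qc
    return spots


def estimate_error_rate(
    spots: pd.DataFrame, codebook: Codebook, qc_only: bool = False
) -> ErrorRateReport:
    """Blank-normalized misidentification rate, as a percentage.

    ``rate = (n_blank / B) / ((n_total − n_blank) / R) × 100`` with
    ``R`` targeting+control barcodes and ``B`` blank barcodes in the
    codebook.  ``qc_only`` restricts the counts to qc-passing spots.
    """
    B = codebook.n_blank
    R = codebook.n_targeting
    if B < 1:
        raise DecodeError("no blank barcodes in codebook: error rate undefined")
    sub = spots[spots["qc_pass"]] if qc_only else spots
    sub = sub[sub["identity"].notna()]
    n_total = int(len(sub))
    n_blank = int(sub["is_blank"].sum())
    if n_total <= n_blank:
        raise DecodeError("error rate undefined: no non-blank decoded spots")
    rate = 100.0 * (n_blank / B) / ((n_total - n_blank) / R)
    return ErrorRateReport(n_total, n_blank, R, B, rate)


def decode_field(
    bit_stacks: list[np.ndarray],
    backgrounds: list[np.ndarray],
    codebook: Codebook,
    params: PreprocessParams | None = None,
    channel_of_bit=None,
    qc_seed: int = 0,
) -> pd.DataFrame:
    """Run the full per-field decode chain on raw bit stacks.

    ``backgrounds`` holds one flat-field image per channel;
    ``channel_of_bit`` maps bit index to channel index (defaults to the
    codebook layout).  Returns the QC-annotated spot table.
    """
    params = params or PreprocessParams()
    if channel_of_bit is None:
        channel_of_bit = codebook.layout.bit_channel
    masks, objects, images = [], [], []
    for b, stack in enumerate(bit_stacks):
        bg = backgrounds[channel_of_bit(b)]
        img = preprocess_bit_image(stack, bg, params)
        df, mask = detect_spots(img, params.threshold)
        masks.append(mask)
        objects.append(df)
        images.append(img)
    spots = assemble_and_decode(masks, objects, images, codebook, params.radius)
    if len(spots) >= 2 and spots["identity"].notna().sum() >= 2:
        spots = qc_filter_spots(spots, seed=qc_seed)
    return spots
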