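"""JPEG and JPEG2000 encoding with PSNR accounting and rate search.

JPEG exposes the familiar 1-100 quality score; JPEG2000 (OpenJPEG via
Pillow) is driven to a *target PSNR* by bisecting the codec's
compression-ratio parameter and measuring the round-trip PSNR, mirroring
how PSNR-targeted compression ladders are built in telepathology studies.
The reversible (lossless) JPEG2000 path is exact.

Compression ratio is reported as compressed bytes over the raw bitmap size
H*W*3. Studies that start from already-compressed scanner files divide by
the stored file size instead, so absolute ratios here differ from such
reports by the source files' own compression factor.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass

import numpy as np
from PIL import Image

from .errors import CodecError, ConvergenceError, DimensionError, ParameterError

__all__ = [
    "CompressionRecord",
    "PSNR_CAP_DB",
    "compute_psnr",
    "decode_image",
    "encode_jpeg",
    "encode_jpeg2000_lossless",
    "encode_jpeg2000_rate",
    "compress_to_target_psnr",
]

#: PSNR reported for a zero-MSE (lossless) round trip, in dB.
PSNR_CAP_DB = 100.0

#: Default ladder of JPEG2000 PSNR targets for sweep configs.
DEFAULT_PSNR_LADDER = (18, 20, 22, 25, 30, 35, 40, 50, 60, 70, 80, 90, 100)


@dataclass(frozen=True)
class CompressionRecord:
    """Bookkeeping for one encode: codec, control knob, and what it achieved."""

    codec: str                 # jpeg | jpeg2000 | jpeg2000-lossless
    control: float | None      # quality score (JPEG) or target PSNR dB (JPEG2000)
    achieved_psnr: float       # dB, capped at PSNR_CAP_DB
    compressed_bytes: int
    raw_bytes: int             # H * W * 3
    ratio: float               # compressed_bytes / raw_bytes


def _require_rgb8(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.dtype != np.uint8:
        raise ParameterError(f"expected 8-bit image, got dtype {image.dtype}")
    if image.ndim != 3 or image.shape[2] != 3:
        raise DimensionError(f"expected H x W x 3 RGB image, got shape {image.shape}")
    return image


def compute_psnr(reference: np.ndarray, degraded: np.ndarray) -> float:
    """Peak signal-to-noise ratio 10*log10(255^2 / MSE) in dB.

    MSE is taken over all pixels and channels; identical images return the
    cap value ``PSNR_CAP_DB`` rather than infinity.
    """
    reference = np.asarray(reference)
    degraded = np.asarray(degraded)
    if reference.shape != degraded.shape:
        raise DimensionError(
            f"shape mismatch: {reference.shape} vs {degraded.shape}")
    mse = np.mean((reference.astype(np.float64) - degraded.astype(np.float64)) ** 2)
    if mse == 0:
        return PSNR_CAP_DB
    return min(PSNR_CAP_DB, 10.0 * math.log10(255.0**2 / mse))


def decode_image(data: bytes) -> np.ndarray:
    """Decode an encoded JPEG/JPEG2000 byte stream back to uint8 RGB."""
    try:
        return np.asarray(Image.open(io.BytesIO(data)).convert("RGB"))
    except Exception as exc:  # noqa: BLE001 — surfaced as codec error
        raise CodecError(f"decode failed: {exc}") from exc


def _record(codec, control, image, data) -> CompressionRecord:
    decoded = decode_image(data)
    raw = int(image.shape[0] * image.shape[1] * 3)
    return CompressionRecord(
        codec=codec,
        control=control,
        achieved_psnr=compute_psnr(image, decoded),
        compressed_bytes=len(data),
        raw_bytes=raw,
        ratio=len(data) / raw,
    )


def encode_jpeg(image: np.ndarray, quality: int) -> tuple[bytes, CompressionRecord]:
    """Baseline JPEG at an integer quality score in [1, 100].

    Chroma subsampling is 4:2:0 below quality 95 and 4:4:4 at or above,
    matching common codec defaults; this affects the achieved PSNR.
    """
    image = _require_rgb8(image)
    if not (isinstance(quality, (int, np.integer)) and 1 <= quality <= 100):
        raise ParameterError(f"quality must be an integer in [1, 100], got {quality!r}")
    buf = io.BytesIO()
    subsampling = 0 if quality >= 95 else 2
    try:
        Image.fromarray(image).save(buf, format="JPEG", quality=int(quality),
                                    subsampling=subsampling)
    except Exception as exc:  # noqa: BLE001
        raise CodecError(f"JPEG encode failed: {exc}") from exc
    data = buf.getvalue()
    return data, _record("jpeg", float(quality), image, data)


def encode_jpeg2000_lossless(image: np.ndarray) -> tuple[bytes, CompressionRecord]:
    """Reversible JPEG2000: the decoded image equals the input exactly."""
    image = _require_rgb8(image)
    buf = io.BytesIO()
    try:
        Image.fromarray(image).save(buf, format="JPEG2000", irreversible=False)
    except Exception as exc:  # noqa: BLE001
        raise CodecError(f"JPEG2000 lossless encode failed: {exc}") from exc
    data = buf.getvalue()
    rec = _record("jpeg2000-lossless", None, image, data)
    if rec.achieved_psnr != PSNR_CAP_DB:
        raise CodecError("reversible JPEG2000 round trip was not exact")
    return data, rec


def encode_jpeg2000_rate(image: np.ndarray, ratio: float,
                         target: float | None = None) -> tuple[bytes, CompressionRecord]:
    """Irreversible JPEG2000 at a requested compression ratio in (0, 1].

    The codec treats the ratio as a rate budget, so achieved bytes track but
    do not exactly equal ``ratio * raw_bytes``.
    """
    image = _require_rgb8(image)
    if not (0 < ratio <= 1):
        raise ParameterError(f"ratio must lie in (0, 1], got {ratio}")
    buf = io.BytesIO()
    try:
        Image.fromarray(image).save(
            buf, format="JPEG2000", irreversible=True,
            quality_mode="rates", quality_layers=[1.0 / ratio])
    except Exception as exc:  # noqa: BLE001
        raise CodecError(f"JPEG2000 encode failed: {exc}") from exc
    data = buf.getvalue()
    return data, _record("jpeg2000", target, image, data)


def compress_to_target_psnr(image: np.ndarray, target: float, tol: float = 0.5,
                            max_iter: int = 30) -> tuple[bytes, CompressionRecord]:
    """JPEG2000 encode whose round-trip PSNR is within *tol* dB of *target*.

    The search bisects log2(compression ratio) over [-10, 0] — rate control
    is approximately log-linear in PSNR — measuring the achieved PSNR by
    decode at every step. A target of 100 dB delegates to the reversible
    (lossless) path. If the target cannot be bracketed or the iteration
    budget runs out, a :class:`ConvergenceError` is raised carrying the
    closest encoding achieved.
    """
    image = _require_rgb8(image)
    if not (18.0 <= target <= 100.0):
        raise ParameterError(f"target PSNR must lie in [18, 100] dB, got {target}")
    if tol <= 0:
        raise ParameterError("tol must be positive")
    if target >= PSNR_CAP_DB:
        data, rec = encode_jpeg2000_lossless(image)
        return data, CompressionRecord(codec="jpeg2000-lossless", control=float(target),
                                       achieved_psnr=rec.achieved_psnr,
                                       compressed_bytes=rec.compressed_bytes,
                                       raw_bytes=rec.raw_bytes, ratio=rec.ratio)

    best: tuple[bytes, CompressionRecord] | None = None

    def trial(log2_ratio: float):
        nonlocal best
        data, rec = encode_jpeg2000_rate(image, 2.0**log2_ratio, target=float(target))
        if best is None or abs(rec.achieved_psnr - target) < abs(
                best[1].achieved_psnr - target):
            best = (data, rec)
        return data, rec

    lo, hi = -10.0, 0.0
    _, rec_hi = trial(hi)
    if rec_hi.achieved_psnr < target - tol:
        raise ConvergenceError(
            f"target {target} dB exceeds the lossy ceiling "
            f"{rec_hi.achieved_psnr:.2f} dB for this image", best=best)
    if abs(rec_hi.achieved_psnr - target) <= tol:
        return best
    _, rec_lo = trial(lo)
    if rec_lo.achieved_psnr > target + tol:
        raise ConvergenceError(
            f"target {target} dB is below the floor {rec_lo.achieved_psnr:.2f} dB "
            "reachable for this image", best=best)
    if abs(rec_lo.achieved_psnr - target) <= tol:
        return best

    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        _, rec = trial(mid)
        if abs(rec.achieved_psnr - target) <= tol:
            return best
        if rec.achieved_psnr < target:
            lo = mid
        else:
            hi = mid
    raise ConvergenceError(
        f"no encoding within {tol} dB of {target} dB in {max_iter} iterations "
        f"(best {best[1].achieved_psnr:.2f} dB)", best=best)
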