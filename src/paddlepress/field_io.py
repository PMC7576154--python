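"""Readers and writers for all on-disk artifacts.

Formats (all plain text except TIFF image stacks):

* velocity sequence -- a manifest header (``key value`` lines: nx, ny, dx,
  dy, x0, y0, dt, n_frames, units) followed by per-frame blocks
  ``frame <k>`` and ``i j u v valid`` rows at full decimal precision.
  Diff-able, language-neutral and lossless (floats are written with
  shortest round-trip ``repr``).
* scalar field -- same header style plus ``i j value defined`` rows.
* contours / centerlines -- CSV with columns ``x_m, y_m`` and a comment
  header carrying the closed flag (closure is *not* encoded by repeating
  the first point).
* image stacks -- multi-page grayscale TIFF; pixel size from the TIFF
  resolution tags or a config override.

Coordinate convention: physical x rightward, y upward, units meters; image
row 0 is the top of the frame, so image import flips the vertical axis.
"""
from __future__ import annotations

import csv
from fractions import Fraction
from pathlib import Path

import numpy as np
import tifffile

from .errors import FormatError, MissingCalibrationError, UnsupportedFormatError
from .fields import GridGeometry, ScalarField, VelocityFieldSequence

_VEL_MAGIC = "# paddlepress velocity-field-sequence v1"
_SCA_MAGIC = "# paddlepress scalar-field v1"
_CON_MAGIC = "# paddlepress contour v1"


def _fmt(x: float) -> str:
    return repr(float(x))


# ---------------------------------------------------------------------------
# velocity sequences


def write_velocity_sequence(seq: VelocityFieldSequence, path: str | Path) -> None:
    g = seq.grid
    lines = [
        _VEL_MAGIC,
        f"nx {g.nx}",
        f"ny {g.ny}",
        f"dx {_fmt(g.dx)}",
        f"dy {_fmt(g.dy)}",
        f"x0 {_fmt(g.x0)}",
        f"y0 {_fmt(g.y0)}",
        f"dt {_fmt(seq.dt)}",
        f"n_frames {seq.n_frames}",
        "units m/s",
    ]
    for t in range(seq.n_frames):
        lines.append(f"frame {t}")
        u, v, ok = seq.u[t], seq.v[t], seq.valid[t]
        for j in range(g.ny):
            for i in range(g.nx):
                lines.append(f"{i} {j} {_fmt(u[j, i])} {_fmt(v[j, i])} {int(ok[j, i])}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_velocity_sequence(path: str | Path) -> VelocityFieldSequence:
    raw = Path(path).read_text().splitlines()
    if not raw or raw[0].strip() != _VEL_MAGIC:
        raise FormatError(f"{path}: not a paddlepress velocity-field-sequence file")
    header: dict[str, str] = {}
    pos = 1
    while pos < len(raw) and not raw[pos].startswith("frame "):
        key, _, val = raw[pos].partition(" ")
        header[key.strip()] = val.strip()
        pos += 1
    try:
        nx, ny = int(header["nx"]), int(header["ny"])
        dx, dy = float(header["dx"]), float(header["dy"])
        x0, y0 = float(header["x0"]), float(header["y0"])
        dt = float(header["dt"])
        n_frames = int(header["n_frames"])
    except (KeyError, ValueError) as exc:
        raise FormatError(f"{path}: malformed header ({exc})") from exc
    if dx <= 0 or dy <= 0 or dt <= 0 or nx < 2 or ny < 2 or n_frames < 1:
        raise FormatError(f"{path}: invalid metadata (non-positive dx/dy/dt or grid dims)")
    grid = GridGeometry(nx=nx, ny=ny, dx=dx, dy=dy, x0=x0, y0=y0)
    u = np.full((n_frames, ny, nx), np.nan)
    v = np.full((n_frames, ny, nx), np.nan)
    valid = np.zeros((n_frames, ny, nx), dtype=bool)
    expected = nx * ny
    frame = -1
    count = 0
    for lineno, line in enumerate(raw[pos:], start=pos + 1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("frame "):
            if frame >= 0 and count != expected:
                raise FormatError(
                    f"{path}: frame {frame} has {count} rows, expected {expected}"
                )
            try:
                new = int(line.split()[1])
            except (IndexError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: bad frame marker") from exc
            if new != frame + 1:
                raise FormatError(f"{path}: non-monotone frame index {new} after {frame}")
            frame = new
            count = 0
            continue
        parts = line.split()
        if frame < 0 or len(parts) != 5:
            raise FormatError(f"{path}:{lineno}: malformed data row")
        try:
            i, j = int(parts[0]), int(parts[1])
            uu, vv = float(parts[2]), float(parts[3])
            ok = bool(int(parts[4]))
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric row in frame {frame}") from exc
        if not (0 <= i < nx and 0 <= j < ny):
            raise FormatError(f"{path}: frame {frame} has out-of-range node ({i}, {j})")
        u[frame, j, i] = uu
        v[frame, j, i] = vv
        valid[frame, j, i] = ok
        count += 1
    if frame != n_frames - 1 or count != expected:
        raise FormatError(
            f"{path}: frame {max(frame, 0)} incomplete or frame count != {n_frames}"
        )
    return VelocityFieldSequence(u=u, v=v, grid=grid, dt=dt, valid=valid)


# ---------------------------------------------------------------------------
# scalar fields


def write_scalar_field(field: ScalarField, path: str | Path) -> None:
    g = field.grid
    lines = [
        _SCA_MAGIC,
        f"nx {g.nx}",
        f"ny {g.ny}",
        f"dx {_fmt(g.dx)}",
        f"dy {_fmt(g.dy)}",
        f"x0 {_fmt(g.x0)}",
        f"y0 {_fmt(g.y0)}",
        f"units {field.units}",
    ]
    for j in range(g.ny):
        for i in range(g.nx):
            val = field.values[j, i]
            ok = field.defined[j, i]
            lines.append(f"{i} {j} {_fmt(val) if ok else 'nan'} {int(ok)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_scalar_field(path: str | Path) -> ScalarField:
    raw = Path(path).read_text().splitlines()
    if not raw or raw[0].strip() != _SCA_MAGIC:
        raise FormatError(f"{path}: not a paddlepress scalar-field file")
    header: dict[str, str] = {}
    pos = 1
    while pos < len(raw) and len(raw[pos].split()) == 2 and not raw[pos][0].isdigit():
        key, _, val = raw[pos].partition(" ")
        header[key.strip()] = val.strip()
        pos += 1
    try:
        nx, ny = int(header["nx"]), int(header["ny"])
        grid = GridGeometry(
            nx=nx, ny=ny,
            dx=float(header["dx"]), dy=float(header["dy"]),
            x0=float(header["x0"]), y0=float(header["y0"]),
        )
    except (KeyError, ValueError) as exc:
        raise FormatError(f"{path}: malformed header ({exc})") from exc
    values = np.full((ny, nx), np.nan)
    defined = np.zeros((ny, nx), dtype=bool)
    for lineno, line in enumerate(raw[pos:], start=pos + 1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 4:
            raise FormatError(f"{path}:{lineno}: malformed data row")
        try:
            i, j = int(parts[0]), int(parts[1])
            values[j, i] = float(parts[2])
            defined[j, i] = bool(int(parts[3]))
        except (ValueError, IndexError) as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric row") from exc
    return ScalarField(values=values, grid=grid, units=header.get("units", ""), defined=defined)


# ---------------------------------------------------------------------------
# contours and centerlines


def write_contour_csv(points: np.ndarray, path: str | Path, closed: bool = False) -> None:
    pts = np.asarray(points, dtype=float)
    with open(path, "w", newline="") as fh:
        fh.write(_CON_MAGIC + "\n")
        fh.write(f"# closed {int(closed)}\n")
        writer = csv.writer(fh)
        writer.writerow(["x_m", "y_m"])
        for x, y in pts:
            writer.writerow([_fmt(x), _fmt(y)])


def read_contour_csv(path: str | Path) -> tuple[np.ndarray, bool]:
    """Returns (points, closed). Order is preserved; closure comes from the
    header flag, never from a duplicated first point."""
    lines = Path(path).read_text().splitlines()
    closed = False
    pts: list[tuple[float, float]] = []
    seen_header = False
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("closed"):
                closed = bool(int(body.split()[1]))
            continue
        if not seen_header and line.replace(" ", "").lower().startswith("x_m"):
            seen_header = True
            continue
        parts = [p.strip() for p in line.split(",")]
        try:
            pts.append((float(parts[0]), float(parts[1])))
        except (ValueError, IndexError) as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric contour row") from exc
    minimum = 3 if closed else 2
    if len(pts) < minimum:
        raise FormatError(
            f"{path}: too few points ({len(pts)}; need >= {minimum} for "
            f"{'closed contour' if closed else 'centerline'})"
        )
    return np.asarray(pts, dtype=float), closed


# ---------------------------------------------------------------------------
# image stacks


def write_image_stack(
    frames: np.ndarray, path: str | Path, pixel_size: float | None = None
) -> None:
    """Write grayscale frames (T, H, W) in [0, 1] as a float32 TIFF stack.

    ``pixel_size`` (meters) is recorded in the TIFF resolution tags
    (pixels per centimeter).
    """
    arr = np.asarray(frames, dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[None]
    kwargs = {}
    if pixel_size is not None:
        ppcm = Fraction(1e-2 / pixel_size).limit_denominator(10**6)
        kwargs["resolution"] = ((ppcm.numerator, ppcm.denominator),) * 2
        kwargs["resolutionunit"] = "CENTIMETER"
    tifffile.imwrite(path, arr, photometric="minisblack", **kwargs)


def read_image_stack(
    path: str | Path, pixel_size: float | None = None
) -> tuple[np.ndarray, float]:
    """Read a grayscale stack; returns (frames in [0, 1], pixel size in m).

    Integer images are scaled by their dtype maximum. ``pixel_size``
    overrides (or supplies, when absent) the TIFF calibration.
    """
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        page = tif.pages[0]
        tag_px = _pixel_size_from_tags(page)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise UnsupportedFormatError(f"{path}: expected grayscale pages, got shape {arr.shape}")
    if arr.shape[-1] in (3, 4) and arr.shape[-1] < min(arr.shape[:-1]):
        raise UnsupportedFormatError(f"{path}: color images are not supported")
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float) / np.iinfo(arr.dtype).max
    else:
        arr = np.clip(arr.astype(float), 0.0, 1.0)
    px = pixel_size if pixel_size is not None else tag_px
    if px is None:
        raise MissingCalibrationError(
            f"{path}: no resolution tag and no pixel_size override given"
        )
    return arr, float(px)


def _pixel_size_from_tags(page) -> float | None:
    tags = page.tags
    if "XResolution" not in tags:
        return None
    num, den = tags["XResolution"].value
    if num == 0:
        return None
    unit = tags["ResolutionUnit"].value if "ResolutionUnit" in tags else 2
    unit = getattr(unit, "value", unit)
    meters = {2: 0.0254, 3: 0.01}.get(int(unit))
    if meters is None:
        return None
    return meters * den / num
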