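"""File formats: curve tables, dose-matrix text files, PNG images, config.

Curves travel as two-column delimited text (``#`` comments, optional
header line, whitespace or comma separated): abscissa in cm, dose in
percent.  A profile file carries its reference depth in a
``# ref_depth_cm = ...`` comment.

Dose matrices are written as delimited text with a three-line header
recording the grid origin, spacing, and dimensions, followed by one row of
``%.17g`` values per depth; the round trip through :func:`read_matrix` is
bit-exact.

Configuration is a flat YAML file of sections (geometry, grid, fixture,
palette, validation, output); :func:`default_config` holds every default
and :func:`load_config` merges a user file over it.
"""

from __future__ import annotations

import ast
import io as _io
from pathlib import Path

import numpy as np
import yaml

from .curves import PDDCurve, ProfileCurve
from .geometry import BeamGeometry, GridSpec
from .reconstruct import DoseMatrix
from .render import PaletteBand
from .synthetic import BeamModelParams

__all__ = [
    "read_pdd",
    "read_profile",
    "write_curve",
    "read_matrix",
    "write_matrix",
    "write_png",
    "default_config",
    "load_config",
    "dump_config",
    "geometry_from_config",
    "grid_from_config",
    "params_from_config",
    "palette_from_config",
    "write_sidecar",
    "read_sidecar",
]


# ---------------------------------------------------------------------------
# curve tables
# ---------------------------------------------------------------------------

def _read_table(path) -> tuple[np.ndarray, np.ndarray, dict]:
    meta: dict[str, float] = {}
    rows: list[tuple[float, float]] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, val = body.partition("=")
                try:
                    meta[key.strip()] = float(val.strip())
                except ValueError:
                    pass
            continue
        parts = line.replace(",", " ").split()
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except (ValueError, IndexError):
            if not rows:
                continue  # tolerate one non-numeric header line
            raise ValueError(f"{path}: malformed data line: {raw!r}")
    if len(rows) < 2:
        raise ValueError(f"{path}: need at least 2 data rows")
    arr = np.asarray(rows, dtype=float)
    return arr[:, 0], arr[:, 1], meta


def read_pdd(path) -> PDDCurve:
    """Read a central-axis PDD from a two-column text file."""
    depths, values, _ = _read_table(path)
    return PDDCurve(depths, values)


def read_profile(path, ref_depth: float | None = None) -> ProfileCurve:
    """Read an off-axis profile; the reference depth comes from the
    ``# ref_depth_cm = ...`` header unless overridden."""
    positions, values, meta = _read_table(path)
    if ref_depth is None:
        ref_depth = meta.get("ref_depth_cm")
    if ref_depth is None:
        raise ValueError(f"{path}: no ref_depth_cm header and none supplied")
    return ProfileCurve(positions, values, ref_depth=float(ref_depth))


def write_curve(path, curve, comment: str = "") -> None:
    """Write a curve as two-column text (abscissa_cm, dose_percent)."""
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        if isinstance(curve, ProfileCurve):
            fh.write(f"# ref_depth_cm = {curve.ref_depth!r}\n")
            xs, ys = curve.positions, curve.values
            fh.write("# position_cm dose_percent\n")
        else:
            xs, ys = curve.depths, curve.values
            fh.write("# depth_cm dose_percent\n")
        for x, y in zip(xs, ys):
            fh.write(f"{float(x)!r} {float(y)!r}\n")


# ---------------------------------------------------------------------------
# dose matrices
# ---------------------------------------------------------------------------

def write_matrix(path, dm: DoseMatrix) -> None:
    """Write a dose plane as text: 3 header lines, then one row per depth."""
    g = dm.grid
    buf = _io.StringIO()
    buf.write(f"# lateral_origin_cm={g.lateral_origin!r} depth_origin_cm={g.depth_origin!r}\n")
    buf.write(f"# pixel_cm={g.pixel_spacing!r}\n")
    buf.write(f"# n_depth={g.n_depth} n_lateral={g.n_lateral}\n")
    np.savetxt(buf, dm.values, fmt="%.17g")
    Path(path).write_text(buf.getvalue())


def read_matrix(path) -> DoseMatrix:
    """Read a dose plane written by :func:`write_matrix` (bit-exact)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_head = 0
    for line in lines:
        if not line.startswith("#"):
            break
        n_head += 1
        for tok in line.lstrip("#").split():
            if "=" in tok:
                key, _, val = tok.partition("=")
                header[key] = float(val)
    required = {"lateral_origin_cm", "depth_origin_cm", "pixel_cm", "n_depth", "n_lateral"}
    if not required <= header.keys():
        raise ValueError(f"{path}: missing header keys {sorted(required - header.keys())}")
    values = np.loadtxt(_io.StringIO("".join(lines[n_head:])), ndmin=2)
    grid = GridSpec(
        pixel_spacing=header["pixel_cm"],
        n_lateral=int(header["n_lateral"]),
        n_depth=int(header["n_depth"]),
        lateral_origin=header["lateral_origin_cm"],
        depth_origin=header["depth_origin_cm"],
    )
    return DoseMatrix(grid=grid, values=values)


def write_png(path, image: np.ndarray) -> None:
    """Write an 8-bit image array (2-D gray or (..., 3) RGB) as PNG."""
    from PIL import Image

    if image.dtype != np.uint8:
        raise ValueError("expected a uint8 image array")
    mode = "L" if image.ndim == 2 else "RGB"
    Image.fromarray(image, mode=mode).save(path, format="PNG")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def default_config() -> dict:
    """All tool defaults: an 18 MV-like 10 x 10 cm^2 beam at 100 cm SSD in
    a 50 x 50 x 30 cm^3 water phantom, reconstructed at 0.1 cm pixels."""
    return {
        "geometry": {
            "ssd_cm": 100.0,
            "field_cm": 10.0,
            "phantom_halfwidth_cm": 25.0,
            "phantom_depth_cm": 30.0,
        },
        "grid": {
            "pixel_cm": 0.1,
            "lateral_halfwidth_cm": 15.0,
            "depth_max_cm": 27.95,
        },
        "fixture": {
            "kind": "separable",  # or 'nonseparable'
            "mu_cm": 0.045,
            "d_max_cm": 3.25,
            "penumbra_sigma_cm": 0.3,
            "penumbra_growth": 0.04,
            "tail_amplitude": 0.02,
            "tail_length_cm": 5.0,
            "noise_percent": 0.0,
        },
        "palette": [
            {"lo": 0.0, "hi": 25.0, "hue": 2.0 / 3.0, "saturation": 1.0},
            {"lo": 25.0, "hi": 70.0, "hue": 1.0 / 3.0, "saturation": 1.0},
            {"lo": 70.0, "hi": 80.0, "hue": 1.0 / 6.0, "saturation": 1.0},
            {"lo": 80.0, "hi": 100.0, "hue": 0.06, "saturation": 1.0},
        ],
        "validation": {
            "in_field_bound_pp": 2.0,
            "penumbra_bound_pp": 5.0,
        },
    }


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


def load_config(path=None) -> dict:
    """Load a YAML config file merged over :func:`default_config`."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"{path}: config must be a mapping of sections")
        cfg = _merge(cfg, user)
    return cfg


def dump_config(cfg: dict) -> str:
    return yaml.safe_dump(cfg, sort_keys=False)


def geometry_from_config(cfg: dict) -> BeamGeometry:
    g = cfg["geometry"]
    return BeamGeometry(
        ssd=g["ssd_cm"],
        field_size=g["field_cm"],
        phantom_halfwidth=g["phantom_halfwidth_cm"],
        phantom_depth=g["phantom_depth_cm"],
    )


def grid_from_config(cfg: dict) -> GridSpec:
    g = cfg["grid"]
    return GridSpec.from_extents(
        pixel_spacing=g["pixel_cm"],
        lateral_halfwidth=g["lateral_halfwidth_cm"],
        depth_max=g["depth_max_cm"],
    )


def params_from_config(cfg: dict) -> BeamModelParams:
    f = cfg["fixture"]
    return BeamModelParams(
        mu=f["mu_cm"],
        d_max_target=f["d_max_cm"],
        penumbra_sigma0=f["penumbra_sigma_cm"],
        penumbra_growth=f["penumbra_growth"],
        tail_amplitude=f["tail_amplitude"],
        tail_length=f["tail_length_cm"],
    )


def palette_from_config(cfg: dict) -> tuple[PaletteBand, ...]:
    return tuple(
        PaletteBand(lo=b["lo"], hi=b["hi"], hue=b["hue"], saturation=b.get("saturation", 1.0))
        for b in cfg["palette"]
    )


def write_sidecar(path, entries: dict) -> None:
    """Write a flat key = value provenance sidecar (Python literals)."""
    with open(path, "w") as fh:
        for key, val in entries.items():
            if isinstance(val, (np.floating, np.integer)):
                val = val.item()
            fh.write(f"{key} = {val!r}\n")


def read_sidecar(path) -> dict:
    """Read a sidecar back; values parse as Python literals, else strings."""
    out: dict[str, object] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition("=")
        try:
            out[key.strip()] = ast.literal_eval(val.strip())
        except (ValueError, SyntaxError):
            out[key.strip()] = val.strip()
    return out
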