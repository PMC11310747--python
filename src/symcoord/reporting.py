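"""Human-readable outputs: magnitude tables, Mondrian symmetry diagrams and
their SVG rendering.

A Mondrian diagram places one line per dissymmetric mode at the log10 of
its magnitude — out-of-plane modes as vertical lines, in-plane modes as
horizontal lines — partitioning the canvas into rectangular regions.  Each
region is labeled with the residual point group retained when exactly the
modes whose lines bound it from the retained side (larger magnitudes) are
accepted: the most-symmetric corner (top right) keeps the full group, the
least-symmetric corner retains every drawn mode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .errors import ValidationError
from .groups import PointGroup


def _round2(value: float) -> float:
    """Two-decimal printing rule with decimal half-up ties (5.675 -> 5.68)."""
    d = Decimal(str(round(float(value), 6)))
    return float(d.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))

#: default palette: residual group name -> fill color (user-overridable)
DEFAULT_PALETTE = {
    "C1": "#f4f4f4",
    "Ci": "#d9e8f5",
    "Cs": "#f5e9d9",
    "C2": "#f2d4d4",
    "C3": "#eed9f2",
    "C4": "#d4e8d4",
    "C6": "#d4f2ee",
    "S4": "#e8e0c8",
    "S6": "#e0e8c8",
    "C2v": "#e7c8c8",
    "C3v": "#d8c8e7",
    "C4v": "#c8e7c8",
    "C6v": "#c8e7e0",
    "C2h": "#c8d4e7",
    "C3h": "#e7d4c8",
    "C4h": "#d4c8e7",
    "C6h": "#c8e0e7",
    "D2": "#f0b4b4",
    "D3": "#d3b4f0",
    "D4": "#b4f0b4",
    "D6": "#b4f0e2",
    "D2d": "#e3d2a8",
    "D3d": "#cfe3a8",
    "D2h": "#a8c4e3",
    "D3h": "#e3a8c9",
    "D4h": "#a8e3b8",
    "D6h": "#a8dfe3",
}
_FALLBACK_COLOR = "#ffffff"


@dataclass
class MondrianSpec:
    """Layout of a Mondrian symmetry diagram in log10-magnitude units."""

    group: str
    axis_range: tuple = (-2.0, 1.0)
    #: (irrep label, magnitude A, 'vertical' | 'horizontal')
    lines: list = field(default_factory=list)
    #: ((x0, y0, x1, y1) in log units, residual group name, color)
    regions: list = field(default_factory=list)
    palette: dict = field(default_factory=lambda: dict(DEFAULT_PALETTE))


def mondrian_layout(
    result,
    group: PointGroup,
    axis_range: tuple = (-2.0, 1.0),
    palette: dict | None = None,
) -> MondrianSpec:
    """Build the Mondrian layout for one decomposition result.

    One line per dissymmetric mode with magnitude above the lower axis
    bound; out-of-plane irreps (per the group's parity classification) give
    vertical lines, in-plane irreps horizontal ones.  Regions are
    enumerated by sweeping thresholds between consecutive lines; each cell
    is labeled with the residual group of the modes exceeding its
    thresholds.
    """
    lo, hi = axis_range
    if not hi > lo:
        raise ValidationError("axis_range must be increasing")
    palette = dict(DEFAULT_PALETTE) if palette is None else dict(palette)
    mags = result.magnitudes if hasattr(result, "magnitudes") else dict(result)
    ts = group.totally_symmetric_label
    lines = []
    for row in group.dissymmetric_irreps():
        mag = mags.get(row.label, 0.0)
        if not np.isfinite(mag):
            raise ValidationError(f"magnitude of {row.label} is not finite")
        if mag <= 10.0**lo:
            continue
        pos = min(float(np.log10(mag)), hi)
        direction = "vertical" if row.parity == "out_of_plane" else "horizontal"
        lines.append((row.label, mag, direction))
    spec = MondrianSpec(group.name, (lo, hi), lines, [], palette)
    if not lines:
        warnings.warn(
            "all magnitudes below the axis floor; single full-group region",
            stacklevel=2,
        )
        spec.regions = [
            ((lo, lo, hi, hi), group.name, palette.get(group.name, _FALLBACK_COLOR))
        ]
        return spec

    def _positions(direction):
        pos = sorted(
            {
                min(float(np.log10(m)), hi)
                for (_, m, d) in lines
                if d == direction
            }
        )
        return [lo] + pos + [hi]

    xs = _positions("vertical")
    ys = _positions("horizontal")
    for ix in range(len(xs) - 1):
        for iy in range(len(ys) - 1):
            x0, x1 = xs[ix], xs[ix + 1]
            y0, y1 = ys[iy], ys[iy + 1]
            if x1 - x0 < 1e-12 or y1 - y0 < 1e-12:
                continue
            active = {
                lab
                for (lab, m, d) in lines
                if (d == "vertical" and min(np.log10(m), hi) >= x1 - 1e-12)
                or (d == "horizontal" and min(np.log10(m), hi) >= y1 - 1e-12)
            }
            name = group.residual_group(active)
            spec.regions.append(
                ((x0, y0, x1, y1), name, palette.get(name, _FALLBACK_COLOR))
            )
    return spec


def render_mondrian_svg(spec: MondrianSpec, size: float = 400.0) -> str:
    """Render a Mondrian spec as standalone SVG text.

    Byte-stable for identical input: floats are written with 3 decimals.
    """
    lo, hi = spec.axis_range
    scale = size / (hi - lo)

    def fx(v):
        return (v - lo) * scale

    def fy(v):
        # log magnitude grows downward-left: the most-symmetric corner
        # (high thresholds) is the upper right
        return (hi - v) * scale

    f = lambda v: f"{v:.3f}"  # noqa: E731 - terse local formatter
    parts = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{f(size)}" '
        f'height="{f(size)}" viewBox="0 0 {f(size)} {f(size)}">',
    ]
    for (x0, y0, x1, y1), name, color in spec.regions:
        parts.append(
            f'<rect x="{f(fx(x0))}" y="{f(fy(y1))}" '
            f'width="{f(fx(x1) - fx(x0))}" height="{f(fy(y0) - fy(y1))}" '
            f'fill="{color}"><title>{name}</title></rect>'
        )
        parts.append(
            f'<text x="{f((fx(x0) + fx(x1)) / 2)}" y="{f((fy(y0) + fy(y1)) / 2)}" '
            'font-family="sans-serif" font-size="11" text-anchor="middle" '
            f'fill="#333333">{name}</text>'
        )
    for label, mag, direction in spec.lines:
        v = min(float(np.log10(mag)), hi)
        if direction == "vertical":
            parts.append(
                f'<line x1="{f(fx(v))}" y1="0.000" x2="{f(fx(v))}" '
                f'y2="{f(size)}" stroke="#111111" stroke-width="3">'
                f"<title>{label}: {mag:.2f} &#8491;</title></line>"
            )
        else:
            parts.append(
                f'<line x1="0.000" y1="{f(fy(v))}" x2="{f(size)}" '
                f'y2="{f(fy(v))}" stroke="#111111" stroke-width="3">'
                f"<title>{label}: {mag:.2f} &#8491;</title></line>"
            )
    parts.append("</svg>")
    return "\n".join(parts) + "\n"


def result_table(result, modes=None) -> pd.DataFrame:
    """Per-irrep magnitude table matching the program's printed layout.

    One row per irrep with the summed magnitude ("Sum (A)", 2 decimals);
    with a :class:`PrincipalModeSet` supplied, fitted principal-component
    coefficients and the fit residual are appended for that irrep's row.
    """
    from .groups import build_group

    group = build_group(result.group)
    mags = result.magnitudes
    rows = []
    for irrep in [r.label for r in group.irreps]:
        row = {"Irrep": irrep, "Sum (Å)": _round2(mags.get(irrep, 0.0))}
        rows.append(row)
    df = pd.DataFrame(rows).set_index("Irrep")
    if modes is not None:
        from .collection import mode_row, project_coefficients

        coeffs, residual = project_coefficients(
            mode_row(result, modes.irrep), modes
        )
        for j, c in enumerate(coeffs):
            df.loc[modes.irrep, f"{modes.irrep}({j + 1})"] = round(float(c), 2)
        df.loc[modes.irrep, "residual (Å)"] = round(residual, 2)
    return df
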