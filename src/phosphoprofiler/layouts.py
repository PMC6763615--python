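"""Membrane layout model for duplicate-spotted antibody arrays.

A layout describes where every capture-antibody spot sits on the
nitrocellulose membrane. Each analyte is spotted in duplicate; every
membrane additionally carries three positive-reference duplicate pairs
(used for between-membrane normalization) and one PBS-only negative
control pair (used for background and activation cut-offs).

The built-in layouts carry the analyte identities of the two commercial
kits (49 RTKs; 26 downstream molecules of which 9 are MAPKs) on a regular
synthetic grid: the physical coordinate maps of the kits are proprietary,
and only analyte identity — never physical position — enters the
downstream mathematics. Spot coordinates are pixel-center based, 0-based,
with y increasing downward.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import yaml

from . import _kits
from .errors import LayoutError, RegistrationError

LAYOUT_VERSION = "builtin-grid-1.0"

# Synthetic grid geometry (pixels). The pitch comfortably exceeds twice the
# spot radius so discs never overlap.
SPOT_PITCH = 40.0
SPOT_RADIUS = 13.0
GRID_MARGIN = 40.0

KIND_TARGET = "target"
KIND_POSITIVE_REFERENCE = "positive_reference"
KIND_NEGATIVE_CONTROL = "negative_control"
_KINDS = (KIND_TARGET, KIND_POSITIVE_REFERENCE, KIND_NEGATIVE_CONTROL)


@dataclass(frozen=True)
class SpotAddress:
    """Grid and pixel position of a single spot."""

    row: int
    col: int
    center_x: float
    center_y: float
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise LayoutError(f"spot radius must be positive, got {self.radius}")


@dataclass(frozen=True)
class Analyte:
    """One capture antibody, spotted in duplicate."""

    name: str
    kind: str
    phospho_sites: str = ""
    spots: tuple[SpotAddress, SpotAddress] = ()
    is_mapk: bool = False

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise LayoutError(f"analyte {self.name!r}: unknown kind {self.kind!r}")
        if len(self.spots) != 2:
            raise LayoutError(
                f"analyte {self.name!r}: expected exactly 2 duplicate spots, "
                f"got {len(self.spots)}"
            )


@dataclass(frozen=True)
class ArrayLayout:
    """A full membrane layout: analytes plus reference/negative controls."""

    array_id: str
    grid_rows: int
    grid_cols: int
    analytes: tuple[Analyte, ...]
    version: str = LAYOUT_VERSION

    def __post_init__(self) -> None:
        validate_layout(self)

    @property
    def targets(self) -> tuple[Analyte, ...]:
        return tuple(a for a in self.analytes if a.kind == KIND_TARGET)

    @property
    def positive_references(self) -> tuple[Analyte, ...]:
        return tuple(a for a in self.analytes if a.kind == KIND_POSITIVE_REFERENCE)

    @property
    def negative_controls(self) -> tuple[Analyte, ...]:
        return tuple(a for a in self.analytes if a.kind == KIND_NEGATIVE_CONTROL)

    @property
    def target_names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.targets)

    def analyte(self, name: str) -> Analyte:
        for a in self.analytes:
            if a.name == name:
                return a
        raise KeyError(name)

    def image_shape(self) -> tuple[int, int]:
        """(height, width) of the canonical rendered membrane image."""
        width = int(round(2 * GRID_MARGIN + (self.grid_cols - 1) * SPOT_PITCH)) + 1
        height = int(round(2 * GRID_MARGIN + (self.grid_rows - 1) * SPOT_PITCH)) + 1
        return height, width


def validate_layout(layout: ArrayLayout) -> None:
    """Check all structural invariants; raise LayoutError naming offenders."""
    names = [a.name for a in layout.analytes]
    seen: set[str] = set()
    for n in names:
        if n in seen:
            raise LayoutError(f"duplicate analyte name {n!r}")
        seen.add(n)

    n_ref = sum(a.kind == KIND_POSITIVE_REFERENCE for a in layout.analytes)
    n_neg = sum(a.kind == KIND_NEGATIVE_CONTROL for a in layout.analytes)
    if n_ref != 3:
        raise LayoutError(f"layout must contain exactly 3 positive_reference analytes, got {n_ref}")
    if n_neg != 1:
        raise LayoutError(f"layout must contain exactly 1 negative_control analyte, got {n_neg}")

    spots = [(a.name, s) for a in layout.analytes for s in a.spots]
    for _, s in spots:
        if not (0 <= s.row < layout.grid_rows and 0 <= s.col < layout.grid_cols):
            raise LayoutError(
                f"spot at grid ({s.row}, {s.col}) outside grid "
                f"{layout.grid_rows}x{layout.grid_cols}"
            )
    for i in range(len(spots)):
        for j in range(i + 1, len(spots)):
            (na, sa), (nb, sb) = spots[i], spots[j]
            dist = ((sa.center_x - sb.center_x) ** 2 + (sa.center_y - sb.center_y) ** 2) ** 0.5
            if dist <= sa.radius + sb.radius:
                raise LayoutError(f"spots of {na!r} and {nb!r} overlap (distance {dist:.1f})")


def _grid_spot(row: int, col: int, radius: float = SPOT_RADIUS) -> SpotAddress:
    return SpotAddress(
        row=row,
        col=col,
        center_x=GRID_MARGIN + col * SPOT_PITCH,
        center_y=GRID_MARGIN + row * SPOT_PITCH,
        radius=radius,
    )


def _build_grid_layout(
    array_id: str,
    entries: list[tuple[str, str, str, bool]],
    grid_cols: int,
) -> ArrayLayout:
    """Place analytes row-major, duplicates side by side in adjacent columns."""
    if grid_cols % 2 != 0:
        raise LayoutError("grid_cols must be even so duplicate pairs never wrap")
    n_cells = 2 * len(entries)
    grid_rows = -(-n_cells // grid_cols)
    analytes = []
    for i, (name, kind, sites, is_mapk) in enumerate(entries):
        r, c = divmod(2 * i, grid_cols)
        analytes.append(
            Analyte(
                name=name,
                kind=kind,
                phospho_sites=sites,
                spots=(_grid_spot(r, c), _grid_spot(r, c + 1)),
                is_mapk=is_mapk,
            )
        )
    return ArrayLayout(
        array_id=array_id,
        grid_rows=grid_rows,
        grid_cols=grid_cols,
        analytes=tuple(analytes),
    )


def builtin_layout(array_id: str) -> ArrayLayout:
    """Return a built-in membrane layout ("RTK" or "MAPK").

    Positive references come first (top-left region) and the negative
    control last (bottom-right), mimicking the corner placement of the
    physical membranes.
    """
    key = array_id.upper()
    if key == "RTK":
        entries = [(n, KIND_POSITIVE_REFERENCE, "", False) for n in _kits.POSITIVE_REFERENCE_NAMES]
        entries += [(n, KIND_TARGET, "", False) for n in _kits.RTK_TARGETS]
        entries.append((_kits.NEGATIVE_CONTROL_NAME, KIND_NEGATIVE_CONTROL, "", False))
        return _build_grid_layout("RTK", entries, grid_cols=14)
    if key == "MAPK":
        entries = [(n, KIND_POSITIVE_REFERENCE, "", False) for n in _kits.POSITIVE_REFERENCE_NAMES]
        entries += [
            (name, KIND_TARGET, sites, is_mapk)
            for name, (sites, is_mapk) in _kits.MAPK_TARGETS.items()
        ]
        entries.append((_kits.NEGATIVE_CONTROL_NAME, KIND_NEGATIVE_CONTROL, "", False))
        return _build_grid_layout("MAPK", entries, grid_cols=10)
    raise LayoutError(f"unsupported array_id {array_id!r}; known: RTK, MAPK")


# ---------------------------------------------------------------------------
# Serialization


def layout_to_dict(layout: ArrayLayout) -> dict:
    return {
        "array_id": layout.array_id,
        "version": layout.version,
        "grid": {"rows": layout.grid_rows, "cols": layout.grid_cols},
        "analytes": [
            {
                "name": a.name,
                "kind": a.kind,
                "phospho_sites": a.phospho_sites,
                "is_mapk": a.is_mapk,
                "spots": [
                    {
                        "row": s.row,
                        "col": s.col,
                        "cx": s.center_x,
                        "cy": s.center_y,
                        "r": s.radius,
                    }
                    for s in a.spots
                ],
            }
            for a in layout.analytes
        ],
    }


def layout_from_dict(doc: dict) -> ArrayLayout:
    try:
        analytes = []
        for entry in doc["analytes"]:
            spots = tuple(
                SpotAddress(
                    row=int(s["row"]),
                    col=int(s["col"]),
                    center_x=float(s["cx"]),
                    center_y=float(s["cy"]),
                    radius=float(s["r"]),
                )
                for s in entry["spots"]
            )
            if len(spots) != 2:
                raise LayoutError(
                    f"analyte {entry.get('name')!r}: expected 2 spots, got {len(spots)}"
                )
            analytes.append(
                Analyte(
                    name=str(entry["name"]),
                    kind=str(entry["kind"]),
                    phospho_sites=str(entry.get("phospho_sites", "")),
                    is_mapk=bool(entry.get("is_mapk", False)),
                    spots=spots,
                )
            )
        return ArrayLayout(
            array_id=str(doc["array_id"]),
            grid_rows=int(doc["grid"]["rows"]),
            grid_cols=int(doc["grid"]["cols"]),
            analytes=tuple(analytes),
            version=str(doc.get("version", "custom")),
        )
    except KeyError as exc:
        raise LayoutError(f"layout document missing required key: {exc}") from exc


def load_layout(document: str, dialect: str = "json") -> ArrayLayout:
    """Parse a layout definition from JSON or YAML text."""
    if dialect == "json":
        doc = json.loads(document)
    elif dialect == "yaml":
        doc = yaml.safe_load(document)
    else:
        raise LayoutError(f"unknown layout dialect {dialect!r}")
    if not isinstance(doc, dict):
        raise LayoutError("layout document must be a mapping at top level")
    return layout_from_dict(doc)


def save_layout(layout: ArrayLayout, dialect: str = "json") -> str:
    """Serialize a layout so load_layout round-trips it exactly."""
    doc = layout_to_dict(layout)
    if dialect == "json":
        return json.dumps(doc, indent=2)
    if dialect == "yaml":
        return yaml.safe_dump(doc, sort_keys=False)
    raise LayoutError(f"unknown layout dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Registration


@dataclass(frozen=True)
class Registration:
    """Affine mapping from layout coordinates to image coordinates.

    Applied as pixel = layout_coordinate * scale + offset; the spot radius
    scales with the same factor.
    """

    offset_x: float = 0.0
    offset_y: float = 0.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise RegistrationError(f"scale must be positive, got {self.scale}")


def bind_layout(
    layout: ArrayLayout,
    image_shape: tuple[int, int],
    registration: Registration = Registration(),
) -> ArrayLayout:
    """Resolve spot pixel coordinates against an image of (height, width).

    Fails (rather than silently clipping) if any spot disc would fall
    outside the image after registration.
    """
    height, width = image_shape
    new_analytes = []
    outside: list[str] = []
    for a in layout.analytes:
        new_spots = []
        for s in a.spots:
            cx = s.center_x * registration.scale + registration.offset_x
            cy = s.center_y * registration.scale + registration.offset_y
            r = s.radius * registration.scale
            if cx - r < 0 or cx + r > width - 1 or cy - r < 0 or cy + r > height - 1:
                outside.append(f"{a.name}[{len(new_spots)}] at ({cx:.1f}, {cy:.1f})")
            new_spots.append(replace(s, center_x=cx, center_y=cy, radius=r))
        new_analytes.append(replace(a, spots=tuple(new_spots)))
    if outside:
        raise RegistrationError(
            "registration places spots outside the image: " + "; ".join(outside)
        )
    return replace(layout, analytes=tuple(new_analytes))
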