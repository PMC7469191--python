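"""Abaqus-dialect *.inp serialization of sectioned triangle meshes.

Each subdomain becomes an element set with its own shell section and
material card, so downstream FE work can assign per-region properties
(e.g. stiffer veins than membrane).  Elements are exported as S3
3-node shells; 2-D meshes get z = 0.  A minimal reader supports
roundtrip testing of counts and set memberships.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InpParseError, ValidationError
from .mesher import TriMesh

__all__ = ["MaterialSpec", "AbaqusDeck", "write_inp", "read_inp_minimal", "format_deck"]

DEFAULT_MATERIAL = ("MAT_DEFAULT", 1.0, 0.3, 0.01)


@dataclass(frozen=True)
class MaterialSpec:
    """Linear-elastic shell material for one section.

    youngs_modulus and thickness are in model units; values default to
    placeholders (E=1, nu=0.3, t=0.01) so every exported deck is
    complete and analyzable even without user-supplied properties.
    """

    name: str
    youngs_modulus: float = 1.0
    poisson_ratio: float = 0.3
    thickness: float = 0.01

    def __post_init__(self):
        if self.youngs_modulus <= 0:
            raise ValidationError("Young's modulus must be positive")
        if not -1.0 < self.poisson_ratio < 0.5:
            raise ValidationError("Poisson ratio must lie in (-1, 0.5)")
        if self.thickness <= 0:
            raise ValidationError("shell thickness must be positive")


@dataclass
class AbaqusDeck:
    """Parsed minimal view of an input deck."""

    nodes: list[tuple[int, float, float, float]]
    elements: list[tuple[int, int, int, int]]
    elsets: dict[str, list[int]]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)


def _materials_for_sections(
    sections: list[int], materials: list[MaterialSpec] | None
) -> dict[int, MaterialSpec]:
    materials = list(materials or [])
    out = {}
    for i, k in enumerate(sections):
        if i < len(materials):
            out[k] = materials[i]
        else:
            name, e, nu, t = DEFAULT_MATERIAL
            out[k] = MaterialSpec(f"{name}_{k}", e, nu, t)
    return out


def format_deck(
    mesh: TriMesh,
    materials: list[MaterialSpec] | None = None,
    scale: float = 1.0,
    heading: str = "wingforge model",
) -> str:
    """Render the mesh as deck text (see :func:`write_inp`)."""
    if mesh.n_triangles == 0 or mesh.n_nodes == 0:
        raise ValidationError("cannot export an empty mesh")
    if mesh.section_of is None:
        raise ValidationError("mesh has no section labels; assign sections first")
    if (mesh.section_of < 1).any():
        raise ValidationError("mesh still contains hole elements; remove them first")
    sections = sorted(set(int(s) for s in mesh.section_of))
    mats = _materials_for_sections(sections, materials)

    lines: list[str] = ["*HEADING", heading]
    lines.append("*NODE")
    for i, node in enumerate(mesh.nodes, start=1):
        x, y = node[0] * scale, node[1] * scale
        z = (node[2] * scale) if mesh.is_3d else 0.0
        lines.append(f"{i}, {x:.6f}, {y:.6f}, {z:.6f}")
    lines.append("*ELEMENT, TYPE=S3")
    for i, (a, b, c) in enumerate(mesh.triangles, start=1):
        lines.append(f"{i}, {a + 1}, {b + 1}, {c + 1}")
    for k in sections:
        ids = [i + 1 for i in range(mesh.n_triangles) if mesh.section_of[i] == k]
        lines.append(f"*ELSET, ELSET=SECTION_{k}")
        for start in range(0, len(ids), 16):
            lines.append(", ".join(str(i) for i in ids[start : start + 16]))
    for k in sections:
        m = mats[k]
        lines.append(
            f"*SHELL SECTION, ELSET=SECTION_{k}, MATERIAL={m.name}"
        )
        lines.append(f"{m.thickness:.6g}")
    for k in sections:
        m = mats[k]
        lines.append(f"*MATERIAL, NAME={m.name}")
        lines.append("*ELASTIC")
        lines.append(f"{m.youngs_modulus:.6g}, {m.poisson_ratio:.6g}")
    return "\n".join(lines) + "\n"


def write_inp(
    mesh: TriMesh,
    materials: list[MaterialSpec] | None = None,
    path=None,
    scale: float = 1.0,
    heading: str = "wingforge model",
) -> str:
    """Write the deck to ``path`` (LF line endings) and return the text.

    Layout: *HEADING; *NODE records ``id, x, y, z``; *ELEMENT TYPE=S3
    records; one *ELSET per section (16 ids per line); one
    *SHELL SECTION and one *MATERIAL/*ELASTIC card per section.
    Node and element ids are 1-based and contiguous.
    """
    text = format_deck(mesh, materials=materials, scale=scale, heading=heading)
    if path is not None:
        with open(path, "w", newline="\n") as f:
            f.write(text)
    return text


def read_inp_minimal(path) -> AbaqusDeck:
    """Parse node/element/elset blocks of a deck written by
    :func:`write_inp`; unknown keywords and ``**`` comments are
    skipped.  Malformed data lines raise :class:`InpParseError` with
    the offending line number."""
    nodes: list[tuple[int, float, float, float]] = []
    elements: list[tuple[int, int, int, int]] = []
    elsets: dict[str, list[int]] = {}
    state = None
    current_set = None
    with open(path) as f:
        for ln, raw in enumerate(f, start=1):
            line = raw.strip()
            if not line or line.startswith("**"):
                continue
            if line.startswith("*"):
                kw = line.split(",")[0].strip().upper()
                if kw == "*NODE":
                    state = "node"
                elif kw == "*ELEMENT":
                    state = "element"
                elif kw == "*ELSET":
                    opts = dict(
                        tuple(s.strip() for s in part.split("=", 1))
                        for part in line.split(",")[1:]
                        if "=" in part
                    )
                    name = opts.get("ELSET") or opts.get("elset")
                    if not name:
                        raise InpParseError("*ELSET without ELSET= name", ln)
                    current_set = elsets.setdefault(name, [])
                    state = "elset"
                else:
                    state = None
                continue
            try:
                if state == "node":
                    parts = [s.strip() for s in line.split(",")]
                    if len(parts) != 4:
                        raise ValueError("expected 'id, x, y, z'")
                    nodes.append(
                        (int(parts[0]), float(parts[1]), float(parts[2]), float(parts[3]))
                    )
                elif state == "element":
                    parts = [s.strip() for s in line.split(",")]
                    if len(parts) != 4:
                        raise ValueError("expected 'id, n1, n2, n3'")
                    elements.append(tuple(int(s) for s in parts))
                elif state == "elset":
                    current_set.extend(
                        int(s) for s in line.split(",") if s.strip()
                    )
            except ValueError as exc:
                raise InpParseError(str(exc), ln) from exc
    return AbaqusDeck(nodes=nodes, elements=elements, elsets=elsets)
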