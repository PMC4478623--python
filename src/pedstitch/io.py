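"""Read and write the configuration / pedigree / metadata file trio.

A dataset is described by a configuration file of ``KEY  VALUE`` lines
(case-sensitive keys, ``#`` comments) naming the pedigree file and mapping
columns to the four roles (name, father, mother, sex).  The pedigree file
is a tab-delimited table, one individual per row, with a header row by
default.  Unrecognized configuration keys are appearance options: they are
preserved verbatim and re-emitted byte-identically, never interpreted.

Writing is non-destructive: a file read during the current session is
refused as an output path unless the caller explicitly asks for in-place
editing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .errors import ConfigError, ParseError, SessionOverwriteError
from .model import MISSING, Individual, Pedigree, Sex

#: Configuration keys with fixed meaning; everything else is appearance.
KEY_PEDIGREE_FILE = "PedigreeFile"
KEY_PEDIGREE_NAME = "PedigreeName"
KEY_METADATA_FILE = "MetadataFile"
ROLE_KEYS = {
    "name": "NameVariable",
    "father": "FatherVariable",
    "mother": "MotherVariable",
    "sex": "SexVariable",
}
REQUIRED_KEYS = (KEY_PEDIGREE_FILE,) + tuple(ROLE_KEYS.values())


@dataclass
class PedFileDialect:
    """Low-level file conventions.  The delimiter is always one tab."""

    header_present: bool = True
    missing_value: str = MISSING


@dataclass
class PedConfig:
    """Parsed configuration: file paths, column roles, appearance options."""

    pedigree_path: Path
    pedigree_name: str
    column_roles: dict[str, str]  # role -> column header
    attribute_columns: list[str] | None = None
    metadata_path: Path | None = None
    appearance: list[str] = field(default_factory=list)  # verbatim lines
    source_path: Path | None = None
    session_inputs: set[Path] = field(default_factory=set)

    def role_headers(self) -> list[str]:
        return [self.column_roles[r] for r in ("name", "father", "mother", "sex")]

    def register_input(self, path: Path) -> None:
        self.session_inputs.add(Path(path).resolve())

    def guard_output(self, path: Path, in_place: bool) -> None:
        if not in_place and Path(path).resolve() in self.session_inputs:
            raise SessionOverwriteError(
                f"refusing to overwrite session input {path} "
                "(pass in_place=True / --in-place to edit sources)"
            )


def read_config(path) -> PedConfig:
    """Parse a configuration file.

    Required keys: PedigreeFile and the four role keys NameVariable,
    FatherVariable, MotherVariable, SexVariable.  PedigreeName defaults to
    the pedigree file's stem; MetadataFile is optional.  Duplicate keys are
    errors; unknown keys are stored verbatim as appearance options.
    """
    path = Path(path)
    known: dict[str, str] = {}
    appearance: list[str] = []
    seen: set[str] = set()
    recognized = set(REQUIRED_KEYS) | {KEY_PEDIGREE_NAME, KEY_METADATA_FILE}
    with open(path, encoding="utf-8", newline="") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\r\n")
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split(None, 1)
            key = parts[0]
            value = parts[1] if len(parts) > 1 else ""
            if key in seen:
                raise ConfigError(f"{path}:{lineno}: duplicate key {key!r}")
            seen.add(key)
            if key in recognized:
                if not value:
                    raise ConfigError(f"{path}:{lineno}: key {key!r} has no value")
                known[key] = value
            else:
                appearance.append(line)
    for required in REQUIRED_KEYS:
        if required not in known:
            role = next(
                (r for r, k in ROLE_KEYS.items() if k == required), "pedigree file"
            )
            raise ConfigError(
                f"{path}: missing required key {required!r} ({role} role)"
            )
    roles = {role: known[key] for role, key in ROLE_KEYS.items()}
    if len(set(roles.values())) != 4:
        raise ConfigError(f"{path}: the four role columns must be distinct")
    pedigree_path = path.parent / known[KEY_PEDIGREE_FILE]
    metadata_path = (
        path.parent / known[KEY_METADATA_FILE] if KEY_METADATA_FILE in known else None
    )
    config = PedConfig(
        pedigree_path=pedigree_path,
        pedigree_name=known.get(KEY_PEDIGREE_NAME, Path(known[KEY_PEDIGREE_FILE]).stem),
        column_roles=roles,
        metadata_path=metadata_path,
        appearance=appearance,
        source_path=path,
    )
    config.register_input(path)
    return config


def write_config(config: PedConfig, path, in_place: bool = False) -> None:
    """Serialize a configuration; appearance lines are emitted verbatim."""
    path = Path(path)
    config.guard_output(path, in_place)
    lines = [
        f"{KEY_PEDIGREE_FILE}\t{config.pedigree_path.name}",
        f"{KEY_PEDIGREE_NAME}\t{config.pedigree_name}",
    ]
    for role in ("name", "father", "mother", "sex"):
        lines.append(f"{ROLE_KEYS[role]}\t{config.column_roles[role]}")
    if config.metadata_path is not None:
        lines.append(f"{KEY_METADATA_FILE}\t{config.metadata_path.name}")
    lines.extend(config.appearance)
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_pedigree(config: PedConfig, dialect: PedFileDialect | None = None) -> Pedigree:
    """Read the pedigree file named by a configuration.

    One Individual per data row, ids from the name column, attributes from
    the non-role columns in file order.  Rows shorter than the header are
    padded with the missing sentinel; longer rows are parse errors.
    """
    dialect = dialect or PedFileDialect()
    path = Path(config.pedigree_path)
    with open(path, encoding="utf-8", newline="") as handle:
        lines = [line.rstrip("\r\n") for line in handle]
    while lines and lines[-1] == "":
        lines.pop()
    if dialect.header_present:
        if not lines:
            raise ParseError(f"{path}: empty file, header row required")
        header = lines[0].split("\t")
        data_lines = list(enumerate(lines[1:], start=2))
    else:
        if config.attribute_columns is None:
            raise ConfigError(
                f"{path}: headerless mode requires attribute_columns in the config"
            )
        header = config.role_headers() + list(config.attribute_columns)
        data_lines = list(enumerate(lines, start=1))

    role_headers = config.role_headers()
    for role, head in zip(("name", "father", "mother", "sex"), role_headers):
        if head not in header:
            raise ParseError(
                f"{path}: header lacks {role} column {head!r} (header: {header})"
            )
    role_idx = {r: header.index(h) for r, h in zip(("name", "father", "mother", "sex"), role_headers)}
    attr_columns = [h for h in header if h not in role_headers]
    attr_idx = [header.index(h) for h in attr_columns]

    members: list[Individual] = []
    first_line: dict[str, int] = {}
    for lineno, line in data_lines:
        fields = line.split("\t")
        if len(fields) > len(header):
            raise ParseError(
                f"{path}:{lineno}: expected {len(header)} fields, found {len(fields)}"
            )
        fields += [dialect.missing_value] * (len(header) - len(fields))
        fields = [f if f != "" else dialect.missing_value for f in fields]
        member_id = fields[role_idx["name"]]
        if member_id in first_line:
            raise ParseError(
                f"{path}:{lineno}: duplicate id {member_id!r} "
                f"(first seen on line {first_line[member_id]})"
            )
        first_line[member_id] = lineno
        members.append(
            Individual(
                id=member_id,
                father_id=fields[role_idx["father"]],
                mother_id=fields[role_idx["mother"]],
                sex=Sex.from_code(fields[role_idx["sex"]]),
                attributes={h: fields[i] for h, i in zip(attr_columns, attr_idx)},
            )
        )
    if config.attribute_columns is None:
        config.attribute_columns = attr_columns
    config.register_input(path)
    return Pedigree(config.pedigree_name, attr_columns, members)


def write_pedigree(
    ped: Pedigree, config: PedConfig, path, in_place: bool = False
) -> None:
    """Write a pedigree as tab-delimited text: role columns, then attributes.

    Refuses to overwrite a file read during this session unless ``in_place``
    is set; output is UTF-8 with LF newlines and a constant field count per
    row, so serialization is deterministic.
    """
    path = Path(path)
    config.guard_output(path, in_place)
    header = config.role_headers() + list(ped.columns)
    rows = ["\t".join(header)]
    for member in ped.members:
        row = [member.id, member.father_id, member.mother_id, member.sex.code]
        row += [member.attributes.get(c, MISSING) for c in ped.columns]
        rows.append("\t".join(row))
    path.write_text("\n".join(rows) + "\n", encoding="utf-8")


def export_linkage_ped(
    ped: Pedigree,
    path,
    family_id: str | None = None,
    attributes: list[str] | None = None,
    recode: bool = False,
    map_path=None,
) -> dict[str, str]:
    """Export pre-makeped LINKAGE PED: FamID IndID Father Mother Sex + data.

    Ids containing whitespace are not LINKAGE-safe; pass ``recode=True`` to
    re-code all ids to consecutive integers (the bijection is written as a
    two-column map side file and returned).
    """
    path = Path(path)
    family_id = family_id or ped.name or "FAM"
    attributes = list(ped.columns) if attributes is None else list(attributes)
    if recode:
        mapping = {m.id: str(i) for i, m in enumerate(ped.members, start=1)}
    else:
        bad = [m.id for m in ped.members if any(ch.isspace() for ch in m.id)]
        if bad:
            raise ParseError(
                f"ids not LINKAGE-safe (contain whitespace): {bad}; "
                "use recode=True"
            )
        mapping = {m.id: m.id for m in ped.members}
    lines = []
    for member in ped.members:
        father = mapping.get(member.father_id, MISSING)
        mother = mapping.get(member.mother_id, MISSING)
        row = [family_id, mapping[member.id], father, mother, member.sex.code]
        row += [member.attributes.get(c, MISSING) for c in attributes]
        lines.append("\t".join(row))
    path.write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
    if recode:
        map_path = Path(map_path) if map_path else path.with_suffix(path.suffix + ".map")
        map_lines = [f"{orig}\t{code}" for orig, code in mapping.items()]
        map_path.write_text("\n".join(map_lines) + "\n", encoding="utf-8")
    return mapping


def import_linkage_ped(path, columns: list[str] | None = None, name: str = "") -> Pedigree:
    """Read a pre-makeped LINKAGE PED file back into a Pedigree."""
    path = Path(path)
    columns = list(columns or [])
    members = []
    with open(path, encoding="utf-8", newline="") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 5 or len(fields) > 5 + len(columns):
                raise ParseError(
                    f"{path}:{lineno}: expected 5..{5 + len(columns)} fields, "
                    f"found {len(fields)}"
                )
            fields += [MISSING] * (5 + len(columns) - len(fields))
            members.append(
                Individual(
                    id=fields[1],
                    father_id=fields[2],
                    mother_id=fields[3],
                    sex=Sex.from_code(fields[4]),
                    attributes=dict(zip(columns, fields[5:])),
                )
            )
    return Pedigree(name or path.stem, columns, members)


_DOT_SHAPE = {Sex.MALE: "box", Sex.FEMALE: "ellipse", Sex.UNKNOWN: "diamond"}


def export_dot(ped: Pedigree, path) -> None:
    """Emit a Graphviz digraph of the family structure.

    One node per individual (shape encodes sex: box = male, ellipse =
    female, diamond = unknown), one point-shaped marriage node per distinct
    parental pair, and edges parent -> marriage -> child.  Node order is
    deterministic (file order; marriage nodes in first-child order).
    """
    path = Path(path)
    lines = [f'digraph "{ped.name}" {{']
    for member in ped.members:
        lines.append(
            f'  "{member.id}" [shape={_DOT_SHAPE[member.sex]}, label="{member.id}"];'
        )
    pairs: dict[tuple[str, str], list[str]] = {}
    for member in ped.members:
        if member.father_id == MISSING and member.mother_id == MISSING:
            continue
        pairs.setdefault((member.father_id, member.mother_id), []).append(member.id)
    for i, ((father, mother), children) in enumerate(pairs.items()):
        marriage = f"m{i}"
        lines.append(f'  "{marriage}" [shape=point];')
        if father != MISSING:
            lines.append(f'  "{father}" -> "{marriage}";')
        if mother != MISSING:
            lines.append(f'  "{mother}" -> "{marriage}";')
        for child in children:
            lines.append(f'  "{marriage}" -> "{child}";')
    lines.append("}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
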