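"""Readers/writers: extended-XYZ geometries and trajectories, YAML
simulation settings, fitted-term files, delimited tables and run manifests.

Extended-XYZ is the single geometry format: the comment line carries
``Lattice="L 0 0 0 L 0 0 0 L"`` for periodic boxes, ``energy=<kcal/mol>``
labels, and free ``key=value`` metadata.  Molecules are inferred from the
O,H,H atom ordering.
"""

from __future__ import annotations

import json
import platform
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from . import __version__
from .config import Configuration
from .pimd import SimulationSpec


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


# ---------------------------------------------------------------------------
# extended-XYZ

def _format_comment(config: Configuration, extra: dict | None = None) -> str:
    fields = {}
    if config.box_edge is not None:
        L = config.box_edge
        fields["Lattice"] = f'"{L} 0 0 0 {L} 0 0 0 {L}"'
    fields["Properties"] = "species:S:1:pos:R:3"
    for k, v in {**config.metadata, **(extra or {})}.items():
        if isinstance(v, float):
            fields[k] = repr(v)
        elif isinstance(v, str) and " " in v:
            fields[k] = f'"{v}"'
        else:
            fields[k] = str(v)
    return " ".join(f"{k}={v}" for k, v in fields.items())


def write_xyz(path, configs, extra: dict | None = None, mode: str = "w"):
    """Write one or several configurations as (extended) XYZ frames."""
    if isinstance(configs, Configuration):
        configs = [configs]
    with open(path, mode) as fh:
        for cfg in configs:
            fh.write(f"{cfg.n_atoms}\n")
            fh.write(_format_comment(cfg, extra) + "\n")
            for el, xyz in zip(cfg.elements, cfg.coords):
                fh.write(f"{el} {xyz[0]:.10f} {xyz[1]:.10f} {xyz[2]:.10f}\n")


def _split_comment(line: str) -> dict:
    out = {}
    token = ""
    key = None
    in_quote = False
    for ch in line.strip() + " ":
        if ch == '"':
            in_quote = not in_quote
        elif ch == "=" and not in_quote and key is None:
            key = token
            token = ""
        elif ch == " " and not in_quote:
            if key is not None:
                out[key] = token
                key = None
            token = ""
        else:
            token += ch
    return out


def read_xyz(path) -> list:
    """Read all frames of an (extended) XYZ file into Configurations."""
    frames = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise ParseError(f"line {i + 1}: expected an atom count")
        if i + 1 + n >= len(lines) + 1:
            raise ParseError(f"line {i + 1}: truncated frame ({n} atoms)")
        meta = _split_comment(lines[i + 1])
        elements = []
        coords = []
        for j in range(n):
            parts = lines[i + 2 + j].split()
            if len(parts) < 4:
                raise ParseError(f"line {i + 3 + j}: malformed atom record")
            elements.append(parts[0])
            coords.append([float(x) for x in parts[1:4]])
        box = None
        if "Lattice" in meta:
            vals = [float(x) for x in meta["Lattice"].split()]
            if len(vals) != 9 or vals[0] != vals[4] or vals[0] != vals[8]:
                raise ParseError(
                    f"line {i + 2}: only cubic Lattice fields are supported"
                )
            box = vals[0]
        if n % 3 != 0:
            raise ParseError(
                f"line {i + 1}: {n} atoms is not a whole number of waters"
            )
        for m in range(n // 3):
            trio = elements[3 * m: 3 * m + 3]
            if trio != ["O", "H", "H"]:
                raise ParseError(
                    f"line {i + 3 + 3 * m}: molecule {m} is not ordered "
                    f"O,H,H (found {','.join(trio)})"
                )
        metadata = {k: _coerce(v) for k, v in meta.items()
                    if k not in ("Lattice", "Properties")}
        frames.append(Configuration(
            elements=elements,
            coords=np.array(coords),
            molecule_index=np.repeat(np.arange(n // 3), 3),
            box_edge=box,
            metadata=metadata,
        ))
        i += 2 + n
    return frames


def _coerce(v: str):
    for cast in (int, float):
        try:
            return cast(v)
        except ValueError:
            pass
    return v


def read_trajectory_xyz(path):
    """Rebuild a bead-resolved Trajectory from an extended-XYZ file whose
    frames carry ``frame=``/``bead=`` tags (as written by
    :func:`write_trajectory_xyz`)."""
    from .pimd import SimulationSpec, Trajectory

    frames = read_xyz(path)
    if not frames:
        raise ParseError(f"{path}: no frames")
    by_frame: dict = {}
    for cfg in frames:
        by_frame.setdefault(cfg.metadata.get("frame", 0), []).append(cfg)
    traj = Trajectory(elements=list(frames[0].elements),
                      molecule_index=frames[0].molecule_index.copy(),
                      spec=SimulationSpec())
    for f in sorted(by_frame):
        beads = by_frame[f]
        traj.frames.append(np.stack([b.coords for b in beads]))
        traj.box_edges.append(beads[0].box_edge)
    return traj


def write_trajectory_xyz(path, traj, stride: int = 1):
    """Bead-resolved trajectory frames; each bead is one XYZ frame tagged
    with ``frame=`` and ``bead=``."""
    first = True
    for f in range(0, traj.n_frames, stride):
        for s, cfg in enumerate(traj.configurations(f)):
            cfg.metadata.update(frame=f, bead=s)
            write_xyz(path, cfg, mode="w" if first else "a")
            first = False


# ---------------------------------------------------------------------------
# simulation settings

_SPEC_KEYS = {f.name for f in
              __import__("dataclasses").fields(SimulationSpec)}


def load_config(path) -> SimulationSpec:
    """Simulation settings from YAML; missing keys fall back to the
    standard ambient-water defaults, unknown keys are rejected."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ParseError(f"{path}: expected a mapping of settings")
    unknown = set(data) - _SPEC_KEYS
    if unknown:
        raise ParseError(f"{path}: unknown settings {sorted(unknown)}")
    try:
        return SimulationSpec(**data)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc


def save_config(path, spec: SimulationSpec):
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(spec), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# fitted terms

def save_term(path, term):
    with open(path, "w") as fh:
        yaml.safe_dump(term.to_dict(), fh, sort_keys=False)


def load_term(path):
    from .fitting import FittedTerm

    with open(path) as fh:
        return FittedTerm.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# tables and manifests

def save_table(path, df, **kwargs):
    df.to_csv(path, sep="\t", index=kwargs.pop("index", False), **kwargs)


@dataclass
class RunManifest:
    """Provenance record emitted next to every pipeline output."""

    command: str
    seeds: dict = field(default_factory=dict)
    potential_tags: list = field(default_factory=list)
    inputs: list = field(default_factory=list)
    outputs: list = field(default_factory=list)
    settings: dict = field(default_factory=dict)
    code_version: str = __version__
    timestamp: str = field(
        default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S"))
    host: str = field(default_factory=platform.node)

    def write(self, path):
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)
        return path
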