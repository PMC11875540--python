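"""Extended-XYZ trajectory dialect shared by the MD and bridging modules.

Frame layout::

    <n_atoms>
    Lattice="lx 0 0 0 ly 0 0 0 lz" Properties=species:S:1:pos:R:3:chain:I:1
    <species> <x> <y> <z> <chain_id>
    ...

Chain id -1 marks unbonded beads (free ions).  Only orthorhombic boxes are
supported; coordinates are in Angstrom.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np


def _parse_comment(line: str) -> dict:
    out = {}
    for key, val in re.findall(r'(\w+)=("[^"]*"|\S+)', line):
        out[key] = val.strip('"')
    return out


def read_snapshots(path) -> list:
    """Read all frames of an extended-XYZ file into Configurations."""
    from .cgmd import Configuration

    text = Path(path).read_text()
    lines = text.splitlines()
    frames = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise ValueError(f"line {i+1}: expected atom count") from exc
        if i + 1 + n >= len(lines) + 1 and n > 0 and i + 1 + n > len(lines):
            raise ValueError(f"frame starting at line {i+1}: expected {n} atoms, "
                             f"file truncated")
        meta = _parse_comment(lines[i + 1])
        if "Lattice" not in meta:
            raise ValueError(f"line {i+2}: missing box (Lattice=...)")
        lat = [float(v) for v in meta["Lattice"].split()]
        if len(lat) != 9:
            raise ValueError(f"line {i+2}: Lattice must have 9 components")
        box = (lat[0], lat[4], lat[8])
        species, chains = [], []
        coords = np.empty((n, 3))
        for j in range(n):
            parts = lines[i + 2 + j].split()
            if len(parts) < 5:
                raise ValueError(
                    f"line {i+3+j}: need 'species x y z chain' columns")
            species.append(parts[0])
            coords[j] = [float(parts[1]), float(parts[2]), float(parts[3])]
            chains.append(int(parts[4]))
        frames.append(Configuration(coords=coords, species=species,
                                    chain_ids=chains, box=box))
        i += 2 + n
    return frames


def write_snapshots(path, frames) -> None:
    with open(path, "w") as fh:
        for cfg in frames:
            lx, ly, lz = cfg.box
            fh.write(f"{len(cfg.species)}\n")
            fh.write(f'Lattice="{lx:.8g} 0 0 0 {ly:.8g} 0 0 0 {lz:.8g}" '
                     f"Properties=species:S:1:pos:R:3:chain:I:1\n")
            for sp, xyz, ch in zip(cfg.species, cfg.coords, cfg.chain_ids):
                fh.write(f"{sp} {xyz[0]:.8f} {xyz[1]:.8f} {xyz[2]:.8f} {ch}\n")
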