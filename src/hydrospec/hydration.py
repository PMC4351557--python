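"""Geometric hydration counting on coordinate frames.

The hydration count of a binding site is the number of distinct water
oxygens whose minimum-image distance to at least one site atom is within a
cutoff (0.35 nm by default, the conventional hydrogen-bond distance; 0.30
nm is the stricter alternative).  Boxes are orthorhombic; coordinates are
in nm.

Frames can be supplied directly, read from a simple whitespace-delimited
text format, or adapted from an MDAnalysis Universe when trajectory files
are available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

DEFAULT_CUTOFF = 0.35  # nm
ALT_CUTOFF = 0.30  # nm


class GeometryError(ValueError):
    """Raised when the box cannot support an unambiguous minimum image."""


@dataclass
class Frame:
    """Water-oxygen and per-site head-group atom positions in a periodic box.

    ``site_atoms`` maps a site id to an (n_atoms, 3) array; ``box`` holds
    the three orthorhombic box lengths (nm).
    """

    water_oxygens: np.ndarray
    site_atoms: dict[str, np.ndarray]
    box: np.ndarray
    index: int = 0

    def __post_init__(self) -> None:
        self.water_oxygens = np.asarray(self.water_oxygens, dtype=float).reshape(-1, 3)
        self.box = np.asarray(self.box, dtype=float)
        self.site_atoms = {k: np.asarray(v, dtype=float).reshape(-1, 3) for k, v in self.site_atoms.items()}
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be three positive lengths")
        for arr in [self.water_oxygens, *self.site_atoms.values()]:
            if not np.all(np.isfinite(arr)):
                raise ValueError("coordinates must be finite")


def minimum_image_distances(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Pairwise minimum-image distances between rows of a and rows of b."""
    d = a[:, None, :] - b[None, :, :]
    d -= box * np.rint(d / box)
    return np.sqrt(np.sum(d * d, axis=-1))


def count_waters(frame: Frame, cutoff: float = DEFAULT_CUTOFF) -> dict[str, int]:
    """Count distinct water oxygens within `cutoff` of each site.

    An oxygen is counted once per site if its minimum-image distance to any
    atom of that site is <= cutoff (boundary-inclusive); an oxygen close to
    several sites is counted by each of them independently.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if cutoff >= float(frame.box.min()) / 2:
        raise GeometryError(
            f"cutoff {cutoff} >= half the smallest box length {frame.box.min() / 2}: "
            "minimum-image distances are ambiguous"
        )
    counts: dict[str, int] = {}
    waters = frame.water_oxygens
    for site, atoms in frame.site_atoms.items():
        if waters.size == 0 or atoms.size == 0:
            counts[site] = 0
            continue
        dist = minimum_image_distances(waters, atoms, frame.box)
        counts[site] = int(np.count_nonzero(np.min(dist, axis=1) <= cutoff))
    return counts


def count_waters_trajectory(frames: Iterable[Frame], cutoff: float = DEFAULT_CUTOFF):
    """Apply :func:`count_waters` over frames; returns (site ids, int array)."""
    rows = []
    sites: list[str] | None = None
    for frame in frames:
        c = count_waters(frame, cutoff)
        if sites is None:
            sites = list(c)
        rows.append([c[s] for s in sites])
    if sites is None:
        raise ValueError("no frames supplied")
    return sites, np.asarray(rows, dtype=int)


# ---------------------------------------------------------------------------
# plain-text frame format:
#   # comment / header lines
#   <frame> box  -      Lx Ly Lz
#   <frame> site <id>   x y z
#   <frame> water -     x y z
# ---------------------------------------------------------------------------

def read_frames(path: str | Path) -> Iterator[Frame]:
    """Stream frames from the whitespace-delimited coordinate format."""
    current: int | None = None
    box = None
    waters: list[list[float]] = []
    sites: dict[str, list[list[float]]] = {}

    def flush() -> Frame:
        if box is None:
            raise ValueError(f"frame {current} has no box record")
        return Frame(
            np.asarray(waters, dtype=float).reshape(-1, 3),
            {k: np.asarray(v, dtype=float) for k, v in sites.items()},
            np.asarray(box, dtype=float),
            index=current,
        )

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 6:
                raise ValueError(f"malformed frame record: {line!r}")
            idx = int(parts[0])
            kind, label = parts[1], parts[2]
            xyz = [float(v) for v in parts[3:6]]
            if current is None:
                current = idx
            if idx != current:
                yield flush()
                current, box, waters, sites = idx, None, [], {}
            if kind == "box":
                box = xyz
            elif kind == "water":
                waters.append(xyz)
            elif kind == "site":
                sites.setdefault(label, []).append(xyz)
            else:
                raise ValueError(f"unknown record kind {kind!r}")
    if current is not None:
        yield flush()


def write_frames(path: str | Path, frames: Iterable[Frame]) -> None:
    with open(path, "w") as fh:
        fh.write("# hydrospec frames: frame kind site x y z (nm)\n")
        for frame in frames:
            i = frame.index
            fh.write(f"{i} box - {frame.box[0]:.6f} {frame.box[1]:.6f} {frame.box[2]:.6f}\n")
            for site, atoms in frame.site_atoms.items():
                for x, y, z in atoms:
                    fh.write(f"{i} site {site} {x:.6f} {y:.6f} {z:.6f}\n")
            for x, y, z in frame.water_oxygens:
                fh.write(f"{i} water - {x:.6f} {y:.6f} {z:.6f}\n")


def frames_from_mdanalysis(
    universe, site_selections: dict[str, str], water_selection: str = "name OW or name OH2"
) -> Iterator[Frame]:
    """Adapt an MDAnalysis Universe to Frame objects (optional dependency).

    Positions are converted from MDAnalysis angstroms to nm; the box must
    be orthorhombic.  ``site_selections`` maps site ids to selection
    strings for the head-group atoms.
    """
    site_groups = {k: universe.select_atoms(v) for k, v in site_selections.items()}
    waters = universe.select_atoms(water_selection)
    for ts in universe.trajectory:
        dims = ts.dimensions
        if dims is None or not np.allclose(dims[3:6], 90.0):
            raise GeometryError("only orthorhombic boxes are supported")
        yield Frame(
            waters.positions / 10.0,
            {k: g.positions / 10.0 for k, g in site_groups.items()},
            np.asarray(dims[:3], dtype=float) / 10.0,
            index=int(ts.frame),
        )
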