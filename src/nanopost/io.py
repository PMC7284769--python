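"""Text I/O: extended-XYZ trajectories, provenance-stamped CSV tables
and flat key=value config files.

The trajectory dialect is the common extended-XYZ one: per frame a bead
count line, then a comment line of space-separated key=value pairs
(time stamp, geometry and sampler metadata), then one ``C x y z`` line
per bead.  Analysis code is thereby agnostic about whether frames came
from dynamics, Monte Carlo or a fixture generator.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .simulate import Trajectory

__all__ = [
    "write_xyz",
    "read_xyz",
    "write_csv_with_provenance",
    "read_config",
    "write_config",
]

_SCALARS = (str, int, float, bool, np.integer, np.floating)


def _fmt_value(v) -> str:
    if isinstance(v, (dict, list, tuple)):
        return json.dumps(v, separators=(",", ":"))
    return str(v)


def write_xyz(traj: Trajectory, path: Union[str, Path]) -> None:
    """Write a trajectory as extended XYZ, one block per frame."""
    path = Path(path)
    n = traj.n_beads
    meta = " ".join(
        f"{k}={_fmt_value(v)}" for k, v in sorted(traj.provenance.items())
        if isinstance(v, _SCALARS)
    )
    with path.open("w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{n}\n")
            fh.write(f"time={traj.times[f]:.6f}" + (f" {meta}" if meta else "") + "\n")
            for x, y, z in traj.frames[f]:
                fh.write(f"C {x:.8f} {y:.8f} {z:.8f}\n")


def read_xyz(path: Union[str, Path]) -> Trajectory:
    """Read an extended-XYZ trajectory written by :func:`write_xyz`."""
    path = Path(path)
    frames = []
    times = []
    prov: dict = {}
    with path.open() as fh:
        while True:
            line = fh.readline()
            if not line.strip():
                break
            n = int(line)
            comment = fh.readline().split()
            fields = dict(tok.split("=", 1) for tok in comment if "=" in tok)
            times.append(float(fields.pop("time", len(times))))
            for k, v in fields.items():
                try:
                    prov[k] = float(v) if "." in v or "e" in v.lower() else int(v)
                except ValueError:
                    prov[k] = v
            block = np.empty((n, 3))
            for i in range(n):
                parts = fh.readline().split()
                block[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
            frames.append(block)
    if not frames:
        raise ValueError(f"no frames in {path}")
    return Trajectory(np.stack(frames), np.asarray(times), prov)


def write_csv_with_provenance(df, path: Union[str, Path],
                              provenance: Optional[dict] = None) -> None:
    """Write a DataFrame as CSV preceded by ``#``-prefixed provenance lines."""
    path = Path(path)
    with path.open("w") as fh:
        for k, v in sorted((provenance or {}).items()):
            fh.write(f"# {k} = {_fmt_value(v)}\n")
        df.to_csv(fh, index=False)


def read_config(path: Union[str, Path]) -> dict:
    """Parse a flat ``key = value`` config file (``#`` comments allowed).

    Values are coerced to int, then float, then bool, else kept as str.
    """
    out: dict = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {raw!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        for cast in (int, float):
            try:
                out[key] = cast(val)
                break
            except ValueError:
                continue
        else:
            if val.lower() in ("true", "false"):
                out[key] = val.lower() == "true"
            else:
                out[key] = val
    return out


def write_config(cfg: dict, path: Union[str, Path]) -> None:
    Path(path).write_text(
        "".join(f"{k} = {v}\n" for k, v in cfg.items())
    )
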