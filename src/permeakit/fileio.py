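"""Trajectory and configuration file I/O.

Trajectories travel as GROMACS pull-coordinate-style ``.xvg`` text files:
lines starting with ``#`` or ``@`` are comments/metadata, followed by two
whitespace-separated numeric columns, time (ns) and z (nm).  Campaign
metadata lives in a JSON manifest; configuration files are YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .exceptions import XvgParseError

__all__ = ["read_xvg", "write_xvg", "read_manifest", "write_manifest", "load_config"]


def read_xvg(path):
    """Parse a two-column .xvg file.

    Returns ``(times, values, metadata)`` where metadata collects
    ``@ key value`` annotations.
    """
    path = Path(path)
    times, values = [], []
    metadata = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                continue
            if line.startswith("@"):
                parts = line[1:].strip().split(None, 1)
                if len(parts) == 2:
                    metadata[parts[0]] = parts[1].strip('"')
                continue
            cols = line.split()
            if len(cols) < 2:
                raise XvgParseError(
                    f"{path}:{lineno}: expected 2 columns, got {len(cols)}"
                )
            try:
                times.append(float(cols[0]))
                values.append(float(cols[1]))
            except ValueError as exc:
                raise XvgParseError(
                    f"{path}:{lineno}: non-numeric payload: {line!r}"
                ) from exc
    if not times:
        raise XvgParseError(f"{path}: no data rows found")
    return np.asarray(times), np.asarray(values), metadata


def write_xvg(path, times, values, metadata=None, comment=None):
    """Write a two-column .xvg file with optional ``@``-style metadata."""
    path = Path(path)
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    with open(path, "w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        for key, val in (metadata or {}).items():
            fh.write(f"@ {key} {val}\n")
        for t, v in zip(times, values):
            fh.write(f"{t:.10g} {v:.17g}\n")
    return path


def write_manifest(path, entries):
    """Write the campaign manifest: a JSON list of per-file metadata dicts."""
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(entries, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return path


def read_manifest(path):
    with open(path) as fh:
        return json.load(fh)


def load_config(path):
    """Load a YAML configuration file into a nested dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}
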