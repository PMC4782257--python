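"""Reading and writing TPS landmark files.

The TPS dialect used here is the plain one produced by 2D digitising
software: one record per specimen, uppercase keywords, and an optional
``SCALE`` factor converting raw (pixel) coordinates to physical units::

    LM=19
    12.0 34.5
    ...
    IMAGE=specimen.jpg
    ID=Homo_sapiens
    SCALE=0.01

Coordinates held in :class:`LandmarkConfiguration` are always physical
(raw * scale); :func:`write_tps` divides back out so that a read/write
round trip is exact to full double precision.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence, Tuple

import numpy as np

from .errors import InvalidArgumentError
from .templates import TemplateShape

__all__ = ["LandmarkConfiguration", "read_tps", "write_tps"]


@dataclass
class LandmarkConfiguration:
    """One specimen's raw 2D landmarks, in physical units.

    Role structure (``fixed_idx``/``semi_idx``/``curves``, 1-based) is
    optional at load time and usually attached from a
    :class:`~morphoevo.templates.TemplateShape`.
    """

    specimen_id: str
    points: np.ndarray
    fixed_idx: Tuple[int, ...] = ()
    semi_idx: Tuple[int, ...] = ()
    curves: Mapping[int, Tuple[int, int]] = field(default_factory=dict)
    scale: float = 1.0
    image: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise InvalidArgumentError("points must be a (k, 2) array")
        if self.points.shape[0] < 3:
            raise InvalidArgumentError("a configuration needs at least 3 landmarks")
        if self.scale <= 0:
            raise InvalidArgumentError("scale must be positive")
        # Coincident points defeat Procrustes alignment and sliding.
        k = self.points.shape[0]
        if k <= 512:  # pairwise check is cheap at digitising scales
            d = self.points[:, None, :] - self.points[None, :, :]
            eq = np.all(d == 0.0, axis=2)
            np.fill_diagonal(eq, False)
            if eq.any():
                i, j = np.argwhere(eq)[0]
                raise InvalidArgumentError(
                    f"specimen {self.specimen_id!r}: landmarks {i + 1} and {j + 1} coincide"
                )

    @property
    def k(self) -> int:
        return int(self.points.shape[0])

    def with_roles(self, template: TemplateShape) -> "LandmarkConfiguration":
        """Attach fixed/semi/curve structure from a template of matching k."""
        if template.k != self.k:
            raise InvalidArgumentError(
                f"template has {template.k} landmarks, specimen has {self.k}"
            )
        return LandmarkConfiguration(
            specimen_id=self.specimen_id,
            points=self.points,
            fixed_idx=template.fixed_idx,
            semi_idx=template.semi_idx,
            curves=dict(template.curves),
            scale=self.scale,
            image=self.image,
        )

    def subset(self, indices: Sequence[int], template: TemplateShape | None = None):
        """Restrict to a 1-based index subset, optionally re-attaching roles."""
        idx = [int(i) - 1 for i in indices]
        cfg = LandmarkConfiguration(
            specimen_id=self.specimen_id,
            points=self.points[idx],
            scale=self.scale,
            image=self.image,
        )
        return cfg.with_roles(template) if template is not None else cfg


def read_tps(path, template: TemplateShape | None = None) -> list[LandmarkConfiguration]:
    """Parse a TPS file into a list of configurations (physical coordinates).

    Parameters
    ----------
    path : str, Path or file-like
        TPS source.
    template : TemplateShape, optional
        If given, role structure is attached to every specimen.
    """
    if hasattr(path, "read"):
        text = path.read()
    else:
        text = Path(path).read_text()
    configs: list[LandmarkConfiguration] = []
    lines = text.splitlines()
    i, n_anonymous = 0, 0
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line:
            continue
        if not line.upper().startswith("LM="):
            raise InvalidArgumentError(f"TPS parse error at line {i}: expected LM=, got {line!r}")
        k = int(line.split("=", 1)[1])
        raw = np.empty((k, 2))
        for j in range(k):
            parts = lines[i].split()
            if len(parts) != 2:
                raise InvalidArgumentError(f"TPS parse error at line {i + 1}: bad coordinate line")
            raw[j] = [float(parts[0]), float(parts[1])]
            i += 1
        ident, image, scale = "", "", 1.0
        while i < len(lines):
            tail = lines[i].strip()
            if not tail:
                i += 1
                continue
            if tail.upper().startswith("LM="):
                break
            key, _, value = tail.partition("=")
            key = key.strip().upper()
            if key == "ID":
                ident = value.strip()
            elif key == "IMAGE":
                image = value.strip()
            elif key == "SCALE":
                scale = float(value)
            i += 1
        if not ident:
            ident = f"specimen_{n_anonymous}"
            n_anonymous += 1
        cfg = LandmarkConfiguration(
            specimen_id=ident, points=raw * scale, scale=scale, image=image
        )
        configs.append(cfg.with_roles(template) if template is not None else cfg)
    return configs


def write_tps(configs: Sequence[LandmarkConfiguration], path) -> None:
    """Write configurations as TPS records (raw coordinates = physical / scale)."""
    configs = list(configs)
    if not configs:
        raise InvalidArgumentError("no configurations to write")
    k = configs[0].k
    if any(c.k != k for c in configs):
        raise InvalidArgumentError("all configurations must have the same landmark count")
    buf = io.StringIO()
    for c in configs:
        raw = c.points / c.scale
        buf.write(f"LM={k}\n")
        for x, y in raw:
            buf.write(f"{x:.17g} {y:.17g}\n")
        buf.write(f"IMAGE={c.image}\n")
        buf.write(f"ID={c.specimen_id}\n")
        buf.write(f"SCALE={c.scale:.17g}\n")
    text = buf.getvalue()
    if hasattr(path, "write"):
        path.write(text)
    else:
        Path(path).write_text(text)
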