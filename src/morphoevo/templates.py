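"""Landmark templates for lateral-view skull outlines.

A :class:`TemplateShape` bundles a reference configuration of 2D landmarks
with the bookkeeping the rest of the package needs: which points are fixed
(anatomically homologous) landmarks, which are semi-landmarks free to slide
along a curve, the curve adjacency of every semi-landmark, and a partition of
the points into named skull regions.  Indices are 1-based everywhere in this
module, matching the convention of morphometric digitising software.

Two built-in templates are provided:

``cranium19``
    13 fixed landmarks + 6 semi-landmarks on the braincase vault of a
    generic mammalian cranium in lateral view.  Regions: ``face``
    (points 1-5, 11-13), ``braincase`` (points 6-10, 14-19) and
    ``cranium`` (all points).

``mandible10``
    4 fixed landmarks + 6 semi-landmarks along the lower mandibular border.
    Single region ``mandible``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence, Tuple

import numpy as np

from .errors import InvalidArgumentError

__all__ = ["TemplateShape", "cranium_template", "mandible_template", "get_template"]


@dataclass(frozen=True)
class TemplateShape:
    """A reference landmark configuration with roles, curves and regions.

    Parameters
    ----------
    points : (k, 2) array
        Template coordinates.
    fixed_idx, semi_idx : sequence of int
        1-based indices of fixed landmarks and sliding semi-landmarks.
        Together they must partition ``1..k``.
    curves : mapping int -> (int, int)
        For each semi-landmark, its two curve neighbours (1-based).  Chains
        of semi-landmarks must ultimately anchor on fixed landmarks.
    region_partition : mapping str -> sequence of int
        Named subsets of ``1..k``; regions may overlap (e.g. ``cranium``
        contains both ``face`` and ``braincase``).
    """

    points: np.ndarray
    fixed_idx: Tuple[int, ...]
    semi_idx: Tuple[int, ...]
    curves: Mapping[int, Tuple[int, int]] = field(default_factory=dict)
    region_partition: Mapping[str, Tuple[int, ...]] = field(default_factory=dict)
    name: str = "custom"

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise InvalidArgumentError("template points must be a (k, 2) array")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "fixed_idx", tuple(int(i) for i in self.fixed_idx))
        object.__setattr__(self, "semi_idx", tuple(int(i) for i in self.semi_idx))
        object.__setattr__(
            self, "curves", {int(k): (int(a), int(b)) for k, (a, b) in dict(self.curves).items()}
        )
        object.__setattr__(
            self,
            "region_partition",
            {str(r): tuple(int(i) for i in idx) for r, idx in dict(self.region_partition).items()},
        )
        k = self.k
        fixed, semi = set(self.fixed_idx), set(self.semi_idx)
        if fixed & semi:
            raise InvalidArgumentError("fixed_idx and semi_idx overlap")
        if fixed | semi != set(range(1, k + 1)):
            raise InvalidArgumentError("fixed_idx and semi_idx must partition 1..k")
        if set(self.curves) != semi:
            raise InvalidArgumentError("every semi-landmark needs exactly one curve entry")
        for s, (a, b) in self.curves.items():
            if len({a, b, s}) != 3 or not (1 <= a <= k and 1 <= b <= k):
                raise InvalidArgumentError(f"invalid curve neighbours for semi-landmark {s}")
        for region, idx in self.region_partition.items():
            if not set(idx) <= set(range(1, k + 1)):
                raise InvalidArgumentError(f"region {region!r} indices outside 1..k")

    @property
    def k(self) -> int:
        return int(self.points.shape[0])

    @property
    def shape_dim(self) -> int:
        """Dimension of the shape (Kendall tangent) space: 2k - 4."""
        return 2 * self.k - 4

    def subset(self, indices: Sequence[int], name: str | None = None) -> "TemplateShape":
        """Restrict the template to a 1-based index subset, re-numbering points.

        Semi-landmarks whose curve neighbours are not all retained cannot
        slide in the subset and raise :class:`InvalidArgumentError`.
        """
        idx = [int(i) for i in indices]
        if len(set(idx)) != len(idx) or not set(idx) <= set(range(1, self.k + 1)):
            raise InvalidArgumentError("subset indices must be unique and within 1..k")
        remap = {old: new for new, old in enumerate(idx, start=1)}
        semi_new = {}
        for s in self.semi_idx:
            if s not in remap:
                continue
            a, b = self.curves[s]
            if a not in remap or b not in remap:
                raise InvalidArgumentError(
                    f"semi-landmark {s} loses a curve neighbour in the subset"
                )
            semi_new[remap[s]] = (remap[a], remap[b])
        fixed_new = tuple(remap[i] for i in self.fixed_idx if i in remap)
        return TemplateShape(
            points=self.points[[i - 1 for i in idx]],
            fixed_idx=fixed_new,
            semi_idx=tuple(sorted(semi_new)),
            curves=semi_new,
            region_partition={name or "all": tuple(range(1, len(idx) + 1))},
            name=name or f"{self.name}-subset",
        )

    def region_template(self, region: str) -> "TemplateShape":
        """Template restricted to one named region (re-numbered 1-based)."""
        if region not in self.region_partition:
            raise InvalidArgumentError(
                f"unknown region {region!r}; have {sorted(self.region_partition)}"
            )
        return self.subset(self.region_partition[region], name=region)

    def with_points(self, points: np.ndarray) -> "TemplateShape":
        return replace(self, points=np.asarray(points, dtype=float))


def cranium_template() -> TemplateShape:
    """Generic mammalian cranium, lateral view: 13 fixed + 6 sliding points.

    The rostrum points in +x; the braincase vault carries the semi-landmark
    curve anchored on fixed landmarks 6 (fronto-parietal suture) and 10
    (occipital condyle).
    """
    pts = np.array(
        [
            [1.00, 0.05],   # 1  anterior tip of premaxilla
            [0.95, 0.15],   # 2  tip of nasal
            [0.70, 0.22],   # 3  naso-frontal suture
            [0.55, 0.12],   # 4  anterior orbit margin
            [0.60, 0.00],   # 5  infraorbital region
            [0.35, 0.28],   # 6  fronto-parietal suture (vault anchor)
            [0.30, 0.15],   # 7  postorbital process
            [0.25, 0.00],   # 8  squamosal root of zygomatic
            [0.45, -0.05],  # 9  posterior palate
            [0.00, 0.00],   # 10 occipital condyle (vault anchor)
            [0.80, 0.18],   # 11 facial contour above posterior palate
            [0.75, -0.02],  # 12 mid palate
            [0.90, -0.03],  # 13 canine alveolus
            [0.28, 0.32],   # 14 vault semi-landmark
            [0.20, 0.35],   # 15 vault semi-landmark
            [0.12, 0.35],   # 16 vault semi-landmark
            [0.05, 0.32],   # 17 vault semi-landmark
            [-0.02, 0.25],  # 18 vault semi-landmark
            [-0.04, 0.12],  # 19 vault semi-landmark
        ]
    )
    curves = {
        14: (6, 15),
        15: (14, 16),
        16: (15, 17),
        17: (16, 18),
        18: (17, 19),
        19: (18, 10),
    }
    return TemplateShape(
        points=pts,
        fixed_idx=tuple(range(1, 14)),
        semi_idx=tuple(range(14, 20)),
        curves=curves,
        region_partition={
            "face": (1, 2, 3, 4, 5, 11, 12, 13),
            "braincase": (6, 7, 8, 9, 10, 14, 15, 16, 17, 18, 19),
            "cranium": tuple(range(1, 20)),
        },
        name="cranium19",
    )


def mandible_template() -> TemplateShape:
    """Generic mammalian hemimandible, lateral view: 4 fixed + 6 sliding points."""
    pts = np.array(
        [
            [1.00, 0.00],   # 1  tip of lower incisor alveolus
            [0.25, 0.30],   # 2  coronoid apex
            [0.10, 0.22],   # 3  condyloid process
            [0.05, -0.05],  # 4  angular process (curve anchor)
            [0.20, -0.12],  # 5  ventral border semi-landmark
            [0.35, -0.15],  # 6  ventral border semi-landmark
            [0.50, -0.15],  # 7  ventral border semi-landmark
            [0.65, -0.12],  # 8  ventral border semi-landmark
            [0.80, -0.08],  # 9  ventral border semi-landmark
            [0.92, -0.04],  # 10 ventral border semi-landmark
        ]
    )
    curves = {
        5: (4, 6),
        6: (5, 7),
        7: (6, 8),
        8: (7, 9),
        9: (8, 10),
        10: (9, 1),
    }
    return TemplateShape(
        points=pts,
        fixed_idx=(1, 2, 3, 4),
        semi_idx=(5, 6, 7, 8, 9, 10),
        curves=curves,
        region_partition={"mandible": tuple(range(1, 11))},
        name="mandible10",
    )


_BUILTIN = {"cranium19": cranium_template, "mandible10": mandible_template}


def get_template(name: str) -> TemplateShape:
    """Look up a built-in template by name (``cranium19`` or ``mandible10``)."""
    try:
        return _BUILTIN[name]()
    except KeyError:
        raise InvalidArgumentError(
            f"unknown template {name!r}; built-ins: {sorted(_BUILTIN)}"
        ) from None
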