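"""Droplet geometry and merge-dilution accounting.

Droplets are modeled as perfect spheres; the volumes quoted in screen
designs (e.g. a 75 μm bacterial droplet holding ~220 pL of LB, merged
into a 110 μm / ~700 pL mammalian-cell droplet) follow directly from the
diameter.  Merging two unequal droplets dilutes each component by the
ratio of total to component volume — for a 220 pL LB droplet fused with
a 700 pL cell droplet the growth medium is diluted more than 4-fold.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

__all__ = [
    "DropletRole",
    "MergeConvention",
    "DropletSpec",
    "sphere_volume",
    "dilution_factor",
    "lb_dilution",
    "round_sig",
]

#: 1 pL = 10^3 μm^3 (1 μm^3 = 1 fL).
PL_PER_UM3 = 1e-3


class DropletRole(str, enum.Enum):
    """What a droplet carries in the screening workflow."""

    BACTERIAL = "bacterial"
    MAMMALIAN = "mammalian"
    MERGED = "merged"


class MergeConvention(str, enum.Enum):
    """How a quoted mammalian-droplet volume relates to the merge.

    ``PRE_MERGE``: the quoted volume is the mammalian droplet before
    fusion (merged volume = bacterial + mammalian).  ``POST_MERGE``: the
    quoted volume already includes the fused bacterial droplet.
    """

    PRE_MERGE = "pre_merge"
    POST_MERGE = "post_merge"


def sphere_volume(diameter_um: float) -> float:
    """Volume in pL of a spherical droplet of ``diameter_um`` μm.

    Computes pi * d^3 / 6 and converts μm^3 to pL.  A 75 μm droplet
    gives 220.9 pL; a 110 μm droplet gives 697 pL.

    Raises
    ------
    ValueError
        If the diameter is negative.
    """
    if diameter_um < 0:
        raise ValueError(f"diameter must be non-negative, got {diameter_um}")
    return math.pi * diameter_um**3 / 6.0 * PL_PER_UM3


def dilution_factor(component_volume_pl: float, added_volume_pl: float) -> float:
    """Fold dilution of a component when ``added_volume_pl`` is mixed in.

    Returns ``(component + added) / component``; 1 means no dilution.

    Raises
    ------
    ValueError
        If the component volume is not positive or the added volume is
        negative.
    """
    if component_volume_pl <= 0:
        raise ValueError(
            f"component volume must be positive, got {component_volume_pl}"
        )
    if added_volume_pl < 0:
        raise ValueError(f"added volume must be non-negative, got {added_volume_pl}")
    return (component_volume_pl + added_volume_pl) / component_volume_pl


def lb_dilution(
    bacterial_pl: float,
    mammalian_pl: float,
    convention: MergeConvention = MergeConvention.PRE_MERGE,
) -> float:
    """Fold dilution of the bacterial growth medium upon droplet merging.

    Under ``PRE_MERGE`` (default) the mammalian volume is added to the
    bacterial droplet: (220, 700) -> 4.18-fold.  Under ``POST_MERGE``
    the mammalian figure is the fused droplet, so the added volume is
    ``mammalian_pl - bacterial_pl``: (220, 700) -> 3.18-fold.
    """
    convention = MergeConvention(convention)
    if convention is MergeConvention.PRE_MERGE:
        added = mammalian_pl
    else:
        added = mammalian_pl - bacterial_pl
        if added < 0:
            raise ValueError(
                "post-merge volume smaller than the bacterial droplet volume"
            )
    return dilution_factor(bacterial_pl, added)


def round_sig(x: float, sig: int = 3) -> float:
    """Round ``x`` to ``sig`` significant figures (report convention)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, sig - 1 - math.floor(math.log10(abs(x))))


@dataclass(frozen=True)
class DropletSpec:
    """A droplet class: diameter (μm), volume (pL) and workflow role.

    The stored volume must agree with the sphere volume implied by the
    diameter to within 0.5%, so specs built from the paper-style rounded
    figures (75 μm / 220 pL, 110 μm / 700 pL) validate.
    """

    diameter_um: float
    volume_pl: float
    role: DropletRole

    def __post_init__(self) -> None:
        if self.diameter_um < 0:
            raise ValueError("diameter must be non-negative")
        object.__setattr__(self, "role", DropletRole(self.role))
        if self.diameter_um > 0:
            if self.volume_pl <= 0:
                raise ValueError("positive diameter requires positive volume")
            nominal = sphere_volume(self.diameter_um)
            if abs(self.volume_pl - nominal) / nominal > 0.005:
                raise ValueError(
                    f"volume {self.volume_pl} pL inconsistent with diameter "
                    f"{self.diameter_um} μm (sphere volume {nominal:.4g} pL)"
                )

    @classmethod
    def from_diameter(cls, diameter_um: float, role: DropletRole) -> "DropletSpec":
        """Build a spec with the exact sphere volume for ``diameter_um``."""
        return cls(diameter_um, sphere_volume(diameter_um), role)
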