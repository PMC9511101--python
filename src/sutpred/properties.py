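"""Physicochemical property partitions for the CTD (188D) descriptors.

Each property splits the 20 canonical amino acids into three disjoint
groups (e.g. polar / neutral / hydrophobic for hydrophobicity). The
eight default partitions are the standard three-state tables of the CTD
descriptor literature; they can be overridden from a YAML file for
non-standard group definitions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml

from .sequence_io import AMINO_ACIDS

_AA_SET = frozenset(AMINO_ACIDS)


@dataclass(frozen=True)
class PropertyGrouping:
    """A named 3-way partition of the 20 amino acids."""

    name: str
    groups: tuple[str, str, str]

    def __post_init__(self) -> None:
        letters = "".join(self.groups)
        if len(letters) != 20 or set(letters) != _AA_SET:
            raise ValueError(
                f"{self.name}: groups must partition the 20 amino acids "
                f"exactly; got {self.groups}"
            )

    def group_of(self, residue: str) -> int:
        """0-based index of the group containing ``residue``."""
        for gi, g in enumerate(self.groups):
            if residue in g:
                return gi
        raise KeyError(residue)


#: The eight standard CTD property partitions, in 188D concatenation order.
DEFAULT_GROUPINGS: tuple[PropertyGrouping, ...] = (
    PropertyGrouping("hydrophobicity", ("RKEDQN", "GASTPHY", "CVLIMFW")),
    PropertyGrouping("normalized_vdw_volume", ("GASTCPD", "NVEQIL", "MHKFRYW")),
    PropertyGrouping("polarity", ("LIFWCMVY", "PATGS", "HQRKNED")),
    PropertyGrouping("polarizability", ("GASDT", "CPNVEQIL", "KMHFRYW")),
    PropertyGrouping("charge", ("KR", "ANCQGHILMFPSTWYV", "DE")),
    PropertyGrouping("secondary_structure", ("EALMQKRH", "VIYCWFT", "GNPSD")),
    PropertyGrouping("solvent_accessibility", ("ALFCGIVW", "RKQEND", "MSPTHY")),
    PropertyGrouping("surface_tension", ("GQDNAHR", "KTSEC", "ILMFPWYV")),
)


def load_groupings(path: str | Path) -> tuple[PropertyGrouping, ...]:
    """Load property partitions from YAML: ``{name: [g1, g2, g3], ...}``.

    Order of entries defines the 188D concatenation order.
    """
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping of name -> 3 groups")
    groupings = []
    for name, groups in data.items():
        if not (isinstance(groups, list) and len(groups) == 3):
            raise ValueError(f"{path}: property {name!r} needs exactly 3 groups")
        groupings.append(PropertyGrouping(str(name), tuple(str(g).upper() for g in groups)))
    return tuple(groupings)
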