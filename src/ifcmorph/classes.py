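"""Morphology class taxonomy and defect-to-class precedence rules.

Bovine sperm morphology is scored into eight biological categories plus two
residual ones kept for dataset hygiene:

=====  =============================  ==========
code   meaning                        biological
=====  =============================  ==========
NM     normal morphology              yes
IHS    irregular head shape           yes
TEH    twisted or elongated head      yes
AM     abnormal midpiece              yes
AT     abnormal tail                  yes
PCD    proximal cytoplasmic droplet   yes
DCD    distal cytoplasmic droplet     yes
CTM    coiled tail and midpiece       yes
MULTI  multiple cells in frame        no
DEBRIS non-cellular debris            no
=====  =============================  ==========

A cell frequently carries several co-existing abnormalities, so a frame is
described first by a :class:`DefectSet` (the pre-precedence ground truth) and
only then collapsed to a single class label by :func:`assign_label` under a
fixed, documented priority order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum


class MorphClass(str, Enum):
    """The 10 assignable categories, in canonical (and model output) order."""

    NM = "NM"
    IHS = "IHS"
    TEH = "TEH"
    AM = "AM"
    AT = "AT"
    PCD = "PCD"
    DCD = "DCD"
    CTM = "CTM"
    MULTI = "MULTI"
    DEBRIS = "DEBRIS"

    @property
    def is_biological(self) -> bool:
        """MULTI and DEBRIS are residual gating categories, not biology."""
        return self not in (MorphClass.MULTI, MorphClass.DEBRIS)


#: canonical ordering used for class vectors, confusion matrices, model heads
CLASS_ORDER: tuple[MorphClass, ...] = tuple(MorphClass)

#: the eight biological classes (profiling denominators exclude MULTI/DEBRIS)
BIOLOGICAL_CLASSES: tuple[MorphClass, ...] = tuple(
    c for c in MorphClass if c.is_biological
)

#: atomic defect tags a single cell may carry, any combination
DEFECT_TAGS: tuple[str, ...] = (
    "irregular_head",
    "twisted_elongated_head",
    "abnormal_midpiece",
    "abnormal_tail",
    "coiled_tail_midpiece",
    "proximal_droplet",
    "distal_droplet",
)


@dataclass(frozen=True)
class DefectSet:
    """Pre-precedence ground truth for one frame.

    ``defects`` holds atomic abnormality tags from :data:`DEFECT_TAGS`;
    ``multiplet`` / ``debris`` flag the residual frame-level categories.
    An empty defect set with both flags false denotes a normal cell.
    """

    defects: frozenset[str] = field(default_factory=frozenset)
    multiplet: bool = False
    debris: bool = False

    def __post_init__(self) -> None:
        bad = set(self.defects) - set(DEFECT_TAGS)
        if bad:
            raise ValueError(f"unknown defect tags: {sorted(bad)}")
        object.__setattr__(self, "defects", frozenset(self.defects))

    @property
    def is_normal(self) -> bool:
        return not self.defects and not self.multiplet and not self.debris


# Total label priority. The scoring protocol states two precedence rules:
# coiling of the tail/midpiece supersedes a plain abnormal tail (CTM > AT),
# and a twisted/elongated head supersedes other head irregularities
# (TEH > IHS). All remaining conflicts are resolved by this fixed order so
# labelling is deterministic and auditable; residual flags dominate defects.
_DEFECT_PRIORITY: tuple[tuple[str, MorphClass], ...] = (
    ("coiled_tail_midpiece", MorphClass.CTM),
    ("abnormal_tail", MorphClass.AT),
    ("twisted_elongated_head", MorphClass.TEH),
    ("irregular_head", MorphClass.IHS),
    ("abnormal_midpiece", MorphClass.AM),
    ("proximal_droplet", MorphClass.PCD),
    ("distal_droplet", MorphClass.DCD),
)

#: defect tag -> class it maps to when it is the highest-priority tag present
DEFECT_TO_CLASS: dict[str, MorphClass] = dict(_DEFECT_PRIORITY)


def assign_label(d: DefectSet) -> MorphClass:
    """Collapse a :class:`DefectSet` to a single class label.

    Debris and multiplet flags dominate everything; among atomic defects the
    highest-priority tag present wins (CTM > AT > TEH > IHS > AM > PCD > DCD);
    an empty set is normal.
    """
    if d.debris:
        return MorphClass.DEBRIS
    if d.multiplet:
        return MorphClass.MULTI
    for tag, cls in _DEFECT_PRIORITY:
        if tag in d.defects:
            return cls
    return MorphClass.NM


def defects_for_class(cls: MorphClass) -> DefectSet:
    """Minimal DefectSet whose label is ``cls`` (inverse of assign_label)."""
    if cls is MorphClass.DEBRIS:
        return DefectSet(debris=True)
    if cls is MorphClass.MULTI:
        return DefectSet(multiplet=True)
    if cls is MorphClass.NM:
        return DefectSet()
    for tag, c in _DEFECT_PRIORITY:
        if c is cls:
            return DefectSet(defects=frozenset({tag}))
    raise ValueError(f"unknown class: {cls!r}")
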