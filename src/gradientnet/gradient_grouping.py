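"""Gradient classification and the four response-by-gradient gene groups.

Each gene's expression trend from FUN to CSC (up, down, or flat) is
crossed with its hormone-response direction (member of the auxin-up or
auxin-down regulon) to place it in one of four groups. The six auxin
co-receptor (AFB/TIR1) loci are partitioned the same way into a
down-gradient group and an up-gradient group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

from gradientnet.errors import ValidationError
from gradientnet.expression_io import ExpressionProfile, RegulonTable

__all__ = [
    "GradientGroup",
    "AfbGroupAssignment",
    "ExcludedGene",
    "AFB_LOCI",
    "CANONICAL_AFB1_GROUP",
    "CANONICAL_AFB5_GROUP",
    "classify_gradient",
    "assign_groups",
    "assign_afb_groups",
    "GROUP_SEMANTICS",
]

#: TAIR locus identifiers of the six auxin co-receptor F-box genes.
AFB_LOCI: dict[str, str] = {
    "TIR1": "At3g62980",
    "AFB1": "At4g03190",
    "AFB2": "At3g26810",
    "AFB3": "At1g12820",
    "AFB4": "At4g24390",
    "AFB5": "At5g49980",
}

CANONICAL_AFB1_GROUP = frozenset({"TIR1", "AFB1", "AFB4"})
CANONICAL_AFB5_GROUP = frozenset({"AFB2", "AFB3", "AFB5"})

#: group id -> (auxin response, FUN->CSC gradient). G1 and G4 are fixed by
#: the published group titles; G2/G3 semantics are a documented convention.
GROUP_SEMANTICS: dict[str, tuple[str, str]] = {
    "G1": ("down", "up"),
    "G2": ("down", "down"),
    "G3": ("up", "down"),
    "G4": ("up", "up"),
}


@dataclass(frozen=True)
class GradientGroup:
    group_id: str
    auxin_response: str
    gradient: str
    genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.group_id not in GROUP_SEMANTICS:
            raise ValidationError(f"unknown group id {self.group_id!r}")
        if tuple(self.genes) != tuple(sorted(self.genes)):
            object.__setattr__(self, "genes", tuple(sorted(self.genes)))

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class ExcludedGene:
    gene_id: str
    reason: str


@dataclass(frozen=True)
class AfbGroupAssignment:
    """Partition of the six AFB loci by FUN->CSC gradient direction."""

    afb1_group: frozenset[str]
    afb5_group: frozenset[str]
    derived_from_data: bool

    def __post_init__(self) -> None:
        union = self.afb1_group | self.afb5_group
        if union != frozenset(AFB_LOCI) or (self.afb1_group & self.afb5_group):
            raise ValidationError(
                "afb1_group and afb5_group must partition the six AFB loci"
            )


def classify_gradient(
    profile: ExpressionProfile, tie_epsilon: float = 0.0
) -> str:
    """Classify the FUN->CSC trend as ``"down"``, ``"up"`` or ``"flat"``.

    The comparison is relative: a difference smaller than
    ``tie_epsilon * max(fun, csc)`` counts as flat. DSC is not consulted.
    """
    margin = tie_epsilon * max(profile.fun, profile.csc)
    if profile.fun - profile.csc > margin:
        return "down"
    if profile.csc - profile.fun > margin:
        return "up"
    return "flat"


def assign_groups(
    profiles: Sequence[ExpressionProfile],
    auxin_up: RegulonTable,
    auxin_down: RegulonTable,
    tie_epsilon: float = 0.0,
    group_semantics: Mapping[str, tuple[str, str]] = GROUP_SEMANTICS,
) -> tuple[list[GradientGroup], list[ExcludedGene]]:
    """Place each auxin-regulated gene in one of the four gradient groups.

    Profiles must already be normalized and low-signal filtered. Genes in
    neither regulon, in both regulons, or with a flat gradient are
    excluded with a reason. Output membership lists are sorted; the
    assignment is independent of input row order.
    """
    by_semantics = {sem: gid for gid, sem in group_semantics.items()}
    members: dict[str, list[str]] = {gid: [] for gid in group_semantics}
    excluded: list[ExcludedGene] = []

    for profile in sorted(profiles, key=lambda p: p.gene_id):
        in_up = profile.gene_id in auxin_up
        in_down = profile.gene_id in auxin_down
        if in_up and in_down:
            excluded.append(ExcludedGene(profile.gene_id, "conflicting regulon"))
            continue
        if not in_up and not in_down:
            excluded.append(ExcludedGene(profile.gene_id, "not auxin-regulated"))
            continue
        gradient = classify_gradient(profile, tie_epsilon)
        if gradient == "flat":
            excluded.append(ExcludedGene(profile.gene_id, "flat gradient"))
            continue
        response = "up" if in_up else "down"
        members[by_semantics[(response, gradient)]].append(profile.gene_id)

    groups = [
        GradientGroup(
            group_id=gid,
            auxin_response=group_semantics[gid][0],
            gradient=group_semantics[gid][1],
            genes=tuple(sorted(members[gid])),
        )
        for gid in sorted(group_semantics)
    ]
    return groups, excluded


def assign_afb_groups(
    afb_profiles: Mapping[str, ExpressionProfile],
    tie_epsilon: float = 0.0,
) -> AfbGroupAssignment:
    """Partition the six AFB loci by their FUN->CSC gradients.

    Down-gradient loci join the AFB1 group, up-gradient loci the AFB5
    group. If any locus is flat the canonical published partition is used
    instead, flagged with ``derived_from_data=False`` and a warning.
    """
    missing = sorted(set(AFB_LOCI) - set(afb_profiles))
    if missing:
        raise ValidationError("missing locus " + ", ".join(missing))

    gradients = {
        name: classify_gradient(afb_profiles[name], tie_epsilon) for name in AFB_LOCI
    }
    flat = sorted(name for name, g in gradients.items() if g == "flat")
    if flat:
        warnings.warn(
            "flat FUN->CSC gradient for "
            + ", ".join(flat)
            + "; falling back to the canonical AFB partition",
            stacklevel=2,
        )
        return AfbGroupAssignment(
            afb1_group=CANONICAL_AFB1_GROUP,
            afb5_group=CANONICAL_AFB5_GROUP,
            derived_from_data=False,
        )
    return AfbGroupAssignment(
        afb1_group=frozenset(n for n, g in gradients.items() if g == "down"),
        afb5_group=frozenset(n for n, g in gradients.items() if g == "up"),
        derived_from_data=True,
    )
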