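"""Three-point pairwise R² and the co-expression subgroup partition.

Within each gradient group, genes are agglomerated into subgroups in
which every pair of members has squared Pearson correlation (over the
ordered FUN, CSC, normalized-DSC triple) at or above a threshold,
0.90 by default. The published assignment was manual; the deterministic
greedy complete-linkage rule implemented here is a reconstruction of it:
seed each subgroup with the lexicographically smallest unassigned gene,
repeatedly admit the unassigned gene with the highest minimum R² to the
current members (ties broken by gene ID) while that minimum clears the
threshold, then close the subgroup and repeat.

No p-values are attached to these correlations: three data points are
too few for a meaningful test, so the threshold on R² itself is the
criterion.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from gradientnet.errors import ConfigError, ValidationError
from gradientnet.expression_io import ExpressionProfile
from gradientnet.gradient_grouping import GradientGroup

__all__ = [
    "Profile3",
    "Subgroup",
    "DegenerateProfileError",
    "pairwise_r2",
    "pearson_r3",
    "cluster_subgroups",
    "loo_sum_profile",
    "loo_group_sum_r2",
    "between_subgroup_r2",
    "profiles_to_3point",
    "split_degenerate",
]


class DegenerateProfileError(ValidationError):
    """A zero-variance triple: Pearson correlation is undefined."""


@dataclass(frozen=True)
class Profile3:
    """A gene's ordered (fun, csc, dsc_norm) triple."""

    gene_id: str
    values: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.values) != 3:
            raise ValidationError(f"{self.gene_id}: expected exactly 3 values")
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))

    @property
    def is_degenerate(self) -> bool:
        return self.values[0] == self.values[1] == self.values[2]


@dataclass(frozen=True)
class Subgroup:
    """A set of genes satisfying the all-pairs R² constraint."""

    subgroup_id: str
    parent_group: str
    members: tuple[str, ...]
    min_pairwise_r2: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", tuple(sorted(self.members)))

    def __len__(self) -> int:
        return len(self.members)


def pearson_r3(a: Profile3, b: Profile3) -> float:
    """Pearson correlation of two ordered triples.

    Raises :class:`DegenerateProfileError` if either triple has zero
    variance (correlation undefined, deliberately not coerced to 0).
    """
    xs, ys = a.values, b.values
    mx = sum(xs) / 3.0
    my = sum(ys) / 3.0
    sxx = sum((x - mx) ** 2 for x in xs)
    syy = sum((y - my) ** 2 for y in ys)
    if sxx == 0.0 or syy == 0.0:
        offender = a.gene_id if sxx == 0.0 else b.gene_id
        raise DegenerateProfileError(
            f"degenerate profile {offender}: zero variance across tissues"
        )
    sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    # sqrt factored to avoid underflow of the product for tiny variances
    r = sxy / (math.sqrt(sxx) * math.sqrt(syy))
    return max(-1.0, min(1.0, r))


def pairwise_r2(a: Profile3, b: Profile3) -> float:
    """Squared Pearson correlation of two 3-point profiles, in [0, 1]."""
    r = pearson_r3(a, b)
    return r * r


def profiles_to_3point(
    profiles: Iterable[ExpressionProfile],
) -> dict[str, Profile3]:
    """Build the (fun, csc, dsc_norm) triples used for all correlations."""
    out: dict[str, Profile3] = {}
    for p in profiles:
        if p.dsc_norm is None:
            raise ValidationError(
                f"{p.gene_id}: dsc_norm unset; run normalize_dsc first"
            )
        out[p.gene_id] = Profile3(p.gene_id, (p.fun, p.csc, p.dsc_norm))
    return out


def split_degenerate(
    genes: Iterable[str], profiles: Mapping[str, Profile3]
) -> tuple[list[str], list[str]]:
    """Split gene IDs into (usable, degenerate) by triple variance."""
    usable: list[str] = []
    degenerate: list[str] = []
    for g in sorted(genes):
        (degenerate if profiles[g].is_degenerate else usable).append(g)
    return usable, degenerate


def _subgroup_letters(index: int) -> str:
    # A..Z, then AA, AB, ... for pathological sizes
    letters = ""
    index += 1
    while index > 0:
        index, rem = divmod(index - 1, 26)
        letters = chr(ord("A") + rem) + letters
    return letters


def cluster_subgroups(
    group: GradientGroup,
    profiles: Mapping[str, Profile3],
    r2_min: float = 0.90,
    linkage: str = "complete",
    sign_constraint: str = "any",
) -> list[Subgroup]:
    """Partition a gradient group into subgroups under the R² threshold.

    Parameters
    ----------
    group
        The gradient group whose members are partitioned.
    profiles
        Gene ID -> :class:`Profile3`; must cover every member.
    r2_min
        Admission threshold on R², in [0, 1].
    linkage
        ``"complete"`` (default) requires R² >= ``r2_min`` against every
        current member; ``"single"`` requires it only against the seed
        (reference) gene of the subgroup.
    sign_constraint
        ``"any"`` accepts anti-correlated pairs (R² ignores slope sign);
        ``"positive_slope_only"`` additionally requires positive Pearson r.

    Degenerate (zero-variance) members are excluded with a warning and do
    not appear in any subgroup. Subgroup IDs are the parent group ID plus
    a letter assigned by decreasing size, ties broken by smallest member.
    """
    if not (0.0 <= r2_min <= 1.0):
        raise ConfigError(f"r2_min must be in [0, 1], got {r2_min}")
    if linkage not in ("complete", "single"):
        raise ConfigError(f"unknown linkage {linkage!r}")
    if sign_constraint not in ("any", "positive_slope_only"):
        raise ConfigError(f"unknown sign_constraint {sign_constraint!r}")

    missing = sorted(set(group.genes) - set(profiles))
    if missing:
        raise ValidationError(
            f"{group.group_id}: no profile for " + ", ".join(missing)
        )
    usable, degenerate = split_degenerate(group.genes, profiles)
    if degenerate:
        warnings.warn(
            f"{group.group_id}: excluding degenerate profile(s) "
            + ", ".join(degenerate),
            stacklevel=2,
        )

    def link(candidate: str, members: Sequence[str]) -> float:
        """Admission score: worst-case R² against the linkage targets."""
        targets = members if linkage == "complete" else members[:1]
        score = 1.0
        for m in targets:
            r = pearson_r3(profiles[candidate], profiles[m])
            if sign_constraint == "positive_slope_only" and r <= 0.0:
                return -1.0
            score = min(score, r * r)
        return score

    unassigned = list(usable)  # kept sorted
    raw_subgroups: list[list[str]] = []
    while unassigned:
        seed = unassigned.pop(0)
        members = [seed]
        while unassigned:
            scores = [(link(g, members), g) for g in unassigned]
            best_score = max(s for s, _ in scores)
            if best_score < r2_min:
                break
            best_gene = min(g for s, g in scores if s == best_score)
            members.append(best_gene)
            unassigned.remove(best_gene)
        raw_subgroups.append(sorted(members))

    # Label by decreasing size, ties by smallest member ID.
    raw_subgroups.sort(key=lambda ms: (-len(ms), ms[0]))
    subgroups: list[Subgroup] = []
    for i, ms in enumerate(raw_subgroups):
        if len(ms) > 1:
            min_r2 = min(
                pairwise_r2(profiles[x], profiles[y])
                for j, x in enumerate(ms)
                for y in ms[j + 1 :]
            )
        else:
            min_r2 = 1.0
        subgroups.append(
            Subgroup(
                subgroup_id=f"{group.group_id}{_subgroup_letters(i)}",
                parent_group=group.group_id,
                members=tuple(ms),
                min_pairwise_r2=min_r2,
            )
        )
    return subgroups


def loo_sum_profile(
    subgroup: Subgroup,
    profiles: Mapping[str, Profile3],
    excluded_gene: str,
) -> Profile3:
    """Elementwise sum of all member triples except the excluded gene's."""
    if excluded_gene not in subgroup.members:
        raise ValidationError(
            f"{excluded_gene} is not a member of {subgroup.subgroup_id}"
        )
    if len(subgroup.members) < 2:
        raise ValidationError(
            f"{subgroup.subgroup_id}: leave-one-out undefined for a singleton"
        )
    totals = [0.0, 0.0, 0.0]
    for g in subgroup.members:
        if g == excluded_gene:
            continue
        for t in range(3):
            totals[t] += profiles[g].values[t]
    return Profile3(
        f"{subgroup.subgroup_id}-sum-minus-{excluded_gene}", tuple(totals)
    )


def loo_group_sum_r2(
    subgroup: Subgroup,
    profiles: Mapping[str, Profile3],
    excluded_gene: str,
) -> float:
    """R² between the leave-one-out member sum and the excluded member.

    This is the within-subgroup coherence check: if the subgroup is a set
    of (noisy) scalar multiples of one base profile, the sum of the other
    members stays proportional to any single member.
    """
    return pairwise_r2(
        loo_sum_profile(subgroup, profiles, excluded_gene),
        profiles[excluded_gene],
    )


def between_subgroup_r2(
    a: Subgroup,
    b: Subgroup,
    profiles: Mapping[str, Profile3],
    excluded_a: str,
    excluded_b: str,
) -> float:
    """R² between two subgroups' leave-one-out sum profiles."""
    return pairwise_r2(
        loo_sum_profile(a, profiles, excluded_a),
        loo_sum_profile(b, profiles, excluded_b),
    )
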