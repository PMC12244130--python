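"""Germination-frequency scoring and the paired mutant-vs-control test.

Each mutant dish is paired with one wild-type control dish grown in the
same chamber cluster; germination frequencies fluctuate between runs, so
only the paired two-tailed t-test on per-pair differences is meaningful.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

from scipy import stats

from gradientnet.errors import ValidationError
from gradientnet.expression_io import GerminationAssay

__all__ = [
    "PairedResult",
    "germination_frequency",
    "paired_t_test",
    "pair_assays",
    "analyze_assays",
]


@dataclass(frozen=True)
class PairedResult:
    genotype: str
    n_pairs: int
    mean_mut: float
    mean_wt: float
    t_stat: float
    p_value: float
    direction: str
    degenerate: bool = False
    bonferroni_p: float | None = None


def germination_frequency(assay: GerminationAssay) -> float:
    """Germinated / total for one dish (totals are validated positive)."""
    return assay.germinated / assay.total


def paired_t_test(
    mut_freqs: Sequence[float],
    wt_freqs: Sequence[float],
    genotype: str = "",
) -> PairedResult:
    """Classical paired two-tailed t-test on index-paired frequencies.

    t = mean(d) / (sd(d) / sqrt(n)) with the sample (n-1) standard
    deviation of the per-pair differences d. Degenerate cases: all
    differences zero -> t = 0, p = 1; zero variance with nonzero mean ->
    t = +/-inf, p = 0, flagged ``degenerate``.
    """
    if len(mut_freqs) != len(wt_freqs):
        raise ValidationError(
            f"length mismatch: {len(mut_freqs)} mutant vs {len(wt_freqs)} "
            "control frequencies"
        )
    n = len(mut_freqs)
    if n < 2:
        raise ValidationError("paired t-test needs at least 2 pairs")

    diffs = [m - w for m, w in zip(mut_freqs, wt_freqs)]
    mean_d = sum(diffs) / n
    var_d = sum((d - mean_d) ** 2 for d in diffs) / (n - 1)
    mean_mut = sum(mut_freqs) / n
    mean_wt = sum(wt_freqs) / n
    direction = "higher" if mean_mut >= mean_wt else "lower"

    if var_d == 0.0:
        if mean_d == 0.0:
            t_stat, p_value, degenerate = 0.0, 1.0, False
        else:
            t_stat = math.inf if mean_d > 0 else -math.inf
            p_value, degenerate = 0.0, True
    else:
        t_stat = mean_d / math.sqrt(var_d / n)
        p_value = 2.0 * stats.t.sf(abs(t_stat), df=n - 1)
        degenerate = False

    return PairedResult(
        genotype=genotype,
        n_pairs=n,
        mean_mut=mean_mut,
        mean_wt=mean_wt,
        t_stat=t_stat,
        p_value=p_value,
        direction=direction,
        degenerate=degenerate,
    )


def pair_assays(
    assays: Sequence[GerminationAssay],
) -> dict[str, tuple[list[float], list[float]]]:
    """Group assays by genotype into (mutant, control) frequency lists.

    Pairing is explicit via ``paired_control_dish``; dishes without a
    pairing are treated as controls and matched when referenced. If no
    dish declares a pairing, index-order pairing against the dishes of a
    genotype named ``Col-0`` (or ``WT``) is used with a warning.
    """
    by_dish = {a.dish_id: a for a in assays}
    explicit = [a for a in assays if a.paired_control_dish]
    pairs: dict[str, tuple[list[float], list[float]]] = {}

    if explicit:
        for assay in explicit:
            control = by_dish.get(assay.paired_control_dish)
            if control is None:
                raise ValidationError(
                    f"dish {assay.dish_id}: paired control "
                    f"{assay.paired_control_dish!r} not found"
                )
            mut, wt = pairs.setdefault(assay.genotype, ([], []))
            mut.append(germination_frequency(assay))
            wt.append(germination_frequency(control))
        return pairs

    warnings.warn(
        "no explicit dish pairing found; falling back to index-order "
        "pairing against the wild-type dishes",
        stacklevel=2,
    )
    wt_names = {"Col-0", "WT", "wild-type"}
    controls = [a for a in assays if a.genotype in wt_names]
    if not controls:
        raise ValidationError("no control dishes (Col-0/WT) for fallback pairing")
    for assay in assays:
        if assay.genotype in wt_names:
            continue
        mut, wt = pairs.setdefault(assay.genotype, ([], []))
        if len(mut) >= len(controls):
            raise ValidationError(
                f"genotype {assay.genotype}: more mutant dishes than controls"
            )
        mut.append(germination_frequency(assay))
        wt.append(germination_frequency(controls[len(wt)]))
    return pairs


def analyze_assays(
    assays: Sequence[GerminationAssay],
    bonferroni: bool = False,
) -> list[PairedResult]:
    """Run the paired test per genotype; optional Bonferroni adjustment.

    No multiple-testing correction is applied by default; when enabled,
    ``bonferroni_p = min(1, p * n_genotypes)`` is attached alongside the
    raw p-value.
    """
    pairs = pair_assays(assays)
    results = [
        paired_t_test(mut, wt, genotype=genotype)
        for genotype, (mut, wt) in sorted(pairs.items())
    ]
    if bonferroni and results:
        k = len(results)
        results = [
            PairedResult(
                genotype=r.genotype,
                n_pairs=r.n_pairs,
                mean_mut=r.mean_mut,
                mean_wt=r.mean_wt,
                t_stat=r.t_stat,
                p_value=r.p_value,
                direction=r.direction,
                degenerate=r.degenerate,
                bonferroni_p=min(1.0, r.p_value * k),
            )
            for r in results
        ]
    return results
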