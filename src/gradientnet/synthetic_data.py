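"""Synthetic datasets with planted structure for end-to-end testing.

Genes inside a planted subgroup are scalar multiples of a shared 3-point
base profile with multiplicative log-normal noise, so within-subgroup
pairwise R² is 1 at zero noise and degrades smoothly with the noise CV.
The DSC column is emitted as a raw signal (area ratio times the intended
normalized value) so the pipeline's normalization step is exercised
rather than bypassed. All randomness flows from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from gradientnet.errors import ConfigError
from gradientnet.expression_io import (
    ExpressionProfile,
    GerminationAssay,
    RegulonTable,
    write_expression_table,
)
from gradientnet.normalization import DEFAULT_AREA_RATIO

__all__ = [
    "SimulationConfig",
    "GroundTruthEntry",
    "GroundTruth",
    "SimulatedDataset",
    "simulate_dataset",
    "write_dataset",
    "simulate_germination",
    "write_germination_table",
]


@dataclass(frozen=True)
class SimulationConfig:
    n_subgroups: int = 2
    genes_per_subgroup: int = 5
    base_profiles: Sequence[tuple[float, float, float]] | str = "random"
    max_base_r2: float = 0.5
    scale_range: tuple[float, float] = (0.5, 2.0)
    noise_cv: float = 0.0
    frac_auxin_up: float = 0.5
    frac_auxin_down: float = 0.5
    background_genes: int = 0
    low_signal_frac: float = 0.0
    area_ratio: float = DEFAULT_AREA_RATIO
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subgroups < 1 or self.genes_per_subgroup < 1:
            raise ConfigError("n_subgroups and genes_per_subgroup must be >= 1")
        if self.background_genes < 0:
            raise ConfigError("background_genes must be non-negative")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be non-negative")
        if not (0 <= self.frac_auxin_up <= 1 and 0 <= self.frac_auxin_down <= 1):
            raise ConfigError("regulon fractions must lie in [0, 1]")
        if self.frac_auxin_up + self.frac_auxin_down > 1 + 1e-12:
            raise ConfigError("frac_auxin_up + frac_auxin_down must be <= 1")
        if not (0 <= self.low_signal_frac <= 1):
            raise ConfigError("low_signal_frac must lie in [0, 1]")
        lo, hi = self.scale_range
        if not (0 < lo <= hi):
            raise ConfigError("scale_range must be a positive interval")
        if self.area_ratio <= 0:
            raise ConfigError("area_ratio must be positive")
        if not (0 <= self.max_base_r2 <= 1):
            raise ConfigError("max_base_r2 must lie in [0, 1]")


@dataclass(frozen=True)
class GroundTruthEntry:
    subgroup: str  # "S1", "S2", ... or "background"
    gradient: str  # planted FUN->CSC direction, "flat" for background
    regulon: str  # "auxin-up", "auxin-down", or "none"
    low_signal: bool


@dataclass(frozen=True)
class GroundTruth:
    entries: dict[str, GroundTruthEntry]

    def subgroup_of(self, gene_id: str) -> str:
        return self.entries[gene_id].subgroup

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class SimulatedDataset:
    profiles: list[ExpressionProfile]
    auxin_up: RegulonTable
    auxin_down: RegulonTable
    truth: GroundTruth
    config: SimulationConfig


def _pair_r2(a: np.ndarray, b: np.ndarray) -> float:
    da = a - a.mean()
    db = b - b.mean()
    denom = float(np.sqrt((da @ da) * (db @ db)))
    if denom == 0.0:
        return 1.0  # treat degenerate candidates as maximally collinear
    return float((da @ db) / denom) ** 2


def _draw_base_profiles(config: SimulationConfig, rng: np.random.Generator) -> list[np.ndarray]:
    if config.base_profiles != "random":
        bases = [np.asarray(b, dtype=float) for b in config.base_profiles]
        if len(bases) != config.n_subgroups:
            raise ConfigError(
                f"need {config.n_subgroups} base profiles, got {len(bases)}"
            )
        for b in bases:
            if b.shape != (3,) or np.any(b < 0):
                raise ConfigError("base profiles must be non-negative 3-vectors")
        return bases

    bases: list[np.ndarray] = []
    attempts = 0
    while len(bases) < config.n_subgroups:
        attempts += 1
        if attempts > 20000:
            raise ConfigError(
                "could not draw base profiles satisfying the max_base_r2 "
                f"bound {config.max_base_r2}; relax the bound"
            )
        # FUN/CSC well above the low-signal floor; clear (non-flat) gradient.
        cand = np.array(
            [rng.uniform(30, 500), rng.uniform(30, 500), rng.uniform(1, 300)]
        )
        if abs(cand[0] - cand[1]) <= 0.1 * max(cand[0], cand[1]):
            continue
        if any(_pair_r2(cand, b) > config.max_base_r2 for b in bases):
            continue
        bases.append(cand)
    return bases


def _gene_id(index: int) -> str:
    return f"At{(index % 5) + 1}g{10000 + index:05d}"


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate an expression table, auxin regulons and ground truth.

    Gene ``j`` of subgroup ``s`` gets signal ``c_j * base_s[t] * exp(eps)``
    per tissue, ``eps ~ Normal(0, sigma)`` with
    ``sigma = sqrt(log(1 + cv^2))``; the DSC column is multiplied by the
    area ratio. Background genes draw their three signals independently.
    A ``low_signal_frac`` fraction of genes is rescaled (proportionally,
    preserving profile shape) to sit below the raw-signal floor in both
    FUN and CSC.
    """
    rng = np.random.default_rng(config.seed)
    bases = _draw_base_profiles(config, rng)
    sigma = float(np.sqrt(np.log1p(config.noise_cv**2)))

    # Per-subgroup auxin-response direction, drawn once per subgroup so a
    # whole subgroup lands in one gradient group.
    p_none = max(0.0, 1.0 - config.frac_auxin_up - config.frac_auxin_down)
    directions = rng.choice(
        ["auxin-up", "auxin-down", "none"],
        size=config.n_subgroups,
        p=[config.frac_auxin_up, config.frac_auxin_down, p_none],
    )

    profiles: list[ExpressionProfile] = []
    entries: dict[str, GroundTruthEntry] = {}
    up_genes: set[str] = set()
    down_genes: set[str] = set()
    index = 0

    for s, base in enumerate(bases):
        gradient = "down" if base[0] > base[1] else "up"
        for _ in range(config.genes_per_subgroup):
            gene = _gene_id(index)
            index += 1
            c = rng.uniform(*config.scale_range)
            noise = np.exp(rng.normal(0.0, sigma, size=3)) if sigma > 0 else np.ones(3)
            signal = c * base * noise
            low = bool(rng.random() < config.low_signal_frac)
            if low:
                signal = signal * (rng.uniform(0.5, 9.5) / max(signal[0], signal[1]))
            profiles.append(
                ExpressionProfile(
                    gene_id=gene,
                    fun=float(signal[0]),
                    csc=float(signal[1]),
                    dsc_raw=float(config.area_ratio * signal[2]),
                )
            )
            direction = str(directions[s])
            if direction == "auxin-up":
                up_genes.add(gene)
            elif direction == "auxin-down":
                down_genes.add(gene)
            entries[gene] = GroundTruthEntry(
                subgroup=f"S{s + 1}", gradient=gradient, regulon=direction, low_signal=low
            )

    for _ in range(config.background_genes):
        gene = _gene_id(index)
        index += 1
        signal = rng.uniform(10, 500, size=3)
        low = bool(rng.random() < config.low_signal_frac)
        if low:
            signal = signal * (rng.uniform(0.5, 9.5) / max(signal[0], signal[1]))
        u = rng.random()
        if u < config.frac_auxin_up:
            direction = "auxin-up"
            up_genes.add(gene)
        elif u < config.frac_auxin_up + config.frac_auxin_down:
            direction = "auxin-down"
            down_genes.add(gene)
        else:
            direction = "none"
        profiles.append(
            ExpressionProfile(
                gene_id=gene,
                fun=float(signal[0]),
                csc=float(signal[1]),
                dsc_raw=float(config.area_ratio * signal[2]),
            )
        )
        entries[gene] = GroundTruthEntry(
            subgroup="background", gradient="flat", regulon=direction, low_signal=low
        )

    return SimulatedDataset(
        profiles=profiles,
        auxin_up=RegulonTable("auxin", "up", frozenset(up_genes)),
        auxin_down=RegulonTable("auxin", "down", frozenset(down_genes)),
        truth=GroundTruth(entries),
        config=config,
    )


def write_dataset(dataset: SimulatedDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write expression.tsv, regulon lists and ground_truth.tsv.

    Output is deterministic: identical config (seed included) yields
    byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out_dir / "expression.tsv",
        "auxin_up": out_dir / "auxin_up.txt",
        "auxin_down": out_dir / "auxin_down.txt",
        "ground_truth": out_dir / "ground_truth.tsv",
    }
    write_expression_table(dataset.profiles, paths["expression"])
    paths["auxin_up"].write_text(
        "".join(g + "\n" for g in sorted(dataset.auxin_up.genes))
    )
    paths["auxin_down"].write_text(
        "".join(g + "\n" for g in sorted(dataset.auxin_down.genes))
    )
    lines = ["gene_id\tsubgroup\tgradient\tregulon\tlow_signal"]
    for gene in sorted(dataset.truth.entries):
        e = dataset.truth.entries[gene]
        lines.append(
            f"{gene}\t{e.subgroup}\t{e.gradient}\t{e.regulon}\t{int(e.low_signal)}"
        )
    paths["ground_truth"].write_text("\n".join(lines) + "\n")
    return paths


def _beta_params(mean: float, sd: float) -> tuple[float, float]:
    nu = mean * (1.0 - mean) / (sd * sd) - 1.0
    if nu <= 0:
        raise ConfigError(
            f"dispersion {sd} too large for mean {mean} (needs sd^2 < m(1-m))"
        )
    return mean * nu, (1.0 - mean) * nu


def simulate_germination(
    n_pairs: int,
    wt_mean: float,
    effect: float,
    dispersion: float,
    total_per_dish: int,
    seed: int,
    genotype: str = "mutant",
) -> list[GerminationAssay]:
    """Simulate paired mutant/control dishes with clustered dish means.

    Each pair shares a beta-perturbed baseline germination probability
    (mean ``wt_mean``, sd ``dispersion``); the mutant dish probability is
    the baseline shifted by ``effect``. Counts are binomial.
    """
    if n_pairs < 2:
        raise ConfigError("n_pairs must be >= 2")
    if total_per_dish < 1:
        raise ConfigError("total_per_dish must be >= 1")
    if not (0.0 <= wt_mean <= 1.0 and 0.0 <= wt_mean + effect <= 1.0):
        raise ConfigError("wt_mean and wt_mean + effect must lie in [0, 1]")
    if dispersion < 0:
        raise ConfigError("dispersion must be non-negative")

    rng = np.random.default_rng(seed)
    assays: list[GerminationAssay] = []
    for i in range(1, n_pairs + 1):
        if dispersion == 0.0 or wt_mean in (0.0, 1.0):
            baseline = wt_mean
        else:
            a, b = _beta_params(wt_mean, dispersion)
            baseline = float(rng.beta(a, b))
        p_mut = min(1.0, max(0.0, baseline + effect))
        wt_dish = f"wt-{i:02d}"
        mut_dish = f"{genotype}-{i:02d}"
        assays.append(
            GerminationAssay(
                genotype="Col-0",
                dish_id=wt_dish,
                germinated=int(rng.binomial(total_per_dish, baseline)),
                total=total_per_dish,
            )
        )
        assays.append(
            GerminationAssay(
                genotype=genotype,
                dish_id=mut_dish,
                germinated=int(rng.binomial(total_per_dish, p_mut)),
                total=total_per_dish,
                paired_control_dish=wt_dish,
            )
        )
    return assays


def write_germination_table(
    assays: Sequence[GerminationAssay], path: str | Path
) -> Path:
    path = Path(path)
    lines = ["genotype\tdish_id\tgerminated\ttotal\tpaired_control_dish"]
    for a in assays:
        lines.append(
            f"{a.genotype}\t{a.dish_id}\t{a.germinated}\t{a.total}\t"
            f"{a.paired_control_dish}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path
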