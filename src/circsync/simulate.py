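"""Synthetic multi-tissue circadian expression datasets with ground truth.

The generator emulates a 22-tissue circadian study design: expression is
sampled every 2 h over one 24-h cycle, with 2 biological replicates per time
point, under two feeding conditions (ad libitum, ALF; time-restricted, TRF).
Each gene g in tissue s follows a cosine rhythm

    x_{g,s,t,rep} = b_{g,s} + a_{g,s} * cos(2*pi*(t - phi_{g,s}) / 24) + eps,

with eps ~ Normal(0, noise_sd^2) i.i.d. per replicate and negative values
clipped at zero (count logged). Cross-tissue coordination is encoded in the
per-tissue phases:

* aligned genes share a global phase phi_g, jittered per tissue by
  delta_{g,s} ~ Normal(0, phase_dispersion_h(condition)^2), wrapped mod 24 —
  tighter dispersion under TRF than ALF models feeding-driven entrainment;
* benchmark genes are aligned genes with the smallest dispersion and the
  largest amplitude, standing in for a curated panel of core clock genes;
* scattered genes draw an independent uniform phase in every tissue and
  condition, providing the null background.

Aligned and benchmark genes receive a condition-specific multiplicative
amplitude gain (default 1.5 under TRF). Randomness is organized as one RNG
stream for gene-level parameters plus one stream per (condition, tissue), so
adding tissues never reshuffles earlier draws and every output is fully
reproducible from the single seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import StudyDataset, TimeSeriesExpression, average_replicates
from .errors import ConfigError
from .pathways import GeneSetAnnotation, parse_term_paths

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_dataset",
    "designate_benchmarks",
    "simulate_annotation",
    "write_ground_truth",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the emulated design: 22 tissues x 12 timepoints (every
    2 h) x 2 replicates x 2 conditions, 500 genes of which 10% are aligned
    across tissues (incl. 12 strong benchmarks), per-tissue phase dispersion
    6 h under ALF vs 1.5 h under TRF, and a 1.5x TRF amplitude gain for
    aligned genes. Expression units are arbitrary normalized counts: baseline
    10 +/- 2, amplitude 3 +/- 0.5, replicate noise SD 1.
    """

    n_tissues: int = 22
    n_genes: int = 500
    timepoints_h: tuple[float, ...] = tuple(float(t) for t in range(0, 24, 2))
    n_replicates: int = 2
    conditions: tuple[str, ...] = ("ALF", "TRF")
    baseline_mean: float = 10.0
    baseline_sd: float = 2.0
    amplitude_mean: float = 3.0
    amplitude_sd: float = 0.5
    noise_sd: float = 1.0
    phase_dispersion_h: dict = field(
        default_factory=lambda: {"ALF": 6.0, "TRF": 1.5}
    )
    aligned_fraction: float = 0.1
    amplitude_gain: dict = field(default_factory=lambda: {"ALF": 1.0, "TRF": 1.5})
    benchmark_n: int = 12
    decoy_n: int = 3
    benchmark_dispersion_factor: float = 0.25
    benchmark_amplitude_factor: float = 2.0
    # optional fixed global-phase grid for aligned/benchmark genes (round-robin)
    global_phase_choices_h: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tissues < 2 or self.n_genes < 2:
            raise ConfigError("n_tissues and n_genes must both be >= 2")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        if not 0.0 <= self.aligned_fraction <= 1.0:
            raise ConfigError("aligned_fraction must lie in [0, 1]")
        for name in ("baseline_sd", "amplitude_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for c in self.conditions:
            if c not in self.phase_dispersion_h:
                raise ConfigError(f"phase_dispersion_h missing condition {c!r}")
            if self.phase_dispersion_h[c] < 0:
                raise ConfigError("phase dispersions must be >= 0")
        n_aligned = int(round(self.aligned_fraction * self.n_genes))
        if self.benchmark_n > n_aligned:
            raise ConfigError(
                f"benchmark_n={self.benchmark_n} exceeds aligned gene count {n_aligned}"
            )

    @property
    def n_aligned(self) -> int:
        return int(round(self.aligned_fraction * self.n_genes))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["timepoints_h"] = list(self.timepoints_h)
        d["conditions"] = list(self.conditions)
        if self.global_phase_choices_h is not None:
            d["global_phase_choices_h"] = list(self.global_phase_choices_h)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("timepoints_h", "conditions", "global_phase_choices_h"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class GroundTruth:
    """Planted per-gene parameters of a generated dataset."""

    genes: tuple[str, ...]
    labels: tuple[str, ...]  # aligned | scattered | benchmark, one per gene
    global_phase_h: np.ndarray
    amplitude: np.ndarray
    baseline: np.ndarray
    # (condition, tissue) -> per-gene realized phase (hours)
    tissue_phase_h: dict[tuple[str, str], np.ndarray]
    decoy_genes: tuple[str, ...]
    n_clipped: int

    def genes_with_label(self, label: str) -> list[str]:
        return [g for g, l in zip(self.genes, self.labels) if l == label]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": list(self.genes),
                "label": list(self.labels),
                "global_phase_h": self.global_phase_h,
                "amplitude": self.amplitude,
                "baseline": self.baseline,
                "is_decoy": [g in set(self.decoy_genes) for g in self.genes],
            }
        )


def _tissue_ids(n: int) -> list[str]:
    return [f"tissue{i:02d}" for i in range(n)]


def generate_dataset(
    config: SimulationConfig,
    replicate_level: bool = False,
) -> tuple[StudyDataset, GroundTruth]:
    """Generate a StudyDataset plus its GroundTruth.

    Returns replicate-averaged series by default; with ``replicate_level``
    the raw per-replicate columns are kept (``replicate_averaged=False``).
    """
    cfg = config
    genes = tuple(f"g{i:04d}" for i in range(cfg.n_genes))
    tissues = _tissue_ids(cfg.n_tissues)
    tp = np.asarray(cfg.timepoints_h, dtype=float)
    omega = 2.0 * np.pi / 24.0

    n_aligned = cfg.n_aligned
    labels = tuple(
        "benchmark" if i < cfg.benchmark_n else ("aligned" if i < n_aligned else "scattered")
        for i in range(cfg.n_genes)
    )
    is_coordinated = np.array([l != "scattered" for l in labels])
    is_benchmark = np.array([l == "benchmark" for l in labels])
    scattered_idx = [i for i, l in enumerate(labels) if l == "scattered"]
    if cfg.decoy_n > len(scattered_idx):
        raise ConfigError("decoy_n exceeds the number of scattered genes")
    decoys = tuple(genes[i] for i in scattered_idx[: cfg.decoy_n])

    rng_genes = np.random.default_rng([cfg.seed, 0])
    phi_g = rng_genes.uniform(0.0, 24.0, cfg.n_genes)
    if cfg.global_phase_choices_h is not None:
        choices = np.asarray(cfg.global_phase_choices_h, dtype=float)
        coord_positions = np.flatnonzero(is_coordinated)
        phi_g[coord_positions] = choices[np.arange(len(coord_positions)) % len(choices)]
    amp_g = np.clip(
        rng_genes.normal(cfg.amplitude_mean, cfg.amplitude_sd, cfg.n_genes),
        0.05 * cfg.amplitude_mean,
        None,
    )
    amp_g[is_benchmark] *= cfg.benchmark_amplitude_factor
    base_g = np.clip(
        rng_genes.normal(cfg.baseline_mean, cfg.baseline_sd, cfg.n_genes), 0.0, None
    )

    series: dict[tuple[str, str], TimeSeriesExpression] = {}
    tissue_phase: dict[tuple[str, str], np.ndarray] = {}
    n_clipped = 0
    for ci, cond in enumerate(cfg.conditions):
        disp = cfg.phase_dispersion_h[cond]
        gain = cfg.amplitude_gain.get(cond, 1.0)
        for ti, tissue in enumerate(tissues):
            rng = np.random.default_rng([cfg.seed, 1 + ci, ti])
            delta = rng.normal(0.0, disp, cfg.n_genes)
            delta[is_benchmark] *= cfg.benchmark_dispersion_factor
            phases = np.where(
                is_coordinated,
                (phi_g + delta) % 24.0,
                rng.uniform(0.0, 24.0, cfg.n_genes),
            )
            amps = np.where(is_coordinated, amp_g * gain, amp_g)
            signal = base_g[:, None] + amps[:, None] * np.cos(
                omega * (tp[None, :] - phases[:, None])
            )
            cols = []
            col_idx = []
            for t_i in range(len(tp)):
                for _rep in range(cfg.n_replicates):
                    col_idx.append(t_i)
            noise = rng.normal(
                0.0, cfg.noise_sd, (cfg.n_genes, len(tp), cfg.n_replicates)
            )
            values = (signal[:, :, None] + noise).reshape(
                cfg.n_genes, len(tp) * cfg.n_replicates
            )
            clipped = values < 0
            n_clipped += int(clipped.sum())
            values = np.where(clipped, 0.0, values)
            ts = TimeSeriesExpression(
                tissue_id=tissue,
                condition_id=cond,
                genes=genes,
                timepoints_h=tp,
                values=values,
                replicate_averaged=False,
                column_timepoint_idx=np.array(col_idx, dtype=int),
            )
            if not replicate_level:
                ts = average_replicates(ts)
            series[(cond, tissue)] = ts
            tissue_phase[(cond, tissue)] = phases
    if n_clipped:
        logger.info("clipped %d negative simulated values to 0", n_clipped)

    truth = GroundTruth(
        genes=genes,
        labels=labels,
        global_phase_h=phi_g,
        amplitude=amp_g,
        baseline=base_g,
        tissue_phase_h=tissue_phase,
        decoy_genes=decoys,
        n_clipped=n_clipped,
    )
    dataset = StudyDataset(
        conditions=cfg.conditions,
        tissues=tuple(tissues),
        series=series,
        provenance=f"circsync synthetic dataset (seed={cfg.seed})",
    )
    return dataset, truth


def designate_benchmarks(truth: GroundTruth, config: SimulationConfig) -> list[str]:
    """Benchmark panel: the strong benchmark genes plus any weak decoys.

    Decoys are scattered genes included to emulate the low-ranked members of
    a curated clock-gene list; they anchor the bottom of the benchmark score
    distribution so gap-based threshold calibration has a decline to find.
    """
    strong = truth.genes_with_label("benchmark")
    if len(strong) < config.benchmark_n:
        raise ConfigError(
            f"benchmark_n={config.benchmark_n} exceeds benchmark gene count {len(strong)}"
        )
    return strong + list(truth.decoy_genes)


# -- synthetic pathway annotation --------------------------------------------

_TERM_TREE = {
    "Metabolism": {
        "Lipid metabolism": ["Fatty acid oxidation", "Cardiolipin synthesis"],
        "Carbohydrate metabolism": ["Pyruvate metabolism", "TCA cycle"],
        "Amino acid metabolism": ["BCAA catabolism"],
    },
    "OXPHOS": {
        "Complex I": ["CI subunits", "CI assembly factors"],
        "Complex V": ["CV subunits"],
        "Coenzyme Q metabolism": ["CoQ biosynthesis"],
    },
    "Mitochondrial central dogma": {
        "mtDNA maintenance": ["mtDNA replication"],
        "mtRNA metabolism": ["mtRNA processing", "Translation"],
    },
    "Mitochondrial dynamics and surveillance": {
        "Fission and fusion": ["Fusion"],
        "Mitophagy": ["Receptor-mediated mitophagy"],
    },
    "Signaling": {
        "Calcium homeostasis": ["Calcium uptake"],
        "Immune response": ["Interferon signaling"],
    },
}


def _term_paths(path_sep: str = " > ") -> list[str]:
    paths = []
    for root, children in _TERM_TREE.items():
        for child, leaves in children.items():
            for leaf in leaves:
                paths.append(path_sep.join((root, child, leaf)))
    return paths


def simulate_annotation(
    genes,
    seed: int = 0,
    max_paths_per_gene: int = 3,
) -> GeneSetAnnotation:
    """Random MitoCarta-style hierarchical annotation over ``genes``.

    Each gene draws 1..max_paths_per_gene annotation paths from a fixed
    synthetic term hierarchy (roots including the excluded-by-default
    "Metabolism" category).
    """
    rng = np.random.default_rng([seed, 99])
    paths = _term_paths()
    rows = []
    for gene in genes:
        k = int(rng.integers(1, max_paths_per_gene + 1))
        chosen = rng.choice(len(paths), size=k, replace=True)
        rows.append((gene, ";".join(paths[i] for i in chosen)))
    return parse_term_paths(rows)


def write_ground_truth(truth: GroundTruth, path) -> None:
    truth.to_frame().to_csv(path, sep="\t", index=False)


def write_manifest(config: SimulationConfig, path, extra: dict | None = None) -> None:
    payload = {"simulation": config.to_dict()}
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
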