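"""Synthetic multi-batch expression studies emulating a reference-material design.

The generator produces FPKM-like values and read counts for a design of four
biological groups with three replicates per batch across a configurable number
of batches, mirroring the standard 12-library reference batch.  The generative
model in log2 space is

    log2(abundance) = baseline(gene) + group effect(gene, group)
                      + batch shift(gene, batch) + replicate noise

with gene-wise additive batch shifts — exactly the perturbation model under
which ratio-based correction is exact.  A configurable fraction of genes per
group carries a planted log2 fold change against the first group's baseline;
the ground truth (per-pair DEG labels, true log2 fold changes, batch shifts
and injected outliers) is recorded so recovery tests reduce to joins.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .studydata import ExpressionStudy, StudyDesign

__all__ = ["SimulationConfig", "SyntheticStudy", "simulate_study", "inject_outlier", "export_truth"]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic generator.

    Defaults emulate a proficiency-test batch: 4 groups x 3 replicates, a
    modest fraction of truly differential genes with |log2FC| ~ Uniform(1, 3)
    and random sign, replicate noise s.d. 0.2 on the log2 scale, and per-gene
    per-batch additive shifts with s.d. 1.0.
    """

    n_genes: int = 1000
    groups: tuple[str, ...] = ("D5", "D6", "F7", "M8")
    n_replicates: int = 3
    n_batches: int = 1
    de_fraction: float = 0.1
    log2fc_low: float = 1.0
    log2fc_high: float = 3.0
    noise_sd: float = 0.2
    batch_sd: float = 1.0
    baseline_mean: float = 3.0
    baseline_sd: float = 2.0
    depth_factor: float = 1.0
    nb_dispersion: float | None = None  # None = Poisson counts
    batch_scaling_sd: float = 0.0  # optional multiplicative-on-log contamination
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_genes < 2:
            problems.append("n_genes must be >= 2")
        if len(self.groups) < 2:
            problems.append("need >= 2 groups")
        if self.n_replicates < 1:
            problems.append("n_replicates must be >= 1")
        if self.n_batches < 1:
            problems.append("n_batches must be >= 1")
        if not (0.0 <= self.de_fraction <= 1.0):
            problems.append("de_fraction must be in [0, 1]")
        for name in ("noise_sd", "batch_sd", "baseline_sd", "batch_scaling_sd"):
            if getattr(self, name) < 0:
                problems.append(f"{name} must be >= 0")
        if self.log2fc_low > self.log2fc_high:
            problems.append("log2fc_low must be <= log2fc_high")
        if self.depth_factor <= 0:
            problems.append("depth_factor must be > 0")
        if problems:
            raise ValueError("invalid simulation config: " + "; ".join(problems))


@dataclass
class SyntheticStudy:
    """Per-batch expression studies plus the ground truth behind them."""

    config: SimulationConfig
    batches: list[ExpressionStudy]
    #: genes x groups true group effects on the log2 scale (first group = 0)
    group_effects: pd.DataFrame
    #: genes x batches true additive batch shifts
    batch_shifts: pd.DataFrame
    #: per pair "g/denom": frame with true_log2fc and true label (up/down/non-DE)
    truth: dict[str, pd.DataFrame]
    outliers: list[dict] = field(default_factory=list)

    def pooled(self) -> ExpressionStudy:
        """All batches concatenated into one multi-batch study."""
        values = pd.concat([b.values for b in self.batches], axis=1)
        counts = None
        if all(b.counts is not None for b in self.batches):
            counts = pd.concat([b.counts for b in self.batches], axis=1)
        design = StudyDesign(
            pd.concat([b.design.table for b in self.batches], ignore_index=True)
        )
        return ExpressionStudy(values, design, counts)


def _truth_tables(config: SimulationConfig, effects: pd.DataFrame) -> dict[str, pd.DataFrame]:
    baseline_group = config.groups[0]
    truth = {}
    for a in config.groups:
        for b in config.groups:
            if a == b:
                continue
            lfc = effects[a] - effects[b]
            label = pd.Series("non-DE", index=effects.index, dtype=object)
            label[lfc >= 1.0] = "up"
            label[lfc <= -1.0] = "down"
            truth[f"{a}/{b}"] = pd.DataFrame({"true_log2fc": lfc, "true_label": label})
    return truth


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate a deterministic synthetic multi-batch study from a config."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = [f"G{i:05d}" for i in range(config.n_genes)]

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_genes)

    # Planted group effects: the first group is the unperturbed reference;
    # every other group gets its own DE gene set.
    effects = np.zeros((config.n_genes, len(config.groups)))
    n_de = int(round(config.de_fraction * config.n_genes))
    for gi in range(1, len(config.groups)):
        idx = rng.choice(config.n_genes, size=n_de, replace=False)
        mag = rng.uniform(config.log2fc_low, config.log2fc_high, size=n_de)
        sign = rng.choice([-1.0, 1.0], size=n_de)
        effects[idx, gi] = mag * sign
    effects_df = pd.DataFrame(effects, index=genes, columns=list(config.groups))
    effects_df.index.name = "gene"

    shifts = rng.normal(
        0.0, config.batch_sd, size=(config.n_genes, config.n_batches)
    )
    batch_labels = [f"B{b+1}" for b in range(config.n_batches)]
    shifts_df = pd.DataFrame(shifts, index=genes, columns=batch_labels)
    scalings = (
        rng.normal(1.0, config.batch_scaling_sd, size=config.n_batches)
        if config.batch_scaling_sd > 0
        else np.ones(config.n_batches)
    )

    batches: list[ExpressionStudy] = []
    for b, batch in enumerate(batch_labels):
        rows = []
        cols = {}
        for g, group in enumerate(config.groups):
            for rep in range(1, config.n_replicates + 1):
                sample = f"{group}_{rep}_{batch}"
                noise = rng.normal(0.0, config.noise_sd, size=config.n_genes)
                log2_abund = (
                    scalings[b] * (baseline + effects[:, g]) + shifts[:, b] + noise
                )
                cols[sample] = np.exp2(log2_abund)
                rows.append(
                    {"sample": sample, "group": group, "replicate": rep, "batch": batch}
                )
        values = pd.DataFrame(cols, index=genes)
        lam = values.to_numpy() * config.depth_factor
        if config.nb_dispersion is None:
            counts_arr = rng.poisson(lam)
        else:
            # NB via gamma-Poisson mixture; dispersion = 1/size
            size = 1.0 / config.nb_dispersion
            counts_arr = rng.poisson(rng.gamma(size, lam / size))
        counts = pd.DataFrame(counts_arr, index=genes, columns=values.columns)
        design = StudyDesign(pd.DataFrame(rows))
        batches.append(ExpressionStudy(values, design, counts))

    return SyntheticStudy(
        config=config,
        batches=batches,
        group_effects=effects_df,
        batch_shifts=shifts_df,
        truth=_truth_tables(config, effects_df),
    )


def inject_outlier(
    study: SyntheticStudy, sample: str, severity: float, seed: int | None = None
) -> SyntheticStudy:
    """Perturb one replicate with independent gene-wise noise.

    Adds Normal(0, severity * replicate noise s.d.) to the sample's log2
    values (counts are left untouched) and records the event in the outlier
    registry.  ``severity=0`` leaves the data unchanged apart from the
    registry entry.
    """
    config = study.config
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    new_batches = []
    found = False
    for b in study.batches:
        if sample not in b.samples:
            new_batches.append(b)
            continue
        found = True
        values = b.values.copy()
        perturb = rng.normal(0.0, severity * config.noise_sd, size=len(values))
        values[sample] = np.exp2(np.log2(values[sample].to_numpy()) + perturb)
        new_batches.append(ExpressionStudy(values, b.design, b.counts))
    if not found:
        raise ValueError(f"unknown sample {sample!r}")
    return SyntheticStudy(
        config=config,
        batches=new_batches,
        group_effects=study.group_effects,
        batch_shifts=study.batch_shifts,
        truth=study.truth,
        outliers=study.outliers + [{"sample": sample, "severity": severity}],
    )


def export_truth(study: SyntheticStudy, out_dir) -> dict[str, str]:
    """Write truth tables as TSVs; returns pair -> path.

    Columns match the DEG-table layout (gene, true_log2fc, true_label) so
    recovery checks are plain joins.
    """
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for pair, frame in study.truth.items():
        path = out_dir / f"truth_{pair.replace('/', '_vs_')}.tsv"
        frame.rename_axis("gene").to_csv(path, sep="\t")
        paths[pair] = str(path)
    return paths
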