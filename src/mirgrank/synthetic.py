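"""Synthetic paired miRNA/mRNA two-class data with planted regulators.

The generator emulates the structure the method exploits: a handful of
"planted" miRNAs differ between the two classes (standardized mean difference
``class_effect``) and each represses a private block of target genes, whose
expression is a negative linear transform of the miRNA plus noise calibrated
so the pooled-population Pearson correlation equals ``target_correlation``
exactly.  All remaining miRNAs and genes are i.i.d. noise with no class
signal.  Values sit on an expression-like non-negative scale.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError
from .io_preprocess import ExpressionMatrix, PairedDataset

POSITIVE_LABEL = "pos"
NEGATIVE_LABEL = "neg"


@dataclass
class SyntheticSpec:
    """Generation parameters (counts, effect sizes, noise, seed).

    ``class_effect`` is Cohen's d on the planted miRNAs between classes;
    ``target_correlation`` is the population Pearson r between a planted
    miRNA and each of its targets, pooled over both classes.  ``baseline``
    shifts values onto a non-negative expression-like scale.
    """

    n_samples_per_class: int = 200
    n_mirna: int = 50
    n_genes: int = 1000
    n_planted: int = 5
    targets_per_planted: int = 20
    target_correlation: float = -0.8
    class_effect: float = 1.5
    noise_sd: float = 1.0
    baseline: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planted * self.targets_per_planted > self.n_genes:
            raise ParameterError("planted targets exceed the number of genes")
        if not (-1.0 < self.target_correlation < 0.0):
            raise ParameterError("target_correlation must be in (-1, 0)")
        if self.n_planted > self.n_mirna:
            raise ParameterError("more planted miRNAs than miRNAs")
        if self.noise_sd <= 0:
            raise ParameterError("noise_sd must be positive")


@dataclass
class GroundTruth:
    """Planted miRNA ids and the miRNA -> target-gene map (disjoint blocks)."""

    planted_mirnas: list
    target_map: dict

    def planted_pairs(self) -> set:
        return {(m, g) for m, genes in self.target_map.items() for g in genes}

    def write(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {"planted_mirnas": self.planted_mirnas, "target_map": self.target_map},
                indent=2,
            )
        )


def generate(spec: SyntheticSpec) -> tuple:
    """Draw one paired dataset; returns (PairedDataset, GroundTruth).

    Planted miRNA latent profile: N(+d/2, 1) in cases, N(-d/2, 1) in
    controls.  Each target gene g of miRNA m:
    z_g = rho * u_m + sqrt(1 - rho^2) * eps, with u_m the miRNA profile
    standardized by its pooled population sd sqrt(1 + d^2/4), giving
    corr(g, m) = rho in the population.  Targets therefore also inherit a
    class-mean difference of -rho * d / sqrt(1 + d^2/4) (in sd units).
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = 2 * spec.n_samples_per_class
    labels = np.array(
        [POSITIVE_LABEL] * spec.n_samples_per_class + [NEGATIVE_LABEL] * spec.n_samples_per_class
    )
    class_sign = np.where(labels == POSITIVE_LABEL, 1.0, -1.0)

    mirna_ids = [f"miR-{i + 1:04d}" for i in range(spec.n_mirna)]
    gene_ids = [f"G{j + 1:05d}" for j in range(spec.n_genes)]
    sample_ids = [f"S{k + 1:04d}" for k in range(n)]

    d = spec.class_effect
    rho = spec.target_correlation
    mirna_latent = rng.standard_normal((n, spec.n_mirna))
    mirna_latent[:, : spec.n_planted] += (d / 2.0) * class_sign[:, None]

    gene_latent = rng.standard_normal((n, spec.n_genes))
    pooled_sd = np.sqrt(1.0 + d**2 / 4.0)
    target_map: dict = {}
    for i in range(spec.n_planted):
        u = mirna_latent[:, i] / pooled_sd  # population mean 0, sd 1
        start = i * spec.targets_per_planted
        cols = np.arange(start, start + spec.targets_per_planted)
        eps = gene_latent[:, cols]
        gene_latent[:, cols] = rho * u[:, None] + np.sqrt(1.0 - rho**2) * eps
        target_map[mirna_ids[i]] = [gene_ids[j] for j in cols]

    def expression(latent: np.ndarray) -> np.ndarray:
        return np.maximum(spec.baseline + spec.noise_sd * latent, 0.0)

    index = pd.Index(sample_ids, name="Case ID")
    classes = pd.Series(labels, index=index, name="class")
    genes = ExpressionMatrix(
        pd.DataFrame(expression(gene_latent), index=index, columns=gene_ids), classes
    )
    mirna = ExpressionMatrix(
        pd.DataFrame(expression(mirna_latent), index=index, columns=mirna_ids), classes.copy()
    )
    truth = GroundTruth(planted_mirnas=mirna_ids[: spec.n_planted], target_map=target_map)
    return PairedDataset(genes, mirna), truth


def write_dataset(pair: PairedDataset, truth: GroundTruth, out_dir) -> dict:
    """Write the two delimited expression tables plus the ground-truth sidecar.

    Layout matches the pipeline's input contract: sample-id column, class
    column, then one column per feature.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genes": out / "genes.csv",
        "mirna": out / "mirna.csv",
        "truth": out / "ground_truth.json",
    }
    for key, matrix in (("genes", pair.genes), ("mirna", pair.mirna)):
        frame = matrix.values.copy()
        frame.insert(0, "Class", matrix.classes)
        frame.reset_index().to_csv(paths[key], index=False)
    truth.write(paths["truth"])
    return paths
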