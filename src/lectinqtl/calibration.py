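"""Simulation studies validating the enrichment statistic at genome scale.

Because family labels are assigned to genes by sampling without replacement
(genes never move), the null and alternative distributions of the per-trait
family count x can be studied cheaply: the genome, the QTLs and therefore
every trait's gene content n are generated once, and only the label
assignment is redrawn per replicate. Each redraw re-runs the actual test
(z, two-sided p) on every analyzable trait.

Two studies are provided: :func:`null_calibration` measures the empirical
two-sided rejection rate under uniform labels (it should match the nominal
level), and :func:`planted_power` measures the detection rate for a trait
whose regions attract labels with a relative weight lambda > 1, together
with the false-positive rate on the remaining null traits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .enrichment import hypergeometric_var_x
from .interval_overlap import intersect
from .qtl_processing import drop_geneless_regions, merge_trait_qtls
from .simulate import SimResult, generate, paper_replica_config

__all__ = [
    "TraitMachinery",
    "prepare_traits",
    "replicate_z_scores",
    "null_calibration",
    "planted_power",
]


@dataclass
class TraitMachinery:
    """Per-trait counting apparatus reused across label redraws."""

    sim: SimResult
    traits: list[str]
    n_genes: np.ndarray  # genes per merged trait region set
    masks: np.ndarray  # traits x genome boolean membership matrix

    @property
    def N(self) -> int:
        return self.sim.genome.n_genes

    @property
    def s(self) -> int:
        return len(self.sim.genome.family_members(None))


def prepare_traits(sim: SimResult) -> TraitMachinery:
    """Merge each trait's QTLs, drop gene-empty regions, and build the
    per-trait gene membership masks through the pipeline's own ops."""
    genome = sim.genome
    by_trait: dict[str, list] = {}
    for q in sim.qtls:
        by_trait.setdefault(q.trait, []).append(q)
    merged = [
        drop_geneless_regions(merge_trait_qtls(v), genome)
        for _, v in sorted(by_trait.items())
    ]
    analyzable = [m for m in merged if not m.skip]
    assignment = intersect(genome.genes, analyzable)
    index_of = {g.gene_id: i for i, g in enumerate(genome.genes)}
    masks = np.zeros((len(analyzable), genome.n_genes), dtype=bool)
    for t, m in enumerate(analyzable):
        for gid in assignment.by_trait.get(m.trait, ()):
            masks[t, index_of[gid]] = True
    return TraitMachinery(
        sim=sim,
        traits=[m.trait for m in analyzable],
        n_genes=np.array([m.n_genes for m in analyzable]),
        masks=masks,
    )


def replicate_z_scores(
    machinery: TraitMachinery,
    n_replicates: int,
    seed: int,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """(replicates x traits) matrix of Wald z scores under label redraws.

    Each replicate redraws the full family-label assignment and recomputes
    z for every trait from its fresh x count. ``weights`` overrides the
    simulation's placement weights (e.g. all-ones to study the uniform
    null inside an otherwise enriched configuration).
    """
    from .simulate import draw_family_labels

    N, s = machinery.N, machinery.s
    n = machinery.n_genes
    var_x = np.array([hypergeometric_var_x(int(ni), s, N) for ni in n])
    se = np.sqrt(var_x) / n
    p_g = s / N
    sim = machinery.sim
    if weights is None:
        weights = sim.label_weights
    rng = np.random.default_rng(seed)
    z = np.empty((n_replicates, len(n)))
    for r in range(n_replicates):
        labels = draw_family_labels(sim.config, sim.genome.genes, weights, rng)
        labeled = np.asarray(sorted(labels), dtype=int)
        x = machinery.masks[:, labeled].sum(axis=1)
        z[r] = (x / n - p_g) / se
    return z


def null_calibration(
    seed: int,
    alphas: Sequence[float] = (0.05, 0.001),
    n_trait_tests: int = 2000,
) -> dict[float, tuple[int, int]]:
    """Empirical two-sided rejection counts under the uniform-label null.

    Generates the genome-scale replica once, then redraws labels until at
    least ``n_trait_tests`` trait-level tests have been performed. Returns
    ``alpha -> (rejections, total tests)``.
    """
    sim = generate(paper_replica_config(seed=seed))
    machinery = prepare_traits(sim)
    n_traits = len(machinery.traits)
    n_reps = -(-n_trait_tests // n_traits)
    z = replicate_z_scores(machinery, n_reps, seed=seed + 1)
    total = z.size
    return {
        alpha: (int((np.abs(z) > stats.norm.isf(alpha / 2)).sum()), total)
        for alpha in alphas
    }


def planted_power(
    seed: int,
    enriched_trait: str = "drought tolerance",
    lam: float = 3.0,
    n_replicates: int = 500,
    alpha_corrected: float = 0.001,
) -> dict[str, float]:
    """Detection rate for a planted enrichment, paired with the lambda=1
    rejection rate in the same genome.

    One trait's regions attract family labels with relative weight ``lam``.
    Because QTL regions of different traits share genomic territory, traits
    overlapping the enriched regions are themselves genuinely (partially)
    enriched — they are not lambda=1 traits. The lambda=1 rate is therefore
    measured on the same genome and trait set but under uniform label
    redraws (weight 1 everywhere), pooled across all traits. Returns the
    power for the enriched trait at ``alpha_corrected`` (two-sided), the
    uniform-label rejection rate, and the enriched trait's gene content.
    """
    sim = generate(paper_replica_config(seed=seed, enrichment={enriched_trait: lam}))
    machinery = prepare_traits(sim)
    z_alt = replicate_z_scores(machinery, n_replicates, seed=seed + 1)
    uniform = np.ones(machinery.N)
    z_null = replicate_z_scores(machinery, n_replicates, seed=seed + 2, weights=uniform)
    zcrit = stats.norm.isf(alpha_corrected / 2)
    idx = machinery.traits.index(enriched_trait)
    return {
        "power": float((np.abs(z_alt[:, idx]) > zcrit).mean()),
        "null_rejection_rate": float((np.abs(z_null) > zcrit).mean()),
        "enriched_trait_n_genes": int(machinery.n_genes[idx]),
    }
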