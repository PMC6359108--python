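"""Wald overrepresentation test for family genes in QTL regions.

The null hypothesis is that family (lectin) genes are not preferentially
located in the QTL regions of a trait: the x family genes found among the
n genes of the trait's merged regions behave like a draw without
replacement from a genome of N genes containing s family genes. Under that
null x is hypergeometric, so

    var(x) = (n * s * r / N^2) * ((N - n) / (N - 1)),   r = N - s

and the test statistic is

    z = (p_trait - p_g) / SE(p_trait),
    p_trait = x / n,  p_g = s / N,  SE(p_trait) = sqrt(var(x)) / n

compared two-sided against the standard normal. Each gene is counted once
(unique gene IDs after transcript de-duplication), which is what makes the
without-replacement model appropriate. Multiple testing across traits is
handled with a Bonferroni division of the single-test level.

An exact hypergeometric tail probability is provided as a cross-check
(:func:`exact_hypergeom_pvalue`); the screen itself uses the normal
approximation, with no continuity correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

from .genome_model import Genome
from .interval_overlap import OverlapAssignment, intersect, lectin_count
from .qtl_processing import MergedTraitRegions

__all__ = [
    "EnrichmentInput",
    "EnrichmentResult",
    "hypergeometric_var_x",
    "wald_z",
    "exact_hypergeom_pvalue",
    "bonferroni_screen",
    "enrichment_screen",
    "results_table",
]


@dataclass(frozen=True)
class EnrichmentInput:
    """Counts entering the test for one trait.

    n — unique genes in the trait's merged regions; x — family genes among
    them; N — all genes in the genome; s — family genes in the genome;
    r = N − s non-family genes.
    """

    trait: str
    n: int
    x: int
    N: int
    s: int

    def __post_init__(self) -> None:
        if not (0 < self.n <= self.N):
            raise ValueError(f"{self.trait!r}: require 0 < n <= N, got n={self.n}, N={self.N}")
        if not (0 < self.s < self.N):
            raise ValueError(f"{self.trait!r}: require 0 < s < N, got s={self.s}, N={self.N}")
        if not (0 <= self.x <= min(self.n, self.s)):
            raise ValueError(
                f"{self.trait!r}: require 0 <= x <= min(n, s), "
                f"got x={self.x}, n={self.n}, s={self.s}"
            )

    @property
    def r(self) -> int:
        return self.N - self.s


@dataclass(frozen=True)
class EnrichmentResult:
    """Everything the test computes for one trait; TSV-serializable."""

    input: EnrichmentInput
    p_trait: float
    p_g: float
    var_x: float
    se_p_trait: float
    z: float
    p_value: float
    degenerate: bool
    alpha_corrected: float = math.nan
    significant: bool = False


def hypergeometric_var_x(n: int, s: int, N: int) -> float:
    """Variance of the family-gene count in an n-gene sample drawn without
    replacement from N genes of which s belong to the family.

    This is the textbook hypergeometric variance with finite-population
    correction (N − n)/(N − 1); it vanishes when the sample exhausts the
    genome (n = N).
    """
    if N <= 1:
        raise ValueError(f"N must exceed 1 (finite-population factor), got N={N}")
    if not (0 < n <= N and 0 <= s <= N):
        raise ValueError(f"invalid counts n={n}, s={s}, N={N}")
    r = N - s
    return (n * s * r / N**2) * ((N - n) / (N - 1))


def wald_z(inp: EnrichmentInput) -> EnrichmentResult:
    """Two-sided Wald test of overrepresentation for one trait.

    Returns z and the two-sided normal p-value 2·(1 − Φ(|z|)). When the
    variance is zero (n = N: the regions tile the genome) the result is
    flagged degenerate — z and p are NaN and the significance screen
    ignores it.
    """
    var_x = hypergeometric_var_x(inp.n, inp.s, inp.N)
    p_trait = inp.x / inp.n
    p_g = inp.s / inp.N
    se = math.sqrt(var_x) / inp.n
    if var_x == 0.0:
        return EnrichmentResult(
            input=inp, p_trait=p_trait, p_g=p_g, var_x=var_x, se_p_trait=se,
            z=math.nan, p_value=math.nan, degenerate=True,
        )
    z = (p_trait - p_g) / se
    p_value = 2.0 * stats.norm.sf(abs(z))
    return EnrichmentResult(
        input=inp, p_trait=p_trait, p_g=p_g, var_x=var_x, se_p_trait=se,
        z=z, p_value=float(p_value), degenerate=False,
    )


def exact_hypergeom_pvalue(inp: EnrichmentInput) -> float:
    """Two-sided exact hypergeometric p-value (2·min tail, capped at 1).

    Cross-check only: the screen uses the normal approximation above, and
    this exact tail lets a user gauge the approximation for small traits.
    """
    hg = stats.hypergeom(inp.N, inp.s, inp.n)
    upper = hg.sf(inp.x - 1)  # P(X >= x)
    lower = hg.cdf(inp.x)  # P(X <= x)
    return float(min(1.0, 2.0 * min(upper, lower)))


def bonferroni_screen(
    results: Iterable[EnrichmentResult],
    alpha_single: float = 0.025,
    n_tests: int | None = None,
) -> list[EnrichmentResult]:
    """Apply the Bonferroni-corrected significance threshold.

    ``alpha_corrected = alpha_single / n_tests`` is stamped onto every
    result; a non-degenerate result is significant iff its p-value falls
    below it. ``n_tests`` defaults to the number of non-degenerate results
    and may be overridden (e.g. fixed at 25, which with alpha_single=0.025
    gives the conventional p < 0.001 screen).
    """
    results = list(results)
    if not (0.0 < alpha_single < 1.0):
        raise ValueError(f"alpha_single must lie in (0, 1), got {alpha_single}")
    if n_tests is None:
        n_tests = sum(1 for res in results if not res.degenerate)
        n_tests = max(n_tests, 1)
    if n_tests < 1:
        raise ValueError(f"n_tests must be >= 1, got {n_tests}")
    alpha_corrected = alpha_single / n_tests
    return [
        replace(
            res,
            alpha_corrected=alpha_corrected,
            significant=(not res.degenerate) and res.p_value < alpha_corrected,
        )
        for res in results
    ]


def enrichment_screen(
    genome: Genome,
    merged_traits: Sequence[MergedTraitRegions],
    family: str | None = None,
    alpha_single: float = 0.025,
    n_tests: int | None = None,
    assignment: OverlapAssignment | None = None,
) -> list[EnrichmentResult]:
    """Run the full per-trait screen on merged, gene-filtered trait regions.

    Traits flagged ``skip`` (no gene-bearing regions) are passed over.
    ``family=None`` tests all family-labelled genes together; a specific
    family label restricts both x and s to that family. A precomputed
    ``assignment`` (from :func:`lectinqtl.interval_overlap.intersect` over
    exactly ``merged_traits``) may be supplied to avoid recomputation.
    """
    analyzable = [m for m in merged_traits if not m.skip]
    for m in analyzable:
        if m.n_genes < 0:
            raise ValueError(
                f"trait {m.trait!r}: run drop_geneless_regions before the screen"
            )
    if assignment is None:
        assignment = intersect(genome.genes, analyzable)
    N = genome.n_genes
    s = len(genome.family_members(family))
    results = []
    for m in analyzable:
        x = lectin_count(assignment, genome, m.trait, family=family) if m.trait in assignment.by_trait else 0
        results.append(wald_z(EnrichmentInput(trait=m.trait, n=m.n_genes, x=x, N=N, s=s)))
    return bonferroni_screen(results, alpha_single=alpha_single, n_tests=n_tests)


def results_table(
    results: Sequence[EnrichmentResult],
    categories: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Flatten screen results into the standard results table."""
    rows = []
    for res in results:
        rows.append(
            {
                "trait": res.input.trait,
                "category": (categories or {}).get(res.input.trait, ""),
                "n": res.input.n,
                "x": res.input.x,
                "N": res.input.N,
                "s": res.input.s,
                "p_trait": res.p_trait,
                "p_g": res.p_g,
                "z": res.z,
                "p_value": res.p_value,
                "alpha_corrected": res.alpha_corrected,
                "significant": res.significant,
                "degenerate": res.degenerate,
            }
        )
    return pd.DataFrame(rows)
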