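"""Cross-genome conserved-marker pipeline.

Stage order: mine SSRs in genome A, design flanking primers, self-screen
every pair by electronic PCR against A (a pair must produce at least one
product in its own genome), then e-PCR the survivors against genome B.
A marker is *conserved* when it has at least one qualifying product in
both genomes under the stringent settings; its copy-number class in B is
reported, never filtered on.

The pipeline is deterministic given its inputs, and the survivor counts
form a funnel: conserved <= self-amplifying <= designed <= mined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .epcr import EpcrParams, amplify, classify_copy_number
from .primer_design import DesignFailure, PrimerConstraints, PrimerPair, design_all
from .repeat_finder import find_ssrs

logger = logging.getLogger(__name__)

__all__ = [
    "ConservedMarker",
    "PipelineReport",
    "run_pipeline",
    "conservation_rate",
    "transferability_rates",
]


@dataclass(frozen=True)
class ConservedMarker:
    marker_id: str
    primer_pair: PrimerPair
    n_products_a: int
    n_products_b: int
    copy_class_a: str
    copy_class_b: str
    best_b_size_deviation: int

    def __post_init__(self) -> None:
        if self.n_products_a < 1 or self.n_products_b < 1:
            raise ValueError("a conserved marker needs products in both genomes")


@dataclass
class PipelineReport:
    n_loci_mined: int
    n_primers_designed: int
    n_design_failures: int
    n_with_self_products: int
    n_conserved: int
    copy_number_hist_a: dict[str, int]
    copy_number_hist_b: dict[str, int]
    conservation_rate_vs_designed: float
    conservation_rate_vs_self_amplifying: float
    total_fragments_a: int
    total_fragments_b: int
    design_failure_reasons: dict[str, int] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def conservation_rate(n_conserved: int, n_designed: int) -> float:
    """Conserved markers as a percentage of designed primer pairs."""
    if n_designed <= 0:
        raise ValueError("denominator must be positive")
    return 100.0 * n_conserved / n_designed


def run_pipeline(
    genome_a: Mapping[str, str],
    genome_b: Mapping[str, str],
    thresholds: Mapping[int, int] | None = None,
    constraints: PrimerConstraints | None = None,
    params: EpcrParams | None = None,
    tm_method: str = "nn",
) -> tuple[list[ConservedMarker], PipelineReport]:
    """Mine A, design, self-screen on A, cross-amplify B; report the funnel."""
    if not genome_a or not genome_b:
        raise ValueError("both genomes must be non-empty")
    params = params or EpcrParams()

    loci = find_ssrs(genome_a, thresholds)
    logger.info("mined %d SSR loci in genome A", len(loci))

    pairs, failures = design_all(genome_a, loci, constraints, tm_method)
    logger.info("designed %d primer pairs (%d failures)", len(pairs), len(failures))
    reasons: dict[str, int] = {}
    for f in failures:
        reasons[f.reason] = reasons.get(f.reason, 0) + 1

    hist_a: dict[str, int] = {"1": 0, "2": 0, "3": 0, ">3": 0}
    self_amplifying: list[tuple[PrimerPair, int]] = []
    total_a = 0
    for pair in pairs:
        products = amplify(genome_a, pair, params)
        if products:
            self_amplifying.append((pair, len(products)))
            hist_a[classify_copy_number(len(products))] += 1
            total_a += len(products)
    logger.info("%d pairs self-amplify genome A", len(self_amplifying))
    if not self_amplifying:
        logger.warning("no primer pair self-amplifies genome A")

    hist_b: dict[str, int] = {"1": 0, "2": 0, "3": 0, ">3": 0}
    conserved: list[ConservedMarker] = []
    total_b = 0
    for pair, n_a in self_amplifying:
        products_b = amplify(genome_b, pair, params)
        if not products_b:
            continue
        hist_b[classify_copy_number(len(products_b))] += 1
        total_b += len(products_b)
        best_dev = min(
            abs(p.size - pair.expected_product_size) for p in products_b
        )
        conserved.append(
            ConservedMarker(
                marker_id=pair.marker_id,
                primer_pair=pair,
                n_products_a=n_a,
                n_products_b=len(products_b),
                copy_class_a=classify_copy_number(n_a),
                copy_class_b=classify_copy_number(len(products_b)),
                best_b_size_deviation=int(best_dev),
            )
        )
    logger.info("%d conserved markers", len(conserved))
    if pairs and not conserved:
        logger.warning("no conserved markers between the two genomes")

    report = PipelineReport(
        n_loci_mined=len(loci),
        n_primers_designed=len(pairs),
        n_design_failures=len(failures),
        n_with_self_products=len(self_amplifying),
        n_conserved=len(conserved),
        copy_number_hist_a=hist_a,
        copy_number_hist_b=hist_b,
        conservation_rate_vs_designed=(
            conservation_rate(len(conserved), len(pairs)) if pairs else 0.0
        ),
        conservation_rate_vs_self_amplifying=(
            conservation_rate(len(conserved), len(self_amplifying))
            if self_amplifying
            else 0.0
        ),
        total_fragments_a=total_a,
        total_fragments_b=total_b,
        design_failure_reasons=reasons,
    )
    assert (
        report.n_conserved
        <= report.n_with_self_products
        <= report.n_primers_designed
        <= report.n_loci_mined
    ), "stage survivor counts must form a funnel"
    return conserved, report


def transferability_rates(matrix: pd.DataFrame) -> pd.Series:
    """Per-marker amplification percentage from a 0/1 marker x species matrix.

    Entries may be 0, 1 or missing; missing species are excluded from a
    marker's denominator.  Summary statistics (min/mean/max) are the
    usual reductions of the returned series.
    """
    if matrix.shape[1] == 0:
        raise ValueError("no species columns")
    values = matrix.to_numpy(dtype=float)
    valid = ~np.isnan(values)
    if not np.isin(values[valid], (0.0, 1.0)).all():
        raise ValueError("matrix entries must be 0, 1 or missing")
    denom = valid.sum(axis=1)
    if (denom == 0).any():
        raise ValueError("a marker has no scored species")
    rates = 100.0 * np.nansum(values, axis=1) / denom
    return pd.Series(rates, index=matrix.index, name="transferability_pct")
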