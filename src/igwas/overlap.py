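"""Genetic-overlap enrichment between a proxy (disease) and a target GWAS.

The question: among the top-K SNPs of a large disease GWAS, are more of
them nominally associated with the target phenotype (e.g. exceptional
longevity) than chance predicts? The pipeline is: intersect the two
studies, greedily LD-prune the shared panel (ranked by target P) so that
no retained pair has r² above a threshold, convert target P values to
one-sided form preserving the disease effect direction, then compare the
nominal hit rate among the top-K disease SNPs to the background rate with
an upper-tail hypergeometric test. QQ coordinates against uniform
quantiles are exported for plotting.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .sumstats_io import LdTable

logger = logging.getLogger("igwas")


@dataclass
class OverlapResult:
    """Top-K enrichment of proxy-study SNPs in the target study.

    ``fold`` is (observed_hits / k_top) / expected_rate, where
    ``expected_rate`` is the background nominal hit rate; significance is
    the upper tail P[X >= observed_hits] of
    Hypergeometric(population=n_background, successes=background_hits,
    draws=k_top).
    """

    k_top: int
    n_background: int
    background_hits: int
    observed_hits: int
    expected_rate: float
    fold: float
    p_hypergeometric: float
    alpha: float = 0.05
    qq_points: list[tuple[float, float]] = field(default_factory=list)


def one_sided_p(p_two: float, concordance: str) -> float:
    """Convert a two-sided P to a one-sided P given direction concordance.

    p/2 if the two studies' effect directions agree, 1 - p/2 if they
    oppose. 'unknown' concordance is an error here: the caller must fall
    back to the two-sided value explicitly rather than have it silently
    halved.
    """
    if not (0.0 < p_two <= 1.0):
        raise ValueError(f"p_two={p_two} outside (0, 1]")
    if concordance == "same":
        return p_two / 2.0
    if concordance == "opposite":
        return 1.0 - p_two / 2.0
    raise ValueError(
        f"concordance must be 'same' or 'opposite', got {concordance!r}; "
        "use the two-sided P when direction is unknown"
    )


def ld_prune(
    ranked_ids: list[str],
    ld: LdTable,
    r2_max: float = 0.2,
    exclude_index: str | None = None,
) -> list[str]:
    """Greedy LD pruning of a significance-ranked SNP list.

    ``ranked_ids`` must be ordered by ascending target P (most significant
    first) and duplicate-free. Scan: keep the first unremoved SNP, remove
    every later SNP with r² > ``r2_max`` to it, repeat. Strict inequality:
    a pair at exactly ``r2_max`` is retained. If ``exclude_index`` is
    given, that SNP and everything with r² > ``r2_max`` to it is removed
    first (the index locus is already known and would mask the scan).
    Output preserves input order.
    """
    if len(set(ranked_ids)) != len(ranked_ids):
        raise ValueError("ranked_ids contains duplicates")
    alive = list(ranked_ids)
    if exclude_index is not None:
        alive = [
            s for s in alive
            if s != exclude_index and ld.r2(s, exclude_index) <= r2_max
        ]
    retained: list[str] = []
    while alive:
        keep = alive[0]
        retained.append(keep)
        alive = [s for s in alive[1:] if ld.r2(keep, s) <= r2_max]
    return retained


def rank_by_p(p_by_id: dict[str, float]) -> list[str]:
    """Ids sorted by ascending P; ties broken lexicographically on id."""
    return sorted(p_by_id, key=lambda s: (p_by_id[s], s))


def enrichment_test(
    top_k_one_sided_p: list[float],
    background_one_sided_p: list[float],
    alpha: float = 0.05,
) -> OverlapResult:
    """Upper-tail hypergeometric enrichment of nominal hits in the top K.

    ``top_k_one_sided_p`` are the target-study P values of the top-K proxy
    SNPs; ``background_one_sided_p`` those of the full LD-pruned universe
    (of which the top K are a subset). Both lists must be on the same
    sidedness.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha={alpha} outside (0, 1)")
    k = len(top_k_one_sided_p)
    n_background = len(background_one_sided_p)
    if k > n_background:
        raise ValueError(f"top-K list ({k}) larger than background ({n_background})")
    observed = int(sum(p < alpha for p in top_k_one_sided_p))
    background_hits = int(sum(p < alpha for p in background_one_sided_p))
    expected_rate = background_hits / n_background if n_background else 0.0
    if expected_rate == 0.0:
        fold = math.inf if observed > 0 else 0.0
        if observed > 0:
            logger.warning(
                "background hit rate is 0 with %d observed hits; fold is infinite",
                observed,
            )
    else:
        fold = (observed / k) / expected_rate if k else 0.0
    # P[X >= observed], X ~ Hypergeom(M=n_background, n=background_hits, N=k)
    p_hyper = float(
        stats.hypergeom.sf(observed - 1, n_background, background_hits, k)
    )
    return OverlapResult(
        k_top=k,
        n_background=n_background,
        background_hits=background_hits,
        observed_hits=observed,
        expected_rate=expected_rate,
        fold=fold,
        p_hypergeometric=min(p_hyper, 1.0),
        alpha=alpha,
        qq_points=qq_coordinates(top_k_one_sided_p) if k else [],
    )


def qq_coordinates(p_values: list[float]) -> list[tuple[float, float]]:
    """(expected, observed) quantile pairs for a QQ plot.

    Observed P values are sorted ascending; expected quantiles are
    i/(n+1), the mean of the i-th uniform order statistic.
    """
    if len(p_values) == 0:
        raise ValueError("p_values must be nonempty")
    observed = np.sort(np.asarray(p_values, dtype=float))
    n = observed.size
    expected = np.arange(1, n + 1) / (n + 1.0)
    return list(zip(expected.tolist(), observed.tolist()))


def qq_table(p_values: list[float]) -> "np.ndarray":
    """QQ coordinates on both raw and -log10 scales, as a structured array
    of columns (expected, observed, neglog10_expected, neglog10_observed)."""
    points = qq_coordinates(p_values)
    arr = np.array(points, dtype=float)
    return np.column_stack([arr, -np.log10(arr)])
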