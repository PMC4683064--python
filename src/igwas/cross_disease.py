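"""Cross-trait combination of proxy-study evidence into a per-SNP prior.

Each SNP's two-sided P values across the proxy (disease/trait) studies are
combined with Fisher's method (-2·Σ ln p ~ χ² with 2k df); the meta-P is
converted to a nonnegative Z score and scaled to the target study's sample
size, giving the prior mean η used by the weighting step. Direction of
effect is deliberately ignored in the combination -- it is unavailable for
several published meta-analyses -- so η is a magnitude.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import sqrt

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats_io import SummaryTable

logger = logging.getLogger("igwas")


@dataclass
class CrossDiseaseResult:
    """Per-SNP Fisher combination and prior Z score.

    ``df`` is 2 x the number of studies in which the SNP was present;
    ``z_prior`` is the untruncated-at-zero upper-tail quantile of
    ``p_meta`` (η before sample-size scaling).
    """

    snp_id: str
    k: int
    fisher_stat: float
    p_meta: float
    z_prior: float


def fisher_combine(p_list) -> tuple[float, float]:
    """Fisher's method: returns (-2·Σ ln p_i, χ²_{2k} upper-tail P).

    Each p must be in (0, 1] (P=0 clamping happens at I/O, not here).
    At k=1 the method is the identity on the input P.
    """
    p = np.asarray(p_list, dtype=float)
    if p.size == 0:
        raise ValueError("fisher_combine requires at least one P value")
    if np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValueError("all P values must lie in (0, 1]")
    stat = float(-2.0 * np.sum(np.log(p)))
    p_meta = float(stats.chi2.sf(stat, df=2 * p.size))
    return stat, p_meta


def meta_p_to_z(p_meta: float) -> float:
    """One-sided mapping z = Φ̄⁻¹(p_meta), truncated below at 0.

    η enters the weighting as a magnitude, so meta-P values above 0.5
    (which would give a negative quantile, i.e. a below-genome-average
    prior) truncate to 0 rather than penalizing the SNP.
    """
    if not (0.0 < p_meta <= 1.0):
        raise ValueError(f"p_meta={p_meta} outside (0, 1]")
    return max(0.0, float(stats.norm.isf(p_meta)))


def scale_z(
    z_d: float,
    n_target: int,
    n_proxy: int,
    convention: str = "sqrt",
) -> float:
    """Scale a proxy-study Z score to the target study's sample size.

    Under the standard GWAS power model the noncentrality of a Z score
    grows with the square root of the sample size, so the default is
    z_target = sqrt(n_target / n_proxy) · z_d. ``convention='linear'``
    applies the raw ratio instead.
    """
    if n_target <= 0 or n_proxy <= 0:
        raise ValueError("sample sizes must be positive")
    if convention == "sqrt":
        factor = sqrt(n_target / n_proxy)
    elif convention == "linear":
        factor = n_target / n_proxy
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return factor * z_d


def combine_studies(
    studies: list[SummaryTable],
    snp_ids: list[str] | None = None,
) -> dict[str, CrossDiseaseResult]:
    """Fisher-combine each SNP's P values over the studies where present.

    A SNP absent from some studies is combined over the k studies that
    carry it (df = 2k); a SNP absent from all of them gets k=0,
    p_meta=1, z_prior=0 (weight-neutral), so the full target panel stays
    weightable.
    """
    if not studies:
        raise ValueError("combine_studies requires at least one study")
    if snp_ids is None:
        ids: dict[str, None] = {}
        for study in studies:
            for snp_id in study.records:
                ids.setdefault(snp_id)
        snp_ids = list(ids)
    results: dict[str, CrossDiseaseResult] = {}
    for snp_id in snp_ids:
        p_list = [
            study[snp_id].p_two_sided for study in studies if snp_id in study
        ]
        if not p_list:
            results[snp_id] = CrossDiseaseResult(snp_id, 0, 0.0, 1.0, 0.0)
            continue
        stat, p_meta = fisher_combine(p_list)
        results[snp_id] = CrossDiseaseResult(
            snp_id, len(p_list), stat, p_meta, meta_p_to_z(p_meta)
        )
    return results


def prior_table(
    studies: list[SummaryTable],
    n_target: int,
    n_proxy: int,
    snp_ids: list[str] | None = None,
    convention: str = "sqrt",
) -> pd.DataFrame:
    """Per-SNP prior means for the weighting step, as a DataFrame with
    columns snp, k, fisher_stat, p_meta, z_prior, eta (the scaled Z)."""
    combined = combine_studies(studies, snp_ids=snp_ids)
    rows = [
        {
            "snp": r.snp_id,
            "k": r.k,
            "fisher_stat": r.fisher_stat,
            "p_meta": r.p_meta,
            "z_prior": r.z_prior,
            "eta": scale_z(r.z_prior, n_target, n_proxy, convention=convention),
        }
        for r in combined.values()
    ]
    return pd.DataFrame(
        rows, columns=["snp", "k", "fisher_stat", "p_meta", "z_prior", "eta"]
    )
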