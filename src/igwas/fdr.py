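"""Weighted multiple-testing control and lead-SNP selection.

Raw P values are divided by their (nonnegative, mean-1) weights and the
weighted P values go through the Benjamini–Hochberg step-up procedure,
which controls the FDR at the nominal level for independent P values with
such weights. Lead SNPs are picked per LD block as the record with the
lowest adjusted P. For small follow-up panels the Benjamini–Liu (1999)
step-down procedure is provided as well.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("igwas")


@dataclass
class FdrRecord:
    """One SNP's multiple-testing bookkeeping."""

    snp_id: str
    p_raw: float
    weight: float = 1.0
    p_weighted: float = field(init=False, default=1.0)
    p_adjusted: float = 1.0
    rank: int = 0
    significant: bool = False
    block: str | None = None
    is_lead: bool = False

    def __post_init__(self) -> None:
        self.p_weighted = float(weight_pvalues([self.p_raw], [self.weight])[0])


def weight_pvalues(p, w) -> np.ndarray:
    """Elementwise p/w, clipped to 1; weight 0 maps to 1 (never rejectable)."""
    p = np.asarray(p, dtype=float)
    w = np.asarray(w, dtype=float)
    if p.shape != w.shape:
        raise ValueError(f"length mismatch: {p.shape} p values, {w.shape} weights")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    out = np.ones_like(p)
    nonzero = w > 0
    out[nonzero] = np.minimum(p[nonzero] / w[nonzero], 1.0)
    return out


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted P values (in input order)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return adjusted


def bl_adjust(p, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Liu (1999) step-down FDR procedure.

    Critical value at sorted rank i (1-based, m tests):

        δ_i = 1 − (1 − min(1, m·q/(m−i+1)))^(1/(m−i+1))

    Hypotheses are rejected sequentially from the smallest P while
    p_(i) ≤ δ_i; the first failure stops the scan, so rejections are
    always a prefix of the sorted order. Returns (reject flags, adjusted
    values) in input order; the adjusted value is the smallest q at which
    the hypothesis would be rejected, obtained by inverting the
    sequential rule:

        q_i* = max_{j ≤ i} (m−j+1)/m · (1 − (1 − p_(j))^(m−j+1)).

    The procedure controls the FDR for independent tests and is intended
    for small m (follow-up panels of a handful of lead SNPs).
    """
    p = np.asarray(p, dtype=float)
    m = p.size
    if m == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    if not (0.0 < q < 1.0):
        raise ValueError(f"q={q} outside (0, 1)")
    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    i = np.arange(1, m + 1)
    m_rem = m - i + 1  # hypotheses remaining at step i
    delta = 1.0 - (1.0 - np.minimum(1.0, m * q / m_rem)) ** (1.0 / m_rem)
    passed = p_sorted <= delta
    n_reject = int(np.argmin(passed)) if not passed.all() else m
    # smallest level at which step j passes, then running max over the prefix
    q_star = np.minimum(1.0, (m_rem / m) * (1.0 - (1.0 - p_sorted) ** m_rem))
    adjusted_sorted = np.maximum.accumulate(q_star)
    reject = np.zeros(m, dtype=bool)
    adjusted = np.empty(m)
    reject[order[:n_reject]] = True
    adjusted[order] = adjusted_sorted
    return reject, adjusted


def weighted_fdr_records(
    snp_ids,
    p_raw,
    weights,
    q: float = 0.10,
    blocks: dict[str, str] | None = None,
) -> list[FdrRecord]:
    """Full weighted-BH pass: weight, adjust, rank, flag significance.

    ``q`` is the FDR level (discovery default 10%). ``blocks`` maps
    snp_id -> LD-block label for lead-SNP selection; significant records
    without a label are assigned a singleton block with a warning.
    """
    p_raw = np.asarray(p_raw, dtype=float)
    weights = np.asarray(weights, dtype=float)
    p_weighted = weight_pvalues(p_raw, weights)
    p_adjusted = bh_adjust(p_weighted)
    order = np.argsort(p_adjusted, kind="stable")
    ranks = np.empty(len(order), dtype=int)
    ranks[order] = np.arange(1, len(order) + 1)
    records = []
    for snp_id, pr, w, pw, pa, rank in zip(
        snp_ids, p_raw, weights, p_weighted, p_adjusted, ranks
    ):
        rec = FdrRecord(snp_id=str(snp_id), p_raw=float(pr), weight=float(w))
        rec.p_weighted = float(pw)
        rec.p_adjusted = float(pa)
        rec.rank = int(rank)
        rec.significant = bool(pa < q)
        rec.block = blocks.get(str(snp_id)) if blocks else None
        records.append(rec)
    return select_lead_snps(records)


def select_lead_snps(records: list[FdrRecord]) -> list[FdrRecord]:
    """Flag the lowest-adjusted-P record per LD block as the lead SNP.

    Only significant records compete. Ties on adjusted P break by smaller
    weighted P, then lexicographic snp_id. Significant records without a
    block label get a singleton block (warned).
    """
    by_block: dict[str, list[FdrRecord]] = {}
    for rec in records:
        rec.is_lead = False
        if not rec.significant:
            continue
        block = rec.block
        if block is None:
            block = f"__singleton_{rec.snp_id}"
            logger.warning(
                "significant SNP %s has no LD-block label; treating as its own block",
                rec.snp_id,
            )
            rec.block = block
        by_block.setdefault(block, []).append(rec)
    for block_records in by_block.values():
        lead = min(
            block_records, key=lambda r: (r.p_adjusted, r.p_weighted, r.snp_id)
        )
        lead.is_lead = True
    return records
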