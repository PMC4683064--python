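"""Replication of discovery lead SNPs in independent cohorts.

Each lead SNP carries the direction of effect of its protective allele
from discovery. In every replication cohort where the SNP (or a
caller-designated high-LD proxy, r² > 0.8 and D' = 1 when an LD table is
supplied) is available, the cohort's two-sided P is converted to a
one-sided P that is small only when the replication effect direction
matches discovery. One-sided P values are combined across cohorts with
Stouffer's method (equal weights), and the combined values are corrected
across the lead-SNP set with the Benjamini–Liu step-down procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .fdr import bl_adjust
from .overlap import one_sided_p
from .sumstats_io import LdTable, SnpRecord, SummaryTable

logger = logging.getLogger("igwas")


@dataclass(frozen=True)
class DiscoveryLead:
    """A lead SNP from discovery: id, protective allele, and the direction
    of that allele's effect in the discovery study ('+' = enriched in the
    long-lived group)."""

    snp_id: str
    protective_allele: str = ""
    other_allele: str = ""
    direction: str = "+"


@dataclass
class ReplicationResult:
    """Per-lead-SNP replication summary."""

    snp_id: str
    cohorts: list[str] = field(default_factory=list)
    one_sided: dict[str, float] = field(default_factory=dict)
    proxies_used: dict[str, str] = field(default_factory=dict)
    combined_p: float | None = None
    adjusted_p: float | None = None
    replicated: bool = False
    untestable: bool = False


def stouffer_combine(p_one_sided) -> float:
    """Stouffer's method with equal weights: 1 − Φ(Σ Φ⁻¹(1−p_i) / √k).

    Strictly increasing in each input; the identity at k = 1. P values of
    exactly 0 or 1 are errors (clamping is an I/O concern).
    """
    p = np.asarray(p_one_sided, dtype=float)
    if p.size == 0:
        raise ValueError("stouffer_combine requires at least one P value")
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValueError("all P values must lie strictly in (0, 1)")
    z = stats.norm.isf(p)  # Φ⁻¹(1−p)
    return float(stats.norm.sf(np.sum(z) / np.sqrt(p.size)))


def _cohort_record(
    lead: DiscoveryLead,
    cohort: SummaryTable,
    proxy_map: dict[str, str] | None,
    ld: LdTable | None,
) -> tuple[SnpRecord | None, str | None]:
    """The cohort's record for a lead SNP, via proxy if designated.

    Returns (record, proxy_id or None). A proxy is accepted only if it
    passes the LD quality bar (r² > 0.8 and D' = 1) when an LD table is
    available; D' absent from the table is not held against the proxy.
    """
    if lead.snp_id in cohort:
        return cohort[lead.snp_id], None
    proxy = (proxy_map or {}).get(lead.snp_id)
    if proxy is None or proxy not in cohort:
        return None, None
    if ld is not None:
        r2 = ld.r2(lead.snp_id, proxy)
        dprime = ld.dprime(lead.snp_id, proxy)
        if r2 <= 0.8 or (dprime is not None and dprime != 1.0):
            logger.warning(
                "proxy %s for %s fails LD quality (r2=%.3g, D'=%s); skipped",
                proxy, lead.snp_id, r2, dprime,
            )
            return None, None
    return cohort[proxy], proxy


def _concordance(lead: DiscoveryLead, record: SnpRecord) -> str:
    """Direction concordance of a cohort record with the discovery lead,
    aligning the cohort's effect allele onto the protective allele."""
    if lead.direction == "unknown" or record.effect_direction == "unknown":
        return "unknown"
    direction = record.effect_direction
    if lead.protective_allele and record.effect_allele:
        if record.effect_allele == lead.protective_allele:
            pass
        elif lead.other_allele and record.effect_allele == lead.other_allele:
            direction = {"+": "-", "-": "+"}[direction]
        elif record.other_allele == lead.protective_allele:
            direction = {"+": "-", "-": "+"}[direction]
        else:
            return "unknown"
    return "same" if direction == lead.direction else "opposite"


def replication_report(
    discovery: list[DiscoveryLead],
    cohorts: list[SummaryTable],
    proxy_map: dict[str, str] | None = None,
    ld: LdTable | None = None,
    fdr_level: float = 0.05,
) -> list[ReplicationResult]:
    """One-sided replication of each lead SNP across cohorts.

    SNPs absent from every cohort (with no acceptable proxy) are flagged
    untestable and excluded from the multiple-testing correction; all
    others get a Stouffer combined P and a Benjamini–Liu adjusted P at
    ``fdr_level``.
    """
    results = []
    for lead in discovery:
        result = ReplicationResult(snp_id=lead.snp_id)
        for cohort in cohorts:
            record, proxy = _cohort_record(lead, cohort, proxy_map, ld)
            if record is None:
                continue
            concordance = _concordance(lead, record)
            if concordance == "unknown":
                logger.warning(
                    "%s in %s: direction unknown, using two-sided P",
                    lead.snp_id, cohort.study_name,
                )
                p1 = record.p_two_sided
            else:
                p1 = one_sided_p(record.p_two_sided, concordance)
            result.cohorts.append(cohort.study_name)
            result.one_sided[cohort.study_name] = p1
            if proxy is not None:
                result.proxies_used[cohort.study_name] = proxy
        if not result.one_sided:
            result.untestable = True
            logger.warning(
                "%s: absent from every replication cohort (no proxy); untestable",
                lead.snp_id,
            )
        else:
            result.combined_p = stouffer_combine(list(result.one_sided.values()))
        results.append(result)

    testable = [r for r in results if not r.untestable]
    if testable:
        reject, adjusted = bl_adjust(
            np.array([r.combined_p for r in testable]), q=fdr_level
        )
        for result, rej, adj in zip(testable, reject, adjusted):
            result.adjusted_p = float(adj)
            result.replicated = bool(rej)
    return results
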