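"""Reading, writing and harmonizing GWAS summary-statistic and LD tables.

Summary statistics are tab-separated text with a header. Canonical column
names are ``snp, chr, pos, effect_allele, other_allele, p, direction, n``;
a *dialect* mapping renames arbitrary source headers onto these. LD tables
are tab-separated ``snp_a, snp_b, r2[, dprime]``; block assignments are
``snp, block``.

Positions are 1-based (dbSNP convention) and are carried but never used in
computation: LD tables are authoritative for linkage. Allele strings are
uppercased on read; strand flips are never attempted, so strand-ambiguous
(A/T, C/G) SNPs pass through unchanged.
"""

from __future__ import annotations

import logging
import math
import sys
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger("igwas")

#: Canonical summary-statistic columns. Only ``snp`` and ``p`` are mandatory.
CANONICAL_COLUMNS = (
    "snp", "chr", "pos", "effect_allele", "other_allele", "p", "direction", "n",
)

#: Smallest value a P of exactly zero is clamped to on read.
MIN_P = sys.float_info.min

DIRECTION_VALUES = ("+", "-", "unknown")


class ValidationError(ValueError):
    """Input data violates an invariant (duplicate ids, out-of-range values)."""


class ConfigurationError(ValueError):
    """Input file/dialect mismatch (missing columns, unreadable file)."""


@dataclass(frozen=True)
class SnpRecord:
    """One SNP's summary statistics in one study.

    ``p_two_sided`` is the two-sided association P value in (0, 1];
    ``effect_direction`` is the sign of the effect of ``effect_allele``
    ('+', '-', or 'unknown' -- several published meta-analyses do not
    report direction).
    """

    snp_id: str
    p_two_sided: float
    chrom: str = ""
    pos: int = 0
    effect_allele: str = ""
    other_allele: str = ""
    effect_direction: str = "unknown"
    n: int | None = None

    def __post_init__(self) -> None:
        if not self.snp_id:
            raise ValidationError("snp_id must be nonempty")
        if not (0.0 < self.p_two_sided <= 1.0):
            raise ValidationError(
                f"{self.snp_id}: p_two_sided={self.p_two_sided} outside (0, 1]"
            )
        if self.effect_direction not in DIRECTION_VALUES:
            raise ValidationError(
                f"{self.snp_id}: direction {self.effect_direction!r} not in "
                f"{DIRECTION_VALUES}"
            )


@dataclass
class SummaryTable:
    """Keyed collection of :class:`SnpRecord` for one study.

    ``s_total`` is the number of SNPs tested genome-wide in the study,
    which may exceed ``len(records)`` when the table is a filtered slice;
    it is the ``S`` that sets the per-test threshold q = 1/S downstream.
    """

    study_name: str = ""
    records: dict[str, SnpRecord] = field(default_factory=dict)
    n_total: int | None = None
    s_total: int | None = None

    def __post_init__(self) -> None:
        if self.s_total is not None and self.s_total < len(self.records):
            raise ValidationError(
                f"s_total={self.s_total} < number of records {len(self.records)}"
            )

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self.records

    def __getitem__(self, snp_id: str) -> SnpRecord:
        return self.records[snp_id]

    def add(self, record: SnpRecord) -> None:
        if record.snp_id in self.records:
            raise ValidationError(f"duplicate snp_id: {record.snp_id}")
        if self.s_total is not None and len(self.records) >= self.s_total:
            raise ValidationError(
                f"table already holds s_total={self.s_total} records"
            )
        self.records[record.snp_id] = record

    @property
    def snp_ids(self) -> list[str]:
        return list(self.records)

    @property
    def effective_s(self) -> int:
        """``s_total`` if set, else the number of records."""
        return self.s_total if self.s_total is not None else len(self.records)


@dataclass
class LdTable:
    """Pairwise r²/D' lookup plus optional LD-block labels.

    Lookups are symmetric in the pair; a pair absent from the table is
    treated as unlinked (r² = 0).
    """

    pairs: dict[tuple[str, str], tuple[float, float | None]] = field(
        default_factory=dict
    )
    blocks: dict[str, str] = field(default_factory=dict)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add_pair(self, a: str, b: str, r2: float, dprime: float | None = None) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise ValidationError(f"r2={r2} for ({a}, {b}) outside [0, 1]")
        if dprime is not None and not (0.0 <= dprime <= 1.0):
            raise ValidationError(f"dprime={dprime} for ({a}, {b}) outside [0, 1]")
        self.pairs[self._key(a, b)] = (float(r2), dprime)

    def r2(self, a: str, b: str) -> float:
        pair = self.pairs.get(self._key(a, b))
        return pair[0] if pair is not None else 0.0

    def dprime(self, a: str, b: str) -> float | None:
        pair = self.pairs.get(self._key(a, b))
        return pair[1] if pair is not None else None

    def block_of(self, snp_id: str) -> str | None:
        return self.blocks.get(snp_id)


# ---------------------------------------------------------------------------
# summary-statistic I/O


def _apply_dialect(df: pd.DataFrame, dialect: Mapping[str, str] | None) -> pd.DataFrame:
    if dialect:
        # dialect maps source header -> canonical name
        df = df.rename(columns=dict(dialect))
    return df


def read_summary_table(
    path,
    dialect: Mapping[str, str] | None = None,
    study_name: str = "",
    n_total: int | None = None,
    s_total: int | None = None,
) -> SummaryTable:
    """Read a tab-separated summary-statistic table.

    Rows whose P value is unparseable or outside (0, 1] are rejected and
    counted in the log; P values of exactly 0 are clamped to the smallest
    positive float with a warning (downstream log/quantile transforms must
    not see zero). A missing ``direction`` column yields 'unknown'.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except FileNotFoundError:
        raise ConfigurationError(f"file not found: {path}") from None
    df = _apply_dialect(df, dialect)
    for col in ("snp", "p"):
        if col not in df.columns:
            raise ConfigurationError(
                f"{path}: required column {col!r} missing "
                f"(have {list(df.columns)}; check the dialect mapping)"
            )

    table = SummaryTable(
        study_name=study_name or str(path), n_total=n_total, s_total=None
    )
    n_rejected = n_clamped = 0
    for raw in df.to_dict("records"):
        def get(name):
            value = raw.get(name)
            if value is None or (isinstance(value, float) and math.isnan(value)):
                return None
            return value

        try:
            p = float(get("p"))
        except (TypeError, ValueError):
            n_rejected += 1
            continue
        if math.isnan(p) or p < 0.0 or p > 1.0:
            n_rejected += 1
            continue
        if p == 0.0:
            p = MIN_P
            n_clamped += 1
        direction = get("direction")
        if direction is None:
            direction = "unknown"
        elif direction not in DIRECTION_VALUES:
            # a signed beta column is reduced to its sign
            try:
                direction = "+" if float(direction) >= 0 else "-"
            except ValueError:
                direction = "unknown"
        n_raw = get("n")
        record = SnpRecord(
            snp_id=str(get("snp")),
            p_two_sided=p,
            chrom=str(get("chr") or ""),
            pos=int(float(get("pos"))) if get("pos") not in (None, "") else 0,
            effect_allele=str(get("effect_allele") or "").upper(),
            other_allele=str(get("other_allele") or "").upper(),
            effect_direction=direction,
            n=int(float(n_raw)) if n_raw not in (None, "") else None,
        )
        table.add(record)
    table.s_total = s_total
    if n_rejected:
        logger.warning("%s: rejected %d rows with invalid P", path, n_rejected)
    if n_clamped:
        logger.warning("%s: clamped %d rows with P=0 to %.3g", path, n_clamped, MIN_P)
    return table


def write_summary_table(table: SummaryTable, path) -> None:
    """Write a :class:`SummaryTable` in the canonical tab-separated format."""
    rows = [
        {
            "snp": r.snp_id,
            "chr": r.chrom,
            "pos": r.pos,
            "effect_allele": r.effect_allele,
            "other_allele": r.other_allele,
            "p": r.p_two_sided,
            "direction": r.effect_direction,
            "n": "" if r.n is None else r.n,
        }
        for r in table.records.values()
    ]
    pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# study intersection


@dataclass(frozen=True)
class PairedRecord:
    """A SNP present in two studies, with a direction-concordance flag.

    ``concordance`` is 'same'/'opposite'/'unknown', computed after aligning
    the second study's alleles onto the first's (if b's effect allele equals
    a's other allele, b's direction is flipped before comparison).
    """

    snp_id: str
    a: SnpRecord
    b: SnpRecord
    concordance: str


def _flip(direction: str) -> str:
    return {"+": "-", "-": "+"}.get(direction, "unknown")


def intersect_studies(
    a: SummaryTable, b: SummaryTable
) -> list[PairedRecord]:
    """Pair records on shared snp_id, aligning effect alleles.

    Shared ids whose allele sets are incompatible (neither a match nor a
    swap) are excluded and counted in the log. Records without allele
    information pass through with alleles assumed aligned.
    """
    pairs: list[PairedRecord] = []
    n_incompatible = 0
    for snp_id, rec_a in a.records.items():
        rec_b = b.records.get(snp_id)
        if rec_b is None:
            continue
        dir_b = rec_b.effect_direction
        if rec_a.effect_allele and rec_b.effect_allele:
            if (rec_b.effect_allele, rec_b.other_allele) == (
                rec_a.effect_allele, rec_a.other_allele,
            ):
                pass
            elif (rec_b.effect_allele, rec_b.other_allele) == (
                rec_a.other_allele, rec_a.effect_allele,
            ):
                dir_b = _flip(dir_b)
            else:
                n_incompatible += 1
                continue
        if "unknown" in (rec_a.effect_direction, dir_b):
            concordance = "unknown"
        elif rec_a.effect_direction == dir_b:
            concordance = "same"
        else:
            concordance = "opposite"
        pairs.append(
            PairedRecord(
                snp_id=snp_id,
                a=rec_a,
                b=replace(rec_b, effect_direction=dir_b)
                if dir_b != rec_b.effect_direction
                else rec_b,
                concordance=concordance,
            )
        )
    if n_incompatible:
        logger.warning(
            "intersect(%s, %s): excluded %d shared SNPs with incompatible alleles",
            a.study_name, b.study_name, n_incompatible,
        )
    return pairs


# ---------------------------------------------------------------------------
# LD I/O


def read_ld_table(path, blocks_path=None) -> LdTable:
    """Read a tab-separated LD table (``snp_a, snp_b, r2[, dprime]``).

    ``blocks_path``, if given, is a two-column ``snp, block`` table of
    LD-block labels.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("snp_a", "snp_b", "r2"):
        if col not in df.columns:
            raise ConfigurationError(f"{path}: required column {col!r} missing")
    table = LdTable()
    has_dprime = "dprime" in df.columns
    for row in df.itertuples(index=False):
        dprime = float(row.dprime) if has_dprime and not pd.isna(row.dprime) else None
        table.add_pair(str(row.snp_a), str(row.snp_b), float(row.r2), dprime)
    if blocks_path is not None:
        table.blocks.update(read_blocks(blocks_path))
    return table


def read_blocks(path) -> dict[str, str]:
    """Read a two-column ``snp, block`` LD-block assignment table."""
    df = pd.read_csv(path, sep="\t")
    for col in ("snp", "block"):
        if col not in df.columns:
            raise ConfigurationError(f"{path}: required column {col!r} missing")
    return {str(r.snp): str(r.block) for r in df.itertuples(index=False)}


def write_ld_table(table: LdTable, path, blocks_path=None) -> None:
    rows = [
        {"snp_a": a, "snp_b": b, "r2": r2, "dprime": "" if d is None else d}
        for (a, b), (r2, d) in table.pairs.items()
    ]
    pd.DataFrame(rows, columns=["snp_a", "snp_b", "r2", "dprime"]).to_csv(
        path, sep="\t", index=False
    )
    if blocks_path is not None and table.blocks:
        pd.DataFrame(
            [{"snp": s, "block": b} for s, b in table.blocks.items()]
        ).to_csv(blocks_path, sep="\t", index=False)


def table_from_records(
    records: Iterable[SnpRecord], study_name: str = "", **kwargs
) -> SummaryTable:
    """Build a :class:`SummaryTable` from an iterable of records."""
    table = SummaryTable(study_name=study_name, **kwargs)
    for record in records:
        table.add(record)
    return table
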