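"""Reading, validating and writing GWAS summary-statistic tables.

The canonical on-disk dialect is tab-delimited UTF-8 with one header row and
columns ``snp_id  chrom  pos  effect_allele  other_allele  eaf  beta  se
pval  n``.  Missing effect-allele frequency is encoded as ``NA``.  Positions
are 1-based; the genome build is treated as metadata only — every join in the
pipeline is on ``snp_id``.

Exclusion ledgers are JSON lines, one :class:`ExclusionEntry` per line, so a
run's filtering decisions can be audited and replayed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError, ValidationError

VALID_ALLELES = frozenset("ACGT")

CANONICAL_COLUMNS = (
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
)

EXCLUSION_REASONS = frozenset(
    {
        "linkage_disequilibrium",
        "confounder_associated",
        "outcome_associated",
        "palindromic_ambiguous",
        "allele_mismatch",
        "user_supplied",
    }
)


@dataclass(frozen=True)
class GwasSummaryRecord:
    """One SNP's association summary in one GWAS.

    ``beta`` is the log-odds effect per copy of ``effect_allele``; ``n`` is the
    total (cases + controls) sample size and feeds the instrument-strength
    F-statistic.  ``eaf`` may be ``None`` when the source table omits it.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pval: float
    n: int

    def __post_init__(self) -> None:
        ea = self.effect_allele.upper()
        oa = self.other_allele.upper()
        object.__setattr__(self, "effect_allele", ea)
        object.__setattr__(self, "other_allele", oa)
        if ea not in VALID_ALLELES or oa not in VALID_ALLELES:
            raise ValidationError(
                f"{self.snp_id}: alleles must be single bases A/C/G/T, "
                f"got {ea!r}/{oa!r} (indels are not supported)"
            )
        if ea == oa:
            raise ValidationError(f"{self.snp_id}: effect and other allele are identical ({ea})")
        if not (self.se > 0):
            raise ValidationError(f"{self.snp_id}: se must be positive, got {self.se}")
        if not (0 < self.pval <= 1):
            raise ValidationError(f"{self.snp_id}: pval must lie in (0,1], got {self.pval}")
        if self.eaf is not None and not (0 < self.eaf < 1):
            raise ValidationError(f"{self.snp_id}: eaf must lie in (0,1), got {self.eaf}")
        if self.n <= 0:
            raise ValidationError(f"{self.snp_id}: n must be positive, got {self.n}")

    @property
    def is_palindromic(self) -> bool:
        """A/T or C/G variants cannot be strand-resolved from alleles alone."""
        return {self.effect_allele, self.other_allele} in ({"A", "T"}, {"C", "G"})


@dataclass(frozen=True)
class ExclusionEntry:
    """One removal event in the filter ledger."""

    snp_id: str
    reason: str
    detail: str = ""

    def __post_init__(self) -> None:
        if self.reason not in EXCLUSION_REASONS:
            raise ValidationError(
                f"unknown exclusion reason {self.reason!r}; "
                f"expected one of {sorted(EXCLUSION_REASONS)}"
            )


def read_gwas_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> list[GwasSummaryRecord]:
    """Read a tab-delimited summary table into validated records.

    Parameters
    ----------
    path
        Tab-delimited file with one header row.
    column_map
        Optional mapping from canonical field name (e.g. ``effect_allele``)
        to the source file's column name (e.g. ``EA``).  Unmapped fields are
        looked up under their canonical names.

    Input row order is preserved.  Every malformed row is rejected with its
    1-based data-row number; rejection is never silent.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"summary table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA"], keep_default_na=False)

    column_map = dict(column_map or {})
    rename = {}
    for canonical in CANONICAL_COLUMNS:
        source = column_map.get(canonical, canonical)
        if source not in df.columns:
            raise ConfigurationError(
                f"{path}: required column {source!r} (field {canonical!r}) "
                f"is missing; available columns: {list(df.columns)}"
            )
        rename[source] = canonical
    df = df.rename(columns=rename)[list(CANONICAL_COLUMNS)]

    records: list[GwasSummaryRecord] = []
    problems: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            eaf = None if pd.isna(row.eaf) or row.eaf == "" else float(row.eaf)
            rec = GwasSummaryRecord(
                snp_id=str(row.snp_id),
                chrom=str(row.chrom),
                pos=int(row.pos),
                effect_allele=str(row.effect_allele),
                other_allele=str(row.other_allele),
                eaf=eaf,
                beta=float(row.beta),
                se=float(row.se),
                pval=float(row.pval),
                n=int(float(row.n)),
            )
        except (ValueError, TypeError, ValidationError) as exc:
            problems.append(f"row {i}: {exc}")
            continue
        records.append(rec)
    if problems:
        raise ValidationError(f"{path}: {len(problems)} malformed row(s):\n" + "\n".join(problems))

    seen: dict[str, int] = {}
    dupes = []
    for rec in records:
        seen[rec.snp_id] = seen.get(rec.snp_id, 0) + 1
    dupes = sorted(s for s, c in seen.items() if c > 1)
    if dupes:
        raise ValidationError(f"{path}: duplicate snp_id values: {dupes}")
    return records


def write_gwas_table(records: Iterable[GwasSummaryRecord], path: str | Path) -> Path:
    """Write records in the canonical dialect; round-trips field-for-field.

    Floats are serialized with ``repr`` (17 significant digits), so
    ``read_gwas_table(write_gwas_table(x)) == x`` bitwise.
    """
    path = Path(path)
    lines = ["\t".join(CANONICAL_COLUMNS)]
    for rec in records:
        lines.append(
            "\t".join(
                [
                    rec.snp_id,
                    rec.chrom,
                    str(rec.pos),
                    rec.effect_allele,
                    rec.other_allele,
                    "NA" if rec.eaf is None else repr(rec.eaf),
                    repr(rec.beta),
                    repr(rec.se),
                    repr(rec.pval),
                    str(rec.n),
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def write_exclusion_ledger(entries: Iterable[ExclusionEntry], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for e in entries:
            fh.write(json.dumps(asdict(e)) + "\n")
    return path


def read_exclusion_ledger(path: str | Path) -> list[ExclusionEntry]:
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"exclusion ledger not found: {path}")
    entries = []
    for line in path.read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        d = json.loads(line)
        entries.append(ExclusionEntry(snp_id=d["snp_id"], reason=d["reason"], detail=d.get("detail", "")))
    return entries
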