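"""Instrument selection and strength diagnostics.

Valid instruments are exposure-GWAS hits that survive, in order:

1. genome-wide significance (``p < 5e-8``, strict),
2. greedy LD pruning at ``r^2 < 0.001`` against an externally supplied
   pairwise-r^2 matrix (no reference-panel computation here),
3. a curated exclusion list (confounder- or outcome-associated SNPs),
   frozen as input so a run is reproducible regardless of database drift.

Strength is quantified per SNP by the variance explained

    r^2 = 2 beta^2 q(1-q) / (2 beta^2 q(1-q) + 2 n q(1-q) se^2)

(with q the effect-allele frequency; algebraically beta^2/(beta^2 + n se^2))
and the F-statistic F = r^2 (N-2)/(1-r^2).  F > 10 is the conventional
weak-instrument floor; strong sets report min F well above 30.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import EstimationError, ValidationError
from .summary_io import ExclusionEntry, GwasSummaryRecord

DEFAULT_P_THRESHOLD = 5e-8
DEFAULT_LD_R2_THRESHOLD = 0.001


@dataclass(frozen=True)
class InstrumentStrength:
    snp_id: str
    r2: float
    f_stat: float


@dataclass(frozen=True)
class LdMatrix:
    """Pairwise r^2 between candidate instruments, in a fixed SNP order."""

    snp_ids: tuple[str, ...]
    r2: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.r2, dtype=float)
        k = len(self.snp_ids)
        if m.shape != (k, k):
            raise ValidationError(f"LD matrix shape {m.shape} does not match {k} SNP ids")
        if not np.allclose(m, m.T):
            raise ValidationError("LD matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0):
            raise ValidationError("LD matrix diagonal must be 1")
        if (m < 0).any() or (m > 1).any():
            raise ValidationError("LD r^2 values must lie in [0,1]")
        object.__setattr__(self, "r2", m)
        object.__setattr__(self, "snp_ids", tuple(self.snp_ids))

    def lookup(self, a: str, b: str) -> float:
        try:
            i = self.snp_ids.index(a)
            j = self.snp_ids.index(b)
        except ValueError as exc:
            raise ValidationError(f"SNP absent from LD matrix: {exc}") from exc
        return float(self.r2[i, j])


def read_ld_matrix(path) -> LdMatrix:
    """Read a square tab-delimited r^2 matrix with snp_id header row/column."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValidationError("LD matrix header row and column must list the same SNPs in order")
    return LdMatrix(snp_ids=tuple(df.columns), r2=df.to_numpy(dtype=float))


def filter_significant(
    records: Sequence[GwasSummaryRecord],
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> tuple[list[GwasSummaryRecord], list[ExclusionEntry]]:
    """Keep SNPs with ``pval < p_threshold`` (strict).

    Sub-threshold SNPs are simply not instruments; they are not exclusion
    events, so the returned ledger is always empty.
    """
    if not (0 < p_threshold < 1):
        raise ValidationError(f"p_threshold must be in (0,1), got {p_threshold}")
    kept = [r for r in records if r.pval < p_threshold]
    return kept, []


def _prune_order_key(rec: GwasSummaryRecord):
    # lowest p first; ties broken by genomic coordinate then id for determinism
    return (rec.pval, rec.chrom, rec.pos, rec.snp_id)


def ld_prune(
    records: Sequence[GwasSummaryRecord],
    ld: LdMatrix,
    r2_threshold: float = DEFAULT_LD_R2_THRESHOLD,
) -> tuple[list[GwasSummaryRecord], list[ExclusionEntry]]:
    """Greedy LD pruning: accept SNPs in ascending-pval order, rejecting any
    whose r^2 with an already-accepted SNP reaches the threshold.

    The kept set is pairwise independent (all r^2 < threshold) and maximal
    under the greedy order.  Rejections are ledgered with the conflicting
    accepted SNP named.
    """
    missing = [r.snp_id for r in records if r.snp_id not in ld.snp_ids]
    if missing:
        raise ValidationError(f"SNP(s) absent from LD matrix: {missing}")

    accepted: list[GwasSummaryRecord] = []
    ledger: list[ExclusionEntry] = []
    for rec in sorted(records, key=_prune_order_key):
        conflict = next(
            (a for a in accepted if ld.lookup(rec.snp_id, a.snp_id) >= r2_threshold), None
        )
        if conflict is None:
            accepted.append(rec)
        else:
            ledger.append(
                ExclusionEntry(
                    snp_id=rec.snp_id,
                    reason="linkage_disequilibrium",
                    detail=f"r2 >= {r2_threshold} with accepted SNP {conflict.snp_id}",
                )
            )
    # restore input order among kept SNPs
    kept_ids = {r.snp_id for r in accepted}
    kept = [r for r in records if r.snp_id in kept_ids]
    return kept, ledger


def apply_exclusions(
    records: Sequence[GwasSummaryRecord],
    exclusions: Iterable[ExclusionEntry],
) -> tuple[list[GwasSummaryRecord], list[ExclusionEntry]]:
    """Remove SNPs named in a curated exclusion list.

    Exclusions naming SNPs absent from ``records`` are recorded as no-ops
    (detail suffixed) rather than errors, so one ledger can serve several
    source tables.
    """
    by_id: dict[str, ExclusionEntry] = {}
    for e in exclusions:
        by_id.setdefault(e.snp_id, e)
    present = {r.snp_id for r in records}
    ledger: list[ExclusionEntry] = []
    for e in by_id.values():
        if e.snp_id in present:
            ledger.append(e)
        else:
            ledger.append(
                ExclusionEntry(e.snp_id, e.reason, (e.detail + " [not present: no-op]").strip())
            )
    kept = [r for r in records if r.snp_id not in by_id]
    return kept, ledger


def variance_explained(record: GwasSummaryRecord) -> float:
    """Proportion of exposure variance explained by one SNP.

    Uses the standardized-effect approximation
    ``r2 = 2 b^2 q(1-q) / (2 b^2 q(1-q) + 2 n q(1-q) se^2)``.
    Requires the effect-allele frequency.
    """
    if record.eaf is None:
        raise ValidationError(
            f"{record.snp_id}: effect-allele frequency required to compute variance explained"
        )
    q = record.eaf
    num = 2.0 * record.beta**2 * q * (1.0 - q)
    den = num + 2.0 * record.n * q * (1.0 - q) * record.se**2
    return num / den


def f_statistic(r2: float, n: int) -> float:
    """Instrument F-statistic: ``F = r2 (N-2) / (1 - r2)``."""
    if not (0 <= r2 < 1):
        raise ValidationError(f"r2 must lie in [0,1), got {r2}")
    if n < 3:
        raise ValidationError(f"n must be at least 3, got {n}")
    return r2 * (n - 2) / (1.0 - r2)


def instrument_strengths(records: Sequence[GwasSummaryRecord]) -> list[InstrumentStrength]:
    """Per-SNP r^2 and F for a validated instrument set."""
    out = []
    for rec in records:
        r2 = variance_explained(rec)
        out.append(InstrumentStrength(rec.snp_id, r2, f_statistic(r2, rec.n)))
    return out


def instrument_summary(strengths: Sequence[InstrumentStrength]) -> tuple[float, float]:
    """(total variance explained, minimum F) over an instrument set."""
    if not strengths:
        raise EstimationError("instrument_summary requires at least one instrument")
    total_r2 = float(sum(s.r2 for s in strengths))
    min_f = float(min(s.f_stat for s in strengths))
    return total_r2, min_f


def select_instruments(
    records: Sequence[GwasSummaryRecord],
    ld: LdMatrix,
    exclusions: Iterable[ExclusionEntry] = (),
    p_threshold: float = DEFAULT_P_THRESHOLD,
    r2_threshold: float = DEFAULT_LD_R2_THRESHOLD,
) -> tuple[list[GwasSummaryRecord], list[ExclusionEntry]]:
    """Full selection cascade: significance -> LD pruning -> curated exclusions.

    The order is fixed and the combined ledger is complete: every candidate is
    either kept or appears in the ledger (sub-significance SNPs never become
    candidates).
    """
    sig, _ = filter_significant(records, p_threshold)
    pruned, led_ld = ld_prune(sig, ld, r2_threshold)
    kept, led_ex = apply_exclusions(pruned, exclusions)
    return kept, led_ld + led_ex
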