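"""Allele harmonization: express exposure and outcome effects on one allele.

Two GWAS may report the same SNP on different effect alleles or opposite
strands.  Harmonization rewrites the outcome association onto the exposure's
effect allele: a swapped effect/other pair negates the outcome beta and
reflects its frequency; a strand complement relabels alleles before the same
check.  Palindromic variants (A/T, C/G) cannot be strand-resolved from
alleles alone; they are oriented by allele-frequency concordance when the
frequency is informative, and dropped when it is within the ambiguity window
of 0.5 (default 0.08) or missing.

Standard errors are never altered — harmonization flips signs only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

from .errors import ValidationError
from .summary_io import ExclusionEntry, GwasSummaryRecord

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

DEFAULT_PALINDROME_EAF_WINDOW = 0.08

DROP_ACTIONS = frozenset({"dropped_palindromic", "dropped_mismatch"})


@dataclass(frozen=True)
class HarmonizedInstrument:
    """One SNP's exposure and outcome effects on a shared effect allele."""

    snp_id: str
    effect_allele: str
    other_allele: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: float | None
    eaf_out: float | None
    action: str

    @property
    def dropped(self) -> bool:
        return self.action in DROP_ACTIONS


def _is_palindromic(a1: str, a2: str) -> bool:
    return {a1, a2} in ({"A", "T"}, {"C", "G"})


def align_alleles(
    exposure: GwasSummaryRecord,
    outcome: GwasSummaryRecord,
    palindrome_eaf_window: float = DEFAULT_PALINDROME_EAF_WINDOW,
) -> HarmonizedInstrument:
    """Harmonize one exposure/outcome record pair.

    Cases, checked in order:

    * palindromic SNP with ambiguous (near-0.5 or missing) frequency in either
      study -> ``dropped_palindromic``;
    * identical alleles -> ``none``;
    * swapped alleles -> negate outcome beta, reflect eaf, ``swap_flip``;
    * strand complements of the above -> relabel then as above,
      ``strand_complement`` / ``strand_complement_swap_flip``;
    * anything else -> ``dropped_mismatch``.

    For a palindromic SNP outside the ambiguity window the complement branch
    is indistinguishable from identity/swap by alleles alone, so orientation
    falls to frequency concordance: discordant sides of 0.5 imply the outcome
    is reported on the opposite strand's allele and the beta sign flips.
    """
    if exposure.snp_id != outcome.snp_id:
        raise ValidationError(
            f"snp_id mismatch: exposure {exposure.snp_id!r} vs outcome {outcome.snp_id!r}"
        )

    e1, e2 = exposure.effect_allele, exposure.other_allele
    o1, o2 = outcome.effect_allele, outcome.other_allele

    def build(beta_out, eaf_out, action):
        return HarmonizedInstrument(
            snp_id=exposure.snp_id,
            effect_allele=e1,
            other_allele=e2,
            beta_exp=exposure.beta,
            se_exp=exposure.se,
            beta_out=beta_out,
            se_out=outcome.se,
            eaf_exp=exposure.eaf,
            eaf_out=eaf_out,
            action=action,
        )

    if _is_palindromic(e1, e2):
        freqs = [f for f in (exposure.eaf, outcome.eaf)]
        if any(f is None for f in freqs) or any(
            abs(f - 0.5) < palindrome_eaf_window for f in freqs
        ):
            return build(outcome.beta, outcome.eaf, "dropped_palindromic")
        # orient by frequency concordance; alleles cannot distinguish strands
        same_label = (o1, o2) in ((e1, e2), (COMPLEMENT[e1], COMPLEMENT[e2]))
        swapped_label = (o1, o2) in ((e2, e1), (COMPLEMENT[e2], COMPLEMENT[e1]))
        if not (same_label or swapped_label):
            return build(outcome.beta, outcome.eaf, "dropped_mismatch")
        eaf_out = outcome.eaf if same_label else 1.0 - outcome.eaf
        beta_out = outcome.beta if same_label else -outcome.beta
        concordant = (exposure.eaf > 0.5) == (eaf_out > 0.5)
        if concordant:
            return build(beta_out, eaf_out, "none" if same_label else "swap_flip")
        return build(
            -beta_out,
            1.0 - eaf_out,
            "strand_complement" if same_label else "strand_complement_swap_flip",
        )

    if (o1, o2) == (e1, e2):
        return build(outcome.beta, outcome.eaf, "none")
    if (o1, o2) == (e2, e1):
        eaf = None if outcome.eaf is None else 1.0 - outcome.eaf
        return build(-outcome.beta, eaf, "swap_flip")

    c1, c2 = COMPLEMENT[o1], COMPLEMENT[o2]
    if (c1, c2) == (e1, e2):
        return build(outcome.beta, outcome.eaf, "strand_complement")
    if (c1, c2) == (e2, e1):
        eaf = None if outcome.eaf is None else 1.0 - outcome.eaf
        return build(-outcome.beta, eaf, "strand_complement_swap_flip")

    return build(outcome.beta, outcome.eaf, "dropped_mismatch")


def harmonize_set(
    exposure_records: Sequence[GwasSummaryRecord],
    outcome_records: Sequence[GwasSummaryRecord],
    palindrome_eaf_window: float = DEFAULT_PALINDROME_EAF_WINDOW,
) -> tuple[list[HarmonizedInstrument], list[ExclusionEntry], list[str]]:
    """Inner-join on snp_id and harmonize each pair, in exposure order.

    Returns ``(instruments, drop_ledger, join_misses)``; dropped pairs go to
    the ledger with a reason code and exposure SNPs absent from the outcome
    table are listed as join misses.
    """
    out_by_id = {r.snp_id: r for r in outcome_records}
    instruments: list[HarmonizedInstrument] = []
    ledger: list[ExclusionEntry] = []
    misses: list[str] = []
    for exp in exposure_records:
        out = out_by_id.get(exp.snp_id)
        if out is None:
            misses.append(exp.snp_id)
            continue
        h = align_alleles(exp, out, palindrome_eaf_window)
        if h.dropped:
            reason = (
                "palindromic_ambiguous"
                if h.action == "dropped_palindromic"
                else "allele_mismatch"
            )
            ledger.append(ExclusionEntry(h.snp_id, reason, f"harmonization action {h.action}"))
        else:
            instruments.append(h)
    if not instruments and not ledger:
        raise ValidationError("no overlapping instruments between exposure and outcome tables")
    return instruments, ledger, misses
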