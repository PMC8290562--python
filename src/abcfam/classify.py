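"""Family assignment from ranked similarity hits.

A candidate is sorted into an ABC family by, in order of precedence:

1. *4-of-5 vote* — at least 4 of the top 5 hits share one ABC family;
2. *top-3 vote* — the top 3 hits all share one ABC family;
3. *e-value gap* — the top hit is an ABC reference whose e-value is at
   least 5 orders of magnitude below the next-best hit's.

Candidates meeting none of these are not considered ABC transporters.
Reference labels BF and BH (ABC-B full/half) reinforce each other in the
votes as a single "B" super-label; the full/half architecture is then
decided by the number of nucleotide-binding domains on the candidate
(two or more -> BF, one -> BH).  Classified proteins shorter than 250
residues are excluded as fragments.  The proposed ABC-I family is not
part of the reference vocabulary and any such label leads to exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

from .errors import ValidationError
from .io_formats import EXCLUDED, NONABC, ProteinRecord, SimilarityHit

RULE_VOTE_4OF5 = "VOTE_4OF5"
RULE_VOTE_TOP3 = "VOTE_TOP3"
RULE_EVALUE_GAP = "EVALUE_GAP"
RULE_NONE = "NONE"

DEFAULT_MIN_LENGTH = 250
#: Multiplicative reading of "5 orders of magnitude lower".
GAP_FACTOR = 1e-5
#: Bitscore margin standing in for the gap rule when both e-values
#: underflow to zero (the ratio is undefined there).
ZERO_EVALUE_BIT_MARGIN = 50.0

_VOTABLE = {"A", "B", "C", "D", "E", "F", "G", "H"}


@dataclass(frozen=True)
class FamilyCall:
    """Classification verdict for one candidate protein."""

    protein_id: str
    family: str  # A, BF, BH, C..H or EXCLUDED
    rule_used: str
    top_hit_id: str = ""
    top_evalue: Optional[float] = None
    nbd_count: int = 0
    length_filtered: bool = False
    ranked: tuple[SimilarityHit, ...] = ()


def _super_label(family: str) -> str:
    """Collapse ABC-B full/half reference labels for voting purposes."""
    return "B" if family in ("BF", "BH") else family


def rank_hits(hits: Sequence[SimilarityHit]) -> list[SimilarityHit]:
    """Sort hits by significance, keeping one (best) hit per subject.

    Order: ascending e-value, ties by descending bitscore, then
    lexicographic subject id — a total order, so ranking is invariant to
    the input permutation.
    """
    queries = {h.query_id for h in hits}
    if len(queries) > 1:
        raise ValidationError(f"rank_hits mixes queries: {sorted(queries)}")
    best: dict[str, SimilarityHit] = {}
    for hit in hits:
        cur = best.get(hit.subject_id)
        if cur is None or (hit.evalue, -hit.bitscore) < (cur.evalue, -cur.bitscore):
            best[hit.subject_id] = hit
    return sorted(best.values(), key=lambda h: (h.evalue, -h.bitscore, h.subject_id))


def _vote(ranked: Sequence[SimilarityHit]) -> tuple[Optional[str], str]:
    """Apply the 4-of-5 then top-3 consensus rules on super-labels."""
    labels = [_super_label(h.subject_family) for h in ranked]
    if len(labels) >= 5:
        top5 = labels[:5]
        for fam in _VOTABLE:
            if top5.count(fam) >= 4:
                return fam, RULE_VOTE_4OF5
    if len(labels) >= 3:
        top3 = labels[:3]
        if top3[0] == top3[1] == top3[2] and top3[0] in _VOTABLE:
            return top3[0], RULE_VOTE_TOP3
    return None, RULE_NONE


def vote_family(ranked: Sequence[SimilarityHit]) -> Optional[str]:
    """Consensus family from the vote rules, or None (NONABC never wins)."""
    return _vote(ranked)[0]


def gap_rule(ranked: Sequence[SimilarityHit]) -> Optional[str]:
    """Top-hit family when its e-value beats the next best by >= 5 orders.

    The comparison is multiplicative and inclusive: e1 <= e2 * 1e-5.  With
    a single hit the rule fires whenever that hit is an ABC reference.
    When the runner-up e-value is exactly zero the ratio is undefined and
    the rule instead requires both e-values zero plus a bitscore margin of
    at least ``ZERO_EVALUE_BIT_MARGIN`` bits.
    """
    if not ranked:
        return None
    top = ranked[0]
    family = _super_label(top.subject_family)
    if family not in _VOTABLE:
        return None
    if len(ranked) == 1:
        return family
    e1, e2 = top.evalue, ranked[1].evalue
    if e2 == 0.0:
        if e1 == 0.0 and (top.bitscore - ranked[1].bitscore) >= ZERO_EVALUE_BIT_MARGIN:
            return family
        return None
    if e1 <= e2 * GAP_FACTOR:
        return family
    return None


def assign_family(
    protein_id: str,
    ranked: Sequence[SimilarityHit],
    nbd_count: int,
) -> FamilyCall:
    """Full classification of one candidate from its ranked hits.

    The vote rules take precedence over the e-value gap rule; the
    ``rule_used`` field records which path produced the family.  The "B"
    super-label is resolved to BF/BH by ``nbd_count``.
    """
    ranked = list(ranked)
    top_hit_id = ranked[0].subject_id if ranked else ""
    top_evalue = ranked[0].evalue if ranked else None
    family, rule = _vote(ranked)
    if family is None:
        gap = gap_rule(ranked)
        if gap is not None:
            family, rule = gap, RULE_EVALUE_GAP
    if family is None or family == NONABC or family == "I":
        return FamilyCall(
            protein_id=protein_id,
            family=EXCLUDED,
            rule_used=RULE_NONE,
            top_hit_id=top_hit_id,
            top_evalue=top_evalue,
            nbd_count=nbd_count,
            ranked=tuple(ranked),
        )
    if family == "B":
        family = "BF" if nbd_count >= 2 else "BH"
    return FamilyCall(
        protein_id=protein_id,
        family=family,
        rule_used=rule,
        top_hit_id=top_hit_id,
        top_evalue=top_evalue,
        nbd_count=nbd_count,
        ranked=tuple(ranked),
    )


def apply_length_filter(
    calls: Sequence[FamilyCall],
    records: Mapping[str, ProteinRecord] | Sequence[ProteinRecord],
    min_len: int = DEFAULT_MIN_LENGTH,
) -> list[FamilyCall]:
    """Exclude classified proteins shorter than ``min_len`` residues.

    "Under 250 residues" is strict: a 250-residue protein is retained.
    The original rule provenance is preserved and ``length_filtered`` set,
    so excluded fragments remain auditable.
    """
    if not isinstance(records, Mapping):
        records = {rec.protein_id: rec for rec in records}
    out: list[FamilyCall] = []
    for call in calls:
        if call.protein_id not in records:
            raise ValidationError(f"no sequence record for {call.protein_id!r}")
        if call.family != EXCLUDED and len(records[call.protein_id]) < min_len:
            out.append(replace(call, family=EXCLUDED, length_filtered=True))
        else:
            out.append(call)
    return out
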