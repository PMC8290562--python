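"""Independent re-implementations used as test oracles.

These deliberately avoid the code paths they check: the local-alignment
oracle enumerates gap lengths explicitly instead of using the affine
three-state recursion, and the classification oracle re-derives the
voting/gap verdict directly from the rule statements.
"""

import numpy as np


def oracle_local_score(S, gap_open, gap_extend):
    """Best local alignment score by brute-force enumeration.

    E[i, j] is the best score of an alignment ending with residue i
    matched to profile column j; its predecessor is the empty alignment,
    the diagonal cell, or any earlier cell reached across a pure gap in
    one dimension (cost gap_open + (g-1) * gap_extend for gap length g).
    Scores are in the same (half-bit) units as ``S``.
    """
    n, m = S.shape
    E = np.full((n, m), -np.inf)
    best = 0.0
    for i in range(n):
        for j in range(m):
            prev = 0.0
            if i > 0 and j > 0:
                prev = max(prev, E[i - 1, j - 1])
                col = E[: i - 1, j - 1]
                if col.size:
                    g = np.arange(col.size, 0, -1)
                    prev = max(prev, np.max(col + gap_open + (g - 1) * gap_extend))
                row = E[i - 1, : j - 1]
                if row.size:
                    g = np.arange(row.size, 0, -1)
                    prev = max(prev, np.max(row + gap_open + (g - 1) * gap_extend))
            E[i, j] = prev + S[i, j]
            best = max(best, E[i, j])
    return best


def oracle_classification(ranked, nbd_count):
    """Re-derive (family, rule) from ranked hits, straight from the rules.

    Returns (family, rule) where family is None when the candidate is not
    an ABC transporter.  BF/BH reference labels pool as "B"; a "B"
    verdict resolves to BF when nbd_count >= 2, else BH.
    """
    def pool(fam):
        return "B" if fam in ("BF", "BH") else fam

    labels = [pool(h.subject_family) for h in ranked]
    family = rule = None
    if len(labels) >= 5:
        top5 = labels[:5]
        winners = {f for f in set(top5) if top5.count(f) >= 4 and f != "NONABC"}
        if winners:
            family, rule = winners.pop(), "VOTE_4OF5"
    if family is None and len(labels) >= 3:
        if labels[0] == labels[1] == labels[2] != "NONABC":
            family, rule = labels[0], "VOTE_TOP3"
    if family is None and ranked:
        top = ranked[0]
        if pool(top.subject_family) != "NONABC":
            fires = False
            if len(ranked) == 1:
                fires = True
            else:
                e1, e2 = top.evalue, ranked[1].evalue
                if e2 == 0.0:
                    fires = e1 == 0.0 and (top.bitscore - ranked[1].bitscore) >= 50.0
                else:
                    fires = e1 <= e2 * 1e-5
            if fires:
                family, rule = pool(top.subject_family), "EVALUE_GAP"
    if family == "B":
        family = "BF" if nbd_count >= 2 else "BH"
    return family, (rule or "NONE")
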