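"""NBD (nucleotide-binding domain) detection and counting.

Candidate ABC transporters are proteins carrying at least one match to a
nucleotide-binding-domain profile.  Two backends feed this module: parsed
HMMER3 per-domain tables (the production path) and a built-in
position-specific scoring matrix (PSSM) scanned with local Smith-Waterman
alignment, which makes the whole pipeline exercisable without external
binaries.  The built-in scorer is a plain PSSM local aligner, not a full
profile HMM: there are no insert/delete emission states, and its e-values
follow a fixed Karlin-Altschul-shaped formula

    E = 2**(-bitscore) * protein_length * profile_length

rather than a calibrated distribution.  Scores are computed in half-bit
units internally; reported bitscores are in bits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import _align
from .alphabet import AA20, BACKGROUND, X_INDEX, X_SCORE, encode
from .errors import ParseError, ValidationError
from .io_formats import DomainHit, ProteinRecord, ReferenceDB, SimilarityHit

DEFAULT_GAP_OPEN = -11.0  # half-bits
DEFAULT_GAP_EXTEND = -2.0  # half-bits
DEFAULT_PSEUDOCOUNT = 0.5
DEFAULT_SCORE_THRESHOLD = 25.0  # bits

#: Per-domain independent e-value bound used when counting NBDs.
DEFAULT_DOMAIN_IEVALUE = 0.01
#: Maximum allowed overlap between two accepted NBD intervals, as a
#: fraction of the shorter interval.
DEFAULT_MAX_OVERLAP_FRAC = 0.5

_MAX_HITS_PER_PROTEIN = 50


@dataclass
class Profile:
    """Position-specific scoring matrix over the 20 standard residues + X.

    ``match_scores`` has shape (length, 21) in half-bit log-odds against
    the fixed background composition; column 21 is the constant X score.
    """

    length: int
    match_scores: np.ndarray
    gap_open: float = DEFAULT_GAP_OPEN
    gap_extend: float = DEFAULT_GAP_EXTEND
    score_threshold: float = DEFAULT_SCORE_THRESHOLD
    profile_id: str = "NBD_profile"

    def __post_init__(self) -> None:
        self.match_scores = np.asarray(self.match_scores, dtype=np.float64)
        if self.length < 10:
            raise ValidationError("profile length must be >= 10")
        if self.match_scores.shape != (self.length, 21):
            raise ValidationError("match_scores must have shape (length, 21)")
        if self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValidationError("gap penalties must be negative")


@dataclass(frozen=True)
class NbdCount:
    """Number of distinct NBDs on one protein after overlap resolution."""

    protein_id: str
    count: int
    intervals: tuple[tuple[int, int], ...]  # 0-based half-open, disjoint


# ---------------------------------------------------------------------------
# Profile construction and serialization


def build_profile(
    aligned_seqs: Sequence[str],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    *,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
    profile_id: str = "NBD_profile",
) -> Profile:
    """Build a PSSM from equal-length aligned sequences.

    Columns with more than 50% gap characters (``-``) are removed; at
    least 10 columns must remain.  Column probabilities are smoothed with
    ``pseudocount`` times the background frequency, and scores are
    2*log2(p/background) half-bits.
    """
    if len(aligned_seqs) < 2:
        raise ValidationError("need at least 2 aligned sequences")
    ncol = len(aligned_seqs[0])
    if any(len(s) != ncol for s in aligned_seqs):
        raise ValidationError("aligned sequences must have equal length")
    aa_index = {aa: i for i, aa in enumerate(AA20)}
    columns = []
    for j in range(ncol):
        col = [s[j].upper() for s in aligned_seqs]
        if col.count("-") / len(col) > 0.5:
            continue
        columns.append(col)
    if len(columns) < 10:
        raise ValidationError("fewer than 10 usable columns after gap removal")
    scores = np.empty((len(columns), 21))
    for j, col in enumerate(columns):
        counts = np.zeros(20)
        for c in col:
            if c in aa_index:
                counts[aa_index[c]] += 1
        n_obs = counts.sum()
        probs = (counts + pseudocount * BACKGROUND) / (n_obs + pseudocount)
        scores[j, :20] = 2.0 * np.log2(probs / BACKGROUND)
        scores[j, 20] = X_SCORE
    return Profile(
        length=len(columns),
        match_scores=scores,
        gap_open=gap_open,
        gap_extend=gap_extend,
        score_threshold=score_threshold,
        profile_id=profile_id,
    )


def profile_from_sequence(
    sequence: str,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    **kwargs,
) -> Profile:
    """Degenerate single-sequence PSSM (used for pairwise similarity search)."""
    aa_index = {aa: i for i, aa in enumerate(AA20)}
    scores = np.empty((len(sequence), 21))
    for j, c in enumerate(sequence.upper()):
        counts = np.zeros(20)
        if c in aa_index:
            counts[aa_index[c]] = 1.0
        n_obs = counts.sum()
        probs = (counts + pseudocount * BACKGROUND) / (n_obs + pseudocount)
        scores[j, :20] = 2.0 * np.log2(probs / BACKGROUND)
        scores[j, 20] = X_SCORE
    if len(sequence) < 10:
        raise ValidationError("sequence too short for a profile (< 10 residues)")
    return Profile(length=len(sequence), match_scores=scores, **kwargs)


def write_profile(profile: Profile, path: str | Path) -> None:
    """Serialize a profile as a TSV matrix with a 3-line header."""
    with open(path, "w") as fh:
        fh.write(f"#length\t{profile.length}\t{profile.profile_id}\n")
        fh.write(f"#gaps\t{profile.gap_open:.17g}\t{profile.gap_extend:.17g}\n")
        fh.write(f"#threshold\t{profile.score_threshold:.17g}\n")
        for row in profile.match_scores:
            fh.write("\t".join(f"{v:.17g}" for v in row) + "\n")


def read_profile(path: str | Path) -> Profile:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 3 or not all(lines[i].startswith("#") for i in range(3)):
        raise ParseError(f"{path}: expected 3-line profile header")
    h1, h2, h3 = (line.split("\t") for line in lines[:3])
    length = int(h1[1])
    profile_id = h1[2] if len(h1) > 2 else "NBD_profile"
    gap_open, gap_extend = float(h2[1]), float(h2[2])
    threshold = float(h3[1])
    rows = [list(map(float, line.split("\t"))) for line in lines[3:] if line.strip()]
    if len(rows) != length:
        raise ParseError(f"{path}: header says {length} rows, found {len(rows)}")
    return Profile(
        length=length,
        match_scores=np.array(rows),
        gap_open=gap_open,
        gap_extend=gap_extend,
        score_threshold=threshold,
        profile_id=profile_id,
    )


# ---------------------------------------------------------------------------
# Scanning


def _score_matrix(profile: Profile, encoded_seq: np.ndarray) -> np.ndarray:
    """Per-position match scores: rows = sequence residues, cols = profile."""
    return profile.match_scores[:, encoded_seq].T.copy()


def synthetic_evalue(bitscore: float, seq_len: int, profile_len: int) -> float:
    """Karlin-Altschul-shaped e-value with fixed constants."""
    try:
        return float(seq_len) * float(profile_len) * math.pow(2.0, -bitscore)
    except OverflowError:
        return 0.0 if bitscore > 0 else math.inf


def best_local_score(profile: Profile, sequence: str) -> float:
    """Best local alignment score in bits (0 if nothing scores positively)."""
    S = _score_matrix(profile, encode(sequence))
    raw = _align.sw_best_score(S, profile.gap_open, profile.gap_extend)
    return max(0.0, raw) / 2.0


def scan_protein(profile: Profile, record: ProteinRecord) -> list[DomainHit]:
    """Find all local profile matches scoring at least the profile threshold.

    Matches are reported best-score first; after each reported match its
    sequence interval is masked and the protein re-scanned, so reported
    intervals are disjoint.  All hits on a protein share the same
    full-sequence e-value (that of the best match).
    """
    enc = encode(record.sequence)
    S = _score_matrix(profile, enc)
    n = len(record.sequence)
    raw_hits: list[tuple[float, int, int]] = []
    for _ in range(_MAX_HITS_PER_PROTEIN):
        M, Ix, Iy = _align.sw_matrices(S, profile.gap_open, profile.gap_extend)
        flat = int(np.argmax(M))
        end_i, end_j = divmod(flat, M.shape[1])
        best = M[end_i, end_j]
        bits = best / 2.0
        if bits < profile.score_threshold or best <= 0:
            break
        seq_start, seq_end, _, _, _ = _align.traceback(
            M, Ix, Iy, S, profile.gap_open, profile.gap_extend, end_i, end_j
        )
        raw_hits.append((bits, seq_start, seq_end))
        S[seq_start:seq_end, :] = _align.NEG
    if not raw_hits:
        return []
    best_eval = min(
        synthetic_evalue(bits, n, profile.length) for bits, _, _ in raw_hits
    )
    hits = [
        DomainHit(
            protein_id=record.protein_id,
            profile_id=profile.profile_id,
            seq_start=start + 1,
            seq_end=end,
            full_seq_evalue=best_eval,
            domain_ievalue=synthetic_evalue(bits, n, profile.length),
            bitscore=bits,
        )
        for bits, start, end in raw_hits
    ]
    hits.sort(key=lambda h: (-h.bitscore, h.seq_start))
    return hits


def filter_candidates(
    hits: Iterable[DomainHit], evalue_cutoff: float = 10.0
) -> set[str]:
    """Protein ids whose best full-sequence e-value is strictly below cutoff."""
    if evalue_cutoff <= 0:
        raise ValidationError("evalue_cutoff must be > 0")
    best: dict[str, float] = {}
    for hit in hits:
        cur = best.get(hit.protein_id)
        if cur is None or hit.full_seq_evalue < cur:
            best[hit.protein_id] = hit.full_seq_evalue
    return {pid for pid, e in best.items() if e < evalue_cutoff}


def count_nbds(
    hits: Sequence[DomainHit],
    domain_evalue_cutoff: float = DEFAULT_DOMAIN_IEVALUE,
    max_overlap_frac: float = DEFAULT_MAX_OVERLAP_FRAC,
) -> NbdCount:
    """Count distinct NBDs on one protein.

    Hits with per-domain independent e-value below the cutoff are accepted
    greedily by ascending e-value (ties: higher bitscore, then smaller
    start); a hit is rejected when its interval overlaps an accepted one
    by more than ``max_overlap_frac`` of the shorter interval.
    """
    hits = list(hits)
    if not hits:
        return NbdCount(protein_id="", count=0, intervals=())
    ids = {h.protein_id for h in hits}
    if len(ids) != 1:
        raise ValidationError(f"count_nbds mixes protein ids: {sorted(ids)}")
    protein_id = hits[0].protein_id
    eligible = [h for h in hits if h.domain_ievalue < domain_evalue_cutoff]
    eligible.sort(key=lambda h: (h.domain_ievalue, -h.bitscore, h.seq_start))
    accepted: list[tuple[int, int]] = []
    for hit in eligible:
        start, end = hit.interval
        length = end - start
        ok = True
        for a_start, a_end in accepted:
            overlap = max(0, min(end, a_end) - max(start, a_start))
            shorter = min(length, a_end - a_start)
            if overlap > max_overlap_frac * shorter:
                ok = False
                break
        if ok:
            accepted.append((start, end))
    accepted.sort()
    return NbdCount(protein_id=protein_id, count=len(accepted), intervals=tuple(accepted))


# ---------------------------------------------------------------------------
# Built-in similarity search (pairwise, per-subject degenerate PSSMs)


def similarity_search(
    queries: Sequence[ProteinRecord],
    refdb: ReferenceDB,
    evalue_cutoff: float = 1e-5,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> list[SimilarityHit]:
    """All-vs-all local alignment of queries against the reference database.

    Each reference sequence is turned into a degenerate single-sequence
    PSSM and aligned locally against every query; hits with synthetic
    e-value below ``evalue_cutoff`` are reported in (query order, database
    order).  Deterministic for fixed inputs.
    """
    subject_pssms = []
    for ref in refdb.records:
        pssm = profile_from_sequence(ref.sequence, pseudocount)
        subject_pssms.append((ref, pssm))
    hits: list[SimilarityHit] = []
    for query in queries:
        enc = encode(query.sequence)
        n = len(query.sequence)
        for ref, pssm in subject_pssms:
            S = pssm.match_scores[:, enc].T
            raw = _align.sw_best_score(S, gap_open, gap_extend)
            bits = raw / 2.0
            if bits <= 0:
                continue
            evalue = synthetic_evalue(bits, n, pssm.length)
            if evalue >= evalue_cutoff:
                continue
            S = np.ascontiguousarray(S)
            M, Ix, Iy = _align.sw_matrices(S, gap_open, gap_extend)
            flat = int(np.argmax(M))
            end_i, end_j = divmod(flat, M.shape[1])
            _, _, _, _, pairs = _align.traceback(
                M, Ix, Iy, S, gap_open, gap_extend, end_i, end_j
            )
            subj_enc = encode(ref.sequence)
            identical = sum(
                1
                for qi, sj in pairs
                if enc[qi] == subj_enc[sj] and enc[qi] != X_INDEX
            )
            pident = 100.0 * identical / len(pairs) if pairs else 0.0
            hits.append(
                SimilarityHit(
                    query_id=query.protein_id,
                    subject_id=ref.full_id,
                    subject_family=ref.family,
                    percent_identity=round(pident, 2),
                    evalue=evalue,
                    bitscore=round(bits, 4),
                )
            )
    return hits
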