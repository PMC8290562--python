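"""Fully-labelled synthetic fixtures for the whole pipeline.

The generators emulate the structure the classifier exploits in real
proteomes: each ABC family is represented by a distinct ~180-residue
nucleotide-binding-domain (NBD) archetype derived from one shared core
(~60% identity between families, >90% within a family), embedded in
random flanking sequence.  ABC-B full-transporter genes carry two NBD
blocks, half transporters one.  Decoys are random background sequences
plus sub-250-residue fragments of planted genes, which exercise the
length filter.  Every generator is a pure function of its seed and
parameters, and every generated protein has exactly one truth row.

The mutation model is substitution-only (no indels) so planted NBD
coordinates stay exact; substitution targets are drawn from the
background composition, excluding the current residue.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alphabet import AA20, BACKGROUND
from .errors import ValidationError
from .io_formats import (
    ABC_FAMILIES,
    NONABC,
    ProteinRecord,
    ReferenceDB,
    RefRecord,
    SimilarityHit,
)
from .search import Profile, build_profile, similarity_search

NBD_LENGTH = 180
#: Per-site divergence of each family archetype from the shared core;
#: two archetypes then agree at ~(1-rate)^2 = ~61% of sites.
FAMILY_DIVERGENCE = 0.22
#: Within-family divergence of reference database copies.
REFERENCE_MUTATION_RATE = 0.05

DECOY = "DECOY"
_REF_SPECIES = ("Hsap", "Tcas", "Dmel", "Turt")

_AA_ARRAY = np.array(list(AA20))


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_AA_ARRAY, size=length, p=BACKGROUND))


def mutate(sequence: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each site with probability ``rate`` (target != current)."""
    if not (0.0 <= rate <= 0.5):
        raise ValidationError("mutation rate must be in [0, 0.5]")
    if rate == 0.0:
        return sequence
    seq = list(sequence)
    hit_mask = rng.random(len(seq)) < rate
    aa_index = {aa: i for i, aa in enumerate(AA20)}
    for pos in np.nonzero(hit_mask)[0]:
        cur = seq[pos]
        probs = BACKGROUND.copy()
        if cur in aa_index:
            probs[aa_index[cur]] = 0.0
        probs /= probs.sum()
        seq[pos] = str(rng.choice(_AA_ARRAY, p=probs))
    return "".join(seq)


def _rng(seed: int, stream: int) -> np.random.Generator:
    # distinct child stream per generator so fixtures sharing a seed are
    # statistically independent of each other
    return np.random.default_rng([seed, stream])


def make_family_archetypes(seed: int) -> dict[str, str]:
    """One distinguishable NBD archetype per family, from a shared core."""
    rng = _rng(seed, 0)
    core = _random_sequence(rng, NBD_LENGTH)
    return {fam: mutate(core, FAMILY_DIVERGENCE, rng) for fam in ABC_FAMILIES}


def make_reference_db(
    seed: int,
    n_per_family: int = 5,
    n_decoys: int = 5,
    archetypes: Mapping[str, str] | None = None,
) -> ReferenceDB:
    """Family-labelled reference database of mutated archetype copies.

    BF records carry two NBD blocks, all other families one; decoys are
    random sequences labelled NONABC.  ``n_per_family`` must be >= 3 so
    the top-3 voting rule can ever fire.
    """
    if n_per_family < 3:
        raise ValidationError("n_per_family must be >= 3 (voting needs >= 3 hits)")
    rng = _rng(seed, 1)
    if archetypes is None:
        archetypes = make_family_archetypes(seed)
    records: list[RefRecord] = []
    for fam in ABC_FAMILIES:
        for i in range(n_per_family):
            species = _REF_SPECIES[(len(records)) % len(_REF_SPECIES)]
            nbd = mutate(archetypes[fam], REFERENCE_MUTATION_RATE, rng)
            flank1 = _random_sequence(rng, int(rng.integers(25, 51)))
            flank2 = _random_sequence(rng, int(rng.integers(25, 51)))
            if fam == "BF":
                nbd2 = mutate(archetypes[fam], REFERENCE_MUTATION_RATE, rng)
                linker = _random_sequence(rng, int(rng.integers(60, 101)))
                seq = flank1 + nbd + linker + nbd2 + flank2
            else:
                seq = flank1 + nbd + flank2
            records.append(RefRecord(f"{fam}{i + 1}", species, fam, seq))
    for i in range(n_decoys):
        species = _REF_SPECIES[i % len(_REF_SPECIES)]
        seq = _random_sequence(rng, int(rng.integers(200, 401)))
        records.append(RefRecord(f"BG{i + 1}", species, NONABC, seq))
    return ReferenceDB(records)


def make_proteome(
    seed: int,
    plan: Sequence[tuple[str, int, float]],
    n_decoys: int = 10,
    decoy_len_range: tuple[int, int] = (150, 400),
    fragment_frac: float = 0.3,
    species_id: str = "synthetic",
    archetypes: Mapping[str, str] | None = None,
) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Proteome with planted ABC genes and decoys, plus its truth table.

    ``plan`` lists (family, n, mutation_rate) triples.  Planted genes are
    archetype copies mutated at the stated per-site rate inside random
    flanks (total length >= 300); BF plants carry two NBD blocks at least
    60 residues apart.  ``fragment_frac`` of the decoys are sub-250-residue
    truncations of planted genes (labelled DECOY in the truth table); the
    rest are random sequences.  Returns (records, truth) where the truth
    frame is indexed by protein_id with columns true_family, planted_nbds
    and mutation_rate.
    """
    rng = _rng(seed, 2)
    if archetypes is None:
        archetypes = make_family_archetypes(seed)
    records: list[ProteinRecord] = []
    truth_rows: list[dict] = []
    plant_parts: list[tuple[str, int, float]] = []  # (sequence, flank1_len, rate)
    for fam, n, rate in plan:
        if fam not in ABC_FAMILIES:
            raise ValidationError(f"unknown family in plan: {fam!r}")
        if not (0.0 <= rate <= 0.5):
            raise ValidationError("plan mutation rates must be in [0, 0.5]")
        for i in range(n):
            flank1 = _random_sequence(rng, int(rng.integers(60, 101)))
            flank2 = _random_sequence(rng, int(rng.integers(60, 101)))
            nbd = mutate(archetypes[fam], rate, rng)
            if fam == "BF":
                nbd2 = mutate(archetypes[fam], rate, rng)
                linker = _random_sequence(rng, int(rng.integers(60, 101)))
                seq = flank1 + nbd + linker + nbd2 + flank2
                planted_nbds = 2
            else:
                seq = flank1 + nbd + flank2
                planted_nbds = 1
            pid = f"{fam}.p{i + 1}"
            records.append(ProteinRecord(pid, species_id, seq))
            truth_rows.append(
                {
                    "protein_id": pid,
                    "true_family": fam,
                    "planted_nbds": planted_nbds,
                    "mutation_rate": rate,
                }
            )
            plant_parts.append((seq, len(flank1), rate))
    n_fragments = int(round(fragment_frac * n_decoys)) if plant_parts else 0
    for i in range(n_decoys):
        if i < n_fragments:
            src_seq, flank1_len, rate = plant_parts[int(rng.integers(len(plant_parts)))]
            frag_len = min(flank1_len + 140, 249)
            seq = src_seq[:frag_len]
        else:
            lo, hi = decoy_len_range
            seq = _random_sequence(rng, int(rng.integers(lo, hi + 1)))
            rate = 0.0
        pid = f"decoy{i + 1}"
        records.append(ProteinRecord(pid, species_id, seq))
        truth_rows.append(
            {
                "protein_id": pid,
                "true_family": DECOY,
                "planted_nbds": 0,
                "mutation_rate": rate,
            }
        )
    truth = pd.DataFrame(truth_rows).set_index("protein_id")
    return records, truth


def make_profile(
    seed: int,
    pseudocount: float = 0.5,
    score_threshold: float = 25.0,
    archetypes: Mapping[str, str] | None = None,
) -> Profile:
    """NBD search profile built from the nine family archetypes."""
    if archetypes is None:
        archetypes = make_family_archetypes(seed)
    seqs = [archetypes[fam] for fam in ABC_FAMILIES]
    return build_profile(seqs, pseudocount, score_threshold=score_threshold)


def make_similarity_hits(
    proteome: Sequence[ProteinRecord],
    refdb: ReferenceDB,
    evalue_cutoff: float = 1e-5,
) -> list[SimilarityHit]:
    """In-package substitute for an external BLASTP run (e < 1e-5 kept)."""
    return similarity_search(proteome, refdb, evalue_cutoff)


def make_grouped_counts(
    seed: int,
    k_groups: int = 4,
    n_per_group: int = 10,
    base_mean: float = 10.0,
    shifted_group: int | None = None,
    shift: float = 0.0,
) -> dict[str, list[int]]:
    """Poisson family-size fixture with one optionally shifted group mean."""
    if shift < 0:
        raise ValidationError("shift must be >= 0")
    rng = _rng(seed, 3)
    data: dict[str, list[int]] = {}
    for g in range(k_groups):
        mean = base_mean + (shift if g == shifted_group else 0.0)
        data[f"G{g + 1}"] = [int(v) for v in rng.poisson(mean, size=n_per_group)]
    return data
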