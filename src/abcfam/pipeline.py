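"""Per-species orchestration, quality gating, aggregation and benchmarking.

A species run chains: NBD-profile search -> candidate e-value filter ->
similarity ranking against the labelled reference database -> family
assignment -> length filter.  Species whose proteome BUSCO single-copy
completeness is below 80% are excluded before any aggregation, since an
incomplete gene set would bias family counts downward.
"""

from __future__ import annotations

import json
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import search as search_mod
from .classify import FamilyCall, apply_length_filter, assign_family, rank_hits
from .errors import ValidationError
from .io_formats import (
    ABC_FAMILIES,
    EXCLUDED,
    ProteinRecord,
    ReferenceDB,
    SpeciesMeta,
    parse_blast_tab,
    parse_domtblout,
    read_fasta,
    read_reference_db,
    read_species_meta,
    write_results,
)

logger = logging.getLogger("abcfam")

DEFAULT_BUSCO_THRESHOLD = 80.0


@dataclass
class ScanConfig:
    """Thresholds for one species scan (defaults follow the pipeline rules)."""

    candidate_evalue: float = 10.0
    similarity_evalue: float = 1e-5
    domain_ievalue: float = search_mod.DEFAULT_DOMAIN_IEVALUE
    max_overlap_frac: float = search_mod.DEFAULT_MAX_OVERLAP_FRAC
    min_length: int = 250


class BuiltinBackend:
    """Search backend using the package's own PSSM scanner and aligner."""

    def __init__(self, profile: search_mod.Profile):
        self.profile = profile

    def domain_hits(self, records: Sequence[ProteinRecord]):
        hits = []
        for rec in records:
            hits.extend(search_mod.scan_protein(self.profile, rec))
        return hits

    def similarity_hits(self, records, refdb: ReferenceDB, evalue_cutoff: float):
        return search_mod.similarity_search(records, refdb, evalue_cutoff)


class ExternalBackend:
    """Backend reading pre-computed HMMER domtblout + BLAST tabular files."""

    def __init__(self, domtbl_path: str | Path, blast_tab_path: str | Path):
        self.domtbl_path = Path(domtbl_path)
        self.blast_tab_path = Path(blast_tab_path)

    def domain_hits(self, records):
        return parse_domtblout(self.domtbl_path)

    def similarity_hits(self, records, refdb, evalue_cutoff):
        hits = parse_blast_tab(self.blast_tab_path, refdb)
        return [h for h in hits if h.evalue < evalue_cutoff]


def busco_gate(
    meta: Sequence[SpeciesMeta], threshold: float = DEFAULT_BUSCO_THRESHOLD
) -> list[str]:
    """Species ids whose BUSCO single-copy completeness is >= threshold.

    Species strictly below the threshold are excluded.
    """
    retained = []
    for m in meta:
        if not (0.0 <= m.busco_single_copy_pct <= 100.0):
            raise ValidationError(
                f"{m.species_id}: BUSCO score outside [0, 100]"
            )
        if m.busco_single_copy_pct >= threshold:
            retained.append(m.species_id)
    return retained


def scan_species(
    proteome: Sequence[ProteinRecord],
    reference_db: ReferenceDB,
    backend,
    config: ScanConfig | None = None,
) -> list[FamilyCall]:
    """Run the full identification/classification chain on one proteome.

    Returns one :class:`FamilyCall` per candidate protein (proteins with
    no NBD match below the candidate e-value cutoff yield no call).
    """
    config = config or ScanConfig()
    try:
        domain_hits = backend.domain_hits(proteome)
    except Exception as exc:
        raise type(exc)(f"domain search stage: {exc}") from exc
    candidates = search_mod.filter_candidates(domain_hits, config.candidate_evalue)
    logger.info(
        "candidate filter: %d/%d proteins retained (e < %g)",
        len(candidates), len(proteome), config.candidate_evalue,
    )
    candidate_records = [r for r in proteome if r.protein_id in candidates]
    try:
        sim_hits = backend.similarity_hits(
            candidate_records, reference_db, config.similarity_evalue
        )
    except Exception as exc:
        raise type(exc)(f"similarity search stage: {exc}") from exc
    sim_by_query: dict[str, list] = defaultdict(list)
    for hit in sim_hits:
        sim_by_query[hit.query_id].append(hit)
    dom_by_protein: dict[str, list] = defaultdict(list)
    for hit in domain_hits:
        dom_by_protein[hit.protein_id].append(hit)
    calls: list[FamilyCall] = []
    for rec in candidate_records:
        ranked = rank_hits(sim_by_query.get(rec.protein_id, []))
        ranked = [h for h in ranked if h.evalue < config.similarity_evalue]
        nbd = search_mod.count_nbds(
            dom_by_protein[rec.protein_id],
            config.domain_ievalue,
            config.max_overlap_frac,
        )
        calls.append(assign_family(rec.protein_id, ranked, nbd.count))
    n_classified = sum(c.family != EXCLUDED for c in calls)
    logger.info("classification: %d/%d candidates assigned a family",
                n_classified, len(calls))
    calls = apply_length_filter(calls, proteome, config.min_length)
    n_final = sum(c.family != EXCLUDED for c in calls)
    logger.info("length filter: %d removed, %d final", n_classified - n_final, n_final)
    return calls


# ---------------------------------------------------------------------------
# Aggregation


@dataclass
class FamilySizeMatrix:
    """Species x family counts with attached taxonomy metadata."""

    counts: pd.DataFrame  # index species_id; columns ABC_FAMILIES + total
    meta: pd.DataFrame  # index species_id; columns taxon_order, busco

    def to_tsv(self, path: str | Path) -> None:
        df = self.counts.copy()
        df.insert(0, "taxon_order", self.meta.loc[df.index, "taxon_order"])
        df.to_csv(path, sep="\t", index_label="species_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FamilySizeMatrix":
        df = pd.read_csv(path, sep="\t", index_col="species_id")
        meta = pd.DataFrame(
            {"taxon_order": df.pop("taxon_order"),
             "busco_single_copy_pct": 100.0},
            index=df.index,
        )
        return cls(counts=df, meta=meta)


def aggregate_counts(
    calls_by_species: Mapping[str, Sequence[FamilyCall]],
    meta: Sequence[SpeciesMeta],
) -> FamilySizeMatrix:
    """Count classified (non-excluded) calls per species and family."""
    meta_by_id = {m.species_id: m for m in meta}
    rows = {}
    for species_id, calls in calls_by_species.items():
        if species_id not in meta_by_id:
            raise ValidationError(f"no metadata for species {species_id!r}")
        counts = {fam: 0 for fam in ABC_FAMILIES}
        for call in calls:
            if call.family != EXCLUDED:
                counts[call.family] += 1
        counts["total"] = sum(counts.values())
        rows[species_id] = counts
    columns = list(ABC_FAMILIES) + ["total"]
    if rows:
        counts_df = pd.DataFrame.from_dict(rows, orient="index").astype(int)
    else:
        counts_df = pd.DataFrame(columns=columns, dtype=int)
    counts_df = counts_df[columns]
    counts_df = counts_df.sort_index()
    meta_df = pd.DataFrame(
        {
            "taxon_order": {s: meta_by_id[s].taxon_order for s in counts_df.index},
            "busco_single_copy_pct": {
                s: meta_by_id[s].busco_single_copy_pct for s in counts_df.index
            },
        }
    )
    return FamilySizeMatrix(counts=counts_df, meta=meta_df)


# ---------------------------------------------------------------------------
# Benchmark against literature counts


@dataclass
class BenchmarkReport:
    """Signed percent deviation of predicted vs literature family totals."""

    per_species: dict[str, float]
    mean_abs_deviation: float
    mean_signed_deviation: float


def benchmark(
    matrix_totals: Mapping[str, int], literature_totals: Mapping[str, int]
) -> BenchmarkReport:
    """Percent deviation 100 * (predicted - literature) / literature."""
    shared = sorted(set(matrix_totals) & set(literature_totals))
    if not shared:
        raise ValidationError("no shared species between predictions and literature")
    per_species = {}
    for sp in shared:
        lit = literature_totals[sp]
        if lit <= 0:
            raise ValidationError(f"{sp}: literature count must be > 0")
        per_species[sp] = 100.0 * (matrix_totals[sp] - lit) / lit
    devs = list(per_species.values())
    return BenchmarkReport(
        per_species=per_species,
        mean_abs_deviation=sum(abs(d) for d in devs) / len(devs),
        mean_signed_deviation=sum(devs) / len(devs),
    )


# ---------------------------------------------------------------------------
# Batch driver


def run_batch(config_path: str | Path, out_dir: str | Path | None = None) -> FamilySizeMatrix:
    """Run the pipeline for every species in a JSON batch config.

    Config keys: ``reference_db``, ``species_meta``, ``profile`` (needed
    for the built-in backend), ``species`` (list of objects with
    species_id, proteome and optionally domtbl + blast_tab), ``out_dir``,
    optional ``thresholds`` (ScanConfig fields), ``busco_threshold`` and
    ``seed``.  Relative paths resolve against the config file location.
    Outputs: per-species ``<id>.tsv``/``<id>.faa``, ``counts.tsv`` and a
    deterministic ``run.log``.
    """
    config_path = Path(config_path)
    with open(config_path) as fh:
        cfg = json.load(fh)
    base = config_path.parent
    required = ["reference_db", "species_meta", "species"]
    if out_dir is None:
        required.append("out_dir")
    missing = [k for k in required if k not in cfg]
    if missing:
        raise ValidationError(f"batch config missing keys: {missing}")

    def _resolve(p: str) -> Path:
        path = Path(p)
        return path if path.is_absolute() else base / path

    refdb = read_reference_db(_resolve(cfg["reference_db"]))
    meta = read_species_meta(_resolve(cfg["species_meta"]))
    scan_cfg = ScanConfig(**cfg.get("thresholds", {}))
    busco_threshold = float(cfg.get("busco_threshold", DEFAULT_BUSCO_THRESHOLD))
    out = Path(out_dir) if out_dir is not None else _resolve(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    profile = None
    if cfg.get("profile"):
        profile = search_mod.read_profile(_resolve(cfg["profile"]))

    retained = set(busco_gate(meta, busco_threshold))
    log_lines = [f"busco gate: {len(retained)}/{len(meta)} species retained "
                 f"(threshold {busco_threshold:g})"]
    calls_by_species: dict[str, list[FamilyCall]] = {}
    kept_meta: list[SpeciesMeta] = []
    for spec in sorted(cfg["species"], key=lambda s: s["species_id"]):
        species_id = spec["species_id"]
        if species_id not in retained:
            log_lines.append(f"{species_id}: excluded by BUSCO gate")
            continue
        proteome = read_fasta(_resolve(spec["proteome"]), species_id=species_id)
        if spec.get("domtbl") and spec.get("blast_tab"):
            backend = ExternalBackend(_resolve(spec["domtbl"]), _resolve(spec["blast_tab"]))
        elif profile is not None:
            backend = BuiltinBackend(profile)
        else:
            raise ValidationError(
                f"{species_id}: no domtbl/blast_tab and no built-in profile configured"
            )
        calls = scan_species(proteome, refdb, backend, scan_cfg)
        write_results(calls, proteome, out / species_id)
        n_class = sum(c.family != EXCLUDED for c in calls)
        log_lines.append(
            f"{species_id}: {len(proteome)} proteins, {len(calls)} candidates, "
            f"{n_class} classified"
        )
        calls_by_species[species_id] = calls
        kept_meta.append(next(m for m in meta if m.species_id == species_id))
    matrix = aggregate_counts(calls_by_species, kept_meta)
    matrix.to_tsv(out / "counts.tsv")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    for line in log_lines:
        logger.info("%s", line)
    return matrix
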